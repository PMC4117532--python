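"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with xcistr's algorithms: the aligner is a
plain Needleman-Wunsch fit alignment against an explicitly repeated unit,
the repeat scanner enumerates literal copies, the site scanner compares
characters against IUPAC sets position by position, and the rank
correlation is computed from mid-ranks and the Pearson formula.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def fit_align_tandem(text: str, unit: str, match=2, mismatch=7, indel=7):
    """Best fit alignment of ``text`` against an explicit unit repetition.

    The pattern is ``unit`` repeated ``len(text) + 2`` times; alignment may
    start and end anywhere in the pattern (free pattern end gaps).  Returns
    (score, matches, mismatches, indels) of one optimal traceback.
    """
    pattern = unit * (len(text) + 2)
    n, m = len(text), len(pattern)
    NEG = -(10 ** 9)
    D = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    D[0, :] = 0
    for i in range(1, n + 1):
        D[i, 0] = -indel * i
        row = D[i]
        prev = D[i - 1]
        c = text[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if c == pattern[j - 1] else -mismatch)
            up = prev[j] - indel
            left = row[j - 1] - indel
            row[j] = max(diag, up, left)
    j = int(np.argmax(D[n]))
    score = int(D[n, j])
    i = n
    matches = mismatches = indels = 0
    while i > 0:
        if j > 0 and D[i, j] == D[i - 1, j - 1] + (
            match if text[i - 1] == pattern[j - 1] else -mismatch
        ):
            if text[i - 1] == pattern[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i, j = i - 1, j - 1
        elif D[i, j] == D[i - 1, j] - indel:
            indels += 1
            i -= 1
        elif j > 0 and D[i, j] == D[i, j - 1] - indel:
            indels += 1
            j -= 1
        else:  # free start row
            break
    return score, matches, mismatches, indels


def perfect_arrays(seq: str, min_period: int, max_period: int, min_copies: float):
    """Maximal perfect tandem arrays by literal enumeration.

    Enumerates every start/period whose run of exact unit copies reaches
    ``min_copies`` and is left-maximal, then merges overlapping same-period
    runs (phase shifts of one array) into their union.  Returns a set of
    (start, end, period) spans.
    """
    hits: dict[int, list[tuple[int, int]]] = {}
    n = len(seq)
    for p in range(min_period, max_period + 1):
        for i in range(n - 2 * p + 1):
            unit = seq[i:i + p]
            if "N" in unit:
                continue
            k = 1
            j = i + p
            while seq[j:j + p] == unit:
                k += 1
                j += p
            if k >= min_copies and not (i >= p and seq[i - p:i] == unit):
                hits.setdefault(p, []).append((i, j))
    out = set()
    for p, spans in hits.items():
        spans.sort()
        merged = [list(spans[0])]
        for a, b in spans[1:]:
            if a < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            out.add((a, b, p))
    return out


def scan_sites_naive(seq: str, enzymes):
    """(enzyme, start, strand) site set by per-position IUPAC comparison."""
    out = set()
    for enz in enzymes:
        for rec, strand in ((enz.recognition, "+"), (revcomp(enz.recognition), "-")):
            if strand == "-" and rec == enz.recognition:
                continue  # palindromic: one report on '+'
            L = len(rec)
            for i in range(len(seq) - L + 1):
                if all(seq[i + k] in IUPAC_SETS[rec[k]] for k in range(L)):
                    out.add((enz.name, i, strand))
    return out


def qualifying_cgi_union(seq: str, w: int, min_gc: float, min_oe: float):
    """Union of all qualifying fixed-width windows, as merged (start, end) runs."""
    spans = []
    for i in range(len(seq) - w + 1):
        win = seq[i:i + w]
        c, g, cg = win.count("C"), win.count("G"), win.count("CG")
        gc = (c + g) / w
        oe = (cg * w) / (c * g) if c and g else 0.0
        if gc >= min_gc and oe >= min_oe:
            spans.append((i, i + w))
    merged = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def spearman_manual(x, y) -> float:
    """Spearman r via explicit mid-ranks and the Pearson formula."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def overlaps_naive(q, track) -> bool:
    return any(
        q.chrom == t.chrom and q.start < t.end and t.start < q.end for t in track
    )
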