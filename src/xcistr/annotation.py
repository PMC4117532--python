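"""CpG-island detection and methylation-sensitive restriction-site scanning.

CpG islands may come from an annotated BED track (the preferred, ``annotated``
source) or be computed with the classic composition rule: windows of at least
``min_length`` bp with GC fraction >= ``min_gc`` and observed/expected CpG
ratio >= ``min_oe``, where obs/exp = (#CpG x L) / (#C x #G).

Restriction sites are matched under IUPAC semantics on both strands.  The
built-in table covers the five 5meCpG-sensitive enzymes the X-inactivation
assay uses (AciI, BstUI, FauI, HhaI, HpaII); sites of different enzymes whose
CpG dinucleotides coincide are cross-flagged, because methylation of an
overlapping CpG can block cleavage by the neighbouring enzyme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigError, InputError
from .intervals import GenomicInterval

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str
    methylation_sensitive: bool = True
    cpg_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ConfigError(f"{self.name}: recognition site shorter than 4 bp")
        for ch in rec:
            if ch not in IUPAC:
                raise ConfigError(
                    f"{self.name}: invalid IUPAC code {ch!r} in recognition {rec!r}"
                )
        object.__setattr__(self, "recognition", rec)
        if not self.cpg_offsets:
            offsets = tuple(
                i for i in range(len(rec) - 1) if rec[i] == "C" and rec[i + 1] == "G"
            )
            object.__setattr__(self, "cpg_offsets", offsets)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


#: The five 5meCpG-sensitive enzymes whose sites flank the assayed repeats.
BUILTIN_ENZYMES: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("AciI", "CCGC"),
    RestrictionEnzyme("BstUI", "CGCG"),
    RestrictionEnzyme("FauI", "CCCGC"),
    RestrictionEnzyme("HhaI", "GCGC"),
    RestrictionEnzyme("HpaII", "CCGG"),
)


def enzyme_by_name(name: str, enzymes: Sequence[RestrictionEnzyme] = BUILTIN_ENZYMES) -> RestrictionEnzyme:
    for enz in enzymes:
        if enz.name == name:
            return enz
    raise ConfigError(f"unknown enzyme {name!r}")


@dataclass(frozen=True)
class RestrictionSite:
    interval: GenomicInterval
    enzyme: str
    strand: str
    cpg_positions: tuple[int, ...] = ()           # absolute, forward-strand coords
    overlapping_site_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp_cpg: float
    source: str = "computed"  # {annotated, computed}


def _iupac_regex(rec: str) -> re.Pattern[str]:
    return re.compile("".join(
        ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]" for ch in rec
    ))


def scan_restriction_sites(
    seq: str,
    enzymes: Sequence[RestrictionEnzyme] = BUILTIN_ENZYMES,
    chrom: str = "seq",
) -> list[RestrictionSite]:
    """All enzyme recognition sites in ``seq``, both strands, IUPAC-expanded.

    Palindromic sites are reported once on '+'.  Sites of different enzymes
    sharing a CpG position carry each other's names in
    ``overlapping_site_names``.
    """
    seq = seq.upper()
    found: list[tuple[GenomicInterval, str, str, tuple[int, ...]]] = []
    for enz in enzymes:
        strands = [("+", enz.recognition)]
        if not enz.is_palindromic:
            strands.append(("-", revcomp(enz.recognition)))
        L = len(enz.recognition)
        for strand, rec in strands:
            pat = _iupac_regex(rec)
            # lookahead to catch overlapping occurrences
            for m in re.finditer(f"(?=({pat.pattern}))", seq):
                pos = m.start()
                if strand == "+":
                    cpgs = tuple(pos + o for o in enz.cpg_offsets)
                else:
                    cpgs = tuple(pos + L - o - 2 for o in enz.cpg_offsets)
                found.append(
                    (GenomicInterval(chrom, pos, pos + L, strand), enz.name, strand, cpgs)
                )
    # cross-flag sites sharing a CpG position
    by_cpg: dict[int, set[int]] = {}
    for idx, (_, _, _, cpgs) in enumerate(found):
        for c in cpgs:
            by_cpg.setdefault(c, set()).add(idx)
    sites: list[RestrictionSite] = []
    for idx, (iv, name, strand, cpgs) in enumerate(found):
        partners = sorted({
            found[j][1] for c in cpgs for j in by_cpg.get(c, ())
            if j != idx and found[j][1] != name
        })
        sites.append(RestrictionSite(
            interval=iv, enzyme=name, strand=strand,
            cpg_positions=cpgs, overlapping_site_names=tuple(partners),
        ))
    sites.sort(key=lambda s: (s.interval.start, s.enzyme, s.strand))
    return sites


def _composition(counts_c: int, counts_g: int, counts_cg: int, length: int) -> tuple[float, float]:
    gc = (counts_c + counts_g) / length if length else 0.0
    oe = (counts_cg * length) / (counts_c * counts_g) if counts_c and counts_g else 0.0
    return gc, oe


def island_stats(seq: str) -> tuple[float, float]:
    """(gc_fraction, obs_exp_cpg) of a sequence."""
    c = seq.count("C")
    g = seq.count("G")
    cg = seq.count("CG")
    return _composition(c, g, cg, len(seq))


def detect_cpg_islands(
    seq: str,
    min_length: int = 200,
    min_gc: float = 0.50,
    min_oe: float = 0.60,
    chrom: str = "seq",
) -> list[CpGIsland]:
    """Sliding-window CpG-island detection (window = ``min_length``, step 1).

    Qualifying windows are merged; each merged island is trimmed, if needed,
    until it itself satisfies the thresholds, so every returned island
    re-tests positive.
    """
    seq = seq.upper()
    n = len(seq)
    if n < min_length:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cg[:-1] = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
    pc = np.concatenate(([0], np.cumsum(is_c)))
    pg = np.concatenate(([0], np.cumsum(is_g)))
    pcg = np.concatenate(([0], np.cumsum(is_cg)))
    w = min_length
    starts = np.arange(0, n - w + 1)
    cs = pc[starts + w] - pc[starts]
    gs = pg[starts + w] - pg[starts]
    # CpG dinucleotides fully inside the window
    cgs = pcg[starts + w - 1] - pcg[starts]
    gc = (cs + gs) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((cs > 0) & (gs > 0), (cgs * w) / (cs * gs), 0.0)
    ok = (gc >= min_gc) & (oe >= min_oe)
    islands: list[CpGIsland] = []
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    # merge qualifying windows whose spans overlap or touch
    span_start = int(idx[0])
    prev = int(idx[0])
    merged: list[tuple[int, int]] = []
    for i in idx[1:]:
        i = int(i)
        if i <= prev + w:  # windows [prev, prev+w) and [i, i+w) overlap/touch
            prev = i
        else:
            merged.append((span_start, prev + w))
            span_start = prev = i
    merged.append((span_start, prev + w))
    for a, b in merged:
        iv = _trim_island(seq, a, b, min_length, min_gc, min_oe)
        if iv is None:
            continue
        a2, b2 = iv
        gc_f, oe_f = island_stats(seq[a2:b2])
        islands.append(CpGIsland(
            interval=GenomicInterval(chrom, a2, b2),
            gc_fraction=gc_f, obs_exp_cpg=oe_f, source="computed",
        ))
    return islands


def _trim_island(
    seq: str, a: int, b: int, min_length: int, min_gc: float, min_oe: float
) -> tuple[int, int] | None:
    """Shrink [a, b) from the edges until it satisfies the thresholds."""
    def ok(x: int, y: int) -> bool:
        gc, oe = island_stats(seq[x:y])
        return gc >= min_gc and oe >= min_oe

    while b - a > min_length and not ok(a, b):
        # drop the edge base contributing least to CpG density
        left_bad = seq[a] not in "CG"
        right_bad = seq[b - 1] not in "CG"
        if left_bad and not right_bad:
            a += 1
        elif right_bad and not left_bad:
            b -= 1
        else:
            gc_l, oe_l = island_stats(seq[a + 1:b])
            gc_r, oe_r = island_stats(seq[a:b - 1])
            if (gc_l + oe_l) >= (gc_r + oe_r):
                a += 1
            else:
                b -= 1
    if ok(a, b):
        return a, b
    # fall back to the best qualifying window of exactly min_length inside
    best = None
    for x in range(a, b - min_length + 1):
        gc, oe = island_stats(seq[x:x + min_length])
        if gc >= min_gc and oe >= min_oe and (best is None or gc + oe > best[0]):
            best = (gc + oe, x)
    if best is None:
        return None
    return best[1], best[1] + min_length


def load_enzyme_table(path: str) -> list[RestrictionEnzyme]:
    """Load a TSV enzyme override table: name, recognition, methylation_sensitive."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "recognition", "methylation_sensitive"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"enzyme table missing columns: {sorted(missing)}")
    enzymes = []
    for _, row in df.iterrows():
        enzymes.append(RestrictionEnzyme(
            name=row["name"],
            recognition=row["recognition"],
            methylation_sensitive=str(row["methylation_sensitive"]).lower()
            in ("true", "1", "yes"),
        ))
    return enzymes
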