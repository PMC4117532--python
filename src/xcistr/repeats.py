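"""Tandem-repeat detection and scoring.

Short tandem repeats (period 1–6 bp) are found by seeding on perfect runs
(positions where ``seq[i] == seq[i + p]``), joining profitable neighbouring
runs under the +2 match / −7 mismatch / −7 indel weighting, and re-scoring
each candidate with a wraparound dynamic-programming alignment against its
repeat unit.  The match percentage is the fraction of aligned columns that
match, expressed 0–100; copy number is total array length divided by the
period, so partial trailing copies count fractionally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .exceptions import InputError
from .intervals import GenomicInterval

_ALPHABET = frozenset("ACGTN")

#: Locus-family overrides applied after lexicographic rotation canonicalisation.
#: The GAAA family is conventionally written GAAA, not its lexicographically
#: minimal rotation AAAG, because the polymorphic alleles are built from GAAA
#: units; likewise the polyglutamine family is written CAG, not AGC.
UNIT_OVERRIDES: dict[str, str] = {"AAAG": "GAAA", "AGC": "CAG"}


@dataclass(frozen=True)
class RepeatScanParams:
    """Thresholds and alignment weights for the repeat scan."""

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_period: int = 1
    max_period: int = 6
    min_copy_number: float = 3.0
    min_match_pct: float = 80.0

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0 or self.indel_penalty < 0:
            raise InputError("alignment penalties must be non-negative")
        if self.min_period > self.max_period or self.min_period < 1:
            raise InputError("need 1 <= min_period <= max_period")


@dataclass(frozen=True)
class TandemRepeat:
    """A detected tandem array."""

    interval: GenomicInterval
    unit: str               # canonical rotation
    period: int
    copy_number: float      # array length / period
    match_pct: float        # 0-100, matches / aligned columns
    indel_pct: float        # 0-100, indels / aligned columns
    longest_perfect_run: int  # units, any phase
    score: int = 0          # wraparound alignment score (+2/-7/-7)


@dataclass(frozen=True)
class AlignmentStats:
    score: int
    matches: int
    mismatches: int
    indels: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.indels

    @property
    def match_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def indel_pct(self) -> float:
        return 100.0 * self.indels / self.columns if self.columns else 0.0


def canonical_unit(unit: str) -> str:
    """Canonical representative of a repeat unit's rotation class.

    The lexicographically smallest rotation is chosen, then locus-family
    overrides (e.g. AAAG → GAAA) are applied, so all rotations of one unit
    map to a single stable name.
    """
    if not unit:
        raise InputError("empty repeat unit")
    rotations = {unit[i:] + unit[:i] for i in range(len(unit))}
    rep = min(rotations)
    return UNIT_OVERRIDES.get(rep, rep)


def count_uninterrupted_units(seq: str, unit: str) -> int:
    """Maximum number of consecutive exact copies of ``unit`` anywhere in ``seq``."""
    if not unit:
        raise InputError("empty repeat unit")
    u = len(unit)
    best = 0
    i = 0
    n = len(seq)
    while i < n:
        if seq.startswith(unit, i):
            k = 1
            j = i + u
            while seq.startswith(unit, j):
                k += 1
                j += u
            if k > best:
                best = k
            i += 1  # a shifted phase may start a longer run
        else:
            i += 1
    return best


def wraparound_align(
    text: str,
    unit: str,
    match_weight: int = 2,
    mismatch_penalty: int = 7,
    indel_penalty: int = 7,
) -> AlignmentStats:
    """Globally align ``text`` against tandem copies of ``unit``.

    Start and end phase within the unit are free; the pattern wraps around.
    Returns the best score together with column counts from a traceback.
    """
    n, p = len(text), len(unit)
    if p == 0:
        raise InputError("empty repeat unit")
    NEG = -(10**9)
    # D[i][j]: best score aligning text[:i], next pattern char is unit[j].
    D = [[NEG] * p for _ in range(n + 1)]
    # back[i][j] = (pi, pj, op) with op in {M, X, I, D}
    back: list[list[Optional[tuple[int, int, str]]]] = [
        [None] * p for _ in range(n + 1)
    ]
    for j in range(p):
        D[0][j] = 0
    for i in range(n + 1):
        row = D[i]
        if i > 0:
            prev = D[i - 1]
            c = text[i - 1]
            for j in range(p):
                jm1 = (j - 1) % p
                # diagonal: consume text[i-1] against unit[jm1]
                if c == unit[jm1]:
                    sc, op = prev[jm1] + match_weight, "M"
                else:
                    sc, op = prev[jm1] - mismatch_penalty, "X"
                if sc > row[j]:
                    row[j] = sc
                    back[i][j] = (i - 1, jm1, op)
                # insertion in text (gap in pattern)
                sc = prev[j] - indel_penalty
                if sc > row[j]:
                    row[j] = sc
                    back[i][j] = (i - 1, j, "I")
        # deletions (gap in text) cycle within the row; two sweeps settle
        # them because every full wrap has strictly negative weight.
        for _ in range(2):
            for j in range(p):
                jm1 = (j - 1) % p
                sc = row[jm1] - indel_penalty
                if sc > row[j]:
                    row[j] = sc
                    back[i][j] = (i, jm1, "D")
    j_best = max(range(p), key=lambda j: D[n][j])
    score = D[n][j_best]
    matches = mismatches = indels = 0
    i, j = n, j_best
    while not (i == 0 and back[i][j] is None):
        step = back[i][j]
        if step is None:  # i == 0 start state
            break
        pi, pj, op = step
        if op == "M":
            matches += 1
        elif op == "X":
            mismatches += 1
        else:
            indels += 1
        i, j = pi, pj
    return AlignmentStats(score=score, matches=matches, mismatches=mismatches, indels=indels)


# ---------------------------------------------------------------------------
# candidate detection


def _validate_alphabet(seq: str) -> None:
    for offset, ch in enumerate(seq):
        if ch not in _ALPHABET:
            raise InputError(f"invalid character {ch!r} at offset {offset}")


def _split_at_n(seq: str) -> Iterable[tuple[int, str]]:
    """Yield (offset, segment) for maximal N-free segments."""
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, seq[start:]


@dataclass
class _Seed:
    start: int      # region start
    end: int        # region end (start of run + run length + period)
    matches: int    # matched positions (run length)
    unit: str       # canonical unit


def _is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a power of a shorter string.

    A homopolymer run matches every period; only the minimal period is the
    repeat's true period, so non-primitive units are rejected and picked up
    by the scan at their minimal period (if in range).
    """
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def _perfect_run_seeds(seg: str, p: int) -> list[_Seed]:
    arr = np.frombuffer(seg.encode(), dtype=np.uint8)
    if len(arr) <= p:
        return []
    eq = arr[:-p] == arr[p:]
    if not eq.any():
        return []
    # maximal True runs in eq
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    seeds = []
    for a, b in zip(starts, ends):
        if b - a < p:  # require at least one full repeated period
            continue
        unit = seg[a:a + p]
        if not _is_primitive(unit):
            continue
        seeds.append(
            _Seed(start=int(a), end=int(b) + p, matches=int(b - a),
                  unit=canonical_unit(unit))
        )
    return seeds


def _join_seeds(seeds: list[_Seed], mismatch_penalty: int, match_weight: int) -> list[tuple[int, int, str]]:
    """Join same-unit neighbouring seeds when bridging the gap pays off.

    Kadane-style maximal positive segments under +match_weight per matched
    position and −mismatch_penalty per gap base.  Returns (start, end, unit)
    candidate regions.
    """
    regions: list[tuple[int, int, str]] = []
    i = 0
    while i < len(seeds):
        unit = seeds[i].unit
        cur_start = seeds[i].start
        cur_end = seeds[i].end
        cur_score = match_weight * seeds[i].matches
        best_unit_len = seeds[i].matches
        j = i + 1
        while j < len(seeds) and seeds[j].unit == unit:
            gap = max(0, seeds[j].start - cur_end)
            carry = cur_score - mismatch_penalty * gap
            if carry <= 0:
                break
            cur_score = carry + match_weight * seeds[j].matches
            cur_end = max(cur_end, seeds[j].end)
            if seeds[j].matches > best_unit_len:
                best_unit_len = seeds[j].matches
            j += 1
        regions.append((cur_start, cur_end, unit))
        i = j if j > i + 1 else i + 1
    return regions


def _evaluate_region(
    seg: str,
    offset: int,
    chrom: str,
    start: int,
    end: int,
    unit: str,
    params: RepeatScanParams,
) -> Optional[TandemRepeat]:
    region = seg[start:end]
    p = len(unit)
    stats = wraparound_align(
        region, unit, params.match_weight, params.mismatch_penalty, params.indel_penalty
    )
    copy_number = len(region) / p
    if copy_number < params.min_copy_number:
        return None
    if not stats.match_pct > params.min_match_pct:
        return None
    lpr = max(
        count_uninterrupted_units(region, unit[i:] + unit[:i]) for i in range(p)
    )
    return TandemRepeat(
        interval=GenomicInterval(chrom, offset + start, offset + end),
        unit=unit,
        period=p,
        copy_number=copy_number,
        match_pct=stats.match_pct,
        indel_pct=stats.indel_pct,
        longest_perfect_run=lpr,
        score=stats.score,
    )


def find_tandem_repeats(
    seq: str,
    params: RepeatScanParams | None = None,
    chrom: str = "seq",
) -> list[TandemRepeat]:
    """Detect tandem repeats in ``seq`` satisfying ``params`` thresholds.

    Candidate regions never span an N.  Overlapping calls with the same
    canonical unit are merged; among overlapping calls with different units
    the higher-scoring one wins (ties: smaller period, then leftmost).
    Output is ordered by (start, period).
    """
    if params is None:
        params = RepeatScanParams()
    seq = seq.upper()
    _validate_alphabet(seq)
    if not seq:
        return []
    candidates: list[TandemRepeat] = []
    for offset, seg in _split_at_n(seq):
        for p in range(params.min_period, params.max_period + 1):
            seeds = _perfect_run_seeds(seg, p)
            for start, end, unit in _join_seeds(
                seeds, params.mismatch_penalty, params.match_weight
            ):
                tr = _evaluate_region(seg, offset, chrom, start, end, unit, params)
                if tr is not None:
                    candidates.append(tr)
    return _resolve_overlaps(candidates, seq, params, chrom)


def _resolve_overlaps(
    candidates: list[TandemRepeat],
    seq: str,
    params: RepeatScanParams,
    chrom: str,
) -> list[TandemRepeat]:
    # merge same-unit overlapping calls into their union, re-scored
    by_unit: dict[str, list[TandemRepeat]] = {}
    for tr in candidates:
        by_unit.setdefault(tr.unit, []).append(tr)
    merged: list[TandemRepeat] = []
    for unit, group in by_unit.items():
        group.sort(key=lambda t: t.interval.start)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.interval.start < cur.interval.end:
                union = _evaluate_region(
                    seq, 0, chrom,
                    cur.interval.start,
                    max(cur.interval.end, nxt.interval.end),
                    unit, params,
                )
                cur = union if union is not None else max(
                    (cur, nxt), key=lambda t: t.score
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    # cross-unit overlaps: greedy by (score desc, period asc, start asc)
    merged.sort(key=lambda t: (-t.score, t.period, t.interval.start))
    kept: list[TandemRepeat] = []
    for tr in merged:
        if not any(tr.interval.overlaps(k.interval) for k in kept):
            kept.append(tr)
    kept.sort(key=lambda t: (t.interval.start, t.period))
    return kept
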