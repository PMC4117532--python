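"""Allele-specific methylation quantification of X-inactivation skewing.

The assay digests genomic DNA with a 5meCpG-sensitive enzyme before
QF-PCR across a polymorphic repeat.  The methylated (Xi) allele survives
digestion, so after normalising each digested peak by its undigested
companion, the share of signal carried by an allele estimates the fraction
of cells in which that allele sits on the inactive X:

    xi_fraction_allele1 = (d1/u1) / (d1/u1 + d2/u2)

Peak areas are first corrected for polymerase stutter (an artifact peak one
repeat unit below a true allele, proportional to the true-allele area).
Skewing is two-class: random when the main inactive allele is <= 80 %,
non-random above; >= 90 % additionally raises an ``extremely_skewed`` flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    EstimationError,
    InputError,
    InsufficientDataError,
    MendelianInconsistencyError,
)

UNDIGESTED = "undigested"

#: Default stutter fractions: the tetranucleotide GAAA locus stutters at a
#: mean 2.6 % of the true-allele area, the trinucleotide CAG locus at 17.6 %.
DEFAULT_STUTTER_FRACTIONS: dict[str, float] = {"RP2": 0.026, "AR": 0.176}
DEFAULT_REPEAT_UNIT_BP: dict[str, int] = {"RP2": 4, "AR": 3}

RANDOM_MAX_PCT = 80.0      # random XCI band: 50-80 %, strict > above
EXTREME_SKEW_PCT = 90.0    # reporting flag only; classification stays 2-class
SIZE_TOL_BP = 1.0          # +-1 bp matching window for allele/stutter sizes


@dataclass(frozen=True)
class StutterModel:
    locus: str
    repeat_unit_bp: int
    stutter_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.stutter_fraction < 1:
            raise InputError("stutter_fraction must be in [0, 1)")
        if self.repeat_unit_bp < 1:
            raise InputError("repeat_unit_bp must be >= 1")


@dataclass(frozen=True)
class XCIResult:
    sample: str
    locus: str
    treatment: str
    alleles: tuple[float, float]
    xi_fraction_allele1: float
    skew_class: str                 # random | non_random
    main_inactive_pct: float
    qc: tuple[str, ...] = ()

    @property
    def xi_fraction_allele2(self) -> float:
        return 1.0 - self.xi_fraction_allele1


@dataclass(frozen=True)
class PopulationStats:
    locus: str
    n_typed: int
    n_heterozygous: int
    observed_heterozygosity: float
    expected_heterozygosity: float
    allele_frequencies: dict[float, float]


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    spearman_r: float
    ci95: tuple[float, float]
    p_value: float


# ---------------------------------------------------------------------------
# stutter

def estimate_stutter_fraction(
    peaks: pd.DataFrame,
    locus: str,
    repeat_unit_bp: int | None = None,
) -> float:
    """Mean stutter/true area ratio over single-allele (hemizygous) samples.

    The true allele is the tallest undigested peak per sample; the stutter
    peak is sought one repeat unit below it (+-1 bp).  Samples without a
    detectable stutter peak contribute 0.
    """
    if repeat_unit_bp is None:
        repeat_unit_bp = DEFAULT_REPEAT_UNIT_BP.get(locus)
        if repeat_unit_bp is None:
            raise InputError(f"repeat_unit_bp required for unknown locus {locus!r}")
    sub = peaks[(peaks["locus"] == locus) & (peaks["treatment"] == UNDIGESTED)]
    ratios: list[float] = []
    for _, grp in sub.groupby("sample"):
        grp = grp.sort_values("area", ascending=False)
        true_size = float(grp.iloc[0]["allele_size"])
        true_area = float(grp.iloc[0]["area"])
        others = grp.iloc[1:]
        # single-allele sample: everything else must sit at the stutter position
        non_stutter = others[
            (others["allele_size"] - (true_size - repeat_unit_bp)).abs() > SIZE_TOL_BP
        ]
        if len(non_stutter):
            continue  # not single-allele; skip
        stutter = others[
            (others["allele_size"] - (true_size - repeat_unit_bp)).abs() <= SIZE_TOL_BP
        ]
        if true_area <= 0:
            continue
        ratios.append(float(stutter["area"].sum()) / true_area)
    if not ratios:
        raise EstimationError(
            f"no single-allele samples for locus {locus!r}; supply a StutterModel"
        )
    return float(np.mean(ratios))


def correct_stutter(
    sizes: Sequence[float],
    areas: Sequence[float],
    model: StutterModel,
) -> tuple[list[float], list[str]]:
    """Stutter-correct allele areas for one sample/locus/treatment.

    When the two alleles are exactly one repeat unit apart, the shorter
    allele's observed area contains the longer allele's stutter; subtract
    ``stutter_fraction x longer_area`` (floored at 0).  Otherwise areas are
    returned unchanged.  Returns (corrected_areas, qc_flags).
    """
    sizes = [float(s) for s in sizes]
    areas = [float(a) for a in areas]
    if len(sizes) != len(areas):
        raise InputError("sizes and areas length mismatch")
    flags: list[str] = []
    if len(sizes) != 2 or model.stutter_fraction == 0:
        return areas, flags
    order = sorted(range(2), key=lambda i: sizes[i])
    short_i, long_i = order[0], order[1]
    gap = sizes[long_i] - sizes[short_i]
    if abs(gap - model.repeat_unit_bp) > SIZE_TOL_BP:
        return areas, flags
    subtracted = model.stutter_fraction * areas[long_i]
    corrected = areas[short_i] - subtracted
    if corrected < 0:
        if -corrected > 0.05 * areas[short_i]:
            flags.append("stutter_overcorrection")
        corrected = 0.0
    out = list(areas)
    out[short_i] = corrected
    return out, flags


# ---------------------------------------------------------------------------
# ratios and classification

def compute_xci_ratio(
    undigested: tuple[float, float],
    digested: tuple[float, float],
) -> tuple[float, list[str]]:
    """Xi fraction attributed to allele 1, with QC flags.

    Each digested area is normalised by its undigested companion to remove
    amplification bias; the Xi fraction of allele 1 is its share of the
    normalised digested signal.  Swapping allele labels maps r to 1 - r.
    """
    u1, u2 = float(undigested[0]), float(undigested[1])
    d1, d2 = float(digested[0]), float(digested[1])
    flags: list[str] = []
    if u1 <= 0 or u2 <= 0:
        raise InputError("uninformative_or_allele_dropout: undigested area <= 0")
    if d1 < 0 or d2 < 0:
        raise InputError("digested areas must be >= 0")
    if d1 + d2 == 0:
        raise InputError("total_digestion_no_signal: both digested areas are 0")
    r1 = d1 / u1
    r2 = d2 / u2
    return r1 / (r1 + r2), flags


def classify_skewing(main_inactive_pct: float) -> str:
    """Two-class skewing call: random (<= 80 %) vs non_random (> 80 %)."""
    if main_inactive_pct < 50 or main_inactive_pct > 100:
        raise InputError(
            "main_inactive_pct must be in [50, 100]; fold to the main allele first"
        )
    return "non_random" if main_inactive_pct > RANDOM_MAX_PCT else "random"


def build_result(
    sample: str,
    locus: str,
    treatment: str,
    alleles: tuple[float, float],
    xi_fraction_allele1: float,
    qc: Iterable[str] = (),
) -> XCIResult:
    main_pct = 100.0 * max(xi_fraction_allele1, 1.0 - xi_fraction_allele1)
    flags = list(qc)
    if main_pct >= EXTREME_SKEW_PCT:
        flags.append("extremely_skewed")
    return XCIResult(
        sample=sample, locus=locus, treatment=treatment, alleles=alleles,
        xi_fraction_allele1=xi_fraction_allele1,
        skew_class=classify_skewing(main_pct),
        main_inactive_pct=main_pct,
        qc=tuple(flags),
    )


def digestion_qc(
    undigested_area: float, digested_area: float, tolerance: float = 0.05
) -> bool:
    """Digestion control on a single-X (male) sample.

    The male X is active and unmethylated, so complete digestion leaves no
    amplifiable template: pass iff residual digested / undigested <= tolerance.
    """
    if undigested_area <= 0:
        raise InputError("missing or empty undigested companion for QC sample")
    return digested_area / undigested_area <= tolerance


def digestion_qc_batch(
    peaks: pd.DataFrame,
    male_samples: Sequence[str],
    locus: str,
    enzyme: str,
    tolerance: float = 0.05,
) -> bool | None:
    """Batch digestion QC over known single-X samples; None if no control."""
    males = [s for s in male_samples if s in set(peaks["sample"])]
    if not males:
        warnings.warn("no single-X control samples in batch; digestion QC skipped")
        return None
    for sample in males:
        sub = peaks[(peaks["sample"] == sample) & (peaks["locus"] == locus)]
        u = float(sub[sub["treatment"] == UNDIGESTED]["area"].sum())
        d = float(sub[sub["treatment"] == enzyme]["area"].sum())
        if not digestion_qc(u, d, tolerance):
            return False
    return True


# ---------------------------------------------------------------------------
# cohort quantification

def call_alleles(
    undigested: pd.DataFrame,
    repeat_unit_bp: int,
    min_rel_area: float = 0.05,
    stutter_rel_max: float = 0.5,
) -> list[tuple[float, float]]:
    """Call 1 or 2 true alleles from an undigested peak group.

    Peaks one repeat unit (+-1 bp) below a taller peak are treated as stutter
    and excluded, unless their area exceeds ``stutter_rel_max`` of the taller
    peak (a genuine one-unit-shorter allele is comparable in size, stutter is
    not); of the rest, peaks above ``min_rel_area`` of the tallest are
    alleles (the two largest are kept).  Returns [(size, area), ...] sorted
    by size.
    """
    grp = undigested.sort_values("area", ascending=False)
    kept: list[tuple[float, float]] = []
    for _, row in grp.iterrows():
        size, area = float(row["allele_size"]), float(row["area"])
        if any(
            abs((ks - repeat_unit_bp) - size) <= SIZE_TOL_BP
            and area < stutter_rel_max * ka
            for ks, ka in kept if ka > area
        ):
            continue  # stutter position of an already-called taller peak
        kept.append((size, area))
    if not kept:
        return []
    top_area = kept[0][1]
    alleles = [(s, a) for s, a in kept if a >= min_rel_area * top_area][:2]
    return sorted(alleles)


def quantify_sample(
    peaks: pd.DataFrame,
    sample: str,
    locus: str,
    enzyme: str,
    model: StutterModel,
) -> XCIResult | None:
    """Quantify one sample at one locus for one enzyme; None if uninformative.

    Allele sizes come from the undigested run; digested peaks are matched to
    those sizes within +-1 bp (digestion can abolish a peak entirely).
    """
    sub = peaks[(peaks["sample"] == sample) & (peaks["locus"] == locus)]
    und = sub[sub["treatment"] == UNDIGESTED]
    dig = sub[sub["treatment"] == enzyme]
    if und.empty or dig.empty:
        return None
    alleles = call_alleles(und, model.repeat_unit_bp)
    if len(alleles) < 2:
        return None  # homozygous or hemizygous: uninformative
    sizes = [a[0] for a in alleles]

    def matched_areas(df: pd.DataFrame) -> list[float]:
        areas = []
        for s in sizes:
            hit = df[(df["allele_size"] - s).abs() <= SIZE_TOL_BP]
            areas.append(float(hit["area"].sum()))
        return areas

    u_areas, u_flags = correct_stutter(sizes, matched_areas(und), model)
    d_areas, d_flags = correct_stutter(sizes, matched_areas(dig), model)
    try:
        r1, flags = compute_xci_ratio((u_areas[0], u_areas[1]), (d_areas[0], d_areas[1]))
    except InputError as exc:
        return XCIResult(
            sample=sample, locus=locus, treatment=enzyme,
            alleles=(sizes[0], sizes[1]), xi_fraction_allele1=float("nan"),
            skew_class="unknown", main_inactive_pct=float("nan"),
            qc=tuple(u_flags + d_flags + [str(exc).split(":")[0]]),
        )
    return build_result(
        sample, locus, enzyme, (sizes[0], sizes[1]), r1, u_flags + d_flags + flags
    )


def quantify_cohort(
    peaks: pd.DataFrame,
    enzyme: str,
    models: Mapping[str, StutterModel] | None = None,
    loci: Sequence[str] | None = None,
    discordance_warn_pp: float = 15.0,
) -> pd.DataFrame:
    """Quantify all samples/loci for one enzyme into a tidy results frame."""
    if loci is None:
        loci = sorted(peaks["locus"].unique())
    if models is None:
        models = {
            loc: StutterModel(loc, DEFAULT_REPEAT_UNIT_BP.get(loc, 4),
                              DEFAULT_STUTTER_FRACTIONS.get(loc, 0.0))
            for loc in loci
        }
    rows = []
    for locus in loci:
        model = models[locus]
        for sample in sorted(peaks[peaks["locus"] == locus]["sample"].unique()):
            res = quantify_sample(peaks, sample, locus, enzyme, model)
            if res is None:
                continue
            rows.append({
                "sample": res.sample, "locus": res.locus, "treatment": res.treatment,
                "allele1": res.alleles[0], "allele2": res.alleles[1],
                "xi_fraction_allele1": res.xi_fraction_allele1,
                "main_inactive_pct": res.main_inactive_pct,
                "skew_class": res.skew_class, "qc": ";".join(res.qc),
            })
    return pd.DataFrame(rows, columns=[
        "sample", "locus", "treatment", "allele1", "allele2",
        "xi_fraction_allele1", "main_inactive_pct", "skew_class", "qc",
    ])


def cross_enzyme_discordance(
    results: pd.DataFrame, warn_pp: float = 15.0
) -> pd.DataFrame:
    """Flag samples whose per-enzyme main_inactive_pct differ by > warn_pp.

    Enzyme results are never averaged; overlapping-CpG chemistry (e.g. the
    HhaI site sharing the CpG of a BstUI site) can make them disagree.
    """
    wide = results.pivot_table(
        index=["sample", "locus"], columns="treatment",
        values="main_inactive_pct", aggfunc="first",
    )
    spread = wide.max(axis=1) - wide.min(axis=1)
    out = wide[spread > warn_pp].copy()
    out["spread_pp"] = spread[spread > warn_pp]
    return out.reset_index()


# ---------------------------------------------------------------------------
# population statistics

def allelic_span(sizes: Iterable[float]) -> float:
    """Difference in bp between the longest and shortest allele of a locus."""
    sizes = list(sizes)
    if not sizes:
        raise InputError("no alleles")
    return float(max(sizes) - min(sizes))


def population_stats(genotypes: pd.DataFrame, locus: str) -> PopulationStats:
    """Observed/expected heterozygosity and allele frequencies for a locus.

    ``genotypes`` columns: sample, locus, sex (F/M), allele1, allele2
    (allele2 empty for hemizygous males).  Males contribute alleles to the
    frequencies but are excluded from the heterozygosity denominator.
    """
    sub = genotypes[genotypes["locus"] == locus]
    females = sub[sub["sex"] == "F"]
    if females.empty:
        raise EstimationError(f"no typed females at locus {locus!r}")
    het = (females["allele1"] != females["allele2"]).sum()
    n_typed = len(females)
    alleles: list[float] = []
    for _, row in sub.iterrows():
        alleles.append(float(row["allele1"]))
        if row["sex"] == "F":
            alleles.append(float(row["allele2"]))
    counts = pd.Series(alleles).value_counts().sort_index()
    freqs = (counts / counts.sum()).to_dict()
    exp_het = 1.0 - sum(f * f for f in freqs.values())
    return PopulationStats(
        locus=locus, n_typed=n_typed, n_heterozygous=int(het),
        observed_heterozygosity=het / n_typed,
        expected_heterozygosity=exp_het,
        allele_frequencies=freqs,
    )


def combined_informativeness(
    stats: Sequence[Mapping[str, float]] | pd.DataFrame,
    mode: str = "independence",
) -> float:
    """Probability that at least one locus is heterozygous.

    ``independence`` mode takes per-locus heterozygosities, one mapping
    {locus: H} per population subset, computes 1 - prod(1 - H) per subset and
    averages subsets with equal weight.  ``empirical`` mode takes a genotype
    frame (sample, locus, sex, allele1, allele2) and returns the fraction of
    females heterozygous at >= 1 locus.
    """
    if mode == "independence":
        if isinstance(stats, pd.DataFrame):
            raise InputError("independence mode expects per-locus heterozygosities")
        values = []
        for subset in stats:
            prod = 1.0
            for h in subset.values():
                prod *= (1.0 - h)
            values.append(1.0 - prod)
        if not values:
            raise InputError("no subsets given")
        return float(np.mean(values))
    if mode == "empirical":
        if not isinstance(stats, pd.DataFrame):
            raise InputError("empirical mode expects a genotype table")
        females = stats[stats["sex"] == "F"]
        loci = females["locus"].unique()
        per_locus_samples = [
            set(females[females["locus"] == loc]["sample"]) for loc in loci
        ]
        common = set.intersection(*per_locus_samples) if per_locus_samples else set()
        if any(s != common for s in per_locus_samples):
            raise InputError("empirical mode requires identical sample sets per locus")
        if not common:
            raise InputError("no samples typed at all loci")
        het = females["allele1"] != females["allele2"]
        by_sample = females.assign(het=het).groupby("sample")["het"].any()
        return float(by_sample.loc[sorted(common)].mean())
    raise InputError(f"unknown mode {mode!r}")


def concordance(a: Sequence[float], b: Sequence[float]) -> ConcordanceResult:
    """Spearman rank correlation of paired main_inactive_pct vectors.

    Ties are mid-ranked; the 95 % CI uses the Fisher z transform with
    1.96/sqrt(n-3).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise InputError("paired vectors must be the same length")
    n = len(a)
    if n < 3:
        raise InsufficientDataError("need >= 3 informative pairs")
    r, p = sps.spearmanr(a, b)
    r = float(r)
    if abs(r) >= 1.0 - 1e-12 or n <= 3:
        ci = (r, r)
    else:
        z = math.atanh(r)
        hw = 1.96 / math.sqrt(n - 3)
        ci = (math.tanh(z - hw), math.tanh(z + hw))
    return ConcordanceResult(n=n, spearman_r=r, ci95=ci, p_value=float(p))


def phase_trio(
    mother: Sequence[float],
    father: Sequence[float],
    child: Sequence[float],
    child_xi_allele: float,
) -> str:
    """Parental origin of the child's inactive X at one locus.

    The father is hemizygous.  Returns 'maternal', 'paternal' or 'ambiguous';
    a child Xi allele absent from both parents raises a Mendelian error.
    """
    mom = {float(x) for x in mother}
    dad = {float(x) for x in father}
    if len(dad) != 1:
        raise InputError("father must be hemizygous (one allele)")
    xi = float(child_xi_allele)
    if xi not in {float(x) for x in child}:
        raise InputError("child_xi_allele is not one of the child's alleles")
    in_mom, in_dad = xi in mom, xi in dad
    if in_mom and not in_dad:
        return "maternal"
    if in_dad and not in_mom:
        return "paternal"
    if in_mom and in_dad:
        return "ambiguous"
    raise MendelianInconsistencyError(
        f"child Xi allele {xi} absent from both parents"
    )
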