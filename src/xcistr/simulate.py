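"""Ground-truthed synthetic genomes and QF-PCR cohorts.

Every generator is a pure function of its spec plus seed, and every planted
feature is emitted in a truth table so detection and quantification can be
verified round-trip.

The synthetic chromosome emulates the screened X-chromosome context: a
CpG-free random background (every background CpG is rewritten, so all CpG
islands and methylation-sensitive restriction sites are planted, never
accidental) into which tandem arrays, CpG islands, genes/exons,
pseudoautosomal intervals and enzyme recognition sites are written at
specified coordinates.

The cohort generator emulates the methylation-sensitive-digest QF-PCR assay:
Hardy-Weinberg genotypes per X haplotype (males hemizygous), one Xi-skew
parameter per female shared by all loci (the loci sit on the same
chromosome), full methylation of the Xi allele and digestion of the Xa
allele scaled by a digestion-efficiency factor, stutter peaks one repeat
unit below each true allele, and multiplicative log-normal area noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import BUILTIN_ENZYMES, CpGIsland, enzyme_by_name, island_stats
from .exceptions import InputError
from .intervals import GenomicInterval
from .io import GeneModel, write_bed, write_fasta, write_gff3, write_tsv
from .xci import UNDIGESTED

# ---------------------------------------------------------------------------
# genome spec


@dataclass(frozen=True)
class PlantedRepeat:
    name: str
    unit: str
    copies: int
    start: int
    purity_pct: float = 100.0  # match percentage target; <100 inserts interruptions

    @property
    def interruptions(self) -> int:
        if self.purity_pct >= 100:
            return 0
        m = len(self.unit) * self.copies
        return max(1, round(m * (100.0 / self.purity_pct - 1.0)))

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies + self.interruptions


@dataclass(frozen=True)
class PlantedCGI:
    name: str
    start: int
    length: int = 400
    gc_fraction: float = 0.60
    obs_exp_cpg: float = 0.75


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    start: int
    length: int = 600
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()  # relative to gene start; default one exon

    def exon_intervals(self, chrom: str) -> tuple[GenomicInterval, ...]:
        rel = self.exons or ((100, min(500, self.length)),)
        return tuple(
            GenomicInterval(chrom, self.start + a, self.start + b, self.strand)
            for a, b in rel
        )


@dataclass(frozen=True)
class PlantedSite:
    enzyme: str
    repeat_name: str
    gap: int  # bp between site and repeat edge; >= 0 downstream, < 0 upstream


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    length: int
    chrom: str = "chrX_syn"
    genes: tuple[PlantedGene, ...] = ()
    pars: tuple[tuple[int, int], ...] = ()
    cgis: tuple[PlantedCGI, ...] = ()
    repeats: tuple[PlantedRepeat, ...] = ()
    sites: tuple[PlantedSite, ...] = ()
    escape_genes: tuple[str, ...] = ()
    gc_background: float = 0.40
    seed: int = 0


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    seq: str
    genes: list[GeneModel]
    cgis: list[CpGIsland]
    pars: list[GenomicInterval]
    repeats: dict[str, GenomicInterval]
    sites: list[tuple[str, GenomicInterval]]
    truth: pd.DataFrame

    @property
    def seqs(self) -> dict[str, str]:
        return {self.spec.chrom: self.seq}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "cgi": outdir / "cgi.bed",
            "par": outdir / "par.bed",
            "escape": outdir / "escape.txt",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.seqs, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        write_bed([c.interval for c in self.cgis], paths["cgi"],
                  names=[f"CGI{i+1}" for i in range(len(self.cgis))])
        write_bed(self.pars, paths["par"],
                  names=[f"PAR{i+1}" for i in range(len(self.pars))])
        with open(paths["escape"], "w") as fh:
            for g in self.spec.escape_genes:
                fh.write(g + "\n")
        write_tsv(self.truth, paths["truth"], meta={"seed": self.spec.seed})
        return paths


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(bases, size=length, p=probs)
    # rewrite every CpG (G -> A) so islands/sites exist only where planted
    while True:
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if cg.size == 0:
            break
        arr[cg + 1] = ord("A")
    return arr


def _cgi_sequence(cgi: PlantedCGI, rng: np.random.Generator) -> str:
    """CpG-island block hitting its GC / obs-exp targets.

    CpGs are planted as A-CG-T motifs (each CpG flanked by A/T), which keeps
    the island free of methylation-sensitive enzyme recognition sites so
    site placement stays fully controlled by the spec.
    """
    L, gc, oe = cgi.length, cgi.gc_fraction, cgi.obs_exp_cpg
    n_cpg = math.ceil(1.15 * oe * (gc * L / 2) ** 2 / L)
    filler_gc = gc  # motifs are 50 % GC; bias filler slightly above target
    filler = _background(L, min(0.95, filler_gc + 0.08), rng)
    motif = np.frombuffer(b"ACGT", dtype=np.uint8)
    step = max(4, L // max(n_cpg, 1))
    for k in range(n_cpg):
        pos = (k * step) % (L - 4)
        filler[pos:pos + 4] = motif
    # planting motifs may abut: re-scrub any CG outside a planted motif
    planted = set()
    for k in range(n_cpg):
        planted.add((k * step) % (L - 4) + 1)
    cg = np.flatnonzero((filler[:-1] == ord("C")) & (filler[1:] == ord("G")))
    for i in cg:
        if int(i) not in planted:
            filler[i + 1] = ord("A")
    return filler.tobytes().decode()


def _repeat_sequence(rep: PlantedRepeat) -> str:
    k = rep.interruptions
    if k == 0:
        return rep.unit * rep.copies
    n_chunks = k + 1
    base, extra = divmod(rep.copies, n_chunks)
    if base < 2:
        raise InputError(
            f"repeat {rep.name}: purity {rep.purity_pct} needs more copies "
            "(each interrupted chunk must keep >= 2 units)"
        )
    chunks = [rep.unit * (base + (1 if i < extra else 0)) for i in range(n_chunks)]
    return "C".join(chunks)


def build_synthetic_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Materialise a spec into sequence + tracks + truth table.

    Planted features must not overlap; regeneration with the same spec is
    bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    arr = _background(spec.length, spec.gc_background, rng)
    chrom = spec.chrom
    occupied: list[tuple[int, int, str]] = []
    truth_rows: list[dict] = []

    def place(start: int, s: str, kind: str, name: str, **extra) -> GenomicInterval:
        end = start + len(s)
        if start < 0 or end > spec.length:
            raise InputError(f"{kind} {name} outside chromosome bounds")
        for a, b, other in occupied:
            if start < b and a < end:
                raise InputError(f"{kind} {name} overlaps planted feature {other}")
        occupied.append((start, end, f"{kind}:{name}"))
        arr[start:end] = np.frombuffer(s.encode(), dtype=np.uint8)
        truth_rows.append({
            "kind": kind, "name": name, "chrom": chrom,
            "start": start, "end": end, **extra,
        })
        return GenomicInterval(chrom, start, end)

    repeats: dict[str, GenomicInterval] = {}
    insulators: list[tuple[int, str]] = []
    for rep in spec.repeats:
        seq = _repeat_sequence(rep)
        p = len(rep.unit)
        repeats[rep.name] = place(
            rep.start, seq, "repeat", rep.name,
            unit=rep.unit, copies=rep.copies, purity_pct=rep.purity_pct,
        )
        # phase-breaking flank bases so the detected array ends exactly at
        # the planted boundaries (an in-phase background base would extend
        # it); applied later, only onto background positions
        if rep.start > 0:
            insulators.append(
                (rep.start - 1, "T" if seq[p - 1] != "T" else "A"))
        if rep.start + len(seq) < spec.length:
            insulators.append(
                (rep.start + len(seq), "T" if seq[len(seq) - p] != "T" else "A"))

    cgis: list[CpGIsland] = []
    for cgi in spec.cgis:
        s = _cgi_sequence(cgi, rng)
        iv = place(cgi.start, s, "cgi", cgi.name,
                   gc_target=cgi.gc_fraction, oe_target=cgi.obs_exp_cpg)
        gc_f, oe_f = island_stats(s)
        cgis.append(CpGIsland(interval=iv, gc_fraction=gc_f,
                              obs_exp_cpg=oe_f, source="annotated"))

    sites: list[tuple[str, GenomicInterval]] = []
    for site in spec.sites:
        enz = enzyme_by_name(site.enzyme)
        rep_iv = repeats.get(site.repeat_name)
        if rep_iv is None:
            raise InputError(f"site references unknown repeat {site.repeat_name!r}")
        rec = enz.recognition
        if site.gap >= 0:
            start = rep_iv.end + site.gap
        else:
            start = rep_iv.start + site.gap - len(rec)
        # insulate the site with A/T so the junction cannot spawn extra sites
        padded = "T" + rec + "A"
        iv_pad = place(start - 1, padded, "site", f"{site.enzyme}:{site.repeat_name}",
                       enzyme=site.enzyme, gap=site.gap)
        sites.append((site.enzyme, GenomicInterval(chrom, start, start + len(rec))))
        truth_rows[-1]["start"], truth_rows[-1]["end"] = start, start + len(rec)

    genes: list[GeneModel] = []
    for g in spec.genes:
        iv = GenomicInterval(chrom, g.start, g.start + g.length, g.strand)
        genes.append(GeneModel(gene_id=g.gene_id, interval=iv,
                               exons=g.exon_intervals(chrom)))
        truth_rows.append({
            "kind": "gene", "name": g.gene_id, "chrom": chrom,
            "start": iv.start, "end": iv.end,
            "escape": g.gene_id in spec.escape_genes,
        })

    for pos, base in insulators:
        if not any(a <= pos < b for a, b, _ in occupied):
            arr[pos] = ord(base)

    pars = [GenomicInterval(chrom, a, b) for a, b in spec.pars]
    for i, p in enumerate(pars):
        truth_rows.append({"kind": "par", "name": f"PAR{i+1}", "chrom": chrom,
                           "start": p.start, "end": p.end})

    truth = pd.DataFrame(truth_rows)
    return SyntheticGenome(
        spec=spec, seq=arr.tobytes().decode(), genes=genes, cgis=cgis,
        pars=pars, repeats=repeats, sites=sites, truth=truth,
    )


# ---------------------------------------------------------------------------
# locus-block helpers (used by tests and the planted-grid acceptance runs)


@dataclass(frozen=True)
class LocusPlan:
    """One screening test block: a repeat with configurable violations.

    Defaults describe a fully compliant locus: a perfect 16-unit GAAA array,
    intergenic, 150 bp upstream of a CpG island linked to a non-escape gene,
    with an HpaII site 50 bp upstream of the repeat.
    """

    name: str
    unit: str = "GAAA"
    copies: int = 16
    purity_pct: float = 100.0
    cgi_gap: int | None = 150       # None -> no CpG island
    enzyme: str | None = "HpaII"    # None -> no restriction site
    enzyme_gap: int = 50
    with_gene: bool = True
    escape: bool = False
    in_exon: bool = False
    in_par: bool = False


BLOCK_SIZE = 3200
_REPEAT_OFFSET = 600  # repeat start within its block


def locus_grid_spec(plans: Sequence[LocusPlan], seed: int = 0) -> SyntheticGenomeSpec:
    """One block per plan on a single synthetic chromosome."""
    repeats, cgis, genes, sites = [], [], [], []
    pars: list[tuple[int, int]] = []
    escape: list[str] = []
    for i, plan in enumerate(plans):
        origin = 400 + i * BLOCK_SIZE
        rstart = origin + _REPEAT_OFFSET
        rep = PlantedRepeat(plan.name, plan.unit, plan.copies, rstart, plan.purity_pct)
        repeats.append(rep)
        rend = rstart + rep.length
        if plan.enzyme is not None:
            sites.append(PlantedSite(plan.enzyme, plan.name, -plan.enzyme_gap))
        if plan.cgi_gap is not None:
            cgi = PlantedCGI(f"{plan.name}_cgi", rend + plan.cgi_gap)
            cgis.append(cgi)
            if plan.with_gene:
                gid = f"{plan.name}_gene"
                genes.append(PlantedGene(gid, cgi.start + cgi.length + 50))
                if plan.escape:
                    escape.append(gid)
        if plan.in_exon:
            gid = f"{plan.name}_exongene"
            gstart = rstart - 100
            genes.append(PlantedGene(
                gid, gstart, length=rep.length + 200,
                exons=((50, rep.length + 150),),
            ))
        if plan.in_par:
            pars.append((rstart - 50, rend + 50))
    length = 400 + len(plans) * BLOCK_SIZE + 800
    return SyntheticGenomeSpec(
        length=length, repeats=tuple(repeats), cgis=tuple(cgis),
        genes=tuple(genes), sites=tuple(sites), pars=tuple(pars),
        escape_genes=tuple(escape), seed=seed,
    )


def decoy_panel_plans() -> list[LocusPlan]:
    """One compliant locus plus decoys each violating exactly one criterion."""
    return [
        LocusPlan("ok"),
        LocusPlan("few_units", copies=11),
        LocusPlan("impure", copies=22, purity_pct=89.8),
        LocusPlan("in_exon", in_exon=True),
        LocusPlan("in_par", in_par=True),
        LocusPlan("no_cgi", cgi_gap=None),
        LocusPlan("far_cgi", cgi_gap=300),
        LocusPlan("escapee", escape=True),
        LocusPlan("no_site", enzyme=None),
    ]


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class LocusModel:
    name: str
    repeat_unit_bp: int
    allele_sizes: tuple[float, ...]
    allele_freqs: tuple[float, ...]
    stutter_fraction: float

    def __post_init__(self) -> None:
        if abs(sum(self.allele_freqs) - 1.0) > 1e-9:
            raise InputError(f"{self.name}: allele frequencies must sum to 1")
        if len(self.allele_sizes) != len(self.allele_freqs):
            raise InputError(f"{self.name}: sizes/freqs length mismatch")


#: Tetranucleotide GAAA locus: amplimers around 350-390 bp, ~0.85
#: heterozygosity, 2.6 % stutter.
RP2_LOCUS = LocusModel(
    "RP2", 4,
    tuple(float(s) for s in range(352, 396, 4)),
    (0.02, 0.05, 0.08, 0.12, 0.18, 0.20, 0.15, 0.10, 0.06, 0.03, 0.01),
    0.026,
)

#: Trinucleotide CAG locus: ~0.85 heterozygosity, 17.6 % stutter.
AR_LOCUS = LocusModel(
    "AR", 3,
    tuple(float(s) for s in range(210, 243, 3)),
    (0.03, 0.06, 0.10, 0.14, 0.18, 0.16, 0.12, 0.09, 0.06, 0.04, 0.02),
    0.176,
)


@dataclass(frozen=True)
class SkewModel:
    """Xi-skew distribution across females.

    A fraction ``p_random`` draws the Xi fraction from a Beta centred on 0.5
    (random XCI, main inactive allele mostly 50-80 %); the rest are skewed at
    one of ``skewed_values`` with random orientation.  ``fixed`` overrides
    everything with one deterministic value.
    """

    p_random: float = 0.7
    beta_a: float = 14.0
    beta_b: float = 14.0
    skewed_values: tuple[float, ...] = (0.85, 0.90, 0.95, 0.99)
    fixed: float | None = None

    def draw(self, rng: np.random.Generator) -> float:
        if self.fixed is not None:
            return float(self.fixed)
        if rng.random() < self.p_random:
            return float(rng.beta(self.beta_a, self.beta_b))
        s = float(rng.choice(self.skewed_values))
        return s if rng.random() < 0.5 else 1.0 - s


@dataclass(frozen=True)
class CohortSpec:
    n_females: int
    n_males: int = 0
    loci: tuple[LocusModel, ...] = (RP2_LOCUS, AR_LOCUS)
    skew: SkewModel = SkewModel()
    digestion_efficiency: float = 1.0
    area_cv: float = 0.05
    enzymes: tuple[str, ...] = ("HpaII",)
    base_area: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.digestion_efficiency <= 1:
            raise InputError("digestion_efficiency must be in [0, 1]")
        if self.area_cv < 0:
            raise InputError("area_cv must be >= 0")


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    genotypes: pd.DataFrame  # sample, locus, sex, allele1, allele2
    peaks: pd.DataFrame      # PeakRecord schema, all treatments
    truth: pd.DataFrame      # sample, locus, allele1, allele2, skew, xi_fraction_allele1


def _noise(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma))


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate genotypes, undigested and per-enzyme digested peak tables.

    One skew parameter per female is shared across loci (both repeats ride
    the same X haplotypes), which is what makes two-locus readouts
    concordant.  With zero noise and full digestion the quantification
    pipeline returns the planted Xi fractions exactly.
    """
    rng = np.random.default_rng(spec.seed)
    geno_rows, truth_rows, peak_acc = [], [], []
    samples = (
        [(f"F{i+1:03d}", "F") for i in range(spec.n_females)]
        + [(f"M{i+1:03d}", "M") for i in range(spec.n_males)]
    )
    for sample, sex in samples:
        skew = spec.skew.draw(rng) if sex == "F" else None  # Xi fraction of hap A
        for locus in spec.loci:
            sizes = np.asarray(locus.allele_sizes)
            freqs = np.asarray(locus.allele_freqs)
            hap_a = float(rng.choice(sizes, p=freqs))
            hap_b = float(rng.choice(sizes, p=freqs)) if sex == "F" else None
            if sex == "F":
                a1, a2 = sorted((hap_a, hap_b))
                geno_rows.append({"sample": sample, "locus": locus.name,
                                  "sex": sex, "allele1": a1, "allele2": a2})
                # xi fraction carried by the smaller allele
                if hap_a == hap_b:
                    xi1 = 0.5
                elif a1 == hap_a:
                    xi1 = skew
                else:
                    xi1 = 1.0 - skew
                truth_rows.append({
                    "sample": sample, "locus": locus.name,
                    "allele1": a1, "allele2": a2,
                    "skew": skew, "xi_fraction_allele1": xi1,
                })
            else:
                geno_rows.append({"sample": sample, "locus": locus.name,
                                  "sex": sex, "allele1": hap_a, "allele2": hap_a})
            # expected (pre-noise) template amounts per allele size
            for treatment in (UNDIGESTED,) + tuple(spec.enzymes):
                expected: dict[float, float] = {}
                if sex == "F":
                    for hap, xi in ((hap_a, skew), (hap_b, 1.0 - skew)):
                        if treatment == UNDIGESTED:
                            amount = 1.0
                        else:
                            amount = xi + (1.0 - xi) * (1.0 - spec.digestion_efficiency)
                        expected[hap] = expected.get(hap, 0.0) + amount
                else:
                    amount = 1.0 if treatment == UNDIGESTED else (1.0 - spec.digestion_efficiency)
                    expected[hap_a] = amount
                peaks: dict[float, float] = {}
                for size, amount in sorted(expected.items()):
                    area = spec.base_area * amount * _noise(rng, spec.area_cv)
                    peaks[size] = peaks.get(size, 0.0) + area
                    st = (spec.base_area * amount * locus.stutter_fraction
                          * _noise(rng, spec.area_cv))
                    if st > 0:
                        pos = size - locus.repeat_unit_bp
                        peaks[pos] = peaks.get(pos, 0.0) + st
                for size, area in sorted(peaks.items()):
                    if area <= 0:
                        continue
                    peak_acc.append({
                        "sample": sample, "locus": locus.name,
                        "treatment": treatment, "allele_size": size,
                        "area": area, "height": area / 20.0,
                    })
    return SimulatedCohort(
        spec=spec,
        genotypes=pd.DataFrame(geno_rows),
        peaks=pd.DataFrame(peak_acc),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_biallelic_population(
    p: float, n: int, seed: int = 0,
    sizes: tuple[float, float] = (318.0, 327.0),
    locus: str = "RP2_marmoset",
) -> pd.DataFrame:
    """Hardy-Weinberg female genotypes at a biallelic locus.

    Observed heterozygosity converges to 2p(1-p) as n grows; the ceiling over
    p is 0.5 at p = 0.5.
    """
    if not 0 < p < 1:
        raise InputError("allele frequency p must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        hap = rng.random(2) < p
        alleles = sorted(sizes[0] if h else sizes[1] for h in hap)
        rows.append({"sample": f"F{i+1:05d}", "locus": locus, "sex": "F",
                     "allele1": alleles[0], "allele2": alleles[1]})
    return pd.DataFrame(rows)
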