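"""Multi-criteria screen for XCI-informative core-promoter STR candidates.

A repeat is accepted when all six sub-criteria hold:

* ``i_repeat``        — tetra/pentanucleotide, >= 12 units, match pct > 90
* ``ii_extragenic``   — no exon overlap
* ``ii_non_par``      — outside pseudoautosomal regions
* ``iii_cgi_proximity`` — < 300 bp edge gap from (or inside) a CpG island
* ``iii_non_escape``  — the island's gene is not an XCI-escape gene
* ``iv_enzyme_site``  — a 5meCpG-sensitive restriction site < 300 bp away

Every detected repeat is emitted with full per-criterion evidence so each
accept/reject decision can be audited and recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .annotation import (
    BUILTIN_ENZYMES,
    CpGIsland,
    RestrictionEnzyme,
    RestrictionSite,
    scan_restriction_sites,
)
from .exceptions import InputError
from .intervals import GenomicInterval, IntervalIndex, distance_to_feature
from .io import GeneModel, read_bed, read_fasta, read_gff3
from .repeats import RepeatScanParams, TandemRepeat, find_tandem_repeats

CRITERIA = (
    "i_repeat",
    "ii_extragenic",
    "ii_non_par",
    "iii_cgi_proximity",
    "iii_non_escape",
    "iv_enzyme_site",
)

#: Screen defaults mirror the published criteria: 4-5 bp units, >= 12 copies,
#: match percentage strictly > 90.
DEFAULT_REPEAT_PARAMS = RepeatScanParams(
    min_period=4, max_period=5, min_copy_number=12.0, min_match_pct=90.0
)


@dataclass(frozen=True)
class ScreenConfig:
    repeat_params: RepeatScanParams = DEFAULT_REPEAT_PARAMS
    cgi_max_distance: int = 300     # strict <, bp edge gap
    enzyme_max_distance: int = 300  # strict <, bp edge gap
    escape_genes: frozenset[str] = frozenset()
    par_track: tuple[GenomicInterval, ...] = ()
    tss_link_window: int = 2000     # CGI-to-gene linkage window, bp
    enzymes: tuple[RestrictionEnzyme, ...] = BUILTIN_ENZYMES

    def __post_init__(self) -> None:
        if self.cgi_max_distance <= 0 or self.enzyme_max_distance <= 0:
            raise InputError("distance cutoffs must be positive")


@dataclass(frozen=True)
class CriterionCheck:
    name: str
    passed: bool
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateLocus:
    repeat: TandemRepeat
    criteria: dict[str, CriterionCheck]
    linked_cgi: CpGIsland | None = None
    nearby_sites: tuple[RestrictionSite, ...] = ()
    gene: str | None = None

    @property
    def accepted(self) -> bool:
        return all(c.passed for c in self.criteria.values())

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        return tuple(name for name in CRITERIA if not self.criteria[name].passed)


def _discovery_params(params: RepeatScanParams) -> RepeatScanParams:
    """Relaxed detection thresholds so near-miss loci appear with provenance."""
    return replace(
        params,
        min_copy_number=min(params.min_copy_number, 5.0),
        min_match_pct=min(params.min_match_pct, 75.0),
    )


def link_cgi_to_gene(
    cgi: GenomicInterval, genes: Sequence[GeneModel], window: int
) -> GeneModel | None:
    """Nearest-TSS assignment of a CpG island to a gene within ``window`` bp."""
    best: tuple[int, GeneModel] | None = None
    for g in genes:
        if g.interval.chrom != cgi.chrom:
            continue
        tss = g.tss
        if cgi.start <= tss < cgi.end:
            d = 0
        else:
            d = min(abs(tss - cgi.start), abs(tss - (cgi.end - 1)))
        if d <= window and (best is None or d < best[0]):
            best = (d, g)
    return best[1] if best else None


def screen_candidates(
    genome: Mapping[str, str] | str | Path,
    annotation: Sequence[GeneModel] | str | Path,
    cgi_track: Sequence[CpGIsland] | Sequence[GenomicInterval] | str | Path,
    config: ScreenConfig | None = None,
) -> list[CandidateLocus]:
    """Run the full screen and return every detected repeat with provenance.

    ``genome`` may be a FASTA path or a {chrom: sequence} mapping; likewise
    the annotation (GFF3 path or gene models) and CpG-island track (BED path
    or interval/island list).  All tracks must use the genome's chromosome
    names.
    """
    if config is None:
        config = ScreenConfig()
    seqs = read_fasta(genome) if isinstance(genome, (str, Path)) else dict(genome)
    genes = read_gff3(annotation) if isinstance(annotation, (str, Path)) else list(annotation)
    if isinstance(cgi_track, (str, Path)):
        cgis = [
            CpGIsland(interval=iv, gc_fraction=float("nan"),
                      obs_exp_cpg=float("nan"), source="annotated")
            for iv in read_bed(cgi_track)
        ]
    else:
        cgis = [
            c if isinstance(c, CpGIsland) else
            CpGIsland(interval=c, gc_fraction=float("nan"),
                      obs_exp_cpg=float("nan"), source="annotated")
            for c in cgi_track
        ]
    _check_chromosomes(seqs, genes, cgis, config.par_track)

    exon_index = IntervalIndex(e for g in genes for e in g.exons)
    par_index = IntervalIndex(config.par_track)
    cgi_index = IntervalIndex(c.interval for c in cgis)
    cgi_by_iv = {c.interval: c for c in cgis}

    disc = _discovery_params(config.repeat_params)
    out: list[CandidateLocus] = []
    for chrom, seq in seqs.items():
        sites = scan_restriction_sites(
            seq,
            [e for e in config.enzymes if e.methylation_sensitive],
            chrom=chrom,
        )
        site_index = IntervalIndex(s.interval for s in sites)
        site_by_iv: dict[GenomicInterval, list[RestrictionSite]] = {}
        for s in sites:
            site_by_iv.setdefault(s.interval, []).append(s)
        for repeat in find_tandem_repeats(seq, disc, chrom=chrom):
            out.append(_evaluate_locus(
                repeat, config, genes, exon_index, par_index,
                cgi_index, cgi_by_iv, site_index, site_by_iv,
            ))
    out.sort(key=lambda c: (c.repeat.interval.chrom, c.repeat.interval.start, c.repeat.period))
    return out


def _check_chromosomes(seqs, genes, cgis, par_track) -> None:
    known = set(seqs)
    offenders = sorted(
        {g.interval.chrom for g in genes if g.interval.chrom not in known}
        | {c.interval.chrom for c in cgis if c.interval.chrom not in known}
        | {p.chrom for p in par_track if p.chrom not in known}
    )
    if offenders:
        raise InputError(
            "chromosome name(s) absent from the genome: " + ", ".join(offenders)
        )


def _evaluate_locus(
    repeat: TandemRepeat,
    config: ScreenConfig,
    genes: Sequence[GeneModel],
    exon_index: IntervalIndex,
    par_index: IntervalIndex,
    cgi_index: IntervalIndex,
    cgi_by_iv: Mapping[GenomicInterval, CpGIsland],
    site_index: IntervalIndex,
    site_by_iv: Mapping[GenomicInterval, list[RestrictionSite]],
) -> CandidateLocus:
    rp = config.repeat_params
    iv = repeat.interval
    criteria: dict[str, CriterionCheck] = {}

    ok_i = (
        rp.min_period <= repeat.period <= rp.max_period
        and repeat.copy_number >= rp.min_copy_number
        and repeat.match_pct > rp.min_match_pct
    )
    criteria["i_repeat"] = CriterionCheck("i_repeat", ok_i, {
        "period": repeat.period,
        "copy_number": round(repeat.copy_number, 3),
        "match_pct": round(repeat.match_pct, 2),
        "min_copy_number": rp.min_copy_number,
        "min_match_pct": rp.min_match_pct,
    })

    exon_hits = exon_index.overlapping(iv)
    criteria["ii_extragenic"] = CriterionCheck("ii_extragenic", not exon_hits, {
        "overlapping_exons": [str(e) for e in exon_hits],
    })
    par_hits = par_index.overlapping(iv)
    criteria["ii_non_par"] = CriterionCheck("ii_non_par", not par_hits, {
        "overlapping_pars": [str(p) for p in par_hits],
    })

    # criterion iii: < cutoff bp from, or inside, a CpG island (edge gap)
    near_cgis = cgi_index.within(iv, config.cgi_max_distance)
    linked_cgi = None
    cgi_gap = None
    for cg in near_cgis:
        gap = distance_to_feature(iv, cg, "edge_gap").bp
        if cgi_gap is None or gap < cgi_gap:
            cgi_gap, linked_cgi = gap, cg
    ok_cgi = cgi_gap is not None and cgi_gap < config.cgi_max_distance
    criteria["iii_cgi_proximity"] = CriterionCheck("iii_cgi_proximity", ok_cgi, {
        "nearest_cgi": str(linked_cgi) if linked_cgi is not None else None,
        "edge_gap_bp": cgi_gap,
        "cutoff_bp": config.cgi_max_distance,
    })

    gene = link_cgi_to_gene(linked_cgi, genes, config.tss_link_window) if linked_cgi else None
    if not config.escape_genes or linked_cgi is None:
        # filtering disabled, or nothing to judge (proximity already failed)
        ok_escape = True
    else:
        # a linked island with no assignable gene cannot be cleared of escape
        ok_escape = gene is not None and gene.gene_id not in config.escape_genes
    criteria["iii_non_escape"] = CriterionCheck("iii_non_escape", ok_escape, {
        "linked_gene": gene.gene_id if gene else None,
        "escape_filtering": bool(config.escape_genes),
        "is_escape": (gene.gene_id in config.escape_genes) if gene else None,
    })

    near_site_ivs = site_index.within(iv, config.enzyme_max_distance)
    best_site = None
    site_gap = None
    nearby: list[RestrictionSite] = []
    for siv in near_site_ivs:
        gap = distance_to_feature(iv, siv, "edge_gap").bp
        for s in site_by_iv[siv]:
            if gap < config.enzyme_max_distance:
                nearby.append(s)
            if site_gap is None or gap < site_gap:
                site_gap, best_site = gap, s
    ok_site = site_gap is not None and site_gap < config.enzyme_max_distance
    criteria["iv_enzyme_site"] = CriterionCheck("iv_enzyme_site", ok_site, {
        "nearest_site": f"{best_site.enzyme}@{best_site.interval}" if best_site else None,
        "edge_gap_bp": site_gap,
        "cutoff_bp": config.enzyme_max_distance,
    })

    return CandidateLocus(
        repeat=repeat,
        criteria=criteria,
        linked_cgi=cgi_by_iv.get(linked_cgi) if linked_cgi is not None else None,
        nearby_sites=tuple(nearby),
        gene=gene.gene_id if gene else None,
    )


def explain_candidate(locus: CandidateLocus) -> dict:
    """JSON-serialisable justification of each pass/fail with evidence."""
    return {
        "locus": str(locus.repeat.interval),
        "unit": locus.repeat.unit,
        "period": locus.repeat.period,
        "copy_number": round(locus.repeat.copy_number, 3),
        "match_pct": round(locus.repeat.match_pct, 2),
        "longest_perfect_run": locus.repeat.longest_perfect_run,
        "gene": locus.gene,
        "accepted": locus.accepted,
        "failed_criteria": list(locus.failed_criteria),
        "criteria": {
            name: {"passed": c.passed, **c.evidence}
            for name, c in locus.criteria.items()
        },
    }
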