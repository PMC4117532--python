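"""File formats and provenance.

BED stays 0-based half-open; GFF3 is 1-based inclusive; results TSVs print
1-based inclusive coordinates to match browser-style reporting.  Every
pipeline output starts with ``#`` provenance lines carrying the package
version, seed and thresholds of the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import CpGIsland
from .exceptions import InputError
from .intervals import GenomicInterval
from .repeats import TandemRepeat

PEAK_COLUMNS = ["sample", "locus", "treatment", "allele_size", "area", "height"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA into {name: sequence} preserving order."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise InputError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as in the file)."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"BED line with <3 columns in {path}: {line!r}")
            strand = fields[5] if len(fields) >= 6 else "."
            ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return ivs


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models

@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    @property
    def tss(self) -> int:
        """0-based transcription start position (strand-aware)."""
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/exon models from GFF3 (via gffutils, in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        iv = GenomicInterval.from_1based(g.seqid, g.start, g.end, g.strand or ".")
        exons = tuple(
            GenomicInterval.from_1based(e.seqid, e.start, e.end, e.strand or ".")
            for e in db.children(g, featuretype="exon", order_by="start")
        )
        genes.append(GeneModel(gene_id=g.id, interval=iv, exons=exons))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "xcistr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start1}\t{iv.end1}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start1}\t{e.end1}\t.\t{e.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# peak tables

def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_peak_table(df)


def validate_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"peak table missing column(s): {', '.join(missing)}")
    df = df.copy()
    df["allele_size"] = df["allele_size"].astype(float)
    df["area"] = df["area"].astype(float)
    df["height"] = df["height"].astype(float)
    if (df["area"] < 0).any() or not df["area"].apply(pd.notna).all():
        raise InputError("peak areas must be finite and >= 0")
    dup = df.duplicated(subset=["sample", "locus", "treatment", "allele_size"])
    if dup.any():
        raise InputError("duplicate (sample, locus, treatment, allele_size) rows")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path, header: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(provenance_header(header))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# provenance + result writers

def provenance_header(meta: Mapping[str, object], comment: str = "#") -> str:
    from . import __version__

    lines = [f"{comment} xcistr version={__version__}"]
    for key, value in meta.items():
        lines.append(f"{comment} {key}={value}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(provenance_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def repeats_to_frame(repeats: Sequence[TandemRepeat]) -> pd.DataFrame:
    """TSV mirror of the repeat BED6+: 1-based inclusive coordinates."""
    return pd.DataFrame({
        "chrom": [t.interval.chrom for t in repeats],
        "start": [t.interval.start1 for t in repeats],
        "end": [t.interval.end1 for t in repeats],
        "unit": [t.unit for t in repeats],
        "period": [t.period for t in repeats],
        "copy_number": [round(t.copy_number, 3) for t in repeats],
        "match_pct": [round(t.match_pct, 2) for t in repeats],
        "indel_pct": [round(t.indel_pct, 2) for t in repeats],
        "longest_perfect_run": [t.longest_perfect_run for t in repeats],
    })


def write_repeats_bed(repeats: Sequence[TandemRepeat], path: str | Path) -> None:
    """BED6+ output: name=canonical unit, score=match_pct, then period,
    copy_number, longest_perfect_run extra columns."""
    with open(path, "w") as fh:
        for t in repeats:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.unit}\t{t.match_pct:.2f}\t"
                f"{iv.strand}\t{t.period}\t{t.copy_number:.3f}\t{t.longest_perfect_run}\n"
            )


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
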