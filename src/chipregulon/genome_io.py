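"""Readers, writers and coordinate conventions shared by the whole pipeline.

Every module in :mod:`chipregulon` works on a single linear chromosome with
1-based, inclusive coordinates — the convention of the position lists this
pipeline produces.  Conversions to 0-based half-open coordinates happen only
at format boundaries (BED, bedGraph).

Supported external formats
--------------------------
* FASTA (single record) for the genome sequence, via Biopython.
* GFF3 or a 5-column TSV (gene_id, start, end, strand, product) for gene
  annotation; the TSV dialect accepts strands coded ``1``/``-1`` as well as
  ``+``/``-``.
* Per-nucleotide coverage as bedGraph or as plain two-column
  (position, value) text — the latter is the native dialect of every track
  this pipeline writes (coverage, enrichment, difference, sigDiff).
* Sorted SAM/BAM alignments, from which per-base depth can be computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "CoverageTrack",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_coverage",
    "coverage_from_alignments",
    "write_track",
    "write_bedgraph",
    "write_bed",
    "write_table",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A single linear chromosome over the alphabet {A, C, G, T, N}."""

    chrom_id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"illegal characters in genome sequence: {sorted(bad)!r} "
                "(alphabet is A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene on the chromosome.

    ``start``/``end`` are 1-based inclusive.  The start codon sits at
    ``start`` for a ``+`` strand gene and at ``end`` for a ``-`` strand
    gene; promoter-distance computations elsewhere rely on this.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def start_codon(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class CoverageTrack:
    """Per-nucleotide read depth over the chromosome.

    ``values[i]`` is the depth at 1-based position ``i + 1``.
    """

    chrom_id: str
    values: np.ndarray
    sample_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-d vector")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be nonnegative")

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a single-record FASTA file; the sequence is upper-cased.

    Multi-record files are rejected: the pipeline is single-chromosome by
    design and silently merging records would corrupt every coordinate.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: empty FASTA, no sequence records")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records found; single chromosome required"
        )
    rec = records[0]
    return GenomeSequence(chrom_id=rec.id, seq=str(rec.seq).upper())


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.chrom_id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables

_TSV_STRANDS = {"+": "+", "-": "-", "−": "-", "1": "+", "-1": "-", "−1": "-"}


def _parse_gff3_genes(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feature_types = set(db.featuretypes())
    # prefer explicit gene features; fall back to CDS
    ftype = "gene" if "gene" in feature_types else "CDS"
    genes = []
    for feat in db.features_of_type(ftype):
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("Name", [None])[0]
            or f"{ftype}_{feat.start}"
        )
        product = feat.attributes.get("product", [""])[0]
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: feature {gene_id} has strand {feat.strand!r}")
        genes.append(
            GeneModel(gene_id=gene_id, start=feat.start, end=feat.end,
                      strand=feat.strand, product=product)
        )
    return genes


def _parse_tsv_genes(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("gene_id", "gene", "id"):
                continue  # header row
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            gene_id, start, end, strand = fields[:4]
            product = fields[4] if len(fields) > 4 else ""
            if strand not in _TSV_STRANDS:
                raise ValueError(f"{path}:{lineno}: unrecognized strand {strand!r}")
            genes.append(
                GeneModel(gene_id=gene_id, start=int(start), end=int(end),
                          strand=_TSV_STRANDS[strand], product=product)
            )
    return genes


def read_gene_table(
    path: str | Path,
    format: str = "tsv",
    genome: GenomeSequence | None = None,
) -> list[GeneModel]:
    """Read gene annotation from GFF3 or tabular text, sorted by start.

    Overlapping genes are legal (common in bacteria) but a warning is
    emitted so unexpected annotation problems surface.  When ``genome`` is
    supplied, coordinates beyond its length are an error.
    """
    path = Path(path)
    if format == "gff3":
        genes = _parse_gff3_genes(path)
    elif format == "tsv":
        genes = _parse_tsv_genes(path)
    else:
        raise ValueError(f"unknown gene table format {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        if genome is not None and g.end > genome.length:
            raise ValueError(
                f"{path}: gene {g.gene_id} ends at {g.end}, beyond genome "
                f"length {genome.length}"
            )
    genes.sort(key=lambda g: (g.start, g.end))
    for prev, cur in zip(genes, genes[1:]):
        if cur.start <= prev.end:
            warnings.warn(
                f"overlapping genes: {prev.gene_id} and {cur.gene_id}",
                stacklevel=2,
            )
            break
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\tproduct\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}\n")


# ---------------------------------------------------------------------------
# Coverage tracks


def read_coverage(
    path: str | Path,
    length: int,
    format: str = "two_column",
    chrom_id: str = "",
    sample_label: str = "",
    condition_label: str = "",
) -> CoverageTrack:
    """Read a coverage track into a dense per-nucleotide vector.

    ``two_column`` files carry 1-based positions; bedGraph intervals are
    0-based half-open per the standard and are converted.  Positions absent
    from the file default to 0.
    """
    values = np.zeros(length, dtype=np.int64)
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if format == "two_column":
                pos, val = int(fields[0]), int(round(float(fields[1])))
                if pos < 1 or pos > length:
                    raise ValueError(
                        f"{path}:{lineno}: position {pos} outside genome [1, {length}]"
                    )
                if val < 0:
                    raise ValueError(f"{path}:{lineno}: negative coverage {val}")
                values[pos - 1] = val
            elif format == "bedgraph":
                chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), fields[3]
                val = int(round(float(val)))
                if start < 0 or end > length or start >= end:
                    raise ValueError(
                        f"{path}:{lineno}: interval [{start}, {end}) outside "
                        f"genome of length {length}"
                    )
                if val < 0:
                    raise ValueError(f"{path}:{lineno}: negative coverage {val}")
                if not chrom_id:
                    chrom_id = chrom
                values[start:end] = val
            else:
                raise ValueError(f"unknown coverage format {format!r}")
    return CoverageTrack(chrom_id=chrom_id, values=values,
                         sample_label=sample_label, condition_label=condition_label)


def coverage_from_alignments(
    path: str | Path,
    genome: GenomeSequence,
    sample_label: str = "",
    condition_label: str = "",
) -> CoverageTrack:
    """Per-base depth from a sorted SAM/BAM file.

    Each primary mapped read increments every reference position it spans;
    secondary, supplementary and unmapped records are excluded.
    """
    import pysam

    values = np.zeros(genome.length, dtype=np.int64)
    with pysam.AlignmentFile(str(path)) as af:
        refs = set(af.references or ())
        if refs and genome.chrom_id not in refs:
            raise ValueError(
                f"{path}: reference names {sorted(refs)} do not include "
                f"genome chromosome {genome.chrom_id!r}"
            )
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != genome.chrom_id:
                raise ValueError(
                    f"{path}: read mapped to {read.reference_name!r}, "
                    f"expected {genome.chrom_id!r}"
                )
            # reference_start/end are 0-based half-open
            start = read.reference_start
            end = read.reference_end
            if end is None:
                continue
            values[start : min(end, genome.length)] += 1
    return CoverageTrack(chrom_id=genome.chrom_id, values=values,
                         sample_label=sample_label, condition_label=condition_label)


# ---------------------------------------------------------------------------
# Writers


def write_track(
    positions: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    path: str | Path,
) -> None:
    """Write a two-column (1-based position, value) text track.

    This is the on-disk dialect used for coverage, enrichment, difference
    and sigDiff files alike.
    """
    positions = np.asarray(positions)
    values = np.asarray(values)
    if positions.shape != values.shape:
        raise ValueError("positions and values must have equal length")
    with open(path, "w") as fh:
        for p, v in zip(positions, values):
            if float(v).is_integer():
                fh.write(f"{int(p)}\t{int(v)}\n")
            else:
                fh.write(f"{int(p)}\t{v:.10g}\n")


def read_track(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (position, value) track back as arrays."""
    positions, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p, v = line.split("\t")
            positions.append(int(p))
            values.append(float(v))
    return np.asarray(positions, dtype=np.int64), np.asarray(values, dtype=float)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Emit a dense coverage vector as bedGraph, merging equal-value runs."""
    vals = track.values
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        # boundaries where the value changes
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vals)]))
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom_id}\t{s}\t{e}\t{int(vals[s])}\n")


def write_bed(
    peaks: Iterable[tuple[int, str, float]],
    chrom_id: str,
    path: str | Path,
) -> None:
    """Write single-nucleotide peak positions as BED6.

    ``peaks`` yields (1-based position, name, score) triples; BED output is
    0-based half-open, so a position ``p`` becomes the interval
    ``[p - 1, p)``.
    """
    with open(path, "w") as fh:
        for pos, name, score in peaks:
            fh.write(f"{chrom_id}\t{pos - 1}\t{pos}\t{name}\t{score:.6g}\t.\n")


def write_table(records, path: str | Path) -> None:
    """Write a pandas DataFrame (or convertible) as UTF-8 TSV with header."""
    import pandas as pd

    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)
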