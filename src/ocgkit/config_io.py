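"""Input parsing, validation and preprocessing.

Reads the headerless comma-separated config file (one row per species:
ID, TPM count table, CDS FASTA, bait-ID list), per-species TPM count
tables, CDS FASTA files, bait lists and optional reference annotation
tables.  Also houses the two upstream preprocessing filters: RNA-seq
sample quality control and longest-isoform reduction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ConfigEntry",
    "PipelineParams",
    "ExpressionMatrix",
    "SequenceRecord",
    "ValidationError",
    "ParseError",
    "parse_config",
    "write_config",
    "clean_gene_id",
    "reduce_isoforms",
    "qc_filter_samples",
    "read_count_table",
    "read_fasta",
    "write_fasta",
    "read_baits",
    "read_annotation_table",
]


class ValidationError(ValueError):
    """Input violates a structural requirement (duplicates, missing IDs...)."""


class ParseError(ValueError):
    """Input file is malformed at a specific location."""


_ID_OK = re.compile(r"[^A-Za-z0-9._-]")


def clean_gene_id(raw_id: str) -> str:
    """Replace every character outside ``[A-Za-z0-9._-]`` with ``_``.

    Deterministic, idempotent and length-preserving; applied to every
    identifier read from any input file so that IDs agree across the
    count table, CDS FASTA and bait list of a species.
    """
    if not raw_id:
        raise ValidationError("gene ID must be non-empty")
    return _ID_OK.sub("_", raw_id)


@dataclass(frozen=True)
class ConfigEntry:
    """One species-level dataset: ID plus the three input file paths."""

    species_id: str
    tpm_path: str
    cds_path: str
    bait_path: str

    def __post_init__(self) -> None:
        if "," in self.species_id:
            raise ValidationError(
                f"species_id {self.species_id!r} may not contain a comma"
            )
        for name in ("tpm_path", "cds_path", "bait_path"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty for {self.species_id}")


@dataclass
class PipelineParams:
    """All tunable thresholds of the pipeline with their default values.

    r_cutoff / p_cutoff / numcut / min_exp_cutoff gate the coexpression
    scan; evalue_cutoff / score_cutoff / len_cutoff / sim_cutoff gate
    similarity hits; occupancy trims alignment columns;
    seqs_cluster_anno controls the annotation subsample;
    min_ocg_size / min_coexp_species are the OCG retention rules.
    """

    r_cutoff: float = 0.7
    p_cutoff: float = 0.05
    numcut: int = 100
    min_exp_cutoff: float = 30.0
    evalue_cutoff: float = 1e-5
    score_cutoff: float = 100.0
    len_cutoff: int = 100
    sim_cutoff: float = 80.0
    occupancy: float = 10.0
    seqs_cluster_anno: float = 50.0
    min_ocg_size: int = 10
    min_coexp_species: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_cutoff <= 1.0:
            raise ValidationError("r_cutoff must be in [0, 1]")
        if not 0.0 < self.p_cutoff <= 1.0:
            raise ValidationError("p_cutoff must be in (0, 1]")
        if self.numcut < 1:
            raise ValidationError("numcut must be >= 1")
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValidationError("occupancy must be in [0, 100]")
        # the annotation percentage has a hard floor of 10%
        if self.seqs_cluster_anno < 10.0:
            self.seqs_cluster_anno = 10.0


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide or peptide sequence with its species of origin."""

    seq_id: str
    sequence: str
    species_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"sequence for {self.seq_id!r} is empty")


@dataclass
class ExpressionMatrix:
    """Per-species gene x sample table of TPM values.

    Wraps a pandas DataFrame (genes as rows, samples as columns) and
    enforces uniqueness of both axes and non-negative finite values.
    """

    species_id: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene IDs in count table of {self.species_id}: {dups[:5]}"
            )
        if df.columns.duplicated().any():
            raise ValidationError(
                f"duplicate sample IDs in count table of {self.species_id}"
            )
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError(
                f"non-finite expression values in count table of {self.species_id}"
            )
        if (arr < 0).any():
            raise ValidationError(
                f"negative expression values in count table of {self.species_id}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def expression_of(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise ValidationError(
                f"gene {gene_id!r} not in count table of {self.species_id}"
            )
        return self.values.loc[gene_id].to_numpy(dtype=float)


def parse_config(path: str | Path) -> list[ConfigEntry]:
    """Parse the headerless, comma-separated config file.

    Each non-empty row must have exactly four fields:
    species ID, TPM table path, CDS FASTA path, bait file path.
    """
    path = Path(path)
    entries: list[ConfigEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 comma-separated fields, "
                    f"got {len(fields)}"
                )
            entry = ConfigEntry(*fields)
            if entry.species_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate species ID {entry.species_id!r}"
                )
            seen.add(entry.species_id)
            entries.append(entry)
    if not entries:
        raise ValidationError(f"{path}: config file contains no entries")
    return entries


def write_config(entries: Sequence[ConfigEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.species_id},{e.tpm_path},{e.cds_path},{e.bait_path}\n")


def reduce_isoforms(
    records: Sequence[SequenceRecord], gene_of: Mapping[str, str]
) -> list[SequenceRecord]:
    """Keep one representative transcript per gene: the longest CDS.

    ``gene_of`` maps every transcript ID to its gene label.  Ties on
    length are broken by the lexicographically smallest transcript ID so
    the output is deterministic.  Output order follows first appearance
    of each gene label in the input.
    """
    best: dict[str, SequenceRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.seq_id not in gene_of:
            raise ValidationError(f"no gene label for transcript {rec.seq_id!r}")
        gene = gene_of[rec.seq_id]
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            order.append(gene)
        elif (len(rec.sequence), _neg_lex(rec.seq_id)) > (
            len(cur.sequence),
            _neg_lex(cur.seq_id),
        ):
            best[gene] = rec
    return [best[g] for g in order]


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller seq_id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def qc_filter_samples(
    read_counts_per_sample: Mapping[str, float],
    per_transcript_reads: Mapping[str, Sequence[float]],
    min_total_reads: float = 1_000_000,
    top_n: int = 100,
    min_top_fraction: float = 0.20,
) -> list[str]:
    """RNA-seq sample quality control.

    A sample is kept iff its total read count reaches one million and
    the 100 most abundant transcripts jointly account for at least 20%
    of its reads (a typical RNA-seq abundance skew; flat distributions
    indicate DNA contamination or degraded libraries).
    """
    if set(read_counts_per_sample) != set(per_transcript_reads):
        missing = set(read_counts_per_sample) ^ set(per_transcript_reads)
        raise ValidationError(f"samples missing from one mapping: {sorted(missing)[:5]}")
    retained = []
    for sample in read_counts_per_sample:
        total = read_counts_per_sample[sample]
        if total < min_total_reads:
            continue
        counts = np.sort(np.asarray(per_transcript_reads[sample], dtype=float))[::-1]
        top = counts[:top_n].sum()
        if total > 0 and top / total >= min_top_fraction:
            retained.append(sample)
    return retained


def read_count_table(path: str | Path, species_id: str = "") -> ExpressionMatrix:
    """Read a tab-separated TPM table: gene IDs in column 1, sample header row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: count table has no sample columns (not TSV?)")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric expression value in sample {col!r}: "
                f"{bad.iloc[0]!r} (gene {bad.index[0]!r})"
            )
    df.index = [clean_gene_id(str(g)) for g in df.index]
    df.columns = [str(c) for c in df.columns]
    return ExpressionMatrix(species_id=species_id or path.stem, values=df)


def read_fasta(path: str | Path, species_id: str = "") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file; IDs are cleaned on the way in."""
    records = [
        SequenceRecord(clean_gene_id(rec.id), str(rec.seq).upper(), species_id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for rec in records:
        if rec.seq_id in seen:
            raise ValidationError(f"{path}: duplicate sequence ID {rec.seq_id!r}")
        seen.add(rec.seq_id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n{rec.sequence}\n")


def read_baits(
    path: str | Path,
    matrix: ExpressionMatrix | None = None,
    cds_ids: set[str] | None = None,
    species_id: str = "",
) -> list[str]:
    """Read bait IDs (one per line); optionally validate their presence.

    A bait missing from the count table or the CDS file of its species
    is a configuration mistake and raises immediately.
    """
    baits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                baits.append(clean_gene_id(line))
    if not baits:
        raise ValidationError(f"{path}: bait file contains no IDs")
    for bait in baits:
        if matrix is not None and bait not in matrix.values.index:
            raise ValidationError(
                f"bait {bait!r} absent from count table of species {species_id!r}"
            )
        if cds_ids is not None and bait not in cds_ids:
            raise ValidationError(
                f"bait {bait!r} absent from CDS file of species {species_id!r}"
            )
    return baits


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Read the 2-column tab-separated reference annotation table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            mapping[clean_gene_id(parts[0])] = parts[1]
    return mapping
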