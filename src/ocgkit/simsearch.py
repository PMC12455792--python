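"""Cross-species protein similarity search.

The pipeline compares candidate peptides against every species'
proteome.  A :class:`SearchEngine` contract decouples the pipeline from
the aligner: the default :class:`BuiltinEngine` runs exact Smith–
Waterman local alignment (BLOSUM62, gap open 11 / extend 1) through
Biopython's PairwiseAligner and scores hits with Karlin–Altschul
statistics, so the whole pipeline works without external binaries;
:class:`ExternalEngine` shells out to `diamond blastp` or NCBI `blastp`
when those are available.  All engines speak BLAST tabular format 6
(12 columns), and all hits pass through the same four filters:
e-value <= cutoff, bit score > cutoff, alignment length > cutoff and
percent identity > cutoff.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .config_io import (
    ParseError,
    PipelineParams,
    SequenceRecord,
    ValidationError,
    clean_gene_id,
    write_fasta,
)

__all__ = [
    "SimilarityHit",
    "SearchEngine",
    "BuiltinEngine",
    "ExternalEngine",
    "translate_cds",
    "filter_hits",
    "parse_tabular6",
    "write_tabular6",
    "collect_candidate_orthologs",
]

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62 (11/1); approximate
# published constants used for bit-score normalisation of the builtin
# engine.  E-values from this engine are internally consistent but are
# not interchangeable with DIAMOND's or BLAST's.
KA_LAMBDA = 0.267
KA_K = 0.041

TAB6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise protein alignment in BLAST tabular-6 terms."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def to_tab6(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pident:.1f}",
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.evalue:.2e}",
                f"{self.bitscore:.1f}",
            ]
        )


def translate_cds(cds: str) -> str:
    """Translate a CDS in frame +1 with the standard genetic code.

    A trailing stop codon is stripped; internal stops are rendered as
    ``X`` with a warning (pseudogene or frame problem — the sequence is
    still searchable); a trailing 1-2 nt remainder is ignored.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValidationError("CDS shorter than one codon")
    usable = len(cds) - len(cds) % 3
    pep = str(Seq(cds[:usable]).translate())
    if pep.endswith("*"):
        pep = pep[:-1]
    if "*" in pep:
        logger.warning("internal stop codon(s) in CDS; rendered as X")
        pep = pep.replace("*", "X")
    return pep


def filter_hits(
    hits: Iterable[SimilarityHit], params: PipelineParams | None = None
) -> list[SimilarityHit]:
    """Apply the four candidate filters plus self-hit removal.

    E-value is inclusive (may equal the cutoff); bit score, alignment
    length and percent identity must strictly exceed theirs.  Input
    order is preserved; the operation is idempotent.
    """
    params = params or PipelineParams()
    return [
        h
        for h in hits
        if h.query_id != h.subject_id
        and h.evalue <= params.evalue_cutoff
        and h.bitscore > params.score_cutoff
        and h.aln_length > params.len_cutoff
        and h.pident > params.sim_cutoff
    ]


def parse_tabular6(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column BLAST/DIAMOND tabular (outfmt 6) file."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    SimilarityHit(
                        query_id=clean_gene_id(parts[0]),
                        subject_id=clean_gene_id(parts[1]),
                        pident=float(parts[2]),
                        aln_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular6(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.to_tab6() + "\n")


class SearchEngine:
    """Contract: deterministic all-vs-all protein search returning tab-6 hits."""

    name: str = "abstract"
    version: str = "0"

    def search(
        self,
        queries: Sequence[SequenceRecord],
        subjects: Sequence[SequenceRecord],
    ) -> list[SimilarityHit]:
        raise NotImplementedError


class BuiltinEngine(SearchEngine):
    """Exact Smith–Waterman local alignment, BLOSUM62, gap open 11 / extend 1.

    Bit score S' = (lambda * S - ln K) / ln 2 with the gapped BLOSUM62
    constants; e-value = m * n * 2^(-S') where m and n are the residue
    totals of queries and subjects.  Quadratic in sequence count, so
    suited to the candidate collections this pipeline handles (hundreds
    of sequences), not whole proteome pairs.
    """

    name = "builtin-sw"
    version = "1"

    def __init__(self) -> None:
        self._aligner = PairwiseAligner()
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.mode = "local"
        self._aligner.open_gap_score = -11.0
        self._aligner.extend_gap_score = -1.0

    def search(
        self,
        queries: Sequence[SequenceRecord],
        subjects: Sequence[SequenceRecord],
    ) -> list[SimilarityHit]:
        if not queries or not subjects:
            raise ValidationError("search requires non-empty query and subject sets")
        queries = [q for q in queries if _warn_if_empty(q)]
        subjects = [s for s in subjects if _warn_if_empty(s)]
        m = sum(len(q.sequence) for q in queries)
        n = sum(len(s.sequence) for s in subjects)
        hits: list[SimilarityHit] = []
        for q in queries:
            for s in subjects:
                hit = self._align_pair(q, s, m, n)
                if hit is not None:
                    hits.append(hit)
        return hits

    def _align_pair(
        self, q: SequenceRecord, s: SequenceRecord, m: int, n: int
    ) -> SimilarityHit | None:
        qseq = _sanitize(q.sequence)
        sseq = _sanitize(s.sequence)
        score = self._aligner.score(qseq, sseq)
        if score <= 0:
            return None
        aln = self._aligner.align(qseq, sseq)[0]
        qa, sa = aln[0], aln[1]
        length = len(qa)
        identities = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
        gaps = sum(1 for a, b in zip(qa, sa) if a == "-" or b == "-")
        mismatches = length - identities - gaps
        gap_opens = _count_gap_opens(qa) + _count_gap_opens(sa)
        qblocks, sblocks = aln.aligned
        q_start = int(qblocks[0][0]) + 1
        q_end = int(qblocks[-1][1])
        s_start = int(sblocks[0][0]) + 1
        s_end = int(sblocks[-1][1])
        bitscore = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
        evalue = m * n * 2.0 ** (-bitscore)
        return SimilarityHit(
            query_id=q.seq_id,
            subject_id=s.seq_id,
            pident=100.0 * identities / length if length else 0.0,
            aln_length=length,
            mismatches=mismatches,
            gap_opens=gap_opens,
            q_start=q_start,
            q_end=q_end,
            s_start=s_start,
            s_end=s_end,
            evalue=evalue,
            bitscore=bitscore,
        )


def _warn_if_empty(rec: SequenceRecord) -> bool:
    if not rec.sequence:
        logger.warning("skipping empty sequence %s", rec.seq_id)
        return False
    return True


def _sanitize(pep: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X."""
    alphabet = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in alphabet else "X" for c in pep.upper())


def _count_gap_opens(row: str) -> int:
    opens = 0
    in_gap = False
    for c in row:
        if c == "-":
            if not in_gap:
                opens += 1
            in_gap = True
        else:
            in_gap = False
    return opens


class ExternalEngine(SearchEngine):
    """Adapter around `diamond blastp` or NCBI `blastp` (tabular outfmt 6)."""

    def __init__(self, binary: str = "diamond", evalue_ceiling: float = 10.0) -> None:
        if shutil.which(binary) is None and shutil.which(
            {"diamond": "blastp", "blastp": "diamond"}.get(binary, binary)
        ) is None:
            raise ValidationError(f"search binary {binary!r} not found on PATH")
        if shutil.which(binary) is None:
            binary = "blastp" if binary == "diamond" else "diamond"
        self.binary = binary
        self.name = binary
        self.evalue_ceiling = evalue_ceiling
        self.version = self._probe_version()

    def _probe_version(self) -> str:
        try:
            out = subprocess.run(
                [self.binary, "-version" if self.binary == "blastp" else "version"],
                capture_output=True,
                text=True,
                check=False,
            )
            return out.stdout.strip().splitlines()[0] if out.stdout else "unknown"
        except OSError:
            return "unknown"

    def search(
        self,
        queries: Sequence[SequenceRecord],
        subjects: Sequence[SequenceRecord],
    ) -> list[SimilarityHit]:
        if not queries or not subjects:
            raise ValidationError("search requires non-empty query and subject sets")
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            qf, sf, out = tmp / "q.fasta", tmp / "s.fasta", tmp / "hits.tsv"
            write_fasta(queries, qf)
            write_fasta(subjects, sf)
            if self.binary == "diamond":
                db = tmp / "db"
                subprocess.run(
                    ["diamond", "makedb", "--in", str(sf), "-d", str(db)],
                    check=True,
                    capture_output=True,
                )
                subprocess.run(
                    [
                        "diamond", "blastp", "-q", str(qf), "-d", str(db),
                        "-o", str(out), "--outfmt", "6",
                        "-e", str(self.evalue_ceiling),
                    ],
                    check=True,
                    capture_output=True,
                )
            else:
                db = tmp / "subjdb"
                subprocess.run(
                    ["makeblastdb", "-in", str(sf), "-dbtype", "prot",
                     "-out", str(db)],
                    check=True,
                    capture_output=True,
                )
                subprocess.run(
                    ["blastp", "-query", str(qf), "-db", str(db),
                     "-out", str(out), "-outfmt", "6",
                     "-evalue", str(self.evalue_ceiling)],
                    check=True,
                    capture_output=True,
                )
            return parse_tabular6(out)


def collect_candidate_orthologs(
    candidate_ids_by_species: Mapping[str, Sequence[str]],
    proteomes: Mapping[str, Sequence[SequenceRecord]],
    engine: SearchEngine,
    params: PipelineParams | None = None,
) -> tuple[list[SequenceRecord], set[str]]:
    """Collect coexpression candidates plus their cross-species matches.

    All candidate peptides serve as queries against every species'
    proteome; subjects of hits surviving :func:`filter_hits` join the
    collection.  Returns the deduplicated records (species of origin
    preserved) and the set of IDs that entered via coexpression — those
    carry the ``_coexp`` suffix in downstream FASTA output.
    """
    params = params or PipelineParams()
    by_id: dict[str, SequenceRecord] = {}
    for sp, recs in proteomes.items():
        for rec in recs:
            if rec.seq_id in by_id:
                raise ValidationError(
                    f"sequence ID {rec.seq_id!r} occurs in more than one species; "
                    "IDs must be unique across the whole dataset"
                )
            by_id[rec.seq_id] = rec

    queries: list[SequenceRecord] = []
    coexp_ids: set[str] = set()
    for sp, ids in candidate_ids_by_species.items():
        for gid in ids:
            if gid not in by_id:
                logger.warning("candidate %s has no peptide; dropped", gid)
                continue
            queries.append(by_id[gid])
            coexp_ids.add(gid)

    collected: dict[str, SequenceRecord] = {q.seq_id: q for q in queries}
    for sp, recs in proteomes.items():
        hits = filter_hits(engine.search(queries, recs), params)
        for h in hits:
            if h.subject_id not in collected:
                collected[h.subject_id] = by_id[h.subject_id]
    return list(collected.values()), coexp_ids
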