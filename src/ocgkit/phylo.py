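"""Per-OCG alignment, occupancy trimming and gene-tree inference.

Global alignment runs through MAFFT or MUSCLE when available, or through
a built-in center-star progressive aligner (pairwise global alignments
against the sequence with the highest summed similarity to all others,
merged on center coordinates) so the pipeline has no hard external
dependency.  Columns with too few residues — below 10% occupancy by
default — are trimmed before tree inference; sparse columns carry more
alignment error than signal in deep cross-species groups.  Trees come
from FastTree (-wag -nosupport), RAxML-NG (LG+G8+F) or IQ-TREE adapters,
or from built-in neighbor-joining on p-distances.  All trees are
unrooted and serialized as Newick.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .config_io import ParseError, SequenceRecord, ValidationError, write_fasta

__all__ = [
    "Alignment",
    "PhyloTree",
    "align_ocg",
    "occupancy_trim",
    "infer_tree",
    "nj_tree",
    "p_distance_matrix",
    "write_newick",
    "parse_newick",
    "write_alignment_fasta",
]

logger = logging.getLogger(__name__)


@dataclass
class Alignment:
    """A gapped peptide alignment: equal-length rows keyed by sequence ID."""

    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise ValidationError("seq_ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows have unequal lengths")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column_occupancy(self) -> np.ndarray:
        """Per-column fraction of non-gap characters."""
        if not self.rows:
            return np.zeros(0)
        mat = np.array([list(r) for r in self.rows])
        return (mat != "-").mean(axis=0)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class PhyloTree:
    """An unrooted gene tree with Newick serialization."""

    tree: dendropy.Tree

    @property
    def leaf_names(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ParseError(f"malformed Newick: {exc}") from exc
        return cls(tree=tree)


# --- alignment -------------------------------------------------------------

_GLOBAL_ALIGNER: PairwiseAligner | None = None


def _global_aligner() -> PairwiseAligner:
    global _GLOBAL_ALIGNER
    if _GLOBAL_ALIGNER is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.mode = "global"
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _GLOBAL_ALIGNER = a
    return _GLOBAL_ALIGNER


def align_ocg(
    peptides: Sequence[SequenceRecord],
    method: str = "builtin",
    binary_path: str | None = None,
) -> Alignment:
    """Globally align an OCG's peptides.

    ``method`` is one of ``mafft``, ``muscle`` (external, tool defaults)
    or ``builtin`` (center-star progressive alignment).  Degapping any
    output row recovers the corresponding input sequence exactly.
    """
    if len(peptides) < 2:
        raise ValidationError("alignment requires at least 2 sequences")
    if method == "builtin":
        return _center_star(peptides)
    if method in ("mafft", "muscle"):
        return _external_align(peptides, method, binary_path)
    raise ValidationError(f"unknown alignment method {method!r}")


def _center_star(peptides: Sequence[SequenceRecord]) -> Alignment:
    aligner = _global_aligner()
    seqs = [p.sequence for p in peptides]
    ids = [p.seq_id for p in peptides]
    k = len(seqs)
    if k == 2:
        center_idx = 0
    else:
        totals = np.zeros(k)
        for i in range(k):
            for j in range(i + 1, k):
                s = aligner.score(seqs[i], seqs[j])
                totals[i] += s
                totals[j] += s
        center_idx = int(np.argmax(totals))

    center = seqs[center_idx]
    master = center  # center row of the growing MSA
    rows: list[str] = []  # non-center rows, in insertion order
    others = [i for i in range(k) if i != center_idx]
    for idx in others:
        aln = aligner.align(center, seqs[idx])[0]
        c_pair, s_pair = aln[0], aln[1]
        master, rows, new_row = _merge(master, rows, c_pair, s_pair)
        rows.append(new_row)

    ordered_rows = []
    it = iter(rows)
    for i in range(k):
        ordered_rows.append(master if i == center_idx else next(it))
    return Alignment(seq_ids=ids, rows=ordered_rows)


def _merge(
    master: str, rows: list[str], c_pair: str, s_pair: str
) -> tuple[str, list[str], str]:
    """Merge a (center, other) pairwise alignment into the MSA.

    Walks the master center row and the pairwise center row in parallel;
    a gap present in one but not the other forces a gap column into the
    opposite side ("once a gap, always a gap").
    """
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_s: list[str] = []
    i = j = 0
    while i < len(master) or j < len(c_pair):
        m_gap = i < len(master) and master[i] == "-"
        c_gap = j < len(c_pair) and c_pair[j] == "-"
        if i < len(master) and j < len(c_pair) and not m_gap and not c_gap:
            new_master.append(master[i])
            for r, nr in zip(rows, new_rows):
                nr.append(r[i])
            new_s.append(s_pair[j])
            i += 1
            j += 1
        elif m_gap:
            new_master.append("-")
            for r, nr in zip(rows, new_rows):
                nr.append(r[i])
            new_s.append("-")
            i += 1
        else:  # c_gap or master exhausted
            new_master.append("-")
            for nr in new_rows:
                nr.append("-")
            new_s.append(s_pair[j])
            j += 1
    return (
        "".join(new_master),
        ["".join(nr) for nr in new_rows],
        "".join(new_s),
    )


def _external_align(
    peptides: Sequence[SequenceRecord], method: str, binary_path: str | None
) -> Alignment:
    binary = binary_path or method
    if shutil.which(binary) is None:
        raise ValidationError(
            f"{method} executable not found; provide its path via --{method}"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(peptides, infile)
        if method == "mafft":
            out = subprocess.run(
                [binary, "--auto", str(infile)],
                check=True,
                capture_output=True,
                text=True,
            ).stdout
        else:
            outfile = Path(tmp) / "out.fasta"
            subprocess.run(
                [binary, "-in", str(infile), "-out", str(outfile)],
                check=True,
                capture_output=True,
            )
            out = outfile.read_text()
    ids, rows = _read_fasta_text(out)
    # restore input order (aligners may reorder)
    by_id = dict(zip(ids, rows))
    return Alignment(
        seq_ids=[p.seq_id for p in peptides],
        rows=[by_id[p.seq_id] for p in peptides],
    )


def _read_fasta_text(text: str) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    rows: list[str] = []
    cur: list[str] = []
    for line in StringIO(text):
        line = line.strip()
        if line.startswith(">"):
            if ids:
                rows.append("".join(cur))
            ids.append(line[1:].split()[0])
            cur = []
        elif line:
            cur.append(line)
    if ids:
        rows.append("".join(cur))
    return ids, rows


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.seq_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


# --- trimming --------------------------------------------------------------


def occupancy_trim(aln: Alignment, occupancy_pct: float = 10.0) -> Alignment:
    """Drop columns whose non-gap fraction is below ``occupancy_pct``%.

    The boundary is inclusive (a column at exactly the cutoff is kept);
    idempotent; row order preserved.
    """
    occ = aln.column_occupancy()
    keep = occ >= occupancy_pct / 100.0
    if not keep.any():
        raise ValidationError(
            "occupancy trimming removed every column; lower --occupancy"
        )
    rows = ["".join(np.array(list(r))[keep]) for r in aln.rows]
    return Alignment(seq_ids=list(aln.seq_ids), rows=rows)


# --- tree inference --------------------------------------------------------


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise p-distances: mismatches / shared non-gap columns.

    A pair with zero shared columns gets 1.1x the maximum observed
    distance (with a warning) so NJ still runs.
    """
    mat = np.array([list(r) for r in aln.rows])
    nongap = mat != "-"
    n = aln.n_seqs
    d = np.zeros((n, n))
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            if ns == 0:
                missing.append((i, j))
                continue
            mism = int((mat[i][shared] != mat[j][shared]).sum())
            d[i, j] = d[j, i] = mism / ns
    if missing:
        fallback = d.max() * 1.1 if d.max() > 0 else 1.0
        logger.warning(
            "%d sequence pairs share no aligned columns; distance set to %.3f",
            len(missing),
            fallback,
        )
        for i, j in missing:
            d[i, j] = d[j, i] = fallback
    return d


def infer_tree(
    aln: Alignment,
    method: str = "builtin-nj",
    binary_path: str | None = None,
) -> PhyloTree:
    """Infer an unrooted gene tree from a trimmed alignment.

    ``builtin-nj`` runs neighbor-joining on p-distances; ``fasttree``
    (-wag -nosupport), ``raxml-ng`` (LG+G8+F) and ``iqtree`` (model
    selection defaults) drive the external tools.
    """
    if aln.n_seqs < 3:
        raise ValidationError("tree inference requires at least 3 sequences")
    if method == "builtin-nj":
        return _builtin_nj(aln)
    if method in ("fasttree", "raxml-ng", "iqtree"):
        return _external_tree(aln, method, binary_path)
    raise ValidationError(f"unknown tree method {method!r}")


def nj_tree(distances: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Neighbor-joining on a symmetric distance matrix (negative branch
    lengths clamped to zero)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids=list(ids))
    newick = str(nj(dm, neg_as_zero=True))
    tree = PhyloTree.from_newick(newick)
    for edge in tree.tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def _builtin_nj(aln: Alignment) -> PhyloTree:
    return nj_tree(p_distance_matrix(aln), aln.seq_ids)


def _external_tree(
    aln: Alignment, method: str, binary_path: str | None
) -> PhyloTree:
    candidates = {
        "fasttree": ["fasttree", "FastTree"],
        "raxml-ng": ["raxml-ng"],
        "iqtree": ["iqtree2", "iqtree"],
    }[method]
    binary = binary_path or next(
        (b for b in candidates if shutil.which(b)), None
    )
    if binary is None or shutil.which(binary) is None:
        raise ValidationError(f"{method} executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "aln.fasta"
        write_alignment_fasta(aln, infile)
        if method == "fasttree":
            out = subprocess.run(
                [binary, "-wag", "-nosupport", str(infile)],
                check=True,
                capture_output=True,
                text=True,
            ).stdout
            return PhyloTree.from_newick(out)
        if method == "raxml-ng":
            prefix = Path(tmp) / "rx"
            subprocess.run(
                [binary, "--msa", str(infile), "--model", "LG+G8+F",
                 "--prefix", str(prefix), "--threads", "1"],
                check=True,
                capture_output=True,
            )
            return PhyloTree.from_newick(
                Path(f"{prefix}.raxml.bestTree").read_text()
            )
        subprocess.run(
            [binary, "-s", str(infile), "-nt", "1"],
            check=True,
            capture_output=True,
        )
        return PhyloTree.from_newick(Path(f"{infile}.treefile").read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write the tree to a `.tree` file in Newick format."""
    Path(path).write_text(tree.to_newick() + "\n")


def parse_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())
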