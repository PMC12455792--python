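"""Species-specific coexpression scan.

Every gene in a species' expression matrix is correlated against every
bait gene of that species with Spearman's rank correlation (ties get
average ranks, two-sided p-value).  A gene becomes a candidate when it
clears four filters: correlation coefficient, p-value, a minimum
cumulative expression across samples (guards against technical
artifacts at trace abundance), and a per-species cap on the number of
retained genes (the strongest correlations win).  Rank correlation is
used deliberately: it also captures monotone non-linear relationships,
e.g. a transcription factor driving the pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .config_io import ExpressionMatrix, PipelineParams, ValidationError

__all__ = [
    "CoexpressionHit",
    "CandidateSet",
    "spearman",
    "cumulative_expression",
    "coexpression_scan",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexpressionHit:
    """One (gene, bait) pair surviving the correlation filters."""

    gene_id: str
    bait_id: str
    species_id: str
    r_s: float
    p_value: float
    best_r: float
    cumulative_tpm: float = float("nan")
    is_bait: bool = False


@dataclass
class CandidateSet:
    """Retained candidates of one species, one entry per gene (its best bait)."""

    species_id: str
    hits: list[CoexpressionHit] = field(default_factory=list)
    bait_ids: list[str] = field(default_factory=list)
    n_constant_skipped: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return [h.gene_id for h in self.hits]

    def best_r_of(self, gene_id: str) -> float:
        for h in self.hits:
            if h.gene_id == gene_id:
                return h.best_r
        raise KeyError(gene_id)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float] | None:
    """Spearman rank correlation with two-sided p-value.

    Returns ``None`` (a no-hit marker) when either vector is constant,
    in which case ranks carry no information and the coefficient is
    undefined; callers skip such genes rather than fail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman requires two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def cumulative_expression(matrix: ExpressionMatrix, gene_id: str) -> float:
    """Sum of a gene's TPM values over all samples."""
    return float(matrix.expression_of(gene_id).sum())


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def coexpression_scan(
    matrix: ExpressionMatrix,
    baits: Sequence[str],
    params: PipelineParams | None = None,
    adjust_p: bool = False,
) -> CandidateSet:
    """Scan one species for genes coexpressed with any bait.

    Retention requires, for at least one bait: r_s >= r_cutoff and
    p <= p_cutoff; plus cumulative TPM >= min_exp_cutoff.  Survivors are
    ranked by their best r_s over all baits (ties broken by gene ID) and
    truncated to ``numcut``.  The baits themselves are then appended as
    members (r_s = 1.0 against themselves) regardless of the filters, so
    downstream clustering always carries the pathway anchors.

    ``adjust_p`` applies a per-bait Benjamini–Hochberg correction across
    genes before the p-filter; the default is the raw two-sided p-value
    of each individual test.
    """
    params = params or PipelineParams()
    if matrix.n_samples < 3:
        raise ValidationError(
            f"{matrix.species_id}: need >= 3 samples for a correlation scan, "
            f"got {matrix.n_samples}"
        )
    bait_set = set(baits)
    for bait in baits:
        if bait not in matrix.values.index:
            raise ValidationError(
                f"bait {bait!r} absent from count table of {matrix.species_id}"
            )

    values = matrix.values.to_numpy(dtype=float)
    gene_ids = matrix.gene_ids
    bait_rows = {b: matrix.expression_of(b) for b in baits}

    n_constant = 0
    # per gene: best (r_s, bait, p) over baits, considering only baits
    # where the pair test is defined
    per_gene: dict[str, list[tuple[str, float, float]]] = {}
    for i, gene in enumerate(gene_ids):
        if gene in bait_set:
            continue
        row = values[i]
        if np.ptp(row) == 0:
            n_constant += 1
            continue
        tests = []
        for bait, brow in bait_rows.items():
            res = spearman(row, brow)
            if res is not None:
                tests.append((bait, res[0], res[1]))
        if tests:
            per_gene[gene] = tests
    if n_constant:
        logger.info(
            "%s: skipped %d constant-expression genes", matrix.species_id, n_constant
        )

    if adjust_p and per_gene:
        by_bait: dict[str, list[tuple[str, int]]] = {}
        for gene, tests in per_gene.items():
            for k, (bait, _r, _p) in enumerate(tests):
                by_bait.setdefault(bait, []).append((gene, k))
        for bait, slots in by_bait.items():
            raw = [per_gene[g][k][2] for g, k in slots]
            adj = benjamini_hochberg(raw)
            for (g, k), q in zip(slots, adj):
                b, r, _ = per_gene[g][k]
                per_gene[g][k] = (b, r, float(q))

    candidates: list[CoexpressionHit] = []
    for gene, tests in per_gene.items():
        best_r = max(r for _b, r, _p in tests)
        passing = [
            (b, r, p)
            for b, r, p in tests
            if r >= params.r_cutoff and p <= params.p_cutoff
        ]
        if not passing:
            continue
        cum = cumulative_expression(matrix, gene)
        if cum < params.min_exp_cutoff:
            continue
        # report the gene with its best passing bait
        b, r, p = max(passing, key=lambda t: (t[1], _inv(t[0])))
        candidates.append(
            CoexpressionHit(
                gene_id=gene,
                bait_id=b,
                species_id=matrix.species_id,
                r_s=r,
                p_value=p,
                best_r=best_r,
                cumulative_tpm=cum,
            )
        )

    candidates.sort(key=lambda h: (-h.best_r, h.gene_id))
    candidates = candidates[: params.numcut]

    for bait in baits:
        candidates.append(
            CoexpressionHit(
                gene_id=bait,
                bait_id=bait,
                species_id=matrix.species_id,
                r_s=1.0,
                p_value=0.0,
                best_r=1.0,
                cumulative_tpm=cumulative_expression(matrix, bait),
                is_bait=True,
            )
        )

    return CandidateSet(
        species_id=matrix.species_id,
        hits=candidates,
        bait_ids=list(baits),
        n_constant_skipped=n_constant,
    )


class _inv(str):
    """Reverses lexicographic comparison (max() picks the smaller ID on ties)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def write_candidate_table(cset: CandidateSet, path) -> None:
    """Per-species candidate TSV: gene, best bait, r_s, p, cumulative TPM."""
    with open(path, "w") as fh:
        fh.write("gene_id\tbait_id\tr_s\tp_value\tcumulative_tpm\n")
        for h in cset.hits:
            fh.write(
                f"{h.gene_id}\t{h.bait_id}\t{h.r_s:.6g}\t{h.p_value:.6g}\t"
                f"{h.cumulative_tpm:.6g}\n"
            )
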