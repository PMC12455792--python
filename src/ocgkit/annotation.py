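"""Majority-vote functional annotation of OCGs.

A random subsample of each OCG (50% by default, never below 10% and
never fewer than five sequences) is searched against a reference
peptide set, e.g. a well-annotated model-species proteome.  Each
sampled sequence votes for its best reference hit by bit score; the
modal reference wins and the fraction of votes it received is reported
as the reliability score — a unanimous OCG scores 1.0, a mixed one
proportionally less.  Sequences without any reference hit vote for the
sentinel "unannotated" so the reliability honestly reflects coverage.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .config_io import SequenceRecord, ValidationError
from .ocg import OCG, OCGMember
from .simsearch import SearchEngine

__all__ = [
    "UNANNOTATED",
    "OCGAnnotation",
    "subsample_size",
    "subsample_sequences",
    "annotate_ocg",
    "write_functional_annotation_table",
]

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class OCGAnnotation:
    ocg_label: str
    n_sampled: int
    annotation_ref_id: str
    annotation_text: str
    reliability: float


def subsample_size(n_total: int, pct: float) -> int:
    """Number of sequences to sample from an OCG of size ``n_total``.

    The percentage is floored at 10 and the resulting count at 5 (both
    capped at the population size); ceil-rounding makes the 10% floor
    binding exactly at its boundary.
    """
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    effective_pct = max(pct, 10.0)
    size = max(math.ceil(effective_pct / 100.0 * n_total), 5)
    return min(size, n_total)


def subsample_sequences(ocg: OCG, size: int, seed: int) -> list[OCGMember]:
    """Uniform sample of OCG members without replacement, reproducible per seed."""
    if size > ocg.n_total:
        raise ValidationError(
            f"sample size {size} exceeds OCG size {ocg.n_total}"
        )
    rng = random.Random(seed)
    return rng.sample(ocg.members, size)


def annotate_ocg(
    sampled: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    annotation_table: Mapping[str, str],
    engine: SearchEngine,
    ocg_label: str = "",
) -> OCGAnnotation:
    """Best-hit search of the subsample against the reference, majority vote.

    Per sampled sequence the reference with the highest bit score wins
    (ties: lexicographically smallest reference ID); the OCG annotation
    is the modal reference (same tie rule) and the reliability is its
    vote fraction.
    """
    if not sampled:
        raise ValidationError("cannot annotate an empty sample")
    if not reference:
        raise ValidationError("reference peptide set is empty")
    hits = engine.search(list(sampled), list(reference))
    best: dict[str, tuple[float, str]] = {}
    for h in hits:
        cur = best.get(h.query_id)
        cand = (h.bitscore, h.subject_id)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[h.query_id] = cand
    votes: dict[str, int] = {}
    for rec in sampled:
        ref = best.get(rec.seq_id, (0.0, UNANNOTATED))[1]
        votes[ref] = votes.get(ref, 0) + 1
    winner = min(votes, key=lambda r: (-votes[r], r))
    return OCGAnnotation(
        ocg_label=ocg_label,
        n_sampled=len(sampled),
        annotation_ref_id=winner,
        annotation_text=annotation_table.get(winner, ""),
        reliability=votes[winner] / len(sampled),
    )


def write_functional_annotation_table(
    ocgs: Sequence[OCG],
    annotations: Mapping[str, OCGAnnotation] | None,
    path: str | Path,
) -> None:
    """`functional_annotation.txt`: one row per OCG in rank order.

    When annotation was not run (no reference given) the annotation
    columns are left empty but the table is still produced.
    """
    annotations = annotations or {}
    with open(path, "w") as fh:
        fh.write(
            "label\tn_total\tn_coexp\tratio\t"
            "annotation_ref_id\tannotation_text\treliability\n"
        )
        for o in ocgs:
            a = annotations.get(o.label)
            if a is None:
                fh.write(f"{o.label}\t{o.n_total}\t{o.n_coexp}\t{o.ratio:.4f}\t\t\t\n")
            else:
                fh.write(
                    f"{o.label}\t{o.n_total}\t{o.n_coexp}\t{o.ratio:.4f}\t"
                    f"{a.annotation_ref_id}\t{a.annotation_text}\t"
                    f"{a.reliability:.4f}\n"
                )
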