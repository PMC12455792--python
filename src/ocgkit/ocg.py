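"""Orthologous Coexpressed Group (OCG) construction.

The filtered all-vs-all similarity hits over the candidate collection
define an undirected graph; its connected components are the OCGs.
Components are retained only if they are large enough (>= 10 members by
default) and contain coexpressed sequences from enough species (>= 3 by
default) — singletons and species-private clusters are likely artifacts
or lineage-specific noise.  Retained OCGs are ranked by their
coexpression ratio: groups dominated by genes found through the
expression scan (rather than pulled in purely by sequence similarity)
presumably sit closest to the pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .config_io import PipelineParams, SequenceRecord, ValidationError
from .simsearch import SimilarityHit

__all__ = [
    "OCGMember",
    "OCG",
    "build_graph",
    "connected_components",
    "filter_ocgs",
    "rank_ocgs",
    "write_ocg_fastas",
    "write_ocg_summary",
]


@dataclass(frozen=True)
class OCGMember:
    seq_id: str
    species_id: str
    is_coexp: bool
    best_r: float | None = None

    @property
    def display_id(self) -> str:
        """ID as written to per-OCG FASTA / trees: coexp members are tagged."""
        return f"{self.seq_id}_coexp" if self.is_coexp else self.seq_id


@dataclass
class OCG:
    """One connected component of the similarity graph, with coexp bookkeeping."""

    index: int
    label: str
    members: list[OCGMember] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.members)

    @property
    def n_coexp(self) -> int:
        return sum(1 for m in self.members if m.is_coexp)

    @property
    def coexp_species(self) -> set[str]:
        return {m.species_id for m in self.members if m.is_coexp}

    @property
    def ratio(self) -> float:
        return self.n_coexp / self.n_total if self.n_total else 0.0

    @property
    def member_ids(self) -> list[str]:
        return [m.seq_id for m in self.members]


def build_graph(filtered_hits: Iterable[SimilarityHit]) -> nx.Graph:
    """Build the undirected similarity graph from already-filtered hits.

    Nodes are every query and subject ID that appears in a hit; one edge
    per unordered pair with at least one surviving hit in either
    direction.  Self-loops never arise (self-hits are filtered earlier)
    but are guarded against anyway.
    """
    g = nx.Graph()
    for h in filtered_hits:
        g.add_node(h.query_id)
        g.add_node(h.subject_id)
        if h.query_id != h.subject_id:
            g.add_edge(h.query_id, h.subject_id)
    return g


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Partition the node set into connected components."""
    return [set(c) for c in nx.connected_components(graph)]


def components_to_ocgs(
    components: Iterable[set[str]],
    species_of: Mapping[str, str],
    coexp_ids: set[str],
    best_r_of: Mapping[str, float] | None = None,
) -> list[OCG]:
    """Attach membership metadata to raw components (unranked, unlabeled)."""
    best_r_of = best_r_of or {}
    ocgs = []
    for comp in components:
        members = [
            OCGMember(
                seq_id=sid,
                species_id=species_of.get(sid, ""),
                is_coexp=sid in coexp_ids,
                best_r=best_r_of.get(sid),
            )
            for sid in sorted(comp)
        ]
        ocgs.append(OCG(index=-1, label="", members=members))
    return ocgs


def filter_ocgs(ocgs: Iterable[OCG], params: PipelineParams | None = None) -> list[OCG]:
    """Retention rules: size >= min_ocg_size and coexpressed members from
    >= min_coexp_species distinct species."""
    params = params or PipelineParams()
    return [
        o
        for o in ocgs
        if o.n_total >= params.min_ocg_size
        and len(o.coexp_species) >= params.min_coexp_species
    ]


def rank_ocgs(ocgs: Sequence[OCG]) -> list[OCG]:
    """Order by coexpression ratio (desc), size (desc), then smallest
    member ID; assign zero-padded labels "0000", "0001", ... in that order."""
    ordered = sorted(
        ocgs,
        key=lambda o: (-o.ratio, -o.n_total, min(o.member_ids)),
    )
    width = max(4, len(str(max(len(ordered) - 1, 0))))
    out = []
    for i, o in enumerate(ordered):
        out.append(OCG(index=i, label=f"{i:0{width}d}", members=list(o.members)))
    return out


def write_ocg_fastas(
    ocgs: Iterable[OCG],
    sequences: Mapping[str, SequenceRecord],
    out_dir: str | Path,
) -> list[Path]:
    """One peptide FASTA per OCG (named <label>.fasta); coexpressed members
    get the "_coexp" ID suffix, all others keep their ID unmodified."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ocg in ocgs:
        path = out_dir / f"{ocg.label}.fasta"
        with open(path, "w") as fh:
            for m in ocg.members:
                if m.seq_id not in sequences:
                    raise ValidationError(
                        f"OCG {ocg.label}: no sequence for member {m.seq_id!r}"
                    )
                fh.write(f">{m.display_id}\n{sequences[m.seq_id].sequence}\n")
        paths.append(path)
    return paths


def write_ocg_summary(ocgs: Iterable[OCG], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tn_total\tn_coexp\tn_species_coexp\tratio\n")
        for o in ocgs:
            fh.write(
                f"{o.label}\t{o.n_total}\t{o.n_coexp}\t"
                f"{len(o.coexp_species)}\t{o.ratio:.4f}\n"
            )
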