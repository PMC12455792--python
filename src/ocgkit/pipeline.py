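"""End-to-end pipeline orchestration.

Runs the whole guilt-by-association workflow: load and validate inputs,
per-species coexpression scan, cross-species similarity search and
ortholog collection, graph clustering into OCGs, optional functional
annotation, per-OCG alignment / trimming / tree inference, and the
report files (docu.txt, species histogram, iTOL sidecars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotation import (
    OCGAnnotation,
    annotate_ocg,
    subsample_sequences,
    subsample_size,
    write_functional_annotation_table,
)
from .coexpression import CandidateSet, coexpression_scan, write_candidate_table
from .config_io import (
    ConfigEntry,
    ExpressionMatrix,
    PipelineParams,
    SequenceRecord,
    ValidationError,
    parse_config,
    read_annotation_table,
    read_baits,
    read_count_table,
    read_fasta,
)
from .ocg import (
    OCG,
    build_graph,
    components_to_ocgs,
    connected_components,
    filter_ocgs,
    rank_ocgs,
    write_ocg_fastas,
    write_ocg_summary,
)
from .phylo import align_ocg, infer_tree, occupancy_trim, write_alignment_fasta, write_newick
from .report import (
    species_histogram,
    write_docu,
    write_itol_coexp_annotation,
    write_itol_gradient_labels,
)
from .simsearch import (
    BuiltinEngine,
    SearchEngine,
    collect_candidate_orthologs,
    filter_hits,
    translate_cds,
)

__all__ = ["SpeciesData", "PipelineResult", "load_species", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class SpeciesData:
    """Validated inputs of one species."""

    species_id: str
    matrix: ExpressionMatrix
    cds: list[SequenceRecord]
    peptides: list[SequenceRecord]
    baits: list[str]


@dataclass
class PipelineResult:
    out_dir: Path
    candidate_sets: dict[str, CandidateSet]
    collection: list[SequenceRecord]
    coexp_ids: set[str]
    ocgs: list[OCG]
    annotations: dict[str, OCGAnnotation] = field(default_factory=dict)
    tree_paths: dict[str, Path] = field(default_factory=dict)


def load_species(entry: ConfigEntry) -> SpeciesData:
    """Load and cross-validate one species' count table, CDS and baits."""
    matrix = read_count_table(entry.tpm_path, species_id=entry.species_id)
    cds = read_fasta(entry.cds_path, species_id=entry.species_id)
    cds_ids = {r.seq_id for r in cds}
    missing = cds_ids - set(matrix.values.index)
    if missing:
        logger.warning(
            "%s: %d CDS IDs absent from count table", entry.species_id, len(missing)
        )
    baits = read_baits(
        entry.bait_path, matrix=matrix, cds_ids=cds_ids, species_id=entry.species_id
    )
    peptides = []
    for rec in cds:
        try:
            pep = translate_cds(rec.sequence)
        except ValidationError:
            logger.warning("%s: CDS %s untranslatable; dropped",
                           entry.species_id, rec.seq_id)
            continue
        peptides.append(
            SequenceRecord(rec.seq_id, pep, species_id=entry.species_id)
        )
    return SpeciesData(
        species_id=entry.species_id,
        matrix=matrix,
        cds=cds,
        peptides=peptides,
        baits=baits,
    )


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    engine: SearchEngine | None = None,
    alnmethod: str = "builtin",
    treemethod: str = "builtin-nj",
    reference_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    build_trees: bool = True,
) -> PipelineResult:
    """Run the full pipeline from a config file into ``out_dir``."""
    params = params or PipelineParams()
    engine = engine or BuiltinEngine()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = parse_config(config_path)
    species = [load_species(e) for e in entries]
    _check_global_uniqueness(species)

    # Step 1 — per-species coexpression scan
    candidate_sets: dict[str, CandidateSet] = {}
    for sp in species:
        cset = coexpression_scan(sp.matrix, sp.baits, params)
        candidate_sets[sp.species_id] = cset
        write_candidate_table(cset, out_dir / f"{sp.species_id}.candidates.tsv")
        logger.info("%s: %d candidates (incl. %d baits)",
                    sp.species_id, len(cset.hits), len(cset.bait_ids))

    # Step 2 — cross-species similarity search, ortholog collection
    proteomes = {sp.species_id: sp.peptides for sp in species}
    candidate_ids = {
        spid: cset.gene_ids for spid, cset in candidate_sets.items()
    }
    collection, coexp_ids = collect_candidate_orthologs(
        candidate_ids, proteomes, engine, params
    )
    logger.info("collected %d sequences (%d via coexpression)",
                len(collection), len(coexp_ids))

    # Step 3 — all-vs-all search over the collection, graph clustering
    hits = filter_hits(engine.search(collection, collection), params)
    graph = build_graph(hits)
    species_of = {rec.seq_id: rec.species_id for rec in collection}
    best_r = {}
    for cset in candidate_sets.values():
        for h in cset.hits:
            best_r[h.gene_id] = h.best_r
    raw = components_to_ocgs(
        connected_components(graph), species_of, coexp_ids, best_r
    )
    ocgs = rank_ocgs(filter_ocgs(raw, params))
    logger.info("%d components, %d OCGs retained", len(raw), len(ocgs))

    seq_by_id = {rec.seq_id: rec for rec in collection}
    ocg_dir = out_dir / "ocgs"
    write_ocg_fastas(ocgs, seq_by_id, ocg_dir)
    write_ocg_summary(ocgs, out_dir / "ocg_summary.tsv")

    # Step 4 — functional annotation (optional; table written regardless)
    annotations: dict[str, OCGAnnotation] = {}
    if reference_path is not None:
        reference = read_fasta(reference_path, species_id="reference")
        anno_table = (
            read_annotation_table(annotation_path) if annotation_path else {}
        )
        for ocg in ocgs:
            size = subsample_size(ocg.n_total, params.seqs_cluster_anno)
            members = subsample_sequences(ocg, size, params.seed + ocg.index)
            sampled = [seq_by_id[m.seq_id] for m in members]
            annotations[ocg.label] = annotate_ocg(
                sampled, reference, anno_table, engine, ocg_label=ocg.label
            )
    write_functional_annotation_table(
        ocgs, annotations, out_dir / "functional_annotation.txt"
    )

    # Steps 5-6 — per-OCG alignment, occupancy trimming, tree inference
    tree_paths: dict[str, Path] = {}
    if build_trees:
        tree_dir = out_dir / "trees"
        tree_dir.mkdir(exist_ok=True)
        for ocg in ocgs:
            display = [
                SequenceRecord(
                    m.display_id, seq_by_id[m.seq_id].sequence, m.species_id
                )
                for m in ocg.members
            ]
            aln = align_ocg(display, method=alnmethod)
            write_alignment_fasta(aln, tree_dir / f"{ocg.label}.aln.fasta")
            trimmed = occupancy_trim(aln, params.occupancy)
            write_alignment_fasta(
                trimmed, tree_dir / f"{ocg.label}.aln.trimmed.fasta"
            )
            tree = infer_tree(trimmed, method=treemethod)
            path = tree_dir / f"{ocg.label}.tree"
            write_newick(tree, path)
            tree_paths[ocg.label] = path
            # Step 7 — iTOL sidecar annotation files
            write_itol_coexp_annotation(
                ocg, tree_dir / f"{ocg.label}.iTOL_coexp_annotation.txt"
            )
            write_itol_gradient_labels(
                ocg,
                tree_dir / f"{ocg.label}.iTOL_gradient_labels.txt",
                r_cutoff=params.r_cutoff,
            )

    # reporting
    sample_counts = {sp.species_id: sp.matrix.n_samples for sp in species}
    species_histogram(candidate_sets, sample_counts, out_dir / "species_count_histogram")
    input_files: list[str] = [str(config_path)]
    for e in entries:
        input_files += [e.tpm_path, e.cds_path, e.bait_path]
    if reference_path is not None:
        input_files.append(str(reference_path))
    if annotation_path is not None:
        input_files.append(str(annotation_path))
    write_docu(
        out_dir / "docu.txt",
        params,
        input_files,
        tool_versions={
            "ocgkit": __version__,
            "search_engine": f"{engine.name} {engine.version}",
            "alignment": alnmethod,
            "tree": treemethod,
        },
    )

    return PipelineResult(
        out_dir=out_dir,
        candidate_sets=candidate_sets,
        collection=collection,
        coexp_ids=coexp_ids,
        ocgs=ocgs,
        annotations=annotations,
        tree_paths=tree_paths,
    )


def _check_global_uniqueness(species: Sequence[SpeciesData]) -> None:
    seen: dict[str, str] = {}
    for sp in species:
        for rec in sp.cds:
            if rec.seq_id in seen:
                raise ValidationError(
                    f"sequence ID {rec.seq_id!r} occurs in both "
                    f"{seen[rec.seq_id]} and {sp.species_id}; prefix IDs with "
                    "the species ID to disambiguate"
                )
            seen[rec.seq_id] = sp.species_id
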