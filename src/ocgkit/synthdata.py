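"""Synthetic multi-species datasets with planted gene families.

Emulates the input structure the pipeline expects from real data:
several species, each with a gene set partitioned into orthologous
families detectable by protein similarity (high within-family, low
between-family identity), of which a subset — the planted pathway
module — is coexpressed with a bait gene across RNA-seq samples, the
rest serving as uncorrelated background.  Expression of pathway genes
is built as monotone transforms of a latent per-species pathway
activity trajectory with multiplicative log-normal noise, so the target
Spearman correlation level is controlled directly (rank correlation is
invariant under the monotone transform; only the noise erodes it).
Truth tables (family membership, pathway membership) are written
alongside the dataset for end-to-end assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config_io import ConfigEntry, ExpressionMatrix, SequenceRecord, write_config

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_families",
           "generate_expression", "emit_dataset"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid keeps back-translation simple and stop-free
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard benchmark: 5 species, 12 orthologous
    families of 2 copies per species (10 members each), 4 of them
    forming the coexpressed pathway module, 50 RNA-seq samples per
    species, ~90% within-family peptide identity and mild log-normal
    expression noise.
    """

    n_species: int = 5
    n_families: int = 12
    family_size_range: tuple[int, int] = (2, 2)
    pathway_families: tuple[int, ...] = (0, 1, 2, 3)
    n_samples_per_species: int = 50
    within_family_identity: float = 90.0
    between_family_identity: float = 30.0
    module_correlation: float = 0.9
    background_correlation: float = 0.3
    noise_sd: float = 0.1
    min_protein_len: int = 150
    max_protein_len: int = 300
    min_cumulative_tpm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if max(self.pathway_families, default=-1) >= self.n_families:
            raise ValueError("pathway family index out of range")
        if self.within_family_identity - self.between_family_identity < 40:
            raise ValueError(
                "within-family identity must exceed between-family by >= 40 points"
            )

    def species_ids(self) -> list[str]:
        return [f"sp{i:02d}" for i in range(self.n_species)]


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    spec: SyntheticSpec
    cds: dict[str, list[SequenceRecord]]  # species -> CDS records
    matrices: dict[str, ExpressionMatrix]
    baits: dict[str, list[str]]
    reference: list[SequenceRecord]  # ancestral peptides, one per family
    annotation: dict[str, str]
    family_of: dict[str, int]  # seq_id -> family index
    pathway_ids: set[str] = field(default_factory=set)

    @property
    def pathway_family_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {f: set() for f in self.spec.pathway_families}
        for sid, fam in self.family_of.items():
            if fam in out:
                out[fam].add(sid)
        return out


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(rate * length) positions (chosen at random).

    Fixing the count rather than drawing per-residue keeps realized
    family identities tightly around their target, so the similarity
    filters behave predictably on planted families.
    """
    out = list(protein)
    k = int(round(rate * len(out)))
    for pos in rng.choice(len(out), size=k, replace=False):
        choices = AMINO_ACIDS.replace(out[pos], "")
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _back_translate(protein: str) -> str:
    return "".join(_CODON_OF[aa] for aa in protein) + "TAA"


def generate_families(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[SequenceRecord]], dict[str, int], list[SequenceRecord]]:
    """Plant orthologous families: one random ancestral protein per family,
    mutated independently per member to the target within-family identity.

    Returns (per-species CDS records, seq_id -> family truth table,
    ancestral reference peptides).
    """
    rng = rng or np.random.default_rng(spec.seed)
    # each member diverges from the ancestor by half the target pairwise
    # divergence, so two members differ by ~ (100 - within_identity)%
    branch_rate = (100.0 - spec.within_family_identity) / 200.0
    cds: dict[str, list[SequenceRecord]] = {sp: [] for sp in spec.species_ids()}
    family_of: dict[str, int] = {}
    reference: list[SequenceRecord] = []
    for fam in range(spec.n_families):
        length = int(rng.integers(spec.min_protein_len, spec.max_protein_len + 1))
        ancestor = "".join(
            AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)
        )
        reference.append(
            SequenceRecord(seq_id=f"REF{fam:02d}", sequence=ancestor, species_id="ref")
        )
        lo, hi = spec.family_size_range
        for sp in spec.species_ids():
            n_copies = int(rng.integers(lo, hi + 1))
            for copy in range(n_copies):
                protein = _mutate_protein(ancestor, branch_rate, rng)
                seq_id = f"{sp}_fam{fam:02d}_{copy}"
                cds[sp].append(
                    SequenceRecord(
                        seq_id=seq_id,
                        sequence=_back_translate(protein),
                        species_id=sp,
                    )
                )
                family_of[seq_id] = fam
    return cds, family_of, reference


def generate_expression(
    spec: SyntheticSpec,
    cds: dict[str, list[SequenceRecord]],
    family_of: dict[str, int],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ExpressionMatrix], dict[str, list[str]]]:
    """Simulate TPM tables: pathway genes track a latent activity
    trajectory through monotone transforms, background genes are
    independent log-normal draws.  One pathway gene per species is
    designated bait."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    pathway = set(spec.pathway_families)
    n = spec.n_samples_per_species
    matrices: dict[str, ExpressionMatrix] = {}
    baits: dict[str, list[str]] = {}
    for sp in spec.species_ids():
        trajectory = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        rows = {}
        bait_id = None
        for rec in cds[sp]:
            fam = family_of[rec.seq_id]
            if fam in pathway:
                amp = rng.uniform(2.0, 10.0)
                power = rng.uniform(0.7, 1.5)
                noise = np.exp(rng.normal(0.0, spec.noise_sd, size=n))
                values = amp * trajectory**power * noise
                if values.sum() < spec.min_cumulative_tpm:
                    values *= spec.min_cumulative_tpm / values.sum() * 1.5
                if bait_id is None and fam == spec.pathway_families[0]:
                    bait_id = rec.seq_id
            else:
                values = rng.lognormal(mean=0.5, sigma=1.0, size=n)
            rows[rec.seq_id] = np.round(values, 4)
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"S{j:03d}" for j in range(n)]
        )
        matrices[sp] = ExpressionMatrix(species_id=sp, values=df)
        baits[sp] = [bait_id] if bait_id else []
    return matrices, baits


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full in-memory dataset for one spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    cds, family_of, reference = generate_families(spec, rng)
    matrices, baits = generate_expression(spec, cds, family_of, rng)
    annotation = {
        f"REF{fam:02d}": (
            f"pathway enzyme family {fam}"
            if fam in spec.pathway_families
            else f"background protein family {fam}"
        )
        for fam in range(spec.n_families)
    }
    pathway_ids = {
        sid for sid, fam in family_of.items() if fam in spec.pathway_families
    }
    return SyntheticDataset(
        spec=spec,
        cds=cds,
        matrices=matrices,
        baits=baits,
        reference=reference,
        annotation=annotation,
        family_of=family_of,
        pathway_ids=pathway_ids,
    )


def emit_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write a complete, valid pipeline input directory.

    Produces the config file, per-species TPM tables / CDS FASTAs / bait
    lists, the reference peptide FASTA + annotation table, and the truth
    tables (family and pathway membership) used by assertions.
    Returns the path to the config file.
    """
    ds = generate_dataset(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sp in spec.species_ids():
        tpm = out_dir / f"{sp}.tpm.tsv"
        ds.matrices[sp].values.to_csv(tpm, sep="\t", float_format="%.4f")
        cds_path = out_dir / f"{sp}.cds.fasta"
        with open(cds_path, "w") as fh:
            for rec in ds.cds[sp]:
                fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
        bait_path = out_dir / f"{sp}.baits.txt"
        bait_path.write_text("".join(b + "\n" for b in ds.baits[sp]))
        entries.append(ConfigEntry(sp, str(tpm), str(cds_path), str(bait_path)))
    config_path = out_dir / "config.csv"
    write_config(entries, config_path)

    with open(out_dir / "reference.fasta", "w") as fh:
        for rec in ds.reference:
            fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
    with open(out_dir / "annotation.tsv", "w") as fh:
        for ref_id, text in ds.annotation.items():
            fh.write(f"{ref_id}\t{text}\n")
    with open(out_dir / "truth_families.tsv", "w") as fh:
        fh.write("seq_id\tfamily\n")
        for sid in sorted(ds.family_of):
            fh.write(f"{sid}\t{ds.family_of[sid]}\n")
    with open(out_dir / "truth_pathway.tsv", "w") as fh:
        fh.write("seq_id\n")
        for sid in sorted(ds.pathway_ids):
            fh.write(f"{sid}\n")
    return config_path
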