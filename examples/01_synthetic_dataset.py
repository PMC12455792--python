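"""Generate a synthetic multi-species dataset with planted gene families.

Builds the default study: 5 species, 12 orthologous families (2 copies
per species), of which families 0-3 form a coexpressed pathway module
tracking a latent activity trajectory; one pathway gene per species is
the bait.  The emitted directory is a complete pipeline input, plus
truth tables for checking recovery.
"""

from pathlib import Path

from ocgkit.synthdata import SyntheticSpec, emit_dataset

out = Path("scratch/example_dataset")
spec = SyntheticSpec(seed=1)
config = emit_dataset(spec, out)

print(f"config file : {config}")
print(f"species     : {spec.n_species}, families: {spec.n_families} "
      f"(pathway: {len(spec.pathway_families)})")
print(f"samples     : {spec.n_samples_per_species} per species")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
print("Each species contributes a TPM table, a CDS FASTA and a bait list;")
print("truth_*.tsv map every sequence to its planted family / pathway role.")
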