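"""Shared fixtures: one synthetic dataset and one full pipeline run,
generated once per session and reused by every test that needs them."""

from __future__ import annotations

import pytest
from hypothesis import settings

from ocgkit.pipeline import PipelineResult, run_pipeline
from ocgkit.synthdata import SyntheticSpec, emit_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

SESSION_SEED = 7


@pytest.fixture(scope="session")
def synth_spec() -> SyntheticSpec:
    """The default study conditions: 5 species, 12 families (4 pathway),
    2 copies per family per species, 50 samples."""
    return SyntheticSpec(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory, synth_spec):
    out = tmp_path_factory.mktemp("synth")
    config = emit_dataset(synth_spec, out)
    return out, config


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory, synth_dir) -> PipelineResult:
    ds_dir, config = synth_dir
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(
        config,
        out,
        reference_path=ds_dir / "reference.fasta",
        annotation_path=ds_dir / "annotation.tsv",
    )


@pytest.fixture(scope="session")
def truth_tables(synth_dir):
    """Ground truth: seq_id -> family index, and the pathway member set."""
    ds_dir, _ = synth_dir
    family_of = {}
    with open(ds_dir / "truth_families.tsv") as fh:
        next(fh)
        for line in fh:
            sid, fam = line.split()
            family_of[sid] = int(fam)
    with open(ds_dir / "truth_pathway.tsv") as fh:
        next(fh)
        pathway = {line.strip() for line in fh if line.strip()}
    return family_of, pathway
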