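"""Run provenance, species histogram and iTOL sidecar files.

`docu.txt` records everything needed to reproduce a run: tool version,
every parameter, engine versions and an MD5 digest of every input file.
The species histogram reports, per species, both the number of RNA-seq
samples and the number of coexpressed sequences retrieved — a species
with few samples and a weak coexpression signal is likely
underrepresented, not uninvolved.  For every OCG tree two iTOL dataset
files are emitted: a binary dataset marking the "_coexp"-tagged leaves
and a gradient dataset coloring each coexpressed leaf by its best
correlation coefficient.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .config_io import PipelineParams
from .coexpression import CandidateSet
from .ocg import OCG

__all__ = [
    "compute_md5",
    "write_docu",
    "parse_docu",
    "species_histogram",
    "write_itol_coexp_annotation",
    "write_itol_gradient_labels",
]


def compute_md5(path: str | Path) -> str:
    """MD5 hex digest of a file's raw bytes."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_docu(
    path: str | Path,
    params: PipelineParams,
    input_files: Sequence[str | Path],
    tool_versions: Mapping[str, str],
) -> None:
    """Write `docu.txt`: version, parameters, tool versions, input MD5s."""
    with open(path, "w") as fh:
        fh.write(f"tool_version\t{__version__}\n")
        for key, value in asdict(params).items():
            fh.write(f"param:{key}\t{value}\n")
        for name, version in sorted(tool_versions.items()):
            fh.write(f"tool:{name}\t{version}\n")
        for f in input_files:
            fh.write(f"input:{f}\t{compute_md5(f)}\n")


def parse_docu(path: str | Path) -> dict[str, dict[str, str]]:
    """Read `docu.txt` back into {params, tools, inputs, meta} sections."""
    out: dict[str, dict[str, str]] = {
        "params": {},
        "tools": {},
        "inputs": {},
        "meta": {},
    }
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            if key.startswith("param:"):
                out["params"][key[6:]] = value
            elif key.startswith("tool:"):
                out["tools"][key[5:]] = value
            elif key.startswith("input:"):
                out["inputs"][key[6:]] = value
            else:
                out["meta"][key] = value
    return out


def species_histogram(
    candidate_sets: Mapping[str, CandidateSet],
    sample_counts: Mapping[str, int],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Per-species sample counts and coexpressed-sequence counts.

    Writes the numbers to `<prefix>.tsv` and a self-contained SVG bar
    chart to `<prefix>.html` (presentation only — the TSV is
    authoritative).  Species with zero candidates are included, so
    underrepresentation stays visible.
    """
    out_prefix = Path(out_prefix)
    species = sorted(set(sample_counts) | set(candidate_sets))
    rows = []
    for sp in species:
        cs = candidate_sets.get(sp)
        n_coexp = len(cs.hits) if cs else 0
        rows.append((sp, int(sample_counts.get(sp, 0)), n_coexp))

    tsv_path = out_prefix.with_suffix(".tsv")
    with open(tsv_path, "w") as fh:
        fh.write("species_id\tn_samples\tn_coexpressed\n")
        for sp, ns, nc in rows:
            fh.write(f"{sp}\t{ns}\t{nc}\n")

    html_path = out_prefix.with_suffix(".html")
    max_val = max([v for _, ns, nc in rows for v in (ns, nc)] + [1])
    bar_w, gap, height = 28, 14, 220
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Species histogram</title></head><body>",
        "<h2>Samples and coexpressed sequences per species</h2>",
        f"<svg width='{len(rows) * (2 * bar_w + gap) + gap}' "
        f"height='{height + 60}'>",
    ]
    for i, (sp, ns, nc) in enumerate(rows):
        x = gap + i * (2 * bar_w + gap)
        for k, (val, color) in enumerate([(ns, "#4c78a8"), (nc, "#f58518")]):
            h = round(height * val / max_val)
            parts.append(
                f"<rect class='bar' x='{x + k * bar_w}' y='{height - h + 10}' "
                f"width='{bar_w - 2}' height='{h}' fill='{color}'>"
                f"<title>{sp}: {val}</title></rect>"
            )
        parts.append(
            f"<text x='{x}' y='{height + 28}' font-size='10'>{sp}</text>"
        )
    parts.append(
        "</svg><p>Blue: RNA-seq samples; orange: coexpressed sequences.</p>"
        "</body></html>"
    )
    html_path.write_text("\n".join(parts))
    return tsv_path, html_path


def write_itol_coexp_annotation(ocg: OCG, path: str | Path) -> None:
    """iTOL binary dataset marking every "_coexp"-tagged leaf of the tree."""
    with open(path, "w") as fh:
        fh.write("DATASET_BINARY\n")
        fh.write("SEPARATOR COMMA\n")
        fh.write(f"DATASET_LABEL,coexpressed members OCG {ocg.label}\n")
        fh.write("COLOR,#f58518\n")
        fh.write("FIELD_SHAPES,2\n")
        fh.write("FIELD_LABELS,coexp\n")
        fh.write("DATA\n")
        for m in ocg.members:
            if m.is_coexp:
                fh.write(f"{m.display_id},1\n")


def write_itol_gradient_labels(
    ocg: OCG, path: str | Path, r_cutoff: float = 0.7
) -> None:
    """iTOL gradient dataset: each coexpressed leaf colored by its best r_s.

    The color scale is anchored at [r_cutoff, 1.0], the attainable range
    of retained correlations; similarity-search orthologs have no
    correlation value and receive no entry.
    """
    with open(path, "w") as fh:
        fh.write("DATASET_GRADIENT\n")
        fh.write("SEPARATOR COMMA\n")
        fh.write(f"DATASET_LABEL,best Spearman r OCG {ocg.label}\n")
        fh.write("COLOR,#4c78a8\n")
        fh.write("COLOR_MIN,#ffffcc\n")
        fh.write("COLOR_MAX,#800026\n")
        fh.write(f"USER_MIN_VALUE,{r_cutoff}\n")
        fh.write("USER_MAX_VALUE,1.0\n")
        fh.write("DATA\n")
        for m in ocg.members:
            if m.is_coexp and m.best_r is not None:
                fh.write(f"{m.display_id},{m.best_r:.4f}\n")
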