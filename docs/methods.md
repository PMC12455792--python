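# Methods

## Pipeline model and assumptions

ocgkit implements guilt-by-association candidate discovery with an
evolutionary filter. The underlying assumptions are: (i) genes of one
biosynthetic pathway are co-regulated, so their expression profiles are
rank-correlated with a bait gene of the pathway within each species;
(ii) orthologs keep detectable protein similarity across the analyzed
species; (iii) a gene family that is *independently* coexpressed with
the pathway in several species is much more likely to act in the
pathway than a family correlated in only one species. The pipeline
therefore intersects two weak signals — within-species correlation and
cross-species similarity — and only reports groups supported by both.

Spearman rather than Pearson correlation is used throughout: rank
correlation is invariant under monotone transforms, so it also captures
saturating or accelerating responses and regulator–target
relationships. The p-value attached to each (gene, bait) pair is the
two-sided test p-value of that single correlation as computed by
`scipy.stats.spearmanr`; **no multiple-testing correction is applied by
default**. A Benjamini–Hochberg switch (`adjust_p=True` on
`coexpression_scan`) is available but off, because at the default
r ≥ 0.7 / n ≥ 30-samples operating point the coefficient filter, not
the p-filter, is binding, and because the cross-species intersection is
the real error control.

## Parameters

| parameter | default | unit / meaning |
|---|---|---|
| `r_cutoff` | 0.7 | minimum Spearman coefficient vs ≥ 1 bait (inclusive) |
| `p_cutoff` | 0.05 | maximum test p-value for that bait (inclusive) |
| `numcut` | 100 | per-species cap on retained genes, best-r first |
| `min_exp_cutoff` | 30 | minimum cumulative TPM over all samples; guards against quantification noise at trace abundance |
| `evalue_cutoff` | 1e-5 | similarity hit: e-value may equal the cutoff |
| `score_cutoff` | 100 | bit score must strictly exceed |
| `len_cutoff` | 100 | alignment columns must strictly exceed |
| `sim_cutoff` | 80 | percent identity must strictly exceed |
| `min_ocg_size` | 10 | component retention: minimum members |
| `min_coexp_species` | 3 | component retention: species with coexpressed members |
| `seqs_cluster_anno` | 50 | % of an OCG sampled for annotation; hard floor 10%, and at least 5 sequences |
| `occupancy` | 10 | % non-gap residues a column needs to survive trimming (inclusive) |
| `seed` | 42 | seeds the annotation subsample |

Inclusive vs strict boundaries follow the verbs of the parameter
documentation ("must not exceed" vs "greater than"/"surpass"); the
correlation, expression and occupancy cutoffs are read inclusively, the
conventional interpretation when no strictness is stated.

## Engines: built-in vs external

The production-grade external tools are available as adapters (DIAMOND or
NCBI blastp for search; MAFFT/MUSCLE for alignment;
FastTree `-wag -nosupport`, RAxML-NG `LG+G8+F`, IQ-TREE for trees), but
every stage also has a built-in engine so the pipeline runs and is
tested with no binaries:

- **Search** — exact Smith–Waterman local alignment (Biopython
  PairwiseAligner), BLOSUM62, gap open 11 / extend 1. Bit scores use
  the standard gapped BLOSUM62 Karlin–Altschul constants
  (λ = 0.267, K = 0.041): S′ = (λS − ln K)/ln 2, and
  e-value = m·n·2^(−S′) with m, n the total query/database residues.
  These statistics are approximate and internally consistent; built-in
  e-values are never compared against DIAMOND's. The engine is
  quadratic in sequence count — appropriate for candidate collections
  (hundreds of sequences), not whole-proteome sweeps. An integration
  test shows NCBI blastp and the built-in engine produce identical
  filtered edge sets on planted families.
- **Alignment** — center-star progressive alignment: the center is the
  sequence with maximal summed pairwise score; every other sequence is
  aligned to it globally and merged under "once a gap, always a gap".
  Degapping any row reproduces its input exactly.
- **Trees** — neighbor-joining (scikit-bio) on p-distances
  (mismatches / shared non-gap columns). A pair sharing no columns
  gets 1.1× the maximum observed distance, with a warning. Negative NJ
  branch lengths are clamped to zero. Trees are left unrooted; display
  rooting is the viewer's job.

## Numerical and tie-breaking choices

- All identifiers are cleaned by replacing characters outside
  `[A-Za-z0-9._-]` with `_` (idempotent, length-preserving), so IDs
  agree across count table, FASTA and bait list.
- Isoform reduction keeps the longest CDS per gene; equal lengths break
  to the lexicographically smallest transcript ID.
- Candidate ranking for the `numcut` truncation uses each gene's best
  r over all baits; ties break lexicographically by gene ID. The cap is
  applied per species (per coexpression analysis), and baits are
  appended afterwards, tagged r = 1, so they always reach clustering.
- Constant-expression genes (zero rank variance) are skipped, counted,
  and reported — their correlation is undefined, not zero.
- One surviving similarity hit in either direction suffices for a graph
  edge; reciprocity is not required. Self-hits are removed before graph
  construction.
- OCG ranking: coexpression ratio desc, then size desc, then smallest
  member ID; labels are zero-padded to 4 digits ("0000", "0001", ...),
  widening automatically beyond 9999. Whether baits count as
  coexpressed members in the ratio: they do, consistent with their
  `_coexp` tagging.
- Annotation: best hit per sampled sequence by bit score (ties:
  smallest reference ID); modal reference wins (ties: smallest ID).
  Sequences with no reference hit vote for the sentinel `unannotated`,
  so reliability honestly reflects annotation coverage rather than
  silently shrinking the denominator. The subsample count is
  `max(ceil(max(pct,10)/100 · n), 5)` capped at n — ceil makes the 10%
  floor binding exactly at its boundary.
- The annotation subsample seed is `seed + OCG index`, recorded in
  `docu.txt`; a rerun on unchanged inputs with built-in engines
  reproduces the summary tables byte for byte.
- `occupancy_trim` erroring out when every column falls below the
  cutoff is deliberate: a silently empty alignment would produce a
  meaningless tree.

## Synthetic data generator

`ocgkit.synthdata` emulates the structure of a real multi-species
compendium at desk scale. Defaults — the standard study conditions used
by the tests and the acceptance script — are 5 species, 12 orthologous
families with 2 copies per family per species (10-member families, so a
complete family exactly reaches the OCG size threshold), 4 families
forming the pathway module, and 50 samples per species.

- **Families**: one random ancestral protein per family (150–300 aa);
  each member substitutes exactly `round(rate·L)` positions with
  `rate = (100 − within_identity)/200`, giving pairwise identities
  tightly around the 90% target (fixed-count mutation keeps realized
  identity predictable for the similarity filters). Between-family
  sequences are independent random proteins (< 30% identity). CDS are
  back-translated with a fixed codon per amino acid plus a stop;
  substitution-only by design so alignment lengths are predictable.
- **Expression**: per species a latent log-normal pathway-activity
  trajectory; each pathway gene is `a·t^p · exp(N(0, noise_sd))` with
  random amplitude and exponent — a monotone transform, so the target
  Spearman level is controlled directly by `noise_sd` (default 0.1,
  log-scale). Background genes are independent log-normal draws. One
  pathway gene per species is the bait. Pathway cumulative TPM is
  floored at 30 so the expression filter never removes planted genes.
- **Truth tables** (family and pathway membership) are emitted next to
  the dataset for recovery scoring.

What passing on this generator does *not* show about real data: no
shared upstream regulation between pathway and background genes, no
large paralogous families blurring component boundaries, no missing
orthologs, no compositional or codon-usage structure, no read-level
noise, and expression noise that is independent across genes. Results
on real compendia depend on bait choice and sample diversity in ways
the generator does not model.

## Problem sizes

The default test and acceptance configurations (5 species × 24 genes,
50 samples; ~40 candidate peptides of 150–300 aa) were chosen so a full
pipeline run with built-in engines completes in well under a minute on
one CPU, while still exercising every stage at the retention-rule
boundaries (10-member families, 5 coexpressed species). Oracle suites
use 1000 random vectors (Spearman), 200 random additive matrices (NJ),
and exhaustive-plus-random graph sets (components).

## Known limitations

- The built-in search engine's e-values are approximate
  (Karlin–Altschul constants are fixed, not fitted) and quadratic cost
  limits it to candidate-scale inputs; use the DIAMOND/blastp adapter
  for large proteomes.
- Connected components merge any families bridged by a single
  above-threshold hit; very similar paralog lineages can coalesce into
  one OCG (no community detection is attempted — plain components are
  the model).
- Annotation is only as good as the reference proteome; functions
  absent from it come back as the sentinel or a homologous stand-in.
- The iTOL sidecar files are written for manual upload; no API client
  is included.
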