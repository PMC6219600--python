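# Methods

`polydart` implements a marker-based genome-analysis workflow for
allopolyploid Triticeae (wheat, *Aegilops* and relatives): which diploid
species donated each subgenome of an allopolyploid? The workflow consumes
genotyping-by-sequencing marker tables of two kinds — dominant SilicoDArT
markers scoring presence/absence variation (PAV) of restriction-fragment
tags, and codominant SNP markers scored 0/1/2 — and proceeds in the order
the analysis runs: call-rate filtering, species-level marker sets,
species-specific marker selection, homoeology-based analyzer selection,
diploid→polyploid retention scoring, progenitor calling, per-chromosome
profiles, and correlation-distance UPGMA clustering.

## Model and assumptions

The core assumption is set-theoretic: an allopolyploid's nuclear marker
complement is approximately the union of its diploid progenitors' marker
sets, eroded by post-polyploidization loss. A marker *specific* to one
diploid species of a panel (present there, absent in all others) is then a
tracer: the proportion of a diploid's specific markers found in a polyploid
— the *retention*, or diploid–polyploid monomorphism — estimates how much
of that diploid's genome the polyploid carries. A diploid whose retention
stands clearly above the rest is a putative subgenome donor; a set of
related diploids with near-tied retentions signals a donor that is none of
them exactly (an ancestral or extinct lineage).

Markers are treated as exchangeable and unlinked: only marginal
presence/absence enters any statistic, so linkage, marker ascertainment and
tag-alignment artefacts are outside the model.

## Filtering and marker sets

- **Call rate** (non-missing fraction per marker) is recomputed from scores
  on load; filtering keeps markers with call rate *strictly* above the
  threshold (defaults: 0.7 for SilicoDArT, 0.9 for SNPs — looser for the
  dominant markers to retain genomic coverage).
- **Species presence** uses the any-sample rule: a marker is present in a
  species if any of its samples scores 1. This matters only for species
  with multiple accessions (e.g. two bread-wheat cultivars); the rule is
  recorded in each set's provenance.
- **Absence** is policy-dependent. Default `lenient`: a missing call counts
  as absent, matching the face-value treatment of a call-rate-filtered
  binary matrix. `strict` (a sensitivity option) refuses to declare absence
  for a species with any missing call, shrinking specific sets.
- Specific percentages are reported half-up at 2 decimals; homoeology
  percentages half-up at 1 decimal, matching the conventions of the
  published summary tables the arithmetic is validated against.

## Analyzer selection by homoeology

For polyploids related to bread wheat, candidate analyzers are screened by
*homoeology*: each marker carries a chromosome label from the 21-chromosome
bread-wheat reference (1A–7D), the label's letter assigns it to the A, B or
D subgenome, and a diploid's homoeology to subgenome G is its marker count
on G as a percentage of the reference's own marker total on G. Species
reaching **at least 10%** (inclusive) on any subgenome qualify; applied to
the published count table this yields exactly 13 analyzers. "Shared" versus
"specific" within a homoeology cell is defined against the other screened
diploids (shared = present in ≥1 of them); the percentage depends only on
the total, so this interpretation does not affect selection. Markers
labelled `unassigned` are excluded from homoeology and chromosome profiles
but kept for retention and specificity.

## Progenitor calling

For one polyploid with ploidy 2m, analyzers are ranked by retention
(descending, label tie-break) and the top m fill the subgenome slots. The
requirement that a donor's retention stand clearly above the field is
operationalized as an absolute retention
margin (default 0.10): the last slot's candidate is compared with the
analyzers ranked below it, and if any lie within the margin the slot is
reported **unresolved**, listing the tied candidate set, rather than
forcing a choice. Design notes on this rule:

- Near-tied analyzers that all fit within the available slots are each
  selected — two true parents at statistically indistinguishable retention
  must not be collapsed into a tie.
- Only the boundary (last) slot can be ambiguous under an absolute margin;
  higher slots are filled by rank. `margin=0` degenerates to a pure argmax
  fill.
- An unresolved slot is the designed output for the extinct-donor scenario:
  when the true donor is not among the analyzers, no extant species stands
  out and the slot reports the near-tied field instead of an arbitrary
  winner.

Retention against an empty analyzer set is an error (flagged cell), never a
silent 0/0. Chromosome profiles recompute retention per chromosome 1–7 of a
chosen subgenome letter; buckets under `n_min = 20` markers are flagged
low-support but reported.

## Clustering

Pearson's r between raw 0/1/2 score vectors (pairwise-complete by default;
listwise optional) is transformed to d = 100(1 − r) ∈ [0, 200]. Trees are
built by classical UPGMA (cluster-size-weighted average linkage), node
height = half the merge distance, with ties broken lexicographically on the
clusters' sorted leaf labels — determinism is preferred over fidelity to
any particular tool's unspecified internals. A constant score vector makes
r undefined and raises, naming the offending pair. Newick output carries
branch lengths on the d scale at 12 significant digits.

## Synthetic data

The generator emulates the data shape the analysis assumes, at the study's
magnitudes (≈10⁴ markers per diploid, 23-species panels), since the
original raw data are not deposited:

- an ancestral pool of presence/absence markers (default 8 000) evolves
  down an ultrametric species tree; on each branch every marker is lost
  independently with probability `branch_loss_rate` (default 0.05, flat per
  branch) and a fixed count of new private markers is gained
  (`branch_gain`, default 500);
- an allopolyploid is the union of its parents' sets with independent
  per-marker loss λ (default 0.2) and a private gain (default 300); a
  per-chromosome loss override supports planted-segment experiments;
- SNP scores (0/1) flip along branches at `snp_substitution_rate` × branch
  length (clock-like, so UPGMA's ultrametric assumption holds by
  construction); a polyploid's SNP score is the parental consensus, or 2
  (heterozygous) where parents disagree;
- missing calls are injected independently at rate 0.02 at emission;
- chromosome labels are uniform over 1A–7D except terminal-branch gains,
  which are biased (0.8) toward the species' configured subgenome affinity,
  giving homoeology screens the structure they expect.

The preset panel (`triticeae_like_config`) has 11 visible diploids in 5
sections plus one hidden diploid `H` attached at a polytomy inside the
S-section radiation, and 12 polyploids: 7 with visible parents (one
hexaploid doubling as the homoeology reference) and 5 descending from `H`,
which is pruned before emission. Because `H` is equidistant from S1–S3, no
extant species monopolizes sharing with it and its subgenome surfaces as an
unresolved slot — the designed stress test for the extinct-donor behaviour.

What the generator does **not** emulate: linkage and segmental inheritance,
ascertainment bias of the genotyping platform, heterozygous SNP calls in
diploids, reference-alignment errors in chromosome assignment, and
introgression. Passing tests therefore demonstrate correctness of the
inference machinery under the stated union-with-loss model, not robustness
to those real-data complications.

## Numerical and procedural choices

- Rounding of published-style percentages is decimal half-up (not banker's),
  at the table-specific precision.
- Missing scores are NaN in float matrices; `-` or an empty cell on read,
  `-` on write. Only the one-row SNP dialect is read; a two-row export is
  rejected with an explicit error.
- Unknown chromosome labels map to `unassigned` with a warning, not an
  error.
- UPGMA inter-cluster distances use the Lance–Williams weighted-average
  update; the test oracle recomputes them as direct means over original
  leaf pairs, an independent route to the same quantity.
- Problem sizes in tests and the acceptance script (100 replicates of the
  preset panel for progenitor recovery, 20 for tree recovery, 50 random
  8-leaf matrices for the UPGMA oracle) were chosen to give stable
  pass/fail behaviour at the stated ≥95% thresholds.

## Known limitations

- Homoeology requires reference-aligned chromosome labels; panels genotyped
  on a different reference need relabelling upstream.
- The margin rule is absolute; for retention values near 0 or 1 a relative
  or variance-aware criterion might discriminate better.
- The published cross-genome monomorphism percentages (72/94/90/84%) are
  not reproducible without the study's raw SNP data; the operation is
  validated on constructed examples only.
- Species with a single accession make species-level and per-sample
  clustering identical; the package clusters per sample and leaves
  consensus construction to the caller.
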