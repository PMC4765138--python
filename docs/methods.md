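# Methods

This note documents the models, algorithms and numerical choices behind
`treegraft`, and what the synthetic-data generator does and does not
emulate.

## The grafting model

The package assumes two marker genes sequenced from the same organisms: a
conserved **foundation** marker whose alignment is reliable across all
taxa of interest (e.g., fungal 18S rRNA), and a fast **extension** marker
that is only alignable within closely related groups (e.g., ITS). Genus
names are the join key: foundation-tree tips are labeled by genus, each
extension tree carries one consensus genus, and grafting replaces the
matching tip with the extension tree's root.

Two deliberate simplifications define the model's scope:

- **No branch-length scaling.** Extension branch lengths are in the fast
  marker's substitution units and foundation lengths in the slow marker's;
  they are combined as-is. Calibrating a rate ratio between markers would
  require external information the inputs do not carry. Downstream metrics
  therefore mix two molecular clocks; the per-edge provenance tags
  (`foundation` / `extension` / `junction`) and `zero_branch_lengths` let a
  user quantify how much each marker's lengths contribute.
- **Junction policy = inherit.** The edge that led to the replaced tip
  keeps its foundation branch length, preserving the foundation tree's
  depth structure. Any other convention (zero, average) would change
  UniFrac values only through these few edges; "inherit" is the least
  surprising choice and is tagged `junction` so it can be ablated.

Grafting is local by construction: the topology induced on ungrafted tips
is exactly the foundation topology (property-tested), and the total branch
length of the hybrid tree equals foundation total (minus replaced tip
edges, plus identical inherited junction edges) plus extension totals.

Unmatched extension genera are excluded and logged, not attached at the
root: a root attachment would add spurious deep branches shared by no
foundation lineage and distort UniFrac. Ungrafted foundation tips are
kept by default (after `filter_table_to_tree` they never carry counts, so
they only contribute to unweighted UniFrac denominators through edges no
sample touches — i.e., not at all); `prune_ungrafted` removes them.

## Foundation stage

- **Column filter.** Gap fraction counts `-` and `.`; entropy is the
  Shannon entropy (bits) of A/C/G/T frequencies among unambiguous,
  non-gap characters, so a conserved column scores 0 and a uniformly
  variable column 2. Defaults: `max_gap_fraction = 0.90` and
  `entropy_quantile = 0.90` (keep the 90 % lowest-entropy columns). These
  defaults target real rRNA reference alignments, which are dominated by
  gappy, noisy columns with a broad entropy distribution. On a *clean*
  low-divergence alignment the quantile criterion is counterproductive:
  when fewer than 10 % of columns vary at all, the 0.90 quantile sits at
  0 bits and the filter removes exactly the informative columns. The
  recovery tests and the acceptance script therefore disable the entropy
  criterion (`max_entropy = 2` bits, vacuous) on fixture data. Both
  criteria are ordinary keyword parameters; exactly one entropy mode is
  active at a time and the build report records resolved values.
- **Representatives.** One sequence per genus: longest after removing
  gaps, ties to the lexicographically smallest accession. The choice is
  recorded in the build report.
- **JC69 distances.** Pairwise deletion of gaps/ambiguities;
  d = −(3/4)·ln(1 − (4/3)p). At saturation (p ≥ 3/4) the formula
  diverges, so the distance is set to a configurable ceiling (default
  5.0 substitutions/site) and the pair is recorded in the report — NJ
  needs finite inputs, and 5.0 is far beyond any resolvable distance.
- **Neighbor joining.** Standard Saitou–Nei with Q-matrix selection.
  Determinism: ties in Q are broken by the lexicographically smallest
  pair of cluster labels, a cluster being labeled by the smallest tip id
  it contains. Negative branch-length estimates are clamped to 0. The
  final edge is split at its midpoint, yielding a rooted binary tree;
  the rooting is arbitrary (NJ estimates an unrooted tree) and all
  topology tests compare unrooted splits. On additive matrices the
  unrooted topology is exact (verified on 500 random instances).
  An `external_tree_cmd` hook substitutes any program that reads aligned
  FASTA on stdin and writes Newick to stdout (FastTree works as-is).

## Extension stage

- **Percent identity** comes from a global Needleman–Wunsch alignment
  (match +1, mismatch −1, gap open −2, gap extend −1, via Biopython);
  identity = identities / alignment length, so gap columns count against
  identity. A `gap_excluded_identity` switch divides by aligned columns
  only. Dedicated clustering tools define identity in their own ways;
  results from such tools can be injected verbatim via
  `external_otu_map`.
- **Greedy clustering** visits sequences by decreasing ungapped length
  (ties by ascending id); each sequence joins the first seed (in
  seed-creation order) within the identity threshold (default 0.97), else
  founds a cluster. Because the visiting order is canonical, the
  partition is invariant to input order, and at threshold 1.0 clusters
  are exactly the sets of identical sequences.
- **Consensus genus** is a qualifying majority (default fraction 0.51)
  over *all* OTU members; unidentified members count in the denominator
  only. An OTU dominated by unannotated sequences resolves to nothing and
  is dropped with its members listed — silently guessing a minority genus
  would place sequences on the wrong subtree.
- **Center-star alignment** picks the sequence with the highest summed
  identity to the rest as the center and merges the pairwise alignments
  under "once a gap, always a gap". For the nearly identical sequences
  inside one genus group this is close to optimal; for divergent inputs a
  dedicated MSA program should be plugged in through
  `external_align_cmd` (stdin FASTA in, aligned FASTA out).

## Diversity layer

- **UniFrac** is computed from a tip-to-edge incidence matrix: one
  postorder pass collects each edge's descendant tip mask, a single
  matrix product gives per-sample per-edge descendant counts, and each
  variant is an edge-length-weighted sum. Unweighted:
  Σ l·|1_A − 1_B| / Σ l·1_{A∪B}; a pair sharing no measured branch length
  (e.g., an all-zero-length tree) is defined as distance 0. Weighted
  defaults to the **raw** (non-normalized) form Σ l·|p_A − p_B|, matching
  the classic QIIME-1 `weighted_unifrac` metric; `normalized=True`
  divides by Σ l·(p_A + p_B). Tree tips absent from the table simply
  carry no counts; table OTUs absent from the tree are an error (filter
  the table first). Agreement with a brute-force per-edge enumeration is
  tested to 1e−12, and against scikit-bio's implementation.
- **ANOSIM** uses average ranks on ties and
  R = (r̄_between − r̄_within) / (n(n−1)/4), so R ∈ [−1, 1] and perfectly
  separated groups give exactly 1. The permutation p-value uses the
  (1 + hits)/(1 + permutations) estimator — never exactly 0 — and a
  caller-supplied seed makes it reproducible. Being rank-based, R is
  invariant under any strictly monotone transform of the distances.
- **PCoA** double-centers the squared distances (B = −½·J·D²·J),
  eigendecomposes, and keeps axes with eigenvalues above a relative
  1e−10 tolerance. Negative eigenvalues (non-Euclidean input) are
  reported and excluded from the percent-explained denominator; no
  Cailliez correction is applied. Axis signs are fixed by making each
  axis's largest-magnitude loading positive.
- Jaccard and Bray–Curtis follow the usual definitions with the 0/0 → 0
  convention for all-empty sample pairs.

## Synthetic data

`make_fixture` draws a random genus tree, evolves one foundation sequence
per genus along it under JC69 (no indels — the foundation "alignment" is
therefore gap-free), draws an independent extension root per genus, and
evolves species-level extension sequences along per-genus random species
trees. Defaults: 6 genera × 4 species, 600 bp foundation / 300 bp
extension, mean root-to-tip divergence 0.05 (foundation) and 0.15
(extension) substitutions/site — the extension marker evolves faster, as
a spacer region does relative to a conserved rRNA gene. A configurable
fraction of extension sequences can be stripped of genus annotation to
exercise the consensus/drop paths.

Random tree edge lengths are drawn Uniform(0.5, 1.5) before depth
scaling, not exponentially: exponential draws routinely produce internal
edges so short that no finite sequence carries their signal, which makes
topology-recovery tests meaningless rather than stringent. Keeping every
edge bounded away from zero makes the generating topology identifiable,
so a recovery failure indicates a pipeline defect, not generator
degeneracy.

All randomness flows from one integer seed through numpy `SeedSequence`
spawning (per-genus, per-sample, per-replicate subseeds), so every
sub-result is independently reproducible.

What the fixture does **not** emulate: insertions/deletions and alignment
error, rate heterogeneity across sites, chimeras, sequencing error and
platform effects, abundance-realistic community structure, and taxonomic
mislabeling. Passing recovery tests therefore show the pipeline's
algebra and inference are correct in a regime where the truth is
recoverable — not that the defaults are tuned for any particular real
reference database.

`simsam` fabricates replicate communities: for each source sample and
replicate, every nonzero count cell moves, in full, to a tip drawn
uniformly among the tips within patristic distance d of its OTU
(including itself); counts landing together are summed, so per-sample
totals are conserved exactly. d = 0 reproduces the source; large d
approaches uniform scattering over the tree. This is a reimplementation
from the qualitative contract — replicates of one source stay
phylogenetically close to it, detectably so under the generating tree's
UniFrac — not a port of any existing simulator, so a specific d value is
comparable only within this package. The evaluation studies set d to
0.6 × the mean tip-pair patristic distance of the tree at hand.

## Problem sizes in the shipped studies

The test suite and acceptance script run at desk scale, chosen so the
statistical checks are sharp yet the whole suite completes in seconds:
500 random additive matrices (n ≤ 12) for NJ exactness, 200 random
tree/table instances (≤ 16 tips, ≤ 6 samples) for UniFrac agreement at
1e−12, 200 null replicates × 999 permutations for ANOSIM type-I-error
calibration against the exact binomial 99 % band, and 6 source × 10
replicate communities for the metric-comparison study. The pipeline
itself is quadratic in sequences per genus group and cubic in genera
(NJ), comfortable up to a few hundred taxa; genuinely large reference
databases are the domain of the external-tool hooks.

## Known limitations

- Grafting is genus-rank only; no fallback to family when a genus is
  missing from the foundation tree.
- No branch-length scaling between markers (see above) — patristic
  distances that cross a junction mix units.
- Center-star alignment and greedy clustering are reference engines for
  the closely-related regime, not replacements for dedicated MSA/OTU
  tools at scale.
- NJ provides no support values; the package does not assess topological
  uncertainty.
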