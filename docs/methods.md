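# Methods

This note documents the models and procedures behind each stage of the
pipeline, the defaults that matter, and the choices made where more than one
reasonable design existed.

## Ortholog clustering and the pan-matrix

Proteins are clustered greedily against cluster representatives, the
semantics of CD-HIT: sequences are processed longest-first (ties broken by
genome then gene id, which makes the result order-independent), and each
sequence joins the first existing cluster whose representative aligns at
identity ≥ 0.5 with coverage ≥ 0.5 **of both sequences**, else it seeds a new
cluster. Requiring coverage of both sequences (rather than the shorter only)
is the stricter reading of "alignment coverage" and prevents length-chimera
clusters; it is a deliberate choice. Alignments are global with free end
gaps, BLOSUM62, gap open 11 / extend 1 (Biopython `PairwiseAligner`);
identity is exact matches over aligned columns after trimming terminal-gap
overhang, and coverage of a sequence is its aligned span over its length, so
a tandem duplicate covers the short partner fully and the long one half.

The pan-matrix is genomes × clusters with copy-number entries. Partitioning:
core ⇔ every genome has ≥ 1 copy; unique ⇔ exactly one genome does; mosaic
is the rest. A single-genome input degenerately satisfies both definitions
and is classified core ("present in all genomes" is literally true). For a
consensus between two clustering methods, a core cluster of method A is
retained iff some core cluster of method B shares at least half of A's
members; the majority-overlap matching rule is this package's choice, since
cluster correspondence between methods is not otherwise defined. Core
deduplication keeps one gene per genome: the longest paralog, ties to the
smallest gene id.

## Pan-genome and core-genome trees

The pan-genome tree is maximum parsimony on the binarised pan-matrix
(abundance ≥ 1 → 1; an A/T text export of the same matrix is provided for
external tools but plays no computational role). The search is heuristic:
neighbor joining on Hamming distances gives the start tree, then
nearest-neighbor-interchange hill climbing under Fitch parsimony length runs
until a full sweep yields no improvement, ties between equally good
neighbours breaking on canonical Newick string order so the search is
deterministic. Parsimony length uses Hartigan's bottom-up rule, which is
exact on multifurcations (the unrooted representation has a trifurcating
root). Bootstrap supports are bipartition frequencies over column-resampled
replicates, each replicate re-analysed by the same NJ + NNI procedure;
1,000 replicates is the default, tests and the acceptance script use 200.

The core-genome tree concatenates the per-cluster protein alignments, drops
every column with a gap in any genome, then drops constant columns (mask
first, then filter variability — the order is stated because it changes the
column count), and runs neighbor joining on p-distances. This is a distance
stand-in for a full maximum-likelihood protein tree: for congruence testing
between core and pan trees the distance tree is sufficient, and ML protein
inference is outside this package's contribution. Negative NJ branch lengths
are clamped to zero with the deficit moved onto the sibling edge, preserving
path lengths.

Tree congruence is reported as the Robinson–Foulds bipartition distance plus
the K score: with b₁, b₂ the branch-length vectors over the union of
bipartitions of the two trees (splits absent from one tree entering with
length 0, trivial leaf splits included), the score is √Σ(K·b₂ − b₁)² at the
closed-form least-squares optimum K = Σb₁b₂ / Σb₂². A tree scored against a
uniformly rescaled copy of itself therefore scores exactly 0.

## Ancestral gene content (asymmetric parsimony)

Both reconstruction modes are one Sankoff dynamic program over integer
states with branch transition cost
`gain_penalty·max(0, child−parent) + loss_penalty·max(0, parent−child)`;
binary mode restricts states to {0, 1}, abundance (Wagner) mode uses
{0..max_state} with max_state = 9 by default to bound the DP (raise it if
your data has higher copy numbers — inputs above the cap are rejected with
that advice). Defaults are gain 1.6, loss 1.0: losses cheaper than gains,
the standard asymmetry for prokaryotic gene content where deletion is easier
than innovation or acquisition.

The traceback defers changes toward the leaves ("late" changes): the root
takes its minimum-cost state with ties resolved to the smallest state
(absence), and each child keeps its parent's state whenever that state is
among the minimisers of transition-plus-subtree cost. The root tie rule is
this package's documented choice — it places family origins as late as
possible, consistent with the late-change traceback.

Event accounting works on the presence view even in abundance mode: gains
are 0 → ≥1 transitions on a branch, losses ≥1 → 0, "present" counts nonzero
states per node; copy-number changes among retained families are reported
separately as expansions/contractions. The identity
present(child) = present(parent) + gains − losses holds exactly on every
branch by construction and is asserted in the tests. With equal penalties
the total event count per cluster equals the Fitch parsimony length, and DP
totals equal exhaustive enumeration over internal labelings on small trees —
both are standing test invariants.

## Recombination screening

MaxChi is implemented natively. For each sequence pair, the scan restricts
to the alignment's polymorphic columns, builds the pair's binary
match/mismatch vector, and slides a split window (default width
2·⌈√m⌉ rounded to even, m = polymorphic sites) across it; at each split the
2×2 χ² contrasts mismatch counts left vs right of the split, and the maximum
over splits is the pair's statistic. Significance comes from a permutation
null — alignment columns permuted, maximum recomputed, default 1,000
permutations — rather than the asymptotic χ², because the maximum over
splits is not χ²-distributed; p-values are Bonferroni-corrected over pairs
(the multiple-testing convention external tools leave unstated; it is
recorded in each call's metadata). The reported breakpoint is the alignment
coordinate of the best split.

The other detectors of an RDP-style battery enter via a TSV importer
(cluster_id, method, p_value, optional breakpoint; unknown columns are kept
as metadata). The consensus rule flags a cluster when at least `k_min`
distinct methods report p < α (defaults 3 and 0.05); it is monotone in both
calls and `k_min`, which is property-tested. Flagged clusters are removed
from the core list order-preservingly before downstream rate analyses.

## Pairwise dN/dS

`ng86_pair` is Nei–Gojobori (1986): per-codon synonymous potential sites as
the per-position synonymous fraction out of 3 (mutations to stop codons
count as nonsynonymous — the classic convention), site counts averaged over
the two sequences; observed differences averaged with equal weights over all
minimal substitution pathways, pathways through stop codons excluded with
renormalisation; Jukes–Cantor correction of both proportions. A saturated
correction (argument ≤ 0) leaves the distance undefined.

`yn00_pair` adds transition/transversion and codon-usage awareness: κ is
estimated by K80 from positions whose degeneracy class (fourfold or
nondegenerate) agrees between the two codons, pooling the two classes'
distance components site-weighted before taking the ratio (pooling the
ratio, not averaging two ratios, roughly halves the estimator's noise and
bias); site counting then weights each candidate change by κ (transitions)
and by the F3x4 target-codon frequency tabulated from the pair. The whole
estimate is wrapped in the convergence loop (iterate until dN and dS move
< 1e-6, flagging non-convergence), which settles as soon as the κ estimate
stabilises. At κ = 1 with uniform codon usage the weighted site counts equal
NG86's exactly, which is unit-tested; on data the residual difference is
dominated by κ-estimation noise, so agreement with NG86 is asserted on means
over seeded pairs rather than per pair.

Validity: a pair is excluded from all averages when dS < 0.1, ω ≥ 99, or
either distance is undefined (dS = 0 with dN > 0 falls under the ω ≥ 99
rule). Group averages are unweighted arithmetic means over valid pairs only,
with the valid count reported; a group with no valid pair is undefined
(NaN), never zero. Whether to weight by cluster length is not determined by
any external convention; unweighted was chosen and is stated here. The
evaluation schedule is exactly C(n_genomes, 2) × n_clusters records
(225,765 at 30 genomes × 519 clusters), enumerable without computing
alignments. Triage keeps clusters with at least one valid pair where dN
strictly exceeds dS.

## Branch-site likelihood-ratio test

The codon model is Goldman–Yang style on the 61 sense codons: single
nucleotide changes at rate π_target × κ^[transition] × ω^[nonsynonymous].
All site classes share a neutral-reference scale — one branch-length unit is
one expected substitution per codon at ω = 1 — so classes under positive
selection genuinely substitute faster rather than merely shifting the
synonymous/nonsynonymous mix; this matches what codeml-style branch lengths
mean and is used identically by the simulator and the likelihood.

Site classes: (ω₀ ≤ 1 everywhere, proportion p₀), (ω₁ = 1 everywhere, p₁),
and a foreground class (background ω₀, foreground ω₂) with ω₂ ≥ 1 free in
the alternative and pinned at 1 in the null. Likelihoods are computed by
Felsenstein pruning over the 61-codon space with per-node rescaling and
site-pattern compression; codon frequencies default to uniform. Branch
lengths are fixed from the input tree, not co-optimised — a deliberate
simplification relative to full codeml. Class proportions enter the
likelihood linearly per site and are profiled out by EM inside every outer
evaluation; the outer optimisation over (κ, ω₀[, ω₂]) uses L-BFGS-B with
bounds κ ∈ [0.2, 20], ω₀ ∈ [1e-4, 1], ω₂ ∈ [1, 50] from three seeded
starting points. The alternative fit additionally starts from the fitted
null with ω₂ = 1, so lnL₁ ≥ lnL₀ holds by construction of the search.

The test statistic is Δ = 2(lnL₁ − lnL₀) against χ²(1), small negative Δ
clamped to zero and a discrepancy beyond 1e-3 treated as an optimisation
error. χ²(1) is used without the 50:50 boundary-mixture correction — the
conventional formula — which makes the test conservative under the null
(the calibration run measures ~0% rejections at α = 0.05, comfortably under
the 10% ceiling).

## Enrichment statistics

Annotation hits survive at identity ≥ 50%, query coverage ≥ 50% and
e ≤ 1e-5; the max-bitscore hit wins per gene (ties: smaller e-value, then
lexicographic category). The gain-vs-loss test per category is the
Yates-corrected χ²,
χ² = N·(max(0, |ad−bc| − N/2))² / ((a+b)(c+d)(a+c)(b+d)),
with the two-tailed P taken as the χ²(1) upper tail (the conventional
reading for a 2×2 table, noted because the χ² statistic is one-sided by
construction). Genes appearing in both the gain and loss sets are counted in
both rows — per-node events are treated as independent observations — and
genes with no surviving annotation are excluded and their counts reported.
No multiple-testing correction is applied to the per-category battery by
default; hypergeometric gene-set enrichment offers an optional
Benjamini–Hochberg column (scipy's `false_discovery_control`).

## Pathway-profile clustering

Genome × KO abundance matrices are clustered by applying the Lance–Williams
Ward update directly to Manhattan (L1) distances between genome rows
(binarised first in presence mode). Ward's method formally presumes squared
Euclidean distances; feeding it raw L1 distances reproduces the behaviour of
the heatmap web tools that accept an arbitrary distance matrix, and that
behaviour — not variance-minimising optimality — is what this module
implements. The agglomeration is O(n³) with ties broken on the smallest
cluster-index pair, returns a scipy-compatible linkage matrix (so
`fcluster`/`dendrogram` work on it), and exports Newick and leaf-order
forms. Merge heights are non-decreasing (Ward is reducible).

## Synthetic-data generators

*Gene content.* No published generative model exists for the gain–loss
process the reconstruction assumes, so the simulator makes one explicit: a
Gillespie process per branch with exponential waiting times, where a genome
with n families gains brand-new families at rate `gain_rate·n`, loses each
family at `loss_rate`, and duplicates each at `dup_rate` (copies capped at 9
to match the Wagner DP bound). Gains never re-create a lost family, keeping
the ground truth unambiguous for reconstruction scoring. The expectation
"branch length × rate × families at risk" then applies uniformly to gains
and losses, which the Poisson bookkeeping test exploits. Family-count
conservation (child = parent + gains − losses) holds exactly by
construction. Defaults in the recovery studies: 8 leaves, 500 root families,
gain = loss = 0.3 per unit, branch lengths ~U(0.05, 0.25) — moderate
turnover under which parsimony recovers the root genome size within 15% in
at least 80% of replicates.

*Codon alignments.* Continuous-time simulation under the same normalised
rate matrices as the likelihood, with sites assigned to classes by
proportion and optional foreground branches substituting their own ω for
the last class's (the canonical branch-site class-2 reading; configurable).
Stop codons are unreachable by construction. Two-sequence studies use
branch lengths 0.2 each (dS ≈ 0.15, safely above the saturation filter);
calibration studies use 5–6 taxa, 200–300 codons, and a foreground branch
of 0.4 for the power check — sizes chosen so the whole statistical suite
runs in minutes on one CPU while leaving the tested effects detectable.

*Recombinants.* Parent A is random sequence; parent B differs per site with
probability `parent_divergence`; the recombinant copies A on even and B on
odd segments of the 0-based half-open breakpoint segmentation; clonal
controls mutate independently from A at half the parent divergence. At
divergence 0.15 a single mid-sequence breakpoint is recovered by MaxChi
within ±10% of the length in essentially all replicates.

What the generators do **not** emulate: real base composition, genome sizes
or operon structure of any particular taxon; insertion–deletion processes
(codon alignments are gap-free by construction); rate heterogeneity beyond
the declared site classes; homologous recombination within the gene-content
process. Passing tests therefore demonstrate correctness and calibration of
the algorithms under their stated models, not robustness to every
real-data pathology.

## Numerical choices and degenerate inputs

Transition probability matrices come from symmetrised eigendecomposition of
the reversible generator (exact for these models and much faster than
repeated matrix exponentials); pruning rescales conditional likelihoods per
node to avoid underflow. The Sankoff traceback compares costs with a 1e-12
tie tolerance. Jukes–Cantor saturation yields NaN distances, which propagate
to the validity flag rather than raising. Degenerate inputs fail loudly:
non-binary trees for the content simulator, taxa/leaf mismatches, abundance
above the Wagner cap, zero-margin contingency tables, empty supermatrices,
study sets outside their background.

## Known limitations

* The branch-site implementation fixes branch lengths and uses uniform codon
  frequencies by default; it is a desk-scale test, not a codeml replacement,
  and offers no Bayes-empirical-Bayes site identification.
* The greedy clusterer compares against representatives only; families whose
  members straddle the identity threshold relative to the representative can
  split (the consensus-core step exists precisely to intersect away such
  artifacts).
* Only MaxChi is implemented natively; the consensus rule is the
  contribution, and other detectors must be imported.
* The YN00-style estimator is a counting method; at high divergence or
  strong codon-usage bias a full ML pairwise estimate would be preferable.
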