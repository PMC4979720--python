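# Methods

## The test

The question is the phylogenetic *polarity* of host-use change in an
herbivore radiation: are major dietary changes concentrated at recent
speciation events (tips) or deep in the tree (root)? The statistic is

S = Σ X·H,

where X is patristic distance between two herbivore tips and H their
host-use dissimilarity, summed by default over all unordered tip pairs.
A node-based variant sums over internal nodes, with X and H averaged
over each node's cross-daughter tip pairs; it weights deep splits less
by pair count and is offered because "a sum over nodes" and "a sum over
pairs" are both natural readings of the quantity. The two modes agree in
sign in every configuration we have simulated; pairwise is the default
because the underlying signal is a pairwise distance–dissimilarity
relationship.

The null model permutes whole host repertoires (matrix rows, with any
off-tree override flag travelling along) across herbivore tips.
Permuting rows and recomputing the dissimilarity matrix is
mathematically identical to permuting the row/column indices of the
precomputed dissimilarity matrix, because each entry depends only on the
unordered pair of host sets; the implementation exploits this, making
each null draw O(n²). Permuting whole repertoires — rather than
individual incidence cells — preserves every species' host breadth and
the marginal structure of the matrix; cell-level shuffling would destroy
observed specialization and answer a different question.

Reported per family × component:

* **sign** of (S − null mean): positive ⇒ dissimilarity concentrated
  between distantly related pairs (root-ward change, conservatism);
  negative ⇒ concentrated between close relatives (tip-ward shifts).
* **SES** = (S − null mean) / null SD, with the sample (n−1) SD. SES is
  comparable across datasets of different size.
* **two-tailed p** = min(1, 2·min[(#{null ≤ S}+1), (#{null ≥ S}+1)]/(n+1)),
  the add-one permutation form, so p > 0 always and ties count toward
  both tails (conservative). The exhaustive enumeration oracle
  (`exact_null`, n ≤ 8 tips) uses the uncorrected 2·min(tail)/n! form,
  since it is a complete distribution, not a sample.
* Degenerate null (SD = 0, e.g. all host sets identical): SES is NaN,
  sign '0', p = 1.

One stream of permutations (drawn from the seed) is shared by all six
family × component tests of a run, so differences across the result row
reflect the indices rather than Monte-Carlo noise.

## Dissimilarity indices

Both families reduce a pair of host repertoires to shared/unique
components (a, b, c) and partition with the Jaccard-family formulas

total = (b+c)/(a+b+c), turnover = 2·min(b,c)/(a+2·min(b,c)),
nestedness = total − turnover.

* Jaccard: a, b, c are set cardinalities.
* Unweighted UniFrac: a, b, c are lengths of host-tree branches covered
  by both, only the first, or only the second repertoire, where a branch
  is covered if at least one repertoire member descends from it. The
  root edge is excluded (it lies above every tip). On a star tree with
  unit branches the components coincide with the Jaccard counts, which
  the suite asserts exactly; UniFrac components are also invariant to
  rescaling all host-tree branch lengths by a positive constant.

The Jaccard-family partition is applied to both families so that the
plain and phylogenetic indices decompose on the same scale. Additivity
(total = turnover + nestedness) holds to 1e-12 by construction and is
property-tested.

**Off-tree override.** A herbivore whose hosts cannot be placed on the
host phylogeny (no usable branch lengths to the rest) may be flagged per
taxon; every pair involving it is assigned turnover 1, nestedness 0,
total 1 — the maximally conservative coding for a diet that is entirely
distinct but at an unquantifiable phylogenetic distance. The flag is per
taxon rather than hard-coded so the treatment generalizes. Because the
fixed value multiplies non-negative distances, adding such a taxon can
only increase the turnover statistic (asserted in the suite).

Presence/absence only; abundance- or preference-weighted variants are a
natural extension point of `PairComponents` but are not implemented.

## Trees

Newick in/out goes through dendropy; parsing errors carry line/column
positions, duplicate tip labels are rejected by name, and labels are
normalized (trim, internal whitespace → underscores). Patristic
distances and branch-coverage masks are computed in-package with a
single postorder pass and cached as numpy arrays. A length on the root
is ignored for both distances and coverage. Polytomies are accepted;
zero-length branches are allowed with a warning (distances become a
semimetric). Pruning collapses unifurcations and sums their lengths, so
patristic distances among kept tips are preserved (tolerance 1e-9 in the
suite). Trees are used exactly as given — phylograms are not
ultrametricized, and the test nowhere assumes ultrametricity.

## Synthetic data

The generator exists to validate the test, so its regimes realize the
two competing hypotheses plus a calibration null, at the study
dimensions (13 herbivores × 20 hosts by default):

* Both trees are Yule (pure-birth) trees rescaled to height 1; the
  generator stops at the n-th speciation, so tip branches are extended
  by the Exp(n·birth) waiting time to the next unrealized event, keeping
  the tree ultrametric with no zero-length cherry.
* A focal host evolves along the insect tree. At each speciation node at
  normalized depth u, a shift event fires with probability
  shift_prob·w(u), with w(u) = u^τ (tipward) or (1−u)^τ (rootward),
  τ = shift_timing (default 2). On firing, one randomly chosen daughter
  jumps to a host drawn with probability ∝ exp((δ−δmax)/σ), δ the
  host-tree patristic distance from the current host, σ = shift_scale
  (default 0.3): a shift is a *major* dietary change, landing far from
  the current host.
* The realized repertoire is the focal host plus each other host j
  independently with probability exp(−δ(focal, j)/λ),
  λ = breadth_decay. λ = 0.48 (height-1 host tree) was calibrated once
  so that breadths span roughly 1–11 with mean ≈ 3, matching the
  motivating system; λ → 0 gives strict specialists, λ → ∞ gives full
  generalists (both asserted).
* The null regime draws each tip's focal host independently and
  uniformly, ignoring the tree entirely.

Why divergent jumps at *nodes*? Any model that places shift events along
branches with a lineage-local kernel makes the expected number of events
on a tip-to-tip path non-decreasing in path depth — the path between a
deep pair contains each tip's recent history plus more — so expected
dissimilarity can never *decrease* with phylogenetic distance and no
timing choice can yield the negative-SES pattern the tipward hypothesis
predicts. Firing at speciation nodes with a far-jump kernel breaks this:
a recently diverged pair is separated by a single near-maximal jump
(above the random-pair mean), while deep pairs mix toward the mean. In
the rootward regime the same mechanism pushes deep clades into different
host-tree regions while recent relatives inherit identical focal hosts.

What the generator does *not* emulate: geographically structured
sampling, unequal host availability, abundance-weighted preference,
extinction, and host trees that are themselves non-ultrametric
consensus phylograms. Passing tests therefore show that the test
statistic behaves correctly when its assumptions hold, not that those
assumptions hold in any particular field system.

## Validation results the suite recomputes

* Exhaustive-enumeration oracle: on random instances with ≤ 7 tips the
  Monte-Carlo two-tailed p (2,000 draws) stays within 3 binomial SEs of
  the exact p, and the statistic equals a brute-force pair sum.
* Type-I error: 1,000 null-regime datasets (n_perm = 499, Jaccard total
  — one family/component kept for a desk-scale budget): rejection rate
  at α = 0.05 inside the 95% binomial interval [0.037, 0.065], SES mean
  within ±0.1 of 0 and SD within ±0.1 of 1.
* Direction: 200 datasets per regime (UniFrac turnover, n_perm = 299):
  mean SES > 2 under rootward, < −0.2 under tipward, at the frozen
  default scenario. The tipward effect is intrinsically weaker: a
  bounded host space means anti-correlation saturates quickly, which is
  itself a known property of this class of tests.

Problem sizes above (replicate counts, permutation counts) are the
package's chosen validation scale; `scripts/acceptance.py` re-runs the
same computations from a single seed.

## Limitations

* The test detects a *pattern* (where on the tree dietary change
  concentrates), not a speciation *process*; tip-ward concentration is
  consistent with, but not proof of, host-shift-driven speciation.
* Power against the tipward alternative is modest at n = 13 (mean SES
  ≈ −0.5 under the default scenario); rejection-rate tables from
  `hostshift power` should accompany any negative claim.
* Extremely high or low host specificity across the whole radiation
  compresses the dissimilarity scale and can mask either signal.
* The node-mode statistic averages over polytomies' clade pairs; on
  heavily unresolved trees the pairwise mode is the safer default.
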