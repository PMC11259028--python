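# Methods

## The analysis in one paragraph

scnkit studies how the covariance structure of regional gray matter
volumes differs between two groups of subjects.  Each subject contributes
one volume per brain region (90 regions by convention, from an AAL-style
parcellation).  After removing linear age, sex and total-intracranial-
volume (TIV) effects by per-region regression, each group's regions are
correlated across subjects (Pearson), negatives and the diagonal are set
to zero, and the matrix is binarized at a series of matched connection
densities.  Graph-theory measures of the resulting binary networks —
clustering, path length, transitivity, global/local efficiency, and their
small-world normalizations against degree-preserving null networks — are
compared between groups by permuting subject labels.  Hub structure is
characterized by fitting an exponentially truncated power law to the
cumulative degree distribution and by simulating random-failure and
targeted-attack node deletion.

## Covariate adjustment

Volumes for region *j* are modeled as
`v_j = b0 + b1·age + b2·sex + b3·tiv + r_j` by ordinary least squares,
and the residuals `r_j` ("corrected volumes") feed the network stage.
The intercept is always included, so residuals are exactly centered and
the subsequent Pearson correlation equals the correlation of standardized
scores.  The default fitting scope is *pooled* (one model over all
subjects regardless of group); a *per-group* scope is available.  Pooled
fitting is the common convention for covariance networks and keeps the
permutation scheme coherent: adjustment is label-blind, so residuals are
exchangeable under the null and are computed once, not per permutation.
Sex enters as a 0/1 code; because residuals are invariant to affine
recoding of a covariate, the choice of which sex is 1 is irrelevant.

## Network construction

Connection density is D = E / (N(N−1)/2).  Graphs are built by **rank
thresholding**: the E* = ⌊D·N(N−1)/2 + 0.5⌋ largest positive correlations
become edges (nearest-integer edge count, exact halves rounding up).
Rank selection, unlike an absolute r cutoff, guarantees both groups'
graphs have identical edge counts at every density, which is what makes
the group comparison fair.  Ties between equal correlations break
lexicographically by node-index pair, so edge sets are deterministic and
nested across densities (the graph at a lower density is always a
subgraph of the graph at a higher one).

The analysis density range is chosen as follows: the lower bound is the
smallest grid density (scan step 0.01) at which **neither** group's graph
contains an isolated node; the upper bound defaults to 0.5, above which
dense graphs degenerate toward random-graph topology.  The metric sweep
uses a step of 0.02, giving 15 density points for the reference 0.22–0.50
range.  All three values are configuration keys.

## Graph metrics

For a binary undirected graph with adjacency A:

* **Cp** — mean over nodes of (triangles at the node) / (k(k−1)/2);
  nodes with degree < 2 contribute 0.
* **Lp** — mean shortest-path length over *reachable* unordered pairs.
  Minimum-density selection removes isolated nodes but cannot guarantee
  connectedness, so unreachable pairs are excluded from the mean and
  their count is reported alongside.
* **T** (transitivity) — 3 × triangles / connected triples.
* **Eg** — mean of 1/d(i,j) over all unordered pairs (1/∞ = 0).
* **Eloc** — mean over nodes of the global efficiency of the subgraph
  induced on the node's neighbors (0 for degree < 2).
* **Dc, Bc** — nodal degree and raw betweenness (shortest-path pair
  counts with fractional splitting among tied paths; no (N−1)(N−2)/2
  normalization, which cancels in group comparisons anyway).

Normalized measures divide by means over **degree-preserving random
references**: each reference applies 10 double-edge-swap attempts per
edge (Maslov–Sneppen rewiring; swaps creating self-loops or multi-edges
are discarded, so every node keeps its exact degree).  γ = Cp/⟨Cp_rand⟩,
λ = Lp/⟨Lp_rand⟩, σ = γ/λ — the identity σ ≡ γ/λ holds exactly in every
output record.  Defaults are 20 references per graph; graphs admitting no
valid swap (stars, complete graphs) are returned unchanged with a logged
warning, which self-normalizes their γ and λ to 1.  Triangle counts come
from diag(A³), distances from C-level breadth-first search, and rewiring
and betweenness are delegated to igraph; brute-force oracles (exhaustive
triangle/path enumeration) and networkx pin all of these down in the test
suite.

## Degree distribution

The empirical cumulative distribution P(k ≥ d), evaluated at each
distinct positive degree over the connected nodes, is fitted with

    P(d) ∝ d^(e−1) · exp(−d/dc)

in log–log space — the exponentially truncated power law typical of
brain covariance networks, where `e` is the scaling exponent and `dc`
the cutoff degree beyond which hub probability decays exponentially.
The cumulative form is used because it is far less noisy than the raw
degree histogram on ~90 nodes.  In log10 space the model is *linear* in
(log10 scale, e−1, 1/dc), so the least-squares optimum is computed
exactly by linear algebra; if the unconstrained optimum would place the
cutoff at a negative value, a bounded nonlinear fit multi-started from a
fixed (e, dc) grid takes over.  Either path is deterministic.  R² is
reported on the log10 p_cum scale; the multiplicative scale is free, so
the fit is invariant to rescaling all probabilities.  At least 4 distinct
degree values are required.

## Robustness simulation

Nodes are deleted one at a time — in descending order of initial degree
(targeted attack, ties by node index) or uniformly at random (random
failure, 1000 seeded repetitions by default) — and the largest remaining
connected component is recorded after every step.  The attack ordering is
fixed at step 0 by default; a variant that re-ranks degrees after each
deletion is available behind a flag.  Each single-order curve is computed
in O(N+E) by processing removals in reverse as union-find insertions.
Curves are summarized by the trapezoidal area under LCC fraction versus
removed fraction; random-failure curves carry a per-step SD band.

## Group inference

Because each group yields a single network per density, significance
comes from **label permutation**: subject group labels are reshuffled
(group sizes preserved), both covariance networks are rebuilt from the
fixed residuals, thresholded at every grid density, and the statistic
recomputed.  The headline statistic is the difference (group b − group a,
sorted label order) in the trapezoidal area under the metric-vs-density
curve; its two-tailed Monte-Carlo p-value uses the +1 correction,
p = (#{|null| ≥ |observed|} + 1)/(n_perm + 1), so p is never exactly 0.
Per-density differences are reported with the null 2.5–97.5% band rather
than multiplicity-corrected per-density p-values.  Nodal degree and
betweenness are tested the same way at the minimum density, with both
uncorrected (α = 0.05) and Benjamini–Hochberg FDR masks (the latter via
statsmodels).  Robustness AUC differences are tested identically, with
per-removal-step flags against the null band.  Defaults: 1000
permutations, seeds mandatory and echoed into the report.

Cohen's d for density-series summaries uses the equal-n pooled form
d = |m₂ − m₁| / √((s₁² + s₂²)/2), where each "sample" is the set of
per-density metric values (15 points for the reference grid).

## Synthetic cohorts

The generator plants a known correlation structure: a seed graph per
group (Watts–Strogatz by default, n = 90, k = 10, p = 0.05) assigns
correlation `r_edge` (default 0.6) to its edges and `r_bg` (default 0.1)
elsewhere; the target matrix is repaired to positive definiteness by
eigenvalue clipping with diagonal renormalization.  Latent residuals are
drawn from the resulting multivariate normal, then baseline volume
(7500 mm³), linear covariate effects (−20 mm³/yr of age, 300 mm³ for
sex, 0.004 mm³ per mm³ of TIV — magnitudes typical of regional gray
matter) and residual scale 750 mm³ are added.  Age is uniform on 18–60,
sex a fair coin, TIV normal (1.45 × 10⁶ ± 1.3 × 10⁵ mm³).  Default group
sizes are 47 and 35 subjects, the size of a typical single-site clinical
cohort.  One master seed streams every draw in fixed order, so cohorts
are byte-reproducible.

Two honest caveats.  First, at strongly non-positive-definite targets
(e.g. k = 10 lattice edges at 0.6 over 0.1 background) *any* repair —
eigenvalue clipping or a full nearest-correlation iteration — must move
entries substantially (max drift ≈ 0.23 for both); clipping is kept
because it is deterministic, fast, and preserves what matters: planted
edges stay well separated from background (≈ 0.46 vs ≈ 0.13), so
recovery and power experiments remain meaningful.  In the genuinely
positive-definite regime (e.g. r_edge ≤ 0.3 at background 0.1) the
target is exact.  Second, the generator emulates multivariate-normal
volumes with linear covariate effects only: no site/scanner effects, no
nonlinear aging, no lesion-driven outliers, no spatial autocorrelation
between neighboring parcels.  Passing tests therefore demonstrate that
the *pipeline* is correct and calibrated under its stated model, not
that real cohorts satisfy that model.

## Problem sizes used in the shipped experiments

The permutation-calibration experiment uses 200 independent null cohorts
of 30 + 30 subjects with 200 permutations each (clustering AUC test);
the planted-effect power experiment uses 20 cohorts of 60 + 60 subjects
with 50 permutations, 3 references and 3 swap attempts per edge for the
γ null.  These sizes give stable rate estimates (binomial SE ≈ 1.5% at
n = 200) while keeping the full suite runnable on a laptop; all counts
are parameters, and production analyses should use the 1000-permutation,
20-reference defaults.

## Known limitations

* Weighted, signed, or negative-correlation networks are out of scope.
* Lp over reachable pairs makes disconnected graphs comparable but
  slightly favors fragmented networks; the unreachable-pair count is
  reported so users can detect this regime.
* The bootstrap-free design gives no subject-level confidence intervals;
  all uncertainty statements are permutation-based at the group level.
* Whether nodal comparisons should use permutation or parametric tests
  is a genuine modeling choice; permutation is used for coherence with
  the global tests.
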