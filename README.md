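# scnkit

Structural covariance network (SCN) analysis of regional gray matter
volumes.

When a morphometric measure (here, regional gray matter volume from a
VBM-style parcellation) is correlated *across subjects*, the resulting
region-by-region correlation matrix defines a brain network: nodes are
regions, edges are strong positive covariance.  Groups of subjects —
e.g. a patient cohort versus matched controls — can then be compared in
terms of network topology even though each subject contributes only one
number per region.  scnkit implements that comparison end to end for
people who have a subjects × regions volume table and want defensible,
reproducible network statistics:

1. **Covariate adjustment** — per-region OLS removes age, sex and total
   intracranial volume; residuals ("corrected volumes") feed everything
   downstream.
2. **Network construction** — per-group Pearson matrices with the
   diagonal and negative entries zeroed, binarized by *rank*
   thresholding so both groups have exactly E = D·N(N−1)/2 edges at each
   density D; the analysis range runs from the smallest density at which
   neither group has an isolated node (default scan) up to D = 0.5.
3. **Graph metrics** — clustering Cp, characteristic path length Lp,
   transitivity T, global/local efficiency Eg/Eloc, nodal degree and
   betweenness, and the small-world coefficients γ = Cp/⟨Cp_rand⟩,
   λ = Lp/⟨Lp_rand⟩, σ = γ/λ against degree-preserving (double-edge-swap)
   null networks.
4. **Degree distribution** — fit of the exponentially truncated power law
   P(d) ∝ d^(e−1)·e^(−d/dc) to the cumulative degree distribution in
   log–log space.
5. **Robustness** — largest-connected-component curves under random
   node failure (1000 seeded repetitions) and degree-targeted attack,
   summarized by AUC.
6. **Inference** — subject-label permutation tests of the
   area-under-the-density-curve difference for every metric, per-node
   permutation tests with Benjamini–Hochberg FDR, and pooled-SD Cohen's d
   effect sizes.

A synthetic-cohort generator with planted correlation structure
(`scnkit.SyntheticSpec` / `scnkit simulate`) makes the whole pipeline
testable without access to clinical data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from scnkit import (DensityGrid, GraphSpec, SyntheticSpec, generate_cohort,
                    residualize, correlation_matrix, find_min_density,
                    threshold_at_density, normalized_metrics, permute_global)

# two 90-region groups: group "b" planted with lattice-like (highly
# clustered) covariance, group "a" with a rewired, less clustered one
spec = SyntheticSpec(
    n_a=60, n_b=60, r_edge=0.6, r_bg=0.1, seed=1000,
    graph_a=GraphSpec(kind="watts_strogatz", k=10, p=0.5),
    graph_b=GraphSpec(kind="watts_strogatz", k=10, p=0.02),
)
table = generate_cohort(spec)
res = residualize(table)                      # remove age/sex/TIV

cov_a = correlation_matrix(res, "a")
cov_b = correlation_matrix(res, "b")
print("Dmin:", find_min_density(cov_a, cov_b))

net_b = threshold_at_density(cov_b, 0.22)
gm = normalized_metrics(net_b, n_random=20, seed=0)
print(f"gamma={gm.gamma:.2f} lambda={gm.lam:.2f} sigma={gm.sigma:.2f}")

r = permute_global(res, "gamma", DensityGrid(0.22, 0.5, 0.02),
                   n_perm=50, n_random_refs=3, n_swaps_per_edge=3, seed=0)
print(f"gamma AUC diff={r.observed_auc_diff:+.3f}  p={r.p_value:.3f}")
```

Output:

```
Dmin: 0.09
gamma=1.80 lambda=1.05 sigma=1.71
gamma AUC diff=+0.044  p=0.020
```

Read: neither group's network has an isolated node from density 0.09
upward, so the whole 0.22–0.50 analysis range is safe.  At density 0.22
the lattice-like group's network has 1.8 times the clustering of its
degree-matched random references (γ = 1.80) at essentially random path
length (λ = 1.05), hence σ = 1.71 — small-world organization.
Integrated over the density range, the γ curve of group b sits above
group a's by 0.044 area units, and none of the 50 label permutations
produced a gap that large, so p = 1/51 ≈ 0.02: the planted clustering
difference is detected.

The same analysis runs from the shell:

```bash
scnkit simulate --out cohort.csv --seed 7
scnkit run --input cohort.csv --out results/ --seed 7
scnkit metrics results/network_dmin_a.tsv
```

`run` writes residuals, correlation matrices, per-density metric curves,
nodal metrics, degree-distribution fits, robustness curves, permutation
results, and a `report.json` echoing the full configuration and seeds.

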