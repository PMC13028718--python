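# biocrust

Community-assembly analysis for artificial cyanobacterial biological soil
crusts (Cyano-BSCs) — and, more generally, for any amplicon (ASV) count
table with treatment groups.

Biocrust restoration experiments inoculate bare sandy soil with cyanobacteria
(e.g. *Microcoleus vaginatus*, *Leptolyngbya* sp.) and ask how the
inoculum reshapes the bacterial community: does assembly stay stochastic
(dispersal-dominated) or become deterministic (selection-dominated), which
taxa become keystones of the co-occurrence network, and does the restructured
community in turn drive crust growth (organic matter, coverage)? This package
implements that analysis chain as a tested, reusable library:

* **Diversity & ordination** — Shannon entropy, Bray–Curtis dissimilarity,
  principal coordinates (classical scaling), and PERMANOVA
  (Anderson's pseudo-F with permutation p, exhaustive enumeration on small
  designs).
* **Co-occurrence networks** — thresholded Spearman networks
  (|ρ| > 0.6 and Benjamini–Hochberg q < 0.001 over the top-300 most abundant
  ASVs by default), the full topology panel (degree, density, clustering,
  geodesics, power-law R², relative modularity against degree-preserving
  nulls), and Zi–Pi topological roles: with Zi the within-module degree
  z-score and Pi = 1 − Σₛ(k\_is/k\_i)² the participation coefficient, nodes
  classify as module hubs (Zi > 2.5, Pi < 0.62), connectors (Zi < 2.5,
  Pi > 0.62), network hubs (both) or peripherals (neither).
* **Sloan neutral community model (NCM)** — an ASV with mean relative
  abundance *p* in a community of N reads coupled to the source pool with
  migration rate *m* is detected with probability
  f̂(p) = 1 − I\_d(Nm·p, Nm·(1−p)), where I is the regularized incomplete
  beta function and d = 1/N the detection limit. `NeutralCommunityModel.fit()`
  estimates m by bounded least squares, reports R² and bootstrap CIs, and
  partitions ASVs above/within/below the 95 % Wilson band around f̂.
* **Recursive path analysis** — standardized path coefficients for acyclic
  diagrams over observed composites (PCA first component of growth
  indicators, PCoA first axis of community submatrices), with χ², CFI,
  RMSEA and AIC fit indices.
* **Synthetic generators** — neutral communities (lognormal metacommunity,
  Dirichlet(Nm·p) composition, multinomial reads), niche-filtered
  communities with Gaussian environmental responses, planted correlation
  blocks for the network stage, and a linear inoculation → community →
  growth chain — each with known ground truth, so every stage is testable
  without sequencing data.

## Worked example

Fit the neutral model to a simulated neutral community and a path model to a
simulated growth chain:

```python
import biocrust as bc

cfg = bc.SimulationConfig(n_samples=30, n_asvs=500, depth=20000, Nm=2000, seed=42)
table = bc.simulate_neutral(cfg)
res = bc.fit_ncm(table, n_boot=200, seed=1)
print(res.summary())
```

```
Sloan neutral community model fit
----------------------------------------------
  m (migration probability) : 0.126369
  Nm                         : 2527.38  [95% CI 2375.07, 2708.21]
  R^2                        : 0.9365  [95% CI 0.9212, 0.9504]
  N (mean sample depth)      : 20000
  detection limit d = 1/N    : 5e-05
  ASVs fitted                : 500
  partition above/neutral/below : 179/314/7
  bootstrap replicates       : 200
```

The high R² says detection frequencies track the neutral prediction — this
community is dispersal-assembled. The fitted Nm (2527) sits above the
generating value (2000): the standard threshold approximation used by the
fitter systematically overestimates the migration parameter on
Dirichlet-multinomial counts by roughly 15–20 % (see `docs/methods.md`);
R² and the stochastic-vs-deterministic contrast are unaffected.

```python
df = bc.simulate_growth_chain(
    bc.SimulationConfig(n_samples=200, chain=(0.59, 0.64), noise_sd=0.3, seed=0))
df["growth"] = bc.composite_pc1(df[["OM", "coverage"]])
pm = bc.PathModel.from_dataframe(
    df, ["inoculation -> community_axis", "community_axis -> growth"]).fit()
print(pm.summary())
```

```
Recursive path model (standardized estimates)
--------------------------------------------------------
path                            coef      se         p
inoculation -> community_axis   0.611   0.056    0.0000
community_axis -> growth       0.647   0.054    0.0000
--------------------------------------------------------
chi2 = 1.0433  (df = 1, p = 0.3070)
CFI = 0.9998   RMSEA = 0.0148   AIC = 11.04
n = 200, free parameters = 5
```

Both standardized coefficients recover the simulated truths (0.59, 0.64)
within sampling error, and the non-significant χ² with CFI ≈ 1 says the
chain (no direct inoculation → growth path) is consistent with the data.

A `biocrust` command-line tool wraps the same functionality
(`simulate`, `diversity`, `network`, `ncm`, `pathmodel`, and a YAML-driven
`pipeline` that runs the whole chain per treatment group and writes a
seed-complete manifest).

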