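# Methods

This note documents the statistical models, conventions and design choices
behind the package, and what the synthetic-data tests do and do not
establish about real amplicon data.

## Data model and rarefaction

The core container is an integer samples × ASVs count matrix with
authoritative string identifiers (positions carry no meaning). Rarefaction
subsamples each sample to a fixed depth **without replacement** — a
multivariate hypergeometric draw per sample, seed-controlled — so that each
retained sample sums exactly to the depth and no count exceeds its original.
Samples below the requested depth are dropped with a warning rather than
upsampled. The default depth of 20,000 reads reflects typical post-denoising
coverage for soil 16S libraries; Good's coverage (1 − singletons/reads)
is provided to verify the depth is adequate (> 99.9 % for well-sampled
communities). Network and neutral-model inputs are restricted to the top-N
most abundant ASVs (default N = 300), with ties broken by ASV identifier so
the selection is deterministic.

## Diversity and ordination

Shannon entropy uses the natural logarithm by default (base 2 by flag):
printed Shannon values near 7–8 for rich soil communities are consistent
with natural-log entropy. Bray–Curtis dissimilarity,
d(x, y) = 1 − 2·Σmin(xᵢ, yᵢ)/(Σxᵢ + Σyᵢ), is computed on the rarefied
counts. Principal coordinates analysis is classical scaling: double-centre
−D²/2, eigendecompose, scale eigenvectors by √λ. Negative eigenvalues
(Bray–Curtis is not Euclidean-embeddable) are reported but excluded from the
explained-variance denominator; no Cailliez correction is applied by
default. Axes are sign-oriented so each column's largest-magnitude
coordinate is positive, making ordinations reproducible across runs.

PERMANOVA follows Anderson's partition of squared distances:
F = (SS_between/(a−1)) / (SS_within/(n−a)) with SS computed from pairwise
squared distances within groups. p-values use free permutation of group
labels, p = (1 + #{F\* ≥ F}) / (1 + n_permutations), 999 permutations by
default (p-floor 0.001). On small designs an exhaustive mode enumerates all
distinct label assignments and reports the exact permutation p. Note the
attainable p-floor depends on design size: with 3 + 3 samples only 20
distinct assignments exist, so the smallest possible p is 0.1.

## Co-occurrence networks

Edges are ASV pairs whose tie-corrected Spearman correlation (Pearson
correlation of average ranks; p from the t approximation) satisfies
**both** |ρ| > 0.6 and Benjamini–Hochberg FDR q < 0.001 across all pairs of
the top-N ASVs. ASVs with zero variance can never form an edge; ASVs with
no passing edge are excluded from the node set. Correlations are computed on
rarefied counts as-is (no CLR or other compositional transform) — the
convention of the molecular-ecological-network literature this panel
mirrors. Correlations estimated from only five replicates per group are
fragile; the pipeline emits a small-n warning rather than silently
proceeding.

**Modules** are detected by greedy modularity maximisation (deterministic;
Louvain with a recorded seed available by flag) on the **positive-edge
subgraph**: modules are groups of co-occurring taxa, and negative
associations separate modules rather than bind them. This convention is what
lets a planted pair of mutually exclusive taxon blocks resolve into two
modules rather than one.

The topology panel reports: edge and node counts; positive/negative link
percentages (summing to 100 exactly); avgK = 2E/N; density
D = 2E/(N(N−1)); mean local clustering (nodes of degree < 2 contribute 0);
mean geodesic distance over connected pairs (GD); geodesic efficiency E
(mean of 1/d over all pairs, unreachable pairs contributing 0) and harmonic
geodesic distance HD = 1/E; Krackhardt connectedness (fraction of reachable
pairs); the R² of an ordinary least-squares fit of log frequency on log
degree over degrees with nonzero frequency ("power-law R²"); and relative
modularity RM = (M_obs − mean M_null)/mean M_null over degree-preserving
double-edge-swap randomizations (100 by default), where modularity is scored
unweighted on the unsigned skeleton and module detection is re-run on each
null so observed and null networks are treated identically. RM has no
canonical definition in the panel literature; this one is a documented
convention, centred at zero for unstructured (Erdős–Rényi) graphs.

**Zi–Pi roles.** Zi is the z-score of a node's within-module degree relative
to its module (Zi = 0 when the module's within-degree spread is zero);
Pi = 1 − Σₛ(k_is/k_i)² sums over the modules its neighbours occupy
(Pi = 0 for isolated nodes, by convention). Roles use the standard
four-quadrant thresholds (2.5, 0.62) with strict inequalities; boundary
equality resolves to the peripheral-side quadrant, since the published
criteria leave equality undefined.

## Sloan neutral community model

Under neutral assembly with community size N (reads per sample after
rarefaction) and migration probability m, the stationary local relative
abundance of a taxon with metacommunity abundance p is Beta(Nm·p, Nm·(1−p)).
Detection is approximated as "local abundance exceeds d = 1/N", giving the
predicted occurrence frequency f̂(p) = 1 − I_d(Nm·p, Nm·(1−p)). m is
estimated by bounded nonlinear least squares on (p̂ᵢ, fᵢ) pairs — p̂ᵢ the
mean observed relative abundance, fᵢ the detection fraction — via a global
bounded 1-D search on log m refined from starts {0.01, 0.1, 0.5};
R² = 1 − SSE/SST with SST about the mean observed frequency (the common
convention; R² can be negative for terrible fits). Bootstrap CIs (1000
replicates by default) resample ASVs with replacement and refit from the
full-data optimum. ASVs are partitioned above/neutral/below the 95 % Wilson
score interval around f̂ with n = number of samples; the band is analytic
rather than bootstrapped, and it always contains f̂, so an ASV observed
exactly at its prediction is always "neutral".

**Known bias of the threshold approximation.** The neutral generator draws
per-sample composition from Dirichlet(Nm·p) and reads multinomially — the
exact finite-N stationary law (beta-binomial marginals). Under that law the
true detection probability is P(count > 0) = 1 − B(a, b+N)/B(a, b), which
exceeds the threshold approximation P(x > 1/N) for rare taxa. Fitting the
threshold curve therefore overestimates Nm with an asymptotic relative bias
of about +16 % to +20 % (measured at depth 20,000 with a lognormal(0, 1.5)
metacommunity and Nm ∈ {500, 2000, 8000}); the acceptance script reports
the honestly measured recovery error and CI coverage. The estimator itself
is unbiased in the self-consistency sense: when observed frequencies are
generated from the fitted functional form, recovery is accurate (unit
suite). R², the partition, and the stochastic-vs-deterministic *contrast*
between treatments — the quantities the analysis actually interprets — are
insensitive to this scale bias, and environmental filtering reliably lowers
R² relative to matched neutral communities.

## Recursive path analysis

Only acyclic diagrams over observed variables are supported (sufficient for
a three-node inoculation → community → growth chain); latent-variable SEM
is out of scope. Variables are z-scored internally; each endogenous variable
is regressed on its declared parents by OLS, which for recursive
observed-variable models coincides with covariance-based maximum likelihood.
The model-implied covariance Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ (B the path matrix, Ψ
residual variances plus exogenous sample covariances) yields
χ² = (n−1)·F_ML with F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p;
CFI compares against the independence baseline;
RMSEA = √(max(χ²−df, 0)/(df·(n−1))); AIC = χ² + 2q with q the free
parameter count. Just-identified models report χ² = 0, CFI = 1, RMSEA = 0
with a flag, and coefficients are computed even when S is singular (e.g. a
zero-noise copy), since OLS only needs nonsingular design blocks.
Coefficient p-values come from normal-theory standard errors of the
standardized regressions; the type-I error of the nominal 5 % test is
verified at ≈ 5 % on null chains.

Composites: growth indicators (organic matter, coverage) are reduced by PCA
to their first component, sign-oriented so the first declared variable loads
positively; community and keystone-taxa axes use the first principal
coordinate of the Bray–Curtis matrix (identical to the ordination module's
first axis).

## Synthetic generators

All generators are deterministic given their seed and embed their
configuration.

* **Neutral**: lognormal(μ = 0, σ = 1.5) metacommunity (realistic
  rank-abundance skew; log-series available), Dirichlet(Nm·p) composition per
  sample, multinomial reads — the exact stationary sampling scheme rather
  than an agent-based birth–death simulation (faster and analytically
  matched to the model being fitted). Empirical detection frequencies match
  the exact beta-binomial marginal within Monte-Carlo error.
* **Niche**: samples sit on a uniform environmental gradient; each ASV has a
  Gaussian response (width 0.3) around a random optimum, raised to a
  selection-strength power (default 5) that modulates its metacommunity
  abundance before multinomial sampling. Strength 0 degenerates to plain
  multinomial sampling of the metacommunity (the infinite-Nm neutral limit).
* **Blocks**: per-sample standard-normal latent factors; block members load
  on their latent with configured sign and strength on the log scale, plus
  independent log-normal noise (default sd 0.3), softmax, multinomial reads.
  Blocks sharing a latent with opposite signs are mutually exclusive.
  Because abundances are compositional, a block's shared signal bleeds into
  the background through the normalising denominator; the optional
  `block_share` knob pins the block's total metacommunity share, and a small
  share (e.g. 1 %) emulates a rare planted guild whose background stays
  uncorrelated — the regime in which an all-positive block yields a network
  of 100 % positive links.
* **Growth chain**: balanced binary inoculation X; community axis
  M = β₁·X* + √(1−β₁²)·ε and latent growth Y = β₂·M + √(1−β₂²)·ε (X*
  standardized), so the configured β are the standardized path coefficients
  by construction; organic matter and coverage are Y plus independent
  Gaussian noise of sd `noise_sd` (0.3 default — manifest indicators about
  90 % correlated with the latent). `noise_sd = 0` makes the manifest layer
  an exact copy of the latent.

**What passing tests show — and don't.** The generators reproduce the
statistical *structure* each stage assumes (neutral sampling, environmental
filtering, block correlation, a linear causal chain), not the messiness of
real amplicon data: no sequencing error or chimeras, no compositional
zero-inflation beyond sampling, no phylogenetic correlation among ASVs, no
temporal autocorrelation between replicates. Recovery results therefore
validate the implementations and their identifiability, not the biological
correctness of any particular field study.

## Numerical conventions

Rarefaction uses numpy's multivariate hypergeometric sampler. The NCM
objective is optimised on log m over (10⁻⁶, 1) to tolerance 10⁻¹⁰.
Spearman p-values use the t approximation (matching scipy's default); exact
ties are handled by average ranks. BH adjustment delegates to statsmodels.
PCoA eigenvalues below 10⁻¹⁰ × λ_max are treated as zero. Percent changes
for reporting are rounded half-up to two decimals; machine-readable outputs
retain full precision. Pipeline problem sizes in the test suite and
acceptance script (e.g. 50 samples × 500 ASVs × 20,000 reads for neutral
recovery, 20 replicate pairs for the niche contrast, 100/500 replicates for
path recovery and type-I calibration) were chosen as the smallest designs at
which the corresponding estimators are stable.

## Known limitations

* The NCM threshold approximation's ~+18 % scale bias on Nm (above); use Nm
  comparatively, not as an absolute migration estimate.
* Correlation networks on compositional data can contain
  closure-induced edges; no SparCC/SpiecEasi-style correction is provided.
* Only recursive observed-variable path models; no latent constructs,
  bootstrap SEs, or multi-group fits.
* Published topology panels are not always internally consistent with their
  own node/edge counts (avgK ≠ 2E/N); the panel here enforces the identities
  exactly, so such rows cannot be reproduced by construction.
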