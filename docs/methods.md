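# Methods

## The mapping problem

A biparental mapping population (doubled haploids, a first backcross, or
recombinant inbred lines — all carrying exactly two genotype classes per
locus, coded +1 for the P1 class and −1 for the P2 class) is phenotyped for a
quantitative trait in *e* environments.  A QTL at a given genome position has
per-environment additive effects *a*₁, …, *a*ₑ.  These split into an
**average effect** ā = (1/e)Σₕ aₕ and **QTL-by-environment interaction (QEI)
effects** aeₕ = aₕ − ā, which sum to zero by construction.  The goal of the
scan is to locate QTL and separate the two components: a QTL with large ā and
small aeₕ is stable across environments; one with ā ≈ 0 but large aeₕ is
environment-specific or crossover-interacting.

## Inclusive composite interval mapping (ICIM) of QEI

The scan is the two-step ICIM strategy extended to multi-environment data.

**Step 1 — cofactor selection.**  In each environment independently, the
phenotype is regressed on all marker indicator variables and markers are
chosen by forward-entry/backward-removal stepwise regression (entry if the
best candidate's partial-F p-value ≤ `p_in`, removal of any selected marker
with p > `p_out`, iterated to a fixed point, ties broken to the lower marker
index).  Partial (type-III-like) sums of squares are used for the removal
tests; the entry F-statistics are computed by orthogonalizing all candidates
against the current design in one pass (QR), which makes the procedure exact
and fast.  Defaults `p_in = 0.001`, `p_out = 0.002`.  Missing marker codes
are imputed, for the regression only, by the conditional expectation
λ·x_left + ρ·x_right from the nearest non-missing flanking markers (single
nearest marker scaled by 1 − 2r at chromosome ends; population mean 0 when a
whole chromosome is missing).  Missing phenotype cells drop the individual
from that environment's regression only.

**Step 2 — interval scan on adjusted phenotypes.**  For a testing position in
the interval flanked by markers k, k+1, the phenotype is adjusted once per
interval:

    Δy_ih = y_ih − Σ_{j selected, j ∉ {k, k+1}} b̂_jh x_ij ,

removing background genetic variation but keeping the local QTL signal.  The
intercept is not subtracted (immaterial to every likelihood ratio).

At each grid position the individuals fall into four groups by their flanking
marker types, and within group *l* the adjusted phenotype follows a
two-component normal mixture with known mixing proportions π_l1, π_l2 — the
conditional QTL-genotype probabilities given the flanking pair, computed from
the Haldane recombination fractions r₁ (left marker → position) and r₂
(position → right marker), with the flanking-pair fraction composed by the
no-interference identity r = r₁ + r₂ − 2r₁r₂:

    π₁₁ = (1−r₁)(1−r₂)/(1−r)   π₂₁ = (1−r₁)r₂/r   (and mirror groups).

Three nested hypotheses are fit at every position:

* **H0** (no QTL): one normal per environment; closed-form MLE with 1/n
  variances.
* **H1** (any effect): two means per environment plus one shared variance per
  environment, maximized by expectation–conditional-maximization (ECM).
* **H2** (interaction only): as H1 with the constraint ā = 0, enforced in the
  conditional M-step through a Lagrange multiplier
  λ = 2e·Σₕ(m₁ₕ − m₂ₕ) / Σₕ σ²ₕ(1/W₁ₕ + 1/W₂ₕ), which shifts the two
  component means by ∓σ²ₕλ/(2e)/W_kh so that Σₕ(μ₁ₕ − μ₂ₕ) = 0 holds exactly
  at each CM step given the current variances (the final residual is reported
  on the fit).  With complete data the multiplier reduces to the classical
  single-denominator form; the per-environment weights W_kh generalize it to
  missing phenotype cells.

The three LOD statistics are LOD = (ℓ₁ − ℓ₀)/ln 10 (any effect),
LOD_A = (ℓ₁ − ℓ₂)/ln 10 (average effect) and LOD_AE = (ℓ₂ − ℓ₀)/ln 10
(interaction), with LOD = LOD_A + LOD_AE an exact identity.

**Likelihood form.**  The default couples environments through the shared QTL
genotype: each individual contributes
log[π_l1 Πₕ f(Δy_ih; μ₁ₕ, σ²ₕ) + π_l2 Πₕ f(Δy_ih; μ₂ₕ, σ²ₕ)].  This is the
unique likelihood whose EM has exactly the M-step used here (posterior
weights shared across environments), and it reflects the genetics — one
genotype per line expressed in all environments.  A variant that sums the
per-environment densities inside the mixture instead of multiplying them is
available as `likelihood="printed-sum"` for comparison; its weight update is
a legacy formulation and its fixed point is not the maximizer of a proper
joint likelihood, so it is not the default and its iteration is not
guaranteed monotone.

**ECM numerics.**  Initialization from the two double-non-recombinant groups:
μ₁ₕ⁽⁰⁾ = mean of the (+,+) group, μ₂ₕ⁽⁰⁾ = mean of the (−,−) group, pooled
variance from the two; if either group is empty, overall mean ± half the
pooled SD.  Convergence when |Δℓ| < 10⁻⁶, at most 200 iterations (fits are
flagged if unconverged).  A component whose total posterior weight falls
below 10⁻⁸ is pinned to the overall environment mean.  All positions of an
interval share Δy and the group labels, so H1/H2 are fit jointly across the
interval's grid in one vectorized ECM; H0 is computed once per interval.
Scan grid: closed on both interval ends, default step 1 cM; a marker position
shared by two intervals is reported once, from its left interval.
Individuals missing a flanking genotype get per-individual priors from the
nearest informative markers; with no informative marker on the chromosome
they are excluded from that interval's likelihood (all three fits alike, so
the ratios stay comparable).

**Effects and PVE.**  From the H1 fit, aₕ = (μ̂₁ₕ − μ̂₂ₕ)/2.  The 2 × e table
of fitted genotype means, weighted by the estimated marginal genotype
frequencies f̂_k = (1/n)Σᵢ w_ik (cell frequencies f̂_k/e), decomposes
orthogonally into genotype, environment and interaction deviations:

    V_A  = Σ_k f̂_k (μ̂_k· − μ̂··)²      = 4 f̂₁ f̂₂ ā²
    V_AE = Σ_kh f̂_kh QEI_kh²           = (4/e) f̂₁ f̂₂ Σₕ (aₕ − ā)² ,

with QEI_kh = μ̂_kh − μ̂_k· − μ̂_·h + μ̂··.  PVE_A and PVE_AE are percentages of
V_P, the average of the raw per-environment phenotypic variances (1/n
denominators).  Raw rather than adjusted variances are used: the adjusted
phenotype changes from interval to interval and would make PVE incomparable
across the genome.

## LOD thresholds

One-dimensional scans behave like M_eff independent tests, with M_eff
proportional to genome length: 0.072 tests/cM at genome-wide α = 0.05 and
0.084 at α = 0.01 for a 10 cM marker density (other densities need a
user-supplied coefficient).  The threshold is the Bonferroni-corrected
chi-square quantile, LOD* = χ²_{α/M_eff}(df) / (2 ln 10), with df = e for the
overall statistic in two-class populations (2e for F2, supported in the
threshold calculator only), df = 1 for LOD_A and df = e − 1 for LOD_AE.
M_eff is deliberately left un-rounded — rounding to whole tests changes the
second decimal of the threshold at short genomes.  For RIL, accumulated
recombination R = 2r/(1+2r) expands short map distances ~1.9-fold
(1.98/1.91/1.83 at 1/5/10 cM), so the genome length is multiplied by 1.9
before applying the formula.  A permutation alternative shuffles whole
phenotype rows (an individual's environment vector stays together), reruns
stepwise + scan per permutation, and takes the (1−α) percentile of the
genome-wide maximum LOD.

## The simulator and what it emulates

Genotypes are simulated as a first-order Markov chain over the merged
(marker ∪ QTL) loci of each chromosome: first locus ±1 with probability ½,
transition probability equal to the Haldane fraction of the inter-locus
distance — mapped through R = 2r/(1+2r) for RIL, which reproduces the
marginal two-locus distribution of repeated selfing without iterating
generations.  Phenotypes are y_ih = μₕ + Σⱼ a_jh g_ij + ε_ih with
ε_ih ~ N(0, σ²ₕ) and σ²ₕ = V_G,h (1 − H²)/H², where the per-environment
genetic variance V_G,h = Σⱼ a_jh² + 2Σ_{j<j'} a_jh a_j'h (1 − 2r_jj') is
closed-form (covariance zero across chromosomes).  This enforces the design
heritability per environment exactly in expectation and makes per-QTL PVE
available in closed form: V_P = mean_h(V_G,h)/H², PVE_j = mean_h(a_jh²)/V_P.
Intercepts μₕ default to 0 (all statistics are translation-invariant).  When
an environment has zero genetic variance under an environment-specific
architecture, its error variance is set to the mean of the informative
environments' error variances so every trait still carries noise
(overridable via `floor_sigma2`).

The benchmark design used throughout validation: 6 chromosomes × 150 cM with
16 evenly spaced markers (10 cM density), DH populations of n = 200 in e = 2
environments; the unlinked preset places five QTL (average effects 0.5, 0,
0.25, 0.25, 0.5 with interaction effects 0, ±0.5, ∓0.25, ±0.25, 0) at
16/3/33/26/35 cM on chromosomes 1–5 at H² = 0.5, giving each QTL a known PVE
of 12.5 or 6.25%; eight linked two-QTL scenarios (L1–L8, QTL at 25 and 55 cM
on chromosome 1) cover coupling/repulsion linkage at H² ∈ {0.1, 0.5, 0.8}.

What the simulator does **not** emulate: genotyping error (only a uniform
missing-rate option), segregation distortion, non-normal or heteroscedastic
residuals within an environment, replicated plot structure, correlated
environmental errors, dominance, or epistasis.  Passing power/FDR checks on
these simulations therefore demonstrate correctness of the algorithm under
its own model assumptions, not robustness to violations of them.

## Power, FDR and calibration studies

A significant peak is one maximal contiguous run of scan positions with
LOD ≥ threshold, called at the run's maximum (leftmost on ties).  A true QTL
is detected in a replicate when ≥ 1 call falls inside its support interval
(±5 cM); calls outside every support interval are false positives, and
FDR = false calls / all calls pooled over replicates.  A call inside two
overlapping support intervals is assigned to the nearest truth and never
double-counted; multiple same-replicate calls in one interval count as one
detection.  Estimated positions and effects are averaged over the assigned
calls of detecting replicates.

Problem sizes: the replicated validation studies run 200 power replicates of
the unlinked design and 500 null replicates for threshold calibration —
large enough that a 5-percentage-point power deviation or a miscalibrated
threshold (outside 5% ± 3 binomial SE exceedance) is detectable, while
keeping the full validation suite at desk scale.  The null study skips the
H2 fit, since the genome-wide maximum of LOD = (ℓ₁ − ℓ₀)/ln 10 does not
require the decomposition.

## Design choices that were genuinely open

* **RIL conditional probabilities.**  r₁ and r₂ are converted to accumulated
  R individually and the flanking fraction is then composed from the
  converted values by the no-interference identity.  Composing first and
  converting all three independently breaks row normalization of the π table
  (rows sum to ≈1.02 at 10 cM); the adopted order keeps π a proper
  conditional distribution and matches the Markov transition model the RIL
  simulator uses, at the cost of ignoring the (weak) dependence between the
  two sides' accumulated recombination events.
* **Stepwise removal tests** use partial (type-III-like) sums of squares;
  sequential alternatives would make the result order-dependent.
* **V_P for PVE** uses raw phenotypic variances (see above).
* **Peak calling** is not defined by the method itself; the
  one-call-per-contiguous-run rule is the simplest deterministic convention
  and is what the power/FDR numbers are conditioned on.
* **H2 enforcement** iterates the single-multiplier CM update to joint
  convergence rather than re-solving the constrained maximization exactly at
  each step; the final constraint residual is checked (|Σₕ Δμₕ| below 10⁻⁶
  of the data scale in practice) and exposed on the fit object.

## Known limitations

* F2 populations (dominance) and two-dimensional epistatic scans are not
  implemented; only their threshold df rules are honored.
* The M_eff coefficients are built in only for 10 cM marker density at
  α ∈ {0.05, 0.01}.
* The constant 1.9 RIL expansion is used regardless of marker density,
  although the exact factor drifts from 1.98 (1 cM) to 1.83 (10 cM).
* Support-interval scoring with truths closer than 10 cM attributes each
  call to the nearest truth; very tightly linked QTL are not separately
  scoreable at the default scan step.
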