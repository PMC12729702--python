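# Methods

This note documents the statistical model behind `phenodiv`, the defaults
and numerical choices, and what the synthetic-data generator does and does
not emulate.

## Model and estimators

All analyses assume a balanced completely randomized design (CRD):
g genotypes, each measured in k ≥ 2 replicates, one-way model
`Y_ij = µ + G_i + e_ij` with genotype effects G_i and residuals e_ij.
Unbalanced inputs are rejected rather than approximated — every estimator
below relies on the exact expected-mean-squares algebra
E[QMg] = k·σ²_g + σ²_e, E[QMr] = σ²_e, which holds only at a common k.

Per trait the variance components are moment estimators:
σ²_f = QMg/k, σ²_e = QMr/k, σ²_g = (QMg − QMr)/k, and broad-sense
heritability h² = σ²_g/σ²_f = (QMg − QMr)/QMg. When QMg < QMr the raw
negative σ²_g is preserved and flagged while h² is floored at 0; the floor
makes the per-trial estimator positively biased near h² = 0, which is why
estimator-null checks should pool mean squares across trials rather than
average floored per-trial h² values.

**CVe convention.** The environmental coefficient of variation uses the
replicate-level residual standard deviation: CVe = 100·√QMr/m, not
100·√(QMr/k)/m. Under this reading CVe coincides with the experiment-wide
CV and the ratio CVg/CVe equals √((QMg − QMr)/(k·QMr)); it is the only
convention under which published per-trait tables of this kind are
internally consistent (e.g. a trait with QMg = 720.45, QMr = 265.81, k = 4
giving h² = 63.1% and CVg/CVe = 0.65). Percentage-scale traits are analyzed
untransformed; CVs of 35–50% for emergence traits are expected and are not
a defect.

Pearson correlations are computed across genotype means (n = g, df = n − 2),
the convention used for published trait-correlation tables in this setting;
replicate-level correlation would mix environmental covariance into r.

## Scott–Knott

At each node the sorted means are split at the contiguous partition
maximizing the between-group sum of squares B₀ (ties → smallest split
index, for determinism). The test statistic is λ = π/(2(π−2)) · B₀/σ̂₀²
with σ̂₀² = (Σ(ȳᵢ − ȳ)² + ν·s²_ȳ)/(g + ν), s²_ȳ = QMr/k and ν the ANOVA
residual df; the split is accepted when λ exceeds the χ² quantile at
g/(π−2) degrees of freedom. Fractional df are evaluated with the continuous
χ² quantile (no rounding), and ν and s²_ȳ stay global during recursion while
g is the size of the node under test — both choices match the reference
implementations of the method. Letters run a, b, c, … from the highest-mean
group downward.

## Distances, Tocher, UPGMA/Mojena

The pooled residual covariance S = E/(g(k−1)) (E the within-genotype
sums-of-products matrix) is inverted by Cholesky solve; a condition-number
estimate above 1e12 raises an error advising trait removal, with an
optional explicit ridge (off by default — a silent pseudo-inverse would
change D² without warning). Mahalanobis D² then weights mean differences by
S⁻¹. The standardized mean Euclidean alternative z-scores each trait across
genotype means (sample sd) and averages the squared differences over traits
before the square root, so it is invariant to per-trait affine rescaling.

Published descriptions of this analysis chain are ambiguous about which
metric fed the Tocher clustering (the method is usually described on D²
while the accompanying tables are sometimes captioned with the standardized
Euclidean distance). Both metrics are implemented; the pipeline defaults to
Mahalanobis D² for Tocher and standardized Euclidean for UPGMA, and the
choice is a flag (`--distance`).

Tocher uses the classical Rao formulation: θ = max over genotypes of the
nearest-neighbor distance, computed once from the full matrix; clusters are
seeded with the closest unassigned pair and grow by admitting the candidate
with the smallest mean distance to the cluster while that mean is ≤ θ
(boundary admits, so a constant matrix forms one cluster). Ties break by
(distance, label index). The "modified Tocher" sequential variant is not
implemented.

UPGMA heights are the unweighted average cross-pair distances themselves
(hclust convention, not halved) — this is the scale on which Mojena's rule
h\* = mean + c·sd (sample sd over the g−1 heights) operates; halving
appears only in the Newick export, where leaf-to-root path length is half
the root height so that leaf-to-leaf path length equals the cophenetic
distance. The Mojena constant defaults to c = 1.25, the value recommended
in the clustering literature for this rule; it is exposed as a parameter
and the resulting cutoff is always reported, never hard-coded. The linkage,
cophenetic and flat-cut computations are delegated to
`scipy.cluster.hierarchy` (average linkage is exactly UPGMA); tests verify
the heights against a naive O(n³) average-linkage reference and the Newick
round trip against an independent tree parser.

## Singh importance and canonical variates

Singh's decomposition keeps signed per-pair contributions
c_j = δ_j·(S⁻¹δ)_j and sums them over pairs, preserving the exact identity
Σ_j S_j = Σ_pairs D². With strongly correlated traits an individual trait's
contribution can be negative (and another's can exceed 100%); in the
data regime this package targets they remain positive. No absolute values
are taken — doing so would break the identity with total divergence.

CVA solves B v = λ W v on replicate-level data (B between-genotype, W
pooled within-genotype sums of products) by Cholesky whitening of W and a
symmetric eigensolver, which is numerically stabler than forming W⁻¹B; at
most min(p, g−1) non-zero eigenvalues are kept. Proportions are invariant
to any invertible linear transform of the trait space (tested).

## Emergence metrics

SE, ESI (Maguire) and MET (Edmond–Drapalla) are computed per replicate from
daily newly-emerged counts (a flag accepts cumulative series and
differences them). A replicate with zero emergence has SE = ESI = 0 but an
undefined MET; such replicates are excluded from the genotype MET mean and
the exclusion count is reported (`n_met`). Days are counted after sowing,
and the observation window defaults to 90 days.

## Synthetic-data generator

The generator runs the CRD model forward: genotype effect vectors from
MVN(0, D_g R_g D_g) and residuals from MVN(0, D_e R_e D_e), with per-trait
genetic variances obtained from target heritabilities by inverting the
expected-mean-squares algebra, σ²_g = h²σ²_e/(k(1−h²)), so E-recovery of
h² is exact by construction. Defaults describe a 38-genotype × 4-replicate
trial with three populations (13 + 8 + 17 genotypes), the ten standard
diaspore traits (FL, FD, FFM, EL, EW, ET, EM, SE, ESI, MET) with grand
means near the reported population medians, residual variances equal to
the reported residual mean squares, target h² equal to the reported
per-trait values (63.1–98.5%), and the reported trait-correlation matrix
(positive definite as printed, smallest eigenvalue ≈ 0.016) as the genetic
correlation matrix. Environmental correlations default to identity.
Populations carry labels but no mean effect by default (matching the
one-way model); an optional per-population mean shift enables
between-population contrasts.

Emergence kinetics: per-genotype final emergence probability uniform on
(0.05, 0.75) — spanning the reported population means (11–30%) up to the
best single genotype (75%) — binomial final counts over 25 sown seeds, and
lognormal emergence timing with median 40 days and log-sd 0.35, truncated
at the 90-day window and binned to integer days, which reproduces the
reported MET range (≈36–54 days).

Randomness uses sub-streams keyed (seed, role, genotype[, replicate]);
standard normals are drawn trait-by-trait and mixed through the Cholesky
factor, whose leading block is unchanged when a trait is appended, so
adding traits never perturbs existing columns. Identical seeds give
byte-identical CSVs.

**What the generator does not emulate** — and therefore what passing tests
do not demonstrate about real data: traits are unbounded Gaussians, so
percentage traits can stray outside [0, 100] (bounding them would bias the
variance-component recovery the generator exists to test); there are no
genotype × environment interactions, spatial field effects, measurement
rounding, or between-population genetic structure by default; and the
Gaussian phenotype columns for SE/ESI/MET are generated independently of
the emergence-count series rather than derived from it. Recovery of a
published trial's *specific* group memberships is out of reach regardless,
since that depends on the unpublished raw data.

## Problem sizes and tolerances

Simulation-based checks use 200 trials per heritability target (recovery
within ±0.03 of {0.60, 0.90, 0.98}) and 500 trials for the expected-mean-
squares identities (within 2%), at the study design g = 38, k = 4 — sizes
at which the Monte-Carlo standard error is comfortably below the asserted
bands. Oracle-equivalence tests run at tolerance 1e−8 (eigenvalues,
identity-covariance D²) and 1e−6 relative (Singh sum identity). Scott–Knott
agreement with the enumeration oracle is exact (same partitions) for
g ≤ 8 random instances.
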