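# Methods

`pharmgbc` reimplements, as a tested pipeline over synthetic data with known
ground truth, the analysis chain used in pharmacological resting-state fMRI
studies of drug-induced connectivity change: per-session denoising and global
brain connectivity (GBC), drug-minus-placebo (Δ) maps, PCA across subjects
with permutation significance, participation-ratio effective dimensionality,
spatial-autocorrelation-preserving gene-map association, and mass-univariate
brain–behavior mapping with single-subject projections.

## Connectivity pipeline

A scan is a frames × parcels BOLD matrix with motion traces. Denoising
follows the standard scrub-then-regress recipe:

- **Scrubbing.** A frame is flagged when framewise displacement exceeds
  0.5 mm or the normalized intensity RMS exceeds 1.6× the scan's median RMS;
  the frames immediately before and after any flagged frame are discarded
  too. Subjects with more than 50% flagged frames are excluded outright.
  Fewer than 30 surviving frames raises an error (configurable): correlation
  estimates below that are not usable.
- **High-pass filter, 0.008 Hz.** Implemented as discrete-cosine basis
  regression: every DCT regressor with frequency below the cutoff (plus the
  intercept) is projected out. This removes DC exactly, has no filter
  ringing, and composes with the nuisance design in one joint OLS.
- **Nuisance regression.** Arbitrary nuisance columns, their backward-
  difference first derivatives (zero first row, preserving frame count), the
  optional global mean signal (GSR) and its derivative, and the DCT columns
  enter a single joint regression; residuals are exactly orthogonal to every
  regressor. Collinear columns are dropped with a warning. Joint rather than
  sequential regression avoids re-introducing removed variance.
- **FC and GBC.** Pearson correlations between all parcel pairs, |r| clipped
  at 1−1e−7, Fisher r-to-z. GBC(x) is the mean z over all y ≠ x. The
  self-correlation is excluded (including it would add atanh(1) = ∞);
  `include_self` exists as a flag for completeness.

## Neural PCA and permutation significance

The Δ-GBC PCA runs across subjects with parcels as features, centered but
not variance-scaled (Δ-GBC values share units; the behavioral PCA, whose
items do not, is scaled). The solution is an SVD; K = min(S−1, P) components
are kept internally. Signs are fixed so each loading correlates
non-negatively with the mean Δ map (ties: largest-|loading| parcel positive).

Significance uses a parcel-shuffle null: each permutation independently
shuffles every subject's parcel vector, the PCA is refit, and the variance
fraction at each rank is recorded; p_k = (1 + #{null ≥ observed})/(n_perm+1).

**Retention is sequential**: components are retained while p_k < 0.05 and
retention stops at the first non-significant rank. A marginal reading
("every component with p < 0.05") admits about 0.05·K false components under
the global null — with K ≈ 31–39 that is one or two spurious components in
most null datasets — whereas a rank-k component is only interpretable when
all larger components are above chance. The sequential rule gives a ~5%
family-wise chance of retaining anything under the null.

Network summaries average a Z-scored map within each network and test the
association-vs-sensory contrast by permuting class labels across parcels
(10,000 draws, two-tailed); parcels within a network are not independent, so
no parametric two-sample test is assumed.

## Effective dimensionality

PR = (Σ λ̄_i²)⁻¹ with λ̄_i = λ_i/Σλ over eigenvalues of the feature-centered
sample covariance (eigenvalues below 1e−12·λ_max set to zero). PR is 1 for
rank-1 data and N for N equal eigenvalues. Because PR depends on sample
size, condition comparisons use equal-n subsample distributions — full
enumeration, leave-one-out jackknife, or seeded random distinct subsets —
followed by a one-way ANOVA and pairwise Welch t-tests with Bonferroni
correction (Welch because subsample distributions need not share variance).

Two caveats the tests make explicit:

- With iid subject scores the *sample* spectrum of a planted-k condition is
  spread by Wishart sampling (PR ≈ k/(1+k/S), not k). When the planted
  dimensionality itself is the quantity under study, the generator's
  `orthonormal_scores=True` orthonormalizes the score matrix so the cohort's
  sample spectrum equals the planted one exactly; two independent cohorts
  with the same planted k are then genuinely exchangeable, which is what
  makes an "8-dim vs 8-dim indistinguishable" claim testable at all.
- Jackknife/subsample PR values are pseudo-replicates, so the ANOVA and
  t-tests describe the distributions, not independent samples; degrees of
  freedom are reported from the actual inputs.

## Surrogate-map gene association

Correlating two spatially smooth cortical maps inflates parametric p-values
(neighbouring parcels are not independent). The null here preserves the
target map's spatial autocorrelation, summarized by its binned empirical
variogram γ(h) = ½·mean over parcel pairs in distance bin h of (v_i − v_j)²,
with 25 equal-count bins by default. Each surrogate is built per hemisphere
and merged: (1) permute the target's values; (2) smooth with a row-normalized
exponential distance-decay kernel over the k nearest neighbours, for each k
in {3, 5, 10, 20, 50, 100} (k = 0, the unsmoothed permutation, is also a
candidate so targets without autocorrelation reduce to plain permutation
nulls); (3) rescale the candidate — scaling a map by a multiplies its
variogram by a², so the best a² ≥ 0 is a one-parameter least-squares fit to
the target variogram; (4) keep the candidate with the smallest variogram SSE.
A two-parameter scale-plus-nugget fit (adding white noise to match a
variogram offset) was evaluated and rejected: the realized nugget noise
widened the null correlation distribution and degraded type-I calibration.

The test statistic is the Pearson correlation of the gene map with the
target; the null is its correlation with each surrogate;
p = (1 + #{|r_null| ≥ |r_obs|})/(M + 1), two-tailed. Calibration on
independent smooth fields (exponential correlation scale 1.0 on the unit
sphere, P = 200, M = 1000) yields uniform p-values while the naive
parametric test rejects at ~6–8× its nominal level. The p-value floor is
1/(M+1); M = 1000 serves tests and per-subject profiles, larger M is only a
cost question.

Gene screening removes maps whose differential stability lies in the 0 ± 0.1
ambiguity band; multiple tests are corrected by Benjamini–Hochberg FDR.
Per-subject profiles run the surrogate test of each subject's Δ map against
each named gene map (ensemble generated from that subject's own map) and
label subjects by the sign pair of their correlations (e.g. "+−" for
SST-positive/PVALB-negative coupling).

## Behavioral model

The battery mirrors an acute-pharmacology psychosis assessment: 30 PANSS
items (Positive 7, Negative 7, General 16) plus one spatial working-memory
cognition score — 31 Δ variables. Missing cells are imputed with the column
mean (which leaves column means unchanged). The behavioral PCA standardizes
items to unit variance; its permutation null shuffles subject order
independently within each item column; retention is sequential as above.
Subscale scores are sums of member items; the three-factor scheme covers all
30 PANSS items exactly once, while the shipped five-factor alternative is
the 20-item consensus model (Positive, Negative, Disorganized, Excited,
Depressed), which by design leaves some items unassigned — the config
validator enforces full coverage only for schemes that declare it.

The Pitman–Morgan test compares variances of paired score vectors:
t = (F − 1)·√(S − 2) / (2·√(F(1 − r²))), F = s_x²/s_y², df = S − 2,
two-tailed. It is algebraically the t-test of corr(x+y, x−y), which the
suite uses as an independent oracle. At r → ±1 with F ≠ 1 the statistic
diverges (p → 0); F = 1 gives t = 0.

## Neuro-behavioral mapping

A standardized behavioral score is regressed on Δ-GBC at every parcel; the
slope map is Z-scored across parcels. Family-wise error over parcels is
controlled by subject-shuffle permutation with the max-statistic rule
(exactly valid, assumption-light); TFCE (E = 0.5, H = 2, graph
connected-component formulation over a k-nearest-neighbour parcel adjacency,
k = 6) is available where spatially extended effects are expected. Power of
any FWER-valid test at this scale is bounded: with S = 40 and P = 200 the
permutation null of the max |slope| sits near 0.59 while a per-parcel
r = 0.6 effect yields an observed slope of ~N(0.6, 0.128²), i.e. ~55–65%
detection; single-parcel effects need r ≳ 0.7 to be reliably detected at
this resolution, and the test suite documents this operating point.

Subject projections correlate each subject's Δ map with a reference map and
Z-score the r values across the cohort; constant maps are flagged invalid
rather than scored. The gene-coupling analysis correlates each subject's
SST−PVALB association difference with their projection score.

## Synthetic data: what it emulates, and what it does not

- **Atlas.** Parcel centroids on a Fibonacci lattice over the unit sphere
  (deterministic, non-degenerate pairwise distances); hemisphere from the
  sign of the first coordinate; parcels split evenly across 12 networks,
  half association (DMN, FPN, LAN, OAN, VMM, PMM, CON, DAN) and half sensory
  (AUD, VIS1, SOM, VIS2).
- **Sessions.** One-factor BOLD model x_p(t) = w_p·g(t) + ε_p(t) with unit
  Gaussian factor and noise, so the expected inter-parcel correlation is
  r_pq = w_p w_q/√((w_p²+1)(w_q²+1)), monotone in the weights — GBC rank
  order recovers the weight map. Motion spikes are injected into the FD/RMS
  traces only; the BOLD stays clean, so scrubbing is tested on its flag
  logic, not on artifact modelling. Defaults mirror the study dimensions at
  desk cost: 40 subjects × 2 conditions, 200–718 parcels, 400 frames at
  TR = 0.7 s.
- **Δ-GBC maps.** mean map + Σ_k score_sk·√λ_k·u_k + iid noise with
  orthonormal planted components; u_1 contrasts association vs sensory
  parcels so network summaries have planted signal. Recovery of a planted
  subspace is governed by spiked-covariance (BBP) theory: with aspect ratio
  γ = P/S, a component with variance λ is rotated by sin²θ ≈ γσ²/λ, so
  recovery within 10° at γ = 5 needs λ/σ² ≳ 165. The recovery tests use
  λ/σ² = (2000, 1000, 500) — i.e. spectrum (20, 10, 5) at noise 0.1 —
  which clears that bound with margin.
- **Gene maps.** Gaussian fields with exponential spatial covariance
  exp(−d/scale) over centroids, mixed with a standardized target so the
  planted correlation holds exactly in-sample (the field is residualized
  against the target before mixing). One parameter controls autocorrelation,
  which is what the surrogate calibration needs.
- **Behavior.** Linear factor model: scores × coupling + iid noise, with
  optional missing-cell injection for the imputation path.
- **End-to-end chain.** One planted component drives both the drug shift of
  the session weights and the behavioral battery. The chain runs without
  GSR: the generator's global factor is the planted signal and the planted
  contrast map is mean-zero, so GSR would cancel the score-linear part of
  Δ-GBC exactly. On real data GSR removes spatially persistent artifact;
  this generator plants no artifact, so the choice tests the pipeline
  without destroying its target.

Passing tests therefore demonstrate the statistical machinery — estimator
correctness, null calibration, planted-truth recovery at realistic sizes —
not robustness to hemodynamics, physiological noise, spatial artifact
structure, or real PANSS psychometrics, none of which the generator
emulates.

## Numerical choices

- |r| clipped at 1−1e−7 before atanh; clip value returned for degenerate
  (identical) series rather than ±∞.
- PCA sign convention as above; eigenvalues from squared singular values
  over (S−1).
- PR eigenvalue floor 1e−12·λ_max.
- Permutation p-values always use the add-one form (1+#)/(n+1), bounded away
  from zero.
- Variogram bins are equal-count (robust to non-uniform pair-distance
  densities); fewer distinct distances than bins reduces the bin count with
  a warning.
- TSVs are written with `%.17g` and read with round-trip float parsing, so
  generated files reproduce arrays bit-exactly.
- Random subsets in `pr_distribution` are distinct by construction
  (rejection sampling on subset identity), so `n_draws` may not exceed
  C(n, n_sub).

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks run at 40 subjects × 200 parcels with 1000
permutations or surrogates and 100–200 replicates; the full-session chain
uses 400-frame scans. These sizes keep every planted effect in the regime
the theory above prescribes while the whole suite stays desk-scale.
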