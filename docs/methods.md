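# Methods

## Scope and data model

The package analyses per-subject parcellated BOLD tables (T timepoints × N
channels, tab-separated with a header of channel labels), a phenotype table
(subject_id, score, sex ∈ {0,1}, age in years, mean framewise displacement
in mm), and a YAML map from channel label to large-scale network name.
Subjects with mean FD above 0.2 mm are excluded at read time (configurable);
subject matching between tables is by exact string ID, and unmatched
subjects are reported and excluded, never imputed. Network-level signals,
where needed, are the mean of the channels mapped to a network; the first
eigenvariate is a common alternative but the mean is the default convention
here.

## Hidden Markov model

States are multivariate Gaussians over the N channels; the latent chain is
first-order Markov. Estimation is maximum-likelihood EM (Baum–Welch). A
variational-Bayes treatment with priors over state parameters is the other
established route; ML-EM with restart selection by final log-likelihood was
chosen because it has no free prior hyperparameters and the selection-by-
objective structure is the same. Details that matter:

- **Scaling, not raw probabilities.** Forward–backward runs on emission
  densities rescaled by their per-timepoint maximum with per-step
  renormalization of the forward variables (the classical scaling scheme);
  the log-likelihood is recovered from the accumulated scale factors, so
  concatenations of ~10^5 timepoints cannot underflow. Viterbi runs in log
  space; ties break toward the lowest state index.
- **Subject boundaries.** The initial distribution is re-applied at the
  start of every subject and no transition is counted across a boundary.
  Sequences of equal length are batched through the recursions (one
  vectorized step per timepoint for the whole cohort), which is what makes
  cohort-scale fits cheap.
- **Initialization.** k-means on timepoints (one init, seeded per restart)
  for the means; pooled data covariance for every state; uniform initial
  distribution; transition matrix with 0.9 diagonal. Restart r uses
  `random_state + r`.
- **Regularization.** When an M-step covariance has condition number above
  1e10 it receives a ridge of 1e-6 × mean diagonal; a state whose total
  responsibility collapses keeps its previous covariance with a small ridge
  and the event is logged. EM stops when the absolute log-likelihood
  improvement falls below `tol` (default 1e-6, mildly scaled for very large
  |log L|); non-convergence within `max_iter` returns the best-so-far with
  a warning.
- **Model order.** `scan_states` refits K ∈ {8…12} over independent runs
  and summarizes run-to-run stability as the mean pairwise adjusted Rand
  index of the Viterbi paths (ARI is label-permutation invariant, so no
  state matching is needed); this supports a stability-based choice of K.
  The pipeline default is K = 8 with 10 restarts.

**Metrics.** FO, MaxFO and SR are computed from the hard Viterbi path by
default, making SR a literal switch count divided by T; posterior-weighted
occupancy is available via `occupancy="posterior"`. Whether occupancy is
hard or posterior-weighted is a genuine convention choice; hard paths were
made the default so that FO sums to one exactly and SR has a direct
counting interpretation.

## Network temporal variability

For window length l the series is cut into n = ⌊T/l⌋ non-overlapping
windows anchored at t = 0 (remainder discarded; anchoring is a convention —
"non-overlapping" is the substantive choice). Within each window the
Pearson FC pattern of a network (strict upper triangle of its block) or
network pair (full cross-block) is vectorized, and variability is one minus
the mean Pearson correlation over distinct window pairs, averaged over
l = 20, 22, …, 40. An alternative variance-based functional (variance of FC
entries across windows) exists in the literature; the pattern-correlation
form is implemented because it is scale-free and bounded in [0, 2]. FC
vectors are not Fisher-z transformed before pattern correlation; pattern
correlation of a monotone transform changes values only marginally and the
untransformed form is the default; a `fisher_z` flag on the variability
functions applies arctanh to window FC before pattern correlation for
sensitivity analyses.

Within-network patterns need at least 2 FC entries, i.e. at least 3
channels per network; this is enforced with a clear error. The vectorized
implementation (batched over features sharing a pattern size) is tested to
equal the explicit pairwise loop to 1e-12.

## Association battery

Partial correlation residualizes feature and score on [1, sex, age,
mean FD] by OLS and correlates the residuals; the two-sided p comes from
t = r√(df/(1−r²)) with df = S − 2 − c. Benjamini–Hochberg FDR is applied
*within* each family — the K state-FO tests, the 17 within-network tests,
the 136 between-network tests — while MaxFO and SR are reported at raw p,
matching how these two global metrics are conventionally reported; pooling
the 17 + 136 variability tests into one family is the main alternative and
would be slightly more conservative. Network contributions sum the r-values
of significant between-network pairs into both endpoint networks and rank
networks by the cumulative r.

## Synthetic cohorts

The generator's defaults are the study conditions the analysis targets:
696 subjects, T = 242 volumes, K = 8 states, the 17 Schaefer networks, age
19.42 ± 1.38 years, male fraction 204/696, mean FD uniform on [0, 0.2] mm.
Three channels per network (N = 51) stand in for the ~23 Schaefer parcels
per network — the smallest count for which within-network pattern
variability is defined, keeping simulation affordable.

Per subject s: stickiness θ_s ~ U(0.80, 0.98) (dwell times of tens of
volumes at TR scale) sets a transition matrix with diagonal θ_s and uniform
off-diagonal mass; the state path drives Gaussian emissions whose means are
network-level ±(separation/2) loadings with distinct random sign patterns
per state, and whose covariances share a network-block correlation template
(within 0.5, between 0.1) with state-specific sign flips on random blocks.
A drift amplitude δ_s ~ U(0, 0.5) modulates each off-diagonal covariance
entry by 1 + δ_s·sin(2πt/P + φ_s)·G_ij, with G a fixed random symmetric ±1
pattern per subject, projected back to SPD. The sign pattern is essential:
a uniform scaling of all off-diagonals would leave the FC *pattern* — and
hence pattern-correlation variability — unchanged. The period defaults to
one full cycle per scan (P = T): much shorter periods average out within
windows, longer-than-scan periods under-sample the cycle; this was fixed
once from a design scan over P before any downstream checks were frozen.
The sinusoid is quantized to 41 levels so Cholesky factors are shared
within (state, level) groups; the resulting modulation resolution
(δ·0.05) is negligible against windowed-FC sampling noise.

The score is `z(−b_SR·z(θ_s) + b_var·z(δ_s)) + 0.1·sex + 0.1·z(age) +
0.1·z(FD) + N(0, noise_sd)` with b_SR = b_var = 0.3 and noise_sd = 1 by
default. Standardizing θ and δ before weighting gives the two couplings
equal leverage regardless of their raw scales; without it the drift term
(sd ≈ 0.14) would swamp the stickiness term (sd ≈ 0.05) and the planted
MaxFO association would vanish. By construction the score then rises with
true SR and planted variability and falls with MaxFO, and zeroing both
couplings yields an exact null.

**What the generator does not emulate:** hemodynamic convolution and
autocorrelation, scanner noise spectra, physiological confounds,
non-Gaussian emission tails, site effects, and any item-level structure of
the depression scale (only a scalar score is consumed). Passing tests
therefore validate the *estimators and inference machinery* under the
model's own assumptions, not robustness to real-fMRI artefacts.

## Problem sizes in tests and acceptance

Oracle checks use exhaustive enumeration at K ≤ 3, T ≤ 6. Parameter
recovery uses S = 20, T = 242, K = 3, 4-SD separations. Planted-effect sign
recovery uses S = 300 per replicate (20 replicates in the test suite, 5 in
the acceptance script) with single-restart, iteration-capped EM — at 4-SD
class separations the decoded paths are already stable well before full
convergence, and these sizes keep a full run in minutes on one CPU. Null
calibration uses S = 150 cohorts with zero couplings.

## Known limitations

- ML-EM can reach local optima; restarts mitigate but do not eliminate
  this, and the stability scan (ARI across runs) is the recommended guard.
- The EM monotonicity guarantee holds only while no covariance
  regularization event fires in that iteration; events are logged.
- Between-network variability is defined for networks with a single
  channel, but within-network variability requires ≥ 3 channels.
- With K = 8 states at T = 242, per-subject FO estimates are noisy
  (~30 volumes per state on average); associations at realistic effect
  sizes need hundreds of subjects, as in the target design.
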