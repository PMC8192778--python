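# rrbdyn

Dynamic brain-circuit analysis of restricted/repetitive-behavior (RRB)
subtypes in autism.

Restricted and repetitive behaviors — circumscribed interests (CI),
insistence on sameness (IS) and repetitive motor behaviors (RM) — are a
core, heterogeneous feature of autism spectrum disorder.  A circuit-level
hypothesis holds that the *cognitive* components (CI, IS) reflect aberrant
time-varying interactions within the cognitive-control circuit formed by
the salience (SN), central-executive (lCEN/rCEN) and default-mode (DMN)
networks, while the *motoric* component (RM) reflects aberrant dynamics of
the cortico–subcortical motor circuit (cMN, sMN).  `rrbdyn` implements the
full analysis pipeline needed to test this dissociation on network
time-series data, plus a synthetic cohort generator with known ground
truth so every stage is verifiable without access to clinical data.

## Method

For each subject with standardized network time series $x_t \in
\mathbb{R}^K$ (sampling interval TR), the pipeline computes:

1. **Tapered sliding-window connectivity.** For each window of $W$ samples,
   the weighted correlation matrix $R_w$ with exponentially decaying weights
   $w_j \propto e^{-\lambda (W-1-j)}$ (newest sample heaviest; rectangular
   taper available as a robustness option).
2. **Group-wise brain states.** Windows from all subjects of a group are
   vectorized (strict lower triangle, Fisher z) and clustered with k-means;
   the number of states $k$ maximizes the mean silhouette over a candidate
   range, per group (repertoires may differ between groups).
3. **Network interaction indices.** Per window,
   $\mathrm{CNII} = \tfrac12\big(r(\mathrm{SN},\mathrm{lCEN}) +
   r(\mathrm{SN},\mathrm{rCEN})\big) - r(\mathrm{SN},\mathrm{DMN})$ and
   $\mathrm{MNII} = r(\mathrm{cMN},\mathrm{sMN})$.  Subject-level mean and
   SD are taken across dynamic brain states (CNII, default) or across all
   windows (MNII, default).
4. **Group inference.** Two-sided pooled-variance t-tests with Cohen's
   d, and a covariate-adjusted linear model (age, sex, head motion, IQ).
5. **Brain–behavior prediction.** Within the ASD group, OLS of CI/IS/RM
   factor scores on {mean CNII, SD CNII} or {mean MNII} with permutation
   inference on the overall F, and k-fold cross-validation reporting
   $r(\hat y_{\text{out-of-fold}}, y)$ with a permutation p obtained by
   rerunning the whole cross-validation under permuted outcomes.
6. **RRB factor scores.** PCA of the 9-item ADI-R RRB correlation matrix
   (special codes 6/7/8 recoded to 0), components retained by the
   eigenvalue->1 rule, varimax rotation with Kaiser normalization,
   regression-method subject scores, components labeled CI/IS/RM by their
   top-loading items.

The synthetic generator draws, per group, a repertoire of PSD correlation
matrices, switches between them with a Markov chain, and plants effects in
exactly the statistics the pipeline measures: a Cohen's d on mean CNII
(ASD-like lower) and mean MNII (higher), wider state-level CNII
variability, and a correlation $r$ between NII features and the latent
CI/IS/RM factors that generate the discretized item scores.

## Worked example

```python
from rrbdyn import CohortSpec, simulate_cohorts, two_sample_test
from rrbdyn.nii import COGNITIVE_CIRCUIT, windowed_nii
from rrbdyn.windows import make_taper, sliding_window_connectivity

spec = CohortSpec(seed=1)          # 48 ASD-like / 48 TD-like, 6-min series
cohort = simulate_cohorts(spec)

kernel = make_taper(spec.analysis_window_samples)   # 15-sample exp. taper
mean_cnii = {"ASD": [], "TD": []}
groups = dict(zip(cohort.manifest.subject_id, cohort.manifest.group))
for ts in cohort.timeseries:
    wc = sliding_window_connectivity(ts, kernel, step=1)
    mean_cnii[groups[ts.subject_id]].append(
        windowed_nii(wc, COGNITIVE_CIRCUIT).mean())

res = two_sample_test(mean_cnii["ASD"], mean_cnii["TD"], feature="mean CNII")
print(f"mean CNII: t({res.df:.0f}) = {res.t:.2f}, p = {res.p_two_sided:.2g}, "
      f"|d| = {res.cohens_d_magnitude:.2f}")
print(f"group means: ASD = {res.group_means['ASD']:.3f}, "
      f"TD = {res.group_means['TD']:.3f}")
```

prints

```
mean CNII: t(94) = -4.48, p = 2.1e-05, |d| = 0.91
group means: ASD = -0.412, TD = -0.146
```

The cohort was generated with a planted group difference of d = 0.8 on
mean CNII; the observed |d| = 0.91 is one sampling fluctuation of that
effect at n = 48 per group, in the planted direction (ASD-like group shows
weaker SN-CEN engagement relative to SN-DMN decoupling).

A command-line interface mirrors the library:

```bash
rrbdyn simulate --seed 1 --out-dir cohort/
rrbdyn run-all cohort/manifest.csv cohort/timeseries --items cohort/items.csv \
       --out-dir results/
```

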