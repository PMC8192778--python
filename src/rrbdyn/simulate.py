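"""Synthetic cohort generator with known ground truth.

Each subject is a multivariate Gaussian time series whose correlation
structure switches among a small repertoire of latent states following a
Markov chain; the two groups (ASD-like, TD-like) have group-specific
repertoires.  Group effects are planted directly in the statistic the
pipeline measures: the SN-CEN / SN-DMN entries of the ASD-like states are
shifted so the population mean CNII differs from the TD-like group by a
requested Cohen's d (and likewise the cMN-sMN entry for MNII).  Behavioral
item scores are generated from three latent factors (CI, IS, RM) whose
correlation with the realized NII features is planted.

Converting a Cohen's d into a correlation-entry shift requires the
between-subject standard deviation of the measured mean NII, which depends
on scan length and windowing; the generator estimates it with a small
internal pilot simulation (unshifted states) that is part of cohort
construction and fully determined by the cohort seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import GenerationError, ValidationError
from .nii import COGNITIVE_CIRCUIT, MOTOR_CIRCUIT, windowed_nii
from .windows import DEFAULT_NETWORKS, NetworkTimeSeries, make_taper, sliding_window_connectivity

GROUPS = ("ASD", "TD")

#: Which latent factor each ADI-R item loads on in the generator.
ITEM_FACTOR = {67: "IS", 68: "CI", 69: "RM", 70: "IS", 71: "CI",
               75: "IS", 76: "CI", 77: "RM", 78: "RM"}

#: Fixed cut points (standard-normal quantiles) for discretizing latent
#: item values onto the 0-3 scale; mass roughly (35, 30, 23, 12)%.
_CUT_QUANTILES = (0.35, 0.65, 0.88)


@dataclass(frozen=True)
class StateSpec:
    """One latent connectivity state: a PSD correlation matrix."""

    correlation_matrix: np.ndarray
    label: int

    def __post_init__(self):
        m = np.asarray(self.correlation_matrix, dtype=float)
        object.__setattr__(self, "correlation_matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("state correlation matrix must be square")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValidationError("state correlation matrix must have unit diagonal")
        if np.max(np.abs(m - m.T)) > 1e-10:
            raise ValidationError("state correlation matrix must be symmetric")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(m)[0] < -1e-10:
            raise ValidationError("state correlation matrix must be PSD")


@dataclass
class CohortSpec:
    """Generative conditions for a two-group cohort.

    Defaults emulate the study conditions: 48 subjects per group, 6-minute
    scans (180 samples at TR = 2 s), a four-state ASD-like repertoire
    versus two TD-like states, and planted effects of d = 0.8 on mean CNII
    (ASD lower), d = 0.5 on mean MNII (ASD higher) and r = 0.4 between NII
    features and the matching behavioral factors.
    """

    n_per_group: int = 48
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    n_states: dict = field(default_factory=lambda: {"ASD": 4, "TD": 2})
    states_per_group: dict | None = None  # group -> sequence of StateSpec
    transition_matrix: dict | None = None  # group -> row-stochastic matrix
    mean_dwell: float = 40.0  # samples
    noise_sd: float = 0.2
    ar_coef: float = 0.0
    state_separation: float = 0.6
    state_balance_ratio: float | None = 1.35
    planted_cnii_effect_d: float = 0.8
    planted_mnii_effect_d: float = 0.5
    state_cnii_spread: float = 0.3  # +/- CNII offset of the extra ASD states
    planted_behavior_r: float = 0.4
    item_loading: float = 0.8
    item_noise_sd: float = 0.4
    special_code_rate: float = 0.03
    analysis_window_seconds: float = 30.0
    seed: int = 0

    def validate(self):
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        W = self.analysis_window_samples
        if self.n_timepoints < 4 * W:
            raise ValidationError("n_timepoints must be >= 4 x window length")
        if not abs(self.planted_behavior_r) < 1:
            raise ValidationError("|planted_behavior_r| must be < 1")
        if self.mean_dwell < 2:
            raise ValidationError("mean_dwell must be >= 2 samples")
        if not -1 < self.ar_coef < 1:
            raise ValidationError("ar_coef must be in (-1, 1)")
        if self.transition_matrix is not None:
            for g, P in self.transition_matrix.items():
                P = np.asarray(P, dtype=float)
                if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
                    raise ValidationError(f"transition rows for {g} must sum to 1")

    @property
    def analysis_window_samples(self) -> int:
        return max(2, int(round(self.analysis_window_seconds / self.tr_seconds)))


@dataclass
class SubjectGroundTruth:
    """Latent truth for one simulated subject."""

    subject_id: str
    group: str
    state_path: np.ndarray  # 1-based state label per time point
    true_state_cnii: dict  # state -> noise-attenuated population CNII
    true_state_mnii: dict
    true_mean_cnii: float  # occupancy-weighted over the realized path
    true_mean_mnii: float


@dataclass
class CohortGroundTruth:
    subjects: dict  # subject_id -> SubjectGroundTruth
    states_per_group: dict  # group -> list of StateSpec
    cnii_shift: float
    mnii_shift: float
    pilot_sd: dict  # {"cnii": float, "mnii": float}


@dataclass
class SyntheticCohort:
    timeseries: list  # of NetworkTimeSeries, manifest order
    manifest: pd.DataFrame
    ground_truth: CohortGroundTruth
    spec: CohortSpec


def nearest_psd_correlation(matrix: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    evals, evecs = np.linalg.eigh(m)
    if evals[0] < 0:
        evals = np.clip(evals, 1e-8, None)
        m = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def _random_correlation(rng: np.random.Generator, n: int) -> np.ndarray:
    """A varied random correlation matrix from a two-factor model."""
    B = rng.uniform(-1.0, 1.0, size=(n, 2))
    S = B @ B.T + np.diag(rng.uniform(0.3, 1.0, size=n))
    d = np.sqrt(np.diag(S))
    return nearest_psd_correlation(S / np.outer(d, d))


def make_state_correlations(k: int, n_networks: int, separation: float = 0.6,
                            seed: int = 0, avoid=(), max_tries: int = 5000,
                            balance_ratio: float | None = None) -> list:
    """Draw k PSD correlation matrices, pairwise Frobenius distance >= separation.

    ``avoid`` lists additional matrices the new states must also keep their
    distance from (used when extending a repertoire).  With ``balance_ratio``
    the whole set is rejection-sampled until the largest internal pairwise
    distance is at most that multiple of the smallest, so the repertoire has
    no hierarchical super-cluster structure (silhouette-based selection of k
    is ill-posed when states pair up).
    """
    if not 0 < separation <= 2:
        raise ValidationError("separation must lie in (0, 2]")
    if n_networks < 2:
        raise ValidationError("n_networks must be >= 2")
    if balance_ratio is not None and balance_ratio < 1:
        raise ValidationError("balance_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    reference = [np.asarray(a, dtype=float) for a in avoid]

    def _ok_vs_reference(cand, others):
        return all(np.linalg.norm(cand - o) >= separation
                   for o in reference + others)

    if balance_ratio is None or k < 2:
        accepted, tries = [], 0
        while len(accepted) < k:
            if tries >= max_tries:
                raise GenerationError(
                    f"could not place {k} states at separation {separation} "
                    f"within {max_tries} draws")
            tries += 1
            cand = _random_correlation(rng, n_networks)
            if _ok_vs_reference(cand, [s.correlation_matrix for s in accepted]):
                accepted.append(StateSpec(correlation_matrix=cand,
                                          label=len(accepted) + 1))
        return accepted
    for _ in range(max_tries):
        cand = [_random_correlation(rng, n_networks) for _ in range(k)]
        ds = [np.linalg.norm(a - b)
              for i, a in enumerate(cand) for b in cand[:i]]
        if min(ds) < separation or max(ds) / min(ds) > balance_ratio:
            continue
        if all(_ok_vs_reference(c, []) for c in cand):
            return [StateSpec(correlation_matrix=c, label=i + 1)
                    for i, c in enumerate(cand)]
    raise GenerationError(
        f"could not place a balanced set of {k} states at separation "
        f"{separation} within {max_tries} draws")


def _transition_matrix(k: int, mean_dwell: float) -> np.ndarray:
    """Uniform-off-diagonal chain with p_stay = 1 - 1/mean_dwell."""
    if k == 1:
        return np.ones((1, 1))
    p_stay = 1.0 - 1.0 / mean_dwell
    P = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(P, p_stay)
    return P


def _markov_path(P: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    k = P.shape[0]
    cum = np.cumsum(P, axis=1)
    path = np.empty(T, dtype=int)
    path[0] = rng.integers(k)
    u = rng.random(T)
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def _attenuated(corr: np.ndarray, noise_sd: float) -> np.ndarray:
    """Population correlation after adding white measurement noise."""
    out = corr / (1.0 + noise_sd**2)
    np.fill_diagonal(out, 1.0)
    return out


def _state_nii(states, noise_sd: float, circuit) -> dict:
    names = DEFAULT_NETWORKS
    out = {}
    for s in states:
        eff = _attenuated(s.correlation_matrix, noise_sd)
        if circuit == "cognitive":
            sn, l, r, dmn = (names.index(n) for n in ("SN", "lCEN", "rCEN", "DMN"))
            out[s.label] = float((eff[sn, l] + eff[sn, r]) / 2 - eff[sn, dmn])
        else:
            c, m = names.index("cMN"), names.index("sMN")
            out[s.label] = float(eff[c, m])
    return out


def simulate_subject(spec: CohortSpec, group: str, seed: int,
                     subject_id: str | None = None,
                     states=None) -> tuple:
    """Simulate one subject; returns (NetworkTimeSeries, SubjectGroundTruth).

    States come from ``states`` if given, else from ``spec.states_per_group``;
    when neither is available an unshifted repertoire is generated from the
    cohort seed (planted group effects exist only at cohort level).
    """
    spec.validate()
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    if states is None:
        if spec.states_per_group is not None:
            states = spec.states_per_group[group]
        else:
            states = make_state_correlations(
                spec.n_states[group], len(DEFAULT_NETWORKS),
                spec.state_separation, seed=spec.seed + (0 if group == "ASD" else 1),
            )
    states = list(states)
    k = len(states)
    if spec.transition_matrix is not None and group in spec.transition_matrix:
        P = np.asarray(spec.transition_matrix[group], dtype=float)
    else:
        P = _transition_matrix(k, spec.mean_dwell)
    rng = np.random.default_rng(seed)
    T, K = spec.n_timepoints, len(DEFAULT_NETWORKS)
    path = _markov_path(P, T, rng)
    z = rng.standard_normal((T, K))
    if spec.ar_coef != 0.0:
        phi = spec.ar_coef
        for t in range(1, T):
            z[t] = phi * z[t - 1] + np.sqrt(1 - phi**2) * z[t]
    x = np.empty((T, K))
    for idx, s in enumerate(states):
        cov = s.correlation_matrix + spec.noise_sd**2 * np.eye(K)
        L = np.linalg.cholesky(cov)
        mask = path == idx
        x[mask] = z[mask] @ L.T
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    subject_id = subject_id or f"{group.lower()}_{seed}"
    ts = NetworkTimeSeries(subject_id=subject_id, network_names=DEFAULT_NETWORKS,
                           values=x, tr_seconds=spec.tr_seconds)
    cnii = _state_nii(states, spec.noise_sd, "cognitive")
    mnii = _state_nii(states, spec.noise_sd, "motor")
    labels = np.array([states[i].label for i in path])
    gt = SubjectGroundTruth(
        subject_id=subject_id, group=group, state_path=labels,
        true_state_cnii=cnii, true_state_mnii=mnii,
        true_mean_cnii=float(np.mean([cnii[l] for l in labels])),
        true_mean_mnii=float(np.mean([mnii[l] for l in labels])),
    )
    return ts, gt


def _circuit_pairs():
    names = DEFAULT_NETWORKS
    sn, l, r, dmn = (names.index(n) for n in ("SN", "lCEN", "rCEN", "DMN"))
    c, s = names.index("cMN"), names.index("sMN")
    return {"sn_lcen": (sn, l), "sn_rcen": (sn, r), "sn_dmn": (sn, dmn),
            "cmn_smn": (c, s)}


def _impose_entries(matrix: np.ndarray, targets: dict,
                    max_iter: int = 60) -> np.ndarray:
    """Fix selected off-diagonal entries while staying a PSD correlation.

    Alternating projections between the affine constraint (set the entries)
    and the PSD correlation set; ends on the PSD projection so the result
    is a valid state matrix, with the targeted entries met to ~1e-6.
    """
    m = matrix.copy()
    for _ in range(max_iter):
        prev = m
        for (i, j), v in targets.items():
            m[i, j] = m[j, i] = np.clip(v, -0.97, 0.97)
        m = nearest_psd_correlation(m)
        if np.max(np.abs(m - prev)) < 1e-12:
            break
    return m


def _build_asd_states(td_states, extras, cnii_shift: float, mnii_shift: float,
                      cnii_spread: float) -> list:
    """ASD-like repertoire: TD states plus extra states, circuit entries
    pinned to the TD repertoire average.

    The planted mean effect shifts every state's CNII by ``-cnii_shift`` and
    MNII by ``+mnii_shift``; the extra states additionally get symmetric
    ``+/- cnii_spread`` CNII offsets (mean-preserving), emulating a wider
    state repertoire without biasing the group mean.
    """
    P = _circuit_pairs()
    avg = {key: float(np.mean([s.correlation_matrix[ij] for s in td_states]))
           for key, ij in P.items()}
    # guarantee the ASD repertoire's state-level CNII spread exceeds the
    # TD repertoire's: the +/- offset grows with the TD states' own spread
    td_cnii = [(m[P["sn_lcen"]] + m[P["sn_rcen"]]) / 2 - m[P["sn_dmn"]]
               for m in (s.correlation_matrix for s in td_states)]
    td_sd = float(np.std(td_cnii, ddof=1)) if len(td_cnii) > 1 else 0.0
    cnii_spread = cnii_spread + np.sqrt(2) * td_sd if cnii_spread > 0 else 0.0
    out = []
    for s in td_states:  # shared states, shifted in place
        m = s.correlation_matrix
        targets = {
            P["sn_lcen"]: m[P["sn_lcen"]] - cnii_shift / 2,
            P["sn_rcen"]: m[P["sn_rcen"]] - cnii_shift / 2,
            P["sn_dmn"]: m[P["sn_dmn"]] + cnii_shift / 2,
            P["cmn_smn"]: m[P["cmn_smn"]] + mnii_shift,
        }
        out.append(_impose_entries(m, targets))
    n_extra = len(extras)
    for idx, s in enumerate(extras):
        if n_extra >= 2 and idx < 2 * (n_extra // 2):
            h = cnii_spread if idx % 2 == 0 else -cnii_spread
        else:
            h = 0.0  # odd leftover stays at the repertoire mean
        targets = {
            P["sn_lcen"]: avg["sn_lcen"] + h / 2 - cnii_shift / 2,
            P["sn_rcen"]: avg["sn_rcen"] + h / 2 - cnii_shift / 2,
            P["sn_dmn"]: avg["sn_dmn"] - h / 2 + cnii_shift / 2,
            P["cmn_smn"]: avg["cmn_smn"] + mnii_shift,
        }
        out.append(_impose_entries(s.correlation_matrix, targets))
    return [StateSpec(correlation_matrix=m, label=i + 1)
            for i, m in enumerate(out)]


def _mean_windowed_nii(ts: NetworkTimeSeries, window_samples: int) -> tuple:
    kernel = make_taper(window_samples, "exponential")
    wc = sliding_window_connectivity(ts, kernel, step=1)
    return (float(windowed_nii(wc, COGNITIVE_CIRCUIT).mean()),
            float(windowed_nii(wc, MOTOR_CIRCUIT).mean()))


def _pilot_sd(spec: CohortSpec, states: dict, rng: np.random.Generator,
              n_pilot: int = 128) -> dict:
    """Pooled between-subject SD of windowed mean NII, unshifted states."""
    W = spec.analysis_window_samples
    vals = {"cnii": [], "mnii": []}
    for group in GROUPS:
        for i in range(n_pilot):
            seed = int(rng.integers(2**31 - 1))
            ts, _ = simulate_subject(spec, group, seed, states=states[group])
            c, m = _mean_windowed_nii(ts, W)
            vals["cnii"].append(c)
            vals["mnii"].append(m)
    half = n_pilot
    out = {}
    for key, v in vals.items():
        a, b = np.array(v[:half]), np.array(v[half:])
        out[key] = float(np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2))
    return out


def _covariates(rng: np.random.Generator, group: str, n: int) -> pd.DataFrame:
    """Simple demographic distributions mirroring the cohort description."""
    age = np.clip(rng.normal(10.9, 1.8, n), 7.0, 14.0)
    iq_mu, iq_sd = (115, 16) if group == "ASD" else (118, 11)
    iq = rng.normal(iq_mu, iq_sd, n)
    sex = np.where(rng.random(n) < 7 / 48, "F", "M")
    motion = np.exp(rng.normal(-2.6, 0.4, n))  # mean FD around 0.08 mm
    return pd.DataFrame({"group": group, "age": age, "sex": sex, "iq": iq,
                         "motion": motion})


def resolve_states(spec: CohortSpec) -> tuple:
    """Draw, pin and (if requested) shift the group state repertoires.

    Returns ``(states, cnii_shift, mnii_shift, pilot_sd)``.  The whole
    construction, including the calibration pilot, is a deterministic
    function of ``spec``.
    """
    root = np.random.default_rng(spec.seed)
    td_seed, extra_seed, pilot_seed = (int(s) for s in
                                       root.integers(2**31 - 1, size=3))
    k_td, k_asd = spec.n_states["TD"], spec.n_states["ASD"]
    td_states = make_state_correlations(
        k_td, len(DEFAULT_NETWORKS), spec.state_separation, seed=td_seed,
        balance_ratio=spec.state_balance_ratio)
    extras = make_state_correlations(
        k_asd - k_td, len(DEFAULT_NETWORKS), spec.state_separation,
        seed=extra_seed, balance_ratio=spec.state_balance_ratio,
        avoid=[s.correlation_matrix for s in td_states],
    ) if k_asd > k_td else []
    cnii_shift = mnii_shift = 0.0
    pilot = {"cnii": float("nan"), "mnii": float("nan")}
    if spec.planted_cnii_effect_d != 0 or spec.planted_mnii_effect_d != 0:
        unshifted = {
            "ASD": _build_asd_states(td_states, extras, 0.0, 0.0,
                                     spec.state_cnii_spread),
            "TD": td_states,
        }
        pilot = _pilot_sd(spec, unshifted, np.random.default_rng(pilot_seed))
        atten = 1.0 + spec.noise_sd**2
        cnii_shift = spec.planted_cnii_effect_d * pilot["cnii"] * atten
        mnii_shift = spec.planted_mnii_effect_d * pilot["mnii"] * atten
    states = {
        "ASD": _build_asd_states(td_states, extras, cnii_shift, mnii_shift,
                                 spec.state_cnii_spread),
        "TD": td_states,
    }
    return states, cnii_shift, mnii_shift, pilot


def resolve_cohort_spec(spec: CohortSpec) -> CohortSpec:
    """Freeze the state repertoires into the spec (for replicate cohorts).

    Replicates of the same study conditions share one generative truth;
    vary ``seed`` on the returned spec to redraw subjects only.
    """
    states, *_ = resolve_states(spec)
    return replace(spec, states_per_group=states)


def simulate_cohorts(spec: CohortSpec) -> SyntheticCohort:
    """Simulate both groups with planted effects and a subject manifest."""
    spec.validate()
    root = np.random.default_rng(spec.seed)
    if spec.states_per_group is not None:
        states = {g: list(spec.states_per_group[g]) for g in GROUPS}
        cnii_shift = mnii_shift = 0.0
        pilot = {"cnii": float("nan"), "mnii": float("nan")}
        root.integers(2**31 - 1, size=3)  # keep stream aligned with resolve
    else:
        states, cnii_shift, mnii_shift, pilot = resolve_states(spec)
        root.integers(2**31 - 1, size=3)
    ts_list, gt_subjects, manifests = [], {}, []
    for group in GROUPS:
        cov = _covariates(np.random.default_rng(int(root.integers(2**31 - 1))),
                          group, spec.n_per_group)
        ids = [f"{group.lower()}{i + 1:03d}" for i in range(spec.n_per_group)]
        cov.insert(0, "subject_id", ids)
        manifests.append(cov)
        for sid in ids:
            seed = int(root.integers(2**31 - 1))
            ts, gt = simulate_subject(spec, group, seed, subject_id=sid,
                                      states=states[group])
            ts_list.append(ts)
            gt_subjects[sid] = gt
    manifest = pd.concat(manifests, ignore_index=True)
    gt = CohortGroundTruth(subjects=gt_subjects, states_per_group=states,
                           cnii_shift=cnii_shift, mnii_shift=mnii_shift,
                           pilot_sd=pilot)
    return SyntheticCohort(timeseries=ts_list, manifest=manifest,
                           ground_truth=gt, spec=spec)


# ---------------------------------------------------------------------------
# behavioral item scores


@dataclass
class BehaviorGroundTruth:
    factors: pd.DataFrame  # subjects x (CI, IS, RM) latent scores
    loadings: pd.DataFrame  # 9 items x 3 factors (planted pattern)
    planted_r: float


def _planted_loadings(loading: float) -> pd.DataFrame:
    lam = pd.DataFrame(0.0, index=list(ITEM_FACTOR), columns=["CI", "IS", "RM"])
    for item, fac in ITEM_FACTOR.items():
        lam.loc[item, fac] = loading
    return lam


def _items_from_factors(factors: pd.DataFrame, rng: np.random.Generator,
                        loading: float, noise_sd: float,
                        special_rate: float) -> pd.DataFrame:
    lam = _planted_loadings(loading).to_numpy()
    F = factors[["CI", "IS", "RM"]].to_numpy(dtype=float)
    latent = F @ lam.T + noise_sd * rng.standard_normal((len(factors), lam.shape[0]))
    total_sd = np.sqrt(loading**2 + noise_sd**2)
    cuts = total_sd * scipy.stats.norm.ppf(_CUT_QUANTILES)
    scores = np.digitize(latent, cuts)  # 0..3, fixed quantile cuts
    special = rng.random(scores.shape) < special_rate
    scores = np.where(special, rng.choice([6, 7, 8], size=scores.shape), scores)
    items = pd.DataFrame(scores, index=factors.index,
                         columns=[f"item_{i}" for i in ITEM_FACTOR])
    items.attrs["provenance"] = "raw"
    return items


def simulate_behavior(features: pd.DataFrame, spec: CohortSpec,
                      seed: int) -> tuple:
    """ADI-R-style item scores for ASD-like subjects.

    ``features`` must be indexed by subject_id with columns ``cnii_mean``,
    ``cnii_sd`` and ``mnii_mean``.  Latent CI correlates (by construction)
    with mean CNII, IS with CNII variability and RM with mean MNII at
    ``spec.planted_behavior_r``; nine item scores are generated from the
    planted three-factor loading pattern and discretized to the 0-3 range
    with occasional special codes 6/7/8.
    """
    required = ("cnii_mean", "cnii_sd", "mnii_mean")
    for col in required:
        if col not in features.columns:
            raise ValidationError(f"features missing column {col!r}")
        if features[col].isna().any():
            bad = features.index[features[col].isna()][0]
            raise ValidationError(f"missing {col} for subject {bad!r}")
    rng = np.random.default_rng(seed)
    r = spec.planted_behavior_r
    z = (features[list(required)] - features[list(required)].mean()) \
        / features[list(required)].std(ddof=1)
    z_cm, z_cs, z_mm = (z[c].to_numpy() for c in required)
    # CI and IS each correlate r with BOTH the mean and the variability of
    # CNII; the shared signal is their (standardized) sum.
    rho = float(np.clip(np.corrcoef(z_cm, z_cs)[0, 1], -0.5, 0.95))
    c2 = 2 * r**2 / (1 + rho)
    if c2 >= 1:
        raise ValidationError(
            "planted_behavior_r too large for the cognitive feature pair")
    cog = (z_cm + z_cs) / np.sqrt(2 * (1 + rho))
    noise = rng.standard_normal((len(features), 3))
    latent = np.column_stack([
        np.sqrt(c2) * cog + np.sqrt(1 - c2) * noise[:, 0],
        np.sqrt(c2) * cog + np.sqrt(1 - c2) * noise[:, 1],
        r * z_mm + np.sqrt(1 - r**2) * noise[:, 2],
    ])
    factors = pd.DataFrame(latent, index=features.index,
                           columns=["CI", "IS", "RM"])
    items = _items_from_factors(factors, rng, spec.item_loading,
                                spec.item_noise_sd, spec.special_code_rate)
    gt = BehaviorGroundTruth(factors=factors,
                             loadings=_planted_loadings(spec.item_loading),
                             planted_r=r)
    return items, gt


def simulate_item_table(n_subjects: int = 126, seed: int = 0,
                        item_loading: float = 0.8, item_noise_sd: float = 0.4,
                        special_code_rate: float = 0.03) -> tuple:
    """Stand-alone clinical-cohort item table (factors iid standard normal)."""
    rng = np.random.default_rng(seed)
    factors = pd.DataFrame(rng.standard_normal((n_subjects, 3)),
                           index=[f"sub{i + 1:03d}" for i in range(n_subjects)],
                           columns=["CI", "IS", "RM"])
    items = _items_from_factors(factors, rng, item_loading, item_noise_sd,
                                special_code_rate)
    gt = BehaviorGroundTruth(factors=factors,
                             loadings=_planted_loadings(item_loading),
                             planted_r=0.0)
    return items, gt
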