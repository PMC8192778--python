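"""Network Interaction Index (NII) features.

The cognitive NII (CNII) of a window is the difference between the SN-CEN
correlation and the SN-DMN correlation; when the CEN is represented by two
nodes (lCEN, rCEN) the SN-CEN term is the mean of the two correlations.
The motor NII (MNII) is simply the cMN-sMN correlation.  Window-level NII
values are summarized per subject either across dynamic brain states
(unweighted mean of the per-state means; the default for the cognitive
circuit) or across all windows (the default for the motor circuit).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SpecificationError, ValidationError
from .windows import WindowedConnectivity


@dataclass(frozen=True)
class CircuitSpec:
    """Role -> network-name mapping for a cross-network circuit."""

    name: str  # "cognitive" or "motor"
    roles: Mapping[str, tuple]

    def networks(self):
        out = []
        for nodes in self.roles.values():
            out.extend(nodes)
        return tuple(out)


COGNITIVE_CIRCUIT = CircuitSpec(
    name="cognitive",
    roles={"SN": ("SN",), "CEN": ("lCEN", "rCEN"), "DMN": ("DMN",)},
)
MOTOR_CIRCUIT = CircuitSpec(name="motor", roles={"cMN": ("cMN",), "sMN": ("sMN",)})


def _index_of(names, wanted: str) -> int:
    try:
        return list(names).index(wanted)
    except ValueError:
        raise SpecificationError(f"network {wanted!r} absent from matrix") from None


def _pair_r(corr: np.ndarray, names, a: str, b: str) -> float:
    return float(corr[_index_of(names, a), _index_of(names, b)])


def compute_cnii(corr: np.ndarray, names: Sequence[str],
                 spec: CircuitSpec = COGNITIVE_CIRCUIT) -> float:
    """CNII = r(SN, CEN) - r(SN, DMN) for one correlation matrix.

    With a two-node CEN, r(SN, CEN) is the mean of r(SN, lCEN) and
    r(SN, rCEN).  Range [-2, 2].
    """
    if spec.name != "cognitive":
        raise SpecificationError("compute_cnii requires a cognitive circuit spec")
    (sn,) = spec.roles["SN"]
    (dmn,) = spec.roles["DMN"]
    cen_nodes = spec.roles["CEN"]
    r_cen = float(np.mean([_pair_r(corr, names, sn, c) for c in cen_nodes]))
    return r_cen - _pair_r(corr, names, sn, dmn)


def compute_mnii(corr: np.ndarray, names: Sequence[str],
                 spec: CircuitSpec = MOTOR_CIRCUIT) -> float:
    """MNII = r(cMN, sMN) for one correlation matrix."""
    if spec.name != "motor":
        raise SpecificationError("compute_mnii requires a motor circuit spec")
    (c,) = spec.roles["cMN"]
    (s,) = spec.roles["sMN"]
    return _pair_r(corr, names, c, s)


def windowed_nii(wc: WindowedConnectivity, spec: CircuitSpec) -> np.ndarray:
    """Per-window NII trajectory for one subject (vectorized)."""
    names = wc.network_names
    if spec.name == "cognitive":
        sn = _index_of(names, spec.roles["SN"][0])
        dmn = _index_of(names, spec.roles["DMN"][0])
        cen = [_index_of(names, c) for c in spec.roles["CEN"]]
        r_cen = wc.matrices[:, sn, cen].mean(axis=1)
        return r_cen - wc.matrices[:, sn, dmn]
    if spec.name == "motor":
        c = _index_of(names, spec.roles["cMN"][0])
        s = _index_of(names, spec.roles["sMN"][0])
        return wc.matrices[:, c, s].copy()
    raise SpecificationError(f"unknown circuit {spec.name!r}")


def state_specific_nii(per_window_nii: Sequence[float], labels) -> dict:
    """Mean NII per state over this subject's windows in each state.

    States the subject never visits are absent from the result.
    """
    vals = np.asarray(per_window_nii, dtype=float)
    labels = np.asarray(labels)
    if vals.shape[0] != labels.shape[0]:
        raise ValidationError(
            f"{vals.shape[0]} NII values but {labels.shape[0]} labels"
        )
    return {
        int(s): float(vals[labels == s].mean()) for s in np.unique(labels)
    }


def summarize_nii(per_state: Mapping[int, float] | None,
                  per_window: Sequence[float] | None,
                  aggregation: str = "by_state"):
    """Subject-level (mean, sd, n_states_present) of the NII trajectory.

    ``by_state`` takes mean and SD over the subject's per-state mean values
    (states unweighted by occupancy); ``by_window`` over all window values.
    SD uses the sample (n-1) normalization and is ``None`` when only a
    single value exists.
    """
    if aggregation == "by_state":
        if not per_state:
            raise ValidationError("by_state aggregation requires per-state values")
        vals = np.array([per_state[k] for k in sorted(per_state)])
        n_states = len(per_state)
    elif aggregation == "by_window":
        if per_window is None or len(per_window) == 0:
            raise ValidationError("by_window aggregation requires window values")
        vals = np.asarray(per_window, dtype=float)
        n_states = len(per_state) if per_state else 1
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return mean, sd, n_states


@dataclass
class NIIFeatures:
    """Per-subject NII trajectory plus state-conditioned summaries."""

    subject_id: str
    circuit: str
    per_window_nii: np.ndarray
    per_state_nii: dict
    mean_nii: float
    sd_nii: float | None
    aggregation: str
    n_states_present: int


def compute_subject_features(wc: WindowedConnectivity, spec: CircuitSpec,
                             labels=None, aggregation: str = "by_state") -> NIIFeatures:
    """Full NII feature extraction for one subject.

    ``labels`` (state per window) is required for by_state aggregation and
    used, when given, to populate the per-state map in either mode.
    """
    traj = windowed_nii(wc, spec)
    per_state = state_specific_nii(traj, labels) if labels is not None else {}
    if aggregation == "by_state" and not per_state:
        raise ValidationError("by_state aggregation requires window state labels")
    mean, sd, n_states = summarize_nii(per_state or None, traj, aggregation)
    return NIIFeatures(subject_id=wc.subject_id, circuit=spec.name,
                       per_window_nii=traj, per_state_nii=per_state,
                       mean_nii=mean, sd_nii=sd, aggregation=aggregation,
                       n_states_present=n_states)


def features_table(features: Sequence[NIIFeatures]) -> pd.DataFrame:
    """Long-format per-subject feature table (one row per subject x circuit)."""
    rows = [
        {
            "subject_id": f.subject_id,
            "circuit": f.circuit,
            "mean_nii": f.mean_nii,
            "sd_nii": math.nan if f.sd_nii is None else f.sd_nii,
            "n_states_present": f.n_states_present,
            "aggregation": f.aggregation,
        }
        for f in features
    ]
    return pd.DataFrame(rows)
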