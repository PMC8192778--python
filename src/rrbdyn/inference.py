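"""Between-group comparison of NII summary features.

Pooled-variance two-sample t-tests (Welch optional) with Cohen's d, and a
covariate-adjusted variant that models the feature as a linear function of
group plus age, sex, head motion and IQ and reports the group coefficient.
Group order is (ASD, TD): positive t means the ASD mean is larger.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import InferenceError

DEFAULT_CONFOUNDS = ("age", "sex", "motion", "iq")


@dataclass
class GroupComparison:
    feature: str
    t: float
    df: float
    p_two_sided: float
    cohens_d: float
    group_means: dict
    group_sems: dict
    adjusted: bool = False
    confounds_used: tuple = ()

    @property
    def cohens_d_magnitude(self) -> float:
        return abs(self.cohens_d)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "t": self.t,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "cohens_d": self.cohens_d,
            "cohens_d_magnitude": self.cohens_d_magnitude,
            "group_means": self.group_means,
            "group_sems": self.group_sems,
            "adjusted": self.adjusted,
            "confounds_used": list(self.confounds_used),
        }


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def cohens_d(a, b) -> float:
    """(mean_a - mean_b) / pooled SD with (n-1) variance pooling."""
    a, b = _clean(a), _clean(b)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def two_sample_test(a, b, feature: str = "", welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t-test, ASD values first.

    The default is the pooled-variance (Student) test with
    df = n1 + n2 - 2; ``welch=True`` switches to the unequal-variance form.
    """
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise InferenceError("each group needs >= 2 non-missing values")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2a, se2b = va / na, vb / nb
        t = diff / np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return GroupComparison(
        feature=feature, t=float(t), df=float(df), p_two_sided=float(p),
        cohens_d=cohens_d(a, b),
        group_means={"ASD": float(a.mean()), "TD": float(b.mean())},
        group_sems={"ASD": float(a.std(ddof=1) / np.sqrt(na)),
                    "TD": float(b.std(ddof=1) / np.sqrt(nb))},
    )


def confound_adjusted_test(feature_values, manifest: pd.DataFrame,
                           feature: str = "",
                           confounds=DEFAULT_CONFOUNDS) -> GroupComparison:
    """Group effect adjusted for covariates in one linear model.

    Fits ``feature ~ group + confounds`` with group coded ASD=1 / TD=0, sex
    coded M=0 / F=1 and continuous covariates mean-centered, and reports the
    group coefficient's t and p.  Cohen's d (unadjusted) is carried along
    for effect-size context.
    """
    y = np.asarray(feature_values, dtype=float)
    if len(y) != len(manifest):
        raise InferenceError("feature values and manifest lengths differ")
    keep = np.isfinite(y)
    y = y[keep]
    man = manifest.loc[keep].reset_index(drop=True)
    group = (man["group"].to_numpy() == "ASD").astype(float)
    cols, names = [group], ["group"]
    for c in confounds:
        if c == "sex":
            v = (man["sex"].to_numpy() == "F").astype(float)
        else:
            v = man[c].to_numpy(dtype=float)
            v = v - v.mean()
        if np.allclose(v, v[0]):
            raise InferenceError(f"zero-variance covariate {c!r}")
        cols.append(v)
        names.append(c)
    X = np.column_stack([np.ones_like(y)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [n for k, n in enumerate(names, start=1)
               if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank]
        raise InferenceError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    a, b = y[group == 1], y[group == 0]
    return GroupComparison(
        feature=feature, t=float(fit.tvalues[1]), df=float(fit.df_resid),
        p_two_sided=float(fit.pvalues[1]), cohens_d=cohens_d(a, b),
        group_means={"ASD": float(a.mean()), "TD": float(b.mean())},
        group_sems={"ASD": float(a.std(ddof=1) / np.sqrt(a.size)),
                    "TD": float(b.std(ddof=1) / np.sqrt(b.size))},
        adjusted=True, confounds_used=tuple(confounds),
    )
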