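"""Cross-condition normalisation, the combined GLM, and circular
hypothesis tests.

Parameters measured in different experiments (peak rate, burst index,
directionality, PFD drift) are z-scored against the first visual
baseline of their experiment, pooled, and modelled with an
identity-link normal GLM

    y = a + b + c + d + (a x b)

with a = rotation speed (deg/s, 0 for baselines), b = darkness,
c = passive restraint, d = unidirectional rotation, plus an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .circular import circdiff, resultant_vector

__all__ = [
    "NormalizedParam",
    "GLMResult",
    "CircTestResult",
    "normalize",
    "pfd_drift",
    "fit_glm",
    "model_representation",
    "v_test",
    "holm_bonferroni",
    "anova_oneway",
    "dunn_sidak_pairwise",
]

PREDICTORS = ["speed", "dark", "restrained", "unidirectional", "speed_x_dark"]


@dataclass
class NormalizedParam:
    raw: float
    z: float
    baseline_mean: float
    baseline_sd: float


@dataclass
class GLMResult:
    """Identity-link normal GLM fit with standardized coefficients."""

    params: pd.Series  # raw-scale coefficients (incl. intercept)
    beta: pd.Series  # standardized coefficients (z-scored predictors)
    beta_t: pd.Series
    beta_p: pd.Series
    f_stat: float
    f_p: float
    r_squared: float
    n_obs: int
    df_model: int


@dataclass
class CircTestResult:
    statistic: float
    p: float
    mean_direction: float
    n: int


def normalize(values, baseline_values):
    """z-score values against a baseline distribution.

    Returns a list of :class:`NormalizedParam`.  Raises if the baseline
    has fewer than two values or zero SD.
    """
    base = np.asarray(baseline_values, dtype=float)
    if len(base) < 2:
        raise ValueError("need at least 2 baseline values")
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    if sd == 0:
        raise ValueError("baseline SD is zero; normalization undefined")
    return [
        NormalizedParam(float(v), (float(v) - mu) / sd, mu, sd)
        for v in np.atleast_1d(np.asarray(values, dtype=float))
    ]


def pfd_drift(pfds, baseline_pfd):
    """PFD drift as the signed circular difference to the baseline PFD,
    in (-180, 180] degrees (positive = CCW of baseline)."""
    return circdiff(pfds, baseline_pfd)


def _design(speed, dark, restrained, unidirectional):
    df = pd.DataFrame(
        {
            "speed": np.asarray(speed, dtype=float),
            "dark": np.asarray(dark, dtype=float),
            "restrained": np.asarray(restrained, dtype=float),
            "unidirectional": np.asarray(unidirectional, dtype=float),
        }
    )
    df["speed_x_dark"] = df["speed"] * df["dark"]
    return df


def fit_glm(speed, dark, restrained, unidirectional, response) -> GLMResult:
    """Fit the combined identity-link normal GLM.

    ``dark``, ``restrained`` and ``unidirectional`` are 0/1 indicators
    (baselines: light, freely-moving, bidirectional); ``speed`` is the
    rotation speed in deg/s with baselines at 0.  Standardized
    coefficients come from refitting after z-scoring all five design
    columns (including the interaction column).  The F statistic tests
    the model against an intercept-only fit; R^2 is the ordinary
    coefficient of determination.
    """
    y = np.asarray(response, dtype=float)
    X = _design(speed, dark, restrained, unidirectional)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")

    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.values)
    if rank < Xc.shape[1]:
        # name the offending columns via near-zero R diagonal of a QR
        _, R = np.linalg.qr(Xc.values)
        bad = [
            Xc.columns[j]
            for j in range(Xc.shape[1])
            if abs(R[j, j]) < 1e-8 * abs(R).max()
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    glm = sm.GLM(y, Xc, family=sm.families.Gaussian()).fit()
    params = glm.params

    rss = float(((y - glm.fittedvalues) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    p = X.shape[1]
    dof = len(y) - p - 1
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    f = ((tss - rss) / p) / (rss / dof) if rss > 0 else np.inf
    f_p = float(sps.f.sf(f, p, dof)) if np.isfinite(f) else 0.0

    Xz = (X - X.mean()) / X.std(ddof=1)
    glm_z = sm.GLM(y, sm.add_constant(Xz, has_constant="add"),
                   family=sm.families.Gaussian()).fit()
    return GLMResult(
        params=params,
        beta=glm_z.params.drop("const"),
        beta_t=glm_z.tvalues.drop("const"),
        beta_p=glm_z.pvalues.drop("const"),
        f_stat=float(f),
        f_p=f_p,
        r_squared=float(r2),
        n_obs=len(y),
        df_model=p,
    )


def model_representation(result: GLMResult, speeds=(111.0, 195.0, 260.0)):
    """Evaluate the fitted model at the experiments' rotation speeds for
    a freely-moving animal rotating unidirectionally, in the light and
    in the dark.

    Returns a DataFrame indexed by speed with columns 'light', 'dark'.
    """
    rows = {}
    for s in speeds:
        row = {}
        for dark in (0.0, 1.0):
            x = pd.Series(
                {
                    "const": 1.0,
                    "speed": s,
                    "dark": dark,
                    "restrained": 0.0,
                    "unidirectional": 1.0,
                    "speed_x_dark": s * dark,
                }
            )
            row["dark" if dark else "light"] = float(
                (result.params * x[result.params.index]).sum()
            )
        rows[s] = row
    return pd.DataFrame(rows).T


def v_test(angles, mean_dir: float = 0.0) -> CircTestResult:
    """V test for circular nonuniformity around a specified direction.

    V = n * rbar * cos(thetabar - mu); the large-sample statistic
    u = V * sqrt(2 / n) is compared against the standard normal
    (one-sided).  Significance indicates concentration around
    ``mean_dir``.
    """
    a = np.asarray(angles, dtype=float)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 angles")
    r, mean = resultant_vector(a)
    v = n * r * np.cos(np.radians(mean - mean_dir))
    u = v * np.sqrt(2.0 / n)
    p = float(sps.norm.sf(u))
    return CircTestResult(float(v), p, float(mean), n)


def holm_bonferroni(pvals, alpha: float = 0.05):
    """Holm step-down adjustment over one family of tests.

    Returns (reject, p_adjusted) arrays in the input order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        raise ValueError("empty p-value family")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject, p_adj


def anova_oneway(*groups):
    """One-way ANOVA across groups (thin wrapper; returns (F, p))."""
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def dunn_sidak_pairwise(groups, alpha: float = 0.05):
    """All pairwise Welch t tests with Dunn-Sidak correction.

    ``groups`` is a dict name -> values.  Returns a DataFrame with raw
    and corrected p-values and the rejection decision at ``alpha``.
    """
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = sps.ttest_ind(
                np.asarray(groups[names[i]], float),
                np.asarray(groups[names[j]], float),
                equal_var=False,
            )
            p_adj = 1.0 - (1.0 - p) ** m
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "t": float(t),
                    "p": float(p),
                    "p_sidak": float(min(p_adj, 1.0)),
                    "reject": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)
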