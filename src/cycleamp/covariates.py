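"""Generalized linear models of participant amplitude on covariates.

Participant amplitude (RHR_amp or RMSSD_amp) is regressed on age
(linear), the participant's baseline metric value through a natural
cubic spline with four basis terms, and BMI (linear), with a Gaussian
identity-link family:

    amp = b0 + b1*age + sum_k b2k * ns_k(baseline) + b3*bmi + e

"Four knots" is realized as df = 4: boundary knots at the observed
min/max and interior knots at the 25th/50th/75th percentiles of the
baseline metric, which makes the four basis terms correspond to the
quartile partition of the baseline distribution.  Natural splines are
linear beyond the boundary knots and exactly contain linear functions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "natural_spline_basis",
    "AmplitudeGLMFit",
    "fit_amplitude_glm",
    "partial_dependence_glm",
]


def natural_spline_basis(x, df: int = 4, knots: dict | None = None):
    """Natural cubic spline basis matrix (n x df) plus its knots.

    Knot sites are the boundary values (min/max of ``x``) plus interior
    knots at the 25th/50th/75th percentiles (for df = 4), so the basis
    terms correspond to the quartile partition of the baseline
    distribution.  The basis is the *cardinal* natural-spline basis:
    column k is the natural cubic spline that equals 1 at knot site k+1
    and 0 at the other sites (the site-1 column is dropped as redundant
    with the intercept), evaluated with linear extrapolation beyond the
    boundary knots.  Each coefficient therefore reads directly as the
    fitted contribution at its knot site relative to the lowest site,
    and linear functions of x are exactly representable by the basis
    plus an intercept.

    Pass ``knots`` (as returned) to evaluate the same basis at new x.
    """
    from scipy.interpolate import CubicSpline

    x = np.asarray(x, dtype=float)
    if knots is None:
        if np.unique(x).size < 10:
            raise ValueError("need at least 10 distinct values to place knots")
        if np.std(x) < 1e-8 * max(1.0, abs(np.mean(x))):
            raise ValueError("near-constant input: cannot build spline basis")
        n_interior = df - 1
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        knots = {"interior": interior, "boundary": (float(x.min()), float(x.max()))}
    lo, hi = knots["boundary"]
    sites = np.r_[lo, np.asarray(knots["interior"], dtype=float), hi]
    if np.unique(sites).size != sites.size:
        raise ValueError("degenerate knot placement (tied knots)")

    inside = np.clip(x, lo, hi)
    below = x < lo
    above = x > hi
    cols = []
    for j in range(1, sites.size):  # drop the site-1 cardinal column
        e = np.zeros(sites.size)
        e[j] = 1.0
        spl = CubicSpline(sites, e, bc_type="natural")
        col = spl(inside)
        if below.any():
            col[below] = spl(lo) + (x[below] - lo) * spl(lo, 1)
        if above.any():
            col[above] = spl(hi) + (x[above] - hi) * spl(hi, 1)
        cols.append(col)
    return np.column_stack(cols), knots


@dataclasses.dataclass
class AmplitudeGLMFit:
    """Fitted amplitude-on-covariates GLM."""

    metric: str
    coefficients: pd.DataFrame  # term, estimate, ci_lo, ci_hi, p_value
    knots: dict
    n: int
    r_squared: float
    beta: np.ndarray
    cov: np.ndarray
    terms: list
    reference: dict  # sample means used as reference values


def _design(age, baseline, bmi, knots, df_spline):
    N, knots = natural_spline_basis(baseline, df=df_spline, knots=knots)
    X = np.column_stack([np.ones_like(age), age, N, bmi])
    return X, knots


def fit_amplitude_glm(
    amps: pd.DataFrame,
    metric: str = "rhr",
    df_spline: int = 4,
) -> AmplitudeGLMFit:
    """Fit the Gaussian GLM of participant amplitude on age, baseline
    metric (natural spline) and BMI.

    ``amps`` needs one row per participant with columns participant_amp,
    age, bmi and baseline (the participant's mean raw metric value over
    eligible days).  P-values use large-sample normal theory; no
    multiple-testing correction is applied.
    """
    d = amps.dropna(subset=["participant_amp", "age", "bmi", "baseline"])
    y = d["participant_amp"].to_numpy(dtype=float)
    age = d["age"].to_numpy(dtype=float)
    bmi = d["bmi"].to_numpy(dtype=float)
    baseline = d["baseline"].to_numpy(dtype=float)
    X, knots = _design(age, baseline, bmi, None, df_spline)
    if np.linalg.cond(X.T @ X) > 1e12:
        raise np.linalg.LinAlgError(
            "design matrix is rank-deficient beyond tolerance; "
            "check for collinear covariates"
        )
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    tss = float(((y - y.mean()) ** 2).sum())

    ib = knots["interior"]
    spline_labels = [
        f"baseline_ns1 (< {ib[0]:.1f})",
        f"baseline_ns2 ({ib[0]:.1f} - {ib[1]:.1f})",
        f"baseline_ns3 ({ib[1]:.1f} - {ib[2]:.1f})",
        f"baseline_ns4 (> {ib[2]:.1f})",
    ][: df_spline]
    terms = ["intercept", "age", *spline_labels, "bmi"]
    coef = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "std_error": se,
            "ci_lo": beta - z * se,
            "ci_hi": beta + z * se,
            "p_value": pvals,
        }
    )
    return AmplitudeGLMFit(
        metric=metric,
        coefficients=coef,
        knots=knots,
        n=n,
        r_squared=1.0 - rss / tss if tss > 0 else np.nan,
        beta=beta,
        cov=cov,
        terms=terms,
        reference={"age": float(age.mean()), "baseline": float(baseline.mean()),
                   "bmi": float(bmi.mean())},
    )


def partial_dependence_glm(
    fit: AmplitudeGLMFit,
    term: str,
    grid: np.ndarray | None = None,
    n_points: int = 100,
) -> pd.DataFrame:
    """Centered contribution of one covariate with a 95% band.

    The curve is the model prediction with ``term`` varied over a grid
    and the other covariates fixed at their sample means, minus the
    prediction at the term's own mean — i.e. exactly the brute-force
    prediction difference.  The band comes from the coefficient
    covariance of that contrast.
    """
    if term not in ("age", "baseline", "bmi"):
        raise ValueError("term must be one of 'age', 'baseline', 'bmi'")
    ref = fit.reference
    if grid is None:
        lo, hi = {
            "age": (18.0, 55.0),
            "baseline": fit.knots["boundary"],
            "bmi": (16.0, 45.0),
        }[term]
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)

    def row(age, baseline, bmi):
        X, _ = _design(np.atleast_1d(age), np.atleast_1d(baseline), np.atleast_1d(bmi),
                       fit.knots, df_spline=len(fit.knots["interior"]) + 1)
        return X

    vary = {
        "age": lambda g: row(g, np.full_like(g, ref["baseline"]), np.full_like(g, ref["bmi"])),
        "baseline": lambda g: row(np.full_like(g, ref["age"]), g, np.full_like(g, ref["bmi"])),
        "bmi": lambda g: row(np.full_like(g, ref["age"]), np.full_like(g, ref["baseline"]), g),
    }[term]
    Xg = vary(grid)
    Xr = vary(np.asarray([ref[term]]))
    D = Xg - Xr  # contrast against the reference point
    est = D @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, fit.cov, D), 0.0))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({term: grid, "estimate": est, "lo": est - z * se, "hi": est + z * se})
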