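"""Population additive model of metric offset against cycle day.

Fits a penalized additive regression of the per-day offset y_i on a
smooth function of cycle day D with a per-participant random intercept,

    unadjusted:  y_i = f1(D) + f2(pID) + e
    adjusted:    y_i = f1(D) + f2(pID) + f3(age) + f4(kJ)
                       + weekend + BMI + e

where f1, f3, f4 are penalized cubic B-spline smooths (second-difference
curvature penalty, sum-to-zero centered against the data) and f2 is a
ridge-penalized per-participant intercept block — the minimal faithful
random-effect structure.  The day smooth is deliberately not periodic:
the day domain restarts at each bleeding onset and the late-luteal rise
runs into the boundary, so forcing periodicity would distort it.

Smoothing parameters are selected by generalized cross-validation
(default) or an approximate REML criterion, by coordinate-wise grid
search on the profiled normal equations.  Pointwise 95% bands come from
the Bayesian posterior covariance of the penalized fit.

The partial dependence of cycle day — f1 evaluated on a fine grid with
all other terms held at their identifiability-constrained zero — is the
curve from which the population nadir and peak days are read.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "PopulationFit",
    "PartialDependence",
    "Extrema",
    "fit_population",
    "partial_dependence_day",
    "locate_extrema",
]

_LAMBDA_GRID = np.logspace(-3, 7, 11)


def _bspline_design(x: np.ndarray, ndim: int, domain: tuple[float, float], degree: int = 3):
    """Cubic B-spline design matrix with ``ndim`` basis functions over
    uniform breakpoints spanning ``domain``; values are clipped to the
    domain so slight extrapolation cannot produce NaNs."""
    lo, hi = domain
    breaks = np.linspace(lo, hi, ndim - degree + 1)
    knots = np.r_[[lo] * degree, breaks, [hi] * degree]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    # nudge the right edge inside the last knot span
    xc = np.minimum(xc, hi - 1e-9 * (hi - lo))
    return np.asarray(BSpline.design_matrix(xc, knots, degree).todense()), knots


def _second_diff_penalty(ndim: int) -> np.ndarray:
    d2 = np.diff(np.eye(ndim), n=2, axis=0)
    return d2.T @ d2


@dataclasses.dataclass
class _Block:
    name: str
    sl: slice
    penalty: np.ndarray | None  # unscaled penalty for this block, or None (unpenalized)
    lam: float = 1.0
    tune: bool = False
    col_means: np.ndarray | None = None  # centering applied (for smooths)
    meta: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class PopulationFit:
    """A fitted population additive model."""

    metric: str
    adjusted: bool
    beta: np.ndarray
    cov: np.ndarray  # Bayesian posterior covariance of beta
    blocks: dict[str, _Block]
    participants: list
    sigma2: float
    edf_total: float
    edf_terms: dict[str, float]
    p_values: dict[str, float]
    estimates: dict[str, float]  # linear-term coefficients
    std_errors: dict[str, float]
    r_squared: float
    n_observations: int
    day_max: float  # last well-supported day: the grid cap for partial dependence
    day_domain_max: float  # largest observed day (basis domain end)
    lambdas: dict[str, float]
    method: str

    @property
    def random_intercepts(self) -> pd.Series:
        bl = self.blocks["pid"]
        return pd.Series(self.beta[bl.sl], index=self.participants, name="random_intercept")

    def random_intercept_se(self) -> pd.Series:
        bl = self.blocks["pid"]
        se = np.sqrt(np.diag(self.cov)[bl.sl])
        return pd.Series(se, index=self.participants)

    def summary(self) -> pd.DataFrame:
        """Term-level table: estimate (linear terms), edf (smooths), p-value."""
        rows = []
        for name in self.blocks:
            if name == "intercept":
                continue
            rows.append(
                {
                    "term": name,
                    "estimate": self.estimates.get(name, np.nan),
                    "std_error": self.std_errors.get(name, np.nan),
                    "edf": self.edf_terms.get(name, np.nan),
                    "p_value": self.p_values.get(name, np.nan),
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["r_squared"] = self.r_squared
        out.attrs["n_observations"] = self.n_observations
        return out


@dataclasses.dataclass
class PartialDependence:
    """Isolated contribution of the cycle-day smooth with 95% band."""

    metric: str
    day_grid: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day_grid, "estimate": self.estimate,
             "lo": self.ci_lower, "hi": self.ci_upper}
        )


@dataclasses.dataclass
class Extrema:
    nadir_day: float
    peak_day: float
    nadir_day_nearest: int
    peak_day_nearest: int
    nadir_value: float
    peak_value: float


def _gcv(n, rss, edf):
    return n * rss / (n - edf) ** 2


def _solve_stats(XtX, Xty, yty, S, n):
    A = XtX + S
    beta = np.linalg.solve(A, Xty)
    H = np.linalg.solve(A, XtX)  # influence partition: edf_j = diag(H)_j
    edf_cols = np.diag(H)
    rss = float(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta))
    rss = max(rss, 1e-12)
    return beta, edf_cols, rss, A


def fit_population(
    offsets: pd.DataFrame,
    metric: str = "rhr",
    adjusted: bool = False,
    basis_dim: int = 20,
    method: str = "gcv",
    age_basis_dim: int = 10,
    kj_basis_dim: int = 10,
) -> PopulationFit:
    """Fit the population additive model for one metric.

    ``offsets`` is the long per-day table from cycle processing (columns
    metric, day, offset, and — for the adjusted model — age, kj, weekend,
    bmi).  Outlier days (NaN offset) are excluded; rows missing an
    adjusted-model covariate are listwise deleted, so the adjusted n can
    be smaller than the unadjusted n.
    """
    if method not in ("gcv", "reml"):
        raise ValueError("method must be 'gcv' or 'reml'")
    d = offsets[offsets["metric"] == metric].copy()
    d = d[np.isfinite(d["offset"])]
    if adjusted:
        needed = ["age", "kj", "weekend", "bmi"]
        missing_cols = [c for c in needed if c not in d.columns]
        if missing_cols:
            raise ValueError(f"adjusted model requires columns {missing_cols}")
        d = d.dropna(subset=needed)
    if d.empty:
        raise ValueError("no usable offset rows")
    n = len(d)
    y = d["offset"].to_numpy(dtype=float)
    day = d["day"].to_numpy(dtype=float)
    day_domain_max = float(day.max())
    # cap the extrema-reading grid at the last day still reached by >=5%
    # of cycles: beyond it the smooth is estimated from a handful of long
    # cycles and is boundary-dominated
    if "cycle_len" in d.columns:
        cyc_lens = d.groupby(["participant_id", "cycle_index"])["cycle_len"].first()
        day_max = float(min(np.quantile(cyc_lens, 0.95), day_domain_max))
    else:
        day_max = day_domain_max

    pids = sorted(d["participant_id"].unique())
    single_participant = len(pids) <= 1
    if single_participant:
        warnings.warn("single participant: random-intercept term omitted", stacklevel=2)

    cols: list[np.ndarray] = []
    blocks: dict[str, _Block] = {}
    pos = 0

    def add_block(name, X, penalty, tune, center, meta=None):
        nonlocal pos
        col_means = None
        if center:
            col_means = X.mean(axis=0)
            X = X - col_means
        cols.append(X)
        blocks[name] = _Block(
            name, slice(pos, pos + X.shape[1]), penalty,
            tune=tune, col_means=col_means, meta=meta or {},
        )
        pos += X.shape[1]

    add_block("intercept", np.ones((n, 1)), None, False, False)
    domain = (1.0, max(day_domain_max, 10.0))
    Bday, day_knots = _bspline_design(day, basis_dim, domain)
    add_block(
        "day", Bday, _second_diff_penalty(basis_dim), True, True,
        meta={"knots": day_knots, "domain": domain, "ndim": basis_dim},
    )
    if not single_participant:
        codes = pd.Categorical(d["participant_id"], categories=pids).codes
        P = np.zeros((n, len(pids)))
        P[np.arange(n), codes] = 1.0
        add_block("pid", P, np.eye(len(pids)), True, False)
    if adjusted:
        age = d["age"].to_numpy(dtype=float)
        if np.ptp(age) > 1e-9:
            Bage, age_knots = _bspline_design(age, age_basis_dim, (age.min(), age.max()))
            add_block("age", Bage, _second_diff_penalty(age_basis_dim), True, True,
                      meta={"knots": age_knots})
        kj = d["kj"].to_numpy(dtype=float)
        if np.ptp(kj) > 1e-9:
            Bkj, kj_knots = _bspline_design(kj, kj_basis_dim, (kj.min(), kj.max()))
            add_block("kj", Bkj, _second_diff_penalty(kj_basis_dim), True, True,
                      meta={"knots": kj_knots})
        add_block("weekend", d["weekend"].to_numpy(dtype=float).reshape(-1, 1), None, False, False)
        add_block("bmi", d["bmi"].to_numpy(dtype=float).reshape(-1, 1), None, False, False)

    X = np.hstack(cols)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    # tiny null-space ridge per smooth block: curvature penalties do not
    # penalize their linear null space, which can be confounded with the
    # participant dummies (participant-constant covariates such as age),
    # so a small fixed ridge keeps the normal equations well conditioned
    ridge = {
        name: 1e-7 * float(np.mean(np.diag(XtX)[bl.sl]) + 1.0)
        for name, bl in blocks.items()
        if bl.penalty is not None
    }

    def assemble_S():
        S = np.zeros((p, p))
        for bl in blocks.values():
            if bl.penalty is not None:
                blk = bl.lam * bl.penalty + ridge[bl.name] * np.eye(bl.penalty.shape[0])
                S[bl.sl, bl.sl] += blk
        return S

    def score(S):
        beta, edf_cols, rss, A = _solve_stats(XtX, Xty, yty, S, n)
        edf = float(edf_cols.sum())
        if method == "gcv":
            return _gcv(n, rss, edf), (beta, edf_cols, rss, A)
        # approximate REML: profiled Gaussian restricted likelihood up to
        # constants, using the positive part of the penalty spectrum
        sig2 = rss / max(n - edf, 1.0)
        sign, logdet_A = np.linalg.slogdet(A)
        logdet_S = 0.0
        for bl in blocks.values():
            if bl.penalty is not None:
                ev = np.linalg.eigvalsh(bl.lam * bl.penalty)
                logdet_S += float(np.sum(np.log(ev[ev > 1e-10])))
        val = (n - edf) * np.log(sig2) + logdet_A - logdet_S
        return val, (beta, edf_cols, rss, A)

    # coordinate-wise grid search over the tunable smoothing parameters
    tunable = [bl for bl in blocks.values() if bl.tune]
    for _sweep in range(2):
        for bl in tunable:
            best = (np.inf, bl.lam)
            for lam in _LAMBDA_GRID:
                bl.lam = lam
                val, _ = score(assemble_S())
                if val < best[0]:
                    best = (val, lam)
            bl.lam = best[1]

    S = assemble_S()
    beta, edf_cols, rss, A = _solve_stats(XtX, Xty, yty, S, n)
    edf = float(edf_cols.sum())
    sigma2 = rss / max(n - edf, 1.0)
    Ainv = np.linalg.inv(A)
    cov = sigma2 * Ainv

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    edf_terms, p_values, estimates, std_errors = {}, {}, {}, {}
    for name, bl in blocks.items():
        if name == "intercept":
            continue
        b = beta[bl.sl]
        V = cov[bl.sl, bl.sl]
        edf_terms[name] = float(edf_cols[bl.sl].sum())
        if bl.penalty is None and b.size == 1:  # linear term: Wald z
            se = float(np.sqrt(V[0, 0]))
            estimates[name] = float(b[0])
            std_errors[name] = se
            p_values[name] = float(2.0 * stats.norm.sf(abs(b[0]) / se)) if se > 0 else np.nan
        else:  # smooth / random block: Wald chi-square on the block
            stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
            df = max(edf_terms[name], 1e-3)
            p_values[name] = float(stats.chi2.sf(stat, df))

    return PopulationFit(
        metric=metric,
        adjusted=adjusted,
        beta=beta,
        cov=cov,
        blocks=blocks,
        participants=pids if not single_participant else [],
        sigma2=sigma2,
        edf_total=edf,
        edf_terms=edf_terms,
        p_values=p_values,
        estimates=estimates,
        std_errors=std_errors,
        r_squared=r2,
        n_observations=n,
        day_max=day_max,
        day_domain_max=day_domain_max,
        lambdas={bl.name: bl.lam for bl in tunable},
        method=method,
    )


def partial_dependence_day(fit: PopulationFit, grid_step: float = 0.01) -> PartialDependence:
    """Evaluate f1(D) on a fine day grid with its pointwise 95% band.

    All other terms are held at their identifiability-constrained zero,
    so the curve is the centered contribution of cycle day alone, in the
    metric's offset units.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    bl = fit.blocks["day"]
    grid = np.arange(1.0, fit.day_max + grid_step / 2.0, grid_step)
    B, _ = _bspline_design(grid, bl.meta["ndim"], bl.meta["domain"])
    B = B - bl.col_means
    est = B @ fit.beta[bl.sl]
    V = fit.cov[bl.sl, bl.sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    z = stats.norm.ppf(0.975)
    return PartialDependence(fit.metric, grid, est, est - z * se, est + z * se)


def locate_extrema(pdep: PartialDependence, tol: float = 1e-9) -> Extrema:
    """Locate the nadir and peak of the day partial dependence.

    Fractional locations are the grid argmin/argmax (first occurrence,
    i.e. ties resolve to the earlier day); nearest-day values round to
    the nearest integer cycle day, half-day ties also toward the earlier
    day.
    """
    est = np.asarray(pdep.estimate, dtype=float)
    if est.max() - est.min() <= tol:
        raise ValueError("no cycle structure detected: partial dependence is flat")
    i_min = int(np.argmin(est))
    i_max = int(np.argmax(est))
    nadir = float(pdep.day_grid[i_min])
    peak = float(pdep.day_grid[i_max])

    def nearest(x):  # round-half-down: earlier day wins a tie
        return int(np.ceil(x - 0.5))

    lo, hi = 1, int(round(float(pdep.day_grid[-1])))
    return Extrema(
        nadir_day=nadir,
        peak_day=peak,
        nadir_day_nearest=int(np.clip(nearest(nadir), lo, hi)),
        peak_day_nearest=int(np.clip(nearest(peak), lo, hi)),
        nadir_value=float(est[i_min]),
        peak_value=float(est[i_max]),
    )
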