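"""Calibration pipeline for the expolinear-logistic leaf size model.

The pipeline mirrors how the generic parameter sets are estimated from a
multi-experiment training table:

1. observations are grouped by genotype and total leaf number (TLN groups);
2. the seven-parameter curve is fitted to each group by Levenberg-Marquardt
   nonlinear least squares (lmfit ``leastsq``, bounds handled by MINPACK-style
   parameter transforms), one fit per trait;
3. the position of the largest leaf ``xs`` is regressed on TLN — ordinary
   linear for maize/pearl millet, continuous segmented (two slopes, free or
   fixed breakpoint) for sorghum;
4. the logistic decay rate ``dr`` is regressed on TLN with a continuous
   decline-then-plateau (hockey-stick) model after robust bivariate outlier
   removal;
5. the remaining parameters (L1, cm, rm, tb, dsl) are pooled across TLN
   groups (unweighted mean by default, inverse-variance weighting optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.covariance import MinCovDet

from .errors import CalibrationError, DegenerateDataError, GroupSizeError
from .model import _expolinear_raw, _logistic_raw
from .params import (
    ProfileParams,
    SpeciesId,
    SpeciesParameterSet,
    TlnLinearRule,
    TlnPlateauRule,
    TlnSegmentedRule,
    Trait,
    TraitParams,
)

__all__ = [
    "TlnGroup",
    "FitResult",
    "TlnRegressionResult",
    "CalibrationConfig",
    "CalibrationResult",
    "default_init",
    "fit_profile",
    "fit_tln_linear",
    "fit_tln_segmented",
    "fit_tln_plateau",
    "flag_dr_outliers",
    "evaluate_fit",
    "calibrate_species",
]

_PARAM_NAMES = ("L1", "cm", "rm", "tb", "xs", "dr", "dsl")


@dataclass(frozen=True)
class TlnGroup:
    """Observations for one species/genotype/trait at one total leaf number."""

    species: SpeciesId
    genotype: str
    trait: Trait
    tln: int
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape:
            raise ValueError("positions and values must have equal length")
        if np.any(pos < 1) or np.any(pos > self.tln):
            raise ValueError("positions must lie in 1..tln")
        # canonical order: stable sort by position so fits are invariant to
        # the order observations arrive in
        order = np.argsort(pos, kind="stable")
        object.__setattr__(self, "positions", pos[order])
        object.__setattr__(self, "values", val[order])

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class FitResult:
    """Fitted curve for one TLN group with uncertainty and goodness of fit."""

    params: ProfileParams
    std_errors: dict
    rss: float
    rmse: float
    r2: float
    n: int
    converged: bool
    nfev: int = 0


@dataclass(frozen=True)
class TlnRegressionResult:
    """A fitted parameter-versus-TLN rule with diagnostics."""

    rule: object
    std_errors: dict
    residual_sd: float
    n_groups: int
    degenerate: bool = False


def _eval_model(x, L1, cm, rm, tb, xs, dr, dsl):
    """Piecewise curve without validation overhead (optimizer inner loop)."""
    x = np.asarray(x, dtype=float)
    ymax = float(_expolinear_raw(xs, L1, cm, rm, tb))
    return np.where(
        x < xs,
        _expolinear_raw(x, L1, cm, rm, tb),
        _logistic_raw(x, ymax, dsl, dr, xs),
    )


def default_init(group: TlnGroup) -> ProfileParams:
    """Data-driven starting values for one group fit.

    L1 from the smallest observation, xs from the position of the largest,
    cm from the steepest successive increase of per-position means, and
    fixed generic starts for the shape parameters (rm=1, tb=2, dr=0.5,
    dsl = 5% of the maximum).
    """
    pos = group.positions
    val = group.values
    # per-position means, in position order, for slope/argmax heuristics
    uniq, inverse = np.unique(pos, return_inverse=True)
    means = np.bincount(inverse, weights=val) / np.bincount(inverse)
    vmax = float(means.max())
    xs0 = float(uniq[int(np.argmax(means))])
    if len(uniq) > 1:
        cm0 = float(np.max(np.diff(means) / np.diff(uniq)))
    else:
        cm0 = 1.0
    cm0 = max(cm0, 1e-3)
    return ProfileParams(
        L1=max(float(val.min()), 1e-3),
        cm=cm0,
        rm=1.0,
        tb=2.0,
        xs=min(max(xs0, 2.0), group.tln),
        dr=0.5,
        dsl=max(0.05 * vmax, 1e-3),
    ).validate()


def _default_bounds(group: TlnGroup) -> dict:
    vmax = float(group.values.max())
    tln = group.tln
    return {
        "L1": (1e-4, 2.0 * vmax),
        "cm": (1e-4, 4.0 * vmax),
        "rm": (0.01, 20.0),
        "tb": (-10.0, tln + 10.0),
        "xs": (1.5, tln + 1.0),
        "dr": (1e-6, 30.0),
        "dsl": (1e-9, 2.0 * vmax),
    }


def _starting_points(init: ProfileParams, bounds: dict) -> list[ProfileParams]:
    """Deterministic multi-start ladder around the data-driven init.

    The expolinear shape parameters (rm, tb) are the ones prone to local
    minima, so the ladder varies those; each start is clipped to bounds.
    """
    variants = [
        {"rm": 0.3},
        {"rm": 2.0},
        {"rm": 0.15, "tb": init.xs / 2.0},
        {"tb": init.xs / 2.0},
        {"rm": 0.5, "dr": 2.0},
    ]
    starts = []
    for changes in variants:
        p = init.replace(**changes)
        clipped = {
            name: float(np.clip(getattr(p, name), *bounds[name]))
            for name in _PARAM_NAMES
        }
        starts.append(ProfileParams(**clipped))
    return starts


def _lm(residual, pars):
    return lmfit.minimize(residual, pars, method="leastsq", xtol=1e-13, ftol=1e-13)


def _subfit_expolinear(pos, val, bounds):
    """Fit the four expolinear parameters alone (rm multistart)."""
    best = None
    cm0 = 1.0
    if len(pos) > 1:
        cm0 = max(float(np.max(np.diff(val) / np.diff(pos))), 1e-3)
    for rm0 in (0.1, 0.3, 1.0, 3.0):
        pars = lmfit.Parameters()
        pars.add("L1", value=max(float(val.min()), 1e-3),
                 min=bounds["L1"][0], max=bounds["L1"][1])
        pars.add("cm", value=cm0, min=bounds["cm"][0], max=bounds["cm"][1])
        pars.add("rm", value=rm0, min=bounds["rm"][0], max=bounds["rm"][1])
        pars.add("tb", value=2.0, min=bounds["tb"][0], max=bounds["tb"][1])
        try:
            res = _lm(
                lambda p: _expolinear_raw(
                    pos, p["L1"].value, p["cm"].value, p["rm"].value, p["tb"].value
                ) - val,
                pars,
            )
        except Exception:
            continue
        rss = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or rss < best[0]:
            best = (rss, tuple(float(res.params[n].value)
                               for n in ("L1", "cm", "rm", "tb")))
    return best


def _staged_candidates(group: TlnGroup, bounds: dict) -> list[ProfileParams]:
    """Starting points from profiling the peak position xs.

    The full seven-parameter objective is rugged in xs (observations switch
    branch as xs crosses them), so xs is scanned on a fine grid around the
    empirical peak; for each candidate the expolinear rise (four parameters)
    and the logistic decay (dr, dsl given Ymax) are fitted separately —
    both are well-behaved subproblems — and the two lowest-RSS assemblies
    are returned for full polishing.
    """
    uniq, inverse = np.unique(group.positions, return_inverse=True)
    means = np.bincount(inverse, weights=group.values) / np.bincount(inverse)
    # sub-fits run on per-position means: they only seed the full polish,
    # and means are an order of magnitude fewer points than raw replicates
    pos, val = uniq, means
    xs_peak = float(uniq[int(np.argmax(means))])
    # grid offset avoids candidates exactly on integer positions, where a
    # boundary observation pinned at Ymax can trap the subsequent polish
    lo = max(2.125, xs_peak - 2.0 + 0.125)
    hi = min(group.tln + 1.0, xs_peak + 1.375)
    candidates = []
    for xs in np.arange(lo, hi + 1e-9, 0.25):
        asc = pos < xs
        dec = pos >= xs
        if asc.sum() < 5:
            continue
        got = _subfit_expolinear(pos[asc], val[asc], bounds)
        if got is None:
            continue
        rss_asc, (L1, cm, rm, tb) = got
        ymax = float(_expolinear_raw(xs, L1, cm, rm, tb))
        dr, dsl = 0.5, max(0.05 * float(val.max()), 1e-3)
        rss_dec = 0.0
        if dec.sum() >= 2:
            pars = lmfit.Parameters()
            pars.add("dr", value=1.0, min=bounds["dr"][0], max=bounds["dr"][1])
            pars.add("dsl", value=dsl, min=bounds["dsl"][0], max=bounds["dsl"][1])
            try:
                res = _lm(
                    lambda p: _logistic_raw(
                        pos[dec], ymax, p["dsl"].value, p["dr"].value, xs
                    ) - val[dec],
                    pars,
                )
                dr = float(res.params["dr"].value)
                dsl = float(res.params["dsl"].value)
                rss_dec = float(np.sum(np.asarray(res.residual) ** 2))
            except Exception:
                pass
        candidates.append(
            (rss_asc + rss_dec,
             ProfileParams(L1=L1, cm=cm, rm=rm, tb=tb, xs=float(xs), dr=dr,
                           dsl=max(dsl, bounds["dsl"][0])))
        )
    candidates.sort(key=lambda item: item[0])
    return [p for _, p in candidates[:4]]


def fit_profile(
    group: TlnGroup,
    init: Optional[ProfileParams] = None,
    bounds: Optional[dict] = None,
    min_obs: int = 8,
    multistart: bool = True,
) -> FitResult:
    """Fit the seven-parameter curve to one TLN group.

    Levenberg-Marquardt least squares on the residuals
    ``obs - y(position)``; standard errors come from the Jacobian-based
    covariance at the optimum.  With ``multistart`` a small deterministic
    ladder of starting points guards against local minima; the best
    (lowest-RSS) solution is returned.  Non-convergence is reported through
    ``converged=False``, never raised.
    """
    if group.n < min_obs:
        raise GroupSizeError(
            f"group {group.genotype}/tln={group.tln} has {group.n} observations; "
            f"at least {min_obs} required"
        )
    b = dict(_default_bounds(group))
    if bounds:
        b.update(bounds)
    init = init or default_init(group)

    x, y = group.positions, group.values
    sstot = float(np.sum((y - y.mean()) ** 2))
    vmax = float(np.abs(y).max())
    # an essentially-exact fit: further starts cannot improve on this
    rss_perfect = (1e-8 * max(vmax, 1.0)) ** 2 * group.n

    def residual(pars):
        vals = {name: pars[name].value for name in _PARAM_NAMES}
        return _eval_model(x, **vals) - y

    best = None
    nfev_total = 0

    def polish(start):
        nonlocal best, nfev_total
        pars = lmfit.Parameters()
        for name in _PARAM_NAMES:
            lo, hi = b[name]
            pars.add(name, value=float(np.clip(getattr(start, name), lo, hi)),
                     min=lo, max=hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = _lm(residual, pars)
            except Exception:
                return False
        nfev_total += res.nfev
        rss = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
        return best[0] <= rss_perfect

    done = polish(init)
    if multistart and not done:
        # the objective is rugged in xs: profile it via staged sub-fits,
        # then sweep a deterministic ladder of shape-parameter starts
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            staged = _staged_candidates(group, b)
        for start in staged + _starting_points(init, b):
            if polish(start):
                break

    if best is None:
        raise RuntimeError("all optimizer starts failed")
    rss, res = best
    fitted = ProfileParams(**{name: float(res.params[name].value) for name in _PARAM_NAMES})
    std_errors = {
        name: (float(res.params[name].stderr) if res.params[name].stderr else np.nan)
        for name in _PARAM_NAMES
    }
    rmse = float(np.sqrt(rss / group.n))
    r2 = 1.0 - rss / sstot if sstot > 0 else np.nan
    return FitResult(
        params=fitted,
        std_errors=std_errors,
        rss=rss,
        rmse=rmse,
        r2=r2,
        n=group.n,
        converged=bool(res.success),
        nfev=nfev_total,
    )


# ---------------------------------------------------------------------------
# parameter-versus-TLN regressions


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (tln, value)")
    return arr[:, 0], arr[:, 1]


def fit_tln_linear(points) -> TlnRegressionResult:
    """Ordinary least squares of a fitted parameter on TLN."""
    t, y = _as_points(points)
    if len(t) < 3:
        raise DegenerateDataError("linear TLN regression needs at least 3 points")
    if np.ptp(t) == 0:
        raise DegenerateDataError("all TLN values identical: slope is unidentified")
    X = sm.add_constant(t)
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(fit.ssr / max(len(t) - 2, 1)))
    return TlnRegressionResult(
        rule=TlnLinearRule(intercept=float(fit.params[0]), slope=float(fit.params[1])),
        std_errors={"a": float(fit.bse[0]), "b": float(fit.bse[1])},
        residual_sd=resid_sd,
        n_groups=len(t),
    )


def _segmented_design(t, bp):
    return np.column_stack([np.ones_like(t), t, np.maximum(t - bp, 0.0)])


def _plateau_design(t, bp):
    return np.column_stack([np.ones_like(t), np.minimum(t, bp)])


def _profiled_rss(t, y, design, bp):
    X = design(t, bp)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def _best_breakpoint(t, y, design, lo, hi):
    """Profile the RSS over a 0.1-resolution breakpoint grid, then polish."""
    grid = np.arange(lo, hi + 1e-9, 0.1)
    rss = np.array([_profiled_rss(t, y, design, bp)[0] for bp in grid])
    bp0 = float(grid[int(np.argmin(rss))])
    res = minimize_scalar(
        lambda bp: _profiled_rss(t, y, design, bp)[0],
        bounds=(max(lo, bp0 - 0.2), min(hi, bp0 + 0.2)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x) if res.fun <= rss.min() else bp0


def fit_tln_segmented(points, breakpoint: Optional[float] = None) -> TlnRegressionResult:
    """Continuous two-slope regression of xs on TLN (sorghum).

    With ``breakpoint=None`` the breakpoint is free: the RSS is profiled on
    a grid then polished.  Passing a value fixes it (reproduce-published-fit
    mode).  If all points fall on one side of the breakpoint the fit falls
    back to a single line with a warning.
    """
    t, y = _as_points(points)
    if len(t) < 5:
        raise DegenerateDataError("segmented TLN regression needs at least 5 points")
    if breakpoint is None:
        lo, hi = float(t.min()) + 0.5, float(t.max()) - 0.5
        bp = _best_breakpoint(t, y, _segmented_design, lo, hi)
    else:
        bp = float(breakpoint)

    if np.all(t <= bp) or np.all(t >= bp):
        warnings.warn(
            f"all TLN values on one side of breakpoint {bp:g}; "
            "falling back to a single-slope fit",
            stacklevel=2,
        )
        lin = fit_tln_linear(points)
        rule = TlnSegmentedRule(
            intercept=lin.rule.intercept,
            slope_low=lin.rule.slope,
            slope_high=lin.rule.slope,
            breakpoint=float(t.max()),
        )
        return TlnRegressionResult(
            rule=rule,
            std_errors={"a": lin.std_errors["a"], "b": lin.std_errors["b"],
                        "c": lin.std_errors["b"]},
            residual_sd=lin.residual_sd,
            n_groups=len(t),
            degenerate=True,
        )

    X = _segmented_design(t, bp)
    fit = sm.OLS(y, X).fit()
    a, b, c = (float(v) for v in fit.params)
    cov = np.asarray(fit.cov_params())
    se_high = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]))
    resid_sd = float(np.sqrt(fit.ssr / max(len(t) - X.shape[1], 1)))
    # equal slopes make the breakpoint unidentifiable
    degenerate = abs(c) <= 1e-6 * max(1.0, abs(b))
    return TlnRegressionResult(
        rule=TlnSegmentedRule(
            intercept=a, slope_low=b, slope_high=b + c, breakpoint=bp
        ),
        std_errors={"a": float(fit.bse[0]), "b": float(fit.bse[1]), "c": se_high},
        residual_sd=resid_sd,
        n_groups=len(t),
        degenerate=degenerate,
    )


def fit_tln_plateau(points) -> TlnRegressionResult:
    """Continuous decline-then-constant regression of dr on TLN.

    The plateau value is the declining line evaluated at the breakpoint
    (continuity); the breakpoint is profiled on a grid then polished.
    Monotone data with no plateau support pins the breakpoint at the
    largest TLN with a warning; a flat series is flagged degenerate.
    """
    t, y = _as_points(points)
    if len(t) < 5:
        raise DegenerateDataError("plateau TLN regression needs at least 5 points")
    if np.ptp(y) == 0:
        return TlnRegressionResult(
            rule=TlnPlateauRule(intercept=float(y[0]), slope=0.0,
                                breakpoint=float(t.min())),
            std_errors={"a": 0.0, "b": np.nan},
            residual_sd=0.0,
            n_groups=len(t),
            degenerate=True,
        )
    lo, hi = float(t.min()) + 0.5, float(t.max())
    bp = _best_breakpoint(t, y, _plateau_design, lo, hi)
    if bp >= float(t.max()) - 1e-6:
        warnings.warn(
            "no plateau support in the data; breakpoint pinned to the "
            "largest TLN",
            stacklevel=2,
        )
        bp = float(t.max())
    X = _plateau_design(t, bp)
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(fit.ssr / max(len(t) - X.shape[1], 1)))
    return TlnRegressionResult(
        rule=TlnPlateauRule(
            intercept=float(fit.params[0]), slope=float(fit.params[1]), breakpoint=bp
        ),
        std_errors={"a": float(fit.bse[0]), "b": float(fit.bse[1])},
        residual_sd=resid_sd,
        n_groups=len(t),
    )


def flag_dr_outliers(points, quantile: float = 0.975) -> np.ndarray:
    """Robust bivariate outlier mask for (TLN, dr) pairs.

    Location and scatter come from the minimum covariance determinant
    estimator; points whose squared robust Mahalanobis distance exceeds the
    chi-square(2) quantile are candidate outliers.  Because the dr-TLN cloud
    is bilinear rather than elliptical, a candidate is only confirmed when
    it also deviates from a preliminary decline-plateau fit by more than the
    matching normal quantile of the robust residual scale — so points that
    merely sit at the ends of a clean trend are never flagged.  Returns a
    boolean mask (True = outlier).  This is one admissible reading of a
    bivariate-quantile rule; the quantile is configurable.
    """
    t, y = _as_points(points)
    mask = np.zeros(len(t), dtype=bool)
    if len(t) < 5:
        warnings.warn("fewer than 5 points: no dr outliers flagged", stacklevel=2)
        return mask
    if quantile >= 1.0:
        return mask
    X = np.column_stack([t, y])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mcd = MinCovDet(random_state=0).fit(X)
        if np.linalg.matrix_rank(mcd.covariance_) < 2:
            return mask
        d2 = mcd.mahalanobis(X)
    except Exception:
        warnings.warn("robust scatter estimation failed: no dr outliers flagged",
                      stacklevel=2)
        return mask
    candidates = d2 > chi2.ppf(quantile, df=2)
    if not candidates.any():
        return mask
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prelim = fit_tln_plateau(points)
    resid = y - np.array([prelim.rule(ti) for ti in t])
    scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    # floor the scale at numerical-noise level so an essentially perfect
    # trend (residuals ~ machine precision) never produces flags
    floor = 1e-6 * max(float(np.ptp(y)), 1e-12)
    if scale <= floor:
        return mask
    z = np.sqrt(chi2.ppf(quantile, df=1))
    return candidates & (np.abs(resid) > z * scale)


def evaluate_fit(observed, predicted) -> dict:
    """Goodness of fit: RMSE (mm) and coefficient of determination R^2.

    R^2 is returned as NaN when the observations have zero variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ssres = float(np.sum((obs - pred) ** 2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(ssres / obs.size))
    if sstot == 0:
        warnings.warn("observed values have zero variance: R^2 undefined",
                      stacklevel=2)
        return {"rmse": rmse, "r2": np.nan}
    return {"rmse": rmse, "r2": 1.0 - ssres / sstot}


# ---------------------------------------------------------------------------
# species-level calibration


@dataclass(frozen=True)
class CalibrationConfig:
    """Knobs of the calibration pipeline (defaults mirror the generic fits)."""

    min_obs: int = 8            # smallest TLN group fitted
    min_groups: int = 4         # distinct TLN values required per trait
    min_decay_points: int = 3   # observations beyond xs needed for a group's
                                # xs/dr/dsl estimates to enter the pooling
                                # (the decay phase has 3 effective unknowns)
    xs_rule: str = "auto"       # "auto" | "linear" | "segmented"
    xs_breakpoint: Optional[float] = None  # fix the sorghum breakpoint (e.g. 20.5)
    dr_outlier_quantile: float = 0.975
    pooling: str = "mean"       # "mean" | "ivw" for the fixed parameters
    shape_factor_standard: float = 0.71
    shape_factor_flag: float = 0.635
    tln_range: tuple = (8, 45)
    multistart: bool = True


@dataclass
class CalibrationResult:
    """Calibrated parameter set plus per-group and regression diagnostics."""

    parameter_set: SpeciesParameterSet
    group_results: pd.DataFrame
    xs_regressions: dict
    dr_regressions: dict
    dr_outliers: dict
    skipped_groups: list = field(default_factory=list)


def _pool_fixed(values: np.ndarray, ses: np.ndarray, how: str) -> tuple[float, float]:
    """Pool one fixed parameter across TLN groups.

    Group estimates outside median +- 5 MAD are discarded first: a nonlinear
    group fit occasionally leaves a parameter essentially unconstrained
    (e.g. cm when the linear phase is never reached within the group's
    positions), and a single such estimate would dominate the average.
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    keep = np.abs(values - med) <= max(5.0 * mad, 1e-6 * max(1.0, abs(med)))
    values, ses = values[keep], ses[keep]
    if how == "ivw" and np.all(np.isfinite(ses)) and np.all(ses > 0):
        w = 1.0 / ses**2
        mean = float(np.sum(w * values) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        return mean, se
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return mean, se


def calibrate_species(
    records: pd.DataFrame,
    config: Optional[CalibrationConfig] = None,
) -> CalibrationResult:
    """Estimate a species parameter set from a leaf-record table.

    ``records`` follows the leaf CSV dialect and must contain one species.
    Returns the assembled :class:`SpeciesParameterSet` together with
    per-group fit results and the xs/dr regression diagnostics.
    """
    config = config or CalibrationConfig()
    species_values = records["species"].unique()
    if len(species_values) != 1:
        raise CalibrationError(
            f"records must contain exactly one species, got {sorted(species_values)}"
        )
    species = SpeciesId(species_values[0])
    if config.xs_rule == "auto":
        xs_kind = "segmented" if species is SpeciesId.SORGHUM else "linear"
    else:
        xs_kind = config.xs_rule

    trait_columns = {
        Trait.BLADE_LENGTH: "blade_length_mm",
        Trait.BLADE_WIDTH: "blade_width_mm",
    }
    rows = []
    skipped: list[str] = []

    for trait, column in trait_columns.items():
        sub = records.dropna(subset=[column])
        for (genotype, tln), chunk in sub.groupby(["genotype", "tln"], sort=True):
            if len(chunk) < config.min_obs:
                skipped.append(
                    f"{trait.value} {genotype}/tln={tln}: only {len(chunk)} obs "
                    f"(< {config.min_obs})"
                )
                continue
            group = TlnGroup(
                species=species,
                genotype=str(genotype),
                trait=trait,
                tln=int(tln),
                positions=chunk["position"].to_numpy(float),
                values=chunk[column].to_numpy(float),
            )
            result = fit_profile(group, min_obs=config.min_obs,
                                 multistart=config.multistart)
            decay_support = int(np.sum(group.positions > result.params.xs))
            row = {
                "species": species.value,
                "genotype": str(genotype),
                "trait": trait.value,
                "tln": int(tln),
                "n": result.n,
                "rss": result.rss,
                "rmse": result.rmse,
                "r2": result.r2,
                "converged": result.converged,
                "decay_support": decay_support,
            }
            for name in _PARAM_NAMES:
                row[name] = getattr(result.params, name)
                row[f"{name}_se"] = result.std_errors[name]
            rows.append(row)

    group_results = pd.DataFrame(rows)
    traits: dict[Trait, TraitParams] = {}
    xs_regressions, dr_regressions, dr_outliers = {}, {}, {}

    for trait in Trait:
        sub = group_results[
            (group_results["trait"] == trait.value) & group_results["converged"]
        ]
        # groups whose decay phase is actually observed: only these inform
        # xs, dr and dsl (low-TLN groups leave the logistic phase nearly
        # unconstrained and would otherwise contaminate the pooling)
        supported = sub[sub["decay_support"] >= config.min_decay_points]
        distinct = supported["tln"].nunique()
        if distinct < config.min_groups:
            raise CalibrationError(
                f"{species.value}/{trait.value}: {distinct} distinct TLN group(s) "
                f"with an observed decay phase; at least {config.min_groups} "
                "required"
            )
        se_map = {}
        fixed = {}
        for name in ("L1", "cm", "rm", "tb", "dsl"):
            source = supported if name == "dsl" else sub
            values = source[name].to_numpy(float)
            ses = source[f"{name}_se"].to_numpy(float)
            fixed[name], se_map[name] = _pool_fixed(values, ses, config.pooling)

        tlns = supported["tln"].to_numpy(float)
        xs_points = np.column_stack([tlns, supported["xs"].to_numpy(float)])
        if xs_kind == "segmented":
            xs_reg = fit_tln_segmented(xs_points, breakpoint=config.xs_breakpoint)
            se_map.update({"xs.a": xs_reg.std_errors["a"],
                           "xs.b": xs_reg.std_errors["b"],
                           "xs.c": xs_reg.std_errors["c"]})
        else:
            xs_reg = fit_tln_linear(xs_points)
            se_map.update({"xs.a": xs_reg.std_errors["a"],
                           "xs.b": xs_reg.std_errors["b"]})
        xs_regressions[trait] = xs_reg

        dr_points = np.column_stack([tlns, supported["dr"].to_numpy(float)])
        outlier_mask = flag_dr_outliers(dr_points, config.dr_outlier_quantile)
        dr_outliers[trait] = outlier_mask
        dr_reg = fit_tln_plateau(dr_points[~outlier_mask])
        dr_regressions[trait] = dr_reg
        se_map.update({"dr.a": dr_reg.std_errors["a"],
                       "dr.b": dr_reg.std_errors["b"]})

        traits[trait] = TraitParams(
            L1=fixed["L1"],
            cm=fixed["cm"],
            rm=fixed["rm"],
            tb=fixed["tb"],
            dsl=fixed["dsl"],
            xs_rule=xs_reg.rule,
            dr_rule=dr_reg.rule,
            std_errors={k: v for k, v in se_map.items() if np.isfinite(v)},
        )

    pset = SpeciesParameterSet(
        species=species,
        traits=traits,
        shape_factor_standard=config.shape_factor_standard,
        shape_factor_flag=config.shape_factor_flag,
        tln_range=config.tln_range,
    ).validate()
    return CalibrationResult(
        parameter_set=pset,
        group_results=group_results,
        xs_regressions=xs_regressions,
        dr_regressions=dr_regressions,
        dr_outliers=dr_outliers,
        skipped_groups=skipped,
    )
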