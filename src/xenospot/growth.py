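"""Tumour growth kinetics of PDX cohorts on the cube-root scale.

Calliper volumes (V = pi/6 * h * w * d) are modelled on the cube-root
scale, where subcutaneous growth is approximately linear. For one patient
line the mean structure is continuous piecewise-linear: controls grow with
a single slope beta_c; treated mice grow at beta1 until the onset of
treatment effect t1, change to beta2 on [t1, t2) and to beta3 (regrowth)
after t2, with slopes tied continuously at the knots. Each mouse carries a
Normal(0, tau^2) random intercept; residuals are independent Gaussians
with arm-specific variances (treated responses are visibly noisier than
controls, hence the heteroscedastic model).

Estimation maximises the marginal Gaussian likelihood, profiling the fixed
effects out by GLS and optimising the three variance parameters
numerically. The knots (t1, t2) are estimated by joint grid search over
candidate measurement days, minimising the residual sum of squares of
treated observations around the fixed-effects (population) mean. t2 — the
day regrowth starts — is the preclinical analogue of progression-free
survival; the study endpoint is the day tumour volume reaches 1,500 mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError, GridError, RankError

__all__ = [
    "GrowthModelFit",
    "InflectionResult",
    "tumour_volume",
    "fit_growth_model",
    "estimate_inflection_points",
    "compare_growth_rates",
    "predict_fixed",
    "time_to_endpoint",
    "predicted_time_to_endpoint",
    "correlate_outcome",
    "ENDPOINT_VOLUME",
]

ENDPOINT_VOLUME = 1500.0  # mm^3; humane endpoint / overall-survival surrogate
_VAR_FLOOR = 1e-12


def tumour_volume(h, w, d):
    """Ellipsoid-style calliper volume: pi/6 * h * w * d (mm^3)."""
    h, w, d = np.asarray(h, dtype=float), np.asarray(w, dtype=float), np.asarray(d, dtype=float)
    if (h < 0).any() or (w < 0).any() or (d < 0).any():
        raise ValueError("calliper dimensions must be non-negative")
    out = math.pi / 6.0 * h * w * d
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthModelFit:
    """Fitted piecewise mixed model for one patient line."""

    alpha: float
    beta_control: float
    beta1: float
    beta2: float
    beta3: float
    tau2: float
    sigma2_treated: float
    sigma2_control: float
    t1: float
    t2: float
    loglik: float
    converged: bool
    theta: np.ndarray = field(repr=False)  # (alpha, beta_c, beta1, d2, d3)
    cov_theta: np.ndarray = field(repr=False)
    n_obs: int = 0
    n_mice: int = 0
    blocks: Optional[list] = field(default=None, repr=False)  # per-mouse data for df approximations


def _design(days: np.ndarray, is_control: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Columns: const, control slope, treated base slope, two hinges."""
    t = np.asarray(days, dtype=float)
    treated = ~is_control
    x = np.zeros((len(t), 5))
    x[:, 0] = 1.0
    x[:, 1] = np.where(is_control, t, 0.0)
    x[:, 2] = np.where(treated, t, 0.0)
    x[:, 3] = np.where(treated, np.clip(t - t1, 0, None), 0.0)
    x[:, 4] = np.where(treated, np.clip(t - t2, 0, None), 0.0)
    return x


def _groups(measurements: pd.DataFrame, t1: float, t2: float):
    """Per-mouse (y, X, is_control) blocks from a measurement table."""
    if "volume" not in measurements.columns:
        measurements = measurements.assign(
            volume=tumour_volume(measurements["h"], measurements["w"], measurements["d"])
        )
    arms = measurements["arm"].unique()
    for arm in arms:
        if arm not in ("treated", "control"):
            raise FitError(f"unknown arm {arm!r}; expected treated/control")
        n_mice = measurements.loc[measurements["arm"] == arm, "mouse_id"].nunique()
        if n_mice < 2:
            raise RankError(
                f"arm {arm!r} has {n_mice} mouse/mice; random-intercept variance "
                "is not identifiable with fewer than 2 mice per arm"
            )
    blocks = []
    for mouse_id, grp in measurements.groupby("mouse_id", sort=True):
        is_control = np.full(len(grp), (grp["arm"].iloc[0] == "control"))
        y = np.cbrt(grp["volume"].to_numpy(dtype=float))
        x = _design(grp["day"].to_numpy(dtype=float), is_control, t1, t2)
        blocks.append((mouse_id, y, x, bool(is_control[0])))
    return blocks


def _gls(blocks, tau2: float, s2_t: float, s2_c: float):
    """Profiled GLS given variance components.

    Returns (theta, cov_theta, loglik, fitted residual quadratic form).
    V_i = sigma2 I + tau2 J has closed-form inverse/determinant
    (Sherman-Morrison), used throughout.
    """
    p = 5
    a = np.zeros((p, p))
    b = np.zeros(p)
    pieces = []
    for _, y, x, is_control in blocks:
        s2 = s2_c if is_control else s2_t
        n = len(y)
        denom = s2 + n * tau2
        shrink = tau2 / (s2 * denom)
        # V^-1 z = z / s2 - shrink * sum(z) (Sherman-Morrison)
        xv = x / s2 - shrink * x.sum(axis=0)
        a += x.T @ xv
        b += xv.T @ y
        logdet = (n - 1) * math.log(s2) + math.log(denom)
        pieces.append((y, x, s2, shrink, logdet, n))
    try:
        cov = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        raise RankError("singular design: fixed effects not identifiable") from None
    theta = cov @ b
    loglik = 0.0
    for y, x, s2, shrink, logdet, n in pieces:
        r = y - x @ theta
        quad = float(r @ r) / s2 - shrink * float(r.sum()) ** 2
        loglik -= 0.5 * (n * math.log(2 * math.pi) + logdet + quad)
    return theta, cov, loglik


def fit_growth_model(
    measurements: pd.DataFrame,
    knots: tuple[float, float],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GrowthModelFit:
    """Fit the heteroscedastic random-intercept piecewise model.

    ``measurements`` needs ``mouse_id, arm, day`` and either ``volume`` or
    ``h, w, d``. ``knots = (t1, t2)`` with t1 < t2, inside the observed day
    range. Raises :class:`RankError` on non-identifiable designs.
    """
    t1, t2 = float(knots[0]), float(knots[1])
    if not t1 < t2:
        raise FitError(f"need t1 < t2, got ({t1}, {t2})")
    days = measurements["day"].to_numpy(dtype=float)
    if t1 < days.min() or t2 > days.max():
        raise FitError(f"knots ({t1}, {t2}) outside observed day range")
    blocks = _groups(measurements, t1, t2)
    n_obs = sum(len(y) for _, y, _, _ in blocks)

    # OLS initialisation (V = I); also the exact solution for noiseless data
    x_all = np.vstack([x for _, _, x, _ in blocks])
    y_all = np.concatenate([y for _, y, _, _ in blocks])
    if np.linalg.matrix_rank(x_all) < x_all.shape[1]:
        raise RankError("singular design: knots coincide with the day range boundary?")
    theta0, rss0, *_ = np.linalg.lstsq(x_all, y_all, rcond=None)
    rss0 = float(((y_all - x_all @ theta0) ** 2).sum())

    def finish(theta, cov, tau2, s2_t, s2_c, loglik, converged):
        alpha, beta_c, beta1, d2, d3 = theta
        return GrowthModelFit(
            alpha=float(alpha),
            beta_control=float(beta_c),
            beta1=float(beta1),
            beta2=float(beta1 + d2),
            beta3=float(beta1 + d2 + d3),
            tau2=float(tau2),
            sigma2_treated=float(s2_t),
            sigma2_control=float(s2_c),
            t1=t1,
            t2=t2,
            loglik=float(loglik),
            converged=converged,
            theta=np.asarray(theta, dtype=float),
            cov_theta=np.asarray(cov, dtype=float),
            n_obs=n_obs,
            n_mice=len(blocks),
            blocks=blocks,
        )

    if rss0 < 1e-10:  # noiseless data: exact deterministic fit
        return finish(theta0, np.zeros((5, 5)), 0.0, 0.0, 0.0, math.inf, True)

    resid0 = y_all - x_all @ theta0
    s2_init = max(rss0 / max(n_obs - 5, 1), _VAR_FLOOR)
    mouse_means = [float((y - x @ theta0).mean()) for _, y, x, _ in blocks]
    tau2_init = max(float(np.var(mouse_means)), s2_init * 1e-3)

    def negloglik(phi):
        tau2, s2_t, s2_c = np.exp(phi)
        _, _, ll = _gls(blocks, tau2, s2_t, s2_c)
        return -ll

    x0 = np.log([tau2_init, s2_init, s2_init])
    lo, hi = math.log(_VAR_FLOOR), math.log(1e6)
    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * 3,
        options={"ftol": tol, "maxiter": max_iter},
    )
    tau2, s2_t, s2_c = np.exp(res.x)
    theta, cov, loglik = _gls(blocks, tau2, s2_t, s2_c)
    return finish(theta, cov, tau2, s2_t, s2_c, loglik, bool(res.success))


def predict_fixed(fit: GrowthModelFit, days, arm: str) -> np.ndarray:
    """Population (fixed-effects) mean on the cube-root scale."""
    days = np.asarray(days, dtype=float)
    is_control = np.full(len(days), arm == "control")
    x = _design(days, is_control, fit.t1, fit.t2)
    return x @ fit.theta


def _fixed_effects_rss(fit: GrowthModelFit, measurements: pd.DataFrame) -> float:
    """RSS of treated observations around the population expectation."""
    treated = measurements.loc[measurements["arm"] == "treated"]
    if "volume" not in treated.columns:
        treated = treated.assign(volume=tumour_volume(treated["h"], treated["w"], treated["d"]))
    y = np.cbrt(treated["volume"].to_numpy(dtype=float))
    mu = predict_fixed(fit, treated["day"].to_numpy(dtype=float), "treated")
    return float(((y - mu) ** 2).sum())


@dataclass
class InflectionResult:
    t1: float
    t2: float
    rss: float
    identifiable: bool
    surface: pd.DataFrame  # candidate t1, t2, rss
    fit: GrowthModelFit


def estimate_inflection_points(
    measurements: pd.DataFrame,
    candidate_days: Optional[Sequence[float]] = None,
) -> InflectionResult:
    """Joint grid search for the treatment-effect and regrowth knots.

    Candidates default to the interior observed treated measurement days
    (the outermost days would make a hinge column collinear). Every t1 < t2
    pair is fitted and scored by the fixed-effects RSS of treated
    observations; ties resolve to the earliest t1, then earliest t2. A flat
    RSS surface (no treatment effect) is flagged non-identifiable.
    """
    treated_days = np.unique(
        measurements.loc[measurements["arm"] == "treated", "day"].to_numpy(dtype=float)
    )
    if candidate_days is None:
        candidates = treated_days[1:-1]
    else:
        candidates = np.unique(np.asarray(candidate_days, dtype=float))
    pairs = list(combinations(sorted(candidates), 2))
    if len(pairs) < 2:
        raise GridError(f"need >= 2 candidate knot pairs, got {len(pairs)}")
    rows = []
    best = None
    for t1, t2 in pairs:
        try:
            fit = fit_growth_model(measurements, (t1, t2))
        except (RankError, FitError):
            continue
        rss = _fixed_effects_rss(fit, measurements)
        rows.append({"t1": t1, "t2": t2, "rss": rss})
        if best is None or rss < best[0] - 1e-12:
            best = (rss, t1, t2, fit)
    if best is None:
        raise FitError("no candidate knot pair produced an identifiable fit")
    surface = pd.DataFrame(rows)
    spread = float(surface["rss"].max() - surface["rss"].min())
    identifiable = spread > 1e-8 * max(float(surface["rss"].max()), 1.0)
    rss, t1, t2, fit = best
    return InflectionResult(
        t1=t1, t2=t2, rss=rss, identifiable=identifiable, surface=surface, fit=fit
    )


_CONTRASTS = {
    # beta3 - beta1 = d2 + d3 in the internal parameterisation
    "pre_vs_regrowth": np.array([0.0, 0.0, 0.0, 1.0, 1.0]),
    # beta1 - beta_c
    "treated_vs_control_baseline": np.array([0.0, -1.0, 1.0, 0.0, 0.0]),
}


def _reml_nll_factory(blocks):
    """Negative restricted log-likelihood over log variance parameters."""

    def nll(phi):
        tau2, s2_t, s2_c = np.exp(phi)
        ll = _gls(blocks, tau2, s2_t, s2_c)[2]
        p = 5
        a = np.zeros((p, p))
        for _, y, x, is_control in blocks:
            s2 = s2_c if is_control else s2_t
            n = len(y)
            shrink = tau2 / (s2 * (s2 + n * tau2))
            a += x.T @ (x / s2 - shrink * x.sum(axis=0))
        return -(ll - 0.5 * np.linalg.slogdet(a)[1])

    return nll


def _contrast_inference(fit: GrowthModelFit, c: np.ndarray) -> tuple[float, float, float]:
    """(std. error, Satterthwaite df, estimate) for the contrast c'theta.

    Variance components are re-estimated by REML for inference (the point
    fit stays ML); the contrast variance gets a first-order
    Kackar-Harville inflation for the uncertainty of the variance
    parameters, and the reference df follow Satterthwaite — together the
    standard small-sample treatment for mixed-model Wald tests
    (lmerTest / Kenward-Roger territory).
    """
    blocks = fit.blocks
    nll = _reml_nll_factory(blocks)
    x0 = np.log(np.maximum([fit.tau2, fit.sigma2_treated, fit.sigma2_control], 1e-8))
    lo, hi = math.log(_VAR_FLOOR), math.log(1e6)
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 3, options={"ftol": 1e-10}
    )
    phi = res.x

    def estc(p):
        return float(c @ _gls(blocks, *np.exp(p))[0])

    def covc(p):
        return float(c @ _gls(blocks, *np.exp(p))[1] @ c)

    est = estc(phi)
    var = covc(phi)
    h = 1e-4
    grad = np.zeros(3)
    dtheta = np.zeros(3)
    hess = np.zeros((3, 3))
    f0 = nll(phi)
    basis = np.eye(3) * h
    for k in range(3):
        ek = basis[k]
        grad[k] = (covc(phi + ek) - covc(phi - ek)) / (2 * h)
        dtheta[k] = (estc(phi + ek) - estc(phi - ek)) / (2 * h)
        hess[k, k] = (nll(phi + ek) - 2 * f0 + nll(phi - ek)) / h**2
        for l in range(k):
            el = basis[l]
            hess[k, l] = hess[l, k] = (
                nll(phi + ek + el) - nll(phi + ek - el) - nll(phi - ek + el) + nll(phi - ek - el)
            ) / (4 * h**2)
    vphi = np.linalg.pinv(hess)
    var_adj = var + max(float(dtheta @ vphi @ dtheta), 0.0)
    denom = float(grad @ vphi @ grad)
    df = max(2.0 * var**2 / denom, 1.0) if (denom > 0 and var > 0) else float("inf")
    return math.sqrt(var_adj) if var_adj > 0 else 0.0, df, est


def compare_growth_rates(
    fit: GrowthModelFit, contrasts: Sequence[str] = ("pre_vs_regrowth",)
) -> pd.DataFrame:
    """Wald tests on fixed-effect slope contrasts, Holm-adjusted as a family.

    The reference distribution is Student t with Satterthwaite degrees of
    freedom, which keeps the test close to its nominal level at the small
    per-arm mouse counts typical of PDX studies.
    """
    if not fit.converged:
        raise FitError("refusing inference on a non-converged fit")
    rows = []
    for name in contrasts:
        try:
            c = _CONTRASTS[name]
        except KeyError:
            raise ValueError(f"unknown contrast {name!r}") from None
        est = float(c @ fit.theta)
        var = float(c @ fit.cov_theta @ c)
        if var <= 0 or fit.blocks is None:
            # exact fit: a contrast at numerical zero is a true null
            tol = 1e-8 * max(1.0, float(np.abs(fit.theta).max()))
            est = 0.0 if abs(est) < tol else est
            stat = 0.0 if est == 0 else math.inf * math.copysign(1, est)
            df = float("inf")
        else:
            se, df, est = _contrast_inference(fit, c)
            stat = est / se if se > 0 else (0.0 if est == 0 else math.inf * math.copysign(1, est))
        if stat == 0:
            p = 1.0
        elif not math.isfinite(stat):
            p = 0.0
        elif math.isfinite(df):
            p = 2.0 * stats.t.sf(abs(stat), df)
        else:
            p = 2.0 * stats.norm.sf(abs(stat))
        rows.append({"contrast": name, "estimate": est, "statistic": stat, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def time_to_endpoint(
    measurements: pd.DataFrame,
    threshold: float = ENDPOINT_VOLUME,
    censor_day: Optional[float] = None,
) -> pd.DataFrame:
    """First observed day with volume >= threshold, per mouse.

    Mice never crossing the threshold return the censoring day (defaults
    to their last measurement day) with ``censored=True``.
    """
    if "volume" not in measurements.columns:
        measurements = measurements.assign(
            volume=tumour_volume(measurements["h"], measurements["w"], measurements["d"])
        )
    rows = []
    for mouse_id, grp in measurements.sort_values("day").groupby("mouse_id", sort=True):
        crossed = grp.loc[grp["volume"] >= threshold]
        if len(crossed):
            rows.append({"mouse_id": mouse_id, "day": float(crossed["day"].iloc[0]), "censored": False})
        else:
            day = float(censor_day if censor_day is not None else grp["day"].max())
            rows.append({"mouse_id": mouse_id, "day": day, "censored": True})
    return pd.DataFrame(rows)


def predicted_time_to_endpoint(
    fit: GrowthModelFit, arm: str = "treated", threshold: float = ENDPOINT_VOLUME,
    max_day: float = 3650.0,
) -> float:
    """Continuous crossing day of the fixed-effects trajectory.

    Solves mean(t) = threshold^(1/3) segment by segment on the cube-root
    scale (extrapolating the final slope); returns ``nan`` when the mean
    never reaches the threshold before ``max_day``.
    """
    target = threshold ** (1.0 / 3.0)
    if arm == "control":
        knots = [0.0, max_day]
    else:
        knots = [0.0, fit.t1, fit.t2, max_day]
    for lo, hi in zip(knots[:-1], knots[1:]):
        y_lo = float(predict_fixed(fit, [lo], arm)[0])
        y_hi = float(predict_fixed(fit, [hi], arm)[0])
        if y_lo >= target:
            return lo
        if y_hi >= target:
            # linear on this segment
            return lo + (target - y_lo) * (hi - lo) / (y_hi - y_lo)
    return float("nan")


def correlate_outcome(summary: pd.DataFrame) -> dict:
    """Pearson correlations of group mean xTF slope with outcome measures.

    ``summary`` has one row per patient-line x arm group with columns
    ``arm, xtf_slope, t2, time_to_endpoint`` (t2 is NaN for controls).
    Returns ``{"slope_vs_t2": (r, p), "slope_vs_endpoint": (r, p)}``; the
    t2 pairing uses treated groups only. Degenerate pairings yield NaN.
    """

    def _pearson(x, y):
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    treated = summary.loc[summary["arm"] == "treated"]
    return {
        "slope_vs_t2": _pearson(
            treated["xtf_slope"].to_numpy(dtype=float), treated["t2"].to_numpy(dtype=float)
        ),
        "slope_vs_endpoint": _pearson(
            summary["xtf_slope"].to_numpy(dtype=float),
            summary["time_to_endpoint"].to_numpy(dtype=float),
        ),
    }
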