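"""Two-stage meta-analytic pooling of per-cohort estimates.

Each cohort contributes an estimate ``theta_i`` with sampling variance
``v_i``. The random-effects model

    y_i = mu + u_i + e_i,   u_i ~ N(0, tau^2),   e_i ~ N(0, v_i)

is fitted by restricted maximum likelihood (REML): the between-cohort
variance ``tau^2`` maximises the restricted log-likelihood

    l_R(t) = -1/2 [ sum_i log(t + v_i) + log sum_i 1/(t + v_i)
                    + sum_i (y_i - mu_hat(t))^2 / (t + v_i) ]

over t >= 0, with mu_hat(t) the weighted mean under weights 1/(t + v_i).
If REML fails to converge the fit falls back to maximum likelihood, and
then to the inverse-variance fixed-effects estimator

    mu_FE = sum w_i theta_i / sum w_i,   w_i = 1 / v_i.

The estimator that actually produced the result is recorded on the output.
Confidence intervals are Wald: mu +/- 1.96 se. Heterogeneity is summarised
by Higgins' I^2 from Cochran's Q under fixed-effects weights. Proportions
are pooled on the logit scale and back-transformed, which keeps intervals
inside (0, 1); cohorts with zero or full counts get a 0.5/0.5 continuity
correction.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

__all__ = [
    "PooledEstimate",
    "pool_fixed",
    "pool_random_ml",
    "pool_random_reml",
    "heterogeneity_i2",
    "pool_proportions_logit",
    "pool_mean_difference",
    "interpolate_covariate",
]

_Z975 = 1.96  # normal-approximation 95% multiplier


@dataclass(frozen=True)
class PooledEstimate:
    """Cross-cohort pooled estimate with heterogeneity diagnostics."""

    mu: float
    se_mu: float
    ci95: tuple[float, float]
    tau2: float
    i2: float
    k: int
    method: str  # REML | ML | FE
    scale: str = "natural"
    flags: tuple[str, ...] = ()

    def transform(self, f) -> "PooledEstimate":
        """Apply a monotone map to mu and the CI (e.g. inverse-logit)."""
        lo, hi = f(self.ci95[0]), f(self.ci95[1])
        return PooledEstimate(
            mu=f(self.mu), se_mu=self.se_mu, ci95=(min(lo, hi), max(lo, hi)),
            tau2=self.tau2, i2=self.i2, k=self.k, method=self.method,
            scale="natural", flags=self.flags,
        )


def _as_arrays(theta, v) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(theta, float).ravel()
    vv = np.asarray(v, float).ravel()
    if t.size == 0:
        raise ValueError("no cohort estimates to pool")
    if t.size != vv.size:
        raise ValueError("theta and v length mismatch")
    if np.any(vv <= 0) or not np.all(np.isfinite(t)) or not np.all(np.isfinite(vv)):
        raise ValueError("sampling variances must be finite and > 0")
    return t, vv


def _weighted(theta: np.ndarray, v: np.ndarray, tau2: float) -> tuple[float, float]:
    w = 1.0 / (tau2 + v)
    mu = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return mu, se


def heterogeneity_i2(theta, v) -> float:
    """Higgins' I^2 (%) from Cochran's Q under fixed-effects weights;
    NaN for fewer than two cohorts."""
    t, vv = _as_arrays(theta, v)
    k = t.size
    if k < 2:
        return float("nan")
    w = 1.0 / vv
    mu = np.sum(w * t) / np.sum(w)
    q = float(np.sum(w * (t - mu) ** 2))
    if q <= 0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / q) * 100.0)


def pool_fixed(theta, v, flags: Sequence[str] = ()) -> PooledEstimate:
    """Inverse-variance fixed-effects pooling."""
    t, vv = _as_arrays(theta, v)
    mu, se = _weighted(t, vv, 0.0)
    return PooledEstimate(
        mu=mu, se_mu=se, ci95=(mu - _Z975 * se, mu + _Z975 * se),
        tau2=0.0, i2=heterogeneity_i2(t, vv), k=t.size, method="FE",
        flags=tuple(flags),
    )


def _neg_restricted_ll(tau2: float, t: np.ndarray, vv: np.ndarray) -> float:
    w = 1.0 / (tau2 + vv)
    mu = np.sum(w * t) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(tau2 + vv)) + np.log(np.sum(w)) + np.sum(w * (t - mu) ** 2)
    )


def _neg_ml_ll(tau2: float, t: np.ndarray, vv: np.ndarray) -> float:
    w = 1.0 / (tau2 + vv)
    mu = np.sum(w * t) / np.sum(w)
    return 0.5 * (np.sum(np.log(tau2 + vv)) + np.sum(w * (t - mu) ** 2))


def _optimize_tau2(objective, t, vv) -> tuple[float, bool]:
    """Maximise a profile likelihood in tau^2 on [0, 10*var(theta)].

    Returns (tau2_hat, converged). Declared non-converged when the upper
    bound is active or the input is degenerate (no spread in theta).
    """
    spread = float(np.var(t, ddof=1)) if t.size > 1 else 0.0
    tau_max = 10.0 * spread
    if tau_max <= 0.0:
        return 0.0, False
    res = minimize_scalar(
        objective, bounds=(0.0, tau_max), args=(t, vv), method="bounded",
        options={"xatol": 1e-8, "maxiter": 100},
    )
    if not res.success:
        return 0.0, False
    tau2 = float(res.x)
    # the bounded optimizer never lands exactly on a bound; snap to 0 when
    # the boundary value is at least as good
    if objective(0.0, t, vv) <= res.fun:
        tau2 = 0.0
    if tau2 >= tau_max * (1 - 1e-6):
        return tau2, False
    return tau2, True


def pool_random_ml(theta, v) -> PooledEstimate:
    """Random-effects pooling with the (unrestricted) ML variance estimator;
    falls back to fixed effects if the fit is degenerate."""
    t, vv = _as_arrays(theta, v)
    if t.size < 2:
        return pool_fixed(t, vv, flags=("k<2: fixed-effects passthrough",))
    tau2, ok = _optimize_tau2(_neg_ml_ll, t, vv)
    if not ok:
        return pool_fixed(t, vv, flags=("ML did not converge: fixed-effects fallback",))
    mu, se = _weighted(t, vv, tau2)
    return PooledEstimate(
        mu=mu, se_mu=se, ci95=(mu - _Z975 * se, mu + _Z975 * se),
        tau2=tau2, i2=heterogeneity_i2(t, vv), k=t.size, method="ML",
    )


def pool_random_reml(theta, v) -> PooledEstimate:
    """Random-effects pooling by REML with the ML -> fixed-effects fallback
    cascade; the ``method`` field records the estimator that succeeded."""
    t, vv = _as_arrays(theta, v)
    if t.size < 2:
        return pool_fixed(t, vv, flags=("k<2: fixed-effects passthrough",))
    tau2, ok = _optimize_tau2(_neg_restricted_ll, t, vv)
    if not ok:
        out = pool_random_ml(t, vv)
        flags = ("REML did not converge",) + out.flags
        return replace(out, flags=flags)
    mu, se = _weighted(t, vv, tau2)
    return PooledEstimate(
        mu=mu, se_mu=se, ci95=(mu - _Z975 * se, mu + _Z975 * se),
        tau2=tau2, i2=heterogeneity_i2(t, vv), k=t.size, method="REML",
    )


_POOLERS = {"reml": pool_random_reml, "ml": pool_random_ml, "fe": pool_fixed}


def pool_proportions_logit(x, n, method: str = "reml") -> PooledEstimate:
    """Pool per-cohort proportions x_i/n_i on the logit scale.

    Cohorts with zero or full counts receive a continuity correction of 0.5
    added to both successes and failures (that cohort only). The pooled
    estimate and CI are back-transformed to the probability scale, so the
    interval is constrained to (0, 1); ``tau2`` remains on the logit scale.
    """
    xx = np.asarray(x, float).ravel()
    nn = np.asarray(n, float).ravel()
    if np.any(nn < 1) or np.any(xx < 0) or np.any(xx > nn):
        raise ValueError("need 0 <= x_i <= n_i and n_i >= 1")
    flags: list[str] = []
    boundary = (xx == 0) | (xx == nn)
    if boundary.any():
        flags.append(f"continuity correction applied to {int(boundary.sum())} cohort(s)")
    xa = np.where(boundary, xx + 0.5, xx)
    na = np.where(boundary, nn + 1.0, nn)
    p = xa / na
    theta = logit(p)
    v = 1.0 / xa + 1.0 / (na - xa)

    if np.all(xx == 0) or np.all(xx == nn):
        flags.append("all cohorts at boundary: fixed-effects pooling")
        pooled = pool_fixed(theta, v, flags=flags)
    else:
        pooled = _POOLERS[method](theta, v)
        pooled = replace(pooled, flags=pooled.flags + tuple(flags))
    out = pooled.transform(expit)
    return replace(out, scale="natural")


def pool_mean_difference(means, variances, method: str = "reml") -> PooledEstimate:
    """Pool per-cohort mean differences (natural scale) by the chosen method."""
    return _POOLERS[method](means, variances)


def interpolate_covariate(
    series: pd.DataFrame, target_years: Sequence[int],
    max_extrapolation_years: int = 5,
) -> pd.DataFrame:
    """Fill a country-year covariate series at the requested years.

    Years between observed values are linearly interpolated from the nearest
    observed years. Years outside the observed range, but within
    ``max_extrapolation_years`` of it, are extrapolated from a least-squares
    line through all observed years (at least two required). Years further
    out are returned with NaN and flagged absent.

    ``series`` columns: country, year, value. Returns country, year, value,
    observed (bool) for every (country, target year).
    """
    rows = []
    for country, sub in series.dropna(subset=["value"]).groupby("country"):
        sub = sub.sort_values("year")
        yrs = sub["year"].to_numpy(float)
        vals = sub["value"].to_numpy(float)
        line = np.polyfit(yrs, vals, 1) if yrs.size >= 2 else None
        for ty in target_years:
            if ty in yrs:
                val, obs = float(vals[yrs == ty][0]), True
            elif yrs.min() <= ty <= yrs.max():
                val, obs = float(np.interp(ty, yrs, vals)), False
            elif line is not None and (
                0 < (gap := min(abs(ty - yrs.min()), abs(ty - yrs.max()))) <= max_extrapolation_years
            ):
                val, obs = float(np.polyval(line, ty)), False
            else:
                val, obs = float("nan"), False
            rows.append((country, int(ty), val, obs))
    return pd.DataFrame(rows, columns=["country", "year", "value", "observed"])
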