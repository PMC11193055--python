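"""Dose-response curve fitting, AIC model selection and ED50 estimation.

Two model families are supported, both standard in cytotoxicity work:

* EXD3 — three-parameter exponential decay,
  ``f(x) = c + (d - c) * exp(-x / e)``;
* LL4 — four-parameter log-logistic,
  ``f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))``,

where d is the upper asymptote (untreated response), c the lower
asymptote, e a dose scale (for LL4 the inflection dose), and b the LL4
slope.  Models are fitted by nonlinear least squares with jittered
multi-starts, ranked by a Gaussian-likelihood AIC that counts the error
variance as a parameter, and the winner's ED50 (the dose halfway between
the fitted asymptotes) is reported with a nonparametric bootstrap 95%
confidence interval; a delta-method interval is included for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponsePoint", "DoseResponseFit", "Ed50Result",
           "exd3", "ll4", "fit", "select_model", "ed50", "MODELS"]

MODELS = ("EXD3", "LL4")
_PARAM_NAMES = {"EXD3": ("c", "d", "e"), "LL4": ("b", "c", "d", "e")}


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float      # concentration, e.g. uM; >= 0
    response: float  # survival fraction relative to untreated control
    replicate: int = 1

    def __post_init__(self):
        if not math.isfinite(self.dose) or self.dose < 0:
            raise ValueError(f"dose must be finite and >= 0, got {self.dose}")
        if not math.isfinite(self.response):
            raise ValueError("response must be finite")


def exd3(dose, c, d, e):
    """Three-parameter exponential decay: c + (d - c) * exp(-dose / e)."""
    if e <= 0:
        raise ValueError("rate scale e must be > 0")
    dose = np.asarray(dose, dtype=float)
    return c + (d - c) * np.exp(-dose / e)


def ll4(dose, b, c, d, e):
    """Four-parameter log-logistic: c + (d - c) / (1 + exp(b (ln x - ln e))).

    dose = 0 is handled by the analytic limit: d for b > 0, c for b < 0.
    """
    if e <= 0:
        raise ValueError("inflection dose e must be > 0")
    scalar = np.isscalar(dose) or np.ndim(dose) == 0
    dose = np.atleast_1d(np.asarray(dose, dtype=float))
    out = np.empty_like(dose)
    pos = dose > 0
    with np.errstate(over="ignore"):
        out[pos] = c + (d - c) / (1.0 + np.exp(b * (np.log(dose[pos]) - math.log(e))))
    out[~pos] = d if b > 0 else (c if b < 0 else (c + d) / 2.0)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted dose-response model with its AIC and diagnostics."""

    model: str
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    rss: float
    n: int
    aic: float
    converged: bool
    doses: np.ndarray = field(repr=False, default=None)
    responses: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(_PARAM_NAMES[self.model])

    def predict(self, dose):
        p = self.estimates
        if self.model == "EXD3":
            return exd3(dose, p["c"], p["d"], p["e"])
        return ll4(dose, p["b"], p["c"], p["d"], p["e"])


def _predict(model: str, theta: np.ndarray, dose: np.ndarray) -> np.ndarray:
    if model == "EXD3":
        return exd3(dose, *theta)
    return ll4(dose, *theta)


def _initial_guess(model: str, dose: np.ndarray, resp: np.ndarray) -> np.ndarray:
    d0 = float(resp.max())
    c0 = float(resp.min())
    half = (c0 + d0) / 2.0
    pos = dose[dose > 0]
    if pos.size:
        e0 = float(dose[np.argmin(np.abs(resp - half))])
        if e0 <= 0:
            e0 = float(np.median(pos))
    else:
        e0 = 1.0
    if model == "EXD3":
        return np.array([c0, d0, e0])
    return np.array([1.0, c0, d0, e0])


def _bounds(model: str) -> Tuple[np.ndarray, np.ndarray]:
    tiny = 1e-12
    if model == "EXD3":
        lo = np.array([-np.inf, -np.inf, tiny])
        hi = np.array([np.inf, np.inf, np.inf])
    else:
        lo = np.array([-np.inf, -np.inf, -np.inf, tiny])
        hi = np.array([np.inf, np.inf, np.inf, np.inf])
    return lo, hi


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC; +1 counts the error variance
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * (k + 1)


def _jacobian(model: str, theta: np.ndarray, dose: np.ndarray) -> np.ndarray:
    if model == "EXD3":
        c, d, e = theta
        g = np.exp(-dose / e)
        return np.column_stack([1.0 - g, g, (d - c) * g * dose / e ** 2])
    b, c, d, e = theta
    out = np.zeros((dose.size, 4))
    pos = dose > 0
    with np.errstate(over="ignore"):
        z = np.exp(b * (np.log(dose[pos]) - math.log(e)))
    p = 1.0 / (1.0 + z)  # f = c + (d - c) * p
    w = (d - c) * p * p * z  # common factor of the b and e partials
    out[pos, 0] = -w * (np.log(dose[pos]) - math.log(e))
    out[pos, 1] = 1.0 - p
    out[pos, 2] = p
    out[pos, 3] = w * b / e
    out[~pos, 1] = 0.0 if b > 0 else 1.0
    out[~pos, 2] = 1.0 if b > 0 else 0.0
    return out


def _fit_once(model: str, dose: np.ndarray, resp: np.ndarray,
              theta0: np.ndarray):
    lo, hi = _bounds(model)
    theta0 = np.clip(theta0, lo + 1e-12, hi)

    def residuals(theta):
        return _predict(model, theta, dose) - resp

    def jac(theta):
        return _jacobian(model, theta, dose)

    try:
        sol = least_squares(residuals, theta0, jac=jac, bounds=(lo, hi),
                            method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                            max_nfev=500)
    except Exception:
        return None
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return None
    return sol


def fit(data: Sequence[DoseResponsePoint], model: str,
        n_restarts: int = 3, seed: int = 0) -> DoseResponseFit:
    """Nonlinear least-squares fit of one model family.

    Starts from data-driven initial values (d = max response, c = min, e =
    dose nearest the half-range, b = 1) plus ``n_restarts`` multiplicative
    +/-20% jitters of them (seeded), keeping the best-RSS converged
    solution.  The convergence flag is set honestly; a fit that never
    converges is returned flagged, with NaN estimates, not silently
    replaced.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    names = _PARAM_NAMES[model]
    k = len(names)
    dose = np.array([p.dose for p in data], dtype=float)
    resp = np.array([p.response for p in data], dtype=float)
    if len(np.unique(dose)) < k + 1:
        raise ValueError(
            f"{model} needs at least {k + 1} distinct doses, got "
            f"{len(np.unique(dose))}")

    base = _initial_guess(model, dose, resp)
    rng = np.random.default_rng(seed)
    starts = [base] + [base * rng.uniform(0.8, 1.2, size=k)
                       for _ in range(n_restarts)]

    best = None
    for theta0 in starts:
        sol = _fit_once(model, dose, resp, theta0)
        if sol is None:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[1]:
            best = (sol, rss)

    n = len(dose)
    if best is None:
        nan = {p: float("nan") for p in names}
        return DoseResponseFit(model=model, estimates=nan,
                               standard_errors=dict(nan), rss=float("nan"),
                               n=n, aic=float("inf"), converged=False,
                               doses=dose, responses=resp)
    sol, rss = best
    estimates = dict(zip(names, map(float, sol.x)))
    dof = max(n - k, 1)
    sigma2 = rss / dof
    try:
        JtJ = sol.jac.T @ sol.jac
        cov = sigma2 * np.linalg.pinv(JtJ)
        ses = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except Exception:
        ses = {p: float("nan") for p in names}
    return DoseResponseFit(model=model, estimates=estimates,
                           standard_errors={p: float(v) for p, v in ses.items()},
                           rss=rss, n=n, aic=_aic(rss, n, k), converged=True,
                           doses=dose, responses=resp)


def select_model(data: Sequence[DoseResponsePoint], seed: int = 0,
                 models: Sequence[str] = MODELS
                 ) -> Tuple[DoseResponseFit, Dict[str, DoseResponseFit]]:
    """Fit every family and return (winner, all fits), ranked by AIC.

    Ties (|dAIC| < 1e-9) go to the model with fewer parameters.
    """
    fits = {m: fit(data, m, seed=seed) for m in models}
    converged = {m: f for m, f in fits.items() if f.converged}
    if not converged:
        raise RuntimeError(
            "no dose-response model converged; diagnostics: "
            + "; ".join(f"{m}: rss={f.rss}" for m, f in fits.items()))
    ranked = sorted(converged.values(), key=lambda f: (f.k, f.aic))
    best = ranked[0]
    for cand in ranked[1:]:
        if cand.aic < best.aic - 1e-9:  # ties keep the smaller model
            best = cand
    return best, fits


@dataclass(frozen=True)
class Ed50Result:
    """ED50 (dose halfway between the fitted asymptotes) with 95% CIs."""

    ed50: float
    ci_low: float
    ci_high: float
    ci_low_delta: float
    ci_high_delta: float
    n_bootstrap: int
    model: str


def ed50_point(fit_result: DoseResponseFit) -> float:
    """Closed-form ED50: LL4 -> e; EXD3 -> e * ln 2 (requires c < d)."""
    if not fit_result.converged:
        raise ValueError("cannot compute ED50 from a non-converged fit")
    p = fit_result.estimates
    if fit_result.model == "LL4":
        return p["e"]
    if p["c"] >= p["d"]:
        raise ValueError(
            f"degenerate EXD3 fit (c={p['c']:.4g} >= d={p['d']:.4g}); "
            "ED50 undefined")
    return p["e"] * math.log(2.0)


def ed50(fit_result: DoseResponseFit, n_bootstrap: int = 999,
         seed: int = 0, level: float = 0.95) -> Ed50Result:
    """ED50 with a percentile bootstrap CI over replicate-resampled data.

    Responses are resampled with replacement within each dose (the plate's
    replicate structure), the model refitted from the original solution,
    and the percentile interval of the resulting ED50s reported.  A
    delta-method interval from the standard error of e is also returned.
    """
    point = ed50_point(fit_result)
    dose, resp = fit_result.doses, fit_result.responses
    names = _PARAM_NAMES[fit_result.model]
    theta_hat = np.array([fit_result.estimates[p] for p in names])

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(dose == u) for u in np.unique(dose)]
    boot: list[float] = []
    for _ in range(n_bootstrap):
        idx = np.concatenate([g[rng.integers(0, len(g), size=len(g))]
                              for g in groups])
        sol = _fit_once(fit_result.model, dose[idx], resp[idx], theta_hat)
        if sol is None:
            continue
        theta = dict(zip(names, sol.x))
        if fit_result.model == "LL4":
            boot.append(theta["e"])
        elif theta["c"] < theta["d"]:
            boot.append(theta["e"] * math.log(2.0))
    alpha = 1.0 - level
    if boot:
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    else:
        lo = hi = float("nan")

    se_e = fit_result.standard_errors.get("e", float("nan"))
    scale = 1.0 if fit_result.model == "LL4" else math.log(2.0)
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    d_lo, d_hi = point - z * scale * se_e, point + z * scale * se_e

    return Ed50Result(ed50=point, ci_low=float(lo), ci_high=float(hi),
                      ci_low_delta=float(d_lo), ci_high_delta=float(d_hi),
                      n_bootstrap=len(boot), model=fit_result.model)
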