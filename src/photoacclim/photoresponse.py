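"""Saturating / photoinhibition light-response model fitting.

The response of growth or photosynthesis rate R to incident irradiance Ii is
modelled with a Platt-type curve in which the inhibition exponent is expressed
directly as an irradiance threshold beta:

    R(Ii) = Rmax * (1 - exp(-Ii / Ik)) * exp(-Ii / beta)

Rmax is the asymptotic rate, Ik the theoretical saturating irradiance, and
beta the irradiance threshold of photoinhibition.  With beta -> infinity the
model reduces to the Webb saturating exponential (no inhibition); with finite
beta the curve has an interior maximum at

    Ii* = Ik * ln(1 + beta / Ik)

The initial slope is alpha = Rmax / Ik.

Fitting minimises the weighted sum of squared residuals (weights 1/sd^2 when
replicate standard deviations are supplied).  Whether the data support finite
beta at all is decided by an extra-sum-of-squares F-test between the nested
saturating (2-parameter) and full (3-parameter) models, so saturating data is
not assigned spurious inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

REGIME_LIMITED = "light-limited"
REGIME_TRANSITIONAL = "transitional"
REGIME_SATURATED = "light-saturated"


def eval_light_response(Ii, Rmax: float, Ik: float, beta: float = math.inf):
    """Evaluate the light-response model at irradiance(s) ``Ii``."""
    Ii = np.asarray(Ii, dtype=float)
    if Rmax <= 0 or Ik <= 0 or beta <= 0:
        raise ValueError("Rmax, Ik and beta must be positive")
    sat = -np.expm1(-Ii / Ik)  # 1 - exp(-Ii/Ik), accurate near 0
    if math.isinf(beta):
        out = Rmax * sat
    else:
        out = Rmax * sat * np.exp(-Ii / beta)
    return out if out.ndim else float(out)


def peak_irradiance(Ik: float, beta: float) -> float:
    """Irradiance at which the model response is maximal.

    Solves dR/dIi = 0 analytically: Ii* = Ik * ln(1 + beta/Ik).  Infinite
    beta (no inhibition) gives an infinite peak (monotone curve).
    """
    if math.isinf(beta):
        return math.inf
    return Ik * math.log1p(beta / Ik)


@dataclass
class LightResponseFit:
    """Fitted light-response parameters with uncertainties and derivatives."""

    Rmax: float
    Ik: float
    beta: float  # inf for the saturating submodel
    se: dict = field(default_factory=dict)  # parameter -> standard error
    sse: float = float("nan")  # weighted sum of squared residuals
    n: int = 0
    model: str = "saturating"  # "full" or "saturating"
    converged: bool = True
    message: str = ""
    weights: np.ndarray | None = None
    f_pvalue: float | None = None  # nested-model F-test (full vs saturating)

    @property
    def alpha(self) -> float:
        """Initial slope of the response curve, Rmax / Ik."""
        return self.Rmax / self.Ik

    @property
    def peak_Ii(self) -> float:
        return peak_irradiance(self.Ik, self.beta)

    def predict(self, Ii):
        return eval_light_response(Ii, self.Rmax, self.Ik, self.beta)

    def peak_Ii_numeric(self, hi_factor: float = 5.0) -> float:
        """Argmax of the fitted curve found numerically (cross-check of the
        closed form)."""
        if math.isinf(self.beta):
            return math.inf
        hi = hi_factor * max(self.Ik, self.beta)
        res = optimize.minimize_scalar(
            lambda x: -self.predict(x), bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-10})
        return float(res.x)


def _wsse(params, Ii, R, w, finite_beta):
    if finite_beta:
        Rmax, Ik, beta = params
    else:
        Rmax, Ik = params
        beta = math.inf
    resid = R - eval_light_response(Ii, Rmax, Ik, beta)
    return float(np.sum(w * resid ** 2))


def _fit_once(Ii, R, w, p0, finite_beta):
    """One local weighted least-squares fit from a given start."""
    sw = np.sqrt(w)

    def resid(p):
        if finite_beta:
            Rmax, Ik, beta = p
        else:
            Rmax, Ik = p
            beta = math.inf
        return sw * (R - eval_light_response(Ii, Rmax, Ik, beta))

    lo = [1e-12] * len(p0)
    hi = [np.inf] * len(p0)
    try:
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:  # pragma: no cover - pathological starts
        return None
    return sol


def _param_se(sol, n_params, n_points):
    """Standard errors from the Gauss-Newton covariance at the optimum."""
    dof = n_points - n_params
    if dof <= 0:
        return [float("nan")] * n_params
    s2 = 2.0 * sol.cost / dof
    J = sol.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return list(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:
        return [float("nan")] * n_params


def fit_light_response(
    Ii,
    R,
    sd=None,
    model: str = "auto",
    alpha: float = 0.05,
    n_starts: int = 5,
    seed: int = 0,
) -> LightResponseFit:
    """Weighted nonlinear least-squares fit of the light-response model.

    Parameters
    ----------
    Ii, R : array-like
        Irradiances (strictly positive, distinct) and measured rates.
    sd : array-like, optional
        Replicate standard deviations; weights are 1/sd^2 when given,
        otherwise uniform.
    model : {"auto", "full", "saturating"}
        "saturating" fixes beta = inf; "full" fits all three parameters;
        "auto" fits both and keeps finite beta only if the nested F-test
        rejects the saturating submodel at level ``alpha``.
    n_starts : int
        Number of multi-start initialisations per model (data-driven
        heuristics plus jittered restarts with a fixed seed).
    """
    Ii = np.asarray(Ii, dtype=float)
    R = np.asarray(R, dtype=float)
    if Ii.ndim != 1 or Ii.shape != R.shape:
        raise ValueError("Ii and R must be 1-D arrays of equal length")
    if np.any(Ii <= 0):
        raise ValueError("irradiances must be strictly positive")
    if len(np.unique(Ii)) < len(Ii):
        raise ValueError("irradiances must be distinct")
    n = len(Ii)
    min_pts = 3 if model == "saturating" else 4
    if n < min_pts:
        raise ValueError(f"need at least {min_pts} points, got {n}")
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        if np.any(sd <= 0):
            raise ValueError("sd values must be positive")
        w = 1.0 / sd ** 2
    else:
        w = np.ones(n)

    rng = np.random.default_rng(seed)
    rmax0 = float(np.max(R))
    if rmax0 <= 0:
        rmax0 = 1.0
    # irradiance nearest half-maximal response as Ik heuristic
    ik0 = float(Ii[np.argmin(np.abs(R - rmax0 / 2.0))])
    if ik0 <= 0:
        ik0 = float(np.median(Ii))
    max_ii = float(np.max(Ii))

    def run_model(finite_beta):
        starts = []
        beta0s = [2.0 * max_ii, 10.0 * max_ii] if finite_beta else [None]
        for b0 in beta0s:
            base = [rmax0, ik0] + ([b0] if finite_beta else [])
            starts.append(base)
        while len(starts) < n_starts:
            jit = rng.uniform(0.5, 2.0, size=len(starts[0]))
            starts.append([p * j for p, j in zip(starts[0], jit)])
        best = None
        for p0 in starts:
            sol = _fit_once(Ii, R, w, p0, finite_beta)
            if sol is None:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    sat = run_model(False)
    if sat is None:
        return LightResponseFit(math.nan, math.nan, math.inf, model="saturating",
                                converged=False, n=n,
                                message="saturating fit failed to converge")
    sat_sse = 2.0 * sat.cost

    if model == "saturating":
        se = _param_se(sat, 2, n)
        return LightResponseFit(float(sat.x[0]), float(sat.x[1]), math.inf,
                                se={"Rmax": se[0], "Ik": se[1]},
                                sse=sat_sse, n=n, model="saturating",
                                converged=sat.success, weights=w)

    full = run_model(True)
    full_sse = 2.0 * full.cost if full is not None else math.inf
    # the saturating model is nested in the full model; numerically the full
    # optimiser may land a hair above the nested optimum
    full_sse = min(full_sse, sat_sse)

    f_p = None
    use_full = model == "full"
    if model == "auto" and full is not None and n > 3:
        if full_sse <= 0 or sat_sse <= full_sse:
            use_full = False
            f_p = 1.0
        else:
            F = (sat_sse - full_sse) / 1.0 / (full_sse / (n - 3))
            f_p = float(stats.f.sf(F, 1, n - 3))
            use_full = f_p < alpha

    if use_full and full is not None:
        se = _param_se(full, 3, n)
        return LightResponseFit(float(full.x[0]), float(full.x[1]),
                                float(full.x[2]),
                                se={"Rmax": se[0], "Ik": se[1], "beta": se[2]},
                                sse=min(2.0 * full.cost, full_sse), n=n,
                                model="full", converged=full.success,
                                weights=w, f_pvalue=f_p)
    se = _param_se(sat, 2, n)
    return LightResponseFit(float(sat.x[0]), float(sat.x[1]), math.inf,
                            se={"Rmax": se[0], "Ik": se[1]},
                            sse=sat_sse, n=n, model="saturating",
                            converged=sat.success, weights=w, f_pvalue=f_p)


def classify_regimes(Ii, fit, delta: float = 0.25):
    """Label irradiances relative to the saturating irradiance Ik.

    ``fit`` may be a :class:`LightResponseFit` or a bare Ik value.  Ii below
    (1-delta)*Ik is light-limited, above (1+delta)*Ik is light-saturated,
    and the band around Ik is transitional.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    Ik = fit.Ik if isinstance(fit, LightResponseFit) else float(fit)
    if Ik <= 0:
        raise ValueError("Ik must be positive")
    Ii = np.asarray(Ii, dtype=float)
    labels = np.where(Ii < (1.0 - delta) * Ik, REGIME_LIMITED,
                      np.where(Ii > (1.0 + delta) * Ik, REGIME_SATURATED,
                               REGIME_TRANSITIONAL))
    if labels.ndim == 0:
        return str(labels)
    return labels.tolist()
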