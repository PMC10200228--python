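"""Two-component univariate Manly mixture models and decision-boundary cutoffs.

A Manly-Gaussian component with location ``mu``, scale ``sigma`` and skew
``lam`` is the distribution of X such that the exponential (Manly)
transform ::

    T_lam(x) = (exp(lam * x) - 1) / lam        (T_0(x) = x)

is Normal(mu, sigma).  Its density on the measurement scale is the Gaussian
density at ``T_lam(x)`` times the Jacobian ``exp(lam * x)``; ``lam = 0``
recovers the plain Gaussian, positive ``lam`` produces positive skew.  Unlike a
log or Box-Cox transform applied to the whole sample, each component carries
its own skew, which is what makes the family useful for biomarker
distributions whose "negative" and "positive" modes are skewed differently.

Fitting is by EM: posterior responsibilities from the weighted component
densities (E-step); closed-form weights and, per component, closed-form
``(mu, sigma)`` on the transformed scale given ``lam``, with ``lam`` itself
updated by bounded one-dimensional maximization of the component's expected
log-likelihood (M-step).  Data are standardized internally (the fitted mixture
is exactly equivariant under affine maps of the data, so the reported
components are back-transformed to the measurement scale).

The positivity cutoff for a biomarker is the decision boundary between the two
fitted components: the point between the component medians where the posterior
probability crosses 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

#: exp() argument clamp; |lam*x| beyond this saturates rather than overflows.
_EXP_CLAMP = 700.0


class DegenerateFitError(RuntimeError):
    """Every EM start collapsed (constant data or vanishing component)."""


class BoundaryError(RuntimeError):
    """No posterior-0.5 crossing between the component medians."""

    def __init__(self, message: str, grid: np.ndarray | None = None, log_odds: np.ndarray | None = None):
        super().__init__(message)
        self.grid = grid
        self.log_odds = log_odds


def manly_transform(x, lam: float):
    """Exponential Manly transform; identity at ``lam = 0``.

    Strictly increasing in ``x`` for any fixed ``lam`` and continuous in
    ``lam`` at 0.  Arguments with ``|lam * x| > 700`` saturate (the exponent is
    clamped) instead of overflowing.
    """
    x = np.asarray(x, dtype=np.float64)
    if lam == 0.0:
        return x.copy()
    return np.expm1(np.clip(lam * x, -_EXP_CLAMP, _EXP_CLAMP)) / lam


def manly_inverse(y, lam: float):
    """Inverse transform ``x = log(1 + lam*y) / lam``; identity at ``lam = 0``.

    Values with ``1 + lam*y <= 0`` (outside the transform's range, reachable
    only through saturation) are clamped to the boundary.
    """
    y = np.asarray(y, dtype=np.float64)
    if lam == 0.0:
        return y.copy()
    return np.log1p(np.maximum(lam * y, np.nextafter(-1.0, 0.0))) / lam


@dataclass
class ManlyComponent:
    """Weight plus (location, scale, skew) of one mixture component.

    ``mu``/``sigma`` live on the transformed scale; ``lam`` is per unit of the
    measurement ``x``.
    """

    weight: float
    mu: float
    sigma: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight < 1.0:
            raise ValueError("component weight must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("component sigma must be positive")

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return norm.logpdf(manly_transform(x, self.lam), self.mu, self.sigma) + self.lam * x

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    @property
    def median(self) -> float:
        """Median on the measurement scale (the transform is monotone)."""
        return float(manly_inverse(self.mu, self.lam))


@dataclass
class EMConfig:
    max_iter: int = 500
    tol: float = 1e-8
    #: bounds for lam on the internally standardized scale; None -> +/- 5/range.
    lambda_bounds: tuple[float, float] | None = None
    n_starts: int = 5
    seed: int = 0


@dataclass
class ManlyMixtureFit:
    """Fitted two-component mixture, components ordered by measurement-scale median."""

    components: tuple[ManlyComponent, ManlyComponent]
    loglik_trace: list[float]
    converged: bool
    n: int
    cutoff: float | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def logpdf(self, x) -> np.ndarray:
        parts = [math.log(c.weight) + c.logpdf(x) for c in self.components]
        return logsumexp(np.stack(parts), axis=0)

    def posterior(self, x) -> np.ndarray:
        """Posterior probability of the lower (first) component."""
        c1, c2 = self.components
        l1 = math.log(c1.weight) + c1.logpdf(x)
        l2 = math.log(c2.weight) + c2.logpdf(x)
        return 1.0 / (1.0 + np.exp(l2 - l1))

    def to_dict(self) -> dict:
        return {
            "components": [
                {"weight": c.weight, "mu": c.mu, "sigma": c.sigma, "lam": c.lam, "median": c.median}
                for c in self.components
            ],
            "loglik": self.loglik,
            "n_iterations": len(self.loglik_trace),
            "converged": self.converged,
            "n": self.n,
            "cutoff": self.cutoff,
        }


class _StartCollapsed(RuntimeError):
    pass


def _mstep_lambda(z, r, R, sum_rz, bounds):
    """Profile the component's expected log-likelihood over lam.

    Given lam, the optimal (mu, sigma) are the responsibility-weighted mean and
    SD of T_lam(z), so the profiled objective reduces to
    ``-R/2 * log(sigma_hat^2(lam)) + lam * sum_i r_i z_i``.
    """

    def neg_profile(lam: float) -> float:
        y = manly_transform(z, lam)
        mu = float(r @ y) / R
        var = float(r @ (y - mu) ** 2) / R
        if var < 1e-12 or not np.isfinite(var):
            return 1e300
        return -(-0.5 * R * math.log(var) + lam * sum_rz)

    lo, hi = bounds
    if hi - lo < 1e-12:
        lam = 0.5 * (lo + hi)
    else:
        res = minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7})
        lam = float(res.x)
        # the bracket endpoints are legal solutions; keep whichever is best
        for cand in (lo, hi, 0.0):
            if lo <= cand <= hi and neg_profile(cand) < neg_profile(lam):
                lam = cand
    y = manly_transform(z, lam)
    mu = float(r @ y) / R
    var = float(r @ (y - mu) ** 2) / R
    if var < 1e-10:
        raise _StartCollapsed("component variance collapsed")
    return lam, mu, math.sqrt(var)


def _run_em(z, init_q: float, config: EMConfig, bounds) -> tuple[list[dict], list[float], bool]:
    n = z.size
    order = np.argsort(z)
    split = int(round(init_q * n))
    split = min(max(split, 2), n - 2)
    lower, upper = z[order[:split]], z[order[split:]]
    comps = []
    for part, w in ((lower, split / n), (upper, 1 - split / n)):
        sd = float(part.std())
        if sd < 1e-8:
            sd = float(z.std()) / 10 + 1e-8
        comps.append({"w": w, "mu": float(part.mean()), "sigma": sd, "lam": 0.0})

    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        logp = np.stack(
            [
                math.log(c["w"]) + norm.logpdf(manly_transform(z, c["lam"]), c["mu"], c["sigma"]) + c["lam"] * z
                for c in comps
            ]
        )
        tot = logsumexp(logp, axis=0)
        ll = float(tot.sum())
        if not np.isfinite(ll):
            raise _StartCollapsed("non-finite log-likelihood")
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
        resp = np.exp(logp - tot)
        for k, c in enumerate(comps):
            r = resp[k]
            R = float(r.sum())
            if R < 2.0:
                raise _StartCollapsed("component responsibility mass below 2 effective points")
            lam, mu, sigma = _mstep_lambda(z, r, R, float(r @ z), bounds)
            c.update(w=R / n, lam=lam, mu=mu, sigma=sigma)
    return comps, trace, converged


def _back_transform(comp: dict, m: float, s: float) -> ManlyComponent:
    """Map a component fitted on z = (x - m)/s back to the measurement scale.

    T_lam(z) is an affine function of T_{lam/s}(x), and the Gaussian family
    absorbs affine maps, so the standardized-scale fit is exactly a Manly
    component in x with lam_x = lam/s.
    """
    lam, mu, sigma = comp["lam"], comp["mu"], comp["sigma"]
    if lam == 0.0:
        return ManlyComponent(weight=comp["w"], mu=mu * s + m, sigma=sigma * s, lam=0.0)
    lam_x = lam / s
    a = math.exp(-lam_x * m) / s
    b = math.expm1(-lam_x * m) / lam
    return ManlyComponent(weight=comp["w"], mu=(mu - b) / a, sigma=sigma / a, lam=lam_x)


def fit_em(data, config: EMConfig | None = None) -> ManlyMixtureFit:
    """Fit a two-component Manly mixture by EM with multiple seeded starts.

    Starts are quantile-split initializations (lower/upper fractions of the
    sorted sample as the two components, lam = 0); the best final
    log-likelihood wins.  Raises :class:`DegenerateFitError` if every start
    collapses (e.g. constant data).
    """
    config = config or EMConfig()
    x = np.asarray(data, dtype=np.float64).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contain non-finite values")
    m = float(x.mean())
    s = float(x.std())
    if s < 1e-12:
        raise DegenerateFitError("data are (numerically) constant")
    z = (x - m) / s

    if config.lambda_bounds is None:
        span = float(z.max() - z.min())
        bounds = (-5.0 / span, 5.0 / span)
    else:
        bounds = tuple(config.lambda_bounds)

    base_qs = [0.5, 0.35, 0.65, 0.25, 0.75]
    rng = np.random.default_rng(config.seed)
    qs = base_qs[: config.n_starts]
    while len(qs) < config.n_starts:
        qs.append(float(rng.uniform(0.2, 0.8)))

    best = None
    failures: list[str] = []
    for q in qs:
        try:
            comps, trace, converged = _run_em(z, q, config, bounds)
        except _StartCollapsed as exc:
            failures.append(f"start q={q:.2f}: {exc}")
            continue
        if best is None or trace[-1] > best[1][-1]:
            best = (comps, trace, converged)
    if best is None:
        raise DegenerateFitError("all EM starts degenerate: " + "; ".join(failures))

    comps, trace, converged = best
    measured = sorted((_back_transform(c, m, s) for c in comps), key=lambda c: c.median)
    fit = ManlyMixtureFit(components=tuple(measured), loglik_trace=trace, converged=converged, n=x.size)
    try:
        fit.cutoff = decision_boundary(fit)
    except BoundaryError:
        fit.cutoff = None
    return fit


def decision_boundary(fit: ManlyMixtureFit, bracket: tuple[float, float] | None = None) -> float:
    """Measurement value where the component posterior crosses 1/2.

    Scans a dense grid on ``bracket`` (default: the interval between the two
    component medians) for the first rightward crossing where the posterior of
    the lower component drops through 0.5, then polishes the root of the
    weighted log-density difference by Brent's method.
    """
    c1, c2 = fit.components
    if bracket is None:
        bracket = (c1.median, c2.median)
    lo, hi = bracket
    if not hi > lo:
        raise BoundaryError(f"empty bracket [{lo}, {hi}] between component medians")

    def log_odds(xv):
        return (math.log(c1.weight) + c1.logpdf(xv)) - (math.log(c2.weight) + c2.logpdf(xv))

    grid = np.linspace(lo, hi, 2001)
    vals = np.asarray(log_odds(grid))
    cross = np.nonzero((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    if cross.size == 0:
        raise BoundaryError("no posterior-0.5 crossing inside the bracket", grid=grid, log_odds=vals)
    i = int(cross[0])
    if vals[i + 1] == 0.0:
        return float(grid[i + 1])
    return float(brentq(lambda t: float(log_odds(t)), grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16))


def fit_biomarker(cohort: pd.DataFrame, biomarker: str, config: EMConfig | None = None) -> ManlyMixtureFit:
    """Fit one biomarker column of a cohort table (complete cases only)."""
    if biomarker not in cohort.columns:
        raise KeyError(f"biomarker column {biomarker!r} missing from cohort table")
    values = cohort[biomarker].dropna().to_numpy(dtype=float)
    if values.size < 50:
        raise ValueError(f"biomarker {biomarker!r} has only {values.size} non-missing values (need >= 50)")
    try:
        fit = fit_em(values, config)
    except (DegenerateFitError, ValueError) as exc:
        raise DegenerateFitError(f"fit failed for biomarker {biomarker!r}: {exc}") from exc
    if fit.cutoff is None:
        raise BoundaryError(f"no decision boundary found for biomarker {biomarker!r}")
    return fit


def derive_cutoffs(cohort: pd.DataFrame, biomarkers: list[str] | None = None, config: EMConfig | None = None):
    """Mixture-model cutoffs for the cohort's biomarker columns.

    Returns a :class:`tauread.suvr.CutoffConfig` whose requested biomarkers are
    replaced by the fitted decision boundaries (others keep the published
    defaults).  Directions are fixed by biology: the CSF Abeta42/Abeta40 ratio
    is positive *below* its cutoff, all other markers above.
    """
    from .suvr import CutoffConfig  # local import to keep module layering acyclic

    if biomarkers is None:
        biomarkers = ["suvr", "centiloid", "ptau181", "abeta42_40_ratio"]
    field_of = {
        "suvr": "suvr_cutoff",
        "centiloid": "centiloid_cutoff",
        "ptau181": "ptau_cutoff",
        "abeta42_40_ratio": "abeta_ratio_cutoff",
    }
    unknown = [b for b in biomarkers if b not in field_of]
    if unknown:
        raise KeyError(f"unknown biomarkers {unknown}; expected a subset of {sorted(field_of)}")
    values = {}
    for name in biomarkers:
        values[field_of[name]] = float(fit_biomarker(cohort, name, config).cutoff)
    return CutoffConfig(**values)
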