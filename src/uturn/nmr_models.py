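"""Fits for two NMR observables of H-bonded RNA motifs.

1. Trans-hydrogen-bond scalar coupling from a constant-time experiment:
   the cross/reference intensity ratio decays as

       I_cross / I_ref = cos(pi * J * tau_m)

   with a single global coupling J (Hz) shared across replicates.
   Initialization is a grid search over J in [0, 20] Hz (step 0.05 Hz,
   well beyond the few-Hz couplings transmitted across N-H...O-P
   bridges), refined by local least squares; when several J values fit
   equally (sparse delay sets sample the cosine ambiguously) the
   smallest is kept.

2. Chemical-shift titration isotherms, assuming free ligand ~ total
   (mM-scale titrant vs uM-scale RNA, so depletion is negligible):

       single-site:   ddelta(c) = ddelta_max * c / (K_D + c)
       cooperative2:  ddelta(c) = ddelta_max * c^2 / (K_D^2 + c^2)

   The cooperative two-ion model is a Hill form with coefficient fixed
   at 2. Uncertainties come from a seeded residual bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from uturn.model_io import CTIntensitySeries, TitrationSeries

__all__ = ["JCouplingFit", "IsothermFit", "ModelComparison",
           "fit_ct_jcoupling", "fit_binding_isotherm", "compare_models"]

_J_GRID_MAX = 20.0
_J_GRID_STEP = 0.05


@dataclass
class JCouplingFit:
    j: float                      # Hz
    rss: float
    per_replicate_rss: dict[str, float]
    grid_start: float
    converged: bool
    j_se: float | None = None     # bootstrap standard error, Hz
    n_points: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.j < 0:
            raise ValueError("J must be nonnegative")


def _ct_model(j: float, tau: np.ndarray) -> np.ndarray:
    return np.cos(np.pi * j * tau)


def fit_ct_jcoupling(series: list[CTIntensitySeries] | CTIntensitySeries,
                     bootstrap: int = 200, seed: int = 0) -> JCouplingFit:
    """Globally fit one J to pooled constant-time intensity ratios.

    All replicate points are pooled with equal weight per point (so a
    replicate contributes in proportion to its number of delays).
    """
    if isinstance(series, CTIntensitySeries):
        series = [series]
    if not series:
        raise ValueError("no series given")
    tau = np.concatenate([np.asarray(s.tau_m) for s in series])
    ratio = np.concatenate([np.asarray(s.ratio) for s in series])
    if len(np.unique(tau)) < 3:
        raise ValueError("need at least 3 distinct constant-time delays")
    if np.allclose(ratio, 1.0, atol=1e-12):
        warnings.warn("all intensity ratios are 1.0; coupling is "
                      "indistinguishable from zero", stacklevel=2)
        return JCouplingFit(0.0, 0.0,
                            {s.replicate: 0.0 for s in series},
                            0.0, True, 0.0, len(tau), seed)

    grid = np.arange(0.0, _J_GRID_MAX + _J_GRID_STEP, _J_GRID_STEP)
    sse = ((np.cos(np.pi * np.outer(grid, tau)) - ratio) ** 2).sum(axis=1)
    j0 = float(grid[int(np.argmin(sse))])

    def resid(p):
        return _ct_model(p[0], tau) - ratio

    sol = optimize.least_squares(resid, x0=[j0], bounds=([0.0], [np.inf]))
    j_hat = float(sol.x[0])
    rss = float((sol.fun ** 2).sum())
    per_rep = {}
    for s in series:
        t = np.asarray(s.tau_m)
        r = np.asarray(s.ratio)
        per_rep[s.replicate] = float(((_ct_model(j_hat, t) - r) ** 2).sum())
    j_se = None
    if bootstrap and len(tau) > 1:
        rng = np.random.default_rng(seed)
        fitted = _ct_model(j_hat, tau)
        res = ratio - fitted
        draws = np.empty(bootstrap)
        for b in range(bootstrap):
            boot = fitted + rng.choice(res, size=len(res), replace=True)
            sse_b = ((np.cos(np.pi * np.outer(grid, tau)) - boot) ** 2).sum(axis=1)
            jb0 = float(grid[int(np.argmin(sse_b))])
            solb = optimize.least_squares(
                lambda p: _ct_model(p[0], tau) - boot,
                x0=[jb0], bounds=([0.0], [np.inf]))
            draws[b] = solb.x[0]
        j_se = float(draws.std(ddof=1))
    return JCouplingFit(j_hat, rss, per_rep, j0, bool(sol.success), j_se,
                        len(tau), seed)


@dataclass
class IsothermFit:
    model: str                 # 'single-site' or 'cooperative2'
    kd: float                  # mM (same unit as the input concentrations)
    ddelta_max: float          # ppm
    rss: float
    residuals: np.ndarray
    converged: bool
    kd_ci: tuple[float, float] | None = None   # bootstrap 95% interval
    seed: int | None = None

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("K_D must be positive")

    def predict(self, c) -> np.ndarray:
        return _isotherm(self.model)(np.asarray(c, dtype=float),
                                     self.kd, self.ddelta_max)


def _isotherm(model: str):
    if model == "single-site":
        return lambda c, kd, dmax: dmax * c / (kd + c)
    if model == "cooperative2":
        return lambda c, kd, dmax: dmax * c ** 2 / (kd ** 2 + c ** 2)
    raise ValueError(f"unknown isotherm model {model!r}")


def fit_binding_isotherm(series: TitrationSeries, model: str | None = None,
                         bootstrap: int = 200, seed: int = 0) -> IsothermFit:
    """Nonlinear least-squares fit of a binding isotherm.

    K_D is initialized at the concentration whose observed shift is
    nearest half of the maximum observed shift; ddelta_max at the
    largest-magnitude observed shift. K_D is bounded positive.
    """
    model = model or series.model
    fn = _isotherm(model)
    c = np.asarray(series.concentrations, dtype=float)
    d = np.asarray(series.delta_shift, dtype=float)
    if len(c) > 2:
        rho = stats.spearmanr(c, d).statistic
        if np.isfinite(rho) and rho < 0:
            raise ValueError(
                "shift changes decrease with concentration; negate the "
                "shifts (the models fit a common sign)")
    dmax0 = d[np.argmax(np.abs(d))]
    kd0 = _half_sat_guess(c, d)
    if not (c[c > 0].min() <= kd0 <= c.max()):
        warnings.warn("titration points may not span the half-saturation "
                      "region; the fitted K_D is poorly constrained",
                      stacklevel=2)

    def resid(p):
        return fn(c, p[0], p[1]) - d

    sol = optimize.least_squares(resid, x0=[kd0, dmax0],
                                 bounds=([1e-12, -np.inf], [np.inf, np.inf]))
    kd, dmax = map(float, sol.x)
    residuals = fn(c, kd, dmax) - d
    rss = float((residuals ** 2).sum())
    kd_ci = None
    if bootstrap:
        rng = np.random.default_rng(seed)
        fitted = fn(c, kd, dmax)
        res = d - fitted
        draws = []
        for _ in range(bootstrap):
            boot = fitted + rng.choice(res, size=len(res), replace=True)
            try:
                solb = optimize.least_squares(
                    lambda p: fn(c, p[0], p[1]) - boot, x0=[kd, dmax],
                    bounds=([1e-12, -np.inf], [np.inf, np.inf]))
                draws.append(float(solb.x[0]))
            except Exception:
                continue
        if len(draws) >= 20:
            kd_ci = (float(np.percentile(draws, 2.5)),
                     float(np.percentile(draws, 97.5)))
    return IsothermFit(model, kd, dmax, rss, residuals, bool(sol.success),
                       kd_ci, seed)


def _half_sat_guess(c: np.ndarray, d: np.ndarray) -> float:
    target = 0.5 * d[np.argmax(np.abs(d))]
    i = int(np.argmin(np.abs(d - target)))
    guess = c[i]
    if guess <= 0:
        positive = c[c > 0]
        guess = positive.min() if len(positive) else 1.0
    return float(guess)


@dataclass
class ModelComparison:
    single_site: IsothermFit
    cooperative2: IsothermFit
    f_ratio: float      # mean-square ratio, single-site vs cooperative2
    n_points: int

    def table(self) -> list[dict]:
        rows = []
        for fit in (self.single_site, self.cooperative2):
            rows.append({"model": fit.model, "kd": fit.kd,
                         "ddelta_max": fit.ddelta_max, "rss": fit.rss})
        return rows


def compare_models(series: TitrationSeries, bootstrap: int = 0,
                   seed: int = 0) -> ModelComparison:
    """Fit both isotherm models and report residual sums and an F-ratio.

    Both models have two parameters, so the extra-sum-of-squares test
    degenerates; the reported statistic is the ratio of residual mean
    squares (single-site over cooperative2). No automatic verdict is
    rendered — the statistic is reported for the analyst.
    """
    fit1 = fit_binding_isotherm(series, "single-site", bootstrap, seed)
    fit2 = fit_binding_isotherm(series, "cooperative2", bootstrap, seed)
    n = len(series.concentrations)
    df = n - 2
    if df <= 0:
        raise ValueError("insufficient points to compare two 2-parameter models")
    ms1 = fit1.rss / df
    ms2 = fit2.rss / df
    f = float(ms1 / ms2) if ms2 > 0 else float("inf")
    return ModelComparison(fit1, fit2, f, n)
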