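"""Nonlinear least-squares fitting of footprint-titration isotherms.

Fits a single shared equilibrium constant (K_app for the Langmuir model,
K_tot for the two-monomer assembly model) globally across replicate
isotherms, reports the fit standard deviation sqrt(SSR / (N - p)), and
estimates confidence intervals by case-resampling bootstrap.

Objective is unweighted least squares on fractional saturation (no weighting
scheme is assumed).  The one free parameter is optimized on a log10 scale:
the sum of squared residuals is first scanned on a dense log-spaced grid
(8 starts per decade spanning one decade beyond the data range), then the
best grid starts are refined with a derivative-based local optimizer.  This
multi-start strategy makes the global search deterministic and immune to the
local minima a single bad start can produce on sigmoidal data.

Observations with saturation outside [-0.2, 1.2] are rejected as outliers
with a logged warning before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .binding_core import ybar_dimer, ybar_langmuir
from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "Isotherm",
    "BindingFit",
    "fit_binding_model",
    "fit_sd",
    "bootstrap_ci",
    "read_isotherms_csv",
    "write_isotherms_csv",
]

logger = logging.getLogger(__name__)

ModelName = Literal["langmuir", "dimer"]

#: Saturation values outside this window are discarded as outliers.
YBAR_VALID_RANGE = (-0.2, 1.2)

#: Multi-start density for the log-grid scan of the equilibrium constant.
STARTS_PER_DECADE = 8


@dataclass
class Isotherm:
    """One replicate binding isotherm: free monomer concentration vs saturation.

    ``x`` is strictly positive and strictly increasing within a replicate;
    ``ybar`` is finite but may fall slightly outside [0, 1] due to noise.
    """

    x: np.ndarray
    ybar: np.ndarray
    replicate_id: str = "rep1"
    hre: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.ybar = np.asarray(self.ybar, dtype=float)
        if self.x.shape != self.ybar.shape:
            raise InvalidParameterError("x and ybar must have equal length")
        if np.any(self.x <= 0):
            raise InvalidParameterError("concentrations must be strictly positive")
        if np.any(np.diff(self.x) <= 0):
            raise InvalidParameterError(
                "concentrations must be strictly increasing within a replicate"
            )
        if np.any(~np.isfinite(self.ybar)):
            raise InvalidParameterError("ybar must be finite")


@dataclass
class BindingFit:
    """Result of a global single-constant fit.

    ``estimate`` is K_app (molar) for the Langmuir model or K_tot (molar^2)
    for the dimer model.  ``fit_sd`` is sqrt(SSR / (N - p)).  The confidence
    interval is empty (NaN) until :func:`bootstrap_ci` fills it.
    """

    model: ModelName
    estimate: float
    fit_sd: float
    n_points: int
    converged: bool
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)


_MODEL_FUNCS = {"langmuir": ybar_langmuir, "dimer": ybar_dimer}
_N_PARAMS = 1


def fit_sd(residuals: Sequence[float], n_params: int) -> float:
    """Fit standard deviation sqrt(SSR / (N - n_params)).

    Raises
    ------
    InsufficientDataError
        If there are no residual degrees of freedom (N <= n_params).
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n <= n_params:
        raise InsufficientDataError(
            f"need more residuals ({n}) than parameters ({n_params})"
        )
    return float(np.sqrt(np.sum(residuals**2) / (n - n_params)))


def _pool_points(isotherms: Sequence[Isotherm]) -> tuple[np.ndarray, np.ndarray]:
    """Pool points across replicates, dropping outlier saturations."""
    x = np.concatenate([iso.x for iso in isotherms])
    y = np.concatenate([iso.ybar for iso in isotherms])
    lo, hi = YBAR_VALID_RANGE
    keep = (y >= lo) & (y <= hi)
    if not np.all(keep):
        logger.warning(
            "rejecting %d point(s) with ybar outside [%g, %g]",
            int(np.sum(~keep)), lo, hi,
        )
    return x[keep], y[keep]


def _ssr(log10_k: float, x: np.ndarray, y: np.ndarray, model: ModelName) -> float:
    pred = _MODEL_FUNCS[model](x, 10.0**log10_k)
    return float(np.sum((y - pred) ** 2))


def _fit_constant(x: np.ndarray, y: np.ndarray, model: ModelName) -> float:
    """Globally minimize SSR over the equilibrium constant (log10 scale)."""
    # Grid spans one decade beyond the data range; for the dimer model the
    # constant lives on the squared-concentration scale.
    lo, hi = np.log10(x.min() / 10.0), np.log10(x.max() * 10.0)
    if model == "dimer":
        lo, hi = 2 * lo, 2 * hi
    n_starts = max(int(np.ceil((hi - lo) * STARTS_PER_DECADE)) + 1, 4)
    grid = np.linspace(lo, hi, n_starts)
    ssr_grid = np.array([_ssr(g, x, y, model) for g in grid])
    best = np.argsort(ssr_grid)[:3]
    step = grid[1] - grid[0]
    candidates = []
    for i in best:
        # refine in a window of a few grid steps around each candidate start
        res = optimize.minimize_scalar(
            _ssr,
            bounds=(grid[i] - 4 * step, grid[i] + 4 * step),
            args=(x, y, model),
            method="bounded",
            options={"xatol": 1e-12},
        )
        candidates.append((res.fun, res.x))
    return 10.0 ** min(candidates)[1]


def fit_binding_model(
    isotherms: Sequence[Isotherm], model: ModelName = "dimer"
) -> BindingFit:
    """Fit one shared equilibrium constant globally across replicates.

    Parameters
    ----------
    isotherms
        Replicate isotherms; points are pooled and fit with a single
        constant (the global-fit convention for replicate titrations).
    model
        ``"langmuir"`` (fits K_app) or ``"dimer"`` (fits K_tot).

    Returns
    -------
    BindingFit
        Estimate, fit SD and convergence flag.  Flat (non-identifiable)
        data yields ``converged=False`` with a warning.

    Raises
    ------
    InsufficientDataError
        With fewer points than parameters + 2.
    """
    if model not in _MODEL_FUNCS:
        raise InvalidParameterError(f"unknown model {model!r}")
    x, y = _pool_points(isotherms)
    if x.size < _N_PARAMS + 2:
        raise InsufficientDataError(
            f"need at least {_N_PARAMS + 2} points, got {x.size}"
        )
    converged = True
    if np.ptp(y) < 1e-3:
        warnings.warn(
            "saturation data are flat; equilibrium constant is not identifiable",
            stacklevel=2,
        )
        converged = False
    estimate = _fit_constant(x, y, model)
    residuals = y - _MODEL_FUNCS[model](x, estimate)
    return BindingFit(
        model=model,
        estimate=estimate,
        fit_sd=fit_sd(residuals, _N_PARAMS),
        n_points=int(x.size),
        converged=converged,
    )


def bootstrap_ci(
    isotherms: Sequence[Isotherm],
    model: ModelName = "dimer",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile confidence interval by case-resampling bootstrap.

    Pooled points are resampled with replacement ``n_boot`` times and the
    constant refit on each resample; the interval is the percentile range of
    the resampled estimates.  Deterministic under a fixed ``seed``.
    """
    if not 0 < level < 1:
        raise InvalidParameterError("level must be in (0, 1)")
    if n_boot < 50:
        warnings.warn("n_boot < 50 gives unstable percentile intervals", stacklevel=2)
    x, y = _pool_points(isotherms)
    if x.size < _N_PARAMS + 2:
        raise InsufficientDataError("too few points to bootstrap")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        xb, yb = x[idx], y[idx]
        order = np.argsort(xb)
        estimates[b] = _fit_constant(xb[order], yb[order], model)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# CSV I/O: columns hre, replicate, conc_molar, ybar


def read_isotherms_csv(path) -> list[Isotherm]:
    """Read isotherms from CSV with columns hre, replicate, conc_molar, ybar."""
    df = pd.read_csv(path, comment="#")
    required = {"hre", "replicate", "conc_molar", "ybar"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"isotherm CSV missing columns: {sorted(missing)}")
    out = []
    for (hre, rep), grp in df.groupby(["hre", "replicate"], sort=False):
        grp = grp.sort_values("conc_molar")
        out.append(
            Isotherm(
                x=grp["conc_molar"].to_numpy(),
                ybar=grp["ybar"].to_numpy(),
                replicate_id=str(rep),
                hre=str(hre),
            )
        )
    return out


def write_isotherms_csv(isotherms: Sequence[Isotherm], path) -> None:
    """Write isotherms in the dialect :func:`read_isotherms_csv` reads."""
    frames = [
        pd.DataFrame(
            {
                "hre": iso.hre,
                "replicate": iso.replicate_id,
                "conc_molar": iso.x,
                "ybar": iso.ybar,
            }
        )
        for iso in isotherms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
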