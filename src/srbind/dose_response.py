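"""Global thermodynamic model of fold-activation dose-response curves.

Maps in-vitro palindrome assembly affinities (K_tot) onto cellular
fold-activation measured against expression-vector dose D (in ng), through
three scaling factors shared by every response element:

    FA(D) = e + d * Ybar_dimer(f * D; K_tot)

* ``f`` (molar per ng) converts vector dose to free receptor monomer
  concentration — receptor level is taken proportional to dose;
* ``e`` (unitless) is the baseline fold-activation at zero dose;
* ``d`` (unitless) is the amplitude, so the plateau is e + d.

Under an alternate reading where the "maximal" parameter is the plateau
itself, map d_here = d_max - e.

Each curve's K_tot is a *fixed* input (measured independently by footprint
titration); only (d, e, f) float, jointly across all curves, by unweighted
pooled least squares.  Per-point SEM weighting is available behind a flag
but off by default.  Because d, e and f are global, all binding curves are
rescaled identically — the model's explanatory power comes entirely from
the per-HRE affinities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .binding_core import HRERecord, ybar_dimer
from .errors import ConfigurationError, InsufficientDataError, InvalidParameterError

__all__ = [
    "DoseResponseCurve",
    "ScalingParameters",
    "ScalingFit",
    "predict_fold_activation",
    "fit_scaling_global",
    "predict_new_hre",
    "read_curves_csv",
    "write_curves_csv",
]


@dataclass
class DoseResponseCurve:
    """Fold-activation vs expression-vector dose for one HRE.

    Doses are in ng, non-negative and strictly increasing; ``sem`` and
    ``n_rep`` describe the replicate structure of each point (0 / 1 when
    unknown, e.g. for noise-free simulated curves).
    """

    hre: str
    dose_ng: np.ndarray
    fa: np.ndarray
    sem: np.ndarray | None = None
    n_rep: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dose_ng = np.asarray(self.dose_ng, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.sem is None:
            self.sem = np.zeros_like(self.dose_ng)
        else:
            self.sem = np.asarray(self.sem, dtype=float)
        if self.n_rep is None:
            self.n_rep = np.ones_like(self.dose_ng, dtype=int)
        else:
            self.n_rep = np.asarray(self.n_rep, dtype=int)
        if self.dose_ng.size and (
            np.any(self.dose_ng < 0) or np.any(np.diff(self.dose_ng) <= 0)
        ):
            raise InvalidParameterError(
                "doses must be non-negative and strictly increasing"
            )
        if np.any(~np.isfinite(self.fa)):
            raise InvalidParameterError("fold-activation must be finite")


@dataclass(frozen=True)
class ScalingParameters:
    """Global scaling factors (d, e, f) of the dose-response model.

    d: amplitude (unitless, >= 0); e: baseline (unitless, > 0);
    f: molar of receptor per ng of vector (> 0).
    """

    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and self.d >= 0):
            raise InvalidParameterError(f"d must be >= 0, got {self.d!r}")
        if not (np.isfinite(self.e) and self.e > 0):
            raise InvalidParameterError(f"e must be > 0, got {self.e!r}")
        if not (np.isfinite(self.f) and self.f > 0):
            raise InvalidParameterError(f"f must be > 0, got {self.f!r}")


@dataclass
class ScalingFit:
    """Result of the global (d, e, f) fit."""

    params: ScalingParameters
    per_curve_sd: dict[str, float]
    fit_sd: float
    n_points: int
    converged: bool

    def to_json(self, path) -> None:
        payload = {
            "d": self.params.d,
            "e": self.params.e,
            "f_molar_per_ng": self.params.f,
            "per_curve_sd": self.per_curve_sd,
            "fit_sd": self.fit_sd,
            "n_points": self.n_points,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def predict_fold_activation(dose, k_tot: float, s: ScalingParameters):
    """Model fold-activation FA(D) = e + d * Ybar_dimer(f*D, k_tot).

    Monotone non-decreasing in dose, from the baseline e at D=0 toward the
    plateau e + d.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0) or np.any(~np.isfinite(dose)):
        raise InvalidParameterError("dose must be finite and >= 0")
    out = s.e + s.d * ybar_dimer(dose * s.f, k_tot)
    return float(out) if np.ndim(out) == 0 else out


def _ktot_map(hres: Sequence[HRERecord] | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(hres, Mapping):
        return hres
    return {h.name: h.k_tot for h in hres}


def fit_scaling_global(
    curves: Sequence[DoseResponseCurve],
    hres: Sequence[HRERecord] | Mapping[str, float],
    weighted: bool = False,
    f_grid: np.ndarray | None = None,
) -> ScalingFit:
    """Fit shared (d, e, f) to all curves with per-HRE K_tot held fixed.

    Parameters
    ----------
    curves
        Experimental or simulated dose-response curves (>= 2 for a
        well-posed joint fit; one curve is accepted but f is then weakly
        constrained).
    hres
        HRE records (or a name -> K_tot mapping) supplying the fixed
        affinities; every curve's HRE must be present.
    weighted
        If True, residuals are divided by per-point SEM (points with
        SEM = 0 get unit weight).  Default off.
    f_grid
        Optional explicit multi-start grid for f (molar/ng).  Default:
        log-spaced 1e-12 to 1e-6 molar/ng, 2 starts per decade.

    Returns
    -------
    ScalingFit
        Best pooled-least-squares parameters, per-curve residual SDs and a
        convergence flag (False when the data cannot identify f, e.g. a
        single flat curve).
    """
    ktots = _ktot_map(hres)
    missing = [c.hre for c in curves if c.hre not in ktots]
    if missing:
        raise ConfigurationError(f"no K_tot for curve HRE(s): {sorted(set(missing))}")
    doses = np.concatenate([c.dose_ng for c in curves])
    fa = np.concatenate([c.fa for c in curves])
    kt = np.concatenate([np.full(c.dose_ng.size, ktots[c.hre]) for c in curves])
    if fa.size < 5:
        raise InsufficientDataError("need at least 5 points to fit (d, e, f)")
    wts = np.ones_like(fa)
    if weighted:
        sem = np.concatenate([c.sem for c in curves])
        wts = np.where(sem > 0, 1.0 / np.where(sem > 0, sem, 1.0), 1.0)

    converged = True
    if np.ptp(fa) < 1e-3 * max(np.abs(fa).max(), 1.0):
        warnings.warn(
            "fold-activation data are flat; f is not identifiable", stacklevel=2
        )
        converged = False

    def residuals(theta):
        d, e, log10_f = theta
        pred = e + d * (doses * 10.0**log10_f) ** 2 / (
            kt + (doses * 10.0**log10_f) ** 2
        )
        return (fa - pred) * wts

    if f_grid is None:
        f_grid = np.logspace(-12, -6, 13)
    d0 = max(float(np.ptp(fa)), 1e-6)
    e0 = max(float(fa.min()), 1e-6)
    best = None
    for f0 in f_grid:
        res = optimize.least_squares(
            residuals,
            x0=[d0, e0, np.log10(f0)],
            bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    d, e, log10_f = best.x
    params = ScalingParameters(d=float(d), e=float(e), f=float(10.0**log10_f))
    per_curve_sd = {}
    ssr = 0.0
    for c in curves:
        r = c.fa - predict_fold_activation(c.dose_ng, ktots[c.hre], params)
        per_curve_sd[c.hre] = float(np.sqrt(np.mean(r**2)))
        ssr += float(np.sum(r**2))
    dof = max(fa.size - 3, 1)
    return ScalingFit(
        params=params,
        per_curve_sd=per_curve_sd,
        fit_sd=float(np.sqrt(ssr / dof)),
        n_points=int(fa.size),
        converged=converged and best.success,
    )


def predict_new_hre(
    k_tot: float,
    s: ScalingParameters,
    doses: Sequence[float],
    name: str = "predicted",
) -> DoseResponseCurve:
    """Pure prediction of a dose-response curve for a new HRE.

    Evaluates the fitted model at the given doses with no refitting; the
    half-maximal dose sits at f*D = sqrt(k_tot), so a 100x weaker K_tot
    shifts the curve 10x to the right.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        return DoseResponseCurve(hre=name, dose_ng=doses, fa=np.array([]))
    return DoseResponseCurve(
        hre=name, dose_ng=doses, fa=predict_fold_activation(doses, k_tot, s)
    )


# ---------------------------------------------------------------------------
# CSV I/O: columns hre, dose_ng, fold_activation, sem, n_rep


def read_curves_csv(path) -> list[DoseResponseCurve]:
    """Read dose-response curves from CSV (hre, dose_ng, fold_activation, sem, n_rep)."""
    df = pd.read_csv(path, comment="#")
    required = {"hre", "dose_ng", "fold_activation"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"curve CSV missing columns: {sorted(missing)}")
    out = []
    for hre, grp in df.groupby("hre", sort=False):
        grp = grp.sort_values("dose_ng")
        out.append(
            DoseResponseCurve(
                hre=str(hre),
                dose_ng=grp["dose_ng"].to_numpy(),
                fa=grp["fold_activation"].to_numpy(),
                sem=grp["sem"].to_numpy() if "sem" in grp else None,
                n_rep=grp["n_rep"].to_numpy() if "n_rep" in grp else None,
            )
        )
    return out


def write_curves_csv(curves: Sequence[DoseResponseCurve], path) -> None:
    """Write curves in the dialect :func:`read_curves_csv` reads."""
    frames = [
        pd.DataFrame(
            {
                "hre": c.hre,
                "dose_ng": c.dose_ng,
                "fold_activation": c.fa,
                "sem": c.sem,
                "n_rep": c.n_rep,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
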