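"""Synthetic-data generators with the statistical structure of the assays.

Three generators cover the pipeline's inputs:

* :func:`make_isotherm` — replicate footprint-titration isotherms from the
  two-monomer assembly model with additive Gaussian noise (default SD
  0.087, the residual scatter of the reference global fit);
* :func:`simulate_dose_response_family` — noise-free dose-response curves
  under the "maximal f_max-fold activation" model,
  FA(D) = 1 + (f_max - 1) * Ybar_dimer(f*D, K_tot), default f_max = 5;
* :func:`error_perturb` — replicated noisy versions of curves, with
  additive, relative, or per-HRE noise calibrated to the reference panel's
  SEMs (relative SD = sqrt(n) * SEM / FA with n = 3).

All generators are deterministic under a fixed seed.  Synthetic saturation
values are clipped to [-0.2, 1.2] (the fitting modules' validity window);
clipping is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .binding_core import HRERecord, ybar_dimer
from .dose_response import DoseResponseCurve
from .errors import ConfigurationError, InvalidParameterError
from .isotherm_fitting import YBAR_VALID_RANGE, Isotherm

__all__ = [
    "NoiseModel",
    "default_dose_grid",
    "make_isotherm",
    "simulate_dose_response_family",
    "error_perturb",
]

logger = logging.getLogger(__name__)

NoiseKind = Literal["additive_gaussian", "relative_gaussian", "per_hre_sem"]


@dataclass(frozen=True)
class NoiseModel:
    """Reproducible noise specification for the generators.

    ``sd_or_cv`` is an additive SD (additive_gaussian), a coefficient of
    variation (relative_gaussian), or ignored (per_hre_sem, which takes
    per-HRE relative SDs from a reference record table).  Same seed =>
    identical output.
    """

    kind: NoiseKind = "additive_gaussian"
    sd_or_cv: float = 0.087
    n_rep: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "relative_gaussian", "per_hre_sem"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.sd_or_cv < 0:
            raise InvalidParameterError("sd_or_cv must be >= 0")
        if self.n_rep < 1:
            raise InvalidParameterError("n_rep must be >= 1")


def default_dose_grid(n: int = 10) -> np.ndarray:
    """Default expression-vector dose grid: n log-spaced points, 3-1500 ng."""
    return np.logspace(np.log10(3.0), np.log10(1500.0), n)


def make_isotherm(
    k_tot: float,
    grid: Sequence[float],
    noise: NoiseModel,
    hre: str = "synthetic",
) -> list[Isotherm]:
    """Replicate isotherms from the dimer model plus additive Gaussian noise.

    Warns if the concentration grid does not span the half-saturation point
    sqrt(k_tot) (the constant is then poorly identifiable).  Noisy values
    are clipped to the fitting validity window [-0.2, 1.2].
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise InvalidParameterError("grid must be non-empty and strictly positive")
    mid = np.sqrt(k_tot)
    if grid.max() < mid or grid.min() > mid:
        warnings.warn(
            f"grid does not span the midpoint sqrt(k_tot) = {mid:.3g} M; "
            "the constant may not be identifiable",
            stacklevel=2,
        )
    clean = ybar_dimer(grid, k_tot)
    rng = np.random.default_rng(noise.seed)
    lo, hi = YBAR_VALID_RANGE
    out = []
    for rep in range(noise.n_rep):
        if noise.kind == "additive_gaussian":
            y = clean + noise.sd_or_cv * rng.standard_normal(grid.size)
        elif noise.kind == "relative_gaussian":
            y = clean * (1.0 + noise.sd_or_cv * rng.standard_normal(grid.size))
        else:
            raise InvalidParameterError(
                "per_hre_sem noise applies to dose-response curves, not isotherms"
            )
        n_clip = int(np.sum((y < lo) | (y > hi)))
        if n_clip:
            logger.info("clipping %d synthetic saturation value(s) to [%g, %g]",
                        n_clip, lo, hi)
        out.append(
            Isotherm(x=grid, ybar=np.clip(y, lo, hi),
                     replicate_id=f"rep{rep + 1}", hre=hre)
        )
    return out


def simulate_dose_response_family(
    hres: Sequence[HRERecord],
    f_max: float = 5.0,
    f: float = 1e-9,
    doses: Sequence[float] | None = None,
) -> list[DoseResponseCurve]:
    """Noise-free dose-response family under the maximal-f_max-fold model.

    FA_i(D) = 1 + (f_max - 1) * Ybar_dimer(f * D, K_tot_i): each curve is a
    binding isotherm rescaled into dose (ng) and fold-activation units, with
    a common baseline of 1 and plateau of f_max.

    Parameters
    ----------
    hres
        HRE records supplying K_tot for each curve.
    f_max
        Maximal fold-activation at saturation (>= 1; default 5).
    f
        Molar of receptor per ng of vector (default 1 nM/ng).
    doses
        Dose grid in ng; default 10 log-spaced points, 3-1500 ng.
    """
    if f_max < 1:
        raise InvalidParameterError("f_max must be >= 1")
    if f <= 0:
        raise InvalidParameterError("f must be > 0")
    if doses is None:
        doses = default_dose_grid()
    doses = np.asarray(doses, dtype=float)
    curves = []
    for h in hres:
        if h.k_tot is None or h.k_tot <= 0:
            raise ConfigurationError(f"HRE {h.name!r} has no valid K_tot")
        fa = 1.0 + (f_max - 1.0) * ybar_dimer(doses * f, h.k_tot)
        curves.append(DoseResponseCurve(hre=h.name, dose_ng=doses, fa=fa))
    return curves


def error_perturb(
    curves: Sequence[DoseResponseCurve],
    noise: NoiseModel,
    hres: Sequence[HRERecord] | Mapping[str, tuple[float, float]] | None = None,
    return_replicates: bool = False,
):
    """Replicated noisy versions of dose-response curves.

    Draws ``noise.n_rep`` Gaussian replicates per point and returns curves
    carrying the replicate mean, SEM and replicate count.  Noise kinds:

    * ``additive_gaussian`` — constant additive SD on fold-activation;
    * ``relative_gaussian`` — constant coefficient of variation;
    * ``per_hre_sem`` — per-HRE relative SD = sqrt(n_ref) * SEM / FA taken
      from the reference records (n_ref = 3), emulating error of the same
      magnitude as the measured panel.

    With ``return_replicates=True`` also returns the raw replicate arrays
    keyed by HRE name.
    """
    rel_sd_map: dict[str, float] = {}
    if noise.kind == "per_hre_sem":
        if hres is None:
            raise ConfigurationError("per_hre_sem noise requires HRE records")
        if isinstance(hres, Mapping):
            items = hres.items()
            rel_sd_map = {
                name: np.sqrt(3.0) * sem / fa for name, (fa, sem) in items
            }
        else:
            rel_sd_map = {
                h.name: np.sqrt(3.0) * h.fa_sem / h.fold_activation for h in hres
            }
        missing = [c.hre for c in curves if c.hre not in rel_sd_map]
        if missing:
            raise ConfigurationError(f"missing SEM entries for: {sorted(set(missing))}")
    rng = np.random.default_rng(noise.seed)
    out = []
    replicates = {}
    for c in curves:
        reps = np.empty((noise.n_rep, c.dose_ng.size))
        for r in range(noise.n_rep):
            eps = rng.standard_normal(c.dose_ng.size)
            if noise.kind == "additive_gaussian":
                reps[r] = c.fa + noise.sd_or_cv * eps
            elif noise.kind == "relative_gaussian":
                reps[r] = c.fa * (1.0 + noise.sd_or_cv * eps)
            else:
                reps[r] = c.fa * (1.0 + rel_sd_map[c.hre] * eps)
        mean = reps.mean(axis=0)
        if noise.n_rep > 1:
            sem = reps.std(axis=0, ddof=1) / np.sqrt(noise.n_rep)
        else:
            sem = np.zeros_like(mean)
        out.append(
            DoseResponseCurve(
                hre=c.hre,
                dose_ng=c.dose_ng,
                fa=mean,
                sem=sem,
                n_rep=np.full(c.dose_ng.size, noise.n_rep),
            )
        )
        replicates[c.hre] = reps
    if return_replicates:
        return out, replicates
    return out
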