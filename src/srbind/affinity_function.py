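"""Diagnostics of the affinity-function relationship.

A family of saturating dose-response curves, cross-sectioned at a single
expression dose, yields a highly non-linear relation between binding
affinity and measured activity.  This module provides the tools used to
expose that behaviour and its statistical consequences:

* fixed-dose cross-sections through curve families;
* ordinary least-squares regression of activity on affinity, on linear or
  log10 scale, with R^2 and an F-test P-value (the probability that the
  observed R^2 arises from two uncorrelated variables);
* fold-range summaries of affinity columns;
* simulated perturbation experiments — uniform fold-weakening of binding
  affinity (mutagenesis-like) or uniform reduction of maximal activity
  (coactivator-knockdown-like) — reported as per-HRE activity relative to
  wild-type with Welch-test significance flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding_core import HRERecord
from .dose_response import DoseResponseCurve, ScalingParameters, predict_fold_activation
from .errors import (
    DegenerateRegressionError,
    ExtrapolationError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidPerturbationError,
)

__all__ = [
    "RegressionResult",
    "PerturbationSpec",
    "cross_section",
    "regress",
    "regression_pvalue",
    "fold_range",
    "apply_perturbation",
    "perturbation_report",
]

Scale = Literal["linear", "log10"]
PerturbationKind = Literal["affinity_fold_reduction", "max_activity_fold_reduction"]


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary: slope, intercept, R^2 and slope F-test on a given scale."""

    scale: Scale
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PerturbationSpec:
    """A uniform perturbation applied identically to every HRE.

    ``affinity_fold_reduction`` multiplies every dissociation-scale K_tot by
    ``factor`` (weaker binding); ``max_activity_fold_reduction`` divides the
    plateau fold-activation (e + d) by ``factor`` while keeping the baseline.
    """

    kind: PerturbationKind
    factor: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor < 1:
            raise InvalidParameterError(f"factor must be >= 1, got {self.factor!r}")


def cross_section(
    curves: Sequence[DoseResponseCurve],
    dose: float,
    hres: Sequence[HRERecord],
    affinity: Literal["k_app", "k_tot"] = "k_app",
) -> list[tuple[float, float]]:
    """Slice a dose-response family at one dose: (affinity, FA) per HRE.

    Activity at the requested dose is linearly interpolated between adjacent
    measured doses; requesting a dose outside a curve's grid raises
    :class:`ExtrapolationError` (no extrapolation).
    """
    amap = {h.name: getattr(h, affinity) for h in hres}
    pairs = []
    for c in curves:
        if c.hre not in amap:
            raise InvalidParameterError(f"no HRE record for curve {c.hre!r}")
        if not (c.dose_ng.min() <= dose <= c.dose_ng.max()):
            raise ExtrapolationError(
                f"dose {dose} ng outside grid [{c.dose_ng.min()}, "
                f"{c.dose_ng.max()}] for {c.hre!r}"
            )
        fa = float(np.interp(dose, c.dose_ng, c.fa))
        pairs.append((amap[c.hre], fa))
    return pairs


def regress(
    pairs: Sequence[tuple[float, float]], scale: Scale = "log10"
) -> RegressionResult:
    """OLS of activity on affinity, optionally after log10 transform of both.

    P is the survival function of F = R^2 (n-2) / (1 - R^2) with df (1, n-2):
    the probability that an R^2 this large arises from two uncorrelated
    variables.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (affinity, fa) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise InvalidParameterError("log10 scale requires positive values")
        x, y = np.log10(x), np.log10(y)
    elif scale != "linear":
        raise InvalidParameterError(f"unknown scale {scale!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateRegressionError("zero variance in a regression variable")
    fit = stats.linregress(x, y)
    r2 = min(float(fit.rvalue**2), 1.0)
    n = x.size
    if r2 >= 1.0 - 1e-12:  # numerically perfect fit
        r2 = 1.0
    p = regression_pvalue(r2, n)
    f_stat = np.inf if r2 >= 1.0 else r2 * (n - 2) / (1.0 - r2)
    return RegressionResult(
        scale=scale,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        f_stat=float(f_stat),
        p_value=p,
        n=int(n),
    )


def regression_pvalue(r_squared: float, n: int) -> float:
    """P-value that an observed R^2 arises from uncorrelated variables.

    Survival function of F = r^2 (n-2) / (1-r^2) at df (1, n-2).
    """
    if not 0 <= r_squared <= 1:
        raise InvalidParameterError("r_squared must be in [0, 1]")
    if n < 3:
        raise InsufficientDataError("need n >= 3")
    if r_squared == 1.0:
        warnings.warn("R^2 = 1 gives a degenerate P-value of 0", stacklevel=2)
        return 0.0
    f_stat = r_squared * (n - 2) / (1.0 - r_squared)
    return float(stats.f.sf(f_stat, 1, n - 2))


def fold_range(values: Sequence[float]) -> float:
    """max/min ratio of a column of positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("need at least one value")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise InvalidParameterError("all values must be positive and finite")
    return float(arr.max() / arr.min())


def apply_perturbation(
    hres: Sequence[HRERecord],
    s: ScalingParameters,
    spec: PerturbationSpec,
) -> tuple[list[HRERecord], ScalingParameters]:
    """Return perturbed copies of the model inputs.

    affinity_fold_reduction: every K_tot (dissociation scale) is multiplied
    by ``factor`` — binding is uniformly weakened, as a DNA or receptor
    mutation might.  max_activity_fold_reduction: the plateau e + d is
    divided by ``factor`` with the baseline e unchanged (d' = (e+d)/factor
    - e), as a coactivator knockdown might.
    """
    if spec.kind == "affinity_fold_reduction":
        perturbed = [
            HRERecord(
                name=h.name,
                sequence=h.sequence,
                k_app=h.k_app,
                k_app_sd=h.k_app_sd,
                k_tot=h.k_tot * spec.factor,
                k_tot_sd=h.k_tot_sd * spec.factor,
                fold_activation=h.fold_activation,
                fa_sem=h.fa_sem,
            )
            for h in hres
        ]
        return perturbed, s
    if spec.kind == "max_activity_fold_reduction":
        d_new = (s.e + s.d) / spec.factor - s.e
        if d_new < 0:
            raise InvalidPerturbationError(
                f"factor {spec.factor} drives the amplitude below zero "
                f"(plateau {s.e + s.d} / {spec.factor} < baseline {s.e})"
            )
        return list(hres), ScalingParameters(d=d_new, e=s.e, f=s.f)
    raise InvalidParameterError(f"unknown perturbation kind {spec.kind!r}")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    # Welch on two degenerate identical samples is NaN in scipy; two samples
    # with zero spread and equal means are indistinguishable, so p = 1.
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def perturbation_report(
    hres: Sequence[HRERecord],
    s: ScalingParameters,
    spec: PerturbationSpec,
    dose: float,
    n_rep: int = 3,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated perturbation experiment at one expression dose.

    For each HRE, ``n_rep`` noisy replicates of wild-type and perturbed
    activity are drawn (relative Gaussian noise with coefficient of
    variation ``noise_cv``), and the mean perturbed/wild-type ratio, its
    SEM, and a Welch two-sample P-value are reported with significance
    flags at 0.05 (*) and 0.005 (**).

    Returns a tidy DataFrame: hre, wt_mean, pert_mean, ratio, ratio_sem,
    p_value, sig_05, sig_005.
    """
    if n_rep < 2:
        raise InsufficientDataError("need n_rep >= 2 to test for a difference")
    pert_hres, pert_s = apply_perturbation(hres, s, spec)
    rng = np.random.default_rng(seed)
    rows = []
    for h, hp in zip(hres, pert_hres):
        wt = predict_fold_activation(dose, h.k_tot, s)
        pt = predict_fold_activation(dose, hp.k_tot, pert_s)
        wt_reps = wt * (1.0 + noise_cv * rng.standard_normal(n_rep))
        pt_reps = pt * (1.0 + noise_cv * rng.standard_normal(n_rep))
        ratios = pt_reps / np.mean(wt_reps)
        p = _welch_p(pt_reps, wt_reps)
        rows.append(
            {
                "hre": h.name,
                "wt_mean": float(np.mean(wt_reps)),
                "pert_mean": float(np.mean(pt_reps)),
                "ratio": float(np.mean(ratios)),
                "ratio_sem": float(np.std(ratios, ddof=1) / np.sqrt(n_rep)),
                "p_value": p,
                "sig_05": p < 0.05,
                "sig_005": p < 0.005,
            }
        )
    return pd.DataFrame(rows)
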