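"""Closed-form equilibrium binding expressions.

Two saturation models for a receptor binding a hormone response element
(HRE), plus the solution monomer-dimer equilibrium that connects total
receptor concentration to free monomer and pre-formed dimer concentrations.

Conventions
-----------
* All equilibrium constants are **dissociation**-scale: ``K_app`` and
  ``k_dim`` in molar, ``K_tot`` in molar squared.  Association constants are
  their reciprocals (``K_assoc = 1 / K_d``).
* ``x`` always denotes the free receptor **monomer** concentration in molar.
* Printed units in the bundled reference table are nM for ``K_app`` and
  "fM2" for ``K_tot``, where fM2 is read as 1e-15 M^2 (femto-[M^2]), not
  (1e-15 M)^2.  Only that reading is self-consistent: the half-saturation
  point of the two-monomer model is sqrt(K_tot), and
  sqrt(0.800e-15 M^2) = 28 nM, matching the Langmuir midpoint of ~32 nM for
  the same palindrome; the literal reading would put it at 0.9 fM.

The Langmuir model treats the site as binding a single ligand with apparent
constant ``K_app``:

    Ybar = x / (K_app + x)

The dimer-assembly model resolves the *total* constant for loading two
monomers onto a palindrome (a macroscopic product constant over whatever
microscopic path assembles the dimer):

    Ybar = x^2 / (K_tot + x^2)

which is sigmoidal with Hill slope 2 at its midpoint x = sqrt(K_tot).
Singly-ligated palindrome intermediates are not carried as a separate state:
the model is the two-state (empty / doubly-bound) macroscopic formulation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "HRERecord",
    "NM",
    "UM",
    "FM2",
    "ybar_langmuir",
    "ybar_dimer",
    "free_monomer",
    "dimer_conc",
]

#: 1 nanomolar in molar.
NM = 1e-9
#: 1 micromolar in molar.
UM = 1e-6
#: 1 "fM2" in molar squared (femto-[M^2]; see module docstring).
FM2 = 1e-15

_SEQ_RE = re.compile(r"^[ACGTacgt]+$")


@dataclass(frozen=True)
class HRERecord:
    """One hormone response element with its affinities and activity.

    Parameters
    ----------
    name
        Short label (e.g. ``"Pal"``).
    sequence
        HRE sequence, hexamer-spacer-hexamer; case is preserved (lower case
        conventionally marks the spacer) and validated over {A, C, G, T}.
    k_app
        Apparent (Langmuir) dissociation constant, molar.
    k_tot
        Total two-monomer assembly dissociation constant, molar squared.
    k_app_sd, k_tot_sd
        One-standard-deviation uncertainties, same units.
    fold_activation
        Ligand-induced fold-activation of a reporter at the reference
        expression-vector dose (unitless, > 0).
    fa_sem
        Standard error of the mean of ``fold_activation``.
    """

    name: str
    sequence: str
    k_app: float
    k_tot: float
    fold_activation: float
    k_app_sd: float = 0.0
    k_tot_sd: float = 0.0
    fa_sem: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence or not _SEQ_RE.match(self.sequence):
            raise InvalidParameterError(
                f"HRE {self.name!r}: sequence must be non-empty over ACGT, "
                f"got {self.sequence!r}"
            )
        for field in ("k_app", "k_tot", "fold_activation"):
            value = getattr(self, field)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"HRE {self.name!r}: {field} must be positive and finite, "
                    f"got {value!r}"
                )


def _validate_conc(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise InvalidParameterError(f"{name} must be finite and >= 0")
    return x


def _validate_positive(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise InvalidParameterError(f"{name} must be positive and finite, got {value!r}")
    return value


def ybar_langmuir(x, k_app):
    """Fractional saturation under the single-ligand (Langmuir) model.

    Ybar = x / (k_app + x), a rectangular hyperbola with midpoint at
    x = k_app.

    Parameters
    ----------
    x : float or array_like
        Free receptor monomer concentration, molar (>= 0).
    k_app : float
        Apparent dissociation constant, molar (> 0).

    Returns
    -------
    float or ndarray
        Fractional saturation in [0, 1).
    """
    x = _validate_conc(x, "x")
    k_app = _validate_positive(k_app, "k_app")
    out = x / (k_app + x)
    return float(out) if out.ndim == 0 else out


def ybar_dimer(x, k_tot):
    """Fractional saturation under the two-monomer total-assembly model.

    Ybar = x^2 / (k_tot + x^2): sigmoidal with Hill slope 2 and midpoint
    exactly at x = sqrt(k_tot).

    Parameters
    ----------
    x : float or array_like
        Free receptor monomer concentration, molar (>= 0).
    k_tot : float
        Total dissociation constant, molar squared (> 0).

    Returns
    -------
    float or ndarray
        Fractional saturation in [0, 1).
    """
    x = _validate_conc(x, "x")
    k_tot = _validate_positive(k_tot, "k_tot")
    x2 = x * x
    out = x2 / (k_tot + x2)
    return float(out) if out.ndim == 0 else out


def free_monomer(r_total, k_dim=None):
    """Free monomer concentration at total receptor concentration ``r_total``.

    Solves the conservation equation ``r_total = x + 2 x^2 / k_dim`` where
    ``k_dim`` is the dissociation constant of the solution dimerization
    2M <=> M2.  ``k_dim=None`` means no detectable dimerization, in which
    case all receptor is monomeric (x = r_total).

    The positive quadratic root is evaluated in the subtraction-free form
    ``x = 2 r / (1 + sqrt(1 + 8 r / k_dim))``, which stays accurate when
    dimerization is negligible (8r/k_dim << 1).

    Parameters
    ----------
    r_total : float or array_like
        Total receptor concentration (monomer equivalents), molar, >= 0.
    k_dim : float or None
        Dimerization dissociation constant, molar, > 0; None disables
        dimerization.

    Returns
    -------
    float or ndarray
        Free monomer concentration, molar; always <= r_total.
    """
    r_total = _validate_conc(r_total, "r_total")
    if k_dim is None:
        out = r_total + 0.0
        return float(out) if out.ndim == 0 else out
    k_dim = _validate_positive(k_dim, "k_dim")
    out = 2.0 * r_total / (1.0 + np.sqrt(1.0 + 8.0 * r_total / k_dim))
    return float(out) if out.ndim == 0 else out


def dimer_conc(x, k_dim):
    """Solution dimer concentration [M2] = x^2 / k_dim.

    Parameters
    ----------
    x : float or array_like
        Free monomer concentration, molar, >= 0.
    k_dim : float
        Dimerization dissociation constant, molar, > 0.

    Returns
    -------
    float or ndarray
        Dimer concentration, molar.  Consistent with :func:`free_monomer`:
        ``x + 2 * dimer_conc(x, k_dim)`` reconstructs the total.
    """
    x = _validate_conc(x, "x")
    k_dim = _validate_positive(k_dim, "k_dim")
    out = x * x / k_dim
    return float(out) if out.ndim == 0 else out
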