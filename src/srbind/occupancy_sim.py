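"""Statistical-thermodynamic simulator of competitive promoter assembly.

Multiple receptor species compete for a promoter built from an ordered list
of half-sites (bound by monomers) and palindromes (bound by pre-formed
dimers).  The solution-phase monomer-dimer equilibrium of each species sets
its free monomer concentration x and dimer concentration [M2] = x^2/k_dim;
the promoter is assumed to be at trace concentration so it does not deplete
the receptor pool.

Every promoter configuration (microstate) assigns each site to one species
or leaves it empty.  Statistical weights, relative to the empty promoter
(weight 1):

* a half-site occupied by species s contributes x_s / k_half,s;
* a palindrome occupied by species s contributes [M2]_s / k_pal,s
  (dimer pathway only — species without detectable dimerization cannot
  occupy palindromes; singly-ligated palindromes are excluded by default);
* each nearest-neighbour pair of sites both occupied by the *same* species
  contributes one factor of that species' cooperativity k_c, regardless of
  the two site types; heterotypic adjacent pairs get no cooperativity.

Probabilities follow from the configurational partition function
Z = sum of all state weights; "fully ligated" for species s means every
site occupied by s (homotypic), with mixed full states aggregated
separately.

Exact enumeration is used throughout, bounded at 12 sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binding_core import dimer_conc, free_monomer
from .errors import InvalidParameterError, PromoterSizeError

__all__ = [
    "ReceptorSpecies",
    "PromoterArchitecture",
    "OccupancyProfile",
    "enumerate_microstates",
    "state_weight",
    "prob_fully_ligated",
    "state_probabilities",
    "occupancy_sweep",
]

SiteType = Literal["half", "palindrome"]

#: Exact-enumeration bound on promoter length.
MAX_SITES = 12


@dataclass(frozen=True)
class ReceptorSpecies:
    """One receptor species and its microscopic energetic parameters.

    Parameters
    ----------
    name
        Label (e.g. ``"GR"``).
    k_dim
        Solution dimerization dissociation constant, molar.  ``None`` means
        no detectable dimerization; such a species has no dimer pool and
        cannot occupy palindromes.  When only a lower limit was measurable,
        store that limit and set ``k_dim_is_lower_limit=True``; the limit is
        still *used* as the constant (weakest consistent dimerization)
        unless the caller treats the species as non-dimerizing.
    k_half
        Monomer -> half-site dissociation constant, molar.
    k_pal
        Pre-formed dimer -> palindrome dissociation constant, molar.
    k_c
        Unitless nearest-neighbour cooperativity (1 = none).
    """

    name: str
    k_half: float
    k_pal: float
    k_dim: float | None = None
    k_c: float = 1.0
    k_dim_is_lower_limit: bool = False

    def __post_init__(self) -> None:
        for attr in ("k_half", "k_pal", "k_c"):
            v = getattr(self, attr)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"species {self.name!r}: {attr} must be > 0, got {v!r}"
                )
        if self.k_dim is not None and (
            not np.isfinite(self.k_dim) or self.k_dim <= 0
        ):
            raise InvalidParameterError(
                f"species {self.name!r}: k_dim must be > 0 or None"
            )

    def solution_concentrations(self, total: float) -> tuple[float, float]:
        """(free monomer, dimer) concentrations at a given total, molar."""
        if total < 0 or not np.isfinite(total):
            raise InvalidParameterError("total concentration must be finite and >= 0")
        x = free_monomer(total, self.k_dim)
        m2 = 0.0 if self.k_dim is None else dimer_conc(x, self.k_dim)
        return x, m2


@dataclass(frozen=True)
class PromoterArchitecture:
    """Ordered list of binding sites, each ``"half"`` or ``"palindrome"``."""

    sites: tuple[SiteType, ...]

    def __init__(self, sites: Sequence[str]):
        sites = tuple(sites)
        if not 1 <= len(sites) <= MAX_SITES:
            raise PromoterSizeError(
                f"promoter must have 1..{MAX_SITES} sites, got {len(sites)}"
            )
        for s in sites:
            if s not in ("half", "palindrome"):
                raise InvalidParameterError(f"unknown site type {s!r}")
        object.__setattr__(self, "sites", sites)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class OccupancyProfile:
    """Occupancy probabilities over a total-concentration grid.

    ``fully_ligated[name]`` is the probability that every site is occupied
    by that species; ``mixed_full`` is any other all-sites-occupied state;
    ``partial_or_empty`` the remainder.  At each grid point the three
    classes sum to 1.
    """

    totals: np.ndarray
    fully_ligated: dict[str, np.ndarray]
    mixed_full: np.ndarray
    partial_or_empty: np.ndarray
    architecture: PromoterArchitecture = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: conc_molar, species/state_class, probability."""
        rows = []
        for name, probs in self.fully_ligated.items():
            for c, p in zip(self.totals, probs):
                rows.append(
                    {
                        "conc_molar": c,
                        "species": name,
                        "state_class": "fully_ligated",
                        "probability": p,
                    }
                )
        for label, probs in (
            ("mixed_full", self.mixed_full),
            ("partial_or_empty", self.partial_or_empty),
        ):
            for c, p in zip(self.totals, probs):
                rows.append(
                    {
                        "conc_molar": c,
                        "species": "(any)",
                        "state_class": label,
                        "probability": p,
                    }
                )
        return pd.DataFrame(rows)


def enumerate_microstates(
    arch: PromoterArchitecture, species: Sequence[ReceptorSpecies]
) -> list[tuple[int | None, ...]]:
    """All promoter configurations as tuples of per-site occupants.

    Each element of a state tuple is ``None`` (empty site) or the index of
    the occupying species; there are (1 + n_species)^n_sites states.  States
    that are sterically enumerable but energetically inaccessible (a
    non-dimerizing species on a palindrome) carry zero weight rather than
    being excluded here.
    """
    if len(arch) > MAX_SITES:
        raise PromoterSizeError(f"more than {MAX_SITES} sites")
    choices: list[int | None] = [None] + list(range(len(species)))
    return list(product(choices, repeat=len(arch)))


def state_weight(
    state: tuple[int | None, ...],
    arch: PromoterArchitecture,
    species: Sequence[ReceptorSpecies],
    x: Sequence[float],
    m2: Sequence[float],
) -> float:
    """Statistical weight of one microstate relative to the empty promoter.

    ``x`` and ``m2`` are the per-species free monomer and dimer
    concentrations (molar).
    """
    w = 1.0
    for occ, site in zip(state, arch.sites):
        if occ is None:
            continue
        sp = species[occ]
        w *= (x[occ] / sp.k_half) if site == "half" else (m2[occ] / sp.k_pal)
    # one cooperativity factor per adjacent same-species occupied pair
    for a, b in zip(state, state[1:]):
        if a is not None and a == b:
            w *= species[a].k_c
    return w


def _solution_state(
    species: Sequence[ReceptorSpecies], totals: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    if len(totals) != len(species):
        raise InvalidParameterError("one total concentration per species required")
    x = np.empty(len(species))
    m2 = np.empty(len(species))
    for i, (sp, t) in enumerate(zip(species, totals)):
        x[i], m2[i] = sp.solution_concentrations(float(t))
    return x, m2


def state_probabilities(
    arch: PromoterArchitecture,
    species: Sequence[ReceptorSpecies],
    totals: Sequence[float],
) -> dict[tuple[int | None, ...], float]:
    """Probability of every microstate at the given per-species totals."""
    x, m2 = _solution_state(species, totals)
    states = enumerate_microstates(arch, species)
    weights = np.array([state_weight(s, arch, species, x, m2) for s in states])
    z = weights.sum()
    return {s: float(w / z) for s, w in zip(states, weights)}


def prob_fully_ligated(
    arch: PromoterArchitecture,
    species: Sequence[ReceptorSpecies],
    totals: Sequence[float],
) -> dict[str, float]:
    """Per-species probability of homotypic full promoter occupancy.

    For each species s: (sum of weights of states with every site occupied
    by s) / Z.
    """
    probs = state_probabilities(arch, species, totals)
    out = {}
    for i, sp in enumerate(species):
        full = tuple([i] * len(arch))
        out[sp.name] = probs[full]
    return out


def occupancy_sweep(
    arch: PromoterArchitecture,
    species: Sequence[ReceptorSpecies],
    grid: Sequence[float],
    per_species_totals: Sequence[Sequence[float]] | None = None,
) -> OccupancyProfile:
    """Competition sweep over a total-concentration grid.

    By default every species is assigned the same total concentration at
    each grid point (the standard competition setup); ``per_species_totals``
    overrides this with an explicit (n_grid, n_species) array.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("empty concentration grid")
    if per_species_totals is None:
        totals_matrix = np.tile(grid[:, None], (1, len(species)))
    else:
        totals_matrix = np.asarray(per_species_totals, dtype=float)
        if totals_matrix.shape != (grid.size, len(species)):
            raise InvalidParameterError(
                "per_species_totals must have shape (n_grid, n_species)"
            )
    fully = {sp.name: np.empty(grid.size) for sp in species}
    mixed = np.empty(grid.size)
    rest = np.empty(grid.size)
    n_sites = len(arch)
    for g in range(grid.size):
        probs = state_probabilities(arch, species, totals_matrix[g])
        full_total = 0.0
        homo_total = 0.0
        for state, p in probs.items():
            if all(o is not None for o in state):
                full_total += p
        for i, sp in enumerate(species):
            ph = probs[tuple([i] * n_sites)]
            fully[sp.name][g] = ph
            homo_total += ph
        mixed[g] = full_total - homo_total
        rest[g] = 1.0 - full_total
    return OccupancyProfile(
        totals=grid,
        fully_ligated=fully,
        mixed_full=mixed,
        partial_or_empty=rest,
        architecture=arch,
    )
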