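"""Activity-pH models for linear polyprotic ionization schemes.

An enzyme with ``n`` titratable groups that deprotonate in a fixed
(macroscopic, stepwise) order populates ``n + 1`` protonation species.
Each species carries a relative catalytic activity ("weight", in the
same arbitrary % units as the assay data), and the observed activity at
a given pH is the weight-average over the Boltzmann/Henderson population
of species.  The classic bell-shaped two-pKa profile, and its four-pKa
generalisation with three active species, are special cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ProtonationScheme",
    "ActivityCurve",
    "species_fractions",
    "model_activity",
    "activity_curve",
    "eq1_activity",
    "eq2_activity",
    "eq3_activity",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class ProtonationScheme:
    """A linear deprotonation chain with per-species activity weights.

    Parameters
    ----------
    pkas:
        Strictly ascending stepwise pKa values, one per deprotonation
        step (``n_sites`` of them).
    weights:
        ``n_sites + 1`` nonnegative relative activities, ordered from the
        fully protonated to the fully deprotonated species.  Units are
        arbitrary (% activity); values may exceed 100 and no
        normalisation is imposed.
    """

    pkas: tuple[float, ...]
    weights: tuple[float, ...]

    def __init__(self, pkas: Sequence[float], weights: Sequence[float]):
        pkas = tuple(float(p) for p in pkas)
        weights = tuple(float(w) for w in weights)
        if len(pkas) < 1:
            raise ValueError("at least one deprotonation step is required")
        if any(not np.isfinite(p) for p in pkas):
            raise ValueError("pKa values must be finite")
        if any(b <= a for a, b in zip(pkas, pkas[1:])):
            raise ValueError(f"pKas must be strictly ascending, got {pkas}")
        if len(weights) != len(pkas) + 1:
            raise ValueError(
                f"need {len(pkas) + 1} weights for {len(pkas)} sites, "
                f"got {len(weights)}"
            )
        if any(w < 0 for w in weights):
            raise ValueError("weights must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "pkas", pkas)
        object.__setattr__(self, "weights", weights)

    @property
    def n_sites(self) -> int:
        return len(self.pkas)

    @property
    def n_species(self) -> int:
        return len(self.pkas) + 1

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "pkas": list(self.pkas),
            "weights": list(self.weights),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtonationScheme":
        scheme = cls(d["pkas"], d["weights"])
        if "n_sites" in d and int(d["n_sites"]) != scheme.n_sites:
            raise ValueError("n_sites inconsistent with pkas length")
        return scheme


@dataclass(frozen=True)
class ActivityCurve:
    """A model activity profile evaluated on a pH grid (% units)."""

    ph_grid: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        ph = np.asarray(self.ph_grid, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        if ph.shape != act.shape:
            raise ValueError("ph_grid and activity must have the same shape")
        object.__setattr__(self, "ph_grid", ph)
        object.__setattr__(self, "activity", act)


def species_fractions(scheme: ProtonationScheme, ph) -> np.ndarray:
    """Equilibrium fraction of each protonation species at ``ph``.

    Species ``j`` (the one with ``j`` protons removed) has unnormalised
    population ``10 ** sum_{i<=j} (ph - pKa_i)``.  Exponents are shifted
    by their maximum before exponentiation so that extreme pH values do
    not overflow even for pKa spreads of ten units.

    Returns an array of shape ``(n_species,)`` for scalar ``ph``, or
    ``ph.shape + (n_species,)`` for array input; fractions sum to 1.
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH must be finite")
    pkas = np.asarray(scheme.pkas)
    # log10 unnormalised population of species j, referenced to species 0
    exponents = np.concatenate(
        [np.zeros(ph.shape + (1,)), np.cumsum(ph[..., None] - pkas, axis=-1)],
        axis=-1,
    )
    exponents -= exponents.max(axis=-1, keepdims=True)
    pop = np.exp(_LN10 * exponents)
    return pop / pop.sum(axis=-1, keepdims=True)


def model_activity(scheme: ProtonationScheme, ph):
    """Weight-averaged activity of ``scheme`` at ``ph`` (% units)."""
    frac = species_fractions(scheme, ph)
    return frac @ np.asarray(scheme.weights)


def activity_curve(scheme: ProtonationScheme, ph_grid) -> ActivityCurve:
    ph_grid = np.atleast_1d(np.asarray(ph_grid, dtype=float))
    if ph_grid.size == 0:
        raise ValueError("pH grid is empty")
    return ActivityCurve(ph_grid, model_activity(scheme, ph_grid))


def eq1_activity(pka1: float, pka2: float, ph):
    """Classic bell-shaped profile: single active mono-deprotonated species.

    ``1 / (1 + 10**(pKa1 - pH) + 10**(pH - pKa2))`` — a fraction in
    [0, 1], maximal at the midpoint of the two pKas.
    """
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (ph - pka2))


def eq2_activity(pkas: Sequence[float], x: float, y: float, z: float, ph):
    """Four-pKa scheme with three active species (x, y, z weights).

    Literal transcription referenced to the doubly deprotonated species:
    numerator ``x[H+]/Ka2 + y + z Ka3/[H+]`` over the five-term partition
    function.  Identical to :func:`model_activity` with a 4-site scheme
    weighted ``(0, x, y, z, 0)``.
    """
    ph = np.asarray(ph, dtype=float)
    ka1, ka2, ka3, ka4 = (10.0 ** -np.asarray(pkas, dtype=float))
    h = 10.0 ** -ph
    num = x * h / ka2 + y + z * ka3 / h
    den = h**2 / (ka1 * ka2) + h / ka2 + 1.0 + ka3 / h + ka3 * ka4 / h**2
    return num / den


def eq3_activity(pkas: Sequence[float], x: float, y: float, ph):
    """Three-pKa scheme with two active species.

    Literal transcription: numerator ``x + y[H+]/Ka2`` over the four-term
    partition function referenced to the doubly deprotonated species.
    Note the numerator pairs ``x`` with the reference ("1") species and
    ``y`` with the ``[H+]/Ka2`` species, so the equivalent general scheme
    carries weights ``(0, y, x, 0)``.
    """
    ph = np.asarray(ph, dtype=float)
    ka1, ka2, ka3 = (10.0 ** -np.asarray(pkas, dtype=float))
    h = 10.0 ** -ph
    num = x + y * h / ka2
    den = h**2 / (ka1 * ka2) + h / ka2 + 1.0 + ka3 / h
    return num / den
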