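"""Seeded generators for every input the pipeline consumes.

Each generator draws from a single ``numpy`` Generator derived from the
user seed, so identical (parameters, seed) pairs give byte-identical
output regardless of call order.  They provide ground truth for the
recovery tests: bell-shaped activity-pH profiles from a stated species
scheme plus Gaussian noise, Michaelis-Menten velocity data, two-state
coordinate ensembles emulating an open/closed lid loop, and
Markov-switching two-population pKa time series.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble, PkaSeries
from .fitting import ProfileDataset
from .protonation import ProtonationScheme, model_activity

__all__ = [
    "gen_profile",
    "gen_kinetics",
    "gen_two_state_ensemble",
    "gen_pka_series",
]


def gen_profile(
    scheme: ProtonationScheme,
    ph_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> ProfileDataset:
    """Noisy activity-pH profile: model curve + N(0, sd), floored at 0."""
    ph = np.atleast_1d(np.asarray(ph_grid, dtype=float))
    if ph.size == 0:
        raise ValueError("pH grid is empty")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = np.random.default_rng(seed)
    activity = model_activity(scheme, ph)
    if noise_sd > 0:
        activity = np.clip(activity + rng.normal(0.0, noise_sd, ph.size), 0.0, None)
    sd = np.full(ph.size, noise_sd) if noise_sd > 0 else None
    return ProfileDataset(ph, activity, sd, label)


def gen_kinetics(
    vmax: float,
    km: float,
    concentrations: Sequence[float],
    noise_fraction: float = 0.0,
    reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis-Menten velocities with Gaussian noise sd = fraction * Vmax.

    Returns a tidy frame with columns ``maltose_mM``, ``velocity``,
    ``rep``.
    """
    s = np.asarray(concentrations, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    if noise_fraction < 0 or reps < 1:
        raise ValueError("noise fraction must be >= 0 and reps >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(reps):
        v = vmax * s / (km + s)
        if noise_fraction > 0:
            v = np.clip(v + rng.normal(0.0, noise_fraction * vmax, s.size), 0.0, None)
        rows.append(pd.DataFrame({"maltose_mM": s, "velocity": v, "rep": r}))
    return pd.concat(rows, ignore_index=True)


def _self_avoiding_coil(n_atoms: int, rng: np.random.Generator,
                        bond: float = 3.8, min_sep: float = 3.0) -> np.ndarray:
    """Random Calpha-like coil: fixed bond length, clash-rejected steps."""
    coords = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= bond / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i < 2:
                break
            d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
            if np.all(d >= min_sep):
                break
        coords[i] = cand
    return coords


def _markov_states(weights: tuple[float, float], stickiness: float,
                   n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Two-state chain with the given stationary weights.

    ``stickiness`` in [0, 1) scales both switching rates down equally,
    preserving the stationary distribution while adding memory.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("state weights must be nonnegative with positive sum")
    w = w / w.sum()
    t = 1.0 - stickiness
    p_ab, p_ba = t * w[1], t * w[0]   # stationary distribution is w
    states = np.empty(n_frames, dtype=int)
    states[0] = int(rng.random() < w[1])
    u = rng.random(n_frames - 1)
    for i in range(1, n_frames):
        if states[i - 1] == 0:
            states[i] = int(u[i - 1] < p_ab)
        else:
            states[i] = 1 - int(u[i - 1] < p_ba)
    return states


def gen_two_state_ensemble(
    n_atoms: int = 60,
    loop_atoms: Optional[Sequence[int]] = None,
    displacement: float = 5.0,
    state_weights: tuple[float, float] = (0.8, 0.2),
    jitter_sd: float = 0.3,
    n_frames: int = 500,
    frame_spacing_ps: float = 100.0,
    stickiness: float = 0.25,
    seed: int = 0,
    label: str = "two-state",
) -> ConformationalEnsemble:
    """Two-conformation coordinate ensemble (open/closed lid analogue).

    A self-avoiding random coil is the base ("closed") structure; the
    "open" state rigidly displaces the loop atom subset by
    ``displacement`` A along a fixed direction.  Frames are drawn from a
    two-state Markov chain with the given stationary weights, and every
    atom gets isotropic Gaussian jitter of sd ``jitter_sd`` A per
    coordinate.
    """
    import warnings

    if displacement <= 0 and all(w > 0 for w in state_weights):
        warnings.warn("zero displacement with two populated states: "
                      "states are indistinguishable")
    rng = np.random.default_rng(seed)
    if loop_atoms is None:
        # half the chain: a displacement of a few A on a small subset is
        # largely absorbed by the optimal superposition, so the lid-loop
        # analogue must carry enough atoms for the two conformations to be
        # genuinely distinct after least-squares fitting
        loop_atoms = np.arange(n_atoms // 4, n_atoms // 4 + max(n_atoms // 2, 1))
    loop_atoms = np.asarray(loop_atoms, dtype=int)
    base = _self_avoiding_coil(n_atoms, rng)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    open_state = base.copy()
    open_state[loop_atoms] += displacement * direction
    states = _markov_states(state_weights, stickiness, n_frames, rng)
    coords = np.where(states[:, None, None] == 0, base, open_state)
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    atoms = pd.DataFrame(
        {
            "residue_index": np.arange(1, n_atoms + 1),
            "residue_name": ["ALA"] * n_atoms,
            "atom_name": ["CA"] * n_atoms,
            "element": ["C"] * n_atoms,
        }
    )
    ens = ConformationalEnsemble(coords, atoms, frame_spacing_ps, label)
    ens.states = states          # ground truth for tests
    ens.loop_atoms = loop_atoms
    return ens


def gen_pka_series(
    means: Sequence[float],
    sds: Sequence[float],
    transition: np.ndarray,
    n_frames: int = 4000,
    frame_spacing_ps: float = 100.0,
    seed: int = 0,
    residue: str = "D186",
) -> PkaSeries:
    """Markov-switching Gaussian pKa time series.

    ``transition`` is a row-stochastic matrix over the states; the chain
    starts from its stationary distribution.  Emulates a titratable
    residue alternating between environments of very different pKa.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    trans = np.asarray(transition, dtype=float)
    k = means.size
    if sds.size != k or trans.shape != (k, k):
        raise ValueError("means, sds and transition matrix sizes disagree")
    if np.any(sds < 0):
        raise ValueError("sds must be nonnegative")
    if not np.allclose(trans.sum(axis=1), 1.0):
        raise ValueError("transition matrix rows must sum to 1")
    rng = np.random.default_rng(seed)
    # stationary distribution: left eigenvector of the transition matrix
    vals, vecs = np.linalg.eig(trans.T)
    stat = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    stat = np.abs(stat) / np.abs(stat).sum()
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(k, p=stat)
    for i in range(1, n_frames):
        states[i] = rng.choice(k, p=trans[states[i - 1]])
    pka = rng.normal(means[states], sds[states])
    times = frame_spacing_ps * np.arange(1, n_frames + 1)
    series = PkaSeries(residue, times, pka)
    object.__setattr__(series, "states", states)   # ground truth for tests
    return series
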