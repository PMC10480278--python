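"""Desk-scale conformational-ensemble analytics.

Operates on coordinate ensembles supplied as multi-model PDB files (or
built in memory): optimal rigid superposition (Kabsch), RMSD series
against a reference frame, windowed per-residue RMSF, greedy
neighbour-count (GROMOS/Daura) clustering of the pairwise RMSD matrix,
distance-only hydrogen-bond and carbon-contact counters, and Gaussian
mixture decomposition of per-frame pKa series into populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from sklearn.mixture import GaussianMixture

__all__ = [
    "ConformationalEnsemble",
    "Selection",
    "ClusterResult",
    "PkaSeries",
    "PopulationDecomposition",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_windows",
    "pairwise_rmsd",
    "gromos_cluster",
    "hbond_count",
    "contact_metrics",
    "pka_populations",
]


@dataclass
class ConformationalEnsemble:
    """frames x atoms x 3 coordinates (A) with per-atom metadata.

    ``atoms`` columns: ``residue_index`` (1-based, as in the file),
    ``residue_name``, ``atom_name``, ``element``.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_spacing_ps: float = 100.0
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        if len(self.atoms) != c.shape[1]:
            raise ValueError("atom metadata does not match coordinate atom count")
        if self.frame_spacing_ps <= 0:
            raise ValueError("frame_spacing_ps must be positive")
        self.coords = c

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_pdb(cls, path, frame_spacing_ps: float = 100.0,
                 label: str = "") -> "ConformationalEnsemble":
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)
        atoms = pd.DataFrame(
            {
                "residue_index": stack.res_id,
                "residue_name": stack.res_name,
                "atom_name": stack.atom_name,
                "element": stack.element,
            }
        )
        return cls(np.asarray(stack.coord, dtype=float), atoms,
                   frame_spacing_ps, label)

    def to_pdb(self, path) -> None:
        n_f, n_a = self.n_frames, self.n_atoms
        stack = struc.AtomArrayStack(n_f, n_a)
        stack.coord = self.coords.astype(np.float32)
        stack.res_id = self.atoms["residue_index"].to_numpy()
        stack.res_name = np.asarray(self.atoms["residue_name"], dtype="U5")
        stack.atom_name = np.asarray(self.atoms["atom_name"], dtype="U6")
        stack.element = np.asarray(self.atoms["element"], dtype="U2")
        stack.chain_id = np.full(n_a, "A", dtype="U4")
        stack.hetero = np.zeros(n_a, dtype=bool)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(path)


@dataclass(frozen=True)
class Selection:
    """Atom predicate over residue ranges, atom names and elements."""

    atom_names: Optional[frozenset] = None
    elements: Optional[frozenset] = None
    residues: Optional[tuple[int, int]] = None   # inclusive range

    @classmethod
    def make(cls, atom_names=None, elements=None, residues=None) -> "Selection":
        return cls(
            frozenset(atom_names) if atom_names is not None else None,
            frozenset(elements) if elements is not None else None,
            tuple(residues) if residues is not None else None,
        )

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(atoms), dtype=bool)
        if self.atom_names is not None:
            m &= atoms["atom_name"].isin(self.atom_names).to_numpy()
        if self.elements is not None:
            m &= atoms["element"].isin(self.elements).to_numpy()
        if self.residues is not None:
            lo, hi = self.residues
            ri = atoms["residue_index"].to_numpy()
            m &= (ri >= lo) & (ri <= hi)
        if not m.any():
            raise ValueError("selection matches no atoms")
        return m


CA = Selection.make(atom_names={"CA"})


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(mobile, reference) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in
    the least-squares sense; the rotation is proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    x, y = mob - cm, ref - cr
    sv = np.linalg.svd(y, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) reference geometry")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    trans = cr - cm @ rot.T
    return rot, trans, rmsd


def rmsd_series(
    ensemble: ConformationalEnsemble,
    selection: Selection = CA,
    reference_frame: int = 0,
) -> np.ndarray:
    """Per-frame RMSD (A) to a reference frame after Kabsch superposition."""
    m = selection.mask(ensemble.atoms)
    ref = ensemble.coords[reference_frame][m]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        out[i] = kabsch_superpose(ensemble.coords[i][m], ref)[2]
    return out


def rmsf_windows(
    ensemble: ConformationalEnsemble,
    selection: Selection = CA,
    window_ps: float = 100.0,
) -> pd.DataFrame:
    """Per-residue RMSF (A) in non-overlapping time windows.

    Frames are partitioned into windows of
    ``floor(window_ps / frame_spacing_ps)`` frames (trailing partial
    window dropped).  Within each window the frames are superposed onto
    the window-mean structure — seeded by superposing onto the window's
    first frame, then one re-superposition onto the resulting mean —
    and ``RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2)``.

    Returns a tidy frame with columns ``window``, ``residue_index``,
    ``rmsf``.
    """
    frames_per = int(window_ps // ensemble.frame_spacing_ps)
    if frames_per < 2:
        raise ValueError("window must span at least 2 frames")
    m = selection.mask(ensemble.atoms)
    residues = ensemble.atoms.loc[m, "residue_index"].to_numpy()
    coords = ensemble.coords[:, m, :]
    n_windows = ensemble.n_frames // frames_per
    rows = []
    for w in range(n_windows):
        block = coords[w * frames_per:(w + 1) * frames_per]
        aligned = _superpose_stack(block, block[0])
        mean = aligned.mean(axis=0)
        aligned = _superpose_stack(aligned, mean)
        mean = aligned.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
        for res, val in zip(residues, rmsf):
            rows.append({"window": w, "residue_index": int(res), "rmsf": float(val)})
    return pd.DataFrame(rows)


def _superpose_stack(block: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(block)
    for i, frame in enumerate(block):
        rot, trans, _ = kabsch_superpose(frame, reference)
        out[i] = frame @ rot.T + trans
    return out


# ---------------------------------------------------------------------------
# clustering

def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Pairwise superposed RMSD matrix over frames of (F, N, 3) coords.

    Uses the Kabsch singular-value identity
    ``rmsd^2 = (G_i + G_j - 2 (s1 + s2 +/- s3)) / n`` with batched SVDs
    of the 3x3 cross-covariance matrices.
    """
    f, n, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    gram = np.einsum("fij,fij->f", centered, centered)
    out = np.zeros((f, f))
    for i in range(f - 1):
        h = np.einsum("ak,jal->jkl", centered[i], centered[i + 1:])
        s = np.linalg.svd(h, compute_uv=False)
        det = np.linalg.det(h)
        d = np.sum(s[:, :2], axis=1) + np.sign(det) * s[:, 2]
        sq = np.maximum((gram[i] + gram[i + 1:] - 2.0 * d) / n, 0.0)
        out[i, i + 1:] = out[i + 1:, i] = np.sqrt(sq)
    return out


@dataclass
class ClusterResult:
    assignment: np.ndarray   # frame -> cluster id (0 = most populated first found)
    centers: np.ndarray      # representative frame per cluster
    populations: np.ndarray  # fraction per cluster

    def __post_init__(self):
        if not np.isclose(self.populations.sum(), 1.0):
            raise ValueError("cluster populations must sum to 1")


def gromos_cluster(
    ensemble: ConformationalEnsemble,
    selection: Selection = CA,
    cutoff: float = 2.0,
) -> ClusterResult:
    """Greedy neighbour-count (GROMOS/Daura) clustering at ``cutoff`` A.

    Repeatedly takes the unassigned frame with the most unassigned
    neighbours within ``cutoff`` superposed RMSD as a cluster centre,
    assigns it and its neighbours, removes them, and repeats.  Ties are
    broken toward the lowest frame index, making the result
    deterministic.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames to cluster")
    m = selection.mask(ensemble.atoms)
    dist = pairwise_rmsd(ensemble.coords[:, m, :])
    adj = dist <= cutoff
    np.fill_diagonal(adj, True)
    n = ensemble.n_frames
    assignment = np.full(n, -1, dtype=int)
    centers, sizes = [], []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (adj & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))   # argmax takes the first (lowest) index
        members = np.where(adj[center] & remaining)[0]
        assignment[members] = cid
        centers.append(center)
        sizes.append(members.size)
        remaining[members] = False
        cid += 1
    return ClusterResult(
        assignment=assignment,
        centers=np.asarray(centers),
        populations=np.asarray(sizes, dtype=float) / n,
    )


# ---------------------------------------------------------------------------
# distance counters

_HBOND_ELEMENTS = {"N", "O"}


def hbond_count(
    ensemble: ConformationalEnsemble,
    frame: int,
    selection_a: Selection,
    selection_b: Selection,
    cutoff: float = 3.4,
) -> int:
    """Distance-only hydrogen-bond count between two disjoint selections.

    Counts N/O-N/O heavy-atom pairs across the selections at distance
    <= ``cutoff`` A, with no angle restriction.
    """
    ma = selection_a.mask(ensemble.atoms)
    mb = selection_b.mask(ensemble.atoms)
    if np.any(ma & mb):
        raise ValueError("selections must be disjoint")
    el = ensemble.atoms["element"].str.upper().to_numpy()
    polar = np.isin(el, list(_HBOND_ELEMENTS))
    xa = ensemble.coords[frame][ma & polar]
    xb = ensemble.coords[frame][mb & polar]
    if xa.size == 0 or xb.size == 0:
        return 0
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return int(np.count_nonzero(d <= cutoff))


def contact_metrics(
    ensemble: ConformationalEnsemble,
    frame: int,
    selection_a: Selection,
    selection_b: Selection,
    cutoff: float = 6.0,
) -> tuple[int, float]:
    """Carbon-carbon contacts between selections and the minimum distance.

    Returns ``(count of C-C pairs within cutoff, overall minimum C-C
    distance in A)``; the minimum is reported even when it exceeds the
    cutoff.
    """
    ma = selection_a.mask(ensemble.atoms)
    mb = selection_b.mask(ensemble.atoms)
    el = ensemble.atoms["element"].str.upper().to_numpy()
    carbon = el == "C"
    xa = ensemble.coords[frame][ma & carbon]
    xb = ensemble.coords[frame][mb & carbon]
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both selections must contain carbon atoms")
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return int(np.count_nonzero(d <= cutoff)), float(d.min())


# ---------------------------------------------------------------------------
# pKa populations

@dataclass(frozen=True)
class PkaSeries:
    """Per-frame pKa values of one residue along a trajectory."""

    residue: str
    times_ps: np.ndarray
    pka: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_ps, dtype=float)
        p = np.asarray(self.pka, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and pKa values must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_ps", t)
        object.__setattr__(self, "pka", p)

    def __len__(self) -> int:
        return self.pka.size

    @classmethod
    def from_csv(cls, path, residue: str) -> "PkaSeries":
        df = pd.read_csv(path)
        sub = df[df["residue"] == residue].sort_values("time_ps")
        if sub.empty:
            raise ValueError(f"no rows for residue {residue!r}")
        return cls(residue, sub["time_ps"].to_numpy(), sub["pka"].to_numpy())


@dataclass
class PopulationDecomposition:
    """Gaussian mixture summary of a pKa series (components mean-sorted)."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray   # (frames, components)
    bic: float
    low_pka_fraction: float        # frames assigned to the lowest-mean component
    degenerate: bool = False


def pka_populations(
    series: PkaSeries,
    max_components: int = 3,
    seed: int = 0,
) -> PopulationDecomposition:
    """Decompose a per-frame pKa series into Gaussian populations.

    Fits mixtures with 1..``max_components`` components by EM (20
    restarts each, seeded), selects the component count by BIC, and
    reports mean-sorted components plus the fraction of frames whose
    maximum responsibility falls in the lowest-mean ("catalytically
    compatible") population.  A constant series short-circuits to a
    single zero-variance population flagged degenerate.
    """
    x = series.pka
    if x.size < 50:
        raise ValueError("need at least 50 frames for population decomposition")
    if np.ptp(x) == 0.0:
        return PopulationDecomposition(
            n_components=1, means=np.array([x[0]]), sds=np.array([0.0]),
            weights=np.array([1.0]),
            responsibilities=np.ones((x.size, 1)), bic=np.nan,
            low_pka_fraction=1.0, degenerate=True,
        )
    data = x.reshape(-1, 1)
    best = None
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, n_init=20, random_state=seed,
            covariance_type="full", reg_covar=1e-6,
        ).fit(data)
        bic = gm.bic(data)
        if best is None or bic < best[0]:
            best = (bic, gm)
    bic, gm = best
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])
    weights = gm.weights_[order]
    resp = gm.predict_proba(data)[:, order]
    low_fraction = float(np.mean(resp.argmax(axis=1) == 0))
    return PopulationDecomposition(
        n_components=means.size, means=means, sds=sds, weights=weights,
        responsibilities=resp, bic=float(bic), low_pka_fraction=low_fraction,
    )
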