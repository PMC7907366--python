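"""Dihedral PCA, free-energy surfaces, basin analysis, and Kabsch RMSD.

The flexibility analysis layer: backbone dihedral time series are
embedded on the unit circle (cos/sin per angle, the circular-statistics
-safe representation), decomposed by PCA, and the first two principal
coordinates are histogrammed into a Boltzmann-inverted free-energy
surface ``dG = -kB*T*ln(p/p_max)``.  Conformational basins are local
minima of the surface; their relative occupancy and the level-set
flooding barrier between them quantify how the population splits
between conformers and how easily they interconvert.  Kabsch
superposition RMSD provides the companion structure-to-structure
distance measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic_traj import DihedralTrajectory

__all__ = [
    "KB_KJ_PER_MOL_K",
    "DPCAResult",
    "FreeEnergySurface",
    "Basin",
    "BasinSet",
    "sincos_embed",
    "dpca",
    "fes_histogram",
    "find_basins",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsd_matrix",
]

#: Boltzmann constant in kJ/(mol K); kB*300 K = 2.4944 kJ/mol.
KB_KJ_PER_MOL_K = 0.0083145


# ---------------------------------------------------------------------------
# Dihedral PCA
# ---------------------------------------------------------------------------

def sincos_embed(traj: DihedralTrajectory | np.ndarray) -> np.ndarray:
    """Map each angle theta to (cos theta, sin theta).

    Columns are interleaved ``cos_1, sin_1, cos_2, sin_2, ...`` so every
    angle contributes one unit-norm pair per frame.
    """
    angles = traj.angles if isinstance(traj, DihedralTrajectory) else np.asarray(traj)
    if angles.ndim != 2:
        raise ValueError("angles must be a frames x dihedrals matrix")
    n_frames, n_dih = angles.shape
    out = np.empty((n_frames, 2 * n_dih))
    out[:, 0::2] = np.cos(angles)
    out[:, 1::2] = np.sin(angles)
    return out


@dataclass
class DPCAResult:
    """Eigendecomposition of the embedded covariance.

    ``components`` holds one orthonormal basis vector per column,
    ordered by descending eigenvalue; ``projections`` are the frame
    coordinates on the first two components.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    projections: np.ndarray
    total_variance: float


def dpca(embedded: np.ndarray) -> DPCAResult:
    """PCA of the mean-centred sin/cos-embedded trajectory."""
    X = np.asarray(embedded, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a frames x features matrix with >= 2 frames")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(np.trace(cov))
    if total <= 1e-15:
        warnings.warn("constant trajectory: all eigenvalues are zero", stacklevel=2)
    return DPCAResult(
        eigenvalues=evals,
        components=evecs,
        projections=Xc @ evecs[:, :2],
        total_variance=total,
    )


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Boltzmann-inverted 2-D histogram over the first two components.

    ``grid`` is a masked array of dG in kJ/mol (masked where the
    histogram is empty); the global unmasked minimum is exactly 0.
    """

    grid: np.ma.MaskedArray
    bin_edges: tuple[np.ndarray, np.ndarray]
    temperature_K: float = 300.0
    kB: float = KB_KJ_PER_MOL_K
    counts: np.ndarray | None = None

    @property
    def kT(self) -> float:
        return self.kB * self.temperature_K


def fes_histogram(projections: np.ndarray, bins: int = 60,
                  temperature_K: float = 300.0) -> FreeEnergySurface:
    """Free-energy surface ``dG = -kB*T*ln(p / p_max)`` from projections.

    Bins with zero counts are masked rather than assigned infinite dG;
    the most populated bin defines dG = 0.  dG is invariant to uniform
    rescaling of the counts.
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2 or P.shape[0] < 1:
        raise ValueError("projections must be a frames x 2 array")
    counts, xe, ye = np.histogram2d(P[:, 0], P[:, 1], bins=bins)
    pmax = counts.max()
    with np.errstate(divide="ignore"):
        grid = -KB_KJ_PER_MOL_K * temperature_K * np.log(counts / pmax)
    masked = np.ma.masked_array(grid, mask=counts == 0)
    return FreeEnergySurface(
        grid=masked, bin_edges=(xe, ye), temperature_K=temperature_K,
        counts=counts)


# ---------------------------------------------------------------------------
# Basin analysis
# ---------------------------------------------------------------------------

@dataclass
class Basin:
    location: tuple[int, int]
    delta_g_kj_mol: float
    occupancy: float


@dataclass
class BasinSet:
    """Conformational basins of a free-energy surface.

    ``occupancy_ratio`` is the probability mass of the dominant basin
    over the second one (None for a single-basin landscape);
    ``barrier_kj_mol`` is the level-set flooding barrier between the
    two dominant minima, measured from the shallower minimum.
    """

    minima: list[Basin]
    occupancies: list[float]
    occupancy_ratio: float | None
    barrier_kj_mol: float | None


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def find_basins(fes: FreeEnergySurface, max_basins: int = 2,
                min_persistence_kj_mol: float = 1.0,
                min_occupancy: float = 0.01) -> BasinSet:
    """Locate basins, their occupancies, and the interconversion barrier.

    Level-set flooding with persistence merging: unmasked bins are
    added in order of increasing dG and joined into catchments; when
    two catchments meet, the shallower one is kept as a separate basin
    only if its persistence (saddle level minus its minimum) reaches
    ``min_persistence_kj_mol`` — otherwise it is a sampling-noise
    wrinkle and is absorbed.  Basins holding less than
    ``min_occupancy`` of the probability mass (isolated sparsely
    sampled islands) are discarded.  Basins are ranked by occupancy;
    ``occupancy_ratio`` is first/second and the barrier is the saddle
    dG at which the secondary basin connects, measured from the
    shallower of the two minima (``None`` when the basins never
    connect, e.g. separated by unsampled bins).
    """
    G = fes.grid.filled(np.inf)
    if not np.any(np.isfinite(G)):
        raise ValueError("free-energy surface has no unmasked bins")
    if fes.counts is not None:
        mass = fes.counts / fes.counts.sum()
    else:  # hand-built surface: Boltzmann-weight the dG values
        with np.errstate(over="ignore"):
            w = np.where(np.isfinite(G), np.exp(-G / fes.kT), 0.0)
        mass = w / w.sum()

    nr, nc = G.shape
    finite = list(zip(*np.nonzero(np.isfinite(G))))
    order = sorted(finite, key=lambda ij: G[ij])
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    set_min: dict[tuple[int, int], tuple[int, int]] = {}
    set_mass: dict[tuple[int, int], float] = {}
    # finalized sub-basins: (minimum bin, mass at merge, saddle level)
    events: list[tuple[tuple[int, int], float, float]] = []

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ij in order:
        ij = (int(ij[0]), int(ij[1]))
        roots = set()
        for di, dj in _NEIGHBORS:
            nb = (ij[0] + di, ij[1] + dj)
            if nb in parent:
                roots.add(find(nb))
        parent[ij] = ij
        if not roots:                      # new local minimum
            set_min[ij] = ij
            set_mass[ij] = float(mass[ij])
            continue
        deepest = min(roots, key=lambda r: G[set_min[r]])
        level = float(G[ij])
        for r in roots:
            if r is deepest:
                continue
            persistence = level - float(G[set_min[r]])
            if persistence >= min_persistence_kj_mol:
                events.append((set_min[r], set_mass[r], level))
            parent[r] = deepest
            set_mass[deepest] += set_mass[r]
        parent[ij] = deepest
        set_mass[deepest] += float(mass[ij])

    survivors = {find(r) for r in set(parent.values())}
    candidates = [(set_min[r], set_mass[find(r)], None) for r in survivors
                  if find(r) == r]
    candidates += [(m, occ, sad) for m, occ, sad in events]
    candidates = [c for c in candidates if c[1] >= min_occupancy]
    candidates.sort(key=lambda c: c[1], reverse=True)
    top = candidates[:max_basins]
    minima = [Basin(location=(int(m[0]), int(m[1])),
                    delta_g_kj_mol=float(G[m]), occupancy=float(occ))
              for m, occ, _ in top]
    occupancies = [b.occupancy for b in minima]

    if len(minima) < 2:
        return BasinSet(minima=minima, occupancies=occupancies,
                        occupancy_ratio=None, barrier_kj_mol=None)
    ratio = occupancies[0] / occupancies[1]
    saddle = top[1][2]
    barrier = None
    if saddle is not None:
        shallower = max(minima[0].delta_g_kj_mol, minima[1].delta_g_kj_mol)
        barrier = float(saddle - shallower)
    return BasinSet(minima=minima, occupancies=occupancies,
                    occupancy_ratio=float(ratio), barrier_kj_mol=barrier)


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def kabsch_rotation(coords_a: np.ndarray, coords_b: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation superposing b onto a.

    Returns ``(R, ca, cb)`` — the rotation matrix (det +1, reflections
    corrected) and the two centroids — such that ``(b - cb) @ R.T + ca``
    best matches ``a`` in the least-squares sense.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have identical shapes")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need N x 3 coordinates with N >= 3")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, ca, cb


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD (same units as the input, conventionally Angstrom) after
    optimal translation + proper rotation."""
    R, ca, cb = kabsch_rotation(coords_a, coords_b)
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    moved = (B - cb) @ R.T + ca
    return float(np.sqrt(np.mean(np.sum((A - moved) ** 2, axis=1))))


def rmsd_matrix(frames: Sequence[np.ndarray]) -> tuple[np.ndarray, float]:
    """Pairwise Kabsch RMSD over a set of structures.

    Returns the symmetric zero-diagonal matrix and its maximum — the
    group-to-group spread statistic used to compare conformational
    variability between conditions.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    m = len(frames)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = kabsch_rmsd(frames[i], frames[j])
    return out, float(out.max())
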