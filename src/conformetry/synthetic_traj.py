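"""Two-state dihedral trajectory generator.

Emulates the statistical structure of a molecular-dynamics dihedral
time series for a protein hopping between two metastable conformations:
a hidden two-state Markov chain (per-frame switch probabilities) with
von Mises angular emissions around state-specific centre vectors.  The
hidden states are kept as ground truth so downstream basin-recovery can
be validated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TrajectoryConfig",
    "DihedralTrajectory",
    "default_state_centers",
    "simulate_markov_states",
    "emit_dihedrals",
    "simulate_trajectory",
    "save_trajectory",
    "load_trajectory",
]


def default_state_centers(n_dihedrals: int = 10, n_shifted: int = 4,
                          shift: float = math.pi / 2.0) -> np.ndarray:
    """Two centre vectors differing by ``shift`` in the first ``n_shifted``
    coordinates — enough angular separation for two clear basins."""
    centers = np.zeros((2, n_dihedrals))
    centers[1, :n_shifted] = shift
    return centers


@dataclass
class TrajectoryConfig:
    """Two-state Markov/von Mises trajectory parameters.

    ``p_ab``/``p_ba`` are per-frame switch probabilities (A->B, B->A);
    ``kappa`` is the von Mises concentration of the angular emissions
    (40 by default: narrow wells, mimicking stable domains with
    flexible-loop variation).
    """

    n_frames: int = 200_000
    n_dihedrals: int = 10
    p_ab: float = 0.005
    p_ba: float = 0.010
    state_centers: np.ndarray | None = None
    kappa: float = 40.0
    seed: int = 0
    frame_dt: float = 1.0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_dihedrals < 1:
            raise ValueError("n_frames and n_dihedrals must be >= 1")
        if not (0.0 <= self.p_ab <= 1.0 and 0.0 <= self.p_ba <= 1.0):
            raise ValueError("switch probabilities must lie in [0, 1]")
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive")
        if self.state_centers is None:
            self.state_centers = default_state_centers(self.n_dihedrals)
        self.state_centers = np.asarray(self.state_centers, dtype=float)
        if self.state_centers.shape != (2, self.n_dihedrals):
            raise ValueError("state_centers must have shape (2, n_dihedrals)")
        if np.allclose(self.state_centers[0], self.state_centers[1]):
            raise ValueError("state centres must differ in at least one angle")


@dataclass
class DihedralTrajectory:
    """Frames x dihedrals angle matrix, wrapped to (-pi, pi]."""

    angles: np.ndarray
    truth_states: np.ndarray | None = None
    frame_dt: float = 1.0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a frames x dihedrals matrix")
        if np.any(self.angles <= -math.pi) or np.any(self.angles > math.pi):
            raise ValueError("angles must be wrapped to (-pi, pi]")
        if self.truth_states is not None and len(self.truth_states) != len(self.angles):
            raise ValueError("truth_states length must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[1]


def _wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap to the half-open interval (-pi, pi]."""
    out = np.mod(a + math.pi, 2.0 * math.pi) - math.pi
    out[out == -math.pi] = math.pi
    return out


def simulate_markov_states(cfg: TrajectoryConfig,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-frame hidden states (0 = A, 1 = B) of the two-state chain.

    The chain starts from its stationary distribution, so occupancy of
    A is ``p_ba / (p_ab + p_ba)`` in expectation from frame 0 on.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    total = cfg.p_ab + cfg.p_ba
    if total == 0.0:
        warnings.warn("p_ab = p_ba = 0: the chain never switches", stacklevel=2)
        return np.zeros(cfg.n_frames, dtype=np.int8)
    pi_a = cfg.p_ba / total
    states = np.empty(cfg.n_frames, dtype=np.int8)
    u = rng.random(cfg.n_frames)
    states[0] = 0 if u[0] < pi_a else 1
    for t in range(1, cfg.n_frames):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < cfg.p_ab else 0
        else:
            states[t] = 0 if u[t] < cfg.p_ba else 1
    return states


def emit_dihedrals(labels: np.ndarray, cfg: TrajectoryConfig,
                   rng: np.random.Generator | None = None) -> DihedralTrajectory:
    """Von Mises angular emissions around each frame's state centre."""
    if not (cfg.kappa > 0):
        raise ValueError("kappa must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    labels = np.asarray(labels)
    mu = cfg.state_centers[labels]          # frames x dihedrals
    angles = rng.vonmises(mu, cfg.kappa)
    return DihedralTrajectory(
        angles=_wrap_angles(angles), truth_states=labels.copy(),
        frame_dt=cfg.frame_dt)


def simulate_trajectory(cfg: TrajectoryConfig) -> DihedralTrajectory:
    """States + emissions from independent substreams of ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    state_rng, emit_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    labels = simulate_markov_states(cfg, rng=state_rng)
    return emit_dihedrals(labels, cfg, rng=emit_rng)


def save_trajectory(traj: DihedralTrajectory, path: str | Path,
                    truth_path: str | Path | None = None) -> None:
    """Plain-text frames x angles matrix (radians); optional truth labels."""
    np.savetxt(path, traj.angles, fmt="%.6f")
    if truth_path is not None and traj.truth_states is not None:
        np.savetxt(truth_path, traj.truth_states, fmt="%d")


def load_trajectory(path: str | Path,
                    truth_path: str | Path | None = None) -> DihedralTrajectory:
    angles = np.loadtxt(path, dtype=float, ndmin=2)
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = np.loadtxt(truth_path, dtype=int)
    return DihedralTrajectory(angles=_wrap_angles(angles), truth_states=truth)
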