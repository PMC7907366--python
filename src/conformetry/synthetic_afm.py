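"""Synthetic AFM height maps with configurable conformer populations.

Emulates tapping-mode images of a small (~13 nm) plasma protein flatly
adsorbed on mica.  Each simulated molecule is either *closed*
(circularised; rendered as an ellipsoidal cap) or *open* (linearised;
rendered as a gently curved rod), with the aspect ratio R =
length/width drawn from a configurable distribution supported on
R >= 1.  The raster adds the dominant instrumental artifacts: a
background plane tilt, per-scan-line height offsets, tip dilation by a
spherical cap, and Gaussian height noise.

Two named population fixtures mirror the experimental conditions of a
disulfide-reduction study of beta-2-glycoprotein I:

* ``reduced``:   R = 1 + LogNormal(mu, sigma) with mean R 2.97 and 35 %
  of molecules above the open threshold R = 3;
* ``untreated``: R = 1 + Weibull(k, lambda) with mean R 2.58 and 25 %
  open (a shifted lognormal admits no real solution for this pair, so
  the shape/scale are solved numerically at import time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .afm_image import HeightMap

__all__ = [
    "ParticleSpec",
    "AspectRatioModel",
    "ScanConfig",
    "reduced_condition_model",
    "untreated_condition_model",
    "untreated_weibull_params",
    "sample_aspect_ratios",
    "sample_population",
    "render_heightmap",
    "TRUTH_COLUMNS",
    "CLOSED_REFERENCE_LENGTH_NM",
]

#: Footprint length of a reference closed molecule (R = 2), anchored to
#: the ~13 nm hydrodynamic diameter of the globular (closed) protein.
CLOSED_REFERENCE_LENGTH_NM = 13.0
_REFERENCE_R = 2.0
#: Elliptical footprint area (nm^2) conserved across shape classes.
FOOTPRINT_AREA_NM2 = math.pi / 4.0 * CLOSED_REFERENCE_LENGTH_NM * (
    CLOSED_REFERENCE_LENGTH_NM / _REFERENCE_R)

_OPEN_THRESHOLD = 3.0
_DEFAULT_HEIGHT_NM = 1.8          # apparent height of a monolayer-adsorbed molecule
_HEIGHT_JITTER_FRAC = 0.10
_MAX_ARC_ANGLE_RAD = 0.25         # mild random curvature of open rods

TRUTH_COLUMNS = [
    "id", "true_class", "R_true", "length_nm", "width_nm",
    "height_nm", "x_nm", "y_nm", "orientation_rad",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Ground-truth geometry of one simulated molecule."""

    true_class: str               # "closed" | "open"
    aspect_ratio_true: float
    length_nm: float
    width_nm: float
    height_nm: float
    centroid: tuple[float, float]  # (x, y) nm
    orientation: float             # radians

    def __post_init__(self):
        if not (self.width_nm > 0 and self.length_nm >= self.width_nm):
            raise ValueError("need length_nm >= width_nm > 0")
        if not (self.height_nm > 0):
            raise ValueError("height_nm must be positive")
        if abs(self.aspect_ratio_true - self.length_nm / self.width_nm) > 1e-9:
            raise ValueError("aspect_ratio_true must equal length/width")


@dataclass
class AspectRatioModel:
    """Distribution family for aspect ratios, supported on R >= 1.

    Families
    --------
    shifted_lognormal: ``R = 1 + exp(N(mu, sigma))``; parameters
        ``mu`` and ``sigma > 0``.
    shifted_weibull: ``R = 1 + Weibull(shape, scale)``; parameters
        ``shape > 0`` and ``scale > 0``.
    two_component: mixture of two shifted lognormals; parameters
        ``weight`` (mass of the second component, in [0, 1]),
        ``mu1, sigma1, mu2, sigma2``.
    """

    family: str
    parameters: dict
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        p = self.parameters
        try:
            if self.family == "shifted_lognormal":
                if not (float(p["sigma"]) > 0):
                    raise ValueError("sigma must be > 0")
                float(p["mu"])
            elif self.family == "shifted_weibull":
                if not (float(p["shape"]) > 0 and float(p["scale"]) > 0):
                    raise ValueError("shape and scale must be > 0")
            elif self.family == "two_component":
                w = float(p["weight"])
                if not (0.0 <= w <= 1.0):
                    raise ValueError("weight must be in [0, 1]")
                if not (float(p["sigma1"]) > 0 and float(p["sigma2"]) > 0):
                    raise ValueError("sigmas must be > 0")
                float(p["mu1"]), float(p["mu2"])
            else:
                raise ValueError(f"unknown family {self.family!r}")
        except KeyError as exc:
            raise ValueError(f"missing parameter {exc} for {self.family}") from exc

    def sample(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be >= 0")
        if rng is None:
            rng = np.random.default_rng(self.seed)
        p = self.parameters
        if self.family == "shifted_lognormal":
            return 1.0 + rng.lognormal(float(p["mu"]), float(p["sigma"]), size=n)
        if self.family == "shifted_weibull":
            return 1.0 + float(p["scale"]) * rng.weibull(float(p["shape"]), size=n)
        # two_component
        pick2 = rng.random(n) < float(p["weight"])
        out = np.where(
            pick2,
            1.0 + rng.lognormal(float(p["mu2"]), float(p["sigma2"]), size=n),
            1.0 + rng.lognormal(float(p["mu1"]), float(p["sigma1"]), size=n),
        )
        return out


@dataclass
class ScanConfig:
    """Imaging geometry and noise model of one simulated scan.

    512 x 512 pixels at 1 nm/px gives a ~0.5 um field, the sampling a
    single-molecule morphometry scan needs for ~13 nm particles; the
    8 nm tip radius sits inside the < 10 nm radius-of-curvature class
    of the probes used for such imaging.
    """

    image_px: int = 512
    pixel_nm: float = 1.0
    tip_radius_nm: float = 8.0
    noise_sigma_nm: float = 0.06
    line_offset_sigma_nm: float = 0.15
    plane_tilt: tuple[float, float] = (0.02, 0.01)  # (a, b) nm/px along (col, row)

    def __post_init__(self):
        if self.image_px <= 0:
            raise ValueError("image_px must be positive")
        if not (self.pixel_nm > 0):
            raise ValueError("pixel_nm must be positive")
        if self.tip_radius_nm < 0:
            raise ValueError("tip_radius_nm must be >= 0")

    @property
    def field_nm(self) -> float:
        return self.image_px * self.pixel_nm


# ---------------------------------------------------------------------------
# Population fixtures
# ---------------------------------------------------------------------------

def reduced_condition_model(seed: int = 0) -> AspectRatioModel:
    """Aspect-ratio fixture for the disulfide-reduced condition.

    Shifted lognormal solved from mean excess E[R-1] = 1.97 (so mean R
    = 2.97) and P(R > 3) = 0.35: exp(mu + sigma^2/2) = 1.97 and
    1 - Phi((ln 2 - mu)/sigma) = 0.35.
    """
    return AspectRatioModel(
        "shifted_lognormal", {"mu": 0.41217, "sigma": 0.72917}, seed=seed)


@lru_cache(maxsize=None)
def untreated_weibull_params(mean_excess: float = 1.58,
                             tail_prob: float = 0.25) -> tuple[float, float]:
    """Solve (shape, scale) of the untreated Weibull fixture.

    Constraints: ``scale * Gamma(1 + 1/k) = mean_excess`` and
    ``P(W > 2) = tail_prob`` i.e. ``exp(-(2/scale)^k) = tail_prob``.
    """
    ln_inv = math.log(1.0 / tail_prob)

    def scale_of(k: float) -> float:
        return 2.0 / ln_inv ** (1.0 / k)

    def f(k: float) -> float:
        return scale_of(k) * special.gamma(1.0 + 1.0 / k) - mean_excess

    k = optimize.brentq(f, 1.05, 25.0, xtol=1e-12)
    return k, scale_of(k)


def untreated_condition_model(seed: int = 0) -> AspectRatioModel:
    """Aspect-ratio fixture for the untreated (oxidised) condition.

    Shifted Weibull with mean R = 2.58 and P(R > 3) = 0.25
    (shape ~2.746, scale ~1.776, solved numerically).
    """
    k, lam = untreated_weibull_params()
    return AspectRatioModel("shifted_weibull", {"shape": k, "scale": lam}, seed=seed)


NAMED_MODELS = {
    "reduced": reduced_condition_model,
    "untreated": untreated_condition_model,
}


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def sample_aspect_ratios(n: int, model: AspectRatioModel,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` aspect ratios i.i.d. from the model (deterministic per seed)."""
    return model.sample(n, rng=rng)


def _geometry_for(R: float) -> tuple[str, float, float]:
    """(class, length, width) for one aspect ratio, conserving footprint area.

    Every molecule is a round-ended tube (stadium footprint) of total
    length L and width W = L/R; the stadium area W*(L-W) + pi/4*W^2 is
    held at A0 so the adsorbed footprint area is conserved across
    classes (R = 1 degenerates to a disk of area A0).  One footprint
    family for both classes keeps the tip-deconvolution edge model
    uniform.
    """
    width = math.sqrt(FOOTPRINT_AREA_NM2 / (R - 1.0 + math.pi / 4.0))
    cls = "closed" if R <= _OPEN_THRESHOLD else "open"
    return cls, R * width, width


def sample_population(
    n: int,
    model: AspectRatioModel,
    geometry_defaults: ScanConfig | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 20000,
) -> list[ParticleSpec]:
    """Sample ``n`` particle specs and place them in one field of view.

    Aspect ratios come from ``model``; the shape class follows the
    R <= 3 / R > 3 rule; widths conserve the footprint area; centroids
    are placed uniformly with a margin and a minimum pairwise spacing so
    tip-dilated footprints never merge.  A single seed (``model.seed``)
    fans out to independent substreams for ratios, geometry jitter and
    placement.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    scan = geometry_defaults or ScanConfig()
    if rng is None:
        ss = np.random.SeedSequence(model.seed)
        r_rng, g_rng, p_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    else:
        r_rng = g_rng = p_rng = rng
    ratios = sample_aspect_ratios(n, model, rng=r_rng)

    specs: list[ParticleSpec] = []
    geoms = [_geometry_for(float(R)) for R in ratios]
    max_len = max((g[1] for g in geoms), default=0.0)
    margin = max_len / 2.0 + scan.tip_radius_nm + 3.0 * scan.pixel_nm
    lo, hi = margin, scan.field_nm - margin
    if n > 0 and hi <= lo:
        raise ValueError("field of view too small for the requested particles")
    min_sep = max_len + 2.0 * scan.tip_radius_nm + 2.0 * scan.pixel_nm

    placed = np.empty((0, 2))
    tries = 0
    while len(specs) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} particles without overlap "
                f"(field {scan.field_nm:.0f} nm, min spacing {min_sep:.0f} nm)")
        tries += 1
        xy = p_rng.uniform(lo, hi, size=2)
        if placed.size and np.min(np.hypot(*(placed - xy).T)) < min_sep:
            continue
        i = len(specs)
        cls, length, width = geoms[i]
        h = _DEFAULT_HEIGHT_NM * (1.0 + _HEIGHT_JITTER_FRAC * g_rng.standard_normal())
        h = max(h, 0.3 * _DEFAULT_HEIGHT_NM)
        specs.append(ParticleSpec(
            true_class=cls,
            aspect_ratio_true=length / width,
            length_nm=length,
            width_nm=width,
            height_nm=h,
            centroid=(float(xy[0]), float(xy[1])),
            orientation=float(p_rng.uniform(0.0, math.pi)),
        ))
        placed = np.vstack([placed, xy])
    return specs


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _centerline_distance(u, v, length, width, arc_angle):
    """Distance from local coordinates to the particle centreline.

    The centreline is a circular arc of arclength ``length - width``
    (so the *total* support length including the round end caps is
    ``length``) subtending ``arc_angle`` radians, tangent to the local
    u-axis at its midpoint; ``arc_angle -> 0`` gives a straight
    segment and ``length -> width`` a point (disk footprint).
    """
    seg = max(length - width, 0.0)
    if arc_angle < 1e-6 or seg <= 0.0:
        du = np.maximum(np.abs(u) - seg / 2.0, 0.0)
        return np.hypot(du, v)
    rho = seg / arc_angle
    # curvature centre at (0, rho) in local coordinates
    dv = rho - v
    rr = np.hypot(u, dv)
    theta = np.arctan2(u, dv)
    half = arc_angle / 2.0
    on_arc = np.abs(theta) <= half
    d = np.abs(rr - rho)
    # distance to the nearer arc endpoint outside the angular range
    end_u, end_v = rho * math.sin(half), rho - rho * math.cos(half)
    alt = np.minimum(np.hypot(u - end_u, v - end_v),
                     np.hypot(u + end_u, v - end_v))
    return np.where(on_arc, d, alt)


def _tube_profile(width, height, tip_radius_nm, dx=0.02):
    """Radial height profile of a (tip-dilated) tube.

    Returns ``(radii, heights)`` with the elliptical-cap cross-section
    ``z = h*sqrt(1 - (2 d/W)^2)`` grayscale-dilated by the spherical
    tip cap in 1-D.  Because both the tube and the tip are rotationally
    symmetric around the centreline, applying this profile to the
    centreline distance reproduces the continuous 2-D dilation exactly
    (and dilation commutes with the max-combine of nearby particles).
    """
    b = width / 2.0
    span = b + tip_radius_nm + 1.0
    x = np.arange(-span, span + dx, dx)
    f = np.zeros_like(x)
    inside = np.abs(x) < b
    f[inside] = height * np.sqrt(1.0 - (x[inside] / b) ** 2)
    if tip_radius_nm > 0:
        o = np.arange(-tip_radius_nm, tip_radius_nm + dx, dx)
        cap = np.sqrt(np.maximum(tip_radius_nm**2 - o**2, 0.0)) - tip_radius_nm
        f = ndimage.grey_dilation(f, footprint=np.ones(o.size, dtype=bool),
                                  structure=cap)
    keep = x >= 0.0
    return x[keep], f[keep]


def render_heightmap(
    specs: Sequence[ParticleSpec],
    scan: ScanConfig,
    seed: int | None = 0,
) -> tuple[HeightMap, pd.DataFrame]:
    """Rasterise particle specs into a simulated raw AFM image.

    Pipeline: ideal footprints (max-combined) -> grayscale dilation by
    the spherical tip cap -> background plane tilt -> per-scan-line
    offsets -> Gaussian height noise.  Returns the map plus the
    ground-truth table (one row per spec).  ``seed`` drives curvature,
    line offsets and noise; ``None`` disables noise and offsets.
    """
    npx = scan.image_px
    surface = np.zeros((npx, npx))
    rng = np.random.default_rng(seed) if seed is not None else None

    rows = []
    for i, sp in enumerate(specs):
        x0, y0 = sp.centroid
        half_extent = (sp.length_nm / 2.0 + sp.width_nm / 2.0
                       + scan.tip_radius_nm + 2.0 * scan.pixel_nm)
        if (x0 - half_extent < 0 or y0 - half_extent < 0
                or x0 + half_extent > scan.field_nm
                or y0 + half_extent > scan.field_nm):
            raise ValueError(
                f"particle {i} (length {sp.length_nm:.1f} nm at "
                f"({x0:.0f}, {y0:.0f}) nm) does not fit in the "
                f"{scan.field_nm:.0f} nm field of view")
        c0 = max(int((x0 - half_extent) / scan.pixel_nm), 0)
        c1 = int(np.ceil((x0 + half_extent) / scan.pixel_nm)) + 1
        r0 = max(int((y0 - half_extent) / scan.pixel_nm), 0)
        r1 = int(np.ceil((y0 + half_extent) / scan.pixel_nm)) + 1
        cols = (np.arange(c0, min(c1, npx)) + 0.5) * scan.pixel_nm - x0
        rws = (np.arange(r0, min(r1, npx)) + 0.5) * scan.pixel_nm - y0
        X, Y = np.meshgrid(cols, rws)
        ct, st = math.cos(sp.orientation), math.sin(sp.orientation)
        u = X * ct + Y * st
        v = -X * st + Y * ct
        if sp.true_class == "open" and rng is not None:
            arc = rng.uniform(0.0, _MAX_ARC_ANGLE_RAD)
        else:
            arc = 0.0
        d = _centerline_distance(u, v, sp.length_nm, sp.width_nm, arc)
        radii, profile = _tube_profile(sp.width_nm, sp.height_nm,
                                       scan.tip_radius_nm)
        z = np.interp(d, radii, profile, right=0.0)
        sl = np.s_[r0:min(r1, npx), c0:min(c1, npx)]
        surface[sl] = np.maximum(surface[sl], z)
        rows.append([i, sp.true_class, sp.aspect_ratio_true, sp.length_nm,
                     sp.width_nm, sp.height_nm, x0, y0, sp.orientation])

    vals = surface

    a, b = scan.plane_tilt
    cols_idx, rows_idx = np.meshgrid(np.arange(npx), np.arange(npx))
    vals = vals + a * cols_idx + b * rows_idx
    if rng is not None:
        if scan.line_offset_sigma_nm > 0:
            vals = vals + rng.normal(0.0, scan.line_offset_sigma_nm, npx)[:, None]
        if scan.noise_sigma_nm > 0:
            vals = vals + rng.normal(0.0, scan.noise_sigma_nm, (npx, npx))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return HeightMap(vals, scan.pixel_nm, provenance="synthetic"), truth
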