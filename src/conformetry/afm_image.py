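"""Single-particle morphometry of AFM height maps.

Turns a raw height map into a table of per-particle measurements and
open/closed conformation labels.  The pipeline is the standard one for
single molecules flatly adsorbed on mica: line-by-line background
levelling, robust thresholding, connected-component segmentation, and
moment-based shape measurement.  The conformational readout is the
particle aspect ratio R = length / width: compact (circularised)
molecules sit near R = 1, elongated (linearised) molecules extend up to
R ~ 10, and R = 3 separates the two classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure as skmeasure

__all__ = [
    "HeightMap",
    "ParticleRecord",
    "SegmentationResult",
    "read_heightmap",
    "write_heightmap",
    "flatten",
    "segment",
    "measure_particle",
    "measure_particles",
    "classify_conformation",
    "spherical_cap_element",
    "tip_dilate",
    "tip_correct",
    "TipDeconvolver",
    "analyze_heightmap",
    "CLOSED_OPEN_THRESHOLD",
    "MAX_ASPECT_RATIO",
]

#: Aspect-ratio boundary between the closed and the open conformation.
CLOSED_OPEN_THRESHOLD = 3.0
#: Particles above this aspect ratio are treated as aggregates/artifacts.
MAX_ASPECT_RATIO = 10.0

_MAD_TO_SIGMA = 1.4826  # normal-consistent scale factor for the MAD


@dataclass
class HeightMap:
    """A 2-D raster of surface heights with a physical pixel size.

    Parameters
    ----------
    values:
        Rectangular array of heights in nanometres.
    pixel_nm:
        Physical edge length of one (square) pixel, nm.
    provenance:
        Free-text description of where the map came from.
    """

    values: np.ndarray
    pixel_nm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("height map must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("height map contains non-finite values")
        if not (self.pixel_nm > 0):
            raise ValueError("pixel_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray, note: str = "") -> "HeightMap":
        prov = self.provenance if not note else f"{self.provenance}|{note}".lstrip("|")
        return HeightMap(values=values, pixel_nm=self.pixel_nm, provenance=prov)


@dataclass
class ParticleRecord:
    """One segmented molecule and its shape descriptors."""

    id: int
    area_nm2: float
    length_nm: float
    width_nm: float
    aspect_ratio: float
    max_height_nm: float
    centroid_px: tuple[float, float]
    touches_border: bool
    label: str  # "closed" | "open" | "excluded"


RECORD_COLUMNS = [
    "id",
    "area_nm2",
    "length_nm",
    "width_nm",
    "aspect_ratio",
    "max_height_nm",
    "centroid_row_px",
    "centroid_col_px",
    "touches_border",
    "label",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.toml")


def _read_sidecar(path: Path) -> dict:
    import tomllib

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return {}
    with open(sidecar, "rb") as fh:
        return tomllib.load(fh)


def read_heightmap(path: str | Path, pixel_nm: float | None = None) -> HeightMap:
    """Read a height map from float TIFF or a plain-text matrix.

    The pixel size is resolved from, in order of precedence, the
    ``pixel_nm`` argument and a ``<name>.meta.toml`` sidecar file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(path), dtype=float)
    else:
        values = np.loadtxt(path, dtype=float)
    if values.ndim == 1:  # single-row text matrix
        values = values[None, :]

    meta = _read_sidecar(path)
    if pixel_nm is None:
        pixel_nm = meta.get("pixel_nm")
    if pixel_nm is None:
        raise ValueError(
            f"pixel size for {path} not given and no sidecar entry found"
        )
    provenance = meta.get("provenance", str(path))
    return HeightMap(values=values, pixel_nm=float(pixel_nm), provenance=provenance)


def write_heightmap(hmap: HeightMap, path: str | Path) -> Path:
    """Write a height map (32-bit float TIFF or text matrix) plus sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hmap.values.astype(np.float32))
    else:
        np.savetxt(path, hmap.values, fmt="%.6f")
    sidecar = _sidecar_path(path)
    prov = hmap.provenance.replace('"', "'")
    sidecar.write_text(
        f'pixel_nm = {hmap.pixel_nm!r}\nprovenance = "{prov}"\n'
    )
    return path


# ---------------------------------------------------------------------------
# Background levelling
# ---------------------------------------------------------------------------

def _robust_polyfit(x: np.ndarray, y: np.ndarray, order: int,
                    n_iter: int = 3) -> np.ndarray:
    """Polynomial background fit excluding pixels > 3 sigma above the fit.

    Particles only stick *up* from the surface, so the rejection is
    one-sided.  Returns the fitted background evaluated at ``x``.
    """
    mask = np.ones_like(y, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        eff_order = order
        while mask.sum() <= eff_order + 1 and eff_order > 0:
            eff_order -= 1  # degenerate line: fall back toward order 0
        if mask.sum() == 0:
            mask = np.ones_like(y, dtype=bool)
        coef = np.polynomial.polynomial.polyfit(x[mask], y[mask], eff_order)
        fit = np.polynomial.polynomial.polyval(x, coef)
        resid = y - fit
        sigma = _MAD_TO_SIGMA * np.median(np.abs(resid[mask] - np.median(resid[mask])))
        if sigma <= 0:
            break
        mask = resid <= 3.0 * sigma
    return fit


def flatten(hmap: HeightMap, line_order: int = 1) -> HeightMap:
    """Remove per-scan-line background and the residual global plane.

    Each scan line (image row) gets a polynomial of ``line_order``
    fitted to background pixels (pixels more than 3 sigma above the fit
    are iteratively excluded so particles do not bias the background)
    and subtracted.  A global least-squares plane over background
    pixels is then removed and the background median set to zero.
    """
    if line_order not in (0, 1, 2):
        raise ValueError("line_order must be 0, 1 or 2")
    vals = hmap.values.copy()
    ncols = vals.shape[1]
    x = np.arange(ncols, dtype=float)
    for i in range(vals.shape[0]):
        vals[i] -= _robust_polyfit(x, vals[i], line_order)

    # global plane on background pixels (one-sided 3 sigma rejection)
    rows, cols = np.indices(vals.shape)
    design = np.column_stack([np.ones(vals.size), cols.ravel(), rows.ravel()])
    flat = vals.ravel()
    mask = np.ones(vals.size, dtype=bool)
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(design[mask], flat[mask], rcond=None)
        fit = design @ coef
        resid = flat - fit
        sigma = _MAD_TO_SIGMA * np.median(np.abs(resid[mask] - np.median(resid[mask])))
        if sigma <= 0:
            break
        mask = resid <= 3.0 * sigma
    vals = (flat - fit).reshape(vals.shape)

    bg = vals[mask.reshape(vals.shape)] if mask.any() else vals
    vals -= np.median(bg)
    return hmap.copy_with(vals, note=f"flatten(order={line_order})")


# ---------------------------------------------------------------------------
# Tip geometry
# ---------------------------------------------------------------------------

def spherical_cap_element(tip_radius_nm: float, pixel_nm: float
                          ) -> tuple[np.ndarray, np.ndarray] | None:
    """Structuring element for a spherical AFM tip of given radius.

    Returns ``(footprint, structure)`` for grayscale morphology, where
    the structure holds the tip profile ``sqrt(r^2 - d^2) - r`` (apex at
    0, sagging to ``-r`` at the rim), or ``None`` for a zero radius
    (identity element).
    """
    if tip_radius_nm < 0:
        raise ValueError("tip radius must be non-negative")
    if tip_radius_nm == 0:
        return None
    half = int(math.ceil(tip_radius_nm / pixel_nm))
    dx = np.arange(-half, half + 1) * pixel_nm
    d2 = dx[:, None] ** 2 + dx[None, :] ** 2
    footprint = d2 <= tip_radius_nm**2
    structure = np.where(
        footprint, np.sqrt(np.maximum(tip_radius_nm**2 - d2, 0.0)) - tip_radius_nm, 0.0
    )
    return footprint, structure


def tip_dilate(hmap: HeightMap, tip_radius_nm: float) -> HeightMap:
    """Grayscale dilation by a spherical tip cap (tip-convolution model).

    Models the apparent broadening introduced by the finite tip: the
    imaged surface is the locus of the tip apex as the tip touches the
    sample, i.e. the grayscale dilation of the true topography by the
    reflected tip shape.  Output >= input everywhere.
    """
    elem = spherical_cap_element(tip_radius_nm, hmap.pixel_nm)
    if elem is None:
        return hmap.copy_with(hmap.values.copy(), note="tip_dilate(r=0)")
    footprint, structure = elem
    out = ndimage.grey_dilation(hmap.values, footprint=footprint, structure=structure)
    return hmap.copy_with(out, note=f"tip_dilate(r={tip_radius_nm})")


def tip_correct(hmap: HeightMap, tip_radius_nm: float) -> HeightMap:
    """Erosion-based tip correction (certainty-map surface reconstruction).

    Eroding the imaged (tip-dilated) map by the same spherical cap
    yields the morphological opening of the true surface — the tightest
    surface the tip can certify, with the dilation-induced lateral
    broadening removed.  Narrow features keep their footprint but lose
    apparent height (the tip cannot reach their base); this is the
    standard, physically honest inverse of tip convolution.
    """
    elem = spherical_cap_element(tip_radius_nm, hmap.pixel_nm)
    if elem is None:
        return hmap.copy_with(hmap.values.copy(), note="tip_correct(r=0)")
    footprint, structure = elem
    out = ndimage.grey_erosion(hmap.values, footprint=footprint, structure=structure)
    return hmap.copy_with(out, note=f"tip_correct(r={tip_radius_nm})")


class TipDeconvolver:
    """Model-based removal of tip broadening from particle extents.

    The imaged footprint of a round-ended tube (elliptical cross-
    section, half-width b, height h) is broadened laterally by tip
    dilation; the broadening at a given contour level is identical for
    the length and the width direction because both ends and sides
    present the same edge profile.  Consequently ``L_obs - W_obs``
    equals the true ``L - W`` and only the width needs inverting.  The
    forward model — 1-D grayscale dilation of the cross-section by the
    spherical tip cap, Gaussian-smoothed like the measured image, read
    at the measurement level — is tabulated over (b, h) and inverted by
    monotone interpolation.

    Parameters
    ----------
    tip_radius_nm:
        Tip radius used for the dilation model (0 disables correction).
    smooth_sigma_nm:
        Gaussian pre-smoothing applied to the image before contouring;
        included in the forward model.
    level_frac:
        Measurement contour level as a fraction of the particle's
        (smoothed) maximum height; 0.3 keeps the contour well above the
        noise floor but close to the base footprint.
    """

    def __init__(self, tip_radius_nm: float, smooth_sigma_nm: float = 1.0,
                 level_frac: float = 0.3,
                 b_grid: np.ndarray | None = None,
                 h_grid: np.ndarray | None = None) -> None:
        if tip_radius_nm < 0:
            raise ValueError("tip radius must be non-negative")
        self.tip_radius_nm = float(tip_radius_nm)
        self.smooth_sigma_nm = float(smooth_sigma_nm)
        self.level_frac = float(level_frac)
        self.b_grid = np.arange(0.4, 9.01, 0.2) if b_grid is None else b_grid
        self.h_grid = np.arange(0.6, 3.21, 0.1) if h_grid is None else h_grid
        # width_table[i, j]: observed width; peak_table[i, j]: observed
        # (smoothed) peak height; end_table[i, j]: observed end-cap
        # extent — for true b_grid[j], h_grid[i]
        wt, pt, et = [], [], []
        for h in self.h_grid:
            row = [self._forward(b, h) for b in self.b_grid]
            wt.append([2.0 * w for w, _ in row])
            pt.append([p for _, p in row])
            et.append([2.0 * self._forward_end(b, h, self.level_frac * p)
                       for (_, p), b in zip(row, self.b_grid)])
        self._width_table = np.array(wt)
        self._peak_table = np.array(pt)
        self._end_table = np.array(et)

    def _forward(self, b: float, h: float, dx: float = 0.05
                 ) -> tuple[float, float]:
        """(half extent at the measurement level, smoothed peak) of the
        dilated, Gaussian-smoothed cross-section of a tube (b, h)."""
        r = self.tip_radius_nm
        sigma = self.smooth_sigma_nm
        span = b + r + 4.0 * sigma + 2.0
        x = np.arange(-span, span + dx, dx)
        f = np.zeros_like(x)
        inside = np.abs(x) < b
        f[inside] = h * np.sqrt(1.0 - (x[inside] / b) ** 2)
        if r > 0:
            o = np.arange(-r, r + dx, dx)
            cap = np.sqrt(np.maximum(r**2 - o**2, 0.0)) - r
            f = ndimage.grey_dilation(
                f, footprint=np.ones(o.size, dtype=bool), structure=cap)
        if sigma > 0:
            f = ndimage.gaussian_filter1d(f, sigma / dx)
        peak = float(f.max())
        # the measurement contours at level_frac * observed peak, so the
        # model must read its crossing at the same (observable) level
        level = self.level_frac * peak
        above = np.nonzero(f >= level)[0]
        if above.size == 0:
            return 0.0, peak
        i = above[-1]
        if i == x.size - 1:
            return float(x[-1]), peak
        frac = (f[i] - level) / (f[i] - f[i + 1])
        return float(x[i] + frac * dx), peak

    def _forward_end(self, b: float, h: float, level: float,
                     dx: float = 0.1) -> float:
        """Crossing distance at a round end cap.

        In plan view the tube end is a half-disk, so the local surface
        is a dome: the isotropic Gaussian smoothing erodes it more than
        the translation-invariant side ridge.  Modelled by applying the
        dilated radial profile to a 2-D radial field, smoothing in 2-D,
        and reading the crossing along a radial slice at the given
        absolute level (the level is set by the particle's ridge peak,
        which is what the measurement observes).
        """
        r = self.tip_radius_nm
        sigma = self.smooth_sigma_nm
        span = b + r + 4.0 * sigma + 2.0
        xf = np.arange(0.0, span + 0.02, 0.02)
        prof = np.zeros_like(xf)
        inside = xf < b
        prof[inside] = h * np.sqrt(1.0 - (xf[inside] / b) ** 2)
        if r > 0:
            o = np.arange(-r, r + 0.02, 0.02)
            cap = np.sqrt(np.maximum(r**2 - o**2, 0.0)) - r
            full = np.concatenate([prof[::-1][:-1], prof])
            full = ndimage.grey_dilation(
                full, footprint=np.ones(o.size, dtype=bool), structure=cap)
            prof = full[xf.size - 1:]
        x = np.arange(-span, span + dx, dx)
        rho = np.hypot(x[:, None], x[None, :])
        field = np.interp(rho, xf, prof, right=0.0)
        if sigma > 0:
            field = ndimage.gaussian_filter(field, sigma / dx)
        slice_ = field[x.size // 2]
        above = np.nonzero(slice_ >= level)[0]
        if above.size == 0:
            return 0.0
        i = above[-1]
        if i == x.size - 1:
            return float(x[-1])
        frac = (slice_[i] - level) / (slice_[i] - slice_[i + 1])
        return float(x[i] + frac * dx)

    def _rows(self, h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = float(np.clip(h, self.h_grid[0], self.h_grid[-1]))
        k = int(np.clip(np.searchsorted(self.h_grid, h) - 1, 0,
                        self.h_grid.size - 2))
        t = (h - self.h_grid[k]) / (self.h_grid[k + 1] - self.h_grid[k])
        return ((1.0 - t) * self._width_table[k] + t * self._width_table[k + 1],
                (1.0 - t) * self._peak_table[k] + t * self._peak_table[k + 1],
                (1.0 - t) * self._end_table[k] + t * self._end_table[k + 1])

    def correct(self, length_obs: float, width_obs: float, peak_obs: float
                ) -> tuple[float, float, float]:
        """Invert observed (length, width, smoothed peak) to true
        (length, width, R).

        Iterates the true height so that the model's smoothed peak
        matches the observed one (smoothing lowers narrow ridges), then
        inverts the monotone width prediction; the length follows from
        the broadening-cancellation identity ``L - W = L_obs - W_obs``.
        """
        h_true = peak_obs
        width = width_obs
        end_deficit = 0.0
        for _ in range(3):
            pred_w, pred_p, pred_e = self._rows(h_true)
            width = float(np.interp(width_obs, pred_w, 2.0 * self.b_grid,
                                    left=2.0 * self.b_grid[0],
                                    right=2.0 * self.b_grid[-1]))
            peak_model = float(np.interp(width, 2.0 * self.b_grid, pred_p))
            # smoothing erodes the plan-convex end caps more than the
            # straight sides; restore the difference to the length
            end_deficit = float(np.interp(width, 2.0 * self.b_grid,
                                          pred_w - pred_e))
            h_true = float(np.clip(h_true + (peak_obs - peak_model),
                                   self.h_grid[0], self.h_grid[-1]))
        length = max(width + (length_obs - width_obs) + end_deficit, width)
        return length, width, max(length / width, 1.0)


def _support_extents(mask: np.ndarray, pixel_nm: float) -> tuple[float, float]:
    """(length, width) support extents along the principal axes of a mask."""
    pts = np.argwhere(mask).astype(float) * pixel_nm
    if pts.shape[0] == 1:
        return pixel_nm, pixel_nm
    X = pts - pts.mean(axis=0)
    cov = X.T @ X / X.shape[0]
    _, evecs = np.linalg.eigh(cov)
    proj = X @ evecs            # columns: minor axis, major axis
    wext = float(np.ptp(proj[:, 0])) + pixel_nm
    lext = float(np.ptp(proj[:, 1])) + pixel_nm
    return max(lext, wext), min(lext, wext)


def _contour_extents(image: np.ndarray, mask: np.ndarray, level: float,
                     pixel_nm: float) -> tuple[float, float] | None:
    """Sub-pixel (length, width) extents of the level contour around a
    component.

    Marching-squares contours interpolate the level crossing between
    pixels, so the extents are not quantised to whole pixels — at small
    particle widths that sub-pixel accuracy is what makes the tip
    deconvolution well conditioned.
    """
    rr, cc = np.nonzero(mask)
    pad = 3
    r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad + 1, image.shape[0])
    c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad + 1, image.shape[1])
    window = image[r0:r1, c0:c1]
    contours = skmeasure.find_contours(window, level)
    if not contours:
        return None
    pts = max(contours, key=len) * pixel_nm
    X = pts - pts.mean(axis=0)
    cov = X.T @ X / X.shape[0]
    _, evecs = np.linalg.eigh(cov)
    proj = X @ evecs
    wext = float(np.ptp(proj[:, 0]))
    lext = float(np.ptp(proj[:, 1]))
    if lext < wext:
        lext, wext = wext, lext
        proj = proj[:, ::-1]
    # for elongated particles the half-width is constant along the
    # straight section: a median over it beats the extreme-value-biased
    # point-to-point spread
    half_straight = (lext - wext) / 2.0 - pixel_nm
    if half_straight > 0:
        sel = np.abs(proj[:, 1]) <= half_straight
        if sel.sum() >= 6:
            wext = float(2.0 * np.median(np.abs(proj[sel, 0])))
    return lext, wext


# ---------------------------------------------------------------------------
# Segmentation and measurement
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    labels: np.ndarray          # int label image, 0 = background
    n_components: int
    threshold_nm: float
    background_sigma_nm: float


def segment(hmap: HeightMap, k_sigma: float = 3.0) -> SegmentationResult:
    """Threshold a flattened map and label 8-connected components.

    The threshold is ``background median + k_sigma * sigma_bg`` with
    ``sigma_bg`` the MAD-based robust standard deviation, which is
    insensitive to the (sparse) particle pixels.
    """
    vals = hmap.values
    med = float(np.median(vals))
    sigma = float(_MAD_TO_SIGMA * np.median(np.abs(vals - med)))
    # noise-free maps have sigma 0; a tiny floor keeps the threshold
    # strictly above flat background without affecting real noise
    sigma = max(sigma, 1e-9)
    thr = med + k_sigma * sigma
    mask = vals > thr
    labels = skmeasure.label(mask, connectivity=2)
    return SegmentationResult(
        labels=labels,
        n_components=int(labels.max()),
        threshold_nm=thr,
        background_sigma_nm=sigma,
    )


def classify_conformation(
    aspect_ratio: float | np.ndarray,
    open_threshold: float = CLOSED_OPEN_THRESHOLD,
    exclude_above: float = MAX_ASPECT_RATIO,
):
    """Map aspect ratios to conformation labels.

    ``R in [1, open_threshold]`` is closed, ``(open_threshold,
    exclude_above]`` is open, anything larger is excluded as an
    aggregate or imaging artifact.  The boundary value itself counts as
    closed.  Ratios below 1 violate the length >= width definition and
    raise.
    """
    arr = np.asarray(aspect_ratio, dtype=float)
    if np.any(arr < 1.0 - 1e-12):
        raise ValueError("aspect ratio < 1 is undefined (length >= width)")
    out = np.where(arr <= open_threshold, "closed",
                   np.where(arr <= exclude_above, "open", "excluded"))
    if np.isscalar(aspect_ratio) or arr.ndim == 0:
        return str(out)
    return out


def measure_particle(component_mask: np.ndarray, hmap: HeightMap,
                     particle_id: int = 0) -> ParticleRecord:
    """Shape descriptors of one connected component.

    Length and width are the full major/minor axes of the ellipse with
    the same second central moments as the component mask (in nm); the
    aspect ratio is their quotient, floored at 1.  Sub-resolution axes
    are floored at one pixel so a single-pixel component gets R = 1.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty component")
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    px = hmap.pixel_nm
    width = max(props.axis_minor_length * px, px)
    length = max(props.axis_major_length * px, px, width)
    ratio = max(length / width, 1.0)
    nrow, ncol = mask.shape
    rr, cc = np.nonzero(mask)
    touches = bool(rr.min() == 0 or cc.min() == 0
                   or rr.max() == nrow - 1 or cc.max() == ncol - 1)
    return ParticleRecord(
        id=particle_id,
        area_nm2=float(props.area * px * px),
        length_nm=float(length),
        width_nm=float(width),
        aspect_ratio=float(ratio),
        max_height_nm=float(hmap.values[mask].max()),
        centroid_px=(float(props.centroid[0]), float(props.centroid[1])),
        touches_border=touches,
        label="",
    )


def measure_particles(
    seg: SegmentationResult,
    hmap: HeightMap,
    min_area_nm2: float = 20.0,
    max_area_nm2: float = 1.0e4,
    open_threshold: float = CLOSED_OPEN_THRESHOLD,
    exclude_above: float = MAX_ASPECT_RATIO,
    deconvolver: "TipDeconvolver | None" = None,
    smoothed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Measure and label every segmented component.

    Components touching the image border or falling outside the
    ``[min_area_nm2, max_area_nm2]`` window are marked ``excluded`` (the
    single-molecule selection rule); the rest are labelled closed/open
    by aspect ratio.  Without a ``deconvolver`` the axes are the
    moment-equivalent ellipse axes of the threshold mask; with one, the
    support extents at the measurement level are read from the
    ``smoothed`` image and inverted through the tip model.
    """
    rows = []
    px = hmap.pixel_nm
    px2 = px * px
    for region in skmeasure.regionprops(seg.labels):
        mask = seg.labels == region.label
        rec = measure_particle(mask, hmap, particle_id=region.label)
        if deconvolver is not None:
            sm = hmap.values if smoothed is None else smoothed
            h = float(sm[mask].max())
            level = deconvolver.level_frac * h
            extents = _contour_extents(sm, mask, level, px)
            if extents is None:
                level_mask = mask & (sm >= level)
                if level_mask.any():
                    extents = _support_extents(level_mask, px)
            if extents is not None:
                l_obs, w_obs = extents
                length, width, ratio = deconvolver.correct(l_obs, w_obs, h)
                rec.length_nm, rec.width_nm, rec.aspect_ratio = length, width, ratio
        area = region.area * px2
        if rec.touches_border or area < min_area_nm2 or area > max_area_nm2:
            rec.label = "excluded"
        else:
            rec.label = str(classify_conformation(
                rec.aspect_ratio, open_threshold, exclude_above))
        rows.append([
            rec.id, rec.area_nm2, rec.length_nm, rec.width_nm,
            rec.aspect_ratio, rec.max_height_nm,
            rec.centroid_px[0], rec.centroid_px[1],
            rec.touches_border, rec.label,
        ])
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def analyze_heightmap(
    hmap: HeightMap,
    tip_radius_nm: float | None = None,
    line_order: int = 1,
    k_sigma: float = 3.0,
    min_area_nm2: float = 20.0,
    max_area_nm2: float = 1.0e4,
    open_threshold: float = CLOSED_OPEN_THRESHOLD,
    exclude_above: float = MAX_ASPECT_RATIO,
    presmooth_px: float = 1.0,
    level_frac: float = 0.3,
) -> pd.DataFrame:
    """Full analysis of one raw map: flatten, segment, measure, classify.

    ``tip_radius_nm`` enables model-based tip deconvolution of the
    particle extents when the tip geometry is known (always the case
    for simulated data); with ``None``/0 the dilated footprints are
    measured as imaged.
    """
    flat = flatten(hmap, line_order=line_order)
    smoothed = (ndimage.gaussian_filter(flat.values, presmooth_px)
                if presmooth_px > 0 else flat.values)
    seg = segment(flat.copy_with(smoothed, note="smooth"), k_sigma=k_sigma)
    deconv = None
    if tip_radius_nm:
        deconv = _cached_deconvolver(
            float(tip_radius_nm), float(presmooth_px * hmap.pixel_nm),
            float(level_frac))
    return measure_particles(
        seg, flat,
        min_area_nm2=min_area_nm2, max_area_nm2=max_area_nm2,
        open_threshold=open_threshold, exclude_above=exclude_above,
        deconvolver=deconv, smoothed=smoothed,
    )


@lru_cache(maxsize=8)
def _cached_deconvolver(tip_radius_nm: float, smooth_sigma_nm: float,
                        level_frac: float) -> TipDeconvolver:
    return TipDeconvolver(tip_radius_nm, smooth_sigma_nm, level_frac)
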