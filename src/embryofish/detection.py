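"""Spot detection for smFISH images.

Two pipelines are provided, mirroring common practice for nascent-site
versus single-molecule quantification:

* 2D: maximal z-projection -> Laplacian-of-Gaussian (LoG) filter
  (size 15 px, sigma 2.5 px) -> automatic threshold from the plateau of
  the spot-count-versus-threshold scan -> 8-connected components.
* 3D: moving-sphere median background subtraction -> 3D LoG filter ->
  threshold -> 18-connected components, with cumulative and maximal
  intensities measured on the background-subtracted fluorescence image.

Spot tables are plain :class:`pandas.DataFrame` objects with columns
``spot_id, z, y, x, n_vox, cum_int, max_int`` (``z`` is NaN for 2D
detections).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdScan",
    "project_max",
    "log_kernel",
    "log_filter",
    "subtract_local_background",
    "select_threshold",
    "call_spots",
]


def project_max(stack: np.ndarray) -> np.ndarray:
    """Maximal projection of a (z, y, x) stack along z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    return stack.max(axis=0)


def log_kernel(size: int, sigma: float | tuple[float, ...], ndim: int = 2) -> np.ndarray:
    """Sign-flipped Laplacian-of-Gaussian kernel on a ``size``-wide grid.

    The kernel is negated so that bright blobs produce positive response
    peaks, and its mean is subtracted so constant images map exactly to
    zero.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    sig = np.broadcast_to(np.atleast_1d(np.asarray(sigma, dtype=float)), (ndim,))
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    half = size // 2
    axes = np.meshgrid(*([np.arange(-half, half + 1.0)] * ndim), indexing="ij")
    gauss = np.exp(-sum((a**2) / (2 * s**2) for a, s in zip(axes, sig)))
    gauss /= gauss.sum()
    # Laplacian of the Gaussian: sum_i d2G/dx_i^2, then sign-flipped
    lap = gauss * sum((a**2) / s**4 - 1.0 / s**2 for a, s in zip(axes, sig))
    kernel = -lap
    return kernel - kernel.mean()


def log_filter(
    image: np.ndarray, size: int = 15, sigma: float | tuple[float, ...] = 2.5
) -> np.ndarray:
    """LoG band-pass response of a 2D image or 3D stack.

    Boundary handling is reflective; the response has the same shape as
    the input and is positive at the center of bright blobs.
    """
    image = np.asarray(image, dtype=float)
    kernel = log_kernel(size, sigma, ndim=image.ndim)
    return ndimage.convolve(image, kernel, mode="reflect")


def _sphere_footprint(
    radius, ndim: int = 3, inner=0
) -> np.ndarray:
    """Ellipsoidal (or spherical) footprint, optionally with a hollow core."""
    r = np.broadcast_to(np.atleast_1d(np.asarray(radius, dtype=float)), (ndim,))
    ri = np.broadcast_to(np.atleast_1d(np.asarray(inner, dtype=float)), (ndim,))
    half = np.ceil(r).astype(int)
    axes = np.meshgrid(*[np.arange(-h, h + 1.0) for h in half], indexing="ij")
    outer = sum((a / s) ** 2 for a, s in zip(axes, r)) <= 1.0
    if np.all(ri == 0):
        return outer
    core = sum((a / np.maximum(s, 1e-12)) ** 2 for a, s in zip(axes, ri)) <= 1.0
    return outer & ~core


def subtract_local_background(
    stack: np.ndarray,
    radius=5,
    clip: bool = True,
    inner_radius=0,
) -> np.ndarray:
    """Subtract the local background (median in a moving sphere).

    ``radius`` may be a scalar or per-axis tuple (ellipsoid, useful for
    thin z-stacks). The result is clipped at 0 by default. Two options
    matter when the goal is unbiased flux measurement rather than
    detection: ``clip=False`` keeps negative noise excursions so that
    background regions sum to ~0 instead of a positive pedestal, and a
    nonzero ``inner_radius`` hollows out the footprint core so a spot's
    own PSF tails do not inflate its local background estimate.
    """
    stack = np.asarray(stack, dtype=float)
    r = np.broadcast_to(np.atleast_1d(np.asarray(radius, dtype=float)), (stack.ndim,))
    if np.any(r < 1):
        raise ValueError("radius must be >= 1")
    if np.any(2 * np.ceil(r) + 1 > np.asarray(stack.shape)):
        raise ValueError(
            f"sphere diameter {tuple(int(v) for v in 2 * np.ceil(r) + 1)} "
            f"exceeds image shape {stack.shape}"
        )
    fp = _sphere_footprint(radius, stack.ndim, inner=inner_radius)
    bg = ndimage.median_filter(stack, footprint=fp, mode="reflect")
    out = stack - bg
    return np.clip(out, 0, None) if clip else out


def estimate_background_mode(stack: np.ndarray, bin_width: float = 0.5) -> float:
    """Robust global background level: the mode of the voxel histogram.

    In smFISH stacks most voxels are background, so the histogram peak
    sits at the background level regardless of how many bright spots the
    image contains (unlike the mean or even the median, which drift with
    spot density). The peak bin is refined by averaging the voxels
    within one bin width of it.
    """
    vals = np.asarray(stack, dtype=float).ravel()
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return float(lo)
    nbins = max(int(np.ceil((hi - lo) / bin_width)), 10)
    hist, edges = np.histogram(vals, bins=nbins)
    peak = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2.0
    near = vals[np.abs(vals - peak) <= bin_width]
    return float(near.mean()) if near.size else float(peak)


@dataclass
class ThresholdScan:
    """Audit record of the automatic threshold search.

    ``log_changes[i]`` is ``|log10 counts[i+1] - log10 counts[i]|``; the
    chosen threshold is the first candidate whose step change falls below
    half the maximal step change across the scan.
    """

    thresholds: np.ndarray
    counts: np.ndarray
    log_changes: np.ndarray
    chosen: float
    chosen_index: int
    flat: bool = False

    def to_frame(self) -> pd.DataFrame:
        changes = np.full(self.thresholds.size, np.nan)
        changes[: self.log_changes.size] = self.log_changes
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_spots": self.counts,
                "log_change": changes,
                "chosen": np.arange(self.thresholds.size) == self.chosen_index,
            }
        )


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 2 and connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if ndim == 2 and connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if ndim == 3 and connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if ndim == 3 and connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if ndim == 3 and connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(
        f"unsupported connectivity {connectivity} for a {ndim}D grid"
    )


def _count_components(grid: np.ndarray, threshold: float, structure: np.ndarray) -> int:
    return ndimage.label(grid > threshold, structure=structure)[1]


def select_threshold(
    filtered: np.ndarray,
    n_candidates: int = 100,
    connectivity: int | None = None,
    window: int = 5,
    rule: str = "running",
) -> ThresholdScan:
    """Automatic detection threshold from the spot-count plateau.

    Candidate thresholds are ``n_candidates`` geometrically spaced levels
    between the 50th percentile and the maximum of the positive filter
    response. For each candidate the number of connected components above
    it is counted; the threshold is chosen as the first candidate in the
    environment of which the count stays relatively constant, where the
    change at candidate i is ``|log10 counts[i+window] - log10 counts[i]|``
    and a count of 0 ends the usable scan.

    Two readings of "relatively constant" are provided:

    * ``rule="literal"`` — the change is smaller than half the maximal
      change across the whole scan. Adequate for two-phase scans (noise
      shoulder then plateau) on coarse grids, but on fine grids the
      normalizing maximum is dominated by the terminal cliff where the
      brightest spots vanish, so the criterion can trigger inside the
      noise decline.
    * ``rule="running"`` (default) — the change is smaller than half the
      maximal change seen so far (up to candidate i), which detects the
      first flattening after a decline regardless of what the scan does
      later; the chosen threshold is the midpoint of the contiguous run
      of candidates satisfying the criterion, placing it centrally in
      the plateau.

    A scan with zero maximal change (e.g. identical isolated spots on a
    clean background) falls back to the lowest candidate with a warning.
    """
    filtered = np.asarray(filtered, dtype=float)
    if n_candidates < 10:
        raise ValueError("n_candidates must be >= 10")
    if window < 1:
        raise ValueError("window must be >= 1")
    if rule not in ("literal", "running"):
        raise ValueError(f"unknown rule {rule!r}")
    pos = filtered[filtered > 0]
    if pos.size == 0:
        raise ValueError("filter response has no positive values")
    if connectivity is None:
        connectivity = 8 if filtered.ndim == 2 else 18
    structure = _structure(filtered.ndim, connectivity)

    lo = max(np.percentile(pos, 50.0), np.finfo(float).tiny)
    hi = pos.max()
    thresholds = np.geomspace(lo, hi, n_candidates)
    counts = np.array(
        [_count_components(filtered, t, structure) for t in thresholds]
    )

    # a count of 0 ends the usable scan
    nz = np.nonzero(counts == 0)[0]
    end = nz[0] if nz.size else counts.size
    if end < 2:
        logger.warning("threshold scan degenerate (counts vanish immediately)")
        return ThresholdScan(thresholds, counts, np.array([]), float(thresholds[0]), 0, flat=True)

    logc = np.log10(counts[:end].astype(float))
    steps = np.abs(
        logc[np.minimum(np.arange(end) + window, end - 1)] - logc[:end]
    )[: end - 1]
    # below the count maximum neighboring components are still merging,
    # so the count is not a spot count yet; search from the peak onward
    start0 = int(np.argmax(counts[:end]))
    if steps.max() == 0:
        logger.warning("threshold scan flat; falling back to lowest candidate")
        return ThresholdScan(
            thresholds, counts, steps, float(thresholds[0]), 0, flat=True
        )
    if rule == "literal":
        below = start0 + np.nonzero(steps[start0:] < 0.5 * steps.max())[0]
        if below.size:
            i = int(below[0])
            return ThresholdScan(thresholds, counts, steps, float(thresholds[i]), i)
    else:
        tail = steps[start0:]
        running_max = np.maximum.accumulate(tail)
        # <= so that a scan opening directly in a plateau (running max
        # still 0) is recognized as already flat
        ok = tail <= 0.5 * running_max
        start = np.nonzero(ok)[0]
        if start.size:
            i = int(start[0])
            j = i
            while j + 1 < tail.size and ok[j + 1]:
                j += 1
            mid = start0 + (i + j) // 2
            return ThresholdScan(
                thresholds, counts, steps, float(thresholds[mid]), mid
            )
    idx = int(np.argmin(steps))
    logger.warning("no plateau found; choosing the smallest-change candidate")
    return ThresholdScan(thresholds, counts, steps, float(thresholds[idx]), idx)


def call_spots(
    grid: np.ndarray,
    threshold: float,
    connectivity: int | None = None,
    measurement: np.ndarray | None = None,
    channel: str = "",
    measure_dilate: float = 0.0,
    subtract_region_background: bool = False,
) -> pd.DataFrame:
    """Connected components above ``threshold`` as a spot table.

    ``grid`` is the decision image (normally the LoG response);
    ``measurement`` the image intensities summed into ``cum_int`` and
    ``max_int`` (defaults to ``grid``; normally the background-subtracted
    fluorescence image). Centroids are intensity-weighted on the
    measurement image. Connectivity is 8 for 2D grids and 18 for 3D.

    ``measure_dilate`` expands each component by the given distance (in
    voxels, without overlap between neighboring spots) for the
    ``cum_int`` sum only, so that PSF flux just below the decision
    threshold is still counted; ``n_vox`` always refers to the original
    component. With ``subtract_region_background`` the per-voxel median
    of the measurement image outside every (expanded) spot region is
    subtracted from ``cum_int`` and ``max_int`` — an unbiased local
    pedestal estimate even at spot densities where a moving-window
    median would be contaminated by neighboring spots.
    """
    grid = np.asarray(grid, dtype=float)
    if connectivity is None:
        connectivity = 8 if grid.ndim == 2 else 18
    structure = _structure(grid.ndim, connectivity)
    meas = grid if measurement is None else np.asarray(measurement, dtype=float)
    if meas.shape != grid.shape:
        raise ValueError("measurement image shape must match the decision grid")

    labels, n = ndimage.label(grid > threshold, structure=structure)
    if n == 0:
        cols = ["spot_id", "channel", "z", "y", "x", "n_vox", "cum_int", "max_int"]
        return pd.DataFrame(columns=cols)
    idx = np.arange(1, n + 1)
    n_vox = ndimage.sum_labels(np.ones_like(grid), labels, idx).astype(int)
    if measure_dilate > 0:
        from skimage.segmentation import expand_labels

        meas_labels = expand_labels(labels, distance=measure_dilate)
    else:
        meas_labels = labels
    if subtract_region_background:
        outside = meas[meas_labels == 0]
        pedestal = float(np.median(outside)) if outside.size else 0.0
    else:
        pedestal = 0.0
    n_meas_vox = ndimage.sum_labels(np.ones_like(grid), meas_labels, idx)
    cum = ndimage.sum_labels(meas, meas_labels, idx) - pedestal * n_meas_vox
    mx = (
        ndimage.labeled_comprehension(meas, labels, idx, np.max, float, np.nan)
        - pedestal
    )
    # components with no fluorescence support (e.g. filter ringing over a
    # zero background) carry no measurable spot; drop them
    keep = mx > 0
    idx, n_vox, cum, mx = idx[keep], n_vox[keep], cum[keep], mx[keep]
    n = int(keep.sum())
    if n == 0:
        cols = ["spot_id", "channel", "z", "y", "x", "n_vox", "cum_int", "max_int"]
        return pd.DataFrame(columns=cols)
    weights = np.clip(meas, 0, None)
    com = np.atleast_2d(ndimage.center_of_mass(weights, labels, idx))
    if grid.ndim == 2:
        z = np.full(n, np.nan)
        y, x = com[:, 0], com[:, 1]
    else:
        z, y, x = com[:, 0], com[:, 1], com[:, 2]
    return pd.DataFrame(
        {
            "spot_id": np.arange(n),
            "channel": channel,
            "z": z,
            "y": y,
            "x": x,
            "n_vox": n_vox,
            "cum_int": cum,
            "max_int": mx,
        }
    )
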