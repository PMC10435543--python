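"""Synaptic-puncta image pipelines.

Two workflows over punctate fluorescence images:

* **Anatomical synapses** (fixed tissue, two immunolabels): per channel,
  rolling-ball background subtraction (10 px ball), median filtering (2 px
  disk) and Moments auto-thresholding; the pixelwise AND of the two binary
  channels is size-filtered (0.1-5.0 µm² at the closed interval) and counted.

* **Dendritic puncta** (live two-channel z-stacks): the structural channel is
  MaxEntropy-thresholded to a dendritic mask (minus a soma/axon exclusion
  mask), the puncta channel is Moments-thresholded, and puncta inside the
  dendritic mask are counted per slice with components merged across adjacent
  slices when their footprints overlap; density is per µm³ of dendritic mask.

The two histogram auto-thresholds (Kapur's maximum-entropy criterion and the
moment-preserving criterion of Tsai) are implemented here from their
definitions and are exhaustively checked against enumeration oracles in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops

MIN_AREA_UM2 = 0.1
MAX_AREA_UM2 = 5.0
BALL_RADIUS_PX = 10
MEDIAN_RADIUS_PX = 2


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _disk_footprint(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def _ball_structure(radius: int, shape: str) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of the rolling structuring element."""
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    r2 = x * x + y * y
    footprint = r2 <= radius * radius
    if shape == "ball":
        heights = np.sqrt(np.maximum(radius * radius - r2, 0.0))
    elif shape == "paraboloid":
        heights = radius - r2 / (2.0 * radius)
    else:
        raise ValueError(f"unknown structuring element shape: {shape!r}")
    return footprint, np.where(footprint, heights, 0.0)


def rolling_ball_subtract(
    image: np.ndarray, radius_px: int = BALL_RADIUS_PX, shape: str = "ball"
) -> np.ndarray:
    """Background subtraction by grayscale opening with a ball-shaped element.

    The background is the grayscale opening of the image by a non-flat
    structuring element whose height profile is a sphere of the given radius
    (``shape="paraboloid"`` selects the paraboloid dialect).  The result is
    ``image - background`` clipped at zero, returned as float64.
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(image.shape):
        raise ValueError("structuring element larger than the image")
    footprint, heights = _ball_structure(radius_px, shape)
    background = ndi.grey_opening(
        image, footprint=footprint, structure=heights, mode="reflect"
    )
    return np.clip(image - background, 0.0, None)


def median_filter(image: np.ndarray, radius_px: int = MEDIAN_RADIUS_PX) -> np.ndarray:
    """Median over a disk footprint of the given radius, reflect edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    return ndi.median_filter(
        np.asarray(image, dtype=float), footprint=_disk_footprint(radius_px), mode="reflect"
    )


# ---------------------------------------------------------------------------
# histogram auto-thresholding
# ---------------------------------------------------------------------------

def _plateau_mid(indices: np.ndarray) -> int:
    """Deterministic tie-break: the middle of the set of optimal candidates."""
    return int(indices[len(indices) // 2])


def kapur_threshold(counts: np.ndarray, values: np.ndarray | None = None) -> int:
    """Maximum-entropy (Kapur) threshold index for a histogram.

    Chooses the bin index ``k`` maximizing the sum of Shannon entropies of
    the normalized histograms below (``<= k``) and above (``> k``) the
    candidate.  Ties take the middle of the optimal plateau.  Bins with zero
    probability contribute no entropy.
    """
    p = np.asarray(counts, dtype=float)
    if p.sum() <= 0:
        raise ValueError("empty histogram")
    p = p / p.sum()
    n = len(p)
    cum = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    s = np.cumsum(plogp)
    total = s[-1]
    objective = np.full(n - 1, -np.inf)
    for k in range(n - 1):
        p0, p1 = cum[k], 1.0 - cum[k]
        if p0 <= 0 or p1 <= 0:
            continue
        hb = np.log(p0) - s[k] / p0
        hf = np.log(p1) - (total - s[k]) / p1
        objective[k] = hb + hf
    if not np.isfinite(objective).any():
        raise ValueError("histogram has a single occupied bin; no threshold exists")
    best = np.flatnonzero(objective == objective.max())
    return _plateau_mid(best)


def moments_threshold(counts: np.ndarray, values: np.ndarray | None = None) -> int:
    """Moment-preserving (Tsai) threshold index for a histogram.

    For each candidate ``k`` the two-level image keeps the histogram's
    fractions below/above the candidate and the two gray levels that preserve
    the first and second moments exactly; the candidate minimizing the error
    in the third moment is chosen (ties: middle of the optimal plateau).
    """
    p = np.asarray(counts, dtype=float)
    if p.sum() <= 0:
        raise ValueError("empty histogram")
    p = p / p.sum()
    n = len(p)
    v = np.arange(n, dtype=float) if values is None else np.asarray(values, dtype=float)
    m1 = float(np.dot(p, v))
    m2 = float(np.dot(p, v * v))
    m3 = float(np.dot(p, v * v * v))
    var = m2 - m1 * m1
    if var <= 0:
        raise ValueError("histogram has a single occupied value; no threshold exists")
    cum = np.cumsum(p)
    err = np.full(n - 1, np.inf)
    for k in range(n - 1):
        q0, q1 = cum[k], 1.0 - cum[k]
        if q0 <= 0 or q1 <= 0:
            continue
        z0 = m1 - np.sqrt(var * q1 / q0)
        z1 = m1 + np.sqrt(var * q0 / q1)
        err[k] = abs(q0 * z0**3 + q1 * z1**3 - m3)
    if not np.isfinite(err).any():
        raise ValueError("no admissible threshold")
    best = np.flatnonzero(err == err.min())
    return _plateau_mid(best)


def _image_histogram(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-level histogram (counts, bin values) spanning the image range.

    Integer images with a range of at most 256 gray levels are histogrammed
    at their exact values, so thresholds land on actual gray levels and
    translate exactly under constant intensity shifts.
    """
    data = np.asarray(image)
    if data.min() == data.max():
        raise ValueError("constant image: no threshold exists")
    if np.issubdtype(data.dtype, np.integer):
        lo, hi = int(data.min()), int(data.max())
        if hi - lo < 256:
            values = np.arange(lo, hi + 1, dtype=float)
            counts = np.bincount((data.astype(np.int64) - lo).ravel(), minlength=len(values))
            return counts.astype(float), values
    lo, hi = data.min(), data.max()
    edges = np.linspace(float(lo), float(hi), 257)
    counts, _ = np.histogram(data.ravel(), bins=edges)
    return counts.astype(float), edges[1:]  # bin upper edges as threshold values


def auto_threshold(image: np.ndarray, method: str = "moments") -> float:
    """Histogram auto-threshold of an image; pixels strictly above are foreground.

    ``method`` is ``"moments"`` (Tsai) or ``"maxentropy"`` (Kapur).  Raises
    on constant images, for which no threshold exists.
    """
    counts, values = _image_histogram(image)
    if method == "moments":
        k = moments_threshold(counts, values)
    elif method == "maxentropy":
        k = kapur_threshold(counts, values)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(values[k])


def binarize(image: np.ndarray, method: str = "moments") -> np.ndarray:
    """Foreground mask via :func:`auto_threshold`; empty mask for constant images."""
    try:
        t = auto_threshold(image, method)
    except ValueError:
        return np.zeros(np.asarray(image).shape, dtype=bool)
    return np.asarray(image) > t


# ---------------------------------------------------------------------------
# particles and colocalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Punctum:
    n_pixels: int
    area_um2: float
    centroid_um: tuple[float, ...]
    slice_index: int | None = None


@dataclass
class PunctaSet:
    particles: list[Punctum]
    labels: np.ndarray

    @property
    def count(self) -> int:
        return len(self.particles)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.particles])


def colocalization_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixelwise AND of two binary masks (shapes must match)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    return mask_a & mask_b


def find_particles(
    mask: np.ndarray,
    pixel_size: float,
    min_area: float = MIN_AREA_UM2,
    max_area: float = MAX_AREA_UM2,
    connectivity: int = 2,
    slice_index: int | None = None,
) -> PunctaSet:
    """Connected components of a 2-D mask filtered by physical area.

    Components (8-connected by default) whose area, ``n_pixels *
    pixel_size**2``, falls outside the closed interval ``[min_area,
    max_area]`` µm² are discarded; surviving components are returned with
    centroids in µm.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not min_area < max_area:
        raise ValueError("min_area must be smaller than max_area")
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=connectivity)
    kept = []
    out_labels = np.zeros_like(labels)
    for region in regionprops(labels):
        area = region.num_pixels * pixel_size**2
        if min_area <= area <= max_area:
            centroid = tuple(float(c) * pixel_size for c in region.centroid)
            kept.append(Punctum(int(region.num_pixels), float(area), centroid, slice_index))
            out_labels[labels == region.label] = len(kept)
    return PunctaSet(kept, out_labels)


# ---------------------------------------------------------------------------
# end-to-end densities
# ---------------------------------------------------------------------------

@dataclass
class AnatomicalSynapseResult:
    count: int
    field_area_um2: float
    density_per_um2: float
    density_per_field: float  # per 20 µm x 20 µm reference field
    puncta: PunctaSet


def _preprocess_and_binarize(
    image: np.ndarray, method: str, ball_radius: int, median_radius: int
) -> np.ndarray:
    filtered = median_filter(rolling_ball_subtract(image, ball_radius), median_radius)
    return binarize(filtered, method)


def anatomical_synapse_density(
    pre_channel: np.ndarray,
    post_channel: np.ndarray,
    pixel_size: float,
    ball_radius: int = BALL_RADIUS_PX,
    median_radius: int = MEDIAN_RADIUS_PX,
    min_area: float = MIN_AREA_UM2,
    max_area: float = MAX_AREA_UM2,
    connectivity: int = 2,
) -> AnatomicalSynapseResult:
    """Colocalized pre/postsynaptic punctum density in a neuropil field.

    Both channels are background-subtracted, median-filtered and
    Moments-thresholded; the AND of the binary channels is size-filtered and
    counted.  Density is reported per µm² and per 400 µm² (a 20 µm x 20 µm
    field, the sampling unit used for neuropil quantification).
    """
    pre_channel = np.asarray(pre_channel)
    post_channel = np.asarray(post_channel)
    if pre_channel.shape != post_channel.shape:
        raise ValueError("channel shapes differ")
    mask = colocalization_mask(
        _preprocess_and_binarize(pre_channel, "moments", ball_radius, median_radius),
        _preprocess_and_binarize(post_channel, "moments", ball_radius, median_radius),
    )
    puncta = find_particles(mask, pixel_size, min_area, max_area, connectivity)
    field_area = pre_channel.shape[0] * pre_channel.shape[1] * pixel_size**2
    per_um2 = puncta.count / field_area
    return AnatomicalSynapseResult(puncta.count, field_area, per_um2, per_um2 * 400.0, puncta)


@dataclass
class DendriticPunctaResult:
    count: int
    dendrite_volume_um3: float
    density_per_um3: float
    merged_labels: np.ndarray


def dendritic_puncta_density(
    dendrite_stack: np.ndarray,
    puncta_stack: np.ndarray,
    pixel_size: float,
    z_step: float,
    exclusion_mask: np.ndarray | None = None,
    ball_radius: int = BALL_RADIUS_PX,
    median_radius: int = MEDIAN_RADIUS_PX,
    min_area: float = MIN_AREA_UM2,
    max_area: float = MAX_AREA_UM2,
    connectivity: int = 2,
    merge_slices: bool = True,
) -> DendriticPunctaResult:
    """Punctum density within a dendritic mask over a two-channel z-stack.

    Per slice, the structural (dendrite) channel is preprocessed and
    MaxEntropy-thresholded and the puncta channel Moments-thresholded; the
    exclusion mask (somata/axons) is removed from the dendritic mask.  Puncta
    are size-filtered within the dendritic mask per slice, then components in
    adjacent slices with overlapping footprints are merged and counted once.
    Density is the merged count divided by the dendritic mask volume
    (voxels x pixel_size² x z_step, µm³).
    """
    dendrite_stack = np.asarray(dendrite_stack)
    puncta_stack = np.asarray(puncta_stack)
    if dendrite_stack.shape != puncta_stack.shape or dendrite_stack.ndim != 3:
        raise ValueError("stacks must be 3-D with identical shapes")
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    n_slices = dendrite_stack.shape[0]
    dendrite_mask = np.zeros(dendrite_stack.shape, dtype=bool)
    filtered_puncta = np.zeros(dendrite_stack.shape, dtype=bool)
    for z in range(n_slices):
        dmask = _preprocess_and_binarize(
            dendrite_stack[z], "maxentropy", ball_radius, median_radius
        )
        if exclusion_mask is not None:
            dmask &= ~np.asarray(exclusion_mask[z], dtype=bool)
        pmask = _preprocess_and_binarize(
            puncta_stack[z], "moments", ball_radius, median_radius
        )
        dendrite_mask[z] = dmask
        inside = pmask & dmask
        filtered_puncta[z] = find_particles(
            inside, pixel_size, min_area, max_area, connectivity, slice_index=z
        ).labels > 0
    if not dendrite_mask.any():
        raise ValueError("empty dendritic mask")
    volume = float(dendrite_mask.sum()) * pixel_size**2 * z_step
    if merge_slices:
        # In-plane 8-connectivity plus same-pixel adjacency across slices:
        # overlapping footprints in neighbouring slices merge into one punctum.
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1] = True
        structure[0, 1, 1] = structure[2, 1, 1] = True
        merged, n = ndi.label(filtered_puncta, structure=structure)
    else:
        merged = np.zeros(filtered_puncta.shape, dtype=np.int32)
        n = 0
        for z in range(n_slices):
            lab = label(filtered_puncta[z], connectivity=connectivity)
            merged[z] = np.where(lab > 0, lab + n, 0)
            n += lab.max()
    return DendriticPunctaResult(int(n), volume, n / volume, merged)
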