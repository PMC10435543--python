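"""Retinotopic grid mapping from calcium-imaging movies.

A bar stimulus is flashed at 5 equidistant positions along the azimuth or
elevation axis in randomized order while tectal activity is imaged.  Per
pixel (grid map) or per cell-body ROI, the mean ΔF/F₀ response to each
position is computed; the receptive-field centre is estimated as the
response-weighted average position ("optimal stimulus position"), and
receptive-field sharpness as the mean response at the two positions closest
to the optimum divided by the mean response at the remaining positions.
Cells with weak responses, peripheral optima or tiny ROIs are excluded, as
are whole animals with too few surviving cells; the two-sample
Kolmogorov-Smirnov statistic compares pooled sharpness distributions between
rearing conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import kstwobign

N_POSITIONS = 5
BAR_WIDTH_DEG = 18.0
MIN_MAX_RESPONSE = 2.0
MIN_ROI_PX = 30
MIN_CELLS_PER_ANIMAL = 30


# ---------------------------------------------------------------------------
# protocol and movie containers
# ---------------------------------------------------------------------------

@dataclass
class StimulusProtocol:
    """Bar-position schedule tied to frame indices.

    ``presentations`` holds ``(position, onset, offset)`` with 1-based
    positions and half-open frame windows ``[onset, offset)``.
    ``baseline_frames`` are stimulus-free frames used for F₀.
    ``position_degrees`` maps the position indices to visual angles; the
    default places the ``n_positions`` bar centres ``bar_width_deg`` apart,
    centred on zero.
    """

    presentations: list[tuple[int, int, int]]
    baseline_frames: np.ndarray
    n_positions: int = N_POSITIONS
    axis: str = "azimuth"
    bar_width_deg: float = BAR_WIDTH_DEG
    position_degrees: np.ndarray | None = None

    def __post_init__(self):
        if not self.presentations:
            raise ValueError("protocol has no presentations")
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=int)
        seen = {p for p, _, _ in self.presentations}
        if seen != set(range(1, self.n_positions + 1)):
            raise ValueError("every position must be presented at least once")
        for p, on, off in self.presentations:
            if on >= off:
                raise ValueError(f"presentation at position {p}: onset must precede offset")
        if self.position_degrees is None:
            idx = np.arange(1, self.n_positions + 1, dtype=float)
            self.position_degrees = (idx - (self.n_positions + 1) / 2.0) * self.bar_width_deg
        self.position_degrees = np.asarray(self.position_degrees, dtype=float)

    @property
    def n_frames_min(self) -> int:
        return max(off for _, _, off in self.presentations)


def make_bar_protocol(
    n_positions: int = N_POSITIONS,
    n_repeats: int = 3,
    stim_frames: int = 10,
    gap_frames: int = 30,
    pre_frames: int = 30,
    axis: str = "azimuth",
    bar_width_deg: float = BAR_WIDTH_DEG,
    rng: np.random.Generator | int | None = None,
) -> StimulusProtocol:
    """Randomized-order bar protocol with inter-stimulus gaps.

    Presentations of each position are shuffled (``rng`` seeds the order;
    ``None`` keeps a position-cycling deterministic order).  Baseline frames
    are the pre-stimulus period plus the last third of every gap, where the
    indicator transient has decayed furthest.
    """
    order = np.tile(np.arange(1, n_positions + 1), n_repeats)
    if rng is not None:
        gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        gen.shuffle(order)
    presentations = []
    baseline = list(range(pre_frames))
    t = pre_frames
    for pos in order:
        presentations.append((int(pos), t, t + stim_frames))
        gap_start = t + stim_frames
        baseline.extend(range(gap_start + 2 * gap_frames // 3, gap_start + gap_frames))
        t = gap_start + gap_frames
    return StimulusProtocol(
        presentations, np.array(baseline), n_positions, axis, bar_width_deg
    )


def protocol_to_dict(protocol: StimulusProtocol) -> dict:
    return {
        "axis": protocol.axis,
        "n_positions": protocol.n_positions,
        "bar_width_deg": protocol.bar_width_deg,
        "presentations": [list(p) for p in protocol.presentations],
        "baseline_frames": protocol.baseline_frames.tolist(),
        "position_degrees": protocol.position_degrees.tolist(),
    }


def protocol_from_dict(data: dict) -> StimulusProtocol:
    return StimulusProtocol(
        [tuple(p) for p in data["presentations"]],
        np.array(data["baseline_frames"], dtype=int),
        int(data["n_positions"]),
        data.get("axis", "azimuth"),
        float(data.get("bar_width_deg", BAR_WIDTH_DEG)),
        np.array(data["position_degrees"]) if "position_degrees" in data else None,
    )


@dataclass
class CalciumMovie:
    frames: np.ndarray  # (T, H, W)
    frame_rate_hz: float
    pixel_size_um: float = 0.496

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("movie must be (T, H, W)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")


# ---------------------------------------------------------------------------
# ΔF/F₀ and response tables
# ---------------------------------------------------------------------------

def compute_dff(
    movie: CalciumMovie, protocol: StimulusProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ΔF/F₀ with F₀ = mean over the protocol's baseline frames.

    Returns ``(dff, valid)`` where ``dff`` is (T, H, W) and ``valid`` marks
    pixels with positive baseline; invalid pixels are NaN throughout.
    """
    if len(protocol.baseline_frames) == 0:
        raise ValueError("protocol defines no baseline frames")
    f0 = movie.frames[protocol.baseline_frames].mean(axis=0)
    valid = f0 > 0
    if not valid.any():
        raise ValueError("baseline fluorescence is zero everywhere")
    safe_f0 = np.where(valid, f0, 1.0)
    dff = (movie.frames - f0) / safe_f0
    dff[:, ~valid] = np.nan
    return dff, valid


def _response_windows(
    protocol: StimulusProtocol, frame_rate_hz: float, decay_allowance_s: float, n_frames: int
) -> list[tuple[int, np.ndarray]]:
    extra = int(round(decay_allowance_s * frame_rate_hz))
    out = []
    for pos, on, off in protocol.presentations:
        frames = np.arange(on, min(off + extra, n_frames))
        out.append((pos, frames))
    return out


@dataclass
class ResponseTable:
    """Mean ΔF/F₀ response per ROI and stimulus position."""

    responses: np.ndarray  # (n_roi, n_positions)
    roi_sizes_px: np.ndarray
    roi_ids: list[int]
    n_positions: int = N_POSITIONS


def position_response_table(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    roi_masks: list[np.ndarray],
    frame_rate_hz: float,
    decay_allowance_s: float = 1.0,
) -> ResponseTable:
    """Average ΔF/F₀ within each ROI over each presentation's response window.

    The response window runs from stimulus onset to offset plus a decay
    allowance (default 1 s) for the slow indicator transient; windows of the
    same position are averaged.
    """
    n_pos = protocol.n_positions
    windows = _response_windows(protocol, frame_rate_hz, decay_allowance_s, dff.shape[0])
    responses = np.zeros((len(roi_masks), n_pos))
    sizes = np.zeros(len(roi_masks), dtype=int)
    for i, mask in enumerate(roi_masks):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {i} is empty")
        sizes[i] = int(mask.sum())
        trace = np.nanmean(dff[:, mask], axis=1)
        per_pos: dict[int, list[float]] = {p: [] for p in range(1, n_pos + 1)}
        for pos, frames in windows:
            per_pos[pos].append(float(np.nanmean(trace[frames])))
        responses[i] = [np.mean(per_pos[p]) for p in range(1, n_pos + 1)]
    return ResponseTable(responses, sizes, list(range(len(roi_masks))), n_pos)


# ---------------------------------------------------------------------------
# receptive-field statistics
# ---------------------------------------------------------------------------

def optimal_stimulus_position(responses: np.ndarray) -> float:
    """Response-weighted average position (receptive-field centre estimate).

    Responses are rectified at zero; the estimate is Σ i·rᵢ / Σ rᵢ over
    1-based position indices.  NaN when no response is positive (undefined).
    """
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    total = r.sum()
    if not total > 0:
        return float("nan")
    idx = np.arange(1, len(r) + 1, dtype=float)
    return float(np.dot(idx, r) / total)


def receptive_field_sharpness(responses: np.ndarray, optimal: float) -> float:
    """Centre-to-periphery response ratio around the optimal position.

    Positions are ranked by distance ``|i - optimal|`` with ties broken
    toward the lower index; sharpness is the mean response at the two
    closest positions divided by the mean response at the remaining
    positions.  NaN (undefined) when the peripheral mean is not positive.
    """
    r = np.asarray(responses, dtype=float)
    if not np.isfinite(optimal):
        return float("nan")
    idx = np.arange(1, len(r) + 1)
    order = sorted(idx, key=lambda i: (abs(i - optimal), i))
    closest = [i - 1 for i in order[:2]]
    periphery = [i - 1 for i in order[2:]]
    denom = r[periphery].mean()
    if not denom > 0:
        return float("nan")
    return float(r[closest].mean() / denom)


@dataclass
class RFEstimate:
    roi_id: int
    optimal_position: float
    sharpness: float
    max_response: float
    roi_size_px: int
    animal_id: int | str | None = None
    included: bool = False
    exclusion_reason: str | None = None


def estimate_receptive_fields(
    table: ResponseTable, animal_id: int | str | None = None
) -> list[RFEstimate]:
    """Optimal position and sharpness for every ROI of a response table."""
    out = []
    for i, roi_id in enumerate(table.roi_ids):
        r = table.responses[i]
        opt = optimal_stimulus_position(r)
        sharp = receptive_field_sharpness(r, opt)
        out.append(
            RFEstimate(
                roi_id, opt, sharp, float(np.max(r)), int(table.roi_sizes_px[i]), animal_id
            )
        )
    return out


def apply_inclusion_criteria(
    estimates: list[RFEstimate],
    min_max_response: float = MIN_MAX_RESPONSE,
    central_low: float = 2.0,
    central_high: float = 4.0,
    min_roi_px: int = MIN_ROI_PX,
    min_cells_per_animal: int = MIN_CELLS_PER_ANIMAL,
) -> tuple[list[RFEstimate], list[tuple[int, str]]]:
    """Flag estimates against the evaluation criteria; log every exclusion.

    A cell is kept iff its maximal ΔF/F₀ response exceeds ``min_max_response``
    (default 2), its optimal position lies within the three central stimulus
    positions (``[2, 4]`` on a 5-position axis), and its ROI covers at least
    ``min_roi_px`` pixels.  Animals with fewer than ``min_cells_per_animal``
    surviving cells are dropped entirely.  Returns ``(annotated estimates,
    exclusion log)`` with reasons.
    """
    annotated: list[RFEstimate] = []
    log: list[tuple[int, str]] = []

    def _exclude(est: RFEstimate, reason: str) -> RFEstimate:
        log.append((est.roi_id, reason))
        return replace(est, included=False, exclusion_reason=reason)

    for est in estimates:
        if not est.max_response > min_max_response:
            annotated.append(_exclude(est, "weak_response"))
        elif not (central_low <= est.optimal_position <= central_high):
            annotated.append(_exclude(est, "peripheral_optimum"))
        elif est.roi_size_px < min_roi_px:
            annotated.append(_exclude(est, "small_roi"))
        elif not np.isfinite(est.sharpness):
            annotated.append(_exclude(est, "undefined_sharpness"))
        else:
            annotated.append(replace(est, included=True, exclusion_reason=None))

    per_animal: dict = {}
    for est in annotated:
        if est.included:
            per_animal.setdefault(est.animal_id, 0)
            per_animal[est.animal_id] += 1
    final = []
    for est in annotated:
        if est.included and per_animal.get(est.animal_id, 0) < min_cells_per_animal:
            final.append(_exclude(est, "animal_below_min_cells"))
        else:
            final.append(est)
    return final, log


def grid_map(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    frame_rate_hz: float,
    decay_allowance_s: float = 1.0,
) -> np.ndarray:
    """Per-pixel optimal-stimulus-position image (NaN where undefined).

    The pixelwise analogue of the ROI pipeline: mean ΔF/F₀ per position per
    pixel, rectified, then the weighted-average position.
    """
    n_pos = protocol.n_positions
    windows = _response_windows(protocol, frame_rate_hz, decay_allowance_s, dff.shape[0])
    per_pos = np.zeros((n_pos,) + dff.shape[1:])
    counts = np.zeros(n_pos)
    for pos, frames in windows:
        per_pos[pos - 1] += np.nanmean(dff[frames], axis=0)
        counts[pos - 1] += 1
    per_pos /= counts[:, None, None]
    r = np.clip(per_pos, 0.0, None)
    total = r.sum(axis=0)
    idx = np.arange(1, n_pos + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.tensordot(idx, r, axes=(0, 0)) / total
    out[~(total > 0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def ks_two_sample(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic two-sided p-value.

    D is the supremum distance between the two empirical CDFs; the p-value
    comes from the Kolmogorov distribution with effective sample size
    ``n_a n_b / (n_a + n_b)``.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    cdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    d = float(np.abs(cdf_a - cdf_b).max())
    en = len(a) * len(b) / (len(a) + len(b))
    p = float(np.clip(kstwobign.sf(np.sqrt(en) * d), 0.0, 1.0))
    return d, p
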