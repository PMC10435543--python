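"""Synthetic inputs with attached ground truth for every pipeline.

The study's raw data (in vivo reconstructions, confocal fields, calcium
movies) are not deposited, so each analysis stage is exercised on simulated
inputs whose ground truth is known by construction:

* growing/retracting dendritic arbors with terminal-process birth, death and
  Gaussian length-step dynamics (10-min interval, 1-h design: 6 intervals);
* two-channel punctate fields with a controllable colocalized fraction over
  a noisy background (20 µm x 20 µm neuropil sampling unit);
* two-channel dendrite z-stacks (tube-like structural channel, puncta with
  known inside/outside status, a soma exclusion region);
* calcium movies of cells with Gaussian receptive fields over a 5-position
  bar axis, convolved with a single-exponential indicator decay kernel.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arbors import DENDRITE, NeuronArbor, make_arbor, write_swc
from .dynamics import ArborTimeSeries, extract_terminal_processes
from .retinotopy import CalciumMovie, StimulusProtocol

__all__ = [
    "ArborGroundTruth",
    "DynamicsEvent",
    "PunctaGroundTruth",
    "DendriteStackGroundTruth",
    "CellRF",
    "generate_arbor",
    "generate_arbor_series",
    "generate_puncta_field",
    "generate_dendrite_stack",
    "generate_calcium_movie",
    "make_roi_grid",
    "write_series",
]


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicsEvent:
    interval: int
    process_id: int
    event: str  # "added" | "lost" | "delta_length"
    magnitude: float


@dataclass
class ArborGroundTruth:
    total_length: float
    n_tips: int
    event_log: list[DynamicsEvent] = field(default_factory=list)


@dataclass
class PunctaGroundTruth:
    n_spots_channel_a: int
    n_spots_channel_b: int
    n_colocalized: int
    centers_a_um: list[tuple[float, float]]
    centers_b_um: list[tuple[float, float]]
    colocalized_centers_um: list[tuple[float, float]]
    nominal_spot_area_um2: float


@dataclass
class DendriteStackGroundTruth:
    n_puncta_inside: int
    n_puncta_outside: int
    n_puncta_in_soma: int
    inside_centers_um: list[tuple[float, float, float]]  # (z, y, x)
    outside_centers_um: list[tuple[float, float, float]]
    soma_centers_um: list[tuple[float, float, float]]


@dataclass
class CellRF:
    """Ground-truth receptive field of one simulated cell.

    ``center_deg`` and ``width_sigma_deg`` describe a Gaussian tuning curve
    over the stimulus axis in visual degrees; ``amplitude`` is the peak
    evoked response in ΔF/F₀ units; ``roi_mask`` is the cell's pixel set.
    """

    center_deg: float
    width_sigma_deg: float
    amplitude: float
    roi_mask: np.ndarray

    def __post_init__(self):
        if self.width_sigma_deg <= 0:
            raise ValueError("width_sigma_deg must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


# ---------------------------------------------------------------------------
# arbors
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_arbor(
    seed: int,
    n_branch_events: int = 8,
    mean_segment_length: float = 20.0,
) -> tuple[NeuronArbor, ArborGroundTruth]:
    """Random rooted dendritic tree with soma at the origin.

    Growth starts with a single segment from the soma; each branch event
    splits a uniformly chosen tip into two daughter segments whose directions
    perturb the parent direction outward and whose lengths are uniform in
    [0.5, 1.5] x ``mean_segment_length``.  Ground truth records the exact
    total edge length and tip count (``n_branch_events + 1``).
    """
    if mean_segment_length <= 0:
        raise ValueError("mean_segment_length must be positive")
    if n_branch_events < 0:
        raise ValueError("n_branch_events must be >= 0")
    rng = np.random.default_rng(seed)
    xyz = {1: np.zeros(3)}
    parents: dict[int, int | None] = {1: None}
    directions = {1: _unit(rng.normal(size=3))}
    total = 0.0

    def _grow(parent: int, node_id: int) -> None:
        nonlocal total
        direction = _unit(directions[parent] + 0.9 * rng.normal(size=3))
        length = float(rng.uniform(0.5, 1.5) * mean_segment_length)
        xyz[node_id] = xyz[parent] + length * direction
        parents[node_id] = parent
        directions[node_id] = direction
        total += length

    _grow(1, 2)
    tips = [2]
    next_id = 3
    for _ in range(n_branch_events):
        tip = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            _grow(tip, next_id)
            tips.append(next_id)
            next_id += 1
    rows = [
        (nid, parents[nid], float(xyz[nid][0]), float(xyz[nid][1]), float(xyz[nid][2]))
        for nid in sorted(xyz)
    ]
    arbor = make_arbor(rows)
    arbor.process_ids = {leaf: leaf for leaf in arbor.leaf_ids()}
    return arbor, ArborGroundTruth(total_length=total, n_tips=len(tips))


def generate_arbor_series(
    seed: int,
    base: NeuronArbor,
    n_intervals: int = 6,
    p_add: float = 0.4,
    p_loss: float = 0.15,
    step_sd: float = 1.5,
    interval_minutes: float = 10.0,
) -> tuple[ArborTimeSeries, ArborGroundTruth]:
    """Evolve a base arbor through birth-death-length-step dynamics.

    Per interval, each terminal process is lost with probability ``p_loss``
    (its whole leaf-to-anchor chain is removed); with probability ``p_add``
    one new process (a single segment of uniform [1, 5] µm initial length, a
    filopodium) sprouts at the soma or an existing branch point; surviving
    processes take a Gaussian length step of s.d. ``step_sd`` applied along
    their terminal segment (terminal segments are clipped to stay >= 0.1 µm).
    When a loss demotes a branch point, the sibling process absorbs the
    parent segment; the resulting length change is part of that process's
    recorded ``delta_length`` event.  Every event is logged as
    ``(interval, process_id, event, magnitude)``.

    Defaults mirror a 10-min-interval, 1-h time-lapse (6 intervals) of an
    immature tectal arbor with moderate turnover.
    """
    for name, p in (("p_add", p_add), ("p_loss", p_loss)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    rng = np.random.default_rng(seed)

    nodes = {
        int(r.node_id): [int(r.parent_id), np.array([r.x, r.y, r.z]), int(r.type), float(r.radius)]
        for r in base.nodes.itertuples()
    }
    root = base.root_id
    pids = {leaf: base.process_ids.get(leaf, leaf) for leaf in base.leaf_ids()}
    next_id = max(nodes) + 1

    def _children() -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in nodes}
        for nid, (parent, _, _, _) in nodes.items():
            if parent != -1:
                ch[parent].append(nid)
        return ch

    def _snapshot() -> NeuronArbor:
        rows = [
            (nid, nodes[nid][2], nodes[nid][1][0], nodes[nid][1][1], nodes[nid][1][2],
             nodes[nid][3], nodes[nid][0])
            for nid in sorted(nodes)
        ]
        df = pd.DataFrame(rows, columns=["node_id", "type", "x", "y", "z", "radius", "parent_id"])
        return NeuronArbor(df, dict(pids))

    def _chain(leaf: int, children: dict[int, list[int]]) -> list[int]:
        chain = [leaf]
        node = leaf
        while True:
            parent = nodes[node][0]
            if parent == root or len(children[parent]) > 1:
                return chain
            chain.append(parent)
            node = parent

    events: list[DynamicsEvent] = []
    timepoints = [_snapshot()]
    for k in range(n_intervals):
        procs = {p.process_id: p for p in extract_terminal_processes(timepoints[-1])}
        children = _children()
        # losses: decided simultaneously for the processes present at t
        lost = []
        for pid in sorted(procs):
            if rng.random() < p_loss:
                lost.append(pid)
        for pid in lost:
            leaf = procs[pid].leaf_id
            for nid in _chain(leaf, children):
                del nodes[nid]
            del pids[leaf]
            events.append(DynamicsEvent(k, pid, "lost", procs[pid].length))
            children = _children()
        # prune internal stubs orphaned when all daughters of a branch vanish
        while True:
            children = _children()
            orphans = [
                nid for nid, ch in children.items()
                if not ch and nid != root and nid not in pids
            ]
            if not orphans:
                break
            for nid in orphans:
                del nodes[nid]
        # at most one new process per interval, sprouting at soma/branch point
        if rng.random() < p_add:
            children = _children()
            anchors = sorted(
                nid for nid, ch in children.items() if nid == root or len(ch) >= 2
            )
            parent = anchors[int(rng.integers(len(anchors)))]
            length = float(rng.uniform(1.0, 5.0))
            direction = _unit(rng.normal(size=3))
            nodes[next_id] = [parent, nodes[parent][1] + length * direction, DENDRITE, 0.5]
            pids[next_id] = next_id
            events.append(DynamicsEvent(k, next_id, "added", length))
            next_id += 1
        # Gaussian length steps along the terminal segment of each survivor
        for pid in sorted(procs):
            if pid in lost:
                continue
            step = float(rng.normal(0.0, step_sd)) if step_sd > 0 else 0.0
            if step != 0.0:
                leaf = procs[pid].leaf_id
                parent = nodes[leaf][0]
                v = nodes[leaf][1] - nodes[parent][1]
                cur = float(np.linalg.norm(v))
                new_len = max(cur + step, 0.1)
                nodes[leaf][1] = nodes[parent][1] + v / cur * new_len
        nxt = _snapshot()
        new_procs = {p.process_id: p for p in extract_terminal_processes(nxt)}
        for pid in sorted(set(procs) & set(new_procs)):
            delta = new_procs[pid].length - procs[pid].length
            if delta != 0.0:
                events.append(DynamicsEvent(k, pid, "delta_length", delta))
        timepoints.append(nxt)

    parent0, child0 = base.edges_xyz()
    base_length = float(np.linalg.norm(child0 - parent0, axis=1).sum()) if len(child0) else 0.0
    truth = ArborGroundTruth(base_length, len(base.leaf_ids()), events)
    return ArborTimeSeries(timepoints, interval_minutes), truth


# ---------------------------------------------------------------------------
# punctate fields and stacks
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    min_sep: float,
    existing: list[np.ndarray],
    max_tries: int = 20000,
) -> list[np.ndarray]:
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise ValueError("cannot place spots: field too small for the requested counts")
        tries += 1
        cand = rng.uniform(low, high)
        if all(np.linalg.norm(cand - q) >= min_sep for q in existing + placed):
            placed.append(cand)
    return placed


def _render_spots_2d(
    shape: tuple[int, int],
    pixel_size: float,
    centers: list[np.ndarray],
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    h, w = shape
    yy = (np.arange(h) + 0.5) * pixel_size
    xx = (np.arange(w) + 0.5) * pixel_size
    img = np.zeros(shape)
    for c in centers:
        img += amplitude * np.exp(
            -((yy[:, None] - c[0]) ** 2 + (xx[None, :] - c[1]) ** 2) / (2 * sigma**2)
        )
    return img


def generate_puncta_field(
    seed: int,
    field_size_um: tuple[float, float] = (20.0, 20.0),
    pixel_size: float = 0.496,
    n_a: int = 8,
    n_b: int = 8,
    n_coloc: int = 4,
    spot_sigma_um: float = 0.4,
    amplitude: float = 150.0,
    background: float = 20.0,
    noise_sd: float = 4.0,
) -> tuple[tuple[np.ndarray, np.ndarray], PunctaGroundTruth]:
    """Two-channel punctate field with a known colocalized spot count.

    ``n_coloc`` spots share centres across channels; the remaining spots of
    each channel sit at well-separated positions.  Spots are Gaussian blobs
    of s.d. ``spot_sigma_um`` and peak ``amplitude`` over a flat background
    with additive Gaussian noise; images are 8-bit.  Defaults emulate a
    20 µm x 20 µm neuropil field at 0.496 µm/px.
    """
    if n_coloc > min(n_a, n_b):
        raise ValueError("n_coloc cannot exceed the per-channel spot counts")
    rng = np.random.default_rng(seed)
    h = int(round(field_size_um[0] / pixel_size))
    w = int(round(field_size_um[1] / pixel_size))
    margin = 3 * spot_sigma_um + pixel_size
    low = np.array([margin, margin])
    high = np.array([h * pixel_size - margin, w * pixel_size - margin])
    if np.any(high <= low):
        raise ValueError("field too small for the spot size")
    min_sep = max(2.0, 6 * spot_sigma_um)
    coloc = _place_points(rng, n_coloc, low, high, min_sep, [])
    only_a = _place_points(rng, n_a - n_coloc, low, high, min_sep, coloc)
    only_b = _place_points(rng, n_b - n_coloc, low, high, min_sep, coloc + only_a)

    def _channel(centers: list[np.ndarray]) -> np.ndarray:
        img = background + _render_spots_2d((h, w), pixel_size, centers, spot_sigma_um, amplitude)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    img_a = _channel(coloc + only_a)
    img_b = _channel(coloc + only_b)
    truth = PunctaGroundTruth(
        n_a, n_b, n_coloc,
        [tuple(c) for c in coloc + only_a],
        [tuple(c) for c in coloc + only_b],
        [tuple(c) for c in coloc],
        float(np.pi * (2 * spot_sigma_um) ** 2),
    )
    return (img_a, img_b), truth


def generate_dendrite_stack(
    seed: int,
    shape: tuple[int, int, int] = (8, 48, 48),
    pixel_size: float = 0.496,
    z_step: float = 1.0,
    n_puncta_inside: int = 3,
    n_puncta_outside: int = 5,
    n_puncta_in_soma: int = 0,
    tube_radius_um: float = 1.0,
    spot_sigma_um: float = 0.4,
    amplitude: float = 180.0,
    background: float = 12.0,
    noise_sd: float = 0.0,
) -> tuple[tuple[np.ndarray, np.ndarray], DendriteStackGroundTruth, np.ndarray]:
    """Two-channel z-stack: a tube-like dendrite plus puncta of known status.

    The structural channel holds a bright dendritic tube running along x
    through the stack centre and a soma blob at one end; the returned
    exclusion mask covers the soma.  The puncta channel holds 3-D Gaussian
    blobs centred on the tube axis (inside), well away from it (outside), or
    within the soma (excluded by masking).  Noiseless by default so counts
    are exact.
    """
    if tube_radius_um <= 0:
        raise ValueError("zero-volume dendrite rejected: tube_radius_um must be positive")
    if min(n_puncta_inside, n_puncta_outside, n_puncta_in_soma) < 0:
        raise ValueError("puncta counts must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz = (np.arange(nz) + 0.5) * z_step
    yy = (np.arange(ny) + 0.5) * pixel_size
    xx = (np.arange(nx) + 0.5) * pixel_size
    y0, z0 = ny * pixel_size / 2.0, nz * z_step / 2.0
    soma_center = np.array([z0, y0, 4.0])  # (z, y, x) µm
    soma_radius = 3.0

    zg, yg, xg = np.meshgrid(zz, yy, xx, indexing="ij")
    dist_axis = np.sqrt((yg - y0) ** 2 + (zg - z0) ** 2)
    # flat-cored profiles (soft shoulder of 0.5 µm): the structural label fills
    # the dendrite/soma, so foreground forms a single bright intensity mode
    shoulder = 0.5
    tube = np.exp(-(np.maximum(dist_axis - tube_radius_um, 0.0) ** 2) / (2 * shoulder**2))
    d_soma = np.sqrt(
        (zg - soma_center[0]) ** 2 + (yg - soma_center[1]) ** 2 + (xg - soma_center[2]) ** 2
    )
    soma = np.exp(-(np.maximum(d_soma - soma_radius, 0.0) ** 2) / (2 * shoulder**2))
    chan_a = background + amplitude * np.maximum(tube, soma)
    exclusion = d_soma <= soma_radius + shoulder

    x_min = soma_center[2] + soma_radius + 2.0
    x_max = nx * pixel_size - 2.0
    if x_min >= x_max:
        raise ValueError("stack too small to place puncta beyond the soma")
    inside = []
    xs = np.linspace(x_min, x_max, max(n_puncta_inside, 1), endpoint=False)
    for i in range(n_puncta_inside):
        inside.append(np.array([z0, y0, xs[i] + rng.uniform(0.0, 1.0)]))
    outside = []
    tries = 0
    while len(outside) < n_puncta_outside:
        if tries > 20000:
            raise ValueError("cannot place outside puncta")
        tries += 1
        cand = np.array([
            rng.uniform(zz[0], zz[-1]),
            rng.uniform(yy[0] + 1, yy[-1] - 1),
            rng.uniform(xx[0] + 1, xx[-1] - 1),
        ])
        off_axis = np.hypot(cand[1] - y0, cand[0] - z0)
        if off_axis < 3 * tube_radius_um + 1.0:
            continue
        if np.linalg.norm(cand - soma_center) < soma_radius + 3.0:
            continue
        if all(np.linalg.norm(cand - q) >= 2.0 for q in outside):
            outside.append(cand)
    in_soma = [
        soma_center + rng.uniform(-soma_radius / 3, soma_radius / 3, size=3)
        for _ in range(n_puncta_in_soma)
    ]

    sigma_z = 0.7
    chan_b = np.full(shape, background, dtype=float)
    for c in inside + outside + in_soma:
        chan_b += amplitude * np.exp(
            -(
                (zg - c[0]) ** 2 / (2 * sigma_z**2)
                + ((yg - c[1]) ** 2 + (xg - c[2]) ** 2) / (2 * spot_sigma_um**2)
            )
        )
    if noise_sd > 0:
        chan_a = chan_a + rng.normal(0.0, noise_sd, size=shape)
        chan_b = chan_b + rng.normal(0.0, noise_sd, size=shape)
    stack_a = np.clip(np.round(chan_a), 0, 255).astype(np.uint8)
    stack_b = np.clip(np.round(chan_b), 0, 255).astype(np.uint8)
    truth = DendriteStackGroundTruth(
        n_puncta_inside, n_puncta_outside, n_puncta_in_soma,
        [tuple(c) for c in inside], [tuple(c) for c in outside], [tuple(c) for c in in_soma],
    )
    return (stack_a, stack_b), truth, exclusion


# ---------------------------------------------------------------------------
# calcium movies
# ---------------------------------------------------------------------------

def make_roi_grid(
    shape: tuple[int, int], n_cells: int, roi_size: int = 6, stride: int = 8, margin: int = 0
) -> list[np.ndarray]:
    """Disjoint square ROI masks laid out on a grid."""
    h, w = shape
    masks = []
    for row in range(margin, h - roi_size + 1, stride):
        for col in range(margin, w - roi_size + 1, stride):
            if len(masks) == n_cells:
                return masks
            m = np.zeros(shape, dtype=bool)
            m[row : row + roi_size, col : col + roi_size] = True
            masks.append(m)
    if len(masks) < n_cells:
        raise ValueError("field too small for the requested number of ROIs")
    return masks


def generate_calcium_movie(
    seed: int,
    protocol: StimulusProtocol,
    cells: list[CellRF],
    frame_rate_hz: float = 6.0,
    f0: float = 100.0,
    decay_tau_s: float = 1.5,
    noise_sd: float = 0.0,
    pixel_size: float = 0.496,
) -> tuple[CalciumMovie, list[np.ndarray]]:
    """Calcium movie of Gaussian-receptive-field cells under a bar protocol.

    Each presentation of position ``p`` evokes, in each cell, a transient of
    peak amplitude ``A exp(-(deg(p) - center)² / (2 σ²))`` (ΔF/F₀ units)
    with an instantaneous rise at stimulus onset and single-exponential
    decay of time constant ``decay_tau_s`` (GCaMP6s-like, default 1.5 s).
    The fluorescence is ``f0 (1 + signal)`` inside the cell's ROI and ``f0``
    elsewhere, plus additive Gaussian noise of s.d. ``noise_sd`` (intensity
    units).
    """
    if decay_tau_s <= 0:
        raise ValueError("decay_tau_s must be positive")
    if not cells:
        raise ValueError("at least one cell required")
    rng = np.random.default_rng(seed)
    shape = cells[0].roi_mask.shape
    n_frames = int(max(protocol.n_frames_min, protocol.baseline_frames.max() + 1))
    tau_frames = decay_tau_s * frame_rate_hz
    kernel = np.exp(-np.arange(int(np.ceil(12 * tau_frames)) + 1) / tau_frames)
    frames = np.full((n_frames,) + shape, float(f0))
    for cell in cells:
        if cell.roi_mask.shape != shape:
            raise ValueError("all ROI masks must share the movie shape")
        signal = np.zeros(n_frames)
        for pos, onset, _ in protocol.presentations:
            deg = protocol.position_degrees[pos - 1]
            amp = cell.amplitude * np.exp(
                -((deg - cell.center_deg) ** 2) / (2 * cell.width_sigma_deg**2)
            )
            n = min(len(kernel), n_frames - onset)
            if n > 0:
                signal[onset : onset + n] += amp * kernel[:n]
        frames[:, cell.roi_mask] += f0 * signal[:, None]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    movie = CalciumMovie(np.clip(frames, 0.0, None), frame_rate_hz, pixel_size)
    return movie, [c.roi_mask for c in cells]


def generate_rf_cohort(
    seed: int,
    width_sigma_deg: float,
    n_cells: int = 36,
    shape: tuple[int, int] = (48, 48),
    amplitude: float = 8.0,
    noise_sd: float = 2.0,
    frame_rate_hz: float = 6.0,
    decay_tau_s: float = 1.5,
) -> tuple[CalciumMovie, StimulusProtocol, list[np.ndarray], list[CellRF]]:
    """One animal's worth of cells sharing a receptive-field width.

    Cells sit on a disjoint ROI grid, centred on the middle stimulus
    position, with per-cell amplitude jitter of ±1 ΔF/F₀ around
    ``amplitude``; the movie is imaged at 6 Hz with a randomized-order
    3-repeat bar protocol (1 s bars, 4 s gaps) and 2% additive noise by
    default.  Used to compare sharpness distributions between cohorts of
    narrow- and wide-field animals.
    """
    from .retinotopy import make_bar_protocol

    protocol = make_bar_protocol(
        n_repeats=3, stim_frames=6, gap_frames=24, pre_frames=24, rng=seed
    )
    masks = make_roi_grid(shape, n_cells)
    rng = np.random.default_rng(seed + 50000)
    cells = [
        CellRF(0.0, width_sigma_deg, amplitude + rng.uniform(-1.0, 1.0), m) for m in masks
    ]
    movie, rois = generate_calcium_movie(
        seed, protocol, cells,
        frame_rate_hz=frame_rate_hz, decay_tau_s=decay_tau_s, noise_sd=noise_sd,
    )
    return movie, protocol, rois, cells


# ---------------------------------------------------------------------------
# series output
# ---------------------------------------------------------------------------

def write_series(
    series: ArborTimeSeries, truth: ArborGroundTruth, out_dir: str | Path
) -> None:
    """Write a series as per-timepoint SWC files plus a JSON sidecar.

    The sidecar carries the per-timepoint leaf-to-process identity maps and
    the ground-truth event log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    identity = {}
    for t, arbor in enumerate(series.timepoints):
        write_swc(arbor, out / f"timepoint_{t:02d}.swc")
        identity[str(t)] = {str(k): int(v) for k, v in arbor.process_ids.items()}
    sidecar = {
        "interval_minutes": series.interval_minutes,
        "process_identities": identity,
        "ground_truth": {
            "total_length": truth.total_length,
            "n_tips": truth.n_tips,
            "event_log": [asdict(e) for e in truth.event_log],
        },
    }
    (out / "series.json").write_text(json.dumps(sidecar, indent=1))
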