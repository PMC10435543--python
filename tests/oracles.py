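"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives its quantity from first principles (dense sampling,
exhaustive enumeration, per-pixel loops) without touching the library code
paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np


def sholl_by_dense_sampling(arbor, radii, step_um: float = 0.01) -> np.ndarray:
    """Crossing counts by sampling every segment at ``step_um`` resolution."""
    soma = arbor.soma_xyz
    parent, child = arbor.edges_xyz()
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(len(radii), dtype=int)
    for p, c in zip(parent, child):
        seg_len = float(np.linalg.norm(c - p))
        n = max(int(math.ceil(seg_len / step_um)), 1) + 1
        t = np.linspace(0.0, 1.0, n)
        pts = p[None, :] + t[:, None] * (c - p)[None, :]
        d = np.linalg.norm(pts - soma, axis=1)
        for i, r in enumerate(radii):
            s = np.sign(d - r)
            s = s[s != 0]
            counts[i] += int(np.sum(s[1:] * s[:-1] < 0))
    return counts


def kapur_by_enumeration(counts) -> int:
    """Maximum-entropy threshold by explicit evaluation of every candidate."""
    p = [c / sum(counts) for c in counts]
    n = len(p)
    best_val, best_ks = -float("inf"), []
    for k in range(n - 1):
        p0 = sum(p[: k + 1])
        p1 = 1.0 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        hb = -sum(pi / p0 * math.log(pi / p0) for pi in p[: k + 1] if pi > 0)
        hf = -sum(pi / p1 * math.log(pi / p1) for pi in p[k + 1 :] if pi > 0)
        val = hb + hf
        if val > best_val + 1e-12:
            best_val, best_ks = val, [k]
        elif abs(val - best_val) <= 1e-12:
            best_ks.append(k)
    return best_ks[len(best_ks) // 2]


def moments_by_enumeration(counts, values=None) -> int:
    """Moment-preserving threshold by explicit evaluation of every candidate.

    For each candidate the below/above fractions and the two gray levels
    matching the first two moments are computed; the candidate with the
    smallest third-moment error wins (plateau middle on ties).
    """
    total = sum(counts)
    p = [c / total for c in counts]
    n = len(p)
    v = list(range(n)) if values is None else list(values)
    m1 = sum(pi * vi for pi, vi in zip(p, v))
    m2 = sum(pi * vi**2 for pi, vi in zip(p, v))
    m3 = sum(pi * vi**3 for pi, vi in zip(p, v))
    var = m2 - m1 * m1
    best_err, best_ks = float("inf"), []
    q0 = 0.0
    for k in range(n - 1):
        q0 += p[k]
        q1 = 1.0 - q0
        if q0 <= 0 or q1 <= 0:
            continue
        z0 = m1 - math.sqrt(var * q1 / q0)
        z1 = m1 + math.sqrt(var * q0 / q1)
        err = abs(q0 * z0**3 + q1 * z1**3 - m3)
        if err < best_err - 1e-12:
            best_err, best_ks = err, [k]
        elif abs(err - best_err) <= 1e-12:
            best_ks.append(k)
    return best_ks[len(best_ks) // 2]


def opening_by_erode_dilate(image: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with an explicit spherical element, per-pixel loops.

    Valid only where the element fits twice (>= 2*radius from every border);
    other pixels are NaN.
    """
    h, w = image.shape
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            r2 = dy * dy + dx * dx
            if r2 <= radius * radius:
                offs.append((dy, dx, math.sqrt(radius * radius - r2)))
    eroded = np.full((h, w), np.nan)
    for y in range(radius, h - radius):
        for x in range(radius, w - radius):
            eroded[y, x] = min(image[y + dy, x + dx] - b for dy, dx, b in offs)
    opened = np.full((h, w), np.nan)
    for y in range(2 * radius, h - 2 * radius):
        for x in range(2 * radius, w - 2 * radius):
            opened[y, x] = max(eroded[y - dy, x - dx] + b for dy, dx, b in offs)
    return opened


def median_by_sorting(image: np.ndarray, radius: int) -> np.ndarray:
    """Disk-footprint median via per-pixel collection on a reflect-padded copy."""
    # edge-repeating reflection (scipy's "reflect" = numpy's "symmetric")
    padded = np.pad(image.astype(float), radius, mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy * dy + dx * dx <= radius * radius:
                        vals.append(padded[y + radius + dy, x + radius + dx])
            out[y, x] = float(np.median(vals))
    return out


def ks_d_by_pooled_evaluation(a, b) -> float:
    """Two-sample KS D by evaluating both ECDFs at every pooled point."""
    a, b = list(a), list(b)
    best = 0.0
    for x in a + b:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


def aggregate_event_log(base_lengths: dict[int, float], event_log, n_intervals: int, classify):
    """Expected dynamics summary from a generator event log.

    Tracks each process's length trajectory from the base arbor through the
    logged events and aggregates per-class counts, elongation/retraction
    totals and per-interval motility under the same attribution rules the
    dynamics summary documents (class at the earlier timepoint; added by
    first, lost by last observed length).
    """
    lengths = dict(base_lengths)
    agg = {
        k: {"added": 0, "lost": 0, "elong": 0.0, "retr": 0.0, "motility": [0.0] * n_intervals}
        for k in ("filopodium", "branch")
    }
    events = sorted(event_log, key=lambda e: (e.interval, 0 if e.event == "lost" else 1))
    for e in events:
        if e.event == "added":
            agg[classify(e.magnitude)]["added"] += 1
            lengths[e.process_id] = e.magnitude
        elif e.event == "lost":
            agg[classify(lengths.pop(e.process_id))]["lost"] += 1
        else:
            k = classify(lengths[e.process_id])
            if e.magnitude > 0:
                agg[k]["elong"] += e.magnitude
            else:
                agg[k]["retr"] += -e.magnitude
            agg[k]["motility"][e.interval] += abs(e.magnitude)
            lengths[e.process_id] += e.magnitude
    return agg
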