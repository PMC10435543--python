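"""Time-lapse dynamics of terminal dendritic processes.

Terminal processes (the path from each branch tip back to the nearest branch
point or the soma) are classified as filopodia (< 10 µm) or branches
(>= 10 µm) and followed across timepoints through persistent identities
supplied by the reconstruction.  Per-interval additions, losses, elongations,
retractions, motility (sum of absolute length changes) and process density
(processes per µm of arbor) are the readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arbors import NeuronArbor
from .morphometry import total_dendritic_length

FILOPODIUM = "filopodium"
BRANCH = "branch"
CLASS_THRESHOLD_UM = 10.0


@dataclass(frozen=True)
class TerminalProcess:
    process_id: int
    length: float
    klass: str
    leaf_id: int


@dataclass
class ArborTimeSeries:
    """Ordered reconstructions of one cell sharing process identities."""

    timepoints: list[NeuronArbor]
    interval_minutes: float = 10.0

    def __post_init__(self):
        if len(self.timepoints) < 2:
            raise ValueError("a time series needs at least 2 timepoints")

    @property
    def n_intervals(self) -> int:
        return len(self.timepoints) - 1


@dataclass
class ClassDynamics:
    n_added: int = 0
    n_lost: int = 0
    total_elongation: float = 0.0
    total_retraction: float = 0.0
    motility_per_interval: list[float] = field(default_factory=list)
    mean_density: float = float("nan")


@dataclass
class DynamicsSummary:
    filopodia: ClassDynamics
    branches: ClassDynamics

    def for_class(self, klass: str) -> ClassDynamics:
        return self.filopodia if klass == FILOPODIUM else self.branches


def classify_process(length: float, threshold: float = CLASS_THRESHOLD_UM) -> str:
    """Filopodium iff length < threshold (default 10 µm); the boundary is a branch."""
    if length < 0:
        raise ValueError("process length must be non-negative")
    return FILOPODIUM if length < threshold else BRANCH


def extract_terminal_processes(
    arbor: NeuronArbor, threshold: float = CLASS_THRESHOLD_UM
) -> list[TerminalProcess]:
    """One process per leaf: the path back to the nearest branch point or soma.

    The process length is the summed segment length along that path.  The
    persistent identity is taken from ``arbor.process_ids`` when present,
    otherwise the leaf node id is used.
    """
    children = arbor.children_map()
    parents = arbor.parent_map()
    xyz = arbor.xyz()
    root = arbor.root_id
    out = []
    for leaf in arbor.leaf_ids():
        length = 0.0
        node = leaf
        while True:
            parent = parents[node]
            length += float(np.linalg.norm(xyz[node] - xyz[parent]))
            if parent == root or len(children[parent]) > 1:
                break
            node = parent
        pid = arbor.process_ids.get(leaf, leaf)
        out.append(TerminalProcess(pid, length, classify_process(length, threshold), leaf))
    return out


def diff_arbors(
    earlier: NeuronArbor, later: NeuronArbor, threshold: float = CLASS_THRESHOLD_UM
) -> tuple[list[int], list[int], list[tuple[int, float]]]:
    """Identity-matched comparison of two reconstructions.

    Returns ``(added_ids, lost_ids, shared)`` where ``shared`` is a list of
    ``(process_id, delta_length)`` with delta = later - earlier length.
    """
    pe = {p.process_id: p for p in extract_terminal_processes(earlier, threshold)}
    pl = {p.process_id: p for p in extract_terminal_processes(later, threshold)}
    if len(pe) != len(set(pe)) or len(pl) != len(set(pl)):
        raise ValueError("duplicate process identities within a timepoint")
    added = sorted(set(pl) - set(pe))
    lost = sorted(set(pe) - set(pl))
    shared = [(pid, pl[pid].length - pe[pid].length) for pid in sorted(set(pe) & set(pl))]
    return added, lost, shared


def summarize_dynamics(
    series: ArborTimeSeries, threshold: float = CLASS_THRESHOLD_UM
) -> DynamicsSummary:
    """Aggregate per-class dynamics over all intervals of a series.

    Attribution rules: a shared process's interval delta is attributed to its
    class at the *earlier* timepoint; an added process is classified by its
    first observed length, a lost one by its last.  Motility per interval is
    the sum of absolute length changes of persisting processes of the class.
    Mean density averages count/length over timepoints (zero-length
    timepoints, i.e. bare somata, are excluded from the average).
    """
    n_int = series.n_intervals
    summary = DynamicsSummary(
        ClassDynamics(motility_per_interval=[0.0] * n_int),
        ClassDynamics(motility_per_interval=[0.0] * n_int),
    )
    procs = [
        {p.process_id: p for p in extract_terminal_processes(tp, threshold)}
        for tp in series.timepoints
    ]
    for k in range(n_int):
        pe, pl = procs[k], procs[k + 1]
        for pid in sorted(set(pl) - set(pe)):
            summary.for_class(pl[pid].klass).n_added += 1
        for pid in sorted(set(pe) - set(pl)):
            summary.for_class(pe[pid].klass).n_lost += 1
        for pid in sorted(set(pe) & set(pl)):
            delta = pl[pid].length - pe[pid].length
            cd = summary.for_class(pe[pid].klass)
            if delta > 0:
                cd.total_elongation += delta
            elif delta < 0:
                cd.total_retraction += -delta
            cd.motility_per_interval[k] += abs(delta)

    densities: dict[str, list[float]] = {FILOPODIUM: [], BRANCH: []}
    for tp, pmap in zip(series.timepoints, procs):
        length = total_dendritic_length(tp)
        if length <= 0:
            continue
        for klass in (FILOPODIUM, BRANCH):
            n = sum(1 for p in pmap.values() if p.klass == klass)
            densities[klass].append(n / length)
    for klass in (FILOPODIUM, BRANCH):
        if densities[klass]:
            summary.for_class(klass).mean_density = float(np.mean(densities[klass]))
    return summary


def process_density(
    arbor: NeuronArbor, threshold: float = CLASS_THRESHOLD_UM
) -> tuple[float, float]:
    """(filopodia per µm, branches per µm) of total dendritic length."""
    length = total_dendritic_length(arbor)
    if length <= 0:
        raise ValueError("process density undefined for a zero-length arbor")
    procs = extract_terminal_processes(arbor, threshold)
    n_filo = sum(1 for p in procs if p.klass == FILOPODIUM)
    n_branch = len(procs) - n_filo
    return n_filo / length, n_branch / length
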