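"""Time-lapse quantification: fission/fusion events, rates and interaction fates.

Particles are tracked frame-to-frame by mask overlap (IoU, greedy matching
with deterministic tie-breaking). A fission is one particle at frame t whose
mask overlaps two or more particles at t+1 (each child's dominant parent
being that particle); a fusion is the mirror image. Events touching the
field border are discarded, as objects entering or leaving the field
masquerade as events, and an event immediately reversed within one frame
(a merge-split flicker) is debounced.

Rates are expressed as events per cell per second. Interaction analysis
measures contiguous marker-mitochondrion contacts and classes each contact
useful (followed by fission of the contacted mitochondrion during the
contact or within a configurable window after it ends) or futile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError


@dataclass
class DynamicsEvent:
    """A detected fission or fusion between consecutive frames."""

    type: str  # "fission" | "fusion"
    frame: int  # index of the frame where the new configuration appears
    time: float  # frame * frame_interval, s
    parents: list[int]
    children: list[int]


@dataclass
class InteractionEvent:
    """A contiguous marker-mitochondrion contact and its fate."""

    start_frame: int
    end_frame: int
    duration: float  # (end - start + 1) * frame_interval, s
    fate: str  # "useful" | "futile"
    marker: int
    mito_label: int


@dataclass
class RateSummary:
    """Event rates per cell per second."""

    fission_rate: float
    fusion_rate: float
    n_fission: int
    n_fusion: int
    n_cells: int
    observation_time: float


@dataclass
class Correspondence:
    """Frame-to-frame particle correspondence from mask overlap.

    ``matches[t]`` maps labels in frame t to their greedy IoU match in
    frame t+1; ``overlaps[t]`` holds every overlapping label pair as
    ``(label_t, label_t1) -> (overlap_px, iou)``. Border-touching labels
    per frame are recorded so event detection can exclude edge artefacts.
    """

    labels: np.ndarray
    iou_threshold: float
    matches: list[dict[int, int]] = field(default_factory=list)
    overlaps: list[dict[tuple[int, int], tuple[int, float]]] = field(default_factory=list)
    border_labels: list[set[int]] = field(default_factory=list)


def _frame_overlaps(lab_a: np.ndarray, lab_b: np.ndarray) -> dict[tuple[int, int], tuple[int, float]]:
    """Overlap pixels and IoU for every co-occurring label pair."""
    both = (lab_a > 0) & (lab_b > 0)
    out: dict[tuple[int, int], tuple[int, float]] = {}
    if not both.any():
        return out
    pairs, counts = np.unique(
        np.stack([lab_a[both], lab_b[both]]), axis=1, return_counts=True
    )
    area_a = dict(zip(*np.unique(lab_a[lab_a > 0], return_counts=True)))
    area_b = dict(zip(*np.unique(lab_b[lab_b > 0], return_counts=True)))
    for (la, lb), c in zip(pairs.T, counts):
        union = area_a[la] + area_b[lb] - c
        out[(int(la), int(lb))] = (int(c), float(c) / float(union))
    return out


def _border_labels(lab: np.ndarray, border: int) -> set[int]:
    if border <= 0:
        return set()
    edge = np.concatenate(
        [lab[:border].ravel(), lab[-border:].ravel(), lab[:, :border].ravel(), lab[:, -border:].ravel()]
    )
    return set(int(v) for v in np.unique(edge) if v > 0)


def track_components(
    labels: np.ndarray,
    iou_threshold: float = 0.3,
    border: int = 2,
) -> Correspondence:
    """Greedy IoU matching of particles across consecutive frames.

    Candidate pairs with IoU above ``iou_threshold`` are matched greedily
    in order of (IoU descending, labels ascending) so the matching is
    deterministic. Unmatched particles simply have no entry.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.ndim != 3:
        raise DataError("labels must be (T, H, W)")
    corr = Correspondence(labels=labels, iou_threshold=iou_threshold)
    for t in range(labels.shape[0]):
        corr.border_labels.append(_border_labels(labels[t], border))
    for t in range(labels.shape[0] - 1):
        ov = _frame_overlaps(labels[t], labels[t + 1])
        corr.overlaps.append(ov)
        candidates = sorted(
            ((iou, la, lb) for (la, lb), (_, iou) in ov.items() if iou >= iou_threshold),
            key=lambda x: (-x[0], x[1], x[2]),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        match: dict[int, int] = {}
        for iou, la, lb in candidates:
            if la in used_a or lb in used_b:
                continue
            match[la] = lb
            used_a.add(la)
            used_b.add(lb)
        corr.matches.append(match)
    return corr


def detect_events(
    correspondence: Correspondence,
    frame_interval: float,
    min_overlap_px: int = 1,
    debounce: bool = True,
) -> list[DynamicsEvent]:
    """Detect fissions and fusions from the frame-to-frame correspondence.

    Fission: a particle at frame t whose mask is the dominant parent of
    two or more particles at t+1. Fusion: a particle at t+1 whose mask is
    the dominant child of two or more particles at t. Events involving
    border-touching particles are excluded, and with ``debounce`` an event
    undone within one frame (split immediately re-merged, or vice versa)
    is dropped together with its reversal.
    """
    events: list[DynamicsEvent] = []
    for t, ov in enumerate(correspondence.overlaps):
        if not ov:
            continue
        # dominant assignments by overlap pixels (ties to the smaller label)
        best_parent: dict[int, int] = {}
        best_child: dict[int, int] = {}
        for (la, lb), (px, _) in sorted(ov.items()):
            if px < min_overlap_px:
                continue
            if lb not in best_parent or px > ov[(best_parent[lb], lb)][0]:
                best_parent[lb] = la
            if la not in best_child or px > ov[(la, best_child[la])][0]:
                best_child[la] = lb
        children_of: dict[int, list[int]] = {}
        for lb, la in best_parent.items():
            children_of.setdefault(la, []).append(lb)
        parents_of: dict[int, list[int]] = {}
        for la, lb in best_child.items():
            parents_of.setdefault(lb, []).append(la)
        border_t = correspondence.border_labels[t]
        border_t1 = correspondence.border_labels[t + 1]
        for la, kids in sorted(children_of.items()):
            if len(kids) >= 2:
                if la in border_t or any(k in border_t1 for k in kids):
                    continue
                events.append(
                    DynamicsEvent("fission", t + 1, (t + 1) * frame_interval, [la], sorted(kids))
                )
        for lb, pars in sorted(parents_of.items()):
            if len(pars) >= 2:
                if lb in border_t1 or any(p in border_t for p in pars):
                    continue
                events.append(
                    DynamicsEvent("fusion", t + 1, (t + 1) * frame_interval, sorted(pars), [lb])
                )
    if debounce:
        events = _debounce(events)
    return events


def _debounce(events: list[DynamicsEvent]) -> list[DynamicsEvent]:
    """Drop event pairs undone within one frame (merge-split flicker)."""
    drop: set[int] = set()
    for i, e in enumerate(events):
        if i in drop:
            continue
        for j, f in enumerate(events):
            if j <= i or j in drop:
                continue
            if f.frame - e.frame == 1 and e.type != f.type and set(e.children) == set(f.parents):
                drop.update((i, j))
                break
    return [e for i, e in enumerate(events) if i not in drop]


def event_rates(
    events: list[DynamicsEvent], n_cells: int, duration_s: float
) -> RateSummary:
    """Fission/fusion rates in events per cell per second."""
    if duration_s <= 0:
        raise ConfigurationError("duration must be positive")
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    n_fis = sum(1 for e in events if e.type == "fission")
    n_fus = sum(1 for e in events if e.type == "fusion")
    denom = n_cells * duration_s
    return RateSummary(
        fission_rate=n_fis / denom,
        fusion_rate=n_fus / denom,
        n_fission=n_fis,
        n_fusion=n_fus,
        n_cells=n_cells,
        observation_time=duration_s,
    )


def interaction_analysis(
    marker_masks: np.ndarray,
    mito_labels: np.ndarray,
    events: list[DynamicsEvent],
    frame_interval: float,
    fate_window: int = 2,
    min_overlap_px: int = 1,
) -> tuple[list[InteractionEvent], float]:
    """Marker-mitochondrion contact durations and useful/futile fates.

    A contact exists in a frame when the binary marker mask overlaps a
    mitochondrion's mask by at least ``min_overlap_px`` pixels. Contiguous
    contact frames with the same mitochondrion form one interaction whose
    duration is ``(end - start + 1) * frame_interval``. The fate is
    ``useful`` iff a fission with that mitochondrion as parent occurs
    between the contact start and ``fate_window`` frames after the contact
    ends; otherwise ``futile``. Returns the interactions and their mean
    duration (NaN when there are none).
    """
    marker_masks = np.asarray(marker_masks).astype(bool)
    mito_labels = np.asarray(mito_labels)
    if marker_masks.shape != mito_labels.shape:
        raise DataError("marker and mitochondria channels have different shapes")
    if marker_masks.ndim != 3:
        raise DataError("expected (T, H, W) stacks")
    T = marker_masks.shape[0]
    contact_frames: dict[int, list[int]] = {}
    for t in range(T):
        touched = mito_labels[t][marker_masks[t]]
        touched = touched[touched > 0]
        if touched.size == 0:
            continue
        labs, counts = np.unique(touched, return_counts=True)
        for lab, c in zip(labs, counts):
            if c >= min_overlap_px:
                contact_frames.setdefault(int(lab), []).append(t)
    fission_by_parent: dict[int, list[int]] = {}
    for e in events:
        if e.type == "fission":
            for p in e.parents:
                fission_by_parent.setdefault(p, []).append(e.frame)
    interactions: list[InteractionEvent] = []
    for lab in sorted(contact_frames):
        frames = contact_frames[lab]
        runs: list[tuple[int, int]] = []
        start = prev = frames[0]
        for f in frames[1:]:
            if f == prev + 1:
                prev = f
            else:
                runs.append((start, prev))
                start = prev = f
        runs.append((start, prev))
        for s, e_ in runs:
            fission_frames = fission_by_parent.get(lab, [])
            useful = any(s <= ff <= e_ + fate_window for ff in fission_frames)
            interactions.append(
                InteractionEvent(
                    start_frame=s,
                    end_frame=e_,
                    duration=(e_ - s + 1) * frame_interval,
                    fate="useful" if useful else "futile",
                    marker=0,
                    mito_label=lab,
                )
            )
    mean_duration = (
        float(np.mean([i.duration for i in interactions])) if interactions else float("nan")
    )
    return interactions, mean_duration
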