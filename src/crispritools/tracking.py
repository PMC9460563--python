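"""Frame-to-frame cell linking, division detection and lineage construction.

Linking solves a gated linear assignment (Jaqaman-style) between the
objects of consecutive labelled frames; a track that ends while exactly
two new objects appear nearby, with a combined area close to the ended
track's, becomes a mother with two daughters.  No gap closing is
performed: frames are densely sampled, so a cell missing from one frame
terminates its track.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "LinkingParams",
    "Track",
    "TrackSet",
    "Assignment",
    "DivisionEvent",
    "link_frames",
    "detect_divisions",
    "build_lineage",
    "trackset_from_ground_truth",
]

_BIG = 1e12


@dataclass
class LinkingParams:
    """Gates and cost model for frame-to-frame linking.

    ``max_link_distance`` gates ordinary links; ``division_distance``
    gates daughter-to-mother proximity.  ``cost`` is ``"centroid"``
    (Euclidean centroid distance, default) or ``"one_minus_iou"``.
    ``division_area_window`` bounds the daughters' combined area relative
    to the mother's last area.
    """

    max_link_distance: float = 10.0  # px
    division_distance: float = 15.0  # px
    cost: str = "centroid"
    division_area_window: tuple = (0.6, 1.4)

    def __post_init__(self):
        if self.max_link_distance <= 0 or self.division_distance <= 0:
            raise ValueError("gates must be positive")
        if self.cost not in ("centroid", "one_minus_iou"):
            raise ValueError(f"unknown cost {self.cost!r}")

    @classmethod
    def for_colony(cls, pixel_size_um: float, division_length_um: float, **kw):
        """Gates scaled to a colony's geometry.

        At division the daughters' centroids sit about a quarter of the
        mother's length from her centroid, so the division gate must
        exceed ``division_length / 4`` in pixels; ordinary frame-to-frame
        drift is a small fraction of a cell length.
        """
        l_px = division_length_um / pixel_size_um
        kw.setdefault("max_link_distance", max(10.0, 0.20 * l_px))
        kw.setdefault("division_distance", max(15.0, 0.45 * l_px))
        return cls(**kw)


@dataclass
class Assignment:
    """Result of linking two frames: matched label pairs and leftovers."""

    pairs: list  # [(label_t, label_t1), ...]
    unmatched_t: list
    unmatched_t1: list


@dataclass
class DivisionEvent:
    mother_track: int
    daughter_labels: tuple  # labels in frame t+1


def _objects(mask):
    """Per-label centroid (row, col) and area, sorted by label."""
    props = measure.regionprops(mask)
    labels = np.array([p.label for p in props])
    order = np.argsort(labels)
    centroids = np.array([props[i].centroid for i in order], dtype=float).reshape(-1, 2)
    areas = np.array([props[i].area for i in order], dtype=float)
    return labels[order], centroids, areas


def _iou_matrix(mask_t, mask_t1, labels_t, labels_t1):
    joint = pd.crosstab(mask_t.ravel(), mask_t1.ravel())
    areas_t = {l: int((mask_t == l).sum()) for l in labels_t}
    areas_t1 = {l: int((mask_t1 == l).sum()) for l in labels_t1}
    iou = np.zeros((len(labels_t), len(labels_t1)))
    for i, la in enumerate(labels_t):
        for j, lb in enumerate(labels_t1):
            inter = joint.at[la, lb] if (la in joint.index and lb in joint.columns) else 0
            if inter:
                iou[i, j] = inter / (areas_t[la] + areas_t1[lb] - inter)
    return iou


def link_frames(mask_t, mask_t1, params: LinkingParams | None = None) -> Assignment:
    """One-to-one gated minimum-cost assignment between consecutive frames.

    Objects of ``mask_t1`` left unmatched are birth candidates; objects of
    ``mask_t`` left unmatched are track-end candidates.  Deterministic.
    """
    params = params or LinkingParams()
    mask_t = np.asarray(mask_t)
    mask_t1 = np.asarray(mask_t1)
    if mask_t.shape != mask_t1.shape:
        raise ValueError(
            f"frame geometry mismatch: {mask_t.shape} vs {mask_t1.shape}"
        )
    labels_t, cent_t, _ = _objects(mask_t)
    labels_t1, cent_t1, _ = _objects(mask_t1)
    if labels_t.size == 0 or labels_t1.size == 0:
        return Assignment([], list(labels_t), list(labels_t1))

    dist = np.linalg.norm(cent_t[:, None, :] - cent_t1[None, :, :], axis=2)
    feasible = dist <= params.max_link_distance
    if params.cost == "centroid":
        cost = dist.copy()
    else:
        cost = 1.0 - _iou_matrix(mask_t, mask_t1, labels_t, labels_t1)
    cost[~feasible] = _BIG

    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_t, matched_t1 = set(), set()
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            pairs.append((int(labels_t[i]), int(labels_t1[j])))
            matched_t.add(int(labels_t[i]))
            matched_t1.add(int(labels_t1[j]))
    pairs.sort()
    unmatched_t = [int(l) for l in labels_t if l not in matched_t]
    unmatched_t1 = [int(l) for l in labels_t1 if l not in matched_t1]
    return Assignment(pairs, unmatched_t, unmatched_t1)


def detect_divisions(
    ended_tracks: list,
    birth_candidates: list,
    params: LinkingParams | None = None,
) -> list:
    """Pair ended tracks with daughter pairs among the birth candidates.

    ``ended_tracks``: iterable of ``(track_id, centroid (row, col), area)``.
    ``birth_candidates``: iterable of ``(label, centroid, area)``.  An
    ended track becomes a mother when *exactly two* birth candidates lie
    within the division gate of its last centroid and their combined area
    falls within the area window.  Ambiguities (shared candidates,
    crowded neighbourhoods) are logged and skipped, never fatal.
    """
    params = params or LinkingParams()
    lo, hi = params.division_area_window
    events = []
    claimed = set()
    for track_id, centroid, area in ended_tracks:
        centroid = np.asarray(centroid, dtype=float)
        near = [
            (label, np.asarray(c, dtype=float), a)
            for label, c, a in birth_candidates
            if label not in claimed
            and np.linalg.norm(np.asarray(c, dtype=float) - centroid)
            <= params.division_distance
        ]
        if len(near) != 2:
            if len(near) > 2:
                logger.info(
                    "track %s: %d birth candidates in division gate; ambiguous",
                    track_id,
                    len(near),
                )
            continue
        combined = near[0][2] + near[1][2]
        if not lo * area <= combined <= hi * area:
            logger.info(
                "track %s: daughter area sum %.0f outside window of mother %.0f",
                track_id,
                combined,
                area,
            )
            continue
        daughters = tuple(sorted(int(n[0]) for n in near))
        claimed.update(daughters)
        events.append(DivisionEvent(int(track_id), daughters))
    return events


@dataclass
class Track:
    """Per-cell time series with lineage links."""

    cell_id: int
    mother_id: int | None = None
    daughter_ids: tuple = ()
    generation: int = 0
    frames: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    centroids: list = field(default_factory=list)  # (row, col) px
    areas_px: list = field(default_factory=list)
    lengths_um: list = field(default_factory=list)
    total_fluor: list = field(default_factory=list)
    border: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def touches_border(self) -> bool:
        return any(self.border)


@dataclass
class TrackSet:
    """All tracks of one movie plus shared calibration."""

    tracks: dict
    n_frames: int
    pixel_size_um: float
    frame_interval_min: float
    frame_background: list = field(default_factory=list)

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    def tracks_in_frame(self, frame: int):
        return [t for t in self.tracks.values() if frame in t.frames]

    def to_frames_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks.values():
            for k, f in enumerate(t.frames):
                rows.append(
                    {
                        "cell_id": t.cell_id,
                        "frame": f,
                        "label": t.labels[k],
                        "centroid_row": t.centroids[k][0],
                        "centroid_col": t.centroids[k][1],
                        "area_px": t.areas_px[k],
                        "length_um": t.lengths_um[k],
                        "total_fluor": t.total_fluor[k],
                        "border": t.border[k],
                    }
                )
        return pd.DataFrame(rows).sort_values(["cell_id", "frame"]).reset_index(drop=True)

    def to_lineage_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": t.cell_id,
                "mother_id": -1 if t.mother_id is None else t.mother_id,
                "generation": t.generation,
                "first_frame": t.frames[0],
                "last_frame": t.frames[-1],
            }
            for t in self.tracks.values()
        ]
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)

    def lineage_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for t in self.tracks.values():
            g.add_node(t.cell_id, generation=t.generation)
        for t in self.tracks.values():
            for d in t.daughter_ids:
                g.add_edge(t.cell_id, d)
        return g


def _frame_properties(mask, fluor):
    """label -> (centroid, area, major axis px, total fluor, border flag)."""
    props = measure.regionprops(mask, intensity_image=fluor)
    h, w = mask.shape
    out = {}
    for p in props:
        minr, minc, maxr, maxc = p.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        out[p.label] = (
            tuple(p.centroid),
            float(p.area),
            float(p.axis_major_length),
            float(p.image_intensity.sum()),
            border,
        )
    return out


def _modal_background(fluor, mask, n_bins: int = 256) -> float:
    """Mode of the non-cell pixel intensities (densest histogram bin)."""
    bg = np.asarray(fluor, dtype=float)[np.asarray(mask) == 0]
    if bg.size == 0:
        return 0.0
    if np.ptp(bg) == 0:
        return float(bg[0])
    counts, edges = np.histogram(bg, bins=n_bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def build_lineage(
    mask_stack,
    fluor_stack,
    params: LinkingParams | None = None,
    pixel_size_um: float = 0.065,
    frame_interval_min: float = 8.0,
    root_generation: int = 0,
) -> TrackSet:
    """Track every label of a mask stack and assemble the lineage.

    Every label in every frame belongs to exactly one track.  Per frame,
    each track records its label, centroid, area (px), length (major-axis
    length of the second-moment ellipse, um) and total fluorescence; the
    per-frame modal background of non-cell pixels is stored on the
    TrackSet for downstream concentration estimates.  Unexplained
    appearances become new root tracks with ``root_generation``.
    """
    params = params or LinkingParams()
    mask_stack = np.asarray(mask_stack)
    fluor_stack = np.asarray(fluor_stack)
    if mask_stack.shape != fluor_stack.shape:
        raise ValueError("mask and fluorescence stacks have mismatched shapes")
    n_frames = mask_stack.shape[0]

    tracks: dict[int, Track] = {}
    next_id = 1
    frame_bg = []

    def start_track(frame, label, props, mother=None, generation=root_generation):
        nonlocal next_id
        t = Track(cell_id=next_id, mother_id=mother, generation=generation)
        tracks[next_id] = t
        next_id += 1
        append_obs(t, frame, label, props)
        return t

    def append_obs(track, frame, label, props):
        centroid, area, major_px, fluor_tot, border = props[label]
        track.frames.append(frame)
        track.labels.append(int(label))
        track.centroids.append(centroid)
        track.areas_px.append(area)
        track.lengths_um.append(major_px * pixel_size_um)
        track.total_fluor.append(fluor_tot)
        track.border.append(border)

    props_prev = _frame_properties(mask_stack[0], fluor_stack[0])
    frame_bg.append(_modal_background(fluor_stack[0], mask_stack[0]))
    active = {}  # current label -> track
    for label in sorted(props_prev):
        active[label] = start_track(0, label, props_prev)

    for f in range(1, n_frames):
        props_cur = _frame_properties(mask_stack[f], fluor_stack[f])
        frame_bg.append(_modal_background(fluor_stack[f], mask_stack[f]))
        assign = link_frames(mask_stack[f - 1], mask_stack[f], params)

        new_active = {}
        for lab_prev, lab_cur in assign.pairs:
            track = active[lab_prev]
            append_obs(track, f, lab_cur, props_cur)
            new_active[lab_cur] = track

        ended = [
            (active[lab].cell_id, active[lab].centroids[-1], active[lab].areas_px[-1])
            for lab in assign.unmatched_t
        ]
        births = [
            (lab, props_cur[lab][0], props_cur[lab][1]) for lab in assign.unmatched_t1
        ]
        events = detect_divisions(ended, births, params)
        claimed = set()
        for ev in events:
            mother = tracks[ev.mother_track]
            d_ids = []
            for lab in ev.daughter_labels:
                d = start_track(
                    f, lab, props_cur, mother=mother.cell_id,
                    generation=mother.generation + 1,
                )
                new_active[lab] = d
                d_ids.append(d.cell_id)
                claimed.add(lab)
            mother.daughter_ids = tuple(d_ids)
        for lab in assign.unmatched_t1:
            if lab not in claimed:
                new_active[lab] = start_track(f, lab, props_cur)
        active = new_active
        props_prev = props_cur

    return TrackSet(
        tracks=tracks,
        n_frames=n_frames,
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
        frame_background=frame_bg,
    )


def trackset_from_ground_truth(truth, movie) -> TrackSet:
    """Validation helper: assemble a TrackSet directly from generator truth.

    Uses the noiseless per-cell records (area, length, total fluorescence)
    and the true lineage, bypassing segmentation and linking.  Background
    is zero by construction.
    """
    tracks: dict[int, Track] = {}
    lin = truth.lineage.set_index("cell_id")
    for cid, row in lin.iterrows():
        mother = None if row["mother_id"] < 0 else int(row["mother_id"])
        tracks[int(cid)] = Track(
            cell_id=int(cid), mother_id=mother, generation=int(row["generation"])
        )
    for mother_id, grp in lin.groupby("mother_id"):
        if mother_id >= 0:
            tracks[int(mother_id)].daughter_ids = tuple(int(i) for i in grp.index)
    h, w = truth.masks.shape[1:]
    for rec in truth.cells.itertuples():
        t = tracks[int(rec.cell_id)]
        t.frames.append(int(rec.frame))
        t.labels.append(int(rec.cell_id))
        t.centroids.append((rec.centroid_row, rec.centroid_col))
        t.areas_px.append(float(rec.area_px))
        t.lengths_um.append(float(rec.length_um))
        t.total_fluor.append(float(rec.total_fluorescence))
        t.border.append(False)
    n_frames = truth.masks.shape[0]
    return TrackSet(
        tracks=tracks,
        n_frames=n_frames,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_min=movie.frame_interval_min,
        frame_background=[0.0] * n_frames,
    )
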