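"""Single-cell statistics: growth rate, GFP concentration, dF/dt, filamentation.

All estimators act on :class:`~crispritools.tracking.Track` /
:class:`~crispritools.tracking.TrackSet` objects.  Growth rate is the
least-squares slope of ln(cell length) over a track's lifespan; cellular
GFP concentration divides background-subtracted total fluorescence by
cell area; dF/dt is the slope of that concentration over the lifespan.
A cell is classed as filamenting when it never divides over the whole
observation *and* its cross-sectional area exceeds a threshold (default
9 um^2, strictly greater) calibrated as the largest area seen in a
wild-type-phenotype control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tracking import Track, TrackSet

__all__ = [
    "MetricsParams",
    "growth_rate",
    "gfp_concentration",
    "dFdt",
    "population_mean_gfp",
    "classify_filament",
    "generation_filament_fraction",
    "filament_area_fraction",
    "tracks_metrics_table",
]


@dataclass
class MetricsParams:
    pixel_size: float = 0.065  # um per px
    filament_area_threshold: float = 9.0  # um^2
    min_track_frames: int = 3
    exclude_border_cells: bool = True
    background_method: str = "mode"  # "mode" | "none"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.filament_area_threshold <= 0:
            raise ValueError("filament_area_threshold must be positive")
        if self.background_method not in ("mode", "none"):
            raise ValueError("background_method must be 'mode' or 'none'")


def _track_times_h(track: Track, frame_interval_h: float) -> np.ndarray:
    return np.asarray(track.frames, dtype=float) * frame_interval_h


def growth_rate(
    track: Track,
    frame_interval_h: float,
    min_track_frames: int = 3,
) -> float:
    """Least-squares slope of ln(length) vs time (1/h) over the lifespan.

    Returns NaN (with a warning) for tracks shorter than
    ``min_track_frames`` frames or with non-positive lengths.
    """
    lengths = np.asarray(track.lengths_um, dtype=float)
    if lengths.size < min_track_frames:
        warnings.warn(
            f"track {track.cell_id}: only {lengths.size} frames; growth rate undefined"
        )
        return float("nan")
    if np.any(lengths <= 0):
        warnings.warn(f"track {track.cell_id}: non-positive length")
        return float("nan")
    t = _track_times_h(track, frame_interval_h)
    return float(np.polyfit(t, np.log(lengths), 1)[0])


def _concentration_series(
    track: Track, background: float | list | None
) -> np.ndarray:
    tot = np.asarray(track.total_fluor, dtype=float)
    area = np.asarray(track.areas_px, dtype=float)
    if np.any(area <= 0):
        raise ValueError(f"track {track.cell_id}: zero cell area")
    if background is None:
        bg = np.zeros_like(tot)
    elif np.isscalar(background):
        bg = np.full_like(tot, float(background))
    else:
        bg = np.asarray([background[f] for f in track.frames], dtype=float)
    return (tot - bg * area) / area


def gfp_concentration(
    track: Track,
    frame: int,
    background: float | list | None = None,
) -> float:
    """Cellular GFP concentration (AU per px) of a cell in one frame.

    Total fluorescence divided by area (px), after subtracting the
    per-frame background (per-pixel modal intensity of non-cell pixels,
    typically ``TrackSet.frame_background``).
    """
    if frame not in track.frames:
        raise ValueError(f"track {track.cell_id} not present in frame {frame}")
    k = track.frames.index(frame)
    return float(_concentration_series(track, background)[k])


def dFdt(
    track: Track,
    frame_interval_h: float,
    background: float | list | None = None,
    min_track_frames: int = 3,
) -> float:
    """Slope of cellular GFP concentration vs time (AU per px per h)."""
    conc = _concentration_series(track, background)
    if conc.size < min_track_frames:
        warnings.warn(
            f"track {track.cell_id}: only {conc.size} frames; dF/dt undefined"
        )
        return float("nan")
    t = _track_times_h(track, frame_interval_h)
    return float(np.polyfit(t, conc, 1)[0])


def _present_tracks(trackset: TrackSet, frame: int, params: MetricsParams):
    out = []
    for t in trackset.tracks.values():
        if frame not in t.frames:
            continue
        if params.exclude_border_cells and t.border[t.frames.index(frame)]:
            continue
        out.append(t)
    return out


def population_mean_gfp(
    trackset: TrackSet,
    frame: int,
    params: MetricsParams | None = None,
):
    """Unweighted mean and sample sd of cellular GFP concentration in a frame.

    Returns ``(mean, sd, n)``; ``sd`` is reported as 0.0 for a single
    cell (sample sd undefined).  Empty frame -> ``(nan, nan, 0)``.
    """
    params = params or MetricsParams()
    bg = trackset.frame_background if params.background_method == "mode" else None
    tracks = _present_tracks(trackset, frame, params)
    if not tracks:
        return float("nan"), float("nan"), 0
    concs = np.array([gfp_concentration(t, frame, bg) for t in tracks])
    sd = float(concs.std(ddof=1)) if concs.size > 1 else 0.0
    return float(concs.mean()), sd, int(concs.size)


def classify_filament(
    track: Track,
    params: MetricsParams | None = None,
) -> bool:
    """True iff the track never divides and its max area exceeds the threshold.

    Area is converted as ``area_px * pixel_size**2`` (um^2); the boundary
    is strict (> threshold).
    """
    params = params or MetricsParams()
    if len(track.daughter_ids) > 0:
        return False
    if not track.areas_px:
        return False
    max_area_um2 = max(track.areas_px) * params.pixel_size**2
    return max_area_um2 > params.filament_area_threshold


def generation_filament_fraction(
    trackset: TrackSet,
    params: MetricsParams | None = None,
) -> dict:
    """Fraction of cells of each generation classed as filamenting."""
    params = params or MetricsParams()
    totals: dict[int, int] = {}
    filaments: dict[int, int] = {}
    for t in trackset.tracks.values():
        totals[t.generation] = totals.get(t.generation, 0) + 1
        if classify_filament(t, params):
            filaments[t.generation] = filaments.get(t.generation, 0) + 1
    return {g: filaments.get(g, 0) / n for g, n in sorted(totals.items())}


def filament_area_fraction(
    trackset: TrackSet,
    frame: int,
    params: MetricsParams | None = None,
) -> float:
    """Fraction of total cell area in a frame held by filamenting cells."""
    params = params or MetricsParams()
    tracks = _present_tracks(trackset, frame, params)
    if not tracks:
        raise ValueError(f"no cells present in frame {frame}")
    total = 0.0
    fil = 0.0
    for t in tracks:
        a = t.areas_px[t.frames.index(frame)]
        total += a
        if classify_filament(t, params):
            fil += a
    return fil / total


def tracks_metrics_table(
    trackset: TrackSet,
    params: MetricsParams | None = None,
):
    """Per-cell summary table: growth rate, mean concentration, dF/dt, filament flag."""
    import pandas as pd

    params = params or MetricsParams()
    dt_h = trackset.frame_interval_h
    bg = trackset.frame_background if params.background_method == "mode" else None
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in sorted(trackset.tracks.values(), key=lambda t: t.cell_id):
            conc = _concentration_series(t, bg)
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "generation": t.generation,
                    "n_frames": t.n_frames,
                    "growth_rate_per_h": growth_rate(t, dt_h, params.min_track_frames),
                    "mean_conc_au_per_px": float(conc.mean()),
                    "dFdt_au_per_px_per_h": dFdt(t, dt_h, bg, params.min_track_frames),
                    "filament": classify_filament(t, params),
                    "touches_border": t.touches_border,
                }
            )
    return pd.DataFrame(rows)
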