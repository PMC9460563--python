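"""File formats: TIFF movies and masks, long-format CSV tables, FASTA, results JSON.

Conventions: coordinates are 0-based, row-major, pixel-centre; times are in
hours; labelled masks use 0 for background; CSV is comma-separated UTF-8
with '.' decimals and units suffixed in column names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import metadata as _metadata

import numpy as np
import pandas as pd
import tifffile

from .assay import CultureSeries, WellSeries

__all__ = [
    "MovieStack",
    "read_movie",
    "write_movie",
    "read_masks",
    "write_masks",
    "read_plate_csv",
    "write_plate_csv",
    "wells_from_dataframe",
    "read_culture_csv",
    "write_culture_csv",
    "write_results",
    "load_genome",
    "config_hash",
]

PLATE_COLUMNS = ["well", "strain_role", "media_class", "time_h", "od600", "fluor"]
CULTURE_COLUMNS = ["time_h", "od600", "p_ca_mm", "hba_mm", "pca_mm", "bka_mm"]


def _package_version() -> str:
    try:
        return _metadata.version("crispritools")
    except _metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class MovieStack:
    """Paired brightfield + fluorescence stacks with spatial/temporal calibration."""

    brightfield: np.ndarray  # (n_frames, rows, cols)
    fluorescence: np.ndarray
    pixel_size_um: float = 0.065
    frame_interval_min: float = 8.0

    def __post_init__(self):
        self.brightfield = np.asarray(self.brightfield)
        self.fluorescence = np.asarray(self.fluorescence)
        if self.brightfield.ndim != 3 or self.fluorescence.ndim != 3:
            raise ValueError("movie stacks must be 3-D (frame, row, col)")
        if self.brightfield.shape != self.fluorescence.shape:
            raise ValueError(
                "brightfield and fluorescence stacks have mismatched shapes: "
                f"{self.brightfield.shape} vs {self.fluorescence.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.brightfield.shape[0]

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0


def _to_uint16(stack: np.ndarray) -> np.ndarray:
    if stack.dtype in (np.uint8, np.uint16):
        return stack.astype(np.uint16)
    return np.clip(np.rint(stack), 0, 65535).astype(np.uint16)


def write_movie(stack: MovieStack, brightfield_path, fluorescence_path) -> None:
    """Write the two channels as multi-page 16-bit TIFFs.

    Calibration metadata is stored as JSON in the TIFF description tag so a
    read round-trips it losslessly.  Float data is rounded and clipped to
    the 16-bit range.
    """
    meta = json.dumps(
        {
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_min": stack.frame_interval_min,
        }
    )
    for data, path in (
        (stack.brightfield, brightfield_path),
        (stack.fluorescence, fluorescence_path),
    ):
        tifffile.imwrite(
            path, _to_uint16(data), description=meta, photometric="minisblack"
        )


def read_movie(brightfield_path, fluorescence_path) -> MovieStack:
    stacks = []
    meta = {}
    for path in (brightfield_path, fluorescence_path):
        with tifffile.TiffFile(path) as tif:
            stacks.append(tif.asarray())
            desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                pass
    bf, fl = (np.atleast_3d(s) if s.ndim < 3 else s for s in stacks)
    if bf.ndim == 2:
        bf = bf[None]
    if fl.ndim == 2:
        fl = fl[None]
    if bf.shape != fl.shape:
        raise ValueError(
            f"channel shape mismatch: brightfield {bf.shape} vs fluorescence {fl.shape}"
        )
    return MovieStack(
        bf,
        fl,
        pixel_size_um=float(meta.get("pixel_size_um", 0.065)),
        frame_interval_min=float(meta.get("frame_interval_min", 8.0)),
    )


def write_masks(masks: np.ndarray, path) -> None:
    """Write an integer-labelled mask stack as a multi-page TIFF."""
    tifffile.imwrite(
        path, np.asarray(masks).astype(np.int32), photometric="minisblack"
    )


def read_masks(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int32)


# ---------------------------------------------------------------------------
# plate-reader / culture CSV
# ---------------------------------------------------------------------------


def wells_from_dataframe(df: pd.DataFrame) -> list:
    """Long-format plate table -> list of :class:`WellSeries`.

    Rows may arrive in any order; they are sorted by time within each well.
    Non-increasing time after sorting (duplicate time points) raises.
    """
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing column(s): {', '.join(missing)}")
    wells = []
    for well_id, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        roles = grp["strain_role"].unique()
        media = grp["media_class"].unique()
        if len(roles) != 1 or len(media) != 1:
            raise ValueError(f"well {well_id!r}: inconsistent role/media annotations")
        wells.append(
            WellSeries(
                well_id=str(well_id),
                strain_role=str(roles[0]),
                media_class=str(media[0]),
                time_h=grp["time_h"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                fluorescence=grp["fluor"].to_numpy(),
            )
        )
    return wells


def read_plate_csv(path) -> list:
    return wells_from_dataframe(pd.read_csv(path))


def wells_to_dataframe(wells) -> pd.DataFrame:
    frames = []
    for w in wells:
        frames.append(
            pd.DataFrame(
                {
                    "well": w.well_id,
                    "strain_role": w.strain_role,
                    "media_class": w.media_class,
                    "time_h": w.time_h,
                    "od600": w.od600,
                    "fluor": w.fluorescence,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_plate_csv(wells, path) -> None:
    wells_to_dataframe(wells).to_csv(path, index=False)


def write_culture_csv(culture: CultureSeries, path) -> None:
    pd.DataFrame(
        {
            "time_h": culture.time_h,
            "od600": culture.od600,
            "p_ca_mm": culture.p_ca_mm,
            "hba_mm": culture.hba_mm,
            "pca_mm": culture.pca_mm,
            "bka_mm": culture.bka_mm,
        }
    ).to_csv(path, index=False)


def read_culture_csv(path) -> CultureSeries:
    df = pd.read_csv(path)
    missing = [c for c in CULTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"culture table missing column(s): {', '.join(missing)}")
    df = df.sort_values("time_h")
    return CultureSeries(*(df[c].to_numpy() for c in CULTURE_COLUMNS))


# ---------------------------------------------------------------------------
# results + provenance
# ---------------------------------------------------------------------------


def config_hash(config) -> str:
    """SHA-256 of the canonical JSON rendering of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(results: dict, path, config: dict | None = None) -> None:
    """Emit results as JSON, stamped with the package version and config hash."""
    payload = dict(results)
    payload["package_version"] = _package_version()
    if config is not None:
        payload["config_sha256"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def load_genome(path) -> dict:
    """FASTA -> {contig name: upper-case sequence string}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
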