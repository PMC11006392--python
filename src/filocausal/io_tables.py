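"""Reading, writing and quality-filtering of filopodium measurement tables.

Tables are comma-separated with one header row, one row per (track, frame).
Column names follow the Filopodyan/FilopodyanR convention by default but can
be remapped with a ``column_map``. Missing cells (empty or ``NA``) become NaN.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilopodiumTrack",
    "TrackFilterConfig",
    "DEFAULT_COLUMN_MAP",
    "read_track_tables",
    "write_track_tables",
    "apply_track_filters",
    "read_localizations",
    "write_localizations",
]

#: canonical field -> default CSV column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "track_id": "filo_id",
    "frame": "frame",
    "tip_fluor": "tip_fluor",
    "base_fluor": "base_fluor",
    "body_fluor": "body_fluor",
    "boundary_fluor": "boundary_fluor",
    "length": "length",
    "tip_movement": "tip_movement",
    "base_movement": "base_movement",
    "waviness": "waviness",
}

_NUMERIC_FIELDS = [
    "tip_fluor",
    "base_fluor",
    "body_fluor",
    "boundary_fluor",
    "length",
    "tip_movement",
    "base_movement",
    "waviness",
]


class TableFormatError(ValueError):
    """Raised when an input table cannot be parsed into the expected layout."""


@dataclasses.dataclass
class FilopodiumTrack:
    """Per-frame measurements of a single filopodium.

    ``data`` holds one row per frame with columns ``frame`` (1-based, strictly
    increasing) plus the numeric measurement fields; NaN marks a missing cell.
    Frame 1 is time 0, so time = (frame - 1) * frame_interval.
    """

    track_id: str
    frame_interval: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        frames = self.data["frame"].to_numpy()
        if len(frames) and not np.all(np.diff(frames) > 0):
            raise ValueError(f"track {self.track_id}: frame indices must be strictly increasing")
        lengths = self.data["length"].to_numpy(dtype=float)
        if np.any(lengths[np.isfinite(lengths)] < 0):
            raise ValueError(f"track {self.track_id}: negative length")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        """Seconds since the first frame of the movie (frame 1 = 0 s)."""
        return (self.data["frame"].to_numpy(dtype=float) - 1.0) * self.frame_interval

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclasses.dataclass(frozen=True)
class TrackFilterConfig:
    """Track quality thresholds mirroring the Filopodyan filter settings."""

    min_start_frame: int = 1
    min_frames: int = 3
    min_max_length: float = 1.8
    min_length_change: float = 0.1
    max_mean_waviness: float = 0.38

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


def read_track_tables(
    path: str | Path,
    frame_interval: float,
    column_map: Mapping[str, str] | None = None,
) -> list[FilopodiumTrack]:
    """Read a per-filopodium, per-frame CSV into a list of tracks.

    Parameters
    ----------
    path : file path
        CSV with one header row and one row per (track, frame).
    frame_interval : float
        Seconds per frame, attached to every track.
    column_map : mapping, optional
        Canonical field -> column name; defaults to the Filopodyan names.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    try:
        df = pd.read_csv(
            path, na_values=["NA"], keep_default_na=True, float_precision="round_trip"
        )
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    missing_cols = {cmap["track_id"], cmap["frame"]} - set(df.columns)
    if missing_cols:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing_cols)}")
    inv = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=inv)
    for field in _NUMERIC_FIELDS:
        if field not in df.columns:
            df[field] = np.nan
        df[field] = pd.to_numeric(df[field], errors="coerce")
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise ValueError(f"{path}: duplicate (track, frame) rows")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame").reset_index(drop=True)
        tracks.append(
            FilopodiumTrack(
                track_id=str(tid),
                frame_interval=frame_interval,
                data=grp[["frame"] + _NUMERIC_FIELDS].copy(),
            )
        )
    return tracks


def write_track_tables(
    tracks: Sequence[FilopodiumTrack],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write tracks back to the CSV layout `read_track_tables` consumes."""
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    rows = []
    for tr in tracks:
        out = tr.data.copy()
        out.insert(0, "track_id", tr.track_id)
        rows.append(out)
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["track_id", "frame"] + _NUMERIC_FIELDS
    )
    df = df.rename(columns=cmap)
    # repr-round-trip float formatting keeps values bit-identical on re-read
    df.to_csv(path, index=False, na_rep="NA", float_format=None)


def apply_track_filters(
    tracks: Sequence[FilopodiumTrack], cfg: TrackFilterConfig
) -> list[FilopodiumTrack]:
    """Retain tracks passing all Filopodyan-style quality criteria.

    A track survives iff its first frame >= ``min_start_frame``, it has at
    least ``min_frames`` frames, its maximum length >= ``min_max_length``,
    its length range >= ``min_length_change`` and its mean waviness
    <= ``max_mean_waviness``. Order is preserved; the result is a subset.
    """
    kept = []
    for tr in tracks:
        frames = tr.data["frame"].to_numpy()
        if len(frames) == 0 or frames[0] < cfg.min_start_frame:
            continue
        if len(frames) < cfg.min_frames:
            continue
        length = tr.column("length")
        length = length[np.isfinite(length)]
        if length.size == 0 or length.max() < cfg.min_max_length:
            continue
        if length.max() - length.min() < cfg.min_length_change:
            continue
        wav = tr.column("waviness")
        wav = wav[np.isfinite(wav)]
        if wav.size and wav.mean() > cfg.max_mean_waviness:
            continue
        kept.append(tr)
    return kept


_LOC_COLUMNS = ["x", "y", "photons", "precision", "llr", "sigma"]


def read_localizations(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an SMLM localisation table (x, y in nm; photons; precision nm;
    log-likelihood ratio; PSF sigma nm). Extra columns are ignored; row order
    is preserved."""
    cmap = {c: c for c in _LOC_COLUMNS}
    cmap.update(column_map or {})
    try:
        df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _LOC_COLUMNS if cmap[c] not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing localisation columns {missing}")
    out = df.rename(columns={v: k for k, v in cmap.items()})[_LOC_COLUMNS].copy()
    out = out.apply(pd.to_numeric, errors="coerce")
    if (out["photons"] < 0).any():
        raise ValueError("photons must be >= 0")
    if (out["precision"] <= 0).any():
        raise ValueError("precision must be > 0")
    if (out["sigma"] <= 0).any():
        raise ValueError("sigma must be > 0")
    return out.reset_index(drop=True)


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    locs.to_csv(path, index=False)
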