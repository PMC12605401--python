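"""Pose-track tables and apparatus geometry.

Reads and writes per-frame landmark tables (flat CSV, DeepLabCut-style
3-header CSV, or HDF5), and builds the calibrated arena geometry used by
the downstream gating and classification stages.

Coordinate convention: overhead 2D view, origin at the top-left of the
image, y increasing downward, frames 0-based.  Raw tables are in pixels;
everything downstream of calibration is in centimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PoseTrack",
    "ApparatusGeometry",
    "ReferencePointSet",
    "PoseTableError",
    "CalibrationError",
    "GeometryError",
    "read_pose_table",
    "write_pose_table",
    "calibrate_geometry",
    "load_geometry",
    "save_geometry",
    "load_reference_points",
]

REQUIRED_LANDMARKS = ("snout", "mid_body")

#: canonical column order within each landmark block
_COORDS = ("x", "y", "likelihood")


class PoseTableError(ValueError):
    """Raised for malformed or incomplete pose tables."""


class CalibrationError(ValueError):
    """Raised when pixel-to-cm calibration cannot be established."""


class GeometryError(ValueError):
    """Raised for inconsistent apparatus geometry."""


@dataclass
class PoseTrack:
    """One session of per-frame landmark coordinates and likelihoods.

    ``data`` has a MultiIndex column per (landmark, coord) with
    coord in {x, y, likelihood}; the index is the 0-based frame number.
    Missing samples are coded as x = y = NaN with likelihood 0.
    """

    session_id: str
    fps: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise PoseTableError(f"fps must be positive, got {self.fps}")
        idx = np.asarray(self.data.index)
        if len(idx) and (idx[0] != 0 or np.any(np.diff(idx) <= 0)):
            raise PoseTableError("frame indices must increase strictly from 0")
        missing = [lm for lm in REQUIRED_LANDMARKS if lm not in self.landmark_names]
        if missing:
            raise PoseTableError(f"pose table lacks required landmark(s): {missing}")
        self.data = _normalize_missing(self.data)

    @property
    def landmark_names(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def landmark(self, name: str) -> pd.DataFrame:
        """x/y/likelihood columns for one landmark (frames x 3)."""
        return self.data[name]

    def xy(self, name: str) -> np.ndarray:
        return self.data[name][["x", "y"]].to_numpy(float)

    def likelihood(self, name: str) -> np.ndarray:
        return self.data[name]["likelihood"].to_numpy(float)


def _normalize_missing(data: pd.DataFrame) -> pd.DataFrame:
    """Enforce the missing-data coding: any NaN coordinate => both
    coordinates NaN and likelihood 0."""
    data = data.copy()
    for lm in dict.fromkeys(data.columns.get_level_values(0)):
        x = data[(lm, "x")].to_numpy(float)
        y = data[(lm, "y")].to_numpy(float)
        lik = data[(lm, "likelihood")].to_numpy(float)
        bad = ~(np.isfinite(x) & np.isfinite(y))
        bad |= ~np.isfinite(lik)
        if bad.any():
            x[bad] = np.nan
            y[bad] = np.nan
            lik[bad] = 0.0
            data[(lm, "x")] = x
            data[(lm, "y")] = y
            data[(lm, "likelihood")] = lik
        lik = np.clip(lik, 0.0, 1.0)
        data[(lm, "likelihood")] = lik
    return data


@dataclass(frozen=True)
class ReferencePointSet:
    """Annotated apparatus reference points (pixels) with at least one
    pair of known physical separation (cm)."""

    points: Mapping[str, tuple[float, float]]
    known_separations_cm: Sequence[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise CalibrationError("need at least 2 reference points")
        if not self.known_separations_cm:
            raise CalibrationError("need at least one known separation")
        for a, b, cm in self.known_separations_cm:
            if a not in self.points or b not in self.points:
                raise CalibrationError(f"separation refers to unknown point: {a!r}/{b!r}")
            if not cm > 0:
                raise CalibrationError(f"known separation must be > 0 cm, got {cm}")


@dataclass(frozen=True)
class ApparatusGeometry:
    """Calibrated arena layout, all lengths in cm.

    The cage footprint is modelled as a circle in the overhead view.
    The "lower section" of a cage maps to the perimeter annulus of
    width ``sniff_band_cm`` outside the footprint; the "upper section"
    maps to the footprint itself inset by ``rear_inset_cm``.
    """

    px_per_cm: float
    arena_bounds: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    cage_a_center: tuple[float, float]
    cage_b_center: tuple[float, float]
    cage_radius_cm: float
    interaction_radius_cm: float = 5.0
    sniff_band_cm: float = 3.0
    rear_inset_cm: float = 0.0
    rear_fallback_cm: float | None = None  # default cage_radius_cm + 2
    confidence_threshold: float = 0.6
    fps: float = 25.0

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise GeometryError("px_per_cm must be > 0")
        if not self.cage_radius_cm > 0:
            raise GeometryError("cage_radius_cm must be > 0")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise GeometryError("confidence_threshold must be in [0, 1]")
        if self.interaction_radius_cm < self.sniff_band_cm:
            raise GeometryError("interaction_radius_cm must be >= sniff_band_cm")
        x0, y0, x1, y1 = self.arena_bounds
        for cx, cy in (self.cage_a_center, self.cage_b_center):
            if not (x0 <= cx <= x1 and y0 <= cy <= y1):
                raise GeometryError("cage centers must lie inside arena_bounds")
        if self.zones_overlap():
            raise GeometryError("cage interaction zones overlap")
        if self.rear_fallback_cm is None:
            object.__setattr__(self, "rear_fallback_cm", self.cage_radius_cm + 2.0)

    def zones_overlap(self) -> bool:
        d = math.dist(self.cage_a_center, self.cage_b_center)
        return d < 2.0 * (self.cage_radius_cm + self.interaction_radius_cm)

    def cage_centers(self) -> dict[str, tuple[float, float]]:
        return {"A": self.cage_a_center, "B": self.cage_b_center}

    def to_dict(self) -> dict:
        return {
            "px_per_cm": self.px_per_cm,
            "arena_bounds_cm": list(self.arena_bounds),
            "cage_a_center_cm": list(self.cage_a_center),
            "cage_b_center_cm": list(self.cage_b_center),
            "cage_radius_cm": self.cage_radius_cm,
            "interaction_radius_cm": self.interaction_radius_cm,
            "sniff_band_cm": self.sniff_band_cm,
            "rear_inset_cm": self.rear_inset_cm,
            "rear_fallback_cm": self.rear_fallback_cm,
            "confidence_threshold": self.confidence_threshold,
            "fps": self.fps,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ApparatusGeometry":
        return cls(
            px_per_cm=float(d["px_per_cm"]),
            arena_bounds=tuple(float(v) for v in d["arena_bounds_cm"]),
            cage_a_center=tuple(float(v) for v in d["cage_a_center_cm"]),
            cage_b_center=tuple(float(v) for v in d["cage_b_center_cm"]),
            cage_radius_cm=float(d["cage_radius_cm"]),
            interaction_radius_cm=float(d.get("interaction_radius_cm", 5.0)),
            sniff_band_cm=float(d.get("sniff_band_cm", 3.0)),
            rear_inset_cm=float(d.get("rear_inset_cm", 0.0)),
            rear_fallback_cm=(
                None if d.get("rear_fallback_cm") is None else float(d["rear_fallback_cm"])
            ),
            confidence_threshold=float(d.get("confidence_threshold", 0.6)),
            fps=float(d.get("fps", 25.0)),
        )


# ---------------------------------------------------------------------------
# table I/O


def read_pose_table(path: str | Path, dialect: str = "flat_csv",
                    session_id: str | None = None, fps: float = 25.0) -> PoseTrack:
    """Read a pose-track table.

    Dialects
    --------
    ``flat_csv``
        Columns ``frame,landmark,x,y,likelihood`` (long form).
    ``dlc_csv``
        The de-facto pose-estimation export: 3 header rows
        (scorer / bodyparts / coords), one row per frame.
    ``hdf5``
        One group per landmark holding ``x``, ``y``, ``likelihood``
        datasets, plus ``fps`` and ``session_id`` attributes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = session_id if session_id is not None else path.stem

    if dialect == "flat_csv":
        long = pd.read_csv(path, float_precision="round_trip")
        expected = {"frame", "landmark", "x", "y", "likelihood"}
        if not expected.issubset(long.columns):
            raise PoseTableError(f"flat_csv must have columns {sorted(expected)}")
        wide = long.pivot(index="frame", columns="landmark",
                          values=["x", "y", "likelihood"])
        wide = wide.swaplevel(axis=1)
        landmarks = list(dict.fromkeys(long["landmark"]))
        wide = wide.reindex(
            columns=pd.MultiIndex.from_product([landmarks, _COORDS]))
        data = wide.sort_index()
    elif dialect == "dlc_csv":
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                          float_precision="round_trip")
        # drop the scorer level; keep (bodypart, coord)
        raw.columns = pd.MultiIndex.from_arrays(
            [raw.columns.get_level_values(1), raw.columns.get_level_values(2)])
        landmarks = list(dict.fromkeys(raw.columns.get_level_values(0)))
        data = raw.reindex(columns=pd.MultiIndex.from_product([landmarks, _COORDS]))
        data.index = data.index.astype(int)
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            fps = float(f.attrs.get("fps", fps))
            sid = str(f.attrs.get("session_id", sid))
            frames = np.asarray(f["frames"])
            landmarks = [k for k in f if k != "frames"]
            cols = {}
            for lm in landmarks:
                for c in _COORDS:
                    cols[(lm, c)] = np.asarray(f[lm][c], dtype=float)
        data = pd.DataFrame(cols, index=frames)
        data.columns = pd.MultiIndex.from_tuples(data.columns)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    idx = np.asarray(data.index)
    if len(idx) and (idx[0] != 0 or np.any(np.diff(idx) <= 0)):
        raise PoseTableError("non-monotone or non-zero-based frame index")
    return PoseTrack(session_id=sid, fps=fps, data=data.astype(float))


def write_pose_table(track: PoseTrack, path: str | Path,
                     dialect: str = "flat_csv") -> None:
    """Write a pose table; flat_csv round-trips bit-exactly."""
    path = Path(path)
    if dialect == "flat_csv":
        rows = []
        for lm in track.landmark_names:
            block = track.landmark(lm).reset_index(names="frame")
            block.insert(1, "landmark", lm)
            rows.append(block)
        long = pd.concat(rows, ignore_index=True).sort_values(
            ["frame", "landmark"], kind="stable")
        # 17 significant digits round-trip float64, so the CSV is bit-exact
        long.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["fps"] = track.fps
            f.attrs["session_id"] = track.session_id
            f.create_dataset("frames", data=np.asarray(track.data.index, dtype=np.int64))
            for lm in track.landmark_names:
                g = f.create_group(lm)
                for c in _COORDS:
                    g.create_dataset(c, data=track.data[(lm, c)].to_numpy(float))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# calibration


def load_reference_points(refs_csv: str | Path,
                          separations: Iterable[tuple[str, str, float]]) -> ReferencePointSet:
    df = pd.read_csv(refs_csv)
    pts = {str(r["name"]): (float(r["x_px"]), float(r["y_px"])) for _, r in df.iterrows()}
    return ReferencePointSet(points=pts, known_separations_cm=list(separations))


def calibrate_geometry(refs: ReferencePointSet, layout_config: Mapping) -> ApparatusGeometry:
    """Derive px_per_cm from reference pairs and build the geometry.

    ``px_per_cm`` is the mean over declared pairs of
    (pixel distance / known cm separation).  Layout keys ending in
    ``_px`` are converted to cm with that factor; keys ending in
    ``_cm`` are taken as-is.
    """
    ratios = []
    for a, b, cm in refs.known_separations_cm:
        pa, pb = refs.points[a], refs.points[b]
        dpx = math.dist(pa, pb)
        if dpx == 0.0:
            raise CalibrationError(
                f"reference points {a!r} and {b!r} coincide (zero pixel distance)")
        ratios.append(dpx / cm)
    px_per_cm = float(np.mean(ratios))

    def get_len(key: str, default: float | None = None) -> float | None:
        if f"{key}_cm" in layout_config:
            return float(layout_config[f"{key}_cm"])
        if f"{key}_px" in layout_config:
            return float(layout_config[f"{key}_px"]) / px_per_cm
        return default

    def get_point(key: str) -> tuple[float, float]:
        if f"{key}_cm" in layout_config:
            x, y = layout_config[f"{key}_cm"]
            return float(x), float(y)
        if f"{key}_px" in layout_config:
            x, y = layout_config[f"{key}_px"]
            return float(x) / px_per_cm, float(y) / px_per_cm
        raise GeometryError(f"layout config missing {key}_cm or {key}_px")

    if "arena_bounds_cm" in layout_config:
        bounds = tuple(float(v) for v in layout_config["arena_bounds_cm"])
    elif "arena_bounds_px" in layout_config:
        bounds = tuple(float(v) / px_per_cm for v in layout_config["arena_bounds_px"])
    else:
        raise GeometryError("layout config missing arena_bounds_cm or arena_bounds_px")

    return ApparatusGeometry(
        px_per_cm=px_per_cm,
        arena_bounds=bounds,  # type: ignore[arg-type]
        cage_a_center=get_point("cage_a_center"),
        cage_b_center=get_point("cage_b_center"),
        cage_radius_cm=get_len("cage_radius"),
        interaction_radius_cm=get_len("interaction_radius", 5.0),
        sniff_band_cm=get_len("sniff_band", 3.0),
        rear_inset_cm=get_len("rear_inset", 0.0),
        rear_fallback_cm=get_len("rear_fallback", None),
        confidence_threshold=float(layout_config.get("confidence_threshold", 0.6)),
        fps=float(layout_config.get("fps", 25.0)),
    )


def load_geometry(path: str | Path) -> ApparatusGeometry:
    with open(path) as f:
        return ApparatusGeometry.from_dict(yaml.safe_load(f))


def save_geometry(geom: ApparatusGeometry, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(geom.to_dict(), f, sort_keys=False)
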