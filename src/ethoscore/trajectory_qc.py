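"""Frame-inclusion gating and landmark fallback.

A frame is retained iff the mid-body point passes the confidence gate;
the tracking point for a retained frame is the snout when it also passes,
otherwise the mid-body point.  Excluded frames contribute to nothing
downstream — behavior time is counted over retained frames only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pose_io import ApparatusGeometry, PoseTrack

__all__ = ["gate_frames", "retained_fraction", "qc_summary", "write_qc_report"]

#: columns of the tracked-point table returned by :func:`gate_frames`
TRACKED_COLUMNS = ["frame", "retained", "source_landmark", "x_cm", "y_cm"]


def gate_frames(track: PoseTrack, geom: ApparatusGeometry,
                confidence_threshold: float | None = None) -> pd.DataFrame:
    """One tracking point per frame, in cm, with retention flags.

    Returns a DataFrame with columns ``frame`` (original index),
    ``retained`` (bool), ``source_landmark`` ("snout" / "mid_body", or
    NA when excluded), and ``x_cm`` / ``y_cm`` (NaN when excluded).
    """
    thr = geom.confidence_threshold if confidence_threshold is None else confidence_threshold
    mb_lik = track.likelihood("mid_body")
    sn_lik = track.likelihood("snout")
    mb_xy = track.xy("mid_body") / geom.px_per_cm
    sn_xy = track.xy("snout") / geom.px_per_cm

    retained = mb_lik >= thr
    use_snout = retained & (sn_lik >= thr)

    xy = np.full_like(mb_xy, np.nan)
    xy[retained] = mb_xy[retained]
    xy[use_snout] = sn_xy[use_snout]

    source = np.full(track.n_frames, pd.NA, dtype=object)
    source[retained] = "mid_body"
    source[use_snout] = "snout"

    return pd.DataFrame(
        {
            "frame": np.asarray(track.data.index),
            "retained": retained,
            "source_landmark": source,
            "x_cm": xy[:, 0],
            "y_cm": xy[:, 1],
        }
    )


def retained_fraction(points: pd.DataFrame) -> float:
    """count(retained) / count(all); error on an empty sequence."""
    if len(points) == 0:
        raise ValueError("cannot compute retained fraction of an empty sequence")
    return float(points["retained"].sum()) / float(len(points))


def qc_summary(track: PoseTrack, points: pd.DataFrame) -> dict:
    retained = points["retained"]
    n_fallback = int((points.loc[retained, "source_landmark"] == "mid_body").sum())
    return {
        "session_id": track.session_id,
        "n_frames": int(len(points)),
        "n_retained": int(retained.sum()),
        "retained_fraction": retained_fraction(points),
        "n_snout_fallbacks": n_fallback,
        "wall_clock_duration_s": len(points) / track.fps,
        "retained_duration_s": int(retained.sum()) / track.fps,
    }


def write_qc_report(summaries: list[dict], path: str | Path) -> None:
    pd.DataFrame(summaries).to_csv(path, index=False)
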