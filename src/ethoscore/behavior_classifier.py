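"""Per-frame behavior classification near the conspecific cages.

Each retained frame gets a cage context (A, B, or none) from proximity of
the tracking point to the nearest cage-footprint boundary (inclusive
5 cm rule by default), and within context a label:

* ``rear``  — snout over the cage footprint (inset by ``rear_inset_cm``),
  or, when the snout failed the confidence gate, mid-body within
  ``rear_fallback_cm`` of the footprint boundary;
* ``sniff`` — snout in the perimeter annulus of width ``sniff_band_cm``
  outside the footprint;
* ``other`` — in the interaction zone but neither of the above.

Labels are then smoothed with a centered moving-average majority vote
over the joint (cage, label) class, and collapsed to bouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pose_io import ApparatusGeometry, GeometryError, PoseTrack

__all__ = ["classify_frames", "smooth_labels", "extract_bouts", "Bout",
           "LABELS", "CAGES"]

CAGES = ("A", "B", "none")
LABELS = ("sniff", "rear", "other", "none")

#: columns of the per-frame label table (the LabelSeries)
LABEL_COLUMNS = ["frame", "cage_context", "label", "source_landmark", "tie_flag"]


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive retained frames sharing one
    (cage, label) pair; duration counts retained frames at fps."""

    cage_context: str
    label: str
    start_frame: int
    end_frame: int
    n_frames: int
    duration_s: float


def classify_frames(points: pd.DataFrame, track: PoseTrack,
                    geom: ApparatusGeometry) -> pd.DataFrame:
    """Label every retained frame; returns the per-frame label table.

    ``points`` is the gated tracking-point table from
    :func:`ethoscore.trajectory_qc.gate_frames`.
    """
    if geom.zones_overlap():
        raise GeometryError("cage interaction zones overlap")

    ret = points[points["retained"]].reset_index(drop=True)
    n = len(ret)
    if n == 0:
        return pd.DataFrame(columns=LABEL_COLUMNS)

    p = ret[["x_cm", "y_cm"]].to_numpy(float)
    centers = geom.cage_centers()
    r = geom.cage_radius_cm

    # distance from tracking point to the nearest point of each footprint
    # boundary (unsigned: interior points are |d_center - r| away)
    d_bound = {}
    for cage in ("A", "B"):
        d_center = np.linalg.norm(p - np.asarray(centers[cage]), axis=1)
        d_bound[cage] = np.abs(d_center - r)

    da, db = d_bound["A"], d_bound["B"]
    tie = da == db
    nearest_is_a = (da < db) | tie  # equidistant -> A, flagged
    d_near = np.where(nearest_is_a, da, db)
    in_zone = d_near <= geom.interaction_radius_cm  # inclusive
    cage_ctx = np.where(in_zone, np.where(nearest_is_a, "A", "B"), "none")

    # snout / mid-body geometry relative to the context cage center
    frames_pos = track.data.index.get_indexer(ret["frame"].to_numpy())
    sn_xy = track.xy("snout")[frames_pos] / geom.px_per_cm
    mb_xy = track.xy("mid_body")[frames_pos] / geom.px_per_cm
    sn_ok = track.likelihood("snout")[frames_pos] >= geom.confidence_threshold

    ctx_centers = np.full((n, 2), np.nan)
    for cage in ("A", "B"):
        sel = cage_ctx == cage
        ctx_centers[sel] = np.asarray(centers[cage])
    d_sn = np.linalg.norm(sn_xy - ctx_centers, axis=1)
    d_mb = np.linalg.norm(mb_xy - ctx_centers, axis=1)

    with np.errstate(invalid="ignore"):
        rear = (sn_ok & (d_sn <= r - geom.rear_inset_cm)) | (
            ~sn_ok & (np.abs(d_mb - r) <= geom.rear_fallback_cm))
        sniff = sn_ok & (d_sn > r) & (d_sn <= r + geom.sniff_band_cm)

    label = np.full(n, "none", dtype=object)
    interacting = cage_ctx != "none"
    label[interacting] = "other"
    label[interacting & rear] = "rear"
    label[interacting & ~rear & sniff] = "sniff"

    return pd.DataFrame(
        {
            "frame": ret["frame"].to_numpy(),
            "cage_context": np.where(interacting, cage_ctx, "none"),
            "label": label,
            "source_landmark": ret["source_landmark"].to_numpy(),
            "tie_flag": tie & in_zone,
        }
    )


def smooth_labels(series: pd.DataFrame, window_frames: int = 5) -> pd.DataFrame:
    """Centered moving-average majority vote over joint (cage, label)
    classes, in retained-frame order.

    The window shrinks at the edges.  Ties break toward the previous
    output label, else toward the unsmoothed label, else toward the
    class earliest in the window's class order.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 1")
    n = len(series)
    if n == 0 or window_frames == 1:
        return series.copy()

    joint = (series["cage_context"].astype(str) + "|" + series["label"].astype(str))
    classes, codes = np.unique(joint.to_numpy(), return_inverse=True)
    k = len(classes)
    if k == 1:
        return series.copy()

    ind = np.zeros((n, k))
    ind[np.arange(n), codes] = 1.0
    half = window_frames // 2
    # windowed sums via cumulative sums, with edge shrink
    csum = np.vstack([np.zeros((1, k)), np.cumsum(ind, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1) + 1
    wsum = csum[hi] - csum[lo]
    means = wsum / (hi - lo)[:, None]

    best = means.max(axis=1)
    is_best = means >= best[:, None] - 1e-12
    n_best = is_best.sum(axis=1)
    out = np.argmax(means, axis=1)

    if np.any(n_best > 1):
        # sequential resolution: previous output, else the unsmoothed
        # label, else first appearance order within the window
        for i in range(n):
            if n_best[i] > 1:
                prev_code = out[i - 1] if i > 0 else None
                if prev_code is not None and is_best[i, prev_code]:
                    out[i] = prev_code
                elif is_best[i, codes[i]]:
                    out[i] = codes[i]
                else:
                    for j in range(int(lo[i]), int(hi[i])):
                        if is_best[i, codes[j]]:
                            out[i] = codes[j]
                            break

    smoothed = series.copy()
    parts = pd.Series(classes[out]).str.split("|", expand=True)
    smoothed["cage_context"] = parts[0].to_numpy()
    smoothed["label"] = parts[1].to_numpy()
    return smoothed


def extract_bouts(series: pd.DataFrame, fps: float) -> list[Bout]:
    """Run-length encode the label series into bouts (label != none)."""
    n = len(series)
    if n == 0:
        return []
    cage = series["cage_context"].to_numpy()
    lab = series["label"].to_numpy()
    frames = series["frame"].to_numpy()

    change = np.flatnonzero((cage[1:] != cage[:-1]) | (lab[1:] != lab[:-1])) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])

    bouts = []
    for s, e in zip(starts, ends):
        if lab[s] == "none":
            continue
        bouts.append(
            Bout(
                cage_context=str(cage[s]),
                label=str(lab[s]),
                start_frame=int(frames[s]),
                end_frame=int(frames[e - 1]),
                n_frames=int(e - s),
                duration_s=(e - s) / fps,
            )
        )
    return bouts


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cage": b.cage_context,
                "label": b.label,
                "start_frame": b.start_frame,
                "end_frame": b.end_frame,
                "n_frames": b.n_frames,
                "duration_s": b.duration_s,
            }
            for b in bouts
        ],
        columns=["cage", "label", "start_frame", "end_frame", "n_frames", "duration_s"],
    )
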