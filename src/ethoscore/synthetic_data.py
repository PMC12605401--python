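"""Synthetic sessions with known ground truth.

A semi-Markov state machine (roam / idle / approach / sniff / rear) with
geometric dwell times drives a simulated mouse around a three-chamber
arena.  Cage visits target the "novel" cage with probability
``preference_rho``, so the implied total-interaction DI is
2 * rho - 1.  Landmark positions are placed consistently with the state
geometry (sniff -> snout in the perimeter band, rear -> snout over the
footprint, approach -> snout in the outer interaction band, roam/idle ->
outside the interaction zones), with optional Gaussian jitter and
likelihood dropout.  Everything is reproducible under the seed.

Also generates continuous-recognition exploration tables with a
configurable per-group DI shift, per-trial drift and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pose_io import ApparatusGeometry, GeometryError, PoseTrack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_geometry",
    "simulate_tcsi_session",
    "simulate_cnor_tables",
    "write_session",
]

LANDMARKS = ["snout", "left_ear", "right_ear", "neck", "mid_body",
             "tail_base", "mid_tail", "tail_end"]

#: body-chain offsets (cm) along the snout->tail axis, and lateral offsets
_BODY_PLAN = {
    "snout": (0.0, 0.0),
    "left_ear": (1.2, -0.8),
    "right_ear": (1.2, 0.8),
    "neck": (1.5, 0.0),
    "mid_body": (2.5, 0.0),
    "tail_base": (4.5, 0.0),
    "mid_tail": (6.0, 0.0),
    "tail_end": (7.5, 0.0),
}

_STATES = ("roam", "idle", "approach", "sniff", "rear")

_TRANSITIONS: Mapping[str, list[tuple[str, float]]] = {
    "roam": [("approach", 0.75), ("idle", 0.25)],
    "idle": [("roam", 1.0)],
    "approach": [("sniff", 0.6), ("rear", 0.4)],
    "sniff": [("rear", 0.35), ("roam", 0.65)],
    "rear": [("sniff", 0.35), ("roam", 0.65)],
}

#: truth label implied by each state
_STATE_LABEL = {"roam": "none", "idle": "none", "approach": "other",
                "sniff": "sniff", "rear": "rear"}


def default_geometry(px_per_cm: float = 10.0) -> ApparatusGeometry:
    """A plausible three-chamber layout: 60 x 40 cm arena, 5 cm-radius
    cages in the two upper corners."""
    return ApparatusGeometry(
        px_per_cm=px_per_cm,
        arena_bounds=(0.0, 0.0, 60.0, 40.0),
        cage_a_center=(10.0, 8.0),
        cage_b_center=(50.0, 8.0),
        cage_radius_cm=5.0,
    )


@dataclass
class SimConfig:
    seed: int = 0
    fps: float = 25.0
    duration_s: float = 600.0
    geometry: ApparatusGeometry = field(default_factory=default_geometry)
    preference_rho: float = 0.5
    state_dwell_means_s: Mapping[str, float] = field(
        default_factory=lambda: {"roam": 3.0, "idle": 4.0, "approach": 1.2,
                                 "sniff": 2.5, "rear": 2.0})
    jitter_sd_cm: float = 0.0
    dropout_prob: float = 0.0
    novel_cage: str = "A"
    session_id: str = "sim"

    def __post_init__(self) -> None:
        if not (0.0 <= self.preference_rho <= 1.0):
            raise ValueError("preference_rho must be in [0, 1]")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.jitter_sd_cm < 0:
            raise ValueError("jitter_sd_cm must be >= 0")
        if any(v <= 0 for v in self.state_dwell_means_s.values()):
            raise ValueError("state dwell means must be > 0")


@dataclass
class GroundTruth:
    """Per-frame true state/cage/label plus per-(cage,label) seconds."""

    frames: pd.DataFrame  # columns frame, state, cage, label
    seconds: dict         # (cage, label) -> true seconds, labels sniff/rear/other
    implied_di: float
    fps: float

    def total_seconds(self, cage: str) -> float:
        return sum(v for (c, _), v in self.seconds.items() if c == cage)


def _dwell_frames(rng: np.random.Generator, mean_frames: float) -> int:
    # geometric dwell, clipped to >= 3 frames so runs survive 5-frame smoothing
    return max(3, int(rng.geometric(min(1.0, 1.0 / mean_frames))))


def _next_state(rng: np.random.Generator, state: str) -> str:
    options = _TRANSITIONS[state]
    names = [o[0] for o in options]
    probs = [o[1] for o in options]
    return names[rng.choice(len(names), p=probs)]


def _roam_point(rng: np.random.Generator, geom: ApparatusGeometry) -> np.ndarray:
    """A point safely outside both interaction zones (lower arena half)."""
    x0, y0, x1, y1 = geom.arena_bounds
    margin = geom.cage_radius_cm + geom.interaction_radius_cm + 3.0
    centers = [np.asarray(c) for c in geom.cage_centers().values()]
    for _ in range(200):
        p = np.array([rng.uniform(x0 + 2, x1 - 2),
                      rng.uniform(y0 + 0.6 * (y1 - y0), y1 - 2)])
        if all(np.linalg.norm(p - c) > margin for c in centers):
            return p
    raise GeometryError("arena too small to place the mouse away from both cages")


def _place_body(snout: np.ndarray, away: np.ndarray,
                n: int) -> dict[str, np.ndarray]:
    """Lay the 8-landmark chain behind the snout along the unit vector
    ``away`` (pointing from snout toward the tail)."""
    perp = np.array([-away[1], away[0]])
    out = {}
    for lm, (along, lat) in _BODY_PLAN.items():
        pos = snout + along * away + lat * perp
        out[lm] = np.tile(pos, (n, 1))
    return out


def simulate_tcsi_session(config: SimConfig) -> tuple[PoseTrack, GroundTruth]:
    """Simulate one session; returns the pose track (pixels) and truth."""
    geom = config.geometry
    if geom.zones_overlap():
        raise GeometryError("cage interaction zones overlap")
    rng = np.random.default_rng(config.seed)
    n_total = int(round(config.duration_s * config.fps))
    r = geom.cage_radius_cm
    centers = {k: np.asarray(v) for k, v in geom.cage_centers().items()}

    sniff_dist = r + geom.sniff_band_cm / 2.0
    approach_dist = r + (geom.sniff_band_cm + geom.interaction_radius_cm) / 2.0
    rear_dist = 0.5 * max(r - geom.rear_inset_cm, 0.0)

    state = "roam"
    cage = "none"
    t = 0
    seg_states: list[str] = []
    seg_cages: list[str] = []
    seg_lens: list[int] = []
    positions: dict[str, list[np.ndarray]] = {lm: [] for lm in LANDMARKS}

    while t < n_total:
        mean_frames = config.state_dwell_means_s[state] * config.fps
        n = min(_dwell_frames(rng, mean_frames), n_total - t)

        if state == "approach":
            # cage chosen at visit start, novel with probability rho
            cage = (config.novel_cage if rng.random() < config.preference_rho
                    else ("B" if config.novel_cage == "A" else "A"))
        elif state in ("roam", "idle"):
            cage = "none"

        if state in ("sniff", "rear", "approach"):
            center = centers[cage]
            theta = rng.uniform(0.0, 2.0 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])  # outward radial
            dist = {"sniff": sniff_dist, "approach": approach_dist,
                    "rear": rear_dist}[state]
            snout = center + dist * u
            body = _place_body(snout, u, n)
        else:
            p = _roam_point(rng, geom) if state == "roam" else np.array(
                [0.5 * (geom.arena_bounds[0] + geom.arena_bounds[2]),
                 geom.arena_bounds[3] - 4.0])
            theta = rng.uniform(0.0, 2.0 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            body = _place_body(p, u, n)

        for lm in LANDMARKS:
            positions[lm].append(body[lm])
        seg_states.append(state)
        seg_cages.append(cage)
        seg_lens.append(n)
        t += n
        state = _next_state(rng, state)

    xy = {lm: np.vstack(chunks) for lm, chunks in positions.items()}
    states = np.repeat(seg_states, seg_lens)
    cages = np.repeat(seg_cages, seg_lens)
    labels = np.array([_STATE_LABEL[s] for s in states], dtype=object)

    thr = geom.confidence_threshold
    cols = {}
    for lm in LANDMARKS:
        pts = xy[lm]
        if config.jitter_sd_cm > 0:
            pts = pts + rng.normal(0.0, config.jitter_sd_cm, size=pts.shape)
        lik = rng.uniform(thr, 1.0, size=n_total)
        if config.dropout_prob > 0:
            drop = rng.random(n_total) < config.dropout_prob
            lik[drop] = rng.uniform(0.0, thr, size=int(drop.sum()))
            pts = pts.copy()
            pts[drop] += rng.normal(0.0, 5.0, size=(int(drop.sum()), 2))
        cols[(lm, "x")] = pts[:, 0] * geom.px_per_cm
        cols[(lm, "y")] = pts[:, 1] * geom.px_per_cm
        cols[(lm, "likelihood")] = lik

    data = pd.DataFrame(cols, index=pd.RangeIndex(n_total))
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    track = PoseTrack(session_id=config.session_id, fps=config.fps, data=data)

    truth_frames = pd.DataFrame({
        "frame": np.arange(n_total),
        "state": states,
        "cage": cages,
        "label": labels,
    })
    seconds: dict = {}
    for (c, lab), cnt in truth_frames.groupby(["cage", "label"]).size().items():
        if lab != "none":
            seconds[(c, lab)] = cnt / config.fps
    truth = GroundTruth(frames=truth_frames, seconds=seconds,
                        implied_di=2.0 * config.preference_rho - 1.0,
                        fps=config.fps)
    return track, truth


def simulate_cnor_tables(n_subjects: int, n_trials: int = 11,
                         group_effect: float = 0.0, drift: float = 0.0,
                         noise_sd: float = 0.0, seed: int = 0,
                         base_di: float = 0.4,
                         total_exploration_s: float = 20.0,
                         groups: tuple[str, ...] = ("control", "treated"),
                         ) -> pd.DataFrame:
    """Exploration tables for a multi-trial recognition task.

    Per subject and trial the target DI is
    clamp(base + shift + drift * trial + N(0, noise_sd), -1, 1), where
    shift is 0 for the first group and ``group_effect`` for the others;
    the DI is emitted as (time_novel, time_familiar) with a fixed total.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for g_i, group in enumerate(groups):
        shift = 0.0 if g_i == 0 else group_effect
        for s in range(n_subjects):
            sid = f"{group}_{s + 1:02d}"
            for trial in range(1, n_trials + 1):
                di = base_di + shift + drift * trial
                if noise_sd > 0:
                    di += rng.normal(0.0, noise_sd)
                di = float(np.clip(di, -1.0, 1.0))
                rows.append({
                    "subject_id": sid,
                    "group": group,
                    "trial": trial,
                    "time_novel_s": total_exploration_s * (1.0 + di) / 2.0,
                    "time_familiar_s": total_exploration_s * (1.0 - di) / 2.0,
                })
    return pd.DataFrame(rows)


def write_session(track: PoseTrack, truth: GroundTruth,
                  outdir: str | Path) -> None:
    """Emit a flat_csv pose table plus a ground-truth sidecar CSV."""
    from .pose_io import write_pose_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pose_table(track, outdir / f"{track.session_id}_pose.csv", "flat_csv")
    truth.frames.to_csv(outdir / f"{track.session_id}_truth.csv", index=False)
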