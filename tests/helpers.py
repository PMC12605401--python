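"""Independent oracles and scoring helpers shared across test modules.

Everything here is deliberately written as direct, brute-force
computation so it stays independent of the implementation it checks.
"""

import math

import numpy as np
import pandas as pd

from ethoscore import classify_frames, gate_frames, interaction_times, smooth_labels
from ethoscore.memory_metrics import discrimination_index


# ---------------------------------------------------------------------------
# brute-force oracles

def smooth_oracle(joint_labels, window):
    """Reference implementation of centered indicator-mean majority
    smoothing with edge shrink and previous-output/unsmoothed tie rules."""
    n = len(joint_labels)
    half = window // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        win = joint_labels[lo:hi + 1]
        means = {}
        for cls in win:
            means[cls] = win.count(cls) / len(win)
        best = max(means.values())
        tied = [c for c, v in means.items() if v >= best - 1e-12]
        if len(tied) == 1:
            out.append(tied[0])
        elif i > 0 and out[i - 1] in tied:
            out.append(out[i - 1])
        elif joint_labels[i] in tied:
            out.append(joint_labels[i])
        else:
            out.append(tied[0])
    return out


def t_oracle(values, mu0=0.0):
    """One-sample t by direct summation."""
    n = len(values)
    s = sum(values)
    mean = s / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1))
    return (mean - mu0) / (sd / math.sqrt(n))


def pearson_oracle(x, y):
    """Pearson r / slope / intercept by direct summation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    slope = sxy / sxx
    intercept = my - slope * mx
    return r, slope, intercept


def prefix_mean_oracle(values):
    return [sum(values[: k + 1]) / (k + 1) for k in range(len(values))]


# ---------------------------------------------------------------------------
# pipeline scoring against simulator ground truth

def joint_truth(truth, frames):
    """Ground-truth joint (cage:label) strings for the given frames."""
    tf = truth.frames.set_index("frame").loc[frames]
    cage = tf["cage"].where(tf["label"] != "none", "none")
    return (cage + ":" + tf["label"]).to_numpy()


def joint_pred(series):
    return (series["cage_context"] + ":" + series["label"]).to_numpy()


def agreement_and_f1(series, truth):
    pred = joint_pred(series)
    true = joint_truth(truth, series["frame"].to_numpy())
    agree = float(np.mean(pred == true))
    f1 = {}
    for cls in np.unique(true):
        tp = int(np.sum((pred == cls) & (true == cls)))
        fp = int(np.sum((pred == cls) & (true != cls)))
        fn = int(np.sum((pred != cls) & (true == cls)))
        f1[cls] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return agree, f1


def run_pipeline(track, geom, window=5):
    points = gate_frames(track, geom)
    return smooth_labels(classify_frames(points, track, geom), window)


def recovered_total_di(track, geom, novel_cage="A"):
    series = run_pipeline(track, geom)
    summary = interaction_times(series, track.fps)
    familiar = "B" if novel_cage == "A" else "A"
    return discrimination_index(summary.seconds(novel_cage),
                                summary.seconds(familiar))
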