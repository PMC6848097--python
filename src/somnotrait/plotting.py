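"""Figure rendering: permutation QQ plot and jittered extreme-group boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import DataError
from .permutation import PermutationEnvelope


def qq_plot(qq: pd.DataFrame, envelope: PermutationEnvelope, out_path, log_scale: bool = False):
    """Observed vs mean-expected p values with the 5th-95th envelope band.

    The diagonal is the rank-wise mean expected p plotted against
    itself; the gray band spans the envelope percentiles; circles are
    the observed, descending-sorted p values.
    """
    t = envelope.table
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.fill_between(t["mean_expected_p"], t["p5"], t["p95"], color="0.85", label="5th-95th pct")
    ax.plot(t["mean_expected_p"], t["mean_expected_p"], color="k", lw=1)
    ax.scatter(
        qq["expected_p"], qq["observed_p"], s=18, facecolors="none",
        edgecolors="tab:blue", label="observed",
    )
    if log_scale:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("mean expected p (permutation null)")
    ax.set_ylabel("observed p")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _box_stats(v: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {"q1": q1, "med": med, "q3": q3, "whislo": lo, "whishi": hi}


def boxplot_extremes(values, groups, out_path, seed: int = 0, ylabel: str = ""):
    """Two-group boxplot: IQR box, median line, 1.5*IQR whiskers,
    individual points with seeded horizontal jitter."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if len(names) != 2:
        raise DataError("boxplot_extremes expects exactly two groups")
    samples = [values[groups == g] for g in names]
    if any(len(s) == 0 for s in samples):
        raise DataError("empty group")

    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(4, 5))
    for i, (name, v) in enumerate(zip(names, samples)):
        st = _box_stats(v)
        x = i + 1
        ax.add_patch(
            plt.Rectangle((x - 0.25, st["q1"]), 0.5, st["q3"] - st["q1"],
                          fill=False, edgecolor="k")
        )
        ax.plot([x - 0.25, x + 0.25], [st["med"]] * 2, color="k", lw=2)
        for w in ("whislo", "whishi"):
            y0 = st["q1"] if w == "whislo" else st["q3"]
            ax.plot([x, x], sorted([y0, st[w]]), color="k", lw=1)
            ax.plot([x - 0.12, x + 0.12], [st[w]] * 2, color="k", lw=1)
        jitter = rng.uniform(-0.15, 0.15, size=len(v))
        ax.scatter(x + jitter, v, s=8, alpha=0.5, color="tab:blue", zorder=3)
    ax.set_xticks([1, 2])
    ax.set_xticklabels([str(n) for n in names])
    ax.set_ylabel(ylabel)
    ax.set_xlim(0.4, 2.6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
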