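"""Companion plots: per-sample GC-bias profile curves and longitudinal
score tracking across batches/time.

Both plots share the classification thresholds with the scoring code (one
source of truth) and a fixed class -> color/linestyle mapping covering all
five bias classes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gc_model import BiasClass, BiasCurve, Thresholds, DEFAULT_THRESHOLDS

#: color / linestyle per bias class (cosmetic but fixed and total)
CLASS_STYLE: dict[BiasClass, dict] = {
    BiasClass.AT_BIAS_FAIL: {"color": "#b2182b", "linestyle": "-"},
    BiasClass.AT_BIAS_WARN: {"color": "#ef8a62", "linestyle": "--"},
    BiasClass.NO_BIAS: {"color": "#4d4d4d", "linestyle": "-"},
    BiasClass.GC_BIAS_WARN: {"color": "#67a9cf", "linestyle": "--"},
    BiasClass.GC_BIAS_FAIL: {"color": "#2166ac", "linestyle": "-"},
}


def _style(bias_class: Optional[BiasClass]) -> dict:
    if bias_class is None:
        return {"color": "#bdbdbd", "linestyle": ":"}
    return CLASS_STYLE[bias_class]


def plot_gc_profiles(
    curves: Sequence[tuple[str, BiasCurve, Optional[BiasClass]]],
    out_path: str | Path,
    title: str = "GC bias profiles",
) -> Path:
    """Overlay all samples' LOESS depth vs GC percentile, styled by class."""
    if not curves:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(8, 5))
    seen: set[Optional[BiasClass]] = set()
    for sample_id, curve, bias_class in curves:
        lo, hi = curve.domain
        grid = np.arange(lo, hi + 1)
        style = _style(bias_class)
        label = (bias_class.value if bias_class else "UNSCORED")
        ax.plot(
            grid,
            curve.predict(grid),
            label=label if bias_class not in seen else None,
            alpha=0.8,
            **style,
        )
        seen.add(bias_class)
    ax.axhline(1.0, color="black", linewidth=0.6, alpha=0.5)
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("normalized LOESS depth")
    ax.set_title(title)
    ax.legend(fontsize=8)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _order_samples(scores: pd.DataFrame) -> pd.DataFrame:
    """Chronological order: by date when present, else batch, then sample."""
    df = scores.copy()
    if "date" in df.columns and df["date"].notna().any():
        keys = ["date", "batch", "sample_id"]
    elif "batch" in df.columns:
        keys = ["batch", "sample_id"]
    else:
        raise ValueError("longitudinal plot needs a date or batch column")
    keys = [k for k in keys if k in df.columns]
    return df.sort_values(keys, kind="stable").reset_index(drop=True)


def plot_longitudinal(
    scores: pd.DataFrame,
    out_path: str | Path,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    title: str = "Bias scores over time",
) -> Path:
    """Three tracks (b75/25, b75, b25) in chronological order with guide
    lines at the classification thresholds; points colored by class.

    ``scores`` needs columns sample_id, b25, b75, b75_25, bias_class and a
    batch and/or date column for ordering.
    """
    if scores.empty:
        raise ValueError("no scores to plot")
    df = _order_samples(scores)
    x = np.arange(len(df))
    colors = [
        _style(BiasClass(c) if c in BiasClass.__members__ else None)["color"]
        for c in df["bias_class"].astype(str)
    ]
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    tracks = [
        ("b75_25", [thresholds.rel_fail_lo, thresholds.rel_warn_lo,
                    thresholds.rel_warn_hi, thresholds.rel_fail_hi]),
        ("b75", [thresholds.abs_fail]),
        ("b25", [thresholds.abs_fail]),
    ]
    for ax, (col, guides) in zip(axes, tracks):
        ax.scatter(x, df[col].astype(float), c=colors, s=18, zorder=3)
        for g in guides:
            ax.axhline(g, color="grey", linewidth=0.7, linestyle="--", zorder=1)
        ax.set_ylabel(col.replace("_", "/"))
    if "batch" in df.columns:
        # mark batch boundaries
        batches = df["batch"].astype(str).to_numpy()
        boundaries = np.nonzero(batches[1:] != batches[:-1])[0] + 0.5
        for b in boundaries:
            for ax in axes:
                ax.axvline(b, color="lightgrey", linewidth=0.6)
    axes[-1].set_xticks(x)
    axes[-1].set_xticklabels(df["sample_id"], rotation=90, fontsize=6)
    axes[0].set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
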