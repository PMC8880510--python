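"""Diagnostic figures: threshold sweep and per-arm Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import km_estimate


def plot_sweep(sweep: pd.DataFrame, out_path: str | Path,
               chosen: dict | None = None) -> None:
    """Log-rank p and arm hazard ratio across inclusion percentiles."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.4), sharex=True)
    axes[0].plot(sweep["percentile"], sweep["logrank_p"], lw=1.2)
    axes[0].axhline(0.05, color="crimson", ls=":", lw=1)
    axes[0].set_yscale("log")
    axes[0].set_xlabel("inclusion threshold (score percentile)")
    axes[0].set_ylabel("log-rank p (arms, included subset)")
    axes[1].plot(sweep["percentile"], sweep["hr"], lw=1.2)
    axes[1].axhline(1.0, color="grey", ls="--", lw=1)
    axes[1].set_xlabel("inclusion threshold (score percentile)")
    axes[1].set_ylabel("HR experimental vs control")
    if chosen is not None:
        for ax in axes:
            ax.axvline(chosen["percentile"], color="crimson", ls="--", lw=1)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_km_by_arm(clinical: pd.DataFrame, out_path: str | Path,
                   title: str = "") -> None:
    """Kaplan-Meier curves per treatment arm for one patient subset."""
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    for arm in sorted(pd.unique(clinical["arm"])):
        sel = clinical["arm"] == arm
        km = km_estimate(clinical.loc[sel, "time"], clinical.loc[sel, "event"])
        ax.step(np.concatenate([[0], km.times]),
                np.concatenate([[1.0], km.survival]),
                where="post", label=f"{arm} (median {km.median_str()})")
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
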