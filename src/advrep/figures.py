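"""Optional figure outputs (never part of the analysis surface)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_layer_profile(profile_frame: pd.DataFrame, path: str | Path) -> None:
    """RE-AN and RE-AI similarities across the 8 stages."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile_frame["stage"], profile_frame["r_re_an"], "o-", label="RE-AN")
    ax.plot(profile_frame["stage"], profile_frame["r_re_ai"], "s-", label="RE-AI")
    ax.set_xlabel("classifier stage")
    ax.set_ylabel("RDM similarity (Spearman)")
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roi_summary(roi_rsa: dict, path: str | Path) -> None:
    """Per-ROI RE-AN vs RE-AI similarity bars with bootstrap CIs of the diff."""
    rois = list(roi_rsa)
    an = [roi_rsa[r]["r_re_an"] for r in rois]
    ai = [roi_rsa[r]["r_re_ai"] for r in rois]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = range(len(rois))
    ax.bar([i - 0.2 for i in x], an, width=0.4, label="RE-AN")
    ax.bar([i + 0.2 for i in x], ai, width=0.4, label="RE-AI")
    ax.set_xticks(list(x), rois)
    ax.set_ylabel("RDM similarity (Spearman)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_searchlight(sl_map: pd.DataFrame, sheet_table: pd.DataFrame,
                     path: str | Path) -> None:
    """Flat-map scatter of the searchlight RE-AI minus RE-AN difference."""
    merged = sl_map.merge(sheet_table, on=["vertex_id", "roi", "hemisphere"])
    diff = merged["r_re_ai"] - merged["r_re_an"]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    sc = ax.scatter(merged["x"], merged["y"], c=diff, s=8, cmap="RdBu_r",
                    vmin=-1, vmax=1)
    fig.colorbar(sc, ax=ax, label="RE-AI minus RE-AN")
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
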