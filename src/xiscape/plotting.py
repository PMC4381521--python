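"""Minimal figure helpers for the standard views of the pipeline output."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_window_profile(windows: pd.DataFrame, ax=None):
    """Chromosome bar view of a sliding-window allelic profile: biallelic
    windows up (red), monoallelic down (blue)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    ax.bar(windows.center_pos, windows.n_biallelic, width=0,
           edgecolor="crimson", linewidth=0.8, label="biallelic")
    ax.bar(windows.center_pos, -windows.n_monoallelic, width=0,
           edgecolor="steelblue", linewidth=0.8, label="monoallelic")
    ax.axhline(0, color="k", linewidth=0.5)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("expressed informative SNPs / window")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_bin_ratio(ratios: pd.DataFrame, ax=None):
    """Dot plot of per-bin log2 ratios along a chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    centers = (ratios.start + ratios.end) / 2
    ax.plot(centers, ratios.value, ".", ms=3, color="0.2")
    ax.axhline(0, color="crimson", linewidth=0.6)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("log2 ratio vs reference")
    return ax


def plot_tss_profiles(profiles: pd.DataFrame, ax=None):
    """Line plot of mean TSS-centered profiles (one line per gene set)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for name in profiles.columns:
        ax.plot(profiles.index, profiles[name], label=name)
    ax.axvline(0, color="0.7", linewidth=0.6)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("mean coverage")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_boxstats(stats_by_group: dict[str, dict], ax=None):
    """10/90-whisker box plot from population_boxstats summaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + len(stats_by_group), 3))
    stats = [{"label": name, "whislo": s["p10"], "q1": s["p25"],
              "med": s["p50"], "q3": s["p75"], "whishi": s["p90"],
              "fliers": []} for name, s in stats_by_group.items()]
    ax.bxp(stats, showfliers=False)
    for i, s in enumerate(stats_by_group.values(), start=1):
        ax.annotate(str(s["n"]), (i, ax.get_ylim()[0]), ha="center",
                    fontsize=7, xytext=(0, 2), textcoords="offset points")
    ax.set_ylabel("enrichment ratio")
    return ax
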