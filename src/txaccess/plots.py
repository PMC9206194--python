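"""Approximate figure analogues: a tract-category map and an odds-ratio
forest plot, rendered from pipeline output files."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_CATEGORY_COLORS = {
    "lost": "#c0392b",
    "maintained": "#2980b9",
    "gained": "#27ae60",
    "never": "#95a5a6",
}


def plot_category_map(geojson_path, ax=None):
    """Scatter choropleth of tract access-change categories."""
    with open(geojson_path) as fh:
        fc = json.load(fh)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for cat, color in _CATEGORY_COLORS.items():
        xs, ys = [], []
        for feat in fc["features"]:
            if feat["properties"]["category"] == cat:
                x, y = feat["geometry"]["coordinates"]
                xs.append(x)
                ys.append(y)
        if xs:
            ax.scatter(xs, ys, s=4, c=color, label=cat, linewidths=0)
    ax.legend(markerscale=3, fontsize=8)
    ax.set_title("Access to confidential care for minors, by tract")
    ax.set_aspect("equal")
    return ax


def plot_forest(table2_csv, ax=None):
    """Forest plot of the univariate odds ratios with 95% CIs."""
    df = pd.read_csv(table2_csv)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * max(len(df), 4) + 1))
    ypos = range(len(df))[::-1]
    ax.errorbar(
        df["or"],
        list(ypos),
        xerr=[df["or"] - df["ci_low"], df["ci_high"] - df["or"]],
        fmt="o",
        color="black",
        ecolor="gray",
        capsize=2,
    )
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_yticks(list(ypos))
    ax.set_yticklabels([f"{p}: {l}" for p, l in zip(df["predictor"], df["level"])], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("Odds of losing access (log scale)")
    return ax


def render_report(run_dir, outdir) -> list[Path]:
    """Render both figures from a pipeline output directory."""
    run_dir, outdir = Path(run_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    geo = run_dir / "access_categories.geojson"
    if geo.exists():
        ax = plot_category_map(geo)
        p = outdir / "category_map.png"
        ax.figure.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
    t2 = run_dir / "table2_odds_ratios.csv"
    if t2.exists() and pd.read_csv(t2).shape[0]:
        ax = plot_forest(t2)
        p = outdir / "forest_plot.png"
        ax.figure.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
    return written
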