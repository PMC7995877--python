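"""Publication graphics with adaptive level of detail.

With at most ``detail_threshold`` genomes (default 20) individual
genomes are identified: base-composition percentages as grouped bars by
genome, skew scatters colour-coded by genome, amino-acid frequencies as
genome-coloured grouped bars.  Above the threshold the figures switch
to summaries: frequency polygons of the percentages, uncoloured skew
scatters, and per-amino-acid boxplots.  RSCU always gets one figure per
genome, codons colour-coded within each synonymous family.

Testing of figures is structural (mode selection, panel/series counts,
files written), not pixel-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

__all__ = ["PlotSpec", "detail_mode", "plot_base_composition", "plot_skews", "plot_usage"]

_STRAND_MARKERS = {"J": "o", "N": "^"}


@dataclass
class PlotSpec:
    detail_threshold: int = 20
    formats: Sequence[str] = ("png", "pdf")
    dpi: int = 300
    palette: str = "husl"

    def __post_init__(self) -> None:
        if self.detail_threshold < 1:
            raise ValueError("detail_threshold must be >= 1")
        if self.dpi < 72:
            raise ValueError("dpi must be >= 72")


def detail_mode(n_genomes: int, detail_threshold: int = 20) -> str:
    """Pure mode selector: 'detailed' iff n_genomes <= threshold."""
    return "detailed" if n_genomes <= detail_threshold else "summary"


def _save(fig, outdir: Path, stem: str, spec: PlotSpec) -> List[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in spec.formats:
        path = outdir / f"{stem}.{fmt}"
        fig.savefig(path, dpi=spec.dpi, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def plot_base_composition(table, outdir, spec: PlotSpec | None = None) -> List[Path]:
    """AT%/AC%/GT% figure: grouped bars by genome (detailed) or
    frequency polygons of the three percentages (summary)."""
    spec = spec or PlotSpec()
    pct = table.percentages
    mode = detail_mode(len(pct), spec.detail_threshold)
    labels = {"at_pct": "AT%", "ac_pct": "AC% (J)", "gt_pct": "GT% (N)"}
    if mode == "detailed":
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(pct)), 4))
        x = np.arange(len(pct))
        for i, (col, label) in enumerate(labels.items()):
            ax.bar(x + (i - 1) * 0.27, pct[col], width=0.25, label=label)
        ax.set_xticks(x)
        ax.set_xticklabels(pct.index, rotation=90, fontsize=7)
        ax.set_ylabel("percent of countable nucleotides")
    else:
        fig, ax = plt.subplots(figsize=(6, 4))
        for col, label in labels.items():
            values = pct[col].dropna()
            counts, edges = np.histogram(values, bins=min(20, max(5, len(values) // 5)))
            ax.plot((edges[:-1] + edges[1:]) / 2, counts, marker="o", label=label)
        ax.set_xlabel("percent")
        ax.set_ylabel("number of genomes")
    ax.legend(fontsize=8)
    ax.set_title(f"Base composition ({len(pct)} genomes)")
    return _save(fig, Path(outdir), "basecomp", spec)


def plot_skews(table, outdir, spec: PlotSpec | None = None) -> List[Path]:
    """Per-codon-position CG vs AT skew scatters; marker shape encodes
    strand always, colour encodes genome only in detailed mode."""
    spec = spec or PlotSpec()
    skews = table.skews
    genomes = list(table.percentages.index)
    mode = detail_mode(len(genomes), spec.detail_threshold)
    colors = dict(zip(genomes, sns.color_palette(spec.palette, len(genomes))))
    paths: List[Path] = []
    for pos in (1, 2, 3):
        fig, ax = plt.subplots(figsize=(5, 4.5))
        sub = skews[skews["position"] == pos]
        for strand, marker in _STRAND_MARKERS.items():
            ss = sub[sub["strand"] == strand]
            if mode == "detailed":
                for _, row in ss.iterrows():
                    ax.scatter(
                        row["at_skew"],
                        row["cg_skew"],
                        marker=marker,
                        color=colors[row["genome"]],
                        label=f"{row['genome']} ({strand})",
                        s=40,
                    )
            else:
                ax.scatter(
                    ss["at_skew"], ss["cg_skew"], marker=marker, color="0.3",
                    alpha=0.6, s=25, label=f"{strand} strand",
                )
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel("AT skew")
        ax.set_ylabel("CG skew")
        ax.set_title(f"Codon position {pos}")
        if mode == "detailed":
            ax.legend(fontsize=5, ncol=2, markerscale=0.7)
        else:
            ax.legend(fontsize=8)
        paths += _save(fig, Path(outdir), f"skews_pos{pos}", spec)
    return paths


def _aa_freq_panels(aa_freq: pd.DataFrame, mode: str, spec: PlotSpec):
    classes = ["J", "N", "all"]
    fig, axes = plt.subplots(3, 1, figsize=(9, 10), sharex=True)
    aas = sorted(aa_freq["aa"].unique())
    for ax, cls in zip(axes, classes):
        sub = aa_freq[aa_freq["strand_class"] == cls]
        if sub.empty:
            ax.annotate(
                "no data", xy=(0.5, 0.5), xycoords="axes fraction",
                ha="center", fontsize=12, color="grey",
            )
            ax.set_title(f"{cls} strand genes")
            continue
        if mode == "detailed":
            genomes = sorted(sub["genome"].unique())
            colors = dict(zip(genomes, sns.color_palette(spec.palette, len(genomes))))
            width = 0.8 / max(1, len(genomes))
            x = np.arange(len(aas))
            for gi, genome in enumerate(genomes):
                gsub = sub[sub["genome"] == genome].set_index("aa")["freq"]
                ax.bar(
                    x + gi * width - 0.4,
                    [gsub.get(a, 0.0) for a in aas],
                    width=width,
                    color=colors[genome],
                    label=genome,
                )
            ax.set_xticks(x)
            ax.set_xticklabels(aas)
        else:
            data = [sub[sub["aa"] == a]["freq"].values for a in aas]
            ax.boxplot(data, tick_labels=aas)
        ax.set_ylabel("frequency")
        ax.set_title(f"{cls} strand genes")
    if mode == "detailed":
        axes[0].legend(fontsize=5, ncol=4)
    axes[-1].set_xlabel("amino acid")
    fig.suptitle("Amino-acid usage by strand class")
    return fig


def plot_usage(table, outdir, spec: PlotSpec | None = None) -> List[Path]:
    """Amino-acid frequency figure (3 strand panels; bars or boxplots by
    genome count) plus one RSCU figure per genome."""
    spec = spec or PlotSpec()
    outdir = Path(outdir)
    n = table.n_genomes
    mode = detail_mode(n, spec.detail_threshold)
    paths = _save(_aa_freq_panels(table.aa_freq, mode, spec), outdir, "aafreq", spec)
    for genome in sorted(table.codon_table["genome"].unique()):
        sub = table.genome_rscu(genome).copy()
        sub = sub.dropna(subset=["rscu"])
        aas = sorted(sub["aa"].unique())
        fig, ax = plt.subplots(figsize=(10, 4.5))
        x = np.arange(len(aas))
        family_colors = sns.color_palette(spec.palette, 6)
        for xi, aa in enumerate(aas):
            fam = sub[sub["aa"] == aa].sort_values("codon")
            bottom = 0.0
            for ci, (_, row) in enumerate(fam.iterrows()):
                ax.bar(
                    xi, row["rscu"], bottom=bottom,
                    color=family_colors[ci % 6], edgecolor="white", width=0.7,
                )
                if row["rscu"] > 0.15:
                    ax.text(
                        xi, bottom + row["rscu"] / 2, row["codon"],
                        ha="center", va="center", fontsize=5,
                    )
                bottom += row["rscu"]
        ax.set_xticks(x)
        ax.set_xticklabels(aas)
        ax.set_ylabel("RSCU")
        ax.set_title(f"Relative synonymous codon usage: {genome}")
        paths += _save(fig, outdir, f"rscu_{genome}", spec)
    return paths
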