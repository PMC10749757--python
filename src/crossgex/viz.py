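"""Static plots over the result types.

Each plot writes the exact plot-ready table next to the image, so what
was rendered is auditable without pixel inspection: lollipop plots for
CV results, diversity/specificity scatters for DS results, and violin
plots for expression values by tissue and species.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .errors import ValidationError
from .expression_store import ExpressionTable, write_table
from .metrics import CVResult, DSResult

PLOT_KINDS = ("lollipop", "scatter", "violin")


def _companion_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".tsv") if path.suffix == "" \
        else path.with_suffix(".tsv")


def plot_metrics(result, kind: str, path: str | Path) -> Path:
    """Render a result to a static image plus its companion table.

    ``lollipop`` expects a :class:`CVResult`, ``scatter`` a
    :class:`DSResult`, ``violin`` an :class:`ExpressionTable`; any other
    pairing is an error, as is an empty result.
    """
    path = Path(path)
    if kind not in PLOT_KINDS:
        raise ValidationError(f"kind must be one of {PLOT_KINDS}, got {kind!r}")

    if kind == "lollipop":
        if not isinstance(result, CVResult):
            raise ValidationError("lollipop plots require a CVResult")
        df = result.frame
        if df.empty:
            raise ValidationError("empty CVResult; nothing to plot")
        return _lollipop(df, result, path)
    if kind == "scatter":
        if not isinstance(result, DSResult):
            raise ValidationError("scatter plots require a DSResult")
        df = result.frame
        if df.empty:
            raise ValidationError("empty DSResult; nothing to plot")
        return _scatter(df, result, path)
    if not isinstance(result, ExpressionTable):
        raise ValidationError("violin plots require an ExpressionTable")
    if len(result) == 0:
        raise ValidationError("empty expression table; nothing to plot")
    return _violin(result, path)


def _lollipop(df: pd.DataFrame, result: CVResult, path: Path) -> Path:
    plotted = df.dropna(subset=["cv"]).copy()
    plotted["label"] = plotted["gene_id"] + " / " + plotted["species"] \
        + " / " + plotted["group_label"]
    plotted = plotted.sort_values(["gene_id", "species", "group_label"])
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(plotted), 4) + 1.5))
    y = range(len(plotted))
    ax.hlines(y, 0, plotted["cv"], color="grey", lw=1)
    ax.plot(plotted["cv"], list(y), "o", color="tab:blue")
    ax.set_yticks(list(y), plotted["label"])
    ax.set_xlabel("coefficient of variation (sd / median of VST)")
    ax.set_title(f"CV ({plotted['mode'].iloc[0]})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    write_table(CVResult(plotted.drop(columns="label")),
                _companion_path(path))
    return path


def _scatter(df: pd.DataFrame, result: DSResult, path: Path) -> Path:
    plotted = df.dropna(subset=["diversity", "specificity"]).copy()
    fig, ax = plt.subplots(figsize=(6, 6))
    for sp, grp in plotted.groupby("species"):
        ax.scatter(grp["diversity"], grp["specificity"], label=sp, alpha=0.8)
        for _, row in grp.iterrows():
            ax.annotate(row["unit_id"],
                        (row["diversity"], row["specificity"]),
                        fontsize=7, alpha=0.7)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.set_xlabel("diversity")
    ax.set_ylabel("specificity")
    ax.set_title(f"diversity vs specificity ({plotted['mode'].iloc[0]})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    write_table(DSResult(plotted), _companion_path(path))
    return path


def _violin(table: ExpressionTable, path: Path) -> Path:
    df = table.data
    groups = sorted(df.groupby(["tissue", "species"]).groups)
    data = [df[(df["tissue"] == t) & (df["species"] == s)]["value"].to_numpy()
            for t, s in groups]
    labels = [f"{t}\n{s}" for t, s in groups]
    fig, ax = plt.subplots(figsize=(max(1.0 * len(groups), 4), 5))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), labels, fontsize=7)
    ax.set_ylabel(f"expression ({table.scale})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    write_table(table, _companion_path(path))
    return path
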