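"""Specification curves: rank-ordered estimates over the decision grid.

The curve is the standard two-panel display: the top panel shows the effect
estimates in ascending order (with confidence whiskers, significant versus
non-significant estimates visually distinct, and the original specification
enlarged), and the bottom panel shows, for each estimate, a dot per decision
option that produced it, grouped by decision point.  Both panels share the
specification-rank x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .engine import MultiverseResult

EFFECT_TYPES = ("indirect", "direct", "total")


@dataclass
class SpecCurveData:
    """Sorted estimates plus the decision-indicator matrix behind the plot.

    ``frame`` holds one row per specification, ascending by estimate (ties
    broken by universe id); ``decision_matrix`` is an indicator grid over
    (decision point, option) columns aligned row-for-row with ``frame``;
    ``original_index`` is the rank position of the original specification
    (None when the original universe is absent, e.g. it failed).
    """

    effect_type: str
    frame: pd.DataFrame
    decision_matrix: pd.DataFrame
    original_index: int | None

    def __len__(self) -> int:
        return len(self.frame)


def build_curve(result: MultiverseResult, effect_type: str) -> SpecCurveData:
    """Sort the requested effect's rows ascending and build the aligned
    decision-indicator matrix.  Deterministic: ties are broken by universe
    id, so permuting the input rows cannot change the curve."""
    if effect_type not in EFFECT_TYPES:
        raise ValueError(
            f"unknown effect type {effect_type!r}; expected one of {EFFECT_TYPES}"
        )
    rows = result.rows(effect_type)
    rows = rows[rows["estimate"].notna()]
    if rows.empty:
        raise ValueError(f"no non-failed {effect_type!r} rows to plot")
    rows = rows.sort_values(
        ["estimate", "universe_id"], kind="mergesort"
    ).reset_index(drop=True)

    choice_cols = [c for c in rows.columns if c.startswith("choice_")]
    indicators = {}
    for col in choice_cols:
        point = col[len("choice_"):]
        for option in [o for o in rows[col].unique() if o]:
            indicators[(point, option)] = (rows[col] == option).to_numpy()
    matrix = pd.DataFrame(indicators, index=rows.index)
    matrix.columns = pd.MultiIndex.from_tuples(
        matrix.columns, names=["decision_point", "option"]
    )

    originals = rows.index[rows["is_original"].astype(bool)]
    original_index = int(originals[0]) if len(originals) else None
    return SpecCurveData(
        effect_type=effect_type,
        frame=rows,
        decision_matrix=matrix,
        original_index=original_index,
    )


def to_frame(curve: SpecCurveData) -> pd.DataFrame:
    """Flat CSV-ready export: estimates plus 0/1 decision indicators."""
    flat = curve.decision_matrix.copy()
    flat.columns = [f"{p}={o}" for p, o in flat.columns]
    out = pd.concat(
        [
            curve.frame[
                ["universe_id", "estimate", "ci_lower", "ci_upper",
                 "significant", "is_original"]
            ],
            flat.astype(int),
        ],
        axis=1,
    )
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def render_curve(
    curve: SpecCurveData,
    output_path: str,
    format: str = "svg",
    show_ci: bool = True,
    title: str | None = None,
) -> str:
    """Render the two-panel specification curve to SVG or PNG.

    Rendering is deterministic for fixed input: the SVG hash salt and
    metadata are pinned, so identical curves produce identical bytes.
    """
    fmt = format.lower()
    if fmt not in {"svg", "png"}:
        raise ValueError("format must be 'svg' or 'png'")

    n = len(curve)
    x = np.arange(1, n + 1)
    est = curve.frame["estimate"].to_numpy(float)
    sig = curve.frame["significant"].fillna(False).astype(bool).to_numpy()
    matrix = curve.decision_matrix

    n_opts = matrix.shape[1]
    with matplotlib.rc_context({"svg.hashsalt": "medmultiverse"}):
        fig = Figure(figsize=(max(6.0, n * 0.08), 4.5 + 0.22 * n_opts))
        FigureCanvasAgg(fig)
        ax_top, ax_bot = fig.subplots(
            2, 1, sharex=True,
            height_ratios=[3.0, max(1.0, 0.12 * n_opts)],
        )

        if show_ci:
            lo = curve.frame["ci_lower"].to_numpy(float)
            hi = curve.frame["ci_upper"].to_numpy(float)
            ax_top.vlines(x, lo, hi, color="0.75", lw=0.8, zorder=1)
        ax_top.scatter(x[~sig], est[~sig], s=12, color="0.6", zorder=2,
                       label="not significant")
        ax_top.scatter(x[sig], est[sig], s=12, color="#1f77b4", zorder=2,
                       label="significant")
        if curve.original_index is not None:
            i = curve.original_index
            ax_top.scatter([x[i]], [est[i]], s=90, facecolor="none",
                           edgecolor="#d62728", lw=1.6, zorder=3,
                           label="original specification")
        ax_top.axhline(0.0, color="k", lw=0.8, ls="--", zorder=0)
        ax_top.set_ylabel(f"{curve.effect_type} effect estimate")
        ax_top.legend(loc="upper left", fontsize=7, frameon=False)
        if title:
            ax_top.set_title(title)

        yticks, ylabels = [], []
        row = 0
        for point in matrix.columns.get_level_values(0).unique():
            options = matrix[point].columns
            for option in options:
                active = matrix[(point, option)].to_numpy()
                ax_bot.scatter(x[active], np.full(active.sum(), row),
                               s=7, color="#333333", marker="s")
                yticks.append(row)
                ylabels.append(f"{point}: {option}")
                row += 1
            row += 0.6  # gap between decision points
        ax_bot.set_yticks(yticks)
        ax_bot.set_yticklabels(ylabels, fontsize=6)
        ax_bot.invert_yaxis()
        ax_bot.set_xlabel("specification (ranked by estimate)")

        fig.tight_layout()
        metadata = {"Date": None} if fmt == "svg" else {}
        fig.savefig(output_path, format=fmt, metadata=metadata, dpi=150)
    return output_path
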