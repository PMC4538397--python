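"""Largest-tree accumulation curves.

Stems are ranked within each plot by decreasing AGB; the curve tracks, as a
function of the number N of largest trees, the cumulative AGB (and its
fraction of the plot total AGB_TOT) and the cumulative species richness
(and its fraction of the plot total species_TOT). Unidentified stems keep
their AGB but never add to richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stand_data import Plot, TreeRecord


def rank_trees(plot: Plot) -> list[TreeRecord]:
    """Stems of a plot ordered by decreasing AGB.

    Deterministic: AGB ties broken by larger DBH, then by stem id
    (lexicographic). Every stem must have AGB set.
    """
    for t in plot.trees:
        if t.agb is None:
            raise ValueError(f"stem {t.stem_id} in plot {plot.plot_id} has no AGB")
    return sorted(plot.trees, key=lambda t: (-t.agb, -t.dbh, t.stem_id))


@dataclass
class AccumulationCurve:
    """Cumulative AGB and richness over the N largest trees of one plot."""

    plot_id: str
    site_id: str
    n_values: np.ndarray        # 1..stems
    topn_agb: np.ndarray        # kg, cumulative
    agb_fraction: np.ndarray    # of plot AGB_TOT, in [0, 1]
    richness: np.ndarray        # distinct identified species among top N
    richness_fraction: np.ndarray  # of plot species_TOT, in [0, 1]

    @property
    def agb_total(self) -> float:
        return float(self.topn_agb[-1])

    @property
    def species_total(self) -> int:
        return int(self.richness[-1])

    def at(self, n: int) -> dict:
        """Curve values at N largest trees (N capped at the stem count)."""
        i = min(n, len(self.n_values)) - 1
        return {
            "n": int(self.n_values[i]),
            "topn_agb": float(self.topn_agb[i]),
            "agb_fraction": float(self.agb_fraction[i]),
            "richness": int(self.richness[i]),
            "richness_fraction": float(self.richness_fraction[i]),
        }


def cumulative_curve(plot: Plot) -> AccumulationCurve:
    """Accumulation curve of one plot (see module docstring)."""
    ranked = rank_trees(plot)
    if not ranked:
        raise ValueError(f"plot {plot.plot_id} is empty")
    agb = np.array([t.agb for t in ranked])
    cum_agb = np.cumsum(agb)
    total = cum_agb[-1]

    seen: set[str] = set()
    richness = np.empty(len(ranked), dtype=int)
    for i, t in enumerate(ranked):
        if t.is_identified:
            seen.add(t.species)
        richness[i] = len(seen)
    s_tot = richness[-1]

    return AccumulationCurve(
        plot_id=plot.plot_id,
        site_id=plot.site_id,
        n_values=np.arange(1, len(ranked) + 1),
        topn_agb=cum_agb,
        agb_fraction=cum_agb / total,
        richness=richness,
        richness_fraction=richness / s_tot if s_tot else np.zeros(len(ranked)),
    )


def site_summary(
    plots: list[Plot],
    n_grid: np.ndarray | list[int] | None = None,
) -> pd.DataFrame:
    """Across-plot mean and sd of the accumulation fractions per N.

    N is capped at each plot's stem count, so every plot contributes at
    every grid point. With a single plot the sd columns are 0 and the
    ``single_plot`` flag is set.
    """
    if not plots:
        raise ValueError("empty site")
    curves = [cumulative_curve(p) for p in plots]
    grid = np.asarray(n_grid if n_grid is not None else np.arange(1, 101))

    rows = []
    single = len(curves) == 1
    for n in grid:
        af = np.array([c.at(int(n))["agb_fraction"] for c in curves])
        rf = np.array([c.at(int(n))["richness_fraction"] for c in curves])
        ta = np.array([c.at(int(n))["topn_agb"] for c in curves])
        rows.append(
            {
                "n": int(n),
                "agb_fraction_mean": af.mean(),
                "agb_fraction_sd": 0.0 if single else af.std(ddof=1),
                "richness_fraction_mean": rf.mean(),
                "richness_fraction_sd": 0.0 if single else rf.std(ddof=1),
                "topn_agb_mean": ta.mean(),
                "n_plots": len(curves),
                "single_plot": single,
            }
        )
    return pd.DataFrame(rows)


def curves_to_frame(curves: list[AccumulationCurve]) -> pd.DataFrame:
    """Long-format table (site, plot, N, topn_agb_kg, fractions) for export."""
    frames = [
        pd.DataFrame(
            {
                "site": c.site_id,
                "plot": c.plot_id,
                "N": c.n_values,
                "topn_agb_kg": c.topn_agb,
                "agb_fraction": c.agb_fraction,
                "richness": c.richness,
                "richness_fraction": c.richness_fraction,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)
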