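"""Species biomass dominance at site and regional scale.

A species' regional contribution is the unweighted mean over sites of its
site-standardized AGB (t/ha; a site's species totals divided by the site's
sampled area, so every site contributes equally regardless of plot count).
The "biomass hyperdominants" are the minimal set of top-ranked species whose
cumulative contribution reaches 50% of the regional total; "local dominants"
are the same notion within one site. Unidentified stems count toward total
AGB (the denominator) but can never themselves be dominant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .stand_data import INDET, Plot

#: Fraction of regional/site AGB that defines (hyper)dominance.
DEFAULT_THRESHOLD = 0.5


def site_species_agb(plots: Sequence[Plot], include_indet: bool = True) -> pd.Series:
    """Per-species AGB (t/ha) at one site, standardized by sampled area.

    The site area is the number of 1-ha plots; kg are converted to tonnes.
    The sentinel taxon for unidentified stems is kept (it carries real AGB)
    unless ``include_indet`` is False.
    """
    if not plots:
        raise ValueError("empty site")
    area_ha = sum(p.area for p in plots)
    totals: dict[str, float] = {}
    for p in plots:
        for t in p.trees:
            if t.agb is None:
                raise ValueError(f"stem {t.stem_id} has no AGB")
            sp = t.species if t.is_identified else INDET
            totals[sp] = totals.get(sp, 0.0) + t.agb
    s = pd.Series(totals, dtype=float) / 1000.0 / area_ha
    if not include_indet:
        s = s.drop(INDET, errors="ignore")
    return s.sort_values(ascending=False)


def regional_contributions(
    sites: dict[str, list[Plot]],
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Ranked table of species contributions to regional AGB.

    Columns: species, family, agb_t_ha (unweighted mean of site-standardized
    AGB, absent sites counting 0), pct (of regional total including
    unidentified stems), pct_cum (cumulated down the ranking, unidentified
    stems excluded from the ranking), rank, n_sites, sites. Ties in AGB are
    broken alphabetically.
    """
    if not sites:
        raise ValueError("no sites")
    per_site = {s: site_species_agb(ps) for s, ps in sites.items()}
    mat = pd.DataFrame(per_site).fillna(0.0)  # species x sites
    regional = mat.mean(axis=1)
    total = float(regional.sum())  # includes the indet pool

    ranked = regional.drop(INDET, errors="ignore")
    order = sorted(ranked.index, key=lambda sp: (-ranked[sp], sp))
    ranked = ranked.loc[order]

    pct = 100.0 * ranked / total
    presence = (mat > 0).loc[order]
    fam = families or {}
    df = pd.DataFrame(
        {
            "species": order,
            "family": [fam.get(sp, "") for sp in order],
            "agb_t_ha": ranked.values,
            "pct": pct.values,
            "pct_cum": cumulate(pct.values),
            "rank": np.arange(1, len(order) + 1),
            "n_sites": presence.sum(axis=1).values,
            "sites": [",".join(sorted(presence.columns[presence.loc[sp]]))
                      for sp in order],
        }
    ).reset_index(drop=True)
    return df


def cumulate(pct: np.ndarray | Sequence[float]) -> np.ndarray:
    """Running sum of ranked percentage contributions (the cumulation column)."""
    return np.cumsum(np.asarray(pct, dtype=float))


def hyperdominant_set(
    contributions: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Minimal prefix of the ranked species whose cumulative share reaches
    ``threshold`` (inclusive: the species that crosses the line is in)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cum = cumulate(contributions["pct"].values) / 100.0
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(cum))
    return list(contributions["species"].iloc[:k])


def local_dominants(
    plots: Sequence[Plot], threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Species cumulating ``threshold`` of one site's AGB (ranked prefix)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    s = site_species_agb(plots)
    total = float(s.sum())
    s = s.drop(INDET, errors="ignore")
    order = sorted(s.index, key=lambda sp: (-s[sp], sp))
    cum = np.cumsum(s.loc[order].values) / total
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(order))
    return order[:k]


def classify_overlap(
    sites: dict[str, list[Plot]], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per site, how many local dominants are also regional hyperdominants.

    Columns: site, local_and_regional, local_only, n_local (= their sum).
    """
    regional = set(hyperdominant_set(regional_contributions(sites), threshold))
    rows = []
    for site, plots in sites.items():
        local = local_dominants(plots, threshold)
        both = sum(1 for sp in local if sp in regional)
        rows.append(
            {
                "site": site,
                "local_and_regional": both,
                "local_only": len(local) - both,
                "n_local": len(local),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged reference table

@dataclass
class ReferenceTable:
    """The packaged Central African biomass-hyperdominant reference table.

    ``frame`` holds the printed columns (species, family, agb_t_ha, pct,
    pct_cum, n_sites, sites); ``n_recorded_species`` is the total species
    count recorded across the eight surveyed sites.
    """

    frame: pd.DataFrame
    n_recorded_species: int


def load_reference_table() -> ReferenceTable:
    """Load the packaged regional hyperdominants table (printed values)."""
    path = resources.files("toptrees.data").joinpath("regional_hyperdominants.tsv")
    with resources.as_file(path) as p:
        meta = {}
        with open(p) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    meta[k.strip()] = v.strip()
                else:
                    break
        df = pd.read_csv(p, sep="\t", comment="#")
    return ReferenceTable(frame=df, n_recorded_species=int(meta["n_recorded_species"]))
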