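"""Inventory data model, delimited-text I/O and wood-density assignment.

A census is a collection of 1-ha :class:`Plot` objects, each holding
:class:`TreeRecord` stems (DBH >= 10 cm). Wood specific gravity is assigned
per stem from a :class:`WoodDensityTable` with the standard taxonomic
fallback: species mean, else genus mean, else family mean, else the
table-wide mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel taxon for unidentified stems. They keep their AGB but are
#: excluded from species-richness and dominance tallies.
INDET = "indet"

#: Census threshold: stems below 10 cm DBH are not part of the protocol.
MIN_DBH_CM = 10.0

#: Plausible range for wood specific gravity (g/cm3).
WD_RANGE = (0.05, 1.5)

#: Canonical inventory columns written by :func:`write_inventory`.
#: ``agb_kg`` is optional on input and carried on output when computed.
INVENTORY_COLUMNS = [
    "site", "plot", "stem", "family", "genus", "species",
    "dbh_cm", "height_m", "wd", "agb_kg",
]


class InventoryError(ValueError):
    """Raised for unreadable or structurally invalid inventory files."""


@dataclass
class TreeRecord:
    """One measured stem.

    ``species`` is the full binomial (or :data:`INDET`); ``height``,
    ``wood_density`` and ``agb`` may be filled later by the allometry
    pipeline. Units: dbh cm, height m, wood_density g/cm3, agb kg.
    """

    site_id: str
    plot_id: str
    stem_id: str
    species: str = INDET
    genus: str = ""
    family: str = ""
    dbh: float = 0.0
    height: float | None = None
    wood_density: float | None = None
    agb: float | None = None
    wd_level: str | None = None  # provenance: species/genus/family/global

    def validate(self) -> None:
        if not self.dbh > 0:
            raise ValueError(f"stem {self.stem_id}: dbh must be > 0, got {self.dbh}")
        if self.dbh < MIN_DBH_CM:
            raise ValueError(
                f"stem {self.stem_id}: dbh {self.dbh} cm below census threshold "
                f"{MIN_DBH_CM} cm"
            )
        if self.wood_density is not None and not (
            WD_RANGE[0] < self.wood_density < WD_RANGE[1]
        ):
            raise ValueError(
                f"stem {self.stem_id}: wood density {self.wood_density} outside "
                f"{WD_RANGE}"
            )
        if self.agb is not None and not self.agb > 0:
            raise ValueError(f"stem {self.stem_id}: agb must be > 0, got {self.agb}")

    @property
    def is_identified(self) -> bool:
        return bool(self.species) and self.species != INDET


@dataclass
class Plot:
    """A 1-ha inventory plot; ``site_id`` groups plots sharing one H–D fit."""

    plot_id: str
    site_id: str
    trees: list[TreeRecord] = field(default_factory=list)
    area: float = 1.0

    def validate(self) -> None:
        if self.area != 1.0:
            raise ValueError(f"plot {self.plot_id}: area must be 1.0 ha")
        if not self.trees:
            raise ValueError(f"plot {self.plot_id}: no trees")
        for t in self.trees:
            t.validate()

    @property
    def agb_total(self) -> float:
        """Total plot AGB in kg; requires every stem's agb to be set."""
        missing = [t.stem_id for t in self.trees if t.agb is None]
        if missing:
            raise ValueError(f"plot {self.plot_id}: stems without AGB: {missing[:5]}")
        return sum(t.agb for t in self.trees)

    @property
    def species_richness(self) -> int:
        """Distinct identified species (the sentinel taxon does not count)."""
        return len({t.species for t in self.trees if t.is_identified})


@dataclass
class WoodDensityTable:
    """Wood specific gravity lookups at species, genus and family level.

    Genus and family means are derived from the species-level map unless
    provided explicitly; ``global_mean`` is the terminal fallback so every
    stem receives a density.
    """

    species_mean: dict[str, float]
    genus_mean: dict[str, float] = field(default_factory=dict)
    family_mean: dict[str, float] = field(default_factory=dict)
    global_mean: float | None = None

    def __post_init__(self) -> None:
        if not self.species_mean and self.global_mean is None:
            raise ValueError("empty wood-density table")
        if self.species_mean:
            s = pd.Series(self.species_mean)
            if not self.genus_mean:
                genera = s.index.to_series().str.split().str[0]
                self.genus_mean = s.groupby(genera).mean().to_dict()
            if self.global_mean is None:
                self.global_mean = float(s.mean())
        for name, mapping in (
            ("species", self.species_mean),
            ("genus", self.genus_mean),
            ("family", self.family_mean),
        ):
            bad = {k: v for k, v in mapping.items() if not (WD_RANGE[0] < v < WD_RANGE[1])}
            if bad:
                raise ValueError(f"{name}-level densities outside {WD_RANGE}: {bad}")

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        sep: str = ",",
        columns: Mapping[str, str] | None = None,
    ) -> "WoodDensityTable":
        """Read a reference table with family,genus,species,wd columns.

        ``columns`` maps canonical names to the file's header names, so the
        column layout of the global wood-density repository (e.g. its
        "Binomial" / "Wood density (g/cm^3) ..." headers) can be accepted.
        """
        colmap = {"family": "family", "genus": "genus", "species": "species", "wd": "wd"}
        if columns:
            colmap.update(columns)
        df = pd.read_csv(path, sep=sep)
        missing = [v for v in (colmap["species"], colmap["wd"]) if v not in df.columns]
        if missing:
            raise InventoryError(f"wood-density table missing columns: {missing}")
        df = df.rename(columns={v: k for k, v in colmap.items()})
        species = df.groupby("species")["wd"].mean().to_dict()
        family_mean: dict[str, float] = {}
        if "family" in df.columns:
            fam = df.dropna(subset=["family"])
            family_mean = fam.groupby("family")["wd"].mean().to_dict()
        genus_mean: dict[str, float] = {}
        if "genus" in df.columns:
            gen = df.dropna(subset=["genus"])
            genus_mean = gen.groupby("genus")["wd"].mean().to_dict()
        return cls(
            species_mean=species,
            genus_mean=genus_mean,
            family_mean=family_mean,
            global_mean=float(df["wd"].mean()),
        )

    def lookup(self, species: str, genus: str = "", family: str = "") -> tuple[float, str]:
        """Return (density, provenance level) with the taxonomic fallback."""
        if species and species in self.species_mean:
            return self.species_mean[species], "species"
        g = genus or (species.split()[0] if species and species != INDET else "")
        if g and g in self.genus_mean:
            return self.genus_mean[g], "genus"
        if family and family in self.family_mean:
            return self.family_mean[family], "family"
        return float(self.global_mean), "global"


def assign_wood_density(tree: TreeRecord, table: WoodDensityTable) -> TreeRecord:
    """Return a copy of ``tree`` with wood density and its provenance set."""
    wd, level = table.lookup(tree.species if tree.is_identified else "",
                             tree.genus, tree.family)
    return replace(tree, wood_density=wd, wd_level=level)


def assign_wood_densities(plots: Iterable[Plot], table: WoodDensityTable) -> list[Plot]:
    """Wood-density assignment over whole plots (copies, inputs untouched)."""
    return [
        Plot(
            plot_id=p.plot_id,
            site_id=p.site_id,
            trees=[assign_wood_density(t, table) for t in p.trees],
            area=p.area,
        )
        for p in plots
    ]


def read_inventory(
    path: str | Path,
    sep: str = ",",
    columns: Mapping[str, str] | None = None,
    on_small_dbh: str = "warn",
) -> list[Plot]:
    """Read a delimited inventory into plots grouped by (site, plot).

    ``columns`` maps canonical column names (see :data:`INVENTORY_COLUMNS`)
    to the file's header names. ``on_small_dbh`` controls stems below the
    10 cm census threshold: ``"warn"`` drops them with a logged warning,
    ``"error"`` raises.

    Raises :class:`InventoryError` for missing mandatory columns or
    non-numeric DBH values (reported with their 1-based data row number).
    """
    colmap = {c: c for c in INVENTORY_COLUMNS}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mandatory = ["site", "plot", "dbh_cm"]
    missing = [colmap[c] for c in mandatory if colmap[c] not in df.columns]
    if missing:
        raise InventoryError(f"{path}: missing mandatory columns: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items() if v in df.columns})

    dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
    bad_rows = df.index[dbh.isna()] + 1  # 1-based data rows
    if len(bad_rows):
        raise InventoryError(
            f"{path}: non-numeric dbh_cm on data row(s) {list(bad_rows[:10])}"
        )
    df["dbh_cm"] = dbh

    small = df["dbh_cm"] < MIN_DBH_CM
    if small.any():
        if on_small_dbh == "error":
            raise InventoryError(
                f"{path}: {int(small.sum())} stems below {MIN_DBH_CM} cm DBH"
            )
        logger.warning(
            "%s: dropping %d stems below %.0f cm DBH", path, int(small.sum()), MIN_DBH_CM
        )
        df = df[~small]

    def opt_float(row: pd.Series, col: str) -> float | None:
        v = row.get(col, "")
        return float(v) if v not in ("", None) else None

    plots: dict[tuple[str, str], Plot] = {}
    for i, row in df.iterrows():
        key = (str(row["site"]), str(row["plot"]))
        plot = plots.setdefault(key, Plot(plot_id=key[1], site_id=key[0]))
        plot.trees.append(
            TreeRecord(
                site_id=key[0],
                plot_id=key[1],
                stem_id=str(row.get("stem", "")) or f"s{i+1}",
                species=str(row.get("species", "")) or INDET,
                genus=str(row.get("genus", "")),
                family=str(row.get("family", "")),
                dbh=float(row["dbh_cm"]),
                height=opt_float(row, "height_m"),
                wood_density=opt_float(row, "wd"),
                agb=opt_float(row, "agb_kg"),
            )
        )
    return list(plots.values())


def write_inventory(plots: Sequence[Plot], path: str | Path, sep: str = ",") -> None:
    """Write plots back to delimited text re-readable by :func:`read_inventory`."""
    frame = plots_to_frame(plots)
    frame.to_csv(path, sep=sep, index=False)


def plots_to_frame(plots: Sequence[Plot]) -> pd.DataFrame:
    """Flatten plots to a one-row-per-stem DataFrame (canonical columns)."""
    rows = [
        {
            "site": t.site_id,
            "plot": t.plot_id,
            "stem": t.stem_id,
            "family": t.family,
            "genus": t.genus,
            "species": t.species,
            "dbh_cm": t.dbh,
            "height_m": t.height,
            "wd": t.wood_density,
            "agb_kg": t.agb,
        }
        for p in plots
        for t in p.trees
    ]
    return pd.DataFrame(rows, columns=INVENTORY_COLUMNS)


def group_by_site(plots: Iterable[Plot]) -> dict[str, list[Plot]]:
    sites: dict[str, list[Plot]] = {}
    for p in plots:
        sites.setdefault(p.site_id, []).append(p)
    return sites
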