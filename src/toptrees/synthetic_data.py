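"""Synthetic multi-site tropical-forest inventories.

The generator emulates the structural features the analysis pipeline relies
on: a truncated power-law (Pareto) stem-diameter distribution — the inverse
size–abundance relation predicted by metabolic scaling — dominance-skewed
species abundances (log-series or geometric), species-level wood densities,
a noisy power height–diameter allometry, multiplicative site effects on stem
density and stature, and optionally monodominant sites where one species
holds most of the large-tree basal area (mimicking Gilbertiodendron-type
stands). Stem AGB is computed through the allometry module so the full
pipeline is exercised end to end.

Everything is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .allometry import agb_with_height
from .stand_data import INDET, Plot, TreeRecord, WoodDensityTable

#: DBH (cm) above which a stem counts as a "large tree" for monodominance.
LARGE_TREE_DBH = 50.0


@dataclass
class SyntheticConfig:
    """All distributional parameters of the stand generator.

    Defaults describe a Central African moist-forest census: 8 sites of
    20 one-ha plots, ~450 stems/ha >= 10 cm DBH, Pareto(2) diameters
    truncated to [10, 250] cm, a log-series species-abundance distribution
    over a 300-species pool, species wood densities ~ N(0.60, 0.15) g/cm3,
    and a power H–D law H = 3.0 * D^0.56 with 10% lognormal height noise.
    One site is monodominant with the dominant species taking 70% of the
    large-tree pool.
    """

    seed: int = 0
    n_sites: int = 8
    plots_per_site: int = 20
    stems_per_ha: float = 450.0
    dbh_exponent: float = 2.0
    dbh_range: tuple[float, float] = (10.0, 250.0)
    sad: str = "logseries"           # or "geometric"
    sad_shape: float = 0.995         # log-series p, or geometric ratio
    species_pool: int = 300
    wd_mean: float = 0.60
    wd_sd: float = 0.15
    hd: tuple[float, float, float] = (3.0, 0.56, 0.10)  # (a, b, log-sd)
    monodominant_sites: int = 1
    dominant_share: float = 0.70
    site_effects: float = 0.10       # lognormal sd on density & stature

    def validate(self) -> None:
        problems = []
        for name in ("n_sites", "plots_per_site", "species_pool"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        for name in ("stems_per_ha", "wd_mean", "wd_sd", "site_effects"):
            if getattr(self, name) < 0 or (name in ("stems_per_ha", "wd_mean")
                                           and getattr(self, name) <= 0):
                problems.append(f"{name} must be positive")
        if self.dbh_exponent <= 1:
            problems.append("dbh_exponent must be > 1 (integrable tail)")
        if not 0 < self.dbh_range[0] < self.dbh_range[1]:
            problems.append("dbh_range must satisfy 0 < lo < hi")
        if self.dbh_range[0] < 10.0:
            problems.append("dbh_range lower bound below the 10 cm census threshold")
        if self.sad not in ("logseries", "geometric"):
            problems.append(f"unknown sad {self.sad!r}")
        if not 0 < self.sad_shape < 1:
            problems.append("sad_shape must be in (0, 1)")
        if not 0 < self.dominant_share < 1:
            problems.append("dominant_share must be in (0, 1)")
        if self.monodominant_sites > self.n_sites:
            problems.append("monodominant_sites exceeds n_sites")
        if any(v <= 0 for v in self.hd[:2]) or self.hd[2] < 0:
            problems.append("hd coefficients (a, b) must be positive, sd >= 0")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


def truncated_pareto_cdf(d: np.ndarray, exponent: float,
                         lo: float, hi: float) -> np.ndarray:
    """Closed-form CDF of the truncated Pareto diameter law (pdf ~ d^-exponent)."""
    d = np.asarray(d, dtype=float)
    e = 1.0 - exponent
    return (lo**e - np.clip(d, lo, hi) ** e) / (lo**e - hi**e)


def sample_dbh(rng: np.random.Generator, size: int, exponent: float,
               lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF sample of diameters from the truncated Pareto law."""
    u = rng.uniform(size=size)
    e = 1.0 - exponent
    return (lo**e - u * (lo**e - hi**e)) ** (1.0 / e)


def sad_weights(config: SyntheticConfig) -> np.ndarray:
    """Relative abundance of species ranks 1..pool under the chosen SAD."""
    k = np.arange(1, config.species_pool + 1, dtype=float)
    p = config.sad_shape
    if config.sad == "logseries":
        w = p**k / k
    else:  # geometric
        w = (1.0 - p) * p ** (k - 1.0)
    return w / w.sum()


def species_table(config: SyntheticConfig) -> pd.DataFrame:
    """Species pool with taxonomy and true wood densities (one row/species).

    Deterministic given the seed; genera hold ~5 species and families ~3
    genera so the taxonomic fallback levels are all exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    idx = np.arange(config.species_pool)
    genus = [f"Genus{g:03d}" for g in idx // 5]
    family = [f"Family{f:02d}" for f in idx // 15]
    wd = np.clip(rng.normal(config.wd_mean, config.wd_sd, config.species_pool),
                 0.1, 1.2)
    return pd.DataFrame(
        {
            "species": [f"{g} sp{i:03d}" for i, g in zip(idx, genus)],
            "genus": genus,
            "family": family,
            "wd": wd,
        }
    )


def wood_density_table(config: SyntheticConfig) -> WoodDensityTable:
    """The generator's species wood densities as a lookup table."""
    df = species_table(config)
    return WoodDensityTable(
        species_mean=dict(zip(df["species"], df["wd"])),
        family_mean=df.groupby("family")["wd"].mean().to_dict(),
    )


def _generate_site(
    config: SyntheticConfig,
    site_id: str,
    rng: np.random.Generator,
    species: pd.DataFrame,
    monodominant: bool,
    dominant_share: float,
) -> list[Plot]:
    weights = sad_weights(config)
    # each site shuffles which species occupy the abundant ranks, giving
    # compositional turnover between sites
    perm = rng.permutation(config.species_pool)
    density_mult = rng.lognormal(0.0, config.site_effects)
    stature_mult = rng.lognormal(0.0, config.site_effects)
    hd_a, hd_b, hd_sd = config.hd
    lo, hi = config.dbh_range
    dominant_idx = int(perm[0])

    plots = []
    for j in range(config.plots_per_site):
        n_stems = max(1, int(rng.poisson(config.stems_per_ha * density_mult)))
        dbh = sample_dbh(rng, n_stems, config.dbh_exponent, lo, hi)
        sp_idx = perm[rng.choice(config.species_pool, size=n_stems, p=weights)]
        if monodominant:
            # the dominant takes the largest stems until it holds the
            # configured share of the plot's large-tree basal area, the way
            # monodominant canopies monopolise the upper size classes
            large = dbh >= LARGE_TREE_DBH
            if large.any():
                ba = dbh**2
                target = dominant_share * ba[large].sum()
                order = np.argsort(-dbh)
                taken, i = 0.0, 0
                while i < n_stems and taken < target and large[order[i]]:
                    sp_idx[order[i]] = dominant_idx
                    taken += ba[order[i]]
                    i += 1
        height = stature_mult * hd_a * dbh**hd_b * np.exp(
            rng.normal(0.0, hd_sd, n_stems)
        )
        plot_id = f"{site_id}-p{j+1:02d}"
        trees = []
        for s in range(n_stems):
            row = species.iloc[sp_idx[s]]
            wd = float(row["wd"])
            trees.append(
                TreeRecord(
                    site_id=site_id,
                    plot_id=plot_id,
                    stem_id=f"{plot_id}-t{s+1:04d}",
                    species=str(row["species"]),
                    genus=str(row["genus"]),
                    family=str(row["family"]),
                    dbh=float(dbh[s]),
                    height=float(height[s]),
                    wood_density=wd,
                    agb=agb_with_height(float(dbh[s]), float(height[s]), wd),
                    wd_level="species",
                )
            )
        plots.append(Plot(plot_id=plot_id, site_id=site_id, trees=trees))
    return plots


def generate_region(config: SyntheticConfig) -> tuple[list[Plot], dict]:
    """Generate the full multi-site inventory plus a truth sidecar.

    Returns (plots, truth) where ``truth`` records every generating
    parameter needed by recovery tests: the config, per-site multipliers
    and dominant species, and the species pool checksum.
    """
    config.validate()
    species = species_table(config)
    plots: list[Plot] = []
    site_truth = {}
    for i in range(config.n_sites):
        site_id = f"site{i+1:02d}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, i]))
        mono = i < config.monodominant_sites
        # peek the site-level draws for the sidecar with an identical stream
        peek = np.random.default_rng(np.random.SeedSequence([config.seed, 2, i]))
        perm = peek.permutation(config.species_pool)
        site_truth[site_id] = {
            "monodominant": mono,
            "density_mult": peek.lognormal(0.0, config.site_effects),
            "stature_mult": peek.lognormal(0.0, config.site_effects),
            "dominant_species": str(species["species"].iloc[int(perm[0])]),
        }
        plots.extend(
            _generate_site(config, site_id, rng, species, mono,
                           config.dominant_share)
        )
    truth = {
        "config": asdict(config),
        "sites": site_truth,
        "n_species_pool": config.species_pool,
    }
    return plots, truth


def generate_monodominant_site(
    config: SyntheticConfig, site_id: str = "mono", share: float | None = None
) -> list[Plot]:
    """One site where a single species holds ``share`` of the large-tree pool."""
    config.validate()
    share = config.dominant_share if share is None else share
    if not 0 < share < 1:
        raise ValueError(f"dominant share must be in (0, 1), got {share}")
    species = species_table(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    return _generate_site(config, site_id, rng, species, True, share)


def true_agb_law(config: SyntheticConfig, n: int = 20, reps: int = 4) -> dict:
    """Monte-Carlo estimate of the (alpha, beta) the generator implies
    between AGB_topN and AGB_TOT, with standard errors over replicates.

    Each replicate regenerates the region with an independent seed stream
    and fits the per-N power model; the returned means/SEs serve as the
    recovery target for fitting tests.
    """
    from .topn_model import fit_power_model, plot_pairs

    alphas, betas = [], []
    for r in range(reps):
        cfg = SyntheticConfig(**{**asdict(config), "seed": config.seed + 10_000 + r})
        plots, _ = generate_region(cfg)
        x, y = plot_pairs(plots, n)
        m = fit_power_model(x, y, n)
        alphas.append(m.alpha)
        betas.append(m.beta)
    alphas, betas = np.array(alphas), np.array(betas)
    se = lambda v: float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
    return {
        "n": n,
        "reps": reps,
        "alpha": float(alphas.mean()),
        "alpha_se": se(alphas),
        "beta": float(betas.mean()),
        "beta_se": se(betas),
    }
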