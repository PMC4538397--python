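import numpy as np
import pytest

from toptrees import SyntheticConfig, generate_region
from toptrees.stand_data import Plot, TreeRecord


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down region: 4 sites x 6 plots, ~150 stems/ha."""
    return SyntheticConfig(seed=42, n_sites=4, plots_per_site=6, stems_per_ha=150)


@pytest.fixture(scope="session")
def small_region(small_config):
    plots, truth = generate_region(small_config)
    return plots, truth


def make_plot(agbs, species=None, dbhs=None, plot_id="p1", site_id="s1"):
    """Plot from explicit AGB values (kg); dbh defaults track AGB rank."""
    n = len(agbs)
    species = species or [f"Genus000 sp{i:03d}" for i in range(n)]
    dbhs = dbhs or [10.0 + i for i in range(n)]
    trees = [
        TreeRecord(
            site_id=site_id, plot_id=plot_id, stem_id=f"t{i:03d}",
            species=species[i], genus=species[i].split()[0],
            dbh=float(dbhs[i]), agb=float(agbs[i]), wood_density=0.6,
        )
        for i in range(n)
    ]
    return Plot(plot_id=plot_id, site_id=site_id, trees=trees)


def power_law_plot(x_top, alpha, beta, n_top=20, plot_id="p", site_id="s"):
    """Plot whose top-``n_top`` AGB sums to x_top exactly and whose total
    obeys AGB_TOT = alpha * x_top^beta exactly (small-stem filler)."""
    total = alpha * x_top**beta
    big = x_top / n_top
    filler = total - x_top
    assert filler > 0, "law must give total above the top-N sum"
    m = int(np.ceil(filler / (big / 2.0)))
    small = filler / m
    agbs = [big] * n_top + [small] * m
    dbhs = [200.0 - i * 0.1 for i in range(n_top)] + [15.0] * m
    return make_plot(agbs, dbhs=dbhs, plot_id=plot_id, site_id=site_id)
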