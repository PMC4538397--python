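"""Tree-level above-ground biomass and height–diameter allometry.

AGB (kg dry mass) follows the pantropical moist-forest models of Chave and
colleagues. With a height measurement or prediction,

    AGB = a * (rho * D^2 * H)^b        (defaults a=0.0673, b=0.976)

with rho in g/cm3, D in cm, H in m. Without height, the diameter-only model
uses a site-level environmental stress factor E:

    ln AGB = c0 - c1*E + c2*ln(rho) + c3*ln(D) + c4*(ln D)^2

All constants live in :class:`AllometryConfig`, not in code, so alternative
published coefficient sets can be swapped in.

Site-specific height–diameter (H–D) models come in three standard forms —
power, Michaelis–Menten and Weibull — fitted on the log scale (power) or by
nonlinear least squares, with an optional half-variance back-transformation
correction for log-scale fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .stand_data import Plot, TreeRecord

HD_FORMS = ("power", "michaelis_menten", "weibull")

#: Default with-height model constants (a, b) of AGB = a*(rho*D^2*H)^b.
WITH_HEIGHT_COEFFS = (0.0673, 0.976)

#: Default height-free model constants (c0, c1, c2, c3, c4).
WITHOUT_HEIGHT_COEFFS = (-1.803, -0.976, 0.976, 2.673, -0.0299)

#: Constants (h0, h1, h2) of the E-dependent reference H–D relation
#: ln(H) = h0 - E + h1*ln(D) + h2*(ln D)^2, used for cross-checks.
E_HD_COEFFS = (0.893, 0.760, -0.0340)


@dataclass
class AllometryConfig:
    """Which AGB model to use and with which constants.

    ``mode="without_height"`` requires ``env_stress`` (the dimensionless E
    factor; roughly -0.1..0.4 across African moist forests).
    """

    mode: str = "with_height"
    env_stress: float | None = None
    with_height_coeffs: tuple[float, float] = WITH_HEIGHT_COEFFS
    without_height_coeffs: tuple[float, ...] = WITHOUT_HEIGHT_COEFFS

    def __post_init__(self) -> None:
        if self.mode not in ("with_height", "without_height"):
            raise ValueError(f"unknown allometry mode {self.mode!r}")
        if self.mode == "without_height" and self.env_stress is None:
            raise ValueError("mode='without_height' requires env_stress (E)")


def agb_with_height(
    dbh: float, height: float, wd: float,
    coeffs: tuple[float, float] = WITH_HEIGHT_COEFFS,
) -> float:
    """AGB (kg) from DBH (cm), height (m) and wood density (g/cm3)."""
    if dbh <= 0 or height <= 0 or wd <= 0:
        raise ValueError("dbh, height and wood density must all be positive")
    a, b = coeffs
    return a * (wd * dbh**2 * height) ** b


def agb_without_height(
    dbh: float, wd: float, env_stress: float,
    coeffs: Sequence[float] = WITHOUT_HEIGHT_COEFFS,
) -> float:
    """AGB (kg) from DBH and wood density via the E-dependent model."""
    if dbh <= 0 or wd <= 0:
        raise ValueError("dbh and wood density must be positive")
    if env_stress is None:
        raise ValueError("env_stress (E) is required for the height-free model")
    c0, c1, c2, c3, c4 = coeffs
    ln_d = math.log(dbh)
    return math.exp(c0 + c1 * env_stress + c2 * math.log(wd) + c3 * ln_d + c4 * ln_d**2)


def reference_height(dbh: float, env_stress: float,
                     coeffs: Sequence[float] = E_HD_COEFFS) -> float:
    """Height (m) implied by the reference E-dependent H–D relation."""
    h0, h1, h2 = coeffs
    ln_d = math.log(dbh)
    return math.exp(h0 - env_stress + h1 * ln_d + h2 * ln_d**2)


# ---------------------------------------------------------------------------
# Height–diameter models

def _power(d: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * d**b


def _michaelis_menten(d: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * d / (b + d)


def _weibull(d: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * (1.0 - np.exp(-b * d**c))


_HD_FUNCS: dict[str, Callable] = {
    "power": _power,
    "michaelis_menten": _michaelis_menten,
    "weibull": _weibull,
}


@dataclass
class HDModel:
    """A fitted site-level height–diameter allometry.

    ``residual_sd`` is the log-scale residual standard deviation; with
    ``log_correction`` the half-variance factor exp(sd^2/2) is applied at
    prediction time for the log-fitted power form (Baskerville correction).
    """

    site_id: str
    form: str
    coefficients: tuple[float, ...]
    residual_sd: float
    n_obs: int = 0
    log_correction: bool = True

    def predict(self, dbh: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(dbh, dtype=float)
        if np.any(d <= 0):
            raise ValueError("dbh must be positive")
        h = _HD_FUNCS[self.form](d, *self.coefficients)
        if self.form == "power" and self.log_correction:
            h = h * math.exp(self.residual_sd**2 / 2.0)
        return float(h) if np.isscalar(dbh) else h

    def validate(self, d_range: tuple[float, float] = (10.0, 300.0)) -> None:
        grid = np.linspace(*d_range, 200)
        h = _HD_FUNCS[self.form](grid, *self.coefficients)
        if np.any(h <= 0):
            raise ValueError(f"H–D model for {self.site_id} predicts non-positive heights")
        if np.any(np.diff(h) < -1e-9):
            raise ValueError(f"H–D model for {self.site_id} is not monotone in D")


MIN_HD_OBS = 20


def fit_hd_model(
    trees: Iterable[TreeRecord],
    form: str = "power",
    site_id: str | None = None,
    log_correction: bool = True,
) -> HDModel:
    """Fit a site H–D allometry on stems with measured heights.

    ``form="auto"`` tries all three forms and keeps the one with the lowest
    log-scale residual sd. Requires at least 20 height observations.
    """
    obs = [(t.dbh, t.height) for t in trees if t.height is not None and t.height > 0]
    if len(obs) < MIN_HD_OBS:
        raise ValueError(
            f"need >= {MIN_HD_OBS} stems with measured height, got {len(obs)}"
        )
    d = np.array([o[0] for o in obs])
    h = np.array([o[1] for o in obs])
    sid = site_id or "unknown"

    if form == "auto":
        fits = []
        for f in HD_FORMS:
            try:
                fits.append(fit_hd_model(obs_records(d, h, sid), f, sid, log_correction))
            except RuntimeError:
                continue
        if not fits:
            raise RuntimeError("no H–D form converged")
        return min(fits, key=lambda m: m.residual_sd)

    if form == "power":
        # log-log OLS: exact linear solution, residual sd on the log scale
        X = np.column_stack([np.ones_like(d), np.log(d)])
        coef, *_ = np.linalg.lstsq(X, np.log(h), rcond=None)
        a, b = math.exp(coef[0]), coef[1]
        resid = np.log(h) - X @ coef
        sd = float(np.std(resid, ddof=2))
        model = HDModel(sid, "power", (a, b), sd, len(obs), log_correction)
    elif form in ("michaelis_menten", "weibull"):
        func = _HD_FUNCS[form]
        p0 = (45.0, 30.0) if form == "michaelis_menten" else (45.0, 0.05, 0.9)
        try:
            popt, _ = curve_fit(func, d, h, p0=p0, maxfev=20000)
        except RuntimeError as e:
            raise RuntimeError(f"H–D fit did not converge for form {form!r}") from e
        pred = np.maximum(func(d, *popt), 1e-9)
        sd = float(np.std(np.log(h) - np.log(pred), ddof=len(popt)))
        model = HDModel(sid, form, tuple(popt), sd, len(obs), log_correction=False)
    else:
        raise ValueError(f"unknown H–D form {form!r}; options: {HD_FORMS + ('auto',)}")

    model.validate()
    return model


def obs_records(d: np.ndarray, h: np.ndarray, site_id: str) -> list[TreeRecord]:
    """Wrap raw (dbh, height) arrays as minimal records (fitting helper)."""
    return [
        TreeRecord(site_id=site_id, plot_id="", stem_id=str(i), dbh=float(di),
                   height=float(hi))
        for i, (di, hi) in enumerate(zip(d, h))
    ]


def predict_height(model: HDModel, dbh: float | np.ndarray) -> float | np.ndarray:
    """Height (m) predicted by a fitted H–D model."""
    return model.predict(dbh)


# ---------------------------------------------------------------------------
# Pipeline: fill stem AGB over whole plots

def compute_agb(
    plots: Sequence[Plot],
    config: AllometryConfig | None = None,
    hd_models: dict[str, HDModel] | None = None,
) -> list[Plot]:
    """Return plots with every stem's ``agb`` filled (kg).

    In ``with_height`` mode, a stem's own height is used when present,
    otherwise the site's H–D model (``hd_models[site_id]``) predicts it.
    In ``without_height`` mode the E-dependent diameter-only model is used.
    Wood density must already be assigned.
    """
    cfg = config or AllometryConfig()
    out: list[Plot] = []
    for p in plots:
        trees = []
        for t in p.trees:
            if t.wood_density is None:
                raise ValueError(f"stem {t.stem_id} has no wood density assigned")
            if cfg.mode == "with_height":
                h = t.height
                if h is None:
                    if not hd_models or p.site_id not in hd_models:
                        raise ValueError(
                            f"stem {t.stem_id} lacks height and no H–D model for "
                            f"site {p.site_id}"
                        )
                    h = float(hd_models[p.site_id].predict(t.dbh))
                agb = agb_with_height(t.dbh, h, t.wood_density, cfg.with_height_coeffs)
                trees.append(TreeRecord(**{**t.__dict__, "height": h, "agb": agb}))
            else:
                agb = agb_without_height(
                    t.dbh, t.wood_density, cfg.env_stress, cfg.without_height_coeffs
                )
                trees.append(TreeRecord(**{**t.__dict__, "agb": agb}))
        out.append(Plot(plot_id=p.plot_id, site_id=p.site_id, trees=trees, area=p.area))
    return out
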