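"""Predicting whole-plot AGB from the N largest trees.

Per plot, AGB_topN is the summed biomass of the N largest stems and AGB_TOT
the plot total (kg/ha; plots are 1 ha). Across plots the relation is fitted
as a power regression without intercept,

    AGB_TOT = alpha * AGB_topN ** beta                       (per-N model)

by nonlinear least squares on the natural scale (log-log OLS supplies start
values), so the residual standard error is interpretable in kg/ha. A generic
model then captures how the coefficients move with N:

    alpha(N) = a * N ** b                 (power, no intercept)
    beta(N)  = k1 * (1 - exp(-k2 * N ** k3))   (3-parameter Weibull growth)

valid for N in [5, 100]. Site-wise leave-one-out cross-validation refits the
per-N model without one site and scores its plots (Pearson r, mean absolute
relative bias).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .accumulation import cumulative_curve
from .stand_data import Plot

VALID_RANGE = (5, 100)


def plot_pairs(plots: Sequence[Plot], n: int) -> tuple[np.ndarray, np.ndarray]:
    """(AGB_topN, AGB_TOT) arrays in kg/ha, one entry per plot."""
    top, tot = [], []
    for p in plots:
        c = cumulative_curve(p)
        top.append(c.at(n)["topn_agb"] / p.area)
        tot.append(c.agb_total / p.area)
    return np.array(top), np.array(tot)


@dataclass
class PowerModel:
    """Fitted AGB_TOT = alpha * AGB_topN^beta for one value of N."""

    n: int
    alpha: float
    beta: float
    r2: float
    rse: float            # residual standard error, kg/ha
    rser: float           # rse / mean(AGB_TOT)
    n_plots: int
    alpha_se: float = float("nan")
    beta_se: float = float("nan")
    input_hash: str = ""

    def predict(self, topn_agb: float | np.ndarray) -> float | np.ndarray:
        return self.alpha * np.asarray(topn_agb, dtype=float) ** self.beta

    def to_dict(self) -> dict:
        return {
            "n": self.n, "alpha": self.alpha, "beta": self.beta, "r2": self.r2,
            "rse": self.rse, "rser": self.rser, "n_plots": self.n_plots,
            "alpha_se": self.alpha_se, "beta_se": self.beta_se,
            "input_hash": self.input_hash,
        }


class FitError(RuntimeError):
    """Nonlinear fit failure; carries the log-log fallback coefficients."""

    def __init__(self, msg: str, fallback: tuple[float, float]):
        super().__init__(msg)
        self.fallback = fallback


def _pairs_hash(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.round(x, 6).tobytes())
    h.update(np.round(y, 6).tobytes())
    return h.hexdigest()[:12]


def fit_power_model(topn_agb: np.ndarray, agb_tot: np.ndarray, n: int) -> PowerModel:
    """Fit the per-N power model on (AGB_topN, AGB_TOT) pairs.

    Needs at least 5 plots with strictly positive values. R^2 is computed
    about the observed mean (1 - SSres/SStot), on the natural scale.
    """
    x = np.asarray(topn_agb, dtype=float)
    y = np.asarray(agb_tot, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 plots, got {len(x)}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("AGB values must be strictly positive")

    # log-log OLS start values (exact when the relation is noise-free)
    X = np.column_stack([np.ones_like(x), np.log(x)])
    coef, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    a0, b0 = float(np.exp(coef[0])), float(coef[1])

    log_resid = np.log(y) - X @ coef
    if np.max(np.abs(log_resid)) < 1e-12:
        # exact power relation: the linear solution is the NLS optimum
        alpha, beta = a0, b0
        cov = np.zeros((2, 2))
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                (alpha, beta), cov = curve_fit(
                    lambda xx, a, b: a * xx**b, x, y, p0=(a0, b0), maxfev=20000
                )
        except RuntimeError as e:
            raise FitError(f"power fit (N={n}) did not converge", (a0, b0)) from e

    resid = y - alpha * x**beta
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    rse = float(np.sqrt(ss_res / dof))
    se = np.sqrt(np.diag(cov)) if np.all(np.isfinite(cov)) else (np.nan, np.nan)
    return PowerModel(
        n=n, alpha=float(alpha), beta=float(beta), r2=r2, rse=rse,
        rser=rse / float(y.mean()), n_plots=len(x),
        alpha_se=float(se[0]), beta_se=float(se[1]),
        input_hash=_pairs_hash(x, y),
    )


def fit_power_models(plots: Sequence[Plot], n_values: Sequence[int]) -> list[PowerModel]:
    """Per-N power models over a grid of N, from whole plots."""
    return [fit_power_model(*plot_pairs(plots, n), n) for n in n_values]


def _weibull_growth(i: np.ndarray, k1: float, k2: float, k3: float) -> np.ndarray:
    return k1 * (1.0 - np.exp(-k2 * i**k3))


@dataclass
class GenericModel:
    """Meta-model giving alpha(N), beta(N) of the per-N power models."""

    alpha_coeffs: tuple[float, float]              # (a, b) of a*N^b
    beta_coeffs: tuple[float, float, float]        # (k1, k2, k3) Weibull
    valid_range: tuple[int, int] = VALID_RANGE
    alpha_r2: float = float("nan")
    beta_r2: float = float("nan")
    input_hash: str = ""

    def _check_n(self, n: int) -> None:
        lo, hi = self.valid_range
        if not lo <= n <= hi:
            raise ValueError(
                f"N={n} outside the generic model's validity range [{lo}, {hi}] "
                f"largest trees"
            )

    def alpha(self, n: int) -> float:
        self._check_n(n)
        a, b = self.alpha_coeffs
        return a * n**b

    def beta(self, n: int) -> float:
        self._check_n(n)
        return float(_weibull_growth(np.asarray(float(n)), *self.beta_coeffs))

    def to_dict(self) -> dict:
        return {
            "alpha_coeffs": list(self.alpha_coeffs),
            "beta_coeffs": list(self.beta_coeffs),
            "valid_range": list(self.valid_range),
            "alpha_r2": self.alpha_r2, "beta_r2": self.beta_r2,
            "input_hash": self.input_hash,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GenericModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alpha_coeffs=tuple(d["alpha_coeffs"]),
            beta_coeffs=tuple(d["beta_coeffs"]),
            valid_range=tuple(d["valid_range"]),
            alpha_r2=d.get("alpha_r2", float("nan")),
            beta_r2=d.get("beta_r2", float("nan")),
            input_hash=d.get("input_hash", ""),
        )


def fit_generic_model(models: Sequence[PowerModel]) -> GenericModel:
    """Fit alpha(N) and beta(N) meta-models over per-N fits spanning [5, 100]."""
    ns = np.array([m.n for m in models], dtype=float)
    if len(np.unique(ns)) < 10:
        raise ValueError("need >= 10 distinct N values spanning the validity range")
    alphas = np.array([m.alpha for m in models])
    betas = np.array([m.beta for m in models])

    # alpha(N) = a*N^b: log-log start, NLS refine
    Xl = np.column_stack([np.ones_like(ns), np.log(ns)])
    c, *_ = np.linalg.lstsq(Xl, np.log(alphas), rcond=None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        (a, b), _ = curve_fit(
            lambda i, aa, bb: aa * i**bb, ns, alphas,
            p0=(float(np.exp(c[0])), float(c[1])), maxfev=20000,
        )
    alpha_pred = a * ns**b
    alpha_r2 = _r2(alphas, alpha_pred)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k, _ = curve_fit(
                _weibull_growth, ns, betas, p0=(1.0, 0.1, 1.0),
                bounds=([0, 0, -5], [10, 50, 5]), maxfev=50000,
            )
    except RuntimeError as e:
        raise RuntimeError(
            "Weibull fit of beta(N) did not converge; consider overriding start "
            "values (k1, k2, k3)"
        ) from e
    beta_r2 = _r2(betas, _weibull_growth(ns, *k))

    return GenericModel(
        alpha_coeffs=(float(a), float(b)),
        beta_coeffs=tuple(float(v) for v in k),
        alpha_r2=alpha_r2, beta_r2=beta_r2,
        input_hash=_pairs_hash(ns, betas),
    )


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def predict_agb_tot(
    topn_agb: float | np.ndarray, n: int, model: GenericModel | PowerModel
) -> float | np.ndarray:
    """AGB_TOT (kg/ha) predicted from AGB_topN (kg/ha)."""
    x = np.asarray(topn_agb, dtype=float)
    if np.any(x <= 0):
        raise ValueError("topn_agb must be positive")
    if isinstance(model, GenericModel):
        out = model.alpha(n) * x ** model.beta(n)
    else:
        out = model.predict(x)
    return float(out) if np.isscalar(topn_agb) else out


def loocv_by_site(sites: dict[str, list[Plot]], n: int = 20) -> pd.DataFrame:
    """Site-wise leave-one-out cross-validation of the per-N power model.

    Each site in turn is held out; the model is fitted on the remaining
    sites' plots and scored on the held-out plots. Returns one row per site
    (pearson_r, bias = mean |pred-obs|/obs, signed_bias) plus an ``average``
    row. Sites with fewer than 2 plots are excluded with a warning.
    """
    usable = {s: ps for s, ps in sites.items() if len(ps) >= 2}
    dropped = set(sites) - set(usable)
    if dropped:
        warnings.warn(f"excluding sites with < 2 plots: {sorted(dropped)}")
    if len(usable) < 3:
        raise ValueError(f"need >= 3 sites with >= 2 plots, got {len(usable)}")

    pairs = {s: plot_pairs(ps, n) for s, ps in usable.items()}
    rows = []
    for held in usable:
        x_train = np.concatenate([pairs[s][0] for s in usable if s != held])
        y_train = np.concatenate([pairs[s][1] for s in usable if s != held])
        model = fit_power_model(x_train, y_train, n)
        x_test, y_test = pairs[held]
        pred = model.predict(x_test)
        if np.std(pred) == 0 or np.std(y_test) == 0:
            r = 1.0 if np.allclose(pred, y_test) else float("nan")
        else:
            r = float(pearsonr(pred, y_test)[0])
        rel = (pred - y_test) / y_test
        rows.append(
            {
                "site": held,
                "n_plots": len(y_test),
                "pearson_r": r,
                "bias": float(np.mean(np.abs(rel))),
                "signed_bias": float(np.mean(rel)),
            }
        )
    df = pd.DataFrame(rows)
    avg = {
        "site": "average",
        "n_plots": int(df["n_plots"].sum()),
        "pearson_r": float(df["pearson_r"].mean()),
        "bias": float(df["bias"].mean()),
        "signed_bias": float(df["signed_bias"].mean()),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def fit_richness_model(sites: dict[str, list[Plot]], n: int = 20) -> pd.DataFrame:
    """OLS species_TOT = a + b * richness_topN, per site and pooled.

    A site whose predictor has zero variance is flagged ``degenerate`` (its
    slope is undefined; the intercept-only fit is reported).
    """
    def fit_one(label: str, plots: list[Plot]) -> dict:
        curves = [cumulative_curve(p) for p in plots]
        x = np.array([c.at(n)["richness"] for c in curves], dtype=float)
        y = np.array([c.species_total for c in curves], dtype=float)
        if len(x) < 5:
            raise ValueError(f"{label}: need >= 5 plots, got {len(x)}")
        if np.std(x) == 0:
            return {
                "site": label, "slope": float("nan"), "intercept": float(y.mean()),
                "r2": float("nan"), "n_plots": len(x), "degenerate": True,
            }
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return {
            "site": label, "slope": float(res.params[1]),
            "intercept": float(res.params[0]), "r2": float(res.rsquared),
            "n_plots": len(x), "degenerate": False,
        }

    rows = [fit_one(s, ps) for s, ps in sites.items()]
    rows.append(fit_one("pooled", [p for ps in sites.values() for p in ps]))
    return pd.DataFrame(rows)
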