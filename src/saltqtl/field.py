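"""Field-side computations: soil-salinity calibration, spatial adjustment of
plot traits, and allele-grouped effect reporting.

Soil salinity at a trial is characterized by bulk apparent electrical
conductivity (EM38 EC_a, mS/m) calibrated against the conductivity of a 1:5
soil:water extract (EC_1:5, dS/m) by ordinary least squares; soil-solution
salinity (mM) follows EC_1:5 x 5000 / gravimetric water content.  The water
content enters on the percentage scale (e.g. 17 for 17%) by default — the
only scale consistent with field magnitudes of a few hundred mM — with the
g/g fraction scale available as an option.

Plot traits are summarized per line either as raw replicate means or after a
two-way median-polish adjustment that removes additive row/range trends.
Allele effects at a QTL marker are the percentage difference between the
mean trait of lines carrying the beneficial allele and the mean of the other
lines; a site is concordant when the sign of that difference matches the
glasshouse expectation (lower leaf Na+ for exclusion alleles, higher leaf
K+ or yield for accumulation alleles), with strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationModel",
    "soil_solution_mM",
    "fit_em38_calibration",
    "predict_plot_ec",
    "Em38Calibrator",
    "median_polish",
    "spatial_adjust",
    "allele_effect_report",
    "concordance_summary",
    "DEFAULT_TRAIT_DIRECTIONS",
]

logger = logging.getLogger(__name__)

#: glasshouse-derived expectation for the beneficial allele at each trait
DEFAULT_TRAIT_DIRECTIONS = {
    "leaf_na": "decrease",
    "leaf_k": "increase",
    "yield_t_ha": "increase",
    "leaf_k_na": "increase",
}


def soil_solution_mM(ec_1_5: float, gwc: float, gwc_scale: str = "percent") -> float:
    """Soil-solution salinity (mM) from EC_1:5 (dS/m) and water content.

    ``gwc_scale='percent'`` expects e.g. 17 for 17% water content;
    ``'fraction'`` expects the g/g value (0.17).
    """
    if gwc_scale == "fraction":
        gwc = gwc * 100.0
    elif gwc_scale != "percent":
        raise ValueError("gwc_scale must be 'percent' or 'fraction'")
    if gwc <= 0:
        raise ValueError("water content must be positive")
    if ec_1_5 < 0:
        raise ValueError("EC_1:5 must be nonnegative")
    return ec_1_5 * 5000.0 / gwc


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line EC_1:5 ~ EM38 with its fit statistics."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_em38_calibration(em38, ec_1_5) -> CalibrationModel:
    """Least-squares calibration of EC_1:5 (dS/m) on EM38 EC_a (mS/m)."""
    x = np.asarray(em38, dtype=float)
    y = np.asarray(ec_1_5, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired soil samples")
    if np.ptp(x) == 0:
        raise ValueError("EM38 values have zero variance; calibration undefined")
    fit = linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue), n=int(x.size),
    )


def predict_plot_ec(model: CalibrationModel, em38_value):
    """Predicted plot EC_1:5 from an EM38 reading, floored at zero."""
    pred = model.slope * np.asarray(em38_value, dtype=float) + model.intercept
    if np.any(pred < 0):
        logger.warning("negative EC_1:5 prediction floored at 0")
    pred = np.maximum(pred, 0.0)
    return float(pred) if pred.ndim == 0 else pred


class Em38Calibrator(BaseEstimator, RegressorMixin):
    """Estimator form of the EM38 -> EC_1:5 calibration line."""

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        model = fit_em38_calibration(x, y)
        self.slope_ = model.slope
        self.intercept_ = model.intercept
        self.r_squared_ = model.r_squared
        self.p_value_ = model.p_value
        self.n_ = model.n
        return self

    def predict(self, X):
        if not hasattr(self, "slope_"):
            raise AttributeError("Em38Calibrator is not fitted")
        model = CalibrationModel(self.slope_, self.intercept_, self.r_squared_,
                                 self.p_value_, self.n_)
        return np.atleast_1d(predict_plot_ec(model, np.asarray(X, float).reshape(-1)))


# ---------------------------------------------------------------------------
# Spatial adjustment
# ---------------------------------------------------------------------------

def median_polish(mat: np.ndarray, max_iter: int = 50, tol: float = 1e-9
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way median polish of a (possibly incomplete) matrix.

    Returns ``(overall, row_effects, col_effects, residuals)``; NaN cells are
    ignored and preserved in the residuals.
    """
    resid = np.array(mat, dtype=float)
    nr, nc = resid.shape
    row = np.zeros(nr)
    col = np.zeros(nc)
    overall = 0.0
    for _ in range(max_iter):
        delta = 0.0
        with np.errstate(all="ignore"):
            rmed = np.nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row += rmed
        cmed = np.nanmedian(row) if np.isfinite(np.nanmedian(row)) else 0.0
        row -= cmed
        overall += cmed
        delta += np.abs(rmed).sum() + abs(cmed)
        with np.errstate(all="ignore"):
            cmed_cols = np.nanmedian(resid, axis=0)
        cmed_cols = np.where(np.isnan(cmed_cols), 0.0, cmed_cols)
        resid -= cmed_cols[None, :]
        col += cmed_cols
        rmed2 = np.nanmedian(col) if np.isfinite(np.nanmedian(col)) else 0.0
        col -= rmed2
        overall += rmed2
        delta += np.abs(cmed_cols).sum() + abs(rmed2)
        if delta < tol:
            break
    return float(overall), row, col, resid


def spatial_adjust(trial: pd.DataFrame, trait: str, method: str = "median_polish"
                   ) -> pd.DataFrame:
    """Per-line trait values with the row/range field trend removed.

    ``method='median_polish'`` polishes the row x range plot matrix within
    each (site, year, salt_level) trial and summarizes each line as the mean
    of ``overall + residual`` over its plots; ``'raw'`` uses plain replicate
    means.  Returns a frame (site, year, salt_level, line, value, n_plots).
    """
    if method not in ("median_polish", "raw"):
        raise ValueError("method must be 'median_polish' or 'raw'")
    required = {"site", "year", "salt_level", "row", "range", "line", trait}
    if not required <= set(trial.columns):
        raise ValueError(f"trial table missing columns: {sorted(required - set(trial.columns))}")
    out = []
    for (site, year, salt), sub in trial.groupby(["site", "year", "salt_level"]):
        if sub["row"].nunique() < 2 or sub["range"].nunique() < 2:
            raise ValueError("need at least 2 rows and 2 ranges for adjustment")
        if method == "raw":
            adj = sub.set_index("line")[trait]
        else:
            rows = np.sort(sub["row"].unique())
            cols = np.sort(sub["range"].unique())
            ri = {r: i for i, r in enumerate(rows)}
            ci = {c: i for i, c in enumerate(cols)}
            mat = np.full((rows.size, cols.size), np.nan)
            for _, rec in sub.iterrows():
                mat[ri[rec["row"]], ci[rec["range"]]] = rec[trait]
            overall, _, _, resid = median_polish(mat)
            adj = pd.Series(
                [overall + resid[ri[r], ci[c]] for r, c in zip(sub["row"], sub["range"])],
                index=sub["line"].to_numpy(),
            )
        for line, grp in adj.groupby(level=0):
            vals = grp.dropna()
            if vals.empty:
                continue
            out.append({"site": site, "year": year, "salt_level": salt,
                        "line": line, "value": float(vals.mean()),
                        "n_plots": int(len(vals))})
    return pd.DataFrame(out, columns=["site", "year", "salt_level", "line",
                                      "value", "n_plots"])


# ---------------------------------------------------------------------------
# Allele effects
# ---------------------------------------------------------------------------

def allele_effect_report(
    trial: pd.DataFrame,
    geno: pd.DataFrame,
    marker: str,
    qtl_name: str,
    beneficial_allele: str,
    traits: tuple[str, ...] = ("leaf_na", "leaf_k", "yield_t_ha"),
    directions: dict[str, str] | None = None,
    adjust: str = "raw",
) -> pd.DataFrame:
    """Allele-grouped trait means and percentage differences per trial.

    For each (site, year, salt_level, trait), lines are grouped by their call
    at the QTL marker (lines without a call are excluded);
    ``pct_difference = 100 * (mean_beneficial - mean_other) / mean_other``.
    A trial where either allele group is empty is skipped with a warning.
    """
    if beneficial_allele not in ("E", "K"):
        raise ValueError("beneficial allele must be 'E' or 'K'")
    if marker not in geno.columns:
        raise ValueError(f"marker {marker!r} not in the genotype matrix")
    directions = {**DEFAULT_TRAIT_DIRECTIONS, **(directions or {})}
    calls = geno[marker].dropna()
    other_allele = "K" if beneficial_allele == "E" else "E"
    rows = []
    for trait in traits:
        per_line = spatial_adjust(
            trial, trait, method="median_polish" if adjust == "spatial" else "raw"
        )
        for (site, year, salt), sub in per_line.groupby(["site", "year", "salt_level"]):
            sub = sub[sub["line"].isin(calls.index)]
            grp = {
                allele: sub.loc[
                    sub["line"].map(calls) == allele, "value"
                ]
                for allele in (beneficial_allele, other_allele)
            }
            if any(g.empty for g in grp.values()):
                logger.warning(
                    "skipping %s %s/%s/%s: an allele group is empty",
                    trait, site, year, salt,
                )
                continue
            mean_ben = float(grp[beneficial_allele].mean())
            mean_other = float(grp[other_allele].mean())
            pct = 100.0 * (mean_ben - mean_other) / mean_other
            direction = directions.get(trait, "increase")
            concordant = pct < 0 if direction == "decrease" else pct > 0
            rows.append(
                {
                    "qtl": qtl_name, "marker": marker,
                    "beneficial_allele": beneficial_allele,
                    "site": site, "year": year, "salt_level": salt,
                    "trait": trait, "mean_beneficial": mean_ben,
                    "mean_other": mean_other, "pct_difference": pct,
                    "concordant": bool(concordant),
                }
            )
    cols = ["qtl", "marker", "beneficial_allele", "site", "year", "salt_level",
            "trait", "mean_beneficial", "mean_other", "pct_difference",
            "concordant"]
    return pd.DataFrame(rows, columns=cols)


def concordance_summary(reports: pd.DataFrame) -> pd.DataFrame:
    """Per QTL x trait: number of site-year-salinity trials whose allele
    effect has the expected sign, over the number evaluated."""
    if reports.empty:
        raise ValueError("no allele-effect rows to summarize")
    out = (
        reports.groupby(["qtl", "trait"])
        .agg(n_concordant=("concordant", "sum"), n_total=("concordant", "size"))
        .reset_index()
    )
    out["n_concordant"] = out["n_concordant"].astype(int)
    return out
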