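"""Image-based growth phenotyping: projected shoot area, smoothing splines,
relative growth rates and the shoot ion-independent tolerance index.

Projected shoot area (PSA, kpixels) is the summed pixel count of one top and
two side camera views.  For each plant a cubic smoothing spline with a target
of 4 effective degrees of freedom is fitted to ln(PSA) against day; relative
growth rate (RGR, d^-1) is read off the smoothed log curve, by default as
unit-day differences.  Fitting on the log scale makes the exponential-growth
case exact: a noiseless exponential gives back its generating rate because a
straight line is the penalty-free fixed point of the smoother.

The shoot ion-independent tolerance index of a line is the ratio of the
interval RGR (days 1-5 after salt application by default) of the salt-treated
plant to that of its paired control plant, averaged over replicate pairs.
Pairs whose control RGR is non-positive are excluded: the ratio is
meaningless for a shrinking control plant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SplineFit",
    "psa_from_views",
    "fit_growth_spline",
    "rgr_daily",
    "rgr_interval",
    "tolerance_index",
    "ion_ratio_traits",
    "GrowthPhenotyper",
    "tolerance_table",
    "ion_trait_table",
]

logger = logging.getLogger(__name__)


def psa_from_views(top_px: float, side1_px: float, side2_px: float) -> float:
    """Projected shoot area in kpixels from one top and two side view counts."""
    views = (top_px, side1_px, side2_px)
    if any(v < 0 for v in views):
        raise ValueError("pixel counts must be nonnegative")
    total = sum(views)
    if total == 0:
        raise ValueError("all camera views empty: segmentation produced no pixels")
    return total / 1000.0


# ---------------------------------------------------------------------------
# Smoothing spline with a fixed effective df
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _lambda_for_edf(days_key: tuple[float, ...], target_df: float) -> tuple[float, float]:
    """Smoothing parameter whose smoother trace matches ``target_df``.

    The effective degrees of freedom of a cubic smoothing spline is the trace
    of its hat matrix, which depends only on the abscissae and the smoothing
    parameter; it decreases monotonically from n (interpolation) to 2 (a
    straight line).  Solved by bisection on log10(lambda); cached per day
    grid since all plants of an experiment share one imaging schedule.
    """
    x = np.asarray(days_key, dtype=float)
    n = x.size

    def edf(lam: float) -> float:
        tr = 0.0
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            tr += float(make_smoothing_spline(x, e, lam=lam)(x[j]))
        return tr

    lo, hi = -10.0, 10.0
    # widen the bracket if needed
    while edf(10.0**lo) < target_df and lo > -20:
        lo -= 2
    while edf(10.0**hi) > target_df and hi < 20:
        hi += 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if edf(10.0**mid) > target_df:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** (0.5 * (lo + hi))
    return lam, edf(lam)


@dataclass
class SplineFit:
    """Fitted smooth of ln(PSA) against day for one plant."""

    plant_id: str
    days: np.ndarray
    edf: float
    residual_sd: float
    _spline: object = field(repr=False)

    @property
    def day_range(self) -> tuple[float, float]:
        return float(self.days.min()), float(self.days.max())

    def predict(self, day):
        """Smoothed ln(PSA) at the given day(s) (within the fitted range)."""
        d = np.asarray(day, dtype=float)
        lo, hi = self.day_range
        if np.any(d < lo) or np.any(d > hi):
            raise ValueError(f"day outside fitted range [{lo}, {hi}]")
        out = self._spline(d)
        return float(out) if out.ndim == 0 else out

    def derivative(self, day):
        """Analytic first derivative of the smoothed ln(PSA) curve."""
        d = np.asarray(day, dtype=float)
        lo, hi = self.day_range
        if np.any(d < lo) or np.any(d > hi):
            raise ValueError(f"day outside fitted range [{lo}, {hi}]")
        out = self._spline.derivative()(d)
        return float(out) if out.ndim == 0 else out


def fit_growth_spline(
    days, psa_kpixels, plant_id: str = "", target_df: float = 4.0
) -> SplineFit:
    """Fit a cubic smoothing spline to ln(PSA) at a fixed effective df.

    Requires at least five distinct days and strictly positive PSA values.
    """
    days = np.asarray(days, dtype=float)
    psa = np.asarray(psa_kpixels, dtype=float)
    if days.size != psa.size:
        raise ValueError("days and PSA must have equal length")
    order = np.argsort(days)
    days, psa = days[order], psa[order]
    if np.unique(days).size < 5:
        raise ValueError("need at least 5 distinct imaging days")
    if np.unique(days).size != days.size:
        raise ValueError("duplicate day for one plant")
    if np.any(psa <= 0):
        raise ValueError("PSA must be positive")
    n = days.size
    target = min(target_df, n - 1.0)
    lam, edf = _lambda_for_edf(tuple(days), target)
    y = np.log(psa)
    spline = make_smoothing_spline(days, y, lam=lam)
    resid = y - spline(days)
    return SplineFit(
        plant_id=plant_id,
        days=days,
        edf=edf,
        residual_sd=float(np.std(resid)),
        _spline=spline,
    )


def rgr_daily(fit: SplineFit, day: float) -> float:
    """Daily RGR at ``day``: smoothed ln(PSA)(day+1) - smoothed ln(PSA)(day)."""
    lo, hi = fit.day_range
    if not lo <= day <= hi - 1:
        raise ValueError(f"day {day} outside fitted range for a unit-day difference")
    return float(fit.predict(day + 1) - fit.predict(day))


def rgr_interval(fit: SplineFit, d1: float = 1, d2: float = 5) -> float:
    """Mean RGR over [d1, d2]: the smoothed ln(PSA) slope over the interval."""
    if d2 <= d1:
        raise ValueError("interval end must exceed its start")
    return float((fit.predict(d2) - fit.predict(d1)) / (d2 - d1))


def tolerance_index(salt_rgr: float, control_rgr: float) -> float:
    """Shoot ion-independent tolerance: salt RGR / control RGR for one pair."""
    if control_rgr <= 0:
        raise ValueError("tolerance index undefined for non-positive control RGR")
    return salt_rgr / control_rgr


def ion_ratio_traits(na: float, k: float) -> tuple[float, float]:
    """Leaf ion ratios (Na:K, K:Na) on a dry-weight basis; undefined -> nan."""
    if na < 0 or k < 0:
        raise ValueError("ion concentrations must be nonnegative")
    na_k = na / k if k > 0 else math.nan
    k_na = k / na if na > 0 else math.nan
    return na_k, k_na


# ---------------------------------------------------------------------------
# Line-level trait derivation
# ---------------------------------------------------------------------------

class GrowthPhenotyper(BaseEstimator, TransformerMixin):
    """Derive line-level growth traits from a plant-level shoot-area table.

    Parameters
    ----------
    target_df : effective degrees of freedom of the per-plant smoothing
        spline on ln(PSA).
    interval : (d1, d2) days after salt application over which the interval
        RGR is computed.
    ratio_method : "paired" averages the per-replicate salt/control RGR
        ratios; "mean_ratio" takes the ratio of replicate-mean RGRs.

    Fitted attributes
    -----------------
    plant_fits_ : dict plant_id -> SplineFit
    line_traits_ : long frame (line, trait, value, n_replicates) with traits
        ``G_1_5`` (tolerance index) and ``CRGR`` (control interval RGR).
    excluded_pairs_ : list of (line, replicate, reason) for dropped pairs.
    """

    def __init__(self, target_df: float = 4.0, interval: tuple[float, float] = (1, 5),
                 ratio_method: str = "paired"):
        self.target_df = target_df
        self.interval = interval
        self.ratio_method = ratio_method

    def fit(self, X: pd.DataFrame, y=None):
        if self.ratio_method not in ("paired", "mean_ratio"):
            raise ValueError("ratio_method must be 'paired' or 'mean_ratio'")
        d1, d2 = self.interval
        required = {"plant_id", "line", "treatment", "replicate", "day", "psa_kpixels"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"growth table missing columns: {sorted(missing)}")
        if X.duplicated(["plant_id", "day"]).any():
            raise ValueError("duplicate (plant_id, day) records")

        self.plant_fits_ = {}
        plant_rgr = {}
        meta = {}
        for pid, sub in X.groupby("plant_id", sort=False):
            fit = fit_growth_spline(
                sub["day"], sub["psa_kpixels"], plant_id=str(pid),
                target_df=self.target_df,
            )
            self.plant_fits_[pid] = fit
            plant_rgr[pid] = rgr_interval(fit, d1, d2)
            first = sub.iloc[0]
            meta[pid] = (first["line"], first["treatment"], first["replicate"])

        self.excluded_pairs_ = []
        rows = []
        by_line: dict[str, dict] = {}
        for pid, (line, treatment, rep) in meta.items():
            by_line.setdefault(line, {}).setdefault(rep, {})[treatment] = plant_rgr[pid]
        for line, reps in by_line.items():
            ratios, controls = [], []
            for rep, pair in sorted(reps.items()):
                if "control" in pair:
                    controls.append(pair["control"])
                if "control" not in pair or "salt" not in pair:
                    self.excluded_pairs_.append((line, rep, "unpaired plant"))
                    continue
                if pair["control"] <= 0:
                    self.excluded_pairs_.append((line, rep, "non-positive control RGR"))
                    continue
                ratios.append((pair["salt"], pair["control"]))
            if ratios:
                if self.ratio_method == "paired":
                    value = float(np.mean([s / c for s, c in ratios]))
                else:
                    value = float(
                        np.mean([s for s, _ in ratios]) / np.mean([c for _, c in ratios])
                    )
                rows.append({"line": line, "trait": "G_1_5", "value": value,
                             "n_replicates": len(ratios)})
            if controls:
                rows.append({"line": line, "trait": "CRGR",
                             "value": float(np.mean(controls)),
                             "n_replicates": len(controls)})
        if self.excluded_pairs_:
            logger.warning("excluded %d unpaired/invalid replicate pairs",
                           len(self.excluded_pairs_))
        self.line_traits_ = pd.DataFrame(
            rows, columns=["line", "trait", "value", "n_replicates"]
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "line_traits_"):
            raise AttributeError("GrowthPhenotyper is not fitted")
        return self.line_traits_.copy()


def tolerance_table(growth: pd.DataFrame, target_df: float = 4.0,
                    interval: tuple[float, float] = (1, 5),
                    ratio_method: str = "paired") -> pd.DataFrame:
    """Line-level G_1_5 / CRGR trait table (thin wrapper over GrowthPhenotyper)."""
    return GrowthPhenotyper(
        target_df=target_df, interval=interval, ratio_method=ratio_method
    ).fit(growth).transform(growth)


def ion_trait_table(ions: pd.DataFrame) -> pd.DataFrame:
    """Line-level ion traits from a (line, na, k) table (replicates averaged).

    Emits traits ``Na``, ``K`` (umol/g DW) and the ratios ``Na_K``/``K_Na``
    computed from the line means; undefined ratios are omitted.
    """
    required = {"line", "na", "k"}
    if not required <= set(ions.columns):
        raise ValueError(f"ion table must have columns {sorted(required)}")
    rows = []
    for line, sub in ions.groupby("line", sort=False):
        na, k = float(sub["na"].mean()), float(sub["k"].mean())
        n = len(sub)
        rows.append({"line": line, "trait": "Na", "value": na, "n_replicates": n})
        rows.append({"line": line, "trait": "K", "value": k, "n_replicates": n})
        na_k, k_na = ion_ratio_traits(na, k)
        if not math.isnan(na_k):
            rows.append({"line": line, "trait": "Na_K", "value": na_k, "n_replicates": n})
        if not math.isnan(k_na):
            rows.append({"line": line, "trait": "K_Na", "value": k_na, "n_replicates": n})
    return pd.DataFrame(rows, columns=["line", "trait", "value", "n_replicates"])
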