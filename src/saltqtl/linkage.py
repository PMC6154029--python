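"""Genetic-map curation and construction for doubled-haploid genotype matrices.

A DH population carries only the two parental alleles (coded ``E`` and ``K``
for the Excalibur and Kukri parents of the emulated cross), so every marker
is effectively a biallelic, fully homozygous locus.  This module provides the
standard curation filters applied before mapping (marker missingness,
segregation distortion, excess crossovers per line), recombination-fraction
estimation, conversion to centiMorgans with the Kosambi map function, and a
recombination-count (COUNT) criterion marker-ordering step in the style of
the RECORD algorithm.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "CurationReport",
    "kosambi_cm",
    "kosambi_r",
    "filter_missing_markers",
    "filter_distorted_markers",
    "filter_crossover_lines",
    "count_crossovers",
    "estimate_rf",
    "order_markers_record",
    "count_criterion",
    "build_map",
    "curate_genotypes",
]

#: cap applied to empirical recombination fractions before Kosambi conversion,
#: keeping map distances finite for (near-)unlinked marker pairs
RF_CAP = 0.4999


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Convert recombination fraction(s) to Kosambi map distance in cM.

    d (Morgans) = 1/4 * ln((1 + 2r) / (1 - 2r)); returned as cM.
    Valid for 0 <= r < 0.5; r >= 0.5 means the pair is unlinked.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(distance_cm):
    """Inverse Kosambi: map distance in cM -> recombination fraction.

    r = 1/2 * tanh(2 d), with d in Morgans.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Curation report
# ---------------------------------------------------------------------------

@dataclass
class CurationReport:
    """Record of markers/lines removed during curation and the thresholds used."""

    removed_markers: dict[str, str] = field(default_factory=dict)
    removed_lines: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "CurationReport") -> "CurationReport":
        out = CurationReport(
            removed_markers={**self.removed_markers, **other.removed_markers},
            removed_lines={**self.removed_lines, **other.removed_lines},
            thresholds={**self.thresholds, **other.thresholds},
        )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "removed_markers": self.removed_markers,
                    "removed_lines": self.removed_lines,
                    "thresholds": self.thresholds,
                },
                fh,
                indent=2,
            )


def _validate_geno(geno: pd.DataFrame) -> None:
    if geno.shape[0] < 2 or geno.shape[1] < 2:
        raise ValueError("genotype matrix needs at least 2 lines and 2 markers")
    if geno.index.has_duplicates or geno.columns.has_duplicates:
        raise ValueError("line and marker ids must be unique")


def _calls_float(geno: pd.DataFrame) -> np.ndarray:
    """Genotype calls as float matrix: E -> 1.0, K -> 0.0, missing -> nan."""
    arr = geno.to_numpy(dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "E"] = 1.0
    out[arr == "K"] = 0.0
    bad = ~(np.isin(arr, ("E", "K")) | pd.isna(arr))
    if bad.any():
        raise ValueError(f"unexpected genotype call(s): {set(arr[bad])}")
    return out


# ---------------------------------------------------------------------------
# Curation filters
# ---------------------------------------------------------------------------

def filter_missing_markers(
    geno: pd.DataFrame, max_missing: float = 0.20
) -> tuple[pd.DataFrame, CurationReport]:
    """Drop markers whose missing-call fraction strictly exceeds ``max_missing``."""
    _validate_geno(geno)
    frac = geno.isna().mean(axis=0)
    drop = frac.index[frac > max_missing]
    if len(drop) == geno.shape[1]:
        raise ValueError("all markers exceed the missingness threshold")
    report = CurationReport(
        removed_markers={
            m: f"missingness {frac[m]:.3f} > {max_missing}" for m in drop
        },
        thresholds={"max_missing": max_missing},
    )
    return geno.drop(columns=drop), report


def filter_distorted_markers(
    geno: pd.DataFrame,
    band: tuple[float, float] = (0.40, 0.60),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, CurationReport]:
    """Drop markers with significant segregation distortion.

    A marker is removed iff its E-allele frequency among non-missing calls
    falls outside ``band`` AND a two-sided exact binomial test against the
    Mendelian expectation of 0.5 is significant at ``alpha``.  Markers with no
    non-missing calls are removed unconditionally.
    """
    _validate_geno(geno)
    calls = _calls_float(geno)
    removed: dict[str, str] = {}
    for j, m in enumerate(geno.columns):
        col = calls[:, j]
        obs = ~np.isnan(col)
        n = int(obs.sum())
        if n == 0:
            removed[m] = "no data"
            continue
        n_e = int(col[obs].sum())
        freq = n_e / n
        if freq < band[0] or freq > band[1]:
            p = binomtest(n_e, n, 0.5).pvalue
            if p < alpha:
                removed[m] = f"distortion freq={freq:.3f} p={p:.3g}"
    if len(removed) == geno.shape[1]:
        raise ValueError("all markers removed by distortion filter")
    report = CurationReport(
        removed_markers=removed,
        thresholds={"band_low": band[0], "band_high": band[1], "alpha": alpha},
    )
    return geno.drop(columns=list(removed)), report


def _switch_counts(calls: np.ndarray) -> np.ndarray:
    """Per-row switch counts between consecutive non-missing calls."""
    n, m = calls.shape
    obs = ~np.isnan(calls)
    idx = np.where(obs, np.arange(m)[None, :], -1)
    np.maximum.accumulate(idx, axis=1, out=idx)
    prev = np.full_like(idx, -1)
    prev[:, 1:] = idx[:, :-1]
    valid = obs & (prev >= 0)
    prev_vals = calls[np.arange(n)[:, None], np.clip(prev, 0, None)]
    return (valid & (calls != prev_vals)).sum(axis=1)


def count_crossovers(geno: pd.DataFrame, gmap: pd.DataFrame) -> pd.Series:
    """Observed crossover count per line, summed over linkage groups.

    Along the map order of each group, a crossover is an allele switch between
    consecutive non-missing calls; runs of missing calls therefore contribute
    at most one switch (the net change across the gap).
    """
    counts = pd.Series(0, index=geno.index, dtype=int)
    for group, sub in gmap.groupby("group", sort=False):
        markers = [m for m in sub.sort_values("pos_cm")["marker"] if m in geno.columns]
        if len(markers) < 2:
            continue
        counts += _switch_counts(_calls_float(geno[markers]))
    return counts


def filter_crossover_lines(
    geno: pd.DataFrame, gmap: pd.DataFrame, max_crossovers: int = 100
) -> tuple[pd.DataFrame, CurationReport]:
    """Drop lines whose genome-wide crossover count strictly exceeds the threshold."""
    _validate_geno(geno)
    counts = count_crossovers(geno, gmap)
    drop = counts.index[counts > max_crossovers]
    report = CurationReport(
        removed_lines={
            ln: f"crossovers {counts[ln]} > {max_crossovers}" for ln in drop
        },
        thresholds={"max_crossovers": max_crossovers},
    )
    return geno.drop(index=drop), report


def curate_genotypes(
    geno: pd.DataFrame,
    gmap: pd.DataFrame,
    max_missing: float = 0.20,
    band: tuple[float, float] = (0.40, 0.60),
    alpha: float = 0.05,
    max_crossovers: int = 100,
) -> tuple[pd.DataFrame, CurationReport]:
    """Apply the three curation filters in sequence (missingness, distortion,
    crossover count) and return the curated matrix with a combined report."""
    geno1, rep1 = filter_missing_markers(geno, max_missing)
    geno2, rep2 = filter_distorted_markers(geno1, band, alpha)
    geno3, rep3 = filter_crossover_lines(geno2, gmap, max_crossovers)
    return geno3, rep1.merge(rep2).merge(rep3)


# ---------------------------------------------------------------------------
# Recombination fractions and map building
# ---------------------------------------------------------------------------

def estimate_rf(geno: pd.DataFrame, marker_a: str, marker_b: str) -> tuple[float, int]:
    """Empirical recombination fraction between two markers.

    Returns ``(r_hat, n_informative)`` where informative lines are non-missing
    at both markers.  Estimates at or above 0.5 are capped at 0.4999 so the
    Kosambi conversion stays finite; with no informative lines the estimate is
    undefined and ``(nan, 0)`` is returned.
    """
    a = _calls_float(geno[[marker_a, marker_b]])
    obs = ~np.isnan(a).any(axis=1)
    n = int(obs.sum())
    if n == 0:
        return float("nan"), 0
    r = float((a[obs, 0] != a[obs, 1]).mean())
    return min(r, RF_CAP), n


def count_criterion(geno: pd.DataFrame, order: list[str]) -> int:
    """Total observed recombination events under a marker order (COUNT).

    Summed over lines; missing calls are skipped so that a switch across a
    run of missing data counts once.
    """
    return int(_switch_counts(_calls_float(geno[list(order)])).sum())


def _pairwise_rf(calls: np.ndarray) -> np.ndarray:
    m = calls.shape[1]
    r = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            obs = ~np.isnan(calls[:, i]) & ~np.isnan(calls[:, j])
            if obs.sum() == 0:
                r[i, j] = r[j, i] = 0.5
            else:
                r[i, j] = r[j, i] = (calls[obs, i] != calls[obs, j]).mean()
    return r


def order_markers_record(geno: pd.DataFrame, group_markers: list[str]) -> list[str]:
    """Order markers within one linkage group by COUNT minimization.

    Greedy insertion seeded from the tightest-linked pair, followed by
    segment-reversal and single-marker relocation passes until no move lowers
    COUNT.  Orders are defined only up to reversal.  The returned order never
    has a higher COUNT than the input order.  Groups with fewer than three
    markers are returned unchanged.
    """
    markers = list(group_markers)
    if len(markers) < 3:
        return markers
    sub = geno[markers]
    calls = _calls_float(sub)
    rf = _pairwise_rf(calls)
    m = len(markers)

    def count_of(order_idx: list[int]) -> int:
        return int(_switch_counts(calls[:, order_idx]).sum())

    # seed with the pair of smallest pairwise rf
    iu = np.triu_indices(m, 1)
    best_pair = int(np.argmin(rf[iu]))
    i0, j0 = iu[0][best_pair], iu[1][best_pair]
    order = [int(i0), int(j0)]
    remaining = [i for i in range(m) if i not in order]
    # add markers in order of closeness to the placed set, each at the
    # insertion point that minimizes COUNT
    while remaining:
        dists = [min(rf[i, j] for j in order) for i in remaining]
        nxt = remaining.pop(int(np.argmin(dists)))
        best = None
        for pos in range(len(order) + 1):
            cand = order[:pos] + [nxt] + order[pos:]
            c = count_of(cand)
            if best is None or c < best[0]:
                best = (c, cand)
        order = best[1]

    # local improvement: segment reversals (2-opt) and single relocations
    best_count = count_of(order)
    improved = True
    while improved:
        improved = False
        for i, j in itertools.combinations(range(m), 2):
            cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
            c = count_of(cand)
            if c < best_count:
                order, best_count, improved = cand, c, True
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                cand = order.copy()
                marker = cand.pop(i)
                cand.insert(j, marker)
                c = count_of(cand)
                if c < best_count:
                    order, best_count, improved = cand, c, True

    input_count = count_of(list(range(m)))
    if best_count > input_count:
        return markers
    return [markers[i] for i in order]


def build_map(geno: pd.DataFrame, ordered_groups: dict[str, list[str]]) -> pd.DataFrame:
    """Build a Kosambi-scale map from ordered markers.

    Position of each marker is the cumulative Kosambi distance of the
    adjacent-marker recombination fractions; each group starts at 0 cM.
    Returns a data frame with columns ``marker``, ``group``, ``pos_cm``.
    """
    rows = []
    for group, markers in ordered_groups.items():
        pos = 0.0
        for k, marker in enumerate(markers):
            if k > 0:
                r, n = estimate_rf(geno, markers[k - 1], marker)
                if n == 0:
                    raise ValueError(
                        f"recombination fraction undefined between "
                        f"{markers[k - 1]} and {marker} (no informative lines)"
                    )
                pos += kosambi_cm(min(r, RF_CAP))
            rows.append({"marker": marker, "group": group, "pos_cm": pos})
    return pd.DataFrame(rows, columns=["marker", "group", "pos_cm"])
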