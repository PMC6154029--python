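"""Synthetic data generators emulating a doubled-haploid salinity trial.

The generators produce the four inputs the analysis consumes — a genetic map
with a DH genotype matrix, additive quantitative traits, shoot-area growth
time series under control/salt treatments, and spatially structured field
plot tables — with the statistical structure the downstream modules assume:

* DH lines are fully homozygous; along a linkage group the genotypes form a
  two-state Markov chain whose switch probability between adjacent markers is
  the inverse-Kosambi recombination fraction of their cM distance.
* Traits are additive: with ``s = +1`` for the E allele and ``-1`` for K at
  each causal locus, value = mu + sum(a * s) + Normal(0, sigma^2).
* Shoot growth is exponential on the imaged window (day -4 to +10 relative
  to salt application) with a multiplicative relative-growth-rate penalty in
  the salt treatment from the day of application, and multiplicative
  lognormal measurement noise (pixel areas are positive and their error
  scales with size).
* Field plots carry additive row and column (range) trends plus plot noise
  around line means.

Default scales follow the emulated study: 212 DH lines, five linkage groups
of 120 cM at 5 cM marker spacing (a desk-scale stand-in for the full map,
which only affects runtime, not logic), and a 10 x 12 row-by-range field
layout with three replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .linkage import kosambi_r

__all__ = [
    "SimGenomeSpec",
    "SimQTLSpec",
    "SimGrowthSpec",
    "SimFieldSpec",
    "SimulatedTrait",
    "simulate_dh_population",
    "simulate_trait",
    "simulate_growth",
    "simulate_field_trial",
    "draw_salt_penalties",
    "effect_for_target_r2",
]

DEFAULT_GROUPS = (("1A", 120.0), ("2B", 120.0), ("5A", 120.0), ("6A", 120.0), ("7A", 120.0))


@dataclass(frozen=True)
class SimGenomeSpec:
    """Genome layout for a simulated biparental DH population."""

    linkage_groups: tuple[tuple[str, float], ...] = DEFAULT_GROUPS
    marker_spacing_cm: float = 5.0
    n_lines: int = 212
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.linkage_groups:
            raise ValueError("at least one linkage group required")
        lengths = [length for _, length in self.linkage_groups]
        if any(length <= 0 for length in lengths):
            raise ValueError("linkage group lengths must be positive")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker spacing must be positive")
        if self.marker_spacing_cm > min(lengths):
            raise ValueError("marker spacing exceeds the shortest group length")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.n_lines < 1:
            raise ValueError("need at least one line")


@dataclass(frozen=True)
class SimQTLSpec:
    """Additive architecture for one simulated trait.

    Each locus is ``(linkage_group, position_cM, additive_effect)``; lines
    carrying the E allele at a locus have class mean ``mu + a`` and K-allele
    lines ``mu - a``.
    """

    trait_name: str
    loci: tuple[tuple[str, float, float], ...]
    baseline_mean: float = 0.0
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual sd must be nonnegative")


@dataclass(frozen=True)
class SimGrowthSpec:
    """Exponential shoot-growth model with a salt RGR penalty.

    ``salt_penalty_by_line`` maps line -> multiplicative factor in (0, 1.1]
    applied to the relative growth rate after salt application; lines absent
    from the map grow unpenalized (factor 1.0).
    """

    base_rgr: float = 0.18
    salt_penalty_by_line: Mapping[str, float] | None = None
    initial_psa_kpixels: float = 20.0
    obs_noise_cv: float = 0.05
    days: tuple[int, ...] = tuple(range(-4, 11))
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.base_rgr <= 0:
            raise ValueError("base RGR must be positive")
        if self.obs_noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")
        if self.initial_psa_kpixels <= 0:
            raise ValueError("initial PSA must be positive")
        if len(self.days) == 0:
            raise ValueError("day list must be non-empty")
        if self.salt_penalty_by_line is not None:
            vals = list(self.salt_penalty_by_line.values())
            if any(v <= 0 for v in vals):
                raise ValueError("salt penalties must be positive")


@dataclass(frozen=True)
class SimFieldSpec:
    """Field-trial layout and effects for one site-year-salinity trial."""

    line_effects: Mapping[str, Mapping[str, float]]
    n_rows: int = 10
    n_ranges: int = 12
    n_reps: int = 3
    row_trend_sd: float = 0.0
    col_trend_sd: float = 0.0
    plot_noise_sd: float = 0.0
    site: str = "Whitwarta"
    year: int = 2014
    salt_level: str = "high"
    seed: int = 0

    def __post_init__(self):
        if not self.line_effects:
            raise ValueError("line effects must be non-empty")
        if self.n_rows * self.n_ranges < self.n_reps * len(self.line_effects):
            raise ValueError(
                "field capacity violated: "
                f"{self.n_rows}x{self.n_ranges} plots cannot hold "
                f"{self.n_reps} reps of {len(self.line_effects)} lines"
            )
        if min(self.row_trend_sd, self.col_trend_sd, self.plot_noise_sd) < 0:
            raise ValueError("trend and noise sds must be nonnegative")


# ---------------------------------------------------------------------------
# Genome / genotypes
# ---------------------------------------------------------------------------

def simulate_dh_population(spec: SimGenomeSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genetic map and DH genotype matrix.

    Returns ``(gmap, geno)``: a map frame (``marker``, ``group``, ``pos_cm``)
    and a line x marker frame of calls in {"E", "K"} with missing calls
    injected i.i.d. at ``spec.missing_rate``.  Recombination between adjacent
    markers follows the inverse-Kosambi fraction of their distance, with no
    interference modelled beyond what that pairwise fraction implies.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [f"DH{i + 1:03d}" for i in range(spec.n_lines)]
    map_rows = []
    blocks = []
    for group, length in spec.linkage_groups:
        pos = np.arange(0.0, length + 1e-9, spec.marker_spacing_cm)
        markers = [f"{group}_M{j + 1:03d}" for j in range(pos.size)]
        map_rows.extend(
            {"marker": m, "group": group, "pos_cm": float(p)}
            for m, p in zip(markers, pos)
        )
        r = kosambi_r(np.diff(pos))
        first = rng.random(spec.n_lines) < 0.5
        switches = rng.random((spec.n_lines, pos.size - 1)) < r
        parity = np.zeros((spec.n_lines, pos.size), dtype=int)
        parity[:, 1:] = np.cumsum(switches, axis=1) % 2
        is_e = first[:, None] ^ parity.astype(bool)
        calls = np.where(is_e, "E", "K").astype(object)
        if spec.missing_rate > 0:
            miss = rng.random(calls.shape) < spec.missing_rate
            calls[miss] = np.nan
        blocks.append(pd.DataFrame(calls, index=lines, columns=markers))
    gmap = pd.DataFrame(map_rows, columns=["marker", "group", "pos_cm"])
    geno = pd.concat(blocks, axis=1)
    geno.index.name = "line"
    return gmap, geno


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrait:
    """A simulated trait table plus the realized architecture of its loci."""

    traits: pd.DataFrame  # columns: line, trait, value
    loci: pd.DataFrame  # columns: group, pos_cm, marker, additive, realized_r2


def _nearest_marker(gmap: pd.DataFrame, group: str, pos: float) -> str:
    sub = gmap[gmap["group"] == group]
    if sub.empty:
        raise ValueError(f"unknown linkage group {group!r}")
    span = (sub["pos_cm"].min(), sub["pos_cm"].max())
    if not span[0] <= pos <= span[1]:
        raise ValueError(f"position {pos} cM outside span of group {group}")
    idx = (sub["pos_cm"] - pos).abs().idxmin()
    return sub.loc[idx, "marker"]


def effect_for_target_r2(target_r2: float, residual_sd: float = 1.0) -> float:
    """Additive effect giving a single-locus variance share a^2/(a^2+sigma^2).

    With balanced DH allele classes the genetic variance of a +/-a locus is
    a^2, so the expected single-marker R^2 is a^2 / (a^2 + sigma^2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    return residual_sd * np.sqrt(target_r2 / (1.0 - target_r2))


def simulate_trait(
    gmap: pd.DataFrame, geno: pd.DataFrame, spec: SimQTLSpec
) -> SimulatedTrait:
    """Simulate an additive trait from the genotypes at the nearest markers.

    The QTL genotype of each locus is taken from the marker nearest its
    position; a missing call there is resolved by an unbiased coin flip.
    Realized per-locus R^2 (squared correlation between the +/-1 marker score
    and the trait, a fraction) is reported alongside.
    """
    rng = np.random.default_rng(spec.seed)
    n = geno.shape[0]
    value = np.full(n, float(spec.baseline_mean))
    locus_scores = []
    loci_rows = []
    for group, pos, a in spec.loci:
        marker = _nearest_marker(gmap, group, pos)
        calls = geno[marker].to_numpy(dtype=object)
        s = np.where(calls == "E", 1.0, np.where(calls == "K", -1.0, np.nan))
        miss = np.isnan(s)
        if miss.any():
            s[miss] = rng.choice([-1.0, 1.0], size=int(miss.sum()))
        value = value + a * s
        locus_scores.append((group, pos, marker, a, s))
    value = value + rng.normal(0.0, spec.residual_sd, size=n)
    for group, pos, marker, a, s in locus_scores:
        if np.std(s) > 0 and np.std(value) > 0:
            r2 = float(np.corrcoef(s, value)[0, 1] ** 2)
        else:
            r2 = 0.0
        loci_rows.append(
            {"group": group, "pos_cm": pos, "marker": marker,
             "additive": a, "realized_r2": r2}
        )
    traits = pd.DataFrame(
        {"line": geno.index, "trait": spec.trait_name, "value": value}
    )
    return SimulatedTrait(traits=traits, loci=pd.DataFrame(loci_rows))


# ---------------------------------------------------------------------------
# Growth series
# ---------------------------------------------------------------------------

def draw_salt_penalties(
    lines, low: float = 0.6, high: float = 1.1, seed: int = 0
) -> dict[str, float]:
    """Draw per-line salt RGR penalty factors uniformly on [low, high]."""
    rng = np.random.default_rng(seed)
    return {ln: float(p) for ln, p in zip(lines, rng.uniform(low, high, len(lines)))}


def simulate_growth(geno: pd.DataFrame, spec: SimGrowthSpec) -> pd.DataFrame:
    """Simulate paired control/salt shoot-area series for every line.

    Control plants grow as ``initial * exp(base_rgr * day)`` (day 0 = salt
    application); salt plants grow at ``base_rgr`` before day 0 and at
    ``base_rgr * penalty`` after.  Measurement noise is a mean-one lognormal
    multiplier whose log-sd approximates ``obs_noise_cv``.  Each replicate
    yields one control and one salt plant per line (a paired main plot).
    """
    rng = np.random.default_rng(spec.seed)
    penalties = spec.salt_penalty_by_line or {}
    days = np.asarray(spec.days, dtype=float)
    sdlog = float(np.sqrt(np.log1p(spec.obs_noise_cv**2)))
    rows = []
    for line in geno.index:
        pen = float(penalties.get(line, 1.0))
        for rep in range(1, spec.n_reps + 1):
            for treatment in ("control", "salt"):
                rate_after = spec.base_rgr * (pen if treatment == "salt" else 1.0)
                log_psa = np.where(
                    days <= 0,
                    np.log(spec.initial_psa_kpixels) + spec.base_rgr * days,
                    np.log(spec.initial_psa_kpixels) + rate_after * days,
                )
                if sdlog > 0:
                    log_psa = log_psa + rng.normal(
                        -0.5 * sdlog**2, sdlog, size=days.size
                    )
                plant_id = f"{line}_rep{rep}_{treatment}"
                for day, lp in zip(spec.days, log_psa):
                    rows.append(
                        {
                            "plant_id": plant_id,
                            "line": line,
                            "treatment": treatment,
                            "replicate": rep,
                            "day": int(day),
                            "psa_kpixels": float(np.exp(lp)),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Field trials
# ---------------------------------------------------------------------------

def simulate_field_trial(spec: SimFieldSpec) -> pd.DataFrame:
    """Simulate one field trial on a rows x ranges grid.

    Each line occupies ``n_reps`` randomly assigned plots; every trait value
    is line mean + row effect + range effect + plot noise, with effects drawn
    independently per trait at the configured sds.  Unassigned plots are
    omitted from the output.
    """
    rng = np.random.default_rng(spec.seed)
    lines = list(spec.line_effects)
    traits = sorted({t for eff in spec.line_effects.values() for t in eff})
    plots = [(r, c) for r in range(1, spec.n_rows + 1) for c in range(1, spec.n_ranges + 1)]
    plots = [plots[i] for i in rng.permutation(len(plots))]
    assignment = [ln for ln in lines for _ in range(spec.n_reps)]
    assignment = [assignment[i] for i in rng.permutation(len(assignment))]
    row_eff = {t: rng.normal(0, spec.row_trend_sd, spec.n_rows) for t in traits}
    col_eff = {t: rng.normal(0, spec.col_trend_sd, spec.n_ranges) for t in traits}
    rows = []
    for (r, c), line in zip(plots, assignment):
        rec = {
            "site": spec.site,
            "year": spec.year,
            "salt_level": spec.salt_level,
            "row": r,
            "range": c,
            "line": line,
        }
        for t in traits:
            base = float(spec.line_effects[line].get(t, np.nan))
            noise = rng.normal(0, spec.plot_noise_sd) if spec.plot_noise_sd > 0 else 0.0
            rec[t] = base + row_eff[t][r - 1] + col_eff[t][c - 1] + noise
        rows.append(rec)
    out = pd.DataFrame(rows)
    return out.sort_values(["row", "range"], ignore_index=True)
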