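"""Composite interval mapping (CIM) for doubled-haploid populations.

The scan regresses a trait on the expected genotype score at each position
of a 1 cM genome walk, with a fixed number of background marker cofactors
absorbing other-QTL variance (cofactors within a window of the test position
on the same linkage group are excluded).  The DH population has two genotype
classes, so interval genotypes reduce to a two-state Markov chain: the
probability that a line carries the E (Excalibur) allele at a position is
conditioned on the nearest non-missing flanking markers through
inverse-Kosambi recombination fractions.  Regression on the expected
genotype (Haley-Knott) stands in for the EM mixture likelihood of classical
CIM; for a DH cross at dense marker spacing the two produce near-identical
LOD profiles and the regression form is deterministic.

Conventions
-----------
* genotype score g = 2 p(E) - 1, so E -> +1 and K -> -1;
* LOD = (n/2) log10(RSS_reduced / RSS_full), the reduced model dropping the
  genotype term;
* additive effect a = regression coefficient of g: half the E-minus-K
  class-mean difference, positive when the Excalibur allele raises the trait;
* R^2 (%) = 100 (RSS_reduced - RSS_full) / TSS, the share of total trait
  variance attributable to the QTL term given the cofactors.

Genome-wide significance comes from permutation: trait values are shuffled
across lines, cofactors re-selected, the scan repeated, and the empirical
(1 - alpha) quantile of the per-permutation maximum LOD taken as threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .linkage import kosambi_r

__all__ = [
    "CIMConfig",
    "QTLPeak",
    "PermutationThreshold",
    "CompositeIntervalMapper",
    "genotype_prob",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "call_peaks",
    "merge_unique_qtl",
    "name_qtl",
    "assign_qtl_names",
]

logger = logging.getLogger(__name__)

#: registry of trait codes -> printed trait symbols used in QTL names
TRAIT_CODES = {
    "G_1_5": "G_(1–5)",
    "CRGR": "CRGR",
    "Na": "Na",
    "K": "K",
    "Na_K": "Na:K",
    "K_Na": "K:Na",
}


@dataclass(frozen=True)
class CIMConfig:
    """Scan configuration: cofactor count, exclusion window, walk step,
    permutation count and significance level."""

    n_cofactors: int = 5
    window_cm: float = 10.0
    walk_cm: float = 1.0
    alpha: float = 0.05
    n_perm: int = 1000
    reselect_cofactors: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.window_cm < self.walk_cm:
            raise ValueError("window must be at least one walk step")
        if min(self.n_cofactors, self.window_cm, self.walk_cm) < 0 or self.walk_cm == 0:
            raise ValueError("cofactors, window and walk must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class QTLPeak:
    """A declared QTL peak with its support intervals."""

    trait: str
    group: str
    position_cm: float
    lod: float
    additive: float
    r_squared: float  # percent of trait variance
    support_1lod: tuple[float, float]
    support_2lod: tuple[float, float]
    name: str | None = None


@dataclass
class PermutationThreshold:
    """Genome-wide LOD threshold from a permutation null distribution."""

    trait: str
    alpha: float
    n_perm: int
    threshold_lod: float
    max_lods: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Conditional genotype probabilities
# ---------------------------------------------------------------------------

def _pe_from_flanks(marker_pos: np.ndarray, calls: np.ndarray,
                    query: np.ndarray) -> np.ndarray:
    """P(E allele) at query positions for one line on one linkage group.

    ``calls`` holds 1.0 (E), 0.0 (K) or nan at ``marker_pos``; conditioning
    uses the nearest non-missing flanking markers under the DH two-state
    Markov model with inverse-Kosambi recombination fractions.
    """
    obs = ~np.isnan(calls)
    mp, mc = marker_pos[obs], calls[obs]
    if mp.size == 0:
        return np.full(query.shape, 0.5)
    li = np.searchsorted(mp, query, side="right") - 1
    ri = np.searchsorted(mp, query, side="left")
    has_l, has_r = li >= 0, ri < mp.size
    pe = np.full(query.shape, 0.5)

    both = has_l & has_r
    if both.any():
        r1 = kosambi_r(query[both] - mp[li[both]])
        r2 = kosambi_r(mp[ri[both]] - query[both])
        t1e = np.where(mc[li[both]] == 1.0, 1.0 - r1, r1)
        t2e = np.where(mc[ri[both]] == 1.0, 1.0 - r2, r2)
        num = t1e * t2e
        pe[both] = num / (num + (1.0 - t1e) * (1.0 - t2e))
    only_l = has_l & ~has_r
    if only_l.any():
        r1 = kosambi_r(query[only_l] - mp[li[only_l]])
        pe[only_l] = np.where(mc[li[only_l]] == 1.0, 1.0 - r1, r1)
    only_r = ~has_l & has_r
    if only_r.any():
        r2 = kosambi_r(mp[ri[only_r]] - query[only_r])
        pe[only_r] = np.where(mc[ri[only_r]] == 1.0, 1.0 - r2, r2)
    return pe


def genotype_prob(gmap: pd.DataFrame, geno: pd.DataFrame, line: str,
                  group: str, position_cm: float) -> float:
    """P(line carries the E allele) at a map position (see module notes)."""
    sub = gmap[gmap["group"] == group].sort_values("pos_cm")
    if sub.empty:
        raise ValueError(f"unknown linkage group {group!r}")
    lo, hi = sub["pos_cm"].min(), sub["pos_cm"].max()
    if not lo <= position_cm <= hi:
        raise ValueError(f"position {position_cm} outside group span [{lo}, {hi}]")
    markers = [m for m in sub["marker"] if m in geno.columns]
    pos = sub.set_index("marker").loc[markers, "pos_cm"].to_numpy(dtype=float)
    row = geno.loc[line, markers].to_numpy(dtype=object)
    calls = np.where(row == "E", 1.0, np.where(row == "K", 0.0, np.nan)).astype(float)
    return float(_pe_from_flanks(pos, calls, np.asarray([position_cm]))[0])


# ---------------------------------------------------------------------------
# Scan engine
# ---------------------------------------------------------------------------

def _orth_basis(columns: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space, dropping collinear columns."""
    n = columns.shape[0]
    basis = []
    for j in range(columns.shape[1]):
        v = columns[:, j].astype(float).copy()
        for q in basis:
            v -= q * (q @ v)
        norm = np.linalg.norm(v)
        if norm > 1e-9 * np.sqrt(n):
            basis.append(v / norm)
        else:
            logger.warning("dropping collinear design column %d", j)
    return np.column_stack(basis) if basis else np.zeros((n, 0))


class _ScanEngine:
    """Precomputed genotype scores for repeated scans over one trait's lines.

    Holds the walk grid, the expected genotype score matrix ``G`` (lines x
    walk positions) and the marker-level score matrix ``Xm`` (lines x
    markers), so permutation replicates only redo cheap regressions.
    """

    def __init__(self, gmap: pd.DataFrame, geno: pd.DataFrame, walk_cm: float = 1.0):
        gmap = gmap.sort_values(["group", "pos_cm"], kind="stable")
        self.lines = geno.index.to_numpy()
        self.n = len(self.lines)
        walk_groups, walk_pos, g_cols = [], [], []
        marker_groups, marker_pos, marker_names, xm_cols = [], [], [], []
        for group, sub in gmap.groupby("group", sort=False):
            markers = [m for m in sub["marker"] if m in geno.columns]
            if not markers:
                continue
            mpos = sub.set_index("marker").loc[markers, "pos_cm"].to_numpy(dtype=float)
            arr = geno[markers].to_numpy(dtype=object)
            calls = np.where(arr == "E", 1.0,
                             np.where(arr == "K", 0.0, np.nan)).astype(float)
            length = mpos.max()
            walk = np.arange(mpos.min(), length + 1e-9, walk_cm)
            if walk.size == 0 or walk[-1] < length - 1e-9:
                walk = np.append(walk, length)
            pe_w = np.empty((self.n, walk.size))
            pe_m = np.empty((self.n, mpos.size))
            for i in range(self.n):
                pe_w[i] = _pe_from_flanks(mpos, calls[i], walk)
                pe_m[i] = _pe_from_flanks(mpos, calls[i], mpos)
            g_cols.append(2.0 * pe_w - 1.0)
            xm_cols.append(2.0 * pe_m - 1.0)
            walk_groups.extend([group] * walk.size)
            walk_pos.append(walk)
            marker_groups.extend([group] * mpos.size)
            marker_pos.append(mpos)
            marker_names.extend(markers)
        self.walk_group = np.asarray(walk_groups, dtype=object)
        self.walk_pos = np.concatenate(walk_pos)
        self.G = np.concatenate(g_cols, axis=1)
        self.marker_group = np.asarray(marker_groups, dtype=object)
        self.marker_pos = np.concatenate(marker_pos)
        self.marker_names = marker_names
        self.Xm = np.concatenate(xm_cols, axis=1)

    # -- cofactor selection -------------------------------------------------
    def select_cofactors(self, y: np.ndarray, k: int) -> list[int]:
        """Forward stepwise selection of ``k`` marker indices by largest RSS
        reduction; ties break to the lower marker index."""
        n, m = self.Xm.shape
        if k >= m:
            return list(range(m))
        ones = np.full(n, 1.0 / np.sqrt(n))
        yr = y - ones * (ones @ y)
        Xr = self.Xm - np.outer(ones, ones @ self.Xm)
        selected: list[int] = []
        for _ in range(k):
            num = (Xr.T @ yr) ** 2
            den = (Xr**2).sum(axis=0)
            ok = den > 1e-10 * n
            score = np.where(ok, num / np.where(ok, den, 1.0), -np.inf)
            if selected:
                score[selected] = -np.inf
            j = int(np.argmax(score))
            if not np.isfinite(score[j]):
                break
            selected.append(j)
            q = Xr[:, j] / np.sqrt(den[j])
            yr = yr - q * (q @ yr)
            Xr = Xr - np.outer(q, q @ Xr)
        return selected

    # -- the scan -----------------------------------------------------------
    def scan(self, y: np.ndarray, cofactor_idx: list[int], window_cm: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """LOD, additive effect and R^2 (%) at every walk position."""
        n = y.size
        P = self.walk_pos.size
        tss = float(((y - y.mean()) ** 2).sum())
        cof = np.asarray(cofactor_idx, dtype=int)
        include = np.ones((P, max(cof.size, 1)), dtype=bool)[:, : cof.size]
        for jj, j in enumerate(cof):
            same = self.walk_group == self.marker_group[j]
            include[:, jj] = ~(
                same & (np.abs(self.walk_pos - self.marker_pos[j]) <= window_cm)
            )
        lod = np.zeros(P)
        add = np.zeros(P)
        r2 = np.zeros(P)
        ones = np.ones((n, 1))
        patterns = {}
        for p in range(P):
            patterns.setdefault(include[p].tobytes(), []).append(p)
        for key, idxs in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            design = np.hstack([ones, self.Xm[:, cof[mask]]])
            Q = _orth_basis(design)
            yr = y - Q @ (Q.T @ y)
            rss_red = float(yr @ yr)
            Gs = self.G[:, idxs]
            Gr = Gs - Q @ (Q.T @ Gs)
            sgy = Gr.T @ yr
            sgg = (Gr**2).sum(axis=0)
            ok = sgg > 1e-10 * n
            beta = np.where(ok, sgy / np.where(ok, sgg, 1.0), 0.0)
            drop = np.where(ok, sgy**2 / np.where(ok, sgg, 1.0), 0.0)
            rss_full = np.maximum(rss_red - drop, 0.0)
            with np.errstate(divide="ignore"):
                lod_vals = np.where(
                    rss_full > 0,
                    (n / 2.0) * np.log10(np.where(rss_full > 0, rss_red / rss_full, 1.0)),
                    np.inf,
                )
            lod_vals = np.where(rss_red > 0, lod_vals, 0.0)
            lod[idxs] = lod_vals
            add[idxs] = beta
            r2[idxs] = 100.0 * drop / tss if tss > 0 else 0.0
        return lod, add, r2


def _complete_case(geno: pd.DataFrame, trait: pd.Series
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    trait = trait.dropna()
    lines = geno.index.intersection(trait.index)
    if len(lines) == 0:
        raise ValueError("no lines shared between genotypes and trait")
    return geno.loc[lines], trait.loc[lines].to_numpy(dtype=float)


def select_cofactors(gmap: pd.DataFrame, geno: pd.DataFrame, trait: pd.Series,
                     k: int = 5) -> list[str]:
    """Forward stepwise cofactor markers for a trait (names, in order)."""
    sub, y = _complete_case(geno, trait)
    if y.size < 10:
        raise ValueError("need trait values for at least 10 lines")
    engine = _ScanEngine(gmap, sub)
    return [engine.marker_names[j] for j in engine.select_cofactors(y, k)]


def cim_scan(gmap: pd.DataFrame, geno: pd.DataFrame, trait: pd.Series,
             config: CIMConfig = CIMConfig(), engine: _ScanEngine | None = None
             ) -> pd.DataFrame:
    """Composite interval mapping scan profile for one trait.

    Returns a frame with columns ``trait``, ``group``, ``pos_cm``, ``lod``,
    ``additive``, ``r2`` over the genome walk.
    """
    sub, y = _complete_case(geno, trait)
    if engine is None:
        engine = _ScanEngine(gmap, sub, walk_cm=config.walk_cm)
    n_par = config.n_cofactors + 3
    if y.size < n_par:
        raise ValueError(f"fewer lines ({y.size}) than model parameters ({n_par})")
    cof = engine.select_cofactors(y, config.n_cofactors)
    lod, add, r2 = engine.scan(y, cof, config.window_cm)
    return pd.DataFrame(
        {
            "trait": trait.name or "trait",
            "group": engine.walk_group,
            "pos_cm": engine.walk_pos,
            "lod": lod,
            "additive": add,
            "r2": r2,
        }
    )


def permutation_threshold(gmap: pd.DataFrame, geno: pd.DataFrame,
                          trait: pd.Series, config: CIMConfig = CIMConfig(),
                          engine: _ScanEngine | None = None
                          ) -> PermutationThreshold:
    """Genome-wide LOD threshold by trait permutation.

    Shuffles trait values across lines (genotypes fixed), optionally
    re-selects cofactors each time, and records the genome-wide maximum LOD;
    the threshold is the empirical (1 - alpha) quantile (type-7).
    """
    if config.n_perm < 20:
        raise ValueError("need at least 20 permutations for a usable quantile")
    sub, y = _complete_case(geno, trait)
    if engine is None:
        engine = _ScanEngine(gmap, sub, walk_cm=config.walk_cm)
    rng = np.random.default_rng(config.seed)
    base_cof = engine.select_cofactors(y, config.n_cofactors)
    max_lods = np.empty(config.n_perm)
    for b in range(config.n_perm):
        yp = rng.permutation(y)
        cof = (engine.select_cofactors(yp, config.n_cofactors)
               if config.reselect_cofactors else base_cof)
        lod, _, _ = engine.scan(yp, cof, config.window_cm)
        max_lods[b] = lod.max()
    threshold = float(np.quantile(max_lods, 1.0 - config.alpha))
    return PermutationThreshold(
        trait=str(trait.name or "trait"), alpha=config.alpha,
        n_perm=config.n_perm, threshold_lod=threshold, max_lods=max_lods,
    )


# ---------------------------------------------------------------------------
# Peak calling, unique loci, naming
# ---------------------------------------------------------------------------

def _support(pos: np.ndarray, lod: np.ndarray, peak_idx: int, k: float
             ) -> tuple[float, float]:
    floor = lod[peak_idx] - k
    left = peak_idx
    while left > 0 and lod[left - 1] >= floor:
        left -= 1
    right = peak_idx
    while right < lod.size - 1 and lod[right + 1] >= floor:
        right += 1
    return float(pos[left]), float(pos[right])


def call_peaks(profile: pd.DataFrame, threshold: float,
               merge_within_cm: float = 15.0) -> list[QTLPeak]:
    """Declare QTL peaks from a scan profile.

    Local LOD maxima at or above ``threshold`` are kept; within a linkage
    group, maxima separated by at most ``merge_within_cm`` are merged keeping
    the higher one (the unique-locus rule).  Support intervals are the
    contiguous stretch of the walk where LOD stays within 1 (or 2) of the
    peak value.
    """
    peaks: list[QTLPeak] = []
    for (trait, group), sub in profile.groupby(["trait", "group"], sort=False):
        sub = sub.sort_values("pos_cm")
        pos = sub["pos_cm"].to_numpy(dtype=float)
        lod = sub["lod"].to_numpy(dtype=float)
        add = sub["additive"].to_numpy(dtype=float)
        r2 = sub["r2"].to_numpy(dtype=float)
        cands = []
        for i in range(lod.size):
            if lod[i] < threshold:
                continue
            left_ok = i == 0 or lod[i] > lod[i - 1]
            right_ok = i == lod.size - 1 or lod[i] >= lod[i + 1]
            if left_ok and right_ok:
                cands.append(i)
        accepted: list[int] = []
        for i in sorted(cands, key=lambda i: (-lod[i], pos[i])):
            if all(abs(pos[i] - pos[j]) > merge_within_cm for j in accepted):
                accepted.append(i)
        for i in sorted(accepted, key=lambda i: pos[i]):
            peaks.append(
                QTLPeak(
                    trait=trait, group=group, position_cm=float(pos[i]),
                    lod=float(lod[i]), additive=float(add[i]),
                    r_squared=float(r2[i]),
                    support_1lod=_support(pos, lod, i, 1.0),
                    support_2lod=_support(pos, lod, i, 2.0),
                )
            )
    return peaks


def merge_unique_qtl(peaks: list[QTLPeak], max_gap_cm: float = 15.0
                     ) -> list[list[QTLPeak]]:
    """Group peaks (across traits) into unique loci by single-linkage
    clustering on the same linkage group with gaps of at most ``max_gap_cm``."""
    clusters: list[list[QTLPeak]] = []
    by_group: dict[str, list[QTLPeak]] = {}
    for p in peaks:
        by_group.setdefault(p.group, []).append(p)
    for group in sorted(by_group):
        members = sorted(by_group[group], key=lambda p: p.position_cm)
        current = [members[0]]
        for p in members[1:]:
            if p.position_cm - current[-1].position_cm <= max_gap_cm:
                current.append(p)
            else:
                clusters.append(current)
                current = [p]
        clusters.append(current)
    return clusters


def name_qtl(trait_code: str, linkage_group: str, ordinal: int | None = None,
             lab: str = "asl") -> str:
    """Wheat-format QTL name: Q<trait>.<lab>-<chromosome>[.<n>].

    The ordinal suffix is used only when two or more QTL for the trait share
    a chromosome.
    """
    if trait_code not in TRAIT_CODES:
        raise ValueError(f"unknown trait code {trait_code!r}; "
                         f"known: {sorted(TRAIT_CODES)}")
    name = f"Q{TRAIT_CODES[trait_code]}.{lab}-{linkage_group}"
    if ordinal is not None:
        name += f".{ordinal}"
    return name


def assign_qtl_names(peaks: list[QTLPeak], lab: str = "asl") -> list[QTLPeak]:
    """Fill in wheat-format names, numbering same-trait peaks that share a
    linkage group by position order."""
    by_tg: dict[tuple[str, str], list[QTLPeak]] = {}
    for p in peaks:
        by_tg.setdefault((p.trait, p.group), []).append(p)
    for (trait, group), members in by_tg.items():
        members.sort(key=lambda p: p.position_cm)
        for i, p in enumerate(members, start=1):
            p.name = name_qtl(trait, group, ordinal=i if len(members) > 1 else None,
                              lab=lab)
    return peaks


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    """Tabulate peaks with one row per QTL (trait, name, position, LOD,
    additive effect, R^2 and support intervals)."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "trait": p.trait, "qtl": p.name, "group": p.group,
                "pos_cm": p.position_cm, "lod": p.lod, "additive": p.additive,
                "r2": p.r_squared,
                "support_1lod_lo": p.support_1lod[0],
                "support_1lod_hi": p.support_1lod[1],
                "support_2lod_lo": p.support_2lod[0],
                "support_2lod_hi": p.support_2lod[1],
            }
        )
    cols = ["trait", "qtl", "group", "pos_cm", "lod", "additive", "r2",
            "support_1lod_lo", "support_1lod_hi", "support_2lod_lo",
            "support_2lod_hi"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class CompositeIntervalMapper(BaseEstimator):
    """Scikit-learn-style estimator running the full CIM procedure.

    ``fit(X, y)`` takes the genotype matrix ``X`` (lines x markers, calls
    E/K/missing) and the trait ``y`` (Series indexed by line); it computes
    the scan profile, a permutation threshold (when ``n_perm > 0``) and the
    named peaks.

    Fitted attributes: ``cofactors_`` (marker names), ``profile_`` (scan
    frame), ``permutation_`` (PermutationThreshold or None),
    ``threshold_lod_``, ``peaks_`` (list of QTLPeak), ``n_lines_``.
    """

    def __init__(self, genetic_map: pd.DataFrame | None = None,
                 n_cofactors: int = 5, window_cm: float = 10.0,
                 walk_cm: float = 1.0, alpha: float = 0.05, n_perm: int = 1000,
                 reselect_cofactors: bool = True, merge_within_cm: float = 15.0,
                 lab: str = "asl", random_state: int | None = None):
        self.genetic_map = genetic_map
        self.n_cofactors = n_cofactors
        self.window_cm = window_cm
        self.walk_cm = walk_cm
        self.alpha = alpha
        self.n_perm = n_perm
        self.reselect_cofactors = reselect_cofactors
        self.merge_within_cm = merge_within_cm
        self.lab = lab
        self.random_state = random_state

    def _config(self) -> CIMConfig:
        return CIMConfig(
            n_cofactors=self.n_cofactors, window_cm=self.window_cm,
            walk_cm=self.walk_cm, alpha=self.alpha,
            n_perm=max(self.n_perm, 20), reselect_cofactors=self.reselect_cofactors,
            seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y: pd.Series):
        if self.genetic_map is None:
            raise ValueError("a genetic_map frame (marker, group, pos_cm) is required")
        config = self._config()
        sub, yv = _complete_case(X, y)
        engine = _ScanEngine(self.genetic_map, sub, walk_cm=config.walk_cm)
        self.n_lines_ = yv.size
        cof_idx = engine.select_cofactors(yv, config.n_cofactors)
        self.cofactors_ = [engine.marker_names[j] for j in cof_idx]
        lod, add, r2 = engine.scan(yv, cof_idx, config.window_cm)
        self.profile_ = pd.DataFrame(
            {"trait": y.name or "trait", "group": engine.walk_group,
             "pos_cm": engine.walk_pos, "lod": lod, "additive": add, "r2": r2}
        )
        if self.n_perm > 0:
            self.permutation_ = permutation_threshold(
                self.genetic_map, sub, pd.Series(yv, index=sub.index, name=y.name),
                config, engine=engine,
            )
            self.threshold_lod_ = self.permutation_.threshold_lod
            self.peaks_ = assign_qtl_names(
                call_peaks(self.profile_, self.threshold_lod_,
                           merge_within_cm=self.merge_within_cm),
                lab=self.lab,
            ) if (y.name in TRAIT_CODES) else call_peaks(
                self.profile_, self.threshold_lod_,
                merge_within_cm=self.merge_within_cm,
            )
        else:
            self.permutation_ = None
            self.threshold_lod_ = None
            self.peaks_ = None
        return self
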