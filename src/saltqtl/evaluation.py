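"""Simulation-based evaluation of the QTL scan: detection power on the
default synthetic scenario and genome-wide type-I error under the null.

These experiments regenerate a DH population per replicate, run the full
composite-interval-mapping procedure (cofactor selection, scan, permutation
threshold, peak calling) and summarize recovery of the planted architecture.
They are used by the test suite and the reproduction script; problem sizes
default to the desk-scale scenario (212 lines, five 120 cM groups at 5 cM
spacing, 200 permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtl import CIMConfig, _ScanEngine, call_peaks, cim_scan, permutation_threshold
from .simulate import SimGenomeSpec, SimQTLSpec, effect_for_target_r2, simulate_dh_population, simulate_trait

__all__ = ["RecoveryResult", "qtl_recovery_experiment", "null_scan_type1_error"]


@dataclass
class RecoveryResult:
    """Per-replicate outcomes of the planted-QTL recovery experiment."""

    detected: list[bool]
    distance_cm: list[float]  # |called peak - planted locus|, detections only
    sign_correct: list[bool]  # detections only
    thresholds: list[float]

    @property
    def detection_rate(self) -> float:
        return float(np.mean(self.detected))

    @property
    def median_distance_cm(self) -> float:
        return float(np.median(self.distance_cm)) if self.distance_cm else float("nan")

    @property
    def all_signs_correct(self) -> bool:
        return all(self.sign_correct) if self.sign_correct else False


def qtl_recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    target_r2: float = 0.15,
    locus: tuple[str, float] = ("7A", 60.0),
    genome: SimGenomeSpec | None = None,
    config: CIMConfig | None = None,
) -> RecoveryResult:
    """Planted-QTL recovery over independent population replicates.

    Each replicate simulates a fresh DH population and one additive trait at
    the target single-locus variance share, runs CIM with a permutation
    threshold, and records whether a peak was called on the planted linkage
    group, its distance to the planted position, and whether the additive
    effect carried the planted sign (positive: E allele raises the trait).
    """
    if config is None:
        config = CIMConfig(n_perm=200, seed=0)
    a = effect_for_target_r2(target_r2)
    detected, distances, signs, thresholds = [], [], [], []
    for i in range(n_seeds):
        seed = base_seed + 1000 * i
        spec = genome or SimGenomeSpec(seed=seed)
        if genome is not None:
            spec = SimGenomeSpec(
                linkage_groups=genome.linkage_groups,
                marker_spacing_cm=genome.marker_spacing_cm,
                n_lines=genome.n_lines, missing_rate=genome.missing_rate,
                seed=seed,
            )
        gmap, geno = simulate_dh_population(spec)
        sim = simulate_trait(
            gmap, geno,
            SimQTLSpec("G_1_5", (locus + (a,),), seed=seed + 1),
        )
        y = pd.Series(sim.traits["value"].to_numpy(),
                      index=sim.traits["line"].to_numpy(), name="G_1_5")
        run_cfg = CIMConfig(
            n_cofactors=config.n_cofactors, window_cm=config.window_cm,
            walk_cm=config.walk_cm, alpha=config.alpha, n_perm=config.n_perm,
            reselect_cofactors=config.reselect_cofactors, seed=seed + 2,
        )
        engine = _ScanEngine(gmap, geno, walk_cm=run_cfg.walk_cm)
        profile = cim_scan(gmap, geno, y, run_cfg, engine=engine)
        perm = permutation_threshold(gmap, geno, y, run_cfg, engine=engine)
        thresholds.append(perm.threshold_lod)
        on_group = [p for p in call_peaks(profile, perm.threshold_lod)
                    if p.group == locus[0]]
        if on_group:
            best = max(on_group, key=lambda p: p.lod)
            detected.append(True)
            distances.append(abs(best.position_cm - locus[1]))
            signs.append(best.additive > 0)
        else:
            detected.append(False)
    return RecoveryResult(detected=detected, distance_cm=distances,
                          sign_correct=signs, thresholds=thresholds)


def null_scan_type1_error(
    n_traits: int = 100,
    base_seed: int = 0,
    genome: SimGenomeSpec | None = None,
    config: CIMConfig | None = None,
) -> float:
    """Genome-wide false-positive rate of the permutation threshold.

    One genome is simulated; for each of ``n_traits`` independent pure-noise
    traits the scan is run and its own permutation threshold computed; the
    returned rate is the fraction of traits whose genome-wide maximum LOD
    exceeds that threshold (nominally alpha).
    """
    if config is None:
        config = CIMConfig(n_perm=200, seed=0)
    spec = genome or SimGenomeSpec(seed=base_seed)
    gmap, geno = simulate_dh_population(spec)
    engine = _ScanEngine(gmap, geno, walk_cm=config.walk_cm)
    rng = np.random.default_rng(base_seed + 7)
    hits = 0
    for i in range(n_traits):
        y = pd.Series(rng.normal(size=geno.shape[0]), index=geno.index,
                      name="null")
        run_cfg = CIMConfig(
            n_cofactors=config.n_cofactors, window_cm=config.window_cm,
            walk_cm=config.walk_cm, alpha=config.alpha, n_perm=config.n_perm,
            reselect_cofactors=config.reselect_cofactors,
            seed=base_seed + 13 * i + 1,
        )
        profile = cim_scan(gmap, geno, y, run_cfg, engine=engine)
        perm = permutation_threshold(gmap, geno, y, run_cfg, engine=engine)
        if profile["lod"].max() > perm.threshold_lod:
            hits += 1
    return hits / n_traits
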