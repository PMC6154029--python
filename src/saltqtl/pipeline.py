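"""Pipeline orchestration: simulate -> phenotype -> map -> scan -> validate.

A run is driven by a single configuration mapping (usually loaded from YAML)
with one section per stage plus a master seed.  Stage seeds are derived as
stable hashes of (master seed, stage name), so a rerun with the same config
and seed is byte-identical.  Every run writes a JSON manifest digesting the
configuration, derived seeds, per-stage outputs and their SHA-256 hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .field import allele_effect_report, concordance_summary
from .growth import ion_trait_table, tolerance_table
from .linkage import curate_genotypes
from .qtl import CIMConfig, assign_qtl_names, call_peaks, cim_scan, peaks_to_frame, permutation_threshold
from .simulate import (
    SimFieldSpec,
    SimGenomeSpec,
    SimGrowthSpec,
    SimQTLSpec,
    simulate_dh_population,
    simulate_field_trial,
    simulate_growth,
    simulate_trait,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "map", "scan", "validate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _mark_partial(paths: list[Path]) -> None:
    for p in paths:
        if p.exists():
            p.rename(p.with_suffix(p.suffix + ".partial"))


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {
        "config": config,
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
        "outputs": {},
        "files": {},
        "counts": {},
    }
    state: dict[str, object] = {}

    for stage in STAGES:
        section = config.get(stage, {})
        if not section or not section.get("enabled", False):
            continue
        written: list[Path] = []
        try:
            runner = globals()[f"_stage_{stage}"]
            outputs = runner(section, state, outdir,
                             stage_seed(seed, stage), written)
        except Exception as exc:
            _mark_partial(written)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["outputs"][stage] = {k: str(v) for k, v in outputs.items()}
        for p in written:
            manifest["files"][str(p)] = _sha256(p)
        if stage == "simulate" and "geno" in state:
            manifest["counts"]["lines"] = int(state["geno"].shape[0])
            manifest["counts"]["markers"] = int(state["geno"].shape[1])
        if stage == "map":
            manifest["counts"]["markers_retained"] = int(state["geno"].shape[1])
            manifest["counts"]["lines_retained"] = int(state["geno"].shape[0])
        if stage == "scan" and "peaks" in state:
            manifest["counts"]["peaks"] = int(len(state["peaks"]))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete; manifest at %s", manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(section, state, outdir, seed, written):
    genome_cfg = dict(section.get("genome", {}))
    groups = genome_cfg.pop("linkage_groups", None)
    if groups is not None:
        genome_cfg["linkage_groups"] = tuple((str(g), float(L)) for g, L in groups)
    spec = SimGenomeSpec(seed=seed, **genome_cfg)
    gmap, geno = simulate_dh_population(spec)
    state["gmap"], state["geno"] = gmap, geno
    outputs = {}
    io.write_map_csv(gmap, outdir / "map.csv")
    io.write_genotype_csv(geno, outdir / "geno.csv")
    written += [outdir / "map.csv", outdir / "geno.csv"]
    outputs["map"], outputs["geno"] = outdir / "map.csv", outdir / "geno.csv"

    trait_frames = []
    for i, tcfg in enumerate(section.get("qtl_traits", [])):
        tcfg = dict(tcfg)
        tcfg["loci"] = tuple((str(g), float(p), float(a)) for g, p, a in tcfg["loci"])
        sim = simulate_trait(gmap, geno, SimQTLSpec(seed=seed + 1 + i, **tcfg))
        trait_frames.append(sim.traits)
    if trait_frames:
        traits = pd.concat(trait_frames, ignore_index=True)
        io.write_traits_csv(traits, outdir / "sim_traits.csv")
        written.append(outdir / "sim_traits.csv")
        outputs["sim_traits"] = outdir / "sim_traits.csv"
        state["sim_traits"] = traits

    growth_cfg = dict(section.get("growth", {}))
    if growth_cfg.pop("enabled", True):
        locus = growth_cfg.pop("penalty_locus", None)
        effect = float(growth_cfg.pop("penalty_effect", 0.0))
        mean = float(growth_cfg.pop("penalty_mean", 0.85))
        penalties = {}
        if locus is not None:
            from .simulate import _nearest_marker

            marker = _nearest_marker(gmap, str(locus[0]), float(locus[1]))
            for line in geno.index:
                call = geno.loc[line, marker]
                s = 1.0 if call == "E" else -1.0
                penalties[line] = mean + effect * s
        else:
            penalties = {line: mean for line in geno.index}
        if "days" in growth_cfg:
            growth_cfg["days"] = tuple(int(d) for d in growth_cfg["days"])
        gspec = SimGrowthSpec(salt_penalty_by_line=penalties, seed=seed + 101,
                              **growth_cfg)
        growth = simulate_growth(geno, gspec)
        io.write_growth_csv(growth, outdir / "growth.csv")
        written.append(outdir / "growth.csv")
        outputs["growth"] = outdir / "growth.csv"
        state["growth"] = growth

    field_cfg = dict(section.get("field", {}))
    if field_cfg.pop("enabled", False):
        rng = np.random.default_rng(seed + 202)
        n_field_lines = int(field_cfg.pop("n_lines", 40))
        base = float(field_cfg.pop("yield_base_t_ha", 2.5))
        pct = float(field_cfg.pop("allele_effect_pct", 0.0))
        beneficial = str(field_cfg.pop("beneficial_allele", "K"))
        locus = field_cfg.pop("locus", None)
        lines = list(geno.index[:n_field_lines])
        effects = {}
        for line in lines:
            y = base
            if locus is not None and pct != 0.0:
                from .simulate import _nearest_marker

                marker = _nearest_marker(gmap, str(locus[0]), float(locus[1]))
                if geno.loc[line, marker] == beneficial:
                    y = base * (1 + pct / 100.0)
            effects[line] = {"yield_t_ha": y}
        fspec = SimFieldSpec(line_effects=effects, seed=int(rng.integers(2**31)),
                             **field_cfg)
        trial = simulate_field_trial(fspec)
        io.write_field_csv(trial, outdir / "field.csv")
        written.append(outdir / "field.csv")
        outputs["field"] = outdir / "field.csv"
        state["field"] = trial
    return outputs


def _stage_phenotype(section, state, outdir, seed, written):
    growth = state.get("growth")
    if section.get("growth"):
        growth = io.read_growth_csv(section["growth"])
    if growth is None:
        raise ValueError("no growth table available (simulate first or give a path)")
    traits = tolerance_table(
        growth,
        target_df=float(section.get("target_df", 4.0)),
        interval=tuple(section.get("interval", (1, 5))),
        ratio_method=section.get("ratio_method", "paired"),
    )
    if section.get("ions"):
        ions = pd.read_csv(section["ions"])
        traits = pd.concat([traits, ion_trait_table(ions)], ignore_index=True)
    io.write_traits_csv(traits, outdir / "traits.csv")
    written.append(outdir / "traits.csv")
    state["traits"] = traits
    return {"traits": outdir / "traits.csv"}


def _stage_map(section, state, outdir, seed, written):
    geno = io.read_genotype_csv(section["geno"]) if section.get("geno") else state["geno"]
    gmap = io.read_map_csv(section["map"]) if section.get("map") else state["gmap"]
    geno, report = curate_genotypes(
        geno, gmap,
        max_missing=float(section.get("max_missing", 0.20)),
        band=tuple(section.get("band", (0.40, 0.60))),
        alpha=float(section.get("alpha", 0.05)),
        max_crossovers=int(section.get("max_crossovers", 100)),
    )
    gmap = gmap[gmap["marker"].isin(geno.columns)].reset_index(drop=True)
    if section.get("rebuild_positions", False):
        from .linkage import build_map

        ordered = {
            g: list(sub.sort_values("pos_cm")["marker"])
            for g, sub in gmap.groupby("group", sort=False)
        }
        gmap = build_map(geno, ordered)
    state["geno"], state["gmap"] = geno, gmap
    io.write_genotype_csv(geno, outdir / "geno_curated.csv")
    io.write_map_csv(gmap, outdir / "map_curated.csv")
    report.to_json(outdir / "curation_report.json")
    written += [outdir / "geno_curated.csv", outdir / "map_curated.csv",
                outdir / "curation_report.json"]
    return {"geno": outdir / "geno_curated.csv", "map": outdir / "map_curated.csv",
            "report": outdir / "curation_report.json"}


def _stage_scan(section, state, outdir, seed, written):
    geno = io.read_genotype_csv(section["geno"]) if section.get("geno") else state["geno"]
    gmap = io.read_map_csv(section["map"]) if section.get("map") else state["gmap"]
    traits = (io.read_traits_csv(section["traits"]) if section.get("traits")
              else state["traits"])
    config = CIMConfig(
        n_cofactors=int(section.get("n_cofactors", 5)),
        window_cm=float(section.get("window_cm", 10.0)),
        walk_cm=float(section.get("walk_cm", 1.0)),
        alpha=float(section.get("alpha", 0.05)),
        n_perm=int(section.get("n_perm", 1000)),
        reselect_cofactors=bool(section.get("reselect_cofactors", True)),
        seed=seed,
    )
    trait_names = section.get("traits_to_scan") or sorted(traits["trait"].unique())
    profiles, all_peaks, thresholds = [], [], {}
    for name in trait_names:
        y = io.trait_series(traits, name)
        profile = cim_scan(gmap, geno, y, config)
        perm = permutation_threshold(gmap, geno, y, config)
        peaks = call_peaks(profile, perm.threshold_lod)
        profiles.append(profile)
        all_peaks.extend(peaks)
        thresholds[name] = perm.threshold_lod
        logger.info("trait %s: threshold %.2f, %d peak(s)",
                    name, perm.threshold_lod, len(peaks))
    try:
        assign_qtl_names(all_peaks)
    except ValueError:
        pass  # non-registry trait codes stay unnamed
    state["peaks"] = all_peaks
    profile_all = pd.concat(profiles, ignore_index=True)
    profile_all.to_csv(outdir / "scan_profile.tsv", sep="\t", index=False)
    peaks_to_frame(all_peaks).to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=2)
    written += [outdir / "scan_profile.tsv", outdir / "peaks.tsv",
                outdir / "thresholds.json"]
    return {"profile": outdir / "scan_profile.tsv", "peaks": outdir / "peaks.tsv",
            "thresholds": outdir / "thresholds.json"}


def _stage_validate(section, state, outdir, seed, written):
    trial = io.read_field_csv(section["field"]) if section.get("field") else state["field"]
    geno = io.read_genotype_csv(section["geno"]) if section.get("geno") else state["geno"]
    report = allele_effect_report(
        trial, geno,
        marker=section["marker"],
        qtl_name=section.get("qtl_name", section["marker"]),
        beneficial_allele=section.get("beneficial_allele", "E"),
        traits=tuple(section.get("traits", ("yield_t_ha",))),
        adjust=section.get("adjust", "raw"),
    )
    summary = concordance_summary(report) if not report.empty else pd.DataFrame()
    report.to_csv(outdir / "allele_effects.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    written += [outdir / "allele_effects.tsv", outdir / "concordance.tsv"]
    return {"allele_effects": outdir / "allele_effects.tsv",
            "concordance": outdir / "concordance.tsv"}
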