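"""Tests of conditional genotype probabilities, cofactor selection, the CIM
scan, permutation thresholds, peak calling and QTL naming."""

import itertools

import numpy as np
import pandas as pd
import pytest

from saltqtl.linkage import kosambi_r
from saltqtl.qtl import (
    CIMConfig,
    CompositeIntervalMapper,
    QTLPeak,
    assign_qtl_names,
    call_peaks,
    cim_scan,
    genotype_prob,
    merge_unique_qtl,
    name_qtl,
    permutation_threshold,
    select_cofactors,
)
from saltqtl.simulate import SimGenomeSpec, SimQTLSpec, effect_for_target_r2, simulate_dh_population, simulate_trait

from conftest import make_geno


def trait_series(values, lines, name="Na"):
    return pd.Series(np.asarray(values, dtype=float), index=lines, name=name)


def single_marker_lod(y, g):
    """Independent oracle: LOD of a simple regression y ~ 1 + g."""
    n = y.size
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(((y - X @ beta) ** 2).sum())
    rss_red = float(((y - y.mean()) ** 2).sum())
    return (n / 2) * np.log10(rss_red / rss_full)


class TestGenotypeProb:
    def test_at_genotyped_marker(self, tiny_map):
        geno = make_geno({"m1": ["E"], "m2": ["K"], "m3": ["E"]}, lines=["L1"])
        assert genotype_prob(tiny_map, geno, "L1", "7A", 0.0) == 1.0
        assert genotype_prob(tiny_map, geno, "L1", "7A", 10.0) == 0.0

    def test_midpoint_between_discordant_flanks(self, tiny_map):
        geno = make_geno({"m1": ["E"], "m2": ["K"], "m3": ["E"]}, lines=["L1"])
        assert genotype_prob(tiny_map, geno, "L1", "7A", 5.0) == pytest.approx(0.5)
        assert genotype_prob(tiny_map, geno, "L1", "7A", 15.0) == pytest.approx(0.5)

    def test_concordant_flanks_formula(self, tiny_map):
        # flanks both E at 10 cM each side: (1-r)^2 / ((1-r)^2 + r^2)
        geno = make_geno({"m1": ["E"], "m2": [None], "m3": ["E"]}, lines=["L1"])
        r = kosambi_r(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert genotype_prob(tiny_map, geno, "L1", "7A", 10.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.988, abs=5e-4)

    def test_all_flanks_missing_gives_half(self, tiny_map):
        geno = make_geno({"m1": [None], "m2": [None], "m3": [None]}, lines=["L1"])
        assert genotype_prob(tiny_map, geno, "L1", "7A", 10.0) == 0.5

    def test_position_outside_span_rejected(self, tiny_map):
        geno = make_geno({"m1": ["E"], "m2": ["K"], "m3": ["E"]}, lines=["L1"])
        with pytest.raises(ValueError):
            genotype_prob(tiny_map, geno, "L1", "7A", 25.0)


class TestCofactorSelection:
    def test_noiseless_causal_marker_selected_first(self, small_population):
        gmap, geno = small_population
        sim = simulate_trait(
            gmap, geno, SimQTLSpec("Na", (("7A", 30.0, 5.0),), residual_sd=0.0, seed=1)
        )
        y = trait_series(sim.traits["value"], sim.traits["line"])
        marker = sim.loci["marker"].iloc[0]
        assert select_cofactors(gmap, geno, y, k=1)[0] == marker

    def test_null_trait_selection_deterministic(self, small_population):
        gmap, geno = small_population
        rng = np.random.default_rng(5)
        y = trait_series(rng.normal(size=geno.shape[0]), geno.index)
        first = select_cofactors(gmap, geno, y, k=5)
        assert first == select_cofactors(gmap, geno, y, k=5)
        assert len(first) == 5

    def test_matches_exhaustive_forward_path(self):
        # brute-force oracle: forward path over all 3 markers at k=2
        rng = np.random.default_rng(7)
        n = 50
        calls = rng.choice(["E", "K"], size=(n, 3))
        geno = pd.DataFrame(calls, columns=["a", "b", "c"],
                            index=[f"L{i}" for i in range(n)], dtype=object)
        gmap = pd.DataFrame({"marker": ["a", "b", "c"], "group": "1A",
                             "pos_cm": [0.0, 40.0, 80.0]})
        score = np.where(calls == "E", 1.0, -1.0)
        y_vals = 2.0 * score[:, 1] + rng.normal(size=n)
        y = trait_series(y_vals, geno.index)

        def rss(cols):
            X = np.column_stack([np.ones(n)] + [score[:, j] for j in cols])
            beta, *_ = np.linalg.lstsq(X, y_vals, rcond=None)
            return float(((y_vals - X @ beta) ** 2).sum())

        first = min(range(3), key=lambda j: rss([j]))
        second = min((j for j in range(3) if j != first),
                     key=lambda j: rss([first, j]))
        expected = [["a", "b", "c"][first], ["a", "b", "c"][second]]
        assert select_cofactors(gmap, geno, y, k=2) == expected


class TestCIMScan:
    def test_zero_cofactors_equals_single_marker_regression(self):
        # oracle: simple regression LOD at every genotyped marker, 50 x 20
        spec = SimGenomeSpec(linkage_groups=(("1A", 95.0),), marker_spacing_cm=5.0,
                             n_lines=50, seed=21)
        gmap, geno = simulate_dh_population(spec)
        sim = simulate_trait(gmap, geno,
                             SimQTLSpec("Na", (("1A", 45.0, 1.0),), seed=22))
        y = trait_series(sim.traits["value"], sim.traits["line"])
        profile = cim_scan(gmap, geno, y, CIMConfig(n_cofactors=0, n_perm=20))
        score = np.where(geno.to_numpy(dtype=object) == "E", 1.0, -1.0)
        for j, (_, row) in enumerate(gmap.iterrows()):
            got = profile.loc[profile["pos_cm"] == row["pos_cm"], "lod"].iloc[0]
            assert got == pytest.approx(single_marker_lod(y.to_numpy(), score[:, j]),
                                        abs=1e-8)

    def test_constant_trait_flat_profile(self, small_population):
        gmap, geno = small_population
        y = trait_series(np.full(geno.shape[0], 3.0), geno.index)
        profile = cim_scan(gmap, geno, y, CIMConfig(n_cofactors=2, n_perm=20))
        assert np.allclose(profile["lod"], 0.0)

    def test_noiseless_additive_effect_and_label_swap(self, small_population):
        gmap, geno = small_population
        sim = simulate_trait(
            gmap, geno,
            SimQTLSpec("K", (("2B", 30.0, 10.0),), residual_sd=0.0, seed=23),
        )
        y = trait_series(sim.traits["value"], sim.traits["line"], name="K")
        marker = sim.loci["marker"].iloc[0]
        pos = gmap.set_index("marker").loc[marker, "pos_cm"]
        config = CIMConfig(n_cofactors=0, n_perm=20)
        profile = cim_scan(gmap, geno, y, config)
        at_peak = profile[(profile.group == "2B") & (profile.pos_cm == pos)]
        assert at_peak["additive"].iloc[0] == pytest.approx(10.0, abs=1e-8)
        swapped = geno.replace({"E": "K", "K": "E"})
        profile2 = cim_scan(gmap, swapped, y, config)
        assert np.allclose(profile2["additive"], -profile["additive"], atol=1e-8)
        finite = np.isfinite(profile["lod"])
        assert np.allclose(profile2["lod"][finite], profile["lod"][finite], atol=1e-6)

    def test_lod_invariant_under_affine_trait_transform(self, small_population):
        gmap, geno = small_population
        sim = simulate_trait(gmap, geno,
                             SimQTLSpec("Na", (("7A", 20.0, 1.0),), seed=24))
        y = trait_series(sim.traits["value"], sim.traits["line"])
        config = CIMConfig(n_cofactors=3, n_perm=20)
        p1 = cim_scan(gmap, geno, y, config)
        p2 = cim_scan(gmap, geno, 3.0 * y + 100.0, config)
        assert np.allclose(p1["lod"], p2["lod"], atol=1e-8)
        assert np.allclose(3.0 * p1["additive"], p2["additive"], atol=1e-8)

    def test_walk_covers_groups_inclusively(self, small_population):
        gmap, geno = small_population
        y = trait_series(np.arange(geno.shape[0], dtype=float), geno.index)
        profile = cim_scan(gmap, geno, y, CIMConfig(n_cofactors=0, n_perm=20))
        for group, sub in profile.groupby("group"):
            assert sub["pos_cm"].min() == 0.0
            assert sub["pos_cm"].max() == 60.0
            assert np.all(np.diff(np.sort(sub["pos_cm"])) <= 1.0 + 1e-9)


class TestPermutationThreshold:
    def test_same_seed_reproducible(self, small_population):
        gmap, geno = small_population
        rng = np.random.default_rng(31)
        y = trait_series(rng.normal(size=geno.shape[0]), geno.index)
        config = CIMConfig(n_cofactors=2, n_perm=50, seed=7)
        t1 = permutation_threshold(gmap, geno, y, config)
        t2 = permutation_threshold(gmap, geno, y, config)
        assert t1.threshold_lod == t2.threshold_lod
        assert np.array_equal(t1.max_lods, t2.max_lods)

    def test_alpha_one_is_sample_minimum(self, small_population):
        gmap, geno = small_population
        rng = np.random.default_rng(32)
        y = trait_series(rng.normal(size=geno.shape[0]), geno.index)
        config = CIMConfig(n_cofactors=2, n_perm=30, alpha=1.0, seed=8)
        t = permutation_threshold(gmap, geno, y, config)
        assert t.threshold_lod == pytest.approx(t.max_lods.min())

    def test_too_few_permutations_rejected(self, small_population):
        gmap, geno = small_population
        y = trait_series(np.arange(geno.shape[0], dtype=float), geno.index)
        with pytest.raises(ValueError):
            permutation_threshold(gmap, geno, y, CIMConfig(n_perm=10))


class TestPeakCalling:
    @staticmethod
    def toy_profile(lods, group="7A", trait="Na"):
        return pd.DataFrame(
            {"trait": trait, "group": group,
             "pos_cm": np.arange(len(lods), dtype=float),
             "lod": np.asarray(lods, dtype=float),
             "additive": np.ones(len(lods)), "r2": np.ones(len(lods))}
        )

    def test_hand_enumerated_toy_vector(self):
        # [1, 2, 5, 4, 4.2, 1] at 0..5 cM, threshold 3: single peak at 2 cM
        # (the 4.2 shoulder merges into the main peak); LOD stays within both
        # 1 and 2 of the maximum exactly over positions 2..4
        peaks = call_peaks(self.toy_profile([1, 2, 5, 4, 4.2, 1]), threshold=3.0)
        assert len(peaks) == 1
        assert peaks[0].position_cm == 2.0
        assert peaks[0].support_1lod == (2.0, 4.0)
        assert peaks[0].support_2lod == (2.0, 4.0)

    def test_all_below_threshold_empty(self):
        assert call_peaks(self.toy_profile([1, 2, 1]), threshold=3.0) == []

    def test_support_contains_peak_and_nests(self, small_population):
        gmap, geno = small_population
        sim = simulate_trait(
            gmap, geno,
            SimQTLSpec("Na", (("7A", 30.0, effect_for_target_r2(0.3)),), seed=41),
        )
        y = trait_series(sim.traits["value"], sim.traits["line"])
        profile = cim_scan(gmap, geno, y, CIMConfig(n_cofactors=0, n_perm=20))
        peaks = call_peaks(profile, threshold=3.0)
        assert peaks
        for p in peaks:
            lo1, hi1 = p.support_1lod
            lo2, hi2 = p.support_2lod
            assert lo2 <= lo1 <= p.position_cm <= hi1 <= hi2

    def test_nearby_maxima_merged_distant_kept(self):
        lods = np.ones(40)
        lods[10] = 5.0
        lods[20] = 6.0  # 10 cM away: merged, higher wins
        peaks = call_peaks(self.toy_profile(lods), threshold=3.0)
        assert [p.position_cm for p in peaks] == [20.0]
        lods2 = np.ones(40)
        lods2[5] = 5.0
        lods2[25] = 6.0  # 20 cM away: both reported
        peaks2 = call_peaks(self.toy_profile(lods2), threshold=3.0)
        assert [p.position_cm for p in peaks2] == [5.0, 25.0]


class TestUniqueLociAndNames:
    @staticmethod
    def peak(trait, group, pos):
        return QTLPeak(trait=trait, group=group, position_cm=pos, lod=5.0,
                       additive=1.0, r_squared=10.0, support_1lod=(pos - 1, pos + 1),
                       support_2lod=(pos - 2, pos + 2))

    def test_within_15cm_single_locus(self):
        clusters = merge_unique_qtl([self.peak("Na", "7A", 10.0),
                                     self.peak("K", "7A", 20.0)])
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_beyond_15cm_two_loci(self):
        clusters = merge_unique_qtl([self.peak("Na", "7A", 10.0),
                                     self.peak("K", "7A", 30.0)])
        assert len(clusters) == 2

    def test_fifteen_detections_at_ten_loci(self):
        # population-level shape: 15 peaks across traits clustering into 10
        # unique loci (five co-locating pairs plus five isolated peaks)
        peaks = []
        positions = {
            "1A": [(100.0, "Na"), (112.0, "Na_K")],
            "2B": [(52.6, "K"), (87.8, "K"), (90.0, "Na_K")],
            "5A": [(125.5, "K"), (126.2, "CRGR"), (172.2, "Na_K")],
            "6A": [(0.0, "Na_K"), (29.9, "Na"), (80.3, "K_Na"), (85.0, "K")],
            "7A": [(39.3, "Na_K"), (99.4, "CRGR"), (112.3, "G_1_5")],
        }
        for group, entries in positions.items():
            for pos, trait in entries:
                peaks.append(self.peak(trait, group, pos))
        clusters = merge_unique_qtl(peaks)
        assert len(peaks) == 15
        assert len(clusters) == 10
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]

    def test_wheat_format_names(self):
        assert name_qtl("Na", "7A") == "QNa.asl-7A"
        assert name_qtl("K", "2B", ordinal=1) == "QK.asl-2B.1"
        assert name_qtl("G_1_5", "7A") == "QG_(1–5).asl-7A"
        with pytest.raises(ValueError):
            name_qtl("Yield", "2B")

    def test_ordinals_only_when_shared(self):
        peaks = [self.peak("K", "2B", 52.6), self.peak("K", "2B", 87.8),
                 self.peak("Na", "7A", 75.0)]
        assign_qtl_names(peaks)
        assert {p.name for p in peaks} == {"QK.asl-2B.1", "QK.asl-2B.2", "QNa.asl-7A"}


class TestEstimator:
    def test_fit_exposes_profile_threshold_and_peaks(self, small_population):
        gmap, geno = small_population
        sim = simulate_trait(
            gmap, geno,
            SimQTLSpec("Na", (("7A", 30.0, effect_for_target_r2(0.25)),), seed=51),
        )
        y = trait_series(sim.traits["value"], sim.traits["line"], name="Na")
        mapper = CompositeIntervalMapper(
            genetic_map=gmap, n_cofactors=3, n_perm=60, random_state=1
        )
        mapper.fit(geno, y)
        assert mapper.n_lines_ == geno.shape[0]
        assert len(mapper.cofactors_) == 3
        assert mapper.threshold_lod_ > 0
        assert mapper.peaks_ and mapper.peaks_[0].group == "7A"
        assert mapper.peaks_[0].name.startswith("QNa.asl-7A")
        params = mapper.get_params()
        assert params["n_cofactors"] == 3 and params["window_cm"] == 10.0
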