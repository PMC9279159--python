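from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bridgemap as bm
from bridgemap.epicompare import Bin, _grid_bin
from conftest import make_fixture
from oracles import fisher_two_sided_exact


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


class TestBinRegions:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (10_000, 10),   # exact tiling
            (10_400, 10),   # 400 bp remainder < half bin: dropped
            (10_600, 11),   # 600 bp remainder >= half bin: kept
        ],
    )
    def test_partial_terminal_bin_rule(self, length, expected):
        region = bm.GenomicInterval("chr1", 0, length, "r")
        bins = bm.bin_regions([region], 1000)
        assert len(bins) == expected
        assert bins[0].region_name == "r"

    def test_region_shorter_than_half_bin_yields_no_bins(self):
        region = bm.GenomicInterval("chr1", 0, 400)
        assert bm.bin_regions([region], 1000) == []

    def test_bins_tile_the_region_contiguously(self):
        region = bm.GenomicInterval("chr1", 500, 5_100)
        bins = bm.bin_regions([region], 1000)
        assert bins[0].start == 500
        assert all(b.end - b.start == 1000 for b in bins[:-1])
        assert all(a.end == b.start for a, b in zip(bins, bins[1:]))
        assert bins[-1].end == 5_100  # 600 bp terminal bin kept

    def test_non_positive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            bm.bin_regions([bm.GenomicInterval("chr1", 0, 1000)], 0)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def _track_from_bin_values(assembly, values, bin_size=10):
    records = [
        ("chr1", i * bin_size, (i + 1) * bin_size, float(v))
        for i, v in enumerate(values)
    ]
    return bm.SignalTrack(assembly, records)


class TestQuantileTransform:
    def test_distinct_values_get_rank_over_n(self, assembly_a):
        track = _track_from_bin_values(assembly_a, [1, 2, 3, 4])
        bins = [Bin("chr1", i * 10, (i + 1) * 10) for i in range(4)]
        np.testing.assert_allclose(
            bm.quantile_transform(track, bins), [0.25, 0.5, 0.75, 1.0]
        )

    def test_ties_share_the_mean_rank(self, assembly_a):
        track = _track_from_bin_values(assembly_a, [5, 5, 1, 9])
        bins = [Bin("chr1", i * 10, (i + 1) * 10) for i in range(4)]
        np.testing.assert_allclose(
            bm.quantile_transform(track, bins), [0.625, 0.625, 0.25, 1.0]
        )

    def test_all_zero_track_is_all_tied_at_the_minimum(self, assembly_a):
        track = bm.SignalTrack(assembly_a, [])
        bins = [Bin("chr1", i * 10, (i + 1) * 10) for i in range(5)]
        q = bm.quantile_transform(track, bins)
        assert np.all(q == q[0])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=40),
    )
    def test_invariant_under_strictly_monotone_transform(self, values):
        assembly = bm.GenomeAssembly("s", {"chr1": 10_000})
        bins = [Bin("chr1", i * 10, (i + 1) * 10) for i in range(len(values))]
        raw = _track_from_bin_values(assembly, values)
        squared = _track_from_bin_values(assembly, [v * v + 1 for v in values])
        np.testing.assert_allclose(
            bm.quantile_transform(raw, bins), bm.quantile_transform(squared, bins)
        )


# ---------------------------------------------------------------------------
# bin comparison
# ---------------------------------------------------------------------------


class TestCompareBins:
    def test_mutually_enriched_pair(self):
        category, ratio, amplitude = bm.compare_bins(0.9, 0.9)
        assert category == "mutually-enriched"
        assert ratio == 0.0
        assert amplitude == pytest.approx(0.9 ** 10)
        assert amplitude == pytest.approx(0.3487, abs=5e-5)

    def test_source_specific_ratio_capped_at_one(self):
        category, ratio, _ = bm.compare_bins(0.99, 0.01)
        assert category == "source-specific"
        assert ratio == 1.0  # log2(0.99/0.01) = 6.6, capped

    def test_neither_when_both_below_threshold(self):
        category, ratio, amplitude = bm.compare_bins(0.2, 0.2)
        assert category == "neither"
        assert amplitude == pytest.approx(0.2 ** 10)

    def test_target_specific(self):
        category, ratio, _ = bm.compare_bins(0.1, 0.95)
        assert category == "target-specific"
        assert ratio == -1.0

    def test_quantile_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bm.compare_bins(1.5, 0.5)

    @settings(deadline=None, max_examples=200)
    @given(
        q1=st.floats(0, 1), q2=st.floats(0, 1),
        enrich_q=st.floats(0.05, 0.95),
    )
    def test_swapping_species_mirrors_category_and_negates_ratio(
        self, q1, q2, enrich_q
    ):
        cat_ab, ratio_ab, amp_ab = bm.compare_bins(q1, q2, enrich_q)
        cat_ba, ratio_ba, amp_ba = bm.compare_bins(q2, q1, enrich_q)
        mirrored = {
            "source-specific": "target-specific",
            "target-specific": "source-specific",
        }
        assert cat_ba == mirrored.get(cat_ab, cat_ab)
        assert ratio_ba == pytest.approx(-ratio_ab, abs=1e-12)
        assert amp_ba == amp_ab
        assert (cat_ab == "mutually-enriched") == (q1 >= enrich_q and q2 >= enrich_q)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_matches_enumeration_oracle_on_an_unbalanced_table(self):
        result = bm.fisher_exact_2x2(10, 2, 3, 9)
        assert result.p_value == pytest.approx(
            fisher_two_sided_exact(10, 2, 3, 9), rel=1e-12
        )
        assert result.odds_ratio == pytest.approx(10 * 9 / (2 * 3))

    def test_perfect_independence(self):
        result = bm.fisher_exact_2x2(5, 5, 5, 5)
        assert result.p_value == 1.0
        assert result.odds_ratio == 1.0
        assert not result.degenerate

    def test_p_strictly_decreases_along_the_diagonal(self):
        previous = 2.0
        for n in range(1, 8):
            p = bm.fisher_exact_2x2(n, 0, 0, n).p_value
            assert p < previous
            previous = p

    def test_infinite_and_undefined_odds_ratios(self):
        assert bm.fisher_exact_2x2(5, 0, 0, 5).odds_ratio == math.inf
        assert math.isnan(bm.fisher_exact_2x2(0, 3, 0, 4).odds_ratio)

    def test_empty_margin_flagged_degenerate(self):
        assert bm.fisher_exact_2x2(0, 0, 3, 4).degenerate

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            bm.fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            bm.fisher_exact_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# region comparison end to end
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_comparison():
    """Dense-anchor two-species fixture with planted signal domains."""
    fixture = make_fixture(seed=11, n_species=2, default_density=0.5,
                           master_length=500_000, scale_jitter_sd=0.05)
    # per-species enriched coverage is kept above the 20% implied by the
    # 0.8 enrichment quantile, so in the high-SNR limit every background
    # bin ranks below the threshold in both species
    domains = (
        bm.PlantedDomain(60_000, 90_000, "shared"),
        bm.PlantedDomain(150_000, 180_000, "shared"),
        bm.PlantedDomain(250_000, 300_000, "source-specific"),
        bm.PlantedDomain(350_000, 400_000, "target-specific"),
    )
    signal_config = bm.SignalConfig("zeb", "bri", domains=domains, snr=8.0)
    sim = bm.simulate_signal(signal_config, fixture.truth, seed=42,
                             assemblies=fixture.assemblies)
    graph = fixture.graph()
    length = fixture.assemblies["zeb"].chrom_lengths["chr1"]
    regions = [bm.GenomicInterval("chr1", 0, length, "tad")]
    comparisons, summary = bm.compare_regions(
        regions, sim.source_track, sim.target_track, graph, "zeb", "bri"
    )
    return fixture, sim, comparisons, summary


class TestCompareRegionsExact:
    """Grid-aligned deterministic fixture: categories recovered exactly.

    Two species of equal size with jitter-free identity-like anchors; the
    planted domains align with the 1-kb bin grid and per-species enriched
    coverage is exactly the top quintile (5 of 25 bins at enrich_q 0.8),
    so every bin's category follows from the construction.
    """

    @staticmethod
    @pytest.fixture(scope="class")
    def exact():
        n_bins = 25
        length = n_bins * 1000
        assembly_a = bm.GenomeAssembly("a", {"chr1": length})
        assembly_b = bm.GenomeAssembly("b", {"chr1": length})
        blocks = [
            bm.AnchorBlock("chr1", p, p + 100, "chr1", p, p + 100, "+")
            for p in range(0, length, 1000)
        ] + [bm.AnchorBlock("chr1", length - 100, length,
                            "chr1", length - 100, length, "+")]
        aset = bm.AnchorSet(assembly_a, assembly_b, blocks)
        graph = bm.SpeciesGraph([assembly_a, assembly_b])
        graph.add_anchor_set(aset)
        # bins 5-7 shared, 10-11 source-specific, 15-16 target-specific:
        # exactly 5 enriched bins per species
        shared, src_only, tgt_only = {5, 6, 7}, {10, 11}, {15, 16}
        def track(assembly, enriched_bins):
            return bm.SignalTrack(assembly, [
                ("chr1", i * 1000, (i + 1) * 1000,
                 100.0 if i in enriched_bins else 1.0)
                for i in range(n_bins)
            ])
        track_a = track(assembly_a, shared | src_only)
        track_b = track(assembly_b, shared | tgt_only)
        regions = [bm.GenomicInterval("chr1", 0, length, "r")]
        comparisons, summary = bm.compare_regions(
            regions, track_a, track_b, graph, "a", "b", direct_anchor_set=aset
        )
        return shared, src_only, tgt_only, comparisons, summary

    def test_exactly_the_planted_bins_get_each_category(self, exact):
        shared, src_only, tgt_only, comparisons, _ = exact
        expected = {}
        for i in shared:
            expected[i] = "mutually-enriched"
        for i in src_only:
            expected[i] = "source-specific"
        for i in tgt_only:
            expected[i] = "target-specific"
        for idx, c in enumerate(comparisons):
            assert c.category == expected.get(idx, "neither")

    def test_shared_fraction_summary_matches_construction(self, exact):
        shared, _, _, comparisons, summary = exact
        assert summary["r"] == pytest.approx(len(shared) / len(comparisons))


class TestCompareRegions:
    def test_planted_shared_domains_are_mostly_mutually_enriched(
        self, planted_comparison
    ):
        fixture, sim, comparisons, _ = planted_comparison
        cats = [
            c.category for c in comparisons
            if c.category != "unprojectable"
            and sim.domain_kind_at(c.source_bin.center) == "shared"
        ]
        assert cats
        # per-species enriched coverage (22%) slightly exceeds the top
        # quintile, so a small band of shared bins ranks below 0.8 in one
        # species; the bulk must still be recovered
        assert sum(c == "mutually-enriched" for c in cats) / len(cats) >= 0.85

    def test_species_specific_domains_are_never_mutually_enriched(
        self, planted_comparison
    ):
        fixture, sim, comparisons, _ = planted_comparison
        by_kind = {"source-specific": [], "target-specific": []}
        for c in comparisons:
            if c.category == "unprojectable":
                continue
            kind = sim.domain_kind_at(c.source_bin.center)
            if kind in by_kind:
                by_kind[kind].append(c.category)
        opposite = {"source-specific": "target-specific",
                    "target-specific": "source-specific"}
        for kind, cats in by_kind.items():
            assert cats, f"no bins for {kind}"
            # enriched coverage >= 20% per species keeps every background
            # bin below the threshold, so the inactive species can never
            # co-report enrichment
            assert "mutually-enriched" not in cats
            assert opposite[kind] not in cats
            assert sum(cat == kind for cat in cats) / len(cats) >= 0.7

    def test_summary_reports_shared_fraction(self, planted_comparison):
        fixture, sim, comparisons, summary = planted_comparison
        projectable = [c for c in comparisons if c.category != "unprojectable"]
        shared = sum(c.category == "mutually-enriched" for c in projectable)
        assert summary["tad"] == pytest.approx(shared / len(projectable))

    def test_identity_comparison_is_symmetric_with_zero_ratios(self):
        # one species compared against itself through identity anchors
        assembly = bm.GenomeAssembly("same", {"chr1": 50_000})
        blocks = [
            bm.AnchorBlock("chr1", p, p + 100, "chr1", p, p + 100, "+")
            for p in range(0, 50_000, 2_000)
        ]
        aset = bm.AnchorSet(assembly, assembly, blocks)
        graph = bm.SpeciesGraph([assembly])
        graph.edges[("same", "same")] = aset
        rng = np.random.default_rng(7)
        records = [
            ("chr1", s, s + 100, float(v))
            for s, v in zip(range(0, 50_000, 100),
                            rng.poisson(5, size=500))
        ]
        track = bm.SignalTrack(assembly, records)
        regions = [bm.GenomicInterval("chr1", 0, 50_000, "r")]
        comparisons, _ = bm.compare_regions(
            regions, track, track, graph, "same", "same", direct_anchor_set=aset
        )
        assert comparisons
        for c in comparisons:
            assert c.category in ("mutually-enriched", "neither")
            assert c.ratio == 0.0

    def test_no_planted_domains_gives_chance_level_co_enrichment(self):
        # with pure noise, thresholding quantiles at 0.8 marks ~20% of bins
        # per species; mutual enrichment is the ~4% binomial coincidence
        fixture = make_fixture(seed=19, n_species=2, default_density=0.5,
                               master_length=500_000)
        sim = bm.simulate_signal(bm.SignalConfig("zeb", "bri"), fixture.truth,
                                 seed=3, assemblies=fixture.assemblies)
        graph = fixture.graph()
        length = fixture.assemblies["zeb"].chrom_lengths["chr1"]
        regions = [bm.GenomicInterval("chr1", 0, length, "r")]
        comparisons, _ = bm.compare_regions(
            regions, sim.source_track, sim.target_track, graph, "zeb", "bri"
        )
        usable = [c for c in comparisons if c.category != "unprojectable"]
        enriched_src = sum(c.q_source >= 0.8 for c in usable) / len(usable)
        mutual = sum(c.category == "mutually-enriched" for c in usable) / len(usable)
        assert enriched_src == pytest.approx(0.2, abs=0.05)
        assert mutual == pytest.approx(0.04, abs=0.03)

    def test_zero_target_track_gives_no_mutual_enrichment(self):
        fixture = make_fixture(seed=13, n_species=2, default_density=0.5,
                               master_length=100_000)
        graph = fixture.graph()
        rng = np.random.default_rng(1)
        zeb_len = fixture.assemblies["zeb"].chrom_lengths["chr1"]
        records = [
            ("chr1", s, min(s + 100, zeb_len), float(v))
            for s, v in zip(range(0, zeb_len, 100),
                            rng.poisson(5, size=zeb_len // 100 + 1))
        ]
        source_track = bm.SignalTrack(fixture.assemblies["zeb"], records)
        target_track = bm.SignalTrack(fixture.assemblies["bri"], [])
        regions = [bm.GenomicInterval("chr1", 0, zeb_len, "r")]
        comparisons, _ = bm.compare_regions(
            regions, source_track, target_track, graph, "zeb", "bri"
        )
        # all target quantiles tied at the maximum tie-rank of an all-zero
        # distribution; no bin can show *mutual* enrichment asymmetry —
        # mutual enrichment requires genuine target signal above threshold
        assert all(
            c.category != "mutually-enriched" or c.q_target == c.q_source
            for c in comparisons
        )


class TestGridBin:
    def test_projected_point_falls_in_its_fixed_grid_window(self):
        assert _grid_bin(2_944, 1000, 20_000) == (2_000, 3_000)
        assert _grid_bin(999, 1000, 20_000) == (0, 1_000)
        assert _grid_bin(19_999, 1000, 20_000) == (19_000, 20_000)


# ---------------------------------------------------------------------------
# enrichment contrasts
# ---------------------------------------------------------------------------


def _make_comparison(alignable: bool, shared: bool) -> bm.BinComparison:
    return bm.BinComparison(
        Bin("chr1", 0, 1000), "chr1", 0, 1000, 0.5, 0.5,
        "mutually-enriched" if shared else "neither",
        0.0, 0.0, alignable, 1.0,
    )


class TestSharedEnrichmentByAlignability:
    def test_independent_planting_controls_type_I_error(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_datasets = 200
        for _ in range(n_datasets):
            comps = [
                _make_comparison(bool(rng.random() < 0.3),
                                 bool(rng.random() < 0.2))
                for _ in range(150)
            ]
            result = bm.shared_enrichment_by_alignability(comps)
            rejections += result.p_value < 0.05
        # Fisher is conservative; the rejection rate must not exceed the
        # nominal level by more than binomial noise (3 sigma ~ 0.046)
        assert rejections / n_datasets <= 0.05 + 0.05

    def test_shared_signal_planted_on_anchors_gives_positive_association(self):
        comps = (
            [_make_comparison(True, True) for _ in range(30)]
            + [_make_comparison(True, False) for _ in range(10)]
            + [_make_comparison(False, True) for _ in range(10)]
            + [_make_comparison(False, False) for _ in range(30)]
        )
        result = bm.shared_enrichment_by_alignability(comps)
        assert result.odds_ratio > 1
        assert result.p_value < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bm.shared_enrichment_by_alignability([])


class TestEnsembleEnrichment:
    @staticmethod
    @pytest.fixture(scope="class")
    def ensemble_setup():
        fixture = make_fixture(seed=17, n_species=2, default_density=0.5,
                               master_length=400_000, scale_jitter_sd=0.05)
        ensembles_master = [(50_000, 90_000), (200_000, 240_000)]
        ensembles = [
            bm.GenomicInterval(
                "chr1",
                int(fixture.truth.forward("zeb", lo)),
                int(fixture.truth.forward("zeb", hi)),
                f"ens{i}",
            )
            for i, (lo, hi) in enumerate(ensembles_master)
        ]
        return fixture, ensembles_master, ensembles

    def test_signal_planted_inside_ensembles_is_detected(self, ensemble_setup):
        fixture, master, ensembles = ensemble_setup
        domains = tuple(
            bm.PlantedDomain(lo, hi, "target-specific") for lo, hi in master
        )
        sim = bm.simulate_signal(
            bm.SignalConfig("zeb", "bri", domains=domains, snr=8.0),
            fixture.truth, seed=5, assemblies=fixture.assemblies,
        )
        result = bm.ensemble_enrichment(
            ensembles, sim.target_track, fixture.graph(), "zeb", "bri"
        )
        assert result.odds_ratio > 1
        assert result.p_value < 1e-6

    def test_uniform_signal_shows_no_association(self, ensemble_setup):
        fixture, master, ensembles = ensemble_setup
        sim = bm.simulate_signal(
            bm.SignalConfig("zeb", "bri"), fixture.truth, seed=6,
            assemblies=fixture.assemblies,
        )
        result = bm.ensemble_enrichment(
            ensembles, sim.target_track, fixture.graph(), "zeb", "bri"
        )
        assert result.p_value > 0.01

    def test_enrichment_quantile_one_is_degenerate(self, ensemble_setup):
        fixture, master, ensembles = ensemble_setup
        sim = bm.simulate_signal(
            bm.SignalConfig("zeb", "bri"), fixture.truth, seed=8,
            assemblies=fixture.assemblies,
        )
        result = bm.ensemble_enrichment(
            ensembles, sim.target_track, fixture.graph(), "zeb", "bri",
            enrich_q=1.1,
        )
        assert result.degenerate

    def test_unprojectable_ensembles_rejected(self, two_block_set, assembly_a,
                                              assembly_b):
        graph = bm.SpeciesGraph([assembly_a, assembly_b])
        graph.add_anchor_set(two_block_set)
        track = bm.SignalTrack(assembly_b, [])
        with pytest.raises(ValueError, match="projected"):
            bm.ensemble_enrichment(
                [bm.GenomicInterval("chr2", 0, 1000)], track, graph,
                "specA", "specB",
            )
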