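"""Tests for variant-table analytics, coverage ratios and the HGT read rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexistevo.synthetic_data import SynthConfig, gen_coverage, gen_reads
from coexistevo.variant_analysis import (
    CoverageProfile,
    SimpleRead,
    VariantTable,
    classify_hgt_variant,
    convergent_targets,
    count_events,
    dn_ds,
    element_presence_frequency,
    elapsed_generations,
    filter_ancestral_false_positives,
    find_sweeps,
    hgt_tract_extent,
    mutation_rate,
    parallel_targets,
    round_half_away,
)


class TestElapsedGenerations:
    @pytest.mark.parametrize("days, expected", [(88, 1584), (43, 774), (0, 0)])
    def test_gut_generation_conversion(self, days, expected):
        assert elapsed_generations(days) == expected

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            elapsed_generations(-1)


class TestAncestralFilter:
    def test_blacklisted_site_removed(self, variant_factory):
        anc = variant_factory([{"position": 100, "frequency": 0.02, "supporting_reads": 4}])
        ev = variant_factory([{"position": 100}, {"position": 200}])
        kept = filter_ancestral_false_positives(ev, anc)
        assert kept.data["position"].tolist() == [200]

    @pytest.mark.parametrize(
        "freq, reads",
        [(0.015, 4), (0.02, 3), (0.015, 3)],
    )
    def test_strict_inequalities_keep_variant(self, variant_factory, freq, reads):
        # frequency must be ABOVE 0.015 and reads MORE THAN 3 to blacklist
        anc = variant_factory(
            [{"position": 100, "frequency": freq, "supporting_reads": reads}]
        )
        ev = variant_factory([{"position": 100}])
        assert len(filter_ancestral_false_positives(ev, anc)) == 1

    def test_consensus_mode_calls_always_blacklisted(self, variant_factory):
        anc = variant_factory([{"position": 100, "frequency": 0.001, "supporting_reads": 1}])
        anc.data["mode"] = "consensus"
        ev = variant_factory([{"position": 100}])
        assert len(filter_ancestral_false_positives(ev, anc)) == 0

    def test_empty_ancestral_is_identity(self, variant_factory):
        ev = variant_factory([{"position": 1}, {"position": 2}])
        anc = VariantTable(ev.data.iloc[:0])
        out = filter_ancestral_false_positives(ev, anc)
        pd.testing.assert_frame_equal(out.data, ev.data)

    def test_idempotent(self, variant_factory):
        anc = variant_factory([{"position": 100, "frequency": 0.5, "supporting_reads": 50}])
        ev = variant_factory([{"position": 100}, {"position": 300}])
        once = filter_ancestral_false_positives(ev, anc)
        twice = filter_ancestral_false_positives(once, anc)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestCountEvents:
    def test_strain_b1_breakdown(self, variant_factory):
        rows = (
            [{"var_class": "SNP_NS"}] * 34
            + [{"var_class": "SNP_S"}] * 4
            + [{"var_class": "SNP_intergenic"}] * 16
            + [{"var_class": "IS_insertion"}] * 8
            + [{"var_class": "small_indel"}] * 9
            + [{"var_class": "large_deletion"}] * 11
        )
        counts = count_events(variant_factory(rows), n_mice=8)
        assert counts["total"] == 82
        assert counts["by_class"]["SNP_NS"] == 34
        assert counts["mean_per_mouse"] == 10.3  # 82/8 = 10.25, half away from zero

    def test_strain_a_breakdown(self, variant_factory):
        rows = (
            [{"var_class": "SNP_NS"}] * 13
            + [{"var_class": "IS_insertion"}] * 11
            + [{"var_class": "small_indel"}] * 5
            + [{"var_class": "large_deletion"}] * 9
        )
        counts = count_events(variant_factory(rows), n_mice=8)
        assert counts["total"] == 38
        assert counts["mean_per_mouse"] == 4.8  # 38/8 = 4.75

    def test_empty_table_all_zero(self, variant_factory):
        table = VariantTable(variant_factory([{}]).data.iloc[:0])
        counts = count_events(table)
        assert counts["total"] == 0
        assert all(v == 0 for v in counts["by_class"].values())

    def test_totals_additive_across_mice(self, variant_factory):
        t1 = count_events(variant_factory([{"mouse": 1}] * 3 + [{"mouse": 2}] * 5))
        assert t1["total"] == 8
        assert t1["per_mouse"] == {1: 3, 2: 5}


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(10.25, 1, 10.3), (4.75, 1, 4.8), (-10.25, 1, -10.3), (0.225, 2, 0.23)],
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestDnDs:
    def test_printed_count_ratio(self, variant_factory):
        rows = [{"var_class": "SNP_NS"}] * 34 + [{"var_class": "SNP_S"}] * 4
        ratio, defined = dn_ds(variant_factory(rows))
        assert defined and ratio == pytest.approx(8.5)

    def test_zero_synonymous_undefined(self, variant_factory):
        ratio, defined = dn_ds(variant_factory([{"var_class": "SNP_NS"}] * 10))
        assert not defined and math.isnan(ratio)

    def test_equal_counts(self, variant_factory):
        rows = [{"var_class": "SNP_NS"}] * 5 + [{"var_class": "SNP_S"}] * 5
        assert dn_ds(variant_factory(rows))[0] == pytest.approx(1.0)


class TestFindSweeps:
    def test_strict_threshold_and_fixed_flag(self, variant_factory):
        table = variant_factory(
            [
                {"frequency": 0.96, "mouse": 1},
                {"frequency": 0.95, "mouse": 1},
                {"frequency": 1.0, "mouse": 2},
                {"frequency": 0.50, "mouse": 2},
            ]
        )
        hits = find_sweeps(table)
        assert len(hits) == 2
        assert hits["frequency"].tolist() == [0.96, 1.0]
        assert hits["fixed"].tolist() == [False, True]


class TestParallelism:
    def test_gene_level_parallelism_counts_mice(self, variant_factory):
        table = variant_factory(
            [
                {"target": "frlR", "mouse": 1, "position": 10},
                {"target": "frlR", "mouse": 3, "position": 20},
                {"target": "frlR", "mouse": 5, "position": 30},
                {"target": "unique1", "mouse": 1, "position": 40},
            ]
        )
        res = parallel_targets(table)
        assert res["target"].tolist() == ["frlR"]
        assert res["n_mice"].tolist() == [3]
        assert res["level"].tolist() == ["gene"]

    def test_identical_change_is_mutation_level(self, variant_factory):
        table = variant_factory(
            [
                {"target": "fimE", "mouse": 2, "position": 500},
                {"target": "fimE", "mouse": 4, "position": 500},
            ]
        )
        res = parallel_targets(table)
        assert res["level"].tolist() == ["mutation"]

    def test_all_unique_targets_empty(self, variant_factory):
        table = variant_factory(
            [{"target": "a", "mouse": 1}, {"target": "b", "mouse": 2}]
        )
        assert len(parallel_targets(table)) == 0

    def test_single_mouse_rejected(self, variant_factory):
        with pytest.raises(ValueError):
            parallel_targets(variant_factory([{"mouse": 1}, {"mouse": 1}]))

    def test_ordering_by_mouse_count_then_name(self, variant_factory):
        table = variant_factory(
            [
                {"target": "zzz", "mouse": m, "position": 10 * m} for m in (1, 2, 3)
            ]
            + [{"target": "aaa", "mouse": m, "position": 100 + m} for m in (1, 2)]
            + [{"target": "bbb", "mouse": m, "position": 200 + m} for m in (1, 2)]
        )
        res = parallel_targets(table)
        assert res["target"].tolist() == ["zzz", "aaa", "bbb"]


class TestConvergence:
    def test_shared_gene_detected(self, variant_factory):
        a = variant_factory([{"target": "fimH", "strain": "A", "mouse": 1}])
        b = variant_factory([{"target": "fimH", "strain": "B1", "mouse": 1}])
        res = convergent_targets(a, b)
        assert res["name"].tolist() == ["fimH"]
        assert res["level"].tolist() == ["gene"]
        assert res["same_mouse"].tolist() == [True]

    def test_pathway_level_convergence(self, variant_factory):
        a = variant_factory([{"target": "barA", "mouse": 2}])
        b = variant_factory([{"target": "uvrY", "mouse": 5}])
        res = convergent_targets(a, b, {"barA": "BarA/UvrY", "uvrY": "BarA/UvrY"})
        assert res["name"].tolist() == ["BarA/UvrY"]
        assert res["level"].tolist() == ["pathway"]
        assert res["same_mouse"].tolist() == [False]

    def test_disjoint_targets_empty(self, variant_factory):
        a = variant_factory([{"target": "x"}])
        b = variant_factory([{"target": "y"}])
        assert len(convergent_targets(a, b)) == 0


class TestMutationRate:
    def test_single_unit_frequency(self, variant_factory):
        rate = mutation_rate(variant_factory([{"frequency": 1.0}]), generations=1584)
        assert rate.mean == pytest.approx(1 / 1584)
        assert rate.mean == pytest.approx(6.313e-4, rel=1e-3)

    def test_printed_scale_b1(self, variant_factory):
        # frequency sum 2.851 over 1584 generations lands on the resident
        # strain's printed M(t) scale
        freqs = [0.851] + [0.5] * 4
        rate = mutation_rate(
            variant_factory([{"frequency": f, "position": i} for i, f in enumerate(freqs)]),
            generations=1584,
        )
        assert rate.mean == pytest.approx(2.851 / 1584)
        assert round(rate.mean, 4) == pytest.approx(1.8e-3)

    def test_empty_table_zero(self, variant_factory):
        table = VariantTable(variant_factory([{}]).data.iloc[:0])
        assert mutation_rate(table, generations=100).mean == 0.0

    def test_absent_mice_count_as_zero(self, variant_factory):
        rate = mutation_rate(
            variant_factory([{"mouse": 1, "frequency": 1.0}]), generations=100, n_mice=2
        )
        assert rate.mean == pytest.approx(0.005)
        assert rate.sd == pytest.approx(np.std([0.01, 0.0], ddof=1))

    def test_genome_size_normalization(self, variant_factory):
        rate = mutation_rate(
            variant_factory([{"frequency": 1.0}]), generations=100, genome_size=10**6
        )
        assert rate.mean_per_bp == pytest.approx(0.01 / 10**6)

    def test_invalid_generations_rejected(self, variant_factory):
        with pytest.raises(ValueError):
            mutation_rate(variant_factory([{}]), generations=0)

    @given(scale=st.floats(0.1, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_frequencies(self, scale):
        from conftest import make_variant_rows as variant_factory

        base = [0.1, 0.2, 0.3]
        t1 = variant_factory(
            [{"frequency": f, "position": i} for i, f in enumerate(base)]
        )
        t2 = variant_factory(
            [{"frequency": min(f * scale, 1.0), "position": i} for i, f in enumerate(base)]
        )
        if all(f * scale <= 1.0 for f in base):
            r1 = mutation_rate(t1, generations=500).mean
            r2 = mutation_rate(t2, generations=500).mean
            assert r2 == pytest.approx(scale * r1)


class TestElementPresence:
    def _uniform_profile(self, region_depth, flank_depth=60.0):
        flank = 100
        depths = np.full(1000 + 2 * flank, flank_depth)
        depths[flank:-flank] = region_depth
        return CoverageProfile(
            contig="chr", start=0, depths=depths, region=(flank, flank + 1000),
            flank_size=flank,
        )

    @pytest.mark.parametrize(
        "region_depth, presence",
        [(60.0, 1.0), (0.0, 0.0), (30.0, 0.5)],
    )
    def test_uniform_ratios(self, region_depth, presence):
        res = element_presence_frequency(self._uniform_profile(region_depth))
        assert res["presence"] == pytest.approx(presence)
        assert res["deletion_frequency"] == pytest.approx(1 - presence)

    def test_zero_flank_rejected(self):
        with pytest.raises(ValueError):
            element_presence_frequency(self._uniform_profile(30.0, flank_depth=0.0))

    def test_raw_value_retained_when_clipped(self):
        res = element_presence_frequency(self._uniform_profile(90.0))
        assert res["presence"] == 1.0
        assert res["presence_raw"] == pytest.approx(1.5)

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_generator_recovery_within_poisson_noise(self, p):
        cfg = SynthConfig()
        vals = [
            element_presence_frequency(gen_coverage(cfg, p, seed=s)[0])["presence"]
            for s in range(20)
        ]
        assert abs(float(np.mean(vals)) - p) <= 0.05


class TestHgtClassification:
    def _refs(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        recipient = "".join(rng.choice(list(bases), 400))
        donor = list(recipient)
        donor[200] = "A" if recipient[200] != "A" else "C"
        return "".join(donor), recipient

    def _reads(self, donor, recipient, n_donor, n_total, start=150, length=100):
        reads = [
            SimpleRead(f"d{i}", donor[start : start + length], start)
            for i in range(n_donor)
        ]
        reads += [
            SimpleRead(f"r{i}", recipient[start : start + length], start)
            for i in range(n_total - n_donor)
        ]
        return reads

    @pytest.mark.parametrize(
        "n_donor, flagged", [(2, True), (0, False), (1, False)]
    )
    def test_one_percent_rule_is_strict(self, n_donor, flagged):
        donor, recipient = self._refs()
        asn = classify_hgt_variant(
            self._reads(donor, recipient, n_donor, 100), donor, recipient, 200
        )
        assert asn.n_reads == 100
        assert asn.donor_fraction == pytest.approx(n_donor / 100)
        assert asn.flagged is flagged

    def test_no_overlapping_reads_is_no_call(self):
        donor, recipient = self._refs()
        assert classify_hgt_variant([], donor, recipient, 200) is None

    def test_reverse_complement_match(self):
        donor, recipient = self._refs()
        comp = str.maketrans("ACGT", "TGCA")
        rc = donor[150:250].translate(comp)[::-1]
        asn = classify_hgt_variant(
            [SimpleRead("rc", rc, 150)], donor, recipient, 200
        )
        assert asn.n_match_donor == 1

    def test_erroneous_read_matches_neither(self):
        donor, recipient = self._refs()
        seq = list(donor[150:250])
        seq[10] = "A" if seq[10] != "A" else "C"
        asn = classify_hgt_variant(
            [SimpleRead("err", "".join(seq), 150)], donor, recipient, 200
        )
        assert asn.n_match_donor == 0 and asn.n_match_recipient == 0

    def test_generator_donor_fraction_recovery(self):
        cfg = SynthConfig(genome_length=6000, hgt_tract=(1000, 5000), donor_fraction=0.3,
                          read_depth=200.0)
        reads, donor, recipient, truth = gen_reads(cfg, seed=4)
        # pick a diverged site well inside the tract
        sites = [i for i in range(2000, 4000) if donor[i] != recipient[i]]
        site = sites[0]
        asn = classify_hgt_variant(reads, donor, recipient, site)
        f = cfg.donor_fraction
        assert asn.n_reads >= 100
        assert abs(asn.donor_fraction - f) <= 3 * math.sqrt(f * (1 - f) / asn.n_reads)


class TestTractExtent:
    def test_interval_merge(self):
        assert hgt_tract_extent([100, 200, 5000], max_gap=1000) == [
            (100, 201),
            (5000, 5001),
        ]

    def test_single_variant(self):
        assert hgt_tract_extent([42], max_gap=10) == [(42, 43)]

    def test_empty(self):
        assert hgt_tract_extent([], max_gap=10) == []

    def test_planted_tract_recovered_within_read_length(self):
        cfg = SynthConfig(
            genome_length=40_000, hgt_tract=(10_000, 30_000), donor_fraction=0.5,
            read_depth=60.0,
        )
        reads, donor, recipient, truth = gen_reads(cfg, seed=9)
        sites = [i for i, (a, b) in enumerate(zip(donor, recipient)) if a != b]
        flagged = []
        for s in sites:
            asn = classify_hgt_variant(reads, donor, recipient, s)
            if asn is not None and asn.flagged:
                flagged.append(s)
        tracts = hgt_tract_extent(flagged, max_gap=5 * cfg.read_length)
        tracts = [t for t in tracts if t[1] - t[0] > 1000]
        assert len(tracts) == 1
        (t0, t1) = tracts[0]
        # endpoint resolution = read length plus diverged-site spacing
        # (mean gap 1/divergence; 99th percentile ln(100)/divergence)
        tol = cfg.read_length + math.ceil(math.log(100) / cfg.divergence)
        assert abs(t0 - 10_000) <= tol
        assert abs(t1 - 30_000) <= tol
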