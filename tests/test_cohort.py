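import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tp53kit.cohort import (
    class_spectrum,
    cumulated_vaf,
    event_spectrum,
    frameshift_codon_distribution,
    hotspot_enrichment,
    load_cohort,
    low_vaf_census,
    multiclonality,
    splice_signal_distribution,
    vaf_group_comparison,
)
from tp53kit.errors import SchemaError, Tp53KitError
from tp53kit.simulate import simulate_cohort, substitution_menu_by_events

import oracles


def _table(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "assay", "hgvs_c", "vaf", "pathogenicity", "del17p", "treatment"]
    )


class TestLoadCohort:
    def test_duplicate_rows_collapse(self, model):
        df = _table(
            [
                ("P1", "NGS", "c.700T>C", "40", "P", "no", ""),
                ("P1", "NGS", "c.700T>C", "40", "P", "no", ""),
                ("P1", "NGS", "c.637C>T", "10", "P", "no", ""),
            ]
        )
        result = load_cohort(df, model)
        assert len(result.patients) == 1
        assert result.patients[0].n_variants == 2

    def test_parse_failures_reported_not_dropped_silently(self, model):
        df = _table(
            [
                ("P1", "NGS", "c.700X>C", "40", "P", "no", ""),
                ("P2", "NGS", "c.637C>T", "10", "P", "no", ""),
            ]
        )
        result = load_cohort(df, model)
        assert len(result.patients) == 1
        assert len(result.row_errors) == 1
        assert "c.700X>C" in result.row_errors[0][1]

    def test_missing_columns_is_schema_error(self, model):
        with pytest.raises(SchemaError, match="hgvs_c"):
            load_cohort(pd.DataFrame({"patient_id": ["P1"], "assay": ["NGS"]}), model)

    def test_vaf_range_enforced(self, model):
        df = _table([("P1", "NGS", "c.700T>C", "140", "P", "no", "")])
        result = load_cohort(df, model)
        assert not result.patients
        assert "outside" in result.row_errors[0][2]

    def test_sanger_rows_carry_no_vaf(self, model):
        df = _table([("P1", "Sanger", "c.700T>C", "", "P", "", "")])
        result = load_cohort(df, model)
        assert result.patients[0].vafs == [None]


class TestSpectra:
    def test_single_variant_cohort_is_degenerate(self, model):
        df = _table([("P1", "NGS", "c.700T>C", "40", "P", "no", "")])
        spectrum = class_spectrum(load_cohort(df, model).patients)
        assert spectrum["missense"] == 1.0
        assert sum(spectrum.values()) == pytest.approx(1.0)

    def test_all_cpg_transitions_cohort(self, model):
        rows = [(f"P{i}", "NGS", h, "20", "P", "no", "") for i, h in
                enumerate(["c.637C>T", "c.586C>T", "c.742C>T"])]
        spectrum = event_spectrum(load_cohort(_table(rows), model).patients)
        assert spectrum["GC>AT"] == 1.0

    def test_spectra_are_proper_distributions(self, model):
        df, _ = simulate_cohort(300, seed=5)
        patients = load_cohort(df, model).patients
        for spectrum in (class_spectrum(patients), event_spectrum(patients)):
            assert all(v >= 0 for v in spectrum.values())
            assert sum(spectrum.values()) == pytest.approx(1.0)

    def test_event_mixture_recovered_from_known_draw(self, model):
        """Cohort drawn with 25% AT>GC recovers that share within
        binomial error at n=1,000."""
        menu = substitution_menu_by_events(
            model,
            {"GC>AT": 0.30, "AT>GC": 0.25, "GC>TA": 0.15, "GC>CG": 0.10,
             "AT>TA": 0.10, "AT>CG": 0.10},
            seed=1,
        )
        df, _ = simulate_cohort(1000, seed=9, menu=menu, sanger_fraction=0.0,
                                multiclonality_weights=(1.0, 0.0, 0.0, 0.0))
        spectrum = event_spectrum(load_cohort(df, model).patients)
        n = 1000
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(spectrum["AT>GC"] - 0.25) < 4 * se

    def test_empty_cohort_rejected(self):
        with pytest.raises(Tp53KitError):
            class_spectrum([])


class TestMulticlonality:
    def test_singleton_cohort_all_sm(self, model):
        rows = [(f"P{i}", "NGS", "c.700T>C", "20", "P", "no", "") for i in range(5)]
        summary = multiclonality(load_cohort(_table(rows), model).patients)
        assert summary["histogram"] == {"SM": 5, "DM": 0, "MM3": 0, "MM4plus": 0}
        assert summary["n_multi"] == 0

    def test_histogram_counts_sum_to_ngs_patients(self, model):
        df, _ = simulate_cohort(400, seed=2)
        patients = load_cohort(df, model).patients
        summary = multiclonality(patients)
        n_ngs = sum(1 for p in patients if p.assay == "NGS")
        assert sum(summary["histogram"].values()) == n_ngs == summary["n_patients"]

    def test_class_is_pure_function_of_count(self, model):
        df, _ = simulate_cohort(200, seed=3)
        patients = load_cohort(df, model).patients
        for p in patients:
            expected = {1: "SM", 2: "DM", 3: "MM3"}.get(p.n_variants, "MM4plus")
            assert p.multiclonality_class == expected


class TestCumulatedVaf:
    def test_plain_sums(self, model):
        df = _table(
            [("P1", "NGS", h, v, "P", "no", "") for h, v in
             [("c.700T>C", "40"), ("c.637C>T", "30"), ("c.586C>T", "20")]]
        )
        patient = load_cohort(df, model).patients[0]
        total, exceeds = cumulated_vaf(patient)
        assert total == pytest.approx(90.0)
        assert exceeds is False

    def test_exceeding_flagged(self, model):
        df = _table(
            [("P1", "NGS", "c.700T>C", "60", "P", "no", ""),
             ("P1", "NGS", "c.637C>T", "55", "P", "no", "")]
        )
        total, exceeds = cumulated_vaf(load_cohort(df, model).patients[0])
        assert total == pytest.approx(115.0)
        assert exceeds is True

    def test_sanger_record_rejected(self, model):
        df = _table([("P1", "Sanger", "c.700T>C", "", "P", "", "")])
        with pytest.raises(Tp53KitError):
            cumulated_vaf(load_cohort(df, model).patients[0])


class TestLowVafCensus:
    def test_counts_match_direct_enumeration(self, model):
        df, _ = simulate_cohort(500, seed=13)
        patients = load_cohort(df, model).patients
        census = low_vaf_census(patients, 1.0, 5.0)
        expected_any = expected_single = 0
        for p in patients:
            if p.assay != "NGS":
                continue
            if any(v is not None and 1.0 <= v <= 5.0 for v in p.vafs):
                expected_any += 1
                expected_single += p.n_variants == 1
        assert census["patients"] == expected_any
        assert census["single_mutated"] == expected_single
        assert census["patients"] == census["single_mutated"] + census["multi_mutated"]

    def test_empty_band_rejected(self, model):
        df, _ = simulate_cohort(10, seed=1)
        with pytest.raises(Tp53KitError):
            low_vaf_census(load_cohort(df, model).patients, 5.0, 5.0)


class TestHotspotEnrichment:
    def test_chi_square_equals_closed_form(self):
        result = hotspot_enrichment(17, 100, 2, 100)
        assert result.method == "chi2"
        assert result.statistic == pytest.approx(oracles.chi2_2x2(17, 83, 2, 98))

    def test_exhaustive_small_tables(self):
        for a, b, c, d in itertools.product(range(5, 16, 5), repeat=4):
            result = hotspot_enrichment(a, a + b, c, c + d)
            if result.method == "chi2":
                assert result.statistic == pytest.approx(oracles.chi2_2x2(a, b, c, d))

    def test_identical_proportions(self):
        result = hotspot_enrichment(10, 100, 10, 100)
        assert result.p_value == pytest.approx(1.0)
        assert result.odds_ratio == pytest.approx(1.0)

    def test_fisher_fallback_for_sparse_tables(self):
        result = hotspot_enrichment(2, 10, 1, 200)
        assert result.method == "fisher"
        assert 0 <= result.p_value <= 1

    def test_haldane_correction_with_zero_cell(self):
        result = hotspot_enrichment(0, 50, 10, 50)
        assert np.isfinite(result.odds_ratio)

    def test_invalid_counts_rejected(self):
        with pytest.raises(Tp53KitError):
            hotspot_enrichment(5, 0, 1, 10)
        with pytest.raises(Tp53KitError):
            hotspot_enrichment(11, 10, 1, 10)


class TestDistributions:
    def test_single_frameshift_cohort(self, model):
        df = _table([("P1", "NGS", "c.626_627del", "20", "P", "no", "")])
        dist = frameshift_codon_distribution(load_cohort(df, model).patients)
        assert dist == {209: 1.0}

    def test_frameshift_distribution_sums_to_one(self, model):
        df, _ = simulate_cohort(400, seed=21)
        dist = frameshift_codon_distribution(load_cohort(df, model).patients)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_uniform_frameshifts_pass_gof(self, model):
        """Uniform draws over a frameshift menu stay uniform (chi-square
        goodness of fit non-significant)."""
        from tp53kit.simulate import MenuEntry

        menu = [MenuEntry(f"c.{p}del", "frameshift", 1.0) for p in range(101, 1001, 90)]
        df, _ = simulate_cohort(
            2000, seed=17, menu=menu, sanger_fraction=0.0,
            multiclonality_weights=(1.0, 0.0, 0.0, 0.0), cnloh_rate=0, del17p_rate=0,
        )
        dist = frameshift_codon_distribution(load_cohort(df, model).patients)
        observed = np.array(list(dist.values())) * 2000
        p = stats.chisquare(observed).pvalue
        assert p > 0.001

    def test_splice_distribution_toy_cohort(self, model):
        rows = [(f"P{i}", "NGS", "c.74+1G>A", "20", "P", "no", "") for i in range(4)]
        dist = splice_signal_distribution(load_cohort(_table(rows), model).patients, model)
        assert dist["by_signal"]["intron2_donor"] == pytest.approx(1.0)
        assert dist["by_position"]["74+1"] == pytest.approx(1.0)

    def test_splice_distribution_pools_signal_positions(self, model):
        rows = [
            ("P1", "NGS", "c.673-2A>G", "10", "P", "no", ""),
            ("P2", "NGS", "c.673-1G>A", "10", "P", "no", ""),
            ("P3", "NGS", "c.672+1G>A", "10", "P", "no", ""),
        ]
        dist = splice_signal_distribution(load_cohort(_table(rows), model).patients, model)
        assert dist["by_signal"]["intron6_acceptor"] == pytest.approx(2 / 3)
        assert dist["by_signal"]["intron6_donor"] == pytest.approx(1 / 3)


class TestVafGroupComparison:
    def test_identical_groups_p_one(self, model):
        rows = [(f"P{i}", "NGS", h, "20", label, "no", "")
                for i, (h, label) in enumerate(
                    [("c.700T>C", "P"), ("c.637C>T", "P"), ("c.586C>T", "LP"),
                     ("c.524G>A", "LP")])]
        result = vaf_group_comparison(load_cohort(_table(rows), model).patients)
        assert result["pairwise_p"]["LP_vs_P"] == 1.0

    def test_small_groups_skipped_with_notice(self, model):
        rows = [
            ("P1", "NGS", "c.700T>C", "20", "P", "no", ""),
            ("P2", "NGS", "c.637C>T", "30", "P", "no", ""),
            ("P3", "NGS", "c.586C>T", "10", "VUS", "no", ""),
        ]
        result = vaf_group_comparison(load_cohort(_table(rows), model).patients)
        assert "VUS" in result["skipped_groups"]

    def test_null_simulation_p_values_uniform(self, model):
        """Groups drawn from the same VAF distribution: the pairwise
        rank-sum p-values behave uniformly across seeded replicates
        (>0.05 in about 95% of runs)."""
        from tp53kit.cohort import PatientRecord
        from tp53kit.hgvs import classify_variant, parse_hgvs_c

        annotations = {
            label: classify_variant(parse_hgvs_c("c.700T>C"), model,
                                    pathogenicity_label=label)
            for label in ("P", "LP")
        }
        rng = np.random.default_rng(29)
        p_values = []
        for i in range(200):
            patients = []
            for j, label in enumerate(("P", "LP")):
                vafs = rng.uniform(1, 60, size=30)
                for k, vaf in enumerate(vafs):
                    record = PatientRecord(f"P{i}_{j}_{k}", "NGS")
                    record.variants.append((annotations[label].variant, float(vaf)))
                    record.annotations.append(annotations[label])
                    patients.append(record)
            result = vaf_group_comparison(patients)
            p_values.append(result["pairwise_p"]["LP_vs_P"])
        frac_over = np.mean(np.array(p_values) > 0.05)
        assert 0.90 <= frac_over <= 1.0
        assert stats.kstest(p_values, "uniform").pvalue > 0.01
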