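import numpy as np
import pytest
from scipy import stats

from tp53kit.errors import Tp53KitError
from tp53kit.hgvs import parse_hgvs_c
from tp53kit.phasing import (
    ReadObservation,
    error_consistent_bound,
    pair_eligibility,
    phase_pair,
    read_observations_from_sam,
    reconstruct_alleles,
)
from tp53kit.simulate import (
    ClonalArchitecture,
    Clone,
    simulate_read_observations,
    simulate_sam,
    write_read_tsv,
)

V1, V2 = "c.700T>C", "c.701A>G"


def _arch(config: str, f1=30.0, f2=25.0) -> ClonalArchitecture:
    if config == "trans":
        clones = (
            Clone(f1, (V1,), {V1: "A"}),
            Clone(f2, (V2,), {V2: "A"}),
        )
    else:
        clones = (Clone(f1, (V1, V2), {V1: "A", V2: "A"}),)
    return ClonalArchitecture("SIMPT", clones)


class TestEligibility:
    def test_same_codon_pair_is_eligible(self, model):
        assert pair_eligibility(parse_hgvs_c(V1), parse_hgvs_c(V2), model)

    def test_cross_exon_pair_is_not(self, model):
        # c.672 (exon 6) vs c.674 (exon 7): 2 nt apart but different exons
        assert not pair_eligibility(
            parse_hgvs_c("c.672G>A"), parse_hgvs_c("c.674T>A"), model
        )

    def test_distance_bound_is_inclusive(self, model):
        v_a = parse_hgvs_c("c.700T>C")
        v_50 = parse_hgvs_c("c.750A>G")
        v_51 = parse_hgvs_c("c.751G>A")
        assert pair_eligibility(v_a, v_50, model, max_dist=50)
        assert not pair_eligibility(v_a, v_51, model, max_dist=50)

    def test_intronic_variants_ineligible(self, model):
        assert not pair_eligibility(
            parse_hgvs_c("c.673-2A>G"), parse_hgvs_c("c.674T>A"), model
        )


class TestPhasePair:
    def test_trans_counts_spec_example(self):
        observations = (
            [ReadObservation(f"r{i}", {V1: "ref", V2: "ref"}) for i in range(45)]
            + [ReadObservation(f"a{i}", {V1: "alt", V2: "ref"}) for i in range(30)]
            + [ReadObservation(f"b{i}", {V1: "ref", V2: "alt"}) for i in range(25)]
        )
        call = phase_pair(observations, parse_hgvs_c(V1), parse_hgvs_c(V2))
        assert call.configuration == "trans"
        assert call.n_doubly_called == 100

    def test_cis_counts(self):
        observations = (
            [ReadObservation(f"r{i}", {V1: "ref", V2: "ref"}) for i in range(60)]
            + [ReadObservation(f"c{i}", {V1: "alt", V2: "alt"}) for i in range(40)]
        )
        call = phase_pair(observations, parse_hgvs_c(V1), parse_hgvs_c(V2))
        assert call.configuration == "cis"

    def test_insufficient_coverage_is_ambiguous_not_error(self):
        observations = [ReadObservation(f"r{i}", {V1: "ref", V2: "ref"}) for i in range(10)]
        call = phase_pair(observations, parse_hgvs_c(V1), parse_hgvs_c(V2), min_support=20)
        assert call.configuration == "ambiguous"
        assert "doubly-called" in call.reason

    def test_error_free_grid_recovers_truth(self):
        """Exhaustive cis/trans x coverage grid at zero error."""
        for config in ("cis", "trans"):
            for depth, seed in [(60, 1), (100, 2), (200, 3), (500, 4)]:
                observations = simulate_read_observations(
                    _arch(config, 40.0, 35.0), depth, per_site_error=0.0, seed=seed
                )
                call = phase_pair(
                    observations, parse_hgvs_c(V1), parse_hgvs_c(V2),
                    min_support=10, error_rate=0.0,
                )
                assert call.configuration == config, (config, depth)
                absent = call.n_alt_alt if config == "trans" else min(call.n_alt_ref, call.n_ref_alt)
                assert absent == 0

    def test_low_error_rate_tolerated_within_bound(self):
        observations = simulate_read_observations(
            _arch("trans", 40.0, 35.0), 1000, per_site_error=0.005, seed=11
        )
        call = phase_pair(
            observations, parse_hgvs_c(V1), parse_hgvs_c(V2), error_rate=0.005
        )
        assert call.configuration == "trans"
        assert call.n_alt_alt <= call.error_bound

    def test_decision_regions_disjoint(self):
        # a pattern satisfying both rules must resolve to ambiguous
        observations = (
            [ReadObservation(f"a{i}", {V1: "alt", V2: "ref"}) for i in range(30)]
            + [ReadObservation(f"b{i}", {V1: "ref", V2: "alt"}) for i in range(30)]
            + [ReadObservation(f"c{i}", {V1: "alt", V2: "alt"}) for i in range(30)]
            + [ReadObservation(f"r{i}", {V1: "ref", V2: "ref"}) for i in range(1000)]
        )
        call = phase_pair(
            observations, parse_hgvs_c(V1), parse_hgvs_c(V2),
            min_support=20, error_rate=0.05,
        )
        assert call.configuration == "ambiguous"

    def test_error_bound_matches_binomial_quantile(self):
        assert error_consistent_bound(1000, 0.0) == 0
        assert error_consistent_bound(1000, 0.005) == int(
            stats.binom.ppf(0.999, 1000, 0.005)
        )


class TestReadRoutes:
    def test_tsv_round_trip(self, tmp_path):
        observations = simulate_read_observations(_arch("trans"), 400, 0.0, seed=5)
        path = tmp_path / "reads.tsv"
        write_read_tsv(observations, path)
        call = phase_pair(str(path), parse_hgvs_c(V1), parse_hgvs_c(V2), error_rate=0.0)
        assert call.configuration == "trans"

    def test_sam_route_matches_truth(self, model, tmp_path):
        path = tmp_path / "reads.sam"
        simulate_sam(model, _arch("trans", 40.0, 35.0), path, depth=400, seed=6)
        call = phase_pair(str(path), parse_hgvs_c(V1), parse_hgvs_c(V2), error_rate=0.0)
        assert call.configuration == "trans"
        assert call.n_doubly_called == 400

    def test_sam_route_calls_deletions(self, model, tmp_path):
        arch = ClonalArchitecture(
            "PD",
            (
                Clone(35.0, ("c.626_627del",), {"c.626_627del": "A"}),
                Clone(30.0, ("c.637C>T",), {"c.637C>T": "A"}),
            ),
        )
        path = tmp_path / "del.sam"
        simulate_sam(model, arch, path, depth=400, seed=7)
        call = phase_pair(
            str(path), parse_hgvs_c("c.626_627del"), parse_hgvs_c("c.637C>T"),
            error_rate=0.0,
        )
        assert call.configuration == "trans"

    def test_sam_skips_flagged_reads(self, model, tmp_path):
        import pysam

        path = tmp_path / "flagged.sam"
        simulate_sam(model, _arch("trans"), path, depth=30, seed=8)
        text = path.read_text().splitlines()
        # mark every aligned read as a duplicate
        body = [
            line if line.startswith("@") else _set_flag(line, 1024)
            for line in text
        ]
        flagged = tmp_path / "dup.sam"
        flagged.write_text("\n".join(body) + "\n")
        observations = read_observations_from_sam(
            flagged, [parse_hgvs_c(V1), parse_hgvs_c(V2)]
        )
        assert observations == []


def _set_flag(sam_line: str, flag: int) -> str:
    fields = sam_line.split("\t")
    fields[1] = str(int(fields[1]) | flag)
    return "\t".join(fields)


class TestAlleleReconstruction:
    def test_three_clone_mixture_recovered(self):
        """Clones at 30/20/50% allele fractions with 0.5% per-site error:
        frequencies recovered within +/-3% (3 sigma at 2,000 reads)."""
        arch = ClonalArchitecture(
            "P", (Clone(60.0, (V1,), {V1: "A"}), Clone(40.0, (V2,), {V2: "A"}))
        )
        # allele fractions: V1 30%, V2 20%, wt 50%
        observations = simulate_read_observations(arch, 2000, per_site_error=0.005, seed=9)
        table = reconstruct_alleles(observations, [parse_hgvs_c(V1), parse_hgvs_c(V2)])
        assert abs(table.frequency((V1,)) - 0.30) < 0.03
        assert abs(table.frequency((V2,)) - 0.20) < 0.03
        assert abs(table.frequency(()) - 0.50) < 0.03

    def test_frequencies_sum_to_one(self):
        observations = simulate_read_observations(_arch("trans"), 300, 0.01, seed=10)
        table = reconstruct_alleles(observations, [parse_hgvs_c(V1), parse_hgvs_c(V2)])
        assert sum(f for _, _, f in table.alleles) == pytest.approx(1.0)

    def test_single_wildtype_clone(self):
        arch = ClonalArchitecture("P", ())
        observations = simulate_read_observations(
            arch, 100, 0.0, seed=1, variants=[V1]
        )
        table = reconstruct_alleles(observations, [parse_hgvs_c(V1)])
        assert table.alleles == [((), 100, 1.0)]

    def test_cis_clone_gives_combined_signature(self):
        observations = simulate_read_observations(_arch("cis", 50.0), 400, 0.0, seed=2)
        table = reconstruct_alleles(observations, [parse_hgvs_c(V1), parse_hgvs_c(V2)])
        assert table.frequency((V1, V2)) == pytest.approx(0.25, abs=0.06)
        assert table.frequency((V1,)) == 0.0

    def test_convergence_with_depth(self):
        arch = ClonalArchitecture(
            "P", (Clone(60.0, (V1,), {V1: "A"}), Clone(40.0, (V2,), {V2: "A"}))
        )
        errors = []
        for depth, tol in [(100, 0.10), (1000, 0.035)]:
            observations = simulate_read_observations(arch, depth, 0.0, seed=4)
            table = reconstruct_alleles(observations, [parse_hgvs_c(V1), parse_hgvs_c(V2)])
            err = abs(table.frequency((V1,)) - 0.30)
            errors.append(err)
            assert err < tol

    def test_no_spanning_reads_is_error(self):
        observations = [ReadObservation("r1", {V1: "uncalled", V2: "alt"})]
        with pytest.raises(Tp53KitError):
            reconstruct_alleles(observations, [parse_hgvs_c(V1), parse_hgvs_c(V2)])

    def test_noise_floor_flags_rare_signatures(self):
        observations = simulate_read_observations(_arch("trans"), 2000, 0.002, seed=3)
        table = reconstruct_alleles(
            observations, [parse_hgvs_c(V1), parse_hgvs_c(V2)], noise_floor=0.01
        )
        if (V1, V2) in [sig for sig, _, _ in table.alleles]:
            assert (V1, V2) in table.flagged
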