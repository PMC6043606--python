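"""R statistic, genotype classification and coverage diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import clonescan as cs
from clonescan.models import HET, HOM_NONREF, HOM_REF
from clonescan.pileup import (
    class_counts,
    classify_positions,
    compute_R,
    correct_bias,
    coverage_bounds,
    detect_hemizygous_regions,
    estimate_mapping_bias,
    hwe_ratio_test,
    relative_copy_number,
    single_genotype_check,
)


def make_counts(rows):
    """rows: (ref_count, {base: count}) tuples at consecutive positions."""
    recs = []
    for i, (rc, nonref) in enumerate(rows):
        rec = {"chrom": "chr1", "pos": i + 1, "ref_base": "A", "ref_count": rc,
               "A": 0, "C": 0, "G": 0, "T": 0}
        rec.update(nonref)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestComputeR:
    @pytest.mark.parametrize(
        "rc,nc,expected",
        [(5, 5, 0.5), (10, 0, 0.0), (3, 7, 0.7)],
    )
    def test_definition(self, rc, nc, expected):
        track = compute_R(make_counts([(rc, {"T": nc})]))
        assert track["R"].iloc[0] == pytest.approx(expected)
        assert track["depth"].iloc[0] == rc + nc

    def test_uses_most_common_nonref_only(self):
        track = compute_R(make_counts([(10, {"T": 8, "G": 1})]))
        assert track["nc"].iloc[0] == 8
        assert track["R"].iloc[0] == pytest.approx(8 / 18)

    def test_second_allele_flags_ambiguous(self):
        track = compute_R(make_counts([(10, {"T": 10, "G": 4}), (10, {"T": 10, "G": 1})]))
        assert bool(track["ambiguous"].iloc[0])
        assert not bool(track["ambiguous"].iloc[1])

    def test_zero_depth_excluded(self):
        track = compute_R(make_counts([(0, {})]))
        assert np.isnan(track["R"].iloc[0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_R(make_counts([(-1, {"T": 2})]))


class TestClassification:
    def test_all_reference_positions_are_hom_ref(self):
        track = compute_R(make_counts([(20, {})] * 50))
        cls = classify_positions(track, 5, 100)
        assert class_counts(cls)["hom-ref"] == 50

    def test_depth_below_bound_excluded(self):
        track = compute_R(make_counts([(3, {})]))
        cls = classify_positions(track, 5, 100)
        assert cls["gt_class"].iloc[0] == "excluded"

    def test_invalid_bounds_rejected(self):
        track = compute_R(make_counts([(3, {})]))
        with pytest.raises(ValueError):
            classify_positions(track, 10, 10)

    def test_recovers_simulated_truth(self, desk_ref, population):
        # 1% error, 60x: per-class accuracy >= 99% against generator truth
        iso = cs.simulate_sexual_isolate(desk_ref, population, seed=21)
        pu = cs.simulate_pileup(iso, cs.SequencingModel(mean_coverage=60, error_rate=0.01, seed=22))
        track = compute_R(pu)
        lo, hi = coverage_bounds(track)
        cls = classify_positions(track, lo, hi)
        label = {HOM_REF: "hom-ref", HET: "het", HOM_NONREF: "hom-nonref"}
        for code, name in label.items():
            truth = iso.gt == code
            usable = truth & (cls["gt_class"] != "excluded").to_numpy()
            acc = (cls["gt_class"].to_numpy()[usable] == name).mean()
            assert acc >= 0.99, f"{name}: {acc}"

    @given(r1=st.floats(0, 1), r2=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_R(self, r1, r2):
        # raising R never moves a class toward hom-ref
        order = {"hom-ref": 0, "het": 1, "hom-nonref": 2}
        lo_r, hi_r = sorted((r1, r2))
        track = pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [1, 2], "rc": [1, 1], "nc": [1, 1],
             "depth": [30, 30], "R": [lo_r, hi_r], "ambiguous": [False, False]}
        )
        cls = classify_positions(track, 5, 100)["gt_class"].tolist()
        assert order[cls[0]] <= order[cls[1]]


class TestHweRatio:
    def test_table_scale_hwe_counts_accepted(self):
        res = hwe_ratio_test(180_000, 90_000)
        assert res.ratio == pytest.approx(2.0)
        assert res.p_value > 0.05

    def test_clonal_deficit_rejected(self):
        # oracle: exact binomial tail for 40,000 het vs 2,000 hom-nonref
        res = hwe_ratio_test(40_000, 2_000)
        assert res.ratio == pytest.approx(20.0)
        oracle = 2 * stats.binom.sf(39_999, 42_000, 2 / 3)
        assert res.p_value < 1e-10
        assert res.p_value == pytest.approx(min(1.0, oracle), rel=0.2)

    def test_tiny_counts_not_significant(self):
        res = hwe_ratio_test(2, 1)
        assert res.ratio == pytest.approx(2.0)
        assert res.p_value == pytest.approx(1.0, abs=0.2)

    def test_zero_homnonref_gives_infinite_ratio(self):
        res = hwe_ratio_test(10, 0)
        assert np.isinf(res.ratio)
        assert 0 <= res.p_value <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hwe_ratio_test(0, 0)


class TestSingleGenotype:
    def test_single_clone_verdict(self, desk_ref, population):
        iso = cs.simulate_sexual_isolate(desk_ref, population, seed=31)
        pu = cs.simulate_pileup(iso, cs.SequencingModel(seed=32))
        track = compute_R(pu)
        het_R = track["R"].to_numpy()[iso.gt == HET]
        assert single_genotype_check(het_R).verdict == "single"

    def test_fifty_fifty_mixture_detected(self):
        # mixture arithmetic: a site het in one genotype and hom in the other
        # yields read fraction 0.25 or 0.75 in the pooled library
        rng = np.random.default_rng(0)
        depth = 80
        modes = np.concatenate([
            rng.binomial(depth, 0.25, 2000) / depth,
            rng.binomial(depth, 0.75, 2000) / depth,
        ])
        res = single_genotype_check(modes, bias_correct=False)
        assert res.verdict == "mixed"
        assert res.n_modes >= 2

    def test_bias_corrected_single_genotype(self):
        rng = np.random.default_rng(1)
        depth = 60
        biased = rng.binomial(depth, 0.8 / 1.8, 3000) / depth
        res = single_genotype_check(biased, bias_correct=True)
        assert res.verdict == "single"
        assert res.mean_R == pytest.approx(0.5, abs=0.03)
        assert res.bias == pytest.approx(0.8, abs=0.15)

    def test_too_few_sites_indeterminate(self):
        assert single_genotype_check(np.full(10, 0.5)).verdict == "indeterminate"

    def test_bias_inversion_closed_form(self):
        # correcting the biased het mode b/(1+b) recovers exactly 0.5
        for b in (0.5, 0.8, 1.0):
            assert correct_bias(np.array([b / (1 + b)]), b)[0] == pytest.approx(0.5)


class TestCoverageDerived:
    def test_relative_copy_number_recovers_simulated_fold(self, desk_ref, population):
        iso = cs.simulate_sexual_isolate(desk_ref, population, seed=41)
        region = ("chr2", 10_000, 30_000)
        pu = cs.simulate_pileup(
            iso,
            cs.SequencingModel(mean_coverage=40, seed=42),
            ref=desk_ref,
            dense=True,
            copy_number_blocks=[(*region, 8.0)],
        )
        track = compute_R(pu)
        in_region = (
            (track["chrom"] == region[0]) & (track["pos"] >= region[1]) & (track["pos"] < region[2])
        ).to_numpy()
        out_region = ~in_region
        cn = relative_copy_number(track["depth"].to_numpy()[in_region],
                                  track["depth"].to_numpy()[out_region])
        assert cn == pytest.approx(8.0, rel=0.05)

    def test_whole_genome_copy_number_is_one(self):
        depths = np.random.default_rng(2).poisson(50, 1000)
        assert relative_copy_number(depths, depths) == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            relative_copy_number(np.array([]), np.array([50.0]))

    def test_hemizygous_deletion_recovered(self, desk_ref, population):
        block = ("chr1", 30_000, 80_000)
        iso = cs.simulate_sexual_isolate(desk_ref, population, seed=51)
        pu = cs.simulate_pileup(
            iso,
            cs.SequencingModel(mean_coverage=60, seed=52),
            ref=desk_ref,
            dense=True,
            hemizygous_blocks=[block],
        )
        track = compute_R(pu)
        lo, hi = coverage_bounds(track)
        cls = classify_positions(track, lo, hi)
        window = 5_000
        bed = detect_hemizygous_regions(cls, window=window)
        hits = bed[bed["chrom"] == "chr1"]
        assert len(hits) == 1
        start, end = int(hits["start"].iloc[0]), int(hits["end"].iloc[0])
        assert abs(start - (block[1] - 1)) <= 2 * window
        assert abs(end - (block[2] - 1)) <= 2 * window
        assert not (bed["chrom"] != "chr1").any()

    def test_uniform_diploid_coverage_yields_no_intervals(self, desk_ref, population):
        iso = cs.simulate_sexual_isolate(desk_ref, population, seed=61)
        pu = cs.simulate_pileup(iso, cs.SequencingModel(mean_coverage=60, seed=62))
        track = compute_R(pu)
        lo, hi = coverage_bounds(track)
        cls = classify_positions(track, lo, hi)
        assert len(detect_hemizygous_regions(cls)) == 0
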