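import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btmbkit.assay import (classify_btmb_group, classify_germline,
                           compute_btmb, compute_msaf)
from btmbkit.io import VariantCall
from conftest import make_variant, random_variant_list
from oracles import brute_force_btmb

variant_strategy = st.builds(
    VariantCall,
    sample_id=st.just("S1"),
    gene=st.just("TP53"),
    position=st.integers(1, 500),
    ref=st.just("A"),
    alt=st.just("G"),
    variant_class=st.sampled_from(["SNV"]),
    allele_frequency=st.floats(0.0, 1.0, allow_nan=False),
    in_population_db=st.booleans(),
    is_known_driver=st.booleans(),
)


def _flagged(variants, band=0.05):
    return classify_germline(variants, af_germline_band=band)


class TestGermlineSurrogate:
    def test_population_db_membership_is_sufficient(self):
        (v,) = _flagged([make_variant(allele_frequency=0.004,
                                      in_population_db=True)])
        assert v.germline_flag == "germline"

    def test_low_af_non_db_variant_is_somatic(self):
        (v,) = _flagged([make_variant(allele_frequency=0.05)])
        assert v.germline_flag == "somatic"

    @pytest.mark.parametrize("af,expected", [
        (0.49, "germline"), (0.449, "somatic"), (0.549, "germline"),
        (0.551, "somatic"), (0.96, "germline"), (1.0, "germline"),
        (0.94, "somatic"),
    ])
    def test_af_band_rule_boundaries(self, af, expected):
        (v,) = _flagged([make_variant(allele_frequency=af)])
        assert v.germline_flag == expected

    def test_band_rule_matches_brute_force_on_af_grid(self):
        for af in np.linspace(0.0, 1.0, 201):
            (v,) = _flagged([make_variant(allele_frequency=float(af))])
            expected = (abs(af - 0.5) <= 0.05 or abs(af - 1.0) <= 0.05)
            assert (v.germline_flag == "germline") == expected


class TestMsaf:
    def test_highest_somatic_af_below_20_percent(self):
        variants = _flagged([make_variant(position=p, allele_frequency=af)
                             for p, af in [(1, 0.004), (2, 0.05), (3, 0.25)]])
        assert compute_msaf(variants) == pytest.approx(0.05)

    def test_no_somatic_snv_gives_zero(self):
        assert compute_msaf([]) == 0.0
        germline_only = _flagged([make_variant(allele_frequency=0.5)])
        assert compute_msaf(germline_only) == 0.0

    def test_driver_status_does_not_exclude_from_msaf(self):
        variants = _flagged([
            make_variant(position=1, allele_frequency=0.12,
                         is_known_driver=True),
            make_variant(position=2, allele_frequency=0.03),
        ])
        assert compute_msaf(variants) == pytest.approx(0.12)

    def test_indels_never_set_msaf(self):
        variants = _flagged([make_variant(
            variant_class="insertion", ref="A", alt="AT",
            allele_frequency=0.15)])
        assert compute_msaf(variants) == 0.0


class TestBtmbScore:
    def test_sixteen_snvs_on_default_panel_is_14_5_mut_per_mb(self, panel):
        variants = _flagged([make_variant(position=1000 + i,
                                          allele_frequency=0.04)
                             for i in range(16)])
        res = compute_btmb(variants, panel)
        assert res.evaluable and res.btmb_score == 16
        assert round(res.mut_per_mb, 1) == 14.5

    def test_indel_not_counted(self, panel):
        variants = [make_variant(position=1000 + i, allele_frequency=0.04)
                    for i in range(5)]
        variants.append(make_variant(position=2000, variant_class="insertion",
                                     ref="A", alt="AT",
                                     allele_frequency=0.04))
        res = compute_btmb(_flagged(variants), panel)
        assert res.btmb_score == 5

    def test_af_below_half_percent_not_counted(self, panel):
        variants = _flagged([
            make_variant(position=1, allele_frequency=0.004),
            make_variant(position=2, allele_frequency=0.012),
        ])
        assert compute_btmb(variants, panel).btmb_score == 1

    def test_driver_excluded_from_score_but_sets_msaf(self, panel):
        variants = _flagged([
            make_variant(position=1, allele_frequency=0.06,
                         is_known_driver=True),
            make_variant(position=2, allele_frequency=0.02),
        ])
        res = compute_btmb(variants, panel)
        assert res.btmb_score == 1
        assert res.msaf == pytest.approx(0.06)

    def test_low_msaf_masks_score(self, panel):
        variants = _flagged([make_variant(allele_frequency=0.008)])
        res = compute_btmb(variants, panel)
        assert not res.evaluable
        assert res.btmb_score is None and res.mut_per_mb is None

    def test_duplicate_keys_counted_once(self, panel):
        variants = _flagged([make_variant(allele_frequency=0.02),
                             make_variant(allele_frequency=0.03)])
        assert compute_btmb(variants, panel).btmb_score == 1

    def test_empty_panel_is_configuration_error(self, panel):
        with pytest.raises(ValueError):
            PanelZero = type(panel)
            compute_btmb([], PanelZero(genes=panel.genes, total_mb=-1))


class TestGrouping:
    @pytest.mark.parametrize("score,cutoff,expected", [
        (16, 16, "high"), (15, 16, "low"), (0, 16, "low"), (20, 20, "high"),
    ])
    def test_inclusive_boundary(self, panel, score, cutoff, expected):
        variants = _flagged([make_variant(position=1000 + i,
                                          allele_frequency=0.05)
                             for i in range(score)] or
                            [make_variant(allele_frequency=0.05)])
        res = compute_btmb(variants, panel)
        if score == 0:
            res = compute_btmb(_flagged(
                [make_variant(allele_frequency=0.05,
                              is_known_driver=True)]), panel)
        assert classify_btmb_group(res, cutoff) == expected

    def test_low_msaf_sample_is_non_evaluable_regardless_of_calls(self, panel):
        variants = _flagged([make_variant(position=1000 + i,
                                          allele_frequency=0.006)
                             for i in range(30)])
        res = compute_btmb(variants, panel)
        assert classify_btmb_group(res, 16) == "non_evaluable"

    def test_negative_cutoff_rejected(self, panel):
        res = compute_btmb(_flagged([make_variant()]), panel)
        with pytest.raises(ValueError):
            classify_btmb_group(res, -1)


class TestScoringProperties:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.lists(variant_strategy, max_size=25))
    def test_score_equals_brute_force_generatively(self, panel, variants):
        res = compute_btmb(classify_germline(variants), panel)
        msaf, score = brute_force_btmb(variants)
        assert res.msaf == pytest.approx(msaf)
        assert (res.btmb_score if res.evaluable else None) == score

    def test_score_equals_brute_force_on_random_fixtures(self, panel):
        rng = np.random.default_rng(42)
        for _ in range(300):
            variants = random_variant_list(rng)
            res = compute_btmb(classify_germline(variants), panel)
            msaf, score = brute_force_btmb(variants)
            assert res.msaf == pytest.approx(msaf)
            assert (res.btmb_score if res.evaluable else None) == score

    def test_adding_qualifying_snv_is_monotone(self, panel):
        rng = np.random.default_rng(7)
        for _ in range(50):
            variants = random_variant_list(rng)
            before = compute_btmb(classify_germline(variants), panel)
            extra = make_variant(position=999_999,
                                 allele_frequency=float(
                                     rng.uniform(0.01, 0.19)))
            after = compute_btmb(classify_germline(variants + [extra]), panel)
            assert after.msaf >= before.msaf
            if before.evaluable:
                assert after.btmb_score >= before.btmb_score

    def test_score_times_footprint_recovers_count(self, panel):
        rng = np.random.default_rng(3)
        for _ in range(50):
            res = compute_btmb(
                classify_germline(random_variant_list(rng)), panel)
            if res.evaluable:
                assert res.mut_per_mb * panel.total_mb == pytest.approx(
                    res.btmb_score)
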