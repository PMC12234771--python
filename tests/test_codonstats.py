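"""RSCU, ENC, PR2, SVC, stop-codon and group-test behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from camscan._genetic_code import FAMILIES, SENSE_CODONS
from camscan.codonstats import (
    CodonCounts,
    count_codons,
    enc,
    enc_group_test,
    gc_content,
    pool_counts,
    pr2_point,
    rscu,
    stop_codon_tally,
    svc,
)
from camscan.io import degap_and_validate


def _counts(mapping, gene="g", strain="s"):
    return CodonCounts(gene_id=gene, strain_id=strain, counts=dict(mapping))


random_counts = st.dictionaries(
    st.sampled_from(SENSE_CODONS),
    st.integers(min_value=0, max_value=50),
    max_size=61,
)


class TestCountCodons:
    def test_hand_count_with_terminal(self):
        rec = degap_and_validate("g", "s", "ATGAAATAA")
        c = count_codons(rec)
        assert c.counts == {"ATG": 1, "AAA": 1}
        assert c.terminal_codon == "TAA"

    def test_empty_sequence_gives_empty_counts(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = degap_and_validate("g", "s", "---")
        c = count_codons(rec)
        assert c.counts == {}
        assert not c.eligible

    def test_codons_with_n_skipped(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = degap_and_validate(
                "g", "s", "ATGANATAA", drop_terminal=True
            )
        c = count_codons(rec)
        assert "ANA" not in c.counts
        assert c.counts == {"ATG": 1}


class TestRscu:
    def test_uniform_usage_gives_all_ones(self):
        c = _counts({codon: 5 for codon in SENSE_CODONS})
        table = rscu(c)
        assert all(v == pytest.approx(1.0) for v in table.values.values())

    def test_phe_three_to_one(self):
        table = rscu(_counts({"TTT": 3, "TTC": 1}))
        assert table["TTT"] == pytest.approx(1.5)
        assert table["TTC"] == pytest.approx(0.5)

    def test_unused_codon_is_zero(self):
        table = rscu(_counts({"TTT": 4}))
        assert table["TTC"] == 0.0

    def test_absent_family_flagged(self):
        table = rscu(_counts({"TTT": 4}))
        assert "L" in table.absent_families
        assert all(table[c] == 0.0 for c in FAMILIES["L"])

    @given(random_counts)
    def test_family_sums_equal_family_size(self, mapping):
        table = rscu(_counts(mapping))
        for aa, codons in FAMILIES.items():
            total = sum(mapping.get(c, 0) for c in codons)
            if total:
                assert sum(table[c] for c in codons) == pytest.approx(
                    len(codons)
                )


class TestEnc:
    def test_one_codon_per_family_is_twenty(self):
        c = _counts({fam[0]: 100 for fam in FAMILIES.values()})
        assert enc(c).enc == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self):
        c = _counts({codon: 1000 for codon in SENSE_CODONS})
        assert enc(c).enc == pytest.approx(61.0, abs=0.2)

    def test_random_uniform_gene_lands_high(self):
        rng = np.random.default_rng(0)
        draws = rng.choice(np.array(SENSE_CODONS), size=200)
        vals, counts = np.unique(draws, return_counts=True)
        e = enc(_counts(dict(zip(vals.tolist(), counts.tolist()))))
        assert 55.0 <= e.enc <= 61.0

    def test_bounded_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(20, 400)
            draws = rng.choice(np.array(SENSE_CODONS), size=n)
            vals, counts = np.unique(draws, return_counts=True)
            e = enc(_counts(dict(zip(vals.tolist(), counts.tolist()))))
            if e.defined:
                assert 20.0 <= e.enc <= 61.0

    def test_scale_invariance_at_large_counts(self):
        rng = np.random.default_rng(2)
        draws = rng.choice(np.array(SENSE_CODONS), size=300)
        vals, counts = np.unique(draws, return_counts=True)
        # ENC depends on codon frequencies up to the n/(n-1) small-sample
        # factor, which vanishes once every family holds >=100 codons
        base = {k: 100 * int(c) for k, c in zip(vals.tolist(), counts)}
        doubled = {k: 2 * v for k, v in base.items()}
        assert enc(_counts(base)).enc == pytest.approx(
            enc(_counts(doubled)).enc, abs=0.05
        )

    def test_order_invariance(self):
        # counts are a bag: any reordering of the underlying codon stream
        # gives the same value by construction of the count map
        base = {"TTT": 9, "TTC": 3, "GTA": 5, "GTT": 5, "GTC": 4, "GTG": 2}
        shuffled = dict(reversed(list(base.items())))
        assert enc(_counts(base)).enc == enc(_counts(shuffled)).enc

    def test_missing_class_imputed_and_flagged(self):
        # only two-fold families used: Ile/four-fold/six-fold classes imputed
        c = _counts({"TTT": 5, "TTC": 5, "TAT": 3, "TAC": 2})
        e = enc(c)
        assert set(e.imputed_classes) == {3, 4, 6}
        assert e.defined

    def test_all_classes_missing_is_undefined(self):
        e = enc(_counts({"ATG": 3}))
        assert not e.defined
        assert math.isnan(e.enc)


class TestPr2:
    def test_symmetric_counts_centre_the_point(self):
        c = _counts({"GTA": 1, "GTT": 1, "GTG": 1, "GTC": 1})
        p = pr2_point(c)
        assert (p.x, p.y) == (0.5, 0.5)

    def test_hand_ratios(self):
        # third positions over four-fold families: A3=3, T3=1, G3=2, C3=2
        c = _counts({"GTA": 3, "GTT": 1, "GTG": 2, "GTC": 2})
        p = pr2_point(c)
        assert p.y == pytest.approx(0.75)
        assert p.x == pytest.approx(0.5)

    def test_no_fourfold_codons_is_undefined(self):
        p = pr2_point(_counts({"TTT": 10, "AAA": 5}))
        assert not p.defined

    def test_all_codon_mode_counts_every_codon(self):
        c = _counts({"TTT": 2, "GTA": 1})
        p = pr2_point(c, fourfold_only=False)
        assert p.t3 == 2 and p.a3 == 1


class TestSvc:
    def test_identical_tables_empty(self):
        t = rscu(_counts({c: i + 1 for i, c in enumerate(SENSE_CODONS)}))
        assert svc(t, t) == ()

    def test_preference_flip_detected(self):
        a = rscu(_counts({"TTT": 3, "TTC": 1}))  # TTT 1.5, TTC 0.5
        b = rscu(_counts({"TTT": 1, "TTC": 3}))
        got = svc(a, b)
        assert "TTT" in got and "TTC" in got

    def test_boundary_rscu_one_is_unpreferred(self):
        a = rscu(_counts({"TTT": 3, "TTC": 2}))  # TTT 1.2
        b = rscu(_counts({"TTT": 1, "TTC": 1}))  # TTT exactly 1.0
        assert "TTT" in svc(a, b)

    @given(random_counts, random_counts)
    def test_symmetry_and_self_emptiness(self, ma, mb):
        a, b = rscu(_counts(ma)), rscu(_counts(mb))
        assert svc(a, b) == svc(b, a)
        assert svc(a, a) == ()

    def test_singleton_families_never_reported(self):
        a = rscu(_counts({"ATG": 5, "TGG": 5}))
        b = rscu(_counts({"TTT": 5}))
        assert "ATG" not in svc(a, b)
        assert "TGG" not in svc(a, b)


class TestStopCodonTally:
    def test_all_same(self):
        assert stop_codon_tally(["TAA"] * 4)[0] == ("TAA", 4)

    def test_paper_style_ranking(self):
        terms = ["TAG"] * 7 + ["TAA"] * 6 + ["TGA"] * 2
        assert stop_codon_tally(terms) == [("TAG", 7), ("TAA", 6), ("TGA", 2)]

    def test_tie_breaks_taa_first(self):
        terms = ["TAG"] * 3 + ["TAA"] * 3
        ranked = stop_codon_tally(terms)
        assert ranked[0][0] == "TAA"

    def test_non_stop_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            ranked = stop_codon_tally(["AAA", "TAA"])
        assert dict(ranked)["TAA"] == 1


class TestEncGroupTest:
    def test_identical_groups_p_one(self):
        r = enc_group_test("g", [40.0, 41.0, 42.0], [40.0, 41.0, 42.0])
        assert r.t_pvalue == pytest.approx(1.0)
        assert r.tier == ">0.05"

    def test_zero_variances_distinct_means_convention(self):
        r = enc_group_test("g", [40.0, 40.0, 40.0], [44.0] * 4)
        assert r.t_pvalue == 0.0
        assert r.tier == "<0.01"

    def test_zero_variances_equal_means_convention(self):
        r = enc_group_test("g", [40.0] * 3, [40.0] * 4)
        assert r.t_pvalue == 1.0

    def test_variant_switches_at_f_threshold(self):
        from scipy import stats

        a = [39.9, 40.0, 40.1]  # sd 0.1
        # with n=(3,4) the two-sided F test at alpha=0.05 flips when
        # var_a/var_b crosses the critical ratio; construct b on both sides
        crit_hi = stats.f(2, 3).ppf(0.975)
        for ratio, expect in [(crit_hi * 0.5, "equal-variance"),
                              (crit_hi * 4.0, "unequal-variance")]:
            sd_b = 0.1 / math.sqrt(ratio)
            mean_step = sd_b * math.sqrt(3) / 2  # [m-d,m-d,m+d,m+d] has var 4d^2/3
            b = [41.0 - mean_step, 41.0 - mean_step, 41.0 + mean_step,
                 41.0 + mean_step]
            r = enc_group_test("g", a, b)
            assert r.variant == expect

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            enc_group_test("g", [40.0], [41.0, 42.0])


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expect", [("GGCC", 1.0), ("ATGC", 0.5), ("AT", 0.0)]
    )
    def test_string_inputs(self, seq, expect):
        assert gc_content(seq) == pytest.approx(expect)

    def test_n_excluded_from_denominator(self):
        assert gc_content("GNAN") == pytest.approx(0.5)

    def test_empty_is_undefined(self):
        assert math.isnan(gc_content("NNN"))

    def test_third_position_from_counts(self):
        c = _counts({"GTA": 1, "GTG": 3})
        assert gc_content(c, positions="third") == pytest.approx(0.75)

    def test_pooling_sums_counts(self):
        a = _counts({"TTT": 2})
        b = _counts({"TTT": 1, "TTC": 3})
        pooled = pool_counts([a, b])
        assert pooled.counts == {"TTT": 3, "TTC": 3}
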