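"""Delta-method mediation, BH-FDR, screening and evidence-tier logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (InputError, InstrumentSet, InsufficientInstrumentsError,
                       TriangleRecord, assign_evidence_tier, bh_fdr,
                       exclude_step1_instruments, mediate, reverse_mr_filter,
                       screen_step1, shared_mediators)

from conftest import make_table


class TestMediate:
    def test_worked_example_bmi_pathway(self):
        # step-1 effect 0.368, step-2 effect 0.421, total ln(1.267)
        res = mediate(0.368, 0.047, 0.421, 0.134, np.log(1.267), 0.06)
        assert res.indirect == pytest.approx(0.368 * 0.421)
        assert 100 * res.proportion == pytest.approx(65.47, abs=0.01)

    def test_identities_exact(self):
        res = mediate(0.3, 0.05, 0.2, 0.04, 0.25, 0.03)
        assert res.indirect == res.beta1 * res.beta2
        assert res.proportion * res.beta3 == res.indirect

    def test_null_step1(self):
        res = mediate(0.0, 0.05, 0.2, 0.04, 0.25, 0.03)
        assert res.indirect == 0.0
        assert res.proportion == 0.0
        assert not res.significant

    def test_indirect_se_closed_form(self):
        res = mediate(0.3, 0.05, 0.2, 0.04, 0.25, 0.03)
        assert res.indirect_se == pytest.approx(np.sqrt(0.000244), abs=1e-9)
        assert res.indirect_se == pytest.approx(0.015620, abs=1e-6)

    def test_indirect_se_matches_monte_carlo(self, rng):
        b1, s1, b2, s2 = 0.3, 0.05, 0.2, 0.04
        res = mediate(b1, s1, b2, s2, 0.25, 0.03)
        draws = rng.normal(b1, s1, 200_000) * rng.normal(b2, s2, 200_000)
        assert res.indirect_se == pytest.approx(np.std(draws), rel=0.02)

    def test_zero_total_effect_leaves_proportion_undefined(self):
        res = mediate(0.3, 0.05, 0.2, 0.04, 0.0, 0.03)
        assert not res.proportion_defined
        assert res.proportion is None

    def test_inconsistent_mediation_flagged(self):
        res = mediate(0.8, 0.05, 0.8, 0.04, 0.1, 0.03)
        assert res.inconsistent
        assert res.proportion > 1

    def test_se3_term_widens_proportion_interval(self):
        full = mediate(0.3, 0.05, 0.2, 0.04, 0.25, 0.03)
        partial = mediate(0.3, 0.05, 0.2, 0.04, 0.25, 0.03,
                          se3_in_proportion_se=False)
        assert full.proportion_se > partial.proportion_se

    def test_bad_se_rejected(self):
        with pytest.raises(InputError):
            mediate(0.3, 0.0, 0.2, 0.04, 0.25, 0.03)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]),
                                   [0.04, 0.04, 0.04, 0.5])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_matches_bruteforce_step_up(self, rng):
        for _ in range(10):
            p = rng.uniform(0.001, 1.0, rng.integers(2, 40))
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, p[idx] * m / rank)
                adj[idx] = prev
            np.testing.assert_allclose(bh_fdr(p), adj, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=30))
    def test_permutation_invariance_and_dominance(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.0, 0.1])


def iv_set(rsids, exposure="exp"):
    tab = make_table([{"rsid": r} for r in rsids])
    tab["rsid"] = rsids
    return InstrumentSet(exposure, tab, 5e-8, 0.001, 0.0)


class TestExcludeStep1:
    def test_disjoint_sets_unchanged(self):
        s1 = iv_set(["a", "b"])
        s2 = iv_set(["c", "d"], "met")
        assert exclude_step1_instruments(s1, s2).rsids == ["c", "d"]

    def test_subset_is_an_error(self):
        s1 = iv_set(["a", "b", "c"])
        s2 = iv_set(["a", "b"], "met")
        with pytest.raises(InsufficientInstrumentsError, match="a"):
            exclude_step1_instruments(s1, s2)

    def test_partial_overlap_removed(self):
        s1 = iv_set([f"x{i}" for i in range(3)] + ["s1", "s2", "s3"])
        s2 = iv_set([f"y{i}" for i in range(7)] + ["s1", "s2", "s3"], "met")
        out = exclude_step1_instruments(s1, s2)
        assert out.n_instruments == 7
        assert set(out.rsids) == {f"y{i}" for i in range(7)}


class TestScreenStep1:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["mediator", "primary_beta",
                                           "primary_p", "bwmr_beta", "bwmr_p"])

    def test_conjunction_rule(self):
        df = self._frame([("m1", 0.3, 1e-5, 0.3, 0.4),
                          ("m2", 0.3, 1e-5, 0.28, 1e-4)])
        out = screen_step1(df)
        assert not out.loc[out["mediator"] == "m1", "pass"].iloc[0]
        assert out.loc[out["mediator"] == "m2", "pass"].iloc[0]

    def test_discordant_signs_excluded(self):
        df = self._frame([("m1", 0.3, 1e-6, -0.3, 1e-6)])
        assert not screen_step1(df)["pass"].iloc[0]

    def test_fdr_family_is_the_whole_metabolome(self):
        rows = [("null%d" % i, 0.01, p, 0.01, p)
                for i, p in enumerate(np.linspace(0.02, 0.9, 30))]
        rows.append(("hit", 0.4, 1e-9, 0.38, 1e-8))
        out = screen_step1(self._frame(rows))
        # nominal 0.02 does not survive the 31-test family
        assert out.loc[out["mediator"] == "null0", "q_primary"].iloc[0] > 0.05
        assert set(out.loc[out["pass"], "mediator"]) == {"hit"}


class TestSharedMediators:
    def test_groupings_and_exclusion_rule(self):
        sets = {"BMI": {"m1", "m2", "m3"}, "WC": {"m1", "m2", "m3"},
                "BMR": {"m1"}, "MetS": {"m1", "m2"}}
        groups = shared_mediators(sets)
        assert groups[frozenset({"BMI", "WC", "BMR", "MetS"})] == ["m1"]
        assert groups[frozenset({"BMI", "WC", "MetS"})] == ["m2"]
        # m3 is associated with the obesity pair only -> excluded
        assert frozenset({"BMI", "WC"}) not in groups

    def test_matches_bruteforce_set_algebra(self, rng):
        phenos = ["BMI", "WC", "BMR", "MetS"]
        mets = [f"m{i}" for i in range(25)]
        sets = {p: {m for m in mets if rng.random() < 0.4} for p in phenos}
        groups = shared_mediators(sets)
        for m in mets:
            combo = frozenset(p for p in phenos if m in sets[p])
            expect_in = len(combo) >= 2 and combo != frozenset({"BMI", "WC"})
            present = any(m in v for v in groups.values())
            assert present == expect_in
            if expect_in:
                assert m in groups[combo]

    def test_needs_two_phenotypes(self):
        with pytest.raises(InputError):
            shared_mediators({"BMI": {"m1"}})


def triangle():
    return TriangleRecord(mediate(0.3, 0.05, 0.2, 0.04, 0.25, 0.03,
                                  exposure_id="BMI", mediator_id="m1",
                                  outcome_id="CRC"))


class TestReverseFilterAndTiers:
    def test_non_significant_reverse_retained(self):
        tr = reverse_mr_filter(triangle(), {"mediator_to_exposure": 0.4})
        assert not tr.reverse_excluded

    def test_significant_reverse_excluded(self):
        tr = reverse_mr_filter(triangle(), {"mediator_to_exposure": 1e-4,
                                            "outcome_to_mediator": 0.6})
        assert tr.reverse_excluded

    def test_exclusion_is_per_pair(self):
        # the same mediator can be excluded for one phenotype and kept for another
        tr_mets = reverse_mr_filter(triangle(), {"mediator_to_exposure": 1e-4})
        tr_bmi = reverse_mr_filter(triangle(), {"mediator_to_exposure": 0.5})
        assert tr_mets.reverse_excluded and not tr_bmi.reverse_excluded

    @pytest.mark.parametrize("coloc_tier,validated,expected", [
        ("colocalized", True, "two_star"),
        ("suggestive", False, "one_star"),
        ("none", True, "one_star"),
        ("none", False, "none"),
        ("suggestive", True, "two_star"),
    ])
    def test_evidence_tiers(self, coloc_tier, validated, expected):
        tr = triangle()
        tr.coloc_tier = coloc_tier
        tr.validated_external = validated
        assert assign_evidence_tier(tr).evidence_tier == expected

    def test_unknown_tier_rejected(self):
        tr = triangle()
        tr.coloc_tier = "maybe"
        with pytest.raises(InputError):
            assign_evidence_tier(tr)
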