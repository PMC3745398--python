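import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

import snpmeta as sm
from snpmeta.effects import ContrastTable, GeneticModel
from snpmeta.exceptions import DomainError
from conftest import make_effect


def effects_from(ys, vs):
    return [make_effect(y, v, study_id=f"s{i}")
            for i, (y, v) in enumerate(zip(ys, vs))]


class TestInverseVariance:
    def test_single_study_identity(self):
        res = sm.pool_inverse_variance(effects_from([0.3], [0.04]))
        assert res.log_or == pytest.approx(0.3)
        assert res.se == pytest.approx(0.2)
        assert res.q == pytest.approx(0.0)

    def test_equal_weights_hand_value(self):
        res = sm.pool_inverse_variance(effects_from([0.0, 0.2], [0.01, 0.01]))
        assert res.log_or == pytest.approx(0.1)
        assert res.q == pytest.approx(2.0)

    def test_identical_studies_no_dispersion(self):
        res = sm.pool_inverse_variance(effects_from([0.1] * 3, [0.04] * 3))
        assert res.log_or == pytest.approx(0.1)
        assert res.se == pytest.approx(0.11547, abs=1e-5)
        assert res.q == pytest.approx(0.0)

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            sm.pool_inverse_variance([])


class TestDerSimonianLaird:
    def test_hand_computed_tau2(self):
        # Q = 2, C = 200 - 20000/200 = 100, tau2 = (2-1)/100
        res = sm.pool_dersimonian_laird(effects_from([0.0, 0.2], [0.01, 0.01]))
        assert res.tau2 == pytest.approx(0.01)
        assert res.log_or == pytest.approx(0.1)
        assert res.se == pytest.approx(0.1)

    def test_homogeneous_set_collapses_to_fixed_effect(self):
        ys, vs = [0.10, 0.11, 0.09], [0.05, 0.04, 0.06]
        dl = sm.pool_dersimonian_laird(effects_from(ys, vs))
        iv = sm.pool_inverse_variance(effects_from(ys, vs))
        assert dl.tau2 == 0.0
        assert dl.log_or == pytest.approx(iv.log_or)
        assert dl.se == pytest.approx(iv.se)

    def test_matches_statsmodels_reference(self, example_table):
        """Independent cross-check of DL pooling on the shipped 26 studies."""
        effs = [sm.study_effect(r, GeneticModel.ALLELE)
                for r in example_table]
        ours = sm.pool_dersimonian_laird(effs)
        ref = combine_effects(np.array([e.log_or for e in effs]),
                              np.array([e.variance for e in effs]),
                              method_re="dl")
        assert ours.log_or == pytest.approx(float(ref.mean_effect_re),
                                            rel=1e-10)
        assert ours.tau2 == pytest.approx(float(ref.tau2), rel=1e-10)
        assert ours.q == pytest.approx(float(ref.q), rel=1e-10)


class TestMantelHaenszel:
    def test_single_table_identity(self):
        res = sm.pool_mantel_haenszel(
            [ContrastTable(GeneticModel.ALLELE, 10, 10, 10, 10)])
        assert res.or_ == pytest.approx(1.0)

    def test_two_table_hand_value(self):
        tables = [ContrastTable(GeneticModel.ALLELE, 10, 10, 10, 10),
                  ContrastTable(GeneticModel.ALLELE, 20, 10, 10, 20)]
        res = sm.pool_mantel_haenszel(tables)
        assert res.or_ == pytest.approx((2.5 + 400 / 60) / (2.5 + 100 / 60),
                                        rel=1e-12)
        assert res.or_ == pytest.approx(2.2, abs=1e-12)

    def test_consensus_tables_return_common_or(self):
        # every table has OR exactly 2
        tables = [ContrastTable(GeneticModel.ALLELE, 20, 10, 10, 10),
                  ContrastTable(GeneticModel.ALLELE, 40, 10, 20, 10),
                  ContrastTable(GeneticModel.ALLELE, 10, 20, 5, 20)]
        res = sm.pool_mantel_haenszel(tables)
        assert res.or_ == pytest.approx(2.0, rel=1e-12)

    @given(seed=st.integers(0, 50))
    def test_agrees_with_inverse_variance_on_large_homogeneous_sets(self, seed):
        """MH and IV fixed effects agree within 1% when every study shares
        the same odds ratio and all cells are large."""
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.7, 1.6)
        tables, effects = [], []
        for i in range(6):
            b, c, d = rng.integers(80, 600, size=3).astype(float)
            t = ContrastTable(GeneticModel.ALLELE, theta * b * c / d, b, c, d)
            tables.append(t)
            effects.append(sm.woolf_effect(t, study_id=str(i)))
        mh = sm.pool_mantel_haenszel(tables)
        iv = sm.pool_inverse_variance(effects)
        assert mh.or_ == pytest.approx(theta, rel=1e-9)
        assert iv.or_ == pytest.approx(mh.or_, rel=0.01)


class TestHeterogeneity:
    def test_i2_definition(self):
        effs = effects_from([0.0, 0.2], [0.01, 0.01])  # Q = 2, df = 1
        het = sm.heterogeneity(effs)
        assert het.q == pytest.approx(2.0)
        assert het.i2 == pytest.approx(0.5)

    def test_identical_effects(self):
        het = sm.heterogeneity(effects_from([0.1] * 4, [0.02] * 4))
        assert het.q == pytest.approx(0.0)
        assert het.i2 == 0.0
        assert het.p_q == pytest.approx(1.0)

    def test_i2_truncated_at_zero(self):
        # Q = 0.5 < df = 1
        effs = effects_from([0.0, 0.1], [0.01, 0.01])
        het = sm.heterogeneity(effs)
        assert het.q == pytest.approx(0.5)
        assert het.i2 == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(DomainError):
            sm.heterogeneity(effects_from([0.1], [0.01]))


logor = st.floats(-1.5, 1.5)
variance = st.floats(0.001, 0.5)


@given(ys=st.lists(logor, min_size=2, max_size=12),
       vs=st.lists(variance, min_size=12, max_size=12))
def test_pooled_estimate_within_study_range_and_dl_wider(ys, vs):
    effs = effects_from(ys, vs[:len(ys)])
    iv = sm.pool_inverse_variance(effs)
    dl = sm.pool_dersimonian_laird(effs)
    lo, hi = min(ys), max(ys)
    assert lo - 1e-9 <= iv.log_or <= hi + 1e-9
    assert lo - 1e-9 <= dl.log_or <= hi + 1e-9
    assert dl.se >= iv.se - 1e-12


@given(seed=st.integers(0, 30))
def test_mh_pooled_or_within_per_study_or_range(seed):
    rng = np.random.default_rng(seed)
    tables = [ContrastTable(GeneticModel.ALLELE,
                            *map(float, rng.integers(5, 200, size=4)))
              for _ in range(5)]
    mh = sm.pool_mantel_haenszel(tables)
    ors = [t.a * t.d / (t.b * t.c) for t in tables]
    assert min(ors) - 1e-9 <= mh.or_ <= max(ors) + 1e-9
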