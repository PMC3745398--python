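import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import snpmeta as sm
from snpmeta.effects import GeneticModel
from snpmeta.exceptions import (CapabilityError, DomainError,
                                InsufficientStudiesError)
from snpmeta.moderators import q_between_fixed
from conftest import make_effect


def effects_from(ys, vs, prefix="s"):
    return [make_effect(y, v, study_id=f"{prefix}{i}")
            for i, (y, v) in enumerate(zip(ys, vs))]


class TestQBetween:
    def test_identical_groups_give_zero(self):
        g1 = effects_from([0.1, 0.1], [0.01, 0.01])
        g2 = effects_from([0.1, 0.1], [0.01, 0.01], prefix="t")
        q_b, df = q_between_fixed([g1, g2])
        assert q_b == pytest.approx(0.0)
        assert df == 1

    def test_two_singleton_groups_hand_value(self):
        g1 = effects_from([0.1], [0.01])
        g2 = effects_from([0.3], [0.01], prefix="t")
        q_b, df = q_between_fixed([g1, g2])
        # overall fixed mean 0.2, group weights 100: 2 * 100 * 0.1^2
        assert q_b == pytest.approx(2.0)

    @given(seed=st.integers(0, 40))
    def test_fixed_effect_q_decomposition(self, seed):
        """Q_total = sum of within-group Q + Q_between, exactly."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 5, size=3)
        groups = [effects_from(rng.normal(0.1 * g, 0.3, size=n),
                               rng.uniform(0.01, 0.3, size=n),
                               prefix=f"g{g}_")
                  for g, n in enumerate(sizes)]
        q_b, _ = q_between_fixed(groups)
        q_within = sum(sm.pool_inverse_variance(g).q for g in groups)
        q_total = sm.pool_inverse_variance(
            [e for g in groups for e in g]).q
        assert q_within + q_b == pytest.approx(q_total, abs=1e-8)


class TestSubgroupAnalysis:
    def test_design_groups_on_example_table(self, example_table):
        sr = sm.subgroup_analysis(example_table, GeneticModel.ALLELE,
                                  group_by="design")
        assert set(sr.groups) == {"GWAS", "CandidateGene"}
        assert sum(r.k for r in sr.groups.values()) == 26
        assert sr.df_between == 1
        assert 0 <= sr.p_between <= 1

    def test_single_group_input(self, example_table):
        only_gwas = sm.StudyTable(
            [r for r in example_table if r.design is sm.Design.GWAS])
        sr = sm.subgroup_analysis(only_gwas, GeneticModel.ALLELE,
                                  group_by="design")
        assert sr.q_between == 0.0
        assert sr.p_between == 1.0


class TestSubtypeContrast:
    def _table(self, seed=5, or_pos=1.17, or_neg=1.08, k=12, n=4000):
        spec = sm.SubtypeSpec(or_er_pos=or_pos, or_er_neg=or_neg)
        cfg = sm.SimulationConfig(k=k, seed=seed, tau2=0.0, subtype_spec=spec,
                                  n_case_range=(n, n), n_control_range=(n, n))
        return sm.simulate_meta(cfg)

    def test_recovers_generating_subtype_ors(self):
        table = self._table(k=20, n=8000)
        c = sm.subtype_contrast(table, GeneticModel.ALLELE,
                                (sm.StratumLabel.ER_POS,
                                 sm.StratumLabel.ER_NEG))
        assert c.pooled_a.or_ == pytest.approx(1.17, abs=0.05)
        assert c.pooled_b.or_ == pytest.approx(1.08, abs=0.05)
        assert c.diff_log_or > 0

    def test_identical_subtype_ors_give_null_difference(self):
        zs = []
        for seed in range(10):
            table = self._table(seed=seed, or_pos=1.1, or_neg=1.1)
            c = sm.subtype_contrast(table, GeneticModel.ALLELE,
                                    (sm.StratumLabel.ER_POS,
                                     sm.StratumLabel.ER_NEG))
            zs.append(c.diff_z)
        assert abs(np.mean(zs)) < 0.75  # ~2.4 sigma of the replicate mean

    def test_missing_strata_raise_capability_error(self, example_table):
        with pytest.raises(CapabilityError):
            sm.subtype_contrast(example_table, GeneticModel.ALLELE,
                                (sm.StratumLabel.ER_POS,
                                 sm.StratumLabel.ER_NEG))


class TestMetaRegression:
    def test_intercept_only_reduces_to_dl(self, example_table):
        effs = [sm.study_effect(r, GeneticModel.ALLELE)
                for r in example_table]
        mr = sm.meta_regression(effs)
        dl = sm.pool_dersimonian_laird(effs)
        assert mr.coef[0] == pytest.approx(dl.log_or, rel=1e-10)
        assert mr.tau2 == pytest.approx(dl.tau2, rel=1e-10)
        assert mr.se[0] == pytest.approx(dl.se, rel=1e-10)

    def test_exact_linear_fit_recovered(self):
        x = np.arange(6, dtype=float)
        y = 0.05 + 0.1 * x
        effs = effects_from(y, [0.01] * 6)
        mr = sm.meta_regression(effs, covariates=x[:, None], names=["x"])
        assert mr.tau2 == 0.0
        assert mr.coef == pytest.approx([0.05, 0.1], abs=1e-12)

    def test_binary_covariate_matches_between_group_q(self):
        """With tau2-hat = 0 the moderator z^2 equals the two-group Q_between."""
        y = [0.10, 0.11, 0.09, 0.30, 0.31, 0.29]
        v = [0.04] * 6
        x = np.array([0.0, 0, 0, 1, 1, 1])
        effs = effects_from(y, v)
        mr = sm.meta_regression(effs, covariates=x[:, None], names=["grp"])
        assert mr.tau2 == 0.0
        q_b, _ = q_between_fixed([effs[:3], effs[3:]])
        assert mr.z[1] ** 2 == pytest.approx(q_b, rel=0.05)

    def test_rank_deficient_design_names_columns(self):
        effs = effects_from([0.1, 0.2, 0.3, 0.4], [0.01] * 4)
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(DomainError, match="collinear"):
            sm.meta_regression(effs, covariates=X, names=["a", "b"],
                               add_intercept=False)

    def test_too_few_studies_rejected(self):
        effs = effects_from([0.1, 0.2], [0.01] * 2)
        with pytest.raises(InsufficientStudiesError):
            sm.meta_regression(effs, covariates=np.array([[0.], [1.]]))

    def test_ethnicity_effect_sign_recovered_in_simulation(self):
        """A true White-vs-East-Asian effect difference puts the right sign
        on the ethnicity coefficient in the vast majority of replicates."""
        correct = 0
        reps = 50
        rng = np.random.default_rng(4)
        for rep in range(reps):
            seeds = rng.integers(0, 2 ** 31 - 1, size=2)
            white = sm.simulate_meta(sm.SimulationConfig(
                k=20, seed=int(seeds[0]), true_or=1.14, tau2=0.001,
                ethnicity_mix={sm.EthnicGroup.WHITE: 1.0},
                n_case_range=(20000, 20000), n_control_range=(20000, 20000)))
            asian = sm.simulate_meta(sm.SimulationConfig(
                k=20, seed=int(seeds[1]), true_or=1.12, tau2=0.001,
                ethnicity_mix={sm.EthnicGroup.EAST_ASIAN: 1.0},
                n_case_range=(20000, 20000), n_control_range=(20000, 20000)))
            effs = [sm.study_effect(r, GeneticModel.ALLELE)
                    for r in list(white) + list(asian)]
            x = np.array([0.0] * 20 + [1.0] * 20)
            mr = sm.meta_regression(effs, covariates=x[:, None],
                                    names=["east_asian"])
            correct += mr.coef[1] < 0
        assert correct / reps >= 0.9
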