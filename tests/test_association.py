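"""MAF arithmetic, Pearson and logistic tests, topic association, PheWAS."""

import numpy as np
import pytest
import scipy.stats

import genotopics as gt
from genotopics.errors import AlignmentError, DegenerateInputError
from tests.conftest import truth_descriptors


class TestMAF:
    def test_printed_genotype_distribution(self):
        # 85.2% homozygous major, 14.2% het, 0.6% homozygous minor
        g = np.repeat([0, 1, 2], [852, 142, 6])
        assert gt.compute_maf(g) == pytest.approx(0.077, abs=1e-12)

    def test_all_zeros_and_all_twos(self):
        assert gt.compute_maf(np.zeros(10, dtype=int)) == 0.0
        with pytest.warns(UserWarning, match="major"):
            assert gt.compute_maf(np.full(10, 2)) == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.2, 500)
        assert gt.compute_maf(g) == gt.compute_maf(g[::-1])
        assert gt.compute_maf(g) == gt.compute_maf(rng.permutation(g))

    def test_empty_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            gt.compute_maf(np.array([], dtype=int))

    def test_genotype_vector_validates_entries(self):
        with pytest.raises(ValueError):
            gt.GenotypeVector(counts=np.array([0, 3]))


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = gt.pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_symmetric_design_gives_zero_correlation(self):
        r, p = gt.pearson_test([1, 2, 3, 4], [1, 0, 0, 1])
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_reference(self):
        """r from the product-moment formula, p from the t distribution."""
        rng = np.random.default_rng(14)
        for _ in range(50):
            n = rng.integers(5, 200)
            x, y = rng.normal(size=n), rng.normal(size=n)
            xc, yc = x - x.mean(), y - y.mean()
            r_ref = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            t = r_ref * np.sqrt((n - 2) / (1 - r_ref**2))
            p_ref = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
            r, p = gt.pearson_test(x, y)
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(8)
        pvals = np.empty(10_000)
        for i in range(pvals.size):
            pvals[i] = gt.pearson_test(rng.normal(size=50), rng.normal(size=50))[1]
        ks = scipy.stats.kstest(pvals, "uniform").statistic
        crit = 1.628 / np.sqrt(pvals.size)  # alpha = 0.01
        assert ks <= crit

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gt.pearson_test([1, 2], [3, 4])
        with pytest.raises(ValueError):
            gt.pearson_test([1, 1, 1], [1, 2, 3])


class TestLogistic:
    def test_null_model_intercept(self):
        rng = np.random.default_rng(1)
        y = rng.binomial(1, 0.3, 2000)
        x = rng.normal(size=2000)
        res = gt.logistic_fit(y, x[:, None])
        phat = y.mean()
        assert res.coef[0] == pytest.approx(np.log(phat / (1 - phat)), abs=0.15)
        assert abs(res.coef[1]) < 0.15
        assert res.converged

    def test_two_by_two_table_slope_is_log_odds_ratio(self):
        # exposed cases a=30, exposed controls b=10, unexposed c=20, d=40
        y = np.repeat([1, 0, 1, 0], [30, 10, 20, 40])
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [30, 10, 20, 40])
        res = gt.logistic_fit(y, x[:, None])
        assert res.coef[1] == pytest.approx(np.log(6.0), abs=1e-6)

    def test_matches_grid_search_mle(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.4 + 0.8 * x))))
        res = gt.logistic_fit(y, x[:, None])

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -(y @ eta - np.logaddexp(0, eta).sum())

        # coarse-to-fine grid around the truth region
        b0s = np.linspace(-1, 2, 301)
        b1s = np.linspace(-1, 2.5, 351)
        grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        assert res.coef[0] == pytest.approx(b0s[i], abs=1e-2)
        assert res.coef[1] == pytest.approx(b1s[j], abs=1e-2)
        # returned coefficients beat every grid point in likelihood
        assert nll(*res.coef) <= grid.min() + 1e-9

    def test_separation_flagged_not_fatal(self):
        y = np.repeat([0, 1], 20)
        x = np.repeat([0.0, 1.0], 20)
        res = gt.logistic_fit(y, x[:, None])
        assert res.separation_flagged or not res.converged

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        with pytest.raises(np.linalg.LinAlgError):
            gt.logistic_fit((x > 0).astype(int), np.column_stack([x, 2 * x]))

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            gt.logistic_fit(np.array([0, 1, 2]), np.ones((3, 1)))


class TestTopicAssociation:
    def test_planted_topic_detected(self, default_cohort, default_model):
        c, model = default_cohort, default_model
        table = gt.topic_association(model, c.genotype, c.age, c.sex)
        topics = table[table["predictor"].str.startswith("topic_")]
        # identify the fitted topic matched to the planted core
        desc = gt.top_descriptors(model.H, c.X.phecodes, t=c.config.core_size)
        _, matching = gt.topic_agreement(desc, truth_descriptors(c))
        fitted_target = next(i for i, j in matching if j == c.config.target_topic)
        best = topics["r"].abs().idxmax()
        assert topics.loc[best, "predictor"] == f"topic_{fitted_target}"
        assert topics.loc[best, "p_pcc"] < 1e-3
        assert topics.loc[best, "r"] > 0
        assert topics.loc[best, "p_lr"] < 1e-3
        assert topics.loc[best, "lr_coefficient"] > 0

    def test_covariate_rows_present(self, default_cohort, default_model):
        table = gt.topic_association(
            default_model, default_cohort.genotype,
            default_cohort.age, default_cohort.sex,
        )
        assert list(table["predictor"].tail(2)) == ["age", "sex"]
        assert len(table) == default_model.k + 2

    def test_marginal_mode_agrees_in_direction(self, default_cohort, default_model):
        c = default_cohort
        joint = gt.topic_association(default_model, c.genotype, c.age, c.sex)
        marg = gt.topic_association(default_model, c.genotype, c.age, c.sex,
                                    joint=False)
        jt = joint[joint["predictor"].str.startswith("topic_")]
        mt = marg[marg["predictor"].str.startswith("topic_")]
        strongest = jt["r"].abs().idxmax()
        assert np.sign(jt.loc[strongest, "lr_coefficient"]) == np.sign(
            mt.loc[strongest, "lr_coefficient"]
        )

    def test_misaligned_ids_rejected(self, default_model):
        n = default_model.W.shape[0]
        bad = gt.GenotypeVector(
            counts=np.zeros(n, dtype=int),
            individual_ids=[f"missing_{i}" for i in range(n)],
        )
        with pytest.raises(AlignmentError, match="lack genotypes"):
            gt.topic_association(default_model, bad, np.ones(n), np.ones(n))

    def test_permuting_genotype_breaks_association(self, default_cohort, default_model):
        c = default_cohort
        desc = gt.top_descriptors(default_model.H, c.X.phecodes,
                                  t=c.config.core_size)
        _, matching = gt.topic_agreement(desc, truth_descriptors(c))
        target = next(i for i, j in matching if j == c.config.target_topic)
        rng = np.random.default_rng(0)
        n_runs, n_null = 30, 0
        for _ in range(n_runs):
            gperm = rng.permutation(c.genotype.counts)
            p = gt.pearson_test(default_model.W[:, target], gperm)[1]
            n_null += p > 0.05
        # permutation severs the planted signal: the topic is null in the
        # vast majority of shuffles
        assert n_null >= int(0.8 * n_runs)


@pytest.fixture(scope="module")
def phewas_result(default_cohort):
    c = default_cohort
    return gt.phewas(c.X, c.genotype, c.age, c.sex)


class TestPhewas:
    def test_bonferroni_threshold_arithmetic(self, phewas_result):
        assert phewas_result.bonferroni == pytest.approx(
            0.05 / phewas_result.n_tested
        )

    def test_min_case_phecodes_skipped(self, default_cohort):
        c = default_cohort
        res = gt.phewas(c.X, c.genotype, c.age, c.sex, min_cases=10_000)
        assert res.n_tested == 0
        assert (res.table["status"] == "skipped_min_cases").all()

    def test_core_phecodes_enriched_among_top_hits(self, default_cohort,
                                                   phewas_result):
        c = default_cohort
        tab = phewas_result.table.dropna(subset=["p"]).reset_index(drop=True)
        ranks = tab["p"].rank()
        core = set(c.core_phecodes[c.config.target_topic])
        in_core = tab["phecode"].isin(core)
        assert in_core.sum() > 0
        assert ranks[in_core].median() < ranks[~in_core].median()

    def test_direction_agrees_with_topic_association(self, default_cohort,
                                                     phewas_result):
        c = default_cohort
        core = set(c.core_phecodes[c.config.target_topic])
        sub = phewas_result.table[phewas_result.table["phecode"].isin(core)]
        # planted effect is positive, so core phecodes should skew positive
        assert (sub["coefficient"] > 0).mean() > 0.5

    def test_permuted_genotype_controls_familywise_error(self):
        cfg = gt.SimulationConfig(
            n_individuals=400, n_phecodes=100, n_topics=4, core_size=8,
            effect_beta=0.0, target_topic=1, seed=3,
        )
        c = gt.simulate_cohort(cfg)
        rng = np.random.default_rng(5)
        n_clean = 0
        n_runs = 25
        for _ in range(n_runs):
            gperm = gt.GenotypeVector(
                counts=rng.permutation(c.genotype.counts),
                individual_ids=c.X.individual_ids,
            )
            res = gt.phewas(c.X, gperm, c.age, c.sex, min_cases=10)
            pmin = res.table["p"].min()
            n_clean += not (pmin < res.bonferroni)
        assert n_clean >= int(0.9 * n_runs)
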