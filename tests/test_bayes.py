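import numpy as np
import pandas as pd
import pytest

from strokephys import (
    CohortSpec,
    InsufficientDataError,
    ModelSpec,
    ValidationError,
    bf_category,
    compare_if_models,
    directional_bf,
    emmeans,
    fit_hierarchical,
    fit_if_model,
    planned_post_warmup_draws,
    simulate_cohort,
)
from strokephys.bayes import PosteriorSummary


def quick_fit(df, spec=None, seed=0, **kw):
    spec = spec or ModelSpec(outcome_name="y")
    kw.setdefault("chains", 2)
    kw.setdefault("iterations", 1000)
    kw.setdefault("warmup", 400)
    return fit_hierarchical(df, spec, seed=seed, **kw)


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(
        outcome_name="y",
        intercept=-44.0,
        fixed_effects={"group[stroke]": -0.70},
        re_sd_intercept=1.0,
        re_sd_hemisphere=0.4,
        re_corr=0.2,
        residual_sd=1.2,
        seed=21,
    )
    return simulate_cohort(spec)


class TestBFCategories:
    @pytest.mark.parametrize(
        "bf,category",
        [
            (0.5, "none"),
            (1.0, "none"),        # boundary belongs to the lower category
            (1.16, "anecdotal"),  # reported AIS-length evidence ratio
            (3.0, "anecdotal"),
            (4.45, "moderate"),
            (9.52, "moderate"),   # reported AP-threshold evidence ratio
            (10.0, "moderate"),
            (15.1, "strong"),     # reported AP-amplitude evidence ratio
            (100.0, "strong"),
            (117.43, "extreme"),
        ],
    )
    def test_mapping(self, bf, category):
        assert bf_category(bf) == category


class TestDirectionalBF:
    def test_hand_written_draws(self):
        ht = directional_bf(np.array([-1.0, -2.0, -3.0, 1.0]), direction="<")
        assert ht.posterior_prob == 0.75
        assert ht.evidence_ratio == pytest.approx(3.0)
        assert not ht.capped

    def test_symmetric_draws_give_unit_ratio(self):
        draws = np.concatenate([np.linspace(-3, -0.1, 500), np.linspace(0.1, 3, 500)])
        ht = directional_bf(draws, direction="<")
        assert ht.evidence_ratio == pytest.approx(1.0)

    def test_all_one_side_is_capped(self):
        ht = directional_bf(-np.abs(np.random.default_rng(0).normal(size=100)) - 0.1, direction="<")
        assert ht.capped and ht.evidence_ratio == 100.0
        opposite = directional_bf(-np.ones(100), direction=">")
        assert opposite.capped and opposite.evidence_ratio == pytest.approx(0.01)

    def test_er_product_is_one_over_random_contrasts(self):
        """ER(>) x ER(<) = 1 on the same finite draw set, across 100
        random contrasts (uncapped cases)."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            draws = rng.normal(rng.normal(), 1.0, size=400)
            lt = directional_bf(draws, direction="<")
            gt = directional_bf(draws, direction=">")
            if lt.capped or gt.capped:
                continue
            assert lt.evidence_ratio * gt.evidence_ratio == pytest.approx(1.0)

    def test_contrast_by_name_and_weights(self, cohort):
        df, _ = cohort
        post = quick_fit(df)
        by_name = directional_bf(post, "group[stroke]", "<")
        by_weight = directional_bf(post, {"group[stroke]": 1.0}, "<")
        assert by_name.posterior_prob == by_weight.posterior_prob


class TestBookkeeping:
    def test_reported_sampler_settings_draw_total(self):
        from strokephys.reported import SAMPLER_SETTINGS

        assert planned_post_warmup_draws(**SAMPLER_SETTINGS) == 160_000

    def test_fit_draw_shape_matches_bookkeeping(self, cohort):
        df, _ = cohort
        post = quick_fit(df, chains=3, iterations=700, warmup=300)
        assert post.n_draws == 3 * 400
        assert post.beta.shape[:2] == (3, 400)
        assert post.beta_flat.shape[0] == post.n_draws

    def test_invalid_warmup(self):
        with pytest.raises(ValidationError):
            planned_post_warmup_draws(4, 1000, 1000)


class TestFitValidation:
    def test_single_animal_rejected(self, cohort):
        df, _ = cohort
        one = df[df.animal_id == df.animal_id.iloc[0]]
        with pytest.raises(InsufficientDataError):
            quick_fit(one)

    def test_log_transform_needs_positive_outcomes(self, cohort):
        df, _ = cohort
        with pytest.raises(ValidationError):
            quick_fit(df, ModelSpec(outcome_name="y", transform="log"))

    def test_seeded_reproducibility(self, cohort):
        df, _ = cohort
        a = quick_fit(df, seed=9)
        b = quick_fit(df, seed=9)
        assert np.array_equal(a.beta, b.beta)
        c = quick_fit(df, seed=10)
        assert not np.array_equal(a.beta, c.beta)

    def test_posterior_group_effect_near_truth(self, cohort):
        df, _ = cohort
        post = quick_fit(df)
        d = post.coef_draws("group[stroke]")
        lo, hi = np.quantile(d, [0.05, 0.95])
        assert lo < -0.70 < hi or abs(d.mean() + 0.70) < 1.5


class TestEmmeans:
    def test_intercept_only_model_equals_posterior_intercept(self, cohort):
        df, _ = cohort
        post = quick_fit(df, ModelSpec(outcome_name="y", fixed_factors=()))
        em = emmeans(post)
        assert len(em) == 1
        assert em["mean"].iloc[0] == pytest.approx(post.coef_draws("(Intercept)").mean())

    def test_grand_emm_is_mean_of_level_emms(self, cohort):
        """On the identity scale with a balanced grid, the grand EMM is the
        equal-weight average of the per-level EMMs."""
        df, _ = cohort
        post = quick_fit(df)
        grand = emmeans(post)["mean"].iloc[0]
        by_group = emmeans(post, by=["group"])["mean"]
        assert grand == pytest.approx(by_group.mean(), rel=1e-12)

    def test_log_scale_hand_oracle(self):
        """Back-transformed EMMs from 10 hand-written draws match a direct
        hand computation of the grid average + exp."""
        spec = ModelSpec(outcome_name="y", transform="log", fixed_factors=("group",))
        beta = np.column_stack(
            [np.linspace(2.9, 3.1, 10), np.linspace(-0.2, 0.2, 10)]
        )  # (Intercept), group[stroke]
        post = PosteriorSummary(
            spec=spec,
            coef_names=["(Intercept)", "group[stroke]"],
            beta=beta[None],
            theta_natural=np.zeros((1, 10, 4)),
            chains=1,
            iterations=11,
            warmup=1,
            seed=0,
            rhat={},
            ess={},
            reliable=True,
        )
        em = emmeans(post, by=["group"])
        hand_sham = np.exp(beta[:, 0]).mean()
        hand_stroke = np.exp(beta[:, 0] + beta[:, 1]).mean()
        lookup = dict(zip(em["group"], em["mean"]))
        assert lookup["sham"] == pytest.approx(hand_sham)
        assert lookup["stroke"] == pytest.approx(hand_stroke)
        # grand mean averages the two cells on the link scale per draw
        grand = emmeans(post)["mean"].iloc[0]
        assert grand == pytest.approx(np.exp(beta[:, 0] + beta[:, 1] / 2).mean())

    def test_back_transform_preserves_order(self, cohort):
        df, _ = cohort
        post = quick_fit(df, ModelSpec(outcome_name="y", transform="identity"))
        em = emmeans(post, by=["group", "hemisphere"])
        link_rank = em["link_mean"].rank().to_list()
        nat_rank = em["mean"].rank().to_list()
        assert link_rank == nat_rank

    def test_unknown_by_factor_rejected(self, cohort):
        df, _ = cohort
        post = quick_fit(df)
        with pytest.raises(ValidationError):
            emmeans(post, by=["genotype"])


def make_if_long(seed, group_shift=-0.3, current_effect=True):
    """Long-format evoked-frequency table with a shared saturating I-F
    shape on the log1p scale (the generating model of the shared-curve
    fit) and a declared group shift."""
    rng = np.random.default_rng(seed)
    spec = CohortSpec(
        outcome_name="evoked_spike_freq",
        intercept=1.5,
        fixed_effects={"group[stroke]": group_shift},
        re_sd_intercept=0.3,
        re_sd_hemisphere=0.15,
        residual_sd=0.3,
        n_animals_per_cell=2,
        cells_per_stratum=1,
        seed=seed,
    )
    df, _ = simulate_cohort(spec)
    levels = np.arange(25.0, 501.0, 50.0)
    rows = []
    for _, r in df.iterrows():
        for current in levels:
            link = r.outcome_value + 0.2 * rng.standard_normal()
            if current_effect:
                link += 1.2 * np.log1p(current / 100.0)
            rows.append(
                {
                    **r.drop("outcome_value").to_dict(),
                    "current_pA": current,
                    "outcome_value": max(0.0, float(np.expm1(link))),
                }
            )
    return pd.DataFrame(rows)


class TestIFModels:
    def test_missing_current_column_rejected(self, cohort):
        df, _ = cohort
        with pytest.raises(ValidationError):
            fit_if_model(df.assign(outcome_name="evoked_spike_freq"))

    def test_group_shift_recovered_within_cri(self):
        long = make_if_long(seed=1)
        post = fit_if_model(long, chains=2, iterations=1000, warmup=400, seed=1)
        d = post.coef_draws("group[stroke]")
        lo, hi = np.quantile(d, [0.05, 0.95])
        assert lo < -0.3 < hi

    def test_zero_current_effect_basis_cris_contain_zero(self):
        long = make_if_long(seed=2, current_effect=False)
        post = fit_if_model(long, chains=2, iterations=1000, warmup=400, seed=2)
        for name in post.covariate_names:
            d = post.coef_draws(name)
            lo, hi = np.quantile(d, [0.05, 0.95])
            assert lo < 0.0 < hi, name

    def test_identical_models_indeterminate(self):
        long = make_if_long(seed=3)
        post = fit_if_model(long, chains=2, iterations=800, warmup=300, seed=3)
        cmp = compare_if_models(post, post, n_draws=100, seed=0)
        assert cmp.preferred == "indeterminate"
        assert cmp.elpd_diff == 0.0

    def test_mismatched_outcomes_rejected(self):
        m1 = fit_if_model(make_if_long(seed=4), chains=2, iterations=800, warmup=300, seed=4)
        m2 = fit_if_model(
            make_if_long(seed=5, group_shift=0.5), chains=2, iterations=800, warmup=300, seed=5
        )
        with pytest.raises(ValidationError):
            compare_if_models(m1, m2)

    def test_generating_model_preferred(self):
        long = make_if_long(seed=6)
        m1 = fit_if_model(long, model="shared_curve", chains=2, iterations=1000, warmup=400, seed=6)
        m2 = fit_if_model(long, model="factorial_poly", chains=2, iterations=1000, warmup=400, seed=7)
        cmp = compare_if_models(m1, m2, n_draws=200, seed=1)
        assert cmp.preferred == "shared_curve"
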