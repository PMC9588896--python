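import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from escalape import blrm
from escalape.blrm import (
    BLRMPrior,
    CohortRecord,
    EscalationRules,
    GridSpec,
    MtdRule,
    ToxicityIntervals,
)


def mc_interval_probs(prior, cohorts, dose, intervals=ToxicityIntervals(), n=1_000_000, seed=0):
    """Monte-Carlo oracle: prior draws importance-weighted by the likelihood."""
    rng = np.random.default_rng(seed)
    la = rng.normal(prior.mean_log_alpha, prior.sd_log_alpha, n)
    lb = rng.normal(prior.mean_log_beta, prior.sd_log_beta, n)
    logw = np.zeros(n)
    for c in cohorts:
        p = expit(la + np.exp(lb) * np.log(c.dose_mg / prior.ref_dose_mg))
        logw += c.n_dlt_patients * np.log(p) + (c.n_patients - c.n_dlt_patients) * np.log1p(-p)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    p = expit(la + np.exp(lb) * np.log(dose / prior.ref_dose_mg))
    p_under = w[p < intervals.under_upper].sum()
    p_over = w[p >= intervals.target_upper].sum()
    return float(p_under), float(1 - p_under - p_over), float(p_over)


class TestDltProbability:
    def test_half_at_reference_dose(self):
        for lb in (-2.0, 0.0, 1.5):
            assert blrm.dlt_probability(0.0, lb, 720.0, 720.0) == pytest.approx(0.5)

    def test_intercept_sets_reference_rate(self):
        assert blrm.dlt_probability(-1.3862944, 0.0, 100.0, 100.0) == pytest.approx(0.2, abs=1e-7)

    def test_closed_form_at_e_times_ref(self):
        # logit p = -1.3862944 + exp(0)*ln(e) = -0.3862944
        got = blrm.dlt_probability(-1.3862944, 0.0, np.e * 50.0, 50.0)
        assert got == pytest.approx(float(expit(-1.3862944 + 1.0)), abs=1e-12)
        assert got == pytest.approx(0.4046, abs=5e-4)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            blrm.dlt_probability(0.0, 0.0, 0.0, 720.0)
        with pytest.raises(ValueError):
            blrm.dlt_probability(0.0, 0.0, -5.0, 720.0)
        with pytest.raises(ValueError):
            blrm.dlt_probability(0.0, 0.0, 100.0, -1.0)

    @given(
        la=st.floats(-5, 5),
        lb=st.floats(-3, 3),
        d1=st.floats(1.0, 5000.0),
        d2=st.floats(1.0, 5000.0),
    )
    def test_strictly_increasing_in_dose(self, la, lb, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        p_lo = blrm.dlt_probability(la, lb, lo, 720.0)
        p_hi = blrm.dlt_probability(la, lb, hi, 720.0)
        assert 0.0 < p_lo < 1.0
        assert p_lo < p_hi


class TestCohortRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            CohortRecord(-1.0, 3, 0)
        with pytest.raises(ValueError):
            CohortRecord(40.0, 0, 0)
        with pytest.raises(ValueError):
            CohortRecord(40.0, 3, 4)


class TestFitPosterior:
    def test_weights_normalized(self, q3w_prior, q3w):
        post = blrm.fit_posterior(q3w_prior, list(q3w.cohorts))
        assert abs(post.weights.sum() - 1.0) <= 1e-10

    def test_prior_recovery_against_monte_carlo(self, q3w_prior):
        post = blrm.fit_posterior(q3w_prior, [])
        for dose in (40.0, 720.0, 1000.0):
            grid = blrm.interval_probabilities(post, dose)
            mc = mc_interval_probs(q3w_prior, [], dose)
            assert grid == pytest.approx(mc, abs=0.005)

    def test_posterior_against_monte_carlo_three_cohorts(self, q3w_prior, q3w):
        cohorts = list(q3w.cohorts[:3])
        post = blrm.fit_posterior(q3w_prior, cohorts)
        for dose in (120.0, 720.0):
            grid = blrm.interval_probabilities(post, dose)
            mc = mc_interval_probs(q3w_prior, cohorts, dose)
            assert grid == pytest.approx(mc, abs=0.005)

    def test_flat_dose_response_matches_1d_quadrature(self):
        # sd_log_beta -> 0 at mean -20: the slope is ~0 and every dose
        # shares p = expit(log_alpha); the 2-D fit must then agree with a
        # 1-D quadrature over log_alpha alone
        prior = BLRMPrior(
            ref_dose_mg=720.0,
            mean_log_alpha=logit(0.2),
            sd_log_alpha=2.0,
            mean_log_beta=-20.0,
            sd_log_beta=1e-6,
        )
        dose, k, n = 360.0, 2, 10
        # interval-probability error scales with the log_alpha node
        # spacing, so the 1e-4 comparison needs a fine alpha axis; the
        # beta axis is degenerate and can stay minimal
        spec = GridSpec(n_log_alpha=400_001, n_log_beta=2)
        post = blrm.fit_posterior(prior, [CohortRecord(dose, n, k)], spec)
        got = blrm.interval_probabilities(post, dose)

        la = np.linspace(prior.mean_log_alpha - 8 * 2.0, prior.mean_log_alpha + 8 * 2.0, 2_000_001)
        p = expit(la)
        dens = np.exp(-0.5 * ((la - prior.mean_log_alpha) / 2.0) ** 2) * p**k * (1 - p) ** (n - k)
        dens /= dens.sum()
        want = (
            float(dens[p < 0.16].sum()),
            float(dens[(p >= 0.16) & (p < 0.33)].sum()),
            float(dens[p >= 0.33].sum()),
        )
        assert got == pytest.approx(want, abs=1e-4)

    def test_truncating_bounds_warn(self, q3w_prior):
        spec = GridSpec(n_log_alpha=51, n_log_beta=51, log_alpha_bounds=(-1.0, 1.0))
        with pytest.warns(UserWarning, match="truncate"):
            blrm.fit_posterior(q3w_prior, [], spec)

    def test_deterministic(self, q3w_prior, q3w):
        a = blrm.fit_posterior(q3w_prior, list(q3w.cohorts))
        b = blrm.fit_posterior(q3w_prior, list(q3w.cohorts))
        assert np.array_equal(a.weights, b.weights)

    def test_invalid_cohort_type_rejected(self, q3w_prior):
        with pytest.raises(TypeError):
            blrm.fit_posterior(q3w_prior, [(40.0, 3, 0)])


class TestIntervalProbabilities:
    def test_partition_sums_to_one(self, q3w_posterior):
        for dose in (40.0, 360.0, 1000.0):
            probs = blrm.interval_probabilities(q3w_posterior, dose)
            assert sum(probs) == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_under(self, make_point_mass):
        post = make_point_mass(float(logit(0.05)), -20.0)
        assert blrm.interval_probabilities(post, 720.0) == (1.0, 0.0, 0.0)

    def test_point_mass_over(self, make_point_mass):
        post = make_point_mass(float(logit(0.40)), -20.0)
        assert blrm.interval_probabilities(post, 720.0) == (0.0, 0.0, 1.0)


class TestEwoc:
    def test_point_mass_admissible(self, make_point_mass, q3w_rules):
        post = make_point_mass(float(logit(0.10)), -20.0)
        admissible, p_over = blrm.ewoc_admissible(post, 720.0, q3w_rules)
        assert admissible and p_over == 0.0

    def test_point_mass_inadmissible(self, make_point_mass, q3w_rules):
        post = make_point_mass(float(logit(0.50)), -20.0)
        admissible, p_over = blrm.ewoc_admissible(post, 720.0, q3w_rules)
        assert not admissible and p_over == 1.0

    def test_q3w_top_dose_admissible(self, q3w_posterior, q3w_rules):
        admissible, p_over = blrm.ewoc_admissible(q3w_posterior, 1000.0, q3w_rules)
        assert admissible
        assert p_over < 0.25

    def test_monotone_admissibility_in_dose(self, qw_posterior, qw_rules, qw):
        flags = [
            blrm.ewoc_admissible(qw_posterior, d, qw_rules)[0]
            for d in qw.provisional_levels
        ]
        # once a dose fails, every higher dose fails
        for lower, higher in zip(flags, flags[1:]):
            assert lower or not higher

    def test_overdose_prob_nondecreasing_in_dose(self, q3w_posterior, q3w_rules):
        probs = [
            blrm.ewoc_admissible(q3w_posterior, d, q3w_rules)[1]
            for d in (40, 120, 360, 720, 1000)
        ]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_extra_dlt_never_lowers_overdose_prob(self, q3w_prior, q3w_rules):
        base = [CohortRecord(120.0, 4, 1), CohortRecord(360.0, 6, 1)]
        bumped = [CohortRecord(120.0, 4, 1), CohortRecord(360.0, 6, 2)]
        p0 = blrm.fit_posterior(q3w_prior, base)
        p1 = blrm.fit_posterior(q3w_prior, bumped)
        for dose in (360.0, 720.0, 1000.0):
            assert (
                blrm.ewoc_admissible(p1, dose, q3w_rules)[1]
                >= blrm.ewoc_admissible(p0, dose, q3w_rules)[1]
            )


class TestEscalationCap:
    def test_q3w_first_step(self, q3w_rules):
        assert blrm.escalation_cap(40.0, q3w_rules) == pytest.approx(120.0)

    def test_q3w_mid_step(self, q3w_rules):
        assert blrm.escalation_cap(360.0, q3w_rules) == pytest.approx(720.0)

    def test_qw_above_threshold(self, qw_rules):
        assert blrm.escalation_cap(120.0, qw_rules) == pytest.approx(240.0)

    def test_nonpositive_dose_rejected(self, q3w_rules):
        with pytest.raises(ValueError):
            blrm.escalation_cap(0.0, q3w_rules)


class TestRecommendNextDose:
    LEVELS = (40.0, 120.0, 360.0, 720.0, 1000.0)

    def test_all_inadmissible_stops(self, make_point_mass, q3w_rules):
        post = make_point_mass(float(logit(0.9)), -20.0)
        rec = blrm.recommend_next_dose(post, [40.0], self.LEVELS, q3w_rules)
        assert rec.stop and rec.dose_mg is None

    def test_single_admissible_level(self, make_point_mass, q3w_rules):
        # steep curve: admissible only at the lowest level
        post = make_point_mass(float(logit(0.999)), 2.2, ref_dose_mg=120.0)
        rec = blrm.recommend_next_dose(post, [40.0], self.LEVELS, q3w_rules)
        assert rec.dose_mg == 40.0

    def test_q3w_partial_history_recommends_720(self, q3w_prior, q3w_rules):
        cohorts = [CohortRecord(40, 3, 0), CohortRecord(120, 2, 0), CohortRecord(360, 2, 0)]
        post = blrm.fit_posterior(q3w_prior, cohorts)
        rec = blrm.recommend_next_dose(
            post, [c.dose_mg for c in cohorts], self.LEVELS, q3w_rules
        )
        # the +100% cap from 360 mg binds before target-interval maximization
        assert rec.dose_mg == 720.0
        row_1000 = next(r for r in rec.table if r["dose_mg"] == 1000.0)
        assert not row_1000["within_cap"] or not row_1000["reachable"]

    def test_no_skip_blocks_untested_jump(self, q3w_prior, q3w_rules):
        post = blrm.fit_posterior(q3w_prior, [CohortRecord(40, 3, 0)])
        rec = blrm.recommend_next_dose(post, [40.0], self.LEVELS, q3w_rules)
        assert rec.dose_mg == 120.0  # cannot jump past the untested 120

    def test_empty_levels_rejected(self, q3w_posterior, q3w_rules):
        with pytest.raises(ValueError):
            blrm.recommend_next_dose(q3w_posterior, [40.0], [], q3w_rules)


class TestDeclareMtd:
    def test_single_clean_cohort_names_its_dose(self, q3w_prior, q3w_rules):
        cohorts = [CohortRecord(40.0, 3, 0)]
        post = blrm.fit_posterior(q3w_prior, cohorts)
        admissible, p_over = blrm.ewoc_admissible(post, 40.0, q3w_rules)
        assert admissible and p_over < 0.25  # 0/3 cannot trip overdose control
        mtd = blrm.declare_mtd(
            post, cohorts, q3w_rules, MtdRule(min_patients_at_mtd=3)
        )
        assert mtd.dose_mg == 40.0

    def test_point_mass_toxic_everywhere_not_determined(self, make_point_mass, q3w_rules):
        post = make_point_mass(float(logit(0.9)), -20.0)
        mtd = blrm.declare_mtd(
            post, [CohortRecord(40.0, 6, 5)], q3w_rules, MtdRule(min_patients_at_mtd=3)
        )
        assert not mtd.determined

    def test_qw_study_declares_180(self, qw_posterior, qw, qw_rules):
        mtd = blrm.declare_mtd(qw_posterior, list(qw.cohorts), qw_rules)
        assert mtd.dose_mg == 180.0

    def test_requires_cohorts(self, qw_posterior, qw_rules):
        with pytest.raises(ValueError):
            blrm.declare_mtd(qw_posterior, [], qw_rules)


@settings(max_examples=25, deadline=None)
@given(
    n1=st.integers(1, 8),
    k1=st.integers(0, 8),
    n2=st.integers(1, 8),
    k2=st.integers(0, 8),
)
def test_monotone_admissibility_property(n1, k1, n2, k2):
    """If a dose fails overdose control, so does every higher dose."""
    k1, k2 = min(k1, n1), min(k2, n2)
    prior = blrm.reference_prior(720.0)
    rules = EscalationRules(cap_threshold_mg=120.0)
    cohorts = [CohortRecord(120.0, n1, k1), CohortRecord(720.0, n2, k2)]
    post = blrm.fit_posterior(prior, cohorts, GridSpec(n_log_alpha=101, n_log_beta=101))
    flags = [blrm.ewoc_admissible(post, d, rules)[0] for d in (40, 120, 360, 720, 1000)]
    for lower, higher in zip(flags, flags[1:]):
        assert lower or not higher
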