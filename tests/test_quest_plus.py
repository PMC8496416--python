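import math

import numpy as np
import pytest

from oknlab.errors import ConfigError
from oknlab.psychometric import C_WEIBULL, weibull_psi
from oknlab.quest_plus import DEFAULT_SLOPE_GRID, QuestPlus, outcome_likelihood
from oknlab.stimulus_geometry import contrast_ladder
from oracles import quest_posterior_oracle, quest_selection_oracle


@pytest.fixture
def ladder():
    return contrast_ladder()


def small_grid():
    return np.geomspace(0.001, 0.5, 9), np.array([1.0, 2.0, 3.0])


def test_uniform_prior_initialization(ladder):
    q = QuestPlus(ladder)
    assert q.posterior.shape == (39, 11)
    np.testing.assert_allclose(q.posterior, 1.0 / (39 * 11))
    assert q.posterior.sum() == pytest.approx(1.0, abs=1e-12)


def test_degenerate_and_custom_priors(ladder):
    prior = np.zeros((39, 11))
    prior[10, 3] = 1.0
    q = QuestPlus(ladder, prior=prior)
    assert q.posterior[10, 3] == 1.0
    prior2 = np.full((39, 11), 5.0)  # unnormalized mass is renormalized
    q2 = QuestPlus(ladder, prior=prior2)
    np.testing.assert_allclose(q2.posterior.sum(), 1.0)


def test_nonincreasing_ladder_rejected():
    with pytest.raises(ConfigError):
        QuestPlus([0.5, 0.3, 0.7])


def test_likelihood_half_at_candidate_threshold():
    assert outcome_likelihood(0.05, 0.05, 2.0) == pytest.approx(0.5)


def test_likelihood_monotone_and_zero_guess_rate():
    probs = [outcome_likelihood(c, 0.05, 3.0) for c in (0.001, 0.01, 0.05, 0.3)]
    assert all(b > a for a, b in zip(probs, probs[1:]))
    assert outcome_likelihood(1e-9, 0.05, 3.0) < 1e-6


def test_update_requires_ladder_contrast(ladder):
    q = QuestPlus(ladder)
    with pytest.raises(ValueError, match="ladder"):
        q.update(0.1234, True)


def test_posterior_normalized_after_every_update(ladder):
    q = QuestPlus(ladder)
    rng = np.random.default_rng(0)
    for _ in range(30):
        c = float(rng.choice(ladder))
        q.update(c, bool(rng.random() < 0.5))
        assert q.posterior.sum() == pytest.approx(1.0, abs=1e-12)


def test_updates_commute(ladder):
    trials = [(ladder[5], True), (ladder[20], False), (ladder[10], True),
              (ladder[20], True)]
    q1, q2 = QuestPlus(ladder), QuestPlus(ladder)
    for c, s in trials:
        q1.update(c, s)
    for c, s in reversed(trials):
        q2.update(c, s)
    np.testing.assert_allclose(q1.posterior, q2.posterior, atol=1e-14)


@pytest.mark.parametrize("seed", range(50))
def test_posterior_matches_product_of_likelihoods_oracle(seed):
    rng = np.random.default_rng(seed)
    lad, slopes = small_grid()
    q = QuestPlus(lad, slopes)
    trials = [
        (float(rng.choice(lad)), bool(rng.random() < 0.5))
        for _ in range(int(rng.integers(1, 8)))
    ]
    for c, s in trials:
        q.update(c, s)
    prior = [[1.0] * len(slopes) for _ in lad]
    expected = quest_posterior_oracle(lad, slopes, prior, trials)
    np.testing.assert_allclose(q.posterior, expected, atol=1e-12)


@pytest.mark.parametrize("seed", range(50))
def test_selection_matches_entropy_enumeration_oracle(seed):
    rng = np.random.default_rng(seed + 500)
    lad, slopes = small_grid()
    prior = rng.random((len(lad), len(slopes))) + 1e-3
    q = QuestPlus(lad, slopes, prior=prior)
    ehs, best = quest_selection_oracle(lad, slopes, q.posterior.tolist())
    np.testing.assert_allclose(q.expected_entropies(), ehs, atol=1e-10)
    assert q.next_contrast() == pytest.approx(best)
    # argmin definition: no other level does better
    chosen = q.expected_entropies()[list(lad).index(q.next_contrast())]
    assert chosen <= min(ehs) + 1e-12


def test_single_cell_posterior_ties_break_to_lowest(ladder):
    # a fully known observer leaves zero entropy whatever is shown: every
    # candidate ties and the tie-break picks the lowest contrast, exactly
    # as the enumeration oracle does
    prior = np.zeros((39, 11))
    prior[19, 5] = 1.0
    q = QuestPlus(ladder, prior=prior)
    _, best = quest_selection_oracle(
        ladder, DEFAULT_SLOPE_GRID, q.posterior.tolist()
    )
    assert q.next_contrast() == pytest.approx(best)
    assert q.next_contrast() == pytest.approx(ladder[0])


def test_known_threshold_unknown_slope_selects_on_flank(ladder):
    # with only slope uncertainty left, the stimulus exactly at threshold
    # is uninformative (every slope predicts P=0.5 there); the entropy
    # minimizer sits a few ladder steps up the flank, where the slope
    # candidates disagree most, but still close to the known threshold
    step = abs(math.log(ladder[1]) - math.log(ladder[0]))
    for j in (3, 19, 30):
        prior = np.zeros((39, 11))
        prior[j, :] = 1.0
        q = QuestPlus(ladder, prior=prior)
        chosen = q.next_contrast()
        dist = abs(math.log(chosen) - math.log(ladder[j]))
        assert 0 < dist <= 5 * step


def test_symmetric_two_cell_posterior_selects_between(ladder):
    prior = np.zeros((39, 11))
    prior[10, 5] = 0.5
    prior[14, 5] = 0.5
    q = QuestPlus(ladder, prior=prior)
    c = q.next_contrast()
    assert ladder[10] <= c <= ladder[14]


def test_uninformative_likelihood_leaves_posterior_unchanged(ladder):
    # direct check of the Bayes rule with a constant likelihood
    q = QuestPlus(ladder)
    post = q.posterior
    like = np.full(post.size, 0.37)
    updated = post.reshape(-1) * like
    updated /= updated.sum()
    np.testing.assert_allclose(updated.reshape(post.shape), post, atol=1e-14)


def test_estimate_mode_and_mean(ladder):
    prior = np.zeros((39, 11))
    prior[7, 2] = 1.0
    q = QuestPlus(ladder, prior=prior)
    q.update(ladder[7], True)
    est = q.estimate()
    assert est.mode_threshold == pytest.approx(ladder[7])
    assert est.mode_slope == pytest.approx(DEFAULT_SLOPE_GRID[2])

    prior2 = np.zeros((39, 11))
    prior2[10, 5] = 0.5
    prior2[20, 5] = 0.5
    q2 = QuestPlus(ladder, prior=prior2)
    mid = 0.5 * (math.log(ladder[10]) + math.log(ladder[20]))
    assert q2.estimate().mean_log_threshold == pytest.approx(mid)


@pytest.mark.parametrize("seed", range(10))
def test_estimate_mode_matches_argmax_oracle(seed, ladder):
    rng = np.random.default_rng(seed)
    prior = rng.random((39, 11)) + 1e-6
    q = QuestPlus(ladder, prior=prior)
    post = q.posterior
    j, k = max(
        ((j, k) for j in range(39) for k in range(11)),
        key=lambda jk: post[jk[0], jk[1]],
    )
    est = q.estimate()
    assert est.mode_threshold == pytest.approx(ladder[j])
    assert est.mode_slope == pytest.approx(DEFAULT_SLOPE_GRID[k])


def test_mean_expected_entropy_nonincreasing_for_grid_observer(ladder):
    """Adaptive testing reduces expected posterior entropy on average when
    the observer truly sits on the parameter grid."""
    rng = np.random.default_rng(42)
    n_runs, n_trials = 100, 24
    entropies = np.zeros((n_runs, n_trials + 1))
    for r in range(n_runs):
        j = int(rng.integers(5, 34))
        slope = float(rng.choice(DEFAULT_SLOPE_GRID[3:8]))
        m_true, w_true = math.log(ladder[j]), C_WEIBULL / slope
        q = QuestPlus(ladder)
        entropies[r, 0] = -np.sum(
            q.posterior * np.log(q.posterior)
        )
        for i in range(n_trials):
            c = q.next_contrast()
            seen = rng.random() < weibull_psi(c, m=m_true, w=w_true)
            q.update(c, bool(seen))
            p = q.posterior.reshape(-1)
            p = p[p > 0]
            entropies[r, i + 1] = -np.sum(p * np.log(p))
    mean_h = entropies.mean(axis=0)
    # allow tiny stochastic wiggles, require a clearly decreasing trend
    assert np.all(np.diff(mean_h) < 0.05)
    assert mean_h[-1] < mean_h[0] - 1.0


def test_parameter_recovery_over_200_runs(ladder):
    """64-trial QUEST+ runs recover an on-grid observer's log threshold
    with median absolute error below half the ladder spacing."""
    rng = np.random.default_rng(7)
    step = float(np.median(np.diff(np.log(ladder))))
    errors = []
    for _ in range(200):
        j = int(rng.integers(4, 35))
        slope = 3.0
        m_true, w_true = math.log(ladder[j]), C_WEIBULL / slope
        q = QuestPlus(ladder)
        for _ in range(64):
            c = q.next_contrast()
            seen = rng.random() < weibull_psi(c, m=m_true, w=w_true)
            q.update(c, bool(seen))
        errors.append(abs(math.log(q.estimate().mode_threshold) - m_true))
    assert float(np.median(errors)) < step / 2.0
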