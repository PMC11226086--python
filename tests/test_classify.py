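import numpy as np
import pytest

from specdcm.classify import (
    CrossValResult,
    leave_one_state_out,
    losocv,
    predict_membership,
    rank_connections,
    stepwise_subset,
)
from specdcm.peb import BMAResult

from conftest import make_gaussian_posteriors


def cohort(priors, effect, sizes={"control": 11, "uws": 6}, seed=0, like_sd=0.25):
    eff = np.zeros(12)
    eff[5] = effect
    return make_gaussian_posteriors(priors, sizes, {"uws": eff}, seed=seed,
                                    like_sd=like_sd)


# ---------------------------------------------------------------------------
# predict_membership


def test_self_classification(priors):
    posts, labels, _ = cohort(priors, -0.8, seed=1)
    pp = predict_membership(posts[:-1], labels[:-1], posts[-1], [5], priors,
                            positive="uws")
    assert pp > 0.5


def test_label_symmetry(priors):
    posts, labels, _ = cohort(priors, -0.8, seed=2)
    test_post = posts.pop()
    labels = labels[:-1]
    pp_uws = predict_membership(posts, labels, test_post, [5], priors, positive="uws")
    pp_ctrl = predict_membership(posts, labels, test_post, [5], priors,
                                 positive="control")
    assert pp_uws == pytest.approx(1 - pp_ctrl, abs=1e-9)


def test_mean_correct_class_probability(priors):
    pps = []
    for seed in range(10):
        posts, labels, _ = cohort(priors, -0.8, seed=seed)
        for i in (0, len(labels) - 1):  # one control, one unconscious subject
            train_p = [p for j, p in enumerate(posts) if j != i]
            train_l = [l for j, l in enumerate(labels) if j != i]
            pp = predict_membership(train_p, train_l, posts[i], [5], priors,
                                    positive="uws")
            pps.append(pp if labels[i] == "uws" else 1 - pp)
    assert np.mean(pps) > 0.8


def test_argument_validation(priors):
    posts, labels, _ = cohort(priors, -0.5)
    with pytest.raises(ValueError, match="non-empty"):
        predict_membership(posts[:-1], labels[:-1], posts[-1], [], priors)
    with pytest.raises(ValueError, match="2 classes"):
        predict_membership(posts[:3], ["a"] * 3, posts[-1], [5], priors)


# ---------------------------------------------------------------------------
# LOSOCV


def test_losocv_confusion_counts_total(priors):
    posts, labels, _ = cohort(priors, -0.8, seed=3)
    res = losocv(posts, labels, [5], priors, positive="uws")
    c = res.confusion()
    assert c["tp"] + c["fp"] + c["tn"] + c["fn"] == len(labels)
    assert np.all((res.pp >= 0) & (res.pp <= 1))


def test_strong_effect_classifies_well(priors):
    baccs = []
    for seed in range(10):
        posts, labels, _ = cohort(priors, -0.8, seed=seed, like_sd=0.2)
        baccs.append(
            losocv(posts, labels, [5], priors, positive="uws").balanced_accuracy()
        )
    assert np.mean(baccs) >= 0.9


def test_permuted_labels_give_chance_accuracy(priors):
    """The permutation null is centred at chance level.

    Individual permuted-label runs scatter widely (the 17-subject LOSOCV
    balanced accuracy has sd ~ 0.19 under the null because folds share
    training data), so the check is on the mean over 20 permutations.
    """
    rng = np.random.default_rng(0)
    posts, labels, _ = cohort(priors, -0.8, seed=4)
    baccs = []
    for _ in range(20):
        perm = [labels[i] for i in rng.permutation(len(labels))]
        baccs.append(
            losocv(posts, perm, [5], priors, positive="uws").balanced_accuracy()
        )
    assert 0.35 <= np.mean(baccs) <= 0.65


def test_losocv_requires_two_per_class(priors):
    posts, labels, _ = cohort(priors, -0.5, sizes={"control": 4, "uws": 1})
    with pytest.raises(ValueError, match="2 subjects"):
        losocv(posts, labels, [5], priors, positive="uws")


def test_no_training_leakage(priors):
    """Each fold's empirical priors are built from training subjects only."""
    posts, labels, _ = cohort(priors, -0.5, sizes={"control": 3, "uws": 3})
    res = losocv(posts, labels, [5], priors, positive="uws")
    assert len(set(res.fold_checksums)) == len(labels)  # every fold differs
    from specdcm.classify import _training_checksum

    for i, chk in enumerate(res.fold_checksums):
        expected = _training_checksum(
            [p for j, p in enumerate(posts) if j != i],
            [l for j, l in enumerate(labels) if j != i],
        )
        assert chk == expected


def test_calibration_direction(priors):
    """Mean correct-class probability grows with the effect size."""
    means = []
    for effect in (0.0, -0.2, -0.5, -0.8):
        pps = []
        for seed in range(10):
            posts, labels, _ = cohort(priors, effect, seed=seed,
                                      sizes={"control": 6, "uws": 4})
            res = losocv(posts, labels, [5], priors, positive="uws")
            correct = [
                p if l == "uws" else 1 - p for p, l in zip(res.pp, res.true_labels)
            ]
            pps.extend(correct)
        means.append(np.mean(pps))
    assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]


def test_informative_subset_dominates_disjoint_subset(priors):
    wins = 0
    for seed in range(10):
        posts, labels, _ = cohort(priors, -0.8, seed=seed)
        with_true = losocv(posts, labels, [5, 0], priors, positive="uws")
        without = losocv(posts, labels, [1, 2], priors, positive="uws")
        wins += with_true.balanced_accuracy() >= without.balanced_accuracy()
    assert wins >= 8


# ---------------------------------------------------------------------------
# leave-one-state-out


def test_holdout_from_training_distribution_assigned_to_it(priors):
    posts, labels, truths = cohort(priors, -0.8, seed=5)
    hold_posts, _, _ = make_gaussian_posteriors(
        priors, {"holdout": 5}, {}, seed=50
    )  # drawn from the conscious (zero-effect) distribution
    out = leave_one_state_out(posts, labels, hold_posts, [5], priors,
                              positive="control")
    assert out["pp"].mean() > 0.5
    assert out["frac_positive"] + out["frac_negative"] == pytest.approx(1.0)


def test_empty_test_group_rejected(priors):
    posts, labels, _ = cohort(priors, -0.5)
    with pytest.raises(ValueError, match="empty"):
        leave_one_state_out(posts, labels, [], [5], priors, positive="control")


# ---------------------------------------------------------------------------
# ranking and stepwise search


def fake_bma(effects):
    effects = np.asarray(effects, dtype=float)
    return BMAResult(
        expected_effect=np.vstack([np.zeros_like(effects), effects]),
        pp=np.full(effects.size, 0.5),
        covariate=1,
        model_probs=np.array([1.0]),
        model_masks=np.ones((1, effects.size), bool),
        param_indices=np.arange(effects.size),
    )


def test_rank_by_absolute_effect():
    order = rank_connections(fake_bma([-0.9, 0.2, -0.2, 0.05]))
    assert order[0] == 0
    assert order[1:3] == [1, 2]  # equal magnitude: lower index first
    assert order[-1] == 3


def test_rank_true_connection_first(priors):
    from specdcm.peb import DesignMatrix, bma, fit_peb, model_search

    firsts = 0
    for seed in range(10):
        posts, labels, _ = cohort(priors, -0.6, seed=seed, like_sd=0.2)
        X = DesignMatrix.from_labels(labels, positive="uws", negative="control")
        result = bma(model_search(fit_peb(posts, X, priors), "exhaustive"))
        firsts += rank_connections(result)[0] == 5
    assert firsts >= 9


def test_stepwise_stops_at_perfect_single(priors):
    posts, labels, _ = cohort(priors, -3.0, seed=0, like_sd=0.05)
    out = stepwise_subset(posts, labels, [5, 0, 1], priors, positive="uws")
    assert out["best_subset"] == [5]
    assert out["balanced_accuracy"] == 1.0


def test_stepwise_pair_at_least_as_good_as_single(priors):
    eff = np.zeros(12)
    eff[5] = -0.5
    eff[0] = -0.5
    posts, labels, _ = make_gaussian_posteriors(
        priors, {"control": 11, "uws": 6}, {"uws": eff}, seed=2
    )
    out = stepwise_subset(posts, labels, [5, 0, 1, 2], priors, positive="uws")
    single_best = max(
        s["balanced_accuracy"] for s in out["steps"] if len(s["subset"]) == 1
    )
    assert out["balanced_accuracy"] >= single_best


def test_stepwise_null_returns_single_at_chance(priors):
    posts, labels, _ = cohort(priors, 0.0, seed=7)
    out = stepwise_subset(posts, labels, list(range(12)), priors, positive="uws")
    assert 0.0 <= out["balanced_accuracy"] <= 0.75


def test_crossval_result_validation():
    with pytest.raises(ValueError, match="probabilities"):
        CrossValResult(["s0"], ["a"], np.array([1.4]), "a", "b", [0])
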