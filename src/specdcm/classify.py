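"""Predictive classification of group membership from fitted couplings.

A held-out subject is scored by fitting the hierarchical group model to the
training subjects only, forming the posterior-predictive (empirical-prior)
density over couplings under each candidate group label, and evaluating the
subject's first-level evidence under each; Bayes' rule with equal label
priors turns the two evidences into a posterior probability of membership.
Probabilities above 0.5 count as a positive classification.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .inversion import Posterior, PriorSpec
from .peb import (
    DesignMatrix,
    PEBPosterior,
    _kernel_gaussian_evidence,
    _likelihood_kernel,
    fit_peb,
)


@dataclass
class CrossValResult:
    """Per-subject membership probabilities plus confusion summary."""

    subject_ids: list[str]
    true_labels: list[str]
    pp: np.ndarray  # probability of the positive (target) group
    positive: str
    negative: str
    subset: list[int]
    fold_checksums: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if np.any((self.pp < 0) | (self.pp > 1)):
            raise ValueError("membership probabilities must lie in [0, 1]")

    def confusion(self, cut: float = 0.5) -> dict:
        tp = fp = tn = fn = 0
        for lab, p in zip(self.true_labels, self.pp):
            pred_pos = p > cut
            if lab == self.positive:
                tp += pred_pos
                fn += not pred_pos
            else:
                fp += pred_pos
                tn += not pred_pos
        return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}

    def balanced_accuracy(self, cut: float = 0.5) -> float:
        c = self.confusion(cut)
        sens = c["tp"] / max(c["tp"] + c["fn"], 1)
        spec = c["tn"] / max(c["tn"] + c["fp"], 1)
        return 0.5 * (sens + spec)

    def accuracy(self, cut: float = 0.5) -> float:
        c = self.confusion(cut)
        return (c["tp"] + c["tn"]) / max(len(self.true_labels), 1)


def _training_checksum(posteriors: list[Posterior], labels: list[str]) -> str:
    h = hashlib.sha256()
    for post, lab in zip(posteriors, labels):
        h.update(np.ascontiguousarray(post.mean).tobytes())
        h.update(lab.encode())
    return h.hexdigest()[:16]


def predict_membership(
    train_posteriors: list[Posterior],
    train_labels: list[str],
    test_posterior: Posterior,
    subset: list[int],
    priors: PriorSpec,
    positive: str | None = None,
) -> float:
    """Probability that the held-out subject belongs to the positive group.

    The group model is fitted to the training subjects restricted to the
    ``subset`` couplings; the test subject's data kernel is integrated
    against the label-conditional posterior-predictive density for each
    candidate label, and the evidences are normalized under equal priors.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    classes = sorted(set(train_labels))
    if len(classes) != 2:
        raise ValueError(f"training set must contain exactly 2 classes, got {classes}")
    pos = positive if positive is not None else classes[0]
    neg = [c for c in classes if c != pos][0]
    X = DesignMatrix.from_labels(train_labels, positive=pos, negative=neg)
    idx = np.asarray(subset, int)
    peb = fit_peb(train_posteriors, X, priors, param_indices=idx)

    # centred covariate values corresponding to the two labels
    centred = X.matrix[:, 1]
    v_pos = centred[[lab == pos for lab in train_labels]][0]
    v_neg = centred[[lab == neg for lab in train_labels]][0]

    m_t, S_t = test_posterior.marginal(idx)
    mu0 = priors.mean[idx]
    S0 = np.diag(priors.variance[idx])
    P_t, b_t = _likelihood_kernel(m_t, S_t, mu0, S0)

    p = idx.size
    k = X.n_covariates
    Sigma_b = np.diag(peb.random_effect_var)
    logev = {}
    for lab, v in ((pos, v_pos), (neg, v_neg)):
        x = np.array([1.0, v])
        Xt = np.kron(x, np.eye(p))  # (p, k*p), covariate-major
        # theta_t ~ N(Xt beta, Sigma_b); marginalize beta
        mean_pred = Xt @ peb.beta.ravel()
        cov_pred = Sigma_b + Xt @ peb.covariance @ Xt.T
        logev[lab] = _kernel_gaussian_evidence(P_t, b_t, mean_pred, cov_pred)
    d = logev[pos] - logev[neg]
    return float(1.0 / (1.0 + np.exp(-d)))


def losocv(
    posteriors: list[Posterior],
    labels: list[str],
    subset: list[int],
    priors: PriorSpec,
    positive: str,
    subject_ids: list[str] | None = None,
) -> CrossValResult:
    """Leave-one-subject-out cross-validated membership probabilities."""
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"need at least 2 subjects per class (class {c!r})")
    ids = subject_ids or [f"s{i}" for i in range(len(labels))]
    negative = [c for c in classes if c != positive][0]
    pps = []
    checks = []
    for i in range(len(labels)):
        train_post = [p for j, p in enumerate(posteriors) if j != i]
        train_lab = [l for j, l in enumerate(labels) if j != i]
        checks.append(_training_checksum(train_post, train_lab))
        pps.append(
            predict_membership(
                train_post, train_lab, posteriors[i], subset, priors, positive
            )
        )
    return CrossValResult(
        subject_ids=ids,
        true_labels=list(labels),
        pp=np.array(pps),
        positive=positive,
        negative=negative,
        subset=list(subset),
        fold_checksums=checks,
    )


def leave_one_state_out(
    train_posteriors: list[Posterior],
    train_labels: list[str],
    test_posteriors: list[Posterior],
    subset: list[int],
    priors: PriorSpec,
    positive: str,
    test_ids: list[str] | None = None,
) -> dict:
    """Train on two labelled groups, score each unlabelled test subject.

    Returns per-test-subject probabilities of membership in the positive
    training class and the fraction assigned to each class at the 0.5 cut.
    """
    if len(test_posteriors) == 0:
        raise ValueError("test group is empty")
    ids = test_ids or [f"t{i}" for i in range(len(test_posteriors))]
    pps = np.array(
        [
            predict_membership(
                train_posteriors, train_labels, tp, subset, priors, positive
            )
            for tp in test_posteriors
        ]
    )
    negative = [c for c in sorted(set(train_labels)) if c != positive][0]
    return {
        "test_ids": ids,
        "pp": pps,
        "positive": positive,
        "negative": negative,
        "frac_positive": float(np.mean(pps > 0.5)),
        "frac_negative": float(np.mean(pps <= 0.5)),
        "subset": list(subset),
        "checksum": _training_checksum(train_posteriors, train_labels),
    }


def rank_connections(bma_result) -> list[int]:
    """Connections ordered by |expected group-difference effect|, descending.

    Ties break toward the lower canonical edge index.
    """
    eff = np.abs(bma_result.expected_effect[bma_result.covariate])
    order = sorted(range(eff.size), key=lambda j: (-eff[j], j))
    return order


def stepwise_subset(
    posteriors: list[Posterior],
    labels: list[str],
    ranking: list[int],
    priors: PriorSpec,
    positive: str,
    subset_map: list[int] | None = None,
) -> dict:
    """Forward stepwise search over ranked connections.

    Evaluates each single connection in rank order by balanced LOSOCV
    accuracy, then greedily grows the best-performing set, stopping at the
    first non-improvement.  ``subset_map`` translates ranking positions to
    edge indices (identity by default).  Deterministic given its inputs.
    """
    if len(ranking) == 0:
        raise ValueError("ranking must be non-empty")
    emap = subset_map or list(range(max(ranking) + 1))

    def acc(subset: list[int]) -> float:
        return losocv(posteriors, labels, subset, priors, positive).balanced_accuracy()

    singles = [(acc([emap[j]]), j) for j in ranking]
    steps = [
        {"subset": [emap[j]], "balanced_accuracy": a} for a, j in singles
    ]
    best_acc, best_j = max(singles, key=lambda t: (t[0], -ranking.index(t[1])))
    current = [emap[best_j]]
    current_acc = best_acc
    remaining = [j for j in ranking if j != best_j]
    while remaining and current_acc < 1.0:
        trial = [(acc(current + [emap[j]]), j) for j in remaining]
        t_acc, t_j = max(trial, key=lambda t: (t[0], -remaining.index(t[1])))
        steps.extend(
            {"subset": current + [emap[j]], "balanced_accuracy": a} for a, j in trial
        )
        if t_acc > current_acc:
            current = current + [emap[t_j]]
            current_acc = t_acc
            remaining = [j for j in remaining if j != t_j]
        else:
            break
    return {
        "best_subset": current,
        "balanced_accuracy": current_acc,
        "steps": steps,
    }
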