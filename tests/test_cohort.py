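import numpy as np
import pytest
from scipy import stats

from specdcm.cohort import (
    CONTROL,
    HOLDOUT,
    MCS,
    UWS,
    CohortConfig,
    bin_average_csd,
    make_cohort,
    project_modes,
    sample_observed_csd,
    welch_csd,
)
from specdcm.csd import CSDData, Recording
from specdcm.model import predict_csd
from specdcm.params import DCMParams
from specdcm.simulate import simulate_timeseries


# ---------------------------------------------------------------------------
# cohort generation


def test_default_cohort_mirrors_study_sizes():
    coh = make_cohort(CohortConfig(), seed=0)
    sizes = {g: sum(s.group == g for s in coh.subjects) for g in
             (CONTROL, UWS, MCS, HOLDOUT)}
    assert sizes == {CONTROL: 11, UWS: 6, MCS: 12, HOLDOUT: 5}
    training = [s for s in coh.subjects if s.group != HOLDOUT]
    assert len(training) == 29 and len(coh.subjects) == 34


def test_cohort_reproducible_from_seed():
    cfg = CohortConfig(group_sizes={CONTROL: 2, UWS: 2})
    a = make_cohort(cfg, seed=9)
    b = make_cohort(cfg, seed=9)
    for sa, sb in zip(a.subjects, b.subjects):
        assert np.array_equal(sa.csd.csd, sb.csd.csd)
        assert np.array_equal(sa.true_params.a, sb.true_params.a)


def test_group_effect_and_between_subject_spread(key_edge):
    cfg = CohortConfig(group_sizes={CONTROL: 100}, n_epochs=8)
    coh = make_cohort(cfg, seed=4)
    truths = np.array([s.true_params.a[key_edge] for s in coh.subjects])
    assert abs(truths.std() / cfg.sigma_between - 1) < 0.30
    assert abs(truths.mean()) < 0.05
    cfg2 = CohortConfig(group_sizes={UWS: 40}, n_epochs=8)
    uws = np.array(
        [s.true_params.a[key_edge] for s in make_cohort(cfg2, seed=4).subjects]
    )
    assert uws.mean() == pytest.approx(-0.6, abs=0.06)


def test_holdout_drawn_from_conscious_distribution(key_edge):
    coh = make_cohort(CohortConfig(group_sizes={UWS: 1, HOLDOUT: 30}, n_epochs=8), seed=3)
    hold = np.array(
        [s.true_params.a[key_edge] for s in coh.subjects if s.group == HOLDOUT]
    )
    assert abs(hold.mean()) < 0.1  # not shifted by the unconscious effect


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(group_sizes={CONTROL: 0})
    with pytest.raises(ValueError):
        CohortConfig(sigma_between=-0.1)
    with pytest.raises(ValueError):
        CohortConfig(observation="telepathy")


# ---------------------------------------------------------------------------
# Wishart sampling


def small_csd():
    freqs = np.array([5.0, 10.0])
    base = np.array(
        [[2.0, 0.5 + 0.2j, 0.1j], [0.5 - 0.2j, 1.5, 0.3], [-0.1j, 0.3, 1.0]]
    )
    return CSDData(freqs, np.stack([base, 2 * base]), {"n_epochs": 60})


def test_wishart_sample_mean_matches_truth():
    truth = small_csd()
    acc = np.zeros_like(truth.csd)
    n_draw, dof = 800, 10
    for seed in range(n_draw):
        acc += sample_observed_csd(truth, dof, seed=seed).csd
    mean = acc / n_draw
    # element variances ~ |G_ii G_jj| / dof; allow 4 Monte-Carlo SEs
    se = np.sqrt(
        np.abs(np.einsum("fii,fjj->fij", truth.csd, truth.csd)) / dof / n_draw
    )
    assert np.all(np.abs(mean - truth.csd) < 4 * se + 1e-12)


def test_wishart_concentrates_with_many_epochs():
    truth = small_csd()
    obs = sample_observed_csd(truth, 10_000, seed=1)
    rel = np.linalg.norm(obs.csd - truth.csd, axis=(1, 2)) / np.linalg.norm(
        truth.csd, axis=(1, 2)
    )
    assert np.median(rel) < 0.02
    obs.validate()


def test_wishart_requires_enough_epochs():
    with pytest.raises(ValueError, match="n_epochs"):
        sample_observed_csd(small_csd(), 2, seed=0)


# ---------------------------------------------------------------------------
# Welch estimation


def test_welch_sinusoid_peak_and_independence():
    fs, dur = 250.0, 120.0
    t = np.arange(int(fs * dur)) / fs
    rng = np.random.default_rng(0)
    data = np.vstack([np.sin(2 * np.pi * 10.0 * t), rng.standard_normal(t.size)])
    csd = welch_csd(Recording(data, fs), epoch_len=10.0, band=(1, 30))
    peak = csd.freqs[np.argmax(csd.csd[:, 0, 0].real)]
    assert peak == pytest.approx(10.0, abs=0.11)
    cross = np.abs(csd.csd[:, 0, 1])
    auto = np.sqrt(csd.csd[:, 0, 0].real * csd.csd[:, 1, 1].real)
    assert np.median(cross / auto) < 0.3


def test_welch_white_noise_level_within_chi2_band():
    fs, dur, n_ep = 250.0, 600.0, 60
    rng = np.random.default_rng(3)
    data = rng.standard_normal((1, int(fs * dur)))
    csd = welch_csd(Recording(data, fs), epoch_len=10.0, band=(1, 30), n_epochs=n_ep)
    assert csd.meta["n_epochs"] == n_ep
    level = csd.csd[:, 0, 0].real * fs / 2  # one-sided density * Nyquist = variance
    lo, hi = stats.chi2.ppf([0.025, 0.975], 2 * n_ep) / (2 * n_ep)
    frac_in = np.mean((level > lo) & (level < hi))
    assert frac_in > 0.9


def test_welch_argument_validation():
    rec = Recording(np.zeros((2, 2500)), 250.0)
    with pytest.raises(ValueError, match="Nyquist"):
        welch_csd(rec, epoch_len=5.0, band=(1, 200))
    with pytest.raises(ValueError, match="2 epochs"):
        welch_csd(rec, epoch_len=8.0)
    assert np.array_equal(
        welch_csd(rec, 5.0).csd, welch_csd(rec, 5.0).csd
    )


def test_welch_of_simulation_matches_wishart_scale(spec, lead):
    """Fast (Wishart) and slow (time-series) observation paths agree."""
    p = DCMParams()
    rec = simulate_timeseries(p, spec, lead, duration=120, seed=8)
    est = bin_average_csd(
        welch_csd(rec, 10.0, band=(0.8, 30.2)), np.arange(1.0, 30.1, 0.25)
    )
    G = predict_csd(p, spec, lead, est.freqs)
    ratio = np.einsum("fii->fi", est.csd).real / np.einsum("fii->fi", G.csd).real
    assert 0.7 < np.median(ratio) < 1.3


# ---------------------------------------------------------------------------
# mode projection


def test_full_orthonormal_projection_preserves_power():
    truth = small_csd()
    reduced, P = project_modes(truth, 3)
    assert np.allclose(P @ P.T, np.eye(3), atol=1e-10)
    assert np.trace(reduced.csd.sum(axis=0)).real == pytest.approx(
        np.trace(truth.csd.sum(axis=0)).real, rel=1e-9
    )


def test_low_rank_data_captured_by_few_modes():
    rng = np.random.default_rng(2)
    A = rng.standard_normal((6, 2))
    mats = []
    for f in range(5):
        C = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        S = C @ C.conj().T
        mats.append(A @ S @ A.T)
    data = CSDData(np.arange(1.0, 6.0), np.stack(mats), {})
    reduced, P = project_modes(data, 2)
    kept = np.trace(reduced.csd.sum(axis=0)).real
    total = np.trace(data.csd.sum(axis=0)).real
    assert kept / total > 0.99


def test_mode_count_validation():
    with pytest.raises(ValueError):
        project_modes(small_csd(), 0)
    with pytest.raises(ValueError):
        project_modes(small_csd(), 9)


def test_recording_projection_preserves_source_variance(spec, lead):
    """4 modes capture nearly all variance of a noise-free 4-source mix."""
    p = DCMParams()
    rec = simulate_timeseries(p, spec, lead, duration=60, seed=5, noise_scale=0.0)
    reduced, P = project_modes(rec, 4)
    assert reduced.data.shape[0] == 4
    kept = reduced.data.var(axis=1).sum()
    total = (rec.data - rec.data.mean(axis=1, keepdims=True)).var(axis=1).sum()
    assert kept / total > 0.95
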