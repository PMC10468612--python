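import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hybridzone as hz
from hybridzone.cline import ClineData, ClineModel, best_fit


def _simulate_counts(model, x, n, rng):
    p = hz.cline_predict(model, x)
    return ClineData(x, rng.binomial(n, p), np.full(x.size, n))


@pytest.mark.parametrize(
    "x,expected",
    [(0.0, 0.5), (1.0, (1 + np.tanh(1)) / 2), (-500.0, 0.0), (500.0, 1.0)],
)
def test_predict_central_sigmoid(x, expected):
    model = ClineModel(c=0.0, w=2.0)
    assert hz.cline_predict(model, x) == pytest.approx(expected, abs=1e-6)


def test_predict_tanh_value_matches_closed_form():
    model = ClineModel(c=0.0, w=2.0)
    assert hz.cline_predict(model, 1.0) == pytest.approx(0.880797, abs=1e-6)


def test_predict_respects_scaling_asymptotes():
    model = ClineModel(scaling_variant="free", c=0.0, w=1.0, pmin=0.1, pmax=0.8)
    assert hz.cline_predict(model, -1e4) == pytest.approx(0.1, abs=1e-9)
    assert hz.cline_predict(model, 1e4) == pytest.approx(0.8, abs=1e-9)


def test_predict_tail_continuous_at_junction():
    model = ClineModel(tail_variant="both", c=0.0, w=2.0,
                       delta_l=1.5, tau_l=0.4, delta_r=2.0, tau_r=0.7)
    for xj in (-1.5, 2.0):
        below = hz.cline_predict(model, xj - 1e-9)
        above = hz.cline_predict(model, xj + 1e-9)
        assert below == pytest.approx(above, abs=1e-6)


@given(
    c=st.floats(-5, 5),
    w=st.floats(0.1, 10),
    tail=st.sampled_from(["none", "left", "right", "mirror", "both"]),
    dl=st.floats(0, 5),
    tl=st.floats(0, 1),
    dr=st.floats(0, 5),
    tr=st.floats(0, 1),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_predict_monotone_nondecreasing(c, w, tail, dl, tl, dr, tr):
    model = ClineModel(tail_variant=tail, c=c, w=w,
                       delta_l=dl, tau_l=tl, delta_r=dr, tau_r=tr)
    xs = np.linspace(c - 30, c + 30, 400)
    p = hz.cline_predict(model, xs)
    assert (np.diff(p) >= -1e-9).all()


def test_loglik_single_site_and_brute_force_identity():
    data = ClineData(np.array([0.0]), np.array([1.0]), np.array([2.0]))
    model = ClineModel(c=0.0, w=1.0)
    assert hz.cline_loglik(model, data) == pytest.approx(2 * np.log(0.5), abs=1e-12)

    # oracle: direct evaluation over a (c, w) grid matches the function
    rng = np.random.default_rng(0)
    x = np.linspace(-10, 10, 12)
    data = _simulate_counts(ClineModel(c=0.0, w=3.0), x, 20, rng)
    for c in np.linspace(-5, 5, 7):
        for w in np.linspace(0.5, 8, 7):
            m = ClineModel(c=c, w=w)
            p = np.clip(hz.cline_predict(m, x), 1e-6, 1 - 1e-6)
            direct = np.sum(data.k * np.log(p) + (data.n - data.k) * np.log(1 - p))
            assert hz.cline_loglik(m, data) == pytest.approx(direct, abs=1e-12)


def test_loglik_saturates_on_perfectly_fit_step():
    x = np.array([-10.0, -5.0, 5.0, 10.0])
    data = ClineData(x, np.array([0.0, 0.0, 20.0, 20.0]), np.full(4, 20.0))
    model = ClineModel(c=0.0, w=0.01)
    assert hz.cline_loglik(model, data) > -1e-3  # -> 0 as the clamp shrinks


@pytest.mark.parametrize(
    "logL,K,n,expected",
    [(0.0, 2, 10, 4 + 12 / 7), (-10.0, 4, 20, 28 + 40 / 15)],
)
def test_aicc_closed_form(logL, K, n, expected):
    assert hz.aicc(logL, K, n) == pytest.approx(expected, abs=1e-12)


def test_aicc_undefined_for_small_n():
    with pytest.raises(ValueError, match="undefined"):
        hz.aicc(0.0, 4, 5)


def test_fit_is_deterministic_under_seed():
    rng = np.random.default_rng(3)
    x = np.linspace(-15, 15, 14)
    data = _simulate_counts(ClineModel(c=1.0, w=4.0), x, 24, rng)
    f1 = hz.fit_cline(data, seed=9, n_starts=5, mcmc_chains=2, mcmc_steps=2000)
    f2 = hz.fit_cline(data, seed=9, n_starts=5, mcmc_chains=2, mcmc_steps=2000)
    assert f1.model == f2.model
    assert f1.support == f2.support


def test_fit_symmetry_under_dosage_flip():
    """Flipping k -> n-k and x -> -x mirrors the centre and keeps width."""
    rng = np.random.default_rng(14)
    x = np.linspace(-15, 15, 16)
    data = _simulate_counts(ClineModel(c=2.0, w=3.0), x, 30, rng)
    flipped = ClineData(-data.x, data.n - data.k, data.n)
    f = hz.fit_cline(data, seed=0, run_mcmc=False)
    g = hz.fit_cline(flipped, seed=0, run_mcmc=False)
    assert g.model.c == pytest.approx(-f.model.c, abs=0.05)
    assert g.model.w == pytest.approx(f.model.w, rel=0.02)


def test_step_data_width_bounded_by_sampling_gap():
    x = np.arange(-20, 24, 4.0)
    k = np.where(x < 0, 0.0, 28.0)
    data = ClineData(x, k, np.full(x.size, 28.0))
    fit = hz.fit_cline(data, seed=1, run_mcmc=False)
    assert fit.model.w < 4.0


def test_fit_rejects_monomorphic_data():
    data = ClineData(np.arange(6.0), np.zeros(6), np.full(6, 10.0))
    with pytest.raises(ValueError, match="monomorphic"):
        hz.fit_cline(data, seed=0)


def test_model_select_returns_all_variants_with_zero_min_delta():
    rng = np.random.default_rng(5)
    x = np.linspace(-20, 20, 15)
    data = _simulate_counts(ClineModel(c=0.0, w=3.0), x, 20, rng)
    fits = hz.model_select(data, seed=0, mcmc_on="none", n_starts=4)
    assert len(fits) == 15
    deltas = [f.delta_aicc for f in fits if np.isfinite(f.delta_aicc)]
    assert min(deltas) == pytest.approx(0.0, abs=1e-12)
    variants = {(f.model.tail_variant, f.model.scaling_variant) for f in fits}
    assert len(variants) == 15


def test_model_select_prefers_no_tail_on_tail_free_data():
    rng = np.random.default_rng(17)
    hits = 0
    n_rep = 10
    for _ in range(n_rep):
        x = np.linspace(-20, 20, 15)
        data = _simulate_counts(ClineModel(c=0.0, w=3.0), x, 20, rng)
        fits = hz.model_select(data, seed=0, mcmc_on="none", n_starts=4)
        if best_fit(fits).model.tail_variant == "none":
            hits += 1
    assert hits >= 0.8 * n_rep


def test_model_select_detects_strong_tails():
    """Data with heavy introgression tails should beat the no-tail family
    by more than 2 AICc units in the majority of replicates."""
    rng = np.random.default_rng(23)
    wins = 0
    n_rep = 6
    # shallow tails starting half a width from the centre leave long
    # introgression shoulders the no-tail sigmoid cannot follow
    true = ClineModel(tail_variant="both", c=0.0, w=3.0,
                      delta_l=1.5, tau_l=0.15, delta_r=1.5, tau_r=0.15)
    for _ in range(n_rep):
        x = np.linspace(-40, 40, 25)
        data = _simulate_counts(true, x, 80, rng)
        fits = hz.model_select(data, seed=0, mcmc_on="none", n_starts=6)
        no_tail = min(f.aicc for f in fits if f.model.tail_variant == "none")
        tailed = min(f.aicc for f in fits if f.model.tail_variant != "none")
        if no_tail - tailed > 2.0:
            wins += 1
    assert wins > n_rep / 2


def test_support_limits_cover_ml_point():
    rng = np.random.default_rng(19)
    x = np.linspace(-15, 15, 12)
    data = _simulate_counts(ClineModel(c=0.0, w=3.0), x, 24, rng)
    fit = hz.fit_cline(data, seed=4, mcmc_chains=2, mcmc_steps=4000)
    for name, (lo, hi) in fit.support.items():
        val = getattr(fit.model, name)
        assert lo - 1e-9 <= val <= hi + 1e-9


def test_concordance_report_flags_displaced_center():
    rng = np.random.default_rng(29)
    x = np.linspace(-20, 20, 16)
    ref_model = ClineModel(c=0.0, w=3.0)
    ref = hz.fit_cline(_simulate_counts(ref_model, x, 30, rng), seed=0,
                       mcmc_chains=2, mcmc_steps=4000)
    same = hz.fit_cline(_simulate_counts(ref_model, x, 30, rng), seed=1,
                        mcmc_chains=2, mcmc_steps=4000)
    displaced = hz.fit_cline(
        _simulate_counts(ClineModel(c=9.0, w=3.0), x, 30, rng), seed=2,
        mcmc_chains=2, mcmc_steps=4000,
    )
    rows = hz.concordance_report(
        {"ref": ref, "same": same, "shifted": displaced}, "ref"
    )
    by = {r["marker"]: r for r in rows}
    assert by["same"]["center_overlap"] and by["same"]["width_overlap"]
    assert not by["shifted"]["center_overlap"]
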