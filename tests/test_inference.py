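"""Reference levels, cell selection, smoothing, the rank-1 fit."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from mirkinet import synthetic_data as sd
from mirkinet.inference import (
    EmptyPanelError,
    InferenceConfig,
    ReferenceLevels,
    TildeDomainError,
    build_tilde_matrix,
    estimate_reference_levels,
    estimate_reference_levels_by_threshold,
    rank_one_decompose,
    reference_levels_from_params,
    refine_km,
    resolve_scale,
    run_inference,
    select_responsive_cells,
    smooth_expression,
)
from mirkinet.synthetic_data import BenchmarkSpec, ExpressionMatrix


def _noiseless_bench(n_targets=20, n_cells=600, seed=13):
    spec = BenchmarkSpec(n_targets=n_targets, n_cells=n_cells, noise_sigma=0.0, seed=seed)
    return sd.generate_benchmark(spec)


def _smoothed(refs, cells, values):
    """Wrap precomputed values in the SmoothedExpression interface."""
    from mirkinet.inference import SmoothedExpression

    return SmoothedExpression(values=values, cells=cells, refs=refs,
                              n_pass2_entries=0, dropped_targets=[])


def test_reference_levels_recover_t0_on_noiseless_data():
    bench = _noiseless_bench()
    refs = estimate_reference_levels(bench.matrix, n_low=240, n_high=30)
    t0_true = np.array([p.t0 for p in bench.params])
    np.testing.assert_allclose(refs.t0, t0_true[refs.gene_indices], rtol=1e-5)
    # the saturating plateau is approached from above
    tinf_true = np.array([p.tinf for p in bench.params])
    assert np.all(refs.tinf >= tinf_true[refs.gene_indices] * (1 - 1e-9))


def test_reference_levels_drop_non_downregulated_genes():
    rng = np.random.default_rng(0)
    values = rng.uniform(1, 2, size=(100, 3))
    values[50:, 0] = 5.0  # gene 0 goes *up* with the proxy
    values[:50, 1] = 4.0  # gene 1 goes down: retained
    matrix = ExpressionMatrix(values=values, cell_ids=[f"c{i}" for i in range(100)],
                              gene_ids=["up", "down", "flat"],
                              proxy=np.linspace(0, 10, 100))
    refs = estimate_reference_levels(matrix, n_low=40, n_high=40)
    assert "up" in refs.dropped_genes
    assert 1 in refs.gene_indices


def test_reference_levels_by_proxy_threshold():
    values = np.vstack([np.full((5, 2), 10.0), np.full((5, 2), 2.0)])
    matrix = ExpressionMatrix(values=values, cell_ids=[f"c{i}" for i in range(10)],
                              gene_ids=["g1", "g2"],
                              proxy=np.array([0.0] * 5 + [7.0] * 5))
    refs = estimate_reference_levels_by_threshold(matrix, zero_proxy_max=0.0, high_proxy_min=6.8)
    np.testing.assert_allclose(refs.t0, [10.0, 10.0])
    np.testing.assert_allclose(refs.tinf, [2.0, 2.0])


def test_select_responsive_cells_noiseless_midregion():
    bench = _noiseless_bench()
    refs = reference_levels_from_params(bench.params, bench.matrix)
    cells = select_responsive_cells(bench.matrix, refs)
    assert cells.size > 20
    # selection is contiguous in proxy order and strictly decreasing in
    # total target level (the analytic sigmoid mid-region)
    totals = bench.matrix.values[cells][:, refs.gene_indices].sum(axis=1)
    assert np.all(np.diff(totals) < 0)
    proxy = bench.matrix.proxy[cells]
    assert np.all(np.diff(proxy) > 0)


def test_zero_proxy_cells_are_never_selected():
    bench = _noiseless_bench()
    matrix = bench.matrix
    matrix.proxy[:50] = 0.0
    matrix.zero_proxy[:50] = True
    refs = reference_levels_from_params(bench.params, matrix)
    cells = select_responsive_cells(matrix, refs)
    assert not np.intersect1d(cells, np.arange(50)).size


def test_smoothing_leaves_constant_in_range_input_unchanged():
    refs = ReferenceLevels(t0=np.array([10.0]), tinf=np.array([2.0]),
                           gene_indices=np.array([0]), margin_fraction=0.1,
                           low_cells=np.empty(0, int), high_cells=np.empty(0, int))
    matrix = ExpressionMatrix(values=np.full((30, 1), 6.0),
                              cell_ids=[f"c{i}" for i in range(30)],
                              gene_ids=["g"], proxy=np.linspace(1, 2, 30))
    out = smooth_expression(matrix, np.arange(30), refs, first_window=7)
    np.testing.assert_allclose(out.values, 6.0)
    assert out.n_pass2_entries == 0


def test_smoothing_postcondition_on_noisy_benchmark(small_bench, small_config):
    refs = estimate_reference_levels(small_bench.matrix, small_config.n_low, small_config.n_high)
    cells = select_responsive_cells(small_bench.matrix, refs)
    out = smooth_expression(small_bench.matrix, cells, refs)
    sub = out.refs
    assert np.all(out.values > (sub.tinf + sub.c)[None, :])
    assert np.all(out.values < (sub.t0 - sub.c)[None, :])


def test_tilde_transform_values_and_limits():
    refs = ReferenceLevels(t0=np.array([100.0]), tinf=np.array([25.0]),
                           gene_indices=np.array([0]), margin_fraction=0.0,
                           low_cells=np.empty(0, int), high_cells=np.empty(0, int))
    cells = np.arange(3)
    values = np.array([[62.5], [25.0 + 1e-9], [99.999999]])
    tilde = build_tilde_matrix(_smoothed(refs, cells, values))
    # halfway level maps to T0/Tinf = K_M / A_F^C
    assert tilde.values[0, 0] == pytest.approx(4.0, rel=1e-9)
    assert tilde.values[1, 0] == pytest.approx(0.0, abs=1e-7)
    assert tilde.values[2, 0] > 1e5
    with pytest.raises(TildeDomainError):
        build_tilde_matrix(_smoothed(refs, cells, np.array([[62.5], [25.0], [80.0]])))


def test_rank_one_exact_matrix():
    fit = rank_one_decompose(np.array([[3.0, 4.0], [6.0, 8.0]]))
    assert fit.residual == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(np.outer(fit.x, fit.y), [[3, 4], [6, 8]], rtol=1e-12)
    np.testing.assert_allclose(fit.x / fit.x[0], [1.0, 2.0], rtol=1e-12)


def test_rank_one_scale_ambiguity():
    fit = rank_one_decompose(np.array([[3.0, 4.0], [6.0, 8.0]]))
    for a in (0.1, 7.0):
        np.testing.assert_allclose(np.outer(a * fit.x, fit.y / a),
                                   np.outer(fit.x, fit.y), rtol=1e-12)


def test_rank_one_reports_mixed_signs():
    with pytest.warns(RuntimeWarning, match="not rank-1"):
        fit = rank_one_decompose(np.array([[5.0, -4.0], [-4.0, 5.0]]))
    assert fit.negative_cells.size or fit.negative_targets.size


def test_refine_km_identities():
    tilde = np.outer([1.0, 2.0, 4.0], [3.0, 5.0])  # exact K_M/A_F structure
    fit = rank_one_decompose(tilde)
    a_f = 1.0 / fit.x
    np.testing.assert_allclose(refine_km(tilde, a_f), fit.y, rtol=1e-10)
    # single cell: K_M = A_F * Ttilde
    np.testing.assert_allclose(refine_km(tilde[:1], np.array([2.0])), 2.0 * tilde[0])


def test_noiseless_end_to_end_recovery():
    bench = _noiseless_bench(n_targets=30, n_cells=900, seed=17)
    refs = reference_levels_from_params(bench.params, bench.matrix, margin_fraction=0.0)
    cfg = InferenceConfig(margin_fraction=0.0, first_window=1, second_window_start=1)
    res = run_inference(bench.matrix, cfg, refs=refs)
    assert res.residual < 1e-8
    idx = {p.id: i for i, p in enumerate(bench.params)}
    sel = [idx[g] for g in res.gene_ids]
    r, _ = pearsonr(np.log(bench.true_afc[sel]), np.log(res.a_f_c))
    assert r > 0.999


def test_inference_is_deterministic(small_bench, small_config):
    r1 = run_inference(small_bench.matrix, small_config)
    r2 = run_inference(small_bench.matrix, small_config)
    np.testing.assert_array_equal(r1.a_f, r2.a_f)
    np.testing.assert_array_equal(r1.km, r2.km)
    np.testing.assert_array_equal(r1.a_f_c, r2.a_f_c)


def test_inferred_km_spread_is_compressed(match_truth):
    """Smoothing along the cell axis narrows the inferred K_M range
    relative to the input range (a full-benchmark-scale property)."""
    bench = sd.generate_benchmark(BenchmarkSpec(seed=23))
    res = run_inference(bench.matrix)
    _, true_km = match_truth(bench, res)
    assert np.std(np.log(res.km)) <= np.std(np.log(true_km))


def test_refinement_does_not_hurt_km_recovery(small_bench, small_config, match_truth):
    res = run_inference(small_bench.matrix, small_config)
    _, true_km = match_truth(small_bench, res)
    r_ref, _ = pearsonr(np.log(true_km), np.log(res.km))
    r_svd, _ = pearsonr(np.log(true_km), np.log(res.km_svd))
    assert r_ref >= r_svd - 0.05


def test_two_noise_realizations_agree():
    """Independent measurement errors on the same truth give concordant
    estimates (their mutual correlation is about the product of their
    correlations with the truth, as for independent error channels)."""
    spec = BenchmarkSpec(n_targets=60, n_cells=1500, seed=19)
    params = sd.draw_target_params(spec)
    cells = sd.draw_cell_mirna_levels(spec)
    cfg = InferenceConfig(n_low=600, n_high=75)
    logs = []
    for noise_seed in (101, 202):
        mat = sd.generate_expression_matrix(params, cells, spec,
                                            np.random.default_rng(noise_seed))
        res = run_inference(mat, cfg)
        logs.append({g: np.log(v) for g, v in zip(res.gene_ids, res.a_f_c)})
    common = sorted(set(logs[0]) & set(logs[1]))
    assert len(common) > 30
    a = np.array([logs[0][g] for g in common])
    b = np.array([logs[1][g] for g in common])
    idx = {p.id: i for i, p in enumerate(params)}
    arr = sd.params_to_arrays(params)
    truth = np.log(arr["km"] * arr["tinf"] / arr["t0"])[[idx[g] for g in common]]
    r_ab = pearsonr(a, b)[0]
    r_at = pearsonr(a, truth)[0]
    r_bt = pearsonr(b, truth)[0]
    assert r_ab > 0.3
    assert r_ab >= r_at * r_bt - 3.0 / np.sqrt(len(common))


def test_resolve_scale_fixes_the_global_factor(small_bench, small_config):
    res = run_inference(small_bench.matrix, small_config)
    assert not res.scale_identified and res.scale == 1.0
    truth = small_bench.a_free[res.cells]
    ok = truth > 0
    scaled = resolve_scale(res, np.where(ok, truth, res.a_f))
    assert scaled.scale_identified
    np.testing.assert_allclose(scaled.km / res.km, scaled.scale)
    # after calibration the estimates sit on the truth's scale
    log_ratio = np.log(scaled.a_f[ok]) - np.log(truth[ok])
    assert abs(log_ratio.mean()) < 0.5


def test_empty_panel_error():
    with pytest.raises(EmptyPanelError):
        ReferenceLevels(t0=np.empty(0), tinf=np.empty(0),
                        gene_indices=np.empty(0, int), margin_fraction=0.1,
                        low_cells=np.empty(0, int), high_cells=np.empty(0, int))
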