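import numpy as np
import pytest

from indelenrich.enrich import (
    EnrichmentData,
    estimate_lambda,
    exp_transform,
    lrt_pvalue,
    lrt_pvalue_from_stat,
    marginal_loglik,
    posterior_log_odds_ratio,
    rerun_excluding,
)
from indelenrich.simulate import simulate_chi2_matrix


def _data_from_matrix(chi2, ann):
    return EnrichmentData.from_matrix(np.asarray(chi2) / 2.0, ann)


def test_loglik_at_zero_is_uniform_prior():
    chi2 = np.array([[4.0, 2.0, 0.0]])
    data = _data_from_matrix(chi2, np.array([[1, 0, 0]], bool))
    expected = np.log(np.exp([2.0, 1.0, 0.0]).sum()) - np.log(3)
    assert marginal_loglik(data, 0.0) == pytest.approx(expected)


def test_fully_annotated_locus_contributes_constant():
    data = _data_from_matrix(np.array([[4.0, 2.0]]), np.ones((1, 2), bool))
    vals = [marginal_loglik(data, lam) for lam in (-3.0, 0.0, 5.0)]
    assert np.ptp(vals) < 1e-12
    assert not data.identifiable


def test_two_variant_locus_closed_form():
    # logBF = (1, 0), a = (1, 0): l(lam) = log(e^lam * e + 1) - log(e^lam + 1)
    data = EnrichmentData.from_loci([(np.array([1.0, 0.0]), np.array([True, False]))])
    for lam in (0.0, 1.0, -2.0):
        expected = np.log(np.exp(lam) * np.e + 1) - np.log(np.exp(lam) + 1)
        assert marginal_loglik(data, lam) == pytest.approx(expected)
    delta = marginal_loglik(data, 1.0) - marginal_loglik(data, 0.0)
    assert delta == pytest.approx(
        (np.log(np.e * np.e + 1) - np.log(np.e + 1))
        - (np.log(np.e + 1) - np.log(2))
    )


def test_unannotated_input_is_unidentifiable():
    data = _data_from_matrix(np.array([[4.0, 2.0, 1.0]]), np.zeros((1, 3), bool))
    fit = estimate_lambda(data)
    assert not fit.identifiable
    assert fit.lambda_hat == 0.0 and fit.p_value == 1.0


def test_flat_evidence_gives_lambda_near_zero(rng):
    chi2 = np.ones((50, 20))
    ann = rng.random((50, 20)) < 0.3
    fit = estimate_lambda(_data_from_matrix(chi2, ann))
    assert abs(fit.lambda_hat) < 1e-4
    assert fit.lrt_stat == pytest.approx(0.0, abs=1e-9)


def test_planted_enrichment_recovered_and_matches_grid_oracle(rng):
    chi2, ann, _ = simulate_chi2_matrix(200, 50, 0.2, 1.5, 30.0, rng)
    data = _data_from_matrix(chi2, ann)
    fit = estimate_lambda(data)
    assert fit.converged and fit.identifiable and not fit.boundary
    assert fit.lambda_hat == pytest.approx(1.5, abs=0.3)
    grid = np.arange(-5.0, 5.0001, 0.01)
    oracle = grid[np.argmax([marginal_loglik(data, l) for l in grid])]
    assert fit.lambda_hat == pytest.approx(oracle, abs=0.01)


def test_em_trace_is_monotone(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        chi2, ann, _ = simulate_chi2_matrix(60, 25, 0.25, 0.8, 25.0, r)
        fit = estimate_lambda(_data_from_matrix(chi2, ann))
        trace = np.array(fit.em_trace)
        assert (np.diff(trace) >= -1e-9).all()


def test_complementing_annotation_negates_lambda(rng):
    chi2, ann, _ = simulate_chi2_matrix(150, 40, 0.3, 1.0, 30.0, rng)
    fit = estimate_lambda(_data_from_matrix(chi2, ann))
    flipped = estimate_lambda(_data_from_matrix(chi2, ~ann))
    assert flipped.lambda_hat == pytest.approx(-fit.lambda_hat, abs=1e-3)
    assert flipped.lrt_stat == pytest.approx(fit.lrt_stat, abs=1e-6)


def test_degenerate_annotation_hits_boundary():
    # annotated variants never carry evidence: lambda runs to the lower bound
    chi2 = np.tile(np.array([[0.0, 40.0, 38.0]]), (20, 1))
    ann = np.tile(np.array([[True, False, False]]), (20, 1))
    fit = estimate_lambda(_data_from_matrix(chi2, ann))
    assert fit.boundary and fit.lambda_hat == pytest.approx(-20.0)
    # a boundary estimate with weak evidence still yields a calibrated p
    assert 0.0 < fit.p_value <= 1.0


def test_lrt_pvalues():
    assert lrt_pvalue_from_stat(0.0) == 1.0
    assert lrt_pvalue_from_stat(3.84) == pytest.approx(0.050, abs=1e-3)
    with pytest.raises(ValueError):
        lrt_pvalue_from_stat(-1.0)


def test_lrt_pvalue_recomputed_from_fit(rng):
    chi2, ann, _ = simulate_chi2_matrix(50, 20, 0.2, 1.0, 25.0, rng)
    fit = estimate_lambda(_data_from_matrix(chi2, ann))
    assert lrt_pvalue(fit) == pytest.approx(fit.p_value)


def test_exp_transform_report_values():
    assert exp_transform(0.0) == 1.0
    assert exp_transform(3.92, ndigits=1) == 50.4
    assert exp_transform(-16.3) == pytest.approx(8.3e-8, rel=5e-3)
    with pytest.raises(ValueError):
        exp_transform(float("inf"))


def test_posterior_log_odds_ratio_is_mstep_for_equal_composition(rng):
    # equal-composition loci: the closed-form 2x2 log odds ratio is the
    # EM fixed point, so iterating it converges to the same maximum
    chi2, _, _ = simulate_chi2_matrix(100, 20, 0.2, 1.0, 25.0, rng)
    ann = np.zeros((100, 20), bool)
    ann[:, :4] = True  # identical annotation layout at every locus
    data = _data_from_matrix(chi2, ann)
    fit = estimate_lambda(data)
    lam = 0.0
    for _ in range(200):
        lam = posterior_log_odds_ratio(data, lam)
    assert lam == pytest.approx(fit.lambda_hat, abs=1e-4)


def test_rerun_excluding_nothing_is_identity(rng):
    chi2, ann, _ = simulate_chi2_matrix(40, 15, 0.3, 0.5, 25.0, rng)
    data = _data_from_matrix(chi2, ann)
    base = estimate_lambda(data)
    fit, dropped = rerun_excluding(data, np.zeros(data.log_bf.size, bool))
    assert dropped == 0
    assert fit.lambda_hat == pytest.approx(base.lambda_hat, abs=1e-9)


def test_excluding_pure_locus_variants_leaves_lambda_unchanged(rng):
    chi2, ann, _ = simulate_chi2_matrix(40, 15, 0.3, 0.5, 25.0, rng)
    # append a pure annotated locus; its variants contribute a constant
    pure_chi2 = rng.chisquare(1, size=(1, 15))
    loci = [(c / 2.0, a) for c, a in zip(chi2, ann)]
    loci.append((pure_chi2[0] / 2.0, np.ones(15, bool)))
    data = EnrichmentData.from_loci(loci)
    base = estimate_lambda(EnrichmentData.from_loci(loci[:-1]))
    exclude = np.zeros(data.log_bf.size, bool)
    exclude[-15:] = True  # drop the pure locus entirely
    fit, dropped = rerun_excluding(data, exclude)
    assert dropped == 1
    assert fit.lambda_hat == pytest.approx(base.lambda_hat, abs=1e-6)


def test_data_validation():
    with pytest.raises(ValueError):
        EnrichmentData.from_loci([])
    with pytest.raises(ValueError):
        EnrichmentData(np.ones(3), np.ones(2, bool), np.array([0]))
    data = EnrichmentData.from_loci([(np.ones(2), np.array([True, False]))])
    with pytest.raises(ValueError):
        data.subset(np.zeros(2, bool))
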