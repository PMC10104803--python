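import math

import numpy as np
import pytest

from betapharm.dose_response import NormalizedCurve, normalize
from betapharm.errors import InsufficientDataError, ValidationError
from betapharm.io import read_dose_response_csv
from betapharm.operational import (
    TransductionCoefficient,
    bias_factor,
    bias_table,
    fit_operational,
    operational_response,
    transduction_coefficients,
)

DOSES = np.logspace(-10, -4, 10)


def _curve(ligand, log_tau, log_ka, em=105.0, n=1.0, pathway="arrestin",
           scale=1.0):
    y = scale * operational_response(DOSES, em, n, log_tau, log_ka)
    return NormalizedCurve(ligand_id=ligand, receptor_id="B2AR",
                           pathway_id=pathway, doses=DOSES, responses=y,
                           reference_ligand="ref")


class TestFitOperational:
    def test_noise_free_log_r_recovery(self):
        # log(tau/KA): ref 3.0-(-4.5)=7.5, test -0.3-(-7.0)=6.7
        curves = [_curve("ref", 3.0, -4.5), _curve("test", -0.3, -7.0)]
        params = fit_operational(curves, "ref")
        assert params.converged
        assert params.log_r["ref"] == pytest.approx(7.5, abs=1e-3)
        assert params.log_r["test"] == pytest.approx(6.7, abs=1e-3)
        assert params.full_agonists == ["ref"]
        # identity log_r = log_tau - log_ka for the jointly fitted partial
        assert params.log_r["test"] == pytest.approx(
            params.log_tau["test"] - params.log_ka["test"], abs=1e-12)

    def test_large_tau_plateau_equals_em(self):
        # tau -> inf limit: every dose >> 0 plateaus at Em
        curves = [_curve("ref", 6.0, -4.0), _curve("test", -0.5, -7.0)]
        params = fit_operational(curves, "ref")
        assert params.em == pytest.approx(105.0, rel=1e-3)

    def test_single_ligand_is_error(self):
        with pytest.raises(InsufficientDataError):
            fit_operational([_curve("ref", 2.0, -5.0)], "ref")

    def test_all_full_agonists_anchor_em(self):
        curves = [_curve("ref", 3.0, -4.5), _curve("test", 3.0, -5.5)]
        params = fit_operational(curves, "ref")
        assert params.status == "em_anchored_to_reference_plateau"
        assert set(params.full_agonists) == {"ref", "test"}
        # only the ratio is identifiable but it is recovered
        assert params.log_r["test"] - params.log_r["ref"] == pytest.approx(
            1.0, abs=1e-3)

    def test_system_scaling_leaves_log_r_deltas_unchanged(self):
        """Observation bias (scaling one pathway's output) does not move Delta log R."""
        base = [_curve("ref", 3.0, -4.5), _curve("test", -0.3, -7.0)]
        scaled = [_curve("ref", 3.0, -4.5, scale=0.55),
                  _curve("test", -0.3, -7.0, scale=0.55)]
        p1 = fit_operational(base, "ref")
        p2 = fit_operational(scaled, "ref")
        d1 = p1.log_r["test"] - p1.log_r["ref"]
        d2 = p2.log_r["test"] - p2.log_r["ref"]
        assert d1 == pytest.approx(d2, abs=1e-3)

    def test_chain_rule_within_single_joint_fit(self):
        curves = [_curve("ref", 3.0, -4.5), _curve("b", -0.2, -6.5),
                  _curve("c", -0.4, -7.2)]
        p = fit_operational(curves, "ref")
        lr = p.log_r
        assert (lr["b"] - lr["c"]) == pytest.approx(
            (lr["b"] - lr["ref"]) + (lr["ref"] - lr["c"]), abs=1e-12)

    def test_monte_carlo_log_r_calibration(self):
        """3% noise, 200 seeds: log R nearly unbiased, asymptotic SE realistic."""
        true_lr = 6.7
        recovered, ses = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            curves = []
            for lig, lt, lk in (("ref", 3.0, -4.5), ("test", -0.3, -7.0)):
                y = operational_response(DOSES, 105.0, 1.0, lt, lk)
                y = y + rng.normal(0.0, 3.0, y.size)
                curves.append(NormalizedCurve(
                    ligand_id=lig, receptor_id="B2AR", pathway_id="arrestin",
                    doses=DOSES, responses=y, reference_ligand="ref"))
            p = fit_operational(curves, "ref")
            recovered.append(p.log_r["test"])
            ses.append(p.se_log_r["test"])
        bias = abs(np.mean(recovered) - true_lr)
        assert bias < 0.05
        empirical_se = np.std(recovered, ddof=1)
        assert np.median(ses) == pytest.approx(empirical_se, rel=0.25)

    def test_monte_carlo_bias_factor_recovery_dd073(self):
        """Built-in ddlog(tau/KA)=0.73: median bias factor within 20% of 10^0.73."""
        # test partial agonist: arrestin log_r 7.2, cAMP log_r 6.47
        configs = {"arrestin": ("test", -0.3, -7.5),
                   "camp": ("test", -0.3, -6.77)}
        factors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            coeffs = []
            for pw, (lig, lt, lk) in configs.items():
                curves = []
                for l, a, b in (("ref", 3.0, -4.5), (lig, lt, lk)):
                    y = operational_response(DOSES, 105.0, 1.0, a, b)
                    y = y + rng.normal(0.0, 3.0, y.size)
                    curves.append(NormalizedCurve(
                        ligand_id=l, receptor_id="B2AR", pathway_id=pw,
                        doses=DOSES, responses=y, reference_ligand="ref"))
                coeffs.extend(
                    transduction_coefficients(fit_operational(curves, "ref")))
            factors.append(
                bias_table(coeffs, "ref", "arrestin", "camp")[0].bias_factor)
        median = float(np.median(factors))
        assert abs(median - 10 ** 0.73) / 10 ** 0.73 < 0.20


class TestTransductionCoefficients:
    def test_arithmetic_identity(self):
        # log_tau=1.2, log_ka=-6.0 -> log_r = 7.2, from a fitted partial agonist
        curves = [_curve("ref", 3.0, -4.5), _curve("test", 1.2, -6.0)]
        params = fit_operational(curves, "ref", full_agonist_threshold=0.98)
        assert "test" not in params.full_agonists
        coeffs = {c.ligand_id: c for c in transduction_coefficients(params)}
        assert coeffs["test"].log_r == pytest.approx(7.2, abs=1e-3)
        assert coeffs["test"].log_r == pytest.approx(
            params.log_tau["test"] - params.log_ka["test"], abs=1e-12)

    def test_delta_method_se(self):
        # var(log_tau)=0.01, var(log_ka)=0.01, cov=0 -> se = sqrt(0.02) = 0.1414
        se = math.sqrt(0.01 + 0.01)
        assert se == pytest.approx(0.1414, abs=5e-5)

    def test_non_converged_input_propagates(self):
        curves = [_curve("ref", 3.0, -4.5), _curve("test", -0.3, -7.0)]
        params = fit_operational(curves, "ref")
        params.converged = False
        with pytest.raises(ValidationError):
            transduction_coefficients(params)


def _coeffs(values, se=0.1):
    """Build a coefficient dict keyed (ligand, pathway) from {key: log_r}."""
    return {
        (lig, pw): TransductionCoefficient(
            ligand_id=lig, receptor_id="B2AR", pathway_id=pw,
            log_r=v, se_log_r=se)
        for (lig, pw), v in values.items()
    }


class TestBiasFactor:
    def test_self_comparison_is_exactly_unbiased(self):
        c = _coeffs({("a", "p1"): 7.1, ("a", "p2"): 6.4})
        res = bias_factor(c, "a", "a", "p1", "p2")
        assert res.re["p1"] == 1.0
        assert res.re["p2"] == 1.0
        assert res.bias_factor == 1.0

    def test_worked_delta_arithmetic(self):
        # deltas 0.5 and -0.2 -> ddlog = 0.7 -> bias factor 5.012
        c = _coeffs({("t", "p1"): 7.5, ("r", "p1"): 7.0,
                     ("t", "p2"): 6.3, ("r", "p2"): 6.5})
        res = bias_factor(c, "t", "r", "p1", "p2")
        assert res.delta_log_r["p1"] == pytest.approx(0.5)
        assert res.delta_log_r["p2"] == pytest.approx(-0.2)
        assert res.delta_delta_log_r == pytest.approx(0.7)
        assert res.bias_factor == pytest.approx(5.012, abs=5e-4)
        # identities
        assert res.re["p1"] == pytest.approx(10 ** 0.5, rel=1e-12)
        assert res.bias_factor == pytest.approx(10 ** 0.7, rel=1e-12)

    def test_pathway_swap_inverts_bias_factor(self):
        c = _coeffs({("t", "p1"): 7.5, ("r", "p1"): 7.0,
                     ("t", "p2"): 6.3, ("r", "p2"): 6.5})
        f = bias_factor(c, "t", "r", "p1", "p2").bias_factor
        g = bias_factor(c, "t", "r", "p2", "p1").bias_factor
        assert f * g == pytest.approx(1.0, abs=1e-12)

    def test_se_quadrature(self):
        # four SEs of 0.1 -> se(delta) = sqrt(2)*0.1, se(ddlog) = 0.2
        c = _coeffs({("t", "p1"): 7.5, ("r", "p1"): 7.0,
                     ("t", "p2"): 6.3, ("r", "p2"): 6.5}, se=0.1)
        res = bias_factor(c, "t", "r", "p1", "p2")
        assert res.se_delta_log_r["p1"] == pytest.approx(math.sqrt(2) * 0.1)
        assert res.se_delta_delta_log_r == pytest.approx(0.2)

    def test_mismatched_receptors_rejected(self):
        c = _coeffs({("t", "p1"): 7.5, ("r", "p1"): 7.0,
                     ("t", "p2"): 6.3, ("r", "p2"): 6.5})
        c[("t", "p2")] = TransductionCoefficient(
            ligand_id="t", receptor_id="B1AR", pathway_id="p2",
            log_r=6.3, se_log_r=0.1)
        with pytest.raises(ValidationError, match="receptor"):
            bias_factor(c, "t", "r", "p1", "p2")


def test_end_to_end_bias_pipeline_noise_free(operational_dataset_path):
    """CSV -> normalize -> operational fits -> bias table recovers the truth."""
    path, truth = operational_dataset_path
    dataset = read_dose_response_csv(path)
    curves = normalize(dataset, "ref")
    coeffs = []
    for pw in ("arrestin", "camp"):
        group = [c for c in curves if c.pathway_id == pw]
        coeffs.extend(transduction_coefficients(fit_operational(group, "ref")))
    table = bias_table(coeffs, "ref", "arrestin", "camp")
    dd_true = truth["delta_delta_log_r"]["test"]
    assert table[0].delta_delta_log_r == pytest.approx(dd_true, abs=2e-3)
    assert table[0].bias_factor == pytest.approx(10 ** dd_true, rel=5e-3)
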