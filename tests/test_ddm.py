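import numpy as np
import pandas as pd
import pytest

from driftring import (
    DriftDiffusionParams,
    GenerativeModelSpec,
    SessionConfig,
    generate_dataset,
    negative_log_likelihood,
    predict_response_distribution,
    six_attractor_drift,
)
from driftring.ddm import (
    DriftDiffusionModel,
    modeled_conditions_mask,
    stratified_folds,
)
from driftring.fokker_planck import DriftField
from driftring.wheel import TWO_PI, index_to_angle


def true_params(**over) -> DriftDiffusionParams:
    base = dict(
        drift=six_attractor_drift(),
        beta_encode={1: 1.2, 2: 1.2},
        beta_memory={1: 0.6, 2: 0.8},
        sigma_encode={1: 0.25, 2: 0.35},
        sigma_memory={1: 0.35, 2: 0.5},
        p_swap=0.1,
        p_guess={1: 0.05, 2: 0.1},
    )
    base.update(over)
    return DriftDiffusionParams(**base)


class TestPredictResponseDistribution:
    def test_guessing_only_uniform(self):
        p = true_params(p_guess={1: 1.0, 2: 1.0}, p_swap=0.0)
        out = predict_response_distribution({"load": 1, "delay_s": 1.2}, 0.5, p)
        assert np.allclose(out.p, 1 / TWO_PI, atol=1e-9)

    def test_frozen_dynamics_concentrate_at_target(self):
        p = true_params(
            drift=DriftField(np.zeros(12)),
            beta_encode={1: 0, 2: 0}, beta_memory={1: 0, 2: 0},
            sigma_encode={1: 1e-3, 2: 1e-3}, sigma_memory={1: 1e-3, 2: 1e-3},
            p_swap=0.0, p_guess={1: 0.0, 2: 0.0},
        )
        target = np.pi / 2
        out = predict_response_distribution({"load": 1, "delay_s": 1.2}, target, p)
        assert out.grid[np.argmax(out.p)] == pytest.approx(target, abs=out.step)

    def test_swap_mass_bookkeeping(self):
        p = true_params(
            drift=DriftField(np.zeros(12)),
            beta_encode={1: 0, 2: 0}, beta_memory={1: 0, 2: 0},
            sigma_encode={1: 0.05, 2: 0.05}, sigma_memory={1: 0.05, 2: 0.05},
            p_swap=0.3, p_guess={1: 0.0, 2: 0.0},
        )
        target, nontarget = 0.5, 3.5
        out = predict_response_distribution({"load": 2, "delay_s": 1.2}, target, p, nontarget=nontarget)
        near_nt = np.abs(np.angle(np.exp(1j * (out.grid - nontarget)))) < 0.2
        assert np.sum(out.p[near_nt]) * out.step == pytest.approx(0.3, abs=0.02)

    def test_nontarget_requirement(self):
        p = true_params()
        with pytest.raises(ValueError, match="nontarget"):
            predict_response_distribution({"load": 2, "delay_s": 1.2}, 0.5, p)
        with pytest.raises(ValueError, match="nontarget"):
            predict_response_distribution({"load": 1, "delay_s": 1.2}, 0.5, p, nontarget=1.0)


class TestNegativeLogLikelihood:
    def test_guessing_only_closed_form(self, ddm_table):
        sub = ddm_table.loc[modeled_conditions_mask(ddm_table)]
        p = true_params(p_guess={1: 1.0, 2: 1.0}, p_swap=0.0)
        # p_swap must be 0 here: swap density also enters with weight 0
        assert negative_log_likelihood(p, sub) == pytest.approx(len(sub) * np.log(TWO_PI), rel=1e-9)

    def test_additivity_when_doubling_data(self, ddm_table):
        sub = ddm_table.loc[modeled_conditions_mask(ddm_table)]
        p = true_params()
        single = negative_log_likelihood(p, sub)
        double = negative_log_likelihood(p, pd.concat([sub, sub]))
        assert double == pytest.approx(2 * single, rel=1e-9)

    def test_generating_params_beat_perturbations(self, ddm_table):
        sub = ddm_table.loc[modeled_conditions_mask(ddm_table)]
        p = true_params()
        base = negative_log_likelihood(p, sub)
        rng = np.random.default_rng(0)
        worse = 0
        for _ in range(20):
            q = true_params(
                beta_memory={k: max(v * np.exp(rng.normal(0, 0.4)), 0.01) for k, v in p.beta_memory.items()},
                sigma_memory={k: v * np.exp(rng.normal(0, 0.3)) for k, v in p.sigma_memory.items()},
                p_swap=float(np.clip(p.p_swap + rng.normal(0, 0.07), 0.001, 0.4)),
            )
            worse += negative_log_likelihood(q, sub) >= base - 1e-6
        assert worse >= 18  # allow rare lucky perturbations at finite n


class TestModeledConditions:
    def test_simultaneous_cue_and_delay_excluded(self, six_attractor_table):
        mask = modeled_conditions_mask(six_attractor_table)
        kept = six_attractor_table.loc[mask]
        assert not (kept["cue"] == "simultaneous").any()
        assert not (kept["delay_class"] == "simultaneous").any()
        kept_all = six_attractor_table.loc[modeled_conditions_mask(six_attractor_table, True)]
        assert (kept_all["delay_class"] == "simultaneous").any()


class TestFitModel:
    def test_fit_is_deterministic(self, ddm_table):
        kw = dict(variant="pure_diffusion", n_restarts=1, maxiter=15, subsample=800, random_state=3)
        a = DriftDiffusionModel(**kw).fit(ddm_table)
        b = DriftDiffusionModel(**kw).fit(ddm_table)
        assert a.nll_ == b.nll_
        assert np.allclose(a.x_, b.x_)

    def test_full_fit_recovers_attractors(self, ddm_table):
        m = DriftDiffusionModel(variant="full", n_restarts=1, maxiter=60, random_state=0)
        m.fit(ddm_table)
        att = m.attractors()
        assert att.count == 6
        truth = np.arange(6) * np.pi / 3
        for a in att.attractor_angles:
            assert np.min(np.abs(np.angle(np.exp(1j * (a - truth))))) < TWO_PI / 64

    def test_variant_constraints_respected(self, ddm_table):
        m = DriftDiffusionModel(variant="no_memory_drift", n_restarts=1, maxiter=10, subsample=500, random_state=1)
        m.fit(ddm_table)
        assert all(v == 0 for v in m.params_.beta_memory.values())
        p = DriftDiffusionModel(variant="pure_diffusion", n_restarts=1, maxiter=10, subsample=500, random_state=1)
        p.fit(ddm_table)
        assert all(v == 0 for v in p.params_.beta_encode.values())
        assert np.allclose(p.params_.drift.weights, 0)

    def test_too_few_trials_rejected(self, ddm_table):
        with pytest.raises(ValueError, match="100"):
            DriftDiffusionModel().fit(ddm_table.head(50))


class TestCrossValidation:
    def test_stratified_folds_cover_conditions(self, ddm_table):
        folds = stratified_folds(ddm_table, 4, seed=0)
        assert set(folds) == {0, 1, 2, 3}
        for f in range(4):
            sub = ddm_table.loc[folds == f]
            assert sub.groupby(["load", "cue", "delay_class"], observed=True).ngroups == 4

    def test_identical_variants_tie(self, ddm_table):
        # pure diffusion twice: relative NLL ~ 0 in every fold
        from driftring.ddm import cross_validate

        res = cross_validate(
            ddm_table.head(2000), variants=("pure_diffusion", "pure_diffusion"),
            k_folds=2, seed=0, n_restarts=1, maxiter=25, subsample=None,
        )
        rel = res.relative_nll.to_numpy()
        assert np.all(rel.min(axis=1) == 0)
        assert np.all(rel.max(axis=1) < 2.0)  # optimizer noise band
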