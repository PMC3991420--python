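import itertools
import warnings

import numpy as np
import pytest

import synthmap as sm
from synthmap.trial_data import ValidationError

from conftest import fit_quietly


def grid_posterior_univariate(effects, ses, mu_sd=100.0, sig_upper=10.0):
    """Independent oracle for the one-instrument reduction: a standard
    normal-normal random-effects meta-analysis, integrated on a 2-D grid."""
    effects = np.asarray(effects)
    ses = np.asarray(ses)
    mu_grid = np.linspace(effects.min() - 4, effects.max() + 4, 601)
    sig_grid = np.linspace(1e-4, 4.0, 600)
    mu, sig = np.meshgrid(mu_grid, sig_grid, indexing="ij")
    logp = -(mu**2) / (2 * mu_sd**2)
    for d, s in zip(effects, ses):
        v = s**2 + sig**2
        logp += -0.5 * np.log(v) - (d - mu) ** 2 / (2 * v)
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    mu_mean = (w * mu).sum()
    mu_sd_post = np.sqrt((w * (mu - mu_mean) ** 2).sum())
    sig_marg = w.sum(axis=0)
    sig_median = sig_grid[np.searchsorted(np.cumsum(sig_marg), 0.5)]
    return mu_mean, mu_sd_post, sig_median


def one_instrument_blocks(effects, ses):
    blocks = []
    for i, (d, s) in enumerate(zip(effects, ses)):
        blocks.append(
            sm.LikelihoodBlock(
                trial_id=f"T{i}",
                contrast_ids=("1",),
                cells=((("1"), "X"),),
                dhat=np.array([d]),
                S=np.array([[s**2]]),
            )
        )
    return blocks


class TestCoherence:
    def test_invertibility_and_transitivity_every_draw(self, random_fit):
        maps = sm.derive_functional_mappings(random_fit)
        f = maps.functional
        m = f.shape[1]
        for r in range(m):
            assert np.all(f[:, r, r] == 1.0)
        for r, s in itertools.combinations(range(m), 2):
            assert np.allclose(f[:, r, s] * f[:, s, r], 1.0, rtol=1e-12)
        for r, s, t in itertools.combinations(range(m), 3):
            assert np.allclose(
                f[:, r, s] * f[:, s, t], f[:, r, t], rtol=1e-10
            )

    def test_sign_constraint_every_draw(self, random_fit):
        beta = random_fit.flat("beta")
        assert np.all(np.sign(beta) == random_fit.signs[None, :])

    def test_mapping_summary_has_all_pairs(self, random_fit):
        df = sm.derive_functional_mappings(random_fit).summary()
        assert len(df) == 6 * 5


class TestDerivedEffects:
    def test_reference_effect_is_mu1(self, random_fit):
        eff = sm.derive_instrument_effects(random_fit)
        mu1 = random_fit.flat("mu1")
        assert eff.loc["PAIN-VAS", "effect_mean"] == pytest.approx(mu1.mean())
        assert eff.loc["PAIN-VAS", "effect_sd"] == pytest.approx(mu1.std())

    def test_drawwise_identity(self, random_fit):
        eff = sm.derive_instrument_effects(random_fit)
        mu1 = random_fit.flat("mu1")
        sig1 = random_fit.flat("sigma1")
        b = random_fit.beta_draws("BASFI")
        assert eff.loc["BASFI", "effect_mean"] == pytest.approx((b * mu1).mean())
        assert eff.loc["BASFI", "bsd_median"] == pytest.approx(
            np.median(np.abs(b) * sig1)
        )


class TestPredictions:
    def test_predictions_cover_all_instruments(self, random_fit):
        # Brandt reports only BASFI and BASDAI; predictions exist for all 6
        df = sm.predict_trial_effects(random_fit, "brandt-2003")
        assert list(df.columns) == random_fit.instrument_ids
        assert len(df) == random_fit.n_draws

    def test_fixed_mapping_prediction_ratio_is_exact(self, fixed_fit):
        df = sm.predict_trial_effects(fixed_fit, "davis-2003")
        dj = fixed_fit.delta_draws("davis-2003")
        b = fixed_fit.beta_draws("BASDAI")
        assert np.allclose(df["BASDAI"].to_numpy() / dj, b)

    def test_random_mapping_ratio_spread_tracks_phi(self, random_fit):
        # ASQOL is unreported by Davis: its trial-level mapping is posterior
        # predictive, so the ratio spread reflects the full |β|·φ hierarchy
        df = sm.predict_trial_effects(random_fit, "davis-2003")
        dj = random_fit.delta_draws("davis-2003")
        ratio = df["ASQOL"].to_numpy() / dj
        b = random_fit.beta_draws("ASQOL")
        phi = random_fit.flat("phi")
        # total spread of the trial-level mapping ≈ sqrt(E[(βφ)²] + Var(β))
        expected = np.sqrt(np.mean((b * phi) ** 2) + b.var())
        assert ratio.std() == pytest.approx(expected, rel=0.2)

    def test_multiarm_contrast_must_be_named(self, random_fit):
        with pytest.raises(ValidationError, match="contrast"):
            sm.predict_trial_effects(random_fit, "inman-2008")
        df = sm.predict_trial_effects(random_fit, "inman-2008", "2")
        assert df.shape[1] == 6


class TestReductionsAndLimits:
    def test_single_trial_conjugate_limit(self):
        """One trial, one instrument, σ1 pinned near 0: the posterior of μ1
        is the analytic normal N(D̂, se²) under the vague prior."""
        blocks = one_instrument_blocks([-1.7], [0.6])
        res = fit_quietly(
            sm.fit_fixed_mapping,
            blocks,
            {"X": 1},
            sm.Priors(sigma1_upper=1e-3),
            sm.McmcSettings(chains=2, walkers=16, steps=2000, thin=8),
            reference="X",
            seed=3,
        )
        mu = res.flat("mu1")
        assert mu.mean() == pytest.approx(-1.7, abs=0.05)
        assert mu.std() == pytest.approx(0.6, rel=0.08)

    def test_one_instrument_matches_grid_oracle(self):
        """M = 1 reduces to univariate random-effects meta-analysis."""
        effects = [-2.1, -1.4, -2.9, -1.8, -2.5]
        ses = [0.35, 0.5, 0.45, 0.3, 0.6]
        mu_mean, mu_sd, sig_med = grid_posterior_univariate(effects, ses)
        res = fit_quietly(
            sm.fit_fixed_mapping,
            one_instrument_blocks(effects, ses),
            {"X": 1},
            sm.Priors(sigma1_upper=4.0),
            sm.McmcSettings(chains=2, walkers=24, steps=4000, thin=8),
            reference="X",
            seed=4,
        )
        assert res.flat("mu1").mean() == pytest.approx(mu_mean, abs=0.05)
        assert res.flat("mu1").std() == pytest.approx(mu_sd, rel=0.10)
        assert np.median(res.flat("sigma1")) == pytest.approx(sig_med, abs=0.06)

    def test_phi_to_zero_collapses_to_fixed_mapping(self, blocks, signs):
        settings = sm.McmcSettings(chains=2, walkers=96, steps=2500, thin=16)
        res_r = fit_quietly(
            sm.fit_random_mapping, blocks, signs,
            sm.Priors(phi_upper=1e-4), settings, reference="PAIN-VAS", seed=5,
        )
        res_f = fit_quietly(
            sm.fit_fixed_mapping, blocks, signs, None, settings,
            reference="PAIN-VAS", seed=5,
        )
        assert res_r.flat("mu1").mean() == pytest.approx(
            res_f.flat("mu1").mean(), abs=0.06
        )
        assert res_r.beta_draws("BASFI").mean() == pytest.approx(
            res_f.beta_draws("BASFI").mean(), abs=0.02
        )

    def test_scale_equivariance(self):
        """Rescaling one instrument rescales its mapping and nothing else."""
        study = sm.make_study(sm.small_scenario(n_trials=5, phi=0.0), seed=9)
        rho = sm.CorrelationMatrix(
            list(study.spec.instrument_ids),
            np.array([[1, 0.703, -0.668], [0.703, 1, -0.842], [-0.668, -0.842, 1]]),
        )
        signs = sm.derive_signs(rho, "PAIN-VAS")
        settings = sm.McmcSettings(chains=2, walkers=48, steps=2000, thin=8)

        def fit_with_scale(c):
            frame = study.table.to_frame()
            mask = frame["instrument"] == "BASFI"
            frame.loc[mask, ["effect", "se"]] *= c
            import io

            buf = io.StringIO()
            frame.to_csv(buf, index=False)
            buf.seek(0)
            table = sm.load_trials(buf, reference_instrument="PAIN-VAS")
            blocks = sm.assemble_blocks(table, rho)
            return fit_quietly(
                sm.fit_fixed_mapping, blocks, signs, None, settings,
                reference="PAIN-VAS", seed=10,
            )

        base = fit_with_scale(1.0)
        scaled = fit_with_scale(2.5)
        assert scaled.beta_draws("BASFI").mean() == pytest.approx(
            2.5 * base.beta_draws("BASFI").mean(), rel=0.03
        )
        assert scaled.flat("mu1").mean() == pytest.approx(
            base.flat("mu1").mean(), abs=0.08
        )


class TestMachinery:
    def test_determinism_under_seed(self, blocks, signs):
        st = sm.McmcSettings(chains=2, walkers=64, steps=600, thin=8)
        a = fit_quietly(sm.fit_random_mapping, blocks, signs, None, st,
                        reference="PAIN-VAS", seed=7)
        b = fit_quietly(sm.fit_random_mapping, blocks, signs, None, st,
                        reference="PAIN-VAS", seed=7)
        assert np.array_equal(a.draws["mu1"], b.draws["mu1"])
        assert np.array_equal(a.delta, b.delta)
        assert all(
            np.array_equal(x, y)
            for x, y in zip(a.cell_predictions, b.cell_predictions)
        )

    def test_disconnected_network_is_refused(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "trial_id,contrast_id,instrument,effect,se\n"
            "T1,1,A,-1,0.5\nT1,1,B,-1,0.5\nT2,1,C,-1,0.5\nT2,1,D,-1,0.5\n"
        )
        table = sm.load_trials(p)
        rho = sm.CorrelationMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [
                    [1, 0.5, 0.5, 0.5],
                    [0.5, 1, 0.5, 0.5],
                    [0.5, 0.5, 1, 0.5],
                    [0.5, 0.5, 0.5, 1.0],
                ]
            ),
        )
        blocks = sm.assemble_blocks(table, rho)
        with pytest.raises(ValidationError, match="disconnected"):
            sm.fit_fixed_mapping(
                blocks, sm.derive_signs(rho, "A"), reference="A", seed=0
            )

    def test_nonconvergent_run_is_flagged_not_discarded(self, blocks, signs):
        st = sm.McmcSettings(chains=2, walkers=96, steps=200, thin=4)
        with pytest.warns(UserWarning, match="convergence"):
            res = sm.fit_random_mapping(
                blocks, signs, None, st, reference="PAIN-VAS", seed=8
            )
        assert not res.converged
        assert res.n_draws > 0

    def test_summary_layout(self, random_fit):
        s = random_fit.summary()
        assert "phi" in s.index
        assert {"mean", "sd", "median", "q2.5", "q97.5", "rhat", "ess"} <= set(
            s.columns
        )
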