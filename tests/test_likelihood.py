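import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import synthmap as sm
from synthmap.trial_data import ValidationError


def hand_oracle_block(trial, rho):
    """Covariance of a trial's cells via explicit loops (independent oracle)."""
    cells = [(o.contrast_id, o.instrument_id, o.effect, o.se) for o in trial.outcomes]
    d = len(cells)
    s = np.empty((d, d))
    for a in range(d):
        for b in range(d):
            r = rho.value(cells[a][1], cells[b][1])
            shared = 1.0 if cells[a][0] == cells[b][0] else 0.5
            s[a, b] = r * cells[a][3] * cells[b][3] * shared
    return np.array([c[2] for c in cells]), s


class TestChangeScoreVariance:
    @pytest.mark.parametrize(
        "vb, vf, r, expected",
        [(4, 4, 0.5, 4.0), (4, 9, 0.5, 7.0), (4, 9, 1.0, 1.0)],
    )
    def test_values(self, vb, vf, r, expected):
        assert sm.change_score_variance(vb, vf, r) == pytest.approx(expected)

    def test_default_correlation_is_half(self):
        assert sm.change_score_variance(4, 9) == pytest.approx(7.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError):
            sm.change_score_variance(-1, 4)


class TestCovarianceFromArms:
    def test_direct_substitution(self):
        s_rr, s_ss, s_rs = sm.covariance_from_arms(
            rho_rs=0.5, var_r_treat=1, var_r_ctrl=1, var_s_treat=1, var_s_ctrl=1,
            n_treat=100, n_ctrl=100,
        )
        assert s_rr == pytest.approx(0.02)
        assert s_ss == pytest.approx(0.02)
        assert s_rs == pytest.approx(0.01)

    def test_zero_correlation_kills_cross_term(self):
        *_, s_rs = sm.covariance_from_arms(
            rho_rs=0.0, var_r_treat=2, var_r_ctrl=3, var_s_treat=4, var_s_ctrl=5,
            n_treat=10, n_ctrl=20,
        )
        assert s_rs == 0.0

    def test_perfect_correlation_equal_variances(self):
        s_rr, s_ss, s_rs = sm.covariance_from_arms(
            rho_rs=1.0, var_r_treat=2, var_r_ctrl=3, var_s_treat=2, var_s_ctrl=3,
            n_treat=10, n_ctrl=20,
        )
        assert s_rs == pytest.approx(s_rr) == pytest.approx(s_ss)

    @given(
        v=st.floats(0.1, 50),
        w=st.floats(0.1, 50),
        n=st.integers(2, 500),
        rho=st.floats(-0.99, 0.99),
    )
    def test_reduced_form_exact_under_equal_arms(self, v, w, n, rho):
        """With V_mT = V_mC and n_T = n_C the SE-only route is exact."""
        s_rr, s_ss, s_rs = sm.covariance_from_arms(
            rho_rs=rho, var_r_treat=v, var_r_ctrl=v, var_s_treat=w, var_s_ctrl=w,
            n_treat=n, n_ctrl=n,
        )
        assert s_rs == pytest.approx(
            sm.covariance_from_ses(np.sqrt(s_rr), np.sqrt(s_ss), rho), rel=1e-12
        )


class TestCovarianceFromSes:
    def test_trial7_pain_basfi_cell(self):
        # SEs from the printed table, correlation from the external matrix
        assert sm.covariance_from_ses(0.333, 0.230, 0.703) == pytest.approx(
            0.703 * 0.333 * 0.230
        )

    def test_zero_correlation(self):
        assert sm.covariance_from_ses(0.4, 0.6, 0.0) == 0.0

    def test_diagonal_is_squared_se(self):
        assert sm.covariance_from_ses(0.333, 0.333, 1.0) == pytest.approx(0.333**2)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            sm.covariance_from_ses(0.0, 1.0, 0.5)


class TestMultiarmCovariance:
    def test_shared_control_half_term(self, easiqol):
        contrasts = {
            "g50": {"SF36-PCS": 1.164},
            "g100": {"SF36-PCS": 1.069},
        }
        cells, s = sm.multiarm_covariance(contrasts, easiqol)
        assert s[0, 1] == pytest.approx(1.164 * 1.069 / 2)

    def test_single_contrast_reduces_to_se_route(self, easiqol):
        contrasts = {"c": {"PAIN-VAS": 0.333, "BASFI": 0.230}}
        _, s = sm.multiarm_covariance(contrasts, easiqol)
        assert s[0, 1] == pytest.approx(sm.covariance_from_ses(0.333, 0.230, 0.703))

    def test_zero_correlation_zero_cross_term(self):
        rho = sm.CorrelationMatrix(["a", "b"], np.eye(2))
        cells, s = sm.multiarm_covariance(
            {"h": {"a": 0.5}, "k": {"b": 0.7}}, rho
        )
        assert s[0, 1] == 0.0


class TestAssembleBlocks:
    def test_block_dimensions(self, blocks):
        assert sorted(b.dim for b in blocks) == [2, 2, 3, 3, 4, 5, 5, 8]

    def test_gorman_block_exact(self, blocks):
        b = next(x for x in blocks if x.trial_id == "gorman-2002")
        assert np.allclose(b.dhat, [-4.15, -2.2])
        expected = np.array(
            [
                [0.803**2, 0.703 * 0.803 * 0.772],
                [0.703 * 0.803 * 0.772, 0.772**2],
            ]
        )
        assert np.allclose(b.S, expected)

    def test_single_outcome_block_is_squared_se(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "trial_id,contrast_id,instrument,effect,se\nA,1,PAIN-VAS,-1.0,0.5\n"
        )
        rho = sm.CorrelationMatrix(["PAIN-VAS"], np.eye(1))
        [b] = sm.assemble_blocks(sm.load_trials(p), rho)
        assert b.S == pytest.approx(np.array([[0.25]]))

    def test_all_blocks_match_hand_oracle(self, as_table, easiqol, blocks):
        by_id = {b.trial_id: b for b in blocks}
        for trial in as_table.trials:
            dhat, s = hand_oracle_block(trial, easiqol)
            blk = by_id[trial.trial_id]
            assert np.allclose(blk.dhat, dhat)
            assert np.allclose(blk.S, s)

    def test_cauchy_schwarz_on_every_block(self, blocks):
        for b in blocks:
            d = np.sqrt(np.diag(b.S))
            bound = np.outer(d, d)
            assert (np.abs(b.S) <= bound + 1e-12).all()

    def test_blocks_positive_definite(self, blocks):
        for b in blocks:
            assert np.linalg.eigvalsh(b.S)[0] > 0

    def test_permutation_equivariance(self, tmp_path, as_table, easiqol, blocks):
        p = tmp_path / "t.csv"
        sm.write_trials(as_table, p)
        order = list(reversed(as_table.instrument_ids))
        table2 = sm.load_trials(p, reference_instrument="PAIN-VAS",
                                instrument_order=order)
        blocks2 = sm.assemble_blocks(table2, easiqol)
        for b1, b2 in zip(blocks, blocks2):
            assert set(b1.cells) == set(b2.cells)
            perm = [b2.cells.index(c) for c in b1.cells]
            assert np.allclose(b1.dhat, b2.dhat[perm])
            assert np.allclose(b1.S, b2.S[np.ix_(perm, perm)])

    def test_unknown_instrument_rejected(self, as_table):
        rho = sm.CorrelationMatrix(["PAIN-VAS"], np.eye(1))
        with pytest.raises(ValidationError, match="absent"):
            sm.assemble_blocks(as_table, rho)

    def test_indefinite_block_rejected_with_trial_name(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "trial_id,contrast_id,instrument,effect,se\n"
            "A,1,X,-1,0.5\nA,1,Y,-1,0.5\nA,1,Z,-1,0.5\n"
        )
        r = np.array([[1, 0.99, -0.99], [0.99, 1, 0.99], [-0.99, 0.99, 1.0]])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = sm.CorrelationMatrix(["X", "Y", "Z"], r)
        with pytest.raises(ValidationError, match="trial A"):
            sm.assemble_blocks(sm.load_trials(p), rho)


class TestPerturbCorrelations:
    def test_scales_off_diagonals(self, easiqol):
        out = sm.perturb_correlations(easiqol, 0.9)
        assert out.value("PAIN-VAS", "BASDAI") == pytest.approx(0.852 * 0.9)
        assert np.allclose(np.diag(out.rho), 1.0)

    def test_identity_factor(self, easiqol):
        out = sm.perturb_correlations(easiqol, 1.0)
        assert np.allclose(out.rho, easiqol.rho)

    def test_overflow_rejected(self):
        rho = sm.CorrelationMatrix(["a", "b"], np.array([[1, 0.95], [0.95, 1.0]]))
        with pytest.raises(ValidationError, match="> 1"):
            sm.perturb_correlations(rho, 1.1)

    def test_nonpositive_factor_rejected(self, easiqol):
        with pytest.raises(ValidationError):
            sm.perturb_correlations(easiqol, 0.0)
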