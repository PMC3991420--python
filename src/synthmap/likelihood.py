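"""Within-trial likelihood blocks: observed effect vectors and covariances.

Each trial contributes a multivariate normal likelihood
``D̂_j ~ MVN(δ_j, S_j)`` over its reported (contrast, instrument) cells. The
diagonal of ``S_j`` is the squared standard errors; off-diagonals couple
instruments through the externally sourced change-score correlations
``ρ_rs``. For a multi-arm trial the contrasts share a control arm, which
induces covariance between cells of different contrasts (half the
corresponding within-contrast term under equal allocation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trial_data import (
    CorrelationMatrix,
    TrialTable,
    ValidationError,
)

__all__ = [
    "LikelihoodBlock",
    "change_score_variance",
    "covariance_from_arms",
    "covariance_from_ses",
    "multiarm_covariance",
    "assemble_blocks",
    "perturb_correlations",
    "blocks_to_json",
]

#: relative eigenvalue tolerance for positive definiteness of a block
PD_RTOL = 1e-10


@dataclass(frozen=True)
class LikelihoodBlock:
    """Observed effects and covariance for one trial.

    ``cells`` lists the (contrast_id, instrument_id) pairs in stacking
    order; ``dhat`` and ``S`` follow the same order.
    """

    trial_id: str
    contrast_ids: tuple[str, ...]
    cells: tuple[tuple[str, str], ...]
    dhat: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        d = len(self.cells)
        if self.dhat.shape != (d,) or self.S.shape != (d, d):
            raise ValidationError(
                f"block {self.trial_id}: dhat/S dimensions do not match cells"
            )
        eig = np.linalg.eigvalsh(self.S)
        if eig[0] <= PD_RTOL * eig[-1]:
            raise ValidationError(
                f"covariance block for trial {self.trial_id} is not positive "
                f"definite (eigenvalues {np.array2string(eig, precision=3)}); "
                "consider shrinking the external correlations toward zero "
                "(assemble_blocks(..., shrink=...))"
            )

    @property
    def dim(self) -> int:
        return len(self.cells)

    @property
    def n_contrasts(self) -> int:
        return len(self.contrast_ids)


def change_score_variance(
    var_baseline: float, var_followup: float, corr_bf: float = 0.5
) -> float:
    """Variance of the change score from baseline and follow-up variances.

    ``Var(Y_F − Y_B) = V_B + V_F − 2·ρ_BF·√(V_B·V_F)``; when a trial does not
    report the baseline–follow-up correlation the conventional value 0.5 is
    used.
    """
    if var_baseline < 0 or var_followup < 0:
        raise ValidationError("variances must be non-negative")
    if not -1 <= corr_bf <= 1:
        raise ValidationError(f"corr_bf must lie in [-1, 1], got {corr_bf}")
    return float(
        var_baseline + var_followup - 2 * corr_bf * np.sqrt(var_baseline * var_followup)
    )


def covariance_from_arms(
    *,
    rho_rs: float,
    var_r_treat: float,
    var_r_ctrl: float,
    var_s_treat: float,
    var_s_ctrl: float,
    n_treat: int,
    n_ctrl: int,
) -> tuple[float, float, float]:
    """Within-trial (co)variances of two mean treatment differences from
    arm-level change-score variances.

    Returns ``(S_rr, S_ss, S_rs)`` with ``S_mm = V_mT/n_T + V_mC/n_C`` and
    ``S_rs = ρ_rs(√(V_rT·V_sT)/n_T + √(V_rC·V_sC)/n_C)``.
    """
    for v in (var_r_treat, var_r_ctrl, var_s_treat, var_s_ctrl):
        if v < 0:
            raise ValidationError("arm variances must be non-negative")
    if n_treat < 1 or n_ctrl < 1:
        raise ValidationError("arm sizes must be >= 1")
    s_rr = var_r_treat / n_treat + var_r_ctrl / n_ctrl
    s_ss = var_s_treat / n_treat + var_s_ctrl / n_ctrl
    s_rs = rho_rs * (
        np.sqrt(var_r_treat * var_s_treat) / n_treat
        + np.sqrt(var_r_ctrl * var_s_ctrl) / n_ctrl
    )
    return float(s_rr), float(s_ss), float(s_rs)


def covariance_from_ses(se_r: float, se_s: float, rho_rs: float) -> float:
    """Covariance of two treatment differences from their SEs alone:
    ``S_rs = ρ_rs·se_r·se_s``.

    This reduced form equals the arm-level expression exactly when arm
    variances are proportional across instruments, and is the only form
    computable when trials publish difference SEs only.
    """
    if se_r <= 0 or se_s <= 0:
        raise ValidationError("standard errors must be > 0")
    return float(rho_rs * se_r * se_s)


def multiarm_covariance(
    contrasts: dict[str, dict[str, float]],
    rho: CorrelationMatrix,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Joint covariance of all cells of a shared-control multi-arm trial.

    ``contrasts`` maps contrast_id → {instrument_id: se}. Cells of the same
    contrast get the usual ``ρ_rs·se_r·se_s``; cells of different contrasts
    share only the control arm, contributing half of that under equal
    allocation: ``ρ_rs·se_r·se_s / 2`` (including r = s).
    """
    cells: list[tuple[str, str]] = []
    ses: list[float] = []
    for cid, instr in contrasts.items():
        for iid, se in instr.items():
            if se <= 0:
                raise ValidationError("standard errors must be > 0")
            cells.append((cid, iid))
            ses.append(se)
    d = len(cells)
    S = np.empty((d, d))
    for a in range(d):
        for b in range(d):
            r = rho.value(cells[a][1], cells[b][1])
            half = 1.0 if cells[a][0] == cells[b][0] else 0.5
            S[a, b] = r * ses[a] * ses[b] * half
    eig = np.linalg.eigvalsh(S)
    if d and eig[0] <= PD_RTOL * eig[-1]:
        raise ValidationError(
            f"multi-arm covariance not positive definite; eigenvalues "
            f"{np.array2string(eig, precision=3)}"
        )
    return cells, S


def assemble_blocks(
    table: TrialTable,
    rho: CorrelationMatrix,
    *,
    shrink: float = 0.0,
) -> list[LikelihoodBlock]:
    """One likelihood block per trial.

    Instruments a trial does not report are simply absent from its block
    (restriction of the multivariate normal to observed components, i.e.
    missing-at-random marginalization). ``shrink`` in [0, 1) optionally
    scales all off-diagonal correlations toward zero before assembly — an
    explicit repair for indefinite blocks, never applied automatically.
    """
    if not 0 <= shrink < 1:
        raise ValidationError(f"shrink must lie in [0, 1), got {shrink}")
    missing = set()
    for o in table.outcomes():
        if o.instrument_id not in rho.instrument_ids:
            missing.add(o.instrument_id)
    if missing:
        raise ValidationError(
            f"instruments absent from the correlation matrix: {sorted(missing)}"
        )
    blocks = []
    for t in table.trials:
        contrasts: dict[str, dict[str, float]] = {c: {} for c in t.contrast_ids}
        for o in t.outcomes:
            contrasts[o.contrast_id][o.instrument_id] = o.se
        try:
            cells, S = multiarm_covariance(contrasts, rho)
        except ValidationError as exc:
            raise ValidationError(
                f"trial {t.trial_id}: {exc}; consider shrinking the external "
                "correlations toward zero (assemble_blocks(..., shrink=...))"
            ) from exc
        if shrink:
            off = ~np.eye(len(cells), dtype=bool)
            S = S.copy()
            S[off] *= 1.0 - shrink
        lookup = {
            (o.contrast_id, o.instrument_id): o.effect for o in t.outcomes
        }
        dhat = np.array([lookup[c] for c in cells])
        blocks.append(
            LikelihoodBlock(t.trial_id, t.contrast_ids, tuple(cells), dhat, S)
        )
    return blocks


def perturb_correlations(rho: CorrelationMatrix, factor: float) -> CorrelationMatrix:
    """Scale all off-diagonal correlations by ``factor`` (sign-preserving).

    Used by the sensitivity analysis that raises or lowers the assumed
    change-score correlations by 10%.
    """
    if factor <= 0:
        raise ValidationError(f"factor must be > 0, got {factor}")
    r = rho.rho.copy()
    off = ~np.eye(len(r), dtype=bool)
    r[off] *= factor
    if np.any(np.abs(r) > 1):
        worst = np.abs(r).max()
        raise ValidationError(
            f"scaling by {factor} pushes a correlation to {worst:.4g} (> 1)"
        )
    return CorrelationMatrix(list(rho.instrument_ids), r)


def blocks_to_json(blocks: list[LikelihoodBlock], path: str | Path | None = None) -> str:
    """Serialize blocks (for debugging / inspection)."""
    payload = [
        {
            "trial_id": b.trial_id,
            "contrast_ids": list(b.contrast_ids),
            "cells": [list(c) for c in b.cells],
            "dhat": b.dhat.tolist(),
            "S": b.S.tolist(),
        }
        for b in blocks
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
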