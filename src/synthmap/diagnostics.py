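"""Deviance-based model criticism and sensitivity analysis.

The residual deviance of a multivariate-normal likelihood is the summed
Mahalanobis distance between observed and predicted effect vectors,

    D = Σ_j (D̂_j − δ_j)' S_j⁻¹ (D̂_j − δ_j),

averaged over the posterior (D̄). A model fits adequately when D̄ is
approximately equal to the number of data points. The effective number of
parameters pD is D̄ minus the deviance at the posterior-mean predicted
effects (plug-in), and DIC = D̄ + pD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import LikelihoodBlock, assemble_blocks, perturb_correlations
from .model import (
    McmcSettings,
    PosteriorResult,
    Priors,
    fit_fixed_mapping,
    fit_random_mapping,
)
from .trial_data import CorrelationMatrix, TrialTable, ValidationError, derive_signs

__all__ = [
    "DevianceReport",
    "ResidualSet",
    "deviance_report",
    "residual_deviance",
    "effective_parameters",
    "dic",
    "per_trial_deviance",
    "residuals",
    "instrument_bias",
    "sensitivity_suite",
    "plot_residuals",
]


@dataclass
class DevianceReport:
    """Total and per-trial posterior-mean residual deviance, pD and DIC."""

    dbar: float
    per_trial: pd.DataFrame
    pd_plugin: float
    pd_half_variance: float
    n_datapoints: int

    @property
    def pD(self) -> float:
        """Effective parameters via the plug-in at posterior-mean predictions
        (the headline definition; the half-variance variant is also kept)."""
        return self.pd_plugin

    @property
    def dic(self) -> float:
        return self.dbar + self.pD


@dataclass
class ResidualSet:
    """Observed minus posterior-mean predicted effect for every data point."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _prediction_arrays(
    blocks: list[LikelihoodBlock],
    predictions: "PosteriorResult | list[np.ndarray]",
) -> list[np.ndarray]:
    if isinstance(predictions, PosteriorResult):
        preds = predictions.cell_predictions
    else:
        preds = [np.atleast_2d(np.asarray(p, dtype=float)) for p in predictions]
    if len(preds) != len(blocks):
        raise ValidationError(
            f"got {len(preds)} prediction arrays for {len(blocks)} blocks"
        )
    for b, p in zip(blocks, preds):
        if p.shape[1] != b.dim:
            raise ValidationError(
                f"prediction width {p.shape[1]} != block dimension {b.dim} "
                f"for trial {b.trial_id}"
            )
    return preds


def deviance_report(
    blocks: list[LikelihoodBlock],
    predictions: "PosteriorResult | list[np.ndarray]",
) -> DevianceReport:
    """Compute D̄, its per-trial decomposition, pD and DIC.

    ``predictions`` is a fitted :class:`PosteriorResult` or a list of
    (n_draws, d_j) arrays of predicted effect vectors in block cell order.
    """
    preds = _prediction_arrays(blocks, predictions)
    rows = []
    dbar = 0.0
    dplug = 0.0
    dev_draws = None
    for b, p in zip(blocks, preds):
        sinv = np.linalg.inv(b.S)
        r = b.dhat[None, :] - p
        dev = np.einsum("na,ab,nb->n", r, sinv, r)
        dev_draws = dev if dev_draws is None else dev_draws + dev
        rbar = b.dhat - p.mean(axis=0)
        trial_dbar = float(dev.mean())
        dbar += trial_dbar
        dplug += float(rbar @ sinv @ rbar)
        n_pts = b.dim
        rows.append(
            {
                "trial_id": b.trial_id,
                "deviance": trial_dbar,
                "n_points": n_pts,
                # posterior-mean deviance compared against an upper reference
                # quantile of chi-square(n): the working adequacy call
                "adequate": trial_dbar <= stats.chi2.ppf(0.975, n_pts),
            }
        )
    per_trial = pd.DataFrame(rows)
    return DevianceReport(
        dbar=dbar,
        per_trial=per_trial,
        pd_plugin=dbar - dplug,
        pd_half_variance=float(np.var(dev_draws) / 2.0),
        n_datapoints=int(sum(b.dim for b in blocks)),
    )


def residual_deviance(blocks, predictions) -> DevianceReport:
    """Posterior-mean residual deviance D̄ with per-trial decomposition."""
    return deviance_report(blocks, predictions)


def effective_parameters(blocks, predictions) -> float:
    """pD = D̄ − D(δ̄), the plug-in at posterior-mean predicted effects."""
    return deviance_report(blocks, predictions).pD


def dic(report: DevianceReport) -> float:
    """Deviance information criterion, D̄ + pD."""
    return report.dic


def per_trial_deviance(report: DevianceReport) -> pd.DataFrame:
    """Per-trial posterior-mean Mahalanobis deviance with data-point counts."""
    return report.per_trial.copy()


def residuals(
    blocks: list[LikelihoodBlock],
    predictions: "PosteriorResult | list[np.ndarray]",
) -> ResidualSet:
    """Observed minus posterior-mean predicted effect per data point.

    Standardized residuals divide by the marginal SE √S_mm.
    """
    preds = _prediction_arrays(blocks, predictions)
    rows = []
    for b, p in zip(blocks, preds):
        pm = p.mean(axis=0)
        se = np.sqrt(np.diag(b.S))
        for k, (cid, iid) in enumerate(b.cells):
            rows.append(
                {
                    "trial_id": b.trial_id,
                    "contrast_id": cid,
                    "instrument": iid,
                    "observed": b.dhat[k],
                    "predicted": pm[k],
                    "residual": b.dhat[k] - pm[k],
                    "se": se[k],
                    "std_residual": (b.dhat[k] - pm[k]) / se[k],
                }
            )
    return ResidualSet(pd.DataFrame(rows))


def instrument_bias(residual_set: ResidualSet) -> pd.DataFrame:
    """Mean standardized residual per instrument — the check that no
    instrument's predictions are systematically too high or too low."""
    g = residual_set.table.groupby("instrument", sort=False)
    return g["std_residual"].agg(["mean", "count"]).rename(
        columns={"mean": "mean_std_residual", "count": "n"}
    )


def sensitivity_suite(
    table: TrialTable,
    rho: CorrelationMatrix,
    factors=(0.9, 1.0, 1.1),
    *,
    mode: str = "random",
    priors: Priors | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
    signs=None,
) -> pd.DataFrame:
    """Refit after scaling all between-instrument correlations.

    Returns one row per factor with posterior means of the pooled effects
    and mappings, σ1/φ medians and D̄, plus percent changes relative to the
    factor-1.0 fit.
    """
    if 1.0 not in factors:
        factors = (1.0, *factors)
    fit = fit_random_mapping if mode == "random" else fit_fixed_mapping
    reference = table.reference_instrument_id
    rows = {}
    for f in sorted(set(factors)):
        rho_f = perturb_correlations(rho, f)
        signs_f = dict(signs) if signs is not None else derive_signs(rho_f, reference)
        blocks = assemble_blocks(table, rho_f)
        res = fit(blocks, signs_f, priors, settings, reference=reference, seed=seed)
        rep = deviance_report(blocks, res)
        row = {"factor": f, "dbar": rep.dbar,
               "sigma1_median": float(np.percentile(res.flat("sigma1"), 50))}
        if mode == "random":
            row["phi_median"] = float(np.percentile(res.flat("phi"), 50))
        beta = res.flat("beta")
        mu1 = res.flat("mu1")
        for m, iid in enumerate(res.instrument_ids):
            row[f"mu[{iid}]"] = float((beta[:, m] * mu1).mean())
            if m:
                row[f"beta[{iid}]"] = float(beta[:, m].mean())
        rows[f] = row
    df = pd.DataFrame(rows.values()).set_index("factor")
    ref = df.loc[1.0]
    for col in df.columns:
        df[f"pct_change[{col}]"] = 100.0 * (df[col] - ref[col]) / np.abs(ref[col])
    return df


def plot_residuals(residual_set: ResidualSet, path=None):
    """Per-instrument residual scatter (one panel per instrument)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = residual_set.table
    instruments = list(dict.fromkeys(tab["instrument"]))
    fig, axes = plt.subplots(
        1, len(instruments), figsize=(2.2 * len(instruments), 3), sharey=True
    )
    if len(instruments) == 1:
        axes = [axes]
    for ax, iid in zip(axes, instruments):
        sub = tab[tab["instrument"] == iid]
        ax.axhline(0.0, color="0.7", lw=1)
        ax.errorbar(
            range(len(sub)), sub["residual"], yerr=sub["se"], fmt="o", ms=4,
            capsize=2,
        )
        ax.set_title(iid, fontsize=9)
        ax.set_xticks([])
    axes[0].set_ylabel("observed − predicted")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
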