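"""Bayesian synthesis-and-mapping models.

Treatment effects live on a reference instrument: per-contrast effects
δ_j1 follow a normal random-effects model N(μ1, σ1²) (with the σ1²/2
between-contrast covariance for shared-control multi-arm trials). Effects
on every other instrument are linked through mapping coefficients
β_{1→m} — ratios of true treatment effects, with known signs — so that a
trial's predicted effect on instrument m is β_{1→m}·δ_j1.

Two mapping structures are available:

* **fixed** — one mapping per instrument, identical in every trial;
* **random** — trial-level mappings β_{j,1→m} ~ N(β_{1→m}, β_{1→m}²·φ²),
  sharing a single between-trial coefficient of variation φ across
  instruments.

Functional (all-pairs) mappings are ratios of the basic ones, which makes
every draw invertible (β_{r→s}·β_{s→r} = 1) and transitive
(β_{r→s}·β_{s→t} = β_{r→t}) by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .likelihood import LikelihoodBlock
from .trial_data import ValidationError

__all__ = [
    "Priors",
    "McmcSettings",
    "MappingStructure",
    "PosteriorResult",
    "fit_fixed_mapping",
    "fit_random_mapping",
    "derive_functional_mappings",
    "derive_instrument_effects",
    "predict_trial_effects",
]


@dataclass(frozen=True)
class Priors:
    """Vague priors for the hyperparameters.

    μ1 ~ N(0, mu1_sd²); σ1 ~ U(0, sigma1_upper); mapping magnitudes are
    half-normal with scale beta_sd (sign fixed a priori); φ ~ U(0, phi_upper).
    """

    mu1_sd: float = 100.0
    sigma1_upper: float = 10.0
    beta_sd: float = 100.0
    phi_upper: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu1_sd", "sigma1_upper", "beta_sd", "phi_upper"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"prior parameter {name} must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Ensemble-sampler run lengths and convergence gates.

    ``chains`` independent stretch-move ensembles are run; ``walkers=None``
    picks 64 (fixed mapping) or 128 (random mapping) walkers. ``steps`` are
    ensemble steps per chain, of which ``burn`` (default half) are
    discarded and the rest thinned by ``thin``.
    """

    chains: int = 4
    walkers: int | None = None
    steps: int = 8000
    burn: int | None = None
    thin: int = 16
    stretch_scale: float = 2.0
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0


@dataclass
class MappingStructure:
    """Posterior draws of the full mapping matrix.

    ``basic`` holds draws of β_{1→m} (column 0 is the reference, identically
    1); ``functional[r, s]`` = β_{r→s} = β_{1→s}/β_{1→r}.
    """

    reference_instrument: str
    instrument_ids: list[str]
    mode: str
    basic: np.ndarray            # (N, M)
    functional: np.ndarray       # (N, M, M)
    phi: np.ndarray | None = None

    @property
    def sigma_map(self) -> np.ndarray | None:
        """Between-trial mapping SDs σ_{r→s} = |β_{r→s}|·φ (random mode)."""
        if self.phi is None:
            return None
        return np.abs(self.functional) * self.phi[:, None, None]

    def summary(self) -> pd.DataFrame:
        rows = []
        m = len(self.instrument_ids)
        for r in range(m):
            for s in range(m):
                if r == s:
                    continue
                draws = self.functional[:, r, s]
                rows.append(
                    {
                        "from": self.instrument_ids[r],
                        "to": self.instrument_ids[s],
                        "mean": draws.mean(),
                        "sd": draws.std(),
                        "q2.5": np.percentile(draws, 2.5),
                        "median": np.percentile(draws, 50),
                        "q97.5": np.percentile(draws, 97.5),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PosteriorResult:
    """MCMC output: hyperparameter chains, exact-conditional draws of the
    per-contrast effects, per-cell predicted effects, and convergence
    diagnostics."""

    mode: str
    instrument_ids: list[str]
    reference_instrument_id: str
    signs: np.ndarray
    blocks: list[LikelihoodBlock]
    draws: dict[str, np.ndarray]
    delta: np.ndarray                    # (C, N, n_contrasts)
    betaj: np.ndarray                    # (C, N, n_trials, M)
    cell_predictions: list[np.ndarray]   # per block: (C*N, d)
    contrast_index: list[tuple[str, str]]
    convergence: pd.DataFrame
    meta: dict
    priors: Priors
    settings: McmcSettings

    @property
    def n_draws(self) -> int:
        return self.draws["mu1"].size

    def flat(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def converged(self) -> bool:
        return bool(self.meta["converged"])

    def beta_draws(self, instrument_id: str) -> np.ndarray:
        m = self.instrument_ids.index(instrument_id)
        return self.flat("beta")[:, m]

    def delta_draws(self, trial_id: str, contrast_id: str | None = None) -> np.ndarray:
        key = self._contrast_pos(trial_id, contrast_id)
        return self.delta.reshape(-1, self.delta.shape[-1])[:, key]

    def _contrast_pos(self, trial_id: str, contrast_id: str | None) -> int:
        matches = [
            i for i, (t, c) in enumerate(self.contrast_index)
            if t == trial_id and (contrast_id is None or c == contrast_id)
        ]
        if not matches:
            raise ValidationError(
                f"no contrast {contrast_id!r} in trial {trial_id!r}"
            )
        if len(matches) > 1:
            raise ValidationError(
                f"trial {trial_id!r} has several contrasts; specify contrast_id"
            )
        return matches[0]

    def summary(self) -> pd.DataFrame:
        """Posterior summaries: mean (SD) for location parameters, median
        and central 95% interval for SD-type parameters."""
        rows = []

        def add(name, draws, kind):
            rows.append(
                {
                    "parameter": name,
                    "kind": kind,
                    "mean": draws.mean(),
                    "sd": draws.std(),
                    "q2.5": np.percentile(draws, 2.5),
                    "median": np.percentile(draws, 50),
                    "q97.5": np.percentile(draws, 97.5),
                }
            )

        add("mu1", self.flat("mu1"), "location")
        add("sigma1", self.flat("sigma1"), "sd")
        beta = self.flat("beta")
        for m, iid in enumerate(self.instrument_ids):
            if m == 0:
                continue
            add(f"beta[{self.reference_instrument_id}->{iid}]", beta[:, m], "location")
        if self.mode == "random":
            add("phi", self.flat("phi"), "sd")
        df = pd.DataFrame(rows).set_index("parameter")
        conv = self.convergence.set_index("parameter")
        return df.join(conv, how="left")


_TRACKED = ("mu1", "sigma1", "beta", "phi")


def _check_connectivity_from_blocks(
    blocks: list[LikelihoodBlock], reference: str
) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_node(reference)
    for b in blocks:
        ids = list(dict.fromkeys(iid for _, iid in b.cells))
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for c in ids[i + 1:]:
                g.add_edge(a, c)
    comp = nx.node_connected_component(g, reference)
    disconnected = set(g.nodes) - comp
    if disconnected:
        raise ValidationError(
            "instrument network is disconnected from the reference "
            f"({reference}): {sorted(disconnected)}; mappings for these "
            "instruments are not estimable"
        )


def _rhat(chains_by_param: dict[str, np.ndarray]) -> dict[str, float]:
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in chains_by_param.items()})
    r = az.rhat(idata)
    return {k: float(r[k].values) for k in chains_by_param}


def _fit(
    blocks: Sequence[LikelihoodBlock],
    signs: Mapping[str, int],
    *,
    reference: str,
    priors: Priors,
    settings: McmcSettings,
    random: bool,
    seed: int,
) -> PosteriorResult:
    blocks = list(blocks)
    if not blocks:
        raise ValidationError("no likelihood blocks supplied")
    _check_connectivity_from_blocks(blocks, reference)
    design = _engine.build_design(blocks, dict(signs), reference)

    chains, diag = _engine.run_ensembles(design, priors, settings, random, seed)
    c, n, ndim = chains.shape
    flat = chains.reshape(-1, ndim)

    m = design.m
    draws = {
        "mu1": chains[:, :, 0],
        "sigma1": chains[:, :, 1],
        "beta": np.concatenate(
            [
                np.ones((c, n, 1)),
                design.signs[1:] * chains[:, :, 2 : 1 + m],
            ],
            axis=2,
        ),
    }
    if random:
        draws["phi"] = chains[:, :, 1 + m]

    cond_seed = np.random.SeedSequence(seed).spawn(settings.chains + 1)[-1]
    rng = np.random.default_rng(cond_seed)
    delta, preds, betaj = _engine.conditional_draws(design, flat, random, rng)

    # convergence bookkeeping: R-hat across independent ensembles, ESS from
    # the integrated autocorrelation time of the raw walker chains
    names: list[str] = ["mu1", "sigma1"]
    names += [f"beta[{reference}->{iid}]" for iid in design.instrument_ids[1:]]
    cols = list(range(2 + (m - 1)))
    if random:
        names.append("phi")
        cols.append(1 + m)
    per_param = {nm: chains[:, :, col] for nm, col in zip(names, cols)}
    rhat = _rhat(per_param)
    ess = {nm: float(diag["ess"][col]) for nm, col in zip(names, cols)}
    conv = pd.DataFrame(
        {
            "parameter": names,
            "rhat": [rhat[nm] for nm in names],
            "ess": [ess[nm] for nm in names],
        }
    )
    converged = bool(
        (conv["rhat"] <= settings.rhat_threshold).all()
        and (conv["ess"] >= settings.ess_threshold).all()
    )
    if not converged:
        worst = conv.sort_values("rhat").iloc[-1]
        warnings.warn(
            f"MCMC convergence gate failed (worst R-hat {worst['rhat']:.3f} "
            f"on {worst['parameter']}, min ESS {conv['ess'].min():.0f}); "
            "result flagged, consider longer runs",
            stacklevel=3,
        )

    # prior-truncation pile-up check for the uniform upper bounds
    pileups = []
    sig_flat = draws["sigma1"].ravel()
    if np.mean(sig_flat > 0.99 * priors.sigma1_upper) > 0.01:
        pileups.append("sigma1")
    if random:
        phi_flat = draws["phi"].ravel()
        if np.mean(phi_flat > 0.99 * priors.phi_upper) > 0.01:
            pileups.append("phi")
    for nm in pileups:
        warnings.warn(
            f"posterior mass of {nm} piles up at its uniform prior bound; "
            "the bound is likely informative — consider raising it",
            stacklevel=3,
        )

    meta = {
        "seed": seed,
        "converged": converged,
        "acceptance": diag["acceptance"],
        "walkers": diag["walkers"],
        "steps": diag["steps"],
        "burn": diag["burn"],
        "thin": diag["thin"],
        "prior_bound_pileup": pileups,
    }
    return PosteriorResult(
        mode="random" if random else "fixed",
        instrument_ids=design.instrument_ids,
        reference_instrument_id=reference,
        signs=design.signs,
        blocks=blocks,
        draws=draws,
        delta=delta.reshape(c, n, -1),
        betaj=betaj.reshape(c, n, len(blocks), m),
        cell_predictions=preds,
        contrast_index=design.contrast_index,
        convergence=conv,
        meta=meta,
        priors=priors,
        settings=settings,
    )


def fit_fixed_mapping(
    blocks: Sequence[LikelihoodBlock],
    signs: Mapping[str, int],
    priors: Priors | None = None,
    settings: McmcSettings | None = None,
    *,
    reference: str,
    seed: int = 0,
) -> PosteriorResult:
    """Fit the fixed-mapping model (one mapping per instrument, shared by
    all trials)."""
    return _fit(
        blocks,
        signs,
        reference=reference,
        priors=priors or Priors(),
        settings=settings or McmcSettings(),
        random=False,
        seed=seed,
    )


def fit_random_mapping(
    blocks: Sequence[LikelihoodBlock],
    signs: Mapping[str, int],
    priors: Priors | None = None,
    settings: McmcSettings | None = None,
    *,
    reference: str,
    seed: int = 0,
) -> PosteriorResult:
    """Fit the random-mapping model (trial-level mappings drawn around a
    common mean with shared coefficient of variation φ)."""
    return _fit(
        blocks,
        signs,
        reference=reference,
        priors=priors or Priors(),
        settings=settings or McmcSettings(),
        random=True,
        seed=seed,
    )


def derive_functional_mappings(result: PosteriorResult) -> MappingStructure:
    """All-pairs mapping draws β_{r→s} = β_{1→s}/β_{1→r}, per draw.

    The ratio construction makes invertibility and transitivity exact on
    every draw. A guard rejects draws with a numerically zero basic mapping
    (impossible under the sign constraint, but checked).
    """
    basic = result.flat("beta")
    ok = (np.abs(basic) > 1e-300).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} draws with numerically zero mappings")
        basic = basic[ok]
    functional = basic[:, None, :] / basic[:, :, None]
    phi = None
    if result.mode == "random":
        phi = result.flat("phi")
        if dropped:
            phi = phi[ok]
    return MappingStructure(
        reference_instrument=result.reference_instrument_id,
        instrument_ids=list(result.instrument_ids),
        mode=result.mode,
        basic=basic,
        functional=functional,
        phi=phi,
    )


def derive_instrument_effects(result: PosteriorResult) -> pd.DataFrame:
    """Pooled treatment effects expressed on every instrument.

    Draw-by-draw, μ_m = β_{1→m}·μ1 and σ_m = |β_{1→m}|·σ1; summaries follow
    the reporting convention of mean (SD) for effects and percentiles for
    between-study SDs.
    """
    mu1 = result.flat("mu1")
    sig1 = result.flat("sigma1")
    beta = result.flat("beta")
    rows = []
    for m, iid in enumerate(result.instrument_ids):
        mu_m = beta[:, m] * mu1
        sd_m = np.abs(beta[:, m]) * sig1
        rows.append(
            {
                "instrument": iid,
                "effect_mean": mu_m.mean(),
                "effect_sd": mu_m.std(),
                "effect_q2.5": np.percentile(mu_m, 2.5),
                "effect_q97.5": np.percentile(mu_m, 97.5),
                "bsd_q2.5": np.percentile(sd_m, 2.5),
                "bsd_median": np.percentile(sd_m, 50),
                "bsd_q97.5": np.percentile(sd_m, 97.5),
            }
        )
    return pd.DataFrame(rows).set_index("instrument")


def predict_trial_effects(
    result: PosteriorResult,
    trial_id: str,
    contrast_id: str | None = None,
) -> pd.DataFrame:
    """Draws of the predicted treatment effect δ_{jm} = β_{j,1→m}·δ_{j1} on
    *every* instrument for one trial contrast, including instruments the
    trial never reported (posterior predictive for the unreported ones under
    the random-mapping model)."""
    pos = result._contrast_pos(trial_id, contrast_id)
    trial_ids = [b.trial_id for b in result.blocks]
    j = trial_ids.index(trial_id)
    dj = result.delta.reshape(-1, result.delta.shape[-1])[:, pos]
    bj = result.betaj.reshape(-1, *result.betaj.shape[2:])[:, j, :]
    data = {iid: bj[:, m] * dj for m, iid in enumerate(result.instrument_ids)}
    return pd.DataFrame(data)
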