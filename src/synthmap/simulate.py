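"""Synthetic trial networks from a common treatment-factor model.

Individual outcomes on instrument m arise from a single treatment-sensitive
latent construct y and an instrument-specific error ε (orthogonal to y, but
correlated across instruments):

    Y_m = a_m + b_m·(y + δ·treated) + c_m·ε_m,      y, ε ~ N(0, 1)

so a treatment shift δ on the construct manifests as b_m·δ on instrument m
and the implied mapping from r to s is the loading ratio b_s/b_r —
invertible and transitive by construction. Baseline and follow-up scores
share persistent person-level components of both y and ε, giving a
configurable baseline–follow-up correlation (default 0.5, the conventional
working assumption for change scores). Aggregating change scores per arm
reproduces exactly the trial-summary shape the synthesis model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trial_data import (
    ArmSummary,
    Instrument,
    KNOWN_INSTRUMENTS,
    Trial,
    TrialOutcome,
    TrialTable,
    ValidationError,
    _instrument_from_id,
)

__all__ = [
    "SyntheticTrialSpec",
    "FactorModelSpec",
    "ScenarioConfig",
    "SyntheticStudy",
    "generate_individuals",
    "aggregate",
    "make_study",
    "default_scenario",
    "small_scenario",
    "error_correlations_for_targets",
]

#: missingness pattern of the bundled ankylosing spondylitis network:
#: which instruments each trial reports (trial 8 is the three-arm trial)
AS_PATTERN: list[list[str]] = [
    ["PAIN-VAS", "BASFI"],
    ["BASFI", "BASDAI"],
    ["PAIN-VAS", "BASFI", "BASDAI"],
    ["PAIN-VAS", "BASFI", "BASDAI"],
    ["BASFI", "BASDAI", "SF36-PCS", "SF36-MCS"],
    ["BASFI", "BASDAI", "ASQOL", "SF36-PCS", "SF36-MCS"],
    ["PAIN-VAS", "BASFI", "BASDAI", "SF36-PCS", "SF36-MCS"],
    ["PAIN-VAS", "BASFI", "SF36-PCS", "SF36-MCS"],
]


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """One synthetic trial: construct-scale effects per contrast, arm sizes,
    reported instruments, and the realized per-trial loading jitter."""

    trial_id: str
    deltas: dict[str, float]            # contrast_id -> effect on construct
    n_treat: int
    n_ctrl: int
    reported: tuple[str, ...]
    loading_jitter: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_treat < 1 or self.n_ctrl < 1:
            raise ValidationError(
                f"trial {self.trial_id}: arm sizes must be >= 1 "
                f"(got n_treat={self.n_treat}, n_ctrl={self.n_ctrl})"
            )
        if not self.deltas:
            raise ValidationError(f"trial {self.trial_id}: needs >= 1 contrast")
        if not self.reported:
            raise ValidationError(f"trial {self.trial_id}: reports no instruments")


@dataclass
class FactorModelSpec:
    """Population and measurement model for a synthetic study."""

    instrument_ids: list[str]
    intercepts: np.ndarray        # a_m, native scale
    loadings: np.ndarray          # b_m, native scale per construct SD (signed)
    error_loadings: np.ndarray    # c_m > 0
    error_corr: np.ndarray        # correlation of ε across instruments
    trials: list[SyntheticTrialSpec]
    baseline_followup_corr: float = 0.5
    reference: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.instrument_ids)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.error_loadings = np.asarray(self.error_loadings, dtype=float)
        self.error_corr = np.asarray(self.error_corr, dtype=float)
        for name in ("intercepts", "loadings", "error_loadings"):
            if getattr(self, name).shape != (m,):
                raise ValidationError(f"{name} must have length {m}")
        if np.any(self.error_loadings <= 0):
            raise ValidationError("error loadings c_m must be positive")
        if self.error_corr.shape != (m, m):
            raise ValidationError("error_corr has the wrong shape")
        eig = np.linalg.eigvalsh((self.error_corr + self.error_corr.T) / 2)
        if eig[0] < -1e-8:
            raise ValidationError("error correlation matrix must be PSD")
        if not -1 < self.baseline_followup_corr < 1:
            raise ValidationError("baseline_followup_corr must be in (-1, 1)")
        if self.reference is None:
            self.reference = self.instrument_ids[0]
        unknown = {i for t in self.trials for i in t.reported} - set(self.instrument_ids)
        if unknown:
            raise ValidationError(f"trials report unknown instruments {sorted(unknown)}")

    def trial_loadings(self, trial: SyntheticTrialSpec) -> np.ndarray:
        fac = np.array(
            [trial.loading_jitter.get(i, 1.0) for i in self.instrument_ids]
        )
        return self.loadings * fac

    def mapping_truth(self, trial: SyntheticTrialSpec | None = None) -> dict[str, float]:
        b = self.loadings if trial is None else self.trial_loadings(trial)
        ref = self.instrument_ids.index(self.reference)
        return {i: float(b[m] / b[ref]) for m, i in enumerate(self.instrument_ids)}


@dataclass(frozen=True)
class ScenarioConfig:
    """High-level knobs for :func:`make_study`.

    ``mu1``/``sigma1`` are the mean and between-trial SD of the treatment
    effect expressed on the *reference instrument*; ``phi`` the between-trial
    CV of the mappings (0 ⇒ fixed mappings hold exactly in the data).
    """

    instrument_ids: tuple[str, ...]
    intercepts: tuple[float, ...]
    construct_corr: tuple[float, ...]   # correlation of instrument with construct
    scale_sd: tuple[float, ...]         # cross-sectional SD per instrument
    target_corr: np.ndarray | None      # desired between-instrument correlations
    pattern: tuple[tuple[str, ...], ...]
    n_contrasts: tuple[int, ...]
    mu1: float = -2.3
    sigma1: float = 0.42
    phi: float = 0.13
    n_per_arm: int = 140
    baseline_followup_corr: float = 0.5
    reference: str = "PAIN-VAS"


def error_correlations_for_targets(
    construct_corr: np.ndarray, target_corr: np.ndarray
) -> np.ndarray:
    """Back-solve the ε cross-correlations so that the marginal
    between-instrument correlations match a target matrix.

    corr(Y_r, Y_s) = b̃_r·b̃_s + c̃_r·c̃_s·E_rs on standardized scales, so
    E_rs = (ρ_rs − b̃_r·b̃_s)/(c̃_r·c̃_s), clipped to [−0.99, 0.99] and
    eigenvalue-projected to the nearest PSD correlation matrix.
    """
    bt = np.asarray(construct_corr, dtype=float)
    ct = np.sqrt(1.0 - bt**2)
    e = (np.asarray(target_corr, dtype=float) - np.outer(bt, bt)) / np.outer(ct, ct)
    np.fill_diagonal(e, 1.0)
    e = np.clip(e, -0.99, 0.99)
    e = (e + e.T) / 2
    w, v = np.linalg.eigh(e)
    if w[0] < 1e-8:
        w = np.clip(w, 1e-8, None)
        e = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(e))
        e = e / np.outer(d, d)
    return e


def default_scenario(**overrides) -> ScenarioConfig:
    """The bundled-network scenario: 6 instruments, 8 trials (one three-arm)
    with the bundled reporting pattern, effects and mappings at the values
    estimated from the ankylosing spondylitis synthesis."""
    from .trial_data import load_easiqol_correlations

    rho = load_easiqol_correlations()
    beta = {"PAIN-VAS": 1.0, "BASFI": 0.68, "BASDAI": 0.92, "ASQOL": 1.21,
            "SF36-PCS": -2.88, "SF36-MCS": -0.59}
    bt = {"PAIN-VAS": 0.85, "BASFI": 0.83, "BASDAI": 0.93, "ASQOL": 0.88,
          "SF36-PCS": -0.82, "SF36-MCS": -0.52}
    s1 = 2.2
    ids = tuple(KNOWN_INSTRUMENTS)
    scale_sd = tuple(
        beta[i] * s1 * bt["PAIN-VAS"] / bt[i] for i in ids
    )
    cfg = dict(
        instrument_ids=ids,
        intercepts=(6.5, 5.5, 6.0, 10.0, 30.0, 45.0),
        construct_corr=tuple(bt[i] for i in ids),
        scale_sd=scale_sd,
        target_corr=rho.submatrix(list(ids)),
        pattern=tuple(tuple(p) for p in AS_PATTERN),
        n_contrasts=(1, 1, 1, 1, 1, 1, 1, 2),
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


def small_scenario(
    n_trials: int = 6, n_per_arm: int = 140, phi: float = 0.13, **overrides
) -> ScenarioConfig:
    """A compact three-instrument network with full reporting — the
    workhorse for parameter-recovery simulations."""
    ids = ("PAIN-VAS", "BASFI", "SF36-PCS")
    target = np.array(
        [[1.0, 0.703, -0.668], [0.703, 1.0, -0.842], [-0.668, -0.842, 1.0]]
    )
    cfg = dict(
        instrument_ids=ids,
        intercepts=(6.5, 5.5, 30.0),
        construct_corr=(0.85, 0.83, -0.82),
        scale_sd=(2.2, 1.5, 6.5),
        target_corr=target,
        pattern=tuple(ids for _ in range(n_trials)),
        n_contrasts=tuple(1 for _ in range(n_trials)),
        n_per_arm=n_per_arm,
        phi=phi,
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


@dataclass
class SyntheticStudy:
    """A generated evidence base plus the ground truth that produced it."""

    table: TrialTable
    truth: dict
    spec: FactorModelSpec
    individuals: pd.DataFrame | None = None


def _build_spec(scenario: ScenarioConfig, seed: int) -> tuple[FactorModelSpec, dict]:
    ids = list(scenario.instrument_ids)
    bt = np.asarray(scenario.construct_corr, dtype=float)
    sd = np.asarray(scenario.scale_sd, dtype=float)
    b = sd * bt
    c = sd * np.sqrt(1.0 - bt**2)
    if scenario.target_corr is not None:
        ecorr = error_correlations_for_targets(bt, scenario.target_corr)
    else:
        ecorr = np.eye(len(ids))

    ref = ids.index(scenario.reference)
    mu_y = scenario.mu1 / b[ref]
    sig_y = scenario.sigma1 / abs(b[ref])

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2953]))
    trials = []
    truth_delta: dict[str, dict[str, float]] = {}
    truth_betaj: dict[str, dict[str, float]] = {}
    for j, reported in enumerate(scenario.pattern):
        tid = f"trial-{j + 1}"
        nc = scenario.n_contrasts[j]
        u = rng.standard_normal(nc)
        if nc == 1:
            dys = [mu_y + sig_y * u[0]]
        else:
            # shared-control contrasts: between-trial covariance σ²/2
            dys = [mu_y + sig_y * u[0]]
            for k in range(1, nc):
                dys.append(mu_y + sig_y * (0.5 * u[0] + np.sqrt(0.75) * u[k]))
        deltas = {f"c{k + 1}": float(d) for k, d in enumerate(dys)}
        jitter = {}
        if scenario.phi > 0:
            for i in ids:
                if i != scenario.reference:
                    jitter[i] = float(1.0 + scenario.phi * rng.standard_normal())
        trials.append(
            SyntheticTrialSpec(
                trial_id=tid,
                deltas=deltas,
                n_treat=scenario.n_per_arm,
                n_ctrl=scenario.n_per_arm,
                reported=tuple(reported),
                loading_jitter=jitter,
            )
        )
        truth_delta[tid] = {
            k: float(b[ref] * d) for k, d in deltas.items()
        }  # reference-instrument scale
        truth_betaj[tid] = {
            i: float(b[m] * jitter.get(i, 1.0) / b[ref]) for m, i in enumerate(ids)
        }

    spec = FactorModelSpec(
        instrument_ids=ids,
        intercepts=np.asarray(scenario.intercepts, dtype=float),
        loadings=b,
        error_loadings=c,
        error_corr=ecorr,
        trials=trials,
        baseline_followup_corr=scenario.baseline_followup_corr,
        reference=scenario.reference,
        seed=seed,
    )
    truth = {
        "mu1": scenario.mu1,
        "sigma1": scenario.sigma1,
        "phi": scenario.phi,
        "beta": spec.mapping_truth(),
        "delta": truth_delta,
        "betaj": truth_betaj,
    }
    return spec, truth


def generate_individuals(
    spec: FactorModelSpec,
    trial: SyntheticTrialSpec | str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Individual-level baseline and follow-up outcomes for one trial.

    Returns a tidy frame with one row per (arm, subject, instrument); the
    control arm is shared by all contrasts of the trial.
    """
    if isinstance(trial, str):
        trial = next(t for t in spec.trials if t.trial_id == trial)
    if rng is None:
        idx = [t.trial_id for t in spec.trials].index(trial.trial_id)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))

    ids = spec.instrument_ids
    m = len(ids)
    b = spec.trial_loadings(trial)
    a, c = spec.intercepts, spec.error_loadings
    rho = spec.baseline_followup_corr
    chol = np.linalg.cholesky(spec.error_corr + 1e-12 * np.eye(m))

    def draw_arm(arm_id: str, n: int, delta_y: float) -> pd.DataFrame:
        g0 = rng.standard_normal(n)
        g1 = rho * g0 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        e0 = rng.standard_normal((n, m)) @ chol.T
        e1 = rho * e0 + np.sqrt(1 - rho**2) * (rng.standard_normal((n, m)) @ chol.T)
        yb = a[None, :] + b[None, :] * g0[:, None] + c[None, :] * e0
        yf = a[None, :] + b[None, :] * (g1[:, None] + delta_y) + c[None, :] * e1
        return pd.DataFrame(
            {
                "trial_id": trial.trial_id,
                "arm_id": arm_id,
                "subject": np.repeat(np.arange(n), m),
                "instrument": np.tile(ids, n),
                "y_baseline": yb.ravel(),
                "y_followup": yf.ravel(),
            }
        )

    frames = [draw_arm("control", trial.n_ctrl, 0.0)]
    for cid, dy in trial.deltas.items():
        frames.append(draw_arm(cid, trial.n_treat, dy))
    return pd.concat(frames, ignore_index=True)


def aggregate(
    spec: FactorModelSpec, records: pd.DataFrame
) -> tuple[list[TrialOutcome], list[ArmSummary]]:
    """Collapse individual records to trial-summary rows.

    Change scores (follow-up − baseline) are averaged per arm; the reported
    effect is the between-arm difference of mean change with
    SE = √(V_T/n_T + V_C/n_C). The trial's missingness pattern is applied
    here: unreported instruments are dropped from the summaries.
    """
    outcomes: list[TrialOutcome] = []
    arms: list[ArmSummary] = []
    by_trial = {t.trial_id: t for t in spec.trials}
    for tid, sub in records.groupby("trial_id", sort=False):
        trial = by_trial[str(tid)]
        sub = sub.assign(change=sub["y_followup"] - sub["y_baseline"])
        stats = (
            sub.groupby(["arm_id", "instrument"], sort=False)["change"]
            .agg(["mean", "var", "count"])
        )
        basemeans = sub.groupby(["arm_id", "instrument"], sort=False)[
            "y_baseline"
        ].mean()
        followmeans = sub.groupby(["arm_id", "instrument"], sort=False)[
            "y_followup"
        ].mean()
        for (arm_id, iid), row in stats.iterrows():
            if iid not in trial.reported:
                continue
            arms.append(
                ArmSummary(
                    trial_id=str(tid),
                    arm_id=str(arm_id),
                    instrument_id=str(iid),
                    n=int(row["count"]),
                    mean_baseline=float(basemeans.loc[(arm_id, iid)]),
                    mean_followup=float(followmeans.loc[(arm_id, iid)]),
                    var_change=float(row["var"]),
                )
            )
        for cid in trial.deltas:
            for iid in trial.reported:
                mt, vt, nt = stats.loc[(cid, iid)]
                mc, vc, ncn = stats.loc[("control", iid)]
                outcomes.append(
                    TrialOutcome(
                        trial_id=str(tid),
                        contrast_id=str(cid),
                        instrument_id=str(iid),
                        effect=float(mt - mc),
                        se=float(np.sqrt(vt / nt + vc / ncn)),
                        treatment_label="synthetic",
                    )
                )
    return outcomes, arms


def make_study(
    scenario: ScenarioConfig | None = None,
    *,
    seed: int = 0,
    keep_individuals: bool = False,
) -> SyntheticStudy:
    """Generate a full synthetic study: individual data → trial summaries
    → :class:`TrialTable`, with the generating truth attached."""
    scenario = scenario or default_scenario()
    spec, truth = _build_spec(scenario, seed)
    all_records = []
    for idx, t in enumerate(spec.trials):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        all_records.append(generate_individuals(spec, t, rng))
    records = pd.concat(all_records, ignore_index=True)
    outcomes, arms = aggregate(spec, records)

    by_trial: dict[str, list[TrialOutcome]] = {}
    for o in outcomes:
        by_trial.setdefault(o.trial_id, []).append(o)
    trials = [
        Trial(t.trial_id, tuple(t.deltas), tuple(by_trial[t.trial_id]))
        for t in spec.trials
    ]
    instruments = [_instrument_from_id(i) for i in spec.instrument_ids]
    table = TrialTable(trials, instruments, spec.reference, arm_summaries=arms)
    return SyntheticStudy(
        table=table,
        truth=truth,
        spec=spec,
        individuals=records if keep_individuals else None,
    )
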