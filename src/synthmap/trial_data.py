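"""Trial-level evidence tables, instruments and external correlation matrices.

The evidence unit is a *trial outcome*: the mean change-score difference
(treatment − control) reported by one contrast of one trial on one test
instrument, together with its standard error. Trials report arbitrary
subsets of the instrument set; a multi-arm trial contributes several
contrasts sharing one control arm. Between-instrument correlations are not
reported by the trials and are supplied externally from a cross-sectional
cohort (here the EASi-QoL study of ankylosing spondylitis patients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Instrument",
    "TrialOutcome",
    "ArmSummary",
    "Trial",
    "TrialTable",
    "CorrelationMatrix",
    "ConnectivityReport",
    "ValidationError",
    "load_trials",
    "write_trials",
    "load_correlations",
    "validate_connectivity",
    "derive_signs",
    "load_as_trials",
    "load_easiqol_correlations",
]

TRIALS_COLUMNS = [
    "trial_id",
    "contrast_id",
    "treatment_label",
    "followup_weeks",
    "instrument",
    "effect",
    "se",
]

#: Scale metadata for the ankylosing spondylitis instrument set.
KNOWN_INSTRUMENTS = {
    "PAIN-VAS": ("Pain visual analogue scale", 0.0, 10.0),
    "BASFI": ("Bath Ankylosing Spondylitis Functional Index", 0.0, 10.0),
    "BASDAI": ("Bath Ankylosing Spondylitis Disease Activity Index", 0.0, 10.0),
    "ASQOL": ("Ankylosing Spondylitis Quality of Life scale", 0.0, 18.0),
    "SF36-PCS": ("SF-36 physical component summary", 0.0, 100.0),
    "SF36-MCS": ("SF-36 mental component summary", 0.0, 100.0),
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural requirement."""


@dataclass(frozen=True)
class Instrument:
    """A test instrument (outcome measure) on its native scale."""

    id: str
    label: str = ""
    scale_min: float = float("nan")
    scale_max: float = float("nan")
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if self.direction_sign not in (-1, 1):
            raise ValidationError(
                f"direction_sign for {self.id!r} must be +1 or -1, "
                f"got {self.direction_sign}"
            )


@dataclass(frozen=True)
class TrialOutcome:
    """One reported treatment difference on one instrument.

    ``effect`` is the mean change-score difference (treatment − control) on
    the instrument's native scale; ``se`` its standard error.
    """

    trial_id: str
    contrast_id: str
    instrument_id: str
    effect: float
    se: float
    followup_weeks: float = float("nan")
    treatment_label: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(
                f"se must be > 0 (trial {self.trial_id}, contrast "
                f"{self.contrast_id}, instrument {self.instrument_id}: {self.se})"
            )


@dataclass(frozen=True)
class ArmSummary:
    """Optional arm-level summary, for trials reporting per-arm variances.

    Either ``var_change`` or both baseline and follow-up variances must be
    present so that a change-score variance can be formed.
    """

    trial_id: str
    arm_id: str
    instrument_id: str
    n: int
    mean_baseline: float = float("nan")
    mean_followup: float = float("nan")
    var_baseline: float = float("nan")
    var_followup: float = float("nan")
    var_change: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"arm sample size must be >= 1, got {self.n}")
        for name in ("var_baseline", "var_followup", "var_change"):
            v = getattr(self, name)
            if not np.isnan(v) and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if np.isnan(self.var_change) and (
            np.isnan(self.var_baseline) or np.isnan(self.var_followup)
        ):
            raise ValidationError(
                "need var_change, or both var_baseline and var_followup "
                f"(trial {self.trial_id}, arm {self.arm_id})"
            )


@dataclass(frozen=True)
class Trial:
    """A trial: one shared control arm and one or more active contrasts."""

    trial_id: str
    contrast_ids: tuple[str, ...]
    outcomes: tuple[TrialOutcome, ...]

    @property
    def n_contrasts(self) -> int:
        return len(self.contrast_ids)

    @property
    def instrument_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for o in self.outcomes:
            seen.setdefault(o.instrument_id, None)
        return tuple(seen)


@dataclass
class TrialTable:
    """The full trial-level evidence base."""

    trials: list[Trial]
    instruments: list[Instrument]
    reference_instrument_id: str
    arm_summaries: list[ArmSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i.id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise ValidationError("instrument ids must be unique")
        known = set(ids)
        for t in self.trials:
            if not t.outcomes:
                raise ValidationError(f"trial {t.trial_id} reports no outcomes")
            for o in t.outcomes:
                if o.instrument_id not in known:
                    raise ValidationError(
                        f"outcome refers to unknown instrument {o.instrument_id!r}"
                    )
        if self.reference_instrument_id not in known:
            raise ValidationError(
                f"reference instrument {self.reference_instrument_id!r} "
                "not among instruments"
            )
        seen: set[tuple[str, str, str]] = set()
        for o in self.outcomes():
            key = (o.trial_id, o.contrast_id, o.instrument_id)
            if key in seen:
                raise ValidationError(f"duplicate outcome {key}")
            seen.add(key)

    def outcomes(self) -> Iterable[TrialOutcome]:
        for t in self.trials:
            yield from t.outcomes

    @property
    def n_datapoints(self) -> int:
        return sum(len(t.outcomes) for t in self.trials)

    @property
    def instrument_ids(self) -> list[str]:
        return [i.id for i in self.instruments]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_id": o.trial_id,
                "contrast_id": o.contrast_id,
                "treatment_label": o.treatment_label,
                "followup_weeks": o.followup_weeks,
                "instrument": o.instrument_id,
                "effect": o.effect,
                "se": o.se,
            }
            for o in self.outcomes()
        ]
        return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


@dataclass
class CorrelationMatrix:
    """Between-instrument correlations of change scores, externally sourced."""

    instrument_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        m = len(self.instrument_ids)
        if r.shape != (m, m):
            raise ValidationError(f"correlation matrix must be {m}x{m}, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValidationError("correlation matrix is not symmetric (tol 1e-8)")
        r = (r + r.T) / 2.0
        if np.any(np.abs(r) > 1 + 1e-12):
            bad = np.argwhere(np.abs(r) > 1 + 1e-12)[0]
            raise ValidationError(
                "correlation entries must lie in [-1, 1]; "
                f"rho[{self.instrument_ids[bad[0]]}, {self.instrument_ids[bad[1]]}] "
                f"= {r[bad[0], bad[1]]}"
            )
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValidationError("correlation matrix diagonal must be 1")
        np.fill_diagonal(r, 1.0)
        self.rho = r
        eig = np.linalg.eigvalsh(r)
        if eig[0] < -1e-8:
            # only per-trial sub-blocks of the assembled covariance must be
            # positive definite, so a globally indefinite external matrix is
            # tolerated with a warning
            warnings.warn(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig[0]:.3g}); per-trial blocks will still "
                "be checked",
                stacklevel=2,
            )

    def value(self, a: str, b: str) -> float:
        i = self.instrument_ids.index(a)
        j = self.instrument_ids.index(b)
        return float(self.rho[i, j])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.instrument_ids.index(i) for i in ids]
        return self.rho[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rho, index=self.instrument_ids, columns=self.instrument_ids
        )


@dataclass(frozen=True)
class ConnectivityReport:
    """Connected components of the instrument co-reporting graph."""

    components: tuple[frozenset[str], ...]
    reference_instrument_id: str

    @property
    def connected(self) -> bool:
        return len(self.components) == 1

    @property
    def unreachable_from_reference(self) -> frozenset[str]:
        for comp in self.components:
            if self.reference_instrument_id in comp:
                reachable = comp
                break
        else:
            reachable = frozenset()
        out: set[str] = set()
        for comp in self.components:
            out |= comp - reachable
        return frozenset(out)


def _instrument_from_id(iid: str, sign: int = 1) -> Instrument:
    label, lo, hi = KNOWN_INSTRUMENTS.get(iid, (iid, float("nan"), float("nan")))
    return Instrument(id=iid, label=label, scale_min=lo, scale_max=hi,
                      direction_sign=sign)


def load_trials(
    path: str | Path,
    *,
    fmt: str = "csv",
    reference_instrument: str | None = None,
    instrument_order: Sequence[str] | None = None,
) -> TrialTable:
    """Read a trials file into a validated :class:`TrialTable`.

    The file needs columns ``trial_id, contrast_id, instrument, effect, se``
    (``treatment_label`` and ``followup_weeks`` are optional). Rows of a
    multi-arm trial share a ``trial_id`` and differ in ``contrast_id``; all
    contrasts of a trial are taken to share one control arm.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValidationError(f"unknown trials format {fmt!r}")
    df = pd.read_csv(path, sep=sep, dtype={"trial_id": str, "contrast_id": str})
    required = {"trial_id", "contrast_id", "instrument", "effect", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trials file {path} lacks columns: {sorted(missing)}")
    if "treatment_label" not in df.columns:
        df["treatment_label"] = ""
    if "followup_weeks" not in df.columns:
        df["followup_weeks"] = np.nan

    bad = df[~(df["se"] > 0)]
    if len(bad):
        rows = ", ".join(
            f"(row {i + 2}: trial {r.trial_id}, {r.instrument}, se={r.se})"
            for i, r in bad.iterrows()
        )
        raise ValidationError(f"standard errors must be > 0: {rows}")

    if instrument_order is None:
        instrument_order = list(dict.fromkeys(df["instrument"]))
    else:
        unknown = set(df["instrument"]) - set(instrument_order)
        if unknown:
            raise ValidationError(f"instrument_order lacks {sorted(unknown)}")

    trials: list[Trial] = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        contrast_ids = tuple(dict.fromkeys(sub["contrast_id"]))
        outcomes = []
        for cid in contrast_ids:
            rows = sub[sub["contrast_id"] == cid]
            # stable instrument ordering within each contrast
            rows = rows.iloc[
                np.argsort([instrument_order.index(i) for i in rows["instrument"]],
                           kind="stable")
            ]
            for r in rows.itertuples():
                outcomes.append(
                    TrialOutcome(
                        trial_id=str(trial_id),
                        contrast_id=str(cid),
                        instrument_id=r.instrument,
                        effect=float(r.effect),
                        se=float(r.se),
                        followup_weeks=float(r.followup_weeks),
                        treatment_label=str(r.treatment_label),
                    )
                )
        trials.append(Trial(str(trial_id), contrast_ids, tuple(outcomes)))

    if reference_instrument is None:
        reference_instrument = instrument_order[0]
    instruments = [_instrument_from_id(i) for i in instrument_order]
    return TrialTable(trials, instruments, reference_instrument)


def write_trials(table: TrialTable, path: str | Path, *, fmt: str = "csv") -> None:
    """Write a :class:`TrialTable` back to disk (inverse of :func:`load_trials`)."""
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    table.to_frame().to_csv(path, sep=sep, index=False)


def load_correlations(path: str | Path) -> CorrelationMatrix:
    """Read a square correlation CSV (first column = instrument ids)."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != ids:
        raise ValidationError(
            f"correlation file {path}: row labels must match column labels "
            "in the same order"
        )
    return CorrelationMatrix(ids, df.to_numpy(dtype=float))


def validate_connectivity(table: TrialTable) -> ConnectivityReport:
    """Connected components of the instrument co-reporting graph.

    Two instruments are joined when some trial reports both. Mappings are
    estimable only within the component containing the reference instrument;
    model fitting refuses disconnected inputs.
    """
    g = nx.Graph()
    g.add_nodes_from(table.instrument_ids)
    for t in table.trials:
        ids = t.instrument_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                g.add_edge(a, b)
    comps = tuple(frozenset(c) for c in nx.connected_components(g))
    return ConnectivityReport(comps, table.reference_instrument_id)


def derive_signs(
    rho: CorrelationMatrix, reference: str
) -> dict[str, int]:
    """Mapping signs relative to the reference instrument.

    The relative signs of the mappings are treated as known, read off the
    external correlation matrix: sign_m = sign(ρ(reference, m)).
    """
    if reference not in rho.instrument_ids:
        raise ValidationError(f"reference {reference!r} not in correlation matrix")
    signs: dict[str, int] = {}
    for m in rho.instrument_ids:
        if m == reference:
            signs[m] = 1
            continue
        v = rho.value(reference, m)
        if v == 0:
            raise ValidationError(
                f"rho({reference}, {m}) = 0: mapping sign undefined; "
                "supply signs explicitly"
            )
        signs[m] = 1 if v > 0 else -1
    return signs


def _data_path(name: str):
    return resources.files("synthmap.data").joinpath(name)


def load_as_trials() -> TrialTable:
    """The bundled ankylosing spondylitis evidence base (8 TNF-α inhibitor
    trials, 6 instruments, 32 treatment differences; one three-arm trial)."""
    with resources.as_file(_data_path("as_trials.csv")) as p:
        return load_trials(
            p,
            reference_instrument="PAIN-VAS",
            instrument_order=list(KNOWN_INSTRUMENTS),
        )


def load_easiqol_correlations() -> CorrelationMatrix:
    """The bundled EASi-QoL between-instrument correlation matrix
    (571 ankylosing spondylitis patients, cross-sectional)."""
    with resources.as_file(_data_path("easiqol_correlations.csv")) as p:
        return load_correlations(p)
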