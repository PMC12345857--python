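"""Synthetic dispensing-record cohorts from a known trajectory model.

The generator works top-down from the latent structure the analysis is meant
to recover: each patient is assigned to one of a few trajectory groups (a
multinomial-logit membership model, optionally tilted by binary covariates
such as diabetes), each group has a polynomial-in-time logit curve giving the
monthly probability of being adherent, monthly binary adherence indicators
are drawn from those probabilities, and finally a refill stream is
materialised that is *consistent* with each month's indicator: adherent
months receive fills covering at least 80% of their days, non-adherent
months strictly less.  This makes the PDC stage a tested transformation —
running the dispensing records back through PDC + binarisation recovers the
generated monthly pattern exactly.

Defaults emulate a single-centre oral-endocrine-therapy cohort: ~350
patients followed over twelve 30-day periods, three trajectory shapes
(persistently adherent ~44%, gradually declining ~26%, low-then-improving
~31%), a 90-day carry-in window before period 1, and binary comorbidity
covariates that shift membership odds toward the non-adherent groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from .pdc import DispensingRecord, records_to_frame

ANCHOR_DATE = date(2022, 1, 1)  # calendar origin: period 1 day 1

# Default three-group structure: proportions follow the canonical
# adherent / declining / improving split; betas (on raw t = 1..12) give
# clearly separated curves: high-flat ~0.95, 0.95 -> 0.12 decline,
# 0.10 -> 0.75 improvement.
DEFAULT_GROUPS = (
    ("adherent", 0.439, (3.0, 0.05, -0.01)),
    ("gradual_decline", 0.255, (3.2, -0.25, -0.015)),
    ("improving", 0.306, (-2.6, 0.45, -0.012)),
)

# Membership log-odds shifts vs the adherent reference group, mirroring the
# kind of comorbidity effects seen in adherence studies (diabetes pushing
# patients toward the declining trajectory most strongly).
DEFAULT_COVARIATE_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "diabetes": {"gradual_decline": math.log(2.96), "improving": math.log(1.40)},
    "hypertension": {"gradual_decline": math.log(1.32), "improving": math.log(1.82)},
    "depression": {},  # null covariate: prevalent but unrelated to membership
}

DEFAULT_PREVALENCES: Mapping[str, float] = {
    "diabetes": 0.335,
    "hypertension": 0.578,
    "depression": 0.153,
}


@dataclass(frozen=True)
class GroupSpec:
    """One latent trajectory group: label, population share, logit-curve betas."""

    label: str
    proportion: float
    beta: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError(f"proportion must be in (0,1], got {self.proportion}")
        if not all(np.isfinite(self.beta)):
            raise ValueError(f"beta must be finite, got {self.beta}")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort — the simulation's single input."""

    n_patients: int = 350
    n_periods: int = 12
    period_length_days: int = 30
    group_specs: tuple[GroupSpec, ...] = tuple(
        GroupSpec(*g) for g in DEFAULT_GROUPS
    )
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    baseline_covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    carry_in_window_days: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.n_periods < 2:
            raise ValueError("n_periods must be >= 2 (time trend unidentifiable)")
        if self.period_length_days < 5:
            raise ValueError("period_length_days must be >= 5")
        if self.carry_in_window_days < 0:
            raise ValueError("carry_in_window_days must be non-negative")
        total = sum(g.proportion for g in self.group_specs)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"group proportions must sum to 1, got {total!r}")
        labels = {g.label for g in self.group_specs}
        for cov, shifts in self.covariate_effects.items():
            unknown = set(shifts) - labels
            if unknown:
                raise ValueError(f"covariate {cov!r} shifts unknown groups {unknown}")
            if cov not in self.baseline_covariate_prevalences:
                raise ValueError(f"no prevalence given for covariate {cov!r}")
        for cov, prev in self.baseline_covariate_prevalences.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence of {cov!r} must be in (0,1)")

    @property
    def n_groups(self) -> int:
        return len(self.group_specs)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.group_specs]


@dataclass
class SyntheticCohort:
    """Generated cohort: records + covariates + the latent truth behind them."""

    spec: CohortSpec
    records: list[DispensingRecord]
    true_group: np.ndarray          # per-patient group index into spec.group_specs
    covariates: pd.DataFrame        # patient_id + one 0/1 column per covariate
    monthly_truth: np.ndarray       # N x T adherence probabilities p_gt
    monthly_binary: np.ndarray      # N x T drawn adherence indicators
    patient_ids: list[str]

    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "true_group": self.true_group,
                "true_label": [self.spec.labels[g] for g in self.true_group],
            }
        )

    def write_csvs(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "dispensing": outdir / "dispensing.csv",
            "covariates": outdir / "covariates.csv",
            "truth": outdir / "truth.csv",
        }
        self.records_frame().to_csv(paths["dispensing"], index=False)
        self.covariates.to_csv(paths["covariates"], index=False)
        self.truth_frame().to_csv(paths["truth"], index=False)
        return paths


def trajectory_probability(beta: Sequence[float], t) -> np.ndarray | float:
    """Adherence probability inverse-logit(beta0 + beta1 t + beta2 t^2 ...)."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError(f"beta must be finite, got {beta}")
    t_arr = np.asarray(t, dtype=float)
    powers = t_arr[..., None] ** np.arange(beta.size)
    out = expit(powers @ beta)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _effect_matrix(spec: CohortSpec) -> tuple[list[str], np.ndarray]:
    """Covariate membership shifts as a (n_covariates x G) array."""
    label_index = {lab: i for i, lab in enumerate(spec.labels)}
    covs = [c for c in spec.covariate_effects if spec.covariate_effects[c]]
    delta = np.zeros((len(covs), spec.n_groups))
    for r, cov in enumerate(covs):
        for lab, d in spec.covariate_effects[cov].items():
            delta[r, label_index[lab]] = d
    return covs, delta


def calibrated_intercepts(spec: CohortSpec) -> np.ndarray:
    """Membership-logit intercepts such that the *marginal* group proportions
    (averaged over the independent-Bernoulli covariate distribution) equal the
    spec's mixing proportions despite covariate tilting.

    Solved by fixed-point iteration on alpha_g <- alpha_g + log(target/marginal);
    the expectation over covariate patterns is computed exactly by enumerating
    the 2^C combinations of the effect-carrying covariates.
    """
    target = np.array([g.proportion for g in spec.group_specs])
    covs, delta = _effect_matrix(spec)
    alpha = np.log(target / target[0])
    if not covs:
        return alpha
    prevs = np.array([spec.baseline_covariate_prevalences[c] for c in covs])
    combos = np.array(
        [[(j >> b) & 1 for b in range(len(covs))] for j in range(2 ** len(covs))],
        dtype=float,
    )
    weights = np.prod(np.where(combos == 1, prevs, 1.0 - prevs), axis=1)
    shifts = combos @ delta  # (2^C, G)
    for _ in range(200):
        marginal = weights @ softmax(alpha + shifts, axis=1)
        if np.max(np.abs(marginal - target)) < 1e-12:
            break
        alpha = alpha + np.log(target / marginal)
        alpha = alpha - alpha[0]
    return alpha


def membership_probabilities(
    spec: CohortSpec, covariates: pd.DataFrame
) -> np.ndarray:
    """N x G membership probabilities under the multinomial-logit model.

    Intercepts are calibrated so the marginal mixing proportions match the
    spec (group 0 is the reference); each binary covariate then adds its
    per-group log-odds shift when present.
    """
    alpha = calibrated_intercepts(spec)
    logits = np.tile(alpha, (len(covariates), 1))
    label_index = {lab: i for i, lab in enumerate(spec.labels)}
    for cov, shifts in spec.covariate_effects.items():
        x = covariates[cov].to_numpy(dtype=float)
        for lab, delta in shifts.items():
            logits[:, label_index[lab]] += delta * x
    return softmax(logits, axis=1)


def emit_fills(
    per_period_adherent: Sequence[int],
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_id: str = "P0001",
    drug: str = "anastrozole",
    jitter: bool = True,
    carry_in_prob: float = 0.5,
    partial_fill_prob: float = 0.25,
    stale_fill_prob: float = 0.3,
) -> list[DispensingRecord]:
    """Materialise a refill stream consistent with a binary adherence vector.

    Guarantees (with L = period length, threshold 0.8):

    * adherent periods get a standard L-day fill jittered by at most L//5
      days from the period start, so even with banked-supply chaining the
      period's coverage never drops below 0.8 L;
    * non-adherent periods get either no fill or a short partial fill
      (supply <= L//3, start <= L//6) whose coverage — including overhang
      from a previous adherent month — stays strictly below 0.8 L;
    * period 1 may instead be served by a carry-in fill dated up to L//5
      days before the window (the pre-window supply-on-hand convention), and
      an exhausted "stale" fill from deep in the carry-in window may appear,
      exercising window clipping without affecting any period's label.
    """
    v = np.asarray(per_period_adherent, dtype=int)
    if v.ndim != 1 or len(v) != spec.n_periods:
        raise ValueError(
            f"need a binary vector of length n_periods={spec.n_periods}"
        )
    L = spec.period_length_days
    max_jitter = L // 5 if jitter else 0  # 6 days for L=30; keeps coverage >= 0.8 L
    records: list[DispensingRecord] = []

    def add(day_offset: int, supply: int) -> None:
        records.append(
            DispensingRecord(
                patient_id,
                ANCHOR_DATE + timedelta(days=int(day_offset)),
                int(supply),
                drug,
            )
        )

    # occasional exhausted fill from deep in the lookback window
    if spec.carry_in_window_days >= 2 * L and rng.random() < stale_fill_prob:
        stale = rng.integers(2 * L, spec.carry_in_window_days + 1)
        add(-stale, L)

    for k, adherent in enumerate(v):
        start = k * L
        if adherent:
            if (
                k == 0
                and spec.carry_in_window_days > 0
                and max_jitter > 0
                and rng.random() < carry_in_prob
            ):
                # carry-in: supply on hand from just before the window
                c = int(rng.integers(1, min(max_jitter, spec.carry_in_window_days) + 1))
                add(-c, L)
            else:
                add(start + int(rng.integers(0, max_jitter + 1)), L)
        elif rng.random() < partial_fill_prob:
            # sporadic partial fill: realistic noise that cannot flip the label
            add(start + int(rng.integers(0, L // 6 + 1)),
                max(1, int(rng.integers(L // 6, L // 3 + 1))))
    return records


def sample_cohort(spec: CohortSpec, include_fills: bool = True) -> SyntheticCohort:
    """Draw a full synthetic cohort; byte-deterministic under ``spec.seed``.

    ``include_fills=False`` skips refill-stream materialisation (membership,
    covariates and monthly indicators only), for studies that do not need
    dispensing records.
    """
    rng = np.random.default_rng(spec.seed)
    N, T, G = spec.n_patients, spec.n_periods, spec.n_groups
    patient_ids = [f"P{i + 1:04d}" for i in range(N)]

    cov_data = {"patient_id": patient_ids}
    for cov, prev in spec.baseline_covariate_prevalences.items():
        cov_data[cov] = (rng.random(N) < prev).astype(int)
    covariates = pd.DataFrame(cov_data)

    probs = membership_probabilities(spec, covariates)
    u = rng.random(N)
    true_group = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)

    t = np.arange(1, T + 1)
    group_curves = np.vstack(
        [trajectory_probability(g.beta, t) for g in spec.group_specs]
    )
    monthly_truth = group_curves[true_group]
    monthly_binary = (rng.random((N, T)) < monthly_truth).astype(int)

    records: list[DispensingRecord] = []
    if include_fills:
        for i, pid in enumerate(patient_ids):
            records.extend(emit_fills(monthly_binary[i], spec, rng, patient_id=pid))

    return SyntheticCohort(
        spec=spec,
        records=records,
        true_group=true_group,
        covariates=covariates,
        monthly_truth=monthly_truth,
        monthly_binary=monthly_binary,
        patient_ids=patient_ids,
    )


__all__ = [
    "ANCHOR_DATE",
    "DEFAULT_GROUPS",
    "DEFAULT_COVARIATE_EFFECTS",
    "DEFAULT_PREVALENCES",
    "GroupSpec",
    "CohortSpec",
    "SyntheticCohort",
    "trajectory_probability",
    "membership_probabilities",
    "emit_fills",
    "sample_cohort",
]
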