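"""Candidate-grid fitting, BIC selection, and Nagin adequacy diagnostics.

Selection follows the standard workflow for group-based trajectory models:
fit 2-5 groups (orders 2 and 3), rank by BIC, discard any candidate whose
smallest hard-assigned group falls below 5% of the cohort, then take the best
BIC among the survivors.  "Clinical relevance" remains a human judgment: the
selection trace reports every candidate so an analyst can override.

Adequacy of the chosen model is assessed by Nagin's criteria:

* AvePP_g — mean posterior probability of group g among subjects assigned to
  g; >= 0.7 indicates confident assignment.
* OCC_g = [AvePP_g / (1 - AvePP_g)] / [pi_g / (1 - pi_g)] — odds of correct
  classification against chance; >= 5 indicates good discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from . import gbtm

AVEPP_MIN = 0.7
OCC_MIN = 5.0
DEFAULT_MIN_PROP = 0.05


class BicPair(NamedTuple):
    """The Schwarz criterion in both reporting conventions."""

    neg2: float   # -2 logL + k log N: smaller is better
    nagin: float  # logL - (k/2) log N: larger is better


def bic(loglik: float, k: int, n: int) -> BicPair:
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    pen = k * np.log(n)
    return BicPair(neg2=-2.0 * loglik + pen, nagin=loglik - 0.5 * pen)


class SelectionError(ValueError):
    """Every candidate in the grid was disqualified."""


@dataclass
class Candidate:
    n_groups: int
    order: int
    model: gbtm.TrajectoryModel | None
    assigned_props: np.ndarray | None
    error: str | None = None


@dataclass
class CandidateGrid:
    candidates: list[Candidate]
    n_subjects: int

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def fit_grid(
    panel: np.ndarray,
    groups: Iterable[int] = range(2, 6),
    orders: Iterable[int] = (2, 3),
    n_starts: int = gbtm.DEFAULT_N_STARTS,
    seed: int | None = None,
    **fit_kwargs,
) -> CandidateGrid:
    """Fit every (n_groups, order) cell; per-cell failures are recorded in the
    grid, never abort it. Deterministic under a fixed seed (each cell gets a
    distinct seed derived from it)."""
    panel = np.asarray(panel, dtype=float)
    ss = np.random.SeedSequence(seed)
    cells = [(g, o) for g in groups for o in orders]
    cell_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cells))]
    candidates = []
    for (g, o), cs in zip(cells, cell_seeds):
        try:
            model = gbtm.fit(
                panel, n_groups=g, order=o, n_starts=n_starts, seed=cs,
                **fit_kwargs,
            )
            post = gbtm.posterior(model, panel)
            assign = gbtm.hard_assign(post)
            props = np.bincount(assign, minlength=g) / panel.shape[0]
            candidates.append(Candidate(g, o, model, props))
        except Exception as exc:  # noqa: BLE001 - per-cell isolation is the contract
            candidates.append(Candidate(g, o, None, None, error=str(exc)))
    return CandidateGrid(candidates=candidates, n_subjects=panel.shape[0])


def selection_trace(grid: CandidateGrid, min_prop: float = DEFAULT_MIN_PROP) -> pd.DataFrame:
    rows = []
    for c in grid:
        if c.model is None:
            rows.append(
                {
                    "n_groups": c.n_groups, "order": c.order, "loglik": np.nan,
                    "k": np.nan, "bic_neg2": np.nan, "bic_nagin": np.nan,
                    "min_assigned_prop": np.nan, "converged": False,
                    "qualified": False, "reason": f"fit error: {c.error}",
                }
            )
            continue
        m = c.model
        min_assigned = float(c.assigned_props.min())
        qualified = min_assigned >= min_prop
        reason = "" if qualified else (
            f"smallest assigned group {min_assigned:.1%} < {min_prop:.0%}"
        )
        rows.append(
            {
                "n_groups": c.n_groups, "order": c.order, "loglik": m.loglik,
                "k": m.n_params, "bic_neg2": m.bic, "bic_nagin": m.bic_nagin,
                "min_assigned_prop": min_assigned, "converged": m.converged,
                "qualified": qualified, "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def select_model(
    grid: CandidateGrid, min_prop: float = DEFAULT_MIN_PROP
) -> tuple[gbtm.TrajectoryModel, pd.DataFrame]:
    """Best-BIC model among candidates meeting the minimum-membership rule.

    Returns the winner plus the full selection trace (with a ``selected``
    column). Raises :class:`SelectionError` when no candidate qualifies.
    """
    trace = selection_trace(grid, min_prop)
    qualifying = trace.index[trace["qualified"]]
    if len(qualifying) == 0:
        reasons = "; ".join(
            f"G={r.n_groups}/order {r.order}: {r.reason}" for r in trace.itertuples()
        )
        raise SelectionError(f"all candidates disqualified — {reasons}")
    best_idx = trace.loc[qualifying, "bic_neg2"].idxmin()
    trace["selected"] = trace.index == best_idx
    return grid.candidates[best_idx].model, trace


# ---------------------------------------------------------------------------
# Nagin adequacy diagnostics
# ---------------------------------------------------------------------------

def avepp(
    posteriors: np.ndarray, assignments: np.ndarray | None = None
) -> np.ndarray:
    """Per-group average posterior probability among hard-assigned members.

    Empty groups yield NaN (flagged downstream, never an exception).
    """
    P = np.asarray(posteriors, dtype=float)
    if assignments is None:
        assignments = gbtm.hard_assign(P)
    assignments = np.asarray(assignments)
    G = P.shape[1]
    out = np.full(G, np.nan)
    for g in range(G):
        mask = assignments == g
        if mask.any():
            out[g] = P[mask, g].mean()
    return out


def occ(avepp_g, pi_g):
    """Odds of correct classification: assignment odds over chance odds."""
    a = np.asarray(avepp_g, dtype=float)
    p = np.asarray(pi_g, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("pi must lie strictly in (0, 1)")
    with np.errstate(divide="ignore"):
        result = np.where(
            a >= 1.0, np.inf, (a / (1.0 - a)) / (p / (1.0 - p))
        )
    return result if result.ndim else float(result)


def adequacy_report(
    model: gbtm.TrajectoryModel,
    posteriors: np.ndarray,
    min_prop: float = DEFAULT_MIN_PROP,
) -> pd.DataFrame:
    """Per-group adequacy table: pi_hat, assigned share, AvePP, OCC, flags.

    Also reports the pi_hat-vs-assigned-share gap as informational output
    (close agreement is a further sign of adequate fit).
    """
    assignments = gbtm.hard_assign(posteriors)
    G = model.n_groups
    assigned = np.bincount(assignments, minlength=G) / len(assignments)
    av = avepp(posteriors, assignments)
    occ_vals = np.full(G, np.nan)
    ok = ~np.isnan(av)
    occ_vals[ok] = occ(av[ok], model.pi[ok])
    return pd.DataFrame(
        {
            "group": np.arange(G),
            "pi_hat": model.pi,
            "assigned_prop": assigned,
            "pi_vs_assigned_gap": np.abs(model.pi - assigned),
            "avepp": av,
            "occ": occ_vals,
            "avepp_ok": av >= AVEPP_MIN,
            "occ_ok": occ_vals >= OCC_MIN,
            "min_membership_ok": assigned >= min_prop,
        }
    )


__all__ = [
    "BicPair",
    "bic",
    "Candidate",
    "CandidateGrid",
    "SelectionError",
    "fit_grid",
    "selection_trace",
    "select_model",
    "avepp",
    "occ",
    "adequacy_report",
    "AVEPP_MIN",
    "OCC_MIN",
    "DEFAULT_MIN_PROP",
]
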