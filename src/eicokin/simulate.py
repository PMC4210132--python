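"""Time integration, steady states, and DDC-vs-control fold changes.

The eight-week treatment window of the underlying experiments is treated as
a quasi steady state, so the biologically interpreted output of the model is
the converged concentration vector per strain x treatment condition and the
per-metabolite DDC/control ratio.

Steady states are found by integrating the stiff ODE system to
quasi-equilibrium (LSODA) and polishing with a Newton step on the
right-hand side; a result is accepted once max |d[x]/dt| falls below the
tolerance (default 1e-6 nM/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (
    KineticModel,
    StrainCondition,
    make_rhs_function,
)

__all__ = [
    "SteadyStateResult",
    "FoldChangeTable",
    "IntegrationError",
    "NotConvergedError",
    "integrate",
    "steady_state",
    "simulate_condition",
    "fold_changes",
    "DEFAULT_TOL",
]

DEFAULT_TOL = 1e-6  # nM/s, steady-state acceptance on max |d/dt|


class IntegrationError(RuntimeError):
    """The stiff solver failed; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class NotConvergedError(RuntimeError):
    """An operation required a converged steady state but got none."""


@dataclass(frozen=True)
class SteadyStateResult:
    concentrations: Mapping[str, float]  # nM, non-fixed metabolites
    residual_norm: float                 # max |d[x]/dt| in nM/s
    converged: bool
    t_reached: float                     # simulated seconds

    def vector(self, state_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.concentrations[m] for m in state_ids])


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-metabolite DDC/control ratio with up/down/unchanged call."""

    ratios: Mapping[str, float]
    classification: Mapping[str, str]
    threshold: float = 1.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": list(self.ratios),
                "ratio": [self.ratios[m] for m in self.ratios],
                "classification": [self.classification[m] for m in self.ratios],
            }
        )


def integrate(
    model: KineticModel,
    initial_state: Sequence[float] | None = None,
    t_end: float = 1e6,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    activities: Mapping[str, float] | None = None,
    pc_nM: float | None = None,
    t_eval: Sequence[float] | None = None,
):
    """Integrate the ODE system; returns (times, states) with states of shape
    (len(times), n_states) in :data:`~eicokin.model.STATE_IDS` order."""
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if not (rel_tol > 0 and abs_tol > 0):
        raise ValueError("tolerances must be > 0")
    y0 = np.zeros(len(model.state_ids)) if initial_state is None else np.asarray(
        initial_state, dtype=float
    )
    if y0.shape != (len(model.state_ids),):
        raise ValueError("initial state has wrong length")
    f = make_rhs_function(model, activities=activities, pc_nM=pc_nM)
    sol = solve_ivp(
        f, (0.0, t_end), y0, method="LSODA", rtol=rel_tol, atol=abs_tol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"stiff solver failed: {sol.message}", t_fail=float(sol.t[-1]))
    return sol.t, sol.y.T


def steady_state(
    model: KineticModel,
    tol: float = DEFAULT_TOL,
    initial_state: Sequence[float] | None = None,
    activities: Mapping[str, float] | None = None,
    pc_nM: float | None = None,
    t_max: float = 3e7,
    _newton_start: Sequence[float] | None = None,
    fast: bool = False,
) -> SteadyStateResult:
    """Solve for the steady state of the (possibly condition-scaled) model.

    Integration proceeds in growing time horizons; after each leg a Newton
    polish is attempted from the integrated endpoint.  If `_newton_start`
    is given, a direct Newton solve is tried first (used for warm starts
    during calibration).  `fast=True` caps the integration budget (one
    short, loose-tolerance leg) for use inside optimization loops, where a
    non-convergent candidate is simply penalized.  A non-convergent budget
    returns a result with ``converged=False`` rather than raising.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    f = make_rhs_function(model, activities=activities, pc_nM=pc_nM)
    n = len(model.state_ids)

    def finish(y: np.ndarray, t_reached: float) -> SteadyStateResult | None:
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)) or np.any(y < -1e-9 * (1.0 + np.abs(y).max())):
            return None
        y = np.maximum(y, 0.0)
        res = float(np.max(np.abs(f(0.0, y))))
        if res <= tol:
            return SteadyStateResult(
                dict(zip(model.state_ids, y.tolist())), res, True, t_reached
            )
        return None

    def polish(y: np.ndarray, t_reached: float) -> SteadyStateResult | None:
        try:
            sol = root(lambda v: f(0.0, v), y, method="hybr", tol=1e-14)
        except Exception:
            return None
        if sol.success:
            out = finish(sol.x, t_reached)
            if out is not None:
                return out
        return finish(y, t_reached)

    if _newton_start is not None:
        out = polish(np.asarray(_newton_start, dtype=float), 0.0)
        if out is not None:
            return out

    y = np.zeros(n) if initial_state is None else np.asarray(initial_state, dtype=float)
    t_done = 0.0
    horizon = 1e5
    rtol = 1e-6 if fast else 1e-9
    if fast:
        t_max = min(t_max, 2e5)
    while t_done < t_max:
        leg = min(horizon, t_max - t_done)
        try:
            # endpoint-only evaluation keeps memory flat on stiff legs
            sol = solve_ivp(f, (0.0, leg), y, method="LSODA",
                            rtol=rtol, atol=1e-12, t_eval=[leg])
        except Exception:
            break
        if not sol.success:
            break
        y = np.maximum(sol.y[:, -1], 0.0)
        t_done += leg
        out = polish(y, t_done)
        if out is not None:
            return out
        horizon *= 10.0
    res = float(np.max(np.abs(f(0.0, np.maximum(y, 0.0)))))
    return SteadyStateResult(
        dict(zip(model.state_ids, np.maximum(y, 0.0).tolist())), res, False, t_done
    )


def simulate_condition(
    model: KineticModel,
    condition: StrainCondition,
    tol: float = DEFAULT_TOL,
    initial_state: Sequence[float] | None = None,
) -> SteadyStateResult:
    """Steady state under one strain x treatment condition.

    The condition's activity ratios and PC clamp are applied to a copy;
    `model` itself is not modified.
    """
    return steady_state(
        model,
        tol=tol,
        initial_state=initial_state,
        activities=condition.activity_ratios,
        pc_nM=condition.pc_nM,
    )


def classify_ratio(ratio: float, threshold: float = 1.5) -> str:
    if not threshold > 1:
        raise ValueError("threshold must be > 1")
    if ratio >= threshold:
        return "up"
    if ratio <= 1.0 / threshold:
        return "down"
    return "unchanged"


def fold_changes(
    control: SteadyStateResult,
    ddc: SteadyStateResult,
    threshold: float = 1.5,
) -> FoldChangeTable:
    """DDC/control concentration ratios with symmetric-band classification.

    A species is "up" when ratio >= threshold, "down" when
    ratio <= 1/threshold, otherwise "unchanged".  Species with zero control
    concentration get NaN ratio and classification "undefined".
    """
    if not (control.converged and ddc.converged):
        raise NotConvergedError(
            "fold changes require converged steady states "
            f"(control: {control.converged}, ddc: {ddc.converged})"
        )
    ratios: dict[str, float] = {}
    cls: dict[str, str] = {}
    for m, c in control.concentrations.items():
        d = ddc.concentrations[m]
        if c <= 0.0:
            ratios[m] = float("nan")
            cls[m] = "undefined"
        else:
            r = d / c
            ratios[m] = r
            cls[m] = classify_ratio(r, threshold)
    return FoldChangeTable(ratios, cls, threshold)
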