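"""Integration of the clock ODEs and the mutant-perturbation protocols.

All simulations are free-running constant-light (LL) runs.  Because a
free-running limit cycle has no external dawn, recorded windows are
anchored at a peak of the unphosphorylated-KaiC fraction after burn-in
("dawn" = U-rich state), and peak phases are measured from the window
start.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import argrelextrema

from . import model
from .params import FeedbackSpec, PTOParameters, TTFLParameters


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class PerturbationProtocol:
    """A mutant protocol applied from a trigger time onward.

    kind:
        ``none`` | ``knockout_kaiA`` | ``overexpress_kaiA`` |
        ``overexpress_kaiC``.
    fold:
        Multiplicative factor applied to the kaiA transcription rate
        (kaiA protocols) or the KaiC translation rate (KaiC protocol).
        Knockout means fold 0 on kaiA transcription.
    trigger:
        ``"at_mBC_minimum"`` (switch at the kaiBC-transcription minimum,
        as such experiments are staged) or an explicit time in hours.
    """

    kind: str = "none"
    fold: float = 1.0
    trigger: float | str = "at_mBC_minimum"

    def __post_init__(self):
        if self.kind not in ("none", "knockout_kaiA", "overexpress_kaiA",
                             "overexpress_kaiC"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.fold < 0:
            raise ValueError("fold must be non-negative")
        if self.kind == "knockout_kaiA" and self.fold != 0:
            raise ValueError("knockout_kaiA requires fold = 0")
        if self.kind == "none" and self.fold != 1:
            raise ValueError("kind 'none' requires fold = 1")

    def overrides(self) -> model.PerturbationOverrides:
        if self.kind in ("knockout_kaiA", "overexpress_kaiA"):
            return model.PerturbationOverrides(scale_k_1a=self.fold)
        if self.kind == "overexpress_kaiC":
            return model.PerturbationOverrides(scale_k_2bc=self.fold)
        return model.IDENTITY_OVERRIDES


NO_PROTOCOL = PerturbationProtocol()


@dataclass
class TimeSeries:
    """A time grid plus named, aligned channels."""

    t: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = ch

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def window(self, t0: float, t1: float) -> "TimeSeries":
        """Sub-series on [t0, t1], time re-zeroed at t0."""
        mask = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        return TimeSeries(self.t[mask] - t0,
                          {k: v[mask] for k, v in self.channels.items()})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.t})
        for name, ch in self.channels.items():
            df[name] = ch
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeSeries":
        if "time_h" not in df.columns:
            raise ValueError("missing 'time_h' column")
        return cls(df["time_h"].to_numpy(),
                   {c: df[c].to_numpy() for c in df.columns if c != "time_h"})


def _derived_channels(states: np.ndarray) -> dict[str, np.ndarray]:
    """Observable channels from an (n, 15) state trajectory."""
    kaic = np.clip(states[:, 0:12], 0.0, None)
    total = kaic.sum(axis=1)
    u = kaic[:, [0, 4, 8]].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_frac = np.where(total > 0, u / total, np.nan)
    mbc = np.clip(states[:, model.I_MBC], 0.0, None)
    mean = mbc.mean()
    return {
        "mBC_rel": mbc / mean if mean > 0 else mbc,
        "UKaiC_frac": u_frac,
        "PKaiC_frac": 1.0 - u_frac,
    }


def _series_from_solution(t: np.ndarray, states: np.ndarray) -> TimeSeries:
    channels = {name: states[:, i] for i, name in enumerate(model.STATE_NAMES)}
    channels.update(_derived_channels(states))
    return TimeSeries(t, channels)


def _solve(rhs, y0, t0, t1, t_eval, rtol, atol):
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else t0
        raise IntegrationError(f"integration failed at t={last:.3f} h: "
                               f"{sol.message}", last_time=last)
    return sol


def integrate(p: PTOParameters, q: TTFLParameters, spec: FeedbackSpec,
              state0: np.ndarray, t_end: float,
              protocol: PerturbationProtocol | None = None,
              rtol: float = 1e-8, atol: float = 1e-10,
              dt: float = 0.1) -> TimeSeries:
    """Integrate the 15-ODE system on [0, t_end] with dense output.

    A protocol with an explicit trigger time is applied from that time
    onward with a continuous restart at the trigger (state carried over,
    rates rescaled).  ``at_mBC_minimum`` triggers are resolved by
    :func:`run_experiment`, which knows the reference cycle.
    """
    state0 = np.asarray(state0, dtype=float)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if np.any(state0 < 0):
        raise ValueError("initial state must be non-negative")

    t_grid = np.arange(0.0, t_end + dt / 2, dt)
    t_grid = t_grid[t_grid < t_end - 1e-12]
    t_grid = np.append(t_grid, t_end)
    if protocol is None or protocol.kind == "none" \
            or (protocol.kind != "none" and protocol.fold == 1.0
                and protocol.kind != "knockout_kaiA"):
        eff_protocol = None
    else:
        eff_protocol = protocol

    if eff_protocol is None:
        rhs = model.make_rhs(p, q, spec)
        sol = _solve(rhs, state0, 0.0, t_end, t_grid, rtol, atol)
        return _series_from_solution(sol.t, sol.y.T)

    if not isinstance(eff_protocol.trigger, (int, float)):
        raise ValueError(
            "integrate() needs an explicit trigger time; use run_experiment "
            "for 'at_mBC_minimum' protocols")
    t_star = float(eff_protocol.trigger)
    t_star = min(max(t_star, 0.0), t_end)
    pre = t_grid[t_grid <= t_star + 1e-12]
    post = t_grid[t_grid > t_star + 1e-12]

    rhs0 = model.make_rhs(p, q, spec)
    rhs1 = model.make_rhs(p, q, spec, eff_protocol.overrides())

    if t_star > 0:
        eval_pre = pre if len(pre) and abs(pre[-1] - t_star) < 1e-9 \
            else np.append(pre, t_star)
        sol0 = _solve(rhs0, state0, 0.0, t_star, eval_pre, rtol, atol)
        y_star = sol0.y[:, -1]
        n_keep = len(pre)
        t_acc, y_acc = list(sol0.t[:n_keep]), list(sol0.y.T[:n_keep])
    else:
        y_star = state0.copy()
        t_acc, y_acc = [], []
        post = t_grid
    if len(post):
        sol1 = _solve(rhs1, y_star, t_star, t_end, post, rtol, atol)
        t_acc.extend(sol1.t)
        y_acc.extend(sol1.y.T)
    t_out = np.asarray(t_acc)
    keep = np.concatenate([[True], np.diff(t_out) > 0])
    return _series_from_solution(t_out[keep], np.asarray(y_acc)[keep])


def find_mbc_minimum(series: TimeSeries, before: float | None = None) -> tuple[float, bool]:
    """Time of the last local minimum of the kaiBC mRNA channel.

    Returns ``(time, rhythmic)``.  If no interior local minimum exists
    (monotone or flat channel) the global minimum is returned with
    ``rhythmic=False``.
    """
    mbc = series["mBC"] if "mBC" in series.channels else series["mBC_rel"]
    t = series.t
    if before is not None:
        mask = t <= before
        t, mbc = t[mask], mbc[mask]
    idx = argrelextrema(mbc, np.less_equal, order=3)[0]
    idx = idx[(idx > 0) & (idx < len(t) - 1)]
    # discard plateau artefacts: require a genuine dip
    span = mbc.max() - mbc.min()
    idx = [i for i in idx if span > 0
           and mbc[i] < mbc.min() + 0.9 * span]
    if not idx:
        return float(t[int(np.argmin(mbc))]), False
    return float(t[idx[-1]]), True


@dataclass
class ExperimentResult:
    """Wild-type reference window and perturbed window of one protocol run."""

    wild_type: TimeSeries
    perturbed: TimeSeries
    trigger_time: float
    protocol: PerturbationProtocol


DAWN_OFFSET = 1.0


def settle(p: PTOParameters, q: TTFLParameters, spec: FeedbackSpec,
           burn_in: float = 240.0, rtol: float = 1e-8, atol: float = 1e-10,
           state0: np.ndarray | None = None,
           dawn_offset: float = DAWN_OFFSET) -> np.ndarray:
    """Burn in from a generic state and return the state at a dawn anchor.

    A free-running LL oscillation has no external dawn, so one is fixed by
    convention: the unphosphorylated-KaiC fraction peaks ``dawn_offset``
    hours after dawn (U-rich state = early subjective day).  The returned
    state is the trajectory point ``dawn_offset`` hours before the first
    UKaiC-fraction peak past the burn-in.  For arrhythmic parameter sets
    (no UKaiC peak after burn-in) the final probed state is returned.
    """
    y0 = model.default_initial_state() if state0 is None else np.asarray(state0, float)
    probe = integrate(p, q, spec, y0, burn_in + 60.0, rtol=rtol, atol=atol)
    u = probe["UKaiC_frac"]
    t = probe.t
    after = t >= burn_in + dawn_offset
    idx = argrelextrema(u, np.greater, order=5)[0]
    idx = [i for i in idx if after[i]]
    if not idx:
        i_anchor = len(t) - 1
    else:
        i_anchor = idx[0] - int(round(dawn_offset / (t[1] - t[0])))
    states = np.column_stack([probe[name] for name in model.STATE_NAMES])
    return np.clip(states[i_anchor], 0.0, None)


def run_experiment(p: PTOParameters, q: TTFLParameters, spec: FeedbackSpec,
                   protocol: PerturbationProtocol = NO_PROTOCOL,
                   burn_in: float = 240.0, record: float = 120.0,
                   rtol: float = 1e-8, atol: float = 1e-10,
                   dt: float = 0.1) -> ExperimentResult:
    """Settle the model, record a wild-type window, then apply the protocol.

    Both runs start from the same settled dawn-anchored state.  The
    perturbed run covers the pre-trigger segment plus ``record`` hours
    after the trigger.  ``at_mBC_minimum`` triggers resolve to the first
    local minimum of kaiBC mRNA after dawn in the wild-type window.
    """
    y_dawn = settle(p, q, spec, burn_in=burn_in, rtol=rtol, atol=atol)
    wt = integrate(p, q, spec, y_dawn, record, rtol=rtol, atol=atol, dt=dt)

    if protocol.kind == "none":
        return ExperimentResult(wt, wt, 0.0, protocol)

    if isinstance(protocol.trigger, str):
        if protocol.trigger != "at_mBC_minimum":
            raise ValueError(f"unknown trigger {protocol.trigger!r}")
        mins = argrelextrema(wt["mBC"], np.less, order=3)[0]
        mins = mins[(mins > 0)]
        t_star = float(wt.t[mins[0]]) if len(mins) else float(wt.t[np.argmin(wt["mBC"])])
        resolved = replace(protocol, trigger=t_star)
    else:
        t_star = float(protocol.trigger)
        resolved = protocol

    perturbed = integrate(p, q, spec, y_dawn, t_star + record,
                          protocol=resolved, rtol=rtol, atol=atol, dt=dt)
    return ExperimentResult(wt, perturbed, t_star, resolved)
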