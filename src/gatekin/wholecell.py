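"""Whole-cell voltage-step processing: I-V curves, %I_max, EGTA-sensitive current.

A step protocol applies a family of command voltages (typically -100 to
+40 mV from a +20 mV holding potential) and records one current trace per
step.  Steady-state current is read out as the mean over a window late in
the step, assembled into an I-V curve, and optionally normalized to the
current at a reference voltage (%I_max at -100 mV by convention).  The
difference between recordings in divalent-free (DVF, with EGTA) and
nominally divalent-free (nDVF) solutions defines the EGTA-sensitive current.

Sign convention: inward current is negative.  %I_max uses the signed ratio,
so an inward-rectifying curve is +100 at the -100 mV reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .markov_gating import CurrentTrace, TraceMeta

__all__ = [
    "StepProtocolRecording",
    "IVCurve",
    "measure_step_current",
    "build_iv",
    "normalize_percent_imax",
    "egta_sensitive",
    "current_density",
    "synthetic_step_recording",
]

# steady-state read-out window: final quarter of each step by default
DEFAULT_WINDOW_FRACTION = 0.25


@dataclass(frozen=True)
class StepProtocolRecording:
    """One voltage-step family: (command voltage mV, trace) pairs."""

    steps: tuple[tuple[float, CurrentTrace], ...]
    holding_mV: float = 20.0
    solution: str = "DVF"  # "DVF" (with EGTA) or "nDVF"

    def __post_init__(self) -> None:
        volts = [v for v, _ in self.steps]
        if len(set(volts)) != len(volts):
            raise ValueError("step voltages must be unique")
        dts = {t.dt for _, t in self.steps}
        if len(dts) > 1:
            raise ValueError("all step traces must share one sampling interval")


@dataclass(frozen=True)
class IVCurve:
    """Current-voltage relation, ordered by voltage."""

    voltages: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # pA, or %I_max if normalized
    normalized: bool = False
    reference_mV: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)
        if v.shape != i.shape:
            raise ValueError("voltages and currents must have equal length")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.normalized and self.reference_mV is not None:
            at_ref = i[np.isclose(v, self.reference_mV)]
            if len(at_ref) and abs(at_ref[0] - 100.0) > 1e-6:
                raise ValueError("normalized curve must be 100 at the reference voltage")

    def current_at(self, V: float) -> float:
        hit = np.isclose(self.voltages, V)
        if not hit.any():
            raise KeyError(f"voltage {V} mV not in curve")
        return float(self.currents[hit][0])


def measure_step_current(trace: CurrentTrace, window: tuple[float, float]) -> float:
    """Mean current (pA) over a time window of one step trace."""
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= trace.duration + trace.dt / 2):
        raise ValueError(f"window {window} outside trace of {trace.duration:.4g} s")
    i0 = int(np.floor(t0 / trace.dt))
    i1 = int(np.ceil(t1 / trace.dt))
    seg = trace.samples[i0:i1]
    if len(seg) == 0:
        raise ValueError("window contains no samples")
    return float(seg.mean())


def build_iv(
    recording: StepProtocolRecording,
    window: tuple[float, float] | None = None,
) -> IVCurve:
    """Assemble an I-V curve from a step-protocol recording.

    ``window`` defaults to the final 25% of each step (steady state).
    """
    if len(recording.steps) < 2:
        raise ValueError("need at least 2 voltage steps")
    points = []
    for V, trace in recording.steps:
        w = window
        if w is None:
            w = (trace.duration * (1.0 - DEFAULT_WINDOW_FRACTION), trace.duration)
        points.append((V, measure_step_current(trace, w)))
    points.sort(key=lambda p: p[0])
    v, i = zip(*points)
    return IVCurve(np.array(v), np.array(i))


def normalize_percent_imax(iv: IVCurve, V_ref: float = -100.0) -> IVCurve:
    """Express each current as a percentage of the current at ``V_ref``.

    The signed ratio is used, so an inward (negative) reference current maps
    the curve to +100 at V_ref.  Idempotent on an already-normalized curve.
    """
    I_ref = iv.current_at(V_ref)
    if I_ref == 0:
        raise ValueError(f"reference current at {V_ref} mV is zero")
    return IVCurve(
        voltages=iv.voltages.copy(),
        currents=100.0 * iv.currents / I_ref,
        normalized=True,
        reference_mV=V_ref,
    )


def egta_sensitive(iv_DVF: IVCurve, iv_nDVF: IVCurve) -> IVCurve:
    """Pointwise EGTA-sensitive current: I_DVF - I_nDVF on a matching grid."""
    if len(iv_DVF.voltages) != len(iv_nDVF.voltages) or not np.allclose(
        iv_DVF.voltages, iv_nDVF.voltages
    ):
        raise ValueError("voltage grids do not match")
    return IVCurve(
        voltages=iv_DVF.voltages.copy(),
        currents=iv_DVF.currents - iv_nDVF.currents,
    )


def current_density(I: float, capacitance: float) -> float:
    """Current density in pA/pF given membrane capacitance in pF."""
    if capacitance <= 0:
        raise ValueError("capacitance must be > 0")
    return I / capacitance


def synthetic_step_recording(
    voltages: Sequence[float] = tuple(range(-100, 41, 20)),
    g_max_nS: float = 8.0,
    E_rev_mV: float = 10.0,
    rectification_mV: float = 40.0,
    noise_sd_pA: float = 5.0,
    step_duration: float = 0.4,
    dt: float = 2e-4,
    solution: str = "DVF",
    seed: int = 0,
) -> StepProtocolRecording:
    """Synthetic inward-rectifying step family for testing and demos.

    Currents follow I(V) = g * (V - E_rev) * r(V) with a Boltzmann
    rectification factor r(V) = 1 / (1 + exp(V / rectification_mV)) that
    suppresses outward current, mimicking a monovalent current through an
    inwardly rectifying channel.  A 3.6 kHz-filtered recording at 200 us
    sampling is emulated with white noise of sd ``noise_sd_pA``.
    """
    rng = np.random.default_rng(seed)
    steps = []
    n = int(round(step_duration / dt))
    for V in voltages:
        r = 1.0 / (1.0 + np.exp(V / rectification_mV))
        I_ss = g_max_nS * (V - E_rev_mV) * r  # nS * mV = pA
        samples = I_ss + rng.normal(0.0, noise_sd_pA, size=n)
        steps.append(
            (
                float(V),
                CurrentTrace(
                    dt=dt,
                    samples=samples,
                    meta=TraceMeta(holding_mV=20.0, filter_Hz=3600.0, n_channels=1, seed=seed),
                ),
            )
        )
    return StepProtocolRecording(steps=tuple(steps), holding_mV=20.0, solution=solution)
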