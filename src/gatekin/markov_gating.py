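"""Continuous-time Markov gating models and synthetic single-channel data.

The central object is a :class:`RateModel`: a labelled continuous-time Markov
chain whose states are tagged ``open`` or ``closed`` and which carries the
single-channel current amplitude.  The canonical topology is the linear
three-state scheme

    O <-> C2 <-> C1

with an open state ``O``, a pre-open closed state ``C2`` adjacent to it, and a
long-lived closed state ``C1``.  No direct O<->C1 transition exists.

The module provides the analytic predictions of such a model (stationary
occupancy, open probability, dwell-time mixtures) and exact stochastic
simulation (Gillespie) plus rendering of the latent state path into a noisy,
filtered current trace as acquired in cell-attached patch clamp.

Units: seconds and s^-1 internally; picoamperes for current.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RateModel",
    "StateSequence",
    "CurrentTrace",
    "DwellMixture",
    "build_three_state",
    "stationary_distribution",
    "analytic_open_probability",
    "analytic_dwell_mixture",
    "simulate_states",
    "render_trace",
    "superpose_channels",
    "WT_LIKE_RATES",
    "G579A_LIKE_RATES",
    "DEFAULT_AMPLITUDE_PA",
    "DEFAULT_DT_S",
    "DEFAULT_FILTER_HZ",
    "DEFAULT_SWEEP_S",
    "DEFAULT_NOISE_SD_PA",
]

StateClass = Literal["open", "closed"]

# Default acquisition protocol: 10 s sweeps at -80 mV, 100 us sampling,
# 5 kHz low-pass, ~5.5 pA open-channel amplitude.
DEFAULT_AMPLITUDE_PA = 5.5
DEFAULT_DT_S = 1e-4
DEFAULT_FILTER_HZ = 5000.0
DEFAULT_SWEEP_S = 10.0
DEFAULT_NOISE_SD_PA = 0.5
DEFAULT_HOLDING_MV = -80.0

# Reference rate sets (s^-1, order k_oc, k_co, k_21, k_12).  The wild-type-like
# set has analytic Po = 0.21 with a 10 ms mean open time; the low-activity set
# (rigid-hinge phenotype) has Po = 0.03.
WT_LIKE_RATES = (100.0, 70.0, 24.5, 15.0)
G579A_LIKE_RATES = (100.0, 30.0, 43.5, 5.0)

_ROWSUM_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a rate model violates its structural invariants."""


@dataclass(frozen=True)
class RateModel:
    """Labelled CTMC generator with conductance classes.

    Parameters
    ----------
    state_labels : tuple of str
        Ordered state names.
    state_class : tuple of {"open", "closed"}
        Conductance class of each state.
    generator : ndarray, shape (n, n)
        Rate matrix Q in s^-1; off-diagonal entries are transition rates,
        rows sum to zero.
    open_amplitude : float
        Current in pA added per simultaneously open channel.
    closed_level : float
        Baseline current in pA (conventionally 0).
    """

    state_labels: tuple[str, ...]
    state_class: tuple[StateClass, ...]
    generator: np.ndarray
    open_amplitude: float
    closed_level: float = 0.0

    def __post_init__(self) -> None:
        Q = np.asarray(self.generator, dtype=float)
        object.__setattr__(self, "generator", Q)
        n = len(self.state_labels)
        if Q.shape != (n, n):
            raise ModelValidationError(
                f"generator shape {Q.shape} does not match {n} states"
            )
        if len(self.state_class) != n:
            raise ModelValidationError("state_class length mismatch")
        if any(c not in ("open", "closed") for c in self.state_class):
            raise ModelValidationError("state_class entries must be 'open' or 'closed'")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ModelValidationError("off-diagonal generator entries must be >= 0")
        if np.max(np.abs(Q.sum(axis=1))) > _ROWSUM_TOL:
            raise ModelValidationError("generator rows must sum to zero")
        if "open" not in self.state_class or "closed" not in self.state_class:
            raise ModelValidationError("need at least one open and one closed state")
        if not np.isfinite(self.open_amplitude):
            raise ModelValidationError("open_amplitude must be finite")
        if not _is_irreducible(Q):
            raise ModelValidationError("rate model must be irreducible")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def open_states(self) -> np.ndarray:
        return np.array([c == "open" for c in self.state_class])

    def state_index(self, label: str) -> int:
        return self.state_labels.index(label)

    def to_json(self, path: str | Path) -> None:
        """Write the model parameters as a JSON file."""
        doc = {
            "state_labels": list(self.state_labels),
            "state_class": list(self.state_class),
            "generator": self.generator.tolist(),
            "open_amplitude": self.open_amplitude,
            "closed_level": self.closed_level,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RateModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            state_labels=tuple(doc["state_labels"]),
            state_class=tuple(doc["state_class"]),
            generator=np.asarray(doc["generator"], dtype=float),
            open_amplitude=float(doc["open_amplitude"]),
            closed_level=float(doc.get("closed_level", 0.0)),
        )


def _is_irreducible(Q: np.ndarray) -> bool:
    # single communicating class: reachability closure of the adjacency graph
    n = Q.shape[0]
    adj = (Q > 0) & ~np.eye(n, dtype=bool)
    reach = adj | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    return bool(reach.all())


@dataclass(frozen=True)
class StateSequence:
    """Latent gating path: ordered (state index, dwell duration in s)."""

    states: np.ndarray
    durations: np.ndarray
    start_time: float = 0.0
    seed: int | None = None
    last_truncated: bool = True

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        d = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "durations", d)
        if s.shape != d.shape:
            raise ValueError("states and durations must have equal length")
        if np.any(d <= 0):
            raise ValueError("all dwell durations must be > 0")
        if len(s) > 1 and np.any(s[1:] == s[:-1]):
            raise ValueError("consecutive entries must have different states")

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())


@dataclass
class TraceMeta:
    holding_mV: float = DEFAULT_HOLDING_MV
    filter_Hz: float | None = DEFAULT_FILTER_HZ
    n_channels: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("meta.n_channels must be >= 1")


@dataclass
class CurrentTrace:
    """Uniformly sampled current record with acquisition metadata."""

    dt: float
    samples: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def to_csv(self, path: str | Path) -> None:
        """Write `time_s,current_pA` CSV plus a `<name>.meta.json` sidecar."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame({"time_s": self.time, "current_pA": self.samples}).to_csv(
            path, index=False, float_format="%.6g"
        )
        sidecar = path.with_suffix("").with_suffix(".meta.json")
        sidecar.write_text(json.dumps({"dt": self.dt, **asdict(self.meta)}, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurrentTrace":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix("").with_suffix(".meta.json")
        if sidecar.exists():
            doc = json.loads(sidecar.read_text())
            dt = float(doc.pop("dt"))
            meta = TraceMeta(**doc)
        else:
            t = df["time_s"].to_numpy()
            dt = float(np.median(np.diff(t)))
            meta = TraceMeta()
        return cls(dt=dt, samples=df["current_pA"].to_numpy(), meta=meta)


@dataclass(frozen=True)
class DwellMixture:
    """Mixture of exponentials describing dwell times of one class.

    ``time_constants`` are in seconds, strictly decreasing; ``weights`` are
    non-negative and sum to one.
    """

    dwell_class: StateClass
    time_constants: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.time_constants, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "time_constants", tau)
        object.__setattr__(self, "weights", w)
        if np.any(tau <= 0):
            raise ValueError("time constants must be > 0")
        if len(tau) > 1 and np.any(np.diff(tau) >= 0):
            raise ValueError("time constants must be strictly decreasing")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")

    def pdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for tau, w in zip(self.time_constants, self.weights):
            out += w / tau * np.exp(-t / tau)
        return out

    def cdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for tau, w in zip(self.time_constants, self.weights):
            out += w * (1.0 - np.exp(-t / tau))
        return out

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.time_constants))


def build_three_state(
    k_oc: float,
    k_co: float,
    k_21: float,
    k_12: float,
    open_amplitude: float = DEFAULT_AMPLITUDE_PA,
) -> RateModel:
    """Build the linear three-state gating scheme O <-> C2 <-> C1.

    Parameters are transition rates in s^-1: ``k_oc`` O->C2 (the closing
    rate constant), ``k_co`` C2->O, ``k_21`` C2->C1, ``k_12`` C1->C2.
    There is no direct O<->C1 transition.
    """
    for name, val in (("k_oc", k_oc), ("k_co", k_co), ("k_21", k_21), ("k_12", k_12)):
        if not np.isfinite(val) or val <= 0:
            raise ModelValidationError(f"{name} must be > 0 (got {val})")
    Q = np.array(
        [
            [-k_oc, k_oc, 0.0],
            [k_co, -(k_co + k_21), k_21],
            [0.0, k_12, -k_12],
        ]
    )
    return RateModel(
        state_labels=("O", "C2", "C1"),
        state_class=("open", "closed", "closed"),
        generator=Q,
        open_amplitude=float(open_amplitude),
    )


def stationary_distribution(model: RateModel) -> np.ndarray:
    """Stationary occupancy pi solving pi Q = 0, sum(pi) = 1, pi > 0."""
    Q = model.generator
    n = model.n_states
    # Solve the overdetermined system [Q^T; 1] pi = [0; 1] by least squares.
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi <= 0):
        raise ModelValidationError("stationary distribution not strictly positive")
    return pi / pi.sum()


def analytic_open_probability(model: RateModel) -> float:
    """Equilibrium open probability: stationary mass on open-class states."""
    pi = stationary_distribution(model)
    return float(pi[model.open_states].sum())


def analytic_dwell_mixture(model: RateModel, dwell_class: StateClass) -> DwellMixture:
    """Analytic dwell-time distribution of one conductance class.

    Dwells in class ``c`` follow a phase-type distribution governed by the
    sub-generator of the class states, entered according to the equilibrium
    flux from the complementary class.  For the three-state chain the open
    class is a single exponential with tau = 1/k_oc, and the closed class is
    a biexponential whose rates are the eigenvalue magnitudes of the negated
    closed sub-generator, with all entries arriving at the pre-open state C2.
    """
    in_class = np.array([c == dwell_class for c in model.state_class])
    if not in_class.any():
        raise ModelValidationError(f"model has no '{dwell_class}' states")
    Q = model.generator
    idx = np.where(in_class)[0]
    comp = np.where(~in_class)[0]
    Qcc = Q[np.ix_(idx, idx)]

    # Entry distribution: equilibrium probability flux from complementary
    # states into each class state.
    pi = stationary_distribution(model)
    flux = pi[comp] @ Q[np.ix_(comp, idx)]
    phi = flux / flux.sum()

    lam, V = np.linalg.eig(-Qcc)
    lam = lam.real
    V = V.real
    if np.any(lam <= 0):
        raise ModelValidationError("class sub-generator must be strictly stable")
    # Density f(t) = phi expm(Qcc t) u with u = -Qcc 1; expand on eigenbasis.
    u = -Qcc @ np.ones(len(idx))
    Vinv = np.linalg.inv(V)
    coeff = np.array(
        [(phi @ V[:, j]) * (Vinv[j] @ u) for j in range(len(idx))]
    )  # f(t) = sum_j coeff_j exp(-lam_j t)
    tau = 1.0 / lam
    weights = coeff / lam  # integral of each exponential term
    order = np.argsort(-tau)
    tau, weights = tau[order], weights[order]
    weights = np.clip(weights, 0.0, None)
    weights = weights / weights.sum()
    # Merge numerically coincident eigenvalues to keep tau strictly decreasing.
    keep_tau: list[float] = []
    keep_w: list[float] = []
    for t_i, w_i in zip(tau, weights):
        if keep_tau and abs(t_i - keep_tau[-1]) < 1e-12 * keep_tau[-1]:
            keep_w[-1] += w_i
        else:
            keep_tau.append(float(t_i))
            keep_w.append(float(w_i))
    return DwellMixture(dwell_class, np.array(keep_tau), np.array(keep_w))


def simulate_states(
    model: RateModel,
    duration: float,
    seed: int | np.random.Generator,
    start_state: int | None = None,
) -> StateSequence:
    """Exact (Gillespie) realization of the gating chain for ``duration`` s.

    The initial state is drawn from the stationary distribution unless
    ``start_state`` is given.  The final dwell is truncated at the sweep end
    and flagged as such.  Identical (model, duration, seed) gives an
    identical path.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Q = model.generator
    n = model.n_states
    exit_rates = -np.diag(Q)
    jump_cum = np.array(
        [np.cumsum(np.where(np.arange(n) == i, 0.0, Q[i] / exit_rates[i])) for i in range(n)]
    )
    mean_dwell = 1.0 / exit_rates
    if start_state is None:
        pi = stationary_distribution(model)
        state = int(np.searchsorted(np.cumsum(pi), rng.random()))
    else:
        state = int(start_state)

    states: list[int] = []
    durations: list[float] = []
    t = 0.0
    while t < duration:
        dwell = rng.exponential(mean_dwell[state])
        if t + dwell >= duration:
            dwell = duration - t
            states.append(state)
            durations.append(dwell)
            t = duration
            break
        states.append(state)
        durations.append(dwell)
        t += dwell
        state = int(np.searchsorted(jump_cum[state], rng.random(), side="right"))
    return StateSequence(
        states=np.array(states),
        durations=np.array(durations),
        seed=seed if isinstance(seed, int) else None,
        last_truncated=True,
    )


def _sample_path(seq: StateSequence, model: RateModel, dt: float, n_samples: int) -> np.ndarray:
    """Sample the piecewise-constant current of a latent path at interval dt."""
    amp = np.where(model.open_states, model.open_amplitude, model.closed_level)
    edges = np.concatenate([[0.0], np.cumsum(seq.durations)])
    t = (np.arange(n_samples) + 0.5) * dt  # sample at bin centres
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(seq.states) - 1)
    return amp[seq.states[idx]]


def gaussian_filter_sigma_samples(filter_cutoff: float, dt: float) -> float:
    """Std dev (in samples) of a Gaussian FIR whose -3 dB point is filter_cutoff.

    For a Gaussian impulse response of width sigma_t, |H(f)| drops to
    1/sqrt(2) at f_c = sqrt(ln 2)/(2 pi sigma_t), i.e. sigma_t ~ 0.1325/f_c.
    """
    sigma_t = np.sqrt(np.log(2.0)) / (2.0 * np.pi * filter_cutoff)
    return sigma_t / dt


def render_trace(
    seq: StateSequence,
    model: RateModel,
    dt: float = DEFAULT_DT_S,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    filter_cutoff: float | None = DEFAULT_FILTER_HZ,
    seed: int | np.random.Generator = 0,
    holding_mV: float = DEFAULT_HOLDING_MV,
) -> CurrentTrace:
    """Render a latent gating path into a sampled current trace.

    White Gaussian noise of sd ``noise_sd`` is added to the piecewise-constant
    current and the sum is smoothed with a Gaussian FIR approximating the
    recording low-pass filter (``filter_cutoff`` in Hz; None disables).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if filter_cutoff is not None and filter_cutoff <= 0:
        raise ValueError("filter_cutoff must be > 0 or None")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_samples = int(round(seq.total_duration / dt))
    x = _sample_path(seq, model, dt, n_samples)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n_samples)
    if filter_cutoff is not None:
        sigma = gaussian_filter_sigma_samples(filter_cutoff, dt)
        x = gaussian_filter1d(x, sigma, mode="nearest")
    meta = TraceMeta(
        holding_mV=holding_mV,
        filter_Hz=filter_cutoff,
        n_channels=1,
        seed=seed if isinstance(seed, int) else None,
    )
    return CurrentTrace(dt=dt, samples=x, meta=meta)


def superpose_channels(
    n: int,
    model: RateModel,
    duration: float = DEFAULT_SWEEP_S,
    dt: float = DEFAULT_DT_S,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    filter_cutoff: float | None = DEFAULT_FILTER_HZ,
    seed: int = 0,
    holding_mV: float = DEFAULT_HOLDING_MV,
) -> CurrentTrace:
    """Sum of ``n`` independent single-channel records sharing one noise draw.

    Before noise the trace takes levels {0, A, 2A, ..., nA}; this emulates a
    patch containing several identical channels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    n_samples = int(round(duration / dt))
    total = np.zeros(n_samples)
    for _ in range(n):
        seq = simulate_states(model, duration, master)
        total += _sample_path(seq, model, dt, n_samples)
    if noise_sd > 0:
        total = total + master.normal(0.0, noise_sd, size=n_samples)
    if filter_cutoff is not None:
        sigma = gaussian_filter_sigma_samples(filter_cutoff, dt)
        total = gaussian_filter1d(total, sigma, mode="nearest")
    meta = TraceMeta(
        holding_mV=holding_mV, filter_Hz=filter_cutoff, n_channels=n, seed=seed
    )
    return CurrentTrace(dt=dt, samples=total, meta=meta)
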