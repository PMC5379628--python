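"""Dwell-time inference: exponential mixtures and the three-state gating fit.

Idealized records yield open and closed dwell durations.  Open dwells of the
linear scheme O <-> C2 <-> C1 are exponential with rate k_oc (the closing
rate constant); closed dwells, entered at the pre-open state C2, follow the
biexponential phase-type law of the 2x2 closed sub-generator

    Qc = [[-(k_co + k_21), k_21],
          [k_12,          -k_12]],    f(t) = k_co * [exp(Qc t)]_{C2,C2}.

All fits are maximum likelihood with left truncation at the dead time: every
density is renormalized on [dead_time, inf) so that unresolvable short events
are censored rather than corrected for.  Exact missed-event corrections are
out of scope and flagged as a limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .idealization import IdealizedRecord
from .markov_gating import DwellMixture, analytic_open_probability, build_three_state

__all__ = [
    "DwellMixtureFit",
    "ActivityStats",
    "ThreeStateFit",
    "extract_dwells",
    "fit_exp_mixture",
    "select_n_components",
    "empirical_open_probability",
    "fit_three_state",
]

_LOGEPS = 1e-300


@dataclass(frozen=True)
class DwellMixtureFit:
    """MLE of a k-exponential mixture, left-truncated at the dead time."""

    dwell_class: Literal["open", "closed"]
    time_constants: np.ndarray  # s, strictly decreasing
    weights: np.ndarray
    n_events: int
    dead_time: float
    log_likelihood: float

    def __post_init__(self) -> None:
        tau = np.asarray(self.time_constants, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "time_constants", tau)
        object.__setattr__(self, "weights", w)
        if np.any(tau <= 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("invalid mixture parameters")
        if self.n_events < 2 * len(tau):
            raise ValueError("need at least 2 events per mixture component")

    @property
    def k(self) -> int:
        return len(self.time_constants)

    @property
    def bic(self) -> float:
        p = 2 * self.k - 1
        return -2.0 * self.log_likelihood + p * np.log(self.n_events)

    def as_mixture(self) -> DwellMixture:
        return DwellMixture(self.dwell_class, self.time_constants, self.weights)


@dataclass(frozen=True)
class ActivityStats:
    """Per-record activity summary: NPo, Po and open amplitude."""

    Po: float
    NPo: float
    n_channels: int
    mean_open_amplitude: float
    duration: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.Po <= 1.0:
            raise ValueError("Po must lie in [0, 1]")


@dataclass(frozen=True)
class ThreeStateFit:
    """Joint MLE of the O <-> C2 <-> C1 scheme from dwell durations."""

    k_oc: float
    k_co: float
    k_21: float
    k_12: float
    dead_time: float
    log_likelihood: float
    converged: bool
    n_open: int
    n_closed: int
    boundary_flag: bool = False  # k_21 at lower bound: collapsed to two-state

    @property
    def rates(self) -> tuple[float, float, float, float]:
        return (self.k_oc, self.k_co, self.k_21, self.k_12)

    @property
    def closing_rate(self) -> float:
        """Rate of leaving the open state, 1/tau_O (s^-1)."""
        return self.k_oc

    @property
    def tau_open(self) -> float:
        return 1.0 / self.k_oc

    @property
    def tau_closed(self) -> np.ndarray:
        """Closed time constants (s), slow first."""
        lam, _ = _closed_coeffs(self.k_co, self.k_21, self.k_12)
        return np.sort(1.0 / lam)[::-1]

    @property
    def Po(self) -> float:
        model = build_three_state(self.k_oc, self.k_co, self.k_21, self.k_12)
        return analytic_open_probability(model)


def extract_dwells(
    record: IdealizedRecord,
    dwell_class: Literal["open", "closed"],
    censor_edges: bool = True,
) -> np.ndarray:
    """Dwell durations (s) of one class; edge events optionally censored.

    The first and last events of a sweep are incomplete (the sweep begins and
    ends mid-dwell), so they are excluded by default.
    """
    if len(record.events) == 0:
        raise ValueError("record has no events")
    events = record.events[1:-1] if censor_edges and len(record.events) > 2 else (
        () if censor_edges else record.events
    )
    if censor_edges and len(record.events) <= 2:
        events = ()
    return np.array([e.duration for e in events if e.dwell_class == dwell_class])


def _trunc_mix_nll(
    log_tau: np.ndarray, logit_w: np.ndarray, t: np.ndarray, dead_time: float
) -> float:
    tau = np.exp(log_tau)
    w = np.exp(logit_w - logit_w.max())
    w = w / w.sum()
    dens = np.einsum("j,ij->i", w / tau, np.exp(-t[:, None] / tau[None, :]))
    surv = np.dot(w, np.exp(-dead_time / tau))
    return -(np.sum(np.log(dens + _LOGEPS)) - len(t) * np.log(surv + _LOGEPS))


def fit_exp_mixture(
    durations: Sequence[float],
    k: int,
    dead_time: float = 0.0,
    dwell_class: Literal["open", "closed"] = "closed",
    n_starts: int = 5,
    seed: int = 0,
) -> DwellMixtureFit:
    """MLE of a k-component exponential mixture left-truncated at dead_time.

    The density of each component is renormalized on [dead_time, inf).
    Optimization is quasi-Newton on (log tau, weight logits) with multiple
    deterministic starts; k = 1 uses the closed form tau = mean(t) - d.
    """
    t = np.asarray(durations, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(t) == 0:
        raise ValueError("no durations provided")
    if np.any(t < dead_time - 1e-12):
        raise ValueError("all durations must be >= dead_time")
    if k > len(t) // 2:
        raise ValueError(f"k={k} too large for {len(t)} events (need n >= 2k)")

    if np.ptp(t) < 1e-15:  # degenerate: all durations identical
        warnings.warn("degenerate dwell sample: all durations equal", stacklevel=2)
        tau = max(float(t[0]) - dead_time, float(t[0]) * 1e-3)
        ll = float(len(t) * (np.log(1.0 / tau) - (t[0] - dead_time) / tau))
        return DwellMixtureFit(dwell_class, np.array([tau]), np.array([1.0]),
                               len(t), dead_time, ll)

    if k == 1:
        tau = float(t.mean() - dead_time)
        ll = float(np.sum(-np.log(tau) - (t - dead_time) / tau))
        return DwellMixtureFit(dwell_class, np.array([tau]), np.array([1.0]),
                               len(t), dead_time, ll)

    rng = np.random.default_rng(seed)
    mean_excess = max(t.mean() - dead_time, 1e-9)
    best = None
    for s in range(n_starts):
        if s == 0:
            # spread initial taus geometrically around the excess mean
            tau0 = mean_excess * np.geomspace(0.2, 5.0, k)
        else:
            tau0 = mean_excess * np.exp(rng.normal(0.0, 1.5, size=k))
        x0 = np.concatenate([np.log(tau0), np.zeros(k)])
        res = minimize(
            lambda x: _trunc_mix_nll(x[:k], x[k:], t, dead_time),
            x0,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("exponential mixture fit failed to converge")
    tau = np.exp(best.x[:k])
    w = np.exp(best.x[k:] - best.x[k:].max())
    w = w / w.sum()
    order = np.argsort(-tau)
    tau, w = tau[order], w[order]
    # collapse numerically coincident components
    if np.any(np.diff(tau) > -1e-10 * tau[:-1]):
        utau, uw = [tau[0]], [w[0]]
        for ti, wi in zip(tau[1:], w[1:]):
            if utau[-1] - ti <= 1e-10 * utau[-1]:
                uw[-1] += wi
            else:
                utau.append(ti)
                uw.append(wi)
        tau, w = np.array(utau), np.array(uw)
    return DwellMixtureFit(dwell_class, tau, w, len(t), dead_time, float(-best.fun))


def select_n_components(
    durations: Sequence[float],
    k_max: int = 3,
    criterion: Literal["bic", "lrt"] = "bic",
    dead_time: float = 0.0,
    dwell_class: Literal["open", "closed"] = "closed",
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[int, list[DwellMixtureFit]]:
    """Choose the number of exponential components for a dwell sample.

    Fits k = 1..k_max and selects by BIC (default) or by sequential
    likelihood-ratio tests at level ``alpha``.  With fewer than 20 events a
    single component is forced (with a warning).
    """
    t = np.asarray(durations, dtype=float)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if len(t) < 20:
        warnings.warn(
            f"only {len(t)} events: forcing single-component fit", stacklevel=2
        )
        return 1, [fit_exp_mixture(t, 1, dead_time, dwell_class, seed=seed)]
    fits = []
    for k in range(1, k_max + 1):
        if k > len(t) // 2:
            break
        fits.append(fit_exp_mixture(t, k, dead_time, dwell_class, seed=seed))
    if criterion == "bic":
        chosen = int(np.argmin([f.bic for f in fits])) + 1
    elif criterion == "lrt":
        from scipy.stats import chi2

        chosen = 1
        for k in range(1, len(fits)):
            stat = 2.0 * (fits[k].log_likelihood - fits[k - 1].log_likelihood)
            if chi2.sf(max(stat, 0.0), df=2) < alpha:
                chosen = k + 1
            else:
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return chosen, fits


def empirical_open_probability(
    record: IdealizedRecord, n_channels: int | None = None
) -> ActivityStats:
    """Time-averaged NPo and Po of an idealized record.

    NPo = sum_k(level_k * duration_k) / T; Po = NPo / n_channels.  If
    ``n_channels`` is not given, the maximum observed level is used.
    """
    if record.total_duration <= 0:
        raise ValueError("record spans no time")
    levels = record.levels
    durs = record.durations
    max_level = int(levels.max()) if len(levels) else 0
    if n_channels is None:
        n_channels = max(max_level, 1)
    if max_level > n_channels:
        raise ValueError(
            f"observed level {max_level} exceeds n_channels={n_channels}"
        )
    T = record.total_duration
    npo = float(np.dot(levels, durs) / T)
    open_mask = levels > 0
    if open_mask.any():
        amps = np.array([e.mean_amplitude for e in record.events])[open_mask]
        w = durs[open_mask]
        mean_amp = float(np.dot(amps, w) / w.sum())
    else:
        mean_amp = float("nan")
    return ActivityStats(
        Po=npo / n_channels,
        NPo=npo,
        n_channels=n_channels,
        mean_open_amplitude=mean_amp,
        duration=T,
    )


def _closed_coeffs(k_co: float, k_21: float, k_12: float):
    """Eigenrates and density coefficients of the closed-class dwell law.

    Closed dwells start in C2; the density is
    f(t) = c1 exp(-lam1 t) + c2 exp(-lam2 t) with sum(c_i / lam_i) = 1.
    """
    a = k_co + k_21
    b = k_12
    disc = np.sqrt((a - b) ** 2 + 4.0 * k_21 * k_12)
    lam1 = 0.5 * (a + b + disc)
    lam2 = 0.5 * (a + b - disc)
    if lam1 - lam2 < 1e-12 * lam1:  # defective/coincident: nudge apart
        lam2 = lam1 * (1.0 - 1e-9)
    # [exp(Qc t)]_{C2,C2} = ((lam1 - a) exp(-lam2 t) - (lam2 - a) exp(-lam1 t)) / (lam1 - lam2)
    c1 = k_co * (a - lam2) / (lam1 - lam2)
    c2 = k_co * (lam1 - a) / (lam1 - lam2)
    return np.array([lam1, lam2]), np.array([c1, c2])


def _three_state_nll(
    log_rates: np.ndarray,
    t_open: np.ndarray,
    t_closed: np.ndarray,
    dead_time: float,
) -> float:
    k_oc, k_co, k_21, k_12 = np.exp(log_rates)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        # open: Exp(k_oc) truncated at dead_time
        ll = np.sum(np.log(k_oc) - k_oc * (t_open - dead_time))
        # closed: biexponential phase-type truncated at dead_time
        lam, c = _closed_coeffs(k_co, k_21, k_12)
        lam = np.maximum(lam, 1e-12)
        dens = c[0] * np.exp(-lam[0] * t_closed) + c[1] * np.exp(-lam[1] * t_closed)
        surv = (c[0] / lam[0]) * np.exp(-lam[0] * dead_time) + (
            c[1] / lam[1]
        ) * np.exp(-lam[1] * dead_time)
        ll += np.sum(np.log(np.clip(dens, _LOGEPS, None))) - len(t_closed) * np.log(
            max(surv, _LOGEPS)
        )
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def fit_three_state(
    open_dwells: Sequence[float],
    closed_dwells: Sequence[float],
    dead_time: float = 0.0,
    init: tuple[float, float, float, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> ThreeStateFit:
    """Joint MLE of the four rates of the O <-> C2 <-> C1 scheme.

    Open dwells are exponential with rate k_oc; closed dwells follow the
    entry-at-C2 biexponential of the closed sub-generator.  Both densities
    are left-truncated at ``dead_time``.  Optimization is quasi-Newton on the
    log rates with multiple starts seeded from a moment-matched mixture fit.
    A fit with k_21 at its lower bound is flagged: the data are effectively
    single-exponential in the closed class and the scheme collapses to
    two states.
    """
    t_open = np.asarray(open_dwells, dtype=float)
    t_closed = np.asarray(closed_dwells, dtype=float)
    if len(t_open) == 0 or len(t_closed) == 0:
        raise ValueError("need dwells in both classes")
    if len(t_open) < 50 or len(t_closed) < 50:
        warnings.warn(
            f"few dwells (open={len(t_open)}, closed={len(t_closed)}); "
            "rate estimates may be unstable",
            stacklevel=2,
        )
    # closing rate has a closed-form MLE from the open dwells
    k_oc0 = 1.0 / max(t_open.mean() - dead_time, 1e-9)

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.log(np.asarray(init, dtype=float)))
    try:
        mix = fit_exp_mixture(t_closed, min(2, len(t_closed) // 2), dead_time, seed=seed)
        if mix.k == 2:
            (tau_s, tau_f), (w_s, w_f) = mix.time_constants, mix.weights
            # moment-match: fast closed component ~ C2 residence, slow ~ C1 cycling
            k_co0 = max(w_f, 0.05) / tau_f
            k_210 = max(w_s, 0.05) / tau_f
            k_120 = 1.0 / tau_s
        else:
            k_co0, k_210, k_120 = 1.0 / mix.time_constants[0], k_oc0 * 0.1, k_oc0 * 0.05
        starts.append(np.log([k_oc0, k_co0, k_210, k_120]))
    except Exception:
        starts.append(np.log([k_oc0, k_oc0, k_oc0 / 5.0, k_oc0 / 10.0]))
    rng = np.random.default_rng(seed)
    base = starts[-1]
    while len(starts) < n_starts:
        starts.append(base + rng.normal(0.0, 0.7, size=4))

    best = None
    for x0 in starts:
        res = minimize(
            _three_state_nll,
            x0,
            args=(t_open, t_closed, dead_time),
            method="L-BFGS-B",
            bounds=[(np.log(1e-4), np.log(1e7))] * 4,
            options={"maxiter": 3000, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    k_oc, k_co, k_21, k_12 = np.exp(best.x)
    # identifiability check: does the biexponential closed law beat a plain
    # exponential?  If not, the C1 state is unsupported by the data and the
    # scheme collapses to two states (k_21 effectively at its lower bound).
    tau_c = max(t_closed.mean() - dead_time, 1e-12)
    ll_single = float(
        np.sum(np.log(k_oc) - k_oc * (t_open - dead_time))
        + np.sum(-np.log(tau_c) - (t_closed - dead_time) / tau_c)
    )
    lrt = 2.0 * (-best.fun - ll_single)
    boundary = bool(k_21 < 1e-3 or lrt < 5.99)  # chi-square(2), alpha = 0.05
    if boundary:
        warnings.warn(
            "k_21 unsupported: closed dwells effectively single-exponential, "
            "model collapses to two states",
            stacklevel=2,
        )
    return ThreeStateFit(
        k_oc=float(k_oc),
        k_co=float(k_co),
        k_21=float(k_21),
        k_12=float(k_12),
        dead_time=dead_time,
        log_likelihood=float(-best.fun),
        converged=bool(best.success),
        n_open=len(t_open),
        n_closed=len(t_closed),
        boundary_flag=boundary,
    )
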