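"""End-to-end experiment helpers: simulate -> render -> idealize -> fit.

These wrap the full single-channel analysis pipeline for a multi-sweep
cell-attached protocol: 10 s sweeps at -80 mV, 100 us sampling, 5 kHz
low-pass, ~5.5 pA open amplitude, 0.5 pA noise.  They are the entry points
used by the worked examples and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov_gating import (
    DEFAULT_AMPLITUDE_PA,
    DEFAULT_DT_S,
    DEFAULT_FILTER_HZ,
    DEFAULT_NOISE_SD_PA,
    DEFAULT_SWEEP_S,
    build_three_state,
    render_trace,
    simulate_states,
)
from .idealization import half_amplitude_idealize
from .dwell_kinetics import (
    ThreeStateFit,
    empirical_open_probability,
    extract_dwells,
    fit_three_state,
)

__all__ = ["PatchExperimentResult", "run_patch_experiment"]


@dataclass(frozen=True)
class PatchExperimentResult:
    """Pooled outcome of a simulated multi-sweep patch experiment."""

    fit: ThreeStateFit
    true_rates: tuple[float, float, float, float]
    empirical_Po: float
    mean_open_amplitude: float
    n_open: int
    n_closed: int
    total_duration: float

    @property
    def rate_rel_errors(self) -> np.ndarray:
        """Relative error of each fitted rate vs the generating rates."""
        est = np.array(self.fit.rates)
        true = np.array(self.true_rates)
        return (est - true) / true


def run_patch_experiment(
    rates: tuple[float, float, float, float],
    n_sweeps: int = 30,
    sweep_s: float = DEFAULT_SWEEP_S,
    dt: float = DEFAULT_DT_S,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    filter_hz: float | None = DEFAULT_FILTER_HZ,
    amplitude: float = DEFAULT_AMPLITUDE_PA,
    dead_time: float | None = None,
    seed: int = 0,
) -> PatchExperimentResult:
    """Simulate a patch, idealize every sweep, and fit the three-state model.

    Each sweep gets an independent substream of ``seed``; dwells are pooled
    across sweeps (edge dwells censored) before fitting.  ``dead_time``
    defaults to 2 * dt.
    """
    if dead_time is None:
        dead_time = 2.0 * dt
    model = build_three_state(*rates, open_amplitude=amplitude)
    open_d, closed_d = [], []
    npo_weighted = 0.0
    total_t = 0.0
    amp_weighted = 0.0
    amp_time = 0.0
    for sweep in range(n_sweeps):
        rng = np.random.default_rng([seed, sweep])
        seq = simulate_states(model, sweep_s, rng)
        trace = render_trace(
            seq, model, dt=dt, noise_sd=noise_sd, filter_cutoff=filter_hz, seed=rng
        )
        record = half_amplitude_idealize(trace, dead_time=dead_time)
        open_d.append(extract_dwells(record, "open"))
        closed_d.append(extract_dwells(record, "closed"))
        stats = empirical_open_probability(record, 1)
        npo_weighted += stats.NPo * stats.duration
        total_t += stats.duration
        if np.isfinite(stats.mean_open_amplitude):
            open_time = stats.NPo * stats.duration
            amp_weighted += stats.mean_open_amplitude * open_time
            amp_time += open_time
    od = np.concatenate(open_d)
    cd = np.concatenate(closed_d)
    fit = fit_three_state(od, cd, dead_time=dead_time, seed=seed)
    return PatchExperimentResult(
        fit=fit,
        true_rates=tuple(rates),
        empirical_Po=npo_weighted / total_t,
        mean_open_amplitude=amp_weighted / amp_time if amp_time > 0 else float("nan"),
        n_open=len(od),
        n_closed=len(cd),
        total_duration=total_t,
    )
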