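import numpy as np
import pytest

from gatekin.markov_gating import build_three_state, WT_LIKE_RATES, G579A_LIKE_RATES


# reference rate set used throughout: analytic stationary occupancy
# (1/7, 2/7, 4/7) and closed dwell constants {146.3, 13.67} ms
REF_RATES = (100.0, 50.0, 20.0, 10.0)


@pytest.fixture(scope="session")
def ref_model():
    return build_three_state(*REF_RATES)


@pytest.fixture(scope="session")
def wt_model():
    return build_three_state(*WT_LIKE_RATES)


@pytest.fixture(scope="session")
def low_po_model():
    return build_three_state(*G579A_LIKE_RATES)


@pytest.fixture(scope="session")
def ring_structure():
    from gatekin.pore_geometry import make_toy_pore

    return make_toy_pore("ring", ring_radius=5.0, n_atoms=12, vdw=1.70)


@pytest.fixture(scope="session")
def tetramer_gate():
    from gatekin.pore_geometry import make_toy_pore

    return make_toy_pore("tetramer_gate")


def class_dwells(seq, model):
    """Collapse a state path into per-class dwell durations (edges dropped).

    Independent of the idealization code path: works directly on the latent
    Gillespie sequence.
    """
    open_mask = model.open_states[seq.states]
    change = np.flatnonzero(np.diff(open_mask.astype(int))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(open_mask)]])
    open_d, closed_d = [], []
    for k, (s, e) in enumerate(zip(starts, ends)):
        if k == 0 or k == len(starts) - 1:
            continue  # censor edge dwells
        (open_d if open_mask[s] else closed_d).append(seq.durations[s:e].sum())
    return np.array(open_d), np.array(closed_d)
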