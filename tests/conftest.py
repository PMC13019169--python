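import numpy as np
import pytest

from arraycrit.synthetic import SynthCellParams, gen_two_state_activity


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_switching_cell():
    """Noise-free switching cell without stimulus windows (truth attached)."""
    p = SynthCellParams(
        noise_sigma=0.0,
        duration=2000.0,
        attractant_windows=[],
        repellent_windows=[],
        seed=5,
    )
    times, activity, truth = gen_two_state_activity(p)
    return p, times, activity, truth


def match_events(detected, truth, tol=6.0):
    """Pair detected events with nearest same-direction truth events."""
    pairs, used = [], set()
    for e in detected:
        best, best_d = None, tol
        for j, tr in enumerate(truth):
            if j in used or tr["direction"] != e.direction:
                continue
            d = abs(tr["t"] - e.t_event)
            if d < best_d:
                best_d, best = d, j
        if best is not None:
            used.add(best)
            pairs.append((e, truth[best], best))
    return pairs
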