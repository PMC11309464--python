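import numpy as np
import pytest

from eegmci.cluster import StatGrid
from eegmci.cohort import CohortConfig, make_cohort


@pytest.fixture
def small_config() -> CohortConfig:
    return CohortConfig(n_hc=4, n_mci=4, seed=7)


@pytest.fixture
def small_cohort(small_config):
    return make_cohort(small_config)


def grid_from_t(t: np.ndarray, space: str = "channel_frequency",
                df: int = 38) -> StatGrid:
    """StatGrid with p values consistent with the given t map."""
    from scipy import stats

    p = 2.0 * stats.t.sf(np.abs(t), df)
    return StatGrid(np.asarray(t, float), p, space, "independent", df)


def brute_force_components(mask: np.ndarray) -> list[frozenset]:
    """Reference connected components under 4-neighbour adjacency, by BFS."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            r, c = stack.pop()
            comp.add((r, c))
            for r2, c2 in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if (0 <= r2 < mask.shape[0] and 0 <= c2 < mask.shape[1]
                        and mask[r2, c2] and not seen[r2, c2]):
                    seen[r2, c2] = True
                    stack.append((r2, c2))
        comps.append(frozenset(comp))
    return comps
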