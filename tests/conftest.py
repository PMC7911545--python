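import numpy as np
import pytest

from integrinkd import ConditionDataset, PressureSchedule, ReplicateCounts


@pytest.fixture
def schedule():
    """The default six-round 0.07-0.22 atm schedule."""
    return PressureSchedule()


def dataset_from_pressures(per_replicate_pressures, schedule, q=100.0):
    """Build a ConditionDataset from known per-cell critical pressures.

    Each element of ``per_replicate_pressures`` is an array of critical
    detachment pressures for one replicate; a cell survives round n iff its
    critical pressure exceeds p_n.  Used as the ground-truth link between
    per-cell data and count data in oracle tests.
    """
    p = np.asarray(schedule.pressures)
    reps = []
    for pstar in per_replicate_pressures:
        pstar = np.asarray(pstar, dtype=float)
        remaining = tuple(int((pstar > pn).sum()) for pn in p)
        reps.append(ReplicateCounts(initial=len(pstar), remaining=remaining))
    return ConditionDataset(q=q, schedule=schedule, replicates=tuple(reps))


def percell_midpoints(pstar, schedule):
    """Independent per-cell bin-midpoint assignment (the W oracle)."""
    edges = schedule.bin_edges()
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.searchsorted(np.asarray(schedule.pressures), np.asarray(pstar), side="left")
    return mids[idx]
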