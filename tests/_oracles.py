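"""Independent oracles and session builders shared across test modules."""

import numpy as np

from dptsim.synthetic_dpt import CT, IT, DPTDataset, TaskLayout
from dptsim.tlbs import TLBSPoint


def brute_force_pairs(ds):
    """O(n^2) pairing oracle: for every included CT/IT anchor, scan all
    included opposite-type trials for the minimum |position difference|
    (ties to the earlier trial) within the layout's maximum distance."""
    max_d = ds.layout.max_pair_distance
    pos = ds.positions
    points = []
    for i in range(len(ds)):
        if not ds.included[i] or ds.trial_types[i] not in (CT, IT):
            continue
        opposite = IT if ds.trial_types[i] == CT else CT
        best = None
        for j in range(len(ds)):
            if j == i or not ds.included[j] or ds.trial_types[j] != opposite:
                continue
            d = abs(int(pos[i]) - int(pos[j]))
            if d > max_d:
                continue
            if best is None or d < best[0] or (d == best[0] and pos[j] < pos[best[1]]):
                best = (d, j)
        if best is not None:
            j = best[1]
            it_idx, ct_idx = (j, i) if opposite == IT else (i, j)
            points.append(
                TLBSPoint(int(pos[i]), int(pos[j]), float(ds.rt[it_idx] - ds.rt[ct_idx]))
            )
    return points


def random_session(rng, n_min=4, n_max=60):
    """A TL-BS-layout session with random length, types, RTs and flags."""
    layout = TaskLayout.tlbs_style()
    n = int(rng.integers(n_min, n_max + 1))
    types = rng.integers(0, 3, size=n).astype(np.int8)
    rts = rng.normal(600, 30, size=n)
    included = rng.random(n) > 0.15
    return DPTDataset(
        layout=layout,
        trial_types=types,
        rt=rts,
        subset_ids=np.ones(n, dtype=np.int64),
        included=included,
    )


def build_abv_session(rt_by_bin):
    """A 160-trial ABV-layout session: per bin of 20 original positions,
    CT then IT trials with the RTs given as (ct_rts, it_rts)."""
    records = []
    for ct_rts, it_rts in rt_by_bin:
        records += [("CT", v) for v in ct_rts] + [("IT", v) for v in it_rts]
    return DPTDataset.from_trials(TaskLayout.abv_style(), records)


def alternating_bin_session(half_amplitude=5.0):
    """ABV session whose eight bin BIs alternate +2a, -2a, ... around a
    600 ms mean RT."""
    per_bin = []
    for k in range(8):
        sign = 1 if k % 2 == 0 else -1
        per_bin.append(
            ([600 - half_amplitude * sign] * 10, [600 + half_amplitude * sign] * 10)
        )
    return build_abv_session(per_bin)
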