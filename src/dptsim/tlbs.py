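"""Trial-level bias scores (TL-BS): pairing and the five summary indices.

Every included CT and IT trial (the *anchor*) is paired with the included
opposite-type trial closest to it in the session — distance counted over
original trial positions, NT trials included in the metric — up to a
maximum of five positions away. Each pair yields one bias score,
``RT(IT member) - RT(CT member)``, anchored at the anchor's position, so a
mutually-nearest CT/IT pair contributes two points (one per anchor).
Equidistant candidates resolve to the earlier trial.

From the position-ordered point series five indices are derived: mean and
peak of the strictly positive values, mean and peak of the strictly
negative values (all four exactly 0 when that sign is absent), and the
TL-BS variability — the mean Euclidean step length between consecutive
points in the (position, value) plane. An earlier formulation of the
variability index (mean absolute value difference, ignoring the position
axis) is kept available as ``method="absolute"`` for comparison with
historical results; the Euclidean form is the corrected definition and the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from dptsim.synthetic_dpt import CT, IT, DPTDataset, Variant

__all__ = ["TLBSPoint", "TLBSSummary", "pair_trials", "tlbs_variability", "tlbs_summary"]


class TLBSPoint(NamedTuple):
    """One trial-level bias score anchored at a CT or IT trial."""

    anchor_position: int
    partner_position: int
    value: float


@dataclass(frozen=True)
class TLBSSummary:
    """The five TL-BS indices for one dataset.

    ``variability`` is NaN with fewer than two points; the four
    positive/negative fields are 0 when no value of that sign exists.
    """

    mean_pos: float
    peak_pos: float
    mean_neg: float
    peak_neg: float
    variability: float
    n_points: int


def pair_trials(ds: DPTDataset) -> list[TLBSPoint]:
    """Pair each included CT/IT anchor with its nearest included opposite
    trial within the layout's maximum distance; ties go to the earlier
    trial. Anchors with no partner in range yield no point. Points are
    returned in anchor-position order.
    """
    if ds.layout.variant is not Variant.TLBS_STYLE:
        raise ValueError("pair_trials requires a TLBS_STYLE layout")
    max_d = ds.layout.max_pair_distance
    pos = ds.positions
    ct_pos = pos[ds.included & (ds.trial_types == CT)]
    it_pos = pos[ds.included & (ds.trial_types == IT)]
    rt_at = ds.rt  # index by position - 1

    points: list[TLBSPoint] = []
    for anchors, partners, sign in ((ct_pos, it_pos, 1.0), (it_pos, ct_pos, -1.0)):
        if partners.size == 0:
            continue
        # nearest partner by binary search; tie -> earlier partner
        idx = np.searchsorted(partners, anchors)
        left = np.clip(idx - 1, 0, partners.size - 1)
        right = np.clip(idx, 0, partners.size - 1)
        d_left = np.abs(anchors - partners[left])
        d_right = np.abs(anchors - partners[right])
        best = np.where(d_left <= d_right, partners[left], partners[right])
        dist = np.minimum(d_left, d_right)
        for a, p, d in zip(anchors, best, dist):
            if d <= max_d:
                # value is always RT(IT) - RT(CT) regardless of anchor type
                it_rt = rt_at[(p if sign > 0 else a) - 1]
                ct_rt = rt_at[(a if sign > 0 else p) - 1]
                points.append(TLBSPoint(int(a), int(p), float(it_rt - ct_rt)))
    points.sort(key=lambda pt: pt.anchor_position)
    return points


def tlbs_variability(points: Sequence[TLBSPoint], method: str = "euclidean") -> float:
    """Mean step length between consecutive TL-BS points, in anchor order.

    ``method="euclidean"`` (default) uses
    ``sqrt(d_position**2 + d_value**2)`` per step; ``method="absolute"``
    reproduces the superseded formulation, the sum of absolute value
    differences divided by the number of points. NaN with fewer than two
    points.
    """
    if len(points) < 2:
        return float("nan")
    x = np.array([p.anchor_position for p in points], dtype=float)
    y = np.array([p.value for p in points])
    if method == "euclidean":
        return float(np.mean(np.hypot(np.diff(x), np.diff(y))))
    if method == "absolute":
        return float(np.sum(np.abs(np.diff(y))) / len(points))
    raise ValueError(f"unknown variability method: {method!r}")


def tlbs_summary(points: Sequence[TLBSPoint], method: str = "euclidean") -> TLBSSummary:
    """The five TL-BS indices from a point series.

    Zero-valued points count as neither positive nor negative; a sign with
    no values contributes 0 to its mean and peak fields, which is a
    meaningful observation (no bias excursion in that direction), not
    missing data.
    """
    values = np.array([p.value for p in points])
    pos = values[values > 0]
    neg = values[values < 0]
    return TLBSSummary(
        mean_pos=float(pos.mean()) if pos.size else 0.0,
        peak_pos=float(pos.max()) if pos.size else 0.0,
        mean_neg=float(neg.mean()) if neg.size else 0.0,
        peak_neg=float(neg.min()) if neg.size else 0.0,
        variability=tlbs_variability(points, method=method),
        n_points=len(points),
    )
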