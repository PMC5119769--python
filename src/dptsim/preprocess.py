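"""RT outlier exclusion rules for the two index methods.

Both methods apply two single-shot passes: absolute RT bounds first, then
an SD gate computed on the survivors of the bounds pass. The gate is not
iterated — re-applying it to its own output could exclude further trials,
and neither source method describes iteration.

The two methods differ in the SD gate's grouping: the ABV-style rule uses
a mean and SD computed separately per trial type (CT, IT, NT), the
TL-BS-style rule uses a single mean and SD pooled over all trial types.

Filters only set inclusion flags; RT values and positions are never
altered or deleted.
"""

from __future__ import annotations

import logging

import numpy as np

from dptsim.synthetic_dpt import CT, IT, NT, DPTDataset, Variant

__all__ = ["filter_bounds", "filter_abv", "filter_tlbs", "filter_dataset"]

logger = logging.getLogger(__name__)


def _bounds_mask(ds: DPTDataset) -> np.ndarray:
    """Pass 1: discard RTs strictly below the floor or above the ceiling."""
    return (ds.rt >= ds.layout.rt_floor) & (ds.rt <= ds.layout.rt_ceiling)


def _sd_gate(rt: np.ndarray, mask: np.ndarray, k: float, label: str) -> np.ndarray:
    """Exclude values with |rt - mean| strictly greater than k * sample SD,
    where mean and SD are taken over ``mask``; returns the reduced mask.

    With fewer than two survivors the SD is undefined and the gate is
    skipped for that group (logged).
    """
    n = int(mask.sum())
    if n < 2:
        logger.warning(
            "SD gate skipped for %s: only %d surviving trial(s)", label, n
        )
        return mask
    vals = rt[mask]
    mean = vals.mean()
    sd = vals.std(ddof=1)
    out = mask.copy()
    out[mask] = np.abs(vals - mean) <= k * sd
    return out


def filter_bounds(ds: DPTDataset) -> DPTDataset:
    """Absolute-bounds pass only: flag RTs strictly outside the layout's
    floor/ceiling as excluded.

    This is the exclusion state the traditional bias index is computed on;
    the SD gates below are part of the ABV and TL-BS methodologies and are
    applied on top of it for those indices only. A data-driven SD gate
    would otherwise leak extra sampling variance into BI (the trimming
    thresholds are estimated from the same 64 trials they censor, which
    inflates rather than shrinks the variance of the surviving mean).
    """
    return ds.with_included(_bounds_mask(ds))


def filter_abv(ds: DPTDataset) -> DPTDataset:
    """ABV-style exclusion: bounds 150-2000 ms, then a per-type 2-SD gate.

    The mean and sample SD are computed separately for CT, IT and NT trials
    over the bounds-pass survivors; a trial is excluded when its RT deviates
    strictly more than 2 SD from its own type's mean.
    """
    if ds.layout.variant is not Variant.ABV_STYLE:
        raise ValueError("filter_abv requires an ABV_STYLE layout")
    mask = _bounds_mask(ds)
    for code, label in ((CT, "CT"), (IT, "IT"), (NT, "NT")):
        type_mask = mask & (ds.trial_types == code)
        gated = _sd_gate(ds.rt, type_mask, ds.layout.sd_multiplier, label)
        mask &= gated | (ds.trial_types != code)
    return ds.with_included(mask)


def filter_tlbs(ds: DPTDataset) -> DPTDataset:
    """TL-BS-style exclusion: bounds 200-1500 ms, then a pooled 3-SD gate.

    One mean and sample SD are computed over all bounds-pass survivors
    regardless of trial type.
    """
    if ds.layout.variant is not Variant.TLBS_STYLE:
        raise ValueError("filter_tlbs requires a TLBS_STYLE layout")
    mask = _bounds_mask(ds)
    mask = _sd_gate(ds.rt, mask, ds.layout.sd_multiplier, "all trials")
    return ds.with_included(mask)


def filter_dataset(ds: DPTDataset) -> DPTDataset:
    """Dispatch to the filter matching the dataset's layout variant."""
    if ds.layout.variant is Variant.ABV_STYLE:
        return filter_abv(ds)
    return filter_tlbs(ds)
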