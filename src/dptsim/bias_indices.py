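"""Traditional bias index (BI) and the attention-bias-variability (ABV)
coefficient.

BI is the mean incongruent-trial RT minus the mean congruent-trial RT over
all included trials; positive values indicate attention oriented toward
the emotional stimulus.

ABV slices the 160-trial session into eight bins of 20 *original* trial
positions (bin membership is fixed regardless of how many trials were
discarded inside a bin), computes a BI per bin, and divides the sample SD
of the eight bin BIs by the overall mean RT of the included CT and IT
trials. A bin left without any included CT or IT trial makes its BI — and
hence the whole ABV value — undefined (NaN); the formula is deliberately
not rescued with fewer bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dptsim.synthetic_dpt import CT, IT, NT, DPTDataset, Variant

__all__ = ["BinSeries", "traditional_bi", "bin_bias_series", "abv"]


@dataclass(frozen=True)
class BinSeries:
    """Per-bin bias indices; ``values[k]`` is NaN when bin k lacks included
    CT or IT trials. ``edges[k]`` is the (first, last) original position of
    bin k."""

    values: np.ndarray
    edges: tuple[tuple[int, int], ...]


def traditional_bi(ds: DPTDataset) -> float:
    """Mean included-IT RT minus mean included-CT RT, NaN if a type has no
    included trials."""
    it = ds.rt[ds.included & (ds.trial_types == IT)]
    ct = ds.rt[ds.included & (ds.trial_types == CT)]
    if it.size == 0 or ct.size == 0:
        return float("nan")
    return float(it.mean() - ct.mean())


def bin_bias_series(ds: DPTDataset) -> BinSeries:
    """BI per bin of original trial positions (ABV layout only)."""
    layout = ds.layout
    if layout.variant is not Variant.ABV_STYLE:
        raise ValueError("bin_bias_series requires an ABV_STYLE layout")
    n_bins, size = layout.n_bins, layout.bin_size
    bin_index = np.arange(len(ds)) // size  # original position only

    values = np.empty(n_bins)
    inc_it = ds.included & (ds.trial_types == IT)
    inc_ct = ds.included & (ds.trial_types == CT)
    # per-bin sums/counts via bincount keeps this O(n)
    it_sum = np.bincount(bin_index, weights=ds.rt * inc_it, minlength=n_bins)
    it_n = np.bincount(bin_index, weights=inc_it, minlength=n_bins)
    ct_sum = np.bincount(bin_index, weights=ds.rt * inc_ct, minlength=n_bins)
    ct_n = np.bincount(bin_index, weights=inc_ct, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(
            (it_n > 0) & (ct_n > 0),
            it_sum / np.maximum(it_n, 1) - ct_sum / np.maximum(ct_n, 1),
            np.nan,
        )
    edges = tuple((k * size + 1, (k + 1) * size) for k in range(n_bins))
    return BinSeries(values=values, edges=edges)


def abv(ds: DPTDataset) -> float:
    """SD of the eight bin BIs over the mean included CT+IT RT.

    Returns NaN when any bin BI is undefined; the denominator is the mean
    RT of all included CT and IT trials of the whole session.
    """
    series = bin_bias_series(ds)
    if np.isnan(series.values).any():
        return float("nan")
    sd = float(np.std(series.values, ddof=1))
    ct_it = ds.included & (ds.trial_types != NT)
    denom = float(ds.rt[ct_it].mean())
    return sd / denom
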