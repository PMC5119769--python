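"""Synthetic dot-probe task (DPT) dataset generation.

A single simulated participant is a randomly ordered session of congruent
(CT), incongruent (IT) and neutral (NT) trials whose reaction times are
drawn from normal distributions. An attentional bias is implied by giving
IT trials a higher mean RT than CT trials; a *dynamic* bias is implied by
splitting the session into consecutive subsets whose bias alternates in
sign (+m, -m, +m, ...).

Two task layouts are supported, matching the two published index methods:

* ``ABV_STYLE`` — 64 CT / 64 IT / 32 NT trials (160 total), the layout the
  attention-bias-variability coefficient was defined on.
* ``TLBS_STYLE`` — 20 CT / 20 IT / 20 NT trials (60 total), the layout the
  trial-level bias-score indices were defined on.

Datasets are stored column-wise as numpy arrays (one row per trial) so that
filtering and index computation stay vectorised; :class:`TrialRecord` gives
a row-level view for inspection and round-tripping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Variant",
    "TrialType",
    "TaskLayout",
    "GroupSpec",
    "SubsetPlan",
    "TrialRecord",
    "DPTDataset",
    "make_trial_sequence",
    "build_subset_plan",
    "generate_dataset",
]

# integer codes used in the packed trial-type array
CT, IT, NT = 0, 1, 2
_TYPE_NAMES = np.array(["CT", "IT", "NT"])
_TYPE_CODES = {"CT": CT, "IT": IT, "NT": NT}


class Variant(str, enum.Enum):
    """Task-layout variant: which published method the session emulates."""

    ABV_STYLE = "abv"
    TLBS_STYLE = "tlbs"


class TrialType(str, enum.Enum):
    CT = "CT"
    IT = "IT"
    NT = "NT"


@dataclass(frozen=True)
class TaskLayout:
    """Trial counts plus the filtering and index parameters of one method.

    Parameters
    ----------
    variant
        ``ABV_STYLE`` or ``TLBS_STYLE``.
    n_ct, n_it, n_nt
        Trials per type in one session.
    rt_floor, rt_ceiling
        Absolute RT bounds (ms); values strictly outside are discarded.
    sd_multiplier
        RTs deviating more than this many SDs from the relevant mean are
        discarded (per trial type for ABV, pooled for TL-BS).
    bin_size, n_bins
        ABV only: bias indices are computed over consecutive bins of
        ``bin_size`` original trial positions.
    max_pair_distance
        TL-BS only: maximum trial distance when pairing opposite-type trials.
    switch_base
        Trial count divided by the number of bias subsets when placing
        switches: all 160 positions for the ABV layout, the 40 CT+IT trials
        for the TL-BS layout (NT trials inherit the surrounding regime).
    """

    variant: Variant
    n_ct: int
    n_it: int
    n_nt: int
    rt_floor: float
    rt_ceiling: float
    sd_multiplier: float
    switch_base: int
    bin_size: int | None = None
    n_bins: int | None = None
    max_pair_distance: int | None = None

    @property
    def n_trials(self) -> int:
        return self.n_ct + self.n_it + self.n_nt

    @staticmethod
    def abv_style() -> "TaskLayout":
        return TaskLayout(
            variant=Variant.ABV_STYLE,
            n_ct=64, n_it=64, n_nt=32,
            rt_floor=150.0, rt_ceiling=2000.0, sd_multiplier=2.0,
            switch_base=160, bin_size=20, n_bins=8,
        )

    @staticmethod
    def tlbs_style() -> "TaskLayout":
        return TaskLayout(
            variant=Variant.TLBS_STYLE,
            n_ct=20, n_it=20, n_nt=20,
            rt_floor=200.0, rt_ceiling=1500.0, sd_multiplier=3.0,
            switch_base=40, max_pair_distance=5,
        )

    @staticmethod
    def for_variant(variant: Variant | str) -> "TaskLayout":
        variant = Variant(variant)
        if variant is Variant.ABV_STYLE:
            return TaskLayout.abv_style()
        return TaskLayout.tlbs_style()


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for the datasets of one study group.

    With ``n_subsets == 1`` and ``switch_magnitude == 0`` the bias is the
    constant ``it_mean - ct_mean``. With ``switch_magnitude = m > 0`` the
    session is split into ``n_subsets`` spans whose bias alternates
    ``+m, -m, +m, ...`` around the midpoint ``(ct_mean + it_mean) / 2``
    (for the default midpoint 600 and m = 20 this gives CT 590 / IT 610 in
    positive subsets and CT 610 / IT 590 in negative ones).
    """

    ct_mean: float = 600.0
    it_mean: float = 600.0
    nt_mean: float = 600.0
    rt_sd: float = 30.0
    n_subsets: int = 1
    switch_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be non-negative")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")

    @property
    def bias(self) -> float:
        """Constant implied bias (only meaningful when n_subsets == 1)."""
        return self.it_mean - self.ct_mean


@dataclass(frozen=True)
class SubsetPlan:
    """Piecewise-constant bias regimes over one session.

    ``boundaries[k]`` is the (1-based, inclusive) last trial position of
    subset ``k + 1``; ``ct_means[k]`` / ``it_means[k]`` are the per-type RT
    means in force there. ``subset_ids`` maps every position to its subset
    (1-based). Subset signs alternate starting positive.
    """

    boundaries: tuple[int, ...]
    ct_means: tuple[float, ...]
    it_means: tuple[float, ...]
    subset_ids: np.ndarray = field(repr=False, compare=False)

    @property
    def n_subsets(self) -> int:
        return len(self.boundaries)


@dataclass(frozen=True)
class TrialRecord:
    """One DPT trial (row view of a dataset)."""

    position: int
    trial_type: str
    rt: float
    subset_id: int
    included: bool


@dataclass
class DPTDataset:
    """One simulated participant: an ordered DPT session, column-wise.

    Attributes
    ----------
    layout
        The task layout the session follows.
    trial_types
        int8 array of type codes (0 = CT, 1 = IT, 2 = NT), in session order.
    rt
        float array of reaction times (ms), in session order.
    subset_ids
        int array of 1-based bias-subset ids per trial.
    included
        bool array of inclusion flags; all True until a filter runs.
    """

    layout: TaskLayout
    trial_types: np.ndarray
    rt: np.ndarray
    subset_ids: np.ndarray
    included: np.ndarray
    participant_id: str = "sim"
    group_label: str = "control"

    def __len__(self) -> int:
        return self.rt.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """1-based trial positions."""
        return np.arange(1, len(self) + 1)

    @property
    def type_names(self) -> np.ndarray:
        return _TYPE_NAMES[self.trial_types]

    @property
    def trials(self) -> Iterator[TrialRecord]:
        names = self.type_names
        for i in range(len(self)):
            yield TrialRecord(
                position=i + 1,
                trial_type=str(names[i]),
                rt=float(self.rt[i]),
                subset_id=int(self.subset_ids[i]),
                included=bool(self.included[i]),
            )

    def with_included(self, included: np.ndarray) -> "DPTDataset":
        """Copy of the dataset with new inclusion flags."""
        return replace(self, included=np.asarray(included, dtype=bool).copy())

    def type_mask(self, trial_type: str) -> np.ndarray:
        return self.trial_types == _TYPE_CODES[trial_type]

    @staticmethod
    def from_trials(
        layout: TaskLayout,
        records: Sequence[tuple],
        participant_id: str = "sim",
        group_label: str = "control",
    ) -> "DPTDataset":
        """Build a dataset from ``(trial_type, rt)`` or
        ``(trial_type, rt, subset_id)`` tuples in session order."""
        types = np.array([_TYPE_CODES[r[0]] for r in records], dtype=np.int8)
        rts = np.array([r[1] for r in records], dtype=float)
        subsets = np.array(
            [r[2] if len(r) > 2 else 1 for r in records], dtype=np.int64
        )
        return DPTDataset(
            layout=layout,
            trial_types=types,
            rt=rts,
            subset_ids=subsets,
            included=np.ones(len(records), dtype=bool),
            participant_id=participant_id,
            group_label=group_label,
        )


def _as_generator(rng: np.random.Generator | np.random.SeedSequence | int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_trial_sequence(
    layout: TaskLayout, rng: np.random.Generator | np.random.SeedSequence | int
) -> np.ndarray:
    """Uniformly random ordering of the layout's CT/IT/NT trials.

    Returns an int8 array of type codes of length ``layout.n_trials``;
    deterministic for a given generator state.
    """
    rng = _as_generator(rng)
    seq = np.concatenate([
        np.full(layout.n_ct, CT, dtype=np.int8),
        np.full(layout.n_it, IT, dtype=np.int8),
        np.full(layout.n_nt, NT, dtype=np.int8),
    ])
    return rng.permutation(seq)


def build_subset_plan(
    layout: TaskLayout, spec: GroupSpec, sequence: np.ndarray
) -> SubsetPlan:
    """Assign every session position to a bias subset and set subset means.

    Switch placement divides ``layout.switch_base`` by ``spec.n_subsets``:
    for the ABV layout all 160 positions are divided directly (e.g. three
    subsets end at positions 53, 106 and 160, the last absorbing leftover
    trials); for the TL-BS layout a switch falls after every
    ``floor(40 / n_subsets)``-th CT-or-IT trial and NT trials inherit the
    regime in force around them.

    Subset k (1-based) carries bias sign ``+`` for odd k and ``-`` for even
    k, with CT/IT means placed symmetrically around the spec's midpoint so
    that ``it_mean - ct_mean = ±switch_magnitude``.
    """
    n = spec.n_subsets
    sequence = np.asarray(sequence)
    n_positions = sequence.shape[0]
    if n > min(layout.n_ct, layout.n_it):
        raise ValueError(
            f"too many subsets: {n} exceeds available trials of one type"
        )

    span = layout.switch_base // n
    if layout.variant is Variant.ABV_STYLE:
        # divide all session positions directly
        counts_before = np.arange(n_positions)
    else:
        # divide the CT+IT trials; NT inherits the current regime
        is_ct_it = sequence != NT
        counts_before = np.cumsum(is_ct_it) - is_ct_it  # CT/IT trials strictly before
    subset_ids = np.minimum(counts_before // span + 1, n).astype(np.int64)

    # inclusive last position of each subset
    boundaries = tuple(
        int(np.max(np.nonzero(subset_ids == k)[0]) + 1) for k in range(1, n + 1)
    )

    if n == 1 and spec.switch_magnitude == 0:
        ct_means, it_means = (spec.ct_mean,), (spec.it_mean,)
    else:
        mid = 0.5 * (spec.ct_mean + spec.it_mean)
        half = 0.5 * spec.switch_magnitude
        signs = np.where(np.arange(1, n + 1) % 2 == 1, 1.0, -1.0)
        ct_means = tuple(mid - s * half for s in signs)
        it_means = tuple(mid + s * half for s in signs)

    return SubsetPlan(
        boundaries=boundaries,
        ct_means=ct_means,
        it_means=it_means,
        subset_ids=subset_ids,
    )


def generate_dataset(
    layout: TaskLayout,
    spec: GroupSpec,
    rng: np.random.Generator | np.random.SeedSequence | int,
    participant_id: str = "sim",
    group_label: str = "control",
) -> DPTDataset:
    """Generate one participant's session.

    Trial order is a uniform random permutation; each trial's RT is an
    independent normal draw with SD ``spec.rt_sd`` and mean given by its
    type and bias subset (NT trials always use ``spec.nt_mean``). Drawing
    per trial after ordering is distributionally identical to drawing each
    homogeneous batch at once and scattering it over the matching positions.
    """
    rng = _as_generator(rng)
    sequence = make_trial_sequence(layout, rng)
    plan = build_subset_plan(layout, spec, sequence)

    sub0 = plan.subset_ids - 1
    means = np.where(
        sequence == NT,
        spec.nt_mean,
        np.where(
            sequence == CT,
            np.asarray(plan.ct_means)[sub0],
            np.asarray(plan.it_means)[sub0],
        ),
    )
    rts = rng.normal(means, spec.rt_sd)
    return DPTDataset(
        layout=layout,
        trial_types=sequence,
        rt=rts,
        subset_ids=plan.subset_ids,
        included=np.ones(sequence.shape[0], dtype=bool),
        participant_id=participant_id,
        group_label=group_label,
    )
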