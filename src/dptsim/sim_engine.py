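"""Monte-Carlo simulation engine.

Five simulation series probe what each attention-bias index responds to.
Each series runs 10 parameter levels ("runs"); each run simulates many
two-group "studies" (26 change + 26 control participants); each
participant is one synthetic DPT session. Per study and index, the groups
are compared with a Welch t-test; the outcome per run is the percentage of
studies with p < .05.

Series (change group per run r = 1..10; control always at start values
M = 600 ms, SD = 30 ms):

* ``MEAN`` — CT and IT means 600 + 20(r-1); no bias anywhere.
* ``SD`` — RT SD 30 + 2(r-1); no bias anywhere.
* ``BIAS`` — static bias 3(r-1): CT 600 - 1.5(r-1), IT 600 + 1.5(r-1).
* ``DYN_FREQ`` — r alternating ±20 bias subsets (r-1 sign switches);
  control holds a constant +20 bias.
* ``DYN_MAG`` — both groups 4 alternating subsets; change amplitude
  20 + 3(r-1), control amplitude 20.

In the MEAN and SD series the NT mean/SD follow the CT/IT manipulation so
that the whole session shifts together; NT trials never enter any index.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dptsim.bias_indices import abv, traditional_bi
from dptsim.preprocess import filter_bounds, filter_dataset
from dptsim.synthetic_dpt import DPTDataset, GroupSpec, TaskLayout, Variant, generate_dataset
from dptsim.tlbs import pair_trials, tlbs_summary

__all__ = [
    "Series",
    "RunSpec",
    "WelchResult",
    "StudyResult",
    "run_spec",
    "welch_t",
    "percent_significant",
    "simulate_study",
    "run_series",
    "index_names",
]

START_MEAN = 600.0
START_SD = 30.0
N_PER_GROUP = 26
ALPHA = 0.05


class Series(str, enum.Enum):
    MEAN = "mean"
    SD = "sd"
    BIAS = "bias"
    DYN_FREQ = "dyn_freq"
    DYN_MAG = "dyn_mag"


@dataclass(frozen=True)
class RunSpec:
    """Generative parameters of one run of one series."""

    series: Series
    method: Variant
    r: int
    change_spec: GroupSpec
    control_spec: GroupSpec

    @property
    def layout(self) -> TaskLayout:
        return TaskLayout.for_variant(self.method)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class StudyResult:
    """One two-group comparison: per-index group values and Welch tests."""

    spec: RunSpec
    change_values: Mapping[str, np.ndarray]
    control_values: Mapping[str, np.ndarray]
    tests: Mapping[str, WelchResult]
    n_missing_change: Mapping[str, int] = field(default_factory=dict)
    n_missing_control: Mapping[str, int] = field(default_factory=dict)


def index_names(method: Variant) -> list[str]:
    """Indices computed under a method: BI always; ABV for the ABV layout;
    the five TL-BS indices for the TL-BS layout."""
    if Variant(method) is Variant.ABV_STYLE:
        return ["bi", "abv"]
    return [
        "bi",
        "tlbs_mean_pos",
        "tlbs_peak_pos",
        "tlbs_mean_neg",
        "tlbs_peak_neg",
        "tlbs_variability",
    ]


def run_spec(series: Series | str, method: Variant | str, r: int) -> RunSpec:
    """Change/control generative specs for run ``r`` of a series."""
    series = Series(series)
    method = Variant(method)
    if not 1 <= r <= 10:
        raise ValueError(f"run index must be in 1..10, got {r}")

    control = GroupSpec()
    if series is Series.MEAN:
        m = START_MEAN + 20.0 * (r - 1)
        change = GroupSpec(ct_mean=m, it_mean=m, nt_mean=m)
    elif series is Series.SD:
        sd = START_SD + 2.0 * (r - 1)
        change = GroupSpec(rt_sd=sd)
    elif series is Series.BIAS:
        half = 1.5 * (r - 1)
        change = GroupSpec(ct_mean=START_MEAN - half, it_mean=START_MEAN + half)
    elif series is Series.DYN_FREQ:
        change = GroupSpec(n_subsets=r, switch_magnitude=20.0)
        control = GroupSpec(ct_mean=590.0, it_mean=610.0)  # constant +20 bias
    elif series is Series.DYN_MAG:
        change = GroupSpec(n_subsets=4, switch_magnitude=20.0 + 3.0 * (r - 1))
        control = GroupSpec(n_subsets=4, switch_magnitude=20.0)
    else:  # pragma: no cover
        raise ValueError(f"unknown series: {series}")
    return RunSpec(series=series, method=method, r=r, change_spec=change, control_spec=control)


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    Missing (NaN) values are dropped per group; with fewer than two
    remaining values in either group the test is undefined (all NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return WelchResult(float("nan"), float("nan"), float("nan"))
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def percent_significant(pvals: Sequence[float], alpha: float = ALPHA) -> float:
    """100 * #(p < alpha) / #defined; NaN entries leave the denominator."""
    p = np.asarray(pvals, dtype=float)
    defined = p[~np.isnan(p)]
    if defined.size == 0:
        return float("nan")
    return float(100.0 * np.count_nonzero(defined < alpha) / defined.size)


def _dataset_indices(ds: DPTDataset) -> dict[str, float]:
    # BI uses the absolute-bounds exclusions only; the SD gates are part of
    # the ABV / TL-BS methodologies and apply to those indices alone
    out = {"bi": traditional_bi(filter_bounds(ds))}
    ds = filter_dataset(ds)
    if ds.layout.variant is Variant.ABV_STYLE:
        out["abv"] = abv(ds)
    else:
        s = tlbs_summary(pair_trials(ds))
        out["tlbs_mean_pos"] = s.mean_pos
        out["tlbs_peak_pos"] = s.peak_pos
        out["tlbs_mean_neg"] = s.mean_neg
        out["tlbs_peak_neg"] = s.peak_neg
        out["tlbs_variability"] = s.variability
    return out


def simulate_study(
    spec: RunSpec,
    n_per_group: int = N_PER_GROUP,
    rng: np.random.Generator | np.random.SeedSequence | int | None = None,
) -> StudyResult:
    """Simulate one study: ``n_per_group`` datasets per group, filtered and
    reduced to indices, then one Welch t-test per index."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layout = spec.layout
    names = index_names(spec.method)

    groups: dict[str, dict[str, np.ndarray]] = {}
    for label, gspec in (("change", spec.change_spec), ("control", spec.control_spec)):
        vals = {name: np.empty(n_per_group) for name in names}
        for i in range(n_per_group):
            ds = generate_dataset(layout, gspec, rng, group_label=label)
            for name, v in _dataset_indices(ds).items():
                vals[name][i] = v
        groups[label] = vals

    tests = {
        name: welch_t(groups["change"][name], groups["control"][name])
        for name in names
    }
    return StudyResult(
        spec=spec,
        change_values=groups["change"],
        control_values=groups["control"],
        tests=tests,
        n_missing_change={
            n: int(np.isnan(groups["change"][n]).sum()) for n in names
        },
        n_missing_control={
            n: int(np.isnan(groups["control"][n]).sum()) for n in names
        },
    )


def run_studies(
    spec: RunSpec,
    n_studies: int,
    seed: np.random.SeedSequence | int,
    n_per_group: int = N_PER_GROUP,
) -> list[StudyResult]:
    """All studies of one run, each from an independent child seed."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        simulate_study(spec, n_per_group=n_per_group, rng=np.random.default_rng(child))
        for child in root.spawn(n_studies)
    ]


def summarize_run(spec: RunSpec, studies: Sequence[StudyResult]) -> pd.DataFrame:
    """One row per index: % significant, per-group mean index values, and
    missing-value tallies over a run's studies."""
    rows = []
    for name in index_names(spec.method):
        pvals = [s.tests[name].p for s in studies]
        change = np.concatenate([s.change_values[name] for s in studies])
        control = np.concatenate([s.control_values[name] for s in studies])
        rows.append(
            {
                "series": spec.series.value,
                "method": spec.method.value,
                "run": spec.r,
                "index_name": name,
                "pct_significant": percent_significant(pvals),
                "mean_change": float(np.nanmean(change)),
                "mean_control": float(np.nanmean(control)),
                "n_missing_change": sum(s.n_missing_change[name] for s in studies),
                "n_missing_control": sum(s.n_missing_control[name] for s in studies),
            }
        )
    return pd.DataFrame(rows)


def run_series(
    series: Series | str,
    method: Variant | str,
    n_runs: int = 10,
    n_studies: int = 1000,
    seed: np.random.SeedSequence | int = 0,
    n_per_group: int = N_PER_GROUP,
) -> pd.DataFrame:
    """Run a full series: ``n_runs`` runs of ``n_studies`` studies each.

    Seeding: the root seed spawns one child sequence per run, which spawns
    one grandchild per study, so any (run, study) cell is independently
    reproducible from the root seed.

    Returns a long-format frame with one row per (run, index).
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    run_seeds = root.spawn(n_runs)
    frames = []
    for r, run_seed in zip(range(1, n_runs + 1), run_seeds):
        spec = run_spec(series, method, r)
        studies = run_studies(spec, n_studies, run_seed, n_per_group=n_per_group)
        frames.append(summarize_run(spec, studies))
    return pd.concat(frames, ignore_index=True)
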