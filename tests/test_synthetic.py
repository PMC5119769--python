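"""Synthetic DPT dataset generation: trial sequences, bias-subset plans,
and normal RT draws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dptsim.synthetic_dpt import (
    CT,
    IT,
    NT,
    DPTDataset,
    GroupSpec,
    TaskLayout,
    Variant,
    build_subset_plan,
    generate_dataset,
    make_trial_sequence,
)


class TestTrialSequence:
    @pytest.mark.parametrize(
        "layout_name, total, counts",
        [("abv", 160, (64, 64, 32)), ("tlbs", 60, (20, 20, 20))],
    )
    def test_counts_match_layout(self, layout_name, total, counts):
        layout = TaskLayout.for_variant(layout_name)
        seq = make_trial_sequence(layout, np.random.default_rng(0))
        assert seq.shape == (total,)
        assert tuple(np.bincount(seq, minlength=3)) == counts

    def test_same_seed_same_sequence(self):
        layout = TaskLayout.abv_style()
        a = make_trial_sequence(layout, np.random.default_rng(42))
        b = make_trial_sequence(layout, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_order_is_random_across_seeds(self):
        layout = TaskLayout.abv_style()
        a = make_trial_sequence(layout, np.random.default_rng(1))
        b = make_trial_sequence(layout, np.random.default_rng(2))
        assert not np.array_equal(a, b)


class TestSubsetPlan:
    def test_abv_three_subsets_boundaries(self):
        """160 positions divided by 3: switches after trials 53 and 106,
        the last subset absorbing the leftover trial."""
        layout = TaskLayout.abv_style()
        spec = GroupSpec(n_subsets=3, switch_magnitude=40.0)
        seq = make_trial_sequence(layout, np.random.default_rng(0))
        plan = build_subset_plan(layout, spec, seq)
        assert plan.boundaries == (53, 106, 160)
        # alternating signs starting positive, symmetric around 600
        assert plan.it_means[0] - plan.ct_means[0] == pytest.approx(40.0)
        assert plan.it_means[1] - plan.ct_means[1] == pytest.approx(-40.0)
        assert plan.it_means[2] - plan.ct_means[2] == pytest.approx(40.0)

    def test_tlbs_eight_subsets_switch_every_fifth_ct_it_trial(self):
        layout = TaskLayout.tlbs_style()
        spec = GroupSpec(n_subsets=8, switch_magnitude=20.0)
        seq = make_trial_sequence(layout, np.random.default_rng(3))
        plan = build_subset_plan(layout, spec, seq)
        is_ct_it = seq != NT
        for k in range(1, 9):
            in_subset = plan.subset_ids == k
            assert int((is_ct_it & in_subset).sum()) == 5

    def test_single_subset_magnitude_20_gives_590_610(self):
        for layout in (TaskLayout.abv_style(), TaskLayout.tlbs_style()):
            spec = GroupSpec(n_subsets=1, switch_magnitude=20.0)
            seq = make_trial_sequence(layout, np.random.default_rng(0))
            plan = build_subset_plan(layout, spec, seq)
            assert plan.boundaries == (layout.n_trials,)
            assert plan.ct_means == (590.0,)
            assert plan.it_means == (610.0,)

    def test_single_subset_no_magnitude_uses_spec_means(self):
        layout = TaskLayout.tlbs_style()
        spec = GroupSpec(ct_mean=598.5, it_mean=601.5)
        seq = make_trial_sequence(layout, np.random.default_rng(0))
        plan = build_subset_plan(layout, spec, seq)
        assert plan.ct_means == (598.5,)
        assert plan.it_means == (601.5,)

    def test_too_many_subsets_raises(self):
        layout = TaskLayout.tlbs_style()
        seq = make_trial_sequence(layout, np.random.default_rng(0))
        with pytest.raises(ValueError, match="too many subsets"):
            build_subset_plan(layout, GroupSpec(n_subsets=21, switch_magnitude=20.0), seq)

    @settings(max_examples=40, deadline=None)
    @given(
        n_subsets=st.integers(min_value=1, max_value=16),
        variant=st.sampled_from(["abv", "tlbs"]),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_subsets_partition_session(self, n_subsets, variant, seed):
        """Subset ids are non-decreasing, cover 1..n, and sum of subset
        lengths equals the session length; signs alternate giving
        n_subsets - 1 switches."""
        layout = TaskLayout.for_variant(variant)
        spec = GroupSpec(n_subsets=n_subsets, switch_magnitude=20.0)
        seq = make_trial_sequence(layout, np.random.default_rng(seed))
        plan = build_subset_plan(layout, spec, seq)
        ids = plan.subset_ids
        assert ids.shape == (layout.n_trials,)
        assert np.all(np.diff(ids) >= 0)
        assert set(np.unique(ids)) == set(range(1, n_subsets + 1))
        lengths = np.bincount(ids)[1:]
        assert lengths.sum() == layout.n_trials
        assert plan.boundaries[-1] == layout.n_trials
        biases = np.array(plan.it_means) - np.array(plan.ct_means)
        assert np.count_nonzero(np.diff(np.sign(biases))) == n_subsets - 1
        assert biases[0] > 0


class TestGenerateDataset:
    def test_zero_variance_yields_exact_means(self):
        layout = TaskLayout.abv_style()
        ds = generate_dataset(layout, GroupSpec(rt_sd=0.0), np.random.default_rng(0))
        assert np.all(ds.rt == 600.0)

    def test_nt_mean_unaffected_by_subsets(self):
        """NT trials keep the NT mean in every bias subset."""
        layout = TaskLayout.abv_style()
        spec = GroupSpec(rt_sd=0.0, n_subsets=4, switch_magnitude=20.0)
        ds = generate_dataset(layout, spec, np.random.default_rng(0))
        assert np.all(ds.rt[ds.trial_types == NT] == 600.0)
        signs = np.where(ds.subset_ids % 2 == 1, 1.0, -1.0)
        assert np.all(ds.rt[ds.trial_types == CT] == (600.0 - 10.0 * signs)[ds.trial_types == CT])
        assert np.all(ds.rt[ds.trial_types == IT] == (600.0 + 10.0 * signs)[ds.trial_types == IT])

    def test_same_seed_identical_dataset(self):
        layout = TaskLayout.tlbs_style()
        spec = GroupSpec(ct_mean=590, it_mean=610)
        a = generate_dataset(layout, spec, np.random.default_rng(7))
        b = generate_dataset(layout, spec, np.random.default_rng(7))
        assert np.array_equal(a.trial_types, b.trial_types)
        assert np.array_equal(a.rt, b.rt)

    def test_counts_match_layout_before_filtering(self, rng):
        layout = TaskLayout.tlbs_style()
        ds = generate_dataset(layout, GroupSpec(), rng)
        assert tuple(np.bincount(ds.trial_types, minlength=3)) == (20, 20, 20)
        assert np.all(ds.included)

    def test_sample_bias_converges_to_spec(self, rng):
        """With 10 000 trials per type, the sample IT-CT mean difference is
        within 3 analytic standard errors (sd * sqrt(2/n)) of the implied
        bias of 20."""
        n = 10_000
        layout = TaskLayout(
            variant=Variant.TLBS_STYLE, n_ct=n, n_it=n, n_nt=0,
            rt_floor=200, rt_ceiling=1500, sd_multiplier=3,
            switch_base=2 * n, max_pair_distance=5,
        )
        ds = generate_dataset(layout, GroupSpec(ct_mean=590, it_mean=610), rng)
        diff = ds.rt[ds.trial_types == IT].mean() - ds.rt[ds.trial_types == CT].mean()
        se = 30.0 * np.sqrt(2.0 / n)
        assert abs(diff - 20.0) < 3 * se

    def test_per_type_moments_converge(self, rng):
        """Empirical per-type mean and SD approach spec values at n = 1e5."""
        n = 100_000
        layout = TaskLayout(
            variant=Variant.TLBS_STYLE, n_ct=n, n_it=n, n_nt=0,
            rt_floor=200, rt_ceiling=1500, sd_multiplier=3,
            switch_base=2 * n, max_pair_distance=5,
        )
        ds = generate_dataset(layout, GroupSpec(ct_mean=590, it_mean=610), rng)
        for code, mean in ((CT, 590.0), (IT, 610.0)):
            vals = ds.rt[ds.trial_types == code]
            assert vals.mean() == pytest.approx(mean, abs=3 * 30 / np.sqrt(n))
            assert vals.std(ddof=1) == pytest.approx(30.0, abs=3 * 30 / np.sqrt(2 * n))
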