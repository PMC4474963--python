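"""Trajectory reduction: classification, tether/contact stats, summaries."""

import numpy as np
import pandas as pd
import pytest

from pseudopod_ad.config import SimConfig
from pseudopod_ad.engine import Trajectory
from pseudopod_ad.metrics import (bond_count_distribution, classify,
                                  contact_stats, episodes, summarize,
                                  sweep_summary, tether_stats)

DT = 1e-3


def make_traj(bond_counts, termination="reached_x_stop", x=None, y=None,
              contact=None, area=None):
    """Synthetic trajectory with millisecond steps."""
    n = len(bond_counts)
    bond_counts = np.asarray(bond_counts, dtype=np.int64)
    centroid = np.zeros((n, 3))
    centroid[:, 0] = x if x is not None else np.linspace(0.0, n, n)
    if y is not None:
        centroid[:, 1] = y
    any_contact = (np.asarray(contact, dtype=bool) if contact is not None
                   else bond_counts > 0)
    areas = (np.asarray(area, dtype=float) if area is not None
             else np.zeros(n))
    cfg = SimConfig(dt=DT, max_steps=max(n, 1))
    return Trajectory(
        config=cfg, times=np.arange(n) * DT, dts=np.full(n, DT),
        centroid=centroid,
        bond_counts=bond_counts, contact_area=areas,
        any_contact=any_contact, min_gap=np.ones(n), speed=np.zeros(n),
        events=[object()] * int((np.diff(np.r_[0, bond_counts]) > 0).sum()),
        termination_reason=termination,
        per_node_contact_time=np.zeros(4),
        snapshot_times=np.zeros(0), snapshot_quat=np.zeros((0, 4)),
        snapshot_U=np.zeros((0, 3)), snapshot_Omega=np.zeros((0, 3)),
        snapshot_contact=np.zeros((0, 4), dtype=bool),
    )


class TestClassification:
    @pytest.mark.parametrize("counts,term,expected", [
        ([0, 0, 0, 0], "reached_x_stop", "no_bonds"),
        ([0, 1, 3, 5, 40], "firm_adhesion", "firm_first_contact"),
        ([0, 1, 3, 0, 0, 2, 10, 40], "firm_adhesion", "tether_then_firm"),
        ([0, 2, 3, 1, 0, 0, 0], "reached_x_stop", "tether_only"),
        ([0, 1, 0, 0], "max_steps", "censored"),
        ([0, 0], "max_steps", "censored"),
    ])
    def test_decision_table(self, counts, term, expected):
        assert classify(make_traj(counts, term)) == expected

    def test_classification_is_pure(self):
        t = make_traj([0, 1, 0, 0, 2, 0], "reached_x_stop")
        assert classify(t) == classify(t) == "tether_only"

    def test_gap_bridging_merges_episodes(self):
        counts = [0, 1, 2, 0, 3, 0, 0]
        assert len(episodes(counts, gap_steps=1)) == 2
        assert len(episodes(counts, gap_steps=2)) == 1


class TestTetherStats:
    def test_no_episodes(self):
        lifetimes, dists, max_y = tether_stats(make_traj([0, 0, 0], y=[0, 2, -3]))
        assert lifetimes == [] and dists == []
        assert max_y == 3.0

    def test_single_episode_lifetime_and_distance(self):
        # bonded on t in [10, 25) ms while x advances 12 um
        counts = np.zeros(40, dtype=int)
        counts[10:25] = 1
        x = np.zeros(40)
        x[10:26] = np.linspace(0.0, 12.0, 16)  # 12 um by detachment
        x[26:] = x[25]
        lifetimes, dists, _ = tether_stats(make_traj(counts, x=x))
        assert lifetimes == [pytest.approx(15e-3)]
        assert dists == [pytest.approx(12.0)]

    def test_two_episodes_against_brute_force(self):
        rng = np.random.default_rng(0)
        counts = np.array([0, 1, 1, 0, 0, 2, 3, 1, 0, 0])
        x = np.cumsum(rng.random(10))
        lifetimes, dists, _ = tether_stats(make_traj(counts, x=x))
        # brute-force scan of the count series
        assert lifetimes == [pytest.approx(2e-3), pytest.approx(3e-3)]
        assert dists == [pytest.approx(x[3] - x[1]), pytest.approx(x[8] - x[5])]

    def test_unfinished_episode_excluded(self):
        counts = [0, 1, 2, 5]  # still bonded at the end (firm run)
        lifetimes, dists, _ = tether_stats(make_traj(counts, "firm_adhesion"))
        assert lifetimes == [] and dists == []


class TestContactStats:
    def test_all_zero_without_contact(self):
        t = make_traj([0] * 5, contact=[False] * 5, area=[0.0] * 5)
        ct, areas, integral, node_t = contact_stats(t)
        assert ct == 0.0 and integral == 0.0
        assert np.all(areas == 0)

    def test_constant_area_integral(self):
        n, A = 50, 7.5
        t = make_traj([0] * n, contact=[True] * n, area=[A] * n)
        ct, _, integral, _ = contact_stats(t)
        assert ct == pytest.approx(n * DT)
        assert integral == pytest.approx(A * n * DT)

    def test_piecewise_series_against_brute_force(self):
        rng = np.random.default_rng(1)
        area = rng.random(30) * 10
        contact = area > 3
        area[~contact] = 0.0
        t = make_traj([0] * 30, contact=contact, area=area)
        ct, series, integral, _ = contact_stats(t)
        assert ct == pytest.approx(contact.sum() * DT)
        assert integral == pytest.approx(sum(a * DT for a in area))


class TestBondCountDistribution:
    def test_constant_count_episode(self):
        counts = np.zeros(14, dtype=int)
        counts[2:12] = 3
        table, mx = bond_count_distribution([make_traj(counts)])
        assert mx == 3
        assert table.bonds.tolist() == [3]
        assert table.cumulative_frequency.tolist() == [1.0]

    def test_hand_enumerated_cdf(self):
        counts = np.array([0, 1, 1, 2, 5, 0])
        table, mx = bond_count_distribution([make_traj(counts)])
        assert mx == 5
        assert table.bonds.tolist() == [1, 2, 5]
        np.testing.assert_allclose(table.cumulative_frequency, [0.5, 0.75, 1.0])

    def test_empty_trajectory_leaves_table_unchanged(self):
        counts = np.array([0, 1, 1, 2, 5, 0])
        t1, _ = bond_count_distribution([make_traj(counts)])
        t2, _ = bond_count_distribution([make_traj(counts), make_traj([0, 0])])
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_samples_flagged_empty(self):
        table, mx = bond_count_distribution([make_traj([0, 0, 0])])
        assert table.empty and mx == 0

    def test_cdf_monotone_ends_at_one(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 6, 200)
        counts[-1] = 0
        table, _ = bond_count_distribution([make_traj(counts)])
        cdf = table.cumulative_frequency.to_numpy()
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == pytest.approx(1.0)


class TestSweepSummary:
    def test_unanimous_condition_fraction(self):
        summ = [summarize(make_traj([0, 1, 5, 40], "firm_adhesion"))
                for _ in range(10)]
        table = sweep_summary({"c": summ})
        assert table.loc[0, "frac_firm_first_contact"] == 1.0
        assert table.loc[0, "n_runs"] == 10

    def test_mean_and_se_closed_form(self):
        trajs = []
        for L in (1, 2, 3):  # lifetimes 1, 2, 3 ms
            counts = np.zeros(8, dtype=int)
            counts[1:1 + L] = 1
            trajs.append(summarize(make_traj(counts)))
        table = sweep_summary({"c": trajs})
        assert table.loc[0, "tether_lifetime_mean"] == pytest.approx(2e-3)
        assert table.loc[0, "tether_lifetime_se"] == pytest.approx(
            np.std([1e-3, 2e-3, 3e-3], ddof=1) / np.sqrt(3))

    def test_identical_values_zero_se(self):
        counts = np.zeros(8, dtype=int)
        counts[1:4] = 2
        summ = [summarize(make_traj(counts)) for _ in range(4)]
        table = sweep_summary({"c": summ})
        assert table.loc[0, "tether_lifetime_se"] == 0.0
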