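"""Trajectory reduction: behaviour classification, tether statistics,
contact metrics and sweep summaries.

A *tethering episode* is a maximal contiguous interval of time steps with
at least one bond; a configurable gap (in steps, default 1) of zero-bond
steps ends an episode, so a momentary all-bonds-lost step that rebinds
immediately can be bridged by raising ``gap_steps``.

Behaviour categories:

``firm_first_contact``
    Run terminated firmly adhered and the cell never fully detached after
    its first bond.
``tether_then_firm``
    Firm termination after at least one complete detach-reattach cycle.
``tether_only``
    Bonds formed, all detached, and the cell left the study region.
``no_bonds``
    No bond ever formed.
``censored``
    The run hit the step budget before resolving (reported, not
    classified).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory
from .geometry import CellMesh

__all__ = [
    "BehaviorSummary",
    "episodes",
    "classify",
    "tether_stats",
    "contact_stats",
    "bond_count_distribution",
    "sweep_summary",
]

CATEGORIES = ("firm_first_contact", "tether_then_firm", "tether_only",
              "no_bonds", "censored")


@dataclass
class BehaviorSummary:
    """Outcome measures of a single run."""

    category: str
    tether_lifetimes: list[float]          # s, per episode
    tether_rolling_distances: list[float]  # um, per episode
    max_abs_y_displacement: float          # um
    bond_count_samples: np.ndarray         # bond counts during tethering
    contact_time: float                    # s
    contact_area_mean: float               # um^2, mean while in contact
    time_integral_contact_area: float      # um^2 * s
    per_node_contact_time: np.ndarray      # s

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "tether_lifetimes": list(map(float, self.tether_lifetimes)),
            "tether_rolling_distances": list(map(float, self.tether_rolling_distances)),
            "max_abs_y_displacement": float(self.max_abs_y_displacement),
            "n_bond_samples": int(len(self.bond_count_samples)),
            "max_bonds": int(self.bond_count_samples.max()) if len(self.bond_count_samples) else 0,
            "contact_time": float(self.contact_time),
            "contact_area_mean": float(self.contact_area_mean),
            "time_integral_contact_area": float(self.time_integral_contact_area),
        }


def episodes(bond_counts: np.ndarray, gap_steps: int = 1) -> list[tuple[int, int]]:
    """Maximal bonded intervals as half-open step ranges [start, end).

    Zero-bond gaps shorter than ``gap_steps`` do not split an episode.
    """
    bonded = np.asarray(bond_counts) > 0
    if not bonded.any():
        return []
    idx = np.flatnonzero(bonded)
    out = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap_steps:
            out.append((int(start), int(prev) + 1))
            start = i
        prev = i
    out.append((int(start), int(prev) + 1))
    return out


def classify(traj: Trajectory, gap_steps: int = 1) -> str:
    """Assign the behaviour category of a run (see module docstring)."""
    eps = episodes(traj.bond_counts, gap_steps)
    if not eps:
        return "no_bonds" if traj.termination_reason != "max_steps" else "censored"
    if traj.termination_reason == "firm_adhesion":
        # firm on first contact iff the run never fully detached after the
        # first bond, i.e. the firm episode is the first one
        return "firm_first_contact" if len(eps) == 1 else "tether_then_firm"
    if traj.termination_reason == "reached_x_stop":
        return "tether_only"
    return "censored"


def tether_stats(traj: Trajectory, gap_steps: int = 1):
    """Per-episode lifetimes (s) and rolling distances (um), plus the
    maximum |y| centroid excursion of the full trajectory.

    Only completed tether episodes count: an episode still bonded when the
    run ends (the firm episode of an arrested run, or a tether truncated
    at the stop line) has no detachment time and is excluded.
    """
    eps = episodes(traj.bond_counts, gap_steps)
    lifetimes, distances = [], []
    for s, e in eps:
        if e >= traj.n_steps:  # never detached before the run ended
            continue
        # episode spans step s through e-1; detachment happens at step e
        lifetimes.append(float(traj.dts[s:e].sum()))
        distances.append(float(traj.centroid[e, 0] - traj.centroid[s, 0]))
    max_abs_y = float(np.abs(traj.centroid[:, 1]).max()) if traj.n_steps else 0.0
    return lifetimes, distances, max_abs_y


def contact_stats(traj: Trajectory, mesh: CellMesh | None = None):
    """Contact time, instantaneous contact-area series, its time integral,
    and the per-node contact-time map."""
    contact_time = float(traj.dts[traj.any_contact].sum())
    area_series = traj.contact_area
    time_integral = float((area_series * traj.dts).sum())
    return contact_time, area_series, time_integral, traj.per_node_contact_time


def bond_count_distribution(trajs: list[Trajectory], gap_steps: int = 1):
    """Pooled instantaneous bond counts over all tethering episodes.

    Returns (table, max_bonds) where ``table`` is a DataFrame with columns
    ``bonds`` and ``cumulative_frequency`` (empty when no tether samples).
    """
    samples = []
    for traj in trajs:
        for s, e in episodes(traj.bond_counts, gap_steps):
            if e >= traj.n_steps:  # firm/truncated episode, not a tether
                continue
            samples.append(traj.bond_counts[s:e])
    if not samples:
        return pd.DataFrame(columns=["bonds", "cumulative_frequency"]), 0
    pooled = np.concatenate(samples)
    values, counts = np.unique(pooled, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    table = pd.DataFrame({"bonds": values, "cumulative_frequency": cdf})
    return table, int(values.max())


def summarize(traj: Trajectory, gap_steps: int = 1) -> BehaviorSummary:
    """Full outcome reduction of a single run."""
    lifetimes, distances, max_abs_y = tether_stats(traj, gap_steps)
    contact_time, area_series, integral, node_time = contact_stats(traj)
    in_contact = traj.any_contact
    area_mean = float(area_series[in_contact].mean()) if in_contact.any() else 0.0
    samples = []
    for s, e in episodes(traj.bond_counts, gap_steps):
        if e >= traj.n_steps:
            continue
        samples.append(traj.bond_counts[s:e])
    samples = np.concatenate(samples) if samples else np.zeros(0, dtype=np.int64)
    return BehaviorSummary(
        category=classify(traj, gap_steps),
        tether_lifetimes=lifetimes,
        tether_rolling_distances=distances,
        max_abs_y_displacement=max_abs_y,
        bond_count_samples=samples,
        contact_time=contact_time,
        contact_area_mean=area_mean,
        time_integral_contact_area=integral,
        per_node_contact_time=node_time,
    )


def _mean_se(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return np.nan, np.nan
    se = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
    return float(arr.mean()), float(se)


def sweep_summary(groups: dict[object, list[BehaviorSummary]]) -> pd.DataFrame:
    """Per-condition behaviour fractions and mean +/- SE of each metric.

    ``groups`` maps a condition label (e.g. the shear rate) to the run
    summaries obtained under that condition.
    """
    rows = []
    for label, summaries in groups.items():
        n = len(summaries)
        row = {"condition": label, "n_runs": n}
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = sum(s.category == cat for s in summaries) / n
        lifetimes = [lt for s in summaries for lt in s.tether_lifetimes]
        dists = [d for s in summaries for d in s.tether_rolling_distances]
        ys = [s.max_abs_y_displacement for s in summaries]
        for name, vals in (("tether_lifetime", lifetimes),
                           ("tether_rolling_distance", dists),
                           ("max_abs_y", ys)):
            m, se = _mean_se(vals)
            row[f"{name}_mean"] = m
            row[f"{name}_se"] = se
        maxb = [int(s.bond_count_samples.max()) for s in summaries
                if len(s.bond_count_samples)]
        row["max_bonds_in_tether"] = max(maxb) if maxb else 0
        rows.append(row)
    return pd.DataFrame(rows)
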