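"""Greedy allocation of new monitoring sites to under-monitored clusters.

Given per-cluster counts of current monitors, subject residences, and
candidate spots, new sites are placed one at a time: each step restricts to
clusters that still have candidates (and any subjects at all), picks the
cluster with the minimum current-to-subject proportion, places one site
there, and — crucially — counts the placed site as a current location from
the next step on, so the proportion is recomputed before every pick.  A
cluster that runs out of candidates drops out of contention regardless of
its proportion.

Proportions are compared unrounded; for display they are multiplied by
10⁴ and shown to one or two decimals, matching how such tables are
conventionally printed.  Within the chosen cluster the concrete candidate
location is drawn uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusterCounts", "AllocationResult", "current_subject_ratio",
           "allocate", "pick_candidate"]


@dataclass
class ClusterCounts:
    """Per-cluster current/subject/candidate counts.

    ``counts`` has columns ``cluster``, ``n_current``, ``n_subject``,
    ``n_candidate``; cluster labels are arbitrary hashables (the printed
    tables use 1-based integers).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cluster", "n_current", "n_subject", "n_candidate"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.counts[["n_current", "n_subject", "n_candidate"]] < 0).any().any():
            raise ValueError("counts must be non-negative")
        if self.counts["cluster"].duplicated().any():
            raise ValueError("duplicate cluster labels")

    @classmethod
    def from_assignment(cls, locations: pd.DataFrame,
                        assignment: np.ndarray) -> "ClusterCounts":
        """Tabulate role counts per cluster from a clustered location table."""
        df = locations[["id", "role"]].copy()
        df["cluster"] = np.asarray(assignment)
        tab = (df.pivot_table(index="cluster", columns="role", values="id",
                              aggfunc="count", fill_value=0)
               .reindex(columns=["current", "subject", "candidate"],
                        fill_value=0)
               .reset_index())
        tab.columns = ["cluster", "n_current", "n_subject", "n_candidate"]
        return cls(tab)

    @classmethod
    def from_fixture(cls, fixture) -> "ClusterCounts":
        return cls(fixture.counts.copy())

    @classmethod
    def from_csv(cls, path) -> "ClusterCounts":
        return cls(pd.read_csv(path))


def current_subject_ratio(n_current, n_subject):
    """Current-to-subject proportion on the display scale, ×10⁴.

    Accepts scalars or arrays; zero subjects is an error (a cluster with no
    subjects has no representation deficit to measure).
    """
    n_current = np.asarray(n_current, dtype=float)
    n_subject = np.asarray(n_subject, dtype=float)
    if np.any(n_subject <= 0):
        raise ValueError("n_subject must be positive")
    out = 1e4 * n_current / n_subject
    return float(out) if out.ndim == 0 else out


@dataclass
class AllocationResult:
    """Outcome of a greedy allocation run.

    ``new_sites`` maps cluster label to number of sites placed there;
    ``picks`` logs one row per placement (``step``, ``cluster``,
    ``ratio_before_pick`` — the unrounded current/subject proportion that
    won the argmin).  ``chosen_ids`` holds concrete candidate location ids
    when a candidate pool was supplied.
    """

    new_sites: dict
    picks: pd.DataFrame
    chosen_ids: list = field(default_factory=list)

    @property
    def n_placed(self) -> int:
        return int(sum(self.new_sites.values()))


def allocate(counts: ClusterCounts, n_new: int = 20,
             tie_rule: str = "lowest_index", seed: int | None = None,
             candidate_pools: dict | None = None) -> AllocationResult:
    """Place ``n_new`` sites by iterated minimum current/subject proportion.

    ``tie_rule`` breaks equal proportions: ``"lowest_index"`` (default,
    deterministic — both printed applications are invariant to the choice)
    or ``"random"`` (seeded).  ``candidate_pools`` optionally maps cluster
    label to a list of candidate location ids; when given, each pick also
    draws a concrete id uniformly without replacement (seeded).
    """
    if tie_rule not in ("lowest_index", "random"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    df = counts.counts.reset_index(drop=True)
    clusters = df["cluster"].tolist()
    cur = df["n_current"].to_numpy(dtype=float).copy()
    sub = df["n_subject"].to_numpy(dtype=float)
    cand = df["n_candidate"].to_numpy(dtype=int).copy()

    eligible_total = int(cand[(sub > 0)].sum())
    if eligible_total < n_new:
        raise ValueError(
            f"only {eligible_total} candidates available in eligible "
            f"clusters; cannot place {n_new} sites")

    rng = np.random.default_rng(seed)
    pools = {c: list(v) for c, v in (candidate_pools or {}).items()}
    new = dict.fromkeys(clusters, 0)
    log, chosen = [], []
    for step in range(1, n_new + 1):
        elig = np.nonzero((cand > 0) & (sub > 0))[0]
        ratios = cur[elig] / sub[elig]
        winners = elig[ratios == ratios.min()]
        i = (int(winners[0]) if tie_rule == "lowest_index"
             else int(rng.choice(winners)))
        label = clusters[i]
        log.append({"step": step, "cluster": label,
                    "ratio_before_pick": cur[i] / sub[i]})
        if pools.get(label):
            j = int(rng.integers(len(pools[label])))
            chosen.append(pools[label].pop(j))
        new[label] += 1
        cand[i] -= 1
        cur[i] += 1  # a placed site becomes a current location
    picks = pd.DataFrame(log)
    return AllocationResult(new_sites=new, picks=picks, chosen_ids=chosen)


def pick_candidate(cluster, candidate_pool: list, seed: int | None = None):
    """Uniform draw of one candidate id from a cluster's pool (seeded)."""
    if not len(candidate_pool):
        raise ValueError(f"empty candidate pool for cluster {cluster!r}")
    rng = np.random.default_rng(seed)
    return candidate_pool[int(rng.integers(len(candidate_pool)))]
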