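"""Clustering robustness via subsampling and the adjusted Rand index.

The full-data clustering is compared against clusterings of repeated 90%
subsamples: per replicate, 10% of locations are removed at random, k-means
is rerun on the remainder, and the agreement with the full-data partition
(restricted to the retained locations) is summarised by the
Hubert–Arabie adjusted Rand index.  Values above 0.90 / 0.80 / 0.65 are
conventionally read as excellent / good / moderate agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster_engine import kmeans_best

__all__ = ["StabilityReport", "adjusted_rand", "subsample_stability"]

AGREEMENT_BANDS = (("excellent", 0.90), ("good", 0.80), ("moderate", 0.65))


@dataclass
class StabilityReport:
    indices: np.ndarray
    mean: float
    min: float
    max: float
    frac_excellent: float      # fraction of replicates with ARI >= 0.90
    frac_below_moderate: float  # fraction with ARI < 0.65

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"replicate": np.arange(1, len(self.indices) + 1),
                             "ari": self.indices})

    def summary(self) -> str:
        return (f"adjusted Rand over {len(self.indices)} replicates: "
                f"mean {self.mean:.3f} (range {self.min:.3f}-{self.max:.3f}); "
                f"{100 * self.frac_excellent:.0f}% excellent (>=0.90), "
                f"{100 * self.frac_below_moderate:.0f}% below moderate (<0.65)")


def adjusted_rand(assignment_a, assignment_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Chance-corrected pair-counting agreement: 1 for identical partitions
    (up to relabeling), about 0 for independent ones.  Both assignments
    must cover the same locations in the same order.
    """
    a = np.asarray(assignment_a)
    b = np.asarray(assignment_b)
    if a.shape != b.shape:
        raise ValueError(f"partition sizes differ: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def subsample_stability(X_scaled, K: int, full_assignment,
                        n_reps: int = 100, keep_frac: float = 0.90,
                        n_restarts: int = 1000, seed: int = 0,
                        ) -> StabilityReport:
    """Adjusted Rand of ``n_reps`` subsample clusterings vs the full solution.

    Each replicate keeps ``keep_frac`` of the locations (drawn without
    replacement), reruns :func:`kmeans_best`, and scores agreement against
    the full-data assignment restricted to the retained locations.
    Replicate seeds derive from the master seed, so individual replicates
    are reproducible.
    """
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must lie in (0, 1]")
    X = np.asarray(X_scaled, dtype=float)
    full = np.asarray(full_assignment)
    if len(full) != len(X):
        raise ValueError("full_assignment does not cover X_scaled")
    n_keep = int(round(keep_frac * len(X)))
    master = np.random.SeedSequence(seed)
    sub_seeds = master.generate_state(2 * n_reps) % (2 ** 31)
    indices = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(sub_seeds[2 * rep])
        keep = rng.choice(len(X), size=n_keep, replace=False)
        sol = kmeans_best(X[keep], K, n_restarts=n_restarts,
                          seed=int(sub_seeds[2 * rep + 1]))
        indices[rep] = adjusted_rand(full[keep], sol.assignment)
    return StabilityReport(
        indices=indices, mean=float(indices.mean()),
        min=float(indices.min()), max=float(indices.max()),
        frac_excellent=float((indices >= 0.90).mean()),
        frac_below_moderate=float((indices < 0.65).mean()))
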