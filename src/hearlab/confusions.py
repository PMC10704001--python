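"""Consonant confusion matrices, score groups, and agglomerative clustering.

Confusion analysis follows the Miller–Nicely tradition: consonants presented
in C/a/ context are tallied presented-by-responded, and sets of mutually
confused consonants are extracted by hierarchical agglomerative clustering.
The pairwise similarity is the symmetrized off-diagonal confusion
probability ``(p(i->j) + p(j->i)) / 2``; distances are ``1 - s / max(s)``.
The agglomeration threshold is swept to the largest value that yields a
requested number of clusters (singletons included in the count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

#: The 16-consonant inventory (C/a/ context).
CONSONANTS = (
    "p", "t", "k", "b", "d", "g", "m", "n",
    "f", "θ", "s", "ʃ", "v", "ð", "z", "ʒ",
)

#: Score groups reported in the consonant-identification literature:
#: C1 lowest scores, C3 intermediate, C2 highest.
SCORE_GROUPS = {
    "C1": frozenset({"f", "θ", "v", "ð", "b", "m"}),
    "C3": frozenset({"n", "p", "g", "k", "d"}),
    "C2": frozenset({"t", "s", "z", "ʃ", "ʒ"}),
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Presented-by-responded response counts over a consonant inventory."""

    labels: tuple
    counts: np.ndarray  # (n_labels, n_labels) non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the labels")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_records(cls, records, labels=CONSONANTS) -> "ConfusionMatrix":
        """Tally (presented, responded) pairs; unknown labels raise."""
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for presented, responded in records:
            try:
                counts[index[presented], index[responded]] += 1
            except KeyError as err:
                raise ValueError(f"unknown consonant label {err.args[0]!r}") from None
        return cls(labels=tuple(labels), counts=counts)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConfusionMatrix":
        """Read a labeled square count table (rows presented, columns responded)."""
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels must match")
        return cls(labels=tuple(df.index), counts=df.to_numpy().astype(int))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    @property
    def row_probs(self) -> np.ndarray:
        """Row-normalized probabilities; rows without presentations are NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    @property
    def accuracy(self) -> float:
        """Overall proportion correct, trace over total."""
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")


def build_confusion_matrix(records, labels=CONSONANTS) -> ConfusionMatrix:
    """Tally presented->responded records into a :class:`ConfusionMatrix`."""
    return ConfusionMatrix.from_records(records, labels=labels)


def consonant_group_scores(matrix: ConfusionMatrix, groups: dict | None = None) -> pd.Series:
    """Mean diagonal (correct-identification) probability per consonant group.

    Returns a Series sorted ascending, so the hardest group comes first.
    """
    groups = groups or SCORE_GROUPS
    probs = matrix.row_probs
    index = {lab: i for i, lab in enumerate(matrix.labels)}
    out = {}
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
        unknown = [m for m in members if m not in index]
        if unknown:
            raise ValueError(f"group {name!r} has unknown labels {unknown}")
        out[name] = float(np.mean([probs[index[m], index[m]] for m in members]))
    return pd.Series(out).sort_values(kind="stable")


@dataclass(frozen=True)
class Partition:
    """Cluster assignments with the merge trace that produced them."""

    labels: tuple
    assignments: tuple          # cluster id per label
    merge_heights: tuple        # non-decreasing agglomeration heights
    threshold: float
    n_clusters: int

    def clusters(self) -> list:
        """Cluster memberships as frozensets, largest first."""
        by_id: dict = {}
        for lab, cid in zip(self.labels, self.assignments):
            by_id.setdefault(cid, set()).add(lab)
        return sorted((frozenset(v) for v in by_id.values()), key=len, reverse=True)


def confusion_distances(matrix: ConfusionMatrix) -> np.ndarray:
    """Condensed distance vector from symmetrized off-diagonal confusions."""
    probs = np.nan_to_num(matrix.row_probs)
    sim = (probs + probs.T) / 2.0
    np.fill_diagonal(sim, 0.0)
    smax = sim.max()
    if smax <= 0:
        dist = np.ones_like(sim)
    else:
        dist = 1.0 - sim / smax
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def attainable_cluster_counts(matrix: ConfusionMatrix, method: str = "average") -> list:
    """Cluster counts reachable by sweeping the agglomeration threshold."""
    n = len(matrix.labels)
    Z = linkage(confusion_distances(matrix), method=method)
    heights = Z[:, 2]
    counts = {1}
    if heights[0] > 0:
        counts.add(n)
    for h in heights:
        assign = fcluster(Z, t=float(h), criterion="distance")
        counts.add(len(set(assign)))
    return sorted(counts)


def cluster_confusions(
    matrix: ConfusionMatrix,
    target_n_clusters: int,
    method: str = "average",
) -> Partition:
    """Agglomerative clustering of a confusion matrix.

    Consonants start as singletons and merge as the distance criterion is
    relaxed; the threshold is swept to the largest value that yields exactly
    ``target_n_clusters`` clusters (singletons counted).  Linkage is average
    by default; single and complete are also supported.  If no threshold
    yields the target (tied merge heights skip that count), a ``ValueError``
    lists the attainable counts.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")
    if not 1 <= target_n_clusters <= n:
        raise ValueError(f"target_n_clusters must lie in [1, {n}]")
    Z = linkage(confusion_distances(matrix), method=method)
    heights = Z[:, 2]
    # cutting at t merges all links with height <= t: clusters = n - #(h <= t)
    if target_n_clusters == n:
        threshold = float(np.nextafter(heights[0], -np.inf)) if heights[0] > 0 else -1.0
    else:
        threshold = float(heights[n - target_n_clusters - 1])
    assign = fcluster(Z, t=threshold, criterion="distance")
    got = len(set(assign))
    if got != target_n_clusters:
        # tied merge heights skipped this count
        raise ValueError(
            f"{target_n_clusters} clusters unattainable (tied merge heights); "
            f"attainable counts: {attainable_cluster_counts(matrix, method=method)}"
        )
    return Partition(
        labels=tuple(matrix.labels),
        assignments=tuple(int(a) for a in assign),
        merge_heights=tuple(float(h) for h in heights),
        threshold=float(threshold),
        n_clusters=got,
    )
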