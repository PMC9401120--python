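"""Dissimilarity-based clustering and supervised classification of repertoires.

A cohort of sub-repertoires (e.g. X_top, CN > 64) is turned into a
dissimilarity matrix using d_V,J (V and J identity, equally weighted) or d_NC
(the variant-count relation). Samples are then

* clustered into k groups with PAM (K-medoids: BUILD + SWAP on the
  precomputed matrix),
* embedded in the plane with classical metric MDS for visualization, and
* classified supervised by leave-one-out: one medoid is fitted per label
  group on the training samples and the held-out sample takes the label of
  the nearer medoid. The confusion table is evaluated with Fisher's exact
  test against random labelling.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .indices import dissimilarity, nc_dissimilarity_spec, vj_dissimilarity_spec
from .types import DissimilaritySpec, SubRepertoire

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise ValueError("entries must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class ClassificationResult:
    sample_ids: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    confusion: np.ndarray  # 2x2, rows = true, cols = predicted
    fisher_p: float

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def dissimilarity_matrix(
    cohort: list[SubRepertoire],
    spec: str | DissimilaritySpec = "vj",
    weighted: bool = False,
) -> DissimilarityMatrix:
    """All-pairs dissimilarity under d_V,J ('vj'), d_NC ('nc') or a custom spec.

    Empty sub-repertoires are excluded with a warning (their RSI is undefined).
    """
    if spec == "vj":
        dspec = vj_dissimilarity_spec()
    elif spec == "nc":
        dspec = nc_dissimilarity_spec()
    elif isinstance(spec, DissimilaritySpec):
        dspec = spec
    else:
        raise ValueError(f"unknown dissimilarity spec {spec!r}")
    kept = []
    for s in cohort:
        if len(s) == 0:
            logger.warning("excluding %s: empty sub-repertoire", s.parent_id)
        else:
            kept.append(s)
    n = len(kept)
    if n < 2:
        raise ValueError("need >= 2 non-empty sub-repertoires")
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = dissimilarity(kept[i], kept[j], dspec, weighted=weighted)
        m[i, j] = m[j, i] = min(max(d, 0.0), 1.0)
    return DissimilarityMatrix([s.parent_id for s in kept], m)


# ---------------------------------------------------------------------------
# PAM (partitioning around medoids) on a precomputed matrix


def _pam_cost(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD initialization."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - d[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    return medoids


def kmedoids(
    m: DissimilarityMatrix | np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-medoids (PAM) on a precomputed dissimilarity matrix.

    When the medoid search space C(n, k) is small — true for every cohort
    analysed here — the optimal medoid set is found by exhaustive search.
    Otherwise greedy BUILD initialization is followed by SWAP steps until no
    single medoid exchange lowers the total within-cluster dissimilarity
    (so the result always satisfies the SWAP convergence condition). The
    seed deterministically breaks ties among equal-cost swap candidates.

    Returns (cluster assignments, medoid indices).
    """
    d = m.values if isinstance(m, DissimilarityMatrix) else np.asarray(m, dtype=float)
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    # small search spaces (every cohort in this package) are solved exactly;
    # the BUILD+SWAP heuristic only kicks in for large n
    from math import comb

    if comb(n, k) <= 20000:
        best_cost, best_medoids = np.inf, None
        for cand in itertools.combinations(range(n), k):
            cost = _pam_cost(d, np.array(cand))
            if cost < best_cost - 1e-15:
                best_cost, best_medoids = cost, cand
        medoid_arr = np.array(best_medoids)
        assignments = np.argmin(d[:, medoid_arr], axis=1)
        return assignments, medoid_arr
    medoids = _pam_build(d, k)
    rng = np.random.default_rng(seed)
    scan = rng.permutation(n)
    improved = True
    while improved:
        improved = False
        cost = _pam_cost(d, np.array(medoids))
        best = (0.0, None)
        for mi in range(k):
            for h in scan:
                h = int(h)
                if h in medoids:
                    continue
                cand = list(medoids)
                cand[mi] = h
                delta = _pam_cost(d, np.array(cand)) - cost
                if delta < best[0] - 1e-15:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            improved = True
    medoid_arr = np.array(sorted(medoids))
    assignments = np.argmin(d[:, medoid_arr], axis=1)
    return assignments, medoid_arr


def mds_embed(m: DissimilarityMatrix | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical metric MDS (principal coordinates) of a dissimilarity matrix.

    Orientation and sign of the axes are unconstrained; only inter-point
    distances are meaningful. An all-zero matrix embeds every point at the
    origin with a warning.
    """
    d = m.values if isinstance(m, DissimilarityMatrix) else np.asarray(m, dtype=float)
    n = d.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for {dims}-d embedding")
    if not d.any():
        logger.warning("degenerate (all-zero) dissimilarity matrix; embedding at origin")
        return np.zeros((n, dims))
    ids = [str(i) for i in range(n)]
    res = pcoa(DistanceMatrix(d, ids=ids), number_of_dimensions=dims)
    coords = res.samples.to_numpy()[:, :dims]
    if coords.shape[1] < dims:  # rank-deficient input
        coords = np.pad(coords, ((0, 0), (0, dims - coords.shape[1])))
    return coords


def fisher_exact(confusion: np.ndarray) -> float:
    """Two-sided exact Fisher p for a 2x2 confusion table."""
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2) or np.any(confusion < 0):
        raise ValueError("confusion must be a non-negative 2x2 table")
    return float(_scipy_fisher(confusion, alternative="two-sided")[1])


def loo_classify(
    m: DissimilarityMatrix,
    labels: list[str],
    tie_label: str | None = None,
) -> ClassificationResult:
    """Leave-one-out nearest-medoid classification.

    For each held-out sample, one medoid per label group is selected on the
    remaining samples (the training sample minimizing summed dissimilarity
    within its group — K-medoids with k = 1 per group); the held-out sample
    is assigned the label of the nearer medoid. Distance ties predict the
    first label alphabetically unless ``tie_label`` overrides (a conservative,
    logged rule).
    """
    d = m.values
    labels = list(labels)
    if len(labels) != len(m):
        raise ValueError("labels must align with sample_ids")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two label classes, got {uniq}")
    counts = {u: labels.count(u) for u in uniq}
    if min(counts.values()) < 2:
        raise ValueError("each class needs >= 2 members to allow hold-out")
    tie_label = tie_label or uniq[0]
    predicted = []
    for i in range(len(labels)):
        med = {}
        for lab in uniq:
            group = [j for j in range(len(labels)) if j != i and labels[j] == lab]
            # 1-medoid: training sample minimizing summed within-group dissimilarity
            med[lab] = group[int(np.argmin([d[g, group].sum() for g in group]))]
        d0, d1 = d[i, med[uniq[0]]], d[i, med[uniq[1]]]
        if d0 == d1:
            logger.info("sample %s: medoid tie, predicting %s", m.sample_ids[i], tie_label)
            predicted.append(tie_label)
        else:
            predicted.append(uniq[0] if d0 < d1 else uniq[1])
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(labels, predicted):
        confusion[uniq.index(t), uniq.index(p)] += 1
    return ClassificationResult(
        sample_ids=list(m.sample_ids),
        true_labels=labels,
        predicted_labels=predicted,
        confusion=confusion,
        fisher_p=fisher_exact(confusion),
    )
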