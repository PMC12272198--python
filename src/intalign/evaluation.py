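"""Alignment-quality metrics: decoding, ISC, and spatial-constraint probes.

Alignment is judged by whether it makes participants' functional maps more
comparable, not merely smoother:

* **Inter-participant decoding** — a linear SVM trained on some
  participants' labelled task contrast maps predicts the task labels of
  held-out participants' maps; folds partition participants, so accuracy
  measures cross-participant transfer (chance = 1 / n_labels).
* **Parcel-mean augmentation** — solvers that remix values within a parcel
  can reset every parcel's mean activation; appending per-parcel means from
  the pre-alignment map restores that information for a fair comparison.
* **Inter-subject correlation (ISC)** — for each vertex, the mean Pearson
  correlation between one participant's timeseries and every other
  participant's; averaged across vertices into one value per participant.
* **Bump probes / spatial constraint ratio** — a binary map of small
  "bumps" (vertices within ``radius`` of random centers) is pushed through
  a transform; the fraction of the transformed map's Frobenius norm that
  stays inside the original bump support (S in [0, 1]) quantifies how
  spatially local the transform is. S = 1 means a perfectly local map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .datamodel import ContrastMap, Parcellation, SurfaceGeometry, TimeseriesImage

__all__ = [
    "DecodingResult",
    "ISCResult",
    "BumpProbe",
    "augment_parcel_means",
    "decode_tasks",
    "inter_subject_correlation",
    "make_bump_map",
    "spatial_constraint_ratio",
]


def _as_vector(m) -> np.ndarray:
    return m.data if isinstance(m, ContrastMap) else np.asarray(m, dtype=float).reshape(-1)


def augment_parcel_means(
    aligned_map, reference_map, parcellation: Parcellation
) -> np.ndarray:
    """Concatenate an aligned map with per-parcel means of the reference map.

    The reference is the pre-alignment (anatomically aligned) map by
    default convention: its parcel means carry the between-parcel activation
    differences that some transforms remix away. Parcels appear in id order.
    """
    a = _as_vector(aligned_map)
    r = _as_vector(reference_map)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {r.shape}")
    means = np.array([r[parcellation.vertices_of(pid)].mean() for pid in parcellation.parcel_ids])
    return np.concatenate([a, means])


@dataclass
class DecodingResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    n_labels: int
    fold_assignment: dict[str, int]
    classifier: str
    seed: int
    n_test_maps: int

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_labels


def decode_tasks(
    features: Mapping[str, Mapping[str, np.ndarray]],
    n_folds: int = 5,
    seed: int = 0,
) -> DecodingResult:
    """Inter-participant task-label decoding with a linear SVM.

    Parameters
    ----------
    features : mapping participant_id -> mapping task_label -> feature vector
        One vector per task per participant (every participant must have
        every label).
    n_folds : int
        Folds partition *participants*; the classifier is trained on
        training-fold participants' maps and tested on test-fold
        participants' maps. Default regularization, no feature selection.
    """
    pids = sorted(features)
    labels = sorted(features[pids[0]])
    missing = {
        pid: sorted(set(labels) ^ set(features[pid])) for pid in pids
        if set(features[pid]) != set(labels)
    }
    if missing:
        raise ValueError(f"label gaps per participant: {missing}")
    if n_folds > len(pids):
        raise ValueError(f"n_folds={n_folds} exceeds {len(pids)} participants")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    fold_of = {pids[j]: f for f, chunk in enumerate(np.array_split(order, n_folds)) for j in chunk}
    label_code = {lab: i for i, lab in enumerate(labels)}

    fold_acc = []
    n_test_total = 0
    for f in range(n_folds):
        train_p = [p for p in pids if fold_of[p] != f]
        test_p = [p for p in pids if fold_of[p] == f]
        Xtr = np.array([features[p][lab] for p in train_p for lab in labels])
        ytr = np.array([label_code[lab] for _ in train_p for lab in labels])
        Xte = np.array([features[p][lab] for p in test_p for lab in labels])
        yte = np.array([label_code[lab] for _ in test_p for lab in labels])
        clf = LinearSVC(random_state=seed)
        clf.fit(Xtr, ytr)
        fold_acc.append(float((clf.predict(Xte) == yte).mean()))
        n_test_total += len(yte)
    return DecodingResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        n_labels=len(labels),
        fold_assignment=fold_of,
        classifier="LinearSVC(default C, one-vs-rest, no feature selection)",
        seed=seed,
        n_test_maps=n_test_total,
    )


@dataclass
class ISCResult:
    per_participant: dict[str, float]
    per_vertex: np.ndarray | None = None
    excluded: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_participant.values())))


def inter_subject_correlation(
    images: Sequence[TimeseriesImage] | Sequence[np.ndarray],
    keep_vertex_matrix: bool = False,
) -> ISCResult:
    """Mean pairwise inter-subject correlation, one value per participant.

    For each vertex of each participant, the Pearson correlations with every
    other participant's timeseries at that vertex are averaged; the result is
    then averaged across vertices. Vertices with zero variance (or flagged as
    excluded on load) are skipped in that participant's average rather than
    propagating NaN; participants with no usable vertex are absent from the
    result.
    """
    if len(images) < 2:
        raise ValueError("ISC needs at least 2 participants")
    mats, pids, excl = [], [], []
    for i, im in enumerate(images):
        if isinstance(im, TimeseriesImage):
            mats.append(im.data)
            pids.append(im.participant_id or f"p{i}")
            excl.append(set(im.excluded_vertices.tolist()))
        else:
            mats.append(np.asarray(im, dtype=float))
            pids.append(f"p{i}")
            excl.append(set())
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"mismatched shapes: {shapes}")
    n, (v, p) = len(mats), mats[0].shape
    Z = np.empty((n, v, p))
    valid = np.empty((n, v), dtype=bool)
    for i, m in enumerate(mats):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        valid[i] = sd[:, 0] > 0
        if excl[i]:
            valid[i, sorted(excl[i])] = False
        sd[sd == 0] = 1.0
        Z[i] = (m - mu) / sd
    Z[~valid] = 0.0

    # corr(i, j, vertex) = dot of z-scored rows / p
    per_participant: dict[str, float] = {}
    excluded: dict[str, np.ndarray] = {}
    per_vertex = np.full((n, v), np.nan) if keep_vertex_matrix else None
    for i in range(n):
        corr_sum = np.zeros(v)
        pair_count = np.zeros(v)
        for j in range(n):
            if j == i:
                continue
            both = valid[i] & valid[j]
            corr_sum[both] += (Z[i][both] * Z[j][both]).sum(axis=1) / p
            pair_count[both] += 1
        usable = pair_count > 0
        excluded[pids[i]] = np.where(~usable)[0]
        if usable.any():
            vertex_isc = corr_sum[usable] / pair_count[usable]
            per_participant[pids[i]] = float(vertex_isc.mean())
            if per_vertex is not None:
                per_vertex[i, usable] = corr_sum[usable] / pair_count[usable]
    return ISCResult(per_participant=per_participant, per_vertex=per_vertex, excluded=excluded)


@dataclass
class BumpProbe:
    """Binary probe map: 1 on vertices within ``radius`` of any center."""

    centers: np.ndarray
    radius: float
    map: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return np.where(self.map > 0)[0]


def make_bump_map(
    geometry: SurfaceGeometry, n_centers: int, radius: float = 1.0, seed: int = 0
) -> BumpProbe:
    """Random localized bump activations: centers drawn uniformly without
    replacement; vertices within ``radius`` mm of any center get value 1,
    all others 0."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    v = geometry.n_vertices
    if n_centers > v:
        raise ValueError("more centers than vertices")
    rng = np.random.default_rng(seed)
    centers = np.sort(rng.choice(v, size=n_centers, replace=False))
    D = geometry.distances()
    bump = (D[:, centers].min(axis=1) <= radius).astype(float)
    return BumpProbe(centers=centers, radius=float(radius), map=bump)


def spatial_constraint_ratio(transformed, bump: BumpProbe) -> float:
    """S = ||T on original bump support||_F / ||T||_F, in [0, 1].

    1 means the transformed activation stayed entirely within the original
    bumps (perfectly local transform); invariant to global rescaling of T.
    """
    t = _as_vector(transformed)
    if t.shape[0] != bump.map.shape[0]:
        raise ValueError("map length does not match bump probe")
    total = np.linalg.norm(t)
    if total == 0:
        raise ValueError("spatial constraint ratio undefined for an all-zero map")
    return float(np.linalg.norm(t[bump.support]) / total)
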