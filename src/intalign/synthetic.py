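"""Synthetic multi-participant cohorts with known ground-truth topographies.

The generator emulates the structure functional alignment assumes: within
each parcel, all participants share latent vertex-level timecourses ``L``
(the response to a common "movie" stimulus) and latent task activation
patterns (one per task label), but each participant sees them through their
own topographic transform ``G_i`` plus additive Gaussian noise:

    movie_i  = G_i @ L + noise,      task_i[t] = G_i @ z_t + noise

The SAME ``G_i`` is used for movie and task data — the generalization
assumption that a mapping estimated from one stimulus transfers to another.
Task patterns are drawn once per label and shared across participants in
latent space, so task decoding transfers across participants exactly when
the topography has been unmixed.

Topography models
-----------------
* ``identity`` — all participants anatomically aligned (shared-signal ISC
  generator: expected vertex ISC is ``signal^2 / (signal^2 + noise^2)``).
* ``permutation`` — a random vertex permutation per parcel per participant.
* ``orthogonal`` — a random orthogonal matrix per parcel per participant.
* ``smooth_displacement`` — each vertex's position is jittered and it draws
  weight ``exp(-d^2 / (2 tau^2))`` from nearby vertices (row-normalized):
  an "almost anatomical" regime where intermediate gamma should win.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CohortAssignment, ContrastMap, Parcellation, SurfaceGeometry, TimeseriesImage

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "make_synthetic_geometry",
    "make_cohort",
    "corrupt_template_cohort",
    "task_labels",
]

TOPOGRAPHY_MODELS = ("identity", "permutation", "orthogonal", "smooth_displacement")


@dataclass
class SyntheticConfig:
    """Desk-scale defaults: 20 participants, 300 vertices in 10 parcels,
    600 movie timepoints, 18 task labels — minutes on one CPU."""

    n_participants: int = 20
    v: int = 300
    n_parcels: int = 10
    p_movie: int = 600
    n_tasks: int = 18
    topography_model: str = "permutation"
    noise_sigma: float = 0.5
    signal_sigma: float = 1.0
    displacement_sigma: float = 1.0  # mm, smooth_displacement only
    smoothness_tau: float = 1.0  # mm, smooth_displacement kernel width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topography_model not in TOPOGRAPHY_MODELS:
            raise ValueError(
                f"unknown topography_model {self.topography_model!r}; expected one of {TOPOGRAPHY_MODELS}"
            )
        if self.noise_sigma < 0 or self.signal_sigma <= 0:
            raise ValueError("noise_sigma must be >= 0 and signal_sigma > 0")
        if self.v < self.n_parcels:
            raise ValueError("v must be >= n_parcels")
        if self.topography_model != "identity" and self.v // self.n_parcels < 2:
            raise ValueError("non-identity topographies need parcels of size >= 2")


@dataclass
class SyntheticGroundTruth:
    """Per participant, per parcel: the true topographic transform."""

    transforms: dict[str, dict[int, np.ndarray]]
    config: SyntheticConfig
    latent_movie: dict[int, np.ndarray] = field(default_factory=dict)
    latent_tasks: dict[int, np.ndarray] = field(default_factory=dict)

    def transform_of(self, participant_id: str, parcel_id: int) -> np.ndarray:
        return self.transforms[participant_id][parcel_id]


def task_labels(n_tasks: int) -> list[str]:
    return [f"task{t:02d}" for t in range(n_tasks)]


def make_synthetic_geometry(v: int, n_parcels: int, seed: int = 0) -> tuple[Parcellation, SurfaceGeometry]:
    """Contiguous equal-size parcels on a 2-D grid with 1.0 mm spacing."""
    if v < n_parcels:
        raise ValueError("v must be >= n_parcels")
    width = int(np.ceil(np.sqrt(v)))
    idx = np.arange(v)
    coords = np.column_stack([idx // width, idx % width]).astype(float)
    labels = np.zeros(v, dtype=int)
    for pid, chunk in enumerate(np.array_split(idx, n_parcels), start=1):
        labels[chunk] = pid
    return Parcellation(labels), SurfaceGeometry(coordinates=coords)


def _draw_topography(
    model: str,
    idx: np.ndarray,
    geometry: SurfaceGeometry,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    vA = idx.size
    if model == "identity":
        return np.eye(vA)
    if model == "permutation":
        P = np.zeros((vA, vA))
        P[np.arange(vA), rng.permutation(vA)] = 1.0
        return P
    if model == "orthogonal":
        A = rng.standard_normal((vA, vA))
        Q, Rfac = np.linalg.qr(A)
        Q = Q * np.sign(np.diag(Rfac))  # deterministic sign convention
        return Q
    if model == "smooth_displacement":
        X = geometry.coordinates[idx]
        jitter = rng.normal(scale=cfg.displacement_sigma, size=X.shape)
        diff = (X + jitter)[:, None, :] - X[None, :, :]
        W = np.exp(-(diff**2).sum(-1) / (2.0 * cfg.smoothness_tau**2))
        return W / W.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown topography model {model!r}")


def make_cohort(
    config: SyntheticConfig,
    parcellation: Parcellation | None = None,
    geometry: SurfaceGeometry | None = None,
) -> tuple[list[TimeseriesImage], list[dict[str, ContrastMap]], SyntheticGroundTruth]:
    """Generate a cohort of movie timeseries and task contrast maps.

    Returns ``(movies, tasks, ground_truth)`` where ``tasks[i]`` maps each
    task label to participant i's contrast map. Identical config + seed give
    bitwise-identical cohorts.
    """
    cfg = config
    if parcellation is None or geometry is None:
        parcellation, geometry = make_synthetic_geometry(cfg.v, cfg.n_parcels, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    labels = task_labels(cfg.n_tasks)
    pids = [f"sub-{i:03d}" for i in range(cfg.n_participants)]

    latent_movie: dict[int, np.ndarray] = {}
    latent_tasks: dict[int, np.ndarray] = {}
    for pid_parcel in parcellation.parcel_ids:
        vA = parcellation.vertices_of(pid_parcel).size
        latent_movie[pid_parcel] = cfg.signal_sigma * rng.standard_normal((vA, cfg.p_movie))
        latent_tasks[pid_parcel] = cfg.signal_sigma * rng.standard_normal((vA, cfg.n_tasks))

    transforms: dict[str, dict[int, np.ndarray]] = {}
    movies: list[TimeseriesImage] = []
    tasks: list[dict[str, ContrastMap]] = []
    for pid in pids:
        transforms[pid] = {}
        movie = np.zeros((parcellation.n_vertices, cfg.p_movie))
        task_data = np.zeros((parcellation.n_vertices, cfg.n_tasks))
        for parcel_id in parcellation.parcel_ids:
            idx = parcellation.vertices_of(parcel_id)
            G = _draw_topography(cfg.topography_model, idx, geometry, cfg, rng)
            transforms[pid][parcel_id] = G
            movie[idx, :] = G @ latent_movie[parcel_id]
            task_data[idx, :] = G @ latent_tasks[parcel_id]
        if cfg.noise_sigma > 0:
            movie = movie + cfg.noise_sigma * rng.standard_normal(movie.shape)
            task_data = task_data + cfg.noise_sigma * rng.standard_normal(task_data.shape)
        movies.append(
            TimeseriesImage(movie, participant_id=pid, space_tag=f"synthetic-v{cfg.v}")
        )
        tasks.append(
            {
                lab: ContrastMap(task_data[:, t], participant_id=pid, task_label=lab)
                for t, lab in enumerate(labels)
            }
        )
    gt = SyntheticGroundTruth(
        transforms=transforms, config=cfg, latent_movie=latent_movie, latent_tasks=latent_tasks
    )
    return movies, tasks, gt


def corrupt_template_cohort(cohort_ids: list[str], overlap: int) -> CohortAssignment:
    """Deterministic role split with a declared template/test overlap.

    With ``overlap = 0`` the template-generation and test cohorts are the
    disjoint first and second halves; ``overlap = len(cohort_ids)`` is the
    fully in-sample design (template built from the very participants being
    aligned); intermediate values share exactly ``overlap`` ids.
    """
    ids = [str(i) for i in cohort_ids]
    n = len(ids)
    if not 0 <= overlap <= n:
        raise ValueError("overlap must be between 0 and the cohort size")
    k_t = max(int(np.ceil(n / 2)), overlap)
    template_ids = ids[:k_t]
    test_ids = ids[k_t - overlap:]
    assignment = CohortAssignment(
        {"template_generation": template_ids, "test": test_ids},
        allow_overlap=overlap > 0,
    )
    actual = assignment.overlap("template_generation", "test")
    assert len(actual) == overlap, "role split produced the wrong overlap"
    return assignment
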