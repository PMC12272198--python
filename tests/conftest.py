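import numpy as np
import pytest

from intalign import (
    Parcellation,
    SurfaceGeometry,
    SyntheticConfig,
    TimeseriesImage,
    make_cohort,
    make_synthetic_geometry,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_world():
    """20 vertices in 2 parcels of 10, grid geometry."""
    parc, geom = make_synthetic_geometry(20, 2, seed=0)
    return parc, geom


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 participants, permuted topographies, moderate noise (session-cached)."""
    cfg = SyntheticConfig(
        n_participants=8, v=40, n_parcels=4, p_movie=120, n_tasks=6,
        topography_model="permutation", noise_sigma=0.3, seed=7,
    )
    movies, tasks, gt = make_cohort(cfg)
    parc, geom = make_synthetic_geometry(cfg.v, cfg.n_parcels, cfg.seed)
    return movies, tasks, gt, parc, geom


def make_images(n, v, p, seed, parcellation=None, permuted=False):
    """Random images; optionally per-parcel-permuted copies of one base image."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((v, p))
    images = []
    for i in range(n):
        if permuted and parcellation is not None:
            data = base.copy()
            for pid in parcellation.parcel_ids:
                idx = parcellation.vertices_of(pid)
                data[idx] = base[idx][rng.permutation(idx.size)]
        elif permuted:
            raise ValueError("permuted requires a parcellation")
        else:
            data = rng.standard_normal((v, p))
        images.append(TimeseriesImage(data, participant_id=f"sub-{i:03d}"))
    return images
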