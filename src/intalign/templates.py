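"""Template generation: building a common alignment target from a cohort.

A template is a vertices x timepoints image combining several participants'
responses to the shared stimulus; aligning everyone to it places the cohort
in one functional space, and a multi-participant template is less noisy than
any single participant's data. Three builders are provided:

* **GPA** (generalized Procrustes analysis): start from the Euclidean mean
  of the cohort, repeatedly align every participant to the current template
  and average the aligned images.
* **Hyperalignment**: level 1 aligns participants sequentially to a growing
  template seeded by the first participant; level 2 re-aligns everyone to
  the mean of the level-1 aligned images and averages again.
* **PCA**: per parcel, stack the cohort's submatrices along the vertex axis,
  keep the top principal component timecourses, and rotate the reduced
  template toward the cohort mean image so it stays near the anatomical
  orientation (rotation configurable).

The *pairwise* alternative simply uses one participant's data as the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .datamodel import Parcellation, TimeseriesImage
from .solvers import FullTransform, ParcelTransform, fit_parcelwise, procrustes_fit

__all__ = [
    "Template",
    "gpa_template",
    "hyperalignment_template",
    "pca_template",
    "pairwise_align_all",
    "GPATemplate",
    "HyperalignmentTemplate",
    "PCATemplate",
]


@dataclass
class Template:
    """A cohort-derived alignment target with provenance."""

    image: TimeseriesImage
    method: str
    cohort_ids: list[str]
    iterations: int = 0
    solver_method: str = "procrustes"
    provenance: dict = field(default_factory=dict)

    @property
    def data(self) -> np.ndarray:
        return self.image.data

    def overlap_with(self, ids) -> list[str]:
        return sorted(set(self.cohort_ids) & {str(i) for i in ids})


def _check_cohort(cohort: list[TimeseriesImage], minimum: int = 1) -> None:
    if len(cohort) < minimum:
        raise ValueError(f"need at least {minimum} participants, got {len(cohort)}")
    shapes = {im.data.shape for im in cohort}
    if len(shapes) > 1:
        raise ValueError(f"participants have mismatched shapes: {shapes}")


def _mean_image(images: list[TimeseriesImage]) -> np.ndarray:
    return np.mean([im.data for im in images], axis=0)


def gpa_template(
    cohort: list[TimeseriesImage],
    parcellation: Parcellation,
    solver_method: str = "procrustes",
    n_iter: int = 2,
    hyperparams: dict | None = None,
) -> Template:
    """Iterative generalized-Procrustes-analysis template.

    The initial template is the Euclidean mean of the cohort images; each
    iteration aligns every participant to the current template (per parcel,
    chosen solver) and replaces the template with the mean of the aligned
    images. With the Procrustes solver the mean squared residual to the
    template is non-increasing across iterations.
    """
    _check_cohort(cohort, 1)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    template = _mean_image(cohort)
    for _ in range(n_iter):
        aligned = []
        for im in cohort:
            T = fit_parcelwise(im.data, template, parcellation, method=solver_method, hyperparams=hyperparams)
            aligned.append(T.apply_array(im.data))
        template = np.mean(aligned, axis=0)
    image = TimeseriesImage(template, participant_id="template", space_tag=cohort[0].space_tag)
    return Template(
        image=image,
        method="gpa",
        cohort_ids=[im.participant_id for im in cohort],
        iterations=n_iter,
        solver_method=solver_method,
    )


def hyperalignment_template(
    cohort: list[TimeseriesImage],
    parcellation: Parcellation,
    solver_method: str = "procrustes",
    hyperparams: dict | None = None,
) -> Template:
    """Two-level sequential hyperalignment template.

    Level 1 seeds the template with the first participant (cohort order is
    recorded in provenance: results are order-dependent by construction) and
    folds each subsequent participant in by aligning it to the running
    template and averaging. Level 2 re-aligns everyone to the mean of the
    level-1 aligned images; the final template is the mean of the level-2
    aligned images.
    """
    _check_cohort(cohort, 2)

    def align_to(im: TimeseriesImage, target: np.ndarray) -> np.ndarray:
        T = fit_parcelwise(im.data, target, parcellation, method=solver_method, hyperparams=hyperparams)
        return T.apply_array(im.data)

    # level 1: growing template
    template = cohort[0].data.copy()
    level1_aligned = [cohort[0].data.copy()]
    for im in cohort[1:]:
        aligned = align_to(im, template)
        level1_aligned.append(aligned)
        template = 0.5 * (template + aligned)
    # level 2
    level2_target = np.mean(level1_aligned, axis=0)
    level2_aligned = [align_to(im, level2_target) for im in cohort]
    final = np.mean(level2_aligned, axis=0)
    image = TimeseriesImage(final, participant_id="template", space_tag=cohort[0].space_tag)
    return Template(
        image=image,
        method="hyperalignment",
        cohort_ids=[im.participant_id for im in cohort],
        iterations=2,
        solver_method=solver_method,
        provenance={"order": [im.participant_id for im in cohort]},
    )


def _deterministic_component_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    flip = np.sign(components[np.arange(components.shape[0]), np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return components * flip[:, None]


def pca_template(
    cohort: list[TimeseriesImage],
    parcellation: Parcellation,
    n_components: int | str = "parcel_size",
    rotation: str = "to_mean",
) -> Template:
    """PCA template: shared component timecourses per parcel, Procrustes-rotated.

    Per parcel, the cohort's submatrices are stacked along the vertex axis
    into an (n * vA) x p matrix whose principal component timecourses are
    linear combinations of vertices from multiple participants. The top
    ``n_components`` (default: the parcel size, keeping downstream solver
    shapes unchanged) form the raw template. With ``rotation="to_mean"`` the
    raw template is rotated (unscaled Procrustes) toward the cohort's
    elementwise-mean image so the template stays near the anatomical
    orientation; ``rotation="none"`` keeps the raw components. Timepoint
    columns are mean-centered across stacked vertices before decomposition;
    component signs are fixed deterministically.
    """
    _check_cohort(cohort, 1)
    if rotation not in ("to_mean", "none"):
        raise ValueError("rotation must be 'to_mean' or 'none'")
    p = cohort[0].data.shape[1]
    n = len(cohort)
    mean_img = _mean_image(cohort)
    out = np.zeros_like(cohort[0].data)
    for pid in parcellation.parcel_ids:
        idx = parcellation.vertices_of(pid)
        vA = idx.size
        k = vA if n_components == "parcel_size" else int(n_components)
        if k > min(n * vA, p):
            raise ValueError(
                f"parcel {pid}: n_components={k} exceeds min(n*vA, p) = {min(n * vA, p)}"
            )
        if k > vA:
            raise ValueError(f"parcel {pid}: n_components={k} exceeds parcel size {vA}")
        stack = np.vstack([im.data[idx, :] for im in cohort])  # (n*vA) x p
        comps = PCA(n_components=k, svd_solver="full").fit(stack).components_  # k x p
        comps = _deterministic_component_signs(comps)
        block = np.zeros((vA, p))
        block[:k, :] = comps
        if rotation == "to_mean":
            rot = procrustes_fit(block, mean_img[idx, :], allow_scaling=False)
            block = rot.R @ block
        out[idx, :] = block
    image = TimeseriesImage(out, participant_id="template", space_tag=cohort[0].space_tag)
    return Template(
        image=image,
        method="pca",
        cohort_ids=[im.participant_id for im in cohort],
        iterations=0,
        solver_method="pca",
        provenance={"rotation": rotation, "n_components": n_components, "centering": "columns"},
    )


def pairwise_align_all(
    cohort: list[TimeseriesImage],
    target_id: str,
    parcellation: Parcellation,
    solver_method: str = "procrustes",
    hyperparams: dict | None = None,
) -> dict[str, FullTransform]:
    """Align every participant to one target participant's data.

    The target itself maps by identity. Rotating the target role over all
    participants (and averaging downstream scores) reproduces the pairwise
    evaluation scheme.
    """
    by_id = {im.participant_id: im for im in cohort}
    if target_id not in by_id:
        raise KeyError(f"unknown target participant {target_id!r}")
    target = by_id[target_id]
    result: dict[str, FullTransform] = {}
    for pid, im in by_id.items():
        if pid == target_id:
            transforms = [
                ParcelTransform(p, np.eye(parcellation.vertices_of(p).size), "identity")
                for p in parcellation.parcel_ids
            ]
            result[pid] = FullTransform(transforms, parcellation)
        else:
            result[pid] = fit_parcelwise(
                im.data, target.data, parcellation, method=solver_method, hyperparams=hyperparams
            )
    return result


# ---------------------------------------------------------------------------
# Estimator wrappers
# ---------------------------------------------------------------------------

class _TemplateBuilder(BaseEstimator):
    """Base class: fit(list of TimeseriesImage) -> ``template_``."""

    def fit(self, X, y=None):  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def template_image_(self) -> TimeseriesImage:
        return self.template_.image


class GPATemplate(_TemplateBuilder):
    def __init__(self, parcellation=None, solver_method="procrustes", n_iter=2):
        self.parcellation = parcellation
        self.solver_method = solver_method
        self.n_iter = n_iter

    def fit(self, X, y=None):
        self.template_ = gpa_template(X, self.parcellation, self.solver_method, self.n_iter)
        return self


class HyperalignmentTemplate(_TemplateBuilder):
    def __init__(self, parcellation=None, solver_method="procrustes"):
        self.parcellation = parcellation
        self.solver_method = solver_method

    def fit(self, X, y=None):
        self.template_ = hyperalignment_template(X, self.parcellation, self.solver_method)
        return self


class PCATemplate(_TemplateBuilder):
    def __init__(self, parcellation=None, n_components="parcel_size", rotation="to_mean"):
        self.parcellation = parcellation
        self.n_components = n_components
        self.rotation = rotation

    def fit(self, X, y=None):
        self.template_ = pca_template(X, self.parcellation, self.n_components, self.rotation)
        return self
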