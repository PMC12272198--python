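"""Core data containers and file I/O for surface functional alignment.

Conventions
-----------
* Timeseries matrices are ``vertices x timepoints`` (rows are vertices).
  Readers that store data the other way round (e.g. CIFTI-2 dtseries,
  which is timepoints x grayordinates) transpose at the I/O boundary.
* Vertex indexing is 0-based everywhere. Parcel label 0 marks unassigned
  vertices (e.g. the medial wall); those vertices pass through every
  transform unchanged.
* Vertices whose timeseries contain any NaN are zero-filled on load and
  recorded in ``excluded_vertices`` so downstream averaging can skip them
  while matrix shapes stay fixed across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TimeseriesImage",
    "ContrastMap",
    "Parcellation",
    "SurfaceGeometry",
    "CohortAssignment",
    "load_timeseries",
    "save_timeseries",
    "load_parcellation",
    "save_parcellation",
    "restrict_to_parcel",
    "scatter_to_full",
]

#: sanity bound on timepoint count; more columns than this raises a warning
MAX_REASONABLE_TIMEPOINTS = 200_000

ALIGNMENT_STATES = ("anatomical", "functional", "integrated")


def _zero_fill_nan(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-fill rows containing NaN; return (clean data, excluded row indices)."""
    bad = np.where(np.isnan(data).any(axis=-1).reshape(data.shape[0], -1).any(axis=1))[0]
    if bad.size:
        data = data.copy()
        data[bad] = 0.0
    return data, bad


@dataclass
class TimeseriesImage:
    """One participant's functional response, ``v`` vertices by ``p`` timepoints."""

    data: np.ndarray
    participant_id: str = ""
    space_tag: str = ""
    alignment_state: str = "anatomical"
    excluded_vertices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"timeseries must be 2-D (vertices x timepoints), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"timeseries must have v >= 1 and p >= 1, got shape {self.data.shape}")
        if self.alignment_state not in ALIGNMENT_STATES:
            raise ValueError(f"alignment_state must be one of {ALIGNMENT_STATES}")
        self.data, bad = _zero_fill_nan(self.data)
        if bad.size:
            self.excluded_vertices = np.union1d(np.asarray(self.excluded_vertices, dtype=int), bad)
        else:
            self.excluded_vertices = np.asarray(self.excluded_vertices, dtype=int)

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, alignment_state: str | None = None) -> "TimeseriesImage":
        return TimeseriesImage(
            data=data,
            participant_id=self.participant_id,
            space_tag=self.space_tag,
            alignment_state=alignment_state or self.alignment_state,
            excluded_vertices=self.excluded_vertices.copy(),
        )


@dataclass
class ContrastMap:
    """A per-vertex task activation map with its task label."""

    data: np.ndarray
    participant_id: str = ""
    task_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float).reshape(-1)
        if self.data.size < 1:
            raise ValueError("contrast map must have at least one vertex")
        self.data, _ = _zero_fill_nan(self.data[:, None])
        self.data = self.data[:, 0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray) -> "ContrastMap":
        return ContrastMap(data=data, participant_id=self.participant_id, task_label=self.task_label)


class Parcellation:
    """Vertex-to-parcel labelling. Label 0 means unassigned (medial wall).

    Parameters
    ----------
    labels : array of int, length v
        Parcel id per vertex; ids must be non-negative. Empty parcels
        (ids present in ``parcel_ids`` but with no vertices) cannot occur
        because ids are derived from the labels themselves.
    """

    def __init__(self, labels: Sequence[int]):
        labels = np.asarray(labels, dtype=int).reshape(-1)
        if labels.size < 1:
            raise ValueError("parcellation needs at least one vertex")
        if (labels < 0).any():
            raise ValueError("negative parcel labels are not allowed")
        self.labels = labels
        self.parcel_ids: list[int] = sorted(int(i) for i in np.unique(labels) if i > 0)
        self.parcel_vertex_lists: dict[int, np.ndarray] = {
            pid: np.where(labels == pid)[0] for pid in self.parcel_ids
        }

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def unassigned_vertices(self) -> np.ndarray:
        return np.where(self.labels == 0)[0]

    def vertices_of(self, parcel_id: int) -> np.ndarray:
        try:
            return self.parcel_vertex_lists[int(parcel_id)]
        except KeyError:
            raise KeyError(f"parcel id {parcel_id} not present in parcellation") from None

    def checksum(self) -> str:
        import hashlib

        return hashlib.sha1(self.labels.tobytes()).hexdigest()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parcellation) and np.array_equal(self.labels, other.labels)


@dataclass
class SurfaceGeometry:
    """Vertex coordinates in mm, optionally with a precomputed distance matrix."""

    coordinates: np.ndarray
    pairwise_distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be v x d")
        if self.pairwise_distance is not None:
            D = np.asarray(self.pairwise_distance, dtype=float)
            if D.shape[0] != D.shape[1]:
                raise ValueError("distance matrix must be square")
            if not np.allclose(D, D.T) or (np.diag(D) != 0).any() or (D < 0).any():
                raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
            self.pairwise_distance = D

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    def distances(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Pairwise Euclidean distances, optionally restricted to ``indices``."""
        if self.pairwise_distance is not None:
            D = self.pairwise_distance
            return D if indices is None else D[np.ix_(indices, indices)]
        X = self.coordinates if indices is None else self.coordinates[indices]
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(-1))


COHORT_ROLES = ("template_generation", "parameter_optimization", "test")


class CohortAssignment:
    """Participant-id → role mapping with explicit in-sample declaration.

    Roles follow the three-way split used for integrated alignment: a
    template-generation cohort, a parameter-optimization cohort and test
    cohorts. Overlapping roles (an "in-sample" design) must be declared
    via ``allow_overlap=True``; silent reuse of ids raises.
    """

    def __init__(self, roles: Mapping[str, Iterable[str]], allow_overlap: bool = False):
        self.roles: dict[str, list[str]] = {}
        for role, ids in roles.items():
            if role not in COHORT_ROLES:
                raise ValueError(f"unknown role {role!r}; expected one of {COHORT_ROLES}")
            self.roles[role] = [str(i) for i in ids]
        self.allow_overlap = bool(allow_overlap)
        if not allow_overlap:
            seen: dict[str, str] = {}
            for role, ids in self.roles.items():
                for pid in ids:
                    if pid in seen and seen[pid] != role:
                        raise ValueError(
                            f"participant {pid!r} assigned to both {seen[pid]!r} and {role!r}; "
                            "declare an in-sample design with allow_overlap=True"
                        )
                    seen[pid] = role

    def ids(self, role: str) -> list[str]:
        return list(self.roles.get(role, []))

    def overlap(self, role_a: str, role_b: str) -> list[str]:
        return sorted(set(self.ids(role_a)) & set(self.ids(role_b)))


# ---------------------------------------------------------------------------
# Parcel restriction / scatter
# ---------------------------------------------------------------------------

def restrict_to_parcel(image, parcellation: Parcellation, parcel_id: int) -> np.ndarray:
    """Rows of ``image`` at the parcel's vertices, in the parcel's stored order."""
    idx = parcellation.vertices_of(parcel_id)
    data = image.data if hasattr(image, "data") else np.asarray(image)
    if data.ndim == 1:
        return data[idx]
    return data[idx, :]


def scatter_to_full(
    parcellation: Parcellation,
    parcel_blocks: Mapping[int, np.ndarray],
    template: np.ndarray,
) -> np.ndarray:
    """Inverse of per-parcel restriction: place parcel blocks back into a full map.

    ``template`` supplies the values (and shape) for unassigned vertices.
    """
    out = np.array(template, dtype=float, copy=True)
    for pid, block in parcel_blocks.items():
        idx = parcellation.vertices_of(pid)
        out[idx] = block
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _load_cifti2_timeseries(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    # CIFTI-2 dtseries stores timepoints x grayordinates; transpose into
    # the vertices x timepoints convention used internally.
    return data.T


def _load_container_timeseries(path: Path) -> tuple[np.ndarray, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: container missing required 'data' dataset")
        data = f["data"][()]
        attrs = dict(f["data"].attrs)
    return np.asarray(data, dtype=float), attrs


def load_timeseries(path, format: str = "delimited", participant_id: str = "", space_tag: str = "") -> TimeseriesImage:
    """Load a vertices x timepoints matrix from disk.

    Parameters
    ----------
    format : {"cifti2", "matrix_container", "delimited"}
        ``cifti2`` reads a .dtseries.nii (surface grayordinates, transposed
        into rows-as-vertices); ``matrix_container`` reads the HDF5 container
        written by :func:`save_timeseries`; ``delimited`` reads comma- or
        tab-separated text (tiny fixtures only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    attrs: dict = {}
    if format == "cifti2":
        data = _load_cifti2_timeseries(path)
    elif format == "matrix_container":
        data, attrs = _load_container_timeseries(path)
    elif format == "delimited":
        try:
            data = np.atleast_2d(np.loadtxt(path, delimiter=_sniff_delimiter(path)))
        except ValueError as e:
            raise ValueError(f"{path}: could not parse delimited matrix: {e}") from e
    else:
        raise ValueError(f"unknown timeseries format {format!r}")
    if data.shape[1] > MAX_REASONABLE_TIMEPOINTS:
        warnings.warn(
            f"{path}: {data.shape[1]} timepoints exceeds sanity bound "
            f"{MAX_REASONABLE_TIMEPOINTS}; is the matrix transposed?",
            stacklevel=2,
        )
    return TimeseriesImage(
        data=data,
        participant_id=participant_id or str(attrs.get("participant_id", "")),
        space_tag=space_tag or str(attrs.get("space_tag", "")),
        alignment_state=str(attrs.get("alignment_state", "anatomical")),
    )


def save_timeseries(image: TimeseriesImage, path) -> None:
    """Write a TimeseriesImage to the HDF5 container (lossless round-trip)."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=image.data)
        d.attrs["participant_id"] = image.participant_id
        d.attrs["space_tag"] = image.space_tag
        d.attrs["alignment_state"] = image.alignment_state
        f.create_dataset("excluded_vertices", data=image.excluded_vertices)


def _sniff_delimiter(path: Path) -> str | None:
    first = path.read_text().splitlines()[0]
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return None  # whitespace


def load_parcellation(path, format: str = "delimited") -> Parcellation:
    """Load a parcel labelling (one integer label per vertex).

    ``gifti_label`` reads a GIFTI .label.gii; ``delimited`` reads one label
    per line. Empty parcels cannot arise (ids come from the labels); the
    label array length defines the vertex count checked at use time.
    """
    path = Path(path)
    if format == "gifti_label":
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.darrays[0].data, dtype=int)
    elif format == "delimited":
        labels = np.loadtxt(path, dtype=int).reshape(-1)
    else:
        raise ValueError(f"unknown parcellation format {format!r}")
    return Parcellation(labels)


def save_parcellation(parcellation: Parcellation, path, format: str = "delimited") -> None:
    path = Path(path)
    if format == "delimited":
        np.savetxt(path, parcellation.labels, fmt="%d")
    elif format == "gifti_label":
        import nibabel as nib

        darr = nib.gifti.GiftiDataArray(
            parcellation.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
    else:
        raise ValueError(f"unknown parcellation format {format!r}")
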