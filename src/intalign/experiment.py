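"""Experiment orchestration: containers, configs, and end-to-end runs.

An experiment is fully determined by its config plus a single seed:
generate (or load) a cohort, split it into template-generation /
parameter-optimization / test roles, build a template, optionally grid
search gamma on the parameter cohort, align the test cohort, and evaluate
with decoding and/or ISC. All artifacts (tables, transforms, manifest with
config and seeds) are written to the output directory so stages are
re-runnable and auditable.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ContrastMap, Parcellation, SurfaceGeometry, TimeseriesImage
from .evaluation import augment_parcel_means, decode_tasks, inter_subject_correlation
from .integrated import IntegratedConfig, fit_integrated, gamma_grid_search
from .solvers import fit_parcelwise, save_transform
from .synthetic import SyntheticConfig, make_cohort, make_synthetic_geometry
from .templates import Template, gpa_template, hyperalignment_template, pca_template

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_template",
    "load_template",
    "ExperimentConfig",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

def save_cohort(path, movies, tasks, parcellation, geometry, ground_truth=None, config=None) -> None:
    """Write a cohort to the HDF5 container; ground truth goes to a sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=parcellation.labels)
        f.create_dataset("coordinates", data=geometry.coordinates)
        if config is not None:
            f.attrs["config"] = json.dumps(asdict(config))
        gm = f.create_group("movies")
        gt_grp = f.create_group("tasks")
        for im, tmap in zip(movies, tasks):
            d = gm.create_dataset(im.participant_id, data=im.data)
            d.attrs["space_tag"] = im.space_tag
            d.attrs["alignment_state"] = im.alignment_state
            tg = gt_grp.create_group(im.participant_id)
            for lab, cm in tmap.items():
                tg.create_dataset(lab, data=cm.data)
    if ground_truth is not None:
        with h5py.File(path.with_suffix(path.suffix + ".groundtruth"), "w") as f:
            g = f.create_group("transforms")
            for pid, per_parcel in ground_truth.transforms.items():
                pg = g.create_group(pid)
                for parcel_id, G in per_parcel.items():
                    pg.create_dataset(str(parcel_id), data=G)


def load_cohort(path):
    import h5py

    with h5py.File(path, "r") as f:
        parc = Parcellation(f["labels"][()])
        geom = SurfaceGeometry(coordinates=f["coordinates"][()])
        movies, tasks = [], []
        for pid in sorted(f["movies"]):
            d = f["movies"][pid]
            movies.append(
                TimeseriesImage(
                    d[()], participant_id=pid,
                    space_tag=str(d.attrs.get("space_tag", "")),
                    alignment_state=str(d.attrs.get("alignment_state", "anatomical")),
                )
            )
            tg = f["tasks"][pid]
            tasks.append(
                {lab: ContrastMap(tg[lab][()], participant_id=pid, task_label=lab) for lab in sorted(tg)}
            )
    return movies, tasks, parc, geom


def save_template(template: Template, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=template.image.data)
        d.attrs["method"] = template.method
        d.attrs["iterations"] = template.iterations
        d.attrs["solver_method"] = template.solver_method
        d.attrs["cohort_ids"] = json.dumps(template.cohort_ids)
        d.attrs["provenance"] = json.dumps(template.provenance)


def load_template(path) -> Template:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["data"]
        return Template(
            image=TimeseriesImage(d[()], participant_id="template"),
            method=str(d.attrs["method"]),
            cohort_ids=json.loads(d.attrs["cohort_ids"]),
            iterations=int(d.attrs["iterations"]),
            solver_method=str(d.attrs["solver_method"]),
            provenance=json.loads(d.attrs["provenance"]),
        )


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

TEMPLATE_BUILDERS = {"gpa": gpa_template, "hyper": hyperalignment_template, "pca": pca_template}


@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    template_method: str = "gpa"
    solver: str = "procrustes"
    mode: str = "integrated"  # anatomical | functional | integrated | promises
    gamma: float | None = None  # None -> grid search on the parameter cohort
    gamma_grid: tuple[float, ...] | None = None
    k: float = 0.3
    n_folds: int = 5
    metric: str = "decoding"
    n_template: int = 7
    n_param: int = 7
    seed: int = 0
    out_dir: str | None = None

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


def _seed_for(base: int, stage: str) -> int:
    """Deterministic per-stage substream, kept below 2**31."""
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run simulate -> template -> (grid search) -> align -> evaluate.

    Returns the manifest dict; if ``config.out_dir`` is set, tables,
    transforms and the manifest are also written there.
    """
    cfg = config
    syn = SyntheticConfig(**{**asdict(cfg.synthetic), "seed": _seed_for(cfg.seed, "simulate")})
    movies, tasks, gt = make_cohort(syn)
    parc, geom = make_synthetic_geometry(syn.v, syn.n_parcels, syn.seed)
    pids = [im.participant_id for im in movies]
    n = len(pids)
    if cfg.n_template + cfg.n_param >= n:
        raise ValueError("template + parameter cohorts leave no test participants")
    template_idx = list(range(cfg.n_template))
    param_idx = list(range(cfg.n_template, cfg.n_template + cfg.n_param))
    test_idx = list(range(cfg.n_template + cfg.n_param, n))

    builder = TEMPLATE_BUILDERS[cfg.template_method]
    template_cohort = [movies[i] for i in template_idx]
    if cfg.template_method == "pca":
        template = builder(template_cohort, parc)
    else:
        template = builder(template_cohort, parc, solver_method=cfg.solver)

    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "roles": {
            "template_generation": [pids[i] for i in template_idx],
            "parameter_optimization": [pids[i] for i in param_idx],
            "test": [pids[i] for i in test_idx],
        },
        "seeds": {s: _seed_for(cfg.seed, s) for s in ("simulate", "grid", "decode")},
    }

    gamma = cfg.gamma
    grid_table = None
    if cfg.mode == "integrated" and gamma is None:
        icfg = IntegratedConfig(
            gamma_grid=cfg.gamma_grid or IntegratedConfig().gamma_grid, solver_method=cfg.solver
        )
        result = gamma_grid_search(
            [movies[i] for i in param_idx],
            template,
            parc,
            task_maps={pids[i]: tasks[i] for i in param_idx},
            config=icfg,
            n_folds=min(cfg.n_folds, len(param_idx)),
            seed=_seed_for(cfg.seed, "grid"),
            metric="decoding",
        )
        gamma = result.best_value
        grid_table = result.table
        manifest["grid_search"] = {
            "best_gamma": gamma,
            "curve": {str(k): float(v) for k, v in result.curve.items()},
        }

    # align the test cohort
    transforms = {}
    for i in test_idx:
        pid = pids[i]
        if cfg.mode == "anatomical":
            transforms[pid] = fit_integrated(movies[i], template, parc, gamma=1.0, method="procrustes")
        elif cfg.mode == "functional":
            transforms[pid] = fit_parcelwise(movies[i].data, template.image.data, parc, method=cfg.solver)
        elif cfg.mode == "integrated":
            transforms[pid] = fit_integrated(movies[i], template, parc, gamma=gamma, method=cfg.solver)
        elif cfg.mode == "promises":
            transforms[pid] = fit_parcelwise(
                movies[i].data, template.image.data, parc,
                method="promises", hyperparams={"k": cfg.k}, geometry=geom,
            )
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")

    # evaluate: decoding on aligned task maps, ISC on aligned movie data
    features = {}
    for i in test_idx:
        pid = pids[i]
        features[pid] = {
            lab: augment_parcel_means(transforms[pid].apply_array(cm.data), cm.data, parc)
            for lab, cm in tasks[i].items()
        }
    dec = decode_tasks(features, n_folds=min(cfg.n_folds, len(test_idx)), seed=_seed_for(cfg.seed, "decode"))
    aligned_movies = [movies[i].with_data(transforms[pids[i]].apply_array(movies[i].data)) for i in test_idx]
    isc = inter_subject_correlation(aligned_movies)
    manifest["evaluation"] = {
        "decoding_mean_accuracy": dec.mean_accuracy,
        "decoding_fold_accuracies": dec.fold_accuracies,
        "chance_level": dec.chance_level,
        "isc_mean": isc.mean,
        "gamma_used": gamma,
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_cohort(out / "cohort.h5", movies, tasks, parc, geom, ground_truth=gt, config=syn)
        save_template(template, out / "template.h5")
        for pid, T in transforms.items():
            save_transform(T, out / f"transform_{pid}.h5")
        if grid_table is not None:
            grid_table.to_csv(out / "grid_search.csv", index=False)
        pd.DataFrame(
            {"fold": range(len(dec.fold_accuracies)), "accuracy": dec.fold_accuracies}
        ).to_csv(out / "decoding.csv", index=False)
        pd.DataFrame(
            sorted(isc.per_participant.items()), columns=["participant_id", "isc"]
        ).to_csv(out / "isc.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
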