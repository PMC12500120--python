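"""Flat-file I/O: headerless TSV matrices, JSON sidecars, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml


def write_matrix(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, float), delimiter="\t", fmt="%.10g")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _coerce(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_connectome(directory, connectome) -> None:
    d = Path(directory)
    write_matrix(d / f"{connectome.subject_id}_weights.tsv", connectome.weights)
    write_matrix(d / f"{connectome.subject_id}_lengths.tsv", connectome.lengths)


def read_connectomes(directory) -> list:
    from .synthetic import Connectome

    d = Path(directory)
    cohort = []
    for wfile in sorted(d.glob("*_weights.tsv")):
        sid = wfile.name[: -len("_weights.tsv")]
        c = Connectome(
            subject_id=sid,
            weights=read_matrix(wfile),
            lengths=read_matrix(d / f"{sid}_lengths.tsv"),
        )
        c.validate()
        cohort.append(c)
    if not cohort:
        raise FileNotFoundError(f"no *_weights.tsv files under {d}")
    return cohort


def write_cohort(directory, cohort) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ids = cohort.subject_ids or [f"sub-{k + 1:02d}" for k in range(cohort.n_subjects)]
    for sid, series in zip(ids, cohort.series):
        write_matrix(d / f"{sid}_series.tsv", series)
    write_json(
        d / "manifest.json",
        {
            "condition": cohort.condition,
            "target_region": cohort.target_region,
            "dt_sample": cohort.dt_sample,
            "seed": cohort.seed,
            "subject_ids": ids,
        },
    )


def read_cohort(directory):
    from .synthetic import BoldCohort

    d = Path(directory)
    meta = read_json(d / "manifest.json")
    series = [read_matrix(d / f"{sid}_series.tsv") for sid in meta["subject_ids"]]
    return BoldCohort(
        condition=meta["condition"],
        series=series,
        dt_sample=meta["dt_sample"],
        seed=meta["seed"],
        target_region=meta["target_region"],
        subject_ids=meta["subject_ids"],
    )


def read_hoi_maps(directory, prefix: str):
    from .phiid import HOIMaps

    d = Path(directory)
    vec = np.genfromtxt(d / f"{prefix}_strengths.tsv", delimiter="\t", names=True)
    meta = read_json(d / f"{prefix}_meta.json")
    return HOIMaps(
        redundancy=read_matrix(d / f"{prefix}_redundancy.tsv"),
        synergy=read_matrix(d / f"{prefix}_synergy.tsv"),
        median_redundancy=np.atleast_1d(vec["median_redundancy"]),
        median_synergy=np.atleast_1d(vec["median_synergy"]),
        rank_redundancy=np.atleast_1d(vec["rank_redundancy"]),
        rank_synergy=np.atleast_1d(vec["rank_synergy"]),
        tau=meta["tau"],
        n_samples=meta["n_samples"],
    )


def write_hoi_maps(directory, prefix: str, maps) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(d / f"{prefix}_redundancy.tsv", maps.redundancy)
    write_matrix(d / f"{prefix}_synergy.tsv", maps.synergy)
    vectors = np.column_stack(
        [
            maps.median_redundancy,
            maps.median_synergy,
            maps.rank_redundancy,
            maps.rank_synergy,
        ]
    )
    np.savetxt(
        d / f"{prefix}_strengths.tsv",
        vectors,
        delimiter="\t",
        fmt="%.10g",
        header="median_redundancy\tmedian_synergy\trank_redundancy\trank_synergy",
        comments="",
    )
    write_json(
        d / f"{prefix}_meta.json",
        {"tau": maps.tau, "n_samples": maps.n_samples, "units": "nats"},
    )
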