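"""Configuration-driven end-to-end orchestration.

A run is described by a YAML config (see ``configs/demo.yaml``) with a
master seed, per-stage toggles, and parameter blocks.  Stages execute in
dependency order::

    synth -> commodels -> fit -> simulate -> phiid -> contrast
          -> associate -> sweep

Every stage writes its artifacts under the output directory plus a JSON
manifest recording seeds and parameters, so a run is re-derivable from the
manifest alone.  Identical configs produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .comm import build_comm_models, mid_heterogeneity_target, model_vector
from .exceptions import PipelineError
from .fitting import FitTarget, cohort_summary, fit_bias_scale, fit_global_coupling
from .hopf import HopfConfig
from .phiid import hoi_matrices
from .stats import alpha_sweep, model_association, regionwise_contrast
from .synthetic import make_connectome_cohort, make_ground_truth_cohorts, make_region_table

STAGES = (
    "synth",
    "commodels",
    "fit",
    "simulate",
    "phiid",
    "contrast",
    "associate",
    "sweep",
)

_REQUIRES = {
    "commodels": ("synth",),
    "fit": ("synth", "commodels"),
    "simulate": ("synth", "commodels"),
    "phiid": ("simulate",),
    "contrast": ("phiid",),
    "associate": ("commodels", "phiid"),
    "sweep": ("synth", "commodels", "contrast"),
}


@dataclass
class RunConfig:
    """Validated run configuration; see ``from_dict`` for the YAML layout."""

    out_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    commodels: dict = field(default_factory=dict)
    hopf: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    phiid: dict = field(default_factory=dict)
    contrast: dict = field(default_factory=dict)
    associate: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(cfg)
        cfg["out_dir"] = Path(cfg["out_dir"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_yaml(path))

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def hopf_config(self) -> HopfConfig:
        kw = dict(self.hopf)
        if "band" in kw:
            kw["band"] = tuple(kw["band"])
        if "kop_band" in kw:
            kw["kop_band"] = tuple(kw["kop_band"])
        return HopfConfig(**kw)


def _check_dependencies(config: RunConfig) -> None:
    for stage in STAGES:
        if not config.enabled(stage):
            continue
        for dep in _REQUIRES.get(stage, ()):
            if not config.enabled(dep) and not _artifact_present(config, dep):
                raise PipelineError(
                    f"stage '{stage}' needs outputs of disabled stage '{dep}'; "
                    f"enable '{dep}' or provide its artifacts"
                )


def _artifact_present(config: RunConfig, stage: str) -> bool:
    marker = {
        "synth": "regions.csv",
        "commodels": "comm/distance.tsv",
        "fit": "fit/fit.json",
        "simulate": "cohorts/control/manifest.json",
        "phiid": "hoi/control_sub-01_strengths.tsv",
        "contrast": "contrast/contrast.json",
    }.get(stage)
    return marker is not None and (config.out_dir / marker).exists()


def run(config: RunConfig) -> dict:
    """Execute enabled stages in order; returns (and writes) the run manifest."""
    _check_dependencies(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "config_sha256": hashlib.sha256(
            json.dumps(
                {k: str(getattr(config, k)) for k in config.__dataclass_fields__},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }

    table = cohort = None
    if config.enabled("synth"):
        table, cohort = _stage_synth(config, manifest)
    models = beta = None
    if config.enabled("commodels"):
        models, beta = _stage_commodels(config, manifest, cohort)
    fit_params = None
    if config.enabled("fit"):
        fit_params = _stage_fit(config, manifest, cohort, beta)
    cohorts = None
    if config.enabled("simulate"):
        cohorts = _stage_simulate(config, manifest, cohort, beta, fit_params)
    hoi = None
    if config.enabled("phiid"):
        hoi = _stage_phiid(config, manifest, cohorts)
    stat = None
    if config.enabled("contrast"):
        stat = _stage_contrast(config, manifest, hoi)
    if config.enabled("associate"):
        _stage_associate(config, manifest, models, hoi, beta)
    if config.enabled("sweep"):
        _stage_sweep(config, manifest, cohort, beta, fit_params, stat)

    io.write_json(out / "manifest.json", manifest)
    return manifest


# ------------------------------------------------------------------ stages


def _stage_synth(config, manifest):
    seed = config.stage_seed("synth")
    p = dict(config.synth)
    table = make_region_table(p.get("n_regions", 84), seed=seed)
    cohort = make_connectome_cohort(
        table,
        n_subjects=p.get("n_subjects", 20),
        edr_lambda=p.get("edr_lambda", 30.0),
        density=p.get("density", 0.35),
        subject_jitter=p.get("subject_jitter", 0.2),
        seed=seed,
    )
    out = config.out_dir
    table.to_csv(out / "regions.csv")
    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for c in cohort:
        io.write_connectome(conn_dir, c)
    manifest["stages"]["synth"] = {"seed": seed, **p}
    return table, cohort


def _stage_commodels(config, manifest, cohort):
    if cohort is None:
        cohort = io.read_connectomes(config.out_dir / "connectomes")
    norm = config.commodels.get("normalization", "as_printed")
    models = build_comm_models(cohort, normalization=norm)
    comm_dir = config.out_dir / "comm"
    comm_dir.mkdir(exist_ok=True)
    for name, mat in models.as_dict().items():
        io.write_matrix(comm_dir / f"{name}.tsv", mat)
    beta_model = config.commodels.get("beta_model", "distance")
    beta = model_vector(models.as_dict()[beta_model], "node_summary")
    io.write_matrix(comm_dir / "beta.tsv", beta[None, :])
    io.write_json(
        comm_dir / "meta.json",
        {
            "normalization": norm,
            "beta_model": beta_model,
            "n_unreachable": models.n_unreachable,
        },
    )
    manifest["stages"]["commodels"] = {
        "normalization": norm,
        "beta_model": beta_model,
    }
    return models, beta


def _load_beta(config):
    return io.read_matrix(config.out_dir / "comm" / "beta.tsv").ravel()


def _resolve_target(config, beta) -> int:
    """Configured target index, or the mid-heterogeneity region if null."""
    t = config.simulate.get("target")
    return mid_heterogeneity_target(beta) if t is None else int(t)


def _load_models_dict(config) -> dict:
    comm_dir = config.out_dir / "comm"
    return {
        name: io.read_matrix(comm_dir / f"{name}.tsv")
        for name in ("distance", "spe", "si", "cmy")
    }


def _load_hoi(config) -> dict:
    hoi = {}
    for cond in ("control", "tus"):
        meta = io.read_json(config.out_dir / "cohorts" / cond / "manifest.json")
        hoi[cond] = [
            io.read_hoi_maps(config.out_dir / "hoi", f"{cond}_{sid}")
            for sid in meta["subject_ids"]
        ]
    return hoi


def _load_stat(config):
    from .stats import RegionStatMap

    c = io.read_json(config.out_dir / "contrast" / "contrast.json")
    return RegionStatMap(
        t_values=np.asarray(c["t_values"]),
        p_values=np.asarray(c["p_values"]),
        significant=np.asarray(c["significant"], bool),
        n_perm=c["n_perm"],
        seed=c["seed"],
    )


def _stage_fit(config, manifest, cohort, beta):
    if cohort is None:
        cohort = io.read_connectomes(config.out_dir / "connectomes")
    if beta is None:
        beta = _load_beta(config)
    seed = config.stage_seed("fit")
    p = dict(config.fit)
    base = config.hopf_config()
    truth = p.get("truth", {})
    n = cohort[0].n_regions
    G_true = truth.get("G", base.G)

    # Stage 1: recover the global coupling from a homogeneous target.
    from .fitting import HOMOGENEOUS_BIAS

    hom_cfg = base.with_(
        G=G_true, bias=HOMOGENEOUS_BIAS, scale=0.0, beta=np.zeros(n), alpha=0.0
    )
    fc_hom, kop_hom = cohort_summary(cohort, hom_cfg, seed=seed + 1)
    g_fit = fit_global_coupling(
        FitTarget(fc_ref=fc_hom, kop_ref=kop_hom),
        cohort,
        G_grid=np.asarray(p["G_grid"], float) if "G_grid" in p else None,
        seed=seed,
        base_config=base,
    )

    # Stage 2: with G fixed at the fitted value, recover (bias, scale) from
    # the heterogeneous target.
    het_cfg = base.with_(
        G=G_true,
        bias=truth.get("bias", base.bias),
        scale=truth.get("scale", base.scale),
        beta=beta,
        alpha=0.0,
    )
    fc_ref, kop_ref = cohort_summary(cohort, het_cfg, seed=seed + 2)
    target = FitTarget(fc_ref=fc_ref, kop_ref=kop_ref)
    h_fit = fit_bias_scale(
        target,
        cohort,
        G=g_fit.best_params["G"],
        beta=beta,
        bias_grid=np.asarray(p["bias_grid"], float) if "bias_grid" in p else None,
        scale_grid=np.asarray(p["scale_grid"], float) if "scale_grid" in p else None,
        seed=seed,
        base_config=base,
    )
    fit_params = {"G": g_fit.best_params["G"], **h_fit.best_params}
    fit_dir = config.out_dir / "fit"
    fit_dir.mkdir(exist_ok=True)
    io.write_matrix(fit_dir / "score_G.tsv", g_fit.score_surface[None, :])
    io.write_matrix(fit_dir / "score_bias_scale.tsv", h_fit.score_surface)
    io.write_json(
        fit_dir / "fit.json",
        {
            "seed": seed,
            "truth": truth,
            "best": fit_params,
            "best_score": h_fit.best_score,
            "kop_ref": kop_ref,
            "G_grid": g_fit.grid["G"],
            "bias_grid": h_fit.grid["bias"],
            "scale_grid": h_fit.grid["scale"],
        },
    )
    manifest["stages"]["fit"] = {"seed": seed, "best": fit_params}
    return fit_params


def _read_fit_params(config):
    return io.read_json(config.out_dir / "fit" / "fit.json")["best"]


def _stage_simulate(config, manifest, cohort, beta, fit_params):
    if cohort is None:
        cohort = io.read_connectomes(config.out_dir / "connectomes")
    if beta is None:
        beta = _load_beta(config)
    if fit_params is None:
        fit_params = (
            _read_fit_params(config)
            if (config.out_dir / "fit" / "fit.json").exists()
            else {}
        )
    seed = config.stage_seed("simulate")
    p = dict(config.simulate)
    base = config.hopf_config().with_(
        G=fit_params.get("G", config.hopf_config().G),
        bias=fit_params.get("bias", config.hopf_config().bias),
        scale=fit_params.get("scale", config.hopf_config().scale),
        beta=beta,
    )
    target = _resolve_target(config, beta)
    ctrl, tus = make_ground_truth_cohorts(
        cohort,
        base,
        alpha=p.get("alpha", -1.0),
        target=target,
        seed=seed,
        tr=p.get("tr", 2.0),
    )
    io.write_cohort(config.out_dir / "cohorts" / "control", ctrl)
    io.write_cohort(config.out_dir / "cohorts" / "tus", tus)
    manifest["stages"]["simulate"] = {"seed": seed, **p, "target": target}
    return {"control": ctrl, "tus": tus}


def _stage_phiid(config, manifest, cohorts):
    if cohorts is None:
        cohorts = {
            cond: io.read_cohort(config.out_dir / "cohorts" / cond)
            for cond in ("control", "tus")
        }
    tau = config.phiid.get("tau", 1)
    hoi_dir = config.out_dir / "hoi"
    hoi = {}
    for cond, cohort in cohorts.items():
        maps = [hoi_matrices(s, tau=tau) for s in cohort.series]
        ids = cohort.subject_ids or [
            f"sub-{k + 1:02d}" for k in range(cohort.n_subjects)
        ]
        for sid, m in zip(ids, maps):
            io.write_hoi_maps(hoi_dir, f"{cond}_{sid}", m)
        hoi[cond] = maps
    manifest["stages"]["phiid"] = {"tau": tau}
    return hoi


def _stage_contrast(config, manifest, hoi):
    if hoi is None:
        if not (config.out_dir / "hoi").exists():
            raise PipelineError(
                "contrast stage needs HOI maps; enable 'phiid' or provide its artifacts"
            )
        hoi = _load_hoi(config)
    seed = config.stage_seed("contrast")
    p = dict(config.contrast)
    stat = regionwise_contrast(
        hoi["tus"],
        hoi["control"],
        measure=p.get("measure", "redundancy"),
        scale=p.get("scale", "rank"),
        n_perm=p.get("n_perm", 1000),
        seed=seed,
    )
    cdir = config.out_dir / "contrast"
    cdir.mkdir(exist_ok=True)
    io.write_json(
        cdir / "contrast.json",
        {
            "seed": seed,
            "t_values": stat.t_values,
            "p_values": stat.p_values,
            "significant": stat.significant,
            "n_perm": stat.n_perm,
            **{k: p[k] for k in ("measure", "scale") if k in p},
        },
    )
    manifest["stages"]["contrast"] = {"seed": seed, "n_sig": int(stat.significant.sum())}
    return stat


def _stage_associate(config, manifest, models, hoi, beta):
    if models is None:
        if not (config.out_dir / "comm").exists():
            raise PipelineError(
                "associate stage needs communication models; enable 'commodels' "
                "or provide its artifacts"
            )
        model_mats = _load_models_dict(config)
    else:
        model_mats = models.as_dict()
    if hoi is None:
        if not (config.out_dir / "hoi").exists():
            raise PipelineError(
                "associate stage needs HOI maps; enable 'phiid' or provide its artifacts"
            )
        hoi = _load_hoi(config)
    if beta is None:
        beta = _load_beta(config)
    target = _resolve_target(config, beta)
    results = {}
    for measure in ("redundancy", "synergy"):
        attr = f"median_{measure}"
        delta = np.mean([getattr(m, attr) for m in hoi["tus"]], axis=0) - np.mean(
            [getattr(m, attr) for m in hoi["control"]], axis=0
        )
        for name, mat in model_mats.items():
            vec = model_vector(mat, "seed_row", target=target)
            res = model_association(vec, delta, n_tests=8)
            results[f"{measure}_{name}"] = {
                "rho": res.rho,
                "p_raw": res.p_raw,
                "p_corrected": res.p_corrected,
                "n_used": res.n_used,
            }
    adir = config.out_dir / "associations"
    adir.mkdir(exist_ok=True)
    io.write_json(adir / "associations.json", results)
    manifest["stages"]["associate"] = {"n_tests": 8, "target": target}
    return results


def _stage_sweep(config, manifest, cohort, beta, fit_params, stat):
    if cohort is None:
        cohort = io.read_connectomes(config.out_dir / "connectomes")
    if beta is None:
        beta = _load_beta(config)
    if fit_params is None:
        fit_params = _read_fit_params(config)
    if stat is None:
        if not (config.out_dir / "contrast" / "contrast.json").exists():
            raise PipelineError(
                "sweep stage needs the contrast stage's t-map; enable 'contrast' "
                "or provide its artifacts"
            )
        stat = _load_stat(config)
    seed = config.stage_seed("sweep")
    p = dict(config.sweep)
    curve = alpha_sweep(
        stat,
        cohort,
        fit_params,
        beta,
        target=_resolve_target(config, beta),
        alpha_grid=np.asarray(p["alpha_grid"], float) if "alpha_grid" in p else None,
        n_perm=p.get("n_perm", 1000),
        seed=seed,
        measure=p.get("measure", "redundancy"),
        scale=p.get("scale", "rank"),
        base_config=config.hopf_config(),
        tr=p.get("tr", 2.0),
    )
    sdir = config.out_dir / "sweep"
    sdir.mkdir(exist_ok=True)
    np.savetxt(
        sdir / "sweep.tsv",
        np.column_stack([curve.alphas, curve.similarity, curve.sig_count]),
        delimiter="\t",
        fmt="%.10g",
        header="alpha\tsimilarity\tsig_count",
        comments="",
    )
    io.write_json(
        sdir / "sweep.json",
        {
            "seed": seed,
            "alphas": curve.alphas,
            "similarity": curve.similarity,
            "sig_count": curve.sig_count,
        },
    )
    manifest["stages"]["sweep"] = {"seed": seed}
    return curve
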