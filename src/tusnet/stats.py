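"""Permutation group statistics, model-HOI associations, intensity sweeps.

Regional contrasts compare per-subject strength vectors (median persistent
redundancy or synergy, absolute or rank scale) between a stimulated and a
control cohort with a label-permutation Welch t-test per region.  Model
associations rank-correlate a communication-model vector against a
per-region change vector with Bonferroni correction.  The intensity sweep
simulates stimulated cohorts over a grid of intensities and tracks (i) the
similarity between a reference t-map and the simulated t-map, and (ii) the
number of significant regions — the quantity that exposes the local-to-
global transition of stimulation effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateSignalError
from .phiid import HOIMaps, hoi_matrices

__all__ = [
    "RegionStatMap",
    "AssociationResult",
    "SweepCurve",
    "perm_ttest",
    "regionwise_contrast",
    "model_association",
    "alpha_sweep",
]


@dataclass
class RegionStatMap:
    """Per-region Welch t and permutation p for a group contrast (a minus b)."""

    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_perm: int
    seed: int
    alpha_level: float = 0.05


@dataclass
class AssociationResult:
    """One model-vs-change correlation with its Bonferroni-corrected p."""

    rho: float
    p_raw: float
    p_corrected: float
    n_tests: int
    method: str
    n_used: int


@dataclass
class SweepCurve:
    """Similarity and significance counts across stimulation intensities."""

    alphas: np.ndarray
    similarity: np.ndarray
    sig_count: np.ndarray
    t_maps: list[RegionStatMap]


def _welch_t(a_mat: np.ndarray, b_mat: np.ndarray) -> np.ndarray:
    """Row-wise Welch t; inputs are (reps, n_a) and (reps, n_b)."""
    na, nb = a_mat.shape[1], b_mat.shape[1]
    va = a_mat.var(axis=1, ddof=1) / na
    vb = b_mat.var(axis=1, ddof=1) / nb
    return (a_mat.mean(axis=1) - b_mat.mean(axis=1)) / np.sqrt(va + vb)


def perm_ttest(
    group_a, group_b, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation test on the Welch t-statistic (a minus b).

    The p-value is ``(1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)`` over
    random relabelings, so its floor is ``1/(n_perm+1)``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pooled = np.concatenate([a, b])
    if pooled.var(ddof=1) == 0:
        raise DegenerateSignalError("zero pooled variance; t-test undefined")
    na = len(a)
    t_obs = float(_welch_t(a[None, :], b[None, :])[0])
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    shuffled = pooled[perm]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = _welch_t(shuffled[:, :na], shuffled[:, na:])
    exceed = np.sum(np.abs(t_perm) >= abs(t_obs))
    p = (1.0 + exceed) / (n_perm + 1.0)
    return t_obs, float(p)


def _strength_vectors(maps: list[HOIMaps], measure: str, scale: str) -> np.ndarray:
    attr = {
        ("redundancy", "absolute"): "median_redundancy",
        ("redundancy", "rank"): "rank_redundancy",
        ("synergy", "absolute"): "median_synergy",
        ("synergy", "rank"): "rank_synergy",
    }.get((measure, scale))
    if attr is None:
        raise ValueError(f"unknown measure/scale {measure!r}/{scale!r}")
    return np.array([getattr(m, attr) for m in maps])  # subjects x regions


def regionwise_contrast(
    hoi_tus: list[HOIMaps],
    hoi_ctrl: list[HOIMaps],
    measure: str = "redundancy",
    scale: str = "rank",
    n_perm: int = 1000,
    seed: int = 0,
    alpha_level: float = 0.05,
    maxstat: bool = False,
) -> RegionStatMap:
    """Per-region permutation contrast of strength vectors, stimulated minus control.

    Each region gets its own permutation stream (spawned from ``seed``);
    significance is the per-region permutation p below ``alpha_level``.
    ``maxstat=True`` replaces the per-region null with the across-region
    maximum-|t| null (one shared permutation stream), a family-wise
    correction.
    """
    if len(hoi_tus) < 2 or len(hoi_ctrl) < 2:
        raise ValueError("each cohort needs at least 2 subjects")
    A = _strength_vectors(hoi_tus, measure, scale)
    B = _strength_vectors(hoi_ctrl, measure, scale)
    if A.shape[1] != B.shape[1]:
        raise ValueError("cohorts must share the region count")
    n_regions = A.shape[1]

    if maxstat:
        pooled = np.vstack([A, B])  # subjects x regions
        na = A.shape[0]
        t_obs = _welch_t(A.T, B.T)
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_perm)
        for k in range(n_perm):
            idx = rng.permutation(pooled.shape[0])
            t_perm = _welch_t(pooled[idx[:na]].T, pooled[idx[na:]].T)
            null_max[k] = np.max(np.abs(t_perm))
        p = (1.0 + (null_max[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)) / (
            n_perm + 1.0
        )
        t, p = t_obs, p
    else:
        children = np.random.SeedSequence(seed).spawn(n_regions)
        t = np.empty(n_regions)
        p = np.empty(n_regions)
        for r in range(n_regions):
            sub_seed = int(children[r].generate_state(1)[0] % (2**31))
            t[r], p[r] = perm_ttest(A[:, r], B[:, r], n_perm=n_perm, seed=sub_seed)
    return RegionStatMap(
        t_values=t,
        p_values=p,
        significant=p < alpha_level,
        n_perm=n_perm,
        seed=seed,
        alpha_level=alpha_level,
    )


def model_association(
    model_vec, delta_vec, method: str = "spearman", n_tests: int = 8
) -> AssociationResult:
    """Correlation between a model vector and a per-region change vector.

    Non-finite entries (e.g. unreachable pairs, the seed's own NaN entry)
    are removed pairwise; the raw p is Bonferroni-multiplied by ``n_tests``
    (default 8: four models times two measures per target).
    """
    x = np.asarray(model_vec, float)
    y = np.asarray(delta_vec, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("fewer than 3 finite pairs")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult(
        rho=float(rho),
        p_raw=float(p),
        p_corrected=min(1.0, float(p) * n_tests),
        n_tests=n_tests,
        method=method,
        n_used=int(len(x)),
    )


def _cohort_hoi(cohort_series, dt: float, tau: int) -> list[HOIMaps]:
    return [hoi_matrices(s, tau=tau) for s in cohort_series]


def alpha_sweep(
    emp_stat: RegionStatMap,
    connectomes,
    fit_params: dict,
    beta: np.ndarray,
    target: int,
    alpha_grid=None,
    n_perm: int = 1000,
    seed: int = 0,
    measure: str = "redundancy",
    scale: str = "rank",
    tau: int = 1,
    base_config=None,
    tr: float | None = 2.0,
) -> SweepCurve:
    """Sweep the stimulation intensity and compare simulated to reference t-maps.

    For every ``alpha`` a fresh control cohort (``alpha = 0``) and a
    stimulated cohort are simulated with the calibrated parameters (one
    simulation per connectome, independent seeds), so grid points are
    statistically independent.  Each point records the Spearman correlation
    between the reference t-vector and the simulated one, plus the
    simulated significant-region count.
    """
    from .hopf import HopfConfig, decimate_series, preprocess, simulate

    if alpha_grid is None:
        alpha_grid = np.round(np.arange(-1.0, 1.001, 0.1), 10)
    alpha_grid = np.asarray(alpha_grid, float)
    base = base_config or HopfConfig()
    base = replace(
        base,
        G=float(fit_params["G"]),
        bias=float(fit_params["bias"]),
        scale=float(fit_params["scale"]),
        beta=np.asarray(beta, float),
    )
    ss = np.random.SeedSequence(seed)
    alpha_seeds = ss.spawn(2 * len(alpha_grid))

    def run_cohort(cfg, seedseq):
        children = seedseq.spawn(len(connectomes))
        maps = []
        for conn, child in zip(connectomes, children):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            out = simulate(conn, cfg.with_(seed=sub_seed))
            x = preprocess(out, cfg)
            if tr is not None:
                x, _ = decimate_series(x, cfg.dt, tr)
            maps.append(hoi_matrices(x, tau=tau))
        return maps

    sims, counts, t_maps = [], [], []
    perm_seeds = np.random.SeedSequence(seed + 1).spawn(len(alpha_grid))
    for k, alpha in enumerate(alpha_grid):
        ctrl_maps = run_cohort(base.with_(alpha=0.0, target=None), alpha_seeds[2 * k])
        tus_maps = run_cohort(
            base.with_(alpha=float(alpha), target=target), alpha_seeds[2 * k + 1]
        )
        stat = regionwise_contrast(
            tus_maps,
            ctrl_maps,
            measure=measure,
            scale=scale,
            n_perm=n_perm,
            seed=int(perm_seeds[k].generate_state(1)[0] % (2**31)),
        )
        rho, _ = sps.spearmanr(emp_stat.t_values, stat.t_values)
        sims.append(float(rho))
        counts.append(int(stat.significant.sum()))
        t_maps.append(stat)
    return SweepCurve(
        alphas=alpha_grid,
        similarity=np.array(sims),
        sig_count=np.array(counts, dtype=int),
        t_maps=t_maps,
    )
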