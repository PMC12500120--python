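"""Two-stage calibration of the whole-brain model against FC and synchrony.

Stage one fits the global coupling ``G`` with homogeneous bifurcation
parameters; stage two fixes ``G`` and fits the affine map ``(bias, scale)``
from the heterogeneity vector ``beta`` to the per-region bifurcation
parameters.  Both stages grid-search the same score:

    score = corr(FC_sim, FC_ref) * (1 - |KOP_sim - KOP_ref|)

where the FC similarity is the Pearson correlation of the off-diagonal
upper triangles and KOP is the mean Kuramoto order parameter.  Both
summaries are computed in the synchrony band (``config.kop_band``, which
contains the oscillators' carrier frequency): at the durations simulated
here the infra-slow BOLD band carries only a handful of independent FC
samples per pair, far too few to compare FC patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DivergenceError
from .hopf import HopfConfig, fc_matrix, preprocess, simulate

__all__ = [
    "FitTarget",
    "FitResult",
    "fit_score",
    "cohort_summary",
    "fit_global_coupling",
    "fit_bias_scale",
    "DEFAULT_G_GRID",
    "DEFAULT_BIAS_GRID",
    "DEFAULT_SCALE_GRID",
]

DEFAULT_G_GRID = np.round(np.arange(0.0, 0.3001, 0.02), 10)
DEFAULT_BIAS_GRID = np.round(np.arange(-0.3, 0.1001, 0.01), 10)
DEFAULT_SCALE_GRID = np.round(np.arange(0.0, 0.4001, 0.01), 10)

#: Homogeneous bifurcation parameter used in the global-coupling stage.
HOMOGENEOUS_BIAS = -0.02


@dataclass(frozen=True)
class FitTarget:
    """Reference summaries the simulations must reproduce."""

    fc_ref: np.ndarray
    kop_ref: float

    def validate(self) -> None:
        fc = self.fc_ref
        if not np.allclose(fc, fc.T, atol=1e-8) or not np.allclose(np.diag(fc), 1.0):
            raise ValueError("fc_ref must be symmetric with unit diagonal")
        if not 0 <= self.kop_ref <= 1:
            raise ValueError("kop_ref must be in [0, 1]")


@dataclass
class FitResult:
    """Grid axes, score surface, and the selected optimum."""

    grid: dict[str, np.ndarray]
    score_surface: np.ndarray
    fc_similarity: np.ndarray
    kop_gap: np.ndarray
    best_params: dict[str, float]
    best_score: float


def fit_score(fc_sim: np.ndarray, kop_sim: float, target: FitTarget) -> float:
    """Combined goodness of fit, in [-1, 1]."""
    iu = np.triu_indices_from(fc_sim, k=1)
    a, b = fc_sim[iu], target.fc_ref[iu]
    if a.std() == 0 or b.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    gap = abs(float(kop_sim) - target.kop_ref)
    return max(-1.0, r * (1.0 - gap))


def cohort_summary(
    connectomes, config: HopfConfig, seed: int, reps: int = 1
) -> tuple[np.ndarray, float]:
    """Average FC and mean KOP over a cohort of simulations.

    FC is computed on the trimmed series band-passed in the synchrony band
    (``config.kop_band``); KOP comes from the simulator's own summary in the
    same band.
    """
    fcs, kops = [], []
    children = np.random.SeedSequence(seed).spawn(len(connectomes) * reps)
    fit_cfg = config.with_(band=config.kop_band)
    k = 0
    for conn in connectomes:
        for _ in range(reps):
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            out = simulate(conn, config.with_(seed=sub_seed))
            fcs.append(fc_matrix(preprocess(out, fit_cfg)))
            kops.append(out.kop_mean)
    return np.mean(fcs, axis=0), float(np.mean(kops))


def fit_global_coupling(
    target: FitTarget,
    connectomes,
    G_grid: np.ndarray | None = None,
    reps_per_cell: int = 1,
    seed: int = 0,
    base_config: HopfConfig | None = None,
    bias0: float = HOMOGENEOUS_BIAS,
) -> FitResult:
    """Homogeneous stage: grid-search the global coupling ``G``.

    Every cell simulates all connectomes with a uniform bifurcation
    parameter ``bias0`` (default -0.02, just below the bifurcation), scores
    the cohort-average summaries, and the argmax wins; ties go to the
    smallest ``G``.  Cells where every simulation diverges score NaN and
    are excluded with a warning.
    """
    target.validate()
    grid = DEFAULT_G_GRID if G_grid is None else np.asarray(G_grid, float)
    if grid.size == 0 or reps_per_cell < 1:
        raise ValueError("need a nonempty grid and reps_per_cell >= 1")
    grid = np.sort(grid)
    base = base_config or HopfConfig()
    scores = np.full(grid.size, np.nan)
    fc_sim = np.full(grid.size, np.nan)
    kop_gap = np.full(grid.size, np.nan)
    n = connectomes[0].n_regions if hasattr(connectomes[0], "n_regions") else len(
        connectomes[0]
    )
    for k, G in enumerate(grid):
        cfg = base.with_(G=float(G), bias=bias0, scale=0.0, beta=np.zeros(n), alpha=0.0)
        try:
            fc, kop_mean = cohort_summary(connectomes, cfg, seed, reps_per_cell)
        except DivergenceError:
            warnings.warn(f"all simulations diverged at G={G:g}; cell excluded")
            continue
        iu = np.triu_indices(n, k=1)
        fc_sim[k] = np.corrcoef(fc[iu], target.fc_ref[iu])[0, 1]
        kop_gap[k] = abs(kop_mean - target.kop_ref)
        scores[k] = fit_score(fc, kop_mean, target)
    if np.all(np.isnan(scores)):
        raise DivergenceError(0, np.inf)
    best = int(np.nanargmax(scores))  # first index wins ties -> smallest G
    return FitResult(
        grid={"G": grid},
        score_surface=scores,
        fc_similarity=fc_sim,
        kop_gap=kop_gap,
        best_params={"G": float(grid[best])},
        best_score=float(scores[best]),
    )


def fit_bias_scale(
    target: FitTarget,
    connectomes,
    G: float,
    beta: np.ndarray,
    bias_grid: np.ndarray | None = None,
    scale_grid: np.ndarray | None = None,
    reps: int = 1,
    seed: int = 0,
    base_config: HopfConfig | None = None,
) -> FitResult:
    """Heterogeneous stage: grid-search ``(bias, scale)`` at fixed ``G``.

    ``a_i = bias + scale * beta_i``.  Ties on the score go to the smallest
    ``|bias|``, then the smallest ``scale``.  A constant ``beta`` makes the
    two parameters unidentifiable along ``bias + scale*c``; this is flagged
    with a warning.
    """
    target.validate()
    beta = np.asarray(beta, float)
    if np.ptp(beta) < 1e-12:
        warnings.warn(
            "beta is constant: bias and scale are unidentifiable along a ridge",
            RuntimeWarning,
        )
    bias_grid = DEFAULT_BIAS_GRID if bias_grid is None else np.sort(np.asarray(bias_grid, float))
    scale_grid = DEFAULT_SCALE_GRID if scale_grid is None else np.sort(np.asarray(scale_grid, float))
    base = base_config or HopfConfig()
    shape = (bias_grid.size, scale_grid.size)
    scores = np.full(shape, np.nan)
    fc_sim = np.full(shape, np.nan)
    kop_gap = np.full(shape, np.nan)
    for i, bias in enumerate(bias_grid):
        for j, scale in enumerate(scale_grid):
            cfg = base.with_(
                G=float(G), bias=float(bias), scale=float(scale), beta=beta, alpha=0.0
            )
            try:
                fc, kop_mean = cohort_summary(connectomes, cfg, seed, reps)
            except DivergenceError:
                warnings.warn(
                    f"simulations diverged at bias={bias:g}, scale={scale:g}; cell excluded"
                )
                continue
            scores[i, j] = fit_score(fc, kop_mean, target)
            iu = np.triu_indices_from(fc, k=1)
            fc_sim[i, j] = np.corrcoef(fc[iu], target.fc_ref[iu])[0, 1]
            kop_gap[i, j] = abs(kop_mean - target.kop_ref)
    if np.all(np.isnan(scores)):
        raise DivergenceError(0, np.inf)
    top = np.nanmax(scores)
    cand = np.argwhere(scores == top)
    order = sorted(
        (abs(bias_grid[i]), scale_grid[j], i, j) for i, j in cand
    )
    i, j = order[0][2], order[0][3]
    return FitResult(
        grid={"bias": bias_grid, "scale": scale_grid},
        score_surface=scores,
        fc_similarity=fc_sim,
        kop_gap=kop_gap,
        best_params={"bias": float(bias_grid[i]), "scale": float(scale_grid[j])},
        best_score=float(scores[i, j]),
    )
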