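"""Synthetic cohort generation: parcellations, connectomes, ground-truth BOLD.

The generators here stand in for an empirical multimodal dataset: a
Desikan-Killiany-like parcellation of 84 regions (cortex plus subcortical
nuclei in both hemispheres), a cohort of diffusion-imaging-style structural
connectomes, and BOLD-like cohorts produced by the whole-brain oscillator
model under control and stimulated regimes.  Every downstream stage of the
pipeline is exercised on these cohorts, where ground truth is known.

Geometry is deliberately simple: regions are random points in two mirrored
ellipsoids (one per hemisphere), subcortical regions sit medially.  Edge
weights follow an exponential distance rule (EDR), thresholded to a target
density, with per-subject multiplicative lognormal jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .exceptions import DisconnectedGraphError

__all__ = [
    "RegionTable",
    "Connectome",
    "BoldCohort",
    "make_region_table",
    "make_connectome_cohort",
    "make_ground_truth_cohorts",
]

# Subcortical structures included per hemisphere, medial-most first.  The
# first five are the basal-ganglia/thalamic nuclei that any 84-region
# cortical+subcortical scheme carries.
_SUBCORTICAL = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "hippocampus",
    "amygdala",
    "ventraldc",
)

# Hemisphere ellipsoid: semi-axes (mm) and lateral offset of its centre.
_SEMI_AXES = np.array([28.0, 60.0, 45.0])
_LATERAL_OFFSET = 32.0


@dataclass(frozen=True)
class RegionTable:
    """A parcellation: one row per region, fixed ordering for all matrices.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``region_index, name, hemisphere, is_subcortical, x, y, z``;
        coordinates in millimetres (synthetic geometry).
    """

    frame: pd.DataFrame

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    @property
    def coordinates(self) -> np.ndarray:
        return self.frame[["x", "y", "z"]].to_numpy(float)

    def validate(self) -> None:
        f = self.frame
        idx = f["region_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(f))):
            raise ValueError("region_index must be 0..N-1 without gaps")
        if f["name"].duplicated().any():
            raise ValueError("region names must be unique")
        if not set(f["hemisphere"]) <= {"left", "right"}:
            raise ValueError("hemisphere must be 'left' or 'right'")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        t = cls(pd.read_csv(path))
        t.validate()
        return t


@dataclass(frozen=True)
class Connectome:
    """One subject's structural connectivity.

    ``weights`` is a streamline-count-like symmetric nonnegative matrix,
    ``lengths`` the symmetric matrix of streamline lengths in millimetres.
    """

    subject_id: str
    weights: np.ndarray
    lengths: np.ndarray

    def validate(self, atol: float = 1e-10) -> None:
        M, D = self.weights, self.lengths
        if M.shape != D.shape or M.shape[0] != M.shape[1]:
            raise ValueError("weights and lengths must be square and congruent")
        if not np.allclose(M, M.T, atol=atol) or not np.allclose(D, D.T, atol=atol):
            raise ValueError("matrices must be symmetric")
        if np.any(np.diag(M) != 0) or np.any(np.diag(D) != 0):
            raise ValueError("diagonals must be zero")
        if np.any(M < 0) or np.any(D < 0):
            raise ValueError("matrices must be nonnegative")
        if np.any((M > 0) & (D <= 0)):
            raise ValueError("every connected pair needs a positive length")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class BoldCohort:
    """A group of per-subject regional time series under one condition.

    ``series`` holds one ``T x N`` array per subject; durations may differ
    between subjects, the region count and sampling interval may not.
    """

    condition: str  # "control" or "tus"
    series: list[np.ndarray]
    dt_sample: float
    seed: int
    target_region: int | None = None
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_regions(self) -> int:
        return self.series[0].shape[1]

    def validate(self) -> None:
        if self.condition not in ("control", "tus"):
            raise ValueError("condition must be 'control' or 'tus'")
        n = self.n_regions
        for s in self.series:
            if s.shape[1] != n:
                raise ValueError("all subjects must share the region count")
            if np.any(np.std(s, axis=0) == 0):
                raise ValueError("constant (zero-variance) column in series")


def _n_subcortical(n_half: int) -> int:
    """Subcortical count per hemisphere: 8 for the 84-region default (42 per
    hemisphere), scaled down proportionally for small test parcellations."""
    return min(len(_SUBCORTICAL), n_half // 5)


def make_region_table(n_regions: int = 84, seed: int = 0) -> RegionTable:
    """Build a mirrored two-hemisphere parcellation with synthetic geometry.

    Cortical regions are placed near the surface of a hemisphere ellipsoid,
    subcortical regions medially.  The left hemisphere mirrors the right in
    the sagittal (x = 0) plane, so interhemispheric homologues sit at
    mirrored coordinates.

    Parameters
    ----------
    n_regions : int
        Total region count; must be even and at least 4.  Default 84
        (Desikan-Killiany cortex plus subcortical nuclei).
    seed : int
        Seed for the coordinate draw; same seed, same table.
    """
    if n_regions % 2 != 0 or n_regions < 4:
        raise ValueError("n_regions must be even and >= 4")
    rng = np.random.default_rng(seed)
    n_half = n_regions // 2
    n_sub = _n_subcortical(n_half)
    n_ctx = n_half - n_sub

    # Right-hemisphere coordinates; left is the mirror image.
    # Cortex: directions uniform on the sphere, pushed to 80-100% of the
    # ellipsoid surface; subcortex: medial, near the ellipsoid centre.
    u = rng.standard_normal((n_ctx, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radial = rng.uniform(0.8, 1.0, size=(n_ctx, 1))
    ctx = u * radial * _SEMI_AXES
    ctx[:, 0] = np.abs(ctx[:, 0]) + _LATERAL_OFFSET - _SEMI_AXES[0]
    ctx[:, 0] = np.clip(ctx[:, 0], 2.0, None)

    sub = rng.standard_normal((n_sub, 3)) * np.array([3.0, 8.0, 6.0])
    sub[:, 0] = np.abs(sub[:, 0]) + 6.0  # medial but strictly lateralized

    right = np.vstack([ctx, sub]) if n_sub else ctx
    left = right * np.array([-1.0, 1.0, 1.0])

    names_ctx = [f"cortical{i + 1:02d}" for i in range(n_ctx)]
    names_sub = list(_SUBCORTICAL[:n_sub])
    rows = []
    for hemi, coords in (("right", right), ("left", left)):
        suffix = "rh" if hemi == "right" else "lh"
        for k, (name, xyz) in enumerate(
            zip(names_ctx + names_sub, coords, strict=True)
        ):
            rows.append(
                {
                    "name": f"{name}_{suffix}",
                    "hemisphere": hemi,
                    "is_subcortical": k >= n_ctx,
                    "x": xyz[0],
                    "y": xyz[1],
                    "z": xyz[2],
                }
            )
    frame = pd.DataFrame(rows)
    frame.insert(0, "region_index", np.arange(n_regions))
    table = RegionTable(frame)
    table.validate()
    return table


def _lognormal_jitter(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _symmetrize_jitter(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Symmetric matrix of unit-mean lognormal factors, ones on the diagonal."""
    m = n * (n - 1) // 2
    return squareform(_lognormal_jitter(rng, cv, m)) + np.eye(n)


def make_connectome_cohort(
    table: RegionTable,
    n_subjects: int = 20,
    edr_lambda: float = 30.0,
    density: float = 0.35,
    subject_jitter: float = 0.2,
    seed: int = 0,
) -> list[Connectome]:
    """Generate a cohort of EDR connectomes on the table's geometry.

    The group backbone weight decays exponentially with Euclidean distance,
    ``w_ij ~ exp(-d_ij / edr_lambda)``, and is thresholded to the requested
    edge density.  Each subject multiplies backbone weights and Euclidean
    lengths by edge-wise lognormal jitter (unit mean, CV ``subject_jitter``),
    so with ``subject_jitter=0`` every subject equals the backbone exactly.

    Raises
    ------
    DisconnectedGraphError
        If thresholding to ``density`` disconnects the backbone; the error
        reports the largest component size.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    coords = table.coordinates
    n = table.n_regions
    euclid = squareform(pdist(coords))

    backbone = np.exp(-euclid / edr_lambda)
    np.fill_diagonal(backbone, 0.0)
    # Keep the top `density` fraction of the N(N-1)/2 possible edges.
    triu = np.triu_indices(n, k=1)
    n_keep = int(round(density * len(triu[0])))
    order = np.argsort(backbone[triu])[::-1]
    mask_flat = np.zeros(len(triu[0]), dtype=bool)
    mask_flat[order[:n_keep]] = True
    mask = np.zeros((n, n), dtype=bool)
    mask[triu] = mask_flat
    mask |= mask.T
    backbone = np.where(mask, backbone, 0.0)

    n_comp, labels = connected_components(csr_matrix(backbone), directed=False)
    if n_comp > 1:
        largest = int(np.bincount(labels).max())
        raise DisconnectedGraphError(largest, n)

    cohort = []
    for s in range(n_subjects):
        w = backbone * _symmetrize_jitter(rng, subject_jitter, n)
        d = euclid * _symmetrize_jitter(rng, subject_jitter, n)
        np.fill_diagonal(w, 0.0)
        np.fill_diagonal(d, 0.0)
        c = Connectome(subject_id=f"sub-{s + 1:02d}", weights=w, lengths=d)
        c.validate()
        cohort.append(c)
    return cohort


def make_ground_truth_cohorts(
    connectomes: list[Connectome],
    control_params,
    alpha: float,
    target: int,
    seed: int = 0,
    tr: float | None = 2.0,
) -> tuple[BoldCohort, BoldCohort]:
    """Simulate matched control and stimulated BOLD cohorts.

    One simulation per connectome and condition, each with its own seed
    derived from ``seed``.  The control cohort runs the oscillator model with
    ``alpha = 0``; the stimulated cohort adds ``alpha`` to the heterogeneity
    of the target region.  Series are band-pass filtered, trimmed, and (by
    default) decimated to a 2 s fMRI-like sampling interval.

    Parameters
    ----------
    control_params : HopfConfig
        Calibrated control configuration (G, bias, scale, beta, ...).
    alpha : float
        Stimulation intensity for the stimulated cohort.
    target : int
        Stimulated region index.
    tr : float or None
        Sampling interval of the returned series; ``None`` keeps the
        integration grid.
    """
    from dataclasses import replace

    from .hopf import decimate_series, preprocess, simulate

    n = connectomes[0].n_regions
    if not 0 <= target < n:
        raise ValueError(f"target {target} out of range for {n} regions")
    children = np.random.SeedSequence(seed).spawn(2 * len(connectomes))
    cohorts = {}
    for k, (condition, a) in enumerate((("control", 0.0), ("tus", alpha))):
        series = []
        for i, conn in enumerate(connectomes):
            sub_seed = int(children[k * len(connectomes) + i].generate_state(1)[0] % (2**31))
            cfg = replace(
                control_params, alpha=a, target=target if a != 0 else None, seed=sub_seed
            )
            out = simulate(conn, cfg)
            x = preprocess(out.x, cfg)
            dt_sample = cfg.dt
            if tr is not None:
                x, dt_sample = decimate_series(x, cfg.dt, tr)
            series.append(x)
        cohorts[condition] = BoldCohort(
            condition=condition,
            series=series,
            dt_sample=dt_sample,
            seed=seed,
            target_region=target if condition == "tus" else None,
            subject_ids=[c.subject_id for c in connectomes],
        )
    return cohorts["control"], cohorts["tus"]
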