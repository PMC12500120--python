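"""Gaussian integrated information decomposition (MMI) for region pairs.

For two z-scored signals :math:`x, y` observed at times :math:`t-\\tau` and
:math:`t`, the time-delayed mutual information
:math:`I(x_{t-\\tau}, y_{t-\\tau};\\ x_t, y_t)` decomposes into 16 atoms
indexed by pairs of nodes of the partial-information lattice
:math:`\\mathcal{A} = \\{\\{12\\}, \\{1\\}, \\{2\\}, \\{1\\}\\{2\\}\\}` — one
node for how the information was carried in the past, one for how it is
carried in the present.  Atoms are obtained by Möbius inversion of a
cumulative informativeness function on the product lattice
:math:`\\mathcal{A}\\times\\mathcal{A}`.  Under the
minimum-mutual-information (MMI) redundancy function for Gaussian systems,
the cumulative value of a node :math:`\\alpha\\to\\beta` is the minimum of
the Gaussian mutual informations between every source collection composing
:math:`\\alpha` (past variables) and every target collection composing
:math:`\\beta` (present variables).

Two atoms are surfaced throughout the pipeline: persistent redundancy
(``rtr``, redundancy that remains redundancy,
:math:`\\{1\\}\\{2\\}\\to\\{1\\}\\{2\\}`) and persistent synergy (``sts``,
:math:`\\{12\\}\\to\\{12\\}`).  All information quantities are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import DegenerateSignalError, NumericalError

__all__ = [
    "LaggedCov",
    "PhiAtoms",
    "HOIMaps",
    "zscore",
    "lagged_cov",
    "gaussian_mi",
    "build_product_lattice",
    "phiid_mmi_atoms",
    "hoi_matrices",
]

#: Diagonal loading applied when a sample covariance is not positive definite.
EPS_REGULARIZATION = 1e-9

# --------------------------------------------------------------------------
# The PID lattice on two sources and its product with itself.
#
# Each node of A is described by its antichain of source collections; a
# collection is a tuple of source labels (0 and 1).  The partial order is
# "alpha <= beta iff every collection of beta contains some collection of
# alpha" (the usual redundancy-lattice order), which on two sources reduces
# to the chain-with-split drawn below:
#
#          {12}
#         /    \
#       {1}    {2}
#         \    /
#         {1}{2}
# --------------------------------------------------------------------------

_PID_NODES: dict[str, tuple[tuple[int, ...], ...]] = {
    "{1}{2}": ((0,), (1,)),
    "{1}": ((0,),),
    "{2}": ((1,),),
    "{12}": ((0, 1),),
}

_PID_LEQ: dict[tuple[str, str], bool] = {}
for _a, _ca in _PID_NODES.items():
    for _b, _cb in _PID_NODES.items():
        # a <= b iff every collection of b is a superset of some collection of a
        _PID_LEQ[(_a, _b)] = all(
            any(set(ca) <= set(cb) for ca in _ca) for cb in _cb
        )

#: Linear extension of the PID lattice (bottom to top).
_PID_ORDER = ("{1}{2}", "{1}", "{2}", "{12}")


def build_product_lattice() -> tuple[list[str], dict[str, list[str]]]:
    """Return the 16-node product lattice and its strict down-sets.

    Returns
    -------
    nodes : list of str
        The 16 atoms as ``"alpha->beta"`` strings, listed in a linear
        extension of the product order (safe for Möbius recursion).
    downsets : dict
        Maps each node to the list of nodes strictly below it in the
        product order (``alpha' <= alpha`` and ``beta' <= beta``, not both
        equal).
    """
    nodes = [f"{a}->{b}" for a in _PID_ORDER for b in _PID_ORDER]
    downsets: dict[str, list[str]] = {}
    for a in _PID_ORDER:
        for b in _PID_ORDER:
            node = f"{a}->{b}"
            downsets[node] = [
                f"{a2}->{b2}"
                for a2 in _PID_ORDER
                for b2 in _PID_ORDER
                if _PID_LEQ[(a2, a)]
                and _PID_LEQ[(b2, b)]
                and (a2, b2) != (a, b)
            ]
    return nodes, downsets


@dataclass(frozen=True)
class LaggedCov:
    """Sample covariance of ``(x_{t-tau}, y_{t-tau}, x_t, y_t)``.

    Variable order is fixed: indices 0, 1 are the past of the two signals,
    indices 2, 3 their present.
    """

    cov: np.ndarray
    tau: int
    n_samples: int

    def validate(self, tol: float = 1e-8) -> None:
        if self.cov.shape != (4, 4):
            raise ValueError("lagged covariance must be 4x4")
        if not np.allclose(self.cov, self.cov.T, atol=tol):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov)[0] <= 0:
            raise NumericalError("covariance is not positive definite")


@dataclass(frozen=True)
class PhiAtoms:
    """The 16 decomposition atoms of one region pair, in nats."""

    atoms: dict[str, float]
    rtr: float  # persistent redundancy, {1}{2}->{1}{2}
    sts: float  # persistent synergy, {12}->{12}
    tdmi: float  # time-delayed mutual information (sum of all atoms)


@dataclass
class HOIMaps:
    """Pairwise persistence maps and per-region strength summaries.

    Pairwise matrices hold NaN on the diagonal (self-decomposition is not
    defined in the pairwise scheme); medians are taken over off-diagonal
    entries, ranks are ascending (1 = weakest) with ties averaged.
    """

    redundancy: np.ndarray
    synergy: np.ndarray
    median_redundancy: np.ndarray
    median_synergy: np.ndarray
    rank_redundancy: np.ndarray
    rank_synergy: np.ndarray
    tau: int = 1
    n_samples: int = 0
    atoms: list | None = field(default=None, repr=False)  # optional full atoms


def zscore(series: np.ndarray) -> np.ndarray:
    """Standardize a 1-D series to mean 0, variance 1 (ddof=0)."""
    series = np.asarray(series, float)
    sd = series.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("cannot z-score a constant series")
    return (series - series.mean()) / sd


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Ensure positive definiteness via a single diagonal loading."""
    if np.linalg.eigvalsh(cov)[0] > 0:
        return cov
    warnings.warn(
        "covariance not positive definite; adding diagonal regularization",
        RuntimeWarning,
        stacklevel=3,
    )
    cov = cov + EPS_REGULARIZATION * np.eye(cov.shape[0])
    if np.linalg.eigvalsh(cov)[0] <= 0:
        raise NumericalError("covariance singular even after regularization")
    return cov


def lagged_cov(x: np.ndarray, y: np.ndarray, tau: int = 1) -> LaggedCov:
    """Sample covariance of the lagged design ``(x_{t-tau}, y_{t-tau}, x_t, y_t)``.

    Requires ``tau >= 1`` and at least 30 usable samples.  If the sample
    covariance is not positive definite (e.g. ``y`` duplicates ``x``), a
    small diagonal loading is applied with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and congruent")
    T = len(x)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau >= T:
        raise ValueError(f"tau={tau} >= series length {T}")
    if T - tau < 30:
        raise ValueError("need at least 30 usable samples (T - tau >= 30)")
    design = np.column_stack([x[:-tau], y[:-tau], x[tau:], y[tau:]])
    cov = np.cov(design, rowvar=False, ddof=1)
    cov = _regularize(cov)
    return LaggedCov(cov=cov, tau=tau, n_samples=T - tau)


def _mi_from_matrix(cov: np.ndarray, a: tuple, b: tuple) -> float:
    """Gaussian MI between index sets a, b of a covariance matrix, nats."""
    idx_ab = tuple(a) + tuple(b)
    sign_a, ld_a = np.linalg.slogdet(cov[np.ix_(a, a)])
    sign_b, ld_b = np.linalg.slogdet(cov[np.ix_(b, b)])
    sign_ab, ld_ab = np.linalg.slogdet(cov[np.ix_(idx_ab, idx_ab)])
    if sign_a <= 0 or sign_b <= 0 or sign_ab <= 0:
        raise NumericalError("singular submatrix in Gaussian MI")
    return 0.5 * (ld_a + ld_b - ld_ab)


def gaussian_mi(cov: LaggedCov | np.ndarray, set_a, set_b) -> float:
    """Mutual information between two disjoint variable subsets, in nats.

    For jointly Gaussian variables,
    :math:`I(A;B) = \\tfrac12 \\log\\frac{\\det\\Sigma_{AA}\\,\\det\\Sigma_{BB}}
    {\\det\\Sigma_{A\\cup B}}`.
    """
    set_a, set_b = tuple(set_a), tuple(set_b)
    if not set_a or not set_b or set(set_a) & set(set_b):
        raise ValueError("subsets must be disjoint and nonempty")
    mat = cov.cov if isinstance(cov, LaggedCov) else np.asarray(cov, float)
    return _mi_from_matrix(mat, set_a, set_b)


# Past/present variable indices of each PID collection within the 4x4
# lagged covariance: sources live on (0, 1), targets on (2, 3).
_PAST = {(0,): (0,), (1,): (1,), (0, 1): (0, 1)}
_PRESENT = {(0,): (2,), (1,): (3,), (0, 1): (2, 3)}

_LATTICE_NODES, _LATTICE_DOWNSETS = build_product_lattice()


def _mmi_cumulative(cov: np.ndarray) -> dict[str, float]:
    """MMI cumulative value f(alpha->beta) for all 16 product-lattice nodes."""
    # 3x3 table of collection-to-collection MIs, computed once per pair.
    mi: dict[tuple, float] = {}
    for a in _PAST:
        for b in _PRESENT:
            mi[(a, b)] = _mi_from_matrix(cov, _PAST[a], _PRESENT[b])
    f = {}
    for alpha in _PID_ORDER:
        for beta in _PID_ORDER:
            f[f"{alpha}->{beta}"] = min(
                mi[(a, b)]
                for a in _PID_NODES[alpha]
                for b in _PID_NODES[beta]
            )
    return f


def phiid_mmi_atoms(cov: LaggedCov | np.ndarray) -> PhiAtoms:
    """Decompose the time-delayed MI of one pair into its 16 atoms.

    The cumulative informativeness of each product-lattice node is the MMI
    minimum over its source/target collections; atoms follow by Möbius
    inversion along a linear extension:
    ``atom(nu) = f(nu) - sum of atoms strictly below nu``.

    By construction the atoms sum to the cumulative value of the top node,
    which is the time-delayed mutual information of the pair.
    """
    mat = cov.cov if isinstance(cov, LaggedCov) else np.asarray(cov, float)
    f = _mmi_cumulative(mat)
    atoms: dict[str, float] = {}
    for node in _LATTICE_NODES:
        atoms[node] = f[node] - sum(atoms[d] for d in _LATTICE_DOWNSETS[node])
    return PhiAtoms(
        atoms=atoms,
        rtr=atoms["{1}{2}->{1}{2}"],
        sts=atoms["{12}->{12}"],
        tdmi=f["{12}->{12}"],
    )


def _bandpass(series: np.ndarray, band: tuple[float, float], dt: float) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    nyq = 0.5 / dt
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:g})")
    sos = butter(2, band, btype="bandpass", fs=1.0 / dt, output="sos")
    return sosfiltfilt(sos, series, axis=0)


def hoi_matrices(
    subject_series: np.ndarray,
    tau: int = 1,
    band: tuple[float, float] | None = None,
    dt: float | None = None,
    keep_atoms: bool = False,
) -> HOIMaps:
    """Persistent redundancy/synergy maps for one subject's ``T x N`` series.

    Each column is z-scored; for every unordered region pair the lagged
    covariance is assembled and decomposed, and the persistent-redundancy and
    persistent-synergy atoms are stored symmetrically.  Region strengths are
    the row medians of each map (diagonal excluded); ranks are ascending with
    ties averaged.

    Parameters
    ----------
    band, dt : optional
        If given, apply a zero-phase Butterworth band-pass before analysis
        (hook for matching an empirical preprocessing choice).
    keep_atoms : bool
        Retain the full 16-atom decomposition per pair (list indexed by
        ``i * N + j``); off by default to keep the maps light.
    """
    X = np.asarray(subject_series, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a T x N series with N >= 2")
    bad = np.where(X.std(axis=0) == 0)[0]
    if bad.size:
        raise DegenerateSignalError(
            f"constant series in regions {bad.tolist()}; cannot decompose"
        )
    if band is not None:
        if dt is None:
            raise ValueError("dt is required when band is given")
        X = _bandpass(X, band, dt)
    T, N = X.shape
    if T - tau < 30:
        raise ValueError("need at least 30 usable samples (T - tau >= 30)")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)

    # One 2N x 2N lagged covariance, sliced per pair: numerically identical
    # to the per-pair zscore -> lagged_cov route, quadratically cheaper.
    big = np.cov(np.hstack([Z[:-tau], Z[tau:]]), rowvar=False, ddof=1)

    red = np.full((N, N), np.nan)
    syn = np.full((N, N), np.nan)
    all_atoms = [None] * (N * N) if keep_atoms else None
    for i in range(N):
        for j in range(i + 1, N):
            idx = (i, j, N + i, N + j)
            cov = _regularize(big[np.ix_(idx, idx)])
            atoms = phiid_mmi_atoms(cov)
            red[i, j] = red[j, i] = atoms.rtr
            syn[i, j] = syn[j, i] = atoms.sts
            if keep_atoms:
                all_atoms[i * N + j] = atoms

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows cannot occur, N>=2
        med_red = np.nanmedian(red, axis=1)
        med_syn = np.nanmedian(syn, axis=1)
    return HOIMaps(
        redundancy=red,
        synergy=syn,
        median_redundancy=med_red,
        median_synergy=med_syn,
        rank_redundancy=rankdata(med_red),
        rank_synergy=rankdata(med_syn),
        tau=tau,
        n_samples=T - tau,
        atoms=all_atoms,
    )
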