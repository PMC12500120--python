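"""Information decomposition: closed forms, conservation, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tusnet.exceptions import DegenerateSignalError
from tusnet.phiid import (
    LaggedCov,
    build_product_lattice,
    gaussian_mi,
    hoi_matrices,
    lagged_cov,
    phiid_mmi_atoms,
    zscore,
)

from conftest import random_spd


def atoms_via_linear_solve(cov):
    """Independent oracle: solve f = Z a with Z the lattice zeta matrix."""
    nodes, downsets = build_product_lattice()
    # cumulative values recomputed here from first principles (MMI minimum
    # over source/target collection MIs)
    coll = {"{1}{2}": [(0,), (1,)], "{1}": [(0,)], "{2}": [(1,)], "{12}": [(0, 1)]}
    present = {(0,): (2,), (1,): (3,), (0, 1): (2, 3)}
    f = np.empty(len(nodes))
    for k, node in enumerate(nodes):
        a_name, b_name = node.split("->")
        f[k] = min(
            gaussian_mi(cov, a, present[b])
            for a in coll[a_name]
            for b in coll[b_name]
        )
    Z = np.zeros((len(nodes), len(nodes)))
    for i, node in enumerate(nodes):
        Z[i, i] = 1.0
        for below in downsets[node]:
            Z[i, nodes.index(below)] = 1.0
    sol = np.linalg.solve(Z, f)
    return dict(zip(nodes, sol))


class TestZscore:
    def test_constant_series_errors(self):
        with pytest.raises(DegenerateSignalError):
            zscore(np.ones(100))

    def test_moments(self, rng):
        z = zscore(rng.standard_normal(500) * 3 + 7)
        assert abs(z.mean()) < 1e-12
        assert np.isclose(z.var(), 1.0)

    def test_standard_series_unchanged(self, rng):
        x = rng.standard_normal(10000)
        x = (x - x.mean()) / x.std()
        assert np.allclose(zscore(x), x, atol=1e-10)


class TestLaggedCov:
    def test_independent_noise_off_diagonal_small(self, rng):
        T = 20000
        lc = lagged_cov(rng.standard_normal(T), rng.standard_normal(T), tau=1)
        off = lc.cov[np.triu_indices(4, k=1)]
        # drop the two autocovariance-at-lag entries (x_t-1,x_t), (y_t-1,y_t):
        # they are also ~0 for white noise, so keep all six
        assert np.all(np.abs(off) < 3 / np.sqrt(T))

    def test_duplicated_signal_regularized(self, rng):
        x = rng.standard_normal(500)
        with pytest.warns(RuntimeWarning, match="not positive definite"):
            lc = lagged_cov(x, x.copy(), tau=1)
        assert np.linalg.eigvalsh(lc.cov)[0] > 0

    @pytest.mark.parametrize("tau", [1, 2, 3])
    def test_ar1_autocovariance(self, tau):
        # AR(1) x_t = phi x_{t-1} + e has corr(x_{t-tau}, x_t) = phi^tau
        rng = np.random.default_rng(99)
        phi, T = 0.8, 60000
        e = rng.standard_normal(T)
        x = np.empty(T)
        x[0] = e[0]
        for t in range(1, T):
            x[t] = phi * x[t - 1] + e[t]
        lc = lagged_cov(zscore(x), zscore(rng.standard_normal(T)), tau=tau)
        assert lc.cov[0, 2] == pytest.approx(phi**tau, abs=0.03)

    def test_tau_validation(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ValueError):
            lagged_cov(x, x, tau=100)
        with pytest.raises(ValueError):
            lagged_cov(x, x, tau=0)
        with pytest.raises(ValueError):
            lagged_cov(x[:31], x[:31], tau=5)  # fewer than 30 usable samples


class TestGaussianMI:
    def test_identity_covariance_zero(self):
        assert gaussian_mi(np.eye(4), (0, 1), (2, 3)) == pytest.approx(0.0, abs=1e-14)

    def test_bivariate_closed_form(self):
        # I = -0.5 ln(1 - rho^2) for a correlated Gaussian pair
        rho = 0.5
        cov = np.array([[1, rho], [rho, 1]])
        expected = -0.5 * np.log(1 - rho**2)  # 0.14384...
        assert gaussian_mi(cov, (0,), (1,)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.14384, abs=1e-5)

    def test_symmetry(self, rng):
        for _ in range(20):
            S = random_spd(rng)
            assert gaussian_mi(S, (0, 1), (2, 3)) == pytest.approx(
                gaussian_mi(S, (2, 3), (0, 1)), rel=1e-10
            )

    def test_rejects_overlapping_sets(self):
        with pytest.raises(ValueError):
            gaussian_mi(np.eye(4), (0, 1), (1, 2))


class TestLattice:
    def test_sixteen_nodes(self):
        nodes, downsets = build_product_lattice()
        assert len(nodes) == 16
        assert len(set(nodes)) == 16

    def test_bottom_and_top_downsets(self):
        nodes, downsets = build_product_lattice()
        assert downsets["{1}{2}->{1}{2}"] == []
        assert len(downsets["{12}->{12}"]) == 15


class TestPhiidAtoms:
    def test_identity_covariance_all_zero(self):
        atoms = phiid_mmi_atoms(np.eye(4))
        assert all(abs(v) < 1e-12 for v in atoms.atoms.values())

    def test_conservation(self, rng):
        # sum of the 16 atoms equals the time-delayed mutual information
        for _ in range(50):
            S = random_spd(rng)
            atoms = phiid_mmi_atoms(S)
            tdmi = gaussian_mi(S, (0, 1), (2, 3))
            assert sum(atoms.atoms.values()) == pytest.approx(tdmi, abs=1e-8)

    def test_matches_linear_solve_oracle(self, rng):
        for _ in range(30):
            S = random_spd(rng)
            atoms = phiid_mmi_atoms(S)
            oracle = atoms_via_linear_solve(S)
            for node, val in atoms.atoms.items():
                assert val == pytest.approx(oracle[node], abs=1e-10)

    def test_mmi_static_redundancy_identity(self, rng):
        # on the sub-problem with joint target Y = (present pair), the MMI
        # redundancy is exactly min(I(X1;Y), I(X2;Y))
        nodes, downsets = build_product_lattice()
        for _ in range(20):
            S = random_spd(rng)
            atoms = phiid_mmi_atoms(S)
            node = "{1}{2}->{12}"
            cumulative = atoms.atoms[node] + sum(
                atoms.atoms[d] for d in downsets[node]
            )
            expected = min(
                gaussian_mi(S, (0,), (2, 3)), gaussian_mi(S, (1,), (2, 3))
            )
            assert cumulative == pytest.approx(expected, rel=1e-12)

    def test_persistent_redundancy_nonnegative(self, rng):
        for _ in range(30):
            atoms = phiid_mmi_atoms(random_spd(rng))
            assert atoms.rtr >= -1e-12

    @given(seed=st.integers(0, 2**31 - 1), jitter=st.floats(0.05, 1.5))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_decomposition_invariants_property(self, seed, jitter):
        """Conservation, nonnegative persistent redundancy, and the
        top-node identity hold for arbitrary positive-definite covariances."""
        S = random_spd(np.random.default_rng(seed), jitter=jitter)
        atoms = phiid_mmi_atoms(S)
        tdmi = gaussian_mi(S, (0, 1), (2, 3))
        assert sum(atoms.atoms.values()) == pytest.approx(tdmi, abs=1e-8)
        assert atoms.rtr >= -1e-12
        assert atoms.tdmi == pytest.approx(tdmi, rel=1e-12)


class TestHoiMatrices:
    def test_independent_noise_medians_near_zero(self):
        rng = np.random.default_rng(5)
        maps = hoi_matrices(rng.standard_normal((10000, 4)), tau=1)
        assert np.all(np.abs(maps.median_redundancy) < 1e-2)

    def test_matches_per_pair_route(self, rng):
        # the vectorized path must reproduce zscore -> lagged_cov -> atoms
        X = rng.standard_normal((200, 3))
        X[:, 1] += 0.5 * X[:, 0]
        maps = hoi_matrices(X, tau=1)
        for i in range(3):
            for j in range(i + 1, 3):
                lc = lagged_cov(zscore(X[:, i]), zscore(X[:, j]), tau=1)
                atoms = phiid_mmi_atoms(lc)
                assert maps.redundancy[i, j] == pytest.approx(atoms.rtr, abs=1e-10)
                assert maps.synergy[i, j] == pytest.approx(atoms.sts, abs=1e-10)

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((400, 4))
        X[:, 2] += 0.7 * X[:, 0]
        perm = np.array([2, 0, 3, 1])
        a = hoi_matrices(X, tau=1)
        b = hoi_matrices(X[:, perm], tau=1)
        assert np.allclose(
            b.redundancy, a.redundancy[np.ix_(perm, perm)], equal_nan=True
        )
        assert np.allclose(b.median_synergy, a.median_synergy[perm])

    def test_diagonal_is_nan_and_excluded(self, rng):
        maps = hoi_matrices(rng.standard_normal((300, 3)))
        assert np.all(np.isnan(np.diag(maps.redundancy)))
        assert np.all(np.isfinite(maps.median_redundancy))

    def test_rank_vectors_are_tie_averaged_permutations(self, rng):
        maps = hoi_matrices(rng.standard_normal((300, 5)))
        assert sorted(maps.rank_redundancy) == [1, 2, 3, 4, 5]

    def test_degenerate_column_reported(self, rng):
        X = rng.standard_normal((100, 3))
        X[:, 1] = 2.5
        with pytest.raises(DegenerateSignalError, match=r"\[1\]"):
            hoi_matrices(X)

    def test_stationarity_halving(self):
        # doubling T on a stationary process perturbs rtr only by O(1/sqrt T)
        rng = np.random.default_rng(17)
        T = 16000
        drive = rng.standard_normal((T, 1))
        X = 0.6 * drive + rng.standard_normal((T, 3))
        full = hoi_matrices(X, tau=1)
        half = hoi_matrices(X[: T // 2], tau=1)
        assert np.nanmax(np.abs(full.redundancy - half.redundancy)) < 10 / np.sqrt(
            T // 2
        )
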