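"""B-splines, multipole spreading, reciprocal convolution, and agreement of
the mesh with the explicit k-space sum."""

import numpy as np
import pytest
from _helpers import random_traceless

from polarmd import reference as ref
from polarmd.spme import (PMEGrid, bspline_coefficients, default_grid_dims,
                          smooth235, spme_total)
from polarmd.system import ConfigurationError, SimulationBox
from polarmd.units import COULOMB


def naive_bspline(x, n):
    """Direct evaluation of the cardinal B-spline recursion (test oracle)."""
    if n == 1:
        return 1.0 if 0 <= x < 1 else 0.0
    return (x * naive_bspline(x, n - 1)
            + (n - x) * naive_bspline(x - 1, n - 1)) / (n - 1)


class TestBsplines:
    def test_order2_midpoint(self):
        th = bspline_coefficients(0.5, 2, 0)[0]
        assert np.allclose(th, [0.5, 0.5])

    @pytest.mark.parametrize("order", [3, 4, 5, 6, 8])
    def test_partition_of_unity_and_derivative_sums(self, order):
        rng = np.random.default_rng(order)
        for u in rng.uniform(0, 1, 20):
            th, d1, d2, d3 = bspline_coefficients(u, order, 3)
            assert th.sum() == pytest.approx(1.0, abs=1e-14)
            assert abs(d1.sum()) < 1e-13
            assert abs(d2.sum()) < 1e-13
            assert np.all(th >= -1e-15)

    def test_order5_matches_recursion_oracle(self):
        rng = np.random.default_rng(0)
        for u in rng.uniform(0, 1, 200):
            th = bspline_coefficients(u, 5, 0)[0]
            expect = [naive_bspline(u + j, 5) for j in range(5)]
            assert np.allclose(th, expect, atol=1e-13)

    def test_quadrupoles_need_order5(self):
        box = SimulationBox.cubic(10.0)
        with pytest.raises(ConfigurationError):
            PMEGrid(box, 0.5, dims=(16, 16, 16), order=4,
                    has_quadrupoles=True)

    def test_grid_must_cover_spline_support(self):
        box = SimulationBox.cubic(10.0)
        with pytest.raises(ConfigurationError):
            PMEGrid(box, 0.5, dims=(8, 8, 8), order=5)

    def test_table_preset_grid_accepted(self):
        # benchmark preset: 98.5 Å box with a 120-point grid
        box = SimulationBox.cubic(98.5)
        g = PMEGrid(box, 0.4, dims=(120, 120, 120), order=5)
        assert g.dims == (120, 120, 120)

    def test_smooth235(self):
        assert smooth235(17) == 18
        assert smooth235(25) == 25
        assert smooth235(121) == 125
        dims = default_grid_dims((12.4, 12.4, 12.4), 0.675, 5)
        assert all(d >= 10 for d in dims)


class TestSpreading:
    def setup_method(self):
        self.box = SimulationBox.cubic(10.0)
        self.grid = PMEGrid(self.box, 0.5, dims=(20, 20, 20), order=5)

    def test_zero_multipoles_zero_grid(self):
        g = self.grid.spread(np.array([[1.0, 2.0, 3.0]]), np.zeros(1),
                             None, None)
        assert np.all(g == 0)

    def test_charge_sum_conserved(self):
        pos = np.array([[1.2, 3.4, 5.6], [7.0, 0.1, 9.9]])
        g = self.grid.spread(pos, np.array([0.7, -0.2]), None, None)
        assert g.sum() == pytest.approx(0.5, abs=1e-10)

    def test_dipole_spreads_to_zero_total_and_correct_moment(self):
        pos = np.array([[5.0, 5.0, 5.0]])
        mu = np.array([[0.3, -0.1, 0.2]])
        g = self.grid.spread(pos, np.zeros(1), mu, None)
        assert abs(g.sum()) < 1e-12
        # first moment of the grid density reproduces the dipole
        axes = [np.arange(20) * 0.5 for _ in range(3)]
        for c, ax in enumerate(axes):
            shape = [1, 1, 1]
            shape[c] = 20
            m = float(np.sum(g * ax.reshape(shape)))
            assert m == pytest.approx(mu[0, c], abs=1e-6)


class TestReciprocal:
    def test_zero_grid_zero_energy(self):
        box = SimulationBox.cubic(10.0)
        grid = PMEGrid(box, 0.5, dims=(20, 20, 20), order=5)
        phig, e = grid.convolve(np.zeros(grid.dims))
        assert e == 0.0 and np.all(phig == 0)

    def test_wigner_energy_single_charge(self):
        """Full Ewald of one unit charge in a 10 Å cube equals the Wigner
        lattice constant -2.837297/(2L) (mesh-free oracle cross-check)."""
        from polarmd.electrostatics import (background_correction,
                                            self_energy)

        box = SimulationBox.cubic(10.0)
        beta = 0.8
        pos = np.array([[2.0, 3.0, 4.0]])
        q = np.array([1.0])
        out = spme_total(pos, box, q, None, None, beta,
                         dims=(32, 32, 32), order=8, compute_forces=False)
        total = (out["energy"]
                 + self_energy(q, np.zeros((1, 3)), np.zeros((1, 3, 3)), beta)
                 + background_correction(q, beta, box.volume))
        expect = -COULOMB * 2.837297 / 20.0
        assert total == pytest.approx(expect, rel=1e-6)
        oracle = ref.wigner_self_energy(10.0, beta=0.9)
        assert total == pytest.approx(oracle, rel=1e-6)

    def test_matches_explicit_k_oracle(self):
        rng = np.random.default_rng(1)
        box = SimulationBox.cubic(14.0)
        n = 25
        pos = rng.uniform(0, 14, size=(n, 3))
        q = rng.normal(size=n) * 0.3
        q -= q.mean()
        mu = rng.normal(size=(n, 3)) * 0.2
        Q = np.stack([random_traceless(rng) for _ in range(n)])
        beta = 0.5
        ex = ref.ewald_recip_explicit(pos, box, q, mu, Q, beta)
        out = spme_total(pos, box, q, mu, Q, beta, dims=(36, 36, 36),
                         order=8)
        assert out["energy"] == pytest.approx(ex["energy"], rel=1e-6)
        assert np.abs(out["field"] - ex["field"]).max() < \
            1e-6 * np.abs(ex["field"]).max()
        # the raw mesh leaves only a tiny spurious net force
        net = np.abs(out["forces"].sum(axis=0)).max()
        assert net < 1e-5 * np.abs(out["forces"]).max()

    def test_error_decreases_with_grid_and_order(self):
        rng = np.random.default_rng(2)
        box = SimulationBox.cubic(12.0)
        n = 12
        pos = rng.uniform(0, 12, size=(n, 3))
        q = rng.normal(size=n)
        q -= q.mean()
        beta = 0.5
        exact = ref.ewald_recip_explicit(pos, box, q, beta=beta)["energy"]
        errs = []
        for dims, order in (((16, 16, 16), 4), ((24, 24, 24), 6),
                            ((36, 36, 36), 8)):
            e = spme_total(pos, box, q, None, None, beta, dims=dims,
                           order=order, compute_forces=False)["energy"]
            errs.append(abs(e - exact))
        assert errs[0] > errs[1] > errs[2]

    def test_symmetric_charge_pair_forces(self):
        box = SimulationBox.cubic(12.0)
        pos = np.array([[4.0, 6.0, 6.0], [8.0, 6.0, 6.0]])
        q = np.array([1.0, -1.0])
        out = spme_total(pos, box, q, None, None, 0.5, dims=(24, 24, 24),
                         order=6)
        assert np.allclose(out["forces"][0], -out["forces"][1], atol=1e-8)

    def test_recip_force_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        box = SimulationBox.cubic(12.0)
        n = 6
        pos = rng.uniform(2, 10, size=(n, 3))
        q = rng.normal(size=n)
        mu = rng.normal(size=(n, 3)) * 0.2
        Q = np.stack([random_traceless(rng) for _ in range(n)])

        def e_of(p):
            return spme_total(p, box, q, mu, Q, 0.5, dims=(30, 30, 30),
                              order=6, compute_forces=False)["energy"]

        out = spme_total(pos, box, q, mu, Q, 0.5, dims=(30, 30, 30), order=6)
        h = 1e-5
        for (i, c) in ((0, 0), (2, 1), (5, 2)):
            pp = pos.copy()
            pp[i, c] += h
            pm = pos.copy()
            pm[i, c] -= h
            fd = -(e_of(pp) - e_of(pm)) / (2 * h)
            assert out["forces"][i, c] == pytest.approx(fd, rel=1e-6,
                                                        abs=1e-7)

    def test_isolated_dimer_limit(self):
        """Periodic total tends to the bare Coulomb energy as the box grows."""
        from polarmd.electrostatics import (background_correction,
                                            real_space_permanent, self_energy)

        rng = np.random.default_rng(4)
        n = 4
        pos0 = rng.uniform(0, 3, size=(n, 3))
        q = rng.normal(size=n) * 0.2
        q -= q.mean()
        mu = rng.normal(size=(n, 3)) * 0.1
        Q = np.stack([random_traceless(rng) for _ in range(n)])
        bare = ref.coulomb_direct(pos0, q, mu, Q)
        errs = []
        for edge in (20.0, 40.0):
            box = SimulationBox.cubic(edge)
            pos = pos0 + edge / 2
            beta = 0.45
            ii, jj = np.triu_indices(n, k=1)
            rec = spme_total(pos, box, q, mu, Q, beta,
                             dims=(int(edge * 1.5),) * 3, order=8,
                             compute_forces=False)["energy"]
            rl = real_space_permanent(pos, box, (ii, jj), q, mu, Q, beta,
                                      np.ones(len(ii)), False)["energy"]
            slf = self_energy(q, mu, Q, beta)
            errs.append(abs(rec + rl + slf - bare))
        # residual image/boundary interactions vanish with box size
        assert errs[1] < errs[0] / 4.0
        assert errs[1] < 0.05
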