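"""Forward solver physics: reciprocity, symmetry, scaling, Jacobian, noise."""

import numpy as np
import pytest

from eitdct.forward import (ConductivityField, NumericalError,
                            StimulationProtocol, VoltageFrame, add_noise,
                            assign_conductivity, compute_jacobian,
                            normalize_difference, normalized_jacobian,
                            solve_forward)


class TestProtocol:
    def test_measurement_count(self):
        prot = StimulationProtocol(n_elec=16)
        assert prot.n_meas == 16 * 13
        assert len(prot.pairs) == prot.n_meas

    def test_no_measurement_touches_drive(self):
        prot = StimulationProtocol(n_elec=16)
        for d, m in prot.pairs:
            assert {m, (m + 1) % 16}.isdisjoint({d, (d + 1) % 16})


class TestConductivityAssignment:
    def test_lung_background_values(self, phantom, small_mesh):
        field = assign_conductivity(small_mesh, phantom.lung_mask,
                                    phantom.extent, 0.5, 1.0)
        assert set(np.unique(field.sigma)) == {0.5, 1.0}

    def test_all_zero_mask_uniform(self, phantom, small_mesh):
        field = assign_conductivity(small_mesh, np.zeros_like(phantom.lung_mask),
                                    phantom.extent, 0.5, 1.0)
        assert np.all(field.sigma == 1.0)

    def test_matches_centroid_lookup_oracle(self, phantom, small_mesh):
        field = assign_conductivity(small_mesh, phantom.lung_mask,
                                    phantom.extent, 0.5, 1.0)
        ext = phantom.extent
        for e, (cx, cy) in enumerate(small_mesh.element_centroids()):
            col = int((cx - ext.x_min) / ext.dx)
            row = int((ext.y_max - cy) / ext.dy)
            expected = 0.5 if phantom.lung_mask[row, col] else 1.0
            assert field.sigma[e] == expected

    def test_positive_conductivity_enforced(self):
        with pytest.raises(ValueError):
            ConductivityField(sigma=np.array([1.0, -0.5]))


class TestForwardSolve:
    def test_reciprocity(self, phantom, protocol):
        from eitdct.mesh import build_mesh

        mesh = build_mesh(phantom, 16, 800)
        field = assign_conductivity(mesh, phantom.lung_mask, phantom.extent,
                                    0.5, 1.0)
        v = solve_forward(mesh, field, protocol).v
        vals = dict(zip(protocol.pairs, v))
        for (d, m), val in vals.items():
            assert vals[(m, d)] == pytest.approx(val, rel=1e-8)

    def test_rotational_symmetry_on_disk(self, disk_mesh, protocol):
        field = ConductivityField(np.ones(disk_mesh.n_elem))
        v = solve_forward(disk_mesh, field, protocol).v
        vals = dict(zip(protocol.pairs, v))
        for (d, m), val in vals.items():
            rotated = vals[((d + 1) % 16, (m + 1) % 16)]
            assert rotated == pytest.approx(val, rel=1e-6)

    def test_conductivity_scaling_halves_voltages(self, disk_mesh, protocol):
        f1 = ConductivityField(np.ones(disk_mesh.n_elem))
        f2 = ConductivityField(2 * np.ones(disk_mesh.n_elem))
        v1 = solve_forward(disk_mesh, f1, protocol).v
        v2 = solve_forward(disk_mesh, f2, protocol).v
        assert np.allclose(2 * v2, v1, rtol=1e-12)

    def test_normalized_signal_current_invariant(self, disk_mesh):
        """Drive amplitude cancels in the normalized difference."""
        sig0 = np.ones(disk_mesh.n_elem)
        sig1 = sig0.copy()
        sig1[:100] = 0.5
        ys = []
        for amp in (1.0, 3.0):
            prot = StimulationProtocol(n_elec=16, current=amp)
            vb = solve_forward(disk_mesh, ConductivityField(sig0), prot)
            v = solve_forward(disk_mesh, ConductivityField(sig1), prot)
            ys.append(normalize_difference(v, vb))
        assert np.allclose(ys[0], ys[1], rtol=1e-12)


class TestJacobian:
    def test_shape(self, small_mesh, small_jacobian, protocol):
        _, jac = small_jacobian
        assert jac.J.shape == (protocol.n_meas, small_mesh.n_elem)

    def test_columns_match_finite_differences(self, small_mesh, small_jacobian,
                                              protocol, rng):
        lin, jac = small_jacobian
        v0 = solve_forward(small_mesh, lin, protocol).v
        delta = 1e-6
        for j in rng.choice(small_mesh.n_elem, size=12, replace=False):
            s = lin.sigma.copy()
            s[j] += delta
            fd = (solve_forward(small_mesh, ConductivityField(s), protocol).v
                  - v0) / delta
            err = np.linalg.norm(fd - jac.J[:, j]) / np.linalg.norm(jac.J[:, j])
            assert err <= 1e-3

    def test_symmetry_related_columns_equal_norm(self, disk_mesh, protocol):
        field = ConductivityField(np.ones(disk_mesh.n_elem))
        J = compute_jacobian(disk_mesh, field, protocol).J
        norms = np.linalg.norm(J, axis=0)
        # the innermost fan: 32 elements mapped onto each other by rotation
        nb = 32
        assert np.allclose(norms[:nb], norms[0], rtol=1e-9)

    def test_normalized_jacobian_row_scaling(self, small_mesh, small_jacobian,
                                             protocol):
        lin, jac = small_jacobian
        vb = solve_forward(small_mesh, lin, protocol)
        Jn = normalized_jacobian(jac, vb)
        assert np.allclose(Jn * vb.v[:, None], jac.J)


class TestNormalizedDifference:
    def test_identical_frames_zero(self, protocol):
        v = VoltageFrame(np.linspace(1, 2, protocol.n_meas), protocol)
        assert np.allclose(normalize_difference(v, v), 0.0)

    def test_doubled_frame_gives_ones(self, protocol):
        vb = VoltageFrame(np.linspace(1, 2, protocol.n_meas), protocol)
        v = VoltageFrame(2 * vb.v, protocol)
        assert np.allclose(normalize_difference(v, vb), 1.0)

    def test_hand_case(self):
        prot = StimulationProtocol(n_elec=16)
        vb = np.ones(prot.n_meas)
        vv = np.ones(prot.n_meas)
        vb[0], vb[1] = 2.0, 4.0
        vv[0], vv[1] = 1.0, 5.0
        y = normalize_difference(VoltageFrame(vv, prot), VoltageFrame(vb, prot))
        assert y[0] == pytest.approx(-0.5)
        assert y[1] == pytest.approx(0.25)

    def test_zero_baseline_names_index(self, protocol):
        vb = np.ones(protocol.n_meas)
        vb[7] = 0.0
        with pytest.raises(NumericalError, match="7"):
            normalize_difference(VoltageFrame(np.ones(protocol.n_meas), protocol),
                                 VoltageFrame(vb, protocol))


class TestNoise:
    def test_zero_percent_identity(self, rng):
        y = rng.normal(size=208)
        assert np.array_equal(add_noise(y, 0.0, seed=1), y)

    def test_seed_reproducible(self, rng):
        y = rng.normal(size=208)
        assert np.array_equal(add_noise(y, 25.0, seed=42),
                              add_noise(y, 25.0, seed=42))
        assert not np.array_equal(add_noise(y, 25.0, seed=42),
                                  add_noise(y, 25.0, seed=43))

    def test_noise_level_is_25_percent_of_rms(self, rng):
        """Monte-Carlo check of the noise contract over 1000 seeds."""
        y = rng.normal(size=208)
        rms = np.sqrt(np.mean(y**2))
        devs = np.concatenate([add_noise(y, 25.0, seed=s) - y
                               for s in range(1000)])
        assert devs.std() / rms == pytest.approx(0.25, abs=0.01)
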