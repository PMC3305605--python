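"""REV permeability upscaling and auxiliary closed-form parameters."""

import math

import numpy as np
import pytest

from lungflow.upscaling import (
    CapillaryNetwork,
    CapillarySegment,
    PermeabilityTensor,
    build_hexagonal_capillary_bed,
    capillary_surface_density,
    rev_permeability,
    rev_permeability_tensor,
    rotate_tensor_to_shell,
    rotation_matrix_z_to,
    stokes_einstein_diffusivity,
    tumor_permeability,
)

CUBOID = (364e-6, 364e-6, 112e-6)
MU = 2.1e-3


def straight_tube_network(r=4e-6, n_segments=1, cuboid=CUBOID):
    """Collinear tube(s) spanning the cuboid in x at mid height."""
    Lx, Ly, Lz = cuboid
    xs = np.linspace(0.0, Lx, n_segments + 1)
    nodes = {i: (float(x), Ly / 2, Lz / 2) for i, x in enumerate(xs)}
    segments = [
        CapillarySegment(id=i, node_a=i, node_b=i + 1, radius=r,
                         length=float(xs[i + 1] - xs[i]))
        for i in range(n_segments)
    ]
    faces = {0: frozenset({"x_lo"}), n_segments: frozenset({"x_hi"})}
    return CapillaryNetwork(nodes=nodes, segments=segments,
                            cuboid_dims=cuboid, face_labels=faces)


class TestHoneycombBed:
    def test_segment_count_near_requested(self, honeycomb_bed):
        n = honeycomb_bed.metadata["n_segments"]
        assert n == honeycomb_bed.n_segments
        assert abs(n - 1800) <= 0.2 * 1800

    def test_uniform_diameter(self, honeycomb_bed):
        assert all(s.radius == 4e-6 for s in honeycomb_bed.segments)

    def test_planar(self, honeycomb_bed):
        zs = {pos[2] for pos in honeycomb_bed.nodes.values()}
        assert zs == {56e-6}

    def test_interior_degree_three(self, honeycomb_bed):
        from collections import Counter

        deg = Counter()
        for s in honeycomb_bed.segments:
            deg[s.node_a] += 1
            deg[s.node_b] += 1
        interior = [n for n in honeycomb_bed.nodes
                    if n not in honeycomb_bed.face_labels]
        assert interior
        # interior honeycomb vertices have three bonds
        assert all(deg[n] == 3 for n in interior)

    def test_too_small_cuboid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_hexagonal_capillary_bed(cuboid=(1e-5, 1e-5, 1e-5))


class TestRevPermeability:
    def test_single_tube_closed_form(self):
        net = straight_tube_network()
        K = rev_permeability(net, "x", 100.0, 0.0, MU)
        r = 4e-6
        A_x = CUBOID[1] * CUBOID[2]
        assert K == pytest.approx(math.pi * r**4 / (8 * A_x), rel=1e-12)

    def test_segmented_tube_interior_pressures_linear(self):
        # a chain of collinear tube segments is a discrete 1D Darcy column:
        # interior node pressures must fall linearly in x
        from lungflow.hemodynamics import BloodProperties, PressureSystem

        net = straight_tube_network(n_segments=8)
        graph = net.to_vascular_graph()
        blood = BloodProperties(plasma_viscosity=MU,
                                hematocrit_table=((1.0, 0.0),))
        sys = PressureSystem(graph, blood, {0: 100.0, 8: 0.0})
        sol = sys.solve()
        for i in range(9):
            assert sol.pressures[i] == pytest.approx(100.0 * (1 - i / 8),
                                                     abs=1e-9)

    def test_brute_force_conductance_oracle(self):
        # two parallel x-spanning paths: a single tube and a two-segment
        # chain of half length each; total conductance is the sum of the
        # single-tube conductance and the series combination
        Lx, Ly, Lz = CUBOID
        r1, r2 = 4e-6, 3e-6
        nodes = {
            0: (0.0, Ly / 3, Lz / 2), 1: (Lx, Ly / 3, Lz / 2),
            2: (0.0, 2 * Ly / 3, Lz / 2), 3: (Lx / 2, 2 * Ly / 3, Lz / 2),
            4: (Lx, 2 * Ly / 3, Lz / 2),
        }
        segments = [
            CapillarySegment(0, 0, 1, r1, Lx),
            CapillarySegment(1, 2, 3, r2, Lx / 2),
            CapillarySegment(2, 3, 4, r2, Lx / 2),
        ]
        faces = {0: frozenset({"x_lo"}), 2: frozenset({"x_lo"}),
                 1: frozenset({"x_hi"}), 4: frozenset({"x_hi"})}
        net = CapillaryNetwork(nodes, segments, CUBOID, faces)
        g_tube = math.pi * r1**4 / (8 * MU * Lx)
        g_half = math.pi * r2**4 / (8 * MU * (Lx / 2))
        g_total = g_tube + g_half / 2  # two equal conductances in series
        K_expected = g_total * MU * Lx / (Ly * Lz)
        K = rev_permeability(net, "x", 100.0, 0.0, MU)
        assert K == pytest.approx(K_expected, rel=1e-12)

    def test_planar_bed_zero_z_permeability(self, honeycomb_bed):
        with pytest.warns(UserWarning, match="no vessel endpoint"):
            K_z = rev_permeability(honeycomb_bed, "z")
        assert K_z == 0.0

    def test_planar_bed_positive_in_plane_permeability(self, honeycomb_bed):
        assert rev_permeability(honeycomb_bed, "x") > 0.0
        assert rev_permeability(honeycomb_bed, "y") > 0.0

    def test_probing_pressure_invariance(self):
        net = straight_tube_network()
        K1 = rev_permeability(net, "x", 100.0, 0.0, MU)
        K2 = rev_permeability(net, "x", 200.0, 0.0, MU)
        K3 = rev_permeability(net, "x", 50.0, -50.0, MU)
        assert K2 == pytest.approx(K1, rel=1e-14)
        assert K3 == pytest.approx(K1, rel=1e-14)

    def test_equal_pressures_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            rev_permeability(straight_tube_network(), "x", 100.0, 100.0)

    def test_tensor_assembly(self, honeycomb_bed):
        T = rev_permeability_tensor(honeycomb_bed)
        assert T.frame == "cuboid"
        assert T.K[2, 2] == 0.0
        assert T.K[0, 0] > 0 and T.K[1, 1] > 0


class TestTensorRotation:
    def test_identity_rotation(self):
        K = PermeabilityTensor.diagonal(1e-14, 2e-14, 0.0)
        K2 = rotate_tensor_to_shell(K, (0.0, 0.0, 1.0))
        assert np.allclose(K2.K, K.K)
        assert K2.frame == "shell_local"

    def test_rotation_preserves_eigenvalues(self):
        K = PermeabilityTensor.diagonal(1e-14, 2e-14, 3e-15)
        n = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        K2 = rotate_tensor_to_shell(K, n)
        w1 = np.sort(np.linalg.eigvalsh(K.K))
        w2 = np.sort(np.linalg.eigvalsh(K2.K))
        assert np.allclose(w1, w2, rtol=1e-12)
        assert np.isclose(np.linalg.det(K.K), np.linalg.det(K2.K))
        assert np.isclose(np.trace(K.K), np.trace(K2.K))

    def test_planar_tensor_has_zero_normal_component(self):
        K = PermeabilityTensor.diagonal(1.5e-14, 2.2e-14, 0.0)
        for n in ([1, 0, 0], [0, 1, 0], [0.6, 0.0, 0.8]):
            n = np.asarray(n, dtype=float)
            n /= np.linalg.norm(n)
            K2 = rotate_tensor_to_shell(K, n)
            assert K2.normal_component(n) == pytest.approx(0.0, abs=1e-28)

    def test_rotation_matrix_maps_z_to_normal(self):
        for n in ([0, 0, 1], [0, 0, -1], [1, 0, 0], [0.36, 0.48, 0.8]):
            n = np.asarray(n, dtype=float)
            n /= np.linalg.norm(n)
            R = rotation_matrix_z_to(n)
            assert np.allclose(R @ [0, 0, 1], n, atol=1e-12)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)


class TestClosedForms:
    def test_tumor_permeability_value(self):
        K = tumor_permeability(10e-6)
        assert K.K[0, 0] == pytest.approx(1.25e-11)
        assert np.allclose(K.K, K.K[0, 0] * np.eye(3))

    def test_tumor_permeability_quadratic_scaling(self):
        assert tumor_permeability(20e-6).K[0, 0] == pytest.approx(
            4 * tumor_permeability(10e-6).K[0, 0])

    def test_tumor_permeability_consistent_with_tube_rev(self):
        # a single tube probed through its own cross-section: pi r^4 / 8 /
        # (pi r^2) = r^2/8
        r = 4e-6
        Lx = 100e-6
        nodes = {0: (0.0, 0.0, 0.0), 1: (Lx, 0.0, 0.0)}
        segs = [CapillarySegment(0, 0, 1, r, Lx)]
        faces = {0: frozenset({"x_lo"}), 1: frozenset({"x_hi"})}
        # cuboid whose x-face is the tube's own cross-section area
        A = math.pi * r**2
        side = math.sqrt(A)
        net = CapillaryNetwork(nodes, segs, (Lx, side, side), faces)
        K = rev_permeability(net, "x", 100.0, 0.0, MU)
        assert K == pytest.approx(tumor_permeability(r).K[0, 0], rel=1e-12)

    def test_stokes_einstein_value(self):
        D = stokes_einstein_diffusivity(310.15, 2.1e-3, 3.7e-9)
        assert D == pytest.approx(2.92e-11, rel=0.01)

    def test_stokes_einstein_scalings(self):
        D = stokes_einstein_diffusivity(310.15, 2.1e-3, 3.7e-9)
        assert stokes_einstein_diffusivity(310.15, 4.2e-3, 3.7e-9) == \
            pytest.approx(D / 2)
        assert stokes_einstein_diffusivity(0.0, 2.1e-3, 3.7e-9) == 0.0

    def test_capillary_surface_density_value(self):
        sv = capillary_surface_density(1800, 4e-6, 1e-5, 182e-6, 70e-6)
        assert sv == pytest.approx(1.90e4, rel=0.01)

    def test_capillary_surface_density_scalings(self):
        sv = capillary_surface_density(1800, 4e-6, 1e-5, 182e-6, 70e-6)
        assert capillary_surface_density(0, 4e-6, 1e-5, 182e-6, 70e-6) == 0.0
        assert capillary_surface_density(3600, 4e-6, 1e-5, 182e-6, 70e-6) == \
            pytest.approx(2 * sv)

    def test_degenerate_shell_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            capillary_surface_density(1800, 4e-6, 1e-5, 70e-6, 182e-6)
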