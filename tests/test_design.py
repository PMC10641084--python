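"""Ring-phase parameterization, penalty machinery and fabrication tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpfscope.config import OpticalConfig
from bpfscope.design import (
    BPFDesign,
    FabricationSpec,
    PhaseVector,
    binarize,
    bpf_feature_loss,
    cpm_phase_map,
    equal_width_edges,
    etch_depth,
    export_design,
    init_phase,
    load_design,
    make_fabrication_spec,
    penalize,
    penalty_gradient,
    phase_at_wavelength,
    ring_index_map,
    ring_phase_map,
    wrap_phase,
)
from bpfscope.optics import make_pupil_grid


class TestPenalty:
    def test_zero_at_origin(self):
        assert penalize(np.array([0.0]))[0] == 0.0

    def test_value_at_pi(self):
        # direct polynomial evaluation: pi^7/7 - 2 pi^7/5 + pi^7/3 = 8 pi^7/105
        assert penalize(np.array([np.pi]))[0] == pytest.approx(
            8 * np.pi**7 / 105, rel=1e-12
        )

    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, phi):
        assert penalize(np.array([-phi]))[0] == pytest.approx(
            -penalize(np.array([phi]))[0], abs=1e-9
        )

    def test_monotone_on_domain(self):
        grid = np.linspace(-np.pi, np.pi, 10001)
        vals = penalize(grid)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_gradient_zero_exactly_at_wells(self):
        wells = np.array([-np.pi, 0.0, np.pi])
        assert np.all(penalty_gradient(wells) == 0.0)
        grid = np.linspace(-np.pi, np.pi, 10001)[1:-1]
        off = grid[np.abs(grid) > 1e-12]
        assert np.all(penalty_gradient(off) > 0.0)

    def test_gradient_value_at_half_pi(self):
        # phi^2 (phi-pi)^2 (phi+pi)^2 at pi/2 -> 9 pi^6 / 64
        assert penalty_gradient(np.array([np.pi / 2]))[0] == pytest.approx(
            9 * np.pi**6 / 64, rel=1e-12
        )

    def test_gradient_matches_finite_difference_of_penalize(self):
        phi = np.linspace(-3.0, 3.0, 31)
        eps = 1e-6
        fd = (penalize(phi + eps) - penalize(phi - eps)) / (2 * eps)
        assert np.allclose(penalty_gradient(phi), fd, rtol=1e-6, atol=1e-5)


class TestFeatureLoss:
    def test_zero_at_wells(self):
        assert bpf_feature_loss(np.array([0.0, np.pi, -np.pi, 0.0])) == 0.0

    def test_single_element_norm(self):
        assert bpf_feature_loss(np.array([np.pi / 2])) == pytest.approx(
            9 * np.pi**6 / 64, rel=1e-12
        )

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_zero_iff_binary(self, phis):
        phis = np.array(phis)
        loss = bpf_feature_loss(phis)
        at_wells = np.all(
            np.isclose(phis, 0) | np.isclose(np.abs(phis), np.pi)
        )
        if at_wells:
            assert loss < 1e-9
        else:
            assert loss > 0


class TestBinarize:
    def test_wells_map_to_binary(self):
        d = binarize(np.array([-np.pi, 0.0, np.pi]))
        assert np.allclose(d.binary_phases, [np.pi, 0.0, np.pi])

    def test_threshold_rule(self):
        d = binarize(np.array([0.3, 2.9, -2.0]))
        assert np.allclose(d.binary_phases, [0.0, np.pi, np.pi])

    def test_idempotent(self):
        d1 = binarize(np.array([0.4, -3.0, 1.8, 0.0]))
        d2 = binarize(d1.binary_phases)
        assert np.array_equal(d1.binary_phases, d2.binary_phases)

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.1]), threshold=4.0)


class TestInitPhase:
    def test_axicon_zero_slope(self):
        pv = init_phase("axicon", 6, 0.0)
        assert np.all(pv.phases == 0.0)

    def test_axicon_values(self):
        pv = init_phase("axicon", 4, np.pi)
        centers = np.array([0.125, 0.375, 0.625, 0.875])
        assert np.allclose(pv.phases, wrap_phase(np.pi * centers))

    def test_spherical_zero(self):
        pv = init_phase("spherical", 5, 0.0)
        assert np.all(pv.phases == 0.0)

    def test_custom_requires_k_values(self):
        with pytest.raises(ValueError):
            init_phase("custom", 4, np.array([1.0, 2.0]))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            init_phase("vortex", 4, 1.0)


class TestRingPhaseMap:
    def test_single_ring_constant(self, paper_optics):
        grid = make_pupil_grid(paper_optics)
        pm = ring_phase_map(PhaseVector(np.array([1.2])), grid)
        inside = grid.circ_mask.astype(bool)
        assert np.all(pm[inside] == 1.2)

    def test_half_open_edge_convention(self, paper_optics):
        grid = make_pupil_grid(paper_optics)
        k = 64
        idx = ring_index_map(grid, equal_width_edges(k))
        # a pixel with rho exactly 0.5 belongs to ring 33 (1-based)
        on_edge = np.isclose(grid.rho, 0.5)
        if on_edge.any():
            assert np.all(idx[on_edge] == 32)
        # generic arithmetic: rho = 0.5 + tiny -> floor(0.5 * 64) = ring 33
        r = 0.50001
        assert int(np.floor(r * k)) == 32

    def test_matches_bruteforce_ring_search(self, paper_optics, rng):
        grid = make_pupil_grid(paper_optics)
        k = 7
        edges = np.sort(np.concatenate([[0.0, 1.0],
                                        rng.uniform(0.05, 0.95, k - 1)]))
        phases = rng.uniform(-np.pi, np.pi, k)
        pm = ring_phase_map(PhaseVector(phases), grid, edges=edges)
        rho = grid.rho
        brute = np.zeros_like(rho)
        for i in range(k):
            sel = (rho >= edges[i]) & (rho < edges[i + 1])
            brute[sel] = phases[i]
        brute[rho >= 1.0] = 0.0
        inside = rho < 1.0
        assert np.array_equal(pm[inside], brute[inside])

    def test_outside_pupil_zero(self, paper_optics, rng):
        grid = make_pupil_grid(paper_optics)
        pm = ring_phase_map(PhaseVector(rng.uniform(-3, 3, 5)), grid)
        assert np.all(pm[grid.rho > 1.0] == 0.0)


class TestFabrication:
    def test_paper_etch_depth(self):
        # N-BK7 at 525 nm: printed etch depth 509 nm
        assert etch_depth(525.0, 1.5157) == pytest.approx(509.0, abs=0.5)

    def test_unit_contrast_case(self):
        assert etch_depth(633.0, 1.5, 1.0) == pytest.approx(633.0, rel=1e-12)

    def test_bk7_like_index(self):
        assert etch_depth(525.0, 1.52) == pytest.approx(504.8, abs=0.05)

    def test_rejects_nonphysical_indices(self):
        with pytest.raises(ValueError):
            etch_depth(525.0, 0.9)

    def test_phase_at_design_wavelength_is_pi(self):
        spec = FabricationSpec(
            etch_depth_nm=etch_depth(525.0, 1.5157),
            ring_edges_physical_mm=np.array([0.0, 5.0]),
            etched_flags=np.array([True]),
            substrate_index=1.5157,
        )
        assert phase_at_wavelength(spec, 525.0) == pytest.approx(
            np.pi, abs=1e-12
        )

    def test_phase_vanishes_at_long_wavelength(self):
        spec = FabricationSpec(509.0, np.array([0.0, 5.0]),
                               np.array([True]), 1.5157)
        assert phase_at_wavelength(spec, 1e9) < 1e-5

    def test_chromatic_example(self):
        spec = FabricationSpec(509.0, np.array([0.0, 5.0]),
                               np.array([True]), 1.515)
        val = phase_at_wavelength(spec, 635.0, 1.515)
        assert val == pytest.approx(2 * np.pi * 509 * 0.515 / 635, rel=1e-12)
        assert val == pytest.approx(2.594, abs=2e-3)


class TestDesignIO:
    def test_roundtrip(self, tmp_path):
        d = binarize(np.array([0.2, 3.0, -2.9, 0.1, 2.0]))
        path = tmp_path / "design.json"
        export_design(d, path)
        loaded = load_design(path)
        assert np.array_equal(loaded.binary_phases, d.binary_phases)
        assert np.allclose(loaded.ring_edges, d.ring_edges)

    def test_csv_row_count(self, tmp_path):
        d = binarize(np.linspace(-np.pi, np.pi, 9))
        export_design(d, tmp_path / "d.json")
        rows = (tmp_path / "d.csv").read_text().strip().splitlines()
        assert len(rows) == 1 + 9  # header + one row per ring

    def test_all_zero_design_no_etched_rings(self, tmp_path):
        d = binarize(np.zeros(6))
        spec = export_design(d, tmp_path / "z.json")
        assert not spec.etched_flags.any()


def test_cpm_phase_is_cubic_and_masked(paper_optics):
    grid = make_pupil_grid(paper_optics)
    pm = cpm_phase_map(grid, strength=10.0)
    assert np.all(pm[grid.rho > 1.0] == 0.0)
    # antisymmetric under point reflection within the pupil
    n = paper_optics.grid_size
    c = n // 2
    assert pm[c + 5, c + 3] == pytest.approx(-pm[c - 5, c - 3], rel=1e-9)
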