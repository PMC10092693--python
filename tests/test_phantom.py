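"""Phantom generation, interventions (cuts/bridges) and rasterization."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mitoquant.io import VoxelSpacing
from mitoquant.metrics import compute_metrics
from mitoquant.phantom import (
    PhantomSpec,
    _dense_samples,
    _voxel_centers_um,
    expand_network,
    fragment_network,
    generate_network,
    noise_for_snr,
    rasterize,
)


class TestSpecValidation:
    def test_radius_rasterizability_bound(self):
        with pytest.raises(ValueError, match="rasterizable"):
            PhantomSpec(tubule_radius_um=0.1)  # < dz/2 at default spacing

    def test_bad_topology(self):
        with pytest.raises(ValueError):
            PhantomSpec(topology="weird")

    def test_cells_must_fit(self):
        with pytest.raises(ValueError):
            generate_network(PhantomSpec(n_cells=4, shape=(20, 64, 64)))


class TestGenerate:
    def test_deterministic_given_seed(self):
        spec = PhantomSpec(seed=21)
        a, b = generate_network(spec), generate_network(spec)
        assert a.graph.n_edges == b.graph.n_edges
        for (ea, eb) in zip(
            sorted(a.graph.g.edges(keys=True, data=True), key=lambda e: e[:3]),
            sorted(b.graph.g.edges(keys=True, data=True), key=lambda e: e[:3]),
        ):
            assert np.array_equal(ea[3]["polyline"], eb[3]["polyline"])

    def test_single_straight_tubule_has_exact_length(self):
        spec = PhantomSpec(
            n_tubules=1, curvature=0.0, tubule_length_um=(5.0, 5.0), seed=8,
            cell_radius_um=4.5, shape=(20, 160, 160),
        )
        truth = generate_network(spec)
        m = compute_metrics(truth.graph)
        assert (m.n_nodes, m.n_edges) == (2, 1)
        assert m.total_length_um == pytest.approx(5.0, abs=1e-6)

    def test_filamentous_fuses_into_one_component(self):
        truth = generate_network(PhantomSpec(seed=2, topology="filamentous"))
        m = compute_metrics(truth.graph)
        assert m.n_components == 1
        assert m.phi == pytest.approx(1.0)

    def test_fragmented_mode_all_disjoint(self):
        spec = PhantomSpec(seed=2, topology="fragmented", n_tubules=7)
        m = compute_metrics(generate_network(spec).graph)
        assert m.n_components == 7
        assert m.n_junction3 == 0

    def test_tubules_contained_in_their_cells(self):
        truth = generate_network(PhantomSpec(seed=6, n_cells=2, shape=(20, 128, 200)))
        for _, _, d in truth.graph.g.edges(data=True):
            cell = truth.cells[d["cell"]]
            assert cell.contains(d["polyline"]).all()


class TestFragment:
    def test_zero_cuts_is_identity(self, default_truth):
        out = fragment_network(default_truth, 0, seed=1)
        assert out.graph.n_edges == default_truth.graph.n_edges
        assert out.total_length() == pytest.approx(default_truth.total_length())

    def test_one_cut_on_single_edge(self):
        spec = PhantomSpec(n_tubules=1, curvature=0.0, tubule_length_um=(5.0, 5.0),
                           seed=8, shape=(20, 160, 160))
        truth = generate_network(spec)
        cut = fragment_network(truth, 1, seed=3)
        m = compute_metrics(cut.graph)
        assert m.n_components == 2
        assert m.n_free_ends == 4
        assert cut.total_length() == pytest.approx(truth.total_length() - 0.8, abs=1e-6)

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_acyclic_components_grow_by_k(self, k):
        truth = generate_network(PhantomSpec(seed=14))  # filamentous tree
        base = compute_metrics(truth.graph).n_components
        out = fragment_network(truth, k, seed=50 + k)
        assert compute_metrics(out.graph).n_components == base + k

    def test_strictly_decreases_length(self, default_truth):
        out = fragment_network(default_truth, 5, seed=9)
        assert out.total_length() < default_truth.total_length()

    def test_infeasible_cuts_do_feasible_maximum(self):
        spec = PhantomSpec(n_tubules=1, curvature=0.0, tubule_length_um=(3.0, 3.0),
                           seed=8, shape=(20, 160, 160))
        truth = generate_network(spec)
        out = fragment_network(truth, 50, seed=1)  # far more cuts than fit
        assert compute_metrics(out.graph).n_components >= 2
        assert out.total_length() > 0


class TestExpand:
    def test_zero_bridges_is_identity(self, default_truth):
        out = expand_network(default_truth, 0, seed=1)
        assert out.graph.n_edges == default_truth.graph.n_edges

    def test_bridge_between_path_ends_forms_cycle(self):
        from mitoquant.phantom import CellGeometry, GroundTruth
        from mitoquant.skeleton import SkeletonGraph

        # 3-node path A-B-C; only (A, C) is an eligible bridge pair
        g = SkeletonGraph()
        a = g.add_node((4.0, 6.0, 6.0), cell=0)
        b = g.add_node((6.0, 6.0, 6.0), cell=0)
        c = g.add_node((8.0, 6.0, 6.0), cell=0)
        g.add_edge(a, b, [(4, 6, 6), (6, 6, 6)], cell=0)
        g.add_edge(b, c, [(6, 6, 6), (8, 6, 6)], cell=0)
        g.refresh_kinds()
        spec = PhantomSpec(seed=0, shape=(20, 160, 160))
        truth = GroundTruth(g, [CellGeometry((6.0, 6.0, 6.0), (4.5, 4.5, 4.5))], spec)
        out = expand_network(truth, 1, seed=2)
        m0, m1 = compute_metrics(truth.graph), compute_metrics(out.graph)
        assert m1.n_edges == m0.n_edges + 1
        assert m1.n_nodes == m0.n_nodes
        assert m1.n_components == 1
        # a cycle appeared: edges == nodes now
        assert m1.n_edges == m1.n_nodes

    def test_two_components_bridged_gives_phi_one(self):
        truth = generate_network(PhantomSpec(seed=3, topology="fragmented", n_tubules=2))
        assert compute_metrics(truth.graph).n_components == 2
        out = expand_network(truth, 1, seed=5)
        m = compute_metrics(out.graph)
        if m.n_components == 1:  # bridge joined the two components
            assert m.phi == pytest.approx(1.0)
        assert m.total_length_um > truth.total_length()

    def test_strictly_increases_length_keeps_nodes(self, default_truth):
        out = expand_network(default_truth, 4, seed=6)
        assert out.total_length() > default_truth.total_length()
        assert out.graph.g.number_of_nodes() == default_truth.graph.g.number_of_nodes()


class TestRasterize:
    def test_same_seed_identical_image(self, small_truth):
        a, _ = rasterize(small_truth)
        b, _ = rasterize(small_truth)
        assert np.array_equal(a.voxels, b.voxels)

    def test_background_only_field(self):
        spec = PhantomSpec(n_tubules=1, curvature=0.0, tubule_length_um=(1.0, 1.0),
                           seed=8, background=0.2, shape=(10, 64, 64))
        truth = generate_network(spec)
        truth.graph.g.remove_edges_from(list(truth.graph.g.edges(keys=True)))
        img, _ = rasterize(truth)
        sd = np.sqrt(spec.noise_sd**2 + spec.background / spec.photon_scale)
        assert abs(img.voxels.mean() - spec.background) < 4 * sd
        assert abs(img.voxels.std() - sd) < 0.5 * sd

    def test_max_intensity_on_polyline(self, small_truth):
        img, _ = rasterize(small_truth, noise=False, blur=False)
        spec = small_truth.spec
        centers = _voxel_centers_um(spec.shape, spec.spacing)
        d, _ = cKDTree(_dense_samples(small_truth.graph, 0.05)).query(centers, workers=-1)
        d = d.reshape(spec.shape)
        peak = img.voxels.max()
        argmax = np.unravel_index(np.argmax(img.voxels), img.voxels.shape)
        diag = np.linalg.norm(spec.spacing.zyx)
        assert d[argmax] <= diag / 2
        # high-intensity voxels all lie close to the curves
        hot = d[img.voxels > 0.9 * peak]
        assert hot.max() <= diag

    def test_containment_pre_blur(self, small_truth):
        """Pre-PSF tubule intensity outside the owning cell is < 1% of peak."""
        img, _ = rasterize(small_truth, noise=False, blur=False)
        outside = ~small_truth.cell_mask(0)
        assert img.voxels[outside].max() < 0.01 * img.voxels.max()

    def test_membrane_channel_shell(self):
        spec = PhantomSpec(seed=5, membrane_channel=True, n_tubules=2,
                           shape=(14, 96, 96), spacing=VoxelSpacing(0.15, 0.15, 0.6),
                           cell_radius_um=3.2)
        truth = generate_network(spec)
        _, memb = rasterize(truth, noise=False)
        assert memb is not None
        cell = truth.cells[0]
        centre_idx = tuple(
            int(round(c / s)) for c, s in zip(cell.center[::-1], spec.spacing.zyx)
        )
        assert memb.voxels[centre_idx] < 0.2  # dark interior
        edge_idx = (centre_idx[0], centre_idx[1],
                    int(round((cell.center[0] + cell.radii[0]) / spec.spacing.dx)))
        assert memb.voxels[edge_idx] > 0.5  # bright shell


class TestSnrHelper:
    def test_snr_parameterisation(self):
        p = noise_for_snr(5.0)
        total_sd = np.sqrt(p["noise_sd"] ** 2 + 1.0 / p["photon_scale"])
        assert total_sd == pytest.approx(1 / 5.0, rel=1e-6)

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            noise_for_snr(0)
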