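"""Similarity metrics, graph clustering, deconvolution and reproducibility."""

import networkx as nx
import numpy as np
import pytest

from ssnmsi import msi_io, ssn_core
from ssnmsi import synthetic_data as syn
from ssnmsi.ssn_core import (
    ClusterParams,
    ClusterSet,
    DeconvolutedSpectrum,
    MetricSpec,
    PatchConfig,
    build_graph,
    cluster_spectrum,
    coherent_ssn,
    compare_to_reference,
    connected_components,
    cosine_similarity,
    jaccard,
    mse,
    pool_image,
    similarity_matrix,
    sse,
    ssn_cluster,
)


def closure_partition(n_nodes, edges):
    """Independent oracle: components via boolean transitive closure."""
    reach = np.eye(n_nodes, dtype=bool)
    for a, b in edges:
        reach[a, b] = reach[b, a] = True
    for _ in range(n_nodes):
        reach = reach | (reach @ reach)
    seen, parts = set(), []
    for i in range(n_nodes):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(reach[i]).tolist())
        seen |= comp
        parts.append(comp)
    return set(parts)


class TestCosine:
    def test_self_similarity_is_one(self, make_image):
        x = make_image([[1.0, 0.0], [2.0, 5.0]])
        assert cosine_similarity(x, x) == pytest.approx(1.0)

    def test_scale_invariance(self, make_image):
        x = make_image([[1.0, 3.0], [2.0, 0.5]])
        y = make_image(3.0 * x.values)
        assert cosine_similarity(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_is_orthogonal(self, make_image):
        x = make_image([[1.0, 0.0, 2.0, 0.0]])
        y = make_image([[0.0, 3.0, 0.0, 1.0]])
        assert cosine_similarity(x, y) == 0.0

    def test_hand_dot_product(self, make_image):
        x = make_image([[1.0, 2.0]])
        y = make_image([[2.0, 1.0]])
        assert cosine_similarity(x, y) == pytest.approx(0.8)

    def test_all_zero_image_is_degenerate(self, make_image):
        x = make_image([[0.0, 0.0]])
        y = make_image([[1.0, 2.0]])
        assert cosine_similarity(x, y) == 0.0

    def test_mask_mismatch_rejected(self, make_image):
        x = make_image([[1.0, 2.0]])
        y = make_image([[1.0, 0.0]], mask=[[True, False]])
        with pytest.raises(msi_io.IncompatibleImageError):
            cosine_similarity(x, y)


class TestSquaredError:
    def test_identity_is_zero(self, make_image):
        x = make_image([[1.0, 2.0]])
        assert sse(x, x) == 0.0

    def test_hand_arithmetic(self, make_image):
        x = make_image([[1.0, 2.0]])
        y = make_image([[3.0, 0.0]])
        assert sse(x, y) == pytest.approx(8.0)
        assert mse(x, y) == pytest.approx(4.0)

    def test_scale_sensitivity_versus_cosine(self, make_image):
        x = make_image([[1.0, 2.0], [0.5, 4.0]])
        y = make_image(3.0 * x.values)
        assert sse(x, y) > 0.0
        assert cosine_similarity(x, y) == pytest.approx(1.0)

    def test_unit_max_normalization_removes_scale(self, make_image):
        x = make_image([[1.0, 2.0]])
        y = make_image([[3.0, 6.0]])
        assert sse(x, y, normalization="unit_max") == pytest.approx(0.0)


class TestSimilarityMatrix:
    def test_single_image(self, make_image):
        m = similarity_matrix([make_image([[1.0, 2.0]], target_mz=500.0)])
        assert m.S.shape == (1, 1)
        assert m.S[0, 0] == 1.0

    def test_symmetry_and_brute_force_agreement(self, make_image):
        rng = np.random.default_rng(3)
        images = [
            make_image(rng.uniform(0, 10, size=(4, 5)), target_mz=100.0 + i)
            for i in range(5)
        ]
        m = similarity_matrix(images, MetricSpec("cosine"))
        assert np.array_equal(m.S, m.S.T)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert m.S[i, j] == pytest.approx(
                        cosine_similarity(images[i], images[j]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            similarity_matrix([])

    def test_degenerate_images_recorded(self, make_image):
        imgs = [
            make_image([[0.0, 0.0]], target_mz=1.0),
            make_image([[1.0, 2.0]], target_mz=2.0),
        ]
        m = similarity_matrix(imgs)
        assert m.degenerate == {1.0}


class TestGraphAndComponents:
    def test_unreachable_threshold_gives_all_singlets(self, make_image):
        imgs = [make_image([[1.0, 2.0]], target_mz=float(i)) for i in range(4)]
        m = similarity_matrix(imgs)
        g = build_graph(m, ClusterParams(threshold=1.01))
        cs = connected_components(g)
        assert len(cs.clusters) == 4
        assert len(cs.singlets) == 4

    def test_zero_threshold_gives_complete_graph(self, make_image):
        imgs = [make_image([[1.0, 2.0]], target_mz=float(i)) for i in range(4)]
        g = build_graph(similarity_matrix(imgs), ClusterParams(threshold=0.0))
        assert g.number_of_edges() == 6

    def test_metric_mismatch_rejected(self, make_image):
        m = similarity_matrix([make_image([[1.0]], target_mz=1.0)], MetricSpec("sse"))
        with pytest.raises(ValueError, match="cosine"):
            build_graph(m, ClusterParams(threshold=0.9, metric=MetricSpec("cosine")))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ClusterParams(threshold=-0.1)

    def test_edgeless_graph_components(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        cs = connected_components(g)
        assert len(cs.clusters) == 5

    def test_textbook_components(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        cs = connected_components(g)
        assert {frozenset(c) for c in cs.clusters} == {
            frozenset("abc"), frozenset("de")}

    def test_agrees_with_transitive_closure_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = 15
            edges = [
                (int(a), int(b))
                for a, b in rng.integers(0, n, size=(rng.integers(0, 30), 2))
                if a != b
            ]
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            ours = {frozenset(c) for c in connected_components(g).clusters}
            assert ours == closure_partition(n, edges)

    def test_dropout_heavy_ion_stays_singlet_at_high_threshold(self, tmp_path):
        """Low-S/N ions missing from many pixels decorrelate and stay
        singlets at a high similarity threshold, while the stable fragments
        of the same species still cluster."""
        phantom = syn.make_phantom(
            (12, 16), [{"name": "band", "kind": "band", "rows": (2, 9)}]
        )
        species = [syn.SpeciesSpec(
            name="sp", precursor_mz=808.58, window_center=808.6, region="band",
            abundance=1000.0,
            fragments=((400.0, 1.0), (500.0, 0.9), (600.0, 0.2)),
        )]
        _, _, acq = syn.demo_window_scenario()
        noise = syn.NoiseModel(shot=False, baseline_level=0.0,
                               dropout_prob=0.6, dropout_max_rel=0.25)
        path, truth = syn.simulate_dataset(
            phantom, species, acq, noise, seed=5, out_path=tmp_path / "d.mzML")
        ds = msi_io.assign_pixels(msi_io.read_mzml(path), truth.grid,
                                  truth.line_breaks)
        filt = ds.find_ms2_filter(808.6)
        imgs = [msi_io.extract_ion_image(ds, filt, m, 0.3)
                for m in (400.0, 500.0, 600.0)]
        cs = ssn_cluster(imgs, ClusterParams(threshold=0.9))
        assert cs.cluster_of(400.0) == cs.cluster_of(500.0)
        assert cs.cluster_of(600.0) == frozenset({600.0})


class TestMonotoneRefinement:
    def test_raising_similarity_threshold_only_refines(self, make_image):
        rng = np.random.default_rng(42)
        for _ in range(50):
            imgs = [
                make_image(rng.uniform(0, 1, size=(3, 4)), target_mz=float(i))
                for i in range(6)
            ]
            m = similarity_matrix(imgs)
            previous = None
            for tau in (0.2, 0.5, 0.8, 0.95):
                cs = connected_components(build_graph(m, ClusterParams(threshold=tau)))
                nodes = cs.nodes
                assert nodes == set(m.ions)  # always a partition of all ions
                if previous is not None:
                    assert cs.refines(previous)
                previous = cs

    def test_clusterset_rejects_overlap(self):
        with pytest.raises(ValueError, match="disjoint"):
            ClusterSet(clusters=[frozenset({1, 2}), frozenset({2, 3})])


class TestCoherentSSN:
    def test_patch_size_one_reduces_to_plain(self, demo_images):
        _, images = demo_images
        params = ClusterParams(threshold=0.9, patch=PatchConfig(patch_size=1))
        plain = ssn_cluster(images, ClusterParams(threshold=0.9))
        patched = coherent_ssn(images, params)
        assert {frozenset(c) for c in plain.clusters} == {
            frozenset(c) for c in patched.clusters}

    def test_salt_noise_splits_plain_but_not_coherent(self, make_image):
        """Isolated salt spikes at 5% of pixels break pixelwise cosine but
        average out under 4x4 patch pooling."""
        rng = np.random.default_rng(8)
        shape = (16, 16)
        base = np.zeros(shape)
        base[4:12, :] = 100.0
        images = []
        for i in range(2):
            vals = base.copy()
            salt = rng.choice(256, size=13, replace=False)  # ~5 % of pixels
            vals.flat[salt] += 300.0
            images.append(make_image(vals, target_mz=float(i)))
        plain = ssn_cluster(images, ClusterParams(threshold=0.9))
        assert len(plain.clusters) == 2  # split by the salt
        coherent = coherent_ssn(
            images,
            ClusterParams(threshold=0.9, patch=PatchConfig(patch_size=4)),
        )
        assert len(coherent.clusters) == 1  # recovered

    def test_constant_images_cluster_at_any_patch_size(self, make_image):
        imgs = [make_image(np.full((8, 8), 5.0), target_mz=float(i))
                for i in range(3)]
        for p in (1, 2, 4):
            cs = coherent_ssn(imgs, ClusterParams(
                threshold=1.0, patch=PatchConfig(patch_size=p)))
            assert len(cs.clusters) == 1

    def test_oversized_patch_rejected(self, make_image):
        img = make_image(np.ones((4, 4)))
        with pytest.raises(ValueError, match="patch size"):
            pool_image(img, PatchConfig(patch_size=9))

    def test_pooling_respects_mask(self, make_image):
        vals = np.zeros((4, 4))
        vals[0, 0] = 8.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        img = make_image(vals, mask=mask)
        pooled = pool_image(img, PatchConfig(patch_size=2))
        assert pooled.valid_mask.tolist() == [[True, False], [False, False]]
        assert pooled.values[0, 0] == pytest.approx(4.0)  # mean of 8 and 0


class TestClusterSpectrum:
    def test_single_ion_cluster_scales_to_100(self, make_image):
        img = make_image([[2.0, 4.0]], target_mz=500.0)
        spec = cluster_spectrum({500.0}, [img])
        assert spec.mz.tolist() == [500.0]
        assert spec.intensity.tolist() == [100.0]

    def test_generator_ratios_recovered(self, demo_run, demo_images):
        """Noise-free fragment ratios 1.0 : 0.35 : 0.2 reappear as
        100 : 35 : 20 in the deconvoluted spectrum."""
        ions, images = demo_images
        members = [m for m in ions if abs(m - 467.2533) < 0.3
                   or abs(m - 749.5092) < 0.3 or abs(m - 625.5166) < 0.3]
        spec = cluster_spectrum(members, images)
        by_mz = dict(zip(np.round(spec.mz, 2), spec.intensity))
        assert by_mz[467.25] == pytest.approx(100.0)
        assert by_mz[749.51] == pytest.approx(35.0, rel=1e-6)
        assert by_mz[625.52] == pytest.approx(20.0, rel=1e-6)

    def test_all_zero_cluster_flagged_degenerate(self, make_image):
        img = make_image([[0.0, 0.0]], target_mz=500.0)
        spec = cluster_spectrum({500.0}, [img])
        assert spec.degenerate and len(spec) == 0

    def test_empty_cluster_gives_empty_spectrum(self, make_image):
        spec = cluster_spectrum(set(), [make_image([[1.0]], target_mz=1.0)])
        assert len(spec) == 0


class TestCompareToReference:
    def test_identical_spectra_fully_recovered(self):
        s = DeconvolutedSpectrum(np.array([184.1, 603.5]), np.array([100.0, 40.0]))
        assert compare_to_reference(s, s).recovered_fraction == 1.0

    def test_reference_peaks_below_floor_excluded(self):
        ref = DeconvolutedSpectrum(np.array([184.1, 500.0]), np.array([100.0, 0.5]))
        dec = DeconvolutedSpectrum(np.array([184.1]), np.array([100.0]))
        rep = compare_to_reference(dec, ref, min_rel=0.01)
        assert rep.recovered_fraction == 1.0
        assert rep.missed_reference == []

    def test_hand_count(self):
        ref = DeconvolutedSpectrum(np.array([184.1, 603.5]), np.array([100.0, 40.0]))
        dec = DeconvolutedSpectrum(np.array([184.1]), np.array([100.0]))
        rep = compare_to_reference(dec, ref, mz_tol=0.3)
        assert rep.recovered_fraction == pytest.approx(0.5)
        assert rep.missed_reference == [603.5]


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard([{1, 2}, {1, 2}]).jaccard == 1.0

    def test_disjoint_sets(self):
        assert jaccard([{1}, {2}]).jaccard == 0.0

    def test_three_replicates_sharing_17_of_19(self):
        shared = set(range(17))
        cmp = jaccard([shared | {90}, shared | {91}, shared])
        assert cmp.jaccard == pytest.approx(17 / 19)
        assert round(cmp.jaccard, 3) == 0.895
        assert len(cmp.shared_ions) == 17
        assert len(cmp.union_ions) == 19

    def test_single_set_rejected(self):
        with pytest.raises(ValueError, match="two sets"):
            jaccard([{1}])

    def test_mz_matching_within_tolerance(self):
        a = {100.00, 200.00, 300.00}
        b = {100.10, 200.25, 400.00}
        cmp = jaccard([a, b], mz_tol=0.3)
        assert cmp.jaccard == pytest.approx(2 / 4)

    def test_pairwise_values_reported(self):
        cmp = jaccard([{1, 2}, {1, 2}, {1}], pairwise=True)
        assert cmp.pairwise == [1.0, 0.5, 0.5]

    def test_both_empty_defined_as_one(self):
        assert jaccard([set(), set()]).jaccard == 1.0
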