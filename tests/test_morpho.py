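import itertools

import numpy as np
import pytest

from macromate.morpho import (
    LandmarkConfiguration,
    N_LANDMARKS,
    centroid_size,
    compare_shape_groups,
    default_fixed_mask,
    gpa_align,
    mirror_configuration,
    procrustes_distance,
    relative_warps,
    slide_semilandmarks,
    tps_fit,
    tps_grid,
)
from macromate.synth import (
    ShapeSpec,
    SimulationParams,
    gen_stylets,
    species_mean_shapes,
)
from macromate.tpsio import read_tps, write_tps


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@pytest.fixture(scope="module")
def stylet_configs():
    return gen_stylets(SimulationParams(seed=2))


@pytest.fixture(scope="module")
def aligned(stylet_configs):
    return gpa_align(stylet_configs)


class TestCentroidSize:
    def test_unit_square_example(self):
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8))

    def test_homogeneous_in_scale(self, rng):
        pts = rng.normal(size=(20, 2))
        assert centroid_size(3.7 * pts) == pytest.approx(
            3.7 * centroid_size(pts)
        )

    def test_translation_invariant(self, rng):
        pts = rng.normal(size=(20, 2))
        assert centroid_size(pts + [5.0, -3.0]) == pytest.approx(
            centroid_size(pts)
        )

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            centroid_size(np.zeros((5, 2)))


class TestMirror:
    def test_double_mirror_identity(self, stylet_configs):
        c = stylet_configs[0]
        back = mirror_configuration(mirror_configuration(c))
        assert np.allclose(back.points, c.points)
        assert back.mirrored == c.mirrored

    def test_centroid_size_preserved(self, stylet_configs):
        c = stylet_configs[0]
        assert mirror_configuration(c).centroid_size == pytest.approx(
            c.centroid_size
        )

    def test_chiral_shape_distinct_from_mirror(self, stylet_configs):
        c = stylet_configs[0]
        m = mirror_configuration(c)
        assert procrustes_distance(c.points, m.points) > 0.05


class TestGpa:
    def test_copies_of_one_shape_align_exactly(self, rng):
        base = species_mean_shapes()["lignano"]
        copies = [
            base,
            (1.7 * base) @ _rot(0.8).T + [10, -4],
            (0.3 * base) @ _rot(-2.1).T + [-3, 7],
        ]
        d = gpa_align(copies)
        for a, b in itertools.combinations(range(3), 2):
            assert np.linalg.norm(d.aligned[a] - d.aligned[b]) < 1e-8

    def test_invariant_to_input_order(self, rng):
        configs = [
            species_mean_shapes()["lignano"] + rng.normal(0, 1, (60, 2))
            for _ in range(10)
        ]
        d1 = gpa_align(configs)
        perm = rng.permutation(10)
        d2 = gpa_align([configs[i] for i in perm])
        assert np.allclose(d1.consensus, d2.consensus, atol=1e-8)

    def test_invariant_to_similarity_transform_of_one_input(self, rng):
        configs = [
            species_mean_shapes()["janickei"] + rng.normal(0, 1, (60, 2))
            for _ in range(6)
        ]
        d1 = gpa_align(configs)
        configs[3] = (2.5 * configs[3]) @ _rot(1.2).T + [40, -7]
        d2 = gpa_align(configs)
        assert np.allclose(d1.consensus, d2.consensus, atol=1e-8)
        assert np.allclose(d1.aligned, d2.aligned, atol=1e-8)

    def test_residuals_nonincreasing_versus_unrotated(self, stylet_configs):
        d = gpa_align(stylet_configs)
        # final configuration is a least-squares fixed point: rotating any
        # specimen away from its fitted orientation cannot reduce residuals
        ss = np.sum((d.aligned - d.consensus) ** 2)
        bumped = d.aligned.copy()
        bumped[0] = bumped[0] @ _rot(0.05).T
        assert np.sum((bumped - d.consensus) ** 2) > ss

    def test_procrustes_distance_is_a_metric(self, rng):
        shapes = [rng.normal(size=(12, 2)) for _ in range(6)]
        for a, b, c in itertools.combinations(shapes, 3):
            dab = procrustes_distance(a, b)
            dba = procrustes_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-9)
            assert dab <= procrustes_distance(a, c) + procrustes_distance(
                c, b
            ) + 1e-9


class TestSliding:
    def test_identical_shapes_do_not_move(self):
        base = species_mean_shapes()["lignano"]
        d = gpa_align([base, base.copy(), base.copy()])
        slid = slide_semilandmarks(d)
        assert np.allclose(slid.aligned, d.aligned, atol=1e-12)

    @pytest.mark.parametrize("criterion", ["bending", "chord"])
    def test_objective_monotone_nonincreasing(self, aligned, criterion):
        slid = slide_semilandmarks(aligned, criterion=criterion)
        trace = slid.slide_trace
        assert len(trace) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_fixed_landmarks_never_slide(self, aligned):
        """A pure sliding pass leaves the fixed landmarks bit-identical."""
        slid = slide_semilandmarks(aligned, realign=False)
        fixed = default_fixed_mask()
        assert np.array_equal(
            slid.aligned[:, fixed, :], aligned.aligned[:, fixed, :]
        )
        # and the semilandmarks did move
        assert not np.allclose(
            slid.aligned[:, ~fixed, :], aligned.aligned[:, ~fixed, :]
        )


class TestRelativeWarps:
    def test_seventy_one_warps_from_72_specimens(self, aligned):
        rw = relative_warps(aligned)
        assert rw.n_warps == 71

    def test_variance_explained_sums_to_100(self, aligned):
        rw = relative_warps(aligned)
        assert rw.variance_explained.sum() == pytest.approx(100.0)

    def test_warp_count_bounded(self, rng):
        configs = [
            species_mean_shapes()["lignano"] + rng.normal(0, 0.5, (60, 2))
            for _ in range(5)
        ]
        rw = relative_warps(gpa_align(configs))
        assert rw.n_warps <= min(len(configs) - 1, 2 * N_LANDMARKS - 4)

    def test_alpha_zero_matches_pca_oracle(self, aligned):
        """alpha=0 scores equal plain PCA of flattened aligned coordinates."""
        rw = relative_warps(aligned)
        flat = aligned.aligned.reshape(len(aligned.aligned), -1)
        centred = flat - flat.mean(axis=0)
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        oracle = u[:, :5] * s[:5]
        for j in range(5):
            dot = np.dot(rw.scores[:, j], oracle[:, j])
            sign = 1.0 if dot >= 0 else -1.0
            assert np.allclose(rw.scores[:, j], sign * oracle[:, j], atol=1e-8)

    def test_orthogonal_scores(self, aligned):
        rw = relative_warps(aligned)
        gram = rw.scores.T @ rw.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.diag(gram).max()

    def test_too_few_specimens_rejected(self):
        base = species_mean_shapes()["lignano"]
        d = gpa_align([base, base + 0.1])
        with pytest.raises(ValueError):
            relative_warps(d)


class TestTps:
    def test_identity_map_for_equal_shapes(self, aligned):
        grid = tps_grid(aligned.consensus, aligned.consensus)
        assert np.allclose(grid.deformed_grid, grid.reference_grid, atol=1e-9)
        assert grid.bending_energy == pytest.approx(0.0, abs=1e-12)

    def test_affine_target_has_zero_bending_energy(self, aligned):
        target = aligned.consensus @ np.array([[1.2, 0.3], [-0.2, 0.8]]) + [
            0.5, -0.1,
        ]
        _, be = tps_fit(aligned.consensus, target)
        assert be == pytest.approx(0.0, abs=1e-9)

    def test_exact_interpolation_at_landmarks(self, aligned, rng):
        target = aligned.consensus + rng.normal(0, 0.01, (60, 2))
        evaluate, _ = tps_fit(aligned.consensus, target)
        assert np.abs(evaluate(aligned.consensus) - target).max() < 1e-9

    def test_collinear_source_rejected(self):
        src = np.column_stack([np.linspace(0, 1, 8), np.zeros(8)])
        with pytest.raises(ValueError, match="singular|degenerate"):
            tps_fit(src, src + 0.1)


class TestGroupComparison:
    def test_hybrid_intermediate_on_rws1(self, aligned):
        rw = relative_warps(aligned)
        comps = compare_shape_groups(rw)
        rws1 = comps["rws1"]
        assert rws1.p_value < 0.001
        means = rws1.group_means
        lo, hi = sorted([means["lignano"], means["janickei"]])
        assert lo < means["hybrid"] < hi
        assert all(pw.significant for pw in rws1.pairwise)
        assert len(set(rws1.letters.values())) == 3

    def test_identical_groups_not_separated(self, rng):
        base = species_mean_shapes()["lignano"]
        configs = [
            LandmarkConfiguration(
                f"s{i}", ["a", "b", "c"][i % 3],
                base + rng.normal(0, 1.0, (60, 2)),
            )
            for i in range(24)
        ]
        comps = compare_shape_groups(relative_warps(gpa_align(configs)))
        assert len(set(comps["rws1"].letters.values())) == 1


class TestTpsIO:
    def test_round_trip(self, tmp_path, stylet_configs):
        path = tmp_path / "stylets.tps"
        write_tps(stylet_configs[:5], path)
        back = read_tps(path)
        assert len(back) == 5
        for a, b in zip(stylet_configs[:5], back):
            assert a.specimen_id == b.specimen_id
            assert np.allclose(a.points, b.points, atol=1e-9)

    def test_crlf_and_trailing_blanks_tolerated(self, tmp_path):
        pts = species_mean_shapes()["lignano"]
        lines = ["LM=60"] + [f"{x} {y}" for x, y in pts] + [
            "ID=spec1", "SCALE=0.5", "", "",
        ]
        path = tmp_path / "crlf.tps"
        path.write_bytes("\r\n".join(lines).encode())
        (cfg,) = read_tps(path)
        assert cfg.specimen_id == "spec1"
        assert cfg.scale == 0.5
        assert np.allclose(cfg.points, pts)

    def test_landmark_count_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM=60\n0 0\n1 1\nID=x\n")
        with pytest.raises(ValueError, match="landmark"):
            read_tps(path)


def test_shape_spec_validation():
    with pytest.raises(ValueError):
        ShapeSpec(noise_sd=-1.0)
    with pytest.raises(ValueError):
        ShapeSpec(hybrid_weight=1.5)
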