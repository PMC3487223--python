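"""GPA alignment: known-transform inversion, residual monotonicity,
idempotence, and ratio extraction."""

import dataclasses
import math

import numpy as np
import pytest

from dopamet.gpa import (AlignmentError, ArrayConfiguration, extract_ratios,
                         gpa_align, load_configuration, normalize_batch)
from dopamet.simulate import (SimulationConfig, generate_experiment,
                              generate_truth)


def rotation(deg):
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def make_config(points, array_id="a", genes=None, **kwargs):
    genes = genes if genes is not None else np.array(
        [f"g{i}" for i in range(len(points))])
    return ArrayConfiguration(array_id=array_id, dye_reversed=False,
                              points=np.asarray(points, float), gene_ids=genes,
                              **kwargs)


def random_cloud(rng, n=60, base=None):
    """A two-channel log-intensity cloud; pass ``base`` to emulate replicate
    hybridizations of the same samples (shared expression, per-array noise)."""
    a = rng.normal(10, 1.5, n) if base is None else base + rng.normal(0, 0.15, n)
    m = rng.normal(0, 0.4, n)
    return np.column_stack([a + m / 2, a - m / 2])


def replicate_clouds(rng, k, n=60):
    base = rng.normal(10, 1.5, n)
    return [make_config(random_cloud(rng, n, base=base), f"a{i}") for i in range(k)]


class TestLoadConfiguration:
    def test_exact_log(self, small_config):
        truth = generate_truth(small_config)
        arr = generate_experiment(small_config, truth, "depletion", "Hyp")[0]
        arr.spots.loc[0, "intensity_ch1"] = 1024.0
        cfg = load_configuration(arr, floor=1.0)
        assert cfg.points[0, 0] == pytest.approx(10.0)

    def test_floor_clipping(self, small_config):
        truth = generate_truth(small_config)
        arr = generate_experiment(small_config, truth, "depletion", "Hyp")[0]
        arr.spots.loc[0, "intensity_ch1"] = 0.0
        cfg = load_configuration(arr, floor=1.0)
        assert cfg.points[0, 0] == 0.0

    def test_dye_reversed_columns_swapped(self, clean_config):
        truth = generate_truth(clean_config)
        arrays = generate_experiment(clean_config, truth, "depletion", "Hyp")
        rev = next(a for a in arrays if a.dye_reversed)
        cfg = load_configuration(rev)
        np.testing.assert_allclose(
            cfg.points[:, 0], np.log2(rev.spots["intensity_ch2"]), rtol=1e-12)

    def test_invalid_floor(self, small_config):
        truth = generate_truth(small_config)
        arr = generate_experiment(small_config, truth, "depletion", "Hyp")[0]
        with pytest.raises(ValueError):
            load_configuration(arr, floor=0.0)


class TestAlign:
    def test_identity_case(self, rng):
        pts = random_cloud(rng)
        pts -= pts.mean(axis=0)
        fit = gpa_align([make_config(pts, "a"), make_config(pts.copy(), "b")])
        for r in fit.rotations:
            np.testing.assert_allclose(r, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(fit.scales, 1.0, atol=1e-9)
        np.testing.assert_allclose(fit.translations, 0.0, atol=1e-9)
        assert fit.residual_history[-1] == pytest.approx(0.0, abs=1e-20)

    def test_known_transform_inverted(self, rng):
        """B constructed from A by a known rotation/scale/translation: the
        fitted relative transform inverts it and the residual vanishes."""
        a = random_cloud(rng)
        r, s, t = rotation(30), 1.5, np.array([2.0, -1.0])
        b = s * a @ r + t
        fit = gpa_align([make_config(a, "a"), make_config(b, "b")], tol=1e-14)
        assert fit.residual_history[-1] < 1e-12
        # relative rotation between the two fitted transforms undoes r
        rel_rot = fit.rotations[1] @ fit.rotations[0].T
        np.testing.assert_allclose(rel_rot, r.T, atol=1e-9)
        assert fit.scales[1] / fit.scales[0] == pytest.approx(1 / s, abs=1e-9)

    def test_rotation_properties(self, rng):
        configs = replicate_clouds(rng, 5)
        fit = gpa_align(configs)
        for r in fit.rotations:
            np.testing.assert_allclose(r @ r.T, np.eye(2), atol=1e-9)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        assert (fit.scales > 0).all()

    def test_residual_history_non_increasing_and_recomputable(self, rng):
        """Residual history decreases monotonically and the final entry
        matches a direct recomputation from the returned transforms."""
        configs = replicate_clouds(rng, 5)
        fit = gpa_align(configs, tol=1e-10)
        hist = np.array(fit.residual_history)
        assert np.all(np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1.0))
        aligned = [fit.transform(i, c.points) for i, c in enumerate(configs)]
        direct = sum(np.sum((a - fit.consensus) ** 2) for a in aligned)
        assert direct == pytest.approx(hist[-1], rel=1e-9)

    def test_total_size_constraint(self, rng):
        configs = replicate_clouds(rng, 4)
        fit = gpa_align(configs)
        centered = [c.points - c.points.mean(axis=0) for c in configs]
        before = sum(np.sum(x**2) for x in centered)
        after = sum(np.sum((s * x) ** 2) for s, x in zip(fit.scales, centered))
        assert after == pytest.approx(before, rel=1e-9)

    def test_idempotence(self, rng):
        configs = replicate_clouds(rng, 4)
        fit = gpa_align(configs, tol=1e-12)
        aligned = [make_config(fit.transform(i, c.points), f"b{i}")
                   for i, c in enumerate(configs)]
        refit = gpa_align(aligned, tol=1e-12)
        for r in refit.rotations:
            np.testing.assert_allclose(r, np.eye(2), atol=1e-6)
        np.testing.assert_allclose(refit.scales, 1.0, atol=1e-6)
        assert refit.residual_history[-1] <= fit.residual_history[-1] * (1 + 1e-9)

    def test_residual_invariant_under_common_rotation(self, rng):
        """The alignment trajectory equivaries under a shared pre-rotation, so
        the residual history is unchanged (the consensus itself is only
        defined up to that rotation)."""
        configs = replicate_clouds(rng, 4)
        q = rotation(37)
        rotated = [make_config(c.points @ q, f"b{i}") for i, c in enumerate(configs)]
        f1 = gpa_align(configs, tol=1e-10)
        f2 = gpa_align(rotated, tol=1e-10)
        np.testing.assert_allclose(f1.residual_history, f2.residual_history,
                                   rtol=1e-8)

    def test_ratios_invariant_under_per_array_translation(self, rng):
        configs = replicate_clouds(rng, 4)
        shifted = [make_config(c.points + rng.uniform(-3, 3, 2), f"b{i}",
                               genes=c.gene_ids)
                   for i, c in enumerate(configs)]
        r1 = extract_ratios(gpa_align(configs, tol=1e-12), configs)
        r2 = extract_ratios(gpa_align(shifted, tol=1e-12), shifted)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)

    def test_degenerate_configuration_raises(self):
        pts = np.ones((10, 2))
        with pytest.raises(AlignmentError, match="degenerate"):
            gpa_align([make_config(pts, "a"), make_config(pts.copy(), "b")])

    def test_mismatched_spot_sets_raise(self, rng):
        a = make_config(random_cloud(rng), "a")
        b = make_config(random_cloud(rng), "b",
                        genes=np.array([f"x{i}" for i in range(60)]))
        with pytest.raises(AlignmentError, match="spot set"):
            gpa_align([a, b])

    def test_single_configuration_rejected(self, rng):
        with pytest.raises(AlignmentError):
            gpa_align([make_config(random_cloud(rng))])


class TestRatios:
    def test_null_arrays_give_zero_ratios(self, clean_config):
        cfg = dataclasses.replace(clean_config, frac_regulated=0.0)
        truth = generate_truth(cfg)
        arrays = generate_experiment(cfg, truth, "depletion", "Hyp")
        configs = [load_configuration(a) for a in arrays]
        ratios = extract_ratios(gpa_align(configs), configs)
        np.testing.assert_allclose(ratios.to_numpy(), 0.0, atol=1e-9)

    def test_duplicate_spot_mean(self, rng):
        pts = random_cloud(rng, 4)
        pts[:, 0] = pts[:, 1] + np.array([1.0, 2.0, 0.5, 0.7])
        genes = np.array(["g1", "g1", "g2", "g2"])
        configs = [make_config(pts, "a", genes=genes),
                   make_config(pts.copy(), "b", genes=genes)]
        ratios = extract_ratios(gpa_align(configs), configs, anchor="first")
        assert ratios.loc["g1", "a"] == pytest.approx(1.5, abs=1e-9)

    def test_planted_effect_recovered_when_balanced(self, clean_config):
        """Balanced planted effects survive per-array centering exactly: the
        treatment columns read back the true log2 effects to 1e-9."""
        truth = generate_truth(clean_config)
        eff = truth["effect_MPTP_aMPT"].copy()
        # make the planted effects sum exactly to zero (balanced up/down)
        nz = eff[eff != 0]
        eff[nz.index] = np.where(np.arange(len(nz)) % 2 == 0, 1.0, -1.0)
        truth["effect_MPTP_aMPT"] = eff
        arrays = generate_experiment(clean_config, truth, "depletion", "Hyp")
        configs = [load_configuration(a) for a in arrays]
        ratios = extract_ratios(gpa_align(configs, tol=1e-14), configs)
        want = truth.loc[ratios.index, "effect_MPTP_aMPT"].to_numpy()
        np.testing.assert_allclose(ratios.to_numpy(),
                           np.broadcast_to(want[:, None], ratios.shape),
                           atol=1e-9)

    def test_distortion_recovery_first_anchor(self, clean_config, rng):
        """Planted affine distortions on arrays 2..n are inverted to 1e-6 in
        ratio space when anchored to the clean first array."""
        truth = generate_truth(clean_config)
        arrays = generate_experiment(clean_config, truth, "depletion", "Hyp")
        for arr in arrays[1:]:
            pts = np.log2(arr.spots[["intensity_ch1", "intensity_ch2"]].to_numpy())
            pts = rng.uniform(0.5, 2.0) * pts @ rotation(rng.uniform(-45, 45)) \
                + rng.uniform(-2, 2, 2)
            arr.spots["intensity_ch1"] = np.exp2(pts[:, 0])
            arr.spots["intensity_ch2"] = np.exp2(pts[:, 1])
        # tiny floor: distorted intensities below 1 are legitimate here
        configs = [load_configuration(a, floor=1e-9) for a in arrays]
        fit = gpa_align(configs, tol=1e-14)
        ratios = extract_ratios(fit, configs, anchor="first")
        want = truth.loc[ratios.index, "effect_MPTP_aMPT"].to_numpy()
        np.testing.assert_allclose(ratios.to_numpy(),
                           np.broadcast_to(want[:, None], ratios.shape),
                           atol=1e-6)

    def test_normalize_batch_shape_and_labels(self, small_config):
        from dopamet.simulate import generate_design
        arrays = generate_design(small_config)
        ratios, fits = normalize_batch(arrays)
        assert ratios.shape == (small_config.n_genes, len(arrays))
        assert len(fits) == 6  # 2 tissues x 3 experiments
        assert set(ratios.attrs["treatments"].values()) == \
               {"SKF", "LY", "SCH", "sulpiride", "MPTP_aMPT"}
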