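"""Fisher information, Cramér–Rao bound and precision maps."""

from dataclasses import replace

import numpy as np
import pytest

from smlssi import (
    NO_BACKGROUND_SBR,
    Scenario,
    SingularModelError,
    center_improvement_ratio,
    crb_sigma,
    exposure_probabilities,
    fisher_information,
    make_beam_profile,
    minflux_sequence,
    photon_equivalence,
    precision_map,
    probability_gradients,
    rastmin_sequence,
)


def _scenario(order=1.0, sbr=4.0, position=(0.0, 0.0), method="minflux", N=500, L=100.0):
    seq = minflux_sequence(L) if method == "minflux" else rastmin_sequence(L, 4)
    return Scenario(
        beam=make_beam_profile(647.0, 1.4),
        sequence=seq,
        order=order,
        N=N,
        SBR=sbr,
        emitter_position=np.asarray(position, dtype=float),
    )


class TestProbabilityGradients:
    def test_rows_sum_to_zero(self):
        g = probability_gradients(_scenario(order=2.0, position=(17.0, -8.0)))
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-15)

    @pytest.mark.parametrize("order", [1.0, 1.5, 2.0, 3.0])
    @pytest.mark.parametrize("method", ["minflux", "rastmin"])
    def test_matches_central_finite_differences(self, order, method):
        rng = np.random.default_rng(17)
        h = 0.01
        for _ in range(8):
            pos = rng.uniform(-45, 45, 2)
            scn = _scenario(order=order, position=pos, method=method)
            g = probability_gradients(scn)
            fd = np.empty_like(g)
            for axis in range(2):
                e = np.zeros(2)
                e[axis] = h
                fd[:, axis] = (
                    exposure_probabilities(scn.at(pos + e))
                    - exposure_probabilities(scn.at(pos - e))
                ) / (2 * h)
            assert np.linalg.norm(g - fd) <= 1e-6 * np.linalg.norm(fd)

    def test_center_exposure_gradient_vanishes_at_origin(self):
        for c in (1.0, 2.0):
            g = probability_gradients(_scenario(order=c))
            np.testing.assert_allclose(g[3], 0.0, atol=1e-15)


class TestFisherInformation:
    def test_linear_in_photon_budget(self):
        scn = _scenario(position=(12.0, 3.0))
        F1 = fisher_information(scn)
        F2 = fisher_information(replace(scn, N=1000))
        np.testing.assert_allclose(F2, 2 * F1, rtol=1e-12)

    def test_isotropic_at_minflux_center(self):
        F = fisher_information(_scenario())
        assert F[0, 0] == pytest.approx(F[1, 1], rel=1e-10)
        assert F[0, 1] == pytest.approx(0.0, abs=1e-12 * F[0, 0])

    def test_positive_semidefinite_and_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            F = fisher_information(_scenario(order=2.0, position=rng.uniform(-45, 45, 2)))
            assert F[0, 1] == pytest.approx(F[1, 0], rel=1e-12)
            assert np.all(np.linalg.eigvalsh(F) >= 0)

    def test_matches_empirical_score_covariance(self):
        """Score-sampling oracle: cov of the multinomial score equals F."""
        scn = _scenario(order=1.0, sbr=4.0, position=(10.0, 5.0))
        F = fisher_information(scn)
        p = exposure_probabilities(scn)
        g = probability_gradients(scn)
        rng = np.random.default_rng(99)
        draws = rng.multinomial(scn.N, p, size=100_000)
        scores = draws @ (g / p[:, None])  # (M, 2)
        emp = np.cov(scores.T)
        np.testing.assert_allclose(emp, F, rtol=0.05)

    def test_infinite_sbr_center_matches_large_sbr_convention(self):
        """At the exact center the zero-probability center exposure carries zero
        gradient, so the pure-signal Fisher information is finite and agrees
        with the large-SBR stand-in."""
        F_inf = fisher_information(_scenario(sbr=np.inf))
        F_big = fisher_information(_scenario(sbr=1e9))
        np.testing.assert_allclose(F_inf, F_big, rtol=1e-6, atol=1e-12)

    def test_degenerate_geometry_raises_singular_model(self):
        """Two collinear minima carry no information transverse to their axis."""
        from smlssi import ExcitationSequence

        seq = ExcitationSequence(
            method="minflux", L=100.0, positions=np.array([[-30.0, 0.0], [30.0, 0.0]])
        )
        scn = Scenario(
            beam=make_beam_profile(647.0), sequence=seq, SBR=4.0,
            emitter_position=np.array([5.0, 0.0]),
        )
        with pytest.raises(SingularModelError):
            crb_sigma(scn)


class TestCrbSigma:
    def test_inverse_sqrt_photon_law(self):
        scn = _scenario(position=(8.0, -13.0))
        s1 = crb_sigma(scn)
        s4 = crb_sigma(replace(scn, N=4 * scn.N))
        assert s4 == pytest.approx(s1 / 2, rel=1e-12)

    def test_background_monotonicity(self):
        """sigma_CRB is non-increasing in SBR at any fixed position."""
        for pos in [(0.0, 0.0), (20.0, 10.0), (-30.0, 5.0)]:
            sigmas = [crb_sigma(_scenario(sbr=s, position=pos)) for s in (1.0, 2.0, 4.0, 10.0, 100.0)]
            assert np.all(np.diff(sigmas) <= 1e-12)

    def test_reference_center_value(self):
        """Frozen regression value for the reference configuration (nm)."""
        assert crb_sigma(_scenario()) == pytest.approx(2.0210064, rel=1e-6)


class TestCenterComparisons:
    def test_identity_order_ratio(self):
        scn = _scenario()
        assert center_improvement_ratio(scn, 1.0, 1.0) == pytest.approx(1.0, rel=1e-12)
        assert photon_equivalence(scn, 2.0, 2.0) == pytest.approx(1.0, rel=1e-12)

    def test_small_pattern_limit_reaches_order(self):
        """As L/R -> 0 the improvement ratio tends to c (within 1% at L/R <= 0.1)."""
        scn = _scenario(L=20.0)  # L/R ~ 0.087
        assert center_improvement_ratio(scn, 1.0, 3.0) == pytest.approx(3.0, rel=0.01)
        assert photon_equivalence(scn, 1.0, 3.0) == pytest.approx(1 / 9, rel=0.02)

    def test_ratio_uses_no_background_limit(self):
        """The comparison is background-free even if the scenario carries SBR = 4."""
        a = center_improvement_ratio(_scenario(sbr=4.0), 1.0, 2.0)
        b = center_improvement_ratio(_scenario(sbr=NO_BACKGROUND_SBR), 1.0, 2.0)
        assert a == pytest.approx(b, rel=1e-12)


class TestPrecisionMap:
    def test_values_positive_and_finite(self, minflux_scenario=None):
        pmap = precision_map(_scenario(), grid_side=21)
        assert np.all(np.isfinite(pmap.sigma_crb))
        assert np.all(pmap.sigma_crb > 0)

    def test_minflux_three_fold_symmetry(self):
        """sigma at a point equals sigma at its 120-degree rotation."""
        scn = _scenario(order=2.0)
        theta = 2 * np.pi / 3
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rng = np.random.default_rng(8)
        for _ in range(10):
            pos = rng.uniform(-40, 40, 2)
            s1 = crb_sigma(scn.at(pos))
            s2 = crb_sigma(scn.at(rot @ pos))
            assert s2 == pytest.approx(s1, rel=1e-9)

    def test_rastmin_quarter_turn_symmetry(self):
        pmap = precision_map(_scenario(method="rastmin", order=2.0), grid_side=21)
        np.testing.assert_allclose(pmap.sigma_crb, np.rot90(pmap.sigma_crb), rtol=1e-9)

    def test_map_is_deterministic_and_fingerprinted(self):
        a = precision_map(_scenario(), grid_side=11)
        b = precision_map(_scenario(), grid_side=11)
        np.testing.assert_array_equal(a.sigma_crb, b.sigma_crb)
        assert a.fingerprint["method"] == "minflux"
        assert a.fingerprint["grid_side"] == 11

    def test_summary_fields(self):
        summary = precision_map(_scenario(), grid_side=11).summary()
        assert set(summary) == {"min_nm", "max_nm", "center_nm", "mean_nm", "cv", "contrast"}
        assert summary["min_nm"] <= summary["center_nm"] <= summary["max_nm"]

    def test_save_roundtrip(self, tmp_path):
        pmap = precision_map(_scenario(), grid_side=11)
        written = pmap.save(tmp_path / "map", tiff=True)
        assert [p.suffix for p in written] == [".csv", ".json", ".tif"]
        data = np.loadtxt(written[0], delimiter=",", skiprows=1)
        np.testing.assert_allclose(data, pmap.sigma_crb, rtol=1e-6)
        import tifffile

        np.testing.assert_allclose(
            tifffile.imread(written[2]), pmap.sigma_crb.astype(np.float32)
        )

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            precision_map(_scenario(), grid_side=2)

    def test_map_figure_renders(self, tmp_path):
        from smlssi.plotting import plot_precision_map

        pmap = precision_map(_scenario(), grid_side=9)
        out = tmp_path / "map.png"
        plot_precision_map(pmap, out)
        assert out.stat().st_size > 0
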