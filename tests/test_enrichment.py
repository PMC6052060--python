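"""Curvature-enrichment pipeline: per-cell statistics through population
profiles, checked against brute-force face enumeration and generator truth."""

import numpy as np
import pytest

import curvedcell as cc
from curvedcell.enrichment import (
    conditional_expectation,
    curvature_bins,
    enrichment_scalars,
    joint_distribution,
    mean_density,
    population_profile,
    smooth_and_truncate,
    total_intensity,
)


@pytest.fixture(scope="module")
def painted_coarse(coarse_cell, step_paint):
    return cc.paint_enrichment(coarse_cell, step_paint)


class TestPerCellStatistics:
    def test_total_intensity_is_area_weighted_sum(self, painted_coarse):
        expected = float(
            (painted_coarse.face_intensity * painted_coarse.face_area).sum()
        )
        assert total_intensity(painted_coarse) == pytest.approx(expected)

    def test_zero_intensity_gives_zero(self, coarse_cell):
        cell = coarse_cell.with_intensity(np.zeros(len(coarse_cell.mesh.faces)))
        assert total_intensity(cell) == 0.0

    def test_negative_intensity_rejected(self, coarse_cell):
        cell = coarse_cell.with_intensity(
            np.full(len(coarse_cell.mesh.faces), -1.0)
        )
        with pytest.raises(ValueError, match="negative"):
            total_intensity(cell)

    def test_constant_intensity_mean_density(self, coarse_cell):
        cell = coarse_cell.with_intensity(
            np.full(len(coarse_cell.mesh.faces), 3.7)
        )
        assert mean_density(cell) == pytest.approx(3.7)

    def test_joint_distribution_sums_to_one(self, painted_coarse):
        P, _, _ = joint_distribution(painted_coarse)
        assert P.sum() == pytest.approx(1.0)

    def test_joint_distribution_area_split_spherocylinder(self, spherocylinder):
        """Cylinder wall holds 3π of area (75%), the caps π (25%)."""
        cell = cc.paint_enrichment(spherocylinder, cc.PaintSpec(kind="uniform"))
        P, _, k_edges = joint_distribution(
            cell, curvature_edges=np.array([-1.0, 2.0, 5.0])
        )
        pk = P.sum(axis=0)
        assert pk[0] == pytest.approx(0.75, abs=0.01)
        assert pk[1] == pytest.approx(0.25, abs=0.01)

    def test_joint_matches_brute_force(self, painted_coarse):
        """Histogram equals direct enumeration over faces exactly."""
        i_edges = np.linspace(0, 4, 51)
        k_edges = curvature_bins([painted_coarse])
        P, _, _ = joint_distribution(painted_coarse, i_edges, k_edges)
        rel = painted_coarse.face_intensity / mean_density(painted_coarse)
        brute = np.zeros_like(P)
        for r, k, a in zip(
            rel, painted_coarse.face_curvature, painted_coarse.face_area
        ):
            i = min(max(np.searchsorted(i_edges, r, "right") - 1, 0), P.shape[0] - 1)
            j = min(max(np.searchsorted(k_edges, k, "right") - 1, 0), P.shape[1] - 1)
            brute[i, j] += a
        brute /= painted_coarse.face_area.sum()
        assert np.allclose(P, brute, atol=1e-15)

    def test_conditional_expectation_matches_brute_force(self, painted_coarse):
        k_edges = curvature_bins([painted_coarse])
        E, P = conditional_expectation(painted_coarse, k_edges)
        rel = painted_coarse.face_intensity / mean_density(painted_coarse)
        kw = np.clip(
            np.digitize(painted_coarse.face_curvature, k_edges) - 1,
            0,
            len(k_edges) - 2,
        )
        for b in range(len(k_edges) - 1):
            sel = kw == b
            if sel.any():
                brute = np.average(rel[sel], weights=painted_coarse.face_area[sel])
                assert E[b] == pytest.approx(brute, abs=1e-12)
            else:
                assert np.isnan(E[b]) and P[b] == 0.0

    def test_law_of_total_expectation(self, painted_coarse):
        """Σ_K P(K)·E[I/I*|K] = 1 exactly under per-cell normalisation."""
        k_edges = curvature_bins([painted_coarse])
        E, P = conditional_expectation(painted_coarse, k_edges)
        assert np.nansum(np.where(P > 0, E * P, 0.0)) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, painted_coarse):
        """Multiplying one cell's intensities by any constant changes nothing."""
        k_edges = curvature_bins([painted_coarse])
        E1, _ = conditional_expectation(painted_coarse, k_edges)
        scaled = painted_coarse.with_intensity(painted_coarse.face_intensity * 37.5)
        E2, _ = conditional_expectation(scaled, k_edges)
        assert np.allclose(E1, E2, equal_nan=True)


class TestPopulationProfile:
    def test_uniform_population_profile_is_one(self, spherocylinder):
        cell = cc.paint_enrichment(spherocylinder, cc.PaintSpec(kind="uniform"))
        prof = population_profile([cell] * 10)
        assert np.allclose(prof.mean[prof.mask], 1.0)
        assert np.allclose(prof.sem[prof.mask], 0.0)

    def test_two_cell_mean_and_sem(self, spherocylinder):
        """Mean and SEM across cells follow the textbook formulas per bin."""
        lo = cc.paint_enrichment(
            spherocylinder, cc.PaintSpec(kind="step", low=1.1, high=0.6)
        )
        hi = cc.paint_enrichment(
            spherocylinder, cc.PaintSpec(kind="step", low=1.3, high=0.2)
        )
        edges = curvature_bins([lo, hi])
        e1, _ = conditional_expectation(lo, edges)
        e2, _ = conditional_expectation(hi, edges)
        prof = population_profile([lo, hi], curvature_edges=edges)
        both = np.isfinite(e1) & np.isfinite(e2)
        assert np.allclose(prof.mean[both], (e1 + e2)[both] / 2)
        assert np.allclose(prof.sem[both], np.abs(e1 - e2)[both] / 2)

    def test_step_recovery_within_5pct(self, step_population):
        """A 20-cell noisy population recovers the painted step within 5%."""
        cells, _, truth = step_population
        prof = population_profile(cells)
        k = prof.k_centers[prof.mask]
        got = prof.mean[prof.mask]
        want = np.where(k < 2.0, truth["g_low_true"].mean(), truth["g_high_true"].mean())
        assert np.all(np.abs(got - want) / want < 0.05)

    def test_bin_width_halving_insensitive(self, step_population):
        """Halving the curvature bin width moves the profile < 2%."""
        cells, _, _ = step_population
        p1 = population_profile(cells, bin_width=0.25)
        p2 = population_profile(cells, bin_width=0.125)
        # compare on the coarse grid away from the step edge
        for kc, m in zip(p1.k_centers[p1.mask], p1.mean[p1.mask]):
            if abs(kc - 2.0) < 0.5:
                continue
            j = np.argmin(np.abs(p2.k_centers - kc))
            if p2.mask[j]:
                assert abs(p2.mean[j] - m) / m < 0.02


class TestSmoothingAndScalars:
    def test_flat_profile_smooths_to_one(self, spherocylinder):
        cell = cc.paint_enrichment(spherocylinder, cc.PaintSpec(kind="uniform"))
        prof = smooth_and_truncate(population_profile([cell] * 5))
        assert np.allclose(prof.smoothed[prof.mask], 1.0, atol=1e-6)

    def test_truncation_drops_rare_curvatures(self, step_population):
        cells, _, _ = step_population
        prof = smooth_and_truncate(population_profile(cells), p_threshold=5e-3)
        assert (~prof.mask).sum() > 0
        assert np.all(prof.p_avail[~prof.mask & (prof.n_cells > 0)] <= 5e-3)

    def test_noisy_linear_g_spline_within_3pct(self):
        from dataclasses import replace

        strain = replace(
            cc.preset("wt"),
            paint=cc.PaintSpec(kind="linear", low=1.0, slope=-0.1, noise_cv=0.15),
        )
        cells, _, _ = cc.generate_population(strain, 12, master_seed=21)
        prof = smooth_and_truncate(population_profile(cells))
        k = prof.k_centers[prof.mask]
        # expected: per-cell-normalised linear paint
        norms = [
            np.average(1.0 - 0.1 * c.face_curvature, weights=c.face_area)
            for c in cells
        ]
        want = (1.0 - 0.1 * k) / np.mean(norms)
        assert np.all(np.abs(prof.smoothed[prof.mask] - want) / want < 0.03)

    def test_uniform_scalars(self, spherocylinder):
        cell = cc.paint_enrichment(spherocylinder, cc.PaintSpec(kind="uniform"))
        sc = enrichment_scalars([cell] * 3)
        assert sc.below == pytest.approx(1.0)
        assert sc.above == pytest.approx(1.0)

    def test_cell_without_high_curvature_contributes_one_side(self, spherocylinder):
        cell = cc.paint_enrichment(spherocylinder, cc.PaintSpec(kind="uniform"))
        sc = enrichment_scalars([cell], cutoff=1e9)
        assert sc.n_below == 1 and sc.n_above == 0
        assert np.isnan(sc.above)
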