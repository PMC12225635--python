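"""Synthetic cohort generator: masks, decay rendering, cohort sampling."""

import numpy as np
import pytest

import omicm as om
from omicm.simulate import GeometryError, MissingTruthError

from conftest import two_group_design


class TestMasks:
    def test_zero_cells_gives_empty_masks(self, small_spec):
        masks = om.make_cell_masks(0, small_spec, seed=1)
        assert masks.labels.size == 0
        assert not masks.whole_cell.any() and not masks.nuclei.any()

    def test_deterministic_given_seed(self):
        spec = om.AcquisitionSpec(width=128, height=128)
        a = om.make_cell_masks(5, spec, seed=7)
        b = om.make_cell_masks(5, spec, seed=7)
        assert np.array_equal(a.whole_cell, b.whole_cell)
        assert np.array_equal(a.nuclei, b.nuclei)

    def test_nuclei_contained_in_own_cell(self):
        spec = om.AcquisitionSpec(width=128, height=128)
        masks = om.make_cell_masks(5, spec, seed=7)
        assert masks.labels.size == 5
        nuc = masks.nuclei > 0
        assert np.array_equal(masks.whole_cell[nuc], masks.nuclei[nuc])
        for lab in masks.labels:  # nucleus non-degenerate and strictly inside
            assert 0 < (masks.nuclei == lab).sum() < (masks.whole_cell == lab).sum()

    def test_cells_pairwise_disjoint_by_construction(self):
        spec = om.AcquisitionSpec(width=96, height=96)
        masks = om.make_cell_masks(4, spec, seed=2)
        # labels are written once each; disjointness <=> per-label areas sum
        areas = sum(int((masks.whole_cell == lab).sum()) for lab in masks.labels)
        assert areas == int((masks.whole_cell > 0).sum())

    def test_geometry_too_small_raises(self):
        spec = om.AcquisitionSpec(width=16, height=16)
        with pytest.raises(GeometryError):
            om.make_cell_masks(3, spec, seed=0, cell_radius_px=12.0)


class TestRenderDecayCube:
    def _one_cell(self, spec, amplitude, background=0.0):
        masks = om.make_cell_masks(1, spec, seed=3, cell_radius_px=8)
        lab = int(masks.labels[0])
        truth = om.SimGroundTruth(
            "f0", "g",
            {lab: {"NADH": om.DecayTruth(0.5, 2.5, 0.7, amplitude, background)}},
        )
        return masks, truth

    def test_zero_signal_zero_background_gives_all_zero_cube(self, small_spec):
        masks, truth = self._one_cell(small_spec, amplitude=0.0)
        cube = om.render_decay_cube(masks, truth, small_spec, seed=1)
        assert not cube.counts.any()

    def test_total_photons_within_poisson_band(self, small_spec):
        masks, truth = self._one_cell(small_spec, amplitude=1e4)
        cube = om.render_decay_cube(masks, truth, small_spec, seed=1)
        total = cube.counts.sum()
        # Poisson(1e4): 4 sigma = 400; small convolution spill past window
        assert abs(total - 1e4) < 4 * np.sqrt(1e4) + 0.01 * 1e4

    def test_noiseless_delta_irf_single_component_is_exponential(self, small_spec):
        masks = om.make_cell_masks(1, small_spec, seed=3, cell_radius_px=8)
        lab = int(masks.labels[0])
        truth = om.SimGroundTruth(
            "f0", "g", {lab: {"NADH": om.DecayTruth(2.0, 2.0, 1.0, 1e4)}}
        )
        cube = om.render_decay_cube(
            masks, truth, small_spec, seed=0,
            irf=om.delta_irf(small_spec), expectation_only=True,
        )
        r, c = np.argwhere(masks.whole_cell == lab)[0]
        y = cube.counts[r, c]
        t = small_spec.time_axis()
        ratio = y / np.exp(-t / 2.0)
        assert np.allclose(ratio, ratio[0])

    def test_missing_truth_raises(self, small_spec):
        masks = om.make_cell_masks(2, small_spec, seed=5, cell_radius_px=8)
        truth = om.SimGroundTruth(
            "f0", "g", {int(masks.labels[0]): {"NADH": om.DecayTruth(0.5, 2.5, 0.7)}}
        )
        with pytest.raises(MissingTruthError):
            om.render_decay_cube(masks, truth, small_spec, seed=1)

    def test_photon_conservation_in_expectation(self):
        spec = om.AcquisitionSpec(width=32, height=32, n_bins=64)
        masks = om.make_cell_masks(1, spec, seed=4, cell_radius_px=7)
        lab = int(masks.labels[0])
        amp, bg = 2e3, 0.02
        truth = om.SimGroundTruth(
            "f0", "g", {lab: {"NADH": om.DecayTruth(0.5, 2.5, 0.7, amp, bg)}}
        )
        totals = [
            om.render_decay_cube(masks, truth, spec, seed=s).counts.sum()
            for s in range(20)
        ]
        expected = amp + 32 * 32 * 64 * bg
        se = np.sqrt(expected / 20)
        assert abs(np.mean(totals) - expected) < 4 * se + 0.01 * expected


class TestCohort:
    def test_field_and_cell_bookkeeping(self, small_spec):
        design = om.CohortDesign(
            groups=(
                om.GroupDesign("a", {om.NADH: om.default_group(om.NADH),
                                     om.FAD: om.default_group(om.FAD)},
                               n_fields=2, n_cells_per_field=4),
                om.GroupDesign("b", {om.NADH: om.default_group(om.NADH),
                                     om.FAD: om.default_group(om.FAD)},
                               n_fields=2, n_cells_per_field=4),
            ),
            seed=1,
        )
        fields = om.sample_cohort(design, small_spec,
                                  mask_kwargs={"cell_radius_px": 6})
        assert len(fields) == 4
        assert sum(len(f.truth.cells) for f in fields) == 16
        for f in fields:
            assert set(f.cubes) == {om.NADH, om.FAD}
            # ground-truth / mask bijection on cell ids
            assert set(f.truth.cells) == set(int(l) for l in f.masks.labels)

    def test_cohort_reproducible_from_design_seed(self, small_spec):
        design = two_group_design(n_per_group=3, separation=1.0, seed=9)
        a = om.sample_cohort(design, small_spec, mask_kwargs={"cell_radius_px": 6})
        b = om.sample_cohort(design, small_spec, mask_kwargs={"cell_radius_px": 6})
        for fa, fb in zip(a, b):
            assert fa.truth.to_frame().equals(fb.truth.to_frame())
            assert np.array_equal(fa.cubes[om.NADH].counts, fb.cubes[om.NADH].counts)

    def test_bimodal_group_produces_two_tau_m_modes(self):
        lo = om.TruthDistribution(tau2_mean=1.8, tau2_sd=0.05, tau2_range=(1.0, 4.0))
        hi = om.TruthDistribution(tau2_mean=3.4, tau2_sd=0.05, tau2_range=(1.0, 4.0))
        mix = om.MixtureDistribution(components=(lo, hi), weights=(0.5, 0.5))
        design = om.CohortDesign(
            groups=(om.GroupDesign("bimodal", {om.NADH: mix, om.FAD: mix},
                                   n_fields=1, n_cells_per_field=400),),
            seed=2,
        )
        table = om.sample_feature_table(design)
        counts, edges = np.histogram(table["nadh_tm"], bins=12)
        interior = counts[1:-1]
        # two separated local maxima with a dip between
        peaks = [
            i for i in range(1, len(counts) - 1)
            if counts[i] >= counts[i - 1] and counts[i] >= counts[i + 1]
            and counts[i] > 0.1 * counts.max()
        ]
        assert len(peaks) >= 2
        assert counts[(peaks[0] + peaks[-1]) // 2] < 0.6 * counts.max()

    def test_feature_table_consistent_with_truth_formula(self):
        design = two_group_design(n_per_group=50, separation=1.0, seed=4)
        table = om.sample_feature_table(design)
        assert len(table) == 100
        tm = table.nadh_a1 * table.nadh_t1 + (1 - table.nadh_a1) * table.nadh_t2
        assert np.allclose(tm, table.nadh_tm)
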