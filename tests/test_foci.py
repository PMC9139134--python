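import numpy as np
import pytest

import oracles
from conftest import gaussian_spot, quantize8
from focidens import (
    FociParams,
    LabeledObjects,
    OptimizationGrid,
    detect_foci,
    generate_scene,
    optimize_parameters,
)
from focidens.errors import ContractError, InsufficientDataError
from focidens.foci import DEFAULT_R_F_GRID, DEFAULT_T_E_GRID, _candidate_components
from focidens.synth import SceneSpec


def counts_of(results):
    return {r.object_label: r.foci_count for r in results}


class TestDetectFoci:
    def test_zero_raster_gives_zero_counts(self, single_object_labels):
        results = detect_foci(np.zeros((64, 64)), single_object_labels)
        assert counts_of(results) == {1: 0}
        assert results[0].density == 0.0

    def test_single_spot_counted(self, single_object_labels):
        img = quantize8(gaussian_spot((64, 64), (32, 32), 0.8, 3.0))
        results = detect_foci(img, single_object_labels, FociParams(r_f=13, t_e=0.55))
        assert counts_of(results) == {1: 1}
        oracle = oracles.count_foci(img, single_object_labels.labels, 13, 0.55)
        assert counts_of(results) == oracle

    def test_dim_spot_fails_intensity_gate(self):
        labels = np.zeros((160, 60), dtype=np.int32)
        labels[10:70, 10:50] = 1
        labels[90:150, 10:50] = 2
        labeled = LabeledObjects.from_labels(labels)
        img = quantize8(
            gaussian_spot((160, 60), (40, 30), 0.8, 3.0)
            + gaussian_spot((160, 60), (120, 30), 0.45, 3.0)  # > 4*r_f apart
        )
        results = detect_foci(img, labeled, FociParams(r_f=13, t_e=0.55))
        assert counts_of(results) == {1: 1, 2: 0}
        assert counts_of(results) == oracles.count_foci(img, labels, 13, 0.55)

    def test_broad_ramp_yields_no_foci(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[8:56, 8:44] = 1  # object clear of the high-edge border band
        ramp = np.tile(np.linspace(0.0, 0.6, 64), (64, 1))
        results = detect_foci(ramp, LabeledObjects.from_labels(labels),
                              FociParams(r_f=13, t_e=0.55))
        assert counts_of(results) == {1: 0}

    def test_unnormalized_raster_rejected(self, single_object_labels):
        with pytest.raises(ContractError):
            detect_foci(np.full((64, 64), 120.0), single_object_labels)

    def test_empty_labeling_returns_empty_list(self):
        empty = LabeledObjects.from_labels(np.zeros((32, 32), dtype=np.int32))
        assert detect_foci(np.zeros((32, 32)), empty) == []

    def test_deterministic(self, single_object_labels, rng):
        img = quantize8(
            gaussian_spot((64, 64), (30, 30), 0.8, 3.0) + rng.normal(0, 0.02, (64, 64))
        )
        a = detect_foci(img, single_object_labels)
        b = detect_foci(img, single_object_labels)
        assert a == b

    def test_increasing_te_never_increases_counts(self, single_object_labels, rng):
        img = quantize8(
            gaussian_spot((64, 64), (25, 25), 0.9, 2.5)
            + gaussian_spot((64, 64), (45, 40), 0.6, 2.5)
            + rng.normal(0, 0.02, (64, 64))
        )
        previous = None
        for t_e in DEFAULT_T_E_GRID:
            count = counts_of(
                detect_foci(img, single_object_labels, FociParams(r_f=9, t_e=t_e))
            )[1]
            if previous is not None:
                assert count <= previous
            previous = count

    def test_counts_sum_to_union_count(self, rng):
        # conservation: each gated component is attributed to exactly one object
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[5:30, 5:60] = 1
        labels[34:60, 5:60] = 2
        img = np.zeros((64, 64))
        for _ in range(6):
            c = rng.uniform(8, 56, 2)
            img += gaussian_spot((64, 64), c, rng.uniform(0.6, 0.9), 2.0)
        img = quantize8(img)
        per_object = counts_of(detect_foci(img, LabeledObjects.from_labels(labels),
                                           FociParams(r_f=7, t_e=0.55)))
        gated = [
            1
            for intensity, lab in _candidate_components(img, labels, 7)
            if lab > 0 and intensity > 0.55
        ]
        assert sum(per_object.values()) == len(gated)


def _calibration_images(seeds, doses):
    pairs = []
    for seed, dose in zip(seeds, doses):
        spec = SceneSpec(
            seed=seed,
            image_size=(200, 200),
            n_nuclei=3,
            nucleus_radius_range=(28.0, 32.0),
            foci_per_nucleus=int(round(1 + 2 * dose)),
            focus_peak_range=(0.65, 0.8),
            dose_gy=dose,
            group="control",
        )
        pairs.append(generate_scene(spec)[0])
    return pairs


class TestOptimizeParameters:
    def test_single_cell_grid_returns_that_pair(self):
        pairs = _calibration_images([1, 2, 3], [0.0, 1.0, 2.0])
        grid = OptimizationGrid(r_f_values=(13,), t_e_values=(0.55,))
        best, table = optimize_parameters(pairs, grid)
        assert (best.r_f, best.t_e) == (13, 0.55)
        assert len(table) == 1

    def test_too_few_dose_levels_rejected(self):
        pairs = _calibration_images([1, 2], [0.0, 1.0])
        with pytest.raises(InsufficientDataError):
            optimize_parameters(pairs, OptimizationGrid(r_f_values=(13,), t_e_values=(0.55,)))

    def test_default_grids_have_90_cells(self):
        assert len(DEFAULT_R_F_GRID) == 10
        assert len(DEFAULT_T_E_GRID) == 9
        pairs = _calibration_images([1, 2, 3], [0.0, 1.0, 2.0])
        _, table = optimize_parameters(pairs, OptimizationGrid())
        assert len(table) == 90

    def test_argmax_consistent_with_uncached_reevaluation(self):
        # exhaustive per-pair rerun through the public detector is the oracle
        from focidens import segment_nuclei, normalize
        from focidens.foci import _r2_of_mean_density_vs_dose

        pairs = _calibration_images([1, 2, 3, 4], [0.0, 0.5, 1.0, 2.0])
        grid = OptimizationGrid(r_f_values=(7, 13), t_e_values=(0.45, 0.55))
        best, table = optimize_parameters(pairs, grid)

        segmented = [(p, segment_nuclei(p.nuclei)) for p in pairs]
        scores = {}
        for r_f in grid.r_f_values:
            for t_e in grid.t_e_values:
                per_image = []
                for pair, labeled in segmented:
                    res = detect_foci(normalize(pair.foci), labeled,
                                      FociParams(r_f=r_f, t_e=t_e))
                    per_image.append((pair.dose_gy, res))
                scores[(r_f, t_e)] = _r2_of_mean_density_vs_dose(per_image)
        for _, row in table.iterrows():
            assert scores[(row.r_f, row.t_e)] == pytest.approx(row.score, abs=1e-12)
        assert scores[(best.r_f, best.t_e)] == max(scores.values())

    def test_deterministic(self):
        pairs = _calibration_images([5, 6, 7], [0.0, 1.0, 2.0])
        grid = OptimizationGrid(r_f_values=(9, 13), t_e_values=(0.5, 0.55))
        best1, table1 = optimize_parameters(pairs, grid)
        best2, table2 = optimize_parameters(pairs, grid)
        assert best1 == best2
        assert table1.equals(table2)
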