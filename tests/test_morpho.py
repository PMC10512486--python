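"""Soma/process decomposition, per-cell measurements, GFAP+ calling and
field summaries, checked against hand counts and brute-force oracles."""

import numpy as np
import pytest
from skimage.draw import disk

import oracles
from astroquant import (
    ChannelStack,
    classify_gfap_positive,
    decompose_soma_processes,
    generate_field,
    measure_cell,
    populate_field,
    summarize_field,
)
from astroquant.morpho import CellRecord, EmptyPerinuclearZoneError


def make_record(**kw):
    base = dict(
        cell_id=1, nucleus_centroid=(0.0, 0.0), cell_area_px=100,
        soma_area_px=80, process_area_px=20, process_perimeter_px=40,
        perinuclear_gfap_mean=10.0, vimentin_mean=None, gfap_positive=None,
    )
    base.update(kw)
    return CellRecord(**base)


class TestDecomposeSomaProcesses:
    def test_disk_with_spur_matches_brute_force_opening_oracle(self):
        cell = np.zeros((48, 64), dtype=bool)
        rr, cc = disk((24, 20), 10)
        cell[rr, cc] = True
        cell[23:25, 28:43] = True  # 2-px-wide, 15-px-long spur
        nucleus = np.zeros_like(cell)
        rr, cc = disk((24, 20), 4)
        nucleus[rr, cc] = True
        soma, process = decompose_soma_processes(cell, nucleus, 3)
        expected_soma = oracles.brute_opening(cell, 3)
        assert np.array_equal(soma, expected_soma)
        assert np.array_equal(process, cell & ~expected_soma)
        assert process.sum() > 0

    def test_opening_is_identity_on_a_large_disk(self):
        cell = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 20)
        cell[rr, cc] = True
        nucleus = np.zeros_like(cell)
        rr, cc = disk((32, 32), 6)
        nucleus[rr, cc] = True
        soma, process = decompose_soma_processes(cell, nucleus, 8)
        assert process.sum() == 0
        assert np.array_equal(soma, cell)

    def test_empty_cell_mask_rejected(self):
        empty = np.zeros((16, 16), dtype=bool)
        with pytest.raises(ValueError, match="empty cell mask"):
            decompose_soma_processes(empty, empty, 3)

    def test_nucleus_outside_cell_rejected(self):
        cell = np.zeros((32, 32), dtype=bool)
        cell[4:12, 4:12] = True
        nucleus = np.zeros_like(cell)
        nucleus[20:24, 20:24] = True
        with pytest.raises(ValueError, match="outside"):
            decompose_soma_processes(cell, nucleus, 3)

    def test_fallback_soma_when_opening_is_empty(self):
        """A cell thinner than the element everywhere falls back to the
        dilated nucleus as soma."""
        cell = np.zeros((32, 32), dtype=bool)
        cell[15:18, 2:30] = True  # 3-px-thick bar
        nucleus = np.zeros_like(cell)
        nucleus[15:18, 14:17] = True
        soma, process = decompose_soma_processes(cell, nucleus, 8)
        assert soma.sum() > 0
        assert np.array_equal(soma, oracles.brute_dilate(nucleus, 2) & cell)
        assert np.array_equal(soma | process, cell)

    def test_soma_component_nearest_nucleus_is_chosen(self):
        """With two openable lobes, the one holding the nucleus wins."""
        cell = np.zeros((40, 80), dtype=bool)
        rr, cc = disk((20, 20), 10)
        cell[rr, cc] = True
        rr, cc = disk((20, 60), 10)
        cell[rr, cc] = True
        cell[19:22, 28:53] = True  # bridge
        nucleus = np.zeros_like(cell)
        rr, cc = disk((20, 60), 4)
        nucleus[rr, cc] = True
        soma, _ = decompose_soma_processes(cell, nucleus, 5)
        assert soma[20, 60] and not soma[20, 20]


class TestMeasureCell:
    def _uniform_stack(self, shape, gfap=50.0, vimentin=7.0):
        return ChannelStack(
            nuclei=np.zeros(shape), gfap=np.full(shape, gfap),
            vimentin=np.full(shape, vimentin),
        )

    def test_square_process_perimeter_is_forty(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[2:18, 2:18] = True
        process = np.zeros_like(cell)
        process[5:15, 5:15] = True  # 10x10 solid square
        soma = cell & ~process
        peri = np.zeros_like(cell)
        peri[3, 3] = True
        rec = measure_cell(1, cell, soma, process, peri,
                           self._uniform_stack((20, 20)))
        assert rec.process_perimeter_px == 40

    @pytest.mark.parametrize("seed", range(5))
    def test_perimeter_matches_brute_edge_count_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) > 0.6
        from astroquant.maskops import exposed_edge_perimeter

        assert exposed_edge_perimeter(mask) == oracles.brute_perimeter(mask)

    def test_uniform_vimentin_mean_recovered(self):
        cell = np.zeros((16, 16), dtype=bool)
        cell[4:12, 4:12] = True
        peri = np.zeros_like(cell)
        peri[5, 5] = True
        rec = measure_cell(1, cell, cell, np.zeros_like(cell), peri,
                           self._uniform_stack((16, 16), vimentin=7.0))
        assert rec.vimentin_mean == pytest.approx(7.0)
        assert rec.perinuclear_gfap_mean == pytest.approx(50.0)

    def test_areas_are_additive_by_construction(self):
        cell = np.zeros((16, 16), dtype=bool)
        cell[2:12, 2:12] = True
        soma = np.zeros_like(cell)
        soma[2:10, 2:12] = True
        process = cell & ~soma
        peri = np.zeros_like(cell)
        peri[3, 3] = True
        rec = measure_cell(1, cell, soma, process, peri,
                           self._uniform_stack((16, 16)))
        assert rec.soma_area_px + rec.process_area_px == rec.cell_area_px == 100

    def test_empty_perinuclear_zone_raises_dedicated_error(self):
        cell = np.zeros((8, 8), dtype=bool)
        cell[2:6, 2:6] = True
        with pytest.raises(EmptyPerinuclearZoneError, match="cell 9"):
            measure_cell(9, cell, cell, np.zeros_like(cell),
                         np.zeros_like(cell), self._uniform_stack((8, 8)))

    def test_inconsistent_masks_rejected(self):
        cell = np.ones((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="partition"):
            measure_cell(1, cell, cell, cell, cell,
                         self._uniform_stack((8, 8)))

    def test_scale_doubling_quadruples_area_and_doubles_perimeter(self):
        stack_s = self._uniform_stack((32, 32))
        stack_l = self._uniform_stack((64, 64))
        recs = []
        for k, stack in ((1, stack_s), (2, stack_l)):
            cell = np.zeros(stack.shape, dtype=bool)
            cell[4 * k:16 * k, 4 * k:16 * k] = True
            process = np.zeros_like(cell)
            process[6 * k:10 * k, 6 * k:10 * k] = True
            soma = cell & ~process
            peri = np.zeros_like(cell)
            peri[5 * k, 5 * k] = True
            recs.append(measure_cell(1, cell, soma, process, peri, stack))
        small, large = recs
        assert large.cell_area_px == 4 * small.cell_area_px
        assert large.process_area_px == 4 * small.process_area_px
        assert large.process_perimeter_px == 2 * small.process_perimeter_px


class TestClassifyGfapPositive:
    def test_fixed_threshold_splits_at_t(self):
        recs = [make_record(perinuclear_gfap_mean=11.0),
                make_record(perinuclear_gfap_mean=9.0)]
        out, thr = classify_gfap_positive(recs, mode="fixed",
                                          fixed_threshold=10.0)
        assert thr == 10.0
        assert [r.gfap_positive for r in out] == [True, False]

    def test_otsu_on_bimodal_pool_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        lows = rng.normal(50, 3, size=10)
        highs = rng.normal(500, 30, size=10)
        recs = [make_record(perinuclear_gfap_mean=float(v))
                for v in np.concatenate([lows, highs])]
        out, thr = classify_gfap_positive(recs, mode="otsu")
        assert sum(r.gfap_positive for r in out) == 10
        assert all(r.gfap_positive == (r.perinuclear_gfap_mean > thr)
                   for r in out)
        oracle_thr = oracles.otsu_exhaustive(
            np.concatenate([lows, highs]))
        assert thr == pytest.approx(oracle_thr)

    def test_single_record_otsu_rejected(self):
        with pytest.raises(ValueError):
            classify_gfap_positive([make_record()], mode="otsu")

    def test_mode_threshold_pairing_enforced(self):
        with pytest.raises(ValueError, match="fixed_threshold"):
            classify_gfap_positive([make_record()], mode="fixed")


class TestSummarizeField:
    def test_summed_ratio_arithmetic(self):
        recs = [
            make_record(cell_area_px=600, soma_area_px=120,
                        process_area_px=480, process_perimeter_px=200,
                        gfap_positive=True),
            make_record(cell_id=2, cell_area_px=400, soma_area_px=80,
                        process_area_px=320, process_perimeter_px=150,
                        gfap_positive=True),
        ]
        s = summarize_field(recs)
        assert s.soma_to_cell == pytest.approx(200 / 1000)
        assert s.process_to_soma == pytest.approx(800 / 200)
        assert s.process_to_cell == pytest.approx(800 / 1000)
        assert s.process_perimeter_to_cell == pytest.approx(350 / 1000)

    def test_gfap_positive_fraction_counts_all_cells(self):
        recs = [make_record(cell_id=i, gfap_positive=(i < 3))
                for i in range(4)]
        s = summarize_field(recs)
        assert s.gfap_positive_fraction == pytest.approx(0.75)
        assert s.n_cells == 4

    def test_all_soma_field_has_zero_process_ratios(self):
        recs = [make_record(cell_area_px=80, soma_area_px=80,
                            process_area_px=0, process_perimeter_px=0,
                            gfap_positive=True)]
        s = summarize_field(recs)
        assert s.process_to_soma == 0.0
        assert s.process_perimeter_to_cell == 0.0

    def test_morphology_can_include_negative_cells_on_request(self):
        recs = [
            make_record(gfap_positive=True, soma_area_px=50,
                        process_area_px=50),
            make_record(cell_id=2, gfap_positive=False, soma_area_px=100,
                        process_area_px=0),
        ]
        restricted = summarize_field(recs)
        full = summarize_field(recs, gfap_positive_only_for_morphology=False)
        assert restricted.process_to_soma > full.process_to_soma

    def test_zero_cells_or_zero_positive_rejected(self):
        with pytest.raises(ValueError):
            summarize_field([])
        with pytest.raises(ValueError, match="GFAP"):
            summarize_field([make_record(gfap_positive=False)])


class TestMorphologyRecovery:
    def test_stellate_exceeds_flat_process_to_soma_in_all_replicates(self):
        """From rendered truth masks, the summed process/soma ratio of a
        stellate field beats a flat field for every seed tried."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            ratios = {}
            for cls in ("stellate", "flat"):
                specs = populate_field({cls: 1}, (256, 256), seed=seed)
                _, truth = generate_field(specs, (256, 256), seed=seed + 1)
                records = []
                for row in truth.cell_table.itertuples():
                    cell = truth.cell_labels == row.cell_id
                    nucleus = truth.nuclei_labels == row.cell_id
                    soma, process = decompose_soma_processes(cell, nucleus, 8)
                    records.append(make_record(
                        cell_id=row.cell_id,
                        cell_area_px=int(cell.sum()),
                        soma_area_px=int(soma.sum()),
                        process_area_px=int(process.sum()),
                        gfap_positive=True,
                    ))
                ratios[cls] = summarize_field(records).process_to_soma
            wins += ratios["stellate"] > ratios["flat"]
        assert wins == n_rep
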