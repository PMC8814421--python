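"""Synthetic-data generators: sequences, measurement tables, stacks."""

import numpy as np
import pytest

from cisquant import (
    Background,
    ConstructSpec,
    ExpressionSimConfig,
    Plant,
    RenderCell,
    ScanConfig,
    SequenceSimConfig,
    generate_enhancer,
    normalize_experiment,
    overlap_positions,
    render_stack,
    roi_mean,
    scan_sequence,
    simulate_cells,
    simulate_measurements,
    sum_project,
)

BG = Background.uniform()


class TestGenerateEnhancer:
    def test_planted_consensus_is_found_and_unique(self, library):
        cfg = SequenceSimConfig(plants=[Plant("SYN_ETS", 100)], seed=3)
        seq, truth = generate_enhancer(cfg, library)
        assert len(seq) == 377
        hits = scan_sequence(seq, library.loms["SYN_ETS"], BG, ScanConfig(p_threshold=1e-3))
        covering = [h for h in hits if h.start <= 100 <= h.end]
        assert covering, "planted site must be recovered"
        outside = [h for h in hits if h.end < 100 or h.start > 107]
        assert outside == []
        assert truth.planted_hits[0].start == 100

    def test_zero_plants_clean_background(self, library):
        seq, truth = generate_enhancer(SequenceSimConfig(seed=9), library)
        cfg = ScanConfig(p_threshold=1e-3)
        for lom in library.loms.values():
            assert scan_sequence(seq, lom, BG, cfg) == []
        assert truth.planted_hits == []

    def test_core_sharing_site_fully_overlaps_at_relaxed_threshold(self, library):
        """A planted RBPJ-family site embeds a complete Ets-family match.

        The shared GGAA core means the Ets match only appears once the
        p-value threshold is relaxed from 1e-3 to 1e-2 — a low-scoring
        site nested inside (full overlap with) the stricter-threshold hit.
        """
        cfg = SequenceSimConfig(plants=[Plant("SYN_RBPJ", 150)], seed=21)
        seq, _ = generate_enhancer(cfg, library)
        strict = ScanConfig(p_threshold=1e-3)
        relaxed = ScanConfig(p_threshold=1e-2)
        assert scan_sequence(seq, library.loms["SYN_ETS"], BG, strict) == []
        ets = scan_sequence(seq, library.loms["SYN_ETS"], BG, relaxed)
        rbpj = scan_sequence(seq, library.loms["SYN_RBPJ"], BG, strict)
        pairs = overlap_positions(ets, rbpj)
        assert any(kind == "full" for _, _, kind in pairs)

    def test_plant_outside_bounds_rejected(self, library):
        with pytest.raises(ValueError, match="outside"):
            generate_enhancer(
                SequenceSimConfig(plants=[Plant("SYN_BRA", 375)], seed=0), library
            )

    def test_overlapping_plants_need_flag(self, library):
        cfg = SequenceSimConfig(
            plants=[Plant("SYN_ETS", 100), Plant("SYN_ETS", 103)], seed=0
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_enhancer(cfg, library)

    def test_seed_reproducibility(self, library):
        cfg = SequenceSimConfig(plants=[Plant("SYN_FOXA", 50)], seed=123)
        s1, _ = generate_enhancer(cfg, library)
        s2, _ = generate_enhancer(cfg, library)
        assert s1 == s2


class TestSimulateMeasurements:
    def test_noise_free_limit_exact_ratio(self):
        cfg = ExpressionSimConfig(
            constructs=[ConstructSpec("WT"), ConstructSpec("HALF", strength=0.5)],
            n_embryos=3, n_replicates=1,
            efficiency_sigma=0.0, cell_sigma=0.0, baseline=0.0,
            reporter_scale=1000.0, control_scale=2000.0,
            seed=0,
        )
        table, _ = simulate_measurements(cfg)
        wt = table[table["construct_id"] == "WT"]
        half = table[table["construct_id"] == "HALF"]
        assert np.allclose(wt["reporter_mean"] / wt["control_mean"], 0.5)
        assert np.allclose(half["reporter_mean"] / half["control_mean"], 0.25)

    def test_efficiency_varies_raw_but_cancels_in_ratio(self):
        """E_j spreads raw intensities >2-fold yet never touches the ratio."""
        common = dict(
            constructs=[ConstructSpec("WT")], n_embryos=40, n_replicates=1,
            cell_sigma=0.0, baseline=0.0, seed=6,
        )
        noisy, truth = simulate_measurements(ExpressionSimConfig(efficiency_sigma=1.0, **common))
        quiet, _ = simulate_measurements(ExpressionSimConfig(efficiency_sigma=0.0, **common))
        assert noisy["reporter_mean"].max() / noisy["reporter_mean"].min() > 2
        ratios_noisy = noisy["reporter_mean"] / noisy["control_mean"]
        ratios_quiet = quiet["reporter_mean"] / quiet["control_mean"]
        assert np.allclose(sorted(ratios_noisy), sorted(ratios_quiet))
        assert len(truth.efficiencies) == 40

    def test_strength_recovery(self):
        cfg = ExpressionSimConfig(
            constructs=[ConstructSpec("WT"), ConstructSpec("MUT", strength=0.3)],
            n_embryos=200, n_replicates=1, seed=5,
        )
        table, _ = simulate_measurements(cfg)
        norm = normalize_experiment(table, "WT")
        mut_mean = norm.loc[norm["construct_id"] == "MUT", "normalized_ratio"].mean()
        assert mut_mean == pytest.approx(0.3, abs=0.03)

    def test_reproducibility_bit_identical(self):
        cfg = ExpressionSimConfig(n_embryos=4, n_replicates=2, seed=99)
        t1, _ = simulate_measurements(cfg)
        t2, _ = simulate_measurements(cfg)
        assert t1.equals(t2)


class TestSimulateCells:
    def test_zero_mosaicism_all_baseline(self):
        cfg = ExpressionSimConfig(
            constructs=[ConstructSpec("OFF", mosaicism=0.0)],
            control_mosaicism=0.0, n_embryos=3, n_replicates=1, seed=2,
        )
        cells, _ = simulate_cells(cfg)
        assert np.allclose(cells["reporter_mean"], cfg.baseline)
        assert np.allclose(cells["control_mean"], cfg.baseline)

    def test_control_histogram_bimodal(self):
        """Expressing and dark cells sit > 4 log2 units apart."""
        cfg = ExpressionSimConfig(
            constructs=[ConstructSpec("WT")], control_mosaicism=0.7,
            n_embryos=30, n_replicates=1, seed=8,
        )
        cells, _ = simulate_cells(cfg)
        on = np.log2(cells.loc[cells["control_expressed"], "control_mean"])
        off = np.log2(cells.loc[~cells["control_expressed"], "control_mean"])
        assert np.median(on) - np.median(off) > 4

    def test_secondary_attenuation_median_ratio(self):
        cfg = ExpressionSimConfig(
            constructs=[ConstructSpec("WT"), ConstructSpec("RBPJ", secondary_attenuation=0.5)],
            n_embryos=100, n_replicates=1, seed=7,
        )
        table, _ = simulate_measurements(cfg)
        norm = normalize_experiment(table, "WT")
        med = norm.loc[norm["construct_id"] == "RBPJ", "primary_secondary_ratio"].median()
        assert med == pytest.approx(2.0, rel=0.15)


class TestRenderStack:
    def test_single_blob_mass_conserved(self):
        cells = [RenderCell(x=40, y=20, z=4, reporter=500.0, control=900.0)]
        stack, rois, truth = render_stack(cells)
        img = sum_project(stack, "reporter")
        assert img.sum() == pytest.approx(500.0, rel=0.01)
        assert roi_mean(img, rois.whole) > 0
        assert truth.blob_integrals["reporter"].iloc[0] == 500.0

    def test_empty_cells_zero_stack(self):
        stack, _, _ = render_stack([])
        assert not stack.voxels.any()

    def test_channel_linearity(self):
        cells = [RenderCell(x=30, y=20, z=3, reporter=100.0, control=200.0)]
        doubled = [RenderCell(x=30, y=20, z=3, reporter=200.0, control=200.0)]
        s1, rois, _ = render_stack(cells)
        s2, _, _ = render_stack(doubled)
        m1 = roi_mean(sum_project(s1, "reporter"), rois.whole)
        m2 = roi_mean(sum_project(s2, "reporter"), rois.whole)
        assert m2 == pytest.approx(2 * m1)

    def test_centroid_outside_volume_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_stack([RenderCell(x=500, y=0, z=0, reporter=1, control=1)])

    def test_lineage_rois_emitted(self):
        cells = [
            RenderCell(x=10 + 7 * i, y=20, z=3, reporter=300, control=400,
                       lineage="primary" if i < 4 else "secondary")
            for i in range(6)
        ]
        _, rois, _ = render_stack(cells)
        assert rois.primary is not None and rois.secondary is not None


def test_end_to_end_efficiency_cancellation():
    """Render -> project -> ROI -> normalize recovers construct strengths."""
    rng = np.random.default_rng(12)
    rows = []
    for construct, strength in (("WT", 1.0), ("MUT", 0.4)):
        for e in range(6):
            eff = float(rng.lognormal(0, 1))
            cells = [
                RenderCell(x=8 + 10 * i, y=24, z=4,
                           reporter=strength * 600 * eff, control=800 * eff,
                           lineage="primary")
                for i in range(8)
            ]
            stack, rois, _ = render_stack(cells)
            rep = sum_project(stack, "reporter")
            ctl = sum_project(stack, "control")
            rows.append(
                {"embryo_id": f"{construct}{e}", "replicate_id": "r1",
                 "construct_id": construct,
                 "reporter_mean": roi_mean(rep, rois.whole),
                 "control_mean": roi_mean(ctl, rois.whole)}
            )
    import pandas as pd

    norm = normalize_experiment(pd.DataFrame(rows), "WT")
    mut = norm.loc[norm["construct_id"] == "MUT", "normalized_ratio"]
    assert np.allclose(mut, 0.4, atol=1e-6)
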