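"""Tile signal arithmetic, changed-tile calling, metagene, genome-wide shift."""

import numpy as np
import pytest
from scipy import stats as sps

from epipersist import chip
from epipersist.intervals import GenomeLayout, make_tiling
from epipersist.simulate import SimConfig, simulate_chip


def small_tiling(n_tiles=10, width=2000):
    return make_tiling(GenomeLayout.from_dict({"chr1": n_tiles * width}), width)


def track(tiling, counts, lib, label="t"):
    return chip.TileCountTrack(tiling, np.asarray(counts), lib, label)


class TestTileSignal:
    def test_rpm_subtract_rescale_arithmetic(self):
        """chip 200 @ 10M RPM 20, input 50 @ 5M RPM 10 -> (20-10)*10 = 100."""
        tiling = small_tiling(1)
        sig = chip.tile_signal(track(tiling, [200], 10_000_000), track(tiling, [50], 5_000_000))
        assert sig.signal[0] == pytest.approx(100.0)
        assert sig.provenance["library_size_chip"] == 10_000_000

    def test_negative_clamped_to_zero(self):
        tiling = small_tiling(1)
        sig = chip.tile_signal(track(tiling, [10], 1_000_000), track(tiling, [50], 1_000_000))
        assert sig.signal[0] == 0.0

    def test_zero_input_identity(self):
        """With all-zero input the scaling and inverse rescale cancel exactly."""
        tiling = small_tiling(8)
        counts = np.array([0, 3, 17, 250, 999, 5, 61, 42])
        sig = chip.tile_signal(track(tiling, counts, 3_141_592), track(tiling, np.zeros(8), 2_718_281))
        np.testing.assert_array_equal(sig.signal, counts.astype(float))

    def test_scale_consistency(self):
        """Doubling chip counts and L_chip doubles the rescaled signal."""
        tiling = small_tiling(4)
        counts = np.array([10, 100, 40, 7])
        inp = track(tiling, [5, 5, 5, 5], 1_000_000)
        s1 = chip.tile_signal(track(tiling, counts, 1_000_000), inp)
        s2 = chip.tile_signal(track(tiling, 2 * counts, 2_000_000), inp)
        np.testing.assert_allclose(s2.signal, 2 * s1.signal)

    def test_mismatched_tilings_rejected(self):
        with pytest.raises(ValueError):
            chip.tile_signal(
                track(small_tiling(2), [1, 1], 10), track(small_tiling(3), [1, 1, 1], 10)
            )


class TestCountRatioTest:
    def test_central(self):
        assert chip.count_ratio_test(10, 10, 1.0) == 1.0

    def test_one_sided_extreme(self):
        assert chip.count_ratio_test(20, 0, 1.0) == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_both_zero_convention(self):
        assert chip.count_ratio_test(0, 0, 1.0) == 1.0

    def test_null_uniformity(self):
        """Poisson pairs with equal means give uniform p (KS at alpha=0.01)."""
        rng = np.random.default_rng(8)
        lam = rng.uniform(5, 200, size=10_000)
        a = rng.poisson(lam)
        b = rng.poisson(lam)
        p = np.array([chip.count_ratio_test(x, y, 1.0) for x, y in zip(a, b)])
        # discrete exact test: p is stochastically >= uniform; check the
        # rejection-rate side of calibration at several thresholds
        for alpha in (0.01, 0.05, 0.1):
            assert np.mean(p < alpha) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / p.size)


class TestTileLog2FC:
    def test_log_ratio_with_and_without_pseudocount(self):
        tiling = small_tiling(1)
        case = chip.TileSignalTrack(tiling, np.array([8.0]), {"library_size_chip": 10})
        ctrl = chip.TileSignalTrack(tiling, np.array([2.0]), {"library_size_chip": 10})
        assert chip.tile_log2fc(case, ctrl, pseudocount=0).log2fc[0] == pytest.approx(2.0)
        assert chip.tile_log2fc(case, ctrl, pseudocount=1).log2fc[0] == pytest.approx(np.log2(3))

    def test_identical_tracks_null(self):
        tiling = small_tiling(5)
        sig = chip.TileSignalTrack(tiling, np.array([1.0, 5, 10, 50, 3]), {"library_size_chip": 10})
        comp = chip.tile_log2fc(sig, sig)
        np.testing.assert_array_equal(comp.log2fc, 0.0)
        np.testing.assert_array_equal(comp.p, 1.0)

    def test_zero_pseudocount_with_zero_signal_rejected(self):
        tiling = small_tiling(1)
        z = chip.TileSignalTrack(tiling, np.array([0.0]), {})
        with pytest.raises(ValueError, match="pseudocount"):
            chip.tile_log2fc(z, z, pseudocount=0)


def comparison(tiling, log2fc, q):
    n = tiling.n_tiles
    return chip.TileComparison(
        tiling,
        np.full(n, float(log2fc)),
        np.full(n, 0.5),
        np.full(n, float(q)),
        np.zeros(n),
    )


class TestCallChangedTiles:
    def test_gain_in_both_replicates(self):
        t = small_tiling(1)
        calls = chip.call_changed_tiles(
            comparison(t, 0.8, 0.05), comparison(t, 0.6, 0.08),
            comparison(t, 0.0, 1.0), comparison(t, 0.0, 1.0),
        )
        assert calls[0] == "gain"

    def test_fc_fails_in_one_replicate(self):
        t = small_tiling(1)
        calls = chip.call_changed_tiles(comparison(t, 0.8, 0.05), comparison(t, 0.3, 0.05))
        assert calls[0] == "unchanged"

    def test_within_genotype_exclusion(self):
        t = small_tiling(1)
        calls = chip.call_changed_tiles(
            comparison(t, 0.8, 0.05), comparison(t, 0.7, 0.05),
            ctrl_vs_ctrl=comparison(t, 0.9, 0.01),
        )
        assert calls[0] == "excluded"

    def test_loss_symmetric(self):
        t = small_tiling(1)
        calls = chip.call_changed_tiles(comparison(t, -0.8, 0.05), comparison(t, -0.6, 0.02))
        assert calls[0] == "loss"

    def test_categories_partition(self, default_run):
        res, _ = default_run
        assert set(np.unique(res.calls)) <= {"gain", "loss", "unchanged", "excluded"}
        assert res.calls.size == res.mean_comparison.log2fc.size


class TestMetagene:
    def test_anchor_count_and_selection(self):
        tiling = small_tiling(100, width=100)
        sigvals = np.arange(100, dtype=float)
        sig = chip.TileSignalTrack(tiling, sigvals, {})
        comp = comparison(tiling, 0.0, 1.0)
        prof = chip.top_tile_metagene(sig, comp, top_fraction=0.05, flank=2)
        # 5 anchors: the 5 largest signals (tiles 95..99); offset 0 has n=5
        assert prof.loc[prof["offset"] == 0, "n"].item() == 5
        np.testing.assert_array_equal(prof["mean_log2fc"], 0.0)

    def test_chromosome_boundary_dropped(self):
        layout = GenomeLayout.from_dict({"c1": 300, "c2": 300})
        tiling = make_tiling(layout, 100)
        sig = chip.TileSignalTrack(tiling, np.array([9.0, 1, 1, 1, 1, 1]), {})
        comp = comparison(tiling, 1.0, 0.01)
        prof = chip.top_tile_metagene(sig, comp, top_fraction=0.16, flank=2)
        # single anchor at tile 0 of c1: offsets -1, -2 have no tiles
        assert prof.loc[prof["offset"] == -1, "n"].item() == 0
        assert prof.loc[prof["offset"] == 1, "n"].item() == 1

    def test_flattening_profile(self, default_run):
        """Planted depletion: log2FC < 0 at the anchors, > 0 in the flanks."""
        res, _ = default_run
        prof = res.metagene.set_index("offset")["mean_log2fc"]
        assert prof[0] < 0
        for off in (1, 2, 3, -1, -2, -3):
            assert prof[off] > 0


class TestGenomewideShift:
    def test_identical_tracks(self):
        tiling = small_tiling(50, width=100)
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, 50)
        t1 = chip.TileSignalTrack(tiling, vals, {"chip": "a"})
        t2 = chip.TileSignalTrack(tiling, vals.copy(), {"chip": "b"})
        summary, test = chip.genomewide_shift([t1, t2], ["x", "y"])
        assert summary["median"].nunique() == 1
        assert test.p > 0.9

    def test_constant_offset(self):
        tiling = small_tiling(50, width=100)
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, 50)
        a = chip.TileSignalTrack(tiling, vals, {"chip": "a"})
        b = chip.TileSignalTrack(tiling, vals + 1, {"chip": "b"})
        summary, _ = chip.genomewide_shift([a, b], ["ctrl", "cko"])
        med = summary.set_index("condition")["median"]
        assert med["cko"] == pytest.approx(med["ctrl"] + 1)

    def test_flattening_raises_mutant_median(self, default_run):
        """Background gain dominates the bulk: mutant median above control."""
        res, _ = default_run
        med = res.shift_summary.groupby("condition")["median"].mean()
        assert med["cko"] > med["ctrl"]
        assert res.shift_summary["mwu_p"].iloc[0] < 1e-10


class TestChipNullCalibration:
    def test_no_planted_change_few_calls(self):
        """d=1, g=0: gain+loss fraction stays within the FDR bound."""
        cfg = SimConfig(seed=21)
        cfg.chip.depletion = 1.0
        cfg.chip.background_gain_frac = 0.0
        tracks, tiling, truth = simulate_chip(cfg)
        assert truth.gained_tiles.size == 0
        sig = {
            f"{cond}_rep{r}": chip.tile_signal(
                tracks[f"chip_{cond}_rep{r}"], tracks[f"input_{cond}_rep{r}"]
            )
            for cond in ("ctrl", "cko") for r in (1, 2)
        }
        rep1 = chip.tile_log2fc(sig["cko_rep1"], sig["ctrl_rep1"],
                                case_counts=tracks["chip_cko_rep1"],
                                control_counts=tracks["chip_ctrl_rep1"])
        rep2 = chip.tile_log2fc(sig["cko_rep2"], sig["ctrl_rep2"],
                                case_counts=tracks["chip_cko_rep2"],
                                control_counts=tracks["chip_ctrl_rep2"])
        calls = chip.call_changed_tiles(rep1, rep2)
        frac = np.mean(np.isin(calls, ["gain", "loss"]))
        n = calls.size
        assert frac <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / n)


class TestFlatteningRecovery:
    def test_planted_depletion_and_gain_recovered(self, default_run):
        """Depleted tiles are called loss; gain calls concentrate in gained truth."""
        res, _ = default_run
        truth = res.truth
        loss_rate = np.mean(res.calls[truth.depleted_tiles] == "loss")
        assert loss_rate >= 0.8
        gained = np.zeros(res.calls.size, dtype=bool)
        gained[truth.gained_tiles] = True
        gain_call = res.calls == "gain"
        a = int((gain_call & gained).sum())
        b = int((gain_call & ~gained).sum())
        c = int((~gain_call & gained).sum())
        d = int((~gain_call & ~gained).sum())
        odds = (a * d) / max(b * c, 1) if b * c else np.inf
        assert odds > 5


class TestChipIO:
    def test_bedgraph_roundtrip(self, tmp_path):
        tiling = small_tiling(6)
        t = track(tiling, [4, 0, 9, 2, 7, 1], 12345, label="x")
        p = tmp_path / "x.bedgraph"
        chip.write_count_bedgraph(t, p)
        back = chip.read_count_bedgraph(p, tiling, 12345, "x")
        np.testing.assert_array_equal(back.counts, t.counts)
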