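import math

import numpy as np
import pytest

from repscreen import (
    SimConfig,
    compute_quant,
    correct_screen,
    emit_fastq,
    expected_quants,
    interpolate_truth,
    make_library,
    sample_counts,
    simulate_truth,
)
from repscreen.screen_sim import _coupled_expectations


class TestSimulateTruth:
    @pytest.mark.parametrize(
        "v,x,fc,indel",
        [
            (0.0, 0.8, 0.2, 0.0),  # all edited cells die
            (1.0, 0.5, 1.0, 0.5),  # neutral gene: no dropout
            (0.4, 0.7, 0.58, 0.7 * 0.4 / 0.58),
        ],
    )
    def test_closed_form_expectations(self, v, x, fc, indel):
        got_fc, got_indel = _coupled_expectations(x, v)
        assert got_fc == pytest.approx(fc, abs=1e-12)
        assert got_indel == pytest.approx(indel, abs=1e-12)

    def test_truth_fields_consistent(self):
        cfg = SimConfig(seed=3, n_genes=20, n_essential=5, n_controls=10)
        truth = simulate_truth(cfg)
        s = cfg.ddr_slope
        for g in truth.guides:
            v_eff = (g.v_true if g.role == "targeting" else 1.0) * (1 + s)
            assert g.v_eff == pytest.approx(v_eff)
            assert g.fc_expected == pytest.approx((1 - g.x_true) + g.x_true * v_eff)
            assert g.indel_obs_expected == pytest.approx(
                g.x_true * v_eff / g.fc_expected
            )
        ab = [g.abundance0 for g in truth.guides]
        assert sum(ab) == pytest.approx(1.0)
        assert len(truth.guides) == 20 * 3 + 10

    def test_essential_gene_count_and_v_ranges(self):
        cfg = SimConfig(seed=3, n_genes=20, n_essential=5, n_controls=0)
        truth = simulate_truth(cfg)
        ess = [v for v in truth.gene_v.values() if v < 1.0]
        assert len(ess) == 5
        assert all(0.1 <= v <= 0.3 for v in ess)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=42, n_genes=15, n_essential=4, n_controls=8)
        assert simulate_truth(cfg) == simulate_truth(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, coupling_fidelity=1.5)
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_genes=5, n_essential=6)

    def test_timepoint_interpolation(self):
        cfg = SimConfig(seed=3, n_genes=10, n_essential=2, n_controls=5)
        truth = simulate_truth(cfg)
        half = interpolate_truth(truth, 0.5)
        for g0, gh in zip(truth.guides, half.guides):
            assert gh.x_true == pytest.approx(0.5 * g0.x_true)
        assert interpolate_truth(truth, 0.0).guides[0].fc_expected == pytest.approx(1.0)


class TestSampleCounts:
    def test_bit_identical_given_seed(self):
        cfg = SimConfig(seed=9, n_genes=10, n_essential=3, n_controls=5, read_depth=10000)
        truth = simulate_truth(cfg)
        a_ref, a_fin = sample_counts(truth, cfg)
        b_ref, b_fin = sample_counts(truth, cfg)
        assert a_ref.counts == b_ref.counts
        assert a_fin.counts == b_fin.counts

    def test_zero_depth_gives_all_zero(self):
        cfg = SimConfig(seed=9, n_genes=5, n_essential=1, n_controls=3, read_depth=0)
        truth = simulate_truth(cfg)
        ref, fin = sample_counts(truth, cfg)
        assert all(c.n_total == 0 for c in ref.counts.values())
        assert all(c.n_total == 0 for c in fin.counts.values())

    def test_invariants_hold(self):
        cfg = SimConfig(seed=9, n_genes=20, n_essential=5, n_controls=10, read_depth=50000)
        truth = simulate_truth(cfg)
        ref, fin = sample_counts(truth, cfg)
        ref.validate()
        fin.validate()
        assert ref.total_reads() == cfg.read_depth
        assert fin.total_reads() == cfg.read_depth

    def test_fc_converges_with_depth(self):
        cfg_lo = SimConfig(seed=9, n_genes=30, n_essential=10, n_controls=20,
                           read_depth=50_000, ddr_slope=0.0)
        cfg_hi = SimConfig(seed=9, n_genes=30, n_essential=10, n_controls=20,
                           read_depth=5_000_000, ddr_slope=0.0)
        truth = simulate_truth(cfg_lo)
        errs = {}
        for cfg in (cfg_lo, cfg_hi):
            ref, fin = sample_counts(truth, cfg)
            quants = {q.guide_id: q for q in compute_quant(ref, fin)}
            w = sum(g.abundance0 * g.fc_expected for g in truth.guides)
            rel = [
                abs(quants[g.guide_id].fc_raw - g.fc_expected / w) / (g.fc_expected / w)
                for g in truth.guides
            ]
            errs[cfg.read_depth] = float(np.median(rel))
        assert errs[5_000_000] < errs[50_000]
        assert errs[5_000_000] < 0.01

    def test_coupled_fraction_matches_fidelity(self):
        cfg = SimConfig(seed=9, n_genes=30, n_essential=5, n_controls=10,
                        read_depth=500_000, coupling_fidelity=0.94)
        truth = simulate_truth(cfg)
        _, fin = sample_counts(truth, cfg)
        tot = sum(c.n_total for c in fin.counts.values())
        coup = sum(c.n_coupled for c in fin.counts.values())
        # binomial(500k, 0.94): +-3 sd is about +-0.001
        assert coup / tot == pytest.approx(0.94, abs=0.002)


class TestEmitFastq:
    def test_all_unedited_recovered(self, tmp_path, small_sim):
        cfg, truth, library = small_sim
        from repscreen.read_classify import GuideCounts, SampleCounts
        from repscreen import count_sample

        counts = SampleCounts(sample_id="s")
        for rec in library[:5]:
            counts.counts[rec.guide_id] = GuideCounts(40, 40, 0)
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        emit_fastq(truth, counts, library, r1, r2, cfg)
        got, report = count_sample(r1, r2, library)
        assert report["n_edited"] == 0
        assert report["coupling_rate"] == 1.0
        assert all(c.n_edited == 0 for c in got.counts.values())

    def test_known_edited_fraction_recovered_exactly(self, tmp_path, small_sim):
        cfg, truth, library = small_sim
        from repscreen.read_classify import GuideCounts, SampleCounts
        from repscreen import count_sample

        counts = SampleCounts(sample_id="s")
        counts.counts[library[0].guide_id] = GuideCounts(1000, 1000, 400)
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        table = emit_fastq(truth, counts, library, r1, r2, cfg)
        assert (table["edit"] == "edited").sum() == 400
        got, _ = count_sample(r1, r2, library)
        gc = got.counts[library[0].guide_id]
        assert (gc.n_total, gc.n_coupled, gc.n_edited) == (1000, 1000, 400)

    def test_truth_table_matches_counts(self, tmp_path, small_sim):
        cfg, truth, library = small_sim
        _, fin = sample_counts(truth, cfg)
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        table = emit_fastq(truth, fin, library, r1, r2, cfg)
        assert len(table) == fin.total_reads()
        per_guide = table.groupby("guide_id")
        for gid, grp in per_guide:
            gc = fin.counts[gid]
            assert len(grp) == gc.n_total
            assert (grp["coupling"] == "coupled").sum() == gc.n_coupled
            assert (grp["edit"] == "edited").sum() == gc.n_edited

    def test_sequencing_error_degrades_monotonically(self, tmp_path):
        import dataclasses

        base = SimConfig(seed=13, n_genes=8, n_essential=2, guides_per_gene=2,
                         n_controls=6, read_depth=2000, coupling_fidelity=0.95)
        truth = simulate_truth(base)
        library = make_library(base)
        _, fin = sample_counts(truth, base)
        from repscreen import count_sample

        accuracies = []
        for rate in (0.0, 0.01):
            cfg = dataclasses.replace(base, seq_error_rate=rate)
            r1, r2 = tmp_path / f"r1_{rate}.fastq", tmp_path / f"r2_{rate}.fastq"
            table = emit_fastq(truth, fin, library, r1, r2, cfg)
            got, report = count_sample(r1, r2, library)
            assert report["n_pairs"] == len(table)
            # per-guide agreement with the emitted truth table
            agree = 0
            for gid, grp in table.groupby("guide_id"):
                gc = got.counts.get(gid)
                if gc is None:
                    continue
                agree += min(gc.n_edited, (grp["edit"] == "edited").sum())
                agree += min(
                    gc.n_coupled - gc.n_edited, (grp["edit"] == "unedited").sum()
                )
                agree += min(gc.n_total - gc.n_coupled, (grp["coupling"] == "uncoupled").sum())
            accuracies.append(agree / len(table))
        assert accuracies[0] >= accuracies[1]
        assert accuracies[1] >= 0.95  # 1% per-base error must stay classifiable

    def test_read_len_too_short_raises(self, small_sim, tmp_path):
        cfg, truth, library = small_sim
        import dataclasses

        bad = dataclasses.replace(cfg, read_len=30)
        _, fin = sample_counts(truth, cfg)
        with pytest.raises(ValueError, match="read_len"):
            emit_fastq(truth, fin, library, tmp_path / "a.fastq", tmp_path / "b.fastq", bad)


class TestEndToEndRecovery:
    def test_sampled_recovery_at_depth(self):
        # moderate scale for routine testing; the acceptance suite runs the
        # full documented configuration
        cfg = SimConfig(seed=17, n_genes=100, n_essential=25, n_controls=150,
                        read_depth=500_000)
        truth = simulate_truth(cfg)
        ref, fin = sample_counts(truth, cfg)
        from repscreen import apply_qc

        quants = apply_qc(compute_quant(ref, fin))
        metrics, fit = correct_screen(quants, make_library(cfg))
        by_truth = truth.by_id()
        errs = [
            abs(m.v - by_truth[m.guide_id].v_true)
            for m in metrics
            if m.role == "targeting" and m.v_defined
            and by_truth[m.guide_id].x_true >= 0.3
        ]
        assert float(np.median(errs)) < 0.05
        assert fit.slope2 == pytest.approx(cfg.ddr_slope, abs=0.03)

    def test_error_grows_as_x_shrinks(self):
        cfg = SimConfig(seed=17, n_genes=100, n_essential=25, n_controls=150,
                        read_depth=500_000)
        truth = simulate_truth(cfg)
        ref, fin = sample_counts(truth, cfg)
        from repscreen import apply_qc

        metrics, _ = correct_screen(apply_qc(compute_quant(ref, fin)), make_library(cfg))
        by_truth = truth.by_id()
        lo, hi = [], []
        for m in metrics:
            if m.role != "targeting" or not m.v_defined:
                continue
            x = by_truth[m.guide_id].x_true
            err = abs(m.v - by_truth[m.guide_id].v_true)
            (lo if x < 0.3 else hi).append(err)
        assert float(np.median(lo)) > float(np.median(hi))
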