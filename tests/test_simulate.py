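"""Generator-level checks: exactness at zero noise, determinism, truth bookkeeping."""

from __future__ import annotations

import dataclasses
import filecmp

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrnmes import (
    ConfigurationError,
    Scenario,
    SimulationConfig,
    TrajectoryConfig,
    default_genome,
    simulate_chip_landscape,
    simulate_expression_panel,
    simulate_timecourse,
)
from adrnmes import io
from adrnmes.simulate import (
    RBPJ_CONSENSUS,
    cascade_clock,
    cumulative_induction,
)


class TestExpressionPanel:
    def test_zero_noise_means_are_exact(self):
        cfg = SimulationConfig(n_genes=200, n_mes_signature=20, n_adrn_signature=15, noise_cv=0.0, seed=3)
        em, truth = simulate_expression_panel(cfg)
        mes_samples = em.samples.index[em.samples["lineage"] == "MES"]
        adrn_samples = em.samples.index[em.samples["lineage"] == "ADRN"]
        for g in truth.planted_mes_genes:
            mes_vals = em.values.loc[g, mes_samples]
            assert mes_vals.nunique() == 1
            diff = mes_vals.iloc[0] - em.values.loc[g, adrn_samples].iloc[0]
            assert diff == pytest.approx(cfg.effect_linear, abs=1e-9)

    def test_same_seed_gives_byte_identical_tsv(self, tmp_path):
        cfg = SimulationConfig(n_genes=300, n_mes_signature=20, n_adrn_signature=20, seed=1)
        for run in ("r1", "r2"):
            em, _ = simulate_expression_panel(cfg)
            io.write_expression(em, tmp_path / run, "panel")
        for name in ("panel_values.tsv", "panel_detection.tsv", "panel_samples.tsv"):
            assert filecmp.cmp(tmp_path / "r1" / name, tmp_path / "r2" / name, shallow=False)

    def test_planted_sets_disjoint_and_conserved(self, default_panel):
        em, truth = default_panel
        assert not truth.planted_mes_genes & truth.planted_adrn_genes
        assert len(truth.planted_mes_genes) == 300
        assert len(truth.planted_adrn_genes) == 250

    def test_rejects_degenerate_dimensions(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=10, n_mes_signature=6, n_adrn_signature=6)
        with pytest.raises(ConfigurationError):
            SimulationConfig(effect_linear=-5)


class TestTimecourse:
    def _small(self, **kw):
        return SimulationConfig(
            n_genes=400, n_mes_signature=40, n_adrn_signature=30, noise_cv=kw.pop("noise_cv", 0.0), seed=kw.pop("seed", 5)
        )

    def test_gsi_keeps_mes_genes_flat(self):
        cfg = self._small()
        traj = TrajectoryConfig(
            timepoints=(0.0, 1.0, 7.0, 14.0),
            scenarios=(Scenario("gsi", ((0.0, 14.0),), gsi_active=True),),
        )
        em, truth = simulate_timecourse(cfg, traj)
        day0 = em.values["gsi_d0"]
        for day in ("gsi_d7", "gsi_d14"):
            moved = (em.values[day] - day0).abs()
            for g in truth.planted_mes_genes:
                assert moved[g] == pytest.approx(0.0, abs=1e-9)

    def test_committed_washout_reaches_mes_endpoint(self):
        cfg = self._small()
        traj = TrajectoryConfig(
            timepoints=(0.0, 1.0, 7.0, 14.0),
            scenarios=(Scenario("washout", ((0.0, 7.0),)),),
        )
        em, truth = simulate_timecourse(cfg, traj)
        assert truth.committed["washout"]
        # at day 14 the cascade has been active 14 days: MES genes at endpoint
        for g in sorted(truth.planted_mes_genes)[:10]:
            base = em.values.loc[g, "washout_d0"]
            assert em.values.loc[g, "washout_d14"] > base + 0.99 * cfg.effect_linear

    def test_uncommitted_washout_returns_to_baseline(self):
        cfg = self._small()
        traj = TrajectoryConfig(
            timepoints=(0.0, 1.0, 3.0, 7.0, 14.0),
            scenarios=(Scenario("short", ((0.0, 3.0),)),),
        )
        em, truth = simulate_timecourse(cfg, traj)
        assert not truth.committed["short"]
        # closed form: clock rises to 3 by day 3, decays to 0 by day 6, so
        # every cascade probeset sits exactly at baseline from day 7 onward
        utr = em.values.loc["NOTCH3_3utr"]
        assert utr["short_d7"] == pytest.approx(utr["short_d0"], abs=1e-9)
        assert utr["short_d14"] == pytest.approx(utr["short_d0"], abs=1e-9)
        assert cascade_clock(14.0, ((0.0, 3.0),), 5.0, False) == 0.0

    def test_transgene_visible_only_to_cds_probeset(self):
        cfg = self._small()
        traj = TrajectoryConfig(
            timepoints=(0.0, 1.0, 7.0, 14.0),
            scenarios=(Scenario("on", ((0.0, 14.0),)),),
        )
        em, truth = simulate_timecourse(cfg, traj)
        cds = em.values.loc["NOTCH3_cds"]
        utr = em.values.loc["NOTCH3_3utr"]
        assert cds["on_d0"] - utr["on_d0"] == pytest.approx(truth.transgene_level, abs=1e-9)
        assert cds["on_d14"] - utr["on_d14"] == pytest.approx(truth.transgene_level, abs=1e-9)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ConfigurationError):
            TrajectoryConfig(
                timepoints=(0.0, 7.0),
                scenarios=(Scenario("bad", ((0.0, 14.0),)),),
            )

    @settings(deadline=None, max_examples=30)
    @given(
        a=st.floats(0, 10),
        la=st.floats(0.5, 6),
        extra=st.floats(0.1, 6),
    )
    def test_commitment_monotone_in_window_nesting(self, a, la, extra):
        """W1 subset of W2 and committed(W1) implies committed(W2)."""
        commitment = 5.0
        w1 = ((a, a + la),)
        w2 = ((max(0.0, a - extra / 2), a + la + extra / 2),)
        c1 = cumulative_induction(w1, 21.0) >= commitment
        c2 = cumulative_induction(w2, 21.0) >= commitment
        assert not c1 or c2


class TestChipLandscape:
    def test_zero_planted_enhancers_gives_background_tracks(self):
        genome = default_genome(n_mes_se=0, n_adrn_se=0, n_typical=0)
        cfg = SimulationConfig(seed=4)
        track_a, track_b, _, truth = simulate_chip_landscape(cfg, genome)
        assert truth.planted_se["MES-SE"] == []
        # pure Poisson(1) background: nothing clears five times the mean
        from adrnmes import enhancers

        norm = enhancers.normalize_track(track_b)
        peaks = enhancers.call_peaks(norm, enhancers.auto_threshold(norm, 5.0), 200)
        assert peaks == []

    def test_noiseless_difference_is_exact(self):
        genome = default_genome(n_typical=10)
        cfg = SimulationConfig(seed=4)
        track_a, track_b, _, truth = simulate_chip_landscape(
            cfg, genome, poisson_noise=False
        )
        (s, e) = truth.planted_se["MES-SE"][0]
        sl = track_a.bin_slice(s, e)
        levels = {
            (t.start, t.end): (t.state_a_level, t.state_b_level)
            for t in genome.enhancer_truth
        }
        a_level, b_level = levels[(s, e)]
        per_bin = track_b.counts[sl] - track_a.counts[sl]
        assert np.allclose(per_bin, b_level - a_level)

    def test_planted_consensus_rescan_matches_truth(self, default_landscape, tmp_path):
        genome_seq, _, _, truth = default_landscape
        fasta = io.write_fasta(genome_seq.chrom_name, genome_seq.sequence, tmp_path / "g.fa")
        seq = io.read_fasta(fasta)[genome_seq.chrom_name]
        mes_se = truth.planted_se["MES-SE"]

        def in_mes(p):
            return any(s <= p < e for s, e in mes_se)

        found = []
        start = seq.find(RBPJ_CONSENSUS)
        while start != -1:
            found.append(start)
            start = seq.find(RBPJ_CONSENSUS, start + 1)
        truth_pos = [iv[0] for iv, _ in truth.planted_motif_sites]
        assert sorted(found) == sorted(truth_pos)
        # elevated rate inside MES-SEs: site density much higher than elsewhere
        inside = sum(1 for p in truth_pos if in_mes(p))
        total_mes = sum(e - s for s, e in mes_se)
        rate_in = inside / total_mes
        rate_out = (len(truth_pos) - inside) / (len(seq) - total_mes)
        assert rate_in > 3 * rate_out

    def test_same_seed_same_landscape(self):
        genome = default_genome(n_typical=20)
        cfg = SimulationConfig(seed=9)
        a1, b1, g1, t1 = simulate_chip_landscape(cfg, genome)
        a2, b2, g2, t2 = simulate_chip_landscape(cfg, genome)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(b1.counts, b2.counts)
        assert g1.sequence == g2.sequence
        assert t1.planted_motif_sites == t2.planted_motif_sites
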