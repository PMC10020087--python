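"""Synthetic-data generator: determinism, geometry, and moment checks."""

import numpy as np
import pytest
from scipy import stats

from m6asplice.events import EVENT_TYPES, build_events
from m6asplice.simulate import (
    SimConfig, make_annotation, simulate_cohort, simulate_knockdown_pair,
    simulate_peaks, simulate_quantifications, simulate_sequences,
)


class TestConfigValidation:
    def test_bad_event_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(event_mix={"SE": 0.5})
        with pytest.raises(ValueError, match="unknown"):
            SimConfig(event_mix={"XX": 1.0})

    def test_bad_shift_and_censor_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(psi_shift=0.0)
        with pytest.raises(ValueError):
            SimConfig(censor_rate=1.0)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            SimConfig(exon_length=0)

    def test_extra_isoforms_rejected(self):
        with pytest.raises(ValueError, match="isoform"):
            SimConfig(isoforms_per_gene=(2, 4))


class TestAnnotationGenerator:
    def test_single_se_gene_structure(self):
        cfg = SimConfig(n_genes=1, event_mix={"SE": 1.0}, seed=0)
        ann = make_annotation(cfg)
        (gene,) = ann.genes.values()
        assert len(gene.transcripts) == 2
        events = build_events(ann)
        assert [e.event_type for e in events] == ["SE"]

    def test_single_ri_gene_structure(self):
        cfg = SimConfig(n_genes=1, event_mix={"RI": 1.0}, seed=0)
        events = build_events(make_annotation(cfg))
        assert [e.event_type for e in events] == ["RI"]

    @pytest.mark.parametrize("etype", EVENT_TYPES)
    def test_each_type_realized_on_both_strands(self, etype):
        for seed in (0, 1, 2, 3):
            cfg = SimConfig(n_genes=4, event_mix={etype: 1.0}, seed=seed)
            events = build_events(make_annotation(cfg))
            assert [e.event_type for e in events] == [etype] * 4

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_genes=200, seed=7)
        a1 = make_annotation(cfg)
        a2 = make_annotation(cfg)
        assert a1.contig_lengths == a2.contig_lengths
        assert a1.transcripts == a2.transcripts

    def test_exactly_one_event_per_gene(self):
        cfg = SimConfig(n_genes=100, seed=3)
        ann = make_annotation(cfg)
        events = build_events(ann)
        assert len(events) == 100
        assert len({e.gene_id for e in events}) == 100


class TestQuantifications:
    def test_noise_free_tpm_ratio_is_exact(self):
        cfg = SimConfig(n_genes=20, seed=2, psi_noise_sd=0.0, expr_noise_sd=0.0)
        ann = make_annotation(cfg)
        quant, gt = simulate_quantifications(ann, cfg)
        events = {e.event_id: e for e in build_events(ann)}
        for gid, eid in gt.gene_to_event.items():
            ev = events[eid]
            inc = quant.tpm.loc[sorted(ev.inclusion_transcripts)].sum()
            tot = inc + quant.tpm.loc[sorted(ev.exclusion_transcripts)].sum()
            for sample in quant.tpm.columns:
                cond = quant.conditions[sample]
                assert inc[sample] / tot[sample] == pytest.approx(
                    gt.true_psi[eid][cond], abs=1e-12
                )

    def test_zero_dispersion_gives_poisson_counts(self):
        cfg = SimConfig(
            n_genes=1000, seed=0, psi_noise_sd=0.0, expr_noise_sd=0.0,
            dispersion_fn=lambda m: np.zeros_like(np.asarray(m, dtype=float)),
        )
        ann = make_annotation(cfg)
        quant, _ = simulate_quantifications(ann, cfg)
        ctrl = [c for c in quant.counts.columns if c.startswith("control")]
        sub = quant.counts[ctrl].values
        m, v = sub.mean(1), sub.var(1, ddof=1)
        ok = m > 20
        assert ok.sum() > 1000
        assert abs((v[ok] / m[ok]).mean() - 1.0) < 0.1

    def test_nb_dispersion_reproduced(self):
        cfg = SimConfig(
            n_genes=1000, seed=1, psi_noise_sd=0.0, expr_noise_sd=0.0,
            dispersion_fn=lambda m: np.full_like(
                np.asarray(m, dtype=float), 0.2
            ),
        )
        ann = make_annotation(cfg)
        quant, _ = simulate_quantifications(ann, cfg)
        ctrl = [c for c in quant.counts.columns if c.startswith("control")]
        sub = quant.counts[ctrl].values
        m, v = sub.mean(1), sub.var(1, ddof=1)
        ok = m > 50
        ratio = (v[ok] / (m[ok] + 0.2 * m[ok] ** 2)).mean()
        assert abs(ratio - 1.0) < 0.15

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(n_genes=50, seed=5)
        ann = make_annotation(cfg)
        q1, _ = simulate_quantifications(ann, cfg)
        q2, _ = simulate_quantifications(ann, cfg)
        assert q1.tpm.equals(q2.tpm)
        assert q1.counts.equals(q2.counts)

    def test_knockdown_pair_shares_truth_but_not_noise(self):
        cfg = SimConfig(n_genes=50, seed=5)
        ann = make_annotation(cfg)
        q1, q2, gt = simulate_knockdown_pair(ann, cfg)
        assert not q1.tpm.equals(q2.tpm)
        assert len(gt.dse_events) > 0

    def test_planted_psi_within_bounds(self):
        cfg = SimConfig(n_genes=300, seed=8, psi_shift=0.3)
        ann = make_annotation(cfg)
        _, gt = simulate_quantifications(ann, cfg)
        for by_cond in gt.true_psi.values():
            for v in by_cond.values():
                assert 0.0 <= v <= 1.0


class TestPeaks:
    def test_enrichment_half_is_binomial(self):
        cfg = SimConfig(n_genes=100, event_mix={"SE": 1.0}, dse_fraction=1.0,
                        peak_enrichment_fraction=0.5, background_peak_rate=0.0,
                        seed=13)
        ann = make_annotation(cfg)
        _, gt = simulate_quantifications(ann, cfg)
        assert len(gt.dse_events) == 100
        peaks = simulate_peaks(ann, gt, cfg)
        n = len(gt.peak_events)
        sigma = np.sqrt(100 * 0.5 * 0.5)
        assert abs(n - 50) <= 3 * sigma

    def test_summits_inside_their_peak(self):
        cfg = SimConfig(n_genes=50, event_mix={"SE": 1.0}, dse_fraction=0.5,
                        seed=2)
        ann = make_annotation(cfg)
        _, gt = simulate_quantifications(ann, cfg)
        for p in simulate_peaks(ann, gt, cfg):
            assert p.start <= p.summit < p.end

    def test_independent_realizations_differ(self):
        cfg = SimConfig(n_genes=50, event_mix={"SE": 1.0}, dse_fraction=0.5,
                        seed=2)
        ann = make_annotation(cfg)
        _, gt = simulate_quantifications(ann, cfg)
        p1 = simulate_peaks(ann, gt, cfg, seed_offset=0)
        p2 = simulate_peaks(ann, gt, cfg, seed_offset=1)
        assert p1.peaks != p2.peaks


class TestSequences:
    def test_same_seed_identical_genome(self):
        cfg = SimConfig(n_genes=10, seed=4)
        ann = make_annotation(cfg)
        _, gt = simulate_quantifications(ann, cfg)
        peaks = simulate_peaks(ann, gt, cfg)
        g1 = simulate_sequences(ann, peaks, cfg)
        g2 = simulate_sequences(ann, peaks, cfg)
        assert g1 == g2

    def test_contig_lengths_respected(self):
        cfg = SimConfig(n_genes=10, seed=4)
        ann = make_annotation(cfg)
        genome = simulate_sequences(ann, [], cfg)
        for contig, seq in genome.items():
            assert len(seq) == ann.contig_lengths[contig]
            assert set(seq) <= set("ACGT")


class TestCohort:
    def test_zero_betas_times_independent_of_psi(self):
        cfg = SimConfig(n_patients=2000, true_betas=(0.0, 0.0),
                        censor_rate=0.0, seed=6)
        cohort, _ = simulate_cohort(["e1", "e2"], cfg)
        rho, _ = stats.spearmanr(cohort.psi["e1"], cohort.time)
        assert abs(rho) < 0.06

    def test_zero_censoring_all_events_observed(self):
        cfg = SimConfig(n_patients=100, true_betas=(1.0,), censor_rate=0.0,
                        seed=6)
        cohort, _ = simulate_cohort(["e1"], cfg)
        assert (cohort.event == 1).all()

    def test_censor_rate_achieved(self):
        cfg = SimConfig(n_patients=4000, true_betas=(1.0, -1.0),
                        censor_rate=0.3, seed=6)
        cohort, _ = simulate_cohort(["e1", "e2"], cfg)
        assert abs((cohort.event == 0).mean() - 0.3) < 0.03

    def test_hazard_ratio_recovered_within_ci(self):
        cfg = SimConfig(n_patients=2000, true_betas=(1.0,), censor_rate=0.2,
                        seed=17)
        cohort, _ = simulate_cohort(["e1"], cfg)
        from m6asplice.survival import cox_lasso

        model = cox_lasso(cohort, penalty=0.0)
        assert abs(np.exp(model.betas.iloc[0]) / np.e - 1.0) < 0.15

    def test_same_seed_identical_cohort(self):
        cfg = SimConfig(n_patients=200, true_betas=(1.0,), seed=3)
        c1, _ = simulate_cohort(["e1"], cfg)
        c2, _ = simulate_cohort(["e1"], cfg)
        assert c1.psi.equals(c2.psi) and c1.time.equals(c2.time)

    def test_beta_length_mismatch_rejected(self):
        cfg = SimConfig(true_betas=(1.0, 2.0))
        with pytest.raises(ValueError, match="length"):
            simulate_cohort(["e1"], cfg)
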