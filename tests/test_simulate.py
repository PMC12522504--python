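import dataclasses

import numpy as np
import pandas as pd
import pytest

import tfekit as tk
from tfekit.simulate import GenomeCapacityError, generate_reference, simulate_counts


class TestGenerateReference:
    def test_deterministic_for_fixed_seed(self, small_config):
        a = generate_reference(small_config)
        b = generate_reference(small_config)
        assert a.sequences == b.sequences
        assert a.gene_table.equals(b.gene_table)
        assert a.spikeins.equals(b.spikeins)

    def test_no_coding_genes_degenerate_config(self, small_config):
        cfg = dataclasses.replace(small_config, n_coding_genes=0)
        ref = generate_reference(cfg)
        assert all(g.biotype == "noncoding" for g in ref.genes)

    def test_gene_structure_validator(self, small_bundle):
        """Every coding gene: CDS strictly inside the exon span with
        nonempty UTRs on both sides; every gene >= 2 exons; no overlap."""
        by_chrom: dict = {}
        for g in small_bundle.reference.genes:
            assert len(g.exons) >= 2
            if g.biotype == "coding":
                cs, ce = g.cds
                assert g.start < cs < ce < g.end  # nonempty UTR both sides
                assert g.exonic(cs) and g.exonic(ce - 1)
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2, "gene models overlap"

    def test_capacity_error_when_genome_too_small(self, small_config):
        cfg = dataclasses.replace(small_config, chromosome_length=10_000,
                                  n_chromosomes=1)
        with pytest.raises(GenomeCapacityError):
            generate_reference(cfg)

    def test_spikein_manifest_sums_to_input(self, small_bundle):
        sp = small_bundle.reference.spikeins
        assert sp["molecules_per_sample"].sum() == \
            small_bundle.config.spikein_molecules_per_sample
        assert all(n.startswith("spike_") for n in sp.index)


class TestSimulateCounts:
    def test_poisson_limit_without_overdispersion(self, small_config):
        """overdispersion=0 -> counts are Poisson: empirical CV^2 ~ 1/mu."""
        cfg = dataclasses.replace(
            small_config, overdispersion=0.0, samples_per_stage=200,
            stages=("GV",), stage_content_multiplier=(1.0,),
            maternal_decay=(1.0,), n_markers_per_stage=0,
        )
        ref = generate_reference(cfg)
        counts, truth = simulate_counts(ref, cfg)  # 75 genes x 200 draws
        x = counts.to_numpy(dtype=float)
        assert x.size > 10_000
        mu = truth.stage_means["GV"].to_numpy()
        big = mu > 50
        emp_cv2 = x.var(axis=1, ddof=1)[big] / x.mean(axis=1)[big] ** 2
        ratio = emp_cv2 * mu[big]  # Poisson: CV^2 = 1/mu, so ratio ~ 1
        assert abs(np.median(ratio) - 1.0) < 0.25

    def test_marker_zero_outside_its_stage(self, small_bundle):
        truth = small_bundle.truth
        markers = truth.genes[truth.genes["gene_class"] == "marker"]
        for gid, row in markers.iterrows():
            means = truth.stage_means.loc[gid]
            assert means[row["marker_stage"]] > 0
            assert (means.drop(row["marker_stage"]) == 0).all()

    def test_equal_multipliers_equalize_stage_totals(self, small_config):
        cfg = dataclasses.replace(
            small_config, stage_content_multiplier=(1.0,) * 7
        )
        ref = generate_reference(cfg)
        _, truth = simulate_counts(ref, cfg)
        totals = truth.stage_means.sum(axis=0)
        assert np.allclose(totals, totals.iloc[0])

    def test_maternal_decay_waves(self, study):
        """Maternal means decay monotonically after MII with the largest
        consecutive drops at the 2c and 16c stages."""
        truth = study["bundle"].truth
        maternal = truth.genes["gene_class"] == "maternal"
        m = truth.stage_means.loc[maternal].sum(axis=0)
        stages = list(m.index)
        pre_blc = m[stages[:-1]]
        assert (np.diff(pre_blc.to_numpy()) <= 1e-9).all()  # monotone to 16c
        drops = 1 - pre_blc.to_numpy()[1:] / pre_blc.to_numpy()[:-1]
        order = np.argsort(drops)[::-1]
        top2 = {stages[1:][i] for i in order[:2]}
        assert top2 == {"2c", "16c"}

    def test_unknown_stage_label_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, stages=("GV", "GV"))
        with pytest.raises(ValueError):
            cfg.validate()


class TestSimulateAlignments:
    def test_identity_regime_counts_events_exactly(self, small_config):
        """eta=1, no duplicates, no jitter: events per gene/sample equal the
        molecule counts."""
        cfg = dataclasses.replace(
            small_config, capture_efficiency=1.0, pcr_duplicate_rate=0.0,
            tss_jitter_sd=0.0,
        )
        ref = generate_reference(cfg)
        counts, truth = simulate_counts(ref, cfg)
        events = tk.simulate_alignments(counts, truth, cfg, ref)
        endo = events[~events["is_spikein"]]
        per = endo.groupby(["chrom", "pos", "strand", "sample"]).size()
        for gid, row in truth.genes.iterrows():
            expected = counts.loc[gid]
            for sid, n in expected.items():
                got = per.get((row["chrom"], row["tss"], row["strand"], sid), 0)
                assert got == n

    def test_dedup_recovers_preduplication_stream(self, small_config):
        cfg = dataclasses.replace(small_config, pcr_duplicate_rate=1.5)
        ref = generate_reference(cfg)
        counts, truth = simulate_counts(ref, cfg)
        events, predup = tk.simulate_alignments(counts, truth, cfg, ref,
                                                keep_predup=True)
        assert len(events) > len(predup)
        deduped = tk.dedup_events(events)
        assert len(deduped) == len(tk.dedup_events(predup))
        key = ["sample", "chrom", "strand", "pos", "umi"]
        lhs = deduped[key].reset_index(drop=True)
        rhs = tk.dedup_events(predup)[key].reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs)

    def test_minus_strand_gene_emits_at_rightmost_base(self, small_config):
        cfg = dataclasses.replace(small_config, tss_jitter_sd=0.0)
        ref = generate_reference(cfg)
        counts, truth = simulate_counts(ref, cfg)
        events = tk.simulate_alignments(counts, truth, cfg, ref)
        minus = truth.genes[truth.genes["strand"] == "-"]
        gid = minus.index[0]
        gene = next(g for g in ref.genes if g.gene_id == gid)
        sub = events[(events["chrom"] == gene.chrom) & (events["strand"] == "-")
                     & (events["pos"].sub(gene.tss).abs() < 50)]
        assert len(sub) > 0
        assert (sub["pos"] == gene.exons[-1][1] - 1).all()

    def test_expected_event_count_matches_rate_model(self, small_config):
        """E[events per gene.sample] = molecules * eta * (1 + dup rate),
        within 3 standard errors over >= 10,000 molecules."""
        cfg = dataclasses.replace(small_config, samples_per_stage=2)
        ref = generate_reference(cfg)
        counts, truth = simulate_counts(ref, cfg)
        events = tk.simulate_alignments(counts, truth, cfg, ref)
        n_mol = int(counts.to_numpy().sum())
        assert n_mol > 10_000
        eta, rate = cfg.capture_efficiency, cfg.pcr_duplicate_rate
        expected = n_mol * eta * (1 + rate)
        # var per molecule: Bernoulli(eta) thinning x (1 + Poisson) reads
        var = n_mol * (eta * (rate + (1 + rate) ** 2) - (eta * (1 + rate)) ** 2)
        observed = int((~events["is_spikein"]).sum())
        assert abs(observed - expected) < 3 * np.sqrt(var)

    def test_spikein_dedup_concentrates_capture_efficiency(self, small_bundle):
        """Per-sample spike-in UMI count / M -> eta (law of large numbers)."""
        cfg = small_bundle.config
        deduped = tk.dedup_events(small_bundle.events)
        sp = deduped[deduped["is_spikein"]]
        per_sample = sp.groupby("sample").size()
        eta_hat = per_sample / cfg.spikein_molecules_per_sample
        M, eta = cfg.spikein_molecules_per_sample, cfg.capture_efficiency
        se = np.sqrt(eta * (1 - eta) / M)
        assert (np.abs(eta_hat - eta) < 4 * se).all()

    def test_bundle_deterministic_for_seed(self, small_config):
        a = tk.simulate_study(small_config)
        b = tk.simulate_study(small_config)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.counts, b.counts)
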