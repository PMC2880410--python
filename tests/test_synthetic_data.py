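"""Generators: determinism, planted ground truth, correlation structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import promgram as pg
from promgram.coexpression import ExpressionMatrix, max_cc_all, preprocess
from promgram.pwm import ParameterError
from promgram.synthetic_data import write_fasta


class TestGenerateToyPWMs:
    def test_count_anchor_flag_and_normalization(self):
        pwms = pg.generate_toy_pwms(10, (5, 12), seed=1)
        assert len(pwms) == 10
        assert pwms[0].is_anchor and not any(p.is_anchor for p in pwms[1:])
        for p in pwms:
            assert 5 <= len(p) <= 12
            assert np.allclose(p.matrix.sum(axis=1), 1.0, atol=1e-9)
            assert 0 <= p.threshold <= 1

    def test_seed_determinism(self):
        a = pg.generate_toy_pwms(1, (5, 8), seed=7)
        b = pg.generate_toy_pwms(1, (5, 8), seed=7)
        assert np.array_equal(a[0].matrix, b[0].matrix)

    def test_invalid_length_range_raises(self):
        with pytest.raises(ParameterError):
            pg.generate_toy_pwms(2, (3, 5), seed=0)
        with pytest.raises(ParameterError):
            pg.generate_toy_pwms(2, (8, 5), seed=0)


class TestGenerateTrainingSet:
    def test_exact_counts_and_lengths(self, toy_pwms, strong_grammar):
        records, truth = pg.generate_training_set(strong_grammar, toy_pwms,
                                                  68, 68, seed=1)
        assert len(records) == 136
        assert sum(1 for _, lab, _ in records if lab == "histone") == 68
        assert all(len(seq) == 601 for _, _, seq in records)

    def test_no_dropout_plants_all_chain_motifs_in_order(self, toy_pwms,
                                                         strong_grammar):
        records, truth = pg.generate_training_set(strong_grammar, toy_pwms,
                                                  10, 0, seed=2)
        by_seq = {}
        for h in truth:
            by_seq.setdefault(h.seq_id, []).append(h)
        for seq_id, hits in by_seq.items():
            assert len(hits) == len(strong_grammar.motif_chain)
            # hits sorted by start: upstream-most is the last chain slot
            assert [h.motif_id for h in sorted(hits, key=lambda h: h.start)
                    ] == list(reversed(strong_grammar.motif_chain))

    def test_planted_hits_recovered_by_scan(self, toy_pwms, strong_grammar):
        """Consensus planting: every truth hit is found by the scanner."""
        records, truth = pg.generate_training_set(strong_grammar, toy_pwms,
                                                  6, 0, seed=3)
        seqs = {sid: seq for sid, _, seq in records}
        pwms = {p.motif_id: p for p in toy_pwms}
        for h in truth:
            hits = pg.scan_sequence(pwms[h.motif_id], seqs[h.seq_id],
                                    h.seq_id)
            assert any(x.start == h.start and x.strand == h.strand
                       for x in hits)

    def test_byte_identical_fasta_on_same_seed(self, toy_pwms,
                                               strong_grammar, tmp_path):
        paths = []
        for i in (1, 2):
            records, _ = pg.generate_training_set(strong_grammar, toy_pwms,
                                                  5, 5, seed=42)
            path = tmp_path / f"run{i}.fasta"
            write_fasta(((sid, seq) for sid, _, seq in records), path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_chain_too_long_raises(self, toy_pwms):
        grammar = pg.GrammarSpec(
            [p.motif_id for p in toy_pwms[:3]], [0.5] * 3,
            [{400: 1.0}, {400: 1.0}])
        with pytest.raises(ParameterError):
            pg.generate_training_set(grammar, toy_pwms, 1, 0, seq_len=601,
                                     seed=0)


class TestGrammarSpecValidation:
    def test_short_chain_rejected(self, toy_pwms):
        with pytest.raises(ParameterError):
            pg.GrammarSpec([toy_pwms[0].motif_id] * 2, [0.5] * 2,
                           [{10: 1.0}])

    def test_unnormalized_spacers_rejected(self, toy_pwms):
        ids = [p.motif_id for p in toy_pwms[:3]]
        with pytest.raises(ParameterError):
            pg.GrammarSpec(ids, [0.5] * 3, [{10: 0.5}, {10: 1.0}])


class TestGenerateToyGenome:
    def test_truth_records_count_and_strands(self, toy_pwms,
                                             strong_grammar):
        genome, truth, annots = pg.generate_toy_genome(
            strong_grammar, toy_pwms, n_chrom=3, chrom_len=50_000,
            n_planted=12, seed=5)
        assert len(genome) == 3
        assert len(truth) == 12
        assert all(t.end - t.start == 601 for t in truth)
        assert 0 < len(annots) < 12  # some segments stay intergenic

    def test_empty_plant_gives_empty_truth(self, toy_pwms, strong_grammar):
        genome, truth, annots = pg.generate_toy_genome(
            strong_grammar, toy_pwms, 2, 20_000, 0, seed=6)
        assert truth == [] and annots == []

    def test_minus_strand_segment_is_reverse_complemented(self, toy_pwms,
                                                          strong_grammar):
        """The planted plus-orientation window is recovered by exact
        string match after reverse-complementing the genomic interval."""
        genome, truth, _ = pg.generate_toy_genome(
            strong_grammar, toy_pwms, 1, 60_000, 10, seed=7,
            minus_fraction=1.0)
        anchor = toy_pwms[0]
        offset = 601 - 1 - strong_grammar.anchor_offset
        for t in truth:
            assert t.strand == "-"
            window = pg.reverse_complement(
                genome[t.chrom][t.start:t.end])
            assert window[offset:offset + len(anchor)] == anchor.consensus

    def test_overflow_raises(self, toy_pwms, strong_grammar):
        with pytest.raises(ParameterError):
            pg.generate_toy_genome(strong_grammar, toy_pwms, 1, 5000, 50,
                                   seed=8)

    def test_determinism(self, toy_pwms, strong_grammar):
        g1, t1, a1 = pg.generate_toy_genome(strong_grammar, toy_pwms, 2,
                                            20_000, 4, seed=9)
        g2, t2, a2 = pg.generate_toy_genome(strong_grammar, toy_pwms, 2,
                                            20_000, 4, seed=9)
        assert g1 == g2 and t1 == t2 and a1 == a2

    def test_annotation_tss_sits_at_window_equivalent(self, toy_pwms,
                                                      strong_grammar):
        _, truth, annots = pg.generate_toy_genome(
            strong_grammar, toy_pwms, 2, 50_000, 10, seed=10,
            intergenic_fraction=0.0)
        by_name = {t.name: t for t in truth}
        for a in annots:
            t = by_name[f"prom{a.gene_id[-3:]}"]
            if a.strand == "+":
                assert a.tss == t.start + 500
            else:
                assert a.tss == t.start + 100


class TestGenerateExpression:
    def test_shape_and_groups(self):
        spec = pg.ExpressionSpec(n_predicted_probes=200,
                                 n_background_probes=2000)
        values, groups, rep_map = pg.generate_expression(spec, seed=1)
        assert values.shape == (2293, 158)
        assert groups.value_counts().to_dict() == {
            "background": 2000, "predicted": 200, "histone": 93}
        assert len(rep_map) == 158
        assert len(set(rep_map.values())) == 79

    def test_determinism(self):
        spec = pg.ExpressionSpec(n_tissues=5, n_histone_probes=4,
                                 n_predicted_probes=3,
                                 n_background_probes=5)
        v1, _, _ = pg.generate_expression(spec, seed=3)
        v2, _, _ = pg.generate_expression(spec, seed=3)
        assert v1.equals(v2)

    def test_histone_block_correlation_calibrated(self):
        """Realized mean within-block CC (replicate-averaged log2 scale)
        lands within +/-0.05 of rho_histone at the default 79 tissues."""
        spec = pg.ExpressionSpec()
        values, groups, rep_map = pg.generate_expression(spec, seed=21)
        hist = groups.index[groups == "histone"]
        cols: dict[str, list[str]] = {}
        for a, t in rep_map.items():
            cols.setdefault(t, []).append(a)
        mono = pd.DataFrame({t: values[arrs].mean(axis=1)
                             for t, arrs in cols.items()})
        cc = np.corrcoef(np.log2(mono.loc[hist].clip(lower=1.0)))
        mean_cc = cc[np.triu_indices_from(cc, 1)].mean()
        assert abs(mean_cc - spec.rho_histone) < 0.05

    def test_noiseless_perfect_block_correlation(self):
        spec = pg.ExpressionSpec(n_tissues=10, n_histone_probes=5,
                                 n_predicted_probes=3,
                                 n_background_probes=20,
                                 rho_histone=1.0, noise_sd=0.0)
        values, groups, rep_map = pg.generate_expression(spec, seed=4)
        expr = preprocess(ExpressionMatrix(values, rep_map))
        hist = list(groups.index[groups == "histone"])
        cc = np.corrcoef(expr.values.loc[hist].to_numpy())
        assert np.allclose(cc, 1.0, atol=1e-12)

    def test_zero_rho_predicted_indistinguishable_from_background(self):
        """With rho_predicted = 0 the predicted block's maxCC matches the
        background's (pooled two-sample t over seeds, p > 0.01)."""
        pred_means, bg_means = [], []
        for seed in range(20):
            spec = pg.ExpressionSpec(n_tissues=20, n_histone_probes=10,
                                     n_predicted_probes=30,
                                     n_background_probes=30,
                                     rho_predicted=0.0)
            values, groups, rep_map = pg.generate_expression(spec,
                                                             seed=seed)
            expr = preprocess(ExpressionMatrix(values, rep_map))
            hist = list(groups.index[groups == "histone"])
            pred = list(groups.index[groups == "predicted"])
            bg = list(groups.index[groups == "background"])
            pred_means.append(max_cc_all(expr, pred, hist).mean())
            bg_means.append(max_cc_all(expr, bg, hist).mean())
        t, p = stats.ttest_ind(pred_means, bg_means)
        assert p > 0.01

    def test_impossible_correlation_raises(self):
        with pytest.raises(ParameterError):
            pg.ExpressionSpec(rho_histone=-0.2)
        with pytest.raises(ParameterError):
            pg.ExpressionSpec(rho_predicted=1.5)


class TestRotatingGrammarSet:
    def test_counts_labels_and_determinism(self, toy_pwms):
        r1 = pg.generate_rotating_grammar_set(toy_pwms, 10, 10, seed=30)
        r2 = pg.generate_rotating_grammar_set(toy_pwms, 10, 10, seed=30)
        assert r1 == r2
        assert sum(1 for _, lab, _ in r1 if lab == "histone") == 10
        assert all(len(seq) == 601 for _, _, seq in r1)
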