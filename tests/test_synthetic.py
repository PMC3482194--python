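"""Generator invariants: determinism, truth consistency, distributional
recovery of the condition parameters, and truth-PSL emission."""
import numpy as np
import pytest

from polyterm.alignment import parse_psl_lines
from polyterm.model import ConditionParams, ModelError, truth_sequence
from polyterm.simulate import (
    GenomeConfig,
    SizingError,
    build_toy_genome,
    emit_truth_psl,
    simulate_expression,
    ExpressionSimConfig,
    simulate_reads,
)

from conftest import clean_params


class TestBuildToyGenome:
    def test_seeded_determinism(self):
        a = build_toy_genome(GenomeConfig(seed=9))
        b = build_toy_genome(GenomeConfig(seed=9))
        assert a.sequences == b.sequences
        assert a.genes == b.genes
        assert a.repeats == b.repeats
        assert a.duplicated_segments == b.duplicated_segments

    def test_impossible_placement_raises_sizing_error(self):
        with pytest.raises(SizingError):
            build_toy_genome(GenomeConfig(chrom_length=52_000, seed=0))

    def test_short_chromosome_rejected(self):
        with pytest.raises(SizingError):
            build_toy_genome(GenomeConfig(chrom_length=4000, seed=0))

    def test_duplicated_copies_identical(self, bundle):
        for src, cpy in bundle.duplicated_segments:
            assert bundle.fetch(*src) == bundle.fetch(*cpy)

    def test_feature_inventory(self, bundle):
        classes = {}
        for rep in bundle.repeats:
            classes.setdefault(rep.repeat_class, []).append(rep)
        assert any(r.element_length >= 6000 for r in classes["LINE1"])
        assert any(r.element_length < 6000 for r in classes["LINE1"])
        assert classes["SINE"] and classes["LTR"]
        assert any(g.n_exons > 1 for g in bundle.genes)
        assert any(g.n_exons == 1 for g in bundle.genes)
        assert any(not g.is_apa for g in bundle.genes)
        for g in bundle.genes:
            if g.is_apa:
                a, b = g.autr_interval()
                assert b > a  # nonempty aUTR


class TestSimulateReads:
    def test_seeded_determinism(self, bundle):
        params = ConditionParams(n_reads=300, seed=5)
        r1, t1 = simulate_reads(bundle, params)
        r2, t2 = simulate_reads(bundle, params)
        assert r1 == r2
        assert t1 == t2
        assert emit_truth_psl(r1, t1, bundle) == emit_truth_psl(r2, t2, bundle)

    def test_degenerate_parameters_suppress_sources(self, bundle):
        params = clean_params(500, seed=6, distal_frac=0.0)
        _reads, truths = simulate_reads(bundle, params)
        assert not any(t.readthrough_flag for t in truths)
        assert not any(t.source_kind == "repeat" for t in truths)
        assert not any(t.isoform == "distal" for t in truths)

    def test_full_readthrough_flags_reads_past_pas(self, bundle):
        params = clean_params(2000, seed=7, readthrough_prob=1.0)
        _reads, truths = simulate_reads(bundle, params)
        for t in truths:
            if t.source_kind != "gene":
                continue
            gene = next(g for g in bundle.genes if g.gene_id == t.source_id)
            site = (gene.pas_distal if t.isoform == "distal"
                    else gene.pas_proximal)
            crosses = (t.end > site if gene.strand == "+"
                       else t.start < site)
            assert t.readthrough_flag == crosses

    def test_truth_reproduces_read_sequences(self, bundle):
        params = ConditionParams(n_reads=400, seed=8)
        reads, truths = simulate_reads(bundle, params)
        for (rid, seq), truth in zip(reads, truths):
            assert truth.read_id == rid
            if truth.has_placement:
                assert truth_sequence(bundle, truth) == seq

    def test_read_lengths_in_bounds(self, bundle):
        params = ConditionParams(n_reads=500, seed=9)
        reads, _ = simulate_reads(bundle, params)
        for _rid, seq in reads:
            assert len(seq) <= 1000

    def test_distributional_recovery_at_50k(self, bundle):
        """Distal, repeat and read-through fractions converge to the dials."""
        f, lam, rho = 0.3, 0.05, 0.4
        params = ConditionParams(n_reads=50_000, seed=10, distal_frac=f,
                                 line1_rate=lam, readthrough_prob=rho)
        _reads, truths = simulate_reads(bundle, params)
        apa_ids = {g.gene_id for g in bundle.genes if g.is_apa}
        gene_iso = [t.isoform for t in truths
                    if t.source_kind == "gene" and t.source_id in apa_ids]
        distal = sum(i == "distal" for i in gene_iso) / len(gene_iso)
        assert abs(distal - f) <= 3 * np.sqrt(f * (1 - f) / len(gene_iso))
        line1 = np.mean([
            t.source_kind == "repeat" and t.source_id.startswith("LINE1")
            for t in truths
        ])
        assert abs(line1 - lam) <= 3 * np.sqrt(lam * (1 - lam) / len(truths))
        # read-through flags: expected rate is rho times the conditional
        # span probability, estimated from a rho=1 run with the same seed
        full = ConditionParams(n_reads=50_000, seed=10, distal_frac=f,
                               line1_rate=lam, readthrough_prob=1.0)
        _r2, truths_full = simulate_reads(bundle, full)
        span = np.mean([t.readthrough_flag for t in truths_full
                        if t.source_kind == "gene"])
        flags = [t.readthrough_flag for t in truths
                 if t.source_kind == "gene"]
        expected = rho * span
        assert abs(np.mean(flags) - expected) <= 3 * np.sqrt(
            expected * (1 - expected) / len(flags)
        )


class TestEmitTruthPsl:
    def test_unique_and_duplicated_placements(self, bundle):
        params = ConditionParams(n_reads=600, seed=11, intergenic_rate=0.3)
        reads, truths = simulate_reads(bundle, params)
        lines = emit_truth_psl(reads, truths, bundle)
        by_read = {}
        for line in lines:
            by_read.setdefault(line.split("\t")[9], []).append(line)
        dups = [iv for pair in bundle.duplicated_segments for iv in pair]
        seen_double = 0
        for truth in truths:
            if not truth.has_placement:
                assert truth.read_id not in by_read
                continue
            in_dup = any(
                truth.chrom == c and truth.start >= s and truth.end <= e
                for c, s, e in dups
            )
            n_lines = len(by_read[truth.read_id])
            if in_dup:
                assert n_lines == 2
                m1, m2 = (int(l.split("\t")[0])
                          for l in by_read[truth.read_id])
                assert m1 == m2  # exact duplication, equal match counts
                seen_double += 1
            else:
                assert n_lines == 1
        assert seen_double > 0

    def test_round_trip_through_parser(self, bundle):
        params = ConditionParams(n_reads=200, seed=12)
        reads, truths = simulate_reads(bundle, params)
        lines = emit_truth_psl(reads, truths, bundle)
        hits = parse_psl_lines(lines)
        assert len(hits) == len(lines)
        by_id = dict(reads)
        for hit in hits:
            qsize = sum(e - s for s, e in hit.blocks)
            assert qsize == len(by_id[hit.read_id])
            assert hit.matches + hit.mismatches == qsize

    def test_truth_outside_genome_rejected(self, bundle):
        from polyterm.model import SimulationTruth

        chrom = next(iter(bundle.sequences))
        L = len(bundle.sequences[chrom])
        bad = SimulationTruth("rX", "intergenic", "x", "none", False,
                              chrom, L - 10, L + 100, "+",
                              ((L - 10, L + 100),))
        with pytest.raises(ModelError):
            emit_truth_psl([("rX", "A" * 110)], [bad], bundle)


class TestSimulateExpression:
    def test_determinism_and_shape(self):
        cfg = ExpressionSimConfig(seed=3)
        a = simulate_expression(cfg)
        b = simulate_expression(cfg)
        for x, y in zip(a, b):
            assert x.equals(y)
        gene_info, expr_a, expr_b = a
        assert len(gene_info) == len(expr_a) == len(expr_b)
        assert (expr_a["value"] > 0).all()

    def test_null_factor_leaves_groups_exchangeable(self):
        cfg = ExpressionSimConfig(seed=4, isg_down_factor=1.0)
        gene_info, expr_a, expr_b = simulate_expression(cfg)
        change = np.log2((expr_b["value"] + 1) / (expr_a["value"] + 1))
        single_short = (gene_info["n_exons"] == 1) & (gene_info["length"] <= 6500)
        # no systematic shift when the down-regulation factor is off
        assert abs(change[single_short].mean() - change[~single_short].mean()) < 0.15
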