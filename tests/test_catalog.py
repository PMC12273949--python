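"""Unit and property tests for mutation filtering, spectra, and rates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabias.catalog import (
    InputFormatError,
    MutationRecord,
    VariantFilterConfig,
    apply_filters,
    classify_bps,
    compute_bias,
    gene_gc_table,
    mutation_rate,
    poisson_gof,
    recall_check,
    records_to_table,
    spectrum_biases,
    tally_spectrum,
)
from conftest import make_variant_row


class TestApplyFilters:
    def test_strand_support_threshold(self):
        table = pd.DataFrame([make_variant_row(1, reads_plus=3, reads_minus=10, freq=0.95)])
        assert apply_filters(table, None) == []

    def test_frequency_boundary_is_strict(self):
        table = pd.DataFrame(
            [make_variant_row(1, freq=0.80), make_variant_row(2, freq=0.801)]
        )
        records = apply_filters(table, None)
        assert [r.position for r in records] == [2]

    def test_ancestor_subtraction(self, toy_variants):
        ancestor = pd.DataFrame(
            [make_variant_row(100, freq=0.30), make_variant_row(300, ref="G", alt="T", freq=0.95)]
        )
        records = apply_filters(toy_variants, ancestor)
        # 5 variants pass the filters; 2 match the ancestor (at any ancestor
        # frequency) and are removed
        assert sorted(r.position for r in records) == [200, 400, 500]

    def test_idempotent_and_order_independent(self, toy_variants):
        once = apply_filters(toy_variants, None)
        again = apply_filters(records_to_table(once), None)
        assert [r.position for r in once] == [r.position for r in again]
        shuffled = toy_variants.sample(frac=1.0, random_state=0)
        assert sorted(r.position for r in apply_filters(shuffled, None)) == sorted(
            r.position for r in once
        )

    def test_missing_strand_columns_rejected(self):
        table = pd.DataFrame([{"position": 1, "ref": "A", "alt": "G", "freq": 0.9}])
        with pytest.raises(InputFormatError):
            apply_filters(table, None)

    def test_negative_read_counts_rejected(self):
        table = pd.DataFrame([make_variant_row(1, reads_plus=-1)])
        with pytest.raises(ValueError):
            apply_filters(table, None)


class TestClassifyBps:
    @pytest.mark.parametrize(
        "ref,alt,ts_tv,gc",
        [
            ("A", "G", "transition", "AT_to_GC"),
            ("G", "A", "transition", "GC_to_AT"),
            ("C", "T", "transition", "GC_to_AT"),
            ("T", "C", "transition", "AT_to_GC"),
            ("G", "T", "transversion", "GC_to_AT"),
            ("C", "A", "transversion", "GC_to_AT"),
            ("A", "C", "transversion", "AT_to_GC"),
            ("A", "T", "transversion", "no_change"),
            ("G", "C", "transversion", "no_change"),
        ],
    )
    def test_substitution_classes(self, ref, alt, ts_tv, gc):
        assert classify_bps(ref, alt) == (ts_tv, gc)

    def test_strand_symmetry(self):
        # a call and its reverse complement fold onto the same class
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for ref, alt in [("G", "A"), ("A", "C"), ("G", "T")]:
            assert classify_bps(ref, alt) == classify_bps(comp[ref], comp[alt])

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            classify_bps("N", "A")


class TestComputeBias:
    def test_wt_transversion_bias_and_ci(self):
        b = compute_bias(178, 206, 97)
        assert round(b.value, 2) == 0.46
        assert round(b.ci_half_width, 3) == 0.099

    def test_zero_numerator(self):
        b = compute_bias(0, 10, 5)
        assert b.value == 0.0 and b.ci_half_width == 0.0

    def test_undefined_when_no_mutations(self):
        assert not compute_bias(0, 0, 5).defined

    def test_zero_lines_rejected(self):
        with pytest.raises(ValueError):
            compute_bias(1, 1, 0)

    @given(
        a=st.integers(0, 1000), b=st.integers(0, 1000), n=st.integers(1, 500)
    )
    @settings(max_examples=50, deadline=None)
    def test_complementary_biases_sum_to_one(self, a, b, n):
        if a + b == 0:
            return
        assert compute_bias(a, b, n).value + compute_bias(b, a, n).value == pytest.approx(1.0)


class TestMutationRate:
    def test_rate_from_strain_totals(self):
        mu, ci = mutation_rate(789, 4.6e6, [271 * 27])
        assert f"{mu:.1e}" == "2.3e-08"
        assert ci is None  # unavailable without per-line counts

    def test_zero_mutations(self):
        mu, _ = mutation_rate(0, 4.6e6, [100.0])
        assert mu == 0.0

    def test_t_interval_from_per_line_counts(self, rng):
        gens = [27.0] * 50
        counts = rng.poisson(2.0, 50)
        mu, ci = mutation_rate(int(counts.sum()), 4.6e6, gens, per_line_counts=counts)
        assert ci is not None and ci > 0
        # t-interval should bracket the point estimate's scale
        assert ci < mu

    def test_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(5, 4.6e6, [0.0])


def _record(position, ref, alt, cls="BPS", region="noncoding", effect="not_applicable"):
    return MutationRecord(
        strain_id="S", block_id="B1", line_id="L1", position=position,
        ref_allele=ref, alt_allele=alt, mutation_class=cls,
        allele_frequency=0.95, reads_plus=10, reads_minus=10,
        region=region, coding_effect=effect,
    )


class TestTallySpectrum:
    def test_partition_invariants(self):
        muts = [
            _record(1, "A", "G", region="coding", effect="synonymous"),
            _record(2, "G", "A", region="coding", effect="nonsynonymous"),
            _record(3, "A", "T"),
            _record(4, "G", "C", region="coding", effect="nonsynonymous"),
            _record(5, "A", "AT", cls="insertion"),
        ]
        s = tally_spectrum(muts, n_lines=3, total_generations=81.0, genome_size=4.6e6)
        c = s.counts
        assert c["transitions"] + c["transversions"] == c["BPS"] == 4
        assert c["coding"] + c["noncoding"] == c["BPS"]
        assert c["synonymous"] + c["nonsynonymous"] == c["coding"]
        assert c["AT_to_GC"] + c["GC_to_AT"] + c["gc_neutral"] == c["BPS"]
        assert c["indels"] == 1
        assert s.mu == pytest.approx(5 / (4.6e6 * 81.0))

    def test_empty_list(self):
        s = tally_spectrum([], n_lines=3, total_generations=81.0, genome_size=4.6e6)
        assert all(v == 0 for v in s.counts.values())
        assert s.mu == 0.0

    def test_mixed_strains_rejected(self):
        a = _record(1, "A", "G")
        b = MutationRecord(
            strain_id="other", block_id="B1", line_id="L1", position=2,
            ref_allele="A", alt_allele="G", mutation_class="BPS",
            allele_frequency=0.95, reads_plus=10, reads_minus=10,
            region="noncoding", coding_effect="not_applicable",
        )
        with pytest.raises(ValueError):
            tally_spectrum([a, b], 2, 54.0, 4.6e6)

    def test_biases_from_summary(self):
        muts = [_record(i, "A", "C") for i in range(1, 8)] + [_record(10, "A", "G")]
        s = tally_spectrum(muts, n_lines=4, total_generations=27.0, genome_size=4.6e6)
        biases = spectrum_biases(s)
        assert biases["transversion"].value == pytest.approx(7 / 8)


class TestPoissonGOF:
    def test_expected_sums_to_n_lines(self, rng):
        counts = rng.poisson(2.0, 300)
        res = poisson_gof(counts)
        assert res.observed.sum() == 300
        assert res.expected.sum() == pytest.approx(300, abs=1e-6)
        assert res.dof == len(res.expected) - 2

    def test_underdispersion_detected(self):
        res = poisson_gof([8] * 200)
        assert res.p_value < 1e-6

    def test_per_block_analysis(self, rng):
        # blocks with different generation counts have different means and are
        # tested separately; each block alone should fit its own Poisson
        block1 = rng.poisson(1.0, 200)
        block2 = rng.poisson(8.0, 200)
        p1 = poisson_gof(block1).p_value
        p2 = poisson_gof(block2).p_value
        pooled = poisson_gof(np.concatenate([block1, block2])).p_value
        assert p1 > 0.01 and p2 > 0.01
        assert pooled < min(p1, p2)  # the mixture is overdispersed

    def test_degenerate_all_zero(self):
        with pytest.raises(ValueError):
            poisson_gof([0, 0, 0])


class TestRecallCheck:
    def test_planted_recall_fraction(self):
        expected = [(2845011, "G", "A")]
        lists = {}
        for i in range(10):
            if i < 9:
                lists[f"L{i}"] = pd.DataFrame([make_variant_row(2845011, ref="G", alt="A", freq=1.0)])
            else:
                lists[f"L{i}"] = pd.DataFrame([make_variant_row(999, ref="A", alt="C")])
        table, summary = recall_check(lists, expected)
        assert len(table) == 10
        assert summary["recall"].iloc[0] == pytest.approx(0.9)

    def test_absent_everywhere(self):
        lists = {"L1": pd.DataFrame([make_variant_row(5)])}
        _, summary = recall_check(lists, [(123, "G", "A")])
        assert summary["recall"].iloc[0] == 0.0


class TestGeneGC:
    def test_planted_gc_fractions_recovered(self, tmp_path):
        genes = {"g1": "GGCC", "g2": "ATAT", "g3": "GATC", "g4": "GGGA"}
        genome = "".join(genes.values())
        fasta = tmp_path / "genome.fa"
        fasta.write_text(f">chr1\n{genome}\n")
        gff = tmp_path / "genes.gff3"
        lines = ["##gff-version 3"]
        start = 1
        for gid, seq in genes.items():
            end = start + len(seq) - 1
            lines.append(f"chr1\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
            start = end + 1
        gff.write_text("\n".join(lines) + "\n")

        table = gene_gc_table(str(fasta), str(gff)).set_index("gene_id")
        assert table.loc["g1", "gc_fraction"] == 1.0
        assert table.loc["g2", "gc_fraction"] == 0.0
        assert table.loc["g3", "gc_fraction"] == 0.5
        assert table.loc["g1", "gc_class"] == "high"
        assert table.loc["g2", "gc_class"] == "low"

    def test_out_of_bounds_gene_rejected(self, tmp_path):
        (tmp_path / "g.fa").write_text(">c\nACGT\n")
        (tmp_path / "a.gff3").write_text("c\tx\tgene\t1\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError):
            gene_gc_table(str(tmp_path / "g.fa"), str(tmp_path / "a.gff3"))
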