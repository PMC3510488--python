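"""Dinucleotide profiles, cleavage consensus, end and positional filters."""

import numpy as np
import pandas as pd
import pytest

from nucphase import (
    FragmentSet,
    Gene,
    GenomeSeq,
    dinuc_profile,
    end_consensus,
    expected_ww_spacing,
    extract_aligned,
    filter_end_subset,
    group_by_induction,
    iid_dimer_probability,
    select_positional_nucleosomes,
)

from conftest import make_fragments


def repeat_genome(unit: str, length: int, name="c") -> GenomeSeq:
    reps = unit * (length // len(unit) + 1)
    return GenomeSeq({name: reps[:length]})


class TestExtractAligned:
    def test_core_plus_extension_width(self, iid_genome):
        fs = make_fragments([("chrI", 1000, 1147)])
        m = extract_aligned(fs, iid_genome, extension=20)
        assert m.width == 187
        assert m.n_sequences == 1
        seq = m.sequences()[0]
        assert seq == iid_genome.fetch("chrI", 1000 - 20, 1147 + 20)

    def test_minus_strand_reverse_complemented(self, iid_genome):
        fs = FragmentSet(
            pd.DataFrame(
                [("chrI", 1000, 1147, "-")],
                columns=["chrom", "start", "end", "strand"],
            )
        )
        m = extract_aligned(fs, iid_genome, extension=0)
        expected = GenomeSeq.revcomp(iid_genome.fetch("chrI", 1000, 1147))
        assert m.sequences()[0] == expected

    def test_orient_by_gene_body(self, iid_genome):
        fs = make_fragments([("chrI", 1000, 1147)])
        gene = Gene("YA", "chrI", 900, 1400, "-")
        m = extract_aligned(fs, iid_genome, extension=0, orient_by=[gene])
        expected = GenomeSeq.revcomp(iid_genome.fetch("chrI", 1000, 1147))
        assert m.sequences()[0] == expected

    def test_variable_core_lengths_share_dyad_column(self):
        # a single G marks the dyad of both a 147- and a 149-bp fragment
        seq = list("A" * 400)
        seq[200] = "G"
        genome = GenomeSeq({"c": "".join(seq)})
        fs = make_fragments([(("c"), 200 - 73, 200 - 73 + 147),
                             ("c", 200 - 74, 200 - 74 + 149)])
        m = extract_aligned(fs, genome, extension=10)
        col = m.dyad_column
        assert all(row[col] == ord("G") for row in m.matrix)

    def test_out_of_bounds_frames_dropped(self, iid_genome):
        fs = make_fragments([("chrI", 0, 147), ("chrI", 1000, 1147)])
        with pytest.warns(UserWarning, match="dropped"):
            m = extract_aligned(fs, iid_genome, extension=20)
        assert m.n_sequences == 1


class TestDinucProfile:
    def test_poly_a_is_all_ww(self):
        genome = repeat_genome("A", 1000)
        fs = make_fragments([("c", 100, 247)] * 3)
        prof = dinuc_profile(extract_aligned(fs, genome, 20), smoothing_window=3)
        np.testing.assert_allclose(prof.raw_freq["WW"], 1.0)
        np.testing.assert_allclose(prof.raw_freq["SS"], 0.0)

    def test_dimer_classes_partition_unity(self, iid_genome, rng):
        starts = rng.integers(100, 40_000, size=50)
        fs = make_fragments([("chrI", int(s), int(s) + 147) for s in starts])
        prof = dinuc_profile(extract_aligned(fs, iid_genome, 20), 3)
        total = sum(prof.raw_freq[c] for c in ("WW", "SS", "WS", "SW"))
        np.testing.assert_allclose(total, 1.0)

    def test_symmetrization_idempotent_and_mirror_symmetric(self, iid_genome, rng):
        starts = rng.integers(100, 40_000, size=40)
        fs = make_fragments([("chrI", int(s), int(s) + 147) for s in starts])
        m = extract_aligned(fs, iid_genome, 20)
        sym = dinuc_profile(m, smoothing_window=1, symmetrize=True)
        for cls in ("WW", "SS"):
            f = sym.raw_freq[cls]
            np.testing.assert_allclose(f, f[::-1])  # mirror symmetry, exact
        # symmetrizing a symmetric profile changes nothing
        resym = {
            "WW": (sym.raw_freq["WW"] + sym.raw_freq["WW"][::-1]) / 2,
            "WS": (sym.raw_freq["WS"] + sym.raw_freq["SW"][::-1]) / 2,
        }
        np.testing.assert_allclose(resym["WW"], sym.raw_freq["WW"])
        np.testing.assert_allclose(resym["WS"], sym.raw_freq["WS"])

    def test_reverse_complement_invariance(self, iid_genome, rng):
        starts = rng.integers(100, 40_000, size=40)
        plus = FragmentSet(
            pd.DataFrame(
                [("chrI", int(s), int(s) + 147, "+") for s in starts],
                columns=["chrom", "start", "end", "strand"],
            )
        )
        minus = FragmentSet(plus.df.assign(strand="-"))
        p = dinuc_profile(extract_aligned(plus, iid_genome, 20), 1)
        m = dinuc_profile(extract_aligned(minus, iid_genome, 20), 1)
        # WW and SS are self-complementary classes: profiles mirror
        np.testing.assert_allclose(p.raw_freq["WW"], m.raw_freq["WW"][::-1])
        np.testing.assert_allclose(p.raw_freq["SS"], m.raw_freq["SS"][::-1])
        # WS and SW swap under reverse complement
        np.testing.assert_allclose(p.raw_freq["WS"], m.raw_freq["SW"][::-1])

    def test_all_n_rejected(self):
        genome = repeat_genome("N", 500)
        fs = make_fragments([("c", 100, 247)])
        with pytest.raises(ValueError, match="N"):
            dinuc_profile(extract_aligned(fs, genome, 0), 3)


class TestEndConsensus:
    def test_engineered_wwt_tg_consensus(self):
        # every cut context reads ...A A T | T G... at both ends:
        # "AATTG" spans the 5' cut (fragment starts on its second T) and
        # "CAATT" spans the 3' cut read on the minus strand
        unit = "AATTG" + "C" * 146 + "CAATT" + "C" * 4  # period 160
        genome = repeat_genome(unit, 12_000)
        starts = [160 * k + 3 for k in range(5, 50)]  # position 0 is the 2nd A
        fs = make_fragments([("c", s, s + 150) for s in starts])
        cons = end_consensus(fs, genome, flank=5)
        assert cons.ww_cut_fraction == 1.0
        assert "AAT|TG" in cons.consensus(base_threshold=0.6)
        freqs = cons.base_freqs
        # W (A or T) at the four positions around the cut, G just inside
        for p in (-2, -1, 0, 1):
            assert freqs.loc[p, "A"] + freqs.loc[p, "T"] == 1.0
        assert freqs.loc[0, "T"] == 1.0 and freqs.loc[1, "T"] == 1.0
        assert freqs.loc[2, "G"] == 1.0

    def test_single_fragment_indicator_frequencies(self, iid_genome):
        fs = make_fragments([("chrI", 5000, 5147)])
        cons = end_consensus(fs, iid_genome, flank=3)
        values = cons.base_freqs.to_numpy()
        assert set(np.unique(values)) <= {0.0, 0.5, 1.0}  # two ends pooled
        np.testing.assert_allclose(values.sum(axis=1), 1.0)

    def test_uniform_cuts_on_iid_genome_match_at_squared(self, iid_genome, rng):
        starts = rng.integers(100, 49_000, size=4000)
        fs = make_fragments([("chrI", int(s), int(s) + 147) for s in starts])
        cons = end_consensus(fs, iid_genome, flank=2)
        # binomial check: 8000 ends, p = 0.36
        se = np.sqrt(0.36 * 0.64 / cons.n_ends)
        assert abs(cons.ww_cut_fraction - 0.36) < 4 * se

    def test_flank_too_small_rejected(self, iid_genome):
        fs = make_fragments([("chrI", 5000, 5147)])
        with pytest.raises(ValueError):
            end_consensus(fs, iid_genome, flank=1)


class TestEndSubset:
    def test_sc_context_kept_ww_context_removed(self):
        # genome alternating GC everywhere except a planted AA at one start
        seq = list("GC" * 500)
        seq[200] = "A"
        seq[201] = "A"
        genome = GenomeSeq({"c": "".join(seq)})
        kept = make_fragments([("c", 100, 247)])
        removed = make_fragments([("c", 201, 348)])  # cut dimer A|A
        assert len(filter_end_subset(kept, genome)) == 1
        assert len(filter_end_subset(removed, genome)) == 0

    def test_strict_rule_rejects_single_w(self):
        # A at position 0 of the 5' end, S everywhere else: kept under the
        # default dimer rule, removed under the strict no-W rule
        seq = list("GC" * 500)
        seq[199] = "A"  # position 0 for a fragment starting at 200
        genome = GenomeSeq({"c": "".join(seq)})
        fs = make_fragments([("c", 200, 347)])
        assert len(filter_end_subset(fs, genome, rule="no-ww")) == 1
        assert len(filter_end_subset(fs, genome, rule="no-w")) == 0

    def test_edge_fragment_excluded(self):
        genome = repeat_genome("GC", 400)
        fs = make_fragments([("c", 0, 147)])
        assert len(filter_end_subset(fs, genome)) == 0


class TestPositionalSelection:
    genes = [
        Gene("PLUS", "c", 1000, 2500, "+"),
        Gene("MINUS", "c", 4000, 5501, "-"),  # tss = 5500
    ]

    @staticmethod
    def frag_with_dyad(chrom, dyad, length=147):
        start = dyad - length // 2
        return (chrom, start, start + length)

    def test_plus_one_window_boundaries_plus_strand(self):
        sel = lambda d: select_positional_nucleosomes(
            make_fragments([self.frag_with_dyad("c", d)]), self.genes, "+1"
        )
        assert len(sel(1000)) == 1  # dyad on the TSS: coordinate +1
        assert len(sel(1069)) == 1  # +70
        assert len(sel(1139)) == 1  # +140
        assert len(sel(1140)) == 0  # +141: belongs to +2
        assert len(sel(999)) == 0  # upstream: coordinate -1

    def test_plus_one_minus_strand_and_orientation(self):
        fs = make_fragments([self.frag_with_dyad("c", 5500 - 69)])  # +70
        out = select_positional_nucleosomes(fs, self.genes, "+1")
        assert len(out) == 1
        assert next(iter(out)).strand == "-"

    def test_minus_one_and_plus_two_windows(self):
        # -1 default window [-180, -41]; +2 default [141, 300]
        minus1 = make_fragments([self.frag_with_dyad("c", 1000 - 100)])
        plus2 = make_fragments([self.frag_with_dyad("c", 1000 + 200)])
        assert len(select_positional_nucleosomes(minus1, self.genes, "-1")) == 1
        assert len(select_positional_nucleosomes(plus2, self.genes, "+2")) == 1
        assert len(select_positional_nucleosomes(minus1, self.genes, "+2")) == 0

    def test_window_override(self):
        fs = make_fragments([self.frag_with_dyad("c", 1400)])
        out = select_positional_nucleosomes(
            fs, self.genes, "+1", window_override=(380, 420)
        )
        assert len(out) == 1

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            select_positional_nucleosomes(
                make_fragments([("c", 0, 147)]), [], "+1"
            )


class TestInductionGroups:
    @staticmethod
    def gene(i, fold):
        return Gene(f"Y{i:03d}", "c", 100 * i, 100 * i + 90, "+", fold)

    def test_fraction_rounds_up(self):
        genes = [self.gene(i, float(i + 1)) for i in range(10)]
        top, bottom = group_by_induction(genes, 0.2, 0.2)
        assert len(top) == 2 and len(bottom) == 2
        assert {g.gene_id for g in top} == {"Y009", "Y008"}
        assert {g.gene_id for g in bottom} == {"Y000", "Y001"}

    def test_234_genes_default_47_override_45(self):
        genes = [self.gene(i, 2.0 + i * 0.01) for i in range(234)]
        top, bottom = group_by_induction(genes, 0.2, 0.2)
        assert len(top) == 47  # ceil(0.2 * 234)
        top45, bottom45 = group_by_induction(genes, n_per_group=45)
        assert len(top45) == len(bottom45) == 45

    def test_ties_broken_by_gene_id(self):
        genes = [self.gene(i, 5.0) for i in range(6)]
        top, bottom = group_by_induction(genes, 0.33, 0.33)
        assert [g.gene_id for g in top] == ["Y000", "Y001"]
        assert [g.gene_id for g in bottom] == ["Y004", "Y005"]

    def test_overlapping_fractions_rejected(self):
        genes = [self.gene(i, float(i + 1)) for i in range(4)]
        with pytest.raises(ValueError):
            group_by_induction(genes, 0.6, 0.2)

    def test_missing_fold_rejected(self):
        genes = [Gene("YA", "c", 0, 10, "+")]
        with pytest.raises(ValueError):
            group_by_induction(genes)


def test_iid_dimer_expectations():
    assert iid_dimer_probability("WW", 0.6) == pytest.approx(0.36)
    assert iid_dimer_probability("SS", 0.6) == pytest.approx(0.16)
    assert round(expected_ww_spacing(0.6)) == 3
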