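import itertools

import pytest
from Bio.Align import substitution_matrices

from snodkit.io import FormatError, MolType, SequenceRecord
from snodkit.msa import (
    MultipleAlignment,
    align_og,
    back_translate,
    codon_position_mask,
    concat_supermatrix,
    trim_alignment,
)


def prot(gid, seq):
    return SequenceRecord(gid, seq, MolType.PROTEIN)


def aln(rows, moltype=MolType.PROTEIN):
    return MultipleAlignment(rows, moltype)


# ---------------------------------------------------------------------------
# brute-force affine-gap alignment oracle

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _score_alignment(rows: tuple[str, str], open_=-11.0, ext=-1.0) -> float:
    a, b = rows
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == "-":
            score += ext if in_gap_a else open_
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += ext if in_gap_b else open_
            in_gap_b, in_gap_a = True, False
        else:
            score += _BLOSUM[x][y]
            in_gap_a = in_gap_b = False
    return score


def _enumerate_alignments(a: str, b: str):
    """Every global alignment of two short strings (exponential; n <= 8)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def brute_force_best(a: str, b: str) -> float:
    return max(_score_alignment(rows) for rows in _enumerate_alignments(a, b))


class TestAlign:
    def test_identical_sequences_align_gapless(self):
        out = align_og([prot("a", "MKVLITG"), prot("b", "MKVLITG")])
        assert out.length == 7
        assert all("-" not in row for row in out.rows.values())

    def test_single_internal_gap_example(self):
        out = align_og([prot("a", "ACDE"), prot("b", "ACE")])
        assert out.length == 4
        assert out.rows["a"] == "ACDE"
        assert out.rows["b"].count("-") == 1

    @pytest.mark.parametrize(
        "a,b",
        [
            ("MKVLIT", "MKLIT"),
            ("ACDEFG", "ADEFG"),
            ("WYHQDN", "WYHQ"),
            ("MKVL", "MKVLITGA"),
            ("PGPGPG", "PGPG"),
        ],
    )
    def test_pairwise_score_matches_brute_force_enumeration(self, a, b):
        from snodkit.msa import _make_aligner

        pw = _make_aligner(MolType.PROTEIN)
        assert pw.align(a, b).score == pytest.approx(brute_force_best(a, b))

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_og([prot("a", "MKV")])

    def test_family_alignment_recovers_members(self, community):
        fam = community.truth.core_families[0]
        seqs = [
            next(r for r in community.proteomes[g] if r.id == f"{g}|{fam}")
            for g in community.genomes
        ]
        out = align_og(seqs)
        assert set(out.rows) == {s.id for s in seqs}
        for s in seqs:
            assert out.rows[s.id].replace("-", "") == s.seq


class TestTrim:
    def test_constant_column_kept(self):
        a = aln({"x": "M", "y": "M"})
        assert trim_alignment(a).length == 1

    def test_dna_half_half_column_is_boundary_inclusive(self):
        # 50/50 A/C: entropy 1 bit over log2(4) = 0.5, kept at cutoff 0.5
        a = aln({"x": "A", "y": "C"}, MolType.DNA)
        assert trim_alignment(a, entropy_cutoff=0.5, gap_cutoff=0.5).length == 1
        assert trim_alignment(a, entropy_cutoff=0.49, gap_cutoff=0.5).length == 0

    def test_gappy_column_removed(self):
        rows = {f"s{i}": ("-" if i < 3 else "M") + "K" for i in range(10)}
        out = trim_alignment(aln(rows), gap_cutoff=0.2)
        assert out.length == 1  # 30% gaps in column 0

    def test_trimming_is_idempotent(self, community):
        fam = community.truth.core_families[1]
        seqs = [
            next(r for r in community.proteomes[g] if r.id == f"{g}|{fam}")
            for g in community.genomes
        ]
        once = trim_alignment(align_og(seqs))
        twice = trim_alignment(once)
        assert once.rows == twice.rows

    def test_all_columns_removed_warns(self):
        a = aln({"x": "-M", "y": "M-"})
        with pytest.warns(UserWarning):
            out = trim_alignment(a, gap_cutoff=0.0)
        assert out.length == 0


class TestBackTranslate:
    def cds(self, taxon, seq):
        return {taxon: SequenceRecord(taxon, seq, MolType.DNA)}

    def test_single_residue(self):
        out = back_translate(
            MultipleAlignment({"t": "M", "u": "M"}, MolType.PROTEIN),
            {**self.cds("t", "ATG"), **self.cds("u", "ATG")},
        )
        assert out.rows["t"] == "ATG"

    def test_gap_becomes_triple_gap(self):
        out = back_translate(
            MultipleAlignment({"t": "M-K", "u": "MLK"}, MolType.PROTEIN),
            {
                **self.cds("t", "ATGAAA"),
                **self.cds("u", "ATGCTGAAA"),
            },
        )
        assert out.rows["t"] == "ATG---AAA"
        assert out.length == 9

    def test_single_trailing_stop_tolerated(self):
        out = back_translate(
            MultipleAlignment({"t": "MK", "u": "MK"}, MolType.PROTEIN),
            {
                **self.cds("t", "ATGAAATAA"),
                **self.cds("u", "ATGAAA"),
            },
        )
        assert out.rows["t"] == "ATGAAA"

    def test_two_trailing_stops_rejected(self):
        with pytest.raises(FormatError):
            back_translate(
                MultipleAlignment({"t": "MK", "u": "MK"}, MolType.PROTEIN),
                {
                    **self.cds("t", "ATGAAATAATAA"),
                    **self.cds("u", "ATGAAA"),
                },
            )

    def test_translation_mismatch_names_taxon(self):
        with pytest.raises(FormatError, match="t"):
            back_translate(
                MultipleAlignment({"t": "MK", "u": "MK"}, MolType.PROTEIN),
                {
                    **self.cds("t", "ATGCCC"),  # translates MP, not MK
                    **self.cds("u", "ATGAAA"),
                },
            )

    def test_roundtrip_recovers_protein_alignment(self, community):
        from snodkit.msa import align_og
        from Bio.Seq import Seq

        fam = community.truth.core_families[2]
        prots = [
            next(r for r in community.proteomes[g] if r.id == f"{g}|{fam}")
            for g in community.genomes
        ]
        cds = {
            f"{g}|{fam}": next(r for r in community.cds[g] if r.id == f"{g}|{fam}")
            for g in community.genomes
        }
        paln = align_og(prots)
        naln = back_translate(paln, cds)
        assert naln.length == 3 * paln.length
        for taxon, row in naln.rows.items():
            codons = [row[i : i + 3] for i in range(0, len(row), 3)]
            back = "".join(
                "-" if c == "---" else str(Seq(c).translate()) for c in codons
            )
            assert back == paln.rows[taxon]


class TestSupermatrix:
    def two_gene_setup(self, absent=False):
        g1 = aln({t: "MKVLITGAGG" * 10 for t in ("a", "b", "c")})
        rows2 = {t: "WYHQD" * 10 for t in ("a", "b", "c")}
        if absent:
            del rows2["c"]
            rows2["b"] = "WYHQD" * 10  # keep two rows minimum
        g2 = MultipleAlignment(rows2, MolType.PROTEIN)
        return [("g1", g1), ("g2", g2)]

    def test_concatenation_lengths_and_partitions(self):
        sm = concat_supermatrix(self.two_gene_setup(), ["a", "b", "c"])
        assert sm.length == 150
        assert sm.partitions == [("g1", 0, 100), ("g2", 100, 150)]
        assert sm.missing_fraction == 0.0

    def test_absent_taxon_filled_with_missing_states(self):
        sm = concat_supermatrix(self.two_gene_setup(absent=True), ["a", "b", "c"])
        assert sm.matrix["c"][100:] == "?" * 50
        assert sm.missing_fraction == pytest.approx(50 / (3 * 150))

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            concat_supermatrix([], ["a"])

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="not in the master"):
            concat_supermatrix(self.two_gene_setup(), ["a", "b"])


class TestCodonMask:
    def setup_sm(self):
        rows = {t: "ATGAAACCC" * 10 for t in ("a", "b")}
        g = MultipleAlignment(rows, MolType.DNA)
        return concat_supermatrix([("g1", g)], ["a", "b"])

    def test_positions_one_two(self):
        out = codon_position_mask(self.setup_sm(), {1, 2})
        assert out.length == 60
        assert out.matrix["a"][:6] == "ATAACC"[:6]

    def test_identity_mask(self):
        sm = self.setup_sm()
        out = codon_position_mask(sm, {1, 2, 3})
        assert out.matrix == sm.matrix

    def test_complementary_masks_sum(self):
        sm = self.setup_sm()
        third = codon_position_mask(sm, {3})
        onetwo = codon_position_mask(sm, {1, 2})
        assert third.length + onetwo.length == sm.length

    def test_non_codon_partition_rejected(self):
        rows = {t: "ATGAA" for t in ("a", "b")}
        sm = concat_supermatrix(
            [("g1", MultipleAlignment(rows, MolType.DNA))], ["a", "b"]
        )
        with pytest.raises(ValueError):
            codon_position_mask(sm, {3})
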