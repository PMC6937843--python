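"""Character-coding transforms: RY, degeneracy, positions, translation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treestrat.charcoding import (IUPAC_UNION, RaggedStopError, STANDARD_CODE,
                                  GeneticCode, build_degen_table, degen_encode,
                                  extract_codon_positions, ry_encode,
                                  strip_stop_codons, translate)
from treestrat.seqio import MultipleAlignment

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


def aln(*rows, molecule="nt"):
    return MultipleAlignment(tuple(f"t{i+1}" for i in range(len(rows))),
                             tuple(rows), molecule)


def brute_force_degen_table(code):
    """Independent oracle: grow each codon's synonym component by BFS over
    single-substitution synonymous neighbours, then take positionwise
    unions."""
    def neighbours(codon):
        for pos in range(3):
            for b in BASES:
                if b != codon[pos]:
                    other = codon[:pos] + b + codon[pos + 1:]
                    if code.codon_to_aa[other] == code.codon_to_aa[codon]:
                        yield other

    table = {}
    for start in CODONS:
        seen = {start}
        queue = [start]
        while queue:
            cur = queue.pop()
            for nxt in neighbours(cur):
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        table[start] = "".join(
            IUPAC_UNION[frozenset(m[i] for m in seen)] for i in range(3))
    return table


class TestRyEncode:
    def test_all_positions(self):
        assert ry_encode(aln("ACGT")).rows == ("RYRY",)

    def test_gap_missing_and_mixed_ambiguity(self):
        assert ry_encode(aln("A-N?")).rows == ("R-N?",)

    def test_pure_ambiguity_codes_kept(self):
        assert ry_encode(aln("RYSW")).rows == ("RYNN",)

    def test_third_positions_only(self):
        assert ry_encode(aln("ATGCATGAT"), positions="third").rows == ("ATRCAYGAY",)

    def test_third_positions_frame_shift(self):
        # frame 2: codon positions are labelled cyclically, so column 1
        # (the tail of the preceding, truncated codon) is also a third
        # position, alongside columns 4 and 7
        out = ry_encode(aln("ATGCATG"), positions="third", frame=2).rows[0]
        assert out == "RTGYATR"

    def test_invalid_frame(self):
        with pytest.raises(ValueError):
            ry_encode(aln("ACGT"), frame=4)

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGTURYSWKMBDHVN-?", min_size=1, max_size=60))
    def test_idempotent_and_length_preserving(self, seq):
        once = ry_encode(aln(seq))
        assert len(once.rows[0]) == len(seq)
        assert set(once.rows[0]) <= set("RYN-?")
        assert ry_encode(once).rows == once.rows


class TestDegenTable:
    def test_matches_brute_force_oracle_on_all_64_codons(self):
        table = build_degen_table(STANDARD_CODE)
        oracle = brute_force_degen_table(STANDARD_CODE)
        for codon in CODONS:
            assert table[codon] == oracle[codon], codon

    @pytest.mark.parametrize("codon,expect", [
        ("ATG", "ATG"),   # Met: singleton
        ("TGG", "TGG"),   # Trp: singleton
        ("CTA", "YTN"),   # Leu: six-codon component
        ("AGT", "AGY"),   # Ser AGY, disconnected from the TCN component
        ("TCT", "TCN"),   # Ser TCN side
    ])
    def test_spot_values_standard_code(self, codon, expect):
        assert build_degen_table(STANDARD_CODE)[codon] == expect

    def test_component_membership_iff_shared_image(self):
        table = build_degen_table(STANDARD_CODE)
        oracle = brute_force_degen_table(STANDARD_CODE)
        for a, b in itertools.combinations(CODONS, 2):
            assert (table[a] == table[b]) == (oracle[a] == oracle[b])

    def test_vertebrate_mitochondrial_code_differs(self):
        mito = build_degen_table(GeneticCode.from_ncbi_id(2))
        std = build_degen_table(STANDARD_CODE)
        # AGA/AGG are stops in the vertebrate mito code, Arg in the standard
        assert mito["AGA"] != std["AGA"]


class TestDegenEncode:
    def test_basic(self):
        assert degen_encode(aln("ATGCTA")).rows == ("ATGYTN",)

    def test_codon_with_gap_passes_through(self):
        assert degen_encode(aln("AT-CTA")).rows == ("AT-YTN",)

    def test_trailing_partial_codon_unchanged(self):
        assert degen_encode(aln("ATGCT")).rows == ("ATGCT",)

    def test_u_treated_as_t(self):
        assert degen_encode(aln("CUA")).rows == ("YTN",)

    def test_length_preserved(self):
        a = aln("ATGCTAAGTTGA")
        assert len(degen_encode(a).rows[0]) == a.n_sites


class TestCodonPositions:
    def test_keep_third(self):
        assert extract_codon_positions(aln("ACGTCA"), {3}).rows == ("GA",)

    def test_keep_first_second(self):
        assert extract_codon_positions(aln("ACGTCA"), {1, 2}).rows == ("ACTC",)

    def test_keep_all_is_identity(self):
        a = aln("ACGTCA")
        assert extract_codon_positions(a, {1, 2, 3}) == a

    def test_empty_keep_rejected(self):
        with pytest.raises(ValueError):
            extract_codon_positions(aln("ACGTCA"), set())

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT-", min_size=1, max_size=40),
           st.sampled_from([1, 2, 3]))
    def test_column_partition(self, seq, frame):
        a = aln(seq)
        part12 = extract_codon_positions(a, {1, 2}, frame).rows[0]
        part3 = extract_codon_positions(a, {3}, frame).rows[0]
        assert len(part12) + len(part3) == len(seq)
        assert sorted(part12 + part3) == sorted(seq)


class TestTranslate:
    def test_basic(self):
        assert translate(aln("ATGTGG")).rows == ("MW",)

    def test_gap_codon(self):
        assert translate(aln("ATG---")).rows == ("M-",)

    def test_partial_gap_codon_is_x(self):
        assert translate(aln("ATGA-G")).rows == ("MX",)

    def test_stop_rendered_and_strippable(self):
        assert translate(aln("ATGTAA")).rows == ("M*",)
        assert translate(aln("ATGTAA"), strip_final_stop=True).rows == ("M",)

    def test_output_is_amino_acid_alignment(self):
        assert translate(aln("ATGTGG")).molecule == "aa"


class TestStripStops:
    def test_final_only_removes_triple(self):
        out = strip_stop_codons(aln("ATGTAA", "ATGTGA"))
        assert out.rows == ("ATG", "ATG")

    def test_mask_internal(self):
        out = strip_stop_codons(aln("ATGTAAATG"), mode="mask-internal")
        assert out.rows == ("ATGNNNATG",)

    def test_no_stops_identity(self):
        a = aln("ATGTGG")
        assert strip_stop_codons(a) == a

    def test_ragged_final_stops_rejected(self):
        with pytest.raises(RaggedStopError):
            strip_stop_codons(aln("ATGTAA", "ATGTGG"))

    def test_gap_final_codon_ignored(self):
        out = strip_stop_codons(aln("ATGTAA", "ATG---"))
        assert out.rows == ("ATG", "ATG")


class TestDegenPreservesTranslation:
    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from(
        [c for c in CODONS if STANDARD_CODE.codon_to_aa[c] != "*"]),
        min_size=1, max_size=20))
    def test_translation_invariant_under_degeneracy(self, codons):
        """Degeneracy coding must never change amino-acid identity."""
        seq = "".join(codons)
        direct = translate(aln(seq)).rows[0]
        degen = degen_encode(aln(seq)).rows[0]
        # degenerate codons contain IUPAC codes; translate resolves a codon
        # only when unambiguous, so compare on the unambiguous columns
        recoded = translate(aln(degen)).rows[0]
        for a, b in zip(direct, recoded):
            if b != "X":
                assert a == b


class TestGeneticCode:
    def test_from_file_round_trip(self, tmp_path):
        p = tmp_path / "code.txt"
        p.write_text("# test code\n" + "\n".join(
            f"{c} {STANDARD_CODE.codon_to_aa[c]}" for c in CODONS) + "\n")
        assert GeneticCode.from_file(p).codon_to_aa == STANDARD_CODE.codon_to_aa

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError):
            GeneticCode("bad", {"ATG": "M"})

    def test_table_without_stop_rejected(self):
        mapping = {c: "A" for c in CODONS}
        with pytest.raises(ValueError):
            GeneticCode("bad", mapping)
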