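import numpy as np
import pytest

from mirloop import (
    PrecursorRecord,
    SecondaryStructure,
    extract_terminal_loop,
    find_hairpin_loops,
    fold_hairpin,
    pair_table,
    region_sequences,
)
from .conftest import assert_valid_structure, max_pairs_exhaustive, random_rna


class TestFoldHairpin:
    def test_simple_hairpin(self):
        structure = fold_hairpin("GGGAAAACCC")
        assert structure.dotbracket == "(((....)))"

    def test_unpairable_sequence_folds_to_dots(self):
        assert fold_hairpin("AAAA").dotbracket == "...."

    def test_gc_hairpin_reaches_enumeration_maximum(self):
        seq = "GCGCAAAAGCGC"
        structure = fold_hairpin(seq)
        assert structure.n_pairs == max_pairs_exhaustive(seq) == 4
        record = PrecursorRecord(id="x", sequence=seq)
        assert extract_terminal_loop(record, structure).sequence == "AAAA"

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            fold_hairpin("G")

    def test_wobble_toggle(self):
        # G·U is the only admissible pair here
        assert fold_hairpin("GGGGGUUUUU").n_pairs == 3
        assert fold_hairpin("GGGGGUUUUU", allow_gu=False).n_pairs == 0

    def test_matches_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            seq = random_rna(rng, int(rng.integers(5, 15)))
            structure = fold_hairpin(seq)
            assert structure.n_pairs == max_pairs_exhaustive(seq), seq
            assert_valid_structure(seq, structure)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        seq = random_rna(rng, 40)
        assert fold_hairpin(seq).dotbracket == fold_hairpin(seq).dotbracket


class TestPairTable:
    def test_hairpin(self):
        pairs = pair_table("(((....)))")
        assert pairs[0] == 9 and pairs[1] == 8 and pairs[2] == 7
        assert all(pairs[i] is None for i in range(3, 7))

    def test_all_unpaired(self):
        assert pair_table("....") == (None,) * 4

    @pytest.mark.parametrize("bad", ["(()", "())", "(a)"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            pair_table(bad)


class TestHairpinLoops:
    @pytest.mark.parametrize(
        "dotbracket,expected",
        [
            ("(((....)))", [(3, 7)]),
            ("((..))((...))", [(2, 4), (8, 11)]),
            ("..........", []),
            ("((..((...))..))", [(6, 9)]),  # internal-loop runs do not qualify
        ],
    )
    def test_intervals(self, dotbracket, expected):
        structure = SecondaryStructure.from_dotbracket("x", dotbracket)
        assert find_hairpin_loops(structure) == expected


class TestExtractTerminalLoop:
    def test_single_hairpin(self):
        record = PrecursorRecord(id="x", sequence="GGGAAAACCC")
        loop = extract_terminal_loop(record)
        assert (loop.start, loop.end, loop.sequence) == (3, 7, "AAAA")

    def test_descends_through_internal_loops(self):
        seq = "GGAAGGCCCAAUUCC"
        structure = SecondaryStructure.from_dotbracket("x", "((..((...))..))")
        record = PrecursorRecord(id="x", sequence=seq)
        loop = extract_terminal_loop(record, structure)
        assert (loop.start, loop.end) == (6, 9)

    def test_unpaired_structure_raises(self):
        record = PrecursorRecord(id="x", sequence="AAAA")
        with pytest.raises(ValueError, match="no terminal loop"):
            extract_terminal_loop(record)

    def test_multibranch_policies(self):
        db = "(((...)))((....))"
        record = PrecursorRecord(id="x", sequence="GGGAAACCCGGAAAACC")
        structure = SecondaryStructure.from_dotbracket("x", db)
        loop = extract_terminal_loop(record, structure, policy="longest_stem")
        assert (loop.start, loop.end) == (3, 6)  # deeper stem wins
        with pytest.raises(ValueError, match="error_on_multi"):
            extract_terminal_loop(record, structure, policy="error_on_multi")
        with pytest.raises(ValueError, match="policy"):
            extract_terminal_loop(record, structure, policy="nope")

    def test_short_helix_inside_long_stem_is_loop_content(self):
        # a lone pair buried under a 10-pair stem belongs to the loop
        db = "((((((((((..(....)..))))))))))"
        seq = "G" * 10 + "AAGAAAACAA" + "C" * 10
        record = PrecursorRecord(id="x", sequence=seq)
        loop = extract_terminal_loop(record, SecondaryStructure.from_dotbracket("x", db))
        assert (loop.start, loop.end) == (10, 20)
        assert loop.sequence == "AAGAAAACAA"


class TestRegionSequences:
    def test_stem_loop_is_identity(self):
        precursors = {"a": PrecursorRecord(id="a", sequence="GGGAAAACCC")}
        seqs, excluded = region_sequences(precursors, "stem_loop")
        assert seqs == {"a": "GGGAAAACCC"} and excluded == []

    def test_terminal_loop_excludes_unfoldable(self):
        precursors = {
            "a": PrecursorRecord(id="a", sequence="GGGAAAACCC"),
            "b": PrecursorRecord(id="b", sequence="AAAAAA"),
        }
        seqs, excluded = region_sequences(precursors, "terminal_loop")
        assert seqs == {"a": "AAAA"} and excluded == ["b"]

    def test_supplied_structure_overrides_folding(self):
        precursors = {"a": PrecursorRecord(id="a", sequence="GGGAAAACCC")}
        seqs, _ = region_sequences(
            precursors, "terminal_loop", structures={"a": "((......))"}
        )
        assert seqs == {"a": "GAAAAC"}  # interior of the supplied closing pair

    def test_unknown_region(self):
        with pytest.raises(ValueError, match="region"):
            region_sequences({}, "loopy")
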