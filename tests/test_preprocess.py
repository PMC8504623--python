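"""Six-frame fragment extraction: oracle equivalence and coordinate audit."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spacerlink.io import GenomeRecord, SpacerRecord
from spacerlink.preprocess import (
    MIN_FRAGMENT_NT,
    build_sets,
    codon_map,
    extract_fragments,
    revcomp,
)


def brute_force_peptides(seq: str, min_nt: int = MIN_FRAGMENT_NT, table: int = 11):
    """Independent enumeration: split each frame's codon list at stops."""
    cmap = codon_map(table)
    out = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            run = []
            for aa in [cmap.get(c, "X") for c in codons] + ["*"]:
                if aa == "*":
                    if 3 * len(run) >= min_nt:
                        out.append("".join(run))
                    run = []
                else:
                    run.append(aa)
    return Counter(out)


dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestExtractFragments:
    def test_stop_free_33nt_spacer_yields_six_fragments(self):
        seq = "AAA" * 11  # Lys forward, Phe reverse: no stops anywhere
        frags = extract_fragments(seq, "s1", "spacer")
        assert len(frags) == 6
        assert sorted(len(f.aa_sequence) for f in frags) == [10, 10, 10, 10, 11, 11]
        assert Counter(f.aa_sequence for f in frags) == brute_force_peptides(seq)

    def test_early_stop_splits_run_below_threshold(self):
        seq = "ATGTAA" + "GCA" * 8  # 30 nt, stop at codon 2 of frame 0
        frags = extract_fragments(seq, "s1", "spacer")
        assert not [f for f in frags if f.frame == 0 and f.strand == "+"]

    def test_27nt_no_stops_gives_exactly_two_9aa_fragments(self):
        frags = extract_fragments("A" * 27, "s1", "spacer")
        assert len(frags) == 2
        assert all(len(f.aa_sequence) == 9 and f.frame == 0 for f in frags)
        assert {f.strand for f in frags} == {"+", "-"}

    def test_short_sequence_yields_empty_list(self):
        assert extract_fragments("ACGT" * 5, "s1", "spacer") == []

    def test_ambiguity_translates_to_x_and_does_not_split(self):
        seq = "AAANAAAAA" * 3 + "AAA"  # N inside a codon
        frags = extract_fragments(seq, "s1", "spacer")
        fwd0 = [f for f in frags if f.strand == "+" and f.frame == 0]
        assert fwd0 and "X" in fwd0[0].aa_sequence

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna)
    def test_matches_bruteforce_enumeration(self, seq):
        frags = extract_fragments(seq, "p", "genome")
        assert Counter(f.aa_sequence for f in frags) == brute_force_peptides(seq)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna)
    def test_coordinate_audit_and_translation(self, seq):
        cmap = codon_map(11)
        for f in extract_fragments(seq, "p", "genome"):
            oriented = seq if f.strand == "+" else revcomp(seq)
            start = f.nt_start if f.strand == "+" else len(seq) - f.nt_end
            stop = f.nt_end if f.strand == "+" else len(seq) - f.nt_start
            assert oriented[start:stop] == f.nt_sequence
            translated = "".join(
                cmap.get(f.nt_sequence[i : i + 3], "X")
                for i in range(0, len(f.nt_sequence), 3)
            )
            assert translated == f.aa_sequence
            assert len(f.aa_sequence) >= 9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        fwd = Counter(
            (f.aa_sequence, f.strand) for f in extract_fragments(seq, "p", "genome")
        )
        rev = Counter(
            (f.aa_sequence, "+" if f.strand == "-" else "-")
            for f in extract_fragments(revcomp(seq), "p", "genome")
        )
        assert fwd == rev


class TestBuildSets:
    def _spacer(self, acc, gid, seq):
        return SpacerRecord(accession=acc, genome_id=gid, sequence=seq)

    def test_one_set_per_genome(self):
        spacers = {
            "h1": [self._spacer(f"h1s{i}", "h1", "AAA" * 11) for i in range(3)],
            "h2": [self._spacer(f"h2s{i}", "h2", "AAA" * 11) for i in range(3)],
        }
        genomes = [GenomeRecord(accession="p1", sequence="AAA" * 40)]
        queries, targets = build_sets(spacers, genomes)
        assert [q.set_id for q in queries] == ["h1", "h2"]
        assert len(targets) == 1 and targets[0].n_fragments >= 6

    def test_untranslatable_host_is_empty_with_warning(self, caplog):
        spacers = {
            "h1": [self._spacer("a", "h1", "AAA" * 11)],
            "h2": [self._spacer("b", "h2", "ACGT" * 5)],  # 20 nt: below min
        }
        genomes = [GenomeRecord(accession="p1", sequence="AAA" * 40)]
        with caplog.at_level("WARNING"):
            queries, _ = build_sets(spacers, genomes)
        assert queries[1].n_fragments == 0
        assert "h2" in caplog.text

    def test_all_empty_query_sets_is_an_error(self):
        spacers = {"h1": [self._spacer("a", "h1", "ACGT" * 5)]}
        genomes = [GenomeRecord(accession="p1", sequence="AAA" * 40)]
        with pytest.raises(ValueError, match="translatable"):
            build_sets(spacers, genomes)
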