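"""Prefilter, alignment, P-values and nucleotide re-alignment."""

from types import SimpleNamespace

import numpy as np
import pytest
from helpers import gotoh_local_score, random_protein, share_spaced_kmer

from spacerlink import make_phage, plant_protospacers
from spacerlink.io import GenomeRecord
from spacerlink.preprocess import OrfFragment, QuerySet, TargetSet, extract_fragments
from spacerlink.scoring import encode_protein
from spacerlink.search import (
    NEAR_PERFECT_P_FLOOR,
    ProteinHit,
    align_protein,
    hit_pvalue,
    prefilter,
    realign_nucleotide,
    search_pair,
)


def frag(aa: str, **kw) -> OrfFragment:
    """Fragment with the given peptide (nt payload is a placeholder)."""
    defaults = dict(
        parent_accession="x",
        parent_kind="genome",
        frame=0,
        strand="+",
        nt_start=0,
        nt_end=3 * len(aa),
        nt_sequence="A" * (3 * len(aa)),
    )
    defaults.update(kw)
    return OrfFragment(aa_sequence=aa, **defaults)


def qset(*aas):
    return QuerySet(set_id="q", fragments=[frag(a) for a in aas])


def tset(*aas):
    return TargetSet(set_id="t", fragments=[frag(a) for a in aas])


class TestPrefilter:
    def test_identical_fragments_are_candidates(self, scheme):
        aa = "ACDEFGHIK"
        assert prefilter(qset(aa), tset(aa), scheme) == [(0, 0)]

    def test_mismatches_at_wildcard_positions_still_candidate(self, scheme):
        # pattern 10111011: positions 1 and 5 are uninformative
        q = list("ACDEFGHIK")
        t = list("ACDEFGHIK")
        t[1], t[5] = "W", "W"
        assert prefilter(qset("".join(q)), tset("".join(t)), scheme) == [(0, 0)]

    def test_matches_exhaustive_enumeration(self, scheme, rng):
        offsets = scheme.pattern_offsets
        span = len(scheme.kmer_pattern)
        for _ in range(100):
            q = random_protein(rng, int(rng.integers(9, 20)))
            t = random_protein(rng, int(rng.integers(9, 40)))
            expected = share_spaced_kmer(q, t, offsets, span)
            got = bool(prefilter(qset(q), tset(t), scheme))
            assert got == expected


class TestAlignProtein:
    def test_self_alignment_is_full_length_diagonal_sum(self, scheme):
        aa = "MKVLHWACDEFG"
        f = frag(aa)
        score, qs, qe, ts, te = align_protein(f, f, scheme)
        enc = encode_protein(aa)
        assert score == sum(int(scheme.matrix[i, i]) for i in enc)
        assert (qs, qe, ts, te) == (0, len(aa), 0, len(aa))

    def test_scores_equal_dp_oracle(self, scheme, rng):
        for _ in range(50):
            q = random_protein(rng, int(rng.integers(9, 16)))
            t = random_protein(rng, int(rng.integers(20, 80)))
            score, *_ = align_protein(frag(q), frag(t), scheme)
            expected = gotoh_local_score(
                encode_protein(q), encode_protein(t),
                scheme.matrix, scheme.gap_open, scheme.gap_extend,
            )
            assert score == expected

    def test_score_invariant_under_joint_reversal(self, scheme, rng):
        for _ in range(20):
            q = random_protein(rng, 12)
            t = random_protein(rng, 40)
            s1, *_ = align_protein(frag(q), frag(t), scheme)
            s2, *_ = align_protein(frag(q[::-1]), frag(t[::-1]), scheme)
            assert s1 == s2


class TestHitPvalue:
    def test_zero_score_is_near_one(self, scheme):
        assert hit_pvalue(0, 12, 100, scheme) == 1.0

    def test_monotone_decreasing_in_score(self, scheme):
        ps = [hit_pvalue(s, 12, 100, scheme) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_increasing_in_search_space(self, scheme):
        assert hit_pvalue(50, 12, 100, scheme) < hit_pvalue(50, 14, 300, scheme)

    def test_invalid_gumbel_parameters_rejected(self, scheme):
        broken = SimpleNamespace(gumbel_lambda=0.0, gumbel_K=scheme.gumbel_K)
        with pytest.raises(ValueError):
            hit_pvalue(50, 12, 100, broken)


def _planted_hits(k: int, seed: int = 5):
    """Search one planted spacer set against its source phage."""
    genome, plan = make_phage(3000, seed=seed, accession="ph")
    spacers, truth, genome = plant_protospacers(
        genome, plan, 3, mutation_model={"aa_conserving_nt_subs": k}, seed=seed,
        pam_motif=None,
    )
    from spacerlink.scoring import ScoringScheme

    scheme = ScoringScheme()
    Q = QuerySet(
        set_id="h",
        fragments=[
            f for sp in spacers
            for f in extract_fragments(sp.sequence, sp.accession, "spacer")
        ],
    )
    T = TargetSet(
        set_id="ph", fragments=extract_fragments(genome.sequence, "ph", "genome")
    )
    hits = search_pair(Q, T, scheme, {s.accession: s for s in spacers}, genome)
    return spacers, truth, hits


class TestRealignNucleotide:
    def test_exact_protospacer_is_near_perfect_with_floored_pvalue(self):
        spacers, truth, hits = _planted_hits(k=0)
        by_spacer = {}
        for h in hits:
            acc = h.query_fragment.parent_accession
            if acc not in by_spacer or h.p_hit < by_spacer[acc].p_hit:
                by_spacer[acc] = h
        assert set(by_spacer) == {s.accession for s in spacers}
        for t in truth:
            h = by_spacer[t["spacer_accession"]]
            assert h.near_perfect and h.nt_mismatches == 0
            assert h.p_hit <= NEAR_PERFECT_P_FLOOR
            assert (h.proto_start, h.proto_end) == (t["proto_start"], t["proto_end"])

    def test_three_synonymous_substitutions_break_near_perfect(self):
        spacers, truth, hits = _planted_hits(k=3)
        by_spacer = {}
        for h in hits:
            acc = h.query_fragment.parent_accession
            if acc not in by_spacer or h.p_hit < by_spacer[acc].p_hit:
                by_spacer[acc] = h
        assert set(by_spacer) == {s.accession for s in spacers}
        for h in by_spacer.values():
            assert h.nt_mismatches >= 3
            assert not h.near_perfect
            assert h.p_hit > NEAR_PERFECT_P_FLOOR

    def test_window_clipped_at_genome_start_reduces_coverage(self):
        genome = GenomeRecord(accession="g", sequence="ACGT" * 25)
        spacer = SimpleNamespace(sequence="TTT" + genome.sequence[:30])
        q = frag("A" * 10, parent_kind="spacer", nt_start=3, nt_end=33)
        t = frag("A" * 10, nt_start=0, nt_end=30)
        hit = ProteinHit(
            query_fragment=q, target_fragment=t, aln_score=50,
            q_aln_start=0, q_aln_end=10, t_aln_start=0, t_aln_end=10, p_hit=1e-4,
        )
        out = realign_nucleotide(hit, spacer, genome)
        assert out.nt_mismatches == 0 and out.nt_identity == 1.0
        assert not out.near_perfect  # coverage 30/33 < 0.95
        assert (out.proto_start, out.proto_end) == (0, 30)
        assert out.p_hit == 1e-4
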