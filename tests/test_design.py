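"""Tiling, composition filters, blacklist/complexity screens and redundancy removal."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import oracle_redundant, random_dna

from cladecap.design import (
    Bait,
    DesignParams,
    build_panel,
    build_blacklist_index,
    compute_gc,
    compute_tm,
    dedupe_baits,
    is_low_complexity,
    is_redundant_pair,
    screen_blacklist,
    tile_exon,
)
from cladecap.seqio import ExonMap, MultipleAlignment, SequenceRecord, ValidationError, revcomp
from cladecap.select import LocusCandidate, OrthoGroup

P = DesignParams()


class TestTiling:
    @pytest.mark.parametrize(
        "exon_len, expected",
        [
            (80, [0]),
            (107, [0, 27]),
            (160, [0, 27, 54, 80]),
            (79, []),
        ],
    )
    def test_ladder_with_flush_right_bait(self, exon_len, expected):
        assert tile_exon(exon_len, P) == expected

    @given(st.integers(min_value=80, max_value=3000))
    def test_every_position_covered_and_flush(self, exon_len):
        starts = tile_exon(exon_len, P)
        covered = np.zeros(exon_len, dtype=bool)
        for s in starts:
            covered[s:s + 80] = True
        assert covered.all()
        assert starts[-1] == exon_len - 80
        assert all(b > a for a, b in zip(starts, starts[1:]))


class TestComposition:
    def test_gc_and_tm_formulas(self):
        all_gc = "GC" * 40
        assert compute_gc(all_gc) == 100.0
        assert compute_tm(all_gc) == pytest.approx(114.0625)
        half = "GC" * 20 + "AT" * 20
        assert compute_gc(half) == 50.0
        assert compute_tm(half) == pytest.approx(81.5 + 0.41 * 50 - 675 / 80)  # 93.5625

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValidationError):
            compute_gc("ACGN" * 20)


class TestBlacklist:
    def test_exact_and_reverse_complement_hits_fail(self, rng):
        plastome = random_dna(rng, 2000)
        idx = build_blacklist_index([SequenceRecord("pt", plastome)], 24)
        hit = random_dna(rng, 28) + plastome[500:524] + random_dna(rng, 28)
        assert not screen_blacklist(hit, idx, 24)
        rc_hit = random_dna(rng, 28) + revcomp(plastome[500:524]) + random_dna(rng, 28)
        assert not screen_blacklist(rc_hit, idx, 24)

    def test_unrelated_bait_passes(self, rng):
        idx = build_blacklist_index([SequenceRecord("pt", random_dna(rng, 2000))], 24)
        assert screen_blacklist(random_dna(rng, 80), idx, 24)

    def test_k_longer_than_bait_rejected(self, rng):
        idx = build_blacklist_index([SequenceRecord("pt", random_dna(rng, 200))], 24)
        with pytest.raises(ValidationError):
            screen_blacklist("ACGT", idx, 24)


class TestLowComplexity:
    def test_dinucleotide_repeat_flagged(self):
        assert is_low_complexity("AT" * 40, P)

    def test_random_sequence_not_flagged(self, rng):
        # screen a batch: none should trip the period<=6 / 48-base rule
        assert not any(is_low_complexity(random_dna(rng, 80), P) for _ in range(20))

    def test_span_boundary(self):
        # period-3 repeat spanning 47 bases sits below the 48-base (0.6 x 80)
        # threshold; 48 bases trips it.  Flanks are chosen so they cannot
        # extend the repeat run across the junctions.
        repeat47 = ("ACG" * 16)[:47]
        seq = "T" * 20 + repeat47 + "TCTAGGCATGCTA"
        assert len(seq) == 80 and not is_low_complexity(seq, P)
        repeat48 = "ACG" * 16
        seq = "T" * 20 + repeat48 + "TCTAGGCATGCT"
        assert len(seq) == 80 and is_low_complexity(seq, P)


def _bait(i, seq, locus="L1", exon=0, start=0, sp="SpA"):
    return Bait(f"b{i:03d}", locus, sp, exon, start, seq,
                compute_gc(seq), compute_tm(seq))


class TestRedundancy:
    def test_identical_pair_collapses(self, rng):
        seq = random_dna(rng, 80)
        kept, dropped = dedupe_baits(
            [_bait(0, seq, start=0), _bait(1, seq, start=27)], P
        )
        assert len(kept) == 1 and len(dropped) == 1

    def test_67_base_overlap_is_redundant_66_is_not(self, rng):
        base = random_dna(rng, 93)
        a = base[:80]
        b67 = base[13:93]  # 67-base identical overlap at offset 13
        assert is_redundant_pair(a, b67, P)
        assert oracle_redundant(a, b67, 0.95, 0.83)
        base = random_dna(rng, 94)
        a = base[:80]
        b66 = base[14:94]  # only 66 bases overlap
        assert not is_redundant_pair(a, b66, P)
        assert not oracle_redundant(a, b66, 0.95, 0.83)

    def test_greedy_output_contains_no_redundant_pair(self, rng):
        baits = []
        for i in range(60):
            baits.append(_bait(i, random_dna(rng, 80), start=i))
        # plant shifted near-copies of the first 15
        for i in range(15):
            src = baits[i].seq
            shifted = src[10:] + random_dna(rng, 10)
            baits.append(_bait(100 + i, shifted, start=100 + i))
        kept, dropped = dedupe_baits(baits, P)
        assert len(dropped) >= 15
        seqs = [b.seq for b in kept]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert not oracle_redundant(seqs[i], seqs[j], 0.95, 0.83)


class TestPanelBuild:
    def _locus(self, rng, exon_lens, n_species=2, locus="L1"):
        L = sum(exon_lens)
        base = random_dna(rng, L)
        rows = [(f"Sp{i}", base) for i in range(n_species)]
        bounds = np.concatenate([[0], np.cumsum(exon_lens)])
        g = OrthoGroup(
            locus,
            {sp: SequenceRecord("t", row) for sp, row in rows},
            {sp: 1 for sp, _ in rows},
        )
        aln = MultipleAlignment(rows)
        return LocusCandidate(
            g, aln, ExonMap(tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])))
        )

    def test_single_160_base_exon_gives_4_baits_depth_2(self, rng):
        cand = self._locus(rng, [160], n_species=2)
        panel = build_panel([cand], [], P)
        # two identical rows -> duplicates collapse to one species' ladder
        assert panel.n_baits == 4
        row = panel.manifest.iloc[0]
        assert row["exon_len"] == 160 and row["n_tiled"] == 4
        assert panel.manifest["depth"].max() == pytest.approx(2.0)

    def test_blacklisted_bait_recorded_in_ledger(self, rng):
        cand = self._locus(rng, [160], n_species=2)
        seq = cand.alignment.rows[0][1]
        blacklist = [SequenceRecord("pt", seq[30:54])]  # inside the first bait only
        panel = build_panel([cand], blacklist, P)
        reasons = panel.dropped["reason"].value_counts().to_dict()
        assert reasons.get("blacklist", 0) >= 1

    def test_cross_species_duplicates_collapse(self, rng):
        cand = self._locus(rng, [240], n_species=3)
        panel = build_panel([cand], [], P)
        assert len({b.seq for b in panel.baits}) == panel.n_baits
        assert {b.source_species for b in panel.baits} == {"Sp0"}

    def test_short_exon_gets_no_baits(self, rng):
        cand = self._locus(rng, [79, 200], n_species=2)
        panel = build_panel([cand], [], P)
        assert all(b.exon_index == 1 for b in panel.baits)

    def test_determinism_byte_identical(self, rng, tmp_path):
        cand = self._locus(rng, [160, 240], n_species=2)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        build_panel([cand], [], P).to_fasta(p1)
        build_panel([cand], [], P).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_average_depth_approaches_80_over_27_for_long_exons(self, rng):
        cand = self._locus(rng, [5000], n_species=2)
        panel = build_panel([cand], [], P)
        depth = panel.manifest["depth"].max()
        assert depth == pytest.approx(80 / 27, rel=0.02)
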