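"""Ortholog clustering, rescue, exon transfer, trimming and the locus filters."""

import numpy as np
import pytest

from helpers import brute_force_filter_check, exhaustive_best_offset, random_dna

from cladecap.seqio import ExonMap, MultipleAlignment, SequenceRecord
from cladecap.select import (
    LocusCandidate,
    OrthoGroup,
    SelectionParams,
    annotate_exons,
    apply_locus_filters,
    cluster_orthologs,
    count_snp_density,
    rescue_missing,
    trim_to_overlap,
)

PARAMS = SelectionParams()


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestClustering:
    def test_identical_transcript_in_four_species_forms_one_group(self, rng):
        seq = random_dna(rng, 1200)
        sets = {sp: [SequenceRecord("t1", seq)] for sp in "ABCD"}
        groups = cluster_orthologs(sets, PARAMS)
        assert len(groups) == 1
        g = groups[0]
        assert sorted(g.members) == ["A", "B", "C", "D"]
        assert all(c == 1 for c in g.copy_counts.values())

    def test_near_identical_second_copy_flags_multi_copy(self, rng):
        seq = random_dna(rng, 1200)
        copy = _mutate(seq, [600], rng)  # differs by one base
        sets = {sp: [SequenceRecord("t1", seq)] for sp in "ACD"}
        sets["B"] = [SequenceRecord("t1", seq), SequenceRecord("t2", copy)]
        groups = cluster_orthologs(sets, PARAMS)
        flagged = [g for g in groups if len(g.members) == 4]
        assert len(flagged) == 1
        # oracle: exhaustive ungapped identity of both copies vs another member
        # confirms both score within 95% of the best
        _, m1, ov1 = exhaustive_best_offset(seq, seq)
        _, m2, ov2 = exhaustive_best_offset(copy, seq)
        assert (m2 / ov2) >= 0.95 * (m1 / ov1)
        assert flagged[0].copy_counts["B"] == 2
        assert not flagged[0].is_low_copy

    def test_unrelated_transcript_forms_singleton(self, rng):
        seq = random_dna(rng, 1000)
        lone = random_dna(rng, 1000)
        sets = {
            "A": [SequenceRecord("t1", seq)],
            "B": [SequenceRecord("t1", seq)],
            "C": [SequenceRecord("t1", seq), SequenceRecord("orphan", lone)],
        }
        groups = cluster_orthologs(sets, PARAMS)
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [1, 3]

    def test_permutation_invariance(self, rng):
        seqs = [random_dna(rng, 900) for _ in range(3)]
        base = {
            "A": [SequenceRecord(f"a{i}", s) for i, s in enumerate(seqs)],
            "B": [SequenceRecord(f"b{i}", _mutate(s, [10, 50], rng))
                  for i, s in enumerate(seqs)],
        }
        shuffled = {
            "B": list(reversed(base["B"])),
            "A": list(reversed(base["A"])),
        }
        g1 = cluster_orthologs(base, PARAMS)
        g2 = cluster_orthologs(shuffled, PARAMS)
        key = lambda gs: [
            (g.locus_id, sorted((sp, m.id) for sp, m in g.members.items()))
            for g in gs
        ]
        assert key(g1) == key(g2)

    def test_duplicate_ids_rejected(self, rng):
        s = random_dna(rng, 500)
        sets = {
            "A": [SequenceRecord("t", s), SequenceRecord("t", s[::-1])],
            "B": [SequenceRecord("t", s)],
        }
        with pytest.raises(Exception, match="duplicate"):
            cluster_orthologs(sets, PARAMS)


class TestRescue:
    def _group(self, seq):
        return OrthoGroup(
            "G1",
            {sp: SequenceRecord("t1", seq) for sp in "ABC"},
            {sp: 1 for sp in "ABC"},
        )

    def test_exact_copy_is_added(self, rng):
        seq = random_dna(rng, 600)
        g = rescue_missing(self._group(seq), "D", [SequenceRecord("d1", seq)], PARAMS)
        assert "D" in g.members and g.members["D"].id == "d1"

    def test_distant_candidate_rejected(self, rng):
        seq = random_dna(rng, 600)
        # 30% of positions mutated -> ~70% identity, below the 0.80 floor
        diverged = _mutate(seq, rng.choice(600, size=180, replace=False), rng)
        off, m, ov = exhaustive_best_offset(seq, diverged)
        assert m / ov < 0.80  # oracle confirms the construction
        g = rescue_missing(self._group(seq), "D", [SequenceRecord("d1", diverged)], PARAMS)
        assert "D" not in g.members

    def test_empty_candidate_set_is_noop(self, rng):
        seq = random_dna(rng, 600)
        g0 = self._group(seq)
        assert rescue_missing(g0, "D", [], PARAMS) is g0


class TestAnnotateExons:
    def _ref(self, rng, n=250):
        seq = random_dna(rng, n)
        return SequenceRecord("ref", seq), ExonMap(((0, 100), (100, n)))

    def test_identical_member_keeps_boundaries(self, rng):
        ref, emap = self._ref(rng)
        g = OrthoGroup(
            "G1",
            {sp: SequenceRecord("t1", ref.seq) for sp in "AB"},
            {sp: 1 for sp in "AB"},
        )
        cand = annotate_exons(g, ref, emap, PARAMS)
        assert cand.exon_map.intervals == ((0, 100), (100, 250))

    def test_insertion_widens_containing_exon(self, rng):
        ref, emap = self._ref(rng)
        insert = random_dna(rng, 30)
        with_ins = ref.seq[:150] + insert + ref.seq[150:]  # inside exon 2
        g = OrthoGroup(
            "G1",
            {"A": SequenceRecord("t1", ref.seq), "B": SequenceRecord("t1", with_ins)},
            {"A": 1, "B": 1},
        )
        cand = annotate_exons(g, ref, emap, PARAMS)
        lengths = cand.exon_map.lengths()
        assert lengths[0] == 100
        assert lengths[1] == 150 + 30  # widened by the insertion

    def test_truncated_member_marks_exon_absent(self, rng):
        ref, emap = self._ref(rng)
        g = OrthoGroup(
            "G1",
            {
                "A": SequenceRecord("t1", ref.seq),
                "B": SequenceRecord("t1", ref.seq[:100]),  # exon 2 missing
            },
            {"A": 1, "B": 1},
        )
        cand = annotate_exons(g, ref, emap, PARAMS)
        assert cand.exon_presence["A"] == [True, True]
        assert cand.exon_presence["B"] == [True, False]

    def test_unalignable_group_rejected(self, rng):
        ref, emap = self._ref(rng)
        g = OrthoGroup(
            "G1",
            {sp: SequenceRecord("t1", random_dna(rng, 250)) for sp in "AB"},
            {sp: 1 for sp in "AB"},
        )
        cand = annotate_exons(g, ref, emap, PARAMS)
        assert cand.verdict == "fail"
        assert "no_alignable_region" in cand.reasons


class TestTrim:
    def _cand(self, rows, intervals):
        aln = MultipleAlignment(rows)
        g = OrthoGroup(
            "G1",
            {sp: SequenceRecord("t", row.replace("-", "")) for sp, row in rows},
            {sp: 1 for sp, _ in rows},
        )
        return LocusCandidate(g, aln, ExonMap(tuple(intervals)))

    def test_leading_and_trailing_overhangs_removed(self, rng):
        core = random_dna(rng, 12)
        rows = [("A", "-----" + core + "AAA"),
                ("B", "TTTTT" + core + "---")]
        cand = self._cand(rows, [(0, 20)])
        out = trim_to_overlap(cand)
        assert out.alignment.length == 12
        assert out.alignment.row("A") == core
        assert out.exon_map.intervals == ((0, 12),)

    def test_no_common_column_fails(self):
        cand = self._cand([("A", "AAAA----"), ("B", "----TTTT")], [(0, 8)])
        out = trim_to_overlap(cand)
        assert out.verdict == "fail"
        assert "no_overlap" in out.reasons

    def test_full_overlap_unchanged(self, rng):
        core = random_dna(rng, 30)
        cand = self._cand([("A", core), ("B", core)], [(0, 10), (10, 30)])
        out = trim_to_overlap(cand)
        assert out.alignment.row("A") == core
        assert out.exon_map.intervals == ((0, 10), (10, 30))


class TestSnpDensity:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment([(sp, "ACGT" * 25) for sp in "ABCD"])
        assert count_snp_density(aln) == 0.0

    def test_two_polymorphic_columns_in_100_is_exactly_20(self, rng):
        base = random_dna(rng, 100)
        other = _mutate(base, [10, 50], rng)
        aln = MultipleAlignment([("A", base), ("B", other)])
        assert count_snp_density(aln) == 20.0

    def test_gaps_and_n_do_not_create_polymorphism(self):
        aln = MultipleAlignment(
            [("A", "A-N"), ("B", "A-N"), ("C", "AAA"), ("D", "A-A")]
        )
        assert count_snp_density(aln) == 0.0


class TestFilters:
    def _cand(self, rng, exon_lens, n_species=4, poly_per_kb=40):
        L = sum(exon_lens)
        base = random_dna(rng, L)
        n_poly = round(poly_per_kb * L / 1000)
        rows = [("Sp0", base)]
        positions = rng.choice(L, size=n_poly, replace=False)
        rows.append(("Sp1", _mutate(base, positions, rng)))
        for i in range(2, n_species):
            rows.append((f"Sp{i}", base))
        bounds = np.concatenate([[0], np.cumsum(exon_lens)])
        intervals = tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]))
        g = OrthoGroup(
            "G1",
            {sp: SequenceRecord("t", row) for sp, row in rows},
            {sp: 1 for sp, _ in rows},
        )
        return LocusCandidate(g, MultipleAlignment(rows), ExonMap(intervals))

    def test_short_internal_exon_rejected_but_short_terminal_kept(self, rng):
        internal = self._cand(rng, [120, 79, 200])
        terminal = self._cand(rng, [79, 200])
        kept, rejected = apply_locus_filters([internal, terminal], PARAMS)
        assert [c.locus_id for c in rejected] == ["G1"]
        assert rejected[0].reasons == ["short_internal_exon"]
        assert len(kept) == 1  # 79-base *terminal* exon does not disqualify

    def test_density_boundary_is_strict(self, rng):
        low = self._cand(rng, [500, 500], poly_per_kb=19)  # 19 sites -> 19.0
        edge = self._cand(rng, [500, 500], poly_per_kb=20)
        kept, rejected = apply_locus_filters([low, edge], PARAMS)
        assert rejected and rejected[0].snp_density < 20
        assert kept and kept[0].snp_density >= 20.0

    def test_presence_counts_focal_species_only(self, rng):
        cand = self._cand(rng, [200, 200], n_species=3)
        params = SelectionParams(focal_species=("Sp0", "Sp1", "SpX"))
        kept, rejected = apply_locus_filters([cand], params)
        assert not kept
        assert "absent_species" in rejected[0].reasons

    def test_reasons_accumulate(self, rng):
        cand = self._cand(rng, [120, 60, 200], n_species=4, poly_per_kb=2)
        params = SelectionParams(focal_species=("Sp0", "Sp1", "Missing1", "Missing2"))
        _, rejected = apply_locus_filters([cand], params)
        assert rejected[0].reasons == [
            "absent_species", "low_snp_density", "short_internal_exon"
        ]

    def test_agreement_with_brute_force_oracle(self, rng):
        cands = []
        for _ in range(40):
            exons = [int(rng.integers(40, 300)) for _ in range(int(rng.integers(2, 5)))]
            cands.append(
                self._cand(rng, exons, n_species=int(rng.integers(2, 5)),
                           poly_per_kb=float(rng.uniform(0, 60)))
            )
        kept, rejected = apply_locus_filters(cands, PARAMS)
        assert len(kept) + len(rejected) == len(cands)
        for cand in kept + rejected:
            expected = brute_force_filter_check(
                dict(cand.alignment.rows),
                list(cand.exon_map.intervals),
                None,
                PARAMS.min_presence,
                PARAMS.effective_min_exon_len,
                PARAMS.min_snp_density,
            )
            assert cand.reasons == expected
            assert (cand.verdict == "pass") == (not expected)
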