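"""Shared k-mer and seed-and-extend machinery.

Every similarity search in the toolkit (ortholog clustering, missing-species
rescue, blacklist screening, read pseudo-mapping, panel overlap detection) is
built on the same two primitives: canonical k-mer sets and ungapped
seed-and-extend scoring along shared diagonals.  Keeping one implementation
makes the searches deterministic and auditable against exhaustive-offset
oracles in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import revcomp


def forward_kmers(seq: str, k: int) -> set[str]:
    """Set of forward-strand k-mers, skipping any window containing 'N'."""
    return {
        seq[i:i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    }


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Strand-canonical k-mers: min(kmer, revcomp(kmer)) per window."""
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" in w:
            continue
        out.add(min(w, revcomp(w)))
    return out


def shared_kmer_score(a: set[str], b: set[str]) -> float:
    """Shared-k-mer similarity: |a & b| normalised by the smaller set.

    1.0 for identical sequences, ~0 for unrelated ones.
    """
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def matches_at_offset(query: str, subject: str, offset: int) -> tuple[int, int]:
    """(matches, overlap_len) of an ungapped superposition.

    ``offset`` is the subject coordinate under query position 0 (may be
    negative).  'N' never matches anything.
    """
    q, s = _as_array(query), _as_array(subject)
    q_start = max(0, -offset)
    s_start = max(0, offset)
    overlap = min(len(q) - q_start, len(s) - s_start)
    if overlap <= 0:
        return 0, 0
    qa = q[q_start:q_start + overlap]
    sa = s[s_start:s_start + overlap]
    eq = (qa == sa) & (qa != ord("N"))
    return int(eq.sum()), int(overlap)


def seed_offsets(query: str, subject: str, seed_k: int) -> list[int]:
    """Candidate ungapped offsets supported by >=1 shared forward k-mer."""
    if len(query) < seed_k or len(subject) < seed_k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - seed_k + 1):
        w = subject[i:i + seed_k]
        if "N" not in w:
            index.setdefault(w, []).append(i)
    offsets: set[int] = set()
    for i in range(len(query) - seed_k + 1):
        w = query[i:i + seed_k]
        for j in index.get(w, ()):
            offsets.add(j - i)
    return sorted(offsets)


@dataclass(frozen=True)
class UngappedHit:
    """Best ungapped superposition of a query on a subject."""

    offset: int
    matches: int
    overlap: int

    @property
    def identity(self) -> float:
        return self.matches / self.overlap if self.overlap else 0.0


def best_ungapped_hit(query: str, subject: str, seed_k: int) -> UngappedHit | None:
    """Seed-and-extend: best full-overlap superposition among seeded diagonals.

    Returns None when the sequences share no seed k-mer (no detectable
    similarity).  Ties in match count are broken toward the smallest offset.
    """
    best: UngappedHit | None = None
    for off in seed_offsets(query, subject, seed_k):
        m, ov = matches_at_offset(query, subject, off)
        if best is None or m > best.matches:
            best = UngappedHit(off, m, ov)
    return best


@dataclass(frozen=True)
class LocalSegment:
    """Best-scoring ungapped local segment between two sequences."""

    query_start: int
    subject_start: int
    length: int
    matches: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def best_local_segment(
    query: str, subject: str, seed_k: int, match: int = 1, mismatch: int = -1
) -> LocalSegment | None:
    """Best ungapped local alignment restricted to seeded diagonals.

    Along each candidate diagonal a 1-D maximal-scoring-segment scan (local
    alignment with +1/-1 scoring, no gaps) finds the best segment; the best
    segment over all diagonals is returned, ties broken toward smaller
    (query_start, subject_start).
    """
    best: LocalSegment | None = None
    best_score = 0
    for off in seed_offsets(query, subject, seed_k):
        q_start = max(0, -off)
        s_start = max(0, off)
        overlap = min(len(query) - q_start, len(subject) - s_start)
        if overlap <= 0:
            continue
        qa = _as_array(query)[q_start:q_start + overlap]
        sa = _as_array(subject)[s_start:s_start + overlap]
        eq = (qa == sa) & (qa != ord("N"))
        # Kadane scan over +match/-mismatch scores.
        score = 0
        seg_start = 0
        seg_matches = 0
        for i in range(overlap):
            gain = match if eq[i] else mismatch
            if score <= 0:
                score = 0
                seg_start = i
                seg_matches = 0
            score += gain
            if eq[i]:
                seg_matches += 1
            if score > best_score or (
                best is not None
                and score == best_score
                and (q_start + seg_start, s_start + seg_start)
                < (best.query_start, best.subject_start)
            ):
                best_score = score
                best = LocalSegment(
                    q_start + seg_start,
                    s_start + seg_start,
                    i - seg_start + 1,
                    seg_matches,
                )
    return best
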