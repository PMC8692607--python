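"""Independent oracles used by the test suite.

These deliberately re-derive results through different algorithms (exhaustive
scans, correlation arithmetic, naive loops) than the library code paths they
check.
"""

from __future__ import annotations

import numpy as np


def brute_force_filter_check(
    member_rows: dict[str, str],
    exon_intervals: list[tuple[int, int]],
    focal: set[str] | None,
    min_presence: int,
    min_exon_len: int,
    min_snp_density: float,
) -> list[str]:
    """Naive re-check of the three locus filters; returns failure reasons."""
    reasons = []
    present = [sp for sp in member_rows if focal is None or sp in focal]
    if len(present) < min_presence:
        reasons.append("absent_species")
    internal = exon_intervals[1:-1]
    if any((e - s) < min_exon_len for s, e in internal):
        reasons.append("short_internal_exon")
    rows = list(member_rows.values())
    length = len(rows[0])
    poly = 0
    for i in range(length):
        seen = set()
        for row in rows:
            if row[i] in "ACGT":
                seen.add(row[i])
        if len(seen) >= 2:
            poly += 1
    if 1000.0 * poly / length < min_snp_density:
        reasons.append("low_snp_density")
    return sorted(reasons)


def _onehot(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.stack([(arr == ord(c)).astype(float) for c in "ACGT"])


def allpair_match_counts(a: str, b: str) -> np.ndarray:
    """Match counts of a vs b at every ungapped offset, via cross-correlation
    of one-hot channels.  Entry j corresponds to offset j - (len(b) - 1)."""
    oa, ob = _onehot(a), _onehot(b)
    return sum(np.correlate(oa[c], ob[c], mode="full") for c in range(4))


def oracle_redundant(a: str, b: str, identity: float, coverage: float) -> bool:
    """Exhaustive all-offsets redundancy oracle (correlation arithmetic)."""
    assert len(a) == len(b)
    B = len(a)
    counts = allpair_match_counts(b, a)  # entry j: offset j - (B-1) of a on b
    min_overlap = int(np.ceil(coverage * B))
    for j, m in enumerate(counts):
        off = j - (B - 1)
        overlap = B - abs(off)
        if overlap >= min_overlap and m / overlap > identity:
            return True
    return False


def exhaustive_best_offset(query: str, subject: str) -> tuple[int, int, int]:
    """All-offsets ungapped scan: (offset, matches, overlap) with most matches."""
    best = (0, -1, 0)
    for off in range(-(len(query) - 1), len(subject)):
        q0, s0 = max(0, -off), max(0, off)
        ov = min(len(query) - q0, len(subject) - s0)
        if ov <= 0:
            continue
        m = sum(1 for i in range(ov) if query[q0 + i] == subject[s0 + i])
        if m > best[1]:
            best = (off, m, ov)
    return best


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
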