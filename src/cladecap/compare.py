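"""Cross-panel comparison: shared loci and target-length surplus.

Two bait panels' target files are compared locus-by-locus with the shared
seed-and-extend local aligner.  A pair of loci overlaps when the best ungapped
local segment spans more than ``min_overlap_frac`` of the shorter target at
identity >= ``min_identity``; each locus of panel A reports at most its best
partner in panel B.  The surplus is the signed target-length difference
(len_a - len_b) summed over overlapping loci — the extra sequence a
clade-specific panel targets relative to a universal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .kmer import best_local_segment
from .seqio import read_fasta


@dataclass(frozen=True)
class PanelOverlapRecord:
    locus_a: str
    locus_b: str
    overlap_len: int
    overlap_frac: float  # of the shorter target
    identity: float
    surplus_bases: int  # len_a - len_b, signed


def load_panel_targets(path: str | Path) -> dict[str, str]:
    """Read a panel target FASTA into {locus -> representative sequence}.

    Headers of the form ``<Species>-<locus>`` group by locus (the longest
    reference represents the locus); any other header is its own locus id.
    """
    panel: dict[str, str] = {}
    for rec in read_fasta(path):
        locus = rec.id.split("-", 1)[1] if rec.id.count("-") == 1 else rec.id
        if locus not in panel or len(rec.seq) > len(panel[locus]):
            panel[locus] = rec.seq
    return panel


def find_overlaps(
    panel_a: Mapping[str, str] | str | Path,
    panel_b: Mapping[str, str] | str | Path,
    min_overlap_frac: float = 0.05,
    min_identity: float = 0.70,
    seed_k: int = 16,
) -> list[PanelOverlapRecord]:
    """Best overlapping partner in panel B for each locus of panel A.

    The overlap fraction denominator is the shorter target length; the
    identity floor keeps unrelated loci from "overlapping" by chance.  Ties
    break toward the lexicographically first partner.
    """
    if isinstance(panel_a, (str, Path)):
        panel_a = load_panel_targets(panel_a)
    if isinstance(panel_b, (str, Path)):
        panel_b = load_panel_targets(panel_b)
    records = []
    for locus_a in sorted(panel_a):
        seq_a = panel_a[locus_a]
        best = None  # (-matches, locus_b, segment)
        for locus_b in sorted(panel_b):
            seg = best_local_segment(seq_a, panel_b[locus_b], seed_k)
            if seg is None:
                continue
            key = (-seg.matches, locus_b)
            if best is None or key < best[:2]:
                best = (key[0], locus_b, seg)
        if best is None:
            continue
        _, locus_b, seg = best
        seq_b = panel_b[locus_b]
        frac = seg.length / min(len(seq_a), len(seq_b))
        if frac > min_overlap_frac and seg.identity >= min_identity:
            records.append(
                PanelOverlapRecord(
                    locus_a,
                    locus_b,
                    seg.length,
                    frac,
                    seg.identity,
                    len(seq_a) - len(seq_b),
                )
            )
    return records


def surplus_summary(records: Sequence[PanelOverlapRecord]) -> tuple[int, int]:
    """(total surplus bases, mean surplus per overlapping locus).

    Signed semantics: a panel-B locus longer than its panel-A partner
    contributes negatively.  The mean is rounded to the nearest integer.
    """
    if not records:
        raise ValueError("no overlap records to summarise")
    total = sum(r.surplus_bases for r in records)
    return total, round(total / len(records))
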