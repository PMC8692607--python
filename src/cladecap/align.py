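"""Pairwise and star multiple alignment used for exon-boundary transfer.

Pairwise global alignment uses fixed scoring constants match=+1, mismatch=-1,
linear gap=-2 (documented, deterministic: the first optimal trace is taken).
The multiple alignment is a star alignment centred on the annotated reference:
each member is aligned to the centre pairwise and the pairwise alignments are
merged through centre coordinates, taking the maximum insertion length per
inter-centre slot.  Insertions from different members in the same slot are
left-justified against each other.  'N' is scored as 'A' during alignment
(transcript 'N's are rare and never produce baits), the emitted rows keep the
original characters.
"""

from __future__ import annotations

import numpy as np
import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .seqio import GAP, MultipleAlignment

_ALPH = _bseq.NucleotideSequence.alphabet_unamb
_MATRIX = _balign.SubstitutionMatrix(
    _ALPH, _ALPH, np.where(np.eye(4, dtype=bool), 1, -1).astype(np.int32)
)
GAP_PENALTY = -2


def pairwise_global(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two sequences; returns the gapped pair."""
    sa = _bseq.NucleotideSequence(a.replace("N", "A"))
    sb = _bseq.NucleotideSequence(b.replace("N", "A"))
    aln = _balign.align_optimal(
        sa, sb, _MATRIX, gap_penalty=GAP_PENALTY, terminal_penalty=True, local=False
    )[0]
    ga, gb = [], []
    for ia, ib in aln.trace:
        ga.append(a[ia] if ia >= 0 else GAP)
        gb.append(b[ib] if ib >= 0 else GAP)
    return "".join(ga), "".join(gb)


def _against_center(center: str, member: str) -> tuple[list[str], list[str]]:
    """Decompose a pairwise alignment into centre-anchored parts.

    Returns (at, ins): ``at[p]`` is the member character aligned to centre
    position p ('-' for a deletion), ``ins[p]`` the member bases inserted
    before centre position p (``ins[len(center)]`` holds trailing insertions).
    """
    gc, gm = pairwise_global(center, member)
    n = len(center)
    at = [GAP] * n
    ins = [""] * (n + 1)
    p = 0
    for cc, mc in zip(gc, gm):
        if cc == GAP:
            if mc != GAP:
                ins[p] += mc
        else:
            at[p] = mc
            p += 1
    return at, ins


def star_align(
    center_id: str, center: str, members: list[tuple[str, str]]
) -> tuple[MultipleAlignment, list[int]]:
    """Star alignment of ``members`` around ``center``.

    Returns the alignment (centre row first, members in given order) and the
    column index of each centre position.
    """
    parts = [(_against_center(center, seq)) for _, seq in members]
    n = len(center)
    ins_len = [0] * (n + 1)
    for _, ins in parts:
        for p in range(n + 1):
            ins_len[p] = max(ins_len[p], len(ins[p]))

    def build(at: list[str], ins: list[str]) -> str:
        out = []
        for p in range(n):
            out.append(ins[p].ljust(ins_len[p], GAP))
            out.append(at[p])
        out.append(ins[n].ljust(ins_len[n], GAP))
        return "".join(out)

    center_row = build(list(center), [""] * (n + 1))
    rows = [(center_id, center_row)]
    for (name, _), (at, ins) in zip(members, parts):
        rows.append((name, build(at, ins)))

    colmap = []
    col = 0
    for p in range(n):
        col += ins_len[p]
        colmap.append(col)
        col += 1
    return MultipleAlignment(rows), colmap


def consensus(alignment: MultipleAlignment, exclude: set[str] | None = None) -> str:
    """Ungapped per-column majority consensus over {A,C,G,T}.

    Gaps and 'N' never vote; ties break toward the alphabetically first base;
    columns with no voting base are skipped.
    """
    exclude = exclude or set()
    rows = [g for n, g in alignment.rows if n not in exclude]
    out = []
    for i in range(alignment.length):
        counts: dict[str, int] = {}
        for g in rows:
            c = g[i]
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if counts:
            out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)
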