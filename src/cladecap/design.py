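"""Tiled RNA-bait panel design with blacklist, complexity, GC/Tm and redundancy screens.

Baits are 80-mers (configurable) tiled per exon at roughly one-third bait
length spacing ("3x tiling"), constrained within single exons so that probes
never span introns in genomic DNA.  Baits are emitted from every source
species' sequence (a multi-reference panel); cross-species duplicates collapse
in the redundancy screen.

Screens run in a fixed order — low-complexity, blacklist, GC/Tm, redundancy —
and every dropped bait is recorded with its reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .kmer import canonical_kmers, forward_kmers, matches_at_offset
from .seqio import GAP, SequenceRecord, ValidationError, write_fasta
from .select import LocusCandidate

logger = logging.getLogger(__name__)

DROP_REASONS = ("low_complexity", "blacklist", "gc", "tm", "redundant")


@dataclass(frozen=True)
class DesignParams:
    """Tunable thresholds of the bait-design stage.

    ``tm_max`` is disabled by default: the melting temperature computed by the
    basic long-oligo formula is not on the same scale as vendor hybridisation
    models, so the GC ceiling (``gc_max``) is the active high-Tm screen and a
    Tm cutoff is opt-in.
    """

    bait_len: int = 80
    tiling_depth: float = 3.0
    blacklist_k: int = 24
    redundancy_identity: float = 0.95
    redundancy_coverage: float = 0.83
    gc_max: float = 75.0
    tm_max: float | None = None
    low_complexity_max_period: int = 6
    low_complexity_min_span: float = 0.60

    def __post_init__(self):
        if not 0 < self.tiling_depth <= self.bait_len:
            raise ValidationError("tiling_depth must be in (0, bait_len]")
        for f in (self.redundancy_identity, self.redundancy_coverage,
                  self.low_complexity_min_span):
            if not 0 < f <= 1:
                raise ValidationError("fractional thresholds must be in (0, 1]")
        if self.blacklist_k > self.bait_len:
            raise ValidationError("blacklist_k cannot exceed bait_len")

    @property
    def tile_step(self) -> int:
        return round(self.bait_len / self.tiling_depth)

    @property
    def min_redundant_overlap(self) -> int:
        return math.ceil(self.redundancy_coverage * self.bait_len)


@dataclass(frozen=True)
class Bait:
    """An 80-mer probe with provenance and composition statistics."""

    bait_id: str
    locus_id: str
    source_species: str
    exon_index: int
    start: int  # offset within the (ungapped) exon, 0-based
    seq: str
    gc_pct: float
    tm_c: float


@dataclass
class BaitPanel:
    """The filtered panel: retained baits, per-exon manifest, dropped-bait ledger."""

    baits: list[Bait]
    manifest: pd.DataFrame   # locus_id, source_species, exon_index, exon_len, n_tiled, n_kept, depth
    dropped: pd.DataFrame    # bait_id, reason

    @property
    def n_baits(self) -> int:
        return len(self.baits)

    def locus_counts(self) -> pd.Series:
        return pd.Series([b.locus_id for b in self.baits]).value_counts().sort_index()

    def to_fasta(self, path) -> None:
        records = [
            SequenceRecord(
                b.bait_id,
                b.seq,
                f"locus={b.locus_id} exon={b.exon_index} start={b.start} "
                f"gc={b.gc_pct:.1f} tm={b.tm_c:.2f}",
            )
            for b in self.baits
        ]
        write_fasta(records, path)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_exon(exon_len: int, params: DesignParams = DesignParams()) -> list[int]:
    """Bait start offsets tiling one exon.

    A ladder at step ``round(B/d)`` runs while start <= E-B; when the ladder
    does not end flush with the exon, one extra bait is appended at E-B so
    that every exon position is covered.  Exons shorter than one bait receive
    no baits.
    """
    B = params.bait_len
    if exon_len < B:
        logger.debug("exon of %d bp shorter than bait length %d: no baits", exon_len, B)
        return []
    step = params.tile_step
    starts = list(range(0, exon_len - B + 1, step))
    if starts[-1] < exon_len - B:
        starts.append(exon_len - B)
    return starts


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def compute_gc(seq: str) -> float:
    """GC percentage of an unambiguous nucleotide string."""
    if set(seq) - set("ACGT"):
        raise ValidationError("GC computation requires an unambiguous A/C/G/T sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def compute_tm(seq: str) -> float:
    """Melting temperature by the basic long-oligo formula:
    Tm = 81.5 + 0.41*GC% - 675/length."""
    gc = compute_gc(seq)
    return 81.5 + 0.41 * gc - 675.0 / len(seq)


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def build_blacklist_index(records: Iterable[SequenceRecord], k: int) -> frozenset:
    """Canonical k-mer set of the blacklist (both strands collapse)."""
    idx: set[str] = set()
    for rec in records:
        idx |= canonical_kmers(rec.seq, k)
    return frozenset(idx)


def screen_blacklist(bait_seq: str, blacklist_index: frozenset, k: int) -> bool:
    """True (pass) iff the bait shares no canonical k-mer with the blacklist."""
    if k > len(bait_seq):
        raise ValidationError("blacklist k-mer longer than bait")
    return canonical_kmers(bait_seq, k).isdisjoint(blacklist_index)


def is_low_complexity(seq: str, params: DesignParams = DesignParams()) -> bool:
    """True iff an exact tandem repeat of period <= ``low_complexity_max_period``
    spans at least ``low_complexity_min_span`` of the sequence."""
    n = len(seq)
    threshold = params.low_complexity_min_span * n
    for p in range(1, params.low_complexity_max_period + 1):
        run = 0
        best = 0
        for i in range(p, n):
            if seq[i] == seq[i - p]:
                run += 1
                best = max(best, run)
            else:
                run = 0
        if best and best + p >= threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# Redundancy
# ---------------------------------------------------------------------------

def is_redundant_pair(a: str, b: str, params: DesignParams = DesignParams()) -> bool:
    """Two baits are redundant iff at some ungapped relative offset the
    overlap is >= ceil(coverage*B) bases with identity strictly above
    ``redundancy_identity`` over the overlap."""
    B = params.bait_len
    max_shift = B - params.min_redundant_overlap
    for off in range(-max_shift, max_shift + 1):
        m, ov = matches_at_offset(a, b, off)
        if ov >= params.min_redundant_overlap and m / ov > params.redundancy_identity:
            return True
    return False


def dedupe_baits(
    baits: Sequence[Bait], params: DesignParams = DesignParams()
) -> tuple[list[Bait], list[Bait]]:
    """Greedy first-kept-wins redundancy clustering in canonical bait order.

    Baits are visited sorted by (locus, exon, start, species); a bait is kept
    iff it is not redundant with any already-kept bait.  A shared-16-mer
    prescreen makes the pass fast: any redundant pair (>=67-base overlap with
    <=5% mismatches) necessarily shares an exact 16-mer, so the exhaustive
    offset scan only runs on prescreened candidates.
    """
    order = sorted(
        baits, key=lambda b: (b.locus_id, b.exon_index, b.start, b.source_species)
    )
    prescreen_k = 16
    kept: list[Bait] = []
    dropped: list[Bait] = []
    index: dict[str, set[int]] = {}
    for bait in order:
        kms = forward_kmers(bait.seq, prescreen_k)
        candidates = sorted(set().union(*(index.get(k, set()) for k in kms)) if kms else set())
        redundant = any(
            is_redundant_pair(bait.seq, kept[i].seq, params) for i in candidates
        )
        if redundant:
            dropped.append(bait)
        else:
            pos = len(kept)
            kept.append(bait)
            for k in kms:
                index.setdefault(k, set()).add(pos)
    return kept, dropped


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def _exon_sequences(candidate: LocusCandidate) -> list[tuple[str, int, str]]:
    """(species, exon_index, ungapped exon sequence) for every member/exon."""
    out = []
    for sp, row in candidate.alignment.rows:
        for idx, (s, e) in enumerate(candidate.exon_map.intervals):
            out.append((sp, idx, row[s:e].replace(GAP, "")))
    return out


def build_panel(
    kept_loci: Sequence[LocusCandidate],
    blacklist: Sequence[SequenceRecord] = (),
    params: DesignParams = DesignParams(),
) -> BaitPanel:
    """Design the filtered bait panel from kept loci.

    Per locus and per source species every exon of at least one bait length is
    tiled; candidate baits then pass through the screens in order
    low-complexity -> blacklist -> GC/Tm -> redundancy.  Windows containing
    'N' are never emitted.  The manifest reports, per (locus, species, exon),
    the average retained tiling depth = sum of retained bait lengths / exon
    length.
    """
    B = params.bait_len
    bl_index = build_blacklist_index(blacklist, params.blacklist_k)
    candidates: list[Bait] = []
    tiled_counts: dict[tuple[str, str, int], tuple[int, int]] = {}
    for cand in sorted(kept_loci, key=lambda c: c.locus_id):
        if cand.alignment is None or cand.exon_map is None:
            raise ValidationError(f"locus {cand.locus_id} lacks alignment or exon map")
        any_exon = False
        for sp, idx, exon_seq in _exon_sequences(cand):
            starts = tile_exon(len(exon_seq), params)
            n_tiled = 0
            for start in starts:
                window = exon_seq[start:start + B]
                if "N" in window:
                    logger.debug("skipping ambiguous window %s/%s e%d@%d",
                                 cand.locus_id, sp, idx, start)
                    continue
                n_tiled += 1
                candidates.append(
                    Bait(
                        f"{cand.locus_id}_{sp}_e{idx}_{start:05d}",
                        cand.locus_id, sp, idx, start, window,
                        compute_gc(window), compute_tm(window),
                    )
                )
            tiled_counts[(cand.locus_id, sp, idx)] = (len(exon_seq), n_tiled)
            any_exon = any_exon or bool(starts)
        if not any_exon:
            logger.warning("locus %s has no exon >= %d bp: zero baits", cand.locus_id, B)

    survivors: list[Bait] = []
    drops: list[tuple[str, str]] = []
    for bait in candidates:
        if is_low_complexity(bait.seq, params):
            drops.append((bait.bait_id, "low_complexity"))
        elif bl_index and not screen_blacklist(bait.seq, bl_index, params.blacklist_k):
            drops.append((bait.bait_id, "blacklist"))
        elif bait.gc_pct > params.gc_max:
            drops.append((bait.bait_id, "gc"))
        elif params.tm_max is not None and bait.tm_c > params.tm_max:
            drops.append((bait.bait_id, "tm"))
        else:
            survivors.append(bait)

    kept, redundant = dedupe_baits(survivors, params)
    drops.extend((b.bait_id, "redundant") for b in redundant)
    kept = sorted(kept, key=lambda b: (b.locus_id, b.exon_index, b.start, b.source_species))

    kept_by_exon: dict[tuple[str, str, int], int] = {}
    for b in kept:
        key = (b.locus_id, b.source_species, b.exon_index)
        kept_by_exon[key] = kept_by_exon.get(key, 0) + 1
    manifest_rows = []
    for (locus, sp, idx), (exon_len, n_tiled) in sorted(tiled_counts.items()):
        n_kept = kept_by_exon.get((locus, sp, idx), 0)
        manifest_rows.append(
            {
                "locus_id": locus,
                "source_species": sp,
                "exon_index": idx,
                "exon_len": exon_len,
                "n_tiled": n_tiled,
                "n_kept": n_kept,
                "depth": (n_kept * B / exon_len) if exon_len else 0.0,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    dropped = pd.DataFrame(sorted(drops), columns=["bait_id", "reason"])
    return BaitPanel(kept, manifest, dropped)


def target_references(kept_loci: Sequence[LocusCandidate]) -> dict[str, dict[str, str]]:
    """{locus -> {species -> ungapped trimmed sequence}} for the target file."""
    out: dict[str, dict[str, str]] = {}
    for cand in sorted(kept_loci, key=lambda c: c.locus_id):
        out[cand.locus_id] = {
            sp: row.replace(GAP, "") for sp, row in cand.alignment.rows
        }
    return out
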