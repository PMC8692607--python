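"""Capture-experiment evaluation: read mapping, recovery statistics, paralog flags.

Reads are assigned to panel reference sequences by a deterministic
seed-and-extend pseudo-mapper (shared 31-mer seeds, ungapped extension, best
hit only).  Each read is counted once, but the per-locus figure is the maximum
count across that locus's reference species — multi-reference panels map the
same locus independently against each source transcriptome and report the best.
Per-locus read coverage is count * read length / reference locus length, the
reference being the species that yielded the maximum count.

Assembly itself is out of scope: assembled per-sample, per-locus sequences are
inputs (from an external assembler or from the simulator's truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .kmer import matches_at_offset
from .seqio import ReadSet, SequenceRecord, ValidationError, read_target_file, revcomp

#: k-mers occurring more often than this in the reference index are skipped
#: as seeds (repeat masking for seeding only; extension still sees them).
_MAX_KMER_HITS = 20
_MAX_CANDIDATES = 50


@dataclass
class MappingResult:
    """Per-reference and per-locus read counts for one sample."""

    per_reference: dict[tuple[str, str], int]  # (locus, species) -> reads
    ref_lens: dict[tuple[str, str], int]
    total_reads: int
    mapped_reads: int

    def locus_count(self, locus: str) -> int:
        counts = [c for (l, _), c in self.per_reference.items() if l == locus]
        return max(counts, default=0)

    def locus_counts(self) -> dict[str, int]:
        loci = sorted({l for l, _ in self.per_reference})
        return {l: self.locus_count(l) for l in loci}

    def locus_ref_len(self, locus: str) -> int:
        """Length of the reference yielding the maximum count (ties: the
        lexicographically first species)."""
        sps = sorted(sp for (l, sp) in self.per_reference if l == locus)
        if not sps:
            raise KeyError(locus)
        best_sp = min(sps, key=lambda sp: (-self.per_reference[(locus, sp)], sp))
        return self.ref_lens[(locus, best_sp)]


def map_reads(
    reads: ReadSet | Sequence[SequenceRecord],
    targets: Mapping[str, Mapping[str, str]] | str | Path,
    seed_k: int = 31,
    min_identity: float = 0.90,
    min_span: int = 100,
) -> MappingResult:
    """Assign each read to at most one (locus, reference) by seed-and-extend.

    A read maps to the reference maximising ungapped extended identity from a
    shared ``seed_k``-mer (both strands); the hit must span at least
    ``min_span`` bases at identity >= ``min_identity``.  Ties break toward the
    lexicographically first reference id.  Reads sharing no seed with any
    reference are off-target.
    """
    if isinstance(targets, (str, Path)):
        targets = read_target_file(targets)
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)
    if read_list and len(read_list[0].seq) < seed_k:
        raise ValidationError(f"reads shorter than seed length {seed_k}")

    refs: dict[str, tuple[str, str, str]] = {}  # ref_id -> (locus, species, seq)
    for locus in sorted(targets):
        for sp in sorted(targets[locus]):
            refs[f"{sp}-{locus}"] = (locus, sp, targets[locus][sp])
    index: dict[str, list[tuple[str, int]]] = {}
    for ref_id, (_, _, seq) in refs.items():
        for i in range(len(seq) - seed_k + 1):
            w = seq[i:i + seed_k]
            if "N" not in w:
                index.setdefault(w, []).append((ref_id, i))

    per_reference = {
        (locus, sp): 0 for locus, sps in targets.items() for sp in sps
    }
    ref_lens = {
        (locus, sp): len(seq) for locus, sps in targets.items() for sp, seq in sps.items()
    }
    mapped = 0
    for read in read_list:
        best = None  # (-matches, ref_id, offset)
        for oriented in (read.seq, revcomp(read.seq)):
            candidates = set()
            for i in range(len(oriented) - seed_k + 1):
                hits = index.get(oriented[i:i + seed_k])
                if hits is None or len(hits) > _MAX_KMER_HITS:
                    continue
                for ref_id, pos in hits:
                    candidates.add((ref_id, pos - i))
                if len(candidates) >= _MAX_CANDIDATES:
                    break
            for ref_id, offset in sorted(candidates):
                seq = refs[ref_id][2]
                m, ov = matches_at_offset(oriented, seq, offset)
                if ov < min(min_span, len(oriented)) or m / ov < min_identity:
                    continue
                key = (-m, ref_id, offset)
                if best is None or key < best:
                    best = key
        if best is not None:
            locus, sp, _ = refs[best[1]]
            per_reference[(locus, sp)] += 1
            mapped += 1
    return MappingResult(per_reference, ref_lens, len(read_list), mapped)


def pct_on_target(reads_mapped: int, reads_total: int) -> float:
    """On-target percentage, reported to one decimal."""
    if reads_total <= 0:
        raise ValidationError("reads_total must be positive")
    return round(100.0 * reads_mapped / reads_total, 1)


def locus_coverage(locus_count: int, read_len: int, locus_ref_len: int) -> float:
    """Read coverage: reads x read length / reference locus length."""
    if locus_ref_len <= 0:
        raise ValidationError("reference locus length must be positive")
    return locus_count * read_len / locus_ref_len


@dataclass
class SampleCaptureStats:
    """Per-sample capture statistics (one summary-table row)."""

    sample: str
    reads_after_trimming: int
    reads_mapped: int
    pct_on_target: float
    total_assembled_target_len: int
    loci_with_sequence: int
    pct_target_recovered: float
    coverage: dict[str, float] | None = None  # locus -> x


@dataclass
class ParalogFlag:
    """Flag raised when >=2 contigs each cover most of the reference locus."""

    sample: str
    locus: str
    n_competing_contigs: int
    coverage_fractions: tuple[float, ...]


def _reference_lengths(targets: Mapping[str, Mapping[str, str]]) -> dict[str, int]:
    """Per-locus reference target length: the longest reference among the
    panel's source species."""
    return {locus: max(len(s) for s in sps.values()) for locus, sps in targets.items()}


def recovery_stats(
    assemblies: Mapping[str, Mapping[str, Sequence[SequenceRecord]]],
    targets: Mapping[str, Mapping[str, str]] | str | Path,
) -> tuple[dict[str, dict], pd.DataFrame]:
    """Recovery statistics and the loci x samples recovery matrix.

    ``assemblies`` maps sample -> locus -> contigs; a locus's assembled length
    is the length of its longest contig (the assembler's chosen sequence).
    Matrix entries are assembled length / reference target length and may
    exceed 1.0 when extra exon sequence was assembled; such entries are kept
    (the caller can flag entries above any excess threshold).
    """
    if isinstance(targets, (str, Path)):
        targets = read_target_file(targets)
    ref_lens = _reference_lengths(targets)
    loci = sorted(ref_lens)
    total_ref = sum(ref_lens.values())
    samples = list(assemblies)
    matrix = pd.DataFrame(0.0, index=loci, columns=samples)
    per_sample: dict[str, dict] = {}
    for sample in samples:
        total_assembled = 0
        n_with_seq = 0
        for locus, contigs in assemblies[sample].items():
            if locus not in ref_lens:
                raise ValidationError(f"assembly for unknown locus {locus!r}")
            length = max((len(c) for c in contigs), default=0)
            if length > 0:
                n_with_seq += 1
            total_assembled += length
            matrix.loc[locus, sample] = length / ref_lens[locus]
        per_sample[sample] = {
            "total_assembled_target_len": total_assembled,
            "loci_with_sequence": n_with_seq,
            "pct_target_recovered": round(100.0 * total_assembled / total_ref, 1),
        }
    return per_sample, matrix


def flag_paralogs(
    assemblies: Mapping[str, Mapping[str, Sequence[SequenceRecord]]],
    targets: Mapping[str, Mapping[str, str]] | str | Path,
    paralog_min_frac: float = 0.85,
) -> list[ParalogFlag]:
    """Flag (sample, locus) pairs where >=2 contigs each cover at least
    ``paralog_min_frac`` of the reference locus length."""
    if isinstance(targets, (str, Path)):
        targets = read_target_file(targets)
    ref_lens = _reference_lengths(targets)
    flags = []
    for sample in sorted(assemblies):
        for locus in sorted(assemblies[sample]):
            if locus not in ref_lens:
                raise ValidationError(f"assembly for unknown locus {locus!r}")
            fracs = tuple(
                len(c) / ref_lens[locus] for c in assemblies[sample][locus]
            )
            competing = [f for f in fracs if f >= paralog_min_frac]
            if len(competing) >= 2:
                flags.append(ParalogFlag(sample, locus, len(competing), fracs))
    return flags


def evaluate_sample(
    sample: str,
    reads: ReadSet | Sequence[SequenceRecord],
    targets: Mapping[str, Mapping[str, str]] | str | Path,
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    read_len: int,
) -> SampleCaptureStats:
    """Full per-sample evaluation: mapping, on-target fraction, per-locus
    coverage and recovery."""
    if isinstance(targets, (str, Path)):
        targets = read_target_file(targets)
    mapping = map_reads(reads, targets)
    recovery, _ = recovery_stats({sample: assemblies}, targets)
    coverage = {
        locus: locus_coverage(count, read_len, mapping.locus_ref_len(locus))
        for locus, count in mapping.locus_counts().items()
    }
    rec = recovery[sample]
    return SampleCaptureStats(
        sample=sample,
        reads_after_trimming=mapping.total_reads,
        reads_mapped=mapping.mapped_reads,
        pct_on_target=pct_on_target(mapping.mapped_reads, mapping.total_reads),
        total_assembled_target_len=rec["total_assembled_target_len"],
        loci_with_sequence=rec["loci_with_sequence"],
        pct_target_recovered=rec["pct_target_recovered"],
        coverage=coverage,
    )


_COUNT_FIELDS = (
    "reads_after_trimming",
    "reads_mapped",
    "total_assembled_target_len",
    "loci_with_sequence",
)
_PCT_FIELDS = ("pct_on_target", "pct_target_recovered")


def summarize_samples(
    stats: Sequence[SampleCaptureStats], group_label: str = "Average"
) -> dict:
    """Arithmetic mean of each numeric column over a sample group.

    Counts are rounded to the nearest integer, percentages to one decimal —
    the convention of published capture summary tables.  Order-invariant.
    """
    if not stats:
        raise ValidationError("cannot summarise an empty sample group")
    n = len(stats)
    row: dict = {"sample": group_label}
    for f in _COUNT_FIELDS:
        row[f] = round(sum(getattr(s, f) for s in stats) / n)
    for f in _PCT_FIELDS:
        row[f] = round(sum(getattr(s, f) for s in stats) / n, 1)
    return row


def stats_table(
    stats: Sequence[SampleCaptureStats],
    average_label: str | None = "Average",
) -> pd.DataFrame:
    """Per-sample statistics as a DataFrame, optionally with a mean row."""
    rows = [
        {
            "sample": s.sample,
            **{f: getattr(s, f) for f in _COUNT_FIELDS},
            **{f: getattr(s, f) for f in _PCT_FIELDS},
        }
        for s in stats
    ]
    if average_label is not None and stats:
        rows.append(summarize_samples(stats, average_label))
    cols = ["sample", "reads_after_trimming", "reads_mapped", "pct_on_target",
            "total_assembled_target_len", "loci_with_sequence", "pct_target_recovered"]
    return pd.DataFrame(rows)[cols]
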