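"""Core sequence types and readers/writers for the plain-text formats the toolkit touches.

All coordinates are 0-based half-open everywhere in the library; conversion (if any)
happens only at file boundaries.  Transcripts are treated as sense-strand: no
reverse-complement handling occurs at ingest — strand is handled only in blacklist
screening and read mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters accepted in input transcripts; 'N' is allowed on read but
#: forbidden in emitted baits (bait extraction skips ambiguous windows).
DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a format invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence.

    ``id`` must be non-empty and unique within a file; ``seq`` is upper-case
    over {A,C,G,T,N}.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.seq:
            raise ValidationError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class MultipleAlignment:
    """A gapped alignment of >=2 named rows of identical column count.

    The gap character is '-'.  Row order is preserved as given.
    """

    def __init__(self, rows: Sequence[tuple[str, str]]):
        rows = list(rows)
        if len(rows) < 2:
            raise ValidationError("alignment needs at least 2 rows")
        length = len(rows[0][1])
        for name, gapped in rows:
            if len(gapped) != length:
                raise ValidationError(
                    f"alignment row {name!r} has length {len(gapped)}, expected {length}"
                )
            bad = set(gapped) - DNA_ALPHABET - {GAP}
            if bad:
                raise ValidationError(f"alignment row {name!r} has bad characters {sorted(bad)}")
        if length == 0:
            raise ValidationError("zero-length alignment")
        names = [n for n, _ in rows]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate row names in alignment")
        self.rows: list[tuple[str, str]] = rows

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [n for n, _ in self.rows]

    def row(self, name: str) -> str:
        for n, g in self.rows:
            if n == name:
                return g
        raise KeyError(name)

    def column(self, i: int) -> list[str]:
        return [g[i] for _, g in self.rows]

    def slice_columns(self, start: int, stop: int) -> "MultipleAlignment":
        return MultipleAlignment([(n, g[start:stop]) for n, g in self.rows])

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class ExonMap:
    """Ordered exon intervals in transcript coordinates, 0-based half-open.

    Intervals are non-overlapping, sorted, and cover the transcript end-to-end
    with no gaps, so interval k ends exactly where interval k+1 begins.
    """

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValidationError("empty exon map")
        prev_end = None
        for start, end in self.intervals:
            if end <= start:
                raise ValidationError(f"exon interval ({start},{end}) has end <= start")
            if prev_end is None:
                if start != 0:
                    raise ValidationError("exon map must start at position 0")
            elif start != prev_end:
                raise ValidationError(
                    f"exon map not contiguous: interval starts at {start}, previous ends {prev_end}"
                )
            prev_end = end

    @property
    def total_length(self) -> int:
        return self.intervals[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.intervals)

    def lengths(self) -> list[int]:
        return [e - s for s, e in self.intervals]

    def internal_lengths(self) -> list[int]:
        """Lengths of mid-locus (non-terminal) exons; empty for <=2 exons."""
        return [e - s for s, e in self.intervals[1:-1]]


@dataclass
class ReadSet:
    """Uniform-length reads, optionally carrying simulator truth labels.

    ``labels[i]`` is the originating locus id of ``reads[i]``, or
    ``"background"``; labels are present iff the set is simulator-generated.
    """

    reads: list[SequenceRecord]
    read_length: int
    labels: list[str] | None = None

    def __post_init__(self):
        for r in self.reads:
            if len(r) != self.read_length:
                raise ValidationError(
                    f"read {r.id!r} has length {len(r)}, expected {self.read_length}"
                )
        if self.labels is not None and len(self.labels) != len(self.reads):
            raise ValidationError("labels/reads length mismatch")

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, upper-casing sequences.

    Duplicate ids and non-nucleotide characters (other than N) are errors, as
    is an empty file.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ file; qualities are ignored (reads are assumed post-trim)."""
    path = Path(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise ValidationError(f"no FASTQ records in {path}")
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write FASTQ with placeholder 'I' qualities."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# Target reference files ("<Species>-<locus>" FASTA dialect)
# ---------------------------------------------------------------------------

def write_target_file(
    panel_loci: Mapping[str, Mapping[str, str]], path: str | Path
) -> None:
    """Write a capture-target reference FASTA, one record per (species, locus).

    ``panel_loci`` maps locus id -> {species -> ungapped sequence}.  Headers use
    the dash-separated ``<Species>-<locusID>`` dialect used by target-capture
    assemblers, so neither species nor locus ids may contain '-'.
    """
    if not panel_loci:
        logger.warning("writing empty target file %s", path)
        open(path, "w").close()
        return
    records = []
    for locus_id in sorted(panel_loci):
        refs = panel_loci[locus_id]
        if "-" in locus_id:
            raise ValidationError(f"locus id {locus_id!r} contains reserved character '-'")
        if not refs:
            raise ValidationError(f"locus {locus_id!r} has no reference sequences")
        for species in sorted(refs):
            if "-" in species:
                raise ValidationError(f"species {species!r} contains reserved character '-'")
            records.append(SequenceRecord(f"{species}-{locus_id}", refs[species]))
    write_fasta(records, path)


def read_target_file(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a ``<Species>-<locus>`` target FASTA into {locus -> {species -> seq}}."""
    out: dict[str, dict[str, str]] = {}
    for rec in read_fasta(path):
        if rec.id.count("-") != 1:
            raise ValidationError(f"target header {rec.id!r} is not '<Species>-<locus>'")
        species, locus = rec.id.split("-")
        out.setdefault(locus, {})[species] = rec.seq
    return out


# ---------------------------------------------------------------------------
# Exon BED (3-column TSV, 0-based half-open)
# ---------------------------------------------------------------------------

def read_exon_bed(
    path: str | Path, transcripts: Mapping[str, SequenceRecord]
) -> dict[str, ExonMap]:
    """Read per-transcript exon intervals and validate them against transcript lengths.

    Intervals are sorted on read; each transcript's intervals must tile the
    transcript end-to-end.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            tid, start, end = parts[0], int(parts[1]), int(parts[2])
            if tid not in transcripts:
                raise ValidationError(f"{path}:{lineno}: unknown transcript {tid!r}")
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
            if end > len(transcripts[tid]):
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} beyond transcript length "
                    f"{len(transcripts[tid])}"
                )
            raw.setdefault(tid, []).append((start, end))
    out: dict[str, ExonMap] = {}
    for tid, ivs in raw.items():
        ivs.sort()
        emap = ExonMap(tuple(ivs))  # raises on overlap / gap / not starting at 0
        if emap.total_length != len(transcripts[tid]):
            raise ValidationError(
                f"exon map for {tid!r} covers {emap.total_length} bases, "
                f"transcript has {len(transcripts[tid])}"
            )
        out[tid] = emap
    return out


def write_exon_bed(maps: Mapping[str, ExonMap], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(maps):
            for start, end in maps[tid].intervals:
                fh.write(f"{tid}\t{start}\t{end}\n")
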