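"""Synthetic congeneric transcriptomes, ground truth, and capture read sets.

The generator emulates the study design the toolkit targets: a handful of
congeneric ingroup transcriptomes plus one subgeneric outgroup, evolved from
random root sequences under Jukes-Cantor substitution along a fixed ultrametric
tree, with controlled adversarial injections (low-SNP loci, short internal
exons, near-identical paralog copies, absence in one focal species, embedded
simple repeats).  Every injection is constructed to be unambiguous: the
emitted ground-truth manifest states the intended filter outcome per locus and
is recomputable from the emitted sequences by a brute-force re-check.

Reads have no error model: the real pipeline consumes quality-trimmed reads,
so simulated reads stand for post-trim reads.  There are no indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .seqio import (
    ExonMap,
    ReadSet,
    SequenceRecord,
    ValidationError,
    revcomp,
    write_exon_bed,
    write_fasta,
    write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TREE = "((AloeA:0.02,AloeB:0.02):0.01,(AloeC:0.02,Outgroup:0.06):0.01);"


def jc_expected_diff(d: float) -> float:
    """Expected fraction of differing sites after branch length ``d``
    (substitutions/site) under Jukes-Cantor: 3/4 (1 - e^(-4d/3))."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    The defaults describe a 3-ingroup + 1-outgroup design with ingroup
    divergences of a few percent, 2-6 exons of 120-400 bp per locus, and
    MiSeq/HiSeq-style uniform read lengths.  ``seed`` is mandatory: every
    source of randomness flows from it.
    """

    seed: int
    tree: str = DEFAULT_TREE
    focal_species: tuple[str, ...] = ("AloeA", "AloeB", "AloeC")
    n_loci: int = 30
    exon_count_range: tuple[int, int] = (2, 6)
    exon_len_range: tuple[int, int] = (120, 400)
    fraction_low_snp: float = 0.15
    fraction_short_internal_exon: float = 0.15
    fraction_with_paralog: float = 0.10
    fraction_absent_in_one_species: float = 0.10
    repeat_injection: float = 0.10
    read_len: int = 150
    n_reads: int = 20000
    on_target_fraction: float = 0.5
    background_len: int = 100_000
    #: divergence of the exon-annotated reference gene from the locus root
    ref_divergence: float = 0.10
    #: polymorphic-column densities (per kb) the injections aim for
    low_snp_density: float = 8.0
    pass_min_density: float = 30.0

    def __post_init__(self):
        fracs = (
            self.fraction_low_snp,
            self.fraction_short_internal_exon,
            self.fraction_with_paralog,
            self.fraction_absent_in_one_species,
            self.repeat_injection,
            self.on_target_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValidationError("all fractions must lie in [0, 1]")
        if (
            self.fraction_low_snp
            + self.fraction_short_internal_exon
            + self.fraction_with_paralog
            + self.fraction_absent_in_one_species
            > 1
        ):
            raise ValidationError("injection fractions must sum to <= 1")
        if self.exon_len_range[0] < 30:
            raise ValidationError("minimum exon length must be >= 30")
        if self.n_loci <= 0 or self.n_reads <= 0 or self.read_len <= 0:
            raise ValidationError("sizes must be positive")


@dataclass
class LocusTruth:
    """Ground truth for one simulated locus."""

    locus_id: str
    klass: str  # pass | low_snp | short_internal_exon | absent | paralog
    intended_pass: bool
    reasons: list[str]
    exon_map: ExonMap
    absent_species: str | None = None
    paralog_species: str | None = None
    repeat_interval: tuple[int, int] | None = None
    n_polymorphic: int = 0


@dataclass
class TruthManifest:
    loci: dict[str, LocusTruth] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "locus_id\tclass\tintended_pass\treasons\texons\t"
                "absent_species\tparalog_species\trepeat_interval\tn_polymorphic\n"
            )
            for lid in sorted(self.loci):
                t = self.loci[lid]
                exons = ",".join(f"{s}:{e}" for s, e in t.exon_map.intervals)
                rep = (
                    f"{t.repeat_interval[0]}:{t.repeat_interval[1]}"
                    if t.repeat_interval
                    else ""
                )
                fh.write(
                    f"{lid}\t{t.klass}\t{int(t.intended_pass)}\t"
                    f"{';'.join(t.reasons)}\t{exons}\t{t.absent_species or ''}\t"
                    f"{t.paralog_species or ''}\t{rep}\t{t.n_polymorphic}\n"
                )


@dataclass
class SimulatedLocusSet:
    """Everything the selection stage needs, plus ground truth."""

    config: SimConfig
    transcript_sets: dict[str, list[SequenceRecord]]
    references: list[SequenceRecord]
    reference_exons: dict[str, ExonMap]
    truth: TruthManifest


# ---------------------------------------------------------------------------
# Jukes-Cantor evolution on a tree
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    if d < 0:
        raise ValidationError("negative branch length")
    p = jc_expected_diff(d)
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValidationError("root sequence must be over {A,C,G,T}")
    return arr


def evolve_on_tree(
    root_seq: str, tree: str | dendropy.Tree, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve a root sequence down a newick tree under Jukes-Cantor.

    Each site mutates along each branch with probability
    3/4 (1 - e^(-4d/3)) to a uniformly random different base; deterministic
    for a given generator state.  Returns {leaf name -> sequence}.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    root = _encode(root_seq)
    leaves: dict[str, str] = {}

    def walk(node, seq):
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            child_seq = _mutate(seq, d, rng)
            if child.is_leaf():
                leaves[child.taxon.label.replace(" ", "_")] = _decode(child_seq)
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root)
    return leaves


# ---------------------------------------------------------------------------
# Locus-set generation
# ---------------------------------------------------------------------------

def _count_polymorphic(members: Mapping[str, np.ndarray]) -> np.ndarray:
    mat = np.stack(list(members.values()))
    return (mat != mat[0]).any(axis=0)


def make_locus_set(config: SimConfig) -> SimulatedLocusSet:
    """Generate per-species transcript sets, annotated references and truth.

    Locus classes are drawn per locus from the configured fractions; the
    remainder are plain passing loci, a configurable fraction of which carry
    an embedded simple repeat (which does not change the filter verdict but
    exercises the bait complexity screen).
    """
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    species = sorted(
        leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()
    )
    for sp in config.focal_species:
        if sp not in species:
            raise ValidationError(f"focal species {sp!r} not a tree leaf")

    classes = ["low_snp", "short_internal_exon", "paralog", "absent"]
    probs = [
        config.fraction_low_snp,
        config.fraction_short_internal_exon,
        config.fraction_with_paralog,
        config.fraction_absent_in_one_species,
    ]
    probs.append(1.0 - sum(probs))
    classes.append("pass")

    transcript_sets: dict[str, list[SequenceRecord]] = {sp: [] for sp in species}
    references: list[SequenceRecord] = []
    reference_exons: dict[str, ExonMap] = {}
    truth = TruthManifest()

    for i in range(config.n_loci):
        locus_id = f"L{i + 1:03d}"
        klass = rng.choice(classes, p=probs)
        lo, hi = config.exon_count_range
        n_exons = int(rng.integers(lo, hi + 1))
        if klass == "short_internal_exon":
            n_exons = max(n_exons, 3)
        lens = rng.integers(
            config.exon_len_range[0], config.exon_len_range[1] + 1, size=n_exons
        )
        # terminal exons are never forced short: only mid-locus exons disqualify
        lens = np.maximum(lens, 80)
        short_idx = None
        if klass == "short_internal_exon":
            short_idx = int(rng.integers(1, n_exons - 1))
            lens[short_idx] = int(rng.integers(30, 80))
        bounds = np.concatenate([[0], np.cumsum(lens)])
        exon_map = ExonMap(tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])))
        L = int(bounds[-1])

        root = rng.integers(0, 4, size=L).astype(np.uint8)
        ref_arr = _mutate(root, config.ref_divergence, rng)

        if klass == "low_snp":
            members = {sp: root.copy() for sp in species}
            m = max(1, round(config.low_snp_density / 1000.0 * L))
            sites = rng.choice(L, size=m, replace=False)
            for s in sites:
                sp = species[int(rng.integers(len(species)))]
                members[sp][s] = (members[sp][s] + rng.integers(1, 4)) % 4
        else:
            evolved = evolve_on_tree(_decode(root), tree, rng)
            members = {sp: _encode(evolved[sp]) for sp in species}

        absent_sp = None
        if klass == "absent":
            absent_sp = config.focal_species[int(rng.integers(len(config.focal_species)))]
            del members[absent_sp]

        repeat_interval = None
        if klass == "pass" and rng.random() < config.repeat_injection:
            span = 60
            eligible = [
                (s, e) for s, e in exon_map.intervals if e - s >= span + 20
            ]
            if eligible:
                s, e = eligible[int(rng.integers(len(eligible)))]
                pos = int(rng.integers(s, e - span + 1))
                motif = _encode("ACG" * (span // 3))
                for sp in members:
                    members[sp][pos:pos + span] = motif
                repeat_interval = (pos, pos + span)

        if klass != "low_snp":
            poly = _count_polymorphic(members)
            target = math.ceil(config.pass_min_density / 1000.0 * L)
            forbidden = np.zeros(L, dtype=bool)
            if repeat_interval:
                forbidden[repeat_interval[0]:repeat_interval[1]] = True
            deficit = target - int(poly.sum())
            if deficit > 0:
                eligible_sites = np.flatnonzero(~poly & ~forbidden)
                sites = rng.choice(eligible_sites, size=deficit, replace=False)
                sps = sorted(members)
                for s in sites:
                    sp = sps[int(rng.integers(len(sps)))]
                    members[sp][s] = (members[sp][s] + rng.integers(1, 4)) % 4

        paralog_sp = None
        if klass == "paralog":
            paralog_sp = config.focal_species[
                int(rng.integers(len(config.focal_species)))
            ]
            extra_d = rng.uniform(0.01, 0.03)  # 97-99% identity: unambiguous flag
            copy = _mutate(members[paralog_sp], extra_d, rng)
            transcript_sets[paralog_sp].append(
                SequenceRecord(f"{locus_id}_2", _decode(copy))
            )

        for sp in members:
            transcript_sets[sp].append(SequenceRecord(f"{locus_id}_1", _decode(members[sp])))
        ref_id = f"{locus_id}_ref"
        references.append(SequenceRecord(ref_id, _decode(ref_arr)))
        reference_exons[ref_id] = exon_map

        if klass in ("pass",):
            intended, reasons = True, []
        elif klass == "low_snp":
            intended, reasons = False, ["low_snp_density"]
        elif klass == "short_internal_exon":
            intended, reasons = False, ["short_internal_exon"]
        elif klass == "absent":
            intended, reasons = False, ["absent_species"]
        else:  # paralog
            intended, reasons = False, ["multi_copy"]
        truth.loci[locus_id] = LocusTruth(
            locus_id,
            str(klass),
            intended,
            reasons,
            exon_map,
            absent_sp,
            paralog_sp,
            repeat_interval,
            int(_count_polymorphic(members).sum()),
        )

    return SimulatedLocusSet(config, transcript_sets, references, reference_exons, truth)


# ---------------------------------------------------------------------------
# Capture reads
# ---------------------------------------------------------------------------

def simulate_reads(
    targets: Mapping[str, Mapping[str, str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Draw uniform-length reads from targets (probability ``on_target_fraction``)
    or from an i.i.d.-uniform background sequence, on both strands, with
    per-read truth labels."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    records = [
        (locus, sp, targets[locus][sp])
        for locus in sorted(targets)
        for sp in sorted(targets[locus])
    ]
    if not records:
        raise ValidationError("no target sequences to draw reads from")
    for locus, sp, seq in records:
        if len(seq) < config.read_len:
            raise ValidationError(
                f"target {sp}-{locus} shorter than read length {config.read_len}"
            )
    background = _decode(
        rng.integers(0, 4, size=config.background_len).astype(np.uint8)
    )
    reads: list[SequenceRecord] = []
    labels: list[str] = []
    for i in range(config.n_reads):
        on_target = rng.random() < config.on_target_fraction
        if on_target:
            locus, sp, seq = records[int(rng.integers(len(records)))]
            label = locus
        else:
            seq, label = background, "background"
        pos = int(rng.integers(0, len(seq) - config.read_len + 1))
        frag = seq[pos:pos + config.read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(SequenceRecord(f"r{i:06d}", frag))
        labels.append(label)
    return ReadSet(reads, config.read_len, labels)


def simulate_assemblies(
    targets: Mapping[str, Mapping[str, str]],
    rng: np.random.Generator,
    full_fraction: float = 0.8,
) -> dict[str, list[SequenceRecord]]:
    """Per-locus 'assembled' sequences standing in for an assembler's output:
    the first reference either full length or truncated to 40-90%."""
    out: dict[str, list[SequenceRecord]] = {}
    for locus in sorted(targets):
        sp = sorted(targets[locus])[0]
        seq = targets[locus][sp]
        if rng.random() >= full_fraction:
            frac = rng.uniform(0.4, 0.9)
            seq = seq[: max(1, int(len(seq) * frac))]
        out[locus] = [SequenceRecord(f"{locus}|c1", seq)]
    return out


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_locus_set(sim: SimulatedLocusSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in sorted(sim.transcript_sets):
        write_fasta(sim.transcript_sets[sp], outdir / f"{sp}.fasta")
    write_fasta(sim.references, outdir / "reference.fasta")
    write_exon_bed(sim.reference_exons, outdir / "reference_exons.bed")
    sim.truth.to_tsv(outdir / "truth_loci.tsv")


def write_reads(readset: ReadSet, outdir: str | Path, stem: str = "reads") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(readset.reads, outdir / f"{stem}.fastq")
    if readset.labels is not None:
        with open(outdir / f"{stem}_labels.tsv", "w") as fh:
            fh.write("read_id\torigin\n")
            for rec, label in zip(readset.reads, readset.labels):
                fh.write(f"{rec.id}\t{label}\n")
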