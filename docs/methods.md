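# Methods

## Scope and model

`cladecap` re-implements, as a self-contained desk-scale toolkit, the workflow
behind clade-specific target-capture panels for low-copy nuclear (LCN) genes:
ortholog selection from a handful of congeneric transcriptome assemblies, bait
tiling and screening, and the downstream capture-experiment accounting.  The
production workflows it abstracts use heavyweight externals (BLAST-based
ortholog classifiers, MAFFT, RepeatMasker, read mappers and assemblers); each
of those steps is replaced here by a small deterministic algorithm with the
same contract, so every stage can be audited against an independent oracle.
The stages are pure functions of their inputs plus explicit parameter
dataclasses; all randomness lives in the simulator and flows from a single
mandatory seed.

## Ortholog detection

Transcripts are compared by **shared canonical k-mer score**: the number of
k-mers (k = 21, both strands collapsed, 'N'-windows skipped) present in both
sequences, normalised by the smaller k-mer set, so identical sequences score
1.0 and unrelated ones ≈ 0.  Groups are connected components of the
reciprocal-best-hit graph across species; ties break by lexicographic
transcript id, which together with sorted iteration makes the clustering
invariant to input file order.  Transcripts with no reciprocal partner become
singleton groups and fail the presence filter later rather than disappearing
silently.

A species' **copy count** is the number of its transcripts whose best
ungapped-extension *identity* against the group's other members is within 95%
of that species' best.  Identity — not the k-mer score — is deliberate: a
k-mer count ratio decays roughly as (1−e)^k per extra substitution, so at
k = 21 a paralog one substitution further diverged than the true ortholog
already falls below 95% of its score and the rule would never fire.  On the
identity scale the rule behaves as intended: a ~1–3%-diverged duplicate is
flagged, an unrelated transcript (sharing no k-mer, scored 0) is not.  Any
copy count ≥ 2 excludes the group from the single-copy set.

## Exon-boundary transfer and trimming

Group members are star-aligned around the annotated reference gene using
pairwise global alignment with fixed scores match +1 / mismatch −1 / linear
gap −2 (first optimal trace taken; 'N' scored as 'A'; insertions from
different members in the same inter-reference slot are left-justified).
Reference exon starts map to the columns of their reference bases; insertion
columns attach to the preceding exon, so an insertion strictly inside an exon
widens that exon.  The reference row is then dropped, reference-only columns
removed, and terminal columns outside the reference span absorbed into the
terminal exons; per-member exon presence records members with no aligned base
in an exon (truncations).  End-trimming keeps the column range between the
first and last column where **every** member is non-gap; a locus with no such
column fails outright.

## Locus filters

A trimmed candidate is kept iff all three hold:

| rule | default | boundary semantics |
|---|---|---|
| focal-species presence | ≥ 3 of the listed ingroup | missing focal species ⇒ `absent_species` |
| internal exon length | ≥ 80 columns (the bait length) | strictly-shorter internal exons fail; **terminal** exons may be short (they simply receive no baits) |
| SNP density | ≥ 20 polymorphic columns / 1,000 columns | a column is polymorphic when ≥ 2 distinct A/C/G/T bases occur; gaps and N never vote; density exactly 20.0 passes |

Reasons accumulate rather than short-circuit, so a rejected locus reports every
rule it broke.  SNP counting is per-column over the trimmed alignment with the
column count as denominator — the simplest auditable reading of a
"SNPs per 1,000 bp" criterion; per-pairwise-difference counting would scale
with taxon sampling and is not used.

The one-species rescue searches the group **consensus** (column majority of
the star alignment, ties to the alphabetically first base) against the missing
species' unclustered transcripts by seed-and-extend ungapped superposition;
the best hit is accepted at identity ≥ 0.80 over ≥ 50% of the consensus.
These floors keep random transcripts out (an unrelated sequence essentially
never shares a 21-mer seed) while admitting genuine orthologs a clustering
pass missed.

## Bait design

Within each exon of length E ≥ B (B = 80), bait starts form a ladder at step
round(B/3) = 27 with a flush bait appended at E−B when the ladder does not end
flush — every exon position is covered and baits never cross exon boundaries
(a bait spanning an intron in genomic DNA would hybridise poorly, which is
also why sub-bait internal exons disqualify a locus).  The retained tiling
depth of a long unscreened exon tends to 80/27 ≈ 2.96×; the convergence is
from below (edge effects of order 100/E), so depths at a few kb sit 1–2%
under the asymptote.

Screens run in a fixed order and each dropped bait records exactly one reason:

1. **low_complexity** — an exact tandem repeat of period ≤ 6 spanning ≥ 60%
   of the bait (period-p runs found by direct scan);
2. **blacklist** — any canonical 24-mer shared with the blacklist (plastome,
   repeat exemplars); exact k-mer matching is conservative and
   dependency-free, which is the right bias for excluding high-copy sequence;
3. **gc / tm** — GC% > 75 drops a bait.  The melting-temperature model is the
   basic long-oligo formula Tm = 81.5 + 0.41·GC% − 675/L; because that scale
   is not comparable with vendor hybridisation models, the Tm cutoff ships
   **disabled** (`tm_max=None`) and the GC ceiling carries the high-Tm screen;
4. **redundant** — identity > 0.95 over an overlap ≥ ceil(0.83·B) = 67 bases
   at the best ungapped offset.  Greedy first-kept-wins in canonical order
   (locus, exon, start, species); a shared-16-mer prescreen is exact because
   any qualifying pair (≤ 3 mismatches in ≥ 67 bases) must contain a 16-base
   exact run.

Baits are emitted from **every** source species (multi-reference panel);
cross-species near-duplicates collapse in the redundancy screen, which is why
retained per-species depths below 3× are normal for conserved exons.

## Capture evaluation

The pseudo-mapper seeds on shared 31-mers (both read strands), extends
ungapped along the seeded diagonal, and requires ≥ 100 overlapping bases at
≥ 90% identity; each read is assigned to its best reference only (ties to the
lexicographically first reference id; k-mers hitting > 20 reference positions
are skipped as seeds — repeat masking for seeding only).  Per-locus counts
take the maximum across the locus's reference species, mirroring the
per-reference mapping convention of published capture summaries; coverage
divides count × read length by the length of the reference that yielded the
maximum.  The per-locus reference target length is the **longest** reference
among the panel's source species.  A locus's assembled length is its longest
contig; recovery-matrix entries above 1.0 (over-assembly) are retained, and
the paralog flag fires when ≥ 2 contigs each cover ≥ 85% of the reference —
the conventional warning threshold of capture assemblers.

Percentages are reported to one decimal and group summaries are arithmetic
means (counts rounded to integers), matching summary-table conventions.  The
bundled worked-example table reproduces its own printed genus averages under
these rules; two of its printed on-target percentages are inconsistent with
their own printed counts, and the recomputed values are used.

## Panel comparison

Locus pairs are scored by the best ungapped local segment (Kadane scan along
seeded diagonals, +1/−1); an overlap exists when the segment spans > 5% of
the **shorter** target at identity ≥ 0.70.  The identity floor substitutes for
an alignment-significance test so random loci never "overlap"; each locus
reports only its best partner.  Surpluses are signed (len_a − len_b) and the
mean is rounded to the nearest integer.

## Simulator

The generator emulates the study design the toolkit targets: 3 ingroup
species and 1 subgeneric outgroup on the fixed tree
`((AloeA:0.02,AloeB:0.02):0.01,(AloeC:0.02,Outgroup:0.06):0.01)` (branch
lengths in expected substitutions/site, giving ingroup divergences of a few
percent and ~10–13% polymorphic columns per locus), 2–6 exons of 120–400 bp,
an annotated reference gene at 0.10 divergence from each locus root, and
Jukes–Cantor substitution only.  Injection classes are drawn per locus
(defaults: 15% low-SNP, 15% short internal exon, 10% paralog, 10% absent in
one focal species; 10% of plain passing loci carry an embedded 60-base
period-3 repeat).  Injections are constructed to be unambiguous relative to
the filter thresholds: low-SNP loci carry exactly ~8 polymorphic columns/kb
(vs the 20/kb threshold), passing loci are topped up to ≥ 30/kb when the tree
draw leaves them short, and paralog copies sit at 97–99% identity so the
within-95% copy rule fires decisively.  Reads are drawn uniformly from targets
(probability f) or from an i.i.d.-uniform background (1−f), both strands,
fixed length, with per-read truth labels.

What the simulator does **not** model — indels, sequencing error, chimeric
reads, rate heterogeneity, base-composition bias, genuine intron sequence —
bounds what green tests mean: they certify the algorithms' contracts
(filters, tiling, screens, counting rules) under clean conditions, not
robustness to assembler artefacts or alignment ambiguity in real
transcriptomes.  Degraded-material behaviour is represented only as a lower
on-target fraction and shorter reads, not as a damage model.

## Problem sizes and numerical choices

The test and acceptance runs use 200-locus simulations for filter-oracle
agreement (10 seeds), panels of ≤ 500 baits with planted duplicates for the
redundancy oracle, 20,000-read sets at on-target fractions 0.05 and 0.5,
10,000 sites for the substitution-model calibration (3 s.e. band around
3/4·(1−e^(−0.4/3)) ≈ 0.09362), and a bundled 20-locus configuration for full
pipeline closure — sizes chosen so each property is measured with comfortable
statistical margin on a single CPU.  Degenerate inputs fail loudly with
validation errors (empty FASTA, duplicate ids, non-contiguous exon maps,
zero-length alignments, reads shorter than the seed); ties everywhere break
lexicographically, making every pipeline output byte-reproducible from its
inputs and seed.

## Known limitations

* Clustering is all-pairs in the number of transcripts per species and is
  meant for curated LCN candidate sets (hundreds of transcripts), not raw
  100k-transcript assemblies.
* The star alignment inherits the usual centre-bias; with the no-indel
  simulator this is exact, on real data a profile aligner would be preferable.
* Tm values are formula-based and not comparable with vendor hybridisation
  models; the GC ceiling is the operative screen.
* The mapper is ungapped: indel-bearing reads map only if a ≥ 100-base
  ungapped block still clears 90% identity.
* Headline counts of any particular published panel (loci, baits, exon
  totals) are not reproducible without the original transcriptomes and are
  not targets of this package.
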