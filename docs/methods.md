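# Methods

`breakmap` models, end to end, the laboratory workflow by which a reciprocal
translocation breakpoint is mapped: cytogenetic narrowing with large-insert
(BAC) FISH probes, targeted-capture paired-end sequencing of the candidate
regions, discordant read-pair clustering, reconstruction and base-level
characterization of the two fusion junctions, junction PCR for genotyping,
and comparative-Ct quantification of nearby transcripts.  Every stage can be
exercised against fully synthetic data with machine-readable ground truth.

## The rearrangement model

A reciprocal translocation between chromosomes A and B is described by four
breakpoint offsets and two optional junction insertions:

    der(A;B) = A[0:a1] + ins1 + B[b1:]
    der(B;A) = B[0:b2] + ins2 + A[a2:]

with `a1 <= a2` and `b2 <= b1`.  The bases `A[a1:a2]` (`delA = a2 - a1` nt)
and `B[b2:b1]` (`delB`) appear in neither derivative: each chromosome loses
one contiguous segment between its two junction uses.  This matches the
anatomy of simple germline translocations repaired by non-homologous end
joining (NHEJ): small per-chromosome deletions, optional microhomology at a
fusion site, and short (1-3 nt) insertions that are typically templated
copies of immediately flanking sequence.  Inversion-type junctions and
multi-event rearrangements are out of scope.

### Canonical junction representation

When the two partner chromosomes share sequence at a junction, the
breakpoint placement is ambiguous: if `k` bases immediately left of `a1` on
A equal the `k` bases immediately left of `b1` on B (or symmetrically to the
right), representations `(a1 + j, b1 + j)` describe the same derivative for
a range of `j`.  `breakmap` resolves this with a single convention used
everywhere (truth records, junction calls, VCF output): the **prefix-maximal
canon** — the left (prefix) match is extended as far as possible, so
microhomology bases are attributed to the left-side reference.  The
microhomology length is the total overlap `p + s - len(consensus)` of the
maximal prefix and suffix matches.  An insertion that happens to match
flanking reference bases is absorbed into the flanks the same way; only the
unabsorbable middle is reported as inserted sequence.  Because truth and
call use the same canon, recovery is testable as exact equality.

A consequence worth knowing: under flanking homology the *split* of the
total deleted length between the two chromosomes can shift by the homology
length between equivalent representations (the sum `delA + delB - dup` is
invariant).  The exemplar-event generator (`synthetic_genome.exemplar_event`)
therefore fixes the bases just beyond each junction edit to differ between
the partners, so its literal anatomy — 6 bp lost from one chromosome, 8 bp
from the other, a shared GCT triplet at one fusion and a 2-nt templated
duplication at the other — is also the canonical one, for any seed.

## Synthetic data generator

`make_reference` draws i.i.d.-uniform ACGT sequence per chromosome from a
mandatory seed (never the clock).  `random_event` places breakpoints
uniformly in the middle third of each chromosome and plants the requested
junction anatomy by copying flank bases (microhomology is genuine shared
sequence of the two references, not a post-hoc annotation); per-junction
microhomology and duplication are mutually exclusive, as in the NHEJ
signature taxonomy used here.

`simulate_paired_reads` models targeted capture: per window,
`round(depth * W / (2L))` fragments are drawn with length
Normal(`insert_mean`, `insert_sd`) truncated to `[2L, W]` and start uniform
over positions that keep the fragment inside the window; mate 1 reads the
fragment start forward, mate 2 the fragment end reverse-complemented, with
Phred+33 qualities and an optional substitution-only error model (no
indels, no chimeras, no PCR duplicates, no capture-efficiency modelling).
Defaults are the study design: 30-fold coverage, 2x100 nt, 350 +/- 35 nt
insert, error rate 0.  What passing tests show is therefore recovery under
clean substitution-only reads on repeat-free random genomes; real capture
data adds repeats, indel errors and coverage bias that this generator
deliberately does not emulate.

## FISH probe localization

Probes are intervals; against an inter-base breakpoint `bp` a probe is
*split* iff `start < bp < end` (open interior: boundary contact is not
resolvable by FISH), *proximal* iff `end <= bp`, *distal* otherwise.
`localize` inverts a classified panel into the exact consistent position
set: the intersection of split interiors with `[max proximal end, min
distal start]`.  This is sound by construction (the generating breakpoint
always satisfies its own classifications), monotone (more probes never
widen it), and a contradiction raises rather than returning an empty
interval.  Applied to the published split-clone overlap endpoints this
reproduces the ~133 kb (chr5) and ~193 kb (chr8) candidate regions.

## Read mapping

A deliberately minimal seed-and-extend mapper, sufficient for error-light
synthetic reads and interchangeable with external SAM: a complete two-strand
k-mer index (k = 31, odd, 2-bit packed), candidate placements from every
non-overlapping read k-mer, ungapped Hamming verification, best (fewest
mismatches, default allowance 3 per mate) placement reported; equal-best
ties take the lexicographically smallest `(chrom, pos)` with the uniqueness
flag cleared, and downstream stages discard non-unique records.  There is no
gapped or split alignment by design: reads overlapping a fusion junction by
more than the mismatch allowance are reported unmapped, which is precisely
the junction-read signal the caller consumes.  Proper pairs are FR pairs on
one chromosome with insert within `mean +/- 4 sd`.

## Discordant clustering and candidate intervals

Unique-unique pairs with mates on different chromosomes are clustered by
single linkage (join iff same chromosome pair, same orientation consensus,
both footprints within `max_gap = insert_mean + 3 sd` = 455 nt); clusters
below `min_support = 3` pairs are dropped.  The support threshold balances
the ~22.5-pair straddling-fragment expectation at 30X
(`depth * (insert - 2L) / (2L)`) against sporadic mismapping; both knobs
are exposed.

The breakpoint lies in the unsequenced inner gap of straddling fragments,
so candidate intervals come from the insert model, not read footprints
alone: on a `+` side the interval is `[maxEnd - mm, maxEnd + slack)` with
`slack = insert_mean - 2L + 4 sd` (mirrored on `-` sides).  The `mm` (=
mismatch allowance) pad on the inner edge exists because a read may legally
end up to `mm` tolerated mismatching bases *past* the junction; without the
pad the innermost read end would overshoot the breakpoint in a third of
30X simulations.

## Junction reconstruction and characterization

Unmapped reads whose uniquely mapped mates fall near a candidate footprint
*and* match its per-side orientation consensus are collected as junction
reads (orientation matters: with paper-scale deletions the two reciprocal
junctions sit a few bp apart on both chromosomes and are separable only by
strand), oriented to the derivative forward strand, deduplicated, and
merged by greedy maximal exact overlap (floor 20 nt, ties by input order;
inconsistent equal-overlap branching is an error).  The consensus is then
anchored on both references: `p` = longest prefix match within the search
region (candidate +/- 2 inserts), `s` = longest suffix match, both with a
30 nt anchor floor below which random 200 nt consensi anchor spuriously on
desk-scale references.  `p + s >= len` yields microhomology `p + s - len`;
otherwise the middle is an insertion, flagged *templated* when it equals
the <= 3 bases immediately flanking either breakpoint (longer templated
copies are reported as untemplated insertions).  Signatures: blunt,
microhomology, templated-duplication, untemplated-insertion.

The reciprocal summary converts the two calls into per-chromosome deletion
totals by coordinate arithmetic and checks the length identity
`len(der1) + len(der2) = lenA + lenB - delA - delB + dup` against the
derivative sequences when available.  Junctions are exported as paired VCF
4.2 BND records (bracket ALTs, MATEID/EVENT, HOMLEN/HOMSEQ only when
microhomology is present).

## Genotyping PCR and relative expression

In-silico PCR is exact-match only (no thermodynamics or 3'-mismatch model —
the module validates assay logic, not chemistry): amplicons are fwd-site to
reverse-complement-site spans up to `max_product` (default 2000 nt).  A
wild-type assay flanking a breakpoint and a junction assay spanning a
fusion give the classic presence pattern WT-only / both / junction-only for
WT, heterozygous and homozygous template sets; a heterozygote is the union
of the WT and derivative templates.

Relative expression uses the comparative-Ct method with efficiency fixed
at 2: technical replicates are averaged per (sample, gene), per-sample
`dCt = Ct(gene) - Ct(reference)`, group means compared, fold change
`2^-ddCt` with the calibrator group reporting 1 by construction.  Ct values
are validated against the 40-cycle run limit.  With per-well Gaussian noise
sd sigma, `ddCt` is Normal with variance `2 sigma^2 (1/n1 + 1/n2)`, giving
the closed-form interval used to test estimator calibration.

## Problem sizes and numerical choices

The simulation study runs 100 seeded events on 1 Mb chromosome pairs with
100 kb capture windows at 30X (about 60,000 pairs per event including the
matched wild-type control), chosen to keep a full study in minutes on one
CPU while preserving the paper-scale window/insert/coverage geometry.
Oracle comparisons use 5 kb references and 200 nt consensi (500 cases),
probe-panel soundness uses 1,000 panels on 50 kb chromosomes against an
exhaustive all-positions oracle.  All randomness flows from explicit seeds;
read simulation is bit-reproducible; clustering and assembly tie-breaks are
deterministic (input order / lexicographic).  Degenerate inputs raise typed
errors rather than returning empty results: contradictory FISH panels,
unpaired SAM streams, one-sided junction read sets, unanchorable consensi,
assays with no amplicon.

## Known limitations

Random uniform genomes have no repeats, so mapping uniqueness is easier
than on real mm9-like sequence; the mapper is ungapped and substitution-
only; assembly is exact-overlap (a <=1-mismatch-per-overlap mode exists for
error-rate > 0 runs but error-free is the tested regime); only
inter-chromosomal, FR-consistent junction classes are called (no
deletions/inversions/tandem duplications); PCR is exact-match; expression
analysis does no statistical testing of fold changes.
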