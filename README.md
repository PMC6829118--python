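# breakmap

Toolkit for mapping the breakpoints of a reciprocal translocation from
probe hybridization and targeted paired-end sequencing data — the workflow
by which classic mouse germline translocations (such as the chr5;chr8
rearrangement upstream of *Sox1* and between *Galnt17* and *Auts2*) were
resolved to base precision.  It is aimed at people analysing simple two-
chromosome rearrangements, and at anyone who wants a fully synthetic,
ground-truthed test bed for structural-variant breakpoint methods.

A reciprocal translocation between chromosomes A and B produces two
derivatives

    der(A;B) = A[0:a1] + ins1 + B[b1:]      der(B;A) = B[0:b2] + ins2 + A[a2:]

where `delA = a2 − a1` and `delB = b1 − b2` bases are lost from the
partners and `ins1`/`ins2` are short junction insertions — together the
classic non-homologous end-joining signature (small deletions,
microhomology, 1–3 nt templated duplications).  `breakmap` covers each
stage of resolving such an event:

* **fish_localization** — classify interval probes (BACs) as proximal /
  distal / split against a breakpoint and invert a classified panel into
  the minimal consistent breakpoint interval.
* **synthetic_genome** — seeded reference chromosomes, translocation
  events with configurable junction anatomy and canonical truth records,
  targeted-capture paired-end read simulation (30X, 2×100, 350 ± 35 insert
  defaults).
* **read_mapping** — a minimal two-strand k-mer seed-and-extend mapper
  (ungapped, ≤3 mismatches, unique-best placement) producing SAM;
  externally produced SAM is accepted interchangeably.
* **discordant_clustering** — inter-chromosomal unique-unique pair
  extraction, single-linkage clustering, and insert-model candidate
  intervals (BEDPE).
* **junction_caller** — greedy exact-overlap assembly of junction-spanning
  reads, base-level characterization (breakpoints, microhomology,
  insertions, NHEJ signature class), reciprocal deletion accounting, and
  paired VCF 4.2 BND output.
* **genotyping_pcr** — exact-match in-silico PCR predicting the WT / T/+ /
  T/T amplicon presence patterns.
* **relative_expression** — comparative-Ct (2^−ΔΔCt) quantification with a
  synthetic Ct-table generator and closed-form calibration intervals.

See `docs/methods.md` for the model, conventions (canonical junction
representation) and limitations.

## Worked example

Simulate an event with the published junction anatomy — 6 bp deleted from
chr5, 8 bp from chr8, a shared GCT triplet at the der(5;8) fusion and a
2-nt templated duplication at the der(8;5) fusion — then map, cluster,
assemble and characterize:

```python
import numpy as np
from breakmap import synthetic_genome as sg, read_mapping as rm, pipeline as pl

rng = np.random.default_rng(7)
base = sg.make_reference([("chr5", 300_000, 101), ("chr8", 300_000, 102)])
ref, event = sg.exemplar_event(base, "chr5", "chr8", rng)
half = 15_000
wins = [(sg.DER_AB, event.a1 - half, event.a1 + half),
        (sg.DER_BA, event.b2 - half, event.b2 + half)]
ders, truth = sg.apply_translocation(ref, event, capture_windows=wins)
reads = sg.simulate_paired_reads(ders, wins, sg.ReadSimConfig(seed=9))
aln = rm.map_pairs(reads, rm.build_index(ref))
res = pl.discover_junctions(ref, aln, derivatives=ders)
```

which prints (via the candidate/call fields):

```
candidate chr5:194467-194760 <-> chr8:162222-162515  support=29 (+-)
candidate chr5:194213-194506 <-> chr8:162505-162798  support=26 (-+)
derAB: chr5:194490 | chr8:162518  signature=microhomology mh=3(GCT) ins=- reads=24
derBA: chr8:162509 | chr5:194497  signature=templated-duplication mh=0 ins=GG reads=25
summary: delA=6 delB=8 dup=2
```

Reading this: the two discordant clusters (29 and 26 straddling pairs,
opposite orientations — the two reciprocal junctions) localize both
breakpoints; the assembled junction consensus places der(5;8) with its
last chr5 base at 194,490 and first chr8 base at 162,518, sharing one GCT
copy (3 nt microhomology); the reciprocal junction carries a 2-nt
insertion copying adjacent template.  Coordinate arithmetic over both
calls recovers the 6 and 8 bp deletions exactly.  The calls serialize as
cross-referencing VCF breakend pairs:

```
chr5  194490  bnd_derAB_a  T  T[chr8:162518[   .  PASS  SVTYPE=BND;MATEID=bnd_derAB_b;EVENT=derAB;HOMLEN=3;HOMSEQ=GCT
chr8  162518  bnd_derAB_b  A  ]chr5:194490]A   .  PASS  SVTYPE=BND;MATEID=bnd_derAB_a;EVENT=derAB;HOMLEN=3;HOMSEQ=GCT
```

The FISH side works from plain interval tables; applied to the published
split-clone endpoints it reproduces the ~133 kb (chr5) and ~193 kb (chr8)
candidate regions:

```python
from breakmap import fish_localization as fl
probes = (fl.Probe("RP24-234k3-like", "chr8", 12_244_883, 12_450_000),
          fl.Probe("RP24-234a5-like", "chr8", 12_230_000, 12_437_596))
panel = fl.ProbePanel(probes, {p.name: fl.SPLIT for p in probes})
fl.localize(panel)            # LocalizationResult(chrom='chr8', start=12244884, end=12437596)
```

A `breakmap` console script wraps the same steps for shell use
(`simulate`, `map`, `discover`, `call`, `fish-localize`, `insilico-pcr`,
`ddct`); every subcommand reads and writes standard formats (FASTA,
FASTQ, SAM, BED/BEDPE, VCF, TSV).

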