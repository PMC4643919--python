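# plastomics

Comparative analysis of plastid (chloroplast) genomes at shallow
divergence: quadripartite structure and junction analysis, divergence
profiling, outgroup-polarized mutation spectra with repeat-context
classification, genome-size decomposition, Tajima relative-rate testing,
and a plastome simulator that emits ground-truth event logs.

Plastomes of congeneric plants — long-lived trees especially — often
differ by only ~1 substitution per 1,000 sites, so the interesting
questions are structural and mutational: where do the inverted-repeat
(IR) junctions sit, which noncoding loci vary, in which *direction* do
substitutions and indels run once polarized against an outgroup, how much
of a genome-size difference do a handful of large indels explain, and is
one lineage measurably slower than another? This package implements that
analysis suite for anyone comparing a few closely related, fully
assembled plastomes.

## The statistics at the core

* **Uncorrected p-distance** with pairwise deletion:
  p = (mismatching compared columns) / (compared columns).
* **Percent variability** of a noncoding region of aligned length L with
  S substitution sites and E distinct maximal gap-run events:
  100·(S + E)/L (regions with L ≤ 200 are filtered).
* **Polarized spectrum**: for an alignment column where the ingroup is
  biallelic, no taxon is gapped, and the outgroup carries one of the two
  states, the outgroup state is ancestral; events are counted per derived
  allele and tallied into the 12 directed substitution cells, giving
  Ts/Tv = n(transitions)/n(transversions). Indels polarize analogously
  from gap-run patterns, and each is classified as homopolymer-,
  tandem-repeat-associated, or neither — the slipped-strand mispairing
  signature.
* **Tajima's relative-rate test**: with m₁, m₂ the sites unique to each
  ingroup lineage relative to an outgroup,
  χ² = (m₁ − m₂)²/(m₁ + m₂), df = 1.

## Worked example

Simulate a small five-taxon plastome family (a *Tilia*-like quartet plus
a distant outgroup) with known truth, then run the analyses:

```python
import plastomics as pm

cfg = pm.SimulationConfig(seed=42, lsc_length=18000, ssc_length=5000,
                          ir_length=6000, n_repeat_loci=60)
truth = pm.simulate(cfg)
pm.export_fixture(truth, "demo")
```

```sh
$ plastomics structure demo/TiliaA.gb --out demo/structure
$ cat demo/structure/regions.tsv
#region  start  end    length
LSC      1      18039  18039
IRB      18040  24039  6000
SSC      24040  29054  5015
IRA      29055  35054  6000
$ cat demo/structure/junctions.tsv
#junction  position  gene   overlap_into_ir  nearest_gene  nearest_distance
JLB        18040     .      0                rrn1          894
JSB        24040     ycf1   36               .
JSA        29055     .      0                gene009       390
JLA        1         .      0                gene001       611
```

The detector recovered the planted quadripartite layout exactly (the LSC
is 39 bp longer than configured because indels accumulated there), and
the junction report finds the planted *ycf1* gene crossing the IRb/SSC
junction with 36 bp duplicated inside the IR.

```sh
$ plastomics spectrum demo/alignment.one_ir.fasta \
    --ingroup TiliaA --ingroup TiliaB --ingroup TiliaC --ingroup TiliaD \
    --outgroup Outgroup --out demo/spec
```

`demo/spec/summary.json` reports 79 polarized substitutions (24
transitions, 55 transversions, Ts/Tv = 0.44 — near the planted 0.5), 16
insertions vs 8 deletions, and 22 of the 24 indels repeat-associated:
the slipped-strand signal the simulator planted.

```sh
$ plastomics rrt demo/alignment.one_ir.fasta \
    --ingroup1 TiliaA --ingroup2 TiliaC --outgroup Outgroup --out demo/rrt
$ cat demo/rrt/rate_tests.tsv
#ingroup1  ingroup2  outgroup  identical  divergent  uniq1  uniq2  uniq_out  chi_square  p_value  slower
TiliaA     TiliaC    Outgroup  28300      1          29     22     570       0.96        0.327    .
```

The two ingroup lineages were simulated at (nearly) equal rates, and the
test correctly declines to call either slower (χ² = 0.96, p = 0.33). On
real data the same command reproduces the published whole-plastome
comparisons: for example, unique-site counts of 2456 vs 725 give
χ² = 941.96, p < 0.001.

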