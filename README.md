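# ldphase

Linkage-disequilibrium analysis for two-group livestock SNP panels: genotype
QC, phased-haplotype LD statistics, distance-binned LD decay, persistence of
LD phase between genetic groups, and Gabriel-style haplotype blocks — with a
Wright–Fisher admixture simulator so the whole pipeline runs without any
external genotype data.

It is aimed at the situation of a composite breed (for example a herd formed
from 5/8 : 3/8 crosses of two diverged founder breeds and later split into
two management groups): before pooling the groups for genome-wide association
or genomic selection, one wants to know how fast LD decays with physical
distance in each group, whether marker phase is consistent across the groups,
and how the genome partitions into haplotype blocks.

## The statistics

For a SNP pair with phased haplotype counts `n11, n10, n01, n00`
(`n = Σ counts`, allele-1 marginals `p_i`, `p_j`):

```
D    = p_ij − p_i p_j            (computed as (n11·n00 − n10·n01)/n²)
r²   = D² / (p_i(1−p_i) p_j(1−p_j))
D′   = |D| / D_max
signed r = √r² carrying the sign of D
```

* **LD decay** — pairs within 500 kb are binned by distance
  (`< 2.5, 2.5–5, …, 400–500` kb) and r² summarised per bin (count, mean,
  sample SD, exact median), per group and genome-wide.
* **Persistence of LD phase (PL)** — for SNP pairs shared by both groups,
  the per-bin correlation of signed r between the groups. High PL at a
  distance means marker–QTL phase transfers across groups at that scale.
* **Haplotype blocks** — the Gabriel confidence-interval rule: a pair is
  *strong LD* if its 90% D′ CI is (≥ 0.70, ≥ 0.98) and *strong
  recombination* if the upper bound is < 0.90; an interval is a block
  candidate when its endpoint pair is strong LD and ≥ 95% of informative
  internal pairs are strong LD; overlaps resolve greedily by span and
  2-SNP blocks are discarded.

Unphased input is supported through a two-locus EM over the
double-heterozygote ambiguity; the exact conditional test is used for
Hardy–Weinberg QC.

## Worked example

```bash
ldphase simulate --out sim/            # default two-group panel (VCF + group map)
ldphase run-all --vcf sim/panel.vcf --groups sim/groups.tsv --out results/
```

or in Python:

```python
from ldphase import RunConfig, SimConfig, run_pipeline

bundle = run_pipeline(RunConfig(sim=SimConfig(seed=1), out_dir="results"))
print(bundle["summary"][["bin", "CAN_n_pairs", "CAN_mean_r2", "PL"]].head(3))
print(bundle["summary"][["bin", "CAN_n_pairs", "CAN_mean_r2", "PL"]].tail(1))
```

which prints (seed 1):

```
       bin  CAN_n_pairs  CAN_mean_r2        PL
0    < 2.5        12224     0.981906  0.999603
1  2.5 - 5        11035     0.943039  0.998376
2  5 - 7.5         9980     0.910783  0.997074
          bin  CAN_n_pairs  CAN_mean_r2        PL
16  400 - 500        30604     0.034918  0.553451
```

Reading: the joint group's mean r² falls from 0.98 for pairs closer than
2.5 kb to 0.035 at 400–500 kb, and the phase correlation between the two
groups falls from ~1.0 to ~0.55 over the same range — strong short-range LD
and phase agreement, both decaying with distance, as expected for a recently
admixed population pair. `results/` also receives the QC report, per-group
decay tables, a block BED with its per-chromosome summary, and a manifest
that makes the run byte-reproducible.

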