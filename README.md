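# panelsnv

Somatic single-nucleotide variant calling at low allelic fraction, for
tumor samples whose noise floor defeats a plain tumor-vs-normal
comparison — degraded or formalin-fixed (FFPE) tissue, impure tumors,
subclonal mutations. The caller tests each candidate site's tumor
evidence against a **site-specific background error rate** estimated from
a user-defined panel of control samples processed like the tumor, instead
of assuming one genome-wide error model.

It is written for bioinformaticians analysing tumor/matched-normal
sequencing (exome, genome or targeted panels) who have — or can collect —
a set of normal samples from the same wet-lab and alignment pipeline.

## Method

The caller runs three steps per candidate site:

**Step 1 — raw calling.** Walk the tumor against its matched normal and
keep sites where the tumor shows a non-reference base, under strict
filters applied in a fixed, audited order: base quality ≥ 30, mapping
quality ≥ 30, overlapping mates of one fragment counted once, tumor
support from ≥ 2 distinct fragments, rejection of sites whose alternative
bases sit only in the first/last 5 read positions of a strand, and
rejection of sites with ≥ 2 altered reads in the matched normal.

**Step 2 — panel tallies.** At every candidate site, count each control
sample's reads under exactly the same read filters and compute the
per-control allelic fraction AF = alt/total.

**Step 3 — statistics.** If any control shows the variant above a 10% AF
trigger, split the controls by an exact one-dimensional 2-means clustering
of their AFs; the larger-mean cluster is interpreted as germline carriers,
and a site carried by ≥ 2 controls is flagged `germline` and excluded.
The remaining (error-bearing) controls are pooled into the site error
rate

```
p = Σ alt reads over error controls / Σ total reads over error controls
```

and the tumor's alternative read count is tested one-sided against

```
X ~ Binom(n, p),    p-value = P[Binom(n, p) ≥ X]
```

with Bonferroni correction over the m tested sites at family-wise
α = 0.05. Sites lacking 80% power to detect a 30%-AF mutation in the
tumor (50% in the normal) at the per-site level are set aside as
`low_power` rather than reported as negative. Every site ends with a
judgement: `real`, `reject`, `germline` or `low_power`.

## Worked example

`examples/03_germline_clustering.py` builds a 135-control panel in which
5 controls carry a SNP heterozygously (AF centred at 0.35) and 130 show a
2% recurrent artifact, then runs the per-site clustering:

```
germline cluster: 5 controls, mean AF 0.367
error cluster:    130 controls, mean AF 0.019
flagged recurrent germline: True
```

The clustering recovers the planted 5/130 split; the site is excluded
from somatic testing as a recurrent germline variant, and only the
130-control cluster would have been pooled into the error rate.

`examples/04_end_to_end_cohort.py` runs all three steps on a planted
cohort (somatic variants at AF 0.05/0.10/0.15 in a 300× tumor, two
artifact sites at 5% panel-wide error, 100 controls):

```
planted somatic variants (expected judgement: real)
    chr1:1000000  ->  real
    chr1:1000001  ->  real
    chr1:1000002  ->  real
planted artifact sites (expected judgement: reject)
    chr2:2000000  ->  reject
    chr2:2000001  ->  reject
panel-estimated background error rate at a somatic site: 3.73e-04
```

All planted low-fraction variants are recovered and both artifact sites
are rejected because the panel itself exhibits the same elevated error.

The other examples cover raw calling with filter traces (`01`), panel
tallies and error pooling (`02`) and the FFPE C>T/G>A artifact spectrum
(`05`). Each is a plain script: `python examples/04_end_to_end_cohort.py`.

## Command line

The same pipeline is exposed as a thin CLI over pileup TSVs or indexed
BAM/CRAM (with `--reference`):

```bash
panelsnv run-all --tumor tumor.bam --normal normal.bam \
    --panel controls.txt --reference ref.fa --out mycase --vcf
```

or stepwise: `panelsnv call-raw`, `panelsnv control-stats` (resumable),
`panelsnv stats-calling`. `controls.txt` lists one control path per line.
Outputs are TSV (`.candidates.tsv`, `.controls.tsv`, `.calls.tsv`), an
optional minimal VCF, a run log and a JSON summary of judgement counts.

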