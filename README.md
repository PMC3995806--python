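# panelforge

A toolkit for designing and evaluating SNP genotyping-array marker panels,
modelled on the workflow used to build high-density arrays for aquaculture
species such as catfish: start from millions of sequencing-derived
candidate SNPs, filter them down by sequence context, tile oriented
probes, and then grade the finished panel by genotyping cohorts and
classifying every probeset's cluster pattern.

It is aimed at genomics researchers who want to prototype or audit a
panel-design pipeline on data with known truth before committing to a
vendor submission: every stage has a documented, deterministic surrogate
for the proprietary vendor components, and a synthetic-data module
generates genomes, candidate variants, populations and two-channel
intensities with controlled ground truth so the whole pipeline can be
validated closed-loop.

## What it implements

**Candidate filtering.** A SNP survives when a full 71-base flank
(35 bases per side) exists, the allele pair is not A/T or C/G (those need
twice the probes), no other variant lies within ±30 bp, flank GC is in
[30%, 70%], no G/C run exceeds 4 or A/T run exceeds 6, and the flank is
unique in the genome (soft-mask plus 16-mer multiplicity test).

**Design scoring.** A deterministic stand-in for the vendor's per-probe
conversion score ("p-convert"), an explicit logistic of interpretable
penalties over the factors such models use:

    pconvert = σ( b − w_gc·|gc−½| − w_run·max(0, run−3)
                    − w_uniq·log₂(copies) − w_tm·|Tm−70|/70 )

**Array selection.** One SNP per contig under 4 kb, the two maximally
spaced SNPs per contig at or above 4 kb (1–2 per transcript contig for
gene sets); probes below score 0.5 are dropped, both strand probes are
tiled when both scores sit in the marginal (0.5, 0.6) band, else the
higher-scoring strand; plus non-polymorphic 31-mer QC probes split
between A/T- and G/C-terminal classes.

**Genotype calling and classification.** Signals map to contrast
log₂(a/b) and strength ½(log₂a + log₂b); per probeset a 1–3 component
Gaussian mixture on contrast (BIC-selected, deterministic starts) yields
clusters mapped to BB/AB/AA. Samples pass QC with dish-QC ≥ 0.82 and call
rate > 0.97. Probesets are classified into the six standard categories —
PolyHighResolution, NoMinorHom, MonoHighResolution, OTV,
CallRateBelowThreshold, Other — with the first four counted convertible
and the first two polymorphic, and the panel summarised by conversion /
polymorphism rates, MAF spectra (0.05-wide bins), inter-SNP spacing
distributions and cross-population polymorphism overlap.

## Worked example

```python
from panelforge.pipeline import run_scenario
from panelforge.simulate import SimScenario
from panelforge.genotyping import performance_summary

run = run_scenario(SimScenario(rng_seed=1))   # ~1 Mb genome, 3 cohorts
print(run.design.summary)
print(performance_summary(run.callsets, run.manifest).to_string())
```

prints (abridged):

```
{'n_snps': 397, 'n_single_probe': 397, 'n_dual_probe': 0,
 'n_probes': 397, 'n_qc_probes': 300, ...}
  population  samples_processed  samples_passed  pct_converted  pct_polymorphic  avg_call_rate_pct
0       wild                 96              93           99.7             69.3               99.0
1        BC1                 96              92           99.0             66.8               99.0
2        BC3                 96              96           99.2             73.0               99.0
```

Reading the table: of 96 simulated wild samples, 93 pass the two-stage QC;
99.7% of the 397 panel SNPs form interpretable clusters (convertible) and
69.3% are polymorphic. The backcross cohorts show the expected family
structure — BC1 has the lowest polymorphism (markers fixed in the few
cross founders cannot segregate) and an excess of NoMinorHom probesets,
because inter-specific fixed-difference markers segregate AB × AA and
never produce the minor homozygote.

The same stages are available from the shell:

```bash
panelforge simulate --seed 1 --outdir sim/
panelforge filter --genome sim/genome.fa --vcf sim/candidates.vcf --out outcomes.tsv
panelforge design --genome sim/genome.fa --vcf sim/candidates.vcf \
    --out manifest.tsv --qc-out qc_probes.tsv
panelforge run --seed 1 --outdir full_run/
```

## Layout

| module | role |
| --- | --- |
| `panelforge.models` | domain types and stage configurations |
| `panelforge.genome`, `panelforge.io` | genome container, k-mer index; FASTA/VCF/TSV readers and writers |
| `panelforge.filtering` | candidate eligibility rules |
| `panelforge.scoring` | probe design-score surrogate and score-vs-performance curve |
| `panelforge.selection` | per-contig selection, probe tiling, QC probes, manifest |
| `panelforge.genotyping` | calling, sample QC, six-way classification, analytics |
| `panelforge.spacing` | flank mapping, inter-SNP spacing, anchor association |
| `panelforge.simulate` | synthetic genomes, variants, populations, intensities |
| `panelforge.pipeline`, `panelforge.reports`, `panelforge.cli`, `panelforge.config` | orchestration, report tables, CLI, TOML config |

Details of the models, their assumptions and the numerical choices are in
[docs/methods.md](docs/methods.md).
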