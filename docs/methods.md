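# Methods

This note documents the models behind panelforge: what each surrogate
computes, the tunable parameters and their defaults, what the synthetic
data emulates (and does not), and the numerical choices that matter for
reproducibility.

## Coordinates and formats

All positions are 0-based half-open internally and in every emitted TSV;
VCF input is shifted by −1 on ingestion. FASTA lowercase is honoured as
soft-mask (repeat) annotation alongside the self-contained k-mer test, so
both user-supplied masks and mask-free assemblies work. Tabular artifacts
are TSV (diffable, byte-stable on rewrite: floats round-trip through the
shortest-repr writer and a round-trip-precision reader).

## Candidate filtering

A candidate SNP must satisfy six independent predicates; all violations
are recorded, not just the first, and the pass verdict equals the
intersection of the individual rules.

| rule | parameter (default) | reading |
| --- | --- | --- |
| edge | `flank_len` = 35 | a full 71-base flank must exist on the contig |
| allele type | — | A/T and C/G pairs excluded (both alleles label with the same dye; resolving them needs twice the probes) |
| nearby variant | `exclusion_window` = 30 | any other variant at distance ≤ 30 bp disqualifies (inclusive boundary — the conservative reading of "within 30 bp"); applied genome-wide on the candidate's contig |
| GC content | `gc_min/gc_max` = 0.30/0.70 | closed interval on the 71-base flank; ambiguity codes disqualify (probes cannot encode them) |
| homopolymer | `max_gc_run` = 4, `max_at_run` = 6 | "greater than" read strictly: G/C runs of 5+ and A/T runs of 7+ fail; limits apply symmetrically within each complement pair, so the verdict is strand-invariant |
| repeat | `repeat_kmer` = 16, `repeat_max_copies` = 1 | fails if any flank base is soft-masked or any flank 16-mer occurs more than once in the genome |

The k-mer index counts canonical (strand-merged) occurrences, so a probe
matching the reverse strand of another locus is caught. A
reverse-complement-palindromic k-mer occurring once counts once.
Candidates failing a rule are dropped rather than having their flanks
masked — filter semantics, the stricter of the two possible treatments.

## Design-score surrogate

Vendors score each candidate probe with a learned model of conversion
probability; the inputs they name are probe sequence composition, duplex
stability and expected non-specific hybridisation. panelforge replaces
the learned model with an explicit logistic so scores are deterministic
and auditable:

    x = bias − w_gc·|gc − 0.5| − w_run·max(0, longest_run − 3)
             − w_uniq·log2(max k-mer copies) − w_tm·|tm − 70|/70
    pconvert = 1 / (1 + e^(−x))

with `tm = 64.9 + 41·(gc·L − 16.4)/L` (GC-fraction melting proxy, L = 35)
and defaults `w_gc=4, w_run=0.5, w_uniq=1.5, w_tm=1, bias=2.5`. The score
is monotone non-increasing in genome copy number and in |gc − 0.5|, and
probes with ambiguity codes score 0. Absolute values are **not**
comparable to any vendor scale; only the ordering and the [0, 1] range
carry meaning. Each SNP gets one forward and one reverse probe: the 35
bases immediately 5′ of the site on each strand, ending adjacent to the
interrogated base — a declared convention, since exact vendor probe
geometry is not public.

## Array selection

Anonymous contigs shorter than 4 kb contribute one SNP; contigs at or
above 4 kb contribute the two candidates with the largest pairwise
distance (exactly length 4,000 is assigned to the two-SNP rule). Gene
(transcript) contigs contribute one to two SNPs under the same
max-spacing objective regardless of length. Ties break by higher best
probe score, then lower position.

Probe tiling: a SNP is dropped when neither strand score exceeds
`pconvert_min` (0.5, exclusive); both probes are tiled when both scores
fall in (`pconvert_min`, `dual_probe_band_max` = 0.6) — the band is an
explicit parameterisation of "relatively low" scores, where a second
probe meaningfully raises conversion odds; otherwise the single
higher-scoring probe (ties go forward). Under the clean synthetic
generator most surviving probes score well above 0.6, so dual tiling is
rare in simulated manifests; the dual-probe rescue behaviour is exercised
with constructed scores in the tests.

QC probes are 31-mers sampled uniformly from the genome without
replacement, rejected if masked, ambiguous, k-mer-duplicated, overlapping
any known variant, or duplicating an already chosen sequence; exactly
`n_at_terminal` end in A/T and `n_gc_terminal` in G/C (defaults 1,000
each, mirroring common array practice; simulation scenarios use smaller
counts). Sampling is driven by a single seeded generator, so output is
deterministic.

## Intensity model and genotype calling

Two-channel signals (a, b) map to contrast = log₂((a+1)/(b+1)) and
strength = ½(log₂(a+1) + log₂(b+1)); the pseudo-count keeps zero signals
finite.

Per probeset, a univariate Gaussian mixture with k = 1..3 spherical
components is fitted to the contrast of samples passing dish QC, and k is
chosen by BIC. Fitting is deterministic and seed-free: for each k, EM is
started from three fixed initialisations — component means on the
(i+½)/k data quantiles, on an even grid over the data range, and on the
partition induced by the k−1 widest gaps of the sorted data — each with
weights and variances taken from the hard nearest-start partition; the
best final BIC wins. The gap-based start is what lets the fit resolve
minor-homozygote clusters with a handful of members (down to singletons);
quantile starts alone stall EM when cluster sizes are very skewed. The EM
variance is floored at `sd_floor²` (0.05²) via the covariance
regulariser, preventing the likelihood from diverging by collapsing a
component onto one point.

Cluster → genotype mapping: three clusters in canonical geometry (outer
means straddling zero, middle mean within a quarter of the outer span of
zero) are BB/AB/AA by ascending contrast. Otherwise each cluster takes
the homozygote of its sign, or AB when its mean lies within `het_margin`
(0.5) of zero; duplicate labels are allowed and mean one genotype was
split across two fitted components — this avoids inventing a minor
homozygote that the data do not support. With two clusters a label
collision resolves by proximity to zero (nearer = heterozygote); one
cluster is a lone homozygote, or all-AB when centred.

A sample is called to its maximum-posterior cluster when that posterior
is at least `nocall_posterior` (0.95), else NC; missing intensity rows
are NC by definition. Clusters left with no called members are removed
and posteriors recomputed.

## Sample QC

Dish QC (DQC) is defined here as 1 − overlap coefficient of normal fits
to the strengths of the A/T-terminal vs G/C-terminal control probes
(numerically integrated); identical distributions give 0, well-separated
ones approach 1, and the statistic is invariant under common strength
shifts. The 0.82 threshold is kept for interface parity with standard
array QC, with the caveat that this DQC scale is not comparable to any
vendor's. QC is two-stage: samples with DQC ≥ 0.82 are called; samples
whose post-calling call rate is not **strictly** above 0.97 then fail
("0.82 or better" is inclusive, "> 0.97" is not). The per-sample call
rate is computed over all manifest SNPs.

## Probeset classification

Decision order, with defaults: call rate < `snp_call_rate_min` (0.95) →
CallRateBelowThreshold; a called cluster whose mean strength is below the
probeset's median called strength minus `otv_strength_sds` (2.0) standard
deviations → OTV; minimum adjacent-cluster separation
(Δmean / pooled sd) < `sep_min` (2.0) → Other; one cluster →
MonoHighResolution; no minor-homozygote cluster → NoMinorHom; else
PolyHighResolution. The category names follow the standard genotyping
vocabulary; the numeric floors are this package's own documented
defaults, and "cluster property below floor" is operationalised as the
separation floor — the only cluster property observable in this
surrogate's one-dimensional calling world. Convertible = first four
categories, polymorphic = first two. A dual-tiled SNP takes the best of
its probes' categories under the priority PolyHighResolution >
NoMinorHom > OTV > MonoHighResolution > CallRateBelowThreshold > Other —
the point of the second probe is rescue.

Avg. SNP call rate in performance tables is computed over converted SNPs
(the alternative, over all SNPs, would fold design failures into a
sample-quality metric).

MAF uses p = (2·#AA + #AB) / (2·#called), maf = min(p, 1−p), rounded to
two decimals and binned into the labelled closed ranges 0.01–0.05 …
0.46–0.50; a rounded MAF of 0.00 gets its own bin rather than polluting
the first labelled range.

## Spacing analysis

Flank placement on an assembly is exact-match (both strands, via the
reverse complement of the 71-mer); a SNP maps only when exactly one hit
exists, and the mapped coordinate is the flank centre, which is the same
offset on either strand. Exact matching replaces alignment deliberately:
it is deterministic and sufficient for synthetic assemblies, but it will
not tolerate assembly-to-panel sequence divergence the way BLAST-style
mapping does — on real data it under-maps, and a mismatch-tolerant mode
is out of scope. Distances are between consecutive SNP site coordinates
per scaffold; the first SNP of each occupied scaffold contributes no
interval (a scaffold-end gap is unknowable), giving the identity
#intervals = #mapped − #occupied scaffolds. Bins are half-open
lower-inclusive on edges 0, 500, 1000, 2000, …, 6000, ∞ — so a 500 bp
interval falls in [500, 1000) — and cumulative fractions are reported
below 1 kb, within [1 kb, 6 kb), and at or above 6 kb.

## Synthetic data: what it emulates, what it does not

The generator provides closed-loop truth for every pipeline stage.
Genomes are i.i.d. bases at a configurable GC (default 0.41); repeats are
implemented by copying 200 bp segments to second loci and soft-masking
both copies until `repeat_fraction` (3%) of bases are repeat-derived.
Variants are uniform per contig at `snp_density_per_kb` (2.0), with
alternate alleles drawn to a transition:transversion ratio of 1.85 and
indels sprinkled at 0.15/kb to exercise the exclusion-window rule. Each
contig carries one source class (13% channel-gene, 12% blue-gene, 16%
inter-specific, 59% anonymous — mirroring the composition of a
two-species array design).

Populations: `random_mating` draws Hardy–Weinberg genotypes at MAF ~
U(0.05, 0.5); in the wild cohort inter-specific markers are monomorphic
with probability 0.9 and other-species gene markers with probability 0.8
(a fixed difference between species shows no variation within one).
`backcross_like` cohorts segregate fixed-difference inter-specific
markers as AB × AA (1:1 AA/AB, never the minor homozygote) and force
`founder_monomorphic_fraction` of the remaining markers monomorphic
(0.35 for a first-generation backcross, 0.25 for a third — a family
descends from a handful of founder genomes, so markers not heterozygous
in any founder cannot segregate). Backcrosses are modelled at the marker
level; no recombination maps or linkage are simulated.

Intensities: genotype-conditional contrast means +3/0/−3 with sd 0.3,
strength baseline 10 with sd 0.3; 1% of intensity rows are dropped
(missing → NC), matching the sub-1% no-call rates of passing array
samples; 5% of SNPs carry the off-target signature — a 25% carrier
fraction collapsing to contrast ≈ 0 with strength lowered by 4 log₂
units under a major-homozygote background (the geometry that makes an
off-target cluster identifiable in one dimension). QC-probe strengths
put the two terminal classes 3 log₂ units apart (sd 0.5) for clean
samples and collapse them for a configurable "bad" fraction, so bad
samples fail the DQC screen crisply.

What passing closed-loop tests does **not** show: real arrays fail
probes for reasons the generator does not model (cross-hybridisation
families, CNVs, batch and plate effects, strand-biased chemistry), real
cluster shapes are neither Gaussian nor homoscedastic, and real
conversion rates (~80%) are far below the near-complete conversion of
clean synthetic probes. The toolkit's value on real data is the pipeline
structure and the explicit, tunable thresholds, not the synthetic
performance numbers.

## Problem sizes

The default scenario is a ~1 Mb genome (250 contigs of 1.5–6.5 kb, so
both per-contig selection rules fire), ~2,000 candidate SNPs and three
96-sample cohorts, chosen so a full run completes in about a minute. The
genotype-recovery study uses 250 SNPs × 200 samples at contrast sd 0.3
with 2% intensity dropout. The test suite's determinism check reruns a
reduced two-cohort scenario end-to-end and compares artifact bytes.

## Known limitations

- Scores, DQC and classification thresholds are surrogates: calibrated
  for internal consistency, not for agreement with any vendor's values.
- Exact-match spacing under-maps diverged assemblies (see above).
- The mixture caller is one-dimensional; it cannot separate clusters
  that differ only in strength (the OTV rule catches only the
  low-strength signature).
- k is capped at 3: probesets with genuine extra clusters (paralogs,
  CNV) are forced into the nearest three-cluster interpretation and at
  best flagged via separation or OTV.
- Indel and multi-allelic probe design is out of scope; such records are
  consumed only as exclusion-window neighbours.
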