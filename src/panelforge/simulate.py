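"""Synthetic data generation with known ground truth.

Generates every input the pipeline needs: genomes with controlled GC and
duplicated (soft-masked) repeat segments, candidate SNP/indel sets with a
configured transition:transversion ratio, population genotypes under
random mating or backcross-like segregation, and two-channel intensities
with genotype-conditional cluster structure, no-call dropout, off-target
low-strength clusters and per-sample dish-QC behaviour. Everything is
deterministic given the scenario seed; truth tables accompany every
output so downstream tests are closed-loop recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import Contig, Genome
from .models import ArrayManifest, SnpCandidate, SourceClass

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass
class PopulationSpec:
    """One genotyped cohort.

    ``random_mating`` draws Hardy–Weinberg genotypes at a per-SNP minor
    allele frequency from U(maf_min, maf_max); ``backcross_like`` makes
    fixed-difference inter-specific markers segregate as an AB × AA cross
    (1:1 AA/AB offspring, no minor homozygote). ``class_monomorphic_fraction``
    forces markers of a source class to be monomorphic (all AA) with the
    given probability, emulating e.g. blue-catfish-derived or inter-specific
    markers genotyped in a pure channel-catfish population.
    ``founder_monomorphic_fraction`` applies to the remaining markers of a
    backcross-like cohort: a family descends from a handful of founder
    genomes, so a marker not heterozygous in any founder does not segregate.
    """

    name: str
    n_samples: int = 96
    model: str = "random_mating"  # or "backcross_like"
    maf_min: float = 0.05
    maf_max: float = 0.5
    fixed_diff_fraction: float = 0.9
    bad_sample_fraction: float = 0.05
    founder_monomorphic_fraction: float = 0.0
    class_monomorphic_fraction: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("random_mating", "backcross_like"):
            raise ValueError(f"unknown population model {self.model!r}")
        if not (0.0 <= self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("require 0 <= maf_min <= maf_max <= 0.5")


@dataclass
class IntensityModel:
    """Cluster geometry of the simulated two-channel signals.

    Genotype-conditional contrast means are +mu/0/−mu for AA/AB/BB with
    ``cluster_sd`` noise; strengths sit at a common baseline. OTV SNPs
    give a ``otv_carrier_fraction`` of samples an extra cluster at contrast
    ~0 whose strength is ``otv_strength_drop`` log2-units lower. ``nc_rate``
    of the intensity rows are dropped (missing input → no-call). Control
    probes of the two terminal classes are separated in strength for clean
    samples and collapsed for "bad" samples so the latter fail dish QC.
    """

    contrast_mu: float = 3.0
    cluster_sd: float = 0.3
    strength_baseline: float = 10.0
    strength_sd: float = 0.3
    nc_rate: float = 0.01
    otv_fraction: float = 0.05
    otv_carrier_fraction: float = 0.25
    otv_strength_drop: float = 4.0
    qc_at_mean: float = 9.0
    qc_gc_mean: float = 12.0
    qc_sd: float = 0.5


def default_populations() -> List[PopulationSpec]:
    """Wild + two backcross-generation cohorts (96 samples each)."""
    wild_mono = {
        SourceClass.GENE_INTERSPECIFIC.value: 0.9,
        SourceClass.GENE_BLUE.value: 0.8,
    }
    return [
        PopulationSpec(name="wild", model="random_mating", bad_sample_fraction=0.06,
                       class_monomorphic_fraction=wild_mono),
        PopulationSpec(name="BC1", model="backcross_like", bad_sample_fraction=0.06,
                       founder_monomorphic_fraction=0.35),
        PopulationSpec(name="BC3", model="backcross_like", bad_sample_fraction=0.0,
                       fixed_diff_fraction=0.7, founder_monomorphic_fraction=0.25),
    ]


@dataclass
class SimScenario:
    """Full study design for one simulated end-to-end run.

    Defaults give a ~1 Mb genome in sub-4-kb to above-4-kb contigs with
    around 2,000 candidate SNPs and three 96-sample cohorts — large enough
    to exercise every rule, small enough that the suite runs in minutes.
    """

    rng_seed: int = 0
    n_contigs: int = 250
    contig_len_min: int = 1500
    contig_len_max: int = 6500
    gc_background: float = 0.41
    repeat_fraction: float = 0.03
    repeat_segment_len: int = 200
    snp_density_per_kb: float = 2.0
    indel_density_per_kb: float = 0.15
    tstv_ratio: float = 1.85
    source_class_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            SourceClass.GENE_CHANNEL.value: 0.13,
            SourceClass.GENE_BLUE.value: 0.12,
            SourceClass.GENE_INTERSPECIFIC.value: 0.16,
            SourceClass.ANONYMOUS.value: 0.59,
        }
    )
    qc_probes_per_class: int = 150
    populations: List[PopulationSpec] = field(default_factory=default_populations)
    intensity: IntensityModel = field(default_factory=IntensityModel)

    def __post_init__(self) -> None:
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise ValueError("repeat_fraction must lie in [0,1]")
        if self.snp_density_per_kb < 0 or self.indel_density_per_kb < 0:
            raise ValueError("densities must be >= 0")
        total = sum(self.source_class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("source_class_fractions must sum to 1")


def _rng(scenario: SimScenario, *stream: int) -> np.random.Generator:
    return np.random.default_rng([scenario.rng_seed, *stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(scenario: SimScenario) -> Genome:
    """Random genome at the stated GC with duplicated, soft-masked repeats."""
    rng = _rng(scenario, 1)
    gc = scenario.gc_background
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seqs: List[np.ndarray] = []
    masks: List[np.ndarray] = []
    for _ in range(scenario.n_contigs):
        length = int(rng.integers(scenario.contig_len_min, scenario.contig_len_max + 1))
        seqs.append(rng.choice(_BASES, size=length, p=p))
        masks.append(np.zeros(length, dtype=bool))
    total = sum(len(s) for s in seqs)
    seg = scenario.repeat_segment_len
    n_events = int(total * scenario.repeat_fraction / (2 * seg))
    eligible = [i for i, s in enumerate(seqs) if len(s) > seg + 1]
    for _ in range(n_events):
        si = eligible[int(rng.integers(len(eligible)))]
        di = eligible[int(rng.integers(len(eligible)))]
        spos = int(rng.integers(0, len(seqs[si]) - seg))
        dpos = int(rng.integers(0, len(seqs[di]) - seg))
        segment = seqs[si][spos : spos + seg].copy()
        seqs[di][dpos : dpos + seg] = segment
        masks[si][spos : spos + seg] = True
        masks[di][dpos : dpos + seg] = True
    genome = Genome()
    width = len(str(scenario.n_contigs))
    for i, (s, m) in enumerate(zip(seqs, masks)):
        genome.add(Contig(name=f"ctg{i + 1:0{width}d}", seq="".join(s), mask=m))
    return genome


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def simulate_variants(
    genome: Genome, scenario: SimScenario
) -> Tuple[List[SnpCandidate], List[Tuple[str, int, str, str]], pd.DataFrame]:
    """Candidate SNPs and indels with per-SNP truth.

    SNP positions are uniform within each contig at the stated density;
    alternate alleles realise the configured ts:tv ratio; indels (simple
    deletions) exercise the exclusion-window filter downstream. Each contig
    carries one source class drawn at the configured fractions. Truth
    records the ts/tv label and, for inter-specific markers, nothing yet —
    fixed-difference status is a population-level property drawn at
    genotyping time.
    """
    rng = _rng(scenario, 2)
    classes = list(scenario.source_class_fractions)
    probs = np.array([scenario.source_class_fractions[c] for c in classes])
    p_ts = scenario.tstv_ratio / (1.0 + scenario.tstv_ratio)
    candidates: List[SnpCandidate] = []
    others: List[Tuple[str, int, str, str]] = []
    truth_rows = []
    for name, contig in genome.contigs.items():
        source = SourceClass(classes[int(rng.choice(len(classes), p=probs))])
        length = len(contig)
        n_snps = int(rng.poisson(scenario.snp_density_per_kb * length / 1000.0))
        n_snps = min(n_snps, length)
        positions = np.sort(rng.choice(length, size=n_snps, replace=False))
        for pos in positions:
            ref = contig.seq[pos]
            if ref not in "ACGT":
                continue
            if rng.random() < p_ts:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][int(rng.integers(2))]
            snp_id = f"snp_{name}_{pos}"
            cand = SnpCandidate(
                snp_id=snp_id, contig_id=name, pos=int(pos),
                ref_allele=ref, alt_allele=alt, source_class=source,
            )
            candidates.append(cand)
            truth_rows.append(
                {
                    "snp_id": snp_id, "contig_id": name, "pos": int(pos),
                    "ref": ref, "alt": alt, "source_class": source.value,
                    "is_transition": cand.is_transition,
                }
            )
        n_indels = int(rng.poisson(scenario.indel_density_per_kb * length / 1000.0))
        for _ in range(n_indels):
            pos = int(rng.integers(0, length - 1))
            ref = contig.seq[pos : pos + 2]
            if set(ref) - set("ACGT"):
                continue
            others.append((name, pos, ref, ref[0]))
    truth = pd.DataFrame(
        truth_rows,
        columns=["snp_id", "contig_id", "pos", "ref", "alt", "source_class",
                 "is_transition"],
    )
    return candidates, others, truth


# ---------------------------------------------------------------------------
# populations and genotypes
# ---------------------------------------------------------------------------


def simulate_population_calls(
    snps: Sequence[SnpCandidate],
    pop: PopulationSpec,
    scenario: SimScenario,
    pop_index: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """True genotypes (A-allele dosage 0/1/2) for one cohort.

    Returns (genotypes, truth): genotypes is samples × SNPs with 2 = AA,
    1 = AB, 0 = BB; truth records the per-SNP A-allele frequency and, for
    backcross-like cohorts, which inter-specific markers were drawn as
    fixed differences (AB × AA segregation).
    """
    rng = _rng(scenario, 3, pop_index)
    samples = [f"{pop.name}_s{i + 1:03d}" for i in range(pop.n_samples)]
    n = pop.n_samples
    geno = np.empty((n, len(snps)), dtype=np.int8)
    truth_rows = []
    for j, snp in enumerate(snps):
        src = snp.source_class.value
        is_fixed_diff = False
        if (
            pop.model == "backcross_like"
            and snp.source_class is SourceClass.GENE_INTERSPECIFIC
            and rng.random() < pop.fixed_diff_fraction
        ):
            # AB x AA cross: offspring 1:1 AA/AB, never the minor homozygote
            is_fixed_diff = True
            geno[:, j] = np.where(rng.random(n) < 0.5, 2, 1)
            freq_a = 0.75
        else:
            mono_p = pop.class_monomorphic_fraction.get(src, 0.0)
            if pop.model == "backcross_like":
                mono_p = max(mono_p, pop.founder_monomorphic_fraction)
            if rng.random() < mono_p:
                freq_a = 1.0
            else:
                maf = rng.uniform(pop.maf_min, pop.maf_max)
                freq_a = maf if rng.random() < 0.5 else 1.0 - maf
            geno[:, j] = rng.binomial(2, freq_a, size=n)
        truth_rows.append(
            {"snp_id": snp.snp_id, "freq_a": freq_a, "is_fixed_diff": is_fixed_diff}
        )
    genotypes = pd.DataFrame(
        geno, index=pd.Index(samples, name="sample_id"),
        columns=[s.snp_id for s in snps],
    )
    return genotypes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def _signals_from(contrast: np.ndarray, strength: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # inverse of transform_intensities (pseudo-count 1)
    a = np.power(2.0, strength + contrast / 2.0) - 1.0
    b = np.power(2.0, strength - contrast / 2.0) - 1.0
    return np.clip(a, 0.0, None), np.clip(b, 0.0, None)


def simulate_intensities(
    genotypes: pd.DataFrame,
    manifest: ArrayManifest,
    pop: PopulationSpec,
    scenario: SimScenario,
    pop_index: int = 0,
) -> Tuple[pd.DataFrame, Dict]:
    """Two-channel intensities for SNP probes and QC probes of one cohort.

    Returns the long-form intensity frame plus a truth dict with the OTV
    SNP set, per-SNP carrier samples, and the bad-sample list (whose QC
    probe classes collapse so they fail dish QC).
    """
    m = scenario.intensity
    rng = _rng(scenario, 4, pop_index)
    samples = list(genotypes.index)
    n = len(samples)

    snp_ids = [s.snp_id for s in manifest.snps]
    otv_snps: Set[str] = set(
        np.array(snp_ids)[rng.random(len(snp_ids)) < m.otv_fraction]
    )
    bad_samples = set(np.array(samples)[rng.random(n) < pop.bad_sample_fraction])

    frames = []
    otv_carriers: Dict[str, List[str]] = {}
    probes_by_snp = manifest.probes_by_snp()
    for snp in manifest.snps:
        g = genotypes[snp.snp_id].to_numpy()
        base_contrast = m.contrast_mu * (g.astype(float) - 1.0)
        is_otv = snp.snp_id in otv_snps
        carrier = np.zeros(n, dtype=bool)
        if is_otv:
            # canonical off-target signature: the probeset reads as a major
            # homozygote cluster, with divergent-allele carriers collapsing
            # to mid contrast at depressed strength
            carrier = rng.random(n) < m.otv_carrier_fraction
            otv_carriers[snp.snp_id] = [s for s, c in zip(samples, carrier) if c]
            base_contrast = np.full(n, m.contrast_mu)
        for probe in probes_by_snp[snp.snp_id]:
            contrast = base_contrast + rng.normal(0.0, m.cluster_sd, n)
            strength = m.strength_baseline + rng.normal(0.0, m.strength_sd, n)
            if is_otv:
                contrast[carrier] = rng.normal(0.0, m.cluster_sd, carrier.sum())
                strength[carrier] -= m.otv_strength_drop
            a, b = _signals_from(contrast, strength)
            frames.append(
                pd.DataFrame(
                    {"sample_id": samples, "probe_id": probe.probe_id,
                     "signal_a": a, "signal_b": b}
                )
            )
    snp_part = pd.concat(frames, ignore_index=True)
    if m.nc_rate > 0:
        keep = rng.random(len(snp_part)) >= m.nc_rate
        snp_part = snp_part.loc[keep].reset_index(drop=True)

    qc_frames = []
    mid = (m.qc_at_mean + m.qc_gc_mean) / 2.0
    for q in manifest.qc_probes:
        clean_mean = m.qc_at_mean if q.terminal_class == "AT" else m.qc_gc_mean
        means = np.array([mid if s in bad_samples else clean_mean for s in samples])
        strength = means + rng.normal(0.0, m.qc_sd, n)
        a, b = _signals_from(np.zeros(n), strength)
        qc_frames.append(
            pd.DataFrame(
                {"sample_id": samples, "probe_id": q.probe_id,
                 "signal_a": a, "signal_b": b}
            )
        )
    intensity = pd.concat([snp_part, *qc_frames], ignore_index=True)
    truth = {
        "otv_snps": otv_snps,
        "otv_carriers": otv_carriers,
        "bad_samples": sorted(bad_samples),
    }
    return intensity, truth
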