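"""End-to-end orchestration: simulate → filter → score → design → genotype.

The stages are pure library calls; this module wires them together for the
CLI and for closed-loop simulation studies where every downstream result
can be checked against generator truth.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filtering import FilterOutcome, run_filters
from .genome import Genome, KmerIndex
from .genotyping import CallSet, call_dataset
from .models import (
    ArrayManifest,
    ClassifierConfig,
    FilterConfig,
    ProbeSelectionConfig,
    QcProbe,
    QcProbeConfig,
    ReportConfig,
    SampleQcConfig,
    ScoreWeights,
    SelectionConfig,
    SnpCandidate,
    SourceClass,
)
from .scoring import score_snp
from .selection import ProbeChoice, build_manifest, generate_qc_probes, select_per_contig, select_probes
from .simulate import SimScenario, simulate_genome, simulate_intensities, simulate_population_calls, simulate_variants

logger = logging.getLogger(__name__)


@dataclass
class DesignResult:
    outcomes: List[FilterOutcome]
    designs: Dict[str, tuple]
    decisions: Dict[str, ProbeChoice]
    selected: List[SnpCandidate]
    manifest: ArrayManifest
    summary: Dict


def design_panel(
    genome: Genome,
    candidates: Sequence[SnpCandidate],
    other_variants: Sequence[Tuple[str, int]],
    filter_cfg: Optional[FilterConfig] = None,
    selection_cfg: Optional[SelectionConfig] = None,
    probe_cfg: Optional[ProbeSelectionConfig] = None,
    qc_cfg: Optional[QcProbeConfig] = None,
    weights: Optional[ScoreWeights] = None,
) -> DesignResult:
    """Filter, score, select and assemble a manifest from candidates.

    Stage order mirrors array practice: sequence filters → per-strand
    scoring → per-contig spacing selection (gene and anonymous sets
    separately) → score threshold and probe tiling → QC probes.
    """
    filter_cfg = filter_cfg or FilterConfig()
    kmer_index = KmerIndex.from_genome(genome, filter_cfg.repeat_kmer)
    outcomes = run_filters(candidates, other_variants, genome, filter_cfg, kmer_index)
    passed_ids = {o.snp_id for o in outcomes if o.passed}
    survivors = [c for c in candidates if c.snp_id in passed_ids]
    logger.info("design: %d of %d candidates pass filters", len(survivors), len(candidates))

    designs = {c.snp_id: score_snp(c, genome, kmer_index, weights) for c in survivors}
    scores = {sid: max(f.pconvert, r.pconvert) for sid, (f, r) in designs.items()}

    gene_groups: Dict[str, List[SnpCandidate]] = defaultdict(list)
    anon_groups: Dict[str, List[SnpCandidate]] = defaultdict(list)
    for c in survivors:
        (gene_groups if c.source_class.is_gene else anon_groups)[c.contig_id].append(c)
    lengths = genome.lengths()
    selected = select_per_contig(gene_groups, lengths, selection_cfg,
                                 is_gene_set=True, scores=scores)
    selected += select_per_contig(anon_groups, lengths, selection_cfg,
                                  is_gene_set=False, scores=scores)

    decisions = {
        c.snp_id: select_probes(designs[c.snp_id][0].pconvert,
                                designs[c.snp_id][1].pconvert, probe_cfg)
        for c in selected
    }

    variant_positions: Dict[str, List[int]] = defaultdict(list)
    for c in candidates:
        variant_positions[c.contig_id].append(c.pos)
    for contig, pos in other_variants:
        variant_positions[contig].append(pos)
    qc_probes = generate_qc_probes(genome, variant_positions, qc_cfg, kmer_index)

    manifest, summary = build_manifest(selected, designs, decisions, qc_probes)
    logger.info("design: manifest has %d SNPs, %d probes, %d QC probes",
                summary["n_snps"], summary["n_probes"], summary["n_qc_probes"])
    return DesignResult(outcomes=outcomes, designs=designs, decisions=decisions,
                        selected=selected, manifest=manifest, summary=summary)


@dataclass
class ScenarioRun:
    scenario: SimScenario
    genome: Genome
    candidates: List[SnpCandidate]
    other_variants: List[tuple]
    variant_truth: pd.DataFrame
    design: DesignResult
    genotype_truth: Dict[str, pd.DataFrame] = field(default_factory=dict)
    population_truth: Dict[str, pd.DataFrame] = field(default_factory=dict)
    intensities: Dict[str, pd.DataFrame] = field(default_factory=dict)
    intensity_truth: Dict[str, Dict] = field(default_factory=dict)
    callsets: Dict[str, CallSet] = field(default_factory=dict)

    @property
    def manifest(self) -> ArrayManifest:
        return self.design.manifest


def run_scenario(
    scenario: Optional[SimScenario] = None,
    genotype: bool = True,
    sample_cfg: Optional[SampleQcConfig] = None,
    classifier_cfg: Optional[ClassifierConfig] = None,
) -> ScenarioRun:
    """Run the full simulated study for one scenario seed."""
    scenario = scenario or SimScenario()
    genome = simulate_genome(scenario)
    candidates, others, variant_truth = simulate_variants(genome, scenario)
    qc_cfg = QcProbeConfig(
        n_at_terminal=scenario.qc_probes_per_class,
        n_gc_terminal=scenario.qc_probes_per_class,
        rng_seed=scenario.rng_seed,
    )
    design = design_panel(
        genome,
        candidates,
        [(c, p) for c, p, _, _ in others],
        qc_cfg=qc_cfg,
    )
    run = ScenarioRun(
        scenario=scenario,
        genome=genome,
        candidates=candidates,
        other_variants=others,
        variant_truth=variant_truth,
        design=design,
    )
    if not genotype:
        return run
    manifest = design.manifest
    for i, pop in enumerate(scenario.populations):
        genotypes, pop_truth = simulate_population_calls(
            manifest.snps, pop, scenario, pop_index=i
        )
        intensity, int_truth = simulate_intensities(
            genotypes, manifest, pop, scenario, pop_index=i
        )
        run.genotype_truth[pop.name] = genotypes
        run.population_truth[pop.name] = pop_truth
        run.intensities[pop.name] = intensity
        run.intensity_truth[pop.name] = int_truth
        run.callsets[pop.name] = call_dataset(
            intensity, manifest, sample_cfg, classifier_cfg
        )
    return run


def genotype_concordance(calls: pd.DataFrame, truth_dosage: pd.DataFrame) -> float:
    """Fraction of non-NC calls agreeing with true genotypes.

    ``truth_dosage`` holds A-allele dosage (2/1/0 → AA/AB/BB); only
    samples and SNPs present in both frames are compared.
    """
    code = {2: "AA", 1: "AB", 0: "BB"}
    samples = calls.index.intersection(truth_dosage.index)
    snps = calls.columns.intersection(truth_dosage.columns)
    if len(samples) == 0 or len(snps) == 0:
        return float("nan")
    obs = calls.loc[samples, snps].to_numpy()
    exp = truth_dosage.loc[samples, snps].replace(code).to_numpy()
    called = obs != "NC"
    if not called.any():
        return float("nan")
    return float((obs[called] == exp[called]).mean())


# ---------------------------------------------------------------------------
# reduced genotyping-only scenario (parameter recovery studies)
# ---------------------------------------------------------------------------


def make_recovery_inputs(
    seed: int = 0,
    n_snps: int = 250,
    n_samples: int = 200,
    cluster_sd: float = 0.3,
    nc_rate: float = 0.02,
    otv_fraction: float = 0.0,
    n_qc_probes: int = 60,
    model: str = "random_mating",
) -> Tuple[ArrayManifest, pd.DataFrame, pd.DataFrame, SimScenario]:
    """Manifest + intensities for a genotyping-only recovery study.

    Builds a synthetic single-probe manifest directly (no genome or
    filtering), draws Hardy–Weinberg genotypes at MAF ~ U(0.05, 0.5) (or
    backcross-like segregation), and simulates intensities at the stated
    cluster noise. Returns (manifest, intensities, true genotype dosages,
    scenario, intensity truth).
    """
    from .models import ProbeDesign, Strand

    rng = np.random.default_rng([seed, 99])
    bases = np.array(list("ACGT"))
    snps = []
    probes = []
    for j in range(n_snps):
        seq = "".join(rng.choice(bases, size=35))
        src = SourceClass.GENE_INTERSPECIFIC if model == "backcross_like" else SourceClass.ANONYMOUS
        snps.append(
            SnpCandidate(snp_id=f"rsnp{j + 1:04d}", contig_id="simctg", pos=j * 100 + 50,
                         ref_allele="A", alt_allele="G", source_class=src)
        )
        probes.append(
            ProbeDesign(probe_id=f"rsnp{j + 1:04d}_F", snp_id=f"rsnp{j + 1:04d}",
                        strand=Strand.FORWARD, probe_seq=seq, pconvert=0.9)
        )
    qc_probes = []
    for i in range(n_qc_probes):
        klass = "AT" if i % 2 == 0 else "GC"
        seq = "".join(rng.choice(bases, size=30)) + ("A" if klass == "AT" else "G")
        qc_probes.append(
            QcProbe(probe_id=f"rqc{i + 1:03d}", seq=seq, terminal_class=klass,
                    contig_id="simctg", pos=100_000 + 40 * i)
        )
    manifest = ArrayManifest(snps=snps, probes=probes, qc_probes=qc_probes)
    manifest.validate()

    from .simulate import IntensityModel, PopulationSpec

    scenario = SimScenario(
        rng_seed=seed,
        populations=[
            PopulationSpec(name="recovery", n_samples=n_samples, model=model,
                           bad_sample_fraction=0.0, fixed_diff_fraction=1.0)
        ],
        intensity=IntensityModel(cluster_sd=cluster_sd, nc_rate=nc_rate,
                                 otv_fraction=otv_fraction),
    )
    pop = scenario.populations[0]
    genotypes, _ = simulate_population_calls(manifest.snps, pop, scenario)
    intensity, intensity_truth = simulate_intensities(genotypes, manifest, pop, scenario)
    return manifest, intensity, genotypes, scenario, intensity_truth
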