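"""Shared fixtures: tiny deterministic genomes and session-scoped runs.

The expensive simulations (genotype-recovery cohort, end-to-end scenario)
are session-scoped so every test module reuses one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from panelforge.genome import Contig, Genome
from panelforge.genotyping import call_dataset
from panelforge.models import SnpCandidate, SourceClass
from panelforge.pipeline import make_recovery_inputs, run_scenario
from panelforge.simulate import PopulationSpec, SimScenario


def random_contig(name: str, length: int, seed: int, gc: float = 0.5) -> Contig:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return Contig.from_string(name, seq)


@pytest.fixture
def toy_genome() -> Genome:
    """Three random contigs, ~2 kb each, no repeats."""
    g = Genome()
    for i, length in enumerate((2000, 2500, 1800)):
        g.add(random_contig(f"c{i + 1}", length, seed=100 + i))
    return g


def make_candidate(genome: Genome, contig: str, pos: int, snp_id: str = None,
                   source=SourceClass.ANONYMOUS, alt: str = None) -> SnpCandidate:
    ref = genome[contig].seq[pos]
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    return SnpCandidate(
        snp_id=snp_id or f"{contig}_{pos}",
        contig_id=contig,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt or transition[ref],
        source_class=source,
    )


@pytest.fixture(scope="session")
def recovery():
    """Genotyping-only recovery cohort: 250 SNPs × 200 samples, sd 0.3."""
    manifest, intensity, genotypes, scenario, truth = make_recovery_inputs(
        seed=1, n_snps=250, n_samples=200
    )
    callset = call_dataset(intensity, manifest)
    return {
        "manifest": manifest,
        "intensity": intensity,
        "genotypes": genotypes,
        "scenario": scenario,
        "truth": truth,
        "callset": callset,
    }


def small_scenario(seed: int = 11) -> SimScenario:
    """Reduced end-to-end scenario: two 48-sample cohorts, ~80 contigs."""
    return SimScenario(
        rng_seed=seed,
        n_contigs=80,
        qc_probes_per_class=60,
        populations=[
            PopulationSpec(name="wild", model="random_mating",
                           bad_sample_fraction=0.06,
                           class_monomorphic_fraction={
                               SourceClass.GENE_INTERSPECIFIC.value: 0.9,
                               SourceClass.GENE_BLUE.value: 0.8,
                           },
                           n_samples=48),
            PopulationSpec(name="BC1", model="backcross_like",
                           founder_monomorphic_fraction=0.35,
                           bad_sample_fraction=0.0, n_samples=48),
        ],
    )


@pytest.fixture(scope="session")
def scenario_run():
    """One full simulated run (design + genotyping) on the small scenario."""
    return run_scenario(small_scenario())


@pytest.fixture(scope="session")
def design_run():
    """Design-only run (no genotyping) on a slightly larger genome."""
    return run_scenario(SimScenario(rng_seed=5, n_contigs=120), genotype=False)
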