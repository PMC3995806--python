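"""Domain types and configuration objects shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; VCF input
is shifted by −1 on ingestion and every TSV the package emits carries
0-based positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FLANK_LEN = 35  #: bases of context on each side of the interrogated site
FLANK_TOTAL = 2 * FLANK_LEN + 1  #: full flank length including the site (71)


class SourceClass(str, enum.Enum):
    """Origin of a candidate SNP.

    Gene-associated candidates come from transcript contigs of either
    parental species or from fixed inter-specific differences; anonymous
    candidates come from non-coding genomic contigs.
    """

    GENE_CHANNEL = "gene_channel"
    GENE_BLUE = "gene_blue"
    GENE_INTERSPECIFIC = "gene_interspecific"
    ANONYMOUS = "anonymous"

    @property
    def is_gene(self) -> bool:
        return self is not SourceClass.ANONYMOUS


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


_BASES = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


@dataclass
class SnpCandidate:
    """One bi-allelic SNP candidate on a contig.

    ``pos`` is 0-based. ``flank`` (when set) is the 71-base window
    ``contig[pos-35 : pos+36]`` with the reference base at index 35.
    """

    snp_id: str
    contig_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    source_class: SourceClass = SourceClass.ANONYMOUS
    flank: Optional[str] = None

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position {self.pos}")
        if self.flank is not None:
            if len(self.flank) != FLANK_TOTAL:
                raise ValueError(
                    f"{self.snp_id}: flank length {len(self.flank)} != {FLANK_TOTAL}"
                )
            if self.flank[FLANK_LEN].upper() != self.ref_allele:
                raise ValueError(
                    f"{self.snp_id}: flank centre {self.flank[FLANK_LEN]} != ref "
                    f"{self.ref_allele}"
                )

    @property
    def allele_pair(self) -> frozenset:
        return frozenset((self.ref_allele, self.alt_allele))

    @property
    def is_transition(self) -> bool:
        return self.allele_pair in _TRANSITIONS


@dataclass
class ProbeDesign:
    """An oriented 35-mer interrogation probe for one SNP.

    The probe covers the 35 bases immediately 5' of the interrogated site on
    its strand, ending adjacent to the site; ``pconvert`` is the design score
    in [0, 1] predicting conversion on the array.
    """

    probe_id: str
    snp_id: str
    strand: Strand
    probe_seq: str
    pconvert: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pconvert <= 1.0):
            raise ValueError(f"{self.probe_id}: pconvert {self.pconvert} outside [0,1]")


@dataclass
class QcProbe:
    """Non-polymorphic 31-mer control probe used only for sample QC."""

    probe_id: str
    seq: str
    terminal_class: str  # "AT" or "GC", by the final base
    contig_id: str
    pos: int

    def __post_init__(self) -> None:
        if self.terminal_class not in ("AT", "GC"):
            raise ValueError(f"terminal_class must be AT or GC, got {self.terminal_class}")


@dataclass
class ArrayManifest:
    """The finalized panel: SNPs, their 1–2 probes each, and QC probes."""

    snps: list
    probes: list
    qc_probes: list = field(default_factory=list)

    def probes_by_snp(self) -> dict:
        out: dict = {}
        for p in self.probes:
            out.setdefault(p.snp_id, []).append(p)
        return out

    def snp_by_id(self) -> dict:
        return {s.snp_id: s for s in self.snps}

    def validate(self) -> None:
        snp_ids = {s.snp_id for s in self.snps}
        by_snp = self.probes_by_snp()
        for p in self.probes:
            if p.snp_id not in snp_ids:
                raise ValueError(f"probe {p.probe_id} references unknown SNP {p.snp_id}")
        for sid in snp_ids:
            n = len(by_snp.get(sid, []))
            if n not in (1, 2):
                raise ValueError(f"SNP {sid} has {n} probes; expected 1 or 2")
        for s in self.snps:
            if s.allele_pair in (frozenset("AT"), frozenset("CG")):
                raise ValueError(f"A/T or C/G SNP {s.snp_id} present in manifest")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    """Sequence-level eligibility rules for candidate SNPs."""

    flank_len: int = FLANK_LEN
    exclusion_window: int = 30
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_gc_run: int = 4
    max_at_run: int = 6
    repeat_kmer: int = 16
    repeat_max_copies: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min < self.gc_max <= 1.0):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        for name in ("flank_len", "exclusion_window", "max_gc_run", "max_at_run",
                     "repeat_kmer", "repeat_max_copies"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class SelectionConfig:
    """Per-contig selection counts."""

    contig_len_threshold: int = 4000
    max_per_small_contig: int = 1
    max_per_large_contig: int = 2
    gene_min_per_contig: int = 1
    gene_max_per_contig: int = 2

    def __post_init__(self) -> None:
        if self.contig_len_threshold <= 0:
            raise ValueError("contig_len_threshold must be positive")
        if self.max_per_small_contig > self.max_per_large_contig:
            raise ValueError("max_per_small_contig must be <= max_per_large_contig")


@dataclass
class ProbeSelectionConfig:
    """Score threshold and dual-probe band for probe tiling."""

    pconvert_min: float = 0.5
    dual_probe_band_max: float = 0.6

    def __post_init__(self) -> None:
        if not (self.pconvert_min < self.dual_probe_band_max <= 1.0):
            raise ValueError("require pconvert_min < dual_probe_band_max <= 1")


@dataclass
class QcProbeConfig:
    probe_len: int = 31
    n_at_terminal: int = 1000
    n_gc_terminal: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_len < 1:
            raise ValueError("probe_len must be >= 1")
        if self.n_at_terminal < 0 or self.n_gc_terminal < 0:
            raise ValueError("probe counts must be >= 0")


@dataclass
class SampleQcConfig:
    """Two-stage sample QC thresholds (dish QC, then post-calling call rate)."""

    dqc_min: float = 0.82
    call_rate_min: float = 0.97
    nocall_posterior: float = 0.95

    def __post_init__(self) -> None:
        for name in ("dqc_min", "call_rate_min", "nocall_posterior"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")


@dataclass
class ClassifierConfig:
    """Thresholds of the probeset classifier surrogate.

    The six categories are named after the canonical genotyping-console
    vocabulary; the numeric floors are this package's documented defaults
    (the category names alone do not fix them).
    """

    snp_call_rate_min: float = 0.95
    sep_min: float = 2.0
    het_margin: float = 0.5
    otv_strength_sds: float = 2.0
    sd_floor: float = 0.05
    nocall_posterior: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.snp_call_rate_min <= 1.0):
            raise ValueError("snp_call_rate_min must lie in [0,1]")
        if self.sep_min < 0 or self.het_margin < 0 or self.otv_strength_sds < 0:
            raise ValueError("floors must be non-negative")


@dataclass
class ScoreWeights:
    """Weights of the deterministic design-score surrogate."""

    w_gc: float = 4.0
    w_run: float = 0.5
    w_uniq: float = 1.5
    w_tm: float = 1.0
    bias: float = 2.5

    def __post_init__(self) -> None:
        for name in ("w_gc", "w_run", "w_uniq", "w_tm", "bias"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class ReportConfig:
    maf_bin_width: float = 0.05
    spacing_bin_edges: tuple = (0, 500, 1000, 2000, 3000, 4000, 5000, 6000)

    def __post_init__(self) -> None:
        edges = tuple(self.spacing_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("spacing_bin_edges must be strictly increasing")
        if not (0.0 < self.maf_bin_width <= 0.5):
            raise ValueError("maf_bin_width must lie in (0, 0.5]")
        self.spacing_bin_edges = edges


class SnpCategory(str, enum.Enum):
    """Six-way probeset quality classification.

    Convertible probesets are the first four categories; polymorphic ones
    are the first two.
    """

    POLY_HIGH_RESOLUTION = "PolyHighResolution"
    NO_MINOR_HOM = "NoMinorHom"
    MONO_HIGH_RESOLUTION = "MonoHighResolution"
    OTV = "OTV"
    CALL_RATE_BELOW_THRESHOLD = "CallRateBelowThreshold"
    OTHER = "Other"

    @property
    def convertible(self) -> bool:
        return self in _CONVERTIBLE

    @property
    def polymorphic(self) -> bool:
        return self in _POLYMORPHIC


_CONVERTIBLE = frozenset(
    {
        SnpCategory.POLY_HIGH_RESOLUTION,
        SnpCategory.NO_MINOR_HOM,
        SnpCategory.MONO_HIGH_RESOLUTION,
        SnpCategory.OTV,
    }
)
_POLYMORPHIC = frozenset({SnpCategory.POLY_HIGH_RESOLUTION, SnpCategory.NO_MINOR_HOM})

#: dual-probe SNPs take the best of their probes' categories under this order
CATEGORY_PRIORITY = (
    SnpCategory.POLY_HIGH_RESOLUTION,
    SnpCategory.NO_MINOR_HOM,
    SnpCategory.OTV,
    SnpCategory.MONO_HIGH_RESOLUTION,
    SnpCategory.CALL_RATE_BELOW_THRESHOLD,
    SnpCategory.OTHER,
)


def best_category(categories) -> SnpCategory:
    """Highest-priority category among a SNP's probe categories."""
    cats = list(categories)
    if not cats:
        raise ValueError("no categories supplied")
    for c in CATEGORY_PRIORITY:
        if c in cats:
            return c
    raise ValueError(f"unknown categories {cats}")
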