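"""Sequence-level eligibility rules for candidate SNPs.

A candidate survives when its 71-base flank (35 bases each side of the
site) can be extracted, its alleles are resolvable with one probe pair
(no A/T or C/G pairs), no other variant lies within the exclusion window,
flank GC content is balanced, no disqualifying homopolymer run is present,
and the flank is unique and unmasked in the genome. All rules are
independent predicates; every violated rule is recorded, not just the
first.
"""

from __future__ import annotations

import enum
import itertools
import logging
import warnings
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genome import Genome, KmerIndex
from .models import FilterConfig, SnpCandidate

logger = logging.getLogger(__name__)

_AT_CG = (frozenset("AT"), frozenset("CG"))
_ACGT = frozenset("ACGT")


class FilterRule(str, enum.Enum):
    EDGE = "edge"
    NEARBY_VARIANT = "nearby_variant"
    GC_CONTENT = "gc_content"
    HOMOPOLYMER = "homopolymer"
    REPEAT = "repeat"
    AT_CG_ALLELE = "at_cg_allele"


@dataclass
class FilterOutcome:
    snp_id: str
    passed: bool
    failed_rules: List[FilterRule] = field(default_factory=list)
    gc_fraction: Optional[float] = None
    max_run_gc: Optional[int] = None
    max_run_at: Optional[int] = None

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError("passed flag inconsistent with failed_rules")


def extract_flank(
    candidate: SnpCandidate, genome: Genome, cfg: FilterConfig
) -> Optional[FilterRule]:
    """Set ``candidate.flank`` from the genome; return EDGE on failure.

    The flank is ``contig[pos-35 : pos+36]`` (71 bases, site at index 35);
    candidates with fewer than 35 bases on either side fail.
    """
    if candidate.contig_id not in genome:
        raise KeyError(f"contig {candidate.contig_id!r} not in genome")
    contig = genome[candidate.contig_id]
    if candidate.pos >= len(contig):
        raise ValueError(
            f"{candidate.snp_id}: pos {candidate.pos} beyond contig "
            f"length {len(contig)}"
        )
    lo = candidate.pos - cfg.flank_len
    hi = candidate.pos + cfg.flank_len + 1
    if lo < 0 or hi > len(contig):
        return FilterRule.EDGE
    candidate.flank = contig.seq[lo:hi]
    return None


def filter_allele_type(candidate: SnpCandidate) -> bool:
    """Fail (False) for A/T and C/G allele pairs, which need twice the probes."""
    return candidate.allele_pair not in _AT_CG


def classify_ts_tv(candidate: SnpCandidate) -> str:
    """'transition' for {A,G}/{C,T} pairs, else 'transversion'."""
    return "transition" if candidate.is_transition else "transversion"


class VariantNeighbourhood:
    """Sorted per-contig positions of all variants, for window queries."""

    def __init__(self, positions_by_contig: Dict[str, Sequence[int]]):
        self._pos = {c: sorted(p) for c, p in positions_by_contig.items()}

    @classmethod
    def from_variants(
        cls,
        candidates: Iterable[SnpCandidate],
        other_variants: Iterable[Tuple[str, int]],
    ) -> "VariantNeighbourhood":
        by_contig: Dict[str, List[int]] = defaultdict(list)
        for c in candidates:
            by_contig[c.contig_id].append(c.pos)
        for contig, pos in other_variants:
            by_contig[contig].append(pos)
        return cls(by_contig)

    def others_within(self, contig: str, pos: int, window: int) -> int:
        """Count variants other than the one at ``pos`` with |d| <= window."""
        positions = self._pos.get(contig, [])
        lo = bisect_left(positions, pos - window)
        hi = bisect_right(positions, pos + window)
        n = hi - lo
        # discount the candidate's own record (present exactly once)
        lo_self = bisect_left(positions, pos)
        if lo_self < len(positions) and positions[lo_self] == pos:
            n -= 1
        return max(n, 0)


def filter_nearby_variants(
    candidate: SnpCandidate, neighbourhood: VariantNeighbourhood, cfg: FilterConfig
) -> bool:
    """Pass iff no other variant lies within ±exclusion_window (inclusive)."""
    return (
        neighbourhood.others_within(
            candidate.contig_id, candidate.pos, cfg.exclusion_window
        )
        == 0
    )


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def filter_gc(flank: str, cfg: FilterConfig) -> Tuple[bool, float]:
    """Closed-interval GC bounds; ambiguity bases disqualify."""
    frac = gc_fraction(flank)
    if set(flank) - _ACGT:
        return False, frac
    return cfg.gc_min <= frac <= cfg.gc_max, frac


def max_base_runs(seq: str) -> Dict[str, int]:
    """Longest maximal single-base run per base present in ``seq``."""
    runs: Dict[str, int] = {}
    for base, group in itertools.groupby(seq):
        n = sum(1 for _ in group)
        if n > runs.get(base, 0):
            runs[base] = n
    return runs


def filter_homopolymer(flank: str, cfg: FilterConfig) -> Tuple[bool, int, int]:
    """Fail on G/C runs longer than 4 or A/T runs longer than 6.

    Returns (pass, longest G-or-C run, longest A-or-T run). The limits apply
    symmetrically within each complement pair, so the verdict is invariant
    under reverse complement.
    """
    runs = max_base_runs(flank)
    run_gc = max(runs.get("G", 0), runs.get("C", 0))
    run_at = max(runs.get("A", 0), runs.get("T", 0))
    ok = run_gc <= cfg.max_gc_run and run_at <= cfg.max_at_run
    return ok, run_gc, run_at


def filter_repeats(
    candidate: SnpCandidate,
    genome: Genome,
    kmer_index: KmerIndex,
    cfg: FilterConfig,
) -> bool:
    """Fail if any flank base is soft-masked or any flank k-mer is non-unique.

    Flanks shorter than k pass fail-safe with a warning.
    """
    flank = candidate.flank
    if flank is None:
        raise ValueError(f"{candidate.snp_id}: flank not extracted")
    if len(flank) < cfg.repeat_kmer:
        warnings.warn(
            f"{candidate.snp_id}: flank shorter than repeat k-mer "
            f"({len(flank)} < {cfg.repeat_kmer}); repeat test skipped"
        )
        return True
    contig = genome[candidate.contig_id]
    lo = candidate.pos - cfg.flank_len
    hi = candidate.pos + cfg.flank_len + 1
    if contig.mask[lo:hi].any():
        return False
    return kmer_index.max_copies(flank) <= cfg.repeat_max_copies


def run_filters(
    candidates: Sequence[SnpCandidate],
    other_variants: Iterable[Tuple[str, int]],
    genome: Genome,
    cfg: Optional[FilterConfig] = None,
    kmer_index: Optional[KmerIndex] = None,
) -> List[FilterOutcome]:
    """Apply all rules to every candidate, recording every violated rule.

    Order of application: edge, allele type, nearby variant, GC,
    homopolymer, repeat. Sequence-content rules are skipped when no flank
    could be extracted (their inputs do not exist). Flanks are set in place
    on the candidates.
    """
    cfg = cfg or FilterConfig()
    if kmer_index is None:
        kmer_index = KmerIndex.from_genome(genome, cfg.repeat_kmer)
    neighbourhood = VariantNeighbourhood.from_variants(candidates, other_variants)
    outcomes: List[FilterOutcome] = []
    for cand in candidates:
        failed: List[FilterRule] = []
        edge = extract_flank(cand, genome, cfg)
        if edge is not None:
            failed.append(edge)
        if not filter_allele_type(cand):
            failed.append(FilterRule.AT_CG_ALLELE)
        if not filter_nearby_variants(cand, neighbourhood, cfg):
            failed.append(FilterRule.NEARBY_VARIANT)
        frac = run_gc = run_at = None
        if cand.flank is not None:
            ok_gc, frac = filter_gc(cand.flank, cfg)
            if not ok_gc:
                failed.append(FilterRule.GC_CONTENT)
            ok_run, run_gc, run_at = filter_homopolymer(cand.flank, cfg)
            if not ok_run:
                failed.append(FilterRule.HOMOPOLYMER)
            if not filter_repeats(cand, genome, kmer_index, cfg):
                failed.append(FilterRule.REPEAT)
        outcomes.append(
            FilterOutcome(
                snp_id=cand.snp_id,
                passed=not failed,
                failed_rules=failed,
                gc_fraction=frac,
                max_run_gc=run_gc,
                max_run_at=run_at,
            )
        )
    n_pass = sum(o.passed for o in outcomes)
    logger.info("filtered %d candidates: %d pass, %d fail",
                len(outcomes), n_pass, len(outcomes) - n_pass)
    return outcomes


def outcomes_to_frame(outcomes: Sequence[FilterOutcome]):
    """Tabular view of outcomes (TSV schema of the `filter` CLI stage)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "snp_id": [o.snp_id for o in outcomes],
            "passed": [o.passed for o in outcomes],
            "failed_rules": [",".join(r.value for r in o.failed_rules) for o in outcomes],
            "gc_fraction": [o.gc_fraction for o in outcomes],
            "max_run_gc": [o.max_run_gc for o in outcomes],
            "max_run_at": [o.max_run_at for o in outcomes],
        }
    )
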