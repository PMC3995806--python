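"""Turn scored, filtered candidates into a finalized array manifest.

Per-contig selection keeps one SNP on short contigs and two maximally
spaced SNPs on long ones; probe tiling applies the score threshold with a
dual-probe band for low-scoring SNPs; QC probes are non-polymorphic unique
31-mers sampled away from known variants.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import Genome, KmerIndex
from .models import (
    ArrayManifest,
    ProbeDesign,
    ProbeSelectionConfig,
    QcProbe,
    QcProbeConfig,
    SelectionConfig,
    SnpCandidate,
    SourceClass,
    Strand,
)

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class ProbeChoice(enum.Enum):
    DROP_SNP = "drop_snp"
    KEEP_FORWARD = "keep_forward"
    KEEP_REVERSE = "keep_reverse"
    KEEP_BOTH = "keep_both"


def _pick_one(cands: Sequence[SnpCandidate], scores: Mapping[str, float]):
    """Single-SNP tie-break: higher score, then lower position, then id."""
    return min(cands, key=lambda c: (-scores.get(c.snp_id, 0.0), c.pos, c.snp_id))


def select_per_contig(
    candidates_by_contig: Mapping[str, Sequence[SnpCandidate]],
    contig_lengths: Mapping[str, int],
    cfg: Optional[SelectionConfig] = None,
    is_gene_set: bool = False,
    scores: Optional[Mapping[str, float]] = None,
) -> List[SnpCandidate]:
    """Pick 1–2 SNPs per contig for good genome spacing.

    Anonymous contigs shorter than the length threshold contribute one SNP;
    contigs at or above it contribute the two candidates with the largest
    pairwise distance (a single candidate is kept as-is). Gene (transcript)
    contigs contribute between one and two SNPs under the same max-spacing
    rule regardless of length. ``scores`` (snp_id → best probe pconvert)
    break ties: higher score first, then lower position.
    """
    cfg = cfg or SelectionConfig()
    scores = scores or {}
    selected: List[SnpCandidate] = []
    for contig, cands in candidates_by_contig.items():
        if not cands:
            continue
        if is_gene_set:
            n_take = min(cfg.gene_max_per_contig, len(cands))
            n_take = max(n_take, cfg.gene_min_per_contig)
        else:
            length = contig_lengths[contig]
            small = length < cfg.contig_len_threshold
            n_take = cfg.max_per_small_contig if small else cfg.max_per_large_contig
        n_take = min(n_take, len(cands))
        if n_take <= 1:
            selected.append(_pick_one(cands, scores))
        else:
            selected.extend(_max_spacing_pair(cands, scores))
    return selected


def _max_spacing_pair(
    cands: Sequence[SnpCandidate], scores: Mapping[str, float]
) -> Tuple[SnpCandidate, SnpCandidate]:
    """The pair attaining the maximum |pos_i − pos_j|.

    Equivalent to taking one candidate at the minimum and one at the
    maximum position; ties within an endpoint go to the higher-scoring,
    then lower-id candidate.
    """
    lo_pos = min(c.pos for c in cands)
    first = _pick_one([c for c in cands if c.pos == lo_pos], scores)
    rest = [c for c in cands if c is not first]
    hi_pos = max(c.pos for c in rest)
    second = _pick_one([c for c in rest if c.pos == hi_pos], scores)
    return first, second


def select_probes(
    forward_score: float,
    reverse_score: float,
    cfg: Optional[ProbeSelectionConfig] = None,
) -> ProbeChoice:
    """Tiling decision from the two strand scores.

    Drop the SNP when neither probe clears the threshold; tile both probes
    when both scores sit in the low band just above the threshold (dual
    tiling raises the conversion chance of marginal SNPs); otherwise tile
    the single higher-scoring probe (ties go forward).
    """
    cfg = cfg or ProbeSelectionConfig()
    f, r = forward_score, reverse_score
    if max(f, r) <= cfg.pconvert_min:
        return ProbeChoice.DROP_SNP
    lo, hi = cfg.pconvert_min, cfg.dual_probe_band_max
    if lo < f < hi and lo < r < hi:
        return ProbeChoice.KEEP_BOTH
    return ProbeChoice.KEEP_FORWARD if f >= r else ProbeChoice.KEEP_REVERSE


def generate_qc_probes(
    genome: Genome,
    known_variant_positions: Mapping[str, Iterable[int]],
    cfg: Optional[QcProbeConfig] = None,
    kmer_index: Optional[KmerIndex] = None,
    repeat_kmer: int = 16,
) -> List[QcProbe]:
    """Sample non-polymorphic, non-repetitive 31-mers as sample-QC probes.

    Exactly ``n_at_terminal`` probes end in A/T and ``n_gc_terminal`` end in
    G/C; every probe is ambiguity-free, unmasked, unique in the genome by
    the k-mer test, overlaps no known variant, and sequences are distinct.
    Sampling is without replacement and deterministic given the seed.
    """
    cfg = cfg or QcProbeConfig()
    if kmer_index is None:
        kmer_index = KmerIndex.from_genome(genome, repeat_kmer)
    rng = np.random.default_rng(cfg.rng_seed)
    variant_pos = {c: np.sort(np.fromiter(p, dtype=np.int64))
                   for c, p in known_variant_positions.items()}
    names = [n for n in genome if len(genome[n]) >= cfg.probe_len]
    if not names:
        raise ValueError("no contig long enough for QC probes")
    weights = np.array([len(genome[n]) - cfg.probe_len + 1 for n in names], float)
    weights /= weights.sum()
    need = {"AT": cfg.n_at_terminal, "GC": cfg.n_gc_terminal}
    got: Dict[str, int] = {"AT": 0, "GC": 0}
    seen_seqs = set()
    probes: List[QcProbe] = []
    max_attempts = 500 * (sum(need.values()) + 1) + 10_000
    attempts = 0
    while (got["AT"] < need["AT"] or got["GC"] < need["GC"]) and attempts < max_attempts:
        attempts += 1
        contig = genome[names[rng.choice(len(names), p=weights)]]
        start = int(rng.integers(0, len(contig) - cfg.probe_len + 1))
        end = start + cfg.probe_len
        seq = contig.seq[start:end]
        terminal = seq[-1]
        klass = "AT" if terminal in "AT" else ("GC" if terminal in "GC" else None)
        if klass is None or got[klass] >= need[klass]:
            continue
        if seq in seen_seqs or set(seq) - _ACGT:
            continue
        if contig.mask[start:end].any():
            continue
        pos = variant_pos.get(contig.name)
        if pos is not None:
            i = np.searchsorted(pos, start)
            if i < len(pos) and pos[i] < end:
                continue
        if len(seq) >= kmer_index.k and kmer_index.max_copies(seq) > 1:
            continue
        seen_seqs.add(seq)
        got[klass] += 1
        probes.append(
            QcProbe(
                probe_id=f"qc_{klass.lower()}_{got[klass]}",
                seq=seq,
                terminal_class=klass,
                contig_id=contig.name,
                pos=start,
            )
        )
    shortfall = {k: need[k] - got[k] for k in need if got[k] < need[k]}
    if shortfall:
        raise ValueError(
            f"could not place requested QC probes; shortfall by terminal "
            f"class: {shortfall} (genome too small or too repetitive)"
        )
    return probes


def build_manifest(
    selected: Sequence[SnpCandidate],
    designs: Mapping[str, Tuple[ProbeDesign, ProbeDesign]],
    decisions: Mapping[str, ProbeChoice],
    qc_probes: Sequence[QcProbe] = (),
) -> Tuple[ArrayManifest, Dict]:
    """Assemble the manifest from per-SNP probe designs and tiling decisions.

    SNPs whose decision is DROP_SNP are excluded. Returns the manifest and a
    summary with probe-count identities and per-source-class counts.
    """
    snps: List[SnpCandidate] = []
    probes: List[ProbeDesign] = []
    for cand in selected:
        choice = decisions.get(cand.snp_id, ProbeChoice.DROP_SNP)
        if choice is ProbeChoice.DROP_SNP:
            continue
        fwd, rev = designs[cand.snp_id]
        snps.append(cand)
        if choice is ProbeChoice.KEEP_FORWARD:
            probes.append(fwd)
        elif choice is ProbeChoice.KEEP_REVERSE:
            probes.append(rev)
        else:
            probes.extend([fwd, rev])
    manifest = ArrayManifest(snps=snps, probes=probes, qc_probes=list(qc_probes))
    manifest.validate()
    return manifest, manifest_summary(manifest)


def total_probe_count(n_single: int, n_dual: int) -> int:
    """Probe-count identity: single-probe SNPs + 2 × dual-probe SNPs."""
    return n_single + 2 * n_dual


def manifest_summary(manifest: ArrayManifest) -> Dict:
    by_snp = manifest.probes_by_snp()
    n_single = sum(1 for p in by_snp.values() if len(p) == 1)
    n_dual = sum(1 for p in by_snp.values() if len(p) == 2)
    per_source = Counter(s.source_class.value for s in manifest.snps)
    return {
        "n_snps": len(manifest.snps),
        "n_single_probe": n_single,
        "n_dual_probe": n_dual,
        "n_probes": total_probe_count(n_single, n_dual),
        "n_qc_probes": len(manifest.qc_probes),
        "per_source": dict(per_source),
    }
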