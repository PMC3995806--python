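"""Deterministic surrogate for the per-probe conversion design score.

The score ("p-convert") predicts the probability that a probe yields usable
genotype clusters. The real vendor score comes from a proprietary learned
model; this surrogate is an explicit logistic of interpretable penalties
built from the same named factors — probe composition, duplex-stability and
expected non-specific hybridisation:

    pconvert = logistic( bias
                         − w_gc   · |gc − 0.5|
                         − w_run  · max(0, longest_run − 3)
                         − w_uniq · log2(max k-mer genome copies)
                         − w_tm   · |tm_proxy − 70| / 70 )

with tm_proxy = 64.9 + 41·(gc·L − 16.4)/L for probe length L. Scores are
deterministic and ordinally meaningful; absolute values are not comparable
to any vendor's scale.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .filtering import gc_fraction, max_base_runs
from .genome import Genome, KmerIndex, revcomp
from .models import ArrayManifest, ProbeDesign, ScoreWeights, SnpCandidate, Strand

PROBE_LEN = 35
_T0 = 70.0
_ACGT = frozenset("ACGT")


def logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def tm_proxy(gc: float, length: int = PROBE_LEN) -> float:
    """GC-fraction melting-temperature proxy (°C)."""
    return 64.9 + 41.0 * (gc * length - 16.4) / length


def score_probe(
    probe_seq: str,
    kmer_index: KmerIndex,
    weights: Optional[ScoreWeights] = None,
) -> float:
    """Design score in [0, 1] for one probe sequence.

    Probes containing ambiguity codes score 0 (they cannot be synthesised
    faithfully). Deterministic: identical inputs give identical scores.
    """
    if len(probe_seq) != PROBE_LEN:
        raise ValueError(f"probe length {len(probe_seq)} != {PROBE_LEN}")
    probe_seq = probe_seq.upper()
    if set(probe_seq) - _ACGT:
        return 0.0
    weights = weights or ScoreWeights()
    gc = gc_fraction(probe_seq)
    longest_run = max(max_base_runs(probe_seq).values())
    copies = max(kmer_index.max_copies(probe_seq), 1)
    x = (
        weights.bias
        - weights.w_gc * abs(gc - 0.5)
        - weights.w_run * max(0, longest_run - 3)
        - weights.w_uniq * math.log2(copies)
        - weights.w_tm * abs(tm_proxy(gc) - _T0) / _T0
    )
    return logistic(x)


def probe_contexts(candidate: SnpCandidate, genome: Genome) -> Tuple[str, str]:
    """(forward, reverse) 35-base contexts 5' of the site on each strand."""
    contig = genome[candidate.contig_id]
    lo = candidate.pos - PROBE_LEN
    hi = candidate.pos + PROBE_LEN + 1
    if lo < 0 or hi > len(contig):
        raise ValueError(
            f"{candidate.snp_id}: insufficient context for probes "
            f"(pos {candidate.pos}, contig length {len(contig)})"
        )
    forward = contig.seq[lo : candidate.pos]
    reverse = revcomp(contig.seq[candidate.pos + 1 : hi])
    return forward, reverse


def score_snp(
    candidate: SnpCandidate,
    genome: Genome,
    kmer_index: KmerIndex,
    weights: Optional[ScoreWeights] = None,
) -> Tuple[ProbeDesign, ProbeDesign]:
    """Score both strand probes of a SNP; scores ignore the allele pair."""
    fwd_seq, rev_seq = probe_contexts(candidate, genome)
    fwd = ProbeDesign(
        probe_id=f"{candidate.snp_id}_F",
        snp_id=candidate.snp_id,
        strand=Strand.FORWARD,
        probe_seq=fwd_seq,
        pconvert=score_probe(fwd_seq, kmer_index, weights),
    )
    rev = ProbeDesign(
        probe_id=f"{candidate.snp_id}_R",
        snp_id=candidate.snp_id,
        strand=Strand.REVERSE,
        probe_seq=rev_seq,
        pconvert=score_probe(rev_seq, kmer_index, weights),
    )
    return fwd, rev


def score_performance_curve(
    manifest: ArrayManifest,
    probe_convertible: Mapping[str, bool],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Score-bin → conversion table (the design-score vs performance curve).

    Probes are binned by pconvert into ``n_bins`` equal-width bins over
    [0, 1]; each bin reports the fraction of probes whose probeset
    converted and the fraction of distinct SNPs (any probe in the bin)
    that converted via any of their probes. Empty bins are absent from the
    output. The SNP-level fraction can exceed the probe-level fraction in
    low bins — the dual-probe rescue artifact.
    """
    by_snp = manifest.probes_by_snp()
    snp_convertible = {
        sid: any(probe_convertible.get(p.probe_id, False) for p in probes)
        for sid, probes in by_snp.items()
    }
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        if i < n_bins - 1:
            in_bin = [p for p in manifest.probes if lo <= p.pconvert < hi]
        else:
            in_bin = [p for p in manifest.probes if lo <= p.pconvert <= hi]
        if not in_bin:
            continue
        snps = sorted({p.snp_id for p in in_bin})
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_probes": len(in_bin),
                "pct_probes_converted": 100.0
                * np.mean([probe_convertible.get(p.probe_id, False) for p in in_bin]),
                "n_snps": len(snps),
                "pct_snps_converted": 100.0
                * np.mean([snp_convertible[s] for s in snps]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bin_low", "bin_high", "n_probes", "pct_probes_converted",
                 "n_snps", "pct_snps_converted"],
    )


def scores_to_frame(designs: Iterable[ProbeDesign]) -> pd.DataFrame:
    designs = list(designs)
    return pd.DataFrame(
        {
            "snp_id": [d.snp_id for d in designs],
            "strand": [d.strand.value for d in designs],
            "probe_seq": [d.probe_seq for d in designs],
            "pconvert": [d.pconvert for d in designs],
        }
    )
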