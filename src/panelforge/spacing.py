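"""Inter-SNP spacing analysis against an assembly.

Panel SNPs are placed on assembly scaffolds by exact matching of their
71-base flanks (both strands); uniquely mapped SNPs yield per-scaffold
sorted positions, distances to the previous SNP, a binned spacing
distribution and cumulative coverage fractions. The distance from the last
SNP of a scaffold to the next scaffold's first SNP is undefined and not
counted: the first SNP of each occupied scaffold contributes no interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import Genome, revcomp
from .models import ArrayManifest, ReportConfig

FLANK_SITE_OFFSET = 35  # site index within the 71-base flank (strand-symmetric)


@dataclass
class SpacingProfile:
    mapped: Dict[str, Tuple[str, int]]  # snp_id -> (scaffold, site position)
    unmapped_or_multi: List[str]
    intervals: pd.DataFrame  # scaffold, snp_id, dist_prev
    bin_counts: pd.DataFrame  # bin label, count
    cumulative: Dict[str, float]  # pct below / within / above the cut points

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)

    @property
    def n_occupied_scaffolds(self) -> int:
        return len({scaf for scaf, _ in self.mapped.values()})


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def map_flanks(
    manifest: ArrayManifest, assembly: Genome
) -> Tuple[Dict[str, Tuple[str, int]], List[str]]:
    """Exact-match each SNP flank against the assembly, both strands.

    A SNP maps when its flank (or reverse complement) occurs exactly once
    across all scaffolds and strands; the mapped coordinate is the SNP site
    (flank centre, which is strand-symmetric). SNPs without a flank, with
    no hit, or with multiple hits are returned as unmapped/multi.
    """
    mapped: Dict[str, Tuple[str, int]] = {}
    unmapped: List[str] = []
    for snp in manifest.snps:
        if snp.flank is None:
            unmapped.append(snp.snp_id)
            continue
        flank = snp.flank.upper()
        rc = revcomp(flank)
        hits: List[Tuple[str, int]] = []
        for name, contig in assembly.contigs.items():
            for i in _find_all(contig.seq, flank):
                hits.append((name, i + FLANK_SITE_OFFSET))
            if rc != flank:
                for i in _find_all(contig.seq, rc):
                    hits.append((name, i + FLANK_SITE_OFFSET))
            if len(hits) > 1:
                break
        if len(hits) == 1:
            mapped[snp.snp_id] = hits[0]
        else:
            unmapped.append(snp.snp_id)
    return mapped, unmapped


def spacing_bin_label(lo: float, hi: float) -> str:
    return f"[{int(lo)},{'inf' if np.isinf(hi) else int(hi)})"


def inter_snp_spacing(
    mapped: Mapping[str, Tuple[str, int]],
    cfg: Optional[ReportConfig] = None,
) -> SpacingProfile:
    """Per-scaffold inter-SNP distances, binned distribution and cumulants.

    Within each scaffold (positions sorted ascending, ties kept and
    flagged as zero distances) every SNP except the first gets the distance
    to its predecessor. Bins are half-open lower-inclusive on the
    configured edges with a final open-ended bin; cumulative fractions are
    reported below 1 kb, within [1 kb, 6 kb), and at or above 6 kb.
    """
    cfg = cfg or ReportConfig()
    edges = list(cfg.spacing_bin_edges) + [np.inf]
    by_scaffold: Dict[str, List[Tuple[int, str]]] = {}
    for snp_id, (scaf, pos) in mapped.items():
        by_scaffold.setdefault(scaf, []).append((pos, snp_id))
    rows = []
    for scaf in sorted(by_scaffold):
        entries = sorted(by_scaffold[scaf])
        for (prev_pos, _), (pos, snp_id) in zip(entries, entries[1:]):
            rows.append({"scaffold": scaf, "snp_id": snp_id,
                         "dist_prev": pos - prev_pos})
    intervals = pd.DataFrame(rows, columns=["scaffold", "snp_id", "dist_prev"])
    counts = bin_interval_counts(intervals["dist_prev"].to_numpy(), edges)
    return SpacingProfile(
        mapped=dict(mapped),
        unmapped_or_multi=[],
        intervals=intervals,
        bin_counts=counts,
        cumulative=cumulative_fractions(counts),
    )


def bin_interval_counts(distances: np.ndarray, edges: Sequence[float]) -> pd.DataFrame:
    """Histogram of distances over half-open [lo, hi) bins."""
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(distances, bins=edges)
    return pd.DataFrame(
        {
            "bin": [spacing_bin_label(lo, hi) for lo, hi in zip(edges, edges[1:])],
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_intervals": counts.astype(int),
        }
    )


def cumulative_fractions(
    bin_counts: pd.DataFrame, cut_low: float = 1000.0, cut_high: float = 6000.0
) -> Dict[str, float]:
    """Percent of intervals below, within and above the two cut points.

    Requires the cut points to coincide with bin boundaries so the binned
    counts determine the split exactly; percentages round to one decimal.
    """
    lows = bin_counts["bin_low"].to_numpy()
    highs = bin_counts["bin_high"].to_numpy()
    if cut_low not in highs or (cut_high not in highs and cut_high not in lows):
        raise ValueError("cut points must be bin boundaries")
    n = bin_counts["n_intervals"].to_numpy()
    total = int(n.sum())
    below = int(n[highs <= cut_low].sum())
    above = int(n[lows >= cut_high].sum())
    within = total - below - above
    from .genotyping import pct

    return {
        "n_intervals": total,
        "pct_below": pct(below, total),
        "pct_within": pct(within, total),
        "pct_above": pct(above, total),
    }


def profile_spacing(
    manifest: ArrayManifest,
    assembly: Genome,
    cfg: Optional[ReportConfig] = None,
) -> SpacingProfile:
    """Map flanks, then compute the spacing profile in one call."""
    mapped, unmapped = map_flanks(manifest, assembly)
    profile = inter_snp_spacing(mapped, cfg)
    profile.unmapped_or_multi = unmapped
    return profile


def associate_anchors(
    manifest: ArrayManifest, anchors: Genome
) -> Tuple[List[Tuple[str, str]], int, int]:
    """Exact-match SNP flanks against anchor sequences (e.g. BAC ends).

    Returns the (snp_id, anchor_id) containment pairs plus the counts of
    distinct SNPs with at least one anchor hit and distinct anchors hit.
    """
    pairs: List[Tuple[str, str]] = []
    for snp in manifest.snps:
        if snp.flank is None:
            continue
        flank = snp.flank.upper()
        rc = revcomp(flank)
        for name, contig in anchors.contigs.items():
            if flank in contig.seq or (rc != flank and rc in contig.seq):
                pairs.append((snp.snp_id, name))
    n_snps = len({s for s, _ in pairs})
    n_anchors = len({a for _, a in pairs})
    return pairs, n_snps, n_anchors
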