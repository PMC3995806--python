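"""Report tables: design, array, performance, spacing, MAF, overlap.

Every report number is recomputed from the underlying artifacts; counts
and one-decimal percentages are emitted together. ``render_reports``
writes the full TSV set for a scenario run.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from . import io
from .filtering import FilterOutcome, outcomes_to_frame
from .genotyping import (
    maf_spectrum,
    pct,
    performance_by_subset,
    performance_summary,
    polymorphism_overlap,
)
from .models import ArrayManifest, ReportConfig, SnpCandidate
from .scoring import score_performance_curve
from .selection import manifest_summary
from .spacing import profile_spacing


def design_summary(
    candidates: Sequence[SnpCandidate],
    outcomes: Sequence[FilterOutcome],
    manifest: ArrayManifest,
) -> pd.DataFrame:
    """Per-source-class funnel: candidates → filter survivors → on array."""
    passed = {o.snp_id for o in outcomes if o.passed}
    on_array = {s.snp_id for s in manifest.snps}
    n_cand = Counter(c.source_class.value for c in candidates)
    n_pass = Counter(c.source_class.value for c in candidates if c.snp_id in passed)
    n_incl = Counter(c.source_class.value for c in candidates if c.snp_id in on_array)
    classes = sorted(n_cand)
    total_incl = sum(n_incl.values())
    rows = [
        {
            "source_class": cls,
            "n_candidates": n_cand.get(cls, 0),
            "n_passed_filters": n_pass.get(cls, 0),
            "n_on_array": n_incl.get(cls, 0),
            "pct_of_array": pct(n_incl.get(cls, 0), total_incl),
        }
        for cls in classes
    ]
    rows.append(
        {
            "source_class": "total",
            "n_candidates": sum(n_cand.values()),
            "n_passed_filters": sum(n_pass.values()),
            "n_on_array": total_incl,
            "pct_of_array": pct(total_incl, total_incl),
        }
    )
    return pd.DataFrame(rows)


def array_summary(manifest: ArrayManifest) -> pd.DataFrame:
    """Panel composition table (SNPs, single/dual tiling, probes, QC)."""
    s = manifest_summary(manifest)
    rows = [
        ("total_snps", s["n_snps"]),
        ("snps_single_probe", s["n_single_probe"]),
        ("snps_dual_probe", s["n_dual_probe"]),
        ("total_probes", s["n_probes"]),
        ("qc_probes", s["n_qc_probes"]),
    ]
    return pd.DataFrame(rows, columns=["quantity", "count"])


def overlap_table(overlap: Dict) -> pd.DataFrame:
    """Venn-style region counts plus union validation rate, as rows."""
    rows = [
        {"region": "+".join(member) if member else "(none)", "n_snps": count}
        for member, count in sorted(overlap["poly_regions"].items())
    ]
    rows.append({"region": "monomorphic_in_all", "n_snps": overlap["monomorphic_in_all"]})
    rows.append({"region": "converted_in_any", "n_snps": overlap["n_converted_any"]})
    rows.append({"region": "polymorphic_in_any", "n_snps": overlap["n_polymorphic_any"]})
    rows.append(
        {"region": "pct_polymorphic_of_converted",
         "n_snps": overlap["pct_polymorphic_of_converted"]}
    )
    return pd.DataFrame(rows)


def render_reports(run, outdir, report_cfg: Optional[ReportConfig] = None) -> Dict[str, Path]:
    """Write every artifact and report TSV for a scenario run.

    Returns the mapping of artifact name → path. Output is deterministic:
    rerunning the same scenario seed reproduces identical bytes.
    """
    report_cfg = report_cfg or ReportConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    manifest = run.design.manifest
    io.write_fasta(run.genome, outdir / "genome.fa")
    paths["genome"] = outdir / "genome.fa"
    io.write_manifest(manifest, outdir / "manifest.tsv", outdir / "qc_probes.tsv")
    paths["manifest"] = outdir / "manifest.tsv"
    paths["qc_probes"] = outdir / "qc_probes.tsv"

    save("filter_outcomes", outcomes_to_frame(run.design.outcomes))
    save("design_summary", design_summary(run.candidates, run.design.outcomes, manifest))
    save("array_summary", array_summary(manifest))

    profile = profile_spacing(manifest, run.genome, report_cfg)
    save("spacing_intervals", profile.intervals)
    save("spacing_bins", profile.bin_counts)
    save(
        "spacing_summary",
        pd.DataFrame([{"quantity": k, "value": v} for k, v in {
            "n_mapped": profile.n_mapped,
            "n_unmapped_or_multi": len(profile.unmapped_or_multi),
            "n_occupied_scaffolds": profile.n_occupied_scaffolds,
            **{f"cumulative_{k}": v for k, v in profile.cumulative.items()},
        }.items()]),
    )

    if run.callsets:
        save("performance", performance_summary(run.callsets, manifest))
        first = next(iter(run.callsets))
        for key in ("source_class", "tstv", "gene_vs_anonymous"):
            save(f"performance_{first}_by_{key}",
                 performance_by_subset(run.callsets[first], manifest, key))
        save("maf_bins", maf_spectrum(run.callsets[first], report_cfg.maf_bin_width))
        if len(run.callsets) > 1:
            save("polymorphism_overlap", overlap_table(polymorphism_overlap(run.callsets)))
        convertible = {
            pid: cat.convertible
            for pid, cat in run.callsets[first].probe_category.items()
        }
        save("score_performance_curve",
             score_performance_curve(manifest, convertible))
        for name, cs in run.callsets.items():
            io.write_calls(cs.calls, outdir / f"calls_{name}.tsv")
            paths[f"calls_{name}"] = outdir / f"calls_{name}.tsv"
            save(f"sample_qc_{name}", cs.sample_qc)
    return paths
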