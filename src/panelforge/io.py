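"""Readers and writers for every external format the toolkit touches.

FASTA goes through Bio.SeqIO, VCF through pysam, and all tabular artifacts
(manifests, QC probes, intensities, calls) are TSV via pandas so fixtures
stay diffable. Positions in every emitted TSV are 0-based.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

from .genome import Contig, Genome
from .models import ArrayManifest, ProbeDesign, QcProbe, SnpCandidate, SourceClass, Strand

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Genome:
    """Read FASTA into a :class:`Genome`, keeping lowercase as soft-mask.

    Raises ``ValueError`` on duplicate contig ids.
    """
    genome = Genome()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        genome.add(Contig.from_string(record.id, str(record.seq)))
    return genome


def write_fasta(genome: Genome, path, line_width: int = 60) -> None:
    """Write FASTA, rendering soft-masked bases lowercase."""
    with open(path, "w") as fh:
        for contig in genome.contigs.values():
            fh.write(f">{contig.name}\n")
            seq = contig.masked_string()
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_BASES = frozenset("ACGT")


def read_variants(vcf_path) -> Tuple[List[SnpCandidate], List[Tuple[str, int]]]:
    """Read a VCF into SNP candidates plus non-SNP variant positions.

    Bi-allelic SNP records become :class:`SnpCandidate` (flank unset, VCF
    1-based positions shifted to 0-based). Indels and multi-allelic records
    are returned separately as ``(contig, pos)`` "other variants" feeding the
    exclusion-window filter. A record whose contig is missing from the header
    is kept with a warning.
    """
    candidates: List[SnpCandidate] = []
    others: List[Tuple[str, int]] = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {vcf_path}: {exc}") from exc
    header_contigs = set(vcf.header.contigs)
    has_src = "SRC" in vcf.header.info
    auto = 0
    with vcf:
        for rec in vcf:
            if rec.chrom not in header_contigs:
                warnings.warn(
                    f"{vcf_path}: contig {rec.chrom} absent from VCF header "
                    f"(record kept)"
                )
            alts = rec.alts or ()
            is_snp = (
                len(alts) == 1
                and len(rec.ref) == 1
                and len(alts[0]) == 1
                and rec.ref.upper() in _SNP_BASES
                and alts[0].upper() in _SNP_BASES
            )
            if not is_snp:
                others.append((rec.chrom, rec.start))
                continue
            auto += 1
            snp_id = rec.id if rec.id not in (None, ".") else f"snp{auto}"
            src = rec.info.get("SRC") if has_src else None
            if isinstance(src, (tuple, list)):
                src = src[0]
            if src is None:
                src = SourceClass.ANONYMOUS.value
            candidates.append(
                SnpCandidate(
                    snp_id=snp_id,
                    contig_id=rec.chrom,
                    pos=rec.start,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    source_class=SourceClass(src),
                )
            )
    return candidates, others


def write_variants(
    candidates: List[SnpCandidate],
    others: List[Tuple[str, int, str, str]],
    contig_lengths: Dict[str, int],
    path,
) -> None:
    """Write candidates plus other variants (contig, pos, ref, alt) to VCF."""
    header = pysam.VariantHeader()
    header.add_meta(
        "INFO", items=[("ID", "SRC"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Candidate source class")]
    )
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    records = []
    for c in candidates:
        records.append((c.contig_id, c.pos, c.snp_id, c.ref_allele,
                        (c.alt_allele,), c.source_class.value))
    for contig, pos, ref, alt in others:
        records.append((contig, pos, ".", ref, (alt,), None))
    order = {name: i for i, name in enumerate(contig_lengths)}
    records.sort(key=lambda r: (order.get(r[0], len(order)), r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for contig, pos, rid, ref, alts, src in records:
            rec = out.new_record(
                contig=contig, start=pos, stop=pos + len(ref), alleles=(ref,) + alts
            )
            rec.id = rid if rid != "." else None
            if src is not None:
                rec.info["SRC"] = src
            out.write(rec)


# ---------------------------------------------------------------------------
# manifest TSV
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "snp_id", "contig_id", "pos", "ref", "alt", "source_class", "flank",
    "probe_id", "probe_strand", "probe_seq", "pconvert",
]

QC_PROBE_COLUMNS = ["probe_id", "seq", "terminal_class", "contig_id", "pos"]


def write_manifest(manifest: ArrayManifest, path, qc_path=None) -> None:
    """Write one TSV row per probe; QC probes go to ``qc_path`` if given."""
    snps = manifest.snp_by_id()
    rows = []
    for p in manifest.probes:
        s = snps[p.snp_id]
        rows.append(
            {
                "snp_id": s.snp_id,
                "contig_id": s.contig_id,
                "pos": s.pos,
                "ref": s.ref_allele,
                "alt": s.alt_allele,
                "source_class": s.source_class.value,
                "flank": s.flank if s.flank is not None else ".",
                "probe_id": p.probe_id,
                "probe_strand": p.strand.value,
                "probe_seq": p.probe_seq,
                "pconvert": p.pconvert,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
    if qc_path is not None:
        write_qc_probes(manifest.qc_probes, qc_path)


def read_manifest(path, qc_path=None) -> ArrayManifest:
    df = pd.read_csv(path, sep="\t", dtype={"flank": str},
                     float_precision="round_trip")
    unknown = set(df.columns) - set(MANIFEST_COLUMNS)
    if unknown:
        raise ValueError(f"unknown manifest column(s): {sorted(unknown)}")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    snps: Dict[str, SnpCandidate] = {}
    probes: List[ProbeDesign] = []
    for row in df.itertuples(index=False):
        if row.snp_id not in snps:
            flank = None if row.flank == "." else row.flank
            snps[row.snp_id] = SnpCandidate(
                snp_id=row.snp_id,
                contig_id=row.contig_id,
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                source_class=SourceClass(row.source_class),
                flank=flank,
            )
        probes.append(
            ProbeDesign(
                probe_id=row.probe_id,
                snp_id=row.snp_id,
                strand=Strand(row.probe_strand),
                probe_seq=row.probe_seq,
                pconvert=float(row.pconvert),
            )
        )
    qc = read_qc_probes(qc_path) if qc_path is not None else []
    return ArrayManifest(snps=list(snps.values()), probes=probes, qc_probes=qc)


def write_qc_probes(qc_probes: List[QcProbe], path) -> None:
    rows = [
        {"probe_id": q.probe_id, "seq": q.seq, "terminal_class": q.terminal_class,
         "contig_id": q.contig_id, "pos": q.pos}
        for q in qc_probes
    ]
    pd.DataFrame(rows, columns=QC_PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_qc_probes(path) -> List[QcProbe]:
    df = pd.read_csv(path, sep="\t")
    unknown = set(df.columns) - set(QC_PROBE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown QC-probe column(s): {sorted(unknown)}")
    return [
        QcProbe(probe_id=r.probe_id, seq=r.seq, terminal_class=r.terminal_class,
                contig_id=r.contig_id, pos=int(r.pos))
        for r in df.itertuples(index=False)
    ]


CANDIDATE_COLUMNS = ["snp_id", "contig_id", "pos", "ref", "alt", "source_class"]


def write_candidates(candidates: List[SnpCandidate], path) -> None:
    rows = [
        {"snp_id": c.snp_id, "contig_id": c.contig_id, "pos": c.pos,
         "ref": c.ref_allele, "alt": c.alt_allele,
         "source_class": c.source_class.value}
        for c in candidates
    ]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> List[SnpCandidate]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate TSV missing column(s): {sorted(missing)}")
    return [
        SnpCandidate(snp_id=r.snp_id, contig_id=r.contig_id, pos=int(r.pos),
                     ref_allele=r.ref, alt_allele=r.alt,
                     source_class=SourceClass(r.source_class))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# intensities and calls
# ---------------------------------------------------------------------------

INTENSITY_COLUMNS = ["sample_id", "probe_id", "signal_a", "signal_b"]
CALL_COLUMNS = ["sample_id", "snp_id", "call"]


def write_intensities(df: pd.DataFrame, path) -> None:
    df.loc[:, INTENSITY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity TSV missing column(s): {sorted(missing)}")
    if (df["signal_a"] < 0).any() or (df["signal_b"] < 0).any():
        raise ValueError("negative intensities")
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a sample × SNP call matrix as long-form TSV."""
    long = calls.stack().rename("call").reset_index()
    long.columns = CALL_COLUMNS
    long.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls TSV missing column(s): {sorted(missing)}")
    bad = set(df["call"]) - {"AA", "AB", "BB", "NC"}
    if bad:
        raise ValueError(f"unknown call value(s): {sorted(bad)}")
    return df.pivot(index="sample_id", columns="snp_id", values="call")
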