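"""Surrogate genotype calling and probeset classification.

Two-channel intensities are reduced to a log-ratio ("contrast") and an
average log-signal ("strength"). Per probeset, a 1–3 component Gaussian
mixture on contrast (order selected by BIC, deterministic quantile
initialisation) yields genotype clusters; clusters map to AA/AB/BB by mean
contrast. Sample QC is two-stage: a dish-QC (DQC) screen from the
non-polymorphic control probes, then a call-rate screen after calling.
Each probeset is then classified into the six standard categories
(PolyHighResolution, NoMinorHom, MonoHighResolution, OTV,
CallRateBelowThreshold, Other); the first four count as convertible, the
first two as polymorphic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .models import (
    ArrayManifest,
    ClassifierConfig,
    SampleQcConfig,
    SnpCategory,
    best_category,
)

logger = logging.getLogger(__name__)

GENOTYPES = ("AA", "AB", "BB")
NO_CALL = "NC"


def pct(numerator: float, denominator: float) -> float:
    """Percentage rounded to one decimal, the report-layer convention."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# intensity transform and dish QC
# ---------------------------------------------------------------------------


def transform_intensities(signal_a, signal_b) -> Tuple[np.ndarray, np.ndarray]:
    """(contrast, strength) from two-channel signals.

    A pseudo-count of 1 keeps zero signals finite: contrast is
    log2((a+1)/(b+1)) and strength the mean of the two log signals.
    Swapping the channels negates contrast and preserves strength.
    """
    a = np.log2(np.asarray(signal_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(signal_b, dtype=float) + 1.0)
    return a - b, (a + b) / 2.0


def compute_dqc(at_strengths, gc_strengths, grid_points: int = 2001) -> float:
    """Dish QC: 1 − overlap of normal fits to AT- vs GC-probe strengths.

    Normal densities are fitted to the strengths of the two terminal-base
    classes of control probes; the overlap coefficient is integrated
    numerically. Identical distributions give 0, disjoint ones approach 1.
    Invariant under a common additive shift of all strengths.
    """
    at = np.asarray(at_strengths, dtype=float)
    gc = np.asarray(gc_strengths, dtype=float)
    if at.size == 0 or gc.size == 0:
        raise ValueError("both AT and GC control-probe classes are required")
    m1, s1 = at.mean(), max(at.std(), 1e-9)
    m2, s2 = gc.mean(), max(gc.std(), 1e-9)
    lo = min(m1 - 8 * s1, m2 - 8 * s2)
    hi = max(m1 + 8 * s1, m2 + 8 * s2)
    x = np.linspace(lo, hi, grid_points)
    overlap = np.trapezoid(
        np.minimum(norm.pdf(x, m1, s1), norm.pdf(x, m2, s2)), x
    )
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


# ---------------------------------------------------------------------------
# mixture calling
# ---------------------------------------------------------------------------


@dataclass
class ClusterSummary:
    """Per-probeset cluster diagnostics in the contrast coordinate."""

    probeset_id: str
    k: int
    means: List[float]
    sds: List[float]
    sizes: List[int]
    genotypes: List[str]
    call_rate: float
    minor_hom_present: bool
    otv_present: bool
    separation: float

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.sizes)
                == len(self.genotypes) == self.k):
            raise ValueError("cluster list lengths inconsistent with k")


def _fit_mixture(
    x: np.ndarray, max_k: int = 3, var_floor: float = 2.5e-3
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BIC-selected 1..max_k component univariate mixture, deterministic.

    Initial means sit on the (i+0.5)/k quantiles of the data — a fixed grid,
    no random restarts — so repeated fits are identical.
    """
    X = x.reshape(-1, 1)
    n_unique = np.unique(x).size
    lo, hi = x.min(), x.max()
    best = None
    best_bic = np.inf
    for k in range(1, max_k + 1):
        if k > n_unique:
            break
        # three deterministic starts per k: data quantiles (balanced
        # clusters), an even grid over the range, and a split at the k−1
        # widest gaps of the sorted data (finds tiny extreme clusters)
        starts = [np.quantile(x, [(i + 0.5) / k for i in range(k)])]
        if k > 1:
            starts.append(lo + (np.arange(k) + 0.5) / k * (hi - lo))
            xs = np.sort(x)
            gaps = np.diff(xs)
            if len(gaps) >= k - 1:
                cuts = np.sort(np.argpartition(gaps, -(k - 1))[-(k - 1):])
                groups = np.split(xs, cuts + 1)
                if all(len(g) for g in groups):
                    starts.append(np.array([g.mean() for g in groups]))
        for means_init in starts:
            # hard partition to the nearest start fixes initial weights and
            # per-component variances; wide flat starts stall EM early
            assign = np.argmin(np.abs(x[:, None] - means_init[None, :]), axis=1)
            weights_init = np.maximum(np.bincount(assign, minlength=k), 1) / len(x)
            var_init = np.array(
                [max(x[assign == j].var(), var_floor) if np.any(assign == j)
                 else max(x.var(), var_floor)
                 for j in range(k)]
            )
            gm = GaussianMixture(
                n_components=k,
                covariance_type="spherical",
                weights_init=weights_init / weights_init.sum(),
                means_init=means_init.reshape(-1, 1),
                precisions_init=1.0 / var_init,
                reg_covar=var_floor,
                tol=1e-5,
                max_iter=500,
                n_init=1,
                random_state=0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            bic = gm.bic(X)
            if bic < best_bic - 1e-9:
                best_bic = bic
                best = gm
    weights = best.weights_
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    order = np.argsort(means)
    return weights[order], means[order], sds[order]


def _genotype_labels(means: np.ndarray, het_margin: float) -> List[str]:
    """Map cluster means (ascending) to genotype labels.

    Three clusters in the canonical geometry (outer means straddling zero,
    middle mean nearest the centre) are BB/AB/AA by increasing contrast;
    otherwise each cluster takes the homozygote of its sign unless its
    mean lies within ``het_margin`` of zero (then AB) — duplicate labels
    then mean one genotype was split across clusters, which avoids
    inventing a minor-homozygote cluster the data does not show. With two
    clusters a label collision is resolved by proximity to zero: the
    nearer cluster is the heterozygote. One cluster is a lone homozygote
    or, when near zero, all-heterozygous.
    """
    k = len(means)
    if k == 3:
        if (
            means[0] < -het_margin
            and means[2] > het_margin
            and abs(means[1]) <= (means[2] - means[0]) / 4.0
        ):
            return ["BB", "AB", "AA"]
        return [
            "AB" if abs(m) <= het_margin else ("AA" if m > 0 else "BB")
            for m in means
        ]
    if k == 1:
        m = means[0]
        if abs(m) <= het_margin:
            return ["AB"]
        return ["AA"] if m > 0 else ["BB"]
    labels = []
    for m in means:
        if abs(m) <= het_margin:
            labels.append("AB")
        else:
            labels.append("AA" if m > 0 else "BB")
    if labels[0] == labels[1]:
        nearer = int(np.argmin(np.abs(means)))
        if labels[0] == "AB":  # both near zero: farther one is a homozygote
            farther = 1 - nearer
            labels[farther] = "AA" if means[farther] > 0 else "BB"
        else:  # both on one side: nearer to zero is the heterozygote
            labels[nearer] = "AB"
    return labels


def call_genotypes(
    contrast,
    strength=None,
    cfg: Optional[ClassifierConfig] = None,
    probeset_id: str = "",
    max_k: int = 3,
) -> Tuple[np.ndarray, ClusterSummary]:
    """Call one probeset across samples from contrast values.

    Missing (NaN) contrasts become no-calls and are excluded from the fit.
    A sample is called to its maximum-posterior cluster when that posterior
    reaches the no-call threshold, else NC. Cluster standard deviations are
    floored to keep degenerate clusters callable. ``strength`` (same shape)
    feeds the off-target (OTV) low-strength-cluster flag.
    """
    cfg = cfg or ClassifierConfig()
    x = np.asarray(contrast, dtype=float)
    observed = np.isfinite(x)
    if observed.sum() < 10:
        raise ValueError(
            f"probeset {probeset_id or '?'}: need >= 10 samples with data, "
            f"got {int(observed.sum())}"
        )
    weights, means, sds = _fit_mixture(
        x[observed], max_k=max_k, var_floor=cfg.sd_floor**2
    )
    sds = np.maximum(sds, cfg.sd_floor)

    # posterior under the floored-sd model
    xo = x[observed].reshape(-1, 1)
    dens = weights * norm.pdf(xo, means, sds)
    total = dens.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    post = dens / total
    assign = post.argmax(axis=1)
    maxpost = post.max(axis=1)
    called = maxpost >= cfg.nocall_posterior

    # drop clusters that end up with no called members
    keep = np.array([np.any(called & (assign == j)) for j in range(len(means))])
    if keep.any() and not keep.all():
        weights, means, sds = weights[keep], means[keep], sds[keep]
        weights = weights / weights.sum()
        dens = weights * norm.pdf(xo, means, sds)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        post = dens / total
        assign = post.argmax(axis=1)
        maxpost = post.max(axis=1)
        called = maxpost >= cfg.nocall_posterior

    labels = _genotype_labels(means, cfg.het_margin)
    calls = np.full(x.shape, NO_CALL, dtype=object)
    obs_idx = np.flatnonzero(observed)
    for j, label in enumerate(labels):
        calls[obs_idx[called & (assign == j)]] = label

    sizes = [int(np.sum(called & (assign == j))) for j in range(len(means))]
    call_rate = float(np.sum(calls != NO_CALL)) / len(x)
    k = len(means)
    if k > 1:
        gaps = np.diff(means)
        pooled = np.sqrt((sds[:-1] ** 2 + sds[1:] ** 2) / 2.0)
        separation = float(np.min(gaps / pooled))
    else:
        separation = float("inf")

    otv_present = False
    if strength is not None:
        s = np.asarray(strength, dtype=float)[observed]
        called_s = s[called]
        if called_s.size >= 2 and called_s.std() > 0:
            centre = np.median(called_s)
            spread = called_s.std()
            for j in range(k):
                members = s[called & (assign == j)]
                if members.size and members.mean() < centre - cfg.otv_strength_sds * spread:
                    otv_present = True
                    break

    summary = ClusterSummary(
        probeset_id=probeset_id,
        k=k,
        means=[float(m) for m in means],
        sds=[float(v) for v in sds],
        sizes=sizes,
        genotypes=labels,
        call_rate=call_rate,
        minor_hom_present=("AA" in labels and "BB" in labels),
        otv_present=otv_present,
        separation=separation,
    )
    return calls, summary


def classify_probeset(summary: ClusterSummary, cfg: Optional[ClassifierConfig] = None) -> SnpCategory:
    """Six-way category from cluster diagnostics.

    Decision order: call rate below the probeset floor; off-target
    low-strength cluster; poor cluster separation; single cluster
    (monomorphic); polymorphic without the minor homozygote; full
    three-cluster resolution.
    """
    cfg = cfg or ClassifierConfig()
    if summary.call_rate < cfg.snp_call_rate_min:
        return SnpCategory.CALL_RATE_BELOW_THRESHOLD
    if summary.otv_present:
        return SnpCategory.OTV
    if summary.separation < cfg.sep_min:
        return SnpCategory.OTHER
    if summary.k == 1:
        return SnpCategory.MONO_HIGH_RESOLUTION
    if not summary.minor_hom_present:
        return SnpCategory.NO_MINOR_HOM
    return SnpCategory.POLY_HIGH_RESOLUTION


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class CallSet:
    """Calls and diagnostics for one genotyped cohort.

    ``calls`` is a sample × SNP frame (AA/AB/BB/NC) restricted to samples
    passing both QC stages; ``sample_qc`` covers every processed sample.
    """

    calls: pd.DataFrame
    sample_qc: pd.DataFrame  # sample_id, dqc, call_rate, passed
    snp_category: Dict[str, SnpCategory]
    probe_category: Dict[str, SnpCategory]
    cluster_summaries: Dict[str, ClusterSummary] = field(default_factory=dict)

    @property
    def converted_snps(self) -> List[str]:
        return [s for s, c in self.snp_category.items() if c.convertible]

    @property
    def polymorphic_snps(self) -> List[str]:
        return [s for s, c in self.snp_category.items() if c.polymorphic]


def call_dataset(
    intensities: pd.DataFrame,
    manifest: ArrayManifest,
    sample_cfg: Optional[SampleQcConfig] = None,
    classifier_cfg: Optional[ClassifierConfig] = None,
) -> CallSet:
    """Full genotyping run: DQC screen, calling, call-rate screen, categories.

    ``intensities`` is the long-form table (sample_id, probe_id, signal_a,
    signal_b) covering SNP probes and QC probes. Samples failing the DQC
    screen are excluded from calling; sample call rate is computed over all
    manifest SNPs; the returned call matrix keeps only fully passing
    samples. Per-SNP categories take the best probe category (dual tiling
    exists to rescue conversion).
    """
    sample_cfg = sample_cfg or SampleQcConfig()
    classifier_cfg = classifier_cfg or ClassifierConfig()
    if classifier_cfg.nocall_posterior != sample_cfg.nocall_posterior:
        classifier_cfg = ClassifierConfig(
            snp_call_rate_min=classifier_cfg.snp_call_rate_min,
            sep_min=classifier_cfg.sep_min,
            het_margin=classifier_cfg.het_margin,
            otv_strength_sds=classifier_cfg.otv_strength_sds,
            sd_floor=classifier_cfg.sd_floor,
            nocall_posterior=sample_cfg.nocall_posterior,
        )

    df = intensities.copy()
    contrast, strength = transform_intensities(df["signal_a"], df["signal_b"])
    df["contrast"] = contrast
    df["strength"] = strength
    samples = sorted(df["sample_id"].unique())

    # stage 1: dish QC from control probes
    qc_class = {q.probe_id: q.terminal_class for q in manifest.qc_probes}
    dqc = {}
    if qc_class:
        qc_rows = df[df["probe_id"].isin(qc_class)]
        terminal = qc_rows["probe_id"].map(qc_class)
        for sample, grp in qc_rows.groupby("sample_id"):
            t = terminal.loc[grp.index]
            dqc[sample] = compute_dqc(
                grp.loc[t == "AT", "strength"], grp.loc[t == "GC", "strength"]
            )
        dqc_series = pd.Series([dqc.get(s, 0.0) for s in samples], index=samples)
    else:
        warnings.warn("manifest has no QC probes; DQC screen skipped")
        dqc_series = pd.Series(np.nan, index=samples)
    dqc_pass = dqc_series.isna() | (dqc_series >= sample_cfg.dqc_min)
    passing = [s for s in samples if dqc_pass[s]]
    if len(passing) < 10:
        raise ValueError(f"only {len(passing)} samples passed DQC; need >= 10")

    # stage 2: calling on DQC-passing samples
    snp_probe_ids = {p.probe_id for p in manifest.probes}
    snp_rows = df[df["probe_id"].isin(snp_probe_ids) & df["sample_id"].isin(passing)]
    cmat = snp_rows.pivot_table(index="sample_id", columns="probe_id",
                                values="contrast", aggfunc="first").reindex(passing)
    smat = snp_rows.pivot_table(index="sample_id", columns="probe_id",
                                values="strength", aggfunc="first").reindex(passing)

    probe_calls: Dict[str, np.ndarray] = {}
    probe_category: Dict[str, SnpCategory] = {}
    summaries: Dict[str, ClusterSummary] = {}
    nan_col = np.full(len(passing), np.nan)
    for probe in manifest.probes:
        pid = probe.probe_id
        x = cmat[pid].to_numpy() if pid in cmat.columns else nan_col
        s = smat[pid].to_numpy() if pid in smat.columns else nan_col
        calls, summary = call_genotypes(x, s, classifier_cfg, probeset_id=pid)
        probe_calls[pid] = calls
        summaries[pid] = summary
        probe_category[pid] = classify_probeset(summary, classifier_cfg)

    snp_category: Dict[str, SnpCategory] = {}
    snp_calls: Dict[str, np.ndarray] = {}
    for snp_id, probes in manifest.probes_by_snp().items():
        cats = [probe_category[p.probe_id] for p in probes]
        best = best_category(cats)
        snp_category[snp_id] = best
        chosen = probes[cats.index(best)]
        snp_calls[snp_id] = probe_calls[chosen.probe_id]

    calls = pd.DataFrame(snp_calls, index=pd.Index(passing, name="sample_id"))
    calls = calls[[s.snp_id for s in manifest.snps]]
    calls.columns.name = "snp_id"

    # stage 3: call-rate screen
    call_rate = (calls != NO_CALL).mean(axis=1)
    qc_table = pd.DataFrame(
        {
            "sample_id": samples,
            "dqc": dqc_series.to_numpy(),
            "call_rate": [float(call_rate[s]) if s in call_rate.index else np.nan
                          for s in samples],
            "passed": [bool(dqc_pass[s]) and s in call_rate.index
                       and call_rate[s] > sample_cfg.call_rate_min
                       for s in samples],
        }
    )
    passed_samples = qc_table.loc[qc_table["passed"], "sample_id"].tolist()
    logger.info("samples: %d processed, %d passed QC; SNPs: %d converted of %d",
                len(samples), len(passed_samples),
                sum(c.convertible for c in snp_category.values()), len(snp_category))
    return CallSet(
        calls=calls.loc[passed_samples],
        sample_qc=qc_table,
        snp_category=snp_category,
        probe_category=probe_category,
        cluster_summaries=summaries,
    )


# ---------------------------------------------------------------------------
# performance analytics
# ---------------------------------------------------------------------------


def performance_summary(
    callsets: Mapping[str, CallSet],
    manifest: ArrayManifest,
) -> pd.DataFrame:
    """Per-cohort performance table.

    Conversion and polymorphism rates are percentages of the manifest SNP
    total; the average call rate is computed over converted SNPs and
    averaged across passing samples. An empty cohort yields zeros with
    ``n_snps_total`` still reported.
    """
    n_total = len(manifest.snps)
    rows = []
    for name, cs in callsets.items():
        converted = cs.converted_snps
        polymorphic = cs.polymorphic_snps
        if len(cs.calls) and converted:
            avg_cr = pct(
                float((cs.calls[converted] != NO_CALL).mean(axis=1).mean()), 1.0
            )
        else:
            avg_cr = float("nan")
        rows.append(
            {
                "population": name,
                "samples_processed": len(cs.sample_qc),
                "samples_passed": int(cs.sample_qc["passed"].sum()),
                "pct_samples_passed": pct(int(cs.sample_qc["passed"].sum()),
                                          len(cs.sample_qc)),
                "n_snps_total": n_total,
                "snps_converted": len(converted),
                "pct_converted": pct(len(converted), n_total),
                "snps_polymorphic": len(polymorphic),
                "pct_polymorphic": pct(len(polymorphic), n_total),
                "avg_call_rate_pct": avg_cr,
            }
        )
    return pd.DataFrame(rows)


def performance_by_subset(
    callset: CallSet, manifest: ArrayManifest, key: str = "source_class"
) -> pd.DataFrame:
    """Conversion/polymorphism rates within marker subsets.

    ``key`` is one of ``source_class``, ``tstv`` or ``gene_vs_anonymous``,
    supporting the gene-vs-anonymous, intra/inter-specific and
    transition/transversion comparisons.
    """
    def group_of(snp) -> str:
        if key == "source_class":
            return snp.source_class.value
        if key == "tstv":
            return "transition" if snp.is_transition else "transversion"
        if key == "gene_vs_anonymous":
            return "gene" if snp.source_class.is_gene else "anonymous"
        raise ValueError(f"unknown grouping key {key!r}")

    groups: Dict[str, List[str]] = {}
    for snp in manifest.snps:
        groups.setdefault(group_of(snp), []).append(snp.snp_id)
    rows = []
    for group, snp_ids in sorted(groups.items()):
        conv = [s for s in snp_ids if callset.snp_category[s].convertible]
        poly = [s for s in snp_ids if callset.snp_category[s].polymorphic]
        rows.append(
            {
                "group": group,
                "n_snps": len(snp_ids),
                "snps_converted": len(conv),
                "pct_converted": pct(len(conv), len(snp_ids)),
                "snps_polymorphic": len(poly),
                "pct_polymorphic": pct(len(poly), len(snp_ids)),
            }
        )
    return pd.DataFrame(rows)


def compute_maf(calls: pd.Series) -> float:
    """Minor allele frequency from one SNP's calls (NC excluded)."""
    counts = calls.value_counts()
    n_aa = int(counts.get("AA", 0))
    n_ab = int(counts.get("AB", 0))
    n_bb = int(counts.get("BB", 0))
    n_called = n_aa + n_ab + n_bb
    if n_called == 0:
        return float("nan")
    p = (2 * n_aa + n_ab) / (2 * n_called)
    return min(p, 1.0 - p)


def maf_bin_label(maf: float, width: float = 0.05) -> str:
    """Bin label for a MAF rounded to two decimals ('0.01-0.05' style)."""
    m100 = int(round(round(maf, 2) * 100))
    step = int(round(width * 100))
    if m100 <= 0:
        return "0.00"
    idx = -(-m100 // step) - 1  # ceil division
    lo = idx * step + 1
    hi = (idx + 1) * step
    return f"{lo / 100:.2f}-{hi / 100:.2f}"


def maf_spectrum(callset: CallSet, maf_bin_width: float = 0.05) -> pd.DataFrame:
    """Binned MAF distribution over the polymorphic SNPs.

    MAF is min(p, 1−p) with p the A-allele frequency among called
    genotypes, rounded to two decimals, binned into labelled 0.05-wide
    closed ranges (0.01-0.05 … 0.46-0.50). Counts sum to the number of
    polymorphic SNPs.
    """
    labels: List[str] = []
    for snp_id in callset.polymorphic_snps:
        maf = compute_maf(callset.calls[snp_id])
        if np.isnan(maf):
            continue
        labels.append(maf_bin_label(maf, maf_bin_width))
    counts = pd.Series(labels, dtype=object).value_counts().sort_index()
    return pd.DataFrame({"maf_bin": counts.index, "n_snps": counts.to_numpy()})


def polymorphism_overlap(callsets: Mapping[str, CallSet]) -> Dict:
    """Cross-population polymorphism membership (Venn-style region counts).

    For every SNP converted in at least one population, records the exact
    set of populations where it is polymorphic. Returns region counts for
    polymorphic membership, the count monomorphic (converted, never
    polymorphic) in all populations, and the polymorphic-in-≥1 /
    converted-in-≥1 validation rate.
    """
    names = list(callsets)
    poly = {n: set(callsets[n].polymorphic_snps) for n in names}
    conv = {n: set(callsets[n].converted_snps) for n in names}
    converted_any = set().union(*conv.values()) if conv else set()
    poly_any = set().union(*poly.values()) if poly else set()

    regions: Dict[tuple, int] = {}
    for snp in poly_any:
        member = tuple(sorted(n for n in names if snp in poly[n]))
        regions[member] = regions.get(member, 0) + 1
    mono_all = {
        snp for snp in converted_any
        if all(snp in conv[n] for n in names) and snp not in poly_any
    }
    return {
        "populations": names,
        "poly_regions": regions,
        "polymorphic_in_all": regions.get(tuple(sorted(names)), 0),
        "monomorphic_in_all": len(mono_all),
        "n_converted_any": len(converted_any),
        "n_polymorphic_any": len(poly_any),
        "pct_polymorphic_of_converted": pct(len(poly_any), len(converted_any)),
    }
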