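"""Cluster-based genotype calling with SNP classification and sample QC.

This module is a documented, open stand-in for the proprietary Axiom
calling stack, with the same category semantics:

* intensities are transformed to contrast ``log2(a/b)`` and strength
  ``(log2 a + log2 b)/2``;
* per-sample Dish Quality Control (DQC) is the fraction of the
  species' non-polymorphic control probes behaving as expected
  (positive contrast above a margin, strength above a floor);
* genotypes are called per SNP from 1-3 component (diploid) or up to
  5-component (tetraploid) constrained Gaussian mixtures on the
  contrast axis, with model selection by BIC over subsets of prior
  cluster positions and a posterior-confidence no-call rule;
* the off-target-variant (OTV) caller recodes samples that form a
  separate low-strength cluster (null-allele carriers, or diverged
  related-species samples);
* SNPs are classified into PolyHighResolution / NoMinorHom /
  MonoHighResolution / OTV / CallRateBelowThreshold / Other;
* sample QC is two-stage: DQC >= 0.82 and QC call rate >= 95 gate
  genotyping, then samples whose mean allele deviation exceeds 0.85
  are removed and final call rates reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, OTV_CODE, GenotypeMatrix, IntensityMatrix, ReactionPlan
from .gmm import BatchGmmFit, fit_gmm_batch, gaussian_loglik
from .manifest import ArrayManifest

CATEGORIES = ("PolyHighResolution", "NoMinorHom", "MonoHighResolution",
              "OTV", "CallRateBelowThreshold", "Other")


@dataclass
class CallerConfig:
    """Thresholds and numerical settings for calling and QC."""

    dqc_min: float = 0.82
    qc_call_rate_min: float = 95.0
    adm_max: float = 0.85
    snp_call_rate_min: float = 97.0
    confidence_min: float = 0.85
    channel_floor: float = 1e-3
    min_samples: int = 20
    diploid_priors: tuple[float, ...] = (1.5, 0.0, -1.5)
    tetraploid_priors: tuple[float, ...] = (1.5, 0.75, 0.0, -0.75, -1.5)
    sep_min: float = 2.0
    dqc_contrast_min: float = 1.0
    dqc_strength_min: float = 2.0
    qc_subset_fraction: float = 0.10
    qc_subset_min: int = 20
    qc_subset_seed: int = 17
    otv_min_gap: float = 2.0
    otv_min_carriers: int = 3
    em_max_iter: int = 100
    em_tol: float = 1e-6


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def transform(intensities: IntensityMatrix,
              channel_floor: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel transform: contrast = log2(a/b), strength = mean log2.

    Channels are floored at ``channel_floor`` before taking logs. The
    transform is the exact inverse of the simulator's channel
    reconstruction for channels above the floor.
    """
    a = np.maximum(intensities.channel_a, channel_floor)
    b = np.maximum(intensities.channel_b, channel_floor)
    la, lb = np.log2(a), np.log2(b)
    return la - lb, (la + lb) / 2.0


# ---------------------------------------------------------------------------
# species split
# ---------------------------------------------------------------------------

def split_by_species(manifest: ArrayManifest, intensities: IntensityMatrix,
                     plan: ReactionPlan,
                     related_map: dict[str, str] | None = None,
                     ) -> dict[str, IntensityMatrix]:
    """Per-species intensity matrices.

    Each output holds only that species' probes, and each reaction
    containing the species contributes the member sample carrying that
    species' DNA, so a pooled plant+fish well is represented in exactly
    two per-species matrices (under its plant and fish sample names
    respectively). ``related_map`` routes a related species' samples
    onto another species' probes (e.g. seabream -> snapper).
    """
    related_map = related_map or {}
    probe_species: dict[str, str] = {}
    for e in manifest.entries:
        probe_species[e.probe_id] = e.species_id
    for pid in intensities.probe_ids:
        if pid not in probe_species:
            raise KeyError(f"probe {pid} carries no species tag in the manifest")

    member_of: dict[str, list[str]] = {}
    for rx in plan.reactions:
        for sid, sp in rx.members:
            member_of.setdefault(related_map.get(sp, sp), []).append(sid)

    out: dict[str, IntensityMatrix] = {}
    for sp in manifest.species():
        probes = [p for p in intensities.probe_ids if probe_species[p] == sp]
        in_matrix = set(intensities.samples)
        samples = [s for s in member_of.get(sp, []) if s in in_matrix]
        if probes and samples:
            out[sp] = intensities.subset(samples=samples, probe_ids=probes)
    return out


# ---------------------------------------------------------------------------
# DQC
# ---------------------------------------------------------------------------

def compute_dqc(contrast: np.ndarray, strength: np.ndarray,
                config: CallerConfig | None = None) -> np.ndarray:
    """Per-sample DQC over the species' control probes.

    ``contrast``/``strength`` are (n_samples, n_dqc_probes). DQC is the
    fraction of control probes with contrast of the expected (positive,
    homozygous-A) sign of magnitude >= ``dqc_contrast_min`` and strength
    >= ``dqc_strength_min``. With zero control probes DQC is NaN and
    the sample conservatively fails stage-1 filtering.
    """
    config = config or CallerConfig()
    if contrast.shape[1] == 0:
        return np.full(contrast.shape[0], np.nan)
    good = (contrast >= config.dqc_contrast_min) & \
           (strength >= config.dqc_strength_min)
    return good.mean(axis=1)


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Per-SNP fitted mixture: one component per candidate genotype code."""

    codes: tuple[int, ...]       # genotype codes, ascending (contrast descending)
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: float
    loglik: float
    n_fitted: int
    otv_flag: bool = False
    failure: str | None = None   # "insufficient_samples" | "non_convergence"

    @property
    def n_components(self) -> int:
        return len(self.codes)

    @property
    def separation(self) -> float:
        """Min pairwise |delta mean| / pooled sd; inf for one component."""
        if self.n_components < 2:
            return float("inf")
        pooled = float(np.sqrt(np.sum(self.weights * self.sds ** 2)))
        gaps = np.abs(np.diff(self.means))
        return float(gaps.min() / max(pooled, 1e-9))


def _genotype_subsets(n_codes: int) -> list[tuple[int, ...]]:
    """All non-empty subsets of genotype codes 0..n_codes-1."""
    out: list[tuple[int, ...]] = []
    for mask in range(1, 1 << n_codes):
        out.append(tuple(i for i in range(n_codes) if mask >> i & 1))
    return sorted(out, key=len)


def call_genotypes(contrast: np.ndarray, strength: np.ndarray | None,
                   priors: tuple[float, ...] | None = None,
                   confidence_min: float = 0.85,
                   config: CallerConfig | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, list[ClusterModel]]:
    """Call genotypes per SNP from contrast values.

    ``contrast`` is (n_samples, n_snps). For each SNP a constrained
    mixture is fitted for every non-empty subset of the prior cluster
    positions; the subset with the lowest BIC wins and each sample is
    assigned its max-posterior component's genotype when the posterior
    reaches ``confidence_min`` (else no-call). Fully deterministic.

    Returns (calls, posteriors, models) with calls (n_samples, n_snps)
    coded as alt-allele dosage / MISSING.
    """
    config = config or CallerConfig()
    if priors is None:
        priors = config.diploid_priors
    priors_arr = np.asarray(priors, dtype=float)  # descending contrast
    n_samples, n_snps = contrast.shape
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int16)
    post = np.full((n_samples, n_snps), np.nan)

    if n_samples < config.min_samples:
        models = [ClusterModel((), np.empty(0), np.empty(0), np.empty(0),
                               np.inf, -np.inf, n_samples,
                               failure="insufficient_samples")
                  for _ in range(n_snps)]
        return calls, post, models

    x = contrast.T  # (S, N)
    subsets = _genotype_subsets(len(priors_arr))
    # anchor components within half the prior cluster spacing so a
    # component cannot capture a neighbouring genotype's cluster
    max_shift = float(np.min(np.abs(np.diff(priors_arr)))) / 2.0 \
        if len(priors_arr) > 1 else None
    fits: list[BatchGmmFit] = []
    for sub in subsets:
        fits.append(fit_gmm_batch(
            x, priors_arr[list(sub)],
            max_iter=config.em_max_iter, tol=config.em_tol,
            max_shift=max_shift))
    bics = np.stack([f.bic for f in fits])             # (n_models, S)
    best_model = np.argmin(bics, axis=0)               # (S,)

    models: list[ClusterModel] = []
    for s in range(n_snps):
        mi = int(best_model[s])
        fit = fits[mi]
        sub = subsets[mi]
        if not fit.converged[s]:
            models.append(ClusterModel(
                (), np.empty(0), np.empty(0), np.empty(0),
                float(fit.bic[s]), float(fit.loglik[s]), n_samples,
                failure="non_convergence"))
            continue
        resp = fit.responsibilities(x[s:s + 1], rows=np.array([s]))[0]  # (N, k)
        comp = np.argmax(resp, axis=1)
        maxpost = resp[np.arange(n_samples), comp]
        snp_calls = np.asarray(sub, dtype=np.int16)[comp]
        snp_calls[maxpost < confidence_min] = MISSING
        calls[:, s] = snp_calls
        post[:, s] = maxpost
        models.append(ClusterModel(
            tuple(sub), fit.means[s].copy(), fit.sds[s].copy(),
            fit.weights[s].copy(), float(fit.bic[s]),
            float(fit.loglik[s]), n_samples))
    return calls, post, models


def call_dosage_tetraploid(contrast: np.ndarray,
                           priors: tuple[float, ...] | None = None,
                           confidence_min: float = 0.85,
                           config: CallerConfig | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, list[ClusterModel]]:
    """Tetraploid dosage calling: up to five ordered components (0..4).

    Same machinery as the diploid caller over subsets of the five prior
    contrast positions. A polymorphic SNP whose winning fit lacks
    cluster separation (< ``sep_min``) is rejected as all-missing.
    """
    config = config or CallerConfig()
    if priors is None:
        priors = config.tetraploid_priors
    calls, post, models = call_genotypes(
        contrast, None, priors=priors,
        confidence_min=confidence_min, config=config)
    for s, model in enumerate(models):
        if model.failure is None and model.n_components >= 2 \
                and model.separation < config.sep_min:
            calls[:, s] = MISSING
            post[:, s] = np.nan
            model.failure = "no_separation"
    return calls, post, models


# ---------------------------------------------------------------------------
# OTV recall
# ---------------------------------------------------------------------------

def otv_strength_threshold(strength: np.ndarray,
                           min_gap: float = 2.0) -> float | None:
    """Global low-strength threshold from a bimodality check.

    Deterministic two-means on all strength values; if the two centres
    are separated by more than ``min_gap`` log2 units the threshold is
    their midpoint, otherwise None (no background population present).
    """
    x = np.asarray(strength, dtype=float).ravel()
    if x.size < 4:
        return None
    lo, hi = np.percentile(x, [5.0, 95.0])
    if hi - lo < 1e-9:
        return None
    for _ in range(100):
        mid = (lo + hi) / 2.0
        low = x[x <= mid]
        high = x[x > mid]
        if not low.size or not high.size:
            break
        new_lo, new_hi = low.mean(), high.mean()
        if abs(new_lo - lo) < 1e-9 and abs(new_hi - hi) < 1e-9:
            break
        lo, hi = new_lo, new_hi
    if hi - lo > min_gap:
        return float((lo + hi) / 2.0)
    return None


def call_otv(calls: np.ndarray, strength: np.ndarray,
             models: list[ClusterModel], threshold: float | None,
             config: CallerConfig | None = None) -> np.ndarray:
    """Recode low-strength clusters as OTV and flag affected SNPs.

    For each SNP, samples with strength below ``threshold`` form a
    candidate null-carrier cluster; the SNP is flagged when the cluster
    has at least ``otv_min_carriers`` members and a two-component
    normal model of the strength values improves BIC over a single
    component. Flagged SNPs have their low-strength samples recoded
    ``OTV_CODE``; ``models`` gain ``otv_flag``. Returns updated calls.
    """
    config = config or CallerConfig()
    if threshold is None:
        return calls
    n_samples, n_snps = calls.shape
    out = calls.copy()
    for s in range(n_snps):
        if models[s].failure is not None:
            continue
        st = strength[:, s]
        low = st < threshold
        n_low = int(low.sum())
        if n_low < config.otv_min_carriers or n_low == n_samples:
            continue
        ll1 = gaussian_loglik(st, float(st.mean()), float(st.std()))
        ll2 = (gaussian_loglik(st[low], float(st[low].mean()), float(st[low].std()))
               + gaussian_loglik(st[~low], float(st[~low].mean()), float(st[~low].std())))
        n = len(st)
        bic1 = -2 * ll1 + 2 * np.log(n)
        bic2 = -2 * ll2 + 5 * np.log(n)
        if bic2 < bic1:
            out[low, s] = OTV_CODE
            models[s].otv_flag = True
    return out


# ---------------------------------------------------------------------------
# SNP classification
# ---------------------------------------------------------------------------

@dataclass
class SnpClass:
    snp_id: str
    category: str
    snp_call_rate: float       # percent
    n_components: int
    minor_hom_count: int
    separation: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_snp(snp_id: str, calls: np.ndarray, model: ClusterModel,
                 config: CallerConfig | None = None) -> SnpClass:
    """Assign the per-SNP category from its calls and fitted model.

    First matching rule wins: CallRateBelowThreshold when the SNP call
    rate over the final samples falls below ``snp_call_rate_min``; OTV
    when flagged by the OTV caller; MonoHighResolution when one called
    genotype remains; PolyHighResolution when polymorphic with at least
    two minor-homozygote examples and separated clusters; NoMinorHom
    when polymorphic with separated clusters but without a
    minor-homozygote cluster; Other otherwise.
    """
    config = config or CallerConfig()
    n = len(calls)
    called = calls != MISSING
    cr = 100.0 * called.mean() if n else 0.0
    genotype_calls = calls[(calls != MISSING) & (calls != OTV_CODE)]
    distinct = np.unique(genotype_calls)
    hom_lo = int(np.sum(genotype_calls == 0))
    hom_hi = int(np.sum(genotype_calls == 2))
    minor_hom = min(hom_lo, hom_hi)
    sep = model.separation if model.failure is None else 0.0
    n_comp = model.n_components

    if model.failure is not None:
        cat = "Other"
    elif cr < config.snp_call_rate_min:
        cat = "CallRateBelowThreshold"
    elif model.otv_flag:
        cat = "OTV"
    elif len(distinct) <= 1:
        cat = "MonoHighResolution"
    elif minor_hom >= 2 and sep >= config.sep_min:
        cat = "PolyHighResolution"
    elif minor_hom < 2 and sep >= config.sep_min:
        cat = "NoMinorHom"
    else:
        cat = "Other"
    return SnpClass(snp_id, cat, cr, n_comp, minor_hom, sep)


def summarize_classification(classes: list[SnpClass],
                             species: str = "") -> pd.DataFrame:
    """Per-category counts plus the conversion rate (PHR+NMH)/total %.

    Percentages are rounded half-up to integers; counts always
    partition the classified SNP set. An empty input yields zero counts
    and NA conversion.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    for c in classes:
        counts[c.category] += 1
    total = len(classes)
    rows = [{"species": species, "category": cat, "count": n,
             "percent": _round_half_up(100.0 * n / total) if total else 0}
            for cat, n in counts.items()]
    conv = (counts["PolyHighResolution"] + counts["NoMinorHom"])
    rows.append({"species": species, "category": "Total", "count": total,
                 "percent": 100 if total else 0})
    rows.append({
        "species": species, "category": "ConversionRate",
        "count": conv,
        "percent": _round_half_up(100.0 * conv / total) if total else pd.NA})
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# sample QC and the per-species pipeline
# ---------------------------------------------------------------------------

@dataclass
class SampleQc:
    sample: str
    dqc: float
    qc_call_rate: float
    call_rate: float            # NaN unless the sample reaches final calling
    allele_deviation_mean: float
    pass_stage1: bool
    pass_stage2: bool


@dataclass
class CallResult:
    """Everything the validation layer consumes for one species."""

    species: str
    genotypes: GenotypeMatrix           # final (stage-2 passing) samples
    models: list[ClusterModel]
    snp_classes: list[SnpClass]
    sample_qc: pd.DataFrame
    summary: pd.DataFrame
    qc_subset: list[str] = field(default_factory=list)

    @property
    def final_samples(self) -> list[str]:
        return list(self.genotypes.samples)


def allele_deviation(contrast_row: np.ndarray, calls_row: np.ndarray,
                     models: list[ClusterModel]) -> float:
    """Mean normalized deviation of a sample's contrasts from its
    assigned cluster means: min(1, |c - mu| / (3 sd)) over called SNPs.
    Larger is worse; NaN when the sample has no called SNPs."""
    devs = []
    for s, g in enumerate(calls_row):
        if g in (MISSING, OTV_CODE):
            continue
        model = models[s]
        if model.failure is not None or g not in model.codes:
            continue
        k = model.codes.index(int(g))
        d = abs(contrast_row[s] - model.means[k]) / (3.0 * max(model.sds[k], 1e-9))
        devs.append(min(1.0, d))
    return float(np.mean(devs)) if devs else float("nan")


def call_species(intensities: IntensityMatrix, manifest: ArrayManifest,
                 species: str, config: CallerConfig | None = None,
                 ploidy: int = 2) -> CallResult:
    """Run the full per-species pipeline on a species-split matrix.

    Stages: transform; DQC from control probes; QC call rate from a
    seeded 10% SNP subset; stage-1 sample filter (DQC >= dqc_min and
    QC call rate >= qc_call_rate_min, boundary values pass); genotype
    calling of stage-1 passers on all SNPs; OTV recall; allele
    deviation stage-2 filter (removed when > adm_max); final call
    rates; SNP classification over the final samples.
    """
    config = config or CallerConfig()
    geno_ids = [e.probe_id for e in manifest.genotyping if e.species_id == species
                and e.probe_id in set(intensities.probe_ids)]
    dqc_ids = [e.probe_id for e in manifest.dqc if e.species_id == species
               and e.probe_id in set(intensities.probe_ids)]
    samples = list(intensities.samples)
    geno = intensities.subset(probe_ids=geno_ids)
    contrast, strength = transform(geno, config.channel_floor)

    # --- DQC
    if dqc_ids:
        dqc_m = intensities.subset(probe_ids=dqc_ids)
        d_contrast, d_strength = transform(dqc_m, config.channel_floor)
        dqc = compute_dqc(d_contrast, d_strength, config)
    else:
        dqc = np.full(len(samples), np.nan)

    # --- QC call rate on the designated subset (all samples, generic priors)
    rng = np.random.default_rng(config.qc_subset_seed)
    n_qc = int(round(config.qc_subset_fraction * len(geno_ids)))
    n_qc = min(len(geno_ids), max(config.qc_subset_min, n_qc, 1))
    qc_subset = sorted(rng.choice(geno_ids, size=n_qc, replace=False).tolist())
    qc_cols = [geno_ids.index(p) for p in qc_subset]
    qc_calls, _, _ = call_genotypes(
        contrast[:, qc_cols], strength[:, qc_cols],
        priors=config.diploid_priors if ploidy == 2 else config.tetraploid_priors,
        confidence_min=config.confidence_min, config=config)
    qc_call_rate = 100.0 * (qc_calls != MISSING).mean(axis=1)

    stage1 = (~np.isnan(dqc)) & (dqc >= config.dqc_min) & \
             (qc_call_rate >= config.qc_call_rate_min)
    passers = [s for s, ok in zip(samples, stage1) if ok]
    p_idx = np.flatnonzero(stage1)

    # --- genotype stage-1 passers on all SNPs
    sub_contrast = contrast[p_idx]
    sub_strength = strength[p_idx]
    if ploidy == 4:
        calls, post, models = call_dosage_tetraploid(
            sub_contrast, confidence_min=config.confidence_min, config=config)
    else:
        calls, post, models = call_genotypes(
            sub_contrast, sub_strength,
            confidence_min=config.confidence_min, config=config)
        thr = otv_strength_threshold(sub_strength, config.otv_min_gap)
        calls = call_otv(calls, sub_strength, models, thr, config)

    # --- stage 2: allele deviation
    adm = np.full(len(samples), np.nan)
    for row, i in enumerate(p_idx):
        adm[i] = allele_deviation(sub_contrast[row], calls[row], models)
    stage2 = stage1.copy()
    for i in range(len(samples)):
        if stage1[i] and not np.isnan(adm[i]) and adm[i] > config.adm_max:
            stage2[i] = False
    final_rows = [r for r, i in enumerate(p_idx) if stage2[i]]
    final_samples = [samples[i] for i in p_idx[final_rows]] if len(final_rows) else []

    final_calls = calls[final_rows] if len(final_rows) else \
        np.empty((0, len(geno_ids)), dtype=np.int16)
    final_post = post[final_rows] if len(final_rows) else None

    call_rate = np.full(len(samples), np.nan)
    if len(final_rows):
        cr = 100.0 * (final_calls != MISSING).mean(axis=1)
        for r, s in zip(final_rows, final_samples):
            call_rate[samples.index(s)] = cr[final_samples.index(s)]

    genotypes = GenotypeMatrix(final_samples, geno_ids, final_calls,
                               ploidy=ploidy, posteriors=final_post)

    snp_classes = [classify_snp(geno_ids[s], final_calls[:, s], models[s], config)
                   for s in range(len(geno_ids))]
    summary = summarize_classification(snp_classes, species)

    qc = pd.DataFrame({
        "sample": samples, "dqc": dqc, "qc_call_rate": qc_call_rate,
        "call_rate": call_rate, "allele_deviation_mean": adm,
        "pass_stage1": stage1, "pass_stage2": stage2,
    })
    qc.attrs["thresholds"] = {
        "dqc_min": config.dqc_min,
        "qc_call_rate_min": config.qc_call_rate_min,
        "adm_max": config.adm_max,
    }
    return CallResult(species, genotypes, models, snp_classes, qc, summary,
                      qc_subset)
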