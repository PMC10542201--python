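"""Validation analytics: PCA, DAPC-lite, Weir-Cockerham FST, IBS
duplicate detection, and trio parentage by Mendelian exclusion.

These operate on called dosage matrices (off-target-variant recodes are
treated as missing throughout).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def _dosage_nan(genotypes: GenotypeMatrix) -> np.ndarray:
    return genotypes.dosage_float()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coordinates: np.ndarray        # samples x components
    variance_explained: np.ndarray  # percent per component
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.samples, columns=cols)


def pca(genotypes: GenotypeMatrix, n_components: int | None = None,
        scale: bool = False) -> PcaResult:
    """Principal components of the dosage matrix.

    Missing dosages are mean-imputed per SNP; columns are centred
    (optionally unit-scaled); all-missing SNPs are dropped. Variance
    explained comes from the squared singular values.
    """
    if genotypes.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = _dosage_nan(genotypes)
    col_mean = np.nanmean(x, axis=0)
    keep = ~np.isnan(col_mean)
    x = x[:, keep]
    col_mean = col_mean[keep]
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x = x - col_mean
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s ** 2))
    var_pct = 100.0 * s ** 2 / total if total > 0 else np.zeros_like(s)
    coords = u * s
    if n_components is not None:
        coords = coords[:, :n_components]
        var_pct = var_pct[:n_components]
    return PcaResult(coords, var_pct, list(genotypes.samples))


# ---------------------------------------------------------------------------
# DAPC-lite
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    labels: np.ndarray
    k: int
    discriminant_coords: np.ndarray  # samples x (<= k-1) axes
    n_pcs: int
    samples: list[str]


def _kmeans_bic(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a spherical k-means solution (shared variance)."""
    n, d = x.shape
    rss = 0.0
    for c in range(k):
        pts = x[labels == c]
        if len(pts):
            rss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    var = max(rss / max(n * d - k * d, 1), 1e-12)
    ll = -0.5 * n * d * (np.log(2 * np.pi * var) + 1.0)
    n_params = k * d + 1
    return -2.0 * ll + n_params * np.log(n)


def dapc_lite(genotypes: GenotypeMatrix, k_range: range | list[int],
              n_pcs: int = 20, seed: int = 0) -> DapcResult:
    """Discriminant analysis of principal components, reimplemented as
    PCA -> k-means (k selected by BIC over ``k_range``) -> LDA.

    Values of k exceeding the sample count are skipped. With k = 1
    every sample falls in one cluster and there are no discriminant
    axes.
    """
    from sklearn.cluster import KMeans
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    pcs = pca(genotypes).coordinates
    n_pcs = min(n_pcs, pcs.shape[1])
    x = pcs[:, :n_pcs]
    n = x.shape[0]

    best: tuple[float, int, np.ndarray] | None = None
    for k in k_range:
        if k < 1 or k > n:
            continue
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(x)
        bic = _kmeans_bic(x, labels, k)
        if best is None or bic < best[0]:
            best = (bic, k, labels)
    if best is None:
        raise ValueError("no feasible k in k_range")
    _, k, labels = best
    if k == 1:
        coords = np.empty((n, 0))
    else:
        lda = LinearDiscriminantAnalysis(n_components=min(k - 1, n_pcs))
        coords = lda.fit_transform(x, labels)
    return DapcResult(labels, k, coords, n_pcs, list(genotypes.samples))


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_ratio(group_dosages: list[np.ndarray]) -> float:
    """Multi-locus Weir-Cockerham (1984) FST ratio-of-sums estimator.

    ``group_dosages`` holds one (n_i, L) dosage array (0/1/2, NaN
    missing) per group. Loci with fewer than two observations in any
    group, or monomorphic over the pooled groups, contribute nothing.
    Vectorized over loci; negative estimates are reported as-is.
    """
    r = len(group_dosages)
    ok = [~np.isnan(g) for g in group_dosages]
    n = np.stack([m.sum(axis=0).astype(float) for m in ok])           # (r, L)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.stack([np.nansum(g, axis=0) for g in group_dosages]) / (2.0 * n)
        h = np.stack([((g == 1) & m).sum(axis=0) for g, m in
                      zip(group_dosages, ok)]) / n
    valid = (n >= 2).all(axis=0)
    nsum = n.sum(axis=0)
    pbar = (n * p).sum(axis=0) / nsum
    hbar = (n * h).sum(axis=0) / nsum
    valid &= (pbar > 0.0) & (pbar < 1.0)
    if not valid.any():
        return float("nan")
    n, p, h = n[:, valid], p[:, valid], h[:, valid]
    nsum, pbar, hbar = nsum[valid], pbar[valid], hbar[valid]
    nbar = n.mean(axis=0)
    nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    den = (a + b + c).sum()
    return float(a.sum() / den) if den != 0 else float("nan")


def _group_names(groups: np.ndarray, genotypes: GenotypeMatrix) -> list[str]:
    if len(groups) != genotypes.n_samples:
        raise ValueError("groups must label every sample")
    names = list(dict.fromkeys(groups.tolist()))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    return names


def fst(genotypes: GenotypeMatrix, groups: list[str] | np.ndarray) -> pd.DataFrame:
    """Pairwise multi-locus Weir-Cockerham (1984) FST between groups.

    Uses the ratio-of-sums estimator over loci polymorphic in each
    pair; negative estimates are reported as-is. Each group needs at
    least 2 samples. Diagonal is 0.
    """
    groups = np.asarray(groups)
    names = _group_names(groups, genotypes)
    dos = _dosage_nan(genotypes)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for g1, g2 in combinations(names, 2):
        value = _wc_ratio([dos[groups == g1], dos[groups == g2]])
        mat.loc[g1, g2] = mat.loc[g2, g1] = value
    return mat


def fst_global(genotypes: GenotypeMatrix, groups: list[str] | np.ndarray) -> float:
    """Single multi-group Weir-Cockerham FST over all groups at once."""
    groups = np.asarray(groups)
    names = _group_names(groups, genotypes)
    dos = _dosage_nan(genotypes)
    return _wc_ratio([dos[groups == g] for g in names])


# ---------------------------------------------------------------------------
# IBS and duplicate detection
# ---------------------------------------------------------------------------

def ibs_matrix(genotypes: GenotypeMatrix, min_shared: int = 1) -> pd.DataFrame:
    """Pairwise identity-by-state: mean over shared non-missing loci of
    1 - |g_i - g_j| / ploidy. Diagonal 1; NA when a pair shares fewer
    than ``min_shared`` loci."""
    dos = _dosage_nan(genotypes)
    ploidy = genotypes.ploidy
    n = dos.shape[0]
    ok = ~np.isnan(dos)
    filled = np.where(ok, dos, 0.0)
    out = np.full((n, n), np.nan)
    for i in range(n):
        shared = ok[i] & ok
        diff = np.abs(filled[i] - filled)
        sims = 1.0 - diff / ploidy
        counts = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts >= max(min_shared, 1),
                            (sims * shared).sum(axis=1) / counts, np.nan)
        out[i] = vals
        out[i, i] = 1.0 if counts[i] >= min_shared else np.nan
    return pd.DataFrame(out, index=genotypes.samples, columns=genotypes.samples)


def find_duplicates(ibs: pd.DataFrame, threshold: float = 0.97) -> list[tuple[str, str, float]]:
    """Sample pairs with IBS above ``threshold`` (replicates/duplicates)."""
    out = []
    samples = list(ibs.index)
    for i, j in combinations(range(len(samples)), 2):
        v = ibs.iat[i, j]
        if not np.isnan(v) and v > threshold:
            out.append((samples[i], samples[j], float(v)))
    return out


# ---------------------------------------------------------------------------
# trio parentage
# ---------------------------------------------------------------------------

@dataclass
class TrioAssignment:
    offspring_id: str
    parent_pair: tuple[str, str] | None  # unordered; None when unassigned
    mismatch_rate: float
    assigned: bool
    n_informative: int = 0


# trio_conflict[go, gp1, gp2]: offspring genotype impossible given one
# allele from each parent (diploid, biallelic)
_TRIO_CONFLICT = np.zeros((3, 3, 3), dtype=bool)
for _go in range(3):
    for _g1 in range(3):
        for _g2 in range(3):
            gametes1 = {0} if _g1 == 0 else {1} if _g1 == 2 else {0, 1}
            gametes2 = {0} if _g2 == 0 else {1} if _g2 == 2 else {0, 1}
            possible = {a + b for a in gametes1 for b in gametes2}
            _TRIO_CONFLICT[_go, _g1, _g2] = _go not in possible


def opposing_homozygote_rate(g_off: np.ndarray, g_par: np.ndarray) -> float:
    """Fraction of shared loci where offspring and one candidate parent
    are opposite homozygotes (single-parent exclusion screen)."""
    ok = ~(np.isnan(g_off) | np.isnan(g_par))
    if not ok.any():
        return float("nan")
    opp = ((g_off == 0) & (g_par == 2)) | ((g_off == 2) & (g_par == 0))
    return float(opp[ok].mean())


def assign_trios(offspring: GenotypeMatrix, candidate_parents: GenotypeMatrix,
                 eps: float = 0.01, min_call_rate: float = 0.5,
                 ) -> list[TrioAssignment]:
    """Trio parentage by pair-level Mendelian exclusion.

    For every offspring all unordered candidate parent pairs are
    scored: the mismatch rate is the fraction of informative loci
    (non-missing in all three) whose offspring genotype cannot receive
    one allele from each parent. The unique pair minimizing the
    mismatch rate is assigned when its rate is <= ``eps``; ties or no
    qualifying pair leave the offspring unassigned. Offspring with
    call rate below ``min_call_rate`` are unassigned and flagged by a
    NaN mismatch rate.
    """
    if offspring.snp_ids != candidate_parents.snp_ids:
        raise ValueError("offspring and parents must share the same loci")
    g_off = offspring.dosage_float()
    g_par = candidate_parents.dosage_float()
    parents = list(candidate_parents.samples)
    pairs = list(combinations(range(len(parents)), 2))
    out: list[TrioAssignment] = []
    par_ok = ~np.isnan(g_par)
    for i, off_id in enumerate(offspring.samples):
        go = g_off[i]
        ok_o = ~np.isnan(go)
        if ok_o.mean() < min_call_rate:
            out.append(TrioAssignment(off_id, None, float("nan"), False))
            continue
        best_rate = np.inf
        best_pair: tuple[int, int] | None = None
        tied = False
        go_int = np.where(ok_o, go, 0).astype(int)
        for p1, p2 in pairs:
            informative = ok_o & par_ok[p1] & par_ok[p2]
            n_inf = int(informative.sum())
            if n_inf == 0:
                continue
            conflicts = _TRIO_CONFLICT[
                go_int[informative],
                g_par[p1, informative].astype(int),
                g_par[p2, informative].astype(int)]
            rate = conflicts.mean()
            if rate < best_rate - 1e-12:
                best_rate = rate
                best_pair = (p1, p2)
                tied = False
            elif abs(rate - best_rate) <= 1e-12:
                tied = True
        if best_pair is not None and not tied and best_rate <= eps:
            pair_names = (parents[best_pair[0]], parents[best_pair[1]])
            out.append(TrioAssignment(off_id, pair_names, float(best_rate), True))
        else:
            out.append(TrioAssignment(off_id, None,
                                      float(best_rate) if np.isfinite(best_rate)
                                      else float("nan"), False))
    return out
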