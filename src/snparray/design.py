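"""Candidate SNP filtering cascade for multi-species array design.

Per-species variant sets are reduced to array candidates through an
ordered cascade: basic VCF-level filters (biallelic SNP, missingness,
depth, MAF, A/T-C/G exclusion), proximity thinning, LD pruning,
flank extraction with edge rules, cross-taxon hybridization screening,
probe scoring and final even random selection. Every stage is
monotone (output is a subset of input), order-stable and idempotent;
removed candidates carry exactly one removal reason so the removed
set is partitioned by reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_ALLELES = frozenset("ACGT")

#: allele pairs excluded from array designs: their alleles are their own
#: reverse complements, so probe strand cannot disambiguate them.
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

ACTIVE = "active"


@dataclass
class SnpCandidate:
    """A per-species variant flowing through the design cascade.

    Coordinates are 1-based and fully closed (VCF convention).
    ``status`` is either ``"active"`` or ``"removed:<reason>"``.
    """

    species_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    flank_up: str | None = None
    flank_down: str | None = None
    per_pool_maf: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    mean_depth: float = 0.0
    status: str = ACTIVE

    def __post_init__(self) -> None:
        if self.ref_allele in VALID_ALLELES and self.alt_allele in VALID_ALLELES:
            if self.ref_allele == self.alt_allele:
                raise ValueError(f"alleles must differ at {self.chrom}:{self.pos}")
        for fl in (self.flank_up, self.flank_down):
            if fl is not None and len(fl) != 60:
                raise ValueError("flanks must be exactly 60 bases")
        for maf in self.per_pool_maf.values():
            if not 0.0 <= maf <= 0.5:
                raise ValueError("per-pool MAF must lie in [0, 0.5]")

    @property
    def is_active(self) -> bool:
        return self.status == ACTIVE

    @property
    def removal_reason(self) -> str | None:
        if self.status.startswith("removed:"):
            return self.status.split(":", 1)[1]
        return None

    def remove(self, reason: str) -> None:
        if self.is_active:
            self.status = f"removed:{reason}"

    @property
    def snp_id(self) -> str:
        return f"{self.species_id}_{self.chrom}_{self.pos}"


@dataclass
class FilterParams:
    """Thresholds for the per-species filter cascade.

    The defaults mirror a typical fish preset: at most 20% missing data,
    a maximum-depth cap against repetitive regions, MAF >= 0.05,
    proximity thinning at 30 bp and LD pruning at r^2 > 0.2 inside a
    50-SNP window; the cross-hybridization screen uses E <= 1e-5 and
    identity >= 0.8 over the aligned span.
    """

    max_missing: float = 0.2
    max_depth: float = 100.0
    min_maf: float = 0.05
    thin_window: int = 30
    ld_r2_max: float = 0.2
    ld_window: int = 50
    crosshyb_evalue: float = 1e-5
    crosshyb_identity: float = 0.8
    edge_min_bp: int = 60

    def __post_init__(self) -> None:
        for name in ("max_missing", "max_depth", "min_maf", "thin_window",
                     "ld_r2_max", "ld_window", "crosshyb_evalue", "edge_min_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.crosshyb_identity <= 1.0:
            raise ValueError("crosshyb_identity must lie in (0, 1]")


def active(candidates: list[SnpCandidate]) -> list[SnpCandidate]:
    """Candidates still flowing through the cascade."""
    return [c for c in candidates if c.is_active]


def removal_log(candidates: list[SnpCandidate], stage: str = "") -> list[tuple[str, str, str]]:
    """(snp_id, stage, reason) rows for every removed candidate."""
    return [(c.snp_id, stage, c.removal_reason) for c in candidates if not c.is_active]


# ---------------------------------------------------------------------------
# VCF-level filtering
# ---------------------------------------------------------------------------

def _maf_from_af(af: float) -> float:
    return min(af, 1.0 - af)


def candidates_from_vcf(path: str, species_id: str) -> list[SnpCandidate]:
    """Parse a VCF into raw candidates with per-record summary stats.

    Missing rate is the fraction of samples without a genotype call;
    mean depth is averaged over samples with FORMAT/DP (falling back to
    INFO/DP divided by sample count). Multi-allelic and non-SNP records
    are kept but will be removed by :func:`filter_variants`.
    """
    from cyvcf2 import VCF

    out: list[SnpCandidate] = []
    vcf = VCF(path)
    n_samples = len(vcf.samples)
    for i, rec in enumerate(vcf):
        try:
            alt = rec.ALT[0] if rec.ALT else ""
            missing = (
                float(np.sum(rec.gt_types == 2)) / n_samples if n_samples else 0.0
            )
            depth = _record_mean_depth(rec, n_samples)
            maf = _maf_from_af(rec.aaf if rec.aaf is not None else 0.0)
            cand = SnpCandidate.__new__(SnpCandidate)
            # bypass __post_init__ checks: raw records may be indels or
            # multi-allelic; filter_variants removes them with a reason.
            cand.species_id = species_id
            cand.chrom = rec.CHROM
            cand.pos = rec.POS
            cand.ref_allele = rec.REF
            cand.alt_allele = ",".join(rec.ALT) if rec.ALT else ""
            cand.flank_up = None
            cand.flank_down = None
            cand.per_pool_maf = {"all": maf}
            cand.missing_rate = missing
            cand.mean_depth = depth
            cand.status = ACTIVE
            out.append(cand)
        except Exception as exc:  # pragma: no cover - malformed record path
            raise ValueError(f"malformed VCF record at line index {i}: {exc}") from exc
    return out


def _record_mean_depth(rec, n_samples: int) -> float:
    try:
        dp = rec.format("DP")
        if dp is not None:
            vals = np.asarray(dp, dtype=float).ravel()
            vals = vals[vals >= 0]
            if vals.size:
                return float(vals.mean())
    except Exception:
        pass
    info_dp = rec.INFO.get("DP")
    if info_dp is not None and n_samples:
        return float(info_dp) / n_samples
    return 0.0


def filter_variants(candidates: list[SnpCandidate], params: FilterParams) -> list[SnpCandidate]:
    """Apply the record-level filters; returns retained candidates in order.

    Removal reasons (first failing rule wins): ``non_snp`` (indel or
    non-ACGT allele), ``multiallelic``, ``missing_rate``, ``max_depth``,
    ``min_maf``, ``at_cg_exclusion``.
    """
    retained: list[SnpCandidate] = []
    for c in candidates:
        if not c.is_active:
            continue
        alts = c.alt_allele.split(",") if c.alt_allele else []
        if len(alts) > 1:
            c.remove("multiallelic")
            continue
        alt = alts[0] if alts else ""
        if len(c.ref_allele) != 1 or len(alt) != 1 or \
                c.ref_allele not in VALID_ALLELES or alt not in VALID_ALLELES:
            c.remove("non_snp")
            continue
        if c.missing_rate > params.max_missing:
            c.remove("missing_rate")
            continue
        if c.mean_depth > params.max_depth:
            c.remove("max_depth")
            continue
        # a site is worth arraying if sufficiently polymorphic in at
        # least one pool; with a single pooled estimate this is just MAF
        maf = max(c.per_pool_maf.values()) if c.per_pool_maf else 0.0
        if maf < params.min_maf:
            c.remove("min_maf")
            continue
        if frozenset((c.ref_allele, alt)) in AMBIGUOUS_PAIRS:
            c.remove("at_cg_exclusion")
            continue
        retained.append(c)
    return retained


# ---------------------------------------------------------------------------
# Proximity thinning
# ---------------------------------------------------------------------------

def thin_by_proximity(candidates: list[SnpCandidate], window: int,
                      mode: str = "exclusive") -> list[SnpCandidate]:
    """Thin candidates closer than ``window`` bp on the same chromosome.

    ``exclusive`` keeps only SNPs with no other input SNP within the
    window (both members of a close pair drop — "no other neighboring
    polymorphism"); ``keep_first`` scans by position and keeps a SNP only
    if it lies >= window bp from the last kept SNP.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    if mode not in ("exclusive", "keep_first"):
        raise ValueError(f"unknown thinning mode {mode!r}")

    act = active(candidates)
    order = sorted(range(len(act)), key=lambda i: (act[i].chrom, act[i].pos))
    keep: set[int] = set()
    if mode == "exclusive":
        for j, idx in enumerate(order):
            c = act[idx]
            prev = act[order[j - 1]] if j > 0 else None
            nxt = act[order[j + 1]] if j + 1 < len(order) else None
            too_close = (
                (prev is not None and prev.chrom == c.chrom and c.pos - prev.pos < window)
                or (nxt is not None and nxt.chrom == c.chrom and nxt.pos - c.pos < window)
            )
            if not too_close:
                keep.add(idx)
    else:  # keep_first
        last_kept: dict[str, int] = {}
        for idx in order:
            c = act[idx]
            last = last_kept.get(c.chrom)
            if last is None or c.pos - last >= window:
                keep.add(idx)
                last_kept[c.chrom] = c.pos
    retained = []
    for i, c in enumerate(act):
        if i in keep:
            retained.append(c)
        else:
            c.remove("thin_proximity")
    return retained


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of dosages, pairwise-complete.

    Monomorphic columns (zero variance on the shared samples) have
    undefined r^2; treated as 0 so they are never pruned on LD grounds.
    """
    mask = ~(np.isnan(gi) | np.isnan(gj))
    if mask.sum() < 2:
        return 0.0
    x, y = gi[mask], gj[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def prune_ld(genotypes: np.ndarray, candidates: list[SnpCandidate],
             params: FilterParams) -> list[SnpCandidate]:
    """Greedy left-to-right LD pruning within a sliding window per chrom.

    ``genotypes`` is samples x SNPs dosage (0/1/2, NaN missing) with
    columns aligned to ``candidates``. Scanning candidates in input
    order within each chromosome, a SNP is dropped when its r^2 with any
    already-kept SNP among the previous ``ld_window`` candidates of that
    chromosome exceeds ``ld_r2_max``. Deterministic given input order.
    """
    act = active(candidates)
    if genotypes.shape[1] != len(act):
        raise ValueError("genotype columns must align with active candidates")
    genotypes = np.asarray(genotypes, dtype=float)
    kept_by_chrom: dict[str, list[int]] = {}
    idx_in_chrom: dict[str, list[int]] = {}
    retained: list[SnpCandidate] = []
    for j, c in enumerate(act):
        seen = idx_in_chrom.setdefault(c.chrom, [])
        kept = kept_by_chrom.setdefault(c.chrom, [])
        my_rank = len(seen)
        drop = False
        for k in reversed(kept):
            # k is (rank, column); only compare within the window in
            # candidate rank along this chromosome
            if my_rank - k[0] > params.ld_window:
                break
            if _pairwise_r2(genotypes[:, k[1]], genotypes[:, j]) > params.ld_r2_max:
                drop = True
                break
        seen.append(j)
        if drop:
            c.remove("ld_prune")
        else:
            kept.append((my_rank, j))
            retained.append(c)
    return retained


# ---------------------------------------------------------------------------
# Gene-pool MAF classes
# ---------------------------------------------------------------------------

@dataclass
class MafClassRule:
    """One predicate over per-pool MAFs; rules are evaluated in order.

    ``min_maf`` maps pool -> lower bound (inclusive); ``max_maf`` maps
    pool -> upper bound (exclusive). A rule matches when every stated
    bound holds.
    """

    name: str
    min_maf: dict[str, float] = field(default_factory=dict)
    max_maf: dict[str, float] = field(default_factory=dict)


def classify_by_pool_maf(candidate: SnpCandidate,
                         class_rules: list[MafClassRule]) -> str | None:
    """First matching rule's name, or None when no rule matches."""
    pools = candidate.per_pool_maf
    for rule in class_rules:
        for pool in list(rule.min_maf) + list(rule.max_maf):
            if pool not in pools:
                raise KeyError(f"rule {rule.name!r} references unknown pool {pool!r}")
        ok = all(pools[p] >= t for p, t in rule.min_maf.items()) and \
             all(pools[p] < t for p, t in rule.max_maf.items())
        if ok:
            return rule.name
    return None


# ---------------------------------------------------------------------------
# Even random selection
# ---------------------------------------------------------------------------

def select_even_random(candidates: list[SnpCandidate], n: int,
                       genome_bins: int, seed: int) -> list[SnpCandidate]:
    """Select ``n`` candidates evenly across fixed-width genome bins.

    The genome is partitioned into ``genome_bins``-bp bins per
    chromosome; selection proceeds round-robin over bins (each round
    takes at most one SNP per bin, uniformly at random within the bin's
    remaining candidates) until ``n`` SNPs are drawn, which caps
    per-bin quotas for evenness. Deterministic for a given seed.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    act = active(candidates)
    if n >= len(act):
        return list(act)
    rng = np.random.default_rng(seed)
    bins: dict[tuple[str, int], list[int]] = {}
    for i, c in enumerate(act):
        key = (c.chrom, (c.pos - 1) // genome_bins)
        bins.setdefault(key, []).append(i)
    bin_keys = sorted(bins)
    pools = {k: list(bins[k]) for k in bin_keys}
    for k in bin_keys:
        rng.shuffle(pools[k])
    chosen: list[int] = []
    while len(chosen) < n:
        progressed = False
        for k in bin_keys:
            if len(chosen) >= n:
                break
            if pools[k]:
                chosen.append(pools[k].pop())
                progressed = True
        if not progressed:
            break
    chosen_set = set(chosen)
    retained = []
    for i, c in enumerate(act):
        if i in chosen_set:
            retained.append(c)
        else:
            c.remove("not_selected")
    return retained
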