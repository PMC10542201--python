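"""Synthetic two-channel intensity data for pooled two-species reactions.

Everything the caller and the validation layer consume can be generated
here: population genotypes under a Balding-Nichols island model,
pedigreed offspring, and Axiom-style two-channel probe intensities with
controllable cluster geometry, DNA quality, null alleles (off-target
variants), cross-species divergence, and pooling crosstalk.

Signal geometry. A genotype's contrast (log2 ratio of the A and B
channels) is drawn around its cluster mean; signal strength (mean log2
intensity) is drawn around ``strength_mean`` scaled by per-sample
quality. Channels are reconstructed as

    a = 2**(strength + contrast/2),   b = 2**(strength - contrast/2),

the exact inverse of the caller's contrast/strength transform, so the
round trip is the identity at zero noise. Null-allele carriers at
OTV-designated SNPs, probes of species absent from a reaction, and
divergence-nulled probes of related-species samples all emit
background-level strength (``strength_mean + log2(crosstalk)``) with
zero-centred contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix, IntensityMatrix, ReactionPlan
from .manifest import ArrayManifest, ProbeSet


@dataclass
class PopModel:
    """Island-model population structure for genotype simulation.

    Per-locus ancestral frequencies are drawn uniformly from
    ``ancestral_maf_range``; pool frequencies follow a Balding-Nichols
    Beta distribution parameterized by ``fst_target`` and genotypes are
    Hardy-Weinberg within pools.
    """

    n_pools: int = 4
    fst_target: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    samples_per_pool: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")


@dataclass
class SignalModel:
    """Cluster geometry and noise for intensity simulation.

    Defaults give three clearly separated diploid clusters (contrast
    means +1.5 / 0 / -1.5, sd 0.15) at full strength 10 log2 units with
    sd 0.25; ``quality`` in (0, 1] (scalar, or per-sample mapping)
    scales strength and inflates contrast noise; ``crosstalk`` sets the
    background level as a fraction of full strength. ``otv_fraction``
    of the genotyping SNPs per species carry a null allele at frequency
    ``null_allele_freq``; ``divergence`` (scalar or per-sample mapping)
    nulls that fraction of probes for a sample, emulating a related
    species hybridized on another species' probes.
    """

    cluster_contrast_means: tuple[float, float, float] = (1.5, 0.0, -1.5)
    cluster_sd: float = 0.15
    strength_mean: float = 10.0
    strength_sd: float = 0.25
    otv_fraction: float = 0.05
    null_allele_freq: float = 0.3
    quality: float | dict[str, float] = 1.0
    crosstalk: float = 0.02
    divergence: float | dict[str, float] = 0.0
    tetraploid_contrast_means: tuple[float, ...] = (1.5, 0.75, 0.0, -0.75, -1.5)

    def __post_init__(self) -> None:
        aa, ab, bb = self.cluster_contrast_means
        if not (aa > 0 > bb) or ab != 0.0:
            raise ValueError("cluster means must satisfy AA > 0 = AB > BB")

    def quality_of(self, sample: str) -> float:
        q = self.quality.get(sample, 1.0) if isinstance(self.quality, dict) \
            else float(self.quality)
        if not 0.0 < q <= 1.0:
            raise ValueError(f"quality for {sample} must lie in (0, 1]")
        return q

    def divergence_of(self, sample: str) -> float:
        d = self.divergence.get(sample, 0.0) if isinstance(self.divergence, dict) \
            else float(self.divergence)
        return d

    @property
    def background_strength(self) -> float:
        return self.strength_mean + math.log2(self.crosstalk)


@dataclass
class SimTruth:
    """Ground truth recorded by the simulator for recovery tests."""

    otv_probes: set[str] = field(default_factory=set)
    null_carriers: dict[str, set[str]] = field(default_factory=dict)  # probe -> samples
    diverged: dict[str, set[str]] = field(default_factory=dict)  # sample -> probes


def simulate_population_genotypes(
        manifest_subset: list[ProbeSet], pop: PopModel, seed: int,
) -> tuple[GenotypeMatrix, np.ndarray, list[str]]:
    """Simulate diploid genotypes for one species' probes.

    Returns (genotypes, pool_freqs, pool_labels) where ``pool_freqs``
    is the true n_pools x n_loci alt-allele frequency matrix and
    ``pool_labels`` gives each sample's pool. At ``fst_target == 0``
    every pool shares the per-locus ancestral frequency exactly.
    """
    rng = np.random.default_rng(seed)
    loci = [p.probe_id for p in manifest_subset if p.probe_type == "genotyping"]
    n_loci = len(loci)
    lo, hi = pop.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=n_loci)
    if pop.fst_target == 0.0:
        pool_freqs = np.tile(p_anc, (pop.n_pools, 1))
    else:
        f = pop.fst_target
        shape = (1.0 - f) / f
        pool_freqs = rng.beta(p_anc * shape, (1.0 - p_anc) * shape,
                              size=(pop.n_pools, n_loci))
    calls = np.empty((pop.n_pools * pop.samples_per_pool, n_loci), dtype=np.int16)
    labels: list[str] = []
    samples: list[str] = []
    for k in range(pop.n_pools):
        pool = f"pool{k}"
        block = rng.binomial(2, pool_freqs[k],
                             size=(pop.samples_per_pool, n_loci))
        calls[k * pop.samples_per_pool:(k + 1) * pop.samples_per_pool] = block
        for i in range(pop.samples_per_pool):
            samples.append(f"{pool}_s{i}")
            labels.append(pool)
    return GenotypeMatrix(samples, loci, calls), pool_freqs, labels


def simulate_pedigree(
        parents: GenotypeMatrix,
        families: list[tuple[str, str, int]],
        error_rate: float = 0.0,
        seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, tuple[str, str]]]:
    """Mendelian offspring for (sire, dam, n_offspring) families.

    Each offspring receives one allele per parent per locus (a parent
    with genotype g transmits the alt allele with probability g/2;
    missing parental genotypes transmit a fair random allele). With
    probability ``error_rate`` a recorded offspring call is replaced by
    a uniform draw from the other two diploid codes.

    Returns (offspring genotypes, pedigree offspring -> (sire, dam)).
    """
    rng = np.random.default_rng(seed)
    sample_pos = {s: i for i, s in enumerate(parents.samples)}
    n_loci = parents.n_snps
    rows: list[np.ndarray] = []
    names: list[str] = []
    pedigree: dict[str, tuple[str, str]] = {}
    for fam_idx, (sire, dam, n_off) in enumerate(families):
        for pid in (sire, dam):
            if pid not in sample_pos:
                raise KeyError(f"unknown parent id {pid!r}")
        g_sire = parents.calls[sample_pos[sire]].astype(float)
        g_dam = parents.calls[sample_pos[dam]].astype(float)
        p_sire = np.where(g_sire == MISSING, 0.5, g_sire / 2.0)
        p_dam = np.where(g_dam == MISSING, 0.5, g_dam / 2.0)
        for j in range(n_off):
            a1 = rng.random(n_loci) < p_sire
            a2 = rng.random(n_loci) < p_dam
            g = (a1.astype(np.int16) + a2.astype(np.int16))
            if error_rate > 0:
                err = rng.random(n_loci) < error_rate
                # replace with a uniform draw from the other two codes
                shift = rng.integers(1, 3, size=n_loci)
                g = np.where(err, (g + shift) % 3, g).astype(np.int16)
            name = f"fam{fam_idx}_o{j}"
            names.append(name)
            rows.append(g)
            pedigree[name] = (sire, dam)
    calls = np.vstack(rows) if rows else np.empty((0, n_loci), dtype=np.int16)
    return GenotypeMatrix(names, list(parents.snp_ids), calls), pedigree


def simulate_intensities(
        manifest: ArrayManifest,
        genotypes_by_species: dict[str, GenotypeMatrix],
        plan: ReactionPlan,
        sig: SignalModel,
        seed: int = 0,
) -> IntensityMatrix:
    """Two-channel intensities for every planned sample over every probe.

    For each genotyping probe of a species present in the sample's
    reaction, contrast ~ N(cluster mean of the genotype, sd/quality)
    and strength ~ N(strength_mean * quality, strength_sd). DQC probes
    behave as fixed homozygous-A probes. Probes of species absent from
    the reaction — and background-emitting entries (null-allele
    carriers at OTV SNPs, divergence-nulled probes) — get
    background-level strength with zero-centred contrast. Tetraploid
    input (ploidy 4) uses the five tetraploid contrast means.

    The returned matrix carries a :class:`SimTruth` in ``.truth``.
    Identical seeds give bit-identical matrices.
    """
    rng = np.random.default_rng(seed)
    samples = plan.samples
    species_of = plan.species_of_sample()
    probes = manifest.entries
    probe_ids = [p.probe_id for p in probes]
    truth = SimTruth()

    # per-sample map: species present in the sample's reaction -> the
    # member contributing that species' DNA (a pooled well carries both
    # members' signal; each member row records the whole well)
    member_species: dict[str, dict[str, str]] = {}
    for rx in plan.reactions:
        rx_map = {sp: sid for sid, sp in rx.members}
        for sid, _ in rx.members:
            member_species[sid] = rx_map

    # designate OTV probes and null carriers per species
    null_carrier: dict[tuple[str, str], bool] = {}
    for sp, gm in genotypes_by_species.items():
        sp_probes = [p.probe_id for p in probes
                     if p.probe_type == "genotyping" and p.species_id == sp]
        n_otv = int(round(sig.otv_fraction * len(sp_probes)))
        otv_ids = list(rng.choice(sp_probes, size=n_otv, replace=False)) if n_otv else []
        truth.otv_probes.update(otv_ids)
        for pid in otv_ids:
            carriers = truth.null_carriers.setdefault(pid, set())
            for sid in gm.samples:
                n_null = rng.binomial(2, sig.null_allele_freq)
                if n_null > 0:
                    null_carrier[(sid, pid)] = True
                    carriers.add(sid)

    # divergence-nulled probes per related-species sample
    for sid in samples:
        d = sig.divergence_of(sid)
        if d > 0:
            own = [p.probe_id for p in probes
                   if member_species[sid].get(p.species_id) == sid
                   and p.probe_type == "genotyping"]
            n_div = int(round(d * len(own)))
            if n_div:
                nulled = set(rng.choice(own, size=n_div, replace=False))
                truth.diverged[sid] = nulled

    means = np.asarray(sig.cluster_contrast_means)
    tetra_means = np.asarray(sig.tetraploid_contrast_means)
    aa_mean = means[0]
    bg = sig.background_strength

    n, m = len(samples), len(probes)
    contrast = np.empty((n, m))
    strength = np.empty((n, m))
    gm_index: dict[str, dict[str, int]] = {
        sp: {s: i for i, s in enumerate(gm.samples)}
        for sp, gm in genotypes_by_species.items()}
    probe_col: dict[str, dict[str, int]] = {
        sp: {p: j for j, p in enumerate(gm.snp_ids)}
        for sp, gm in genotypes_by_species.items()}

    for i, sid in enumerate(samples):
        rx_map = member_species[sid]
        for j, probe in enumerate(probes):
            source = rx_map.get(probe.species_id)
            if source is None:
                contrast[i, j] = rng.normal(0.0, sig.cluster_sd)
                strength[i, j] = rng.normal(bg, sig.strength_sd)
                continue
            q = sig.quality_of(source)
            c_sd = sig.cluster_sd / q
            s_mu = sig.strength_mean * q
            if probe.probe_type == "dqc":
                contrast[i, j] = rng.normal(aa_mean, c_sd)
                strength[i, j] = rng.normal(s_mu, sig.strength_sd)
                continue
            is_background = (
                null_carrier.get((source, probe.probe_id), False)
                or probe.probe_id in truth.diverged.get(source, ()))
            if is_background:
                contrast[i, j] = rng.normal(0.0, sig.cluster_sd)
                strength[i, j] = rng.normal(bg, sig.strength_sd)
                continue
            gm = genotypes_by_species.get(probe.species_id)
            g = MISSING
            if gm is not None:
                row = gm_index[probe.species_id].get(source)
                col = probe_col[probe.species_id].get(probe.probe_id)
                if row is not None and col is not None:
                    g = int(gm.calls[row, col])
                else:
                    raise KeyError(
                        f"sample {source} / probe {probe.probe_id} missing from "
                        f"genotypes for species {probe.species_id}")
            if g == MISSING:
                contrast[i, j] = rng.normal(0.0, sig.cluster_sd)
                strength[i, j] = rng.normal(bg, sig.strength_sd)
                continue
            mu = tetra_means[g] if gm is not None and gm.ploidy == 4 else means[g]
            contrast[i, j] = rng.normal(mu, c_sd)
            strength[i, j] = rng.normal(s_mu, sig.strength_sd)

    a = np.power(2.0, strength + contrast / 2.0)
    b = np.power(2.0, strength - contrast / 2.0)
    out = IntensityMatrix(samples, probe_ids, a, b)
    out.truth = truth
    return out
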