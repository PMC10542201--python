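"""Shared fixtures: synthetic genomes, candidates, manifests and VCFs."""

from __future__ import annotations

import numpy as np
import pytest

from snparray import (
    ArrayManifest,
    PopModel,
    ProbeSet,
    Reaction,
    ReactionPlan,
    SignalModel,
    SnpCandidate,
    build_manifest,
    simulate_intensities,
    simulate_population_genotypes,
)

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome(rng) -> dict[str, str]:
    return {"chr1": random_sequence(rng, 5000), "chr2": random_sequence(rng, 3000)}


def make_candidate(chrom: str = "chr1", pos: int = 100, species: str = "sp",
                   ref: str = "A", alt: str = "C", **kw) -> SnpCandidate:
    return SnpCandidate(species_id=species, chrom=chrom, pos=pos,
                        ref_allele=ref, alt_allele=alt, **kw)


def candidate_at(genome: dict[str, str], chrom: str, pos: int,
                 species: str = "sp") -> SnpCandidate:
    """A candidate whose ref allele matches the genome base at pos (1-based)."""
    ref = genome[chrom][pos - 1].upper()
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]  # never A/T or C/G pair
    return make_candidate(chrom=chrom, pos=pos, species=species, ref=ref, alt=alt)


def small_manifest(n_snps: int = 100, n_dqc: int = 20,
                   species: str = "fish") -> ArrayManifest:
    probes = [ProbeSet(f"{species}_s{i}", species, "genotyping", "chr1",
                       1000 + 200 * i, "A", "C", "N" * 121)
              for i in range(n_snps)]
    dqc = [ProbeSet(f"{species}_dqc{i}", species, "dqc", "chr1",
                    500_000 + 200 * i, None, None, "N" * 121)
           for i in range(n_dqc)]
    return build_manifest({species: probes}, dqc)


def single_species_run(n_snps: int = 100, n_samples: int = 100, seed: int = 1,
                       sig: SignalModel | None = None, species: str = "fish",
                       fst: float = 0.0, n_pools: int = 1):
    """Simulate a single-species, single-sample-per-reaction experiment.

    Returns (manifest, truth genotypes, plan, intensities)."""
    manifest = small_manifest(n_snps=n_snps, species=species)
    per_pool = n_samples // n_pools
    pop = PopModel(n_pools=n_pools, fst_target=fst, samples_per_pool=per_pool)
    gm, _, _ = simulate_population_genotypes(manifest.genotyping, pop, seed=seed)
    plan = ReactionPlan([Reaction(f"r{i}", [(s, species)])
                         for i, s in enumerate(gm.samples)])
    im = simulate_intensities(manifest, {species: gm}, plan,
                              sig or SignalModel(), seed=seed + 1)
    return manifest, gm, plan, im


def write_vcf(path, records: list[dict], samples: list[str] | None = None) -> str:
    """Write a minimal VCF. Each record dict: chrom, pos, ref, alt,
    gts (list of 'a/b' strings), optional dp (per-sample depth)."""
    samples = samples or [f"s{i}" for i in range(len(records[0]["gts"]))]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "##contig=<ID=chr1,length=100000>",
        "##contig=<ID=chr2,length=100000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for rec in records:
        dp = rec.get("dp", [20] * len(rec["gts"]))
        fields = [rec.get("chrom", "chr1"), str(rec["pos"]), ".", rec["ref"],
                  rec["alt"], ".", "PASS", f"DP={sum(dp)}", "GT:DP"]
        fields += [f"{g}:{d}" for g, d in zip(rec["gts"], dp)]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return str(path)
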