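"""Design a small single-species probe set from a synthetic VCF + genome.

Builds a toy fish genome and variant set, runs the candidate filter
cascade (record filters, proximity thinning, flank extraction,
cross-hybridization screen against a plant genome, even random
selection), designs DQC control probes and prints the manifest counts.
"""

import numpy as np

from snparray import (
    FilterParams,
    SnpCandidate,
    build_manifest,
    design_dqc_probes,
    extract_flanks,
    filter_variants,
    probes_from_candidates,
    screen_cross_hybridization,
    select_even_random,
    thin_by_proximity,
)

rng = np.random.default_rng(11)
BASES = np.array(list("ACGT"))
fish_genome = {"chr1": "".join(rng.choice(BASES, size=200_000))}
plant_genome = {"p1": "".join(rng.choice(BASES, size=100_000))}

# synthetic candidate variants with per-record summary stats
positions = np.sort(rng.choice(np.arange(100, 199_900), 2_000, replace=False))
SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}
candidates = []
for pos in positions:
    ref = fish_genome["chr1"][pos - 1]
    alt = SWAP[ref] if rng.random() < 0.9 else {"A": "T", "T": "A",
                                                "C": "G", "G": "C"}[ref]
    candidates.append(SnpCandidate(
        species_id="fish", chrom="chr1", pos=int(pos),
        ref_allele=ref, alt_allele=alt,
        per_pool_maf={"all": float(rng.uniform(0, 0.5))},
        missing_rate=float(rng.uniform(0, 0.3)),
        mean_depth=float(rng.uniform(5, 60))))

params = FilterParams(max_missing=0.2, max_depth=50, min_maf=0.05,
                      thin_window=30)
kept = filter_variants(candidates, params)
print(f"after record filters: {len(kept)} of {len(candidates)}")
kept = thin_by_proximity(kept, params.thin_window, mode="keep_first")
print(f"after 30 bp thinning: {len(kept)}")
kept = extract_flanks(kept, fish_genome, params.edge_min_bp)
print(f"after flank extraction (edge rule): {len(kept)}")
kept, removed = screen_cross_hybridization(kept, [plant_genome])
print(f"after cross-hybridization screen: {len(kept)} "
      f"({len(removed)} removed)")
kept = select_even_random(kept, 500, genome_bins=10_000, seed=1)
print(f"even random selection: {len(kept)}")

dqc = design_dqc_probes(fish_genome, {"chr1": [c.pos for c in candidates]},
                        200, "fish", seed=1)
manifest = build_manifest({"fish": probes_from_candidates(kept)}, dqc)
print()
print(manifest.counts().to_string(index=False))
# counts: the genotyping row is the arrayed SNP set for the species; the
# dqc row is the non-polymorphic control probes used for sample QC.
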