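# Methods

This note documents the models, numerical choices, and limitations
behind `snparray`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, alleles, probes

All genomic coordinates are 1-based and fully closed (VCF convention).
A probe window is 121 bases: 60 bases of upstream flank, the variant
base at index 61 (1-based), 60 bases of downstream flank. Probes are
designed on the reference plus strand; because A/T and C/G SNPs are
excluded early in the cascade (their alleles are their own reverse
complements and therefore strand-ambiguous on an array), allele
identity is unambiguous without strand bookkeeping. Candidates closer
than 60 bp to either scaffold end cannot yield a full window and are
removed with reason `edge`.

## Design cascade

The cascade is a sequence of monotone, order-stable, idempotent
filters; each removed candidate carries exactly one reason, so reasons
partition the removed set. Defaults (all configurable via
`FilterParams`): missingness ≤ 0.2, mean depth ≤ 100 (a cap against
repetitive regions), MAF ≥ 0.05, thinning window 30 bp, LD pruning at
r² > 0.2 within a 50-SNP window, cross-hybridization thresholds
E ≤ 10⁻⁵ and identity ≥ 0.8.

*Thinning* has two modes. `exclusive` keeps a SNP only when no other
input SNP lies within the window (both members of a close pair drop;
appropriate when "no neighboring polymorphism" is the design goal).
`keep_first` scans by position and keeps a SNP when it is at least a
window from the last kept SNP — the classic VCF-thinning behaviour.
Default is `exclusive`; the fish presets use `keep_first` with 30 bp.

*LD pruning* is greedy left-to-right per chromosome: a SNP is dropped
when its dosage r² (pairwise-complete Pearson, squared) with any
already-kept SNP among the previous 50 candidates exceeds the cap.
Monomorphic columns have undefined r² and are treated as r² = 0 (kept).
The LD parameters are not biologically canonical — they are a
reasonable default for dense resequencing panels and are fully
configurable.

*Cross-hybridization screen.* The 121-base window is searched against
every other-taxon genome on both strands with a seeded ungapped local
aligner: exact 8-mer seeds from a genome k-mer index, X-drop extension
(drop 20), match +1 / mismatch −2. Significance uses Karlin–Altschul
`E = K·m·n·exp(−λS)` with the fixed published ungapped parameters for
+1/−2 scoring (λ = 1.28, K = 0.46) and n = the total other-taxon
genome length. A candidate is removed when its best HSP has E ≤ 10⁻⁵
*and* identity ≥ 0.8 over the aligned span. The contract is
engine-agnostic — an external aligner honouring the same thresholds can
back it — and the tests verify decisions against an exhaustive
all-diagonals alignment oracle. Like any seeded search, hits whose
identity pattern leaves no 8-base exact match can in principle be
missed; at the decision thresholds above such hits are vanishingly
rare.

*Probe convertibility proxy.* The vendor's conversion score is
proprietary, so the two hard rules are applied exactly — no IUPAC
ambiguity code anywhere in the window ("wobbles"), and zero other known
variants inside the window ("poly count") — and the numeric score is a
documented deterministic proxy: starting from 1, subtract
`2·max(0, |GC − 0.5| − 0.2)` (zero inside GC 0.3–0.7) and
`0.1·max(0, longest homopolymer − 6)`, clip to [0, 1], and require
score > 0.6. The proxy supplements, never replaces, the hard rules.

*Secondary-genome check.* Mismatch-only (no indels): the window is
scanned against both strands of the secondary assembly with a
vectorized Hamming profile; a candidate is kept only when exactly one
location matches with ≤ 1 mismatch. Zero hits ("no hits") and multiple
hits (ambiguous placement) both remove.

*Even random selection* partitions each chromosome into fixed-width
bins and draws round-robin across bins — one SNP per bin per round,
uniformly within the bin — until the quota is reached. This caps dense
bins and fills sparse ones, giving an even genomic spread;
deterministic per seed.

*DQC probes* are 121-base windows sampled (seeded) from regions that
overlap no known variant and contain only A/C/G/T, kept
non-overlapping. The published description of the control-probe count
is internally inconsistent, so the per-species count is a free
parameter defaulting to 200.

## Reaction simulator

**What it emulates.** Pool-structured diploid (or tetraploid)
genotypes, pooled two-species reactions, and the cluster geometry of
two-channel array intensities. Pool allele frequencies follow
Balding–Nichols: `p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` around a uniform
ancestral frequency, with Hardy–Weinberg sampling within pools; at
F = 0 all pools share the ancestral frequency exactly. Pedigree
offspring receive one allele per parent per locus; with probability
`error_rate` a recorded call is replaced by a uniform draw from the
other two diploid codes (the Mendel-conflict rate implied by this model
is verified in closed form in the tests).

**Signal model.** Contrast means default to (+1.5, 0, −1.5) for
AA/AB/BB with sd 0.15 — a deliberately "three clear, well-separated
clusters" regime, degradable via config — and (±1.5, ±0.75, 0) in
tetraploid mode. Strength is N(10·q, 0.25) log₂ units where q ∈ (0, 1]
is per-sample quality; lower quality both shrinks strength and inflates
contrast noise (sd/q), which is what makes downstream DQC monotone in
degradation. Channels are `a = 2^(S+K/2)`, `b = 2^(S−K/2)`, the exact
inverse of the caller's transform. Background (absent species,
null-allele carriers, divergence-nulled probes) sits at
`10 + log₂(crosstalk)` with crosstalk defaulting to 2% of full
strength — pooling per se is neutral beyond this constant, a model
assumption justified by the design cascade's cross-hybridization
screen, not a biological claim. A pooled well is one physical
hybridization: each member row records the whole well's signal, and the
species split later attributes each species' probes to the member
carrying that species' DNA.

**Off-target variants.** A fraction (default 5%) of each species'
SNPs carry a null allele at frequency 0.3; any sample with ≥ 1 null
allele emits background-level strength at that probe. The `divergence`
parameter nulls a per-sample fraction of probes, emulating a related
species hybridized to another species' probes.

**What it does not emulate** (hence what passing tests do not show
about real data): plate/batch spatial effects, probe-sequence-specific
affinity, dye bias, partial null-allele intensity (carriers are fully
background), linkage between loci (loci are independent given the pool
frequencies), and ascertainment bias in the arrayed SNP set.

## Caller

The proprietary production caller is replaced by a documented
constrained-EM stand-in with the same category semantics.

*Transform.* `K = log₂(a/b)`, `S = (log₂a + log₂b)/2`, channels floored
at 10⁻³ before logs.

*Genotype calling.* Per SNP, a 1-D Gaussian mixture is fitted on the
contrast for **every non-empty subset** of the prior cluster positions
(7 models diploid, 31 tetraploid); the subset with minimal BIC
(−2ℓ + (3k−1)·ln N) wins. EM is batched across SNPs, fully
deterministic (no random restarts), initialized at the prior positions
with sd 0.2, tolerance 10⁻⁶, ≤ 100 iterations, sd floor 0.05. Each
component mean is anchored within ± half the prior cluster spacing of
its own position (±0.75 diploid, ±0.375 tetraploid) so a component can
never wander onto a neighbouring genotype's cluster — component
identity stays positional, which is what lets a two-component fit mean
"AA + AB" rather than "whichever two clusters exist". Samples get
their max-posterior component's genotype when the posterior reaches
0.85, else no-call. SNPs with fewer than 20 samples, or non-converged
fits, are failed (all-missing, category Other).

*OTV recall.* A global low-strength threshold is estimated by
deterministic two-means on all strength values (midpoint when the
centres separate by > 2 log₂ units, otherwise no OTV population
exists). Per SNP, the below-threshold samples (≥ 3 required) form a
candidate null cluster; when a two-component normal model of the
strength values beats one component by BIC, those samples are recoded
`otv` and the SNP is flagged.

*Sample QC.* DQC is the fraction of the species' control probes whose
contrast has the expected homozygous-A sign with magnitude ≥ 1.0 and
strength ≥ 2.0 log₂ units (the exact production formula is not public;
this stand-in preserves the semantics "near 1 for clean samples,
monotone in quality"). QC call rate is the call percentage on a seeded
10% SNP subset (minimum 20 SNPs, recorded in the manifest metadata).
Stage 1 keeps samples with DQC ≥ 0.82 **and** QC call rate ≥ 95
(boundary values pass). Stage 2 computes, for each genotyped sample,
`allele_deviation_mean` = mean over called SNPs of
`min(1, |K − μ_assigned| / (3σ_assigned))` — larger is worse — and
removes samples exceeding 0.85 (the published threshold names the
metric but not its formula or direction; this definition is the
package's). Final call rate is reported only for samples that reach
final genotyping.

*Classification* (first match wins): `CallRateBelowThreshold` when the
SNP call rate over final samples is < 97% (the per-SNP convention,
deliberately distinct from the 95% *sample* QC threshold); `OTV` when
flagged; `MonoHighResolution` when a single called genotype remains;
`PolyHighResolution` when polymorphic with ≥ 2 minor-homozygote calls
and cluster separation ≥ 2 (min pairwise |Δμ| / pooled σ);
`NoMinorHom` when polymorphic and separated but with < 2
minor-homozygote calls (no minor-homozygote cluster required — the
stricter "het cluster present" reading was considered and not adopted);
`Other` otherwise. Conversion rate is (PHR + NMH)/total, percentages
rounded half-up.

*Tetraploid dosages* use the same machinery over five prior positions;
a winning polymorphic fit without cluster separation is rejected
(all-missing) rather than reported.

## Validation analytics

*PCA*: per-SNP mean imputation of missing dosages, column centring
(optional unit scaling), SVD; variance explained from squared singular
values. *DAPC-lite*: PCA → k-means (10 restarts, fixed seed) for each
candidate k, cluster number chosen by a spherical-Gaussian BIC, then
LDA projection onto ≤ k−1 axes — a deliberately lean reimplementation
of the DAPC recipe. *F_ST*: Weir–Cockerham (1984) ratio-of-sums over
loci with ≥ 2 observations per group and pooled polymorphism, pairwise
or multi-group; negative estimates are reported as-is. *IBS*:
`1 − |gᵢ − gⱼ|/ploidy` averaged over shared non-missing loci (otv codes
are treated as missing); duplicates flagged above 0.97. *Parentage*:
for each offspring every unordered candidate pair is scored by the
fraction of informative loci (non-missing in all three) where the
offspring cannot receive one allele from each parent; the unique
minimizer with mismatch ≤ eps is assigned. eps defaults to 0.01; under
1% simulated genotyping error the acceptance experiments use eps = 0.03
because a true trio's expected mismatch (~0.005) then has non-trivial
mass above 0.01 at 1,000 loci. Exclusion-based assignment (rather than
likelihood-based) was chosen for transparency; it requires enough
informative loci to separate true pairs from relatives.

## Reporting

Welch's unequal-variance t statistic with Satterthwaite df and
two-sided p (sidedness is a package default; significance reported at
0.05); group descriptive statistics with SD undefined below n = 2; and
accounting tables that must partition exactly
(`passed = screened − fail_DQC − fail_QCCR − removed_later`, negative
results are errors, not clamped).

## Problem sizes and determinism

The acceptance experiments run at 200 samples × 1,000 SNPs for the
round trip, 4 pools × 50 samples × 5,000 loci × 10 seeds for F_ST
recovery, and 3 families × 30 offspring × 60 candidates × 1,000 loci
for parentage — sizes chosen so each experiment completes in seconds to
a couple of minutes on one CPU while leaving Monte-Carlo error well
inside the tolerances being checked. Every stochastic component takes
an explicit seed; identical seeds give bit-identical simulations, and
the caller contains no randomness at all (its only seeded choice is the
QC SNP subset).

## Known limitations

The caller stand-in shares category semantics, not numerics, with the
production software — real-data category proportions will differ. The
cross-hybridization screen is ungapped; a gapped aligner would catch
indel-containing homology the screen scores lower. DQC and
allele_deviation_mean are stand-in formulas. The simulator's clean
cluster geometry makes the round-trip concordance an upper bound on
what messy biological data would give; the degradation, OTV and
divergence knobs exist precisely to probe the failure modes, and the
monotonicity checks (not absolute values) are the transferable result.
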