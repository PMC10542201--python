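"""Independent brute-force oracles used to verify the optimized paths.

These deliberately re-derive each quantity from first principles (all
pairs scans, exhaustive diagonals, naive Hamming windows) and share no
code with the implementations they check.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -2

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def exclusive_thinning_oracle(positions: list[int], window: int) -> set[int]:
    """All-pairs check: keep positions with no other position within window."""
    return {p for p in positions
            if all(q == p or abs(q - p) >= window for q in positions)}


def greedy_ld_oracle(genotypes: np.ndarray, window: int,
                     r2_max: float) -> list[int]:
    """Naive greedy left-to-right pruning on one chromosome."""
    kept: list[int] = []
    for j in range(genotypes.shape[1]):
        drop = False
        for i in kept:
            if j - i > window:
                continue
            gi, gj = genotypes[:, i], genotypes[:, j]
            mask = ~(np.isnan(gi) | np.isnan(gj))
            if mask.sum() < 2 or gi[mask].std() == 0 or gj[mask].std() == 0:
                continue
            r = np.corrcoef(gi[mask], gj[mask])[0, 1]
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return kept


def best_ungapped_alignment_oracle(query: str, genome: str) -> tuple[int, float]:
    """Exhaustive best ungapped local alignment over every diagonal of
    both strands (per-diagonal maximum-scoring subarray, +1/-2).
    Returns (best score, identity of the best segment)."""
    best_score, best_ident = 0, 0.0
    for q in (query, revcomp(query)):
        m, n = len(q), len(genome)
        for d in range(-(m - 1), n):
            qi0, gi0 = max(0, -d), max(0, d)
            L = min(m - qi0, n - gi0)
            if L <= 0:
                continue
            score = matches = length = 0
            run_best = (0, 0.0)
            for t in range(L):
                s = MATCH if q[qi0 + t] == genome[gi0 + t] else MISMATCH
                if score <= 0:
                    score = matches = length = 0
                score += s
                matches += s == MATCH
                length += 1
                if score > run_best[0]:
                    run_best = (score, matches / length)
            if run_best[0] > best_score:
                best_score, best_ident = run_best
    return best_score, best_ident


def hamming_hits_oracle(probe: str, genome: str, max_mm: int) -> int:
    """Naive sliding-window mismatch scan of both strands."""
    hits = 0
    for q in (probe, revcomp(probe)):
        for i in range(len(genome) - len(q) + 1):
            mm = sum(a != b for a, b in zip(q, genome[i:i + len(q)]))
            if mm <= max_mm:
                hits += 1
    return hits


def wc_fst_two_group_oracle(counts1: tuple[int, int, int],
                            counts2: tuple[int, int, int]) -> float:
    """Weir-Cockerham (1984) FST for two groups given genotype counts
    (n_AA, n_AB, n_BB), computed step by step from the published
    definitions (spreadsheet style)."""
    n1, n2 = sum(counts1), sum(counts2)
    p1 = (2 * counts1[2] + counts1[1]) / (2 * n1)
    p2 = (2 * counts2[2] + counts2[1]) / (2 * n2)
    h1, h2 = counts1[1] / n1, counts2[1] / n2
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


def ibs_pair_oracle(g1: np.ndarray, g2: np.ndarray, ploidy: int = 2) -> float:
    """Locus-by-locus allele-sharing average over shared non-missing loci."""
    vals = []
    for a, b in zip(g1, g2):
        if np.isnan(a) or np.isnan(b):
            continue
        vals.append(1.0 - abs(a - b) / ploidy)
    return float(np.mean(vals)) if vals else float("nan")
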