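"""Cross-taxon hybridization screening of probe flank regions.

Plant probes whose 121-base flank region resembles fish genomic
sequence (and vice versa) risk cross-hybridization in a pooled
reaction, so candidates are screened by local alignment against every
genome of the other taxon group, on both strands. A hit with E-value
<= 1e-5 and identity >= 0.8 over the aligned span removes the
candidate, mirroring the usual BLASTN screening thresholds.

The built-in engine is a seeded ungapped local aligner (exact k-mer
seeds, X-drop extension) with Karlin-Altschul E-values under fixed
published ungapped nucleotide parameters (match +1 / mismatch -2:
lambda = 1.28, K = 0.46). The database length is the total length of
all other-taxon genomes. The screening contract is engine-agnostic: an
external aligner honouring the same thresholds may back it.

A separate uniqueness check against a secondary genome of the target
taxon keeps a candidate only when its flank region maps to exactly one
location with at most ``max_mismatch`` mismatches over its full length
(no indels), matching the "no hits or more than one mismatch" design
rule for transferring probes between related reference assemblies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .design import SnpCandidate, active
from .flanks import flank121

MATCH = 1
MISMATCH = -2
KA_LAMBDA = 1.28
KA_K = 0.46

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes; non-ACGT bases get code 4 (never match)."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass
class LocalHit:
    score: int
    length: int
    identity: float
    evalue: float


def karlin_altschul_evalue(score: int, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def _build_kmer_index(genome_codes: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    buf = genome_codes.tobytes()
    for i in range(len(genome_codes) - k + 1):
        kmer = buf[i:i + k]
        if b"\x04" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _extend_ungapped(q: np.ndarray, g: np.ndarray, qi: int, gi: int, k: int,
                     xdrop: int) -> tuple[int, int]:
    """X-drop extension of an exact k-mer seed; returns (score, hsp_length)."""
    score = k * MATCH
    best = score
    # right extension
    right = 0
    i, j = qi + k, gi + k
    cur = score
    while i < len(q) and j < len(g):
        cur += MATCH if q[i] == g[j] else MISMATCH
        if cur > best:
            best, right = cur, i - (qi + k) + 1
        if best - cur > xdrop:
            break
        i += 1
        j += 1
    # left extension
    left = 0
    cur = best
    best2 = best
    i, j = qi - 1, gi - 1
    while i >= 0 and j >= 0:
        cur += MATCH if q[i] == g[j] else MISMATCH
        if cur > best2:
            best2, left = cur, qi - i
        if best2 - cur > xdrop:
            break
        i -= 1
        j -= 1
    length = k + right + left
    return best2, length


def best_local_hit(query: str, genome_codes: np.ndarray,
                   index: dict[bytes, list[int]], db_len: int,
                   k: int = 8, xdrop: int = 20) -> LocalHit | None:
    """Best seeded ungapped HSP of ``query`` against one genome strand set.

    The query is searched as given and reverse-complemented. Returns the
    highest-scoring HSP or None when no seed matches.
    """
    best: LocalHit | None = None
    for strand, qseq in enumerate((query, revcomp(query))):
        q = encode(qseq)
        qbuf = q.tobytes()
        seen_diags: set[tuple[int, int]] = set()
        for qi in range(len(q) - k + 1):
            kmer = qbuf[qi:qi + k]
            if b"\x04" in kmer:
                continue
            for gi in index.get(kmer, ()):
                diag = (strand, gi - qi)
                if diag in seen_diags:
                    continue
                seen_diags.add(diag)
                score, length = _extend_ungapped(q, genome_codes, qi, gi, k, xdrop)
                n_match = (score + 2 * length) // 3  # from S = m - 2(L - m)
                identity = n_match / length if length else 0.0
                ev = karlin_altschul_evalue(score, len(q), db_len)
                if best is None or score > best.score:
                    best = LocalHit(score, length, identity, ev)
    return best


def screen_cross_hybridization(candidates: list[SnpCandidate],
                               other_genomes: list,
                               evalue: float = 1e-5,
                               identity: float = 0.8,
                               seed_len: int = 8) -> tuple[list[SnpCandidate], list[SnpCandidate]]:
    """Remove candidates whose flank region hits any other-taxon genome.

    ``other_genomes`` is a list of mappings chrom -> sequence (pyfaidx
    Fasta or dicts). Returns (retained, removed). Removal requires both
    E-value <= ``evalue`` and identity >= ``identity`` on the best HSP.
    """
    act = active(candidates)
    if not other_genomes:
        warnings.warn("no other-taxon genomes supplied; cross-hybridization "
                      "screen is a no-op", stacklevel=2)
        return act, []

    chroms: list[tuple[np.ndarray, dict]] = []
    db_len = 0
    for genome in other_genomes:
        for name in list(genome.keys()):
            seq = str(genome[name][:])
            codes = encode(seq)
            db_len += len(codes)
            chroms.append((codes, _build_kmer_index(codes, seed_len)))

    retained: list[SnpCandidate] = []
    removed: list[SnpCandidate] = []
    for c in act:
        probe = flank121(c)
        hit_found = False
        for codes, index in chroms:
            hit = best_local_hit(probe, codes, index, db_len, k=seed_len)
            if hit and hit.evalue <= evalue and hit.identity >= identity:
                hit_found = True
                break
        if hit_found:
            c.remove("cross_hybridization")
            removed.append(c)
        else:
            retained.append(c)
    return retained, removed


# ---------------------------------------------------------------------------
# Secondary-genome uniqueness check
# ---------------------------------------------------------------------------

def _hamming_profile(query_codes: np.ndarray, genome_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the query at every full-length offset of the genome."""
    L = len(query_codes)
    n = len(genome_codes)
    if n < L:
        return np.empty(0, dtype=np.int32)
    counts = np.zeros(n - L + 1, dtype=np.int32)
    for i in range(L):
        counts += genome_codes[i:i + n - L + 1] != query_codes[i]
    return counts


def count_near_exact_hits(probe: str, genome, max_mismatch: int) -> int:
    """Number of genome locations (both strands) within ``max_mismatch``."""
    hits = 0
    for qseq in (probe, revcomp(probe)):
        q = encode(qseq)
        for name in list(genome.keys()):
            codes = encode(str(genome[name][:]))
            prof = _hamming_profile(q, codes)
            hits += int(np.count_nonzero(prof <= max_mismatch))
    return hits


def check_secondary_genome(candidates: list[SnpCandidate], secondary_genome,
                           max_mismatch: int = 1) -> list[SnpCandidate]:
    """Keep candidates whose flank region maps uniquely to the secondary genome.

    A candidate is retained iff exactly one location (across both
    strands of all sequences) matches its 121-base flank region with at
    most ``max_mismatch`` mismatches over the full probe length.
    Candidates with no such location ("no hits") or several (ambiguous
    placement) are removed with reason ``secondary_genome``.
    """
    retained: list[SnpCandidate] = []
    for c in active(candidates):
        n_hits = count_near_exact_hits(flank121(c), secondary_genome, max_mismatch)
        if n_hits == 1:
            retained.append(c)
        else:
            c.remove("secondary_genome")
    return retained
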