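"""Flank extraction from reference genomes and probe convertibility scoring.

Array probes interrogate a variant through its 121-base context: 60
bases upstream, the variant base at index 61 (1-based), 60 bases
downstream. Candidates too close to a scaffold end to yield full flanks
are dropped ("edge" rule), as are candidates whose stated reference
allele disagrees with the genome.

The vendor's proprietary probe conversion score is replaced by a
documented deterministic proxy combining flank GC content and the
longest homopolymer run; the two hard rules — no IUPAC ambiguity codes
("wobbles") in the flanks, and no other known variant within the probe
window ("poly count = 0") — are applied exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import SnpCandidate, active

IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
FLANK_LEN = 60


class GenomeError(KeyError):
    """A candidate references a sequence absent from the genome."""


def _get_seq(genome, chrom: str):
    try:
        return genome[chrom]
    except KeyError as exc:
        raise GenomeError(f"chromosome {chrom!r} absent from genome") from exc


def extract_flanks(candidates: list[SnpCandidate], genome,
                   edge_min_bp: int = 60) -> list[SnpCandidate]:
    """Fill 60-base flanks from the genome; drop edge/ref-mismatch sites.

    ``genome`` is any mapping chrom -> sequence supporting slicing
    (a :class:`pyfaidx.Fasta` or a plain dict of strings). Positions are
    1-based: flank_up covers pos-60..pos-1 and flank_down pos+1..pos+60.
    Candidates with pos <= edge_min_bp or pos > len(chrom) - edge_min_bp
    are removed with reason ``edge``; candidates whose genome base at
    pos differs from ref_allele are removed with reason ``ref_mismatch``.
    """
    retained: list[SnpCandidate] = []
    for c in active(candidates):
        seq = _get_seq(genome, c.chrom)
        chrom_len = len(seq)
        if c.pos <= edge_min_bp or c.pos > chrom_len - edge_min_bp:
            c.remove("edge")
            continue
        window = str(seq[c.pos - edge_min_bp - 1: c.pos + edge_min_bp]).upper()
        ref = window[edge_min_bp]
        if ref != c.ref_allele:
            c.remove("ref_mismatch")
            continue
        c.flank_up = window[:edge_min_bp]
        c.flank_down = window[edge_min_bp + 1:]
        retained.append(c)
    return retained


def flank121(candidate: SnpCandidate, allele: str | None = None) -> str:
    """The 121-base probe window with the variant base at index 61 (1-based)."""
    if candidate.flank_up is None or candidate.flank_down is None:
        raise ValueError(f"candidate {candidate.snp_id} has no flanks")
    base = allele if allele is not None else candidate.ref_allele
    return candidate.flank_up + base + candidate.flank_down


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = None
    for ch in seq.upper():
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


@dataclass
class ProbeScore:
    recommended: bool
    score: float
    has_wobble: bool
    poly_count: int


def score_probe_proxy(candidate: SnpCandidate,
                      nearby_variants: list[int] | None = None,
                      score_min: float = 0.6,
                      gc_band: tuple[float, float] = (0.3, 0.7),
                      max_homopolymer: int = 6) -> ProbeScore:
    """Deterministic convertibility score for a candidate's probe window.

    recommended <=> no wobble AND poly count 0 AND score > score_min.

    The score starts at 1 and is penalized linearly for GC content
    outside ``gc_band`` (2 points per unit of excess deviation from 0.5
    beyond the band half-width) and for homopolymer runs longer than
    ``max_homopolymer`` (0.1 per extra base), clipped to [0, 1].

    ``nearby_variants`` lists 1-based positions (same chrom) of other
    known variants; any position other than the candidate's own inside
    the 121-base window counts toward the poly count.
    """
    if candidate.flank_up is None or candidate.flank_down is None:
        raise ValueError(f"candidate {candidate.snp_id} has no flanks")
    window = flank121(candidate)
    has_wobble = any(ch in IUPAC_AMBIGUITY for ch in window.upper())
    poly_count = 0
    if nearby_variants:
        lo, hi = candidate.pos - FLANK_LEN, candidate.pos + FLANK_LEN
        poly_count = sum(1 for p in nearby_variants
                         if lo <= p <= hi and p != candidate.pos)
    gc = gc_fraction(window)
    half_band = (gc_band[1] - gc_band[0]) / 2.0
    gc_pen = 2.0 * max(0.0, abs(gc - 0.5) - half_band)
    run_pen = 0.1 * max(0, longest_homopolymer(window) - max_homopolymer)
    score = min(1.0, max(0.0, 1.0 - gc_pen - run_pen))
    recommended = (not has_wobble) and poly_count == 0 and score > score_min
    return ProbeScore(recommended, score, has_wobble, poly_count)
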