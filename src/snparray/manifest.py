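"""Array manifest assembly: genotyping probes plus Dish Quality Control probes.

The manifest is the final description of everything tiled on the array:
one entry per genotyping probe (a biallelic SNP with its 121-base
context) and per DQC probe. DQC probes are sampled from non-polymorphic
genome windows — they carry no alleles and report only hybridization
quality downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SnpCandidate
from .flanks import flank121

PROBE_LEN = 121


@dataclass
class ProbeSet:
    probe_id: str
    species_id: str
    probe_type: str  # "genotyping" | "dqc"
    chrom: str
    pos: int
    allele_ref: str | None = None
    allele_alt: str | None = None
    flank121: str = ""

    def __post_init__(self) -> None:
        if self.probe_type not in ("genotyping", "dqc"):
            raise ValueError(f"unknown probe_type {self.probe_type!r}")
        if self.probe_type == "genotyping" and (
                self.allele_ref is None or self.allele_alt is None):
            raise ValueError(f"genotyping probe {self.probe_id} must carry both alleles")
        if self.probe_type == "dqc" and (
                self.allele_ref is not None or self.allele_alt is not None):
            raise ValueError(f"dqc probe {self.probe_id} must carry no alleles")


@dataclass
class ArrayManifest:
    entries: list[ProbeSet]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.probe_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate probe ids: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genotyping(self) -> list[ProbeSet]:
        return [e for e in self.entries if e.probe_type == "genotyping"]

    @property
    def dqc(self) -> list[ProbeSet]:
        return [e for e in self.entries if e.probe_type == "dqc"]

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.species_id, None)
        return list(seen)

    def counts(self) -> pd.DataFrame:
        """Per-species probe counts plus a Total row (genotyping probes)."""
        rows = []
        for sp in self.species():
            n_geno = sum(1 for e in self.genotyping if e.species_id == sp)
            n_dqc = sum(1 for e in self.dqc if e.species_id == sp)
            rows.append({"species": sp, "genotyping": n_geno, "dqc": n_dqc})
        df = pd.DataFrame(rows, columns=["species", "genotyping", "dqc"])
        total = {"species": "Total",
                 "genotyping": int(df["genotyping"].sum()) if len(df) else 0,
                 "dqc": int(df["dqc"].sum()) if len(df) else 0}
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"probe_id": e.probe_id, "species": e.species_id, "type": e.probe_type,
              "chrom": e.chrom, "pos": e.pos,
              "allele_ref": e.allele_ref or "", "allele_alt": e.allele_alt or "",
              "flank121": e.flank121}
             for e in self.entries])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ArrayManifest":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
        entries = [
            ProbeSet(r.probe_id, r.species, r.type, r.chrom, int(r.pos),
                     r.allele_ref or None, r.allele_alt or None, r.flank121)
            for r in df.itertuples()
        ]
        return cls(entries)


def probes_from_candidates(candidates: list[SnpCandidate]) -> list[ProbeSet]:
    """Genotyping ProbeSets for selected candidates (flanks required)."""
    return [
        ProbeSet(
            probe_id=c.snp_id, species_id=c.species_id, probe_type="genotyping",
            chrom=c.chrom, pos=c.pos,
            allele_ref=c.ref_allele, allele_alt=c.alt_allele,
            flank121=flank121(c),
        )
        for c in candidates
    ]


class InsufficientInvariantSequence(RuntimeError):
    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"requested {requested} DQC probes but only {achievable} "
            f"non-overlapping invariant windows are available")


def design_dqc_probes(genome, variant_positions: dict[str, set[int] | list[int]],
                      n_per_species: int, species_id: str,
                      probe_len: int = PROBE_LEN, seed: int = 0) -> list[ProbeSet]:
    """Sample non-polymorphic, non-overlapping probe windows from a genome.

    ``variant_positions`` maps chrom -> 1-based positions of every known
    variant for the species; a window is eligible when it overlaps no
    variant and contains only A/C/G/T. Windows are drawn uniformly
    (seeded) without replacement and kept if they do not overlap a
    previously accepted window. Raises
    :class:`InsufficientInvariantSequence` reporting the achievable
    count when fewer than ``n_per_species`` windows exist.
    """
    rng = np.random.default_rng(seed)
    eligible: list[tuple[str, int]] = []  # (chrom, 1-based window start)
    for name in list(genome.keys()):
        seq = str(genome[name][:]).upper()
        n = len(seq)
        if n < probe_len:
            continue
        bad = np.zeros(n, dtype=bool)
        for p in variant_positions.get(name, ()):  # 1-based
            if 1 <= p <= n:
                bad[p - 1] = True
        for i, ch in enumerate(seq):
            if ch not in "ACGT":
                bad[i] = True
        # window starting at 0-based i is clean iff no bad base in [i, i+L)
        bad_cum = np.concatenate([[0], np.cumsum(bad)])
        clean = (bad_cum[probe_len:] - bad_cum[:-probe_len]) == 0
        for i in np.flatnonzero(clean):
            eligible.append((name, int(i) + 1))

    order = rng.permutation(len(eligible))
    taken: dict[str, list[tuple[int, int]]] = {}
    probes: list[ProbeSet] = []
    for idx in order:
        if len(probes) >= n_per_species:
            break
        chrom, start = eligible[idx]
        end = start + probe_len - 1
        overlap = any(not (end < s or start > e) for s, e in taken.get(chrom, ()))
        if overlap:
            continue
        taken.setdefault(chrom, []).append((start, end))
        seq = str(genome[chrom][start - 1:end]).upper()
        probes.append(ProbeSet(
            probe_id=f"{species_id}_dqc_{chrom}_{start}",
            species_id=species_id, probe_type="dqc",
            chrom=chrom, pos=start + probe_len // 2, flank121=seq))
    if len(probes) < n_per_species:
        raise InsufficientInvariantSequence(n_per_species, len(probes))
    return sorted(probes, key=lambda p: (p.chrom, p.pos))


def build_manifest(per_species_selections: dict[str, list[ProbeSet]],
                   dqc_probes: list[ProbeSet],
                   metadata: dict | None = None) -> ArrayManifest:
    """Concatenate per-species genotyping probes and DQC probes.

    Raises on duplicate probe ids. Per-species and total counts are
    available from :meth:`ArrayManifest.counts`.
    """
    entries: list[ProbeSet] = []
    for sp, probes in per_species_selections.items():
        for p in probes:
            if p.species_id != sp:
                raise ValueError(
                    f"probe {p.probe_id} tagged {p.species_id!r} under selection {sp!r}")
            entries.append(p)
    entries.extend(dqc_probes)
    return ArrayManifest(entries, metadata=dict(metadata or {}))
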