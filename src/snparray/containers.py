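"""In-memory containers shared by the simulator, caller and validators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype codes: diploid 0/1/2 (alt-allele dosage), tetraploid 0..4,
#: plus sentinel codes for no-calls and off-target-variant recodes.
MISSING = -9
OTV_CODE = -1


@dataclass
class GenotypeMatrix:
    """Called dosages for samples x SNPs.

    ``calls`` uses alt-allele dosage codes (0..ploidy), ``MISSING`` and
    ``OTV_CODE``; ``posteriors`` holds the max-posterior of each call
    (NaN where uncalled), when available.
    """

    samples: list[str]
    snp_ids: list[str]
    calls: np.ndarray  # int8/int16, shape (n_samples, n_snps)
    ploidy: int = 2
    posteriors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError("calls shape must be (n_samples, n_snps)")
        valid = set(range(self.ploidy + 1)) | {MISSING, OTV_CODE}
        bad = set(np.unique(self.calls)) - valid
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def dosage_float(self) -> np.ndarray:
        """Calls as float with MISSING and OTV mapped to NaN."""
        out = self.calls.astype(float)
        out[(self.calls == MISSING) | (self.calls == OTV_CODE)] = np.nan
        return out

    def call_rate_per_sample(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def call_rate_per_snp(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            [self.samples[i] for i in idx], list(self.snp_ids),
            self.calls[idx], self.ploidy,
            None if self.posteriors is None else self.posteriors[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.samples, columns=self.snp_ids)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str, ploidy: int = 2) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=np.int16), ploidy)


@dataclass
class IntensityMatrix:
    """Two-channel (A/B) signals per sample x probe; the caller's sole input."""

    samples: list[str]
    probe_ids: list[str]
    channel_a: np.ndarray
    channel_b: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.samples), len(self.probe_ids))
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        for name, ch in (("channel_a", self.channel_a), ("channel_b", self.channel_b)):
            if ch.shape != shape:
                raise ValueError(f"{name} shape must be (n_samples, n_probes)")
            if np.any(ch < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def subset(self, samples: list[str] | None = None,
               probe_ids: list[str] | None = None) -> "IntensityMatrix":
        sample_pos = {s: i for i, s in enumerate(self.samples)}
        probe_pos = {p: j for j, p in enumerate(self.probe_ids)}
        si = ([sample_pos[s] for s in samples]
              if samples is not None else list(range(self.n_samples)))
        pi = ([probe_pos[p] for p in probe_ids]
              if probe_ids is not None else list(range(self.n_probes)))
        return IntensityMatrix(
            [self.samples[i] for i in si],
            [self.probe_ids[j] for j in pi],
            self.channel_a[np.ix_(si, pi)], self.channel_b[np.ix_(si, pi)])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.samples):
            for j, p in enumerate(self.probe_ids):
                rows.append((s, p, self.channel_a[i, j], self.channel_b[i, j]))
        return pd.DataFrame(rows, columns=["sample", "probe", "channel_a", "channel_b"])

    def to_tsv(self, path: str) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = list(dict.fromkeys(df["sample"]))
        probes = list(dict.fromkeys(df["probe"]))
        a = np.zeros((len(samples), len(probes)))
        b = np.zeros_like(a)
        srow = {s: i for i, s in enumerate(samples)}
        pcol = {p: j for j, p in enumerate(probes)}
        for r in df.itertuples():
            a[srow[r.sample], pcol[r.probe]] = r.channel_a
            b[srow[r.sample], pcol[r.probe]] = r.channel_b
        return cls(samples, probes, a, b)


@dataclass
class Reaction:
    reaction_id: str
    members: list[tuple[str, str]]  # (sample_id, species_id)


@dataclass
class ReactionPlan:
    """Assignment of samples to (possibly pooled) genotyping reactions.

    A reaction holds one or two samples; with a taxon map supplied, at
    most one plant and one fish member are allowed per reaction. A
    sample may appear in exactly one reaction.
    """

    reactions: list[Reaction]
    taxon_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rx in self.reactions:
            if not 1 <= len(rx.members) <= 2:
                raise ValueError(f"reaction {rx.reaction_id} must have 1-2 members")
            taxa = []
            for sample_id, species_id in rx.members:
                if sample_id in seen:
                    raise ValueError(f"sample {sample_id} appears in multiple reactions")
                seen.add(sample_id)
                if self.taxon_of:
                    taxa.append(self.taxon_of.get(species_id))
            if self.taxon_of and len(taxa) == 2 and taxa[0] == taxa[1]:
                raise ValueError(
                    f"reaction {rx.reaction_id} pools two {taxa[0]} samples")

    @property
    def samples(self) -> list[str]:
        return [sid for rx in self.reactions for sid, _ in rx.members]

    def species_of_sample(self) -> dict[str, str]:
        return {sid: sp for rx in self.reactions for sid, sp in rx.members}

    def pooled_flag(self) -> dict[str, bool]:
        return {sid: len(rx.members) == 2
                for rx in self.reactions for sid, _ in rx.members}

    def to_frame(self) -> pd.DataFrame:
        rows = [(rx.reaction_id, sid, sp)
                for rx in self.reactions for sid, sp in rx.members]
        return pd.DataFrame(rows, columns=["reaction_id", "sample", "species"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, taxon_of: dict[str, str] | None = None) -> "ReactionPlan":
        df = pd.read_csv(path, sep="\t")
        reactions = [
            Reaction(str(rid), [(r.sample, r.species) for r in grp.itertuples()])
            for rid, grp in df.groupby("reaction_id", sort=False)
        ]
        return cls(reactions, taxon_of or {})
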