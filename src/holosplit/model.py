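"""Shared data model for holobiont metagenome deconvolution.

All coordinates are 0-based half-open on the forward strand.  Format
conversions (GFF3 is 1-based inclusive) happen at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = set("ACGTN")

FEATURE_KINDS = {
    "gene",
    "retrotransposon",
    "dna_transposon",
    "te_unclassified",
    "rdna_16s",
    "rdna_its",
    "telomere",
    "centromere_call",
}

KINGDOMS = {"fungus", "alga", "bacteria", "organelle", "unassigned"}


@dataclass
class Contig:
    """A DNA sequence with free-form provenance tags."""

    id: str
    seq: str
    tags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"contig {self.id}: invalid characters {sorted(bad)}")
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def gc_percent(self) -> float:
        """GC% over non-N bases; NaN if the contig is all N."""
        acgt = sum(self.seq.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        gc = self.seq.count("G") + self.seq.count("C")
        return 100.0 * gc / acgt


class ContigSet:
    """Ordered collection of contigs with unique ids."""

    def __init__(self, contigs=()):
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id: {contig.id}")
        self._contigs[contig.id] = contig

    def __getitem__(self, cid: str) -> Contig:
        return self._contigs[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._contigs

    def __iter__(self):
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def ids(self) -> list[str]:
        return list(self._contigs)

    def total_length(self) -> int:
        return sum(c.length for c in self)


@dataclass
class FeatureRecord:
    """A located annotation (gene, TE, rDNA, telomere, centromere call)."""

    contig_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"
    family: str | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature on {self.contig_id}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def feature_id(self) -> str:
        return self.attrs.get("ID", f"{self.contig_id}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTable:
    """Contig x sample matrix of mean per-base depth."""

    contig_ids: list[str]
    sample_ids: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.contig_ids), len(self.sample_ids)):
            raise ValueError("depth matrix shape inconsistent with id lists")
        if np.any(self.depth < 0):
            raise ValueError("negative coverage values")

    def row(self, contig_id: str) -> np.ndarray:
        return self.depth[self.contig_ids.index(contig_id)]

    def subset(self, contig_ids) -> "CoverageTable":
        idx = [self.contig_ids.index(c) for c in contig_ids]
        return CoverageTable(list(contig_ids), list(self.sample_ids), self.depth[idx])


@dataclass
class ReadRecord:
    read_id: str
    contig_id: str
    start: int
    end: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.read_id}: start >= end")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"read {self.read_id}: mapq {self.mapq} outside [0,60]")


@dataclass
class ReadTaxon:
    read_id: str
    taxon_group: str  # bacteria | eukaryote | unclassified
    family: str | None = None

    def __post_init__(self) -> None:
        if self.taxon_group not in {"bacteria", "eukaryote", "unclassified"}:
            raise ValueError(f"bad taxon_group {self.taxon_group!r}")


@dataclass
class WindowTrack:
    """Per-window values (GC%, density...) along one contig.

    ``values[i]`` covers ``[start + i*step, start + i*step + window)``;
    NaN marks masked windows (e.g. >50% N).
    """

    contig_id: str
    window: int
    step: int
    values: np.ndarray
    start: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def window_start(self, i: int) -> int:
        return self.start + i * self.step
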