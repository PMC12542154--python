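"""Ground-truthed synthetic lichen holobiont generator.

Emulates the statistical structure a holobiont metagenome assembly presents
to the deconvolution pipeline: a fungal genome with bimodal GC (high-GC genic
blocks, RIP-degraded low-GC transposon blocks including one centromere-scale
block per chromosome), a higher-GC algal genome with telomeric ends and one
retrotransposon-cluster centromere per chromosome, several bacterial genomes
drawn from species-specific order-3 Markov chains with multi-copy
near-identical 16S rDNA, abundance-driven per-sample coverage, optional
planted fungal-bacterial chimeras and a planted HGT gene covered by
bacteria-classified reads.  Every contig, window, breakpoint, bin and HGT
gene has a ground-truth record, so downstream stages are testable offline.

Sequences are "reads-free": mapped reads are interval records, not FASTQ.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .model import (
    Contig,
    ContigSet,
    CoverageTable,
    FeatureRecord,
    ReadRecord,
    ReadTaxon,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class FungalConfig:
    n_chrom: int = 4
    chrom_len: int = 300_000
    genic_gc: float = 48.0
    ripped_gc: float = 16.0
    ripped_fraction: float = 0.375
    centromere_len: int = 100_000
    telomere_motif: str = "CCCTAA"
    base_depth: float = 220.0


@dataclass
class AlgalConfig:
    n_chrom: int = 3
    chrom_len: int = 350_000
    gc: float = 52.0
    telomere_motif: str = "TTTAGGG"
    centromere_len: int = 50_000
    centromere_start: int = 150_000
    centromere_retro_copies: int = 8
    base_depth: float = 21.0


@dataclass
class BacteriumConfig:
    name: str
    genome_len: int = 180_000
    gc: float = 60.0
    markov_bias: float = 0.1
    n_contigs: int = 8
    rdna_copies: int = 3
    rdna_identity_to_ref: float = 97.0
    base_depth: float = 50.0


@dataclass
class SamplesConfig:
    n_samples: int = 12
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0  # bacterial lognormal abundance spread
    host_sigma: float = 0.4  # shared fungus+alga (thallus) abundance
    host_jitter_sigma: float = 0.15
    depth_noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.depth_noise_cv < 0:
            raise ValueError("depth_noise_cv must be >= 0")


@dataclass
class ChimeraConfig:
    n: int = 2
    junction_motifs: tuple = ("telomere", "polyCG", "none")
    segment_len: int = 16_000
    ripped_tail: int = 8_000


@dataclass
class HgtConfig:
    planted: bool = True
    n_bact_reads: int = 10

    def __post_init__(self) -> None:
        if self.n_bact_reads < 0:
            raise ValueError("n_bact_reads must be >= 0")


def default_bacteria() -> list[BacteriumConfig]:
    names = ["BacA", "BacB", "BacC", "BacD", "BacE", "BacF"]
    gcs = [62.0, 63.0, 64.0, 65.0, 66.0, 63.5]
    idents = [99.0, 97.0, 95.0, 91.0, 88.0, 86.0]
    depths = [55.0, 40.0, 70.0, 30.0, 60.0, 45.0]
    return [
        BacteriumConfig(name=n, gc=g, rdna_identity_to_ref=i, base_depth=d)
        for n, g, i, d in zip(names, gcs, idents, depths)
    ]


@dataclass
class HolobiontConfig:
    seed: int = 42
    fungal: FungalConfig = field(default_factory=FungalConfig)
    algal: AlgalConfig = field(default_factory=AlgalConfig)
    bacteria: list = field(default_factory=default_bacteria)
    samples: SamplesConfig = field(default_factory=SamplesConfig)
    chimeras: ChimeraConfig = field(default_factory=ChimeraConfig)
    hgt: HgtConfig = field(default_factory=HgtConfig)

    def __post_init__(self) -> None:
        if self.fungal.ripped_gc >= self.fungal.genic_gc:
            raise ValueError("ripped_gc must be < genic_gc (bimodality unconstructible)")
        for b in self.bacteria:
            if not 0 < b.gc < 100:
                raise ValueError(f"{b.name}: GC outside (0,100)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HolobiontConfig":
        d = dict(d)
        if "fungal" in d:
            d["fungal"] = FungalConfig(**d["fungal"])
        if "algal" in d:
            d["algal"] = AlgalConfig(**d["algal"])
        if "bacteria" in d:
            d["bacteria"] = [BacteriumConfig(**b) for b in d["bacteria"]]
        if "samples" in d:
            d["samples"] = SamplesConfig(**d["samples"])
        if "chimeras" in d:
            c = dict(d["chimeras"])
            if "junction_motifs" in c:
                c["junction_motifs"] = tuple(c["junction_motifs"])
            d["chimeras"] = ChimeraConfig(**c)
        if "hgt" in d:
            d["hgt"] = HgtConfig(**d["hgt"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Random sequence machinery


def _rng(seed: int, *tags) -> np.random.Generator:
    ints = [zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *ints]))


class MarkovComposition:
    """Order-3 Markov chain over ACGT with an exact per-step GC probability.

    Every emitted base is G or C with probability exactly ``gc``; the
    context-dependent splits A-vs-T and G-vs-C carry the species-specific
    tetramer signature (amplitude ``bias``), so genome-wide GC is pinned to
    the target while tetramer profiles separate compositions.
    """

    def __init__(self, gc_percent: float, bias: float, rng: np.random.Generator,
                 base_split: tuple | None = None, species_bias: float = 0.0,
                 species_rng: np.random.Generator | None = None):
        gc = gc_percent / 100.0
        if base_split is None:
            u = rng.uniform(-1.0, 1.0, 64)
            v = rng.uniform(-1.0, 1.0, 64)
        else:
            u, v = base_split
        a_split = 0.5 + bias * u
        g_split = 0.5 + bias * v
        if species_bias and species_rng is not None:
            a_split = a_split + species_bias * species_rng.uniform(-1.0, 1.0, 64)
            g_split = g_split + species_bias * species_rng.uniform(-1.0, 1.0, 64)
        a_split = np.clip(a_split, 0.05, 0.95)
        g_split = np.clip(g_split, 0.05, 0.95)
        p_a = (1.0 - gc) * a_split
        p_c = gc * (1.0 - g_split)
        p_g = gc * g_split
        # cumulative in base order A,C,G,(T)
        self._cum = [
            (float(p_a[c]), float(p_a[c] + p_c[c]), float(p_a[c] + p_c[c] + p_g[c]))
            for c in range(64)
        ]
        self.gc_percent = gc_percent

    def sample(self, n: int, rng: np.random.Generator) -> str:
        u = rng.random(n)
        out = bytearray(n)
        bases = b"ACGT"
        cum = self._cum
        ctx = 0
        for i in range(n):
            x = u[i]
            c = cum[ctx]
            b = 0 if x < c[0] else 1 if x < c[1] else 2 if x < c[2] else 3
            out[i] = bases[b]
            ctx = ((ctx << 2) | b) & 63
        return out.decode("ascii")


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute ``n_subs`` distinct positions to a different base."""
    if n_subs <= 0:
        return seq
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    s = bytearray(seq.encode("ascii"))
    bases = b"ACGT"
    for p in pos:
        cur = s[p]
        choices = [b for b in bases if b != cur]
        s[p] = choices[int(rng.integers(3))]
    return s.decode("ascii")


def _mutate_to_identity(seq: str, identity_percent: float, rng) -> str:
    n_subs = int(round((1.0 - identity_percent / 100.0) * len(seq)))
    return _mutate(seq, n_subs, rng)


# ---------------------------------------------------------------------------
# Truth table


@dataclass
class TruthTable:
    """Ground truth for every emitted contig, window, bin and planted signal."""

    contigs: dict = field(default_factory=dict)
    ripped: dict = field(default_factory=dict)  # cid -> [(s,e), ...]
    centromeres_rip: dict = field(default_factory=dict)  # fungal cid -> (s,e)
    centromeres_retro: dict = field(default_factory=dict)  # algal cid -> (s,e)
    rdna_contigs: dict = field(default_factory=dict)  # cid -> species
    hgt_gene: str | None = None
    base_depths: dict = field(default_factory=dict)  # species -> depth
    rdna_identity_to_ref: dict = field(default_factory=dict)

    def kingdom_of(self, cid: str) -> str:
        return self.contigs[cid]["kingdom"]

    def species_of(self, cid: str) -> str:
        return self.contigs[cid]["species"]

    def kingdom_of_interval(self, cid: str, start: int, end: int) -> str:
        """Truth kingdom of a sub-interval; resolves chimeric contigs by the
        segment containing the interval midpoint."""
        rec = self.contigs[cid]
        if not rec.get("is_chimera"):
            return rec["kingdom"]
        mid = (start + end) / 2.0
        bounds = rec["breakpoints"]
        seg = sum(1 for b in bounds if mid >= b)
        return rec["part_kingdoms"][seg]

    def ripped_fraction(self, contig_lengths: dict) -> float:
        """Truth ripped fraction over the contigs present in ``ripped``."""
        total = sum(contig_lengths[c] for c in self.ripped)
        rip = sum(e - s for c in self.ripped for s, e in self.ripped[c])
        return rip / total if total else float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        tt = cls(**d)
        tt.ripped = {c: [tuple(iv) for iv in v] for c, v in tt.ripped.items()}
        tt.centromeres_rip = {c: tuple(v) for c, v in tt.centromeres_rip.items()}
        tt.centromeres_retro = {c: tuple(v) for c, v in tt.centromeres_retro.items()}
        return tt


# ---------------------------------------------------------------------------
# Coverage simulation


def draw_abundances(species: list[str], euk_species: set, cfg: SamplesConfig,
                    rng: np.random.Generator) -> dict:
    """Per-sample relative abundance per species.

    Eukaryote partners share a per-sample thallus (host) factor with small
    independent jitter, because fungus and alga are one physical organism per
    sample; bacterial species fluctuate independently and strongly, which is
    the signal coverage-correlation binning exploits.
    """
    host = np.exp(rng.normal(0.0, cfg.host_sigma, cfg.n_samples))
    out = {}
    for sp in species:
        if sp in euk_species:
            jitter = np.exp(rng.normal(0.0, cfg.host_jitter_sigma, cfg.n_samples))
            out[sp] = host * jitter
        else:
            out[sp] = np.exp(rng.normal(cfg.abundance_mu, cfg.abundance_sigma, cfg.n_samples))
    return out


def simulate_coverage(
    contig_species: dict,
    base_depths: dict,
    samples_cfg: SamplesConfig,
    seed: int,
    euk_species: set = frozenset(),
    abundances: dict | None = None,
    noise_tag: str = "cov",
) -> CoverageTable:
    """depth(contig, sample) = abundance(species, sample) * base_depth * (1 + cv*eps).

    Contigs of one species share the sample profile up to multiplicative
    noise (cv); depths are clipped at zero.
    """
    if samples_cfg.depth_noise_cv < 0:
        raise ValueError("cv must be >= 0")
    species = sorted(set(contig_species.values()))
    if abundances is None:
        abundances = draw_abundances(species, set(euk_species), samples_cfg,
                                     _rng(seed, "abundance"))
    rng = _rng(seed, "noise", noise_tag)
    cids = list(contig_species)
    depth = np.zeros((len(cids), samples_cfg.n_samples))
    for i, cid in enumerate(cids):
        sp = contig_species[cid]
        base = base_depths[sp]
        eps = rng.standard_normal(samples_cfg.n_samples)
        depth[i] = abundances[sp] * base * (1.0 + samples_cfg.depth_noise_cv * eps)
    np.clip(depth, 0.0, None, out=depth)
    samples = [f"s{j + 1:02d}" for j in range(samples_cfg.n_samples)]
    return CoverageTable(cids, samples, depth)


# ---------------------------------------------------------------------------
# Read planting


def plant_hgt_signal(
    contig: Contig,
    gene_interval: tuple,
    n_bact_reads: int,
    seed: int = 0,
    read_len: int = 300,
    background_step: int = 500,
    background_len: int = 150,
) -> tuple[list[ReadRecord], list[ReadTaxon]]:
    """Reads over one contig: eukaryote-classified background tiling the whole
    contig plus ``n_bact_reads`` bacteria-classified reads over the gene."""
    if n_bact_reads < 0:
        raise ValueError("n_bact_reads must be >= 0")
    gs, ge = gene_interval
    if not (0 <= gs < ge <= contig.length):
        raise ValueError("gene interval outside contig")
    reads: list[ReadRecord] = []
    taxa: list[ReadTaxon] = []
    for k, s in enumerate(range(0, contig.length - background_len + 1, background_step)):
        rid = f"{contig.id}_bg{k:06d}"
        reads.append(ReadRecord(rid, contig.id, s, s + background_len, 60))
        taxa.append(ReadTaxon(rid, "eukaryote"))
    if n_bact_reads:
        starts = np.linspace(max(0, gs - 100), max(0, ge - read_len), n_bact_reads)
        for k, s in enumerate(starts):
            s = int(round(s))
            rid = f"{contig.id}_hgt{k:03d}"
            reads.append(ReadRecord(rid, contig.id, s, min(s + read_len, contig.length), 60))
            taxa.append(ReadTaxon(rid, "bacteria", family="Acetobacteraceae"))
    return reads, taxa


# ---------------------------------------------------------------------------
# Genome builders


def _round500(x: float) -> int:
    return int(round(x / 500.0)) * 500


class _Compositions:
    def __init__(self, cfg: HolobiontConfig):
        s = cfg.seed
        self.fungal_genic = MarkovComposition(cfg.fungal.genic_gc, 0.25, _rng(s, "f_genic"))
        self.fungal_ripped = MarkovComposition(cfg.fungal.ripped_gc, 0.25, _rng(s, "f_rip"))
        self.algal = MarkovComposition(cfg.algal.gc, 0.30, _rng(s, "alga"))
        base_rng = _rng(s, "bact_base")
        base_split = (base_rng.uniform(-1, 1, 64), base_rng.uniform(-1, 1, 64))
        self.bacteria = {
            b.name: MarkovComposition(
                b.gc, 0.30, _rng(s, "unused"), base_split=base_split,
                species_bias=b.markov_bias, species_rng=_rng(s, "bact", b.name),
            )
            for b in cfg.bacteria
        }


def _build_fungal_chromosome(ci: int, cfg: HolobiontConfig, comps: _Compositions):
    f = cfg.fungal
    seed = cfg.seed
    rng = _rng(seed, "f_chrom", ci)
    L = _round500(f.chrom_len)
    rip_total = _round500(f.ripped_fraction * L)
    cen_len = _round500(f.centromere_len)
    extra = rip_total - cen_len
    if extra < 5000:
        raise ValueError("ripped_fraction too small for centromere_len")
    genic_total = L - rip_total
    g1 = _round500(genic_total * 0.30) + int(rng.integers(-8, 9)) * 500
    g2 = _round500(genic_total * 0.40)
    g3 = genic_total - g1 - g2
    layout = [("genic", g1), ("ripped", extra), ("genic", g2), ("ripped", cen_len), ("genic", g3)]

    pieces, feats, ripped_iv = [], [], []
    cid = f"F_chr{ci + 1}"
    pos = 0
    cen_iv = None
    for kind, ln in layout:
        if kind == "genic":
            pieces.append(comps.fungal_genic.sample(ln, rng))
        else:
            pieces.append(comps.fungal_ripped.sample(ln, rng))
            ripped_iv.append((pos, pos + ln))
            if ln == cen_len:
                cen_iv = (pos, pos + ln)
            # tile the block with retrotransposon copies (RIP-degraded)
            te = pos
            while te + 5000 <= pos + ln:
                feats.append(FeatureRecord(cid, te, te + 5000,
                                           "+" if rng.random() < 0.5 else "-",
                                           "retrotransposon", "RT_hopper",
                                           {"ID": f"{cid}_RT{te}"}))
                te += 5000
        pos += ln
    seq = "".join(pieces)

    # telomeres at both ends
    motif = f.telomere_motif
    tlen = (60 // len(motif)) * len(motif)
    left = motif * (tlen // len(motif))
    from .homology import revcomp
    right = revcomp(left)
    seq = left + seq[tlen:-tlen] + right
    feats.append(FeatureRecord(cid, 0, tlen, "+", "telomere", None, {"ID": f"{cid}_telL"}))
    feats.append(FeatureRecord(cid, L - tlen, L, "-", "telomere", None, {"ID": f"{cid}_telR"}))

    # genes and special TE annotations in genic blocks
    blocks = []
    p = 0
    for kind, ln in layout:
        if kind == "genic":
            blocks.append((p, p + ln))
        p += ln
    gi = 0
    for bi, (bs, be) in enumerate(blocks):
        p = bs + 2000
        if ci == 0 and bi == 0:
            # two unripped copies of the retrotransposon family
            for j in range(2):
                feats.append(FeatureRecord(cid, p, p + 5000, "+", "retrotransposon",
                                           "RT_hopper", {"ID": f"{cid}_RTu{j}"}))
                p += 6000
        if bi == 2:
            # two unripped DNA transposon copies per chromosome
            for j in range(2):
                feats.append(FeatureRecord(cid, p, p + 2000, "-", "dna_transposon",
                                           "DTA_mazu", {"ID": f"{cid}_DTA{j}"}))
                p += 3000
        while p + 1500 + 2000 <= be:
            strand = "+" if gi % 2 == 0 else "-"
            feats.append(FeatureRecord(cid, p, p + 1500, strand, "gene", None,
                                       {"ID": f"{cid}_g{gi:04d}"}))
            gi += 1
            p += 3500
    if ci == 1:
        # two RIP-degraded DNA transposon copies inside the small ripped block
        es, ee = ripped_iv[0]
        feats.append(FeatureRecord(cid, ee - 2200, ee - 200, "+", "dna_transposon",
                                   "DTA_mazu", {"ID": f"{cid}_DTAr0"}))
        feats.append(FeatureRecord(cid, es + 200, es + 2200, "+", "dna_transposon",
                                   "DTA_mazu", {"ID": f"{cid}_DTAr1"}))
    contig = Contig(cid, seq)
    return contig, feats, ripped_iv, cen_iv


def _build_algal_chromosome(ci: int, cfg: HolobiontConfig, comps: _Compositions,
                            retro_consensus: str):
    a = cfg.algal
    seed = cfg.seed
    rng = _rng(seed, "a_chrom", ci)
    L = a.chrom_len
    cs, clen = a.centromere_start, a.centromere_len
    cid = f"A_chr{ci + 1}"
    copy_len = clen // a.centromere_retro_copies

    arm1 = comps.algal.sample(cs, rng)
    arm2 = comps.algal.sample(L - cs - clen, rng)
    feats = []
    copies = []
    for j in range(a.centromere_retro_copies):
        copies.append(_mutate(retro_consensus[:copy_len], int(0.01 * copy_len), rng))
        fam = "RLG_cenA" if j % 2 == 0 else "RLG_cenB"
        feats.append(FeatureRecord(cid, cs + j * copy_len, cs + (j + 1) * copy_len,
                                   "+", "retrotransposon", fam,
                                   {"ID": f"{cid}_cenRT{j}"}))
    seq = arm1 + "".join(copies) + arm2

    motif = a.telomere_motif
    tlen = (70 // len(motif)) * len(motif)
    from .homology import revcomp
    seq = motif * (tlen // len(motif)) + seq[tlen:-tlen] + revcomp(motif * (tlen // len(motif)))
    feats.append(FeatureRecord(cid, 0, tlen, "+", "telomere", None, {"ID": f"{cid}_telL"}))
    feats.append(FeatureRecord(cid, L - tlen, L, "-", "telomere", None, {"ID": f"{cid}_telR"}))

    # scattered retrotransposon copies on the arms (annotation-level, low density)
    for j, p in enumerate((50_000, 100_000, cs + clen + 60_000)):
        feats.append(FeatureRecord(cid, p, p + 2000, "+", "retrotransposon",
                                   "RLG_cenB", {"ID": f"{cid}_armRT{j}"}))

    gi = 0
    genes = []
    for bs, be in ((tlen + 1000, cs - 1000), (cs + clen + 1000, L - tlen - 1000)):
        p = bs + 1000
        while p + 1500 + 2000 <= be:
            if not any(p < fe.end and fe.start < p + 1500 for fe in feats):
                strand = "+" if gi % 3 else "-"
                fr = FeatureRecord(cid, p, p + 1500, strand, "gene", None,
                                   {"ID": f"{cid}_g{gi:04d}"})
                feats.append(fr)
                genes.append(fr)
                gi += 1
            p += 4000
    return Contig(cid, seq), feats, (cs, cs + clen), genes


def _build_bacterium(b: BacteriumConfig, cfg: HolobiontConfig, comps: _Compositions,
                     ref_16s: str):
    seed = cfg.seed
    rng = _rng(seed, "b_genome", b.name)
    genome = comps.bacteria[b.name].sample(b.genome_len, rng)
    clen = b.genome_len // b.n_contigs
    species_16s = _mutate_to_identity(ref_16s, b.rdna_identity_to_ref, _rng(seed, "16s", b.name))
    contigs, feats, rdna_cids, rdna_seqs = [], [], [], []
    for j in range(b.n_contigs):
        cid = f"{b.name}_c{j + 1}"
        seq = genome[j * clen : (j + 1) * clen]
        if j < b.rdna_copies:
            copy = _mutate(species_16s, 2, _rng(seed, "16s_copy", b.name, j))
            seq = seq[:1000] + copy + seq[1000 + len(copy):]
            feats.append(FeatureRecord(cid, 1000, 1000 + len(copy), "+", "rdna_16s",
                                       b.name, {"ID": f"{b.name}_16S_{j + 1}"}))
            rdna_cids.append(cid)
            rdna_seqs.append((f"{b.name}_16S_{j + 1}", copy))
        contigs.append(Contig(cid, seq))
    return contigs, feats, rdna_cids, rdna_seqs, genome


def _build_chimera(k: int, cfg: HolobiontConfig, comps: _Compositions):
    seed = cfg.seed
    ch = cfg.chimeras
    rng = _rng(seed, "chimera", k)
    motif_kind = ch.junction_motifs[k % len(ch.junction_motifs)]
    genic_len = ch.segment_len - ch.ripped_tail
    fungal = comps.fungal_genic.sample(genic_len, rng) + comps.fungal_ripped.sample(ch.ripped_tail, rng)
    bact_cfg = cfg.bacteria[k % len(cfg.bacteria)]
    bact = comps.bacteria[bact_cfg.name].sample(ch.segment_len, rng)
    # guard bases so planted motif runs are not extended by chance
    fungal = fungal[:-1] + "A"
    bact = "A" + bact[1:]
    if motif_kind == "telomere":
        motif = cfg.fungal.telomere_motif * 10
        truth_pos = len(fungal) + len(motif)  # last motif base +1
    elif motif_kind == "polyCG":
        motif = "C" * 30
        truth_pos = len(fungal) + 15  # run midpoint
    else:
        motif = ""
        truth_pos = len(fungal)
    cid = f"chim{k + 1}"
    contig = Contig(cid, fungal + motif + bact)
    truth = {
        "kingdom": "chimera",
        "species": "chimera",
        "bin": None,
        "is_chimera": True,
        "breakpoints": [truth_pos],
        "part_kingdoms": ["fungus", "bacteria"],
        "junction_motif": motif_kind,
    }
    return contig, truth


# ---------------------------------------------------------------------------
# Top-level generation


@dataclass
class Holobiont:
    """Everything the generator emits, plus ground truth."""

    config: HolobiontConfig
    contigs: ContigSet
    features: list
    coverage_mq0: CoverageTable
    coverage_mq60: CoverageTable
    reads: list
    read_taxa: list
    rdna: ContigSet  # extracted rDNA copies
    rdna_refs: ContigSet  # the shared reference 16S panel
    truth: TruthTable

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_fasta(self.contigs, outdir / "contigs.fasta")
        hio.write_features(self.features, outdir / "features.gff3", "gff3")
        hio.write_coverage(self.coverage_mq0, outdir / "coverage_mq0.tsv")
        hio.write_coverage(self.coverage_mq60, outdir / "coverage_mq60.tsv")
        hio.write_read_map(self.reads, outdir / "read_map.tsv")
        hio.write_read_taxa(self.read_taxa, outdir / "read_taxon.tsv")
        hio.write_fasta(self.rdna, outdir / "rdna.fasta")
        hio.write_fasta(self.rdna_refs, outdir / "rdna_refs.fasta")
        self.truth.to_json(outdir / "truth.json")
        return {p.name: str(p) for p in sorted(outdir.iterdir())}


def generate_holobiont(config: HolobiontConfig | None = None) -> Holobiont:
    """Generate the synthetic holobiont; deterministic for a fixed config.seed."""
    cfg = config or HolobiontConfig()
    seed = cfg.seed
    comps = _Compositions(cfg)
    truth = TruthTable()
    contigs = ContigSet()
    features: list[FeatureRecord] = []

    # fungus
    for ci in range(cfg.fungal.n_chrom):
        contig, feats, ripped_iv, cen_iv = _build_fungal_chromosome(ci, cfg, comps)
        contigs.add(contig)
        features.extend(feats)
        truth.contigs[contig.id] = {
            "kingdom": "fungus", "species": "fungus", "bin": None,
            "is_chimera": False, "breakpoints": [],
        }
        truth.ripped[contig.id] = ripped_iv
        truth.centromeres_rip[contig.id] = cen_iv

    # alga
    retro_consensus = MarkovComposition(cfg.algal.gc, 0.3, _rng(seed, "a_retro")).sample(
        cfg.algal.centromere_len // cfg.algal.centromere_retro_copies, _rng(seed, "a_retro_seq")
    )
    algal_genes_chr1 = None
    for ci in range(cfg.algal.n_chrom):
        contig, feats, cen_iv, genes = _build_algal_chromosome(ci, cfg, comps, retro_consensus)
        contigs.add(contig)
        features.extend(feats)
        truth.contigs[contig.id] = {
            "kingdom": "alga", "species": "alga", "bin": None,
            "is_chimera": False, "breakpoints": [],
        }
        truth.centromeres_retro[contig.id] = cen_iv
        if ci == 0:
            algal_genes_chr1 = genes

    # bacteria
    ref_16s = MarkovComposition(55.0, 0.1, _rng(seed, "16s_base")).sample(1200, _rng(seed, "16s_seq"))
    rdna = ContigSet()
    genomes = {}
    for b in cfg.bacteria:
        bcontigs, feats, rdna_cids, rdna_seqs, genome = _build_bacterium(b, cfg, comps, ref_16s)
        genomes[b.name] = genome
        features.extend(feats)
        for c in bcontigs:
            contigs.add(c)
            truth.contigs[c.id] = {
                "kingdom": "bacteria", "species": b.name, "bin": b.name,
                "is_chimera": False, "breakpoints": [],
            }
        for cid in rdna_cids:
            truth.rdna_contigs[cid] = b.name
        for rid, seq in rdna_seqs:
            rdna.add(Contig(rid, seq))
        truth.rdna_identity_to_ref[b.name] = b.rdna_identity_to_ref
    rdna_refs = ContigSet([Contig("ref_16S", ref_16s)])

    # short contigs (<10 kb): verbatim excerpts, so homology assignment has truth
    short_specs = []
    fchroms = [f"F_chr{i + 1}" for i in range(cfg.fungal.n_chrom)]
    for j, cid in enumerate(fchroms[:4]):
        cen = truth.centromeres_rip[cid]
        if j < 2:  # RIP-degraded TE excerpt
            seq = contigs[cid].seq[cen[0] + 2000 + 1000 * j : cen[0] + 5000 + 1000 * j]
        else:  # genic excerpt
            seq = contigs[cid].seq[5000 + 5000 * j : 9000 + 5000 * j]
        short_specs.append((f"S_f{j + 1}", "fungus", seq))
    achroms = [f"A_chr{i + 1}" for i in range(cfg.algal.n_chrom)]
    acen = truth.centromeres_retro[achroms[0]]
    a1 = contigs[achroms[0]]
    short_specs.append(("S_a1", "alga", a1.seq[acen[0] + 2000 : acen[0] + 5000]))
    for j, cid in enumerate(achroms[1:3]):
        short_specs.append((f"S_a{j + 2}", "alga", contigs[cid].seq[50_000:54_000]))
    for j, b in enumerate(cfg.bacteria[:4]):
        pos = min(50_000, b.genome_len - 5000)
        short_specs.append((f"S_b{j + 1}", b.name, genomes[b.name][pos : pos + 3000]))
    for sid, sp, seq in short_specs:
        contigs.add(Contig(sid, seq))
        kingdom = "bacteria" if sp.startswith("Bac") else sp
        truth.contigs[sid] = {
            "kingdom": kingdom, "species": sp, "bin": None,
            "is_chimera": False, "breakpoints": [],
        }

    # chimeras
    for k in range(cfg.chimeras.n):
        contig, ctruth = _build_chimera(k, cfg, comps)
        contigs.add(contig)
        truth.contigs[contig.id] = ctruth

    # coverage (mq0/mq60 share abundances, independent noise)
    species_of = {}
    for cid, rec in truth.contigs.items():
        species_of[cid] = "fungus" if rec["is_chimera"] else rec["species"]
    base_depths = {"fungus": cfg.fungal.base_depth, "alga": cfg.algal.base_depth}
    for b in cfg.bacteria:
        base_depths[b.name] = b.base_depth
    truth.base_depths = dict(base_depths)
    euk = {"fungus", "alga"}
    abundances = draw_abundances(sorted(set(species_of.values())), euk, cfg.samples,
                                 _rng(seed, "abundance"))
    cov0 = simulate_coverage(species_of, base_depths, cfg.samples, seed, euk,
                             abundances=abundances, noise_tag="mq0")
    cov60 = simulate_coverage(species_of, base_depths, cfg.samples, seed, euk,
                              abundances=abundances, noise_tag="mq60")

    # reads: background over algal chr1 plus the planted HGT signal
    hgt_gene = algal_genes_chr1[len(algal_genes_chr1) // 2] if algal_genes_chr1 else None
    n_bact = cfg.hgt.n_bact_reads if cfg.hgt.planted else 0
    reads, taxa = plant_hgt_signal(a1, (hgt_gene.start, hgt_gene.end), n_bact, seed)
    if cfg.hgt.planted:
        truth.hgt_gene = hgt_gene.feature_id

    return Holobiont(cfg, contigs, features, cov0, cov60, reads, taxa, rdna, rdna_refs, truth)


# ---------------------------------------------------------------------------
# Chimera-focused test set


def generate_chimera_testset(seed: int = 42, n_clean: int = 50, n_chimera: int = 5):
    """Clean single-organism contigs plus planted fungal-bacterial chimeras.

    Clean contigs are compositionally uniform (bacterial, fungal genic,
    fungal ripped or algal), so they carry no junction; chimeras follow the
    default construction (genic+ripped fungal segment | motif | bacterial
    segment).  Returns (ContigSet, truth dict: cid -> breakpoint record or
    None for clean contigs).
    """
    cfg = HolobiontConfig(seed=seed)
    cfg.chimeras = ChimeraConfig(
        n=n_chimera, junction_motifs=("telomere", "telomere", "polyCG", "polyCG", "none")
    )
    comps = _Compositions(cfg)
    rng = _rng(seed, "chimera_testset")
    contigs = ContigSet()
    truth: dict[str, dict | None] = {}
    kinds = ["bact", "genic", "ripped", "alga"]
    for i in range(n_clean):
        kind = kinds[i % 4]
        if kind == "bact":
            b = cfg.bacteria[i % len(cfg.bacteria)]
            seq = comps.bacteria[b.name].sample(20_000, rng)
        elif kind == "genic":
            seq = comps.fungal_genic.sample(20_000, rng)
        elif kind == "ripped":
            seq = comps.fungal_ripped.sample(20_000, rng)
        else:
            seq = comps.algal.sample(20_000, rng)
        cid = f"clean{i + 1}"
        contigs.add(Contig(cid, seq))
        truth[cid] = None
    for k in range(n_chimera):
        contig, ctruth = _build_chimera(k, cfg, comps)
        contigs.add(contig)
        truth[contig.id] = ctruth
    return contigs, truth
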