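"""Repeat-induced point mutation (RIP) compartment analysis.

RIP is a fungal genome-defence mechanism that mutates C->T in repeated
sequence during sexual reproduction, leaving transposon-derived regions
strongly GC-depleted.  A RIP-affected fungal genome therefore shows a
bimodal GC distribution in genomic windows: a genic mode (~48% GC) and a
"ripped" TE-derived mode (~16%).  This module estimates the threshold
separating the modes, labels 500 bp windows as ripped/unripped, measures GC
around genes and TEs (flanks and metaprofiles), calls centromere-scale
ripped blocks, ranks TE family copies by GC, and calls algal centromeres
from retrotransposon density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .model import Contig, ContigSet, FeatureRecord
from .seqstats import gc_percent, gc_profile

RIP_WINDOW = 500


@dataclass
class ThresholdResult:
    value: float
    fallback_used: bool = False


@dataclass
class RipClassification:
    window: int
    threshold_gc: float
    labels: dict  # contig_id -> array of 'ripped'/'unripped'/'masked'
    fraction_ripped: float
    fraction_unripped: float


@dataclass
class FlankGcRecord:
    feature_id: str
    gc_5prime: float | None
    gc_3prime: float | None
    gc_body: float


@dataclass
class MetaProfile:
    matrix: np.ndarray  # feature x (flank_bins + body_bins + flank_bins)
    flank_bins: int
    body_bins: int

    @property
    def column_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)


@dataclass
class RipBlock:
    contig_id: str
    start: int
    end: int
    centromere_call: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _genome_windows(genome, window: int):
    """Yield (contig_id, values) of non-overlapping window GC tracks."""
    contigs = genome if isinstance(genome, ContigSet) else ContigSet([genome])
    for c in contigs:
        track = gc_profile(c, window=window, step=window)
        yield c.id, track.values


def find_rip_threshold(
    genome: ContigSet | Contig | np.ndarray,
    window: int = RIP_WINDOW,
    fallback: float = 35.0,
    min_windows: int = 1000,
    prominence_frac: float = 0.05,
) -> ThresholdResult:
    """Estimate the GC threshold separating ripped from unripped windows.

    A Gaussian kernel density estimate of the window GC values is scanned for
    its two highest modes; the threshold is the density minimum between them.
    If the distribution is effectively unimodal (no interior minimum with
    prominence >= ``prominence_frac`` of the maximum density) or fewer than
    ``min_windows`` windows are available, the conventional fallback (35%)
    is returned with a flag.
    """
    if isinstance(genome, (ContigSet, Contig)):
        vals = np.concatenate([v for _, v in _genome_windows(genome, window)] or [np.empty(0)])
    else:
        vals = np.asarray(genome, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < min_windows:
        return ThresholdResult(fallback, fallback_used=True)
    kde = gaussian_kde(vals)
    grid = np.arange(0.0, 100.01, 0.1)
    dens = kde(grid)
    peaks, _ = find_peaks(dens)
    if len(peaks) < 2:
        return ThresholdResult(fallback, fallback_used=True)
    top2 = sorted(sorted(peaks, key=lambda p: -dens[p])[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    prominence = min(dens[lo], dens[hi]) - dens[valley]
    if prominence < prominence_frac * dens.max():
        return ThresholdResult(fallback, fallback_used=True)
    return ThresholdResult(float(grid[valley]), fallback_used=False)


def classify_windows(
    genome: ContigSet | Contig, threshold: float, window: int = RIP_WINDOW
) -> RipClassification:
    """Label non-overlapping windows ripped (GC < threshold) or unripped.

    Windows with >50% N are masked; the reported fractions are taken over
    labeled (non-masked) windows only.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0,100]")
    labels = {}
    n_rip = n_lab = 0
    for cid, vals in _genome_windows(genome, window):
        lab = np.where(np.isnan(vals), "masked", np.where(vals < threshold, "ripped", "unripped"))
        labels[cid] = lab
        n_rip += int(np.sum(lab == "ripped"))
        n_lab += int(np.sum(lab != "masked"))
    fr = n_rip / n_lab if n_lab else float("nan")
    return RipClassification(window, threshold, labels, fr, 1.0 - fr if n_lab else float("nan"))


def _oriented(values, strand):
    return values[::-1] if strand == "-" else values


def flank_gc(
    features: list[FeatureRecord], genome: ContigSet, flank: int = 1000
) -> list[FlankGcRecord]:
    """GC% of the 1 kb 5'/3' flanks and the body of each feature.

    Strand-aware: for a '-' feature the 5' flank is genomic-right.  Flanks
    truncated by a contig edge are reported missing (None).
    """
    out = []
    for f in features:
        seq = genome[f.contig_id].seq
        left = seq[f.start - flank : f.start] if f.start >= flank else None
        right = seq[f.end : f.end + flank] if f.end + flank <= len(seq) else None
        body = gc_percent(seq[f.start : f.end])
        if f.strand == "-":
            five, three = right, left
        else:
            five, three = left, right
        out.append(
            FlankGcRecord(
                f.feature_id,
                gc_percent(five) if five else None,
                gc_percent(three) if three else None,
                body,
            )
        )
    return out


def metaprofile(
    features: list[FeatureRecord],
    genome: ContigSet,
    flank: int = 10_000,
    window: int = 200,
    body_bins: int = 50,
) -> MetaProfile:
    """Average GC profile across features: fixed-window flanks, length-
    normalized body.

    Each row covers the 5' flank in ``flank/window`` windows, the body
    resampled into ``body_bins`` equal-length bins, then the 3' flank;
    rows of '-' strand features are orientation-flipped.  Cells falling
    outside the contig are missing (NaN); column means ignore them.
    """
    if not features:
        raise ValueError("no features")
    nf = flank // window
    rows = []
    for f in features:
        seq = genome[f.contig_id].seq
        L = len(seq)
        up = np.full(nf, np.nan)
        down = np.full(nf, np.nan)
        for i in range(nf):
            s = f.start - flank + i * window
            if s >= 0:
                up[i] = gc_percent(seq[s : s + window])
            s = f.end + i * window
            if s + window <= L:
                down[i] = gc_percent(seq[s : s + window])
        body = np.full(body_bins, np.nan)
        edges = np.linspace(f.start, f.end, body_bins + 1).round().astype(int)
        for i in range(body_bins):
            if edges[i + 1] > edges[i]:
                body[i] = gc_percent(seq[edges[i] : edges[i + 1]])
        row = np.concatenate([up, body, down])
        if f.strand == "-":
            row = row[::-1]
        rows.append(row)
    return MetaProfile(np.vstack(rows), nf, body_bins)


def rip_blocks(
    classification: RipClassification,
    min_block: int = 50_000,
    merge_gap: int = 2,
) -> list[RipBlock]:
    """Maximal ripped-window runs (allowing <= merge_gap unripped windows
    inside) of length >= min_block; per contig the largest block is flagged
    as the centromere call."""
    w = classification.window
    blocks: list[RipBlock] = []
    for cid, lab in classification.labels.items():
        ripped_idx = np.where(lab == "ripped")[0]
        if len(ripped_idx) == 0:
            continue
        runs = []
        start = prev = ripped_idx[0]
        for i in ripped_idx[1:]:
            if i - prev - 1 <= merge_gap:
                prev = i
            else:
                runs.append((start, prev))
                start = prev = i
        runs.append((start, prev))
        cand = [
            RipBlock(cid, int(s * w), int((e + 1) * w))
            for s, e in runs
            if (e + 1 - s) * w >= min_block
        ]
        if cand:
            largest = max(cand, key=lambda b: b.length)
            largest.centromere_call = True
        blocks.extend(cand)
    return blocks


def te_family_gc_ranking(
    te_features: list[FeatureRecord], genome: ContigSet
) -> dict[str, list[float]]:
    """Per TE family, the GC% of each copy's body, sorted descending.

    Families are returned in decreasing copy-number order.  In a strongly
    RIP-active genome, retrotransposon families show only a few high-GC
    (unripped) copies followed by a sharp drop; families that escape RIP
    show the inverse shape.
    """
    fams: dict[str, list[float]] = {}
    for f in te_features:
        if f.family is None:
            continue
        gc = gc_percent(genome[f.contig_id].seq[f.start : f.end])
        fams.setdefault(f.family, []).append(gc)
    ranked = {fam: sorted(v, reverse=True) for fam, v in fams.items()}
    return dict(sorted(ranked.items(), key=lambda kv: (-len(kv[1]), kv[0])))


@dataclass
class RetroCentromeres:
    loci: dict = field(default_factory=dict)  # contig_id -> [(s,e), ...]
    flagged: set = field(default_factory=set)  # contigs where locus count != 1


def retro_density_centromeres(
    te_features: list[FeatureRecord],
    chromosomes: ContigSet,
    window: int = 50_000,
    min_density: float = 0.5,
) -> RetroCentromeres:
    """Call retrotransposon-cluster centromeres from copy density.

    Non-overlapping windows whose retrotransposon coverage fraction is
    >= ``min_density`` are merged into loci; chromosomes with a locus count
    other than exactly one are flagged.
    """
    out = RetroCentromeres()
    by_contig: dict[str, list] = {c.id: [] for c in chromosomes}
    for f in te_features:
        if f.kind == "retrotransposon" and f.contig_id in by_contig:
            by_contig[f.contig_id].append((f.start, f.end))
    for c in chromosomes:
        ivs = sorted(by_contig[c.id])
        # merge overlapping feature intervals
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        n_win = c.length // window
        qualifying = []
        for i in range(n_win):
            ws, we = i * window, (i + 1) * window
            cov = sum(min(e, we) - max(s, ws) for s, e in merged if s < we and e > ws)
            if cov / window >= min_density:
                qualifying.append(i)
        loci = []
        for i in qualifying:
            if loci and i * window <= loci[-1][1]:
                loci[-1][1] = (i + 1) * window
            else:
                loci.append([i * window, (i + 1) * window])
        out.loci[c.id] = [tuple(l) for l in loci]
        if len(loci) != 1:
            out.flagged.add(c.id)
    return out
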