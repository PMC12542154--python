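"""Detection and splitting of chimeric contigs.

A chimeric contig fuses segments from different organisms (typically fungus
and bacterium).  Candidates are found as abrupt GC shifts between flanking
window blocks along a 200 bp GC profile, then refined to base precision when
the junction carries a telomeric repeat (multimers of CCCTAA) or a long
poly-C/G stretch, mirroring how such junctions present in real assemblies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .model import Contig, ContigSet, WindowTrack
from .seqstats import gc_profile

logger = logging.getLogger("holosplit")

TELOMERE_RE = re.compile(r"(?:CCCTAA){3,}|(?:TTAGGG){3,}")
POLYCG_RE = re.compile(r"C{20,}|G{20,}")


@dataclass
class Breakpoint:
    """A proposed split position (split occurs before ``pos``)."""

    contig_id: str
    pos: int
    evidence: str  # gc_shift | telomere_motif | polyCG | manual
    left_gc: float
    right_gc: float

    @property
    def gc_delta(self) -> float:
        return abs(self.left_gc - self.right_gc)


def detect_breakpoints(
    track: WindowTrack, delta: float = 20.0, flank_blocks: int = 5
) -> list[Breakpoint]:
    """Report window boundaries where flanking block-mean GC differs by >= delta.

    For each interior window boundary the mean GC of ``flank_blocks`` windows
    on either side is compared (masked windows excluded from the means); runs
    of qualifying boundaries are merged to the boundary of maximal difference.
    """
    n = len(track)
    if n == 0:
        return []
    vals = track.values
    diffs = np.full(n + 1, np.nan)
    lefts = np.full(n + 1, np.nan)
    rights = np.full(n + 1, np.nan)
    for b in range(flank_blocks, n - flank_blocks + 1):
        lv = vals[b - flank_blocks : b]
        rv = vals[b : b + flank_blocks]
        lv = lv[~np.isnan(lv)]
        rv = rv[~np.isnan(rv)]
        if len(lv) == 0 or len(rv) == 0:
            continue
        lefts[b], rights[b] = lv.mean(), rv.mean()
        diffs[b] = abs(lefts[b] - rights[b])
    qualifying = np.where(diffs >= delta)[0]
    out: list[Breakpoint] = []
    if len(qualifying) == 0:
        return out
    # merge consecutive qualifying boundaries, keep the max-difference one
    run_start = 0
    for i in range(1, len(qualifying) + 1):
        if i == len(qualifying) or qualifying[i] != qualifying[i - 1] + 1:
            run = qualifying[run_start:i]
            best = run[int(np.argmax(diffs[run]))]
            out.append(
                Breakpoint(
                    contig_id=track.contig_id,
                    pos=track.start + int(best) * track.step,
                    evidence="gc_shift",
                    left_gc=float(lefts[best]),
                    right_gc=float(rights[best]),
                )
            )
            run_start = i
    return out


def refine_breakpoint(
    contig: Contig, bp: Breakpoint, search_radius: int = 2000
) -> Breakpoint:
    """Snap a GC-shift breakpoint to a junction motif when one is nearby.

    Telomeric repeats (>=3 tandem CCCTAA on either strand) take precedence:
    the telomere belongs to the eukaryotic (lower-GC) side, so the position
    snaps to the motif's outer edge facing the higher-GC flank (the last
    motif base +1 when the foreign segment lies to the right).  Otherwise a
    poly-C/G run of >=20 bp snaps the position to the run midpoint.  With no
    motif within the search radius the breakpoint is returned unchanged.
    """
    lo = max(0, bp.pos - search_radius)
    hi = min(contig.length, bp.pos + search_radius)
    region = contig.seq[lo:hi]

    telo = [(m.start() + lo, m.end() + lo) for m in TELOMERE_RE.finditer(region)]
    if telo:
        s, e = min(telo, key=lambda iv: min(abs(iv[0] - bp.pos), abs(iv[1] - bp.pos)))
        pos = e if bp.right_gc >= bp.left_gc else s
        if 0 < pos < contig.length:
            return Breakpoint(bp.contig_id, pos, "telomere_motif", bp.left_gc, bp.right_gc)
    poly = [(m.start() + lo, m.end() + lo) for m in POLYCG_RE.finditer(region)]
    if poly:
        s, e = min(poly, key=lambda iv: abs((iv[0] + iv[1]) // 2 - bp.pos))
        pos = (s + e) // 2
        if 0 < pos < contig.length:
            return Breakpoint(bp.contig_id, pos, "polyCG", bp.left_gc, bp.right_gc)
    return bp


def scan_contig(
    contig: Contig,
    window: int = 200,
    step: int = 200,
    delta: float = 20.0,
    flank_blocks: int = 5,
    refine: bool = True,
    interkingdom_gc: float | None = 50.0,
    interkingdom_margin: float = 4.0,
) -> list[Breakpoint]:
    """GC-profile a contig, detect and (optionally) refine breakpoints.

    ``interkingdom_gc`` (e.g. 50.0) keeps only breakpoints whose flanks
    straddle that GC level by at least ``interkingdom_margin`` on each side,
    i.e. shifts compatible with a fusion between a low-GC eukaryotic and a
    high-GC bacterial segment; composition shifts within one genome (genic
    vs RIP-degraded fungal sequence, both below 50%) are then not treated as
    mis-assemblies.  The margin absorbs sampling noise of the flank means.
    """
    track = gc_profile(contig, window=window, step=step)
    bps = detect_breakpoints(track, delta=delta, flank_blocks=flank_blocks)
    if interkingdom_gc is not None:
        bps = [
            b
            for b in bps
            if min(b.left_gc, b.right_gc) < interkingdom_gc - interkingdom_margin
            and max(b.left_gc, b.right_gc) > interkingdom_gc + interkingdom_margin
        ]
    if refine:
        bps = [refine_breakpoint(contig, b) for b in bps]
    return bps


def split_contigs(contigs: ContigSet, breakpoints: list[Breakpoint]) -> ContigSet:
    """Split contigs at breakpoints; parts are named id.p1 ... id.p(k+1).

    Total sequence length is conserved; duplicate positions are deduplicated
    with a warning; contigs without breakpoints pass through unchanged.
    """
    by_contig: dict[str, list[int]] = {}
    for bp in breakpoints:
        by_contig.setdefault(bp.contig_id, []).append(bp.pos)
    out = ContigSet()
    for c in contigs:
        positions = sorted(set(by_contig.get(c.id, [])))
        if len(positions) < len(by_contig.get(c.id, [])):
            logger.warning("contig %s: duplicate breakpoint positions deduplicated", c.id)
        positions = [p for p in positions if 0 < p < c.length]
        if not positions:
            out.add(c)
            continue
        bounds = [0] + positions + [c.length]
        for i in range(len(bounds) - 1):
            part = Contig(
                id=f"{c.id}.p{i + 1}",
                seq=c.seq[bounds[i] : bounds[i + 1]],
                tags=set(c.tags) | {f"split_from:{c.id}"},
            )
            out.add(part)
    assert out.total_length() == contigs.total_length()
    return out
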