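"""Screen for horizontal gene transfer (HGT) candidates.

A gene annotated on a eukaryotic (fungal or algal) chromosome whose mapped
reads were taxonomically classified as bacterial is a candidate horizontal
transfer from bacteria.  The screen counts bacteria-classified reads per
gene, supports candidates whose protein identity to bacterial homologs far
exceeds that to eukaryotic ones, and checks read-coverage continuity around
the locus to exclude a local mis-assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Contig, FeatureRecord, ReadRecord, ReadTaxon

logger = logging.getLogger("holosplit")


@dataclass
class HgtCandidate:
    gene_id: str
    contig_id: str
    n_bact_reads: int
    mean_bact_identity: float | None = None
    mean_euk_identity: float | None = None
    coverage_uniform: bool | None = None

    @property
    def identity_margin(self) -> float | None:
        if self.mean_bact_identity is None or self.mean_euk_identity is None:
            return None
        return self.mean_bact_identity - self.mean_euk_identity


def bacterial_read_counts(
    genes: list[FeatureRecord],
    read_map: list[ReadRecord],
    read_taxa: list[ReadTaxon],
    min_mapq: int = 0,
) -> dict[str, int]:
    """Distinct bacteria-classified reads overlapping each gene (>= 1 bp)."""
    taxon = {t.read_id: t.taxon_group for t in read_taxa}
    by_contig: dict[str, list[ReadRecord]] = {}
    known = {g.contig_id for g in genes}
    for r in read_map:
        if r.contig_id not in known:
            logger.warning("read %s mapped to contig %s without genes; skipped",
                           r.read_id, r.contig_id)
            continue
        if r.mapq < min_mapq:
            continue
        if taxon.get(r.read_id) == "bacteria":
            by_contig.setdefault(r.contig_id, []).append(r)
    counts = {}
    for g in genes:
        reads = by_contig.get(g.contig_id, ())
        counts[g.feature_id] = len(
            {r.read_id for r in reads if r.start < g.end and g.start < r.end}
        )
    return counts


def call_candidates(
    counts: dict[str, int],
    genes: list[FeatureRecord],
    min_reads: int = 2,
) -> list[HgtCandidate]:
    """Genes covered by >= ``min_reads`` bacteria-classified reads,
    sorted by count descending."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    contig_of = {g.feature_id: g.contig_id for g in genes}
    cands = [
        HgtCandidate(gid, contig_of.get(gid, ""), n)
        for gid, n in counts.items()
        if n >= min_reads
    ]
    cands.sort(key=lambda c: (-c.n_bact_reads, c.gene_id))
    return cands


def identity_contrast(
    bact_identities,
    euk_identities,
    margin: float = 20.0,
):
    """Mean homolog identities and whether the bacterial excess supports HGT.

    Returns (mean_bact, mean_euk, margin_pp, supported); ``supported`` is
    None (indeterminate) when either list is empty.
    """
    for v in list(bact_identities) + list(euk_identities):
        if not 0 <= v <= 100:
            raise ValueError("identity outside [0,100]")
    mb = float(np.mean(bact_identities)) if len(bact_identities) else None
    me = float(np.mean(euk_identities)) if len(euk_identities) else None
    if mb is None or me is None:
        return mb, me, None, None
    return mb, me, mb - me, bool(mb - me >= margin)


def coverage_continuity(
    contig: Contig,
    read_map: list[ReadRecord],
    gene: FeatureRecord,
    flank: int = 5000,
    window: int = 500,
    min_frac: float = 0.5,
) -> bool:
    """True when read depth around the gene shows no coverage break.

    Depth = reads (any taxon) overlapping each non-overlapping window; the
    locus is uniform iff every window over gene +- flank has depth >=
    ``min_frac`` x the contig-wide median window depth.  A mis-assembled
    insertion would show a coverage gap at its boundary.
    """
    L = contig.length
    n_win = max(L // window, 1)
    depth = np.zeros(n_win)
    for r in read_map:
        if r.contig_id != contig.id:
            continue
        w0 = max(r.start // window, 0)
        w1 = min((r.end - 1) // window, n_win - 1)
        depth[w0 : w1 + 1] += 1
    median = float(np.median(depth))
    lo = max(gene.start - flank, 0) // window
    hi = min((min(gene.end + flank, L) - 1) // window, n_win - 1)
    return bool(np.all(depth[lo : hi + 1] >= min_frac * median))
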