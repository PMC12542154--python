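"""Kingdom assignment of contigs: fungus, alga or bacteria.

Contigs >= 10 kb are classified from tetranucleotide (tetramer) frequency
profiles: PCA of the 256-dimensional profiles followed by k-means with k=3
(the three organism groups a lichen holobiont contributes), with cluster ->
kingdom labels decided by independent evidence votes (RIP signatures mark
the fungal cluster, eukaryotic TE/rDNA evidence marks the algal one).
Contigs < 10 kb carry too little tetramer signal and are assigned by
homology to reference contig sets, or by a fungal RIP signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .chimera import detect_breakpoints
from .homology import SeedIndex
from .model import Contig, ContigSet
from .seqstats import encode, gc_percent, gc_profile

MIN_TETRAMER_LEN = 10_000


@dataclass
class TetramerProfile:
    contig_id: str
    freqs: np.ndarray  # 256 frequencies, lexicographic AAAA..TTTT
    n_windows_counted: int


@dataclass
class KingdomCall:
    contig_id: str
    kingdom: str  # fungus | alga | bacteria | organelle | unassigned
    route: str  # tetramer_pca | te_homology | rip_signature | rdna | manual
    score: float | None = None


def tetramer_freqs(contig: Contig | str) -> TetramerProfile:
    """Frequencies of all 256 tetramers, sliding step 1 on the forward strand.

    Windows containing N are skipped; counts are normalized to frequencies.
    No reverse-complement collapsing: all 256 words are distinct features.
    """
    seq = contig.seq if isinstance(contig, Contig) else contig
    cid = contig.id if isinstance(contig, Contig) else ""
    codes = encode(seq)
    freqs = np.zeros(256)
    if len(codes) < 4:
        return TetramerProfile(cid, freqs, 0)
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
    idx = (c0.astype(np.int32) * 64 + c1 * 16 + c2 * 4 + c3)[valid]
    counts = np.bincount(idx, minlength=256).astype(float)
    n = int(counts.sum())
    if n > 0:
        freqs = counts / n
    return TetramerProfile(cid, freqs, n)


def pca_embed(profiles: list[TetramerProfile], n_components: int = 3):
    """Mean-centered PCA of tetramer profiles.

    Components are ordered by decreasing explained variance and sign-fixed so
    each component's largest-magnitude loading is positive, making the
    embedding deterministic.  Returns (embedding, explained_variance_ratio,
    contig_ids); rows follow the (sorted) contig id order.
    """
    if len(profiles) < n_components:
        raise ValueError(f"need >= {n_components} profiles, got {len(profiles)}")
    profiles = sorted(profiles, key=lambda p: p.contig_id)
    X = np.vstack([p.freqs for p in profiles])
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            emb[:, j] = -emb[:, j]
    return emb, pca.explained_variance_ratio_, [p.contig_id for p in profiles]


def cluster_and_label(
    embedding: np.ndarray,
    contig_ids: list[str],
    evidence: dict,
    random_state: int = 0,
) -> list[KingdomCall]:
    """k-means (k=3) on the embedding; clusters named by evidence votes.

    ``evidence`` maps contig_id -> dict with optional boolean keys
    ``has_ripped_windows``, ``has_euk_te_hit``, ``has_bact_te_hit`` and
    ``rdna_kind`` (e.g. '16S').  The cluster with the largest fraction of
    RIP-marked contigs is the fungus; among the rest the cluster with the
    most eukaryotic TE / eukaryotic rDNA evidence is the alga; the remaining
    cluster is bacteria.  With no evidence at all, calls are still made (by
    descending GC-independent cluster order) but routed "manual".
    """
    order = np.argsort(contig_ids)
    ids_sorted = [contig_ids[i] for i in order]
    emb = np.asarray(embedding)[order]
    km = KMeans(n_clusters=3, n_init=10, random_state=random_state)
    labels = km.fit_predict(emb)

    def frac(lab, key):
        members = [ids_sorted[i] for i in range(len(ids_sorted)) if labels[i] == lab]
        if not members:
            return 0.0
        return sum(bool(evidence.get(c, {}).get(key)) for c in members) / len(members)

    def frac_euk(lab):
        members = [ids_sorted[i] for i in range(len(ids_sorted)) if labels[i] == lab]
        if not members:
            return 0.0
        hit = 0
        for c in members:
            ev = evidence.get(c, {})
            if ev.get("has_euk_te_hit") or ev.get("rdna_kind") in {"ITS", "its"}:
                hit += 1
        return hit / len(members)

    any_evidence = any(
        v.get("has_ripped_windows") or v.get("has_euk_te_hit") or v.get("has_bact_te_hit")
        or v.get("rdna_kind")
        for v in evidence.values()
    )
    def gc_iqr(lab):
        gcs = [
            evidence.get(ids_sorted[i], {}).get("gc")
            for i in range(len(ids_sorted))
            if labels[i] == lab
        ]
        gcs = [g for g in gcs if g is not None]
        if len(gcs) < 2:
            return 0.0
        q75, q25 = np.percentile(gcs, [75, 25])
        return float(q75 - q25)

    clusters = [0, 1, 2]
    rip_fracs = {lab: frac(lab, "has_ripped_windows") for lab in clusters}
    # ties on the RIP vote break toward the widest GC spread (fungal hallmark)
    fungus = max(clusters, key=lambda l: (rip_fracs[l], gc_iqr(l), -l))
    rest = [l for l in clusters if l != fungus]
    alga = max(rest, key=lambda l: (frac_euk(l), -l))
    bacteria = next(l for l in rest if l != alga)
    name = {fungus: "fungus", alga: "alga", bacteria: "bacteria"}

    route = "tetramer_pca" if any_evidence else "manual"
    calls = []
    for i, cid in enumerate(ids_sorted):
        d = float(np.linalg.norm(emb[i] - km.cluster_centers_[labels[i]]))
        calls.append(KingdomCall(cid, name[labels[i]], route, score=-d))
    return calls


def assign_short_by_homology(
    short_contigs,
    fungal_ref: ContigSet | SeedIndex,
    algal_ref: ContigSet | SeedIndex,
    min_hit: int = 300,
    min_identity: float = 85.0,
    ambiguity_margin: float = 0.10,
) -> list[KingdomCall]:
    """Assign sub-10 kb contigs by homology against reference contig sets.

    A qualifying hit is a chained seed-and-extend block span > ``min_hit``
    bp at >= ``min_identity``% identity; the contig goes to the reference
    with the longest qualifying hit.  Hits to both references with spans
    within ``ambiguity_margin`` of each other are ambiguous -> unassigned.
    """
    fidx = fungal_ref if isinstance(fungal_ref, SeedIndex) else SeedIndex(fungal_ref)
    aidx = algal_ref if isinstance(algal_ref, SeedIndex) else SeedIndex(algal_ref)
    calls = []
    for c in short_contigs:
        fhit = fidx.best_hit(c.seq, min_span=min_hit + 1, min_identity=min_identity)
        ahit = aidx.best_hit(c.seq, min_span=min_hit + 1, min_identity=min_identity)
        fspan = fhit.span if fhit else 0
        aspan = ahit.span if ahit else 0
        if fspan == 0 and aspan == 0:
            calls.append(KingdomCall(c.id, "unassigned", "te_homology", None))
        elif min(fspan, aspan) > 0 and abs(fspan - aspan) <= ambiguity_margin * max(fspan, aspan):
            calls.append(KingdomCall(c.id, "unassigned", "te_homology", None))
        elif fspan > aspan:
            calls.append(KingdomCall(c.id, "fungus", "te_homology", float(fspan)))
        else:
            calls.append(KingdomCall(c.id, "alga", "te_homology", float(aspan)))
    return calls


def assign_short_by_rip(
    contig: Contig,
    overall_gc_max: float = 30.0,
    internal_shift: float = 20.0,
    window: int = 200,
) -> bool:
    """Fungal RIP signature on a short contig: overall GC below
    ``overall_gc_max``%, or an internal block-mean GC shift >=
    ``internal_shift`` percentage points."""
    gc = gc_percent(contig.seq)
    if not np.isnan(gc) and gc < overall_gc_max:
        return True
    track = gc_profile(contig, window=window, step=window)
    return bool(detect_breakpoints(track, delta=internal_shift))
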