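"""Reconstruction of bacterial genome bins by consensus over approaches.

Contigs of one bacterial species rise and fall together in abundance across
samples, so their per-sample mean coverage profiles correlate.  Two
hierarchical clusterings of coverage-correlation matrices (built from
mapping-quality-0 and -60 coverage tables), plus a composition+coverage
Gaussian-mixture binner (or externally supplied binner outputs), are
consolidated: a pair of contigs belongs to the same consensus genome when
at least two approaches co-bin it, and rDNA-carrying contigs must satisfy a
stricter three-approach majority rule before being kept in a bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .model import ContigSet, CoverageTable


@dataclass
class BinAssignment:
    approach_id: str
    mapping: dict  # contig_id -> bin label (absent = unbinned)

    def bin_of(self, cid):
        return self.mapping.get(cid)


@dataclass
class ConsensusBins:
    bins: dict  # bin_id -> sorted list of contig ids
    unassigned: list
    support: dict = field(default_factory=dict)  # (cid_a, cid_b) sorted pair -> count

    def mapping(self) -> dict:
        return {c: b for b, cs in self.bins.items() for c in cs}


@dataclass
class CorrelationMatrix:
    contig_ids: list
    r: np.ndarray
    zero_variance: list = field(default_factory=list)


def correlation_matrix(
    coverage: CoverageTable, transform: bool = True
) -> CorrelationMatrix:
    """Contig x contig Pearson correlation of across-sample coverage profiles.

    With ``transform``, depths are first normalized per sample (relative
    abundance) and then log10(x+1)-stabilized.  Contigs with zero variance
    across samples are flagged and given correlation 0 to all others.
    """
    if len(coverage.sample_ids) < 3:
        raise ValueError("need >= 3 samples for correlation binning")
    X = coverage.depth.astype(float)
    if transform:
        colsum = X.sum(axis=0)
        colsum[colsum == 0] = 1.0
        X = np.log10(X / colsum + 1.0)
    sd = X.std(axis=1)
    zero_var = [coverage.contig_ids[i] for i in np.where(sd == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(coverage.contig_ids), r, zero_var)


def hierarchical_bins(
    corr: CorrelationMatrix,
    cut_height: float = 0.25,
    method: str = "average",
    approach_id: str = "corr",
) -> BinAssignment:
    """Average-linkage clustering on distance 1-r, cut at ``cut_height``.

    Singleton clusters are left unbinned.  Input order does not matter:
    contigs are sorted by id before clustering, and bin labels are numbered
    by each bin's lexicographically first member.
    """
    order = np.argsort(corr.contig_ids)
    ids = [corr.contig_ids[i] for i in order]
    r = corr.r[np.ix_(order, order)]
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method=method)
    flat = fcluster(Z, t=cut_height, criterion="distance")
    groups: dict[int, list] = {}
    for cid, g in zip(ids, flat):
        groups.setdefault(g, []).append(cid)
    mapping = {}
    multi = sorted((sorted(v) for v in groups.values() if len(v) >= 2), key=lambda g: g[0])
    for k, members in enumerate(multi, start=1):
        for cid in members:
            mapping[cid] = f"{approach_id}_bin{k:02d}"
    return BinAssignment(approach_id, mapping)


def composition_coverage_bins(
    profiles,
    coverage: CoverageTable,
    k_range=range(1, 11),
    approach_id: str = "composition",
    random_state: int = 0,
    min_occupancy: int = 3,
) -> BinAssignment:
    """Gaussian-mixture binning over [3 tetramer PCs, per-sample log depth].

    Features are standardized; the number of components is selected by the
    Bayesian information criterion over ``k_range`` with a shared (tied)
    covariance, considering only solutions whose smallest component holds
    >= ``min_occupancy`` contigs -- with a few dozen contigs in ~15
    dimensions, unconstrained BIC rewards carving noise into sub-clusters.
    The seed is fixed so results are reproducible.
    """
    from .kingdom import pca_embed

    k_range = [k for k in k_range]
    if not k_range:
        raise ValueError("empty k range")
    emb, _, ids = pca_embed(sorted(profiles, key=lambda p: p.contig_id), 3)
    cov = coverage.subset(ids)
    logdepth = np.log10(cov.depth + 1.0)
    X = np.hstack([emb, logdepth])
    X = StandardScaler().fit_transform(X)
    best = fallback = None
    for k in k_range:
        if k > len(ids):
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="tied",
            reg_covar=1e-2,
            n_init=3,
            random_state=random_state,
        ).fit(X)
        bic = gm.bic(X)
        labels = gm.predict(X)
        occupancy = np.bincount(labels, minlength=k).min()
        if fallback is None or bic < fallback[0]:
            fallback = (bic, labels)
        if occupancy >= min(min_occupancy, len(ids)):
            if best is None or bic < best[0]:
                best = (bic, labels)
    _, labels = best if best is not None else fallback
    mapping = {cid: f"{approach_id}_bin{lab + 1:02d}" for cid, lab in zip(ids, labels)}
    return BinAssignment(approach_id, mapping)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def consensus_bins(
    assignments: list[BinAssignment],
    min_support: int = 2,
    rdna_contigs=frozenset(),
    rdna_min_support: int = 3,
) -> ConsensusBins:
    """Consensus genomes: connected components of the pair-support graph.

    Two contigs are linked when >= ``min_support`` approaches co-bin them;
    consensus bins are components of size >= 2.  An rDNA-carrying contig is
    retained only if >= ``rdna_min_support`` approaches each place it in a
    bin containing the majority (>50%) of its component's other members;
    otherwise it is moved to unassigned (rDNA anchors the bin's taxonomy, so
    the stricter rule protects against mis-attached marker contigs).
    """
    if len(assignments) < 2:
        raise ValueError("need >= 2 bin assignments")
    if min_support > len(assignments):
        raise ValueError("min_support exceeds number of assignments")
    contigs = sorted({c for a in assignments for c in a.mapping})
    support: dict[tuple, int] = {}
    for a in assignments:
        bins: dict[str, list] = {}
        for cid, b in a.mapping.items():
            bins.setdefault(b, []).append(cid)
        for members in bins.values():
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pair = (members[i], members[j])
                    support[pair] = support.get(pair, 0) + 1

    def components(nodes, edge_ok):
        uf = _UnionFind(nodes)
        for (a, b), s in support.items():
            if s >= min_support and a in uf.parent and b in uf.parent and edge_ok(a, b):
                uf.union(a, b)
        comp: dict[str, list] = {}
        for c in nodes:
            comp.setdefault(uf.find(c), []).append(c)
        return [sorted(v) for v in comp.values()]

    comps = components(contigs, lambda a, b: True)
    rdna_contigs = set(rdna_contigs)
    kept_nodes = set(contigs)
    for comp in comps:
        if len(comp) < 2:
            continue
        for cid in comp:
            if cid not in rdna_contigs:
                continue
            others = [c for c in comp if c != cid]
            n_major = 0
            for a in assignments:
                b = a.bin_of(cid)
                if b is None:
                    continue
                together = sum(1 for o in others if a.bin_of(o) == b)
                if together > 0.5 * len(others):
                    n_major += 1
            if n_major < rdna_min_support:
                kept_nodes.discard(cid)

    comps = components(sorted(kept_nodes), lambda a, b: True)
    bins = {}
    unassigned = sorted(set(contigs) - kept_nodes)
    final = sorted((c for c in comps if len(c) >= 2), key=lambda c: c[0])
    for k, comp in enumerate(final, start=1):
        bins[f"bin{k:02d}"] = comp
    for comp in comps:
        if len(comp) < 2:
            unassigned.extend(comp)
    return ConsensusBins(bins, sorted(unassigned), support)


def bin_stats(
    consensus: ConsensusBins, contigs: ContigSet, coverage: CoverageTable
) -> pd.DataFrame:
    """Per-bin summary: contig count, total bp, GC%, mean depth per sample."""
    rows = []
    for bin_id, members in consensus.bins.items():
        total = sum(contigs[c].length for c in members)
        gc = np.average(
            [contigs[c].gc_percent() for c in members],
            weights=[contigs[c].length for c in members],
        )
        sub = coverage.subset([c for c in members if c in coverage.contig_ids])
        mean_depth = sub.depth.mean(axis=0) if len(sub.contig_ids) else np.full(
            len(coverage.sample_ids), np.nan
        )
        row = {"bin": bin_id, "n_contigs": len(members), "total_bp": total, "gc": gc}
        row.update({f"depth_{s}": d for s, d in zip(coverage.sample_ids, mean_depth)})
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("total_bp", ascending=False).reset_index(drop=True)
    return df
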