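"""Lightweight seed-and-extend homology search.

Exact 21-mer seeds are indexed over a reference set; query matches on the
same (reference, diagonal) are chained into blocks, extended ungapped, and
scored by percent identity over the chained span.  This is sufficient for
the contig-assignment and rDNA-location tasks here, where homologs differ by
substitutions far more than by indels; it is not a general gapped aligner.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .model import Contig, ContigSet

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _xdrop_extend(qseq: str, ref: str, qs: int, qe: int, diag: int,
                  xdrop: int = 20, mismatch: int = -2) -> tuple[int, int]:
    """Ungapped X-drop extension of a seed chain along its diagonal.

    Extends while the running score (+1 match, ``mismatch`` otherwise) stays
    within ``xdrop`` of its maximum; the extension ends at the score maximum.
    Needed because exact seeds fragment at moderate divergence (at ~86%
    identity many 21-mers are interrupted), while the homologous span is
    still contiguous.
    """
    # rightward
    best = cur = 0
    best_i = i = qe
    while i < len(qseq) and 0 <= i + diag < len(ref):
        cur += 1 if qseq[i] == ref[i + diag] and qseq[i] != "N" else mismatch
        i += 1
        if cur > best:
            best, best_i = cur, i
        elif best - cur > xdrop:
            break
    qe = best_i
    # leftward
    best = cur = 0
    best_i = i = qs
    while i > 0 and 0 < i + diag <= len(ref):
        i -= 1
        cur += 1 if qseq[i] == ref[i + diag] and qseq[i] != "N" else mismatch
        if cur > best:
            best, best_i = cur, i
        elif best - cur > xdrop:
            break
    return best_i, qe


@dataclass
class Hit:
    ref_id: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float  # percent over the chained span

    @property
    def span(self) -> int:
        return self.query_end - self.query_start


class SeedIndex:
    """Exact k-mer index over a set of reference sequences (both strands)."""

    def __init__(self, refs: ContigSet, k: int = 21):
        self.k = k
        self.refs = {c.id: c.seq for c in refs}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rid, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index[kmer].append((rid, i))

    def _seed_matches(self, query: str):
        k = self.k
        for qpos in range(len(query) - k + 1):
            hits = self._index.get(query[qpos : qpos + k])
            if hits:
                for rid, rpos in hits:
                    yield rid, rpos, qpos

    def search(
        self,
        query: str,
        min_span: int = 300,
        min_identity: float = 85.0,
        diag_tolerance: int = 10,
    ) -> list[Hit]:
        """Chained, diagonal-grouped hits of ``query`` against the index.

        Seeds sharing a reference and (within tolerance) a diagonal are
        chained; the chained span is rescored base-by-base.  Hits below
        ``min_span`` or ``min_identity`` are dropped.  Both query strands
        are searched; coordinates are reported on the forward query.
        """
        hits: list[Hit] = []
        n = len(query)
        for strand, qseq in (("+", query), ("-", revcomp(query))):
            groups: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
            for rid, rpos, qpos in self._seed_matches(qseq):
                groups[(rid, rpos - qpos)].append((qpos, rpos))
            merged: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
            for (rid, diag), seeds in groups.items():
                seeds.sort()
                merged[rid].append((diag, seeds[0][0], seeds[-1][0] + self.k))
            for rid, chains in merged.items():
                # merge chains on nearby diagonals with overlapping query spans
                chains.sort(key=lambda t: (t[1], t[0]))
                fused: list[list[int]] = []
                for diag, qs, qe in chains:
                    if fused and abs(fused[-1][0] - diag) <= diag_tolerance and qs <= fused[-1][2]:
                        fused[-1][2] = max(fused[-1][2], qe)
                    else:
                        fused.append([diag, qs, qe])
                ref = self.refs[rid]
                for diag, qs, qe in fused:
                    qs, qe = _xdrop_extend(qseq, ref, qs, qe, diag)
                    rs, re_ = qs + diag, qe + diag
                    if rs < 0 or re_ > len(ref):
                        continue
                    span = qe - qs
                    if span < min_span:
                        continue
                    matches = sum(
                        1 for a, b in zip(qseq[qs:qe], ref[rs:re_]) if a == b and a != "N"
                    )
                    ident = 100.0 * matches / span
                    if ident < min_identity:
                        continue
                    if strand == "+":
                        q0, q1 = qs, qe
                    else:
                        q0, q1 = n - qe, n - qs
                    hits.append(Hit(rid, q0, q1, rs, re_, strand, ident))
        hits.sort(key=lambda h: (-h.span, -h.identity, h.ref_id, h.query_start))
        return hits

    def best_hit(self, query: str, min_span: int = 300, min_identity: float = 85.0):
        hits = self.search(query, min_span=min_span, min_identity=min_identity)
        return hits[0] if hits else None


def best_hit_against(
    query: str, refs: ContigSet | SeedIndex, min_span: int = 300, min_identity: float = 85.0
):
    index = refs if isinstance(refs, SeedIndex) else SeedIndex(refs)
    return index.best_hit(query, min_span=min_span, min_identity=min_identity)
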