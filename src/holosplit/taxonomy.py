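"""rDNA-based taxonomy and lichen-vs-soil family enrichment.

Bacterial taxonomy is assigned from 16S rDNA percent identity to reference
sequences using rank thresholds (>98% same species, >96% same genus, >90%
same family); eukaryotes use ITS identity (>99% same species).  Because
rDNA operons within one bacterial genome are kept near-identical by gene
conversion, within-bin rDNA identity also validates genome bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .homology import SeedIndex
from .model import Contig, ContigSet


@dataclass
class RdnaRecord:
    contig_id: str
    start: int
    end: int
    kind: str  # 16S | ITS
    seq: str


@dataclass
class TaxonomicCall:
    query_id: str
    best_ref_id: str
    identity: float
    rank: str  # species | genus | family | above_family | no_call


def find_rdna(
    contigs: ContigSet,
    seed_refs: ContigSet,
    kind: str = "16S",
    min_identity: float = 80.0,
    min_span_frac: float = 0.70,
) -> list[RdnaRecord]:
    """Locate rDNA loci by homology to reference marker sequences.

    A hit must cover >= ``min_span_frac`` of a reference's length at
    >= ``min_identity``% identity; the matching contig span is extracted.
    """
    if len(seed_refs) == 0:
        raise ValueError("empty reference set")
    index = SeedIndex(seed_refs)
    min_ref_len = min(c.length for c in seed_refs)
    out = []
    for c in contigs:
        hits = index.search(
            c.seq,
            min_span=int(min_span_frac * min_ref_len),
            min_identity=min_identity,
        )
        taken: list[tuple] = []
        for h in hits:
            if h.span < min_span_frac * len(index.refs[h.ref_id]):
                continue
            if any(h.query_start < e and s < h.query_end for s, e in taken):
                continue  # best hit per locus; hits are span-sorted
            taken.append((h.query_start, h.query_end))
            out.append(RdnaRecord(c.id, h.query_start, h.query_end, kind,
                                  c.seq[h.query_start : h.query_end]))
    return out


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -0.5
        # end gaps free: identity is computed over the aligned core
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
        _aligner = a
    return _aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment percent identity between two DNA sequences.

    Columns inside terminal gap runs (overhangs) are excluded from the
    denominator; internal gap columns count as non-matches.  Arguments are
    ordered canonically before aligning so that co-optimal alignment
    tie-breaking cannot make the measure asymmetric.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if (len(b), b) < (len(a), a):
        a, b = b, a
    aln = _get_aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    n = len(s1)
    lo = 0
    while lo < n and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if s1[i] == s2[i] and s1[i] != "-")
    return 100.0 * matches / cols


def rank_from_identity(
    identity: float,
    domain: str = "bacteria_16S",
    species_threshold: float = 98.0,
    genus_threshold: float = 96.0,
    family_threshold: float = 90.0,
    its_species_threshold: float = 99.0,
    strict: bool = True,
) -> str:
    """Taxonomic rank implied by marker identity (strict > by default)."""
    if not 0 <= identity <= 100:
        raise ValueError("identity outside [0,100]")

    def above(t):
        return identity > t if strict else identity >= t

    if domain == "bacteria_16S":
        if above(species_threshold):
            return "species"
        if above(genus_threshold):
            return "genus"
        if above(family_threshold):
            return "family"
        return "above_family"
    if domain == "eukaryote_ITS":
        return "species" if above(its_species_threshold) else "no_call"
    raise ValueError(f"unknown domain {domain!r}")


def classify_rdna(
    queries: ContigSet | list[Contig],
    refs: ContigSet,
    domain: str = "bacteria_16S",
    **rank_kwargs,
) -> list[TaxonomicCall]:
    """Best-reference identity and rank for each query marker sequence."""
    calls = []
    for q in queries:
        best = None
        for r in refs:
            ident = pairwise_identity(q.seq, r.seq)
            if best is None or ident > best[1]:
                best = (r.id, ident)
        rid, ident = best
        calls.append(TaxonomicCall(q.id, rid, ident, rank_from_identity(ident, domain, **rank_kwargs)))
    return calls


@dataclass
class BinRdnaReport:
    per_bin: dict = field(default_factory=dict)  # bin -> dict(min_within, max_between, flagged)
    skipped: list = field(default_factory=list)  # bins with <2 rDNA records
    flagged: list = field(default_factory=list)


def validate_bin_rdna(
    bin_of_contig: dict,
    rdna_records: list[RdnaRecord],
    identity_fn=pairwise_identity,
) -> BinRdnaReport:
    """Check that rDNA copies cluster by genome bin.

    For every bin with >=2 rDNA records the minimum within-bin identity and
    the maximum identity to any other bin's rDNA are reported; a bin where
    the former is below the latter is flagged as inconsistent.
    """
    report = BinRdnaReport()
    recs = [(r, bin_of_contig.get(r.contig_id)) for r in rdna_records]
    recs = [(r, b) for r, b in recs if b is not None]
    bins = sorted({b for _, b in recs})
    by_bin = {b: [r for r, bb in recs if bb == b] for b in bins}
    cache: dict[tuple, float] = {}

    def ident(r1, r2):
        key = (id(r1), id(r2))
        if key not in cache:
            cache[key] = cache[(id(r2), id(r1))] = identity_fn(r1.seq, r2.seq)
        return cache[key]

    for b in bins:
        mine = by_bin[b]
        if len(mine) < 2:
            report.skipped.append(b)
            continue
        min_within = min(
            ident(mine[i], mine[j]) for i in range(len(mine)) for j in range(i + 1, len(mine))
        )
        others = [r for ob in bins if ob != b for r in by_bin[ob]]
        max_between = max((ident(m, o) for m in mine for o in others), default=float("nan"))
        flagged = bool(others) and min_within < max_between
        report.per_bin[b] = {
            "min_within": min_within,
            "max_between": max_between,
            "flagged": flagged,
        }
        if flagged:
            report.flagged.append(b)
    return report


def family_enrichment(
    lichen_counts: dict,
    soil_counts: dict,
    pseudocount: float = 0.5,
) -> dict:
    """Per-family lichen-vs-soil enrichment factor.

    enrichment = ((c_lichen+p)/N_lichen) / ((c_soil+p)/N_soil) with N the
    total classified reads per habitat.  Families absent from soil are
    additionally flagged lichen_exclusive.
    """
    n_lichen = sum(lichen_counts.values())
    n_soil = sum(soil_counts.values())
    if n_lichen == 0 and n_soil == 0:
        raise ValueError("both habitats have zero classified reads")
    if any(v < 0 for v in list(lichen_counts.values()) + list(soil_counts.values())):
        raise ValueError("negative counts")
    out = {}
    for fam in sorted(set(lichen_counts) | set(soil_counts)):
        cl = lichen_counts.get(fam, 0)
        cs = soil_counts.get(fam, 0)
        enr = ((cl + pseudocount) / max(n_lichen, 1)) / ((cs + pseudocount) / max(n_soil, 1))
        out[fam] = {
            "enrichment": enr,
            "lichen_count": cl,
            "soil_count": cs,
            "lichen_exclusive": cl > 0 and cs == 0,
        }
    return out
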