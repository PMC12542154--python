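"""Readers and writers for FASTA, GFF3, BED and the pipeline's TSV tables.

GFF3 coordinates (1-based inclusive) and BED coordinates (0-based half-open)
are both converted to the internal 0-based half-open convention on read and
converted back on write, so the conversion is tested in exactly one place.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import Contig, ContigSet, CoverageTable, FeatureRecord, ReadRecord, ReadTaxon

logger = logging.getLogger("holosplit")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> ContigSet:
    """Read a FASTA file into a ContigSet.

    Lowercase is normalized to uppercase; characters outside {A,C,G,T,N},
    duplicate ids and empty records are hard errors.
    """
    contigs = ContigSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.add(Contig(id=rec.id, seq=str(rec.seq)))
    if len(contigs) == 0:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: ContigSet, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Features (GFF3 / BED)

_GFF_KIND = {  # internal kind -> SO-ish type written in column 3
    "gene": "gene",
    "retrotransposon": "retrotransposon",
    "dna_transposon": "DNA_transposon",
    "te_unclassified": "transposable_element",
    "rdna_16s": "rRNA_16S",
    "rdna_its": "internal_transcribed_spacer",
    "telomere": "telomere",
    "centromere_call": "centromere",
}
_KIND_FROM_GFF = {v: k for k, v in _GFF_KIND.items()}


def read_features(path, dialect: str = "gff3") -> list[FeatureRecord]:
    """Read annotations; ``dialect`` is 'gff3' (1-based inclusive) or 'bed'."""
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    feats: list[FeatureRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "gff3":
                if len(parts) < 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                contig_id, _src, gtype, s, e, _score, strand, _phase, attr = parts[:9]
                start, end = int(s) - 1, int(e)
                attrs = {}
                for kv in attr.split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k.strip()] = v.strip()
                kind = _KIND_FROM_GFF.get(gtype, attrs.get("kind", "te_unclassified"))
                family = attrs.pop("family", None)
            else:
                if len(parts) < 3:
                    raise ValueError(f"malformed BED line: {line!r}")
                contig_id, s, e = parts[:3]
                start, end = int(s), int(e)
                attrs = {"ID": parts[3]} if len(parts) > 3 else {}
                strand = parts[5] if len(parts) > 5 else "."
                kind = "te_unclassified"  # BED carries no typed vocabulary
                family = None
            if end < start:
                raise ValueError(f"feature end < start after conversion: {line!r}")
            feats.append(
                FeatureRecord(contig_id, start, end, strand or ".", kind, family, attrs)
            )
    return feats


def write_features(features, path, dialect: str = "gff3") -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                attrs = dict(f.attrs)
                if f.family:
                    attrs["family"] = f.family
                attr = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
                fh.write(
                    "\t".join(
                        [
                            f.contig_id,
                            "holosplit",
                            _GFF_KIND[f.kind],
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            attr,
                        ]
                    )
                    + "\n"
                )
        elif dialect == "bed":
            for f in features:
                name = f.attrs.get("ID", f.kind)
                fh.write(
                    f"{f.contig_id}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# TSV tables

_SCHEMAS = {
    "coverage": None,  # contig + one column per sample
    "bins": ["contig", "bin"],
    "read_map": ["read_id", "contig", "start", "end", "mapq"],
    "read_taxon": ["read_id", "taxon_group"],
    "identity": ["query", "reference", "identity"],
}


def read_table(path, schema: str):
    """Read a tab-separated table with a header row into a typed object.

    Unknown columns are kept in the frame but ignored (logged); a missing
    required column is a hard error naming the column.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = _SCHEMAS[schema]
    if schema == "coverage":
        if "contig" not in df.columns:
            raise ValueError("coverage table: missing required column 'contig'")
        samples = [c for c in df.columns if c != "contig"]
        if not samples:
            raise ValueError("coverage table: no sample columns")
        depth = df[samples].to_numpy(dtype=float)
        return CoverageTable(list(df["contig"]), samples, depth)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{schema} table: missing required column '{missing[0]}'")
    extra = [c for c in df.columns if c not in required]
    if extra and schema != "read_taxon":
        logger.warning("%s table: ignoring columns %s", schema, extra)
    if schema == "bins":
        return dict(zip(df["contig"], df["bin"]))
    if schema == "read_map":
        return [
            ReadRecord(r.read_id, r.contig, int(r.start), int(r.end), int(r.mapq))
            for r in df.itertuples()
        ]
    if schema == "read_taxon":
        fams = df["family"] if "family" in df.columns else [None] * len(df)
        return [
            ReadTaxon(rid, grp, None if pd.isna(fam) else fam)
            for rid, grp, fam in zip(df["read_id"], df["taxon_group"], fams)
        ]
    if schema == "identity":
        return df[required].copy()


def write_coverage(table: CoverageTable, path) -> None:
    df = pd.DataFrame(table.depth, columns=table.sample_ids)
    df.insert(0, "contig", table.contig_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_bins(mapping: dict, path) -> None:
    pd.DataFrame(
        {"contig": list(mapping), "bin": [mapping[c] for c in mapping]}
    ).to_csv(path, sep="\t", index=False)


def write_read_map(reads, path) -> None:
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "contig": [r.contig_id for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "mapq": [r.mapq for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def write_read_taxa(taxa, path) -> None:
    pd.DataFrame(
        {
            "read_id": [t.read_id for t in taxa],
            "taxon_group": [t.taxon_group for t in taxa],
            "family": [t.family or "" for t in taxa],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sam_text(path) -> list[ReadRecord]:
    """Parse mapped reads from an uncompressed SAM text file.

    Optional convenience: the canonical mapping input is the read_map TSV.
    Alignment length along the reference is taken from the CIGAR (M/D/N/=/X).
    """
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, rname, pos, mapq, cigar = f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5]
            if rname == "*" or flag & 4:
                continue
            ref_len = 0
            num = ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in "MDN=X":
                        ref_len += int(num)
                    num = ""
            start = pos - 1
            reads.append(ReadRecord(qname, rname, start, start + ref_len, min(mapq, 60)))
    return reads
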