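"""File formats: FASTA, BED, TSV/CSV tables, locus strings, checksums.

Internal coordinates are 0-based half-open everywhere; BED is written and
read in that convention. Locus strings of the browser style
``chr1:16,478,543-16,478,567`` are 1-based inclusive and converted on
parse. Malformed lines are reported with their line number.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .melting import MeltingCurve
from .triplex import NucleicSeq, TriplexHit


class ParseError(ValueError):
    """A malformed input line; message carries file and line number."""


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> list[NucleicSeq]:
    """Read FASTA into NucleicSeq records; alphabet inferred from content.

    A sequence containing U is tagged RNA, anything else DNA. Ambiguity
    codes are rejected by NucleicSeq validation.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        alphabet = "RNA" if "U" in bases else "DNA"
        out.append(NucleicSeq(rec.id, alphabet, bases, rec.description))
    return out


def write_fasta(path, seqs) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description=s.description or "")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genome_fasta(path, genome: dict[str, str]) -> None:
    write_fasta(path, [NucleicSeq(c, "DNA", s) for c, s in sorted(genome.items())])


def read_genome_fasta(path) -> dict[str, str]:
    return {s.id: s.bases for s in read_fasta(path)}


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def read_bed(path) -> list[BedInterval]:
    """Read a 3-6 column BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            out.append(BedInterval(fields[0], start, end, name, score, strand))
    return out


def write_bed(path, intervals) -> None:
    """Write BedInterval records (or (chrom,start,end[,...]) tuples) as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            if not isinstance(iv, BedInterval):
                iv = BedInterval(*iv)
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def hits_to_bed(hits) -> list[BedInterval]:
    """TTS intervals of triplex hits as BED records.

    Name = tfo_id:tfo_start-tfo_end:motif, score = matched positions,
    strand = strand of the purine tract.
    """
    return [
        BedInterval(h.chrom, h.start, h.end, h.name, h.score, h.strand)
        for h in hits
    ]


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def hits_to_table(hits) -> pd.DataFrame:
    """Full triplex hit records as a DataFrame."""
    cols = ["tfo_id", "tfo_start", "tfo_end", "chrom", "start", "end",
            "strand", "orientation", "motif", "mismatches", "length", "score"]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hits],
                        columns=cols)


def table_to_hits(df: pd.DataFrame) -> list[TriplexHit]:
    return [TriplexHit(**{k: row[k] for k in df.columns if k in TriplexHit.__dataclass_fields__})
            for _, row in df.iterrows()]


# --------------------------------------------------------------------------
# Melting-curve CSV
# --------------------------------------------------------------------------

def read_melting_csv(path) -> list[MeltingCurve]:
    """CSV with columns curve_id, temperature, value -> one curve per id."""
    df = pd.read_csv(path)
    missing = {"curve_id", "temperature", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing melting-curve columns {sorted(missing)}")
    curves = []
    for cid, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("temperature")
        curves.append(MeltingCurve(grp["temperature"].to_numpy(),
                                   grp["value"].to_numpy(), str(cid)))
    return curves


def write_melting_csv(path, curves) -> None:
    frames = [
        pd.DataFrame({"curve_id": c.curve_id, "temperature": c.temperatures,
                      "value": c.values})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Locus strings and checksums
# --------------------------------------------------------------------------

def parse_genomic_locus(locus: str, one_based: bool = True) -> tuple[str, int, int]:
    """Parse ``chr1:16,478,543-16,478,567`` into (chrom, start, end).

    Browser-style loci are 1-based inclusive; the result is 0-based
    half-open, so the printed 25-nt span above parses to length 25.
    """
    try:
        chrom, span = locus.split(":")
        lo_s, hi_s = span.replace(",", "").split("-")
        lo, hi = int(lo_s), int(hi_s)
    except ValueError as exc:
        raise ParseError(f"cannot parse locus {locus!r}") from exc
    start = lo - 1 if one_based else lo
    if start < 0 or start >= hi:
        raise ParseError(f"locus {locus!r} has an empty or negative span")
    return chrom, start, hi


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def checksum_tree(paths: dict[str, Path]) -> dict[str, str]:
    return {name: sha256_of(p) for name, p in sorted(paths.items())}
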