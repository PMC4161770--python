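"""Reading and writing the standard formats the pipeline touches.

Internal coordinates are 0-based half-open; GFF3 and BLAST tabular files use
their native 1-based inclusive conventions. Lowercase (soft-masked) residues
are uppercased and not treated as masked.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .model import GenomeSequence, Hit, Interval, TECopy

_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised for malformed input files."""


def _clean_residues(raw: str) -> str:
    return _NON_ACGTN.sub("N", raw.upper())


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into GenomeSequence records.

    Residues are uppercased; any character outside {A,C,G,T,N} is mapped
    to N. Empty files or files without a FASTA header raise FormatError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, residues=_clean_residues(str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                name, seq = rec
            else:
                name, seq = rec.id, rec.residues
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_tabular_hits(path: str | Path) -> list[Hit]:
    """Read NCBI BLAST tabular (12-column outfmt 6) into Hit records.

    Subject coordinates are normalized to 0-based half-open; strand is
    inferred from subject coordinate order (descending = minus).
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}")
            (qseqid, sseqid, pident, _length, _mm, _go,
             _qs, _qe, sstart, send, _evalue, bitscore) = cols
            s, e = int(sstart), int(send)
            if s <= e:
                iv = Interval(sseqid, s - 1, e, "+")
            else:
                iv = Interval(sseqid, e - 1, s, "-")
            hits.append(Hit(query_id=qseqid, location=iv,
                            bit_score=float(bitscore),
                            identity_fraction=min(1.0, float(pident) / 100.0)))
    return hits


def write_tabular_hits(hits: Sequence[Hit], path: str | Path) -> None:
    """Write hits in an outfmt-6-compatible TSV (subject coordinates 1-based)."""
    with open(path, "w") as fh:
        for h in hits:
            iv = h.location
            if iv.strand == "+":
                ss, se = iv.start + 1, iv.end
            else:
                ss, se = iv.end, iv.start + 1
            fh.write("\t".join([
                h.query_id, iv.scaffold_id, f"{h.identity_fraction * 100:.2f}",
                str(iv.length), "0", "0", "1", str(iv.length),
                str(ss), str(se), "0", f"{h.bit_score:.1f}",
            ]) + "\n")


def _gff_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_copies_gff(copies: Sequence[TECopy], path: str | Path,
                     annotations: dict | None = None) -> None:
    """Write TE copies as GFF3 (1-based inclusive coordinates).

    Attributes carry the lineage id, the MITE flag and the ORF status when a
    per-copy annotation mapping is supplied.
    """
    annotations = annotations or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in copies:
            ann = annotations.get(c.id)
            attrs = [f"ID={_gff_escape(c.id)}"]
            attrs.append(f"lineage={_gff_escape(c.lineage_id or 'unassigned')}")
            attrs.append(f"mite={'true' if ann is not None and ann.is_mite else 'false'}")
            if ann is not None:
                attrs.append(f"orf_codons={ann.longest_orf_codons}")
                attrs.append(f"coding={'true' if ann.potentially_coding else 'false'}")
            fh.write("\t".join([
                c.location.scaffold_id, "marinerscape", "mobile_genetic_element",
                str(c.location.start + 1), str(c.location.end), ".",
                c.location.strand, ".", ";".join(attrs),
            ]) + "\n")


def read_gff_intervals(path: str | Path, feature_types: set[str] | None = None
                       ) -> list[Interval]:
    """Read intervals from a GFF3 file (optionally filtered by feature type)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise FormatError(f"short GFF line in {path}: {line!r}")
            if feature_types and cols[2] not in feature_types:
                continue
            strand = cols[6] if cols[6] in "+-" else "+"
            out.append(Interval(cols[0], int(cols[3]) - 1, int(cols[4]), strand))
    return out


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read a BED3+ file into intervals (BED is already 0-based half-open)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise FormatError(f"short BED line in {path}: {line!r}")
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def read_cds_features(path: str | Path) -> list[Interval]:
    """Read CDS features from GFF3 or BED, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() in {".bed"}:
        return read_bed_intervals(path)
    return read_gff_intervals(path, feature_types={"CDS", "gene", "mRNA"}) or \
        read_gff_intervals(path)
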