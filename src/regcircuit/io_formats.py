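"""Readers and writers for the external formats the pipeline touches.

Coordinates are 1-based inclusive internally (GFF3 native); only the BED
exporter converts to 0-based half-open.  Nucleotide sequences are uppercased
on input and any ambiguity code outside ACGT becomes N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.feature import feature_from_line


class FormatError(ValueError):
    """A file violates the dialect this pipeline expects."""


_NT_CLEAN = re.compile(r"[^ACGT]")
_PFAM_ACC = re.compile(r"^PF\d{5}$")
_PFAM_VERSION = re.compile(r"\.\d+$")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_pfam_acc(acc: str) -> str:
    """Strip a version suffix: ``PF00158.27`` -> ``PF00158``.  Idempotent."""
    return _PFAM_VERSION.sub("", acc)


@dataclass
class DomainHit:
    protein_id: str
    pfam_acc: str
    pfam_name: str
    ali_start: int
    ali_end: int
    bitscore: float
    evalue: float
    pfam_acc_raw: str = ""

    def __post_init__(self) -> None:
        if not self.pfam_acc_raw:
            self.pfam_acc_raw = self.pfam_acc
        self.pfam_acc = normalize_pfam_acc(self.pfam_acc)
        if not _PFAM_ACC.match(self.pfam_acc):
            raise FormatError(f"invalid Pfam accession {self.pfam_acc_raw!r}")
        if self.ali_start < 1 or self.ali_end < self.ali_start:
            raise FormatError(
                f"domain hit {self.protein_id}/{self.pfam_acc}: bad alignment "
                f"span {self.ali_start}..{self.ali_end}"
            )
        if self.evalue < 0:
            raise FormatError(f"domain hit {self.protein_id}/{self.pfam_acc}: negative evalue")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: identity out of [0,100]")
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: negative evalue")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file.

    Nucleotide records are uppercased and non-ACGT characters become N;
    protein records are uppercased only.  Raises :class:`FormatError` when
    sequence data precedes the first header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: sequence data before first '>' header")
            break
        else:
            return records  # empty file
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = _NT_CLEAN.sub("N", seq)
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id,
                      description=r.description[len(r.id):].strip()
                      if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path, feature_types: Sequence[str] = ("CDS",)) -> list[GeneRecord]:
    """Extract gene records of the requested feature types from GFF3.

    ``ID`` is preferred for the gene id, ``locus_tag`` is the fallback.
    Coordinate violations name the offending line.
    """
    wanted = set(feature_types)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if cols[2] not in wanted:
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}:{lineno}: unparseable GFF3 row ({exc})") from exc
            start, end = int(cols[3]), int(cols[4])
            if end < start:
                raise FormatError(f"{path}:{lineno}: end ({end}) < start ({start})")
            ids = feat.attributes.get("ID") or feat.attributes.get("locus_tag")
            if not ids:
                raise FormatError(f"{path}:{lineno}: row has neither ID nor locus_tag")
            gene_id = ids[0]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            product = (feat.attributes.get("product") or [""])[0]
            try:
                genes.append(GeneRecord(gene_id, cols[0], start, end, cols[6], product))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gff3(genes: Iterable[GeneRecord], path, feature_type: str = "CDS",
               source: str = "regcircuit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([
                g.replicon_id, source, feature_type, str(g.start), str(g.end),
                ".", g.strand, "0", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Domain table (HMMER-tblout-like TSV)

_DOMAIN_COLUMNS = ["protein_id", "pfam_acc", "pfam_name",
                   "ali_start", "ali_end", "bitscore", "evalue"]


def read_domain_table(path) -> list[DomainHit]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(DomainHit(
            protein_id=row.protein_id,
            pfam_acc=row.pfam_acc,
            pfam_name=row.pfam_name,
            ali_start=int(row.ali_start),
            ali_end=int(row.ali_end),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
            pfam_acc_raw=row.pfam_acc,
        ))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DOMAIN_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join([h.protein_id, h.pfam_acc_raw, h.pfam_name,
                                str(h.ali_start), str(h.ali_end),
                                f"{h.bitscore:g}", f"{h.evalue:g}"]) + "\n")


# ---------------------------------------------------------------------------
# Similarity table (BLAST outfmt-6 style, 12 columns, optional 13th qcovs)

def read_similarity_table(path, query_lengths: dict[str, int] | None = None
                          ) -> list[SimilarityHit]:
    """Read a 12-column tabular similarity file, plus optional 13th
    query-coverage column.  Without that column, coverage is computed as
    100 * alignment_length / query_length, which requires ``query_lengths``.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise FormatError(f"{path}:{lineno}: expected 12 or 13 columns, got {len(cols)}")
            q, s = cols[0], cols[1]
            aln_len = int(cols[3])
            if len(cols) == 13:
                cov = float(cols[12])
            else:
                if query_lengths is None or q not in query_lengths:
                    raise FormatError(
                        f"{path}:{lineno}: no coverage column and no query length for {q!r}")
                cov = 100.0 * aln_len / query_lengths[q]
            hits.append(SimilarityHit(
                query_id=q, subject_id=s,
                pct_identity=float(cols[2]),
                evalue=float(cols[10]), bitscore=float(cols[11]),
                query_coverage=min(cov, 100.0),
            ))
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path) -> None:
    """Write the 12+1 column dialect.  Positional columns the pipeline does
    not consume (mismatches, gap opens, alignment coordinates) are zero."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.pct_identity:g}", "0", "0", "0",
                "0", "0", "0", "0", f"{h.evalue:g}", f"{h.bitscore:g}",
                f"{h.query_coverage:g}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format

def write_meme_motifs(pwms, background, path) -> None:
    """Write PWMs in MEME minimal motif format.

    Refuses to write a matrix whose columns do not sum to 1 within 1e-6.
    ``background`` supplies the 0-order letter frequencies.
    """
    q0 = np.asarray(background.marginal, dtype=float)
    for pwm in pwms:
        sums = pwm.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError(f"motif {pwm.motif_id}: columns not normalized")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.6f C %.6f G %.6f T %.6f\n\n" % tuple(q0))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write("letter-probability matrix: alength= 4 w= %d nsites= %d E= 0\n"
                     % (pwm.width, max(pwm.nsites, 1)))
            for row in pwm.matrix:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")


def read_meme_motifs(path):
    """Read motifs back from MEME minimal format.  Returns (pwms, background
    marginal array)."""
    from .motif import PWM  # local import avoids a cycle

    pwms = []
    q0 = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            q0 = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: MOTIF {motif_id} lacks a probability matrix")
            header = lines[i]
            m = re.search(r"w=\s*(\d+)", header)
            n = re.search(r"nsites=\s*(\d+)", header)
            width = int(m.group(1))
            nsites = int(n.group(1)) if n else 1
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            mat = np.array(rows)
            sums = mat.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-4):
                raise FormatError(f"{path}: MOTIF {motif_id} rows do not sum to 1")
            mat = mat / sums[:, None]  # undo fixed-precision rounding
            pwms.append(PWM(motif_id=motif_id, matrix=mat, nsites=nsites))
            i += 1 + width
            continue
        i += 1
    return pwms, q0


# ---------------------------------------------------------------------------
# BED6+1 site export

def write_sites_bed(hits, path) -> None:
    """Write site hits as BED6+1: 0-based half-open coordinates, score in
    column 5, strand in column 6, p-value in column 7."""
    with open(path, "w") as fh:
        for h in hits:
            name = getattr(h, "motif_id", "site") or "site"
            fh.write("\t".join([
                h.seq_id, str(h.start - 1), str(h.end), name,
                f"{h.score:.4f}", h.strand, f"{h.pvalue:.6g}",
            ]) + "\n")
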