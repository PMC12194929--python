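"""Transcriptional-unit inference from intergenic distances.

Adjacent genes on one replicon join the same transcriptional unit iff they
share a strand and the intergenic gap (bases strictly between them,
``next.start - prev.end - 1``) is at most 40; a gap of more than 40 bases,
or a strand switch, starts a new unit.  Upstream regions extend from the
base before the leader gene back to the previous coding feature, capped at
``max_len`` (default 300 nt), and are returned strand-oriented (reading
toward the gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import GeneRecord, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_GAP_THRESHOLD = 40


@dataclass
class TranscriptionalUnit:
    tu_id: str
    replicon_id: str
    strand: str
    gene_ids: tuple[str, ...]  # ordered 5' -> 3'
    leader_gene_id: str
    upstream_start: int | None = None  # 1-based inclusive, genomic
    upstream_end: int | None = None
    upstream_sequence: str | None = None  # strand-oriented

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


def infer_tus(genes: Sequence[GeneRecord],
              gap_threshold: int = DEFAULT_GAP_THRESHOLD) -> list[TranscriptionalUnit]:
    """Partition one replicon's genes into transcriptional units.

    Genes must belong to a single replicon; they are processed in coordinate
    order.  Overlapping same-strand genes are treated as gap 0 (joined) with
    a log note; a gene fully contained in another is rejected.
    """
    if not genes:
        return []
    replicons = {g.replicon_id for g in genes}
    if len(replicons) != 1:
        raise ValueError(f"infer_tus expects one replicon, got {sorted(replicons)}")
    replicon_id = replicons.pop()
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start >= prev.start and nxt.end <= prev.end:
            raise ValueError(
                f"gene {nxt.gene_id} is contained within {prev.gene_id}; "
                "containment must be resolved upstream")

    runs: list[list[GeneRecord]] = [[ordered[0]]]
    for prev, nxt in zip(ordered, ordered[1:]):
        gap = nxt.start - prev.end - 1
        if gap < 0:
            logger.info("overlapping same-strand genes %s/%s treated as gap 0",
                        prev.gene_id, nxt.gene_id)
            gap = 0
        if nxt.strand == prev.strand and gap <= gap_threshold:
            runs[-1].append(nxt)
        else:
            runs.append([nxt])

    tus = []
    for i, run in enumerate(runs, start=1):
        strand = run[0].strand
        five_to_three = run if strand == "+" else list(reversed(run))
        tus.append(TranscriptionalUnit(
            tu_id=f"{replicon_id}_TU{i:04d}",
            replicon_id=replicon_id,
            strand=strand,
            gene_ids=tuple(g.gene_id for g in five_to_three),
            leader_gene_id=five_to_three[0].gene_id))
    return tus


def extract_upstream(tu: TranscriptionalUnit, replicon: SequenceRecord,
                     genes: Sequence[GeneRecord],
                     max_len: int = 300) -> TranscriptionalUnit:
    """Fill in the upstream region of a transcriptional unit (in place).

    The region runs from the base after the previous coding feature (any
    strand) to the base before the leader gene, capped at ``max_len``; for
    minus-strand units the genomic slice is reverse-complemented so the
    returned string reads toward the gene.  A zero-length gap leaves the
    upstream fields unset.
    """
    by_id = {g.gene_id: g for g in genes}
    leader = by_id[tu.leader_gene_id]
    n = len(replicon.sequence)
    if tu.strand == "+":
        prev_end = max((g.end for g in genes
                        if g.end < leader.start and g.gene_id != leader.gene_id),
                       default=0)
        lo = max(prev_end + 1, leader.start - max_len, 1)
        hi = leader.start - 1
        if lo == 1 and leader.start - max_len < 1:
            logger.info("TU %s: upstream truncated at replicon edge", tu.tu_id)
    else:
        next_start = min((g.start for g in genes
                          if g.start > leader.end and g.gene_id != leader.gene_id),
                         default=n + 1)
        lo = leader.end + 1
        hi = min(next_start - 1, leader.end + max_len, n)
        if hi == n and leader.end + max_len > n:
            logger.info("TU %s: upstream truncated at replicon edge", tu.tu_id)
    if hi < lo:
        tu.upstream_start = tu.upstream_end = None
        tu.upstream_sequence = None
        return tu
    tu.upstream_start, tu.upstream_end = lo, hi
    raw = replicon.sequence[lo - 1:hi]
    tu.upstream_sequence = raw if tu.strand == "+" else reverse_complement(raw)
    return tu


def upstream_records(tus: Iterable[TranscriptionalUnit]) -> list[SequenceRecord]:
    """Upstream regions as FASTA-ready records, one per TU with an upstream
    sequence; headers carry ``tu_id|replicon|start|end|strand``."""
    out = []
    for tu in tus:
        if not tu.upstream_sequence:
            continue
        desc = f"{tu.tu_id}|{tu.replicon_id}|{tu.upstream_start}|{tu.upstream_end}|{tu.strand}"
        out.append(SequenceRecord(tu.tu_id, tu.upstream_sequence, desc))
    return out


def write_tu_table(tus: Sequence[TranscriptionalUnit], path) -> None:
    with open(path, "w") as fh:
        fh.write("tu_id\treplicon_id\tstrand\tleader_gene_id\tgenes"
                 "\tupstream_start\tupstream_end\n")
        for tu in tus:
            fh.write("\t".join([
                tu.tu_id, tu.replicon_id, tu.strand, tu.leader_gene_id,
                ",".join(tu.gene_ids),
                str(tu.upstream_start or ""), str(tu.upstream_end or ""),
            ]) + "\n")
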