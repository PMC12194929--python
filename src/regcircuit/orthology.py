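"""Ortholog groups from reciprocal best hits.

Hits are filtered on E-value (< 1e-10, strict), percent identity (> 60,
strict) and query coverage (>= 60); reciprocal best hits are computed per
ordered genome pair with a fully pinned tie-break (bitscore desc, evalue
asc, subject id asc) so the result is invariant to input row order, and
groups are the connected components of the reciprocal-pair graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import SimilarityHit


@dataclass(frozen=True)
class OrthologyThresholds:
    max_evalue: float = 1e-10
    min_identity: float = 60.0
    min_query_coverage: float = 60.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not 0 < self.min_identity <= 100 or not 0 < self.min_query_coverage <= 100:
            raise ValueError("identity/coverage thresholds must be in (0, 100]")


@dataclass
class OrthologGroup:
    og_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, protein_id)
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.og_id}: empty ortholog group")

    @property
    def size(self) -> int:
        return len(self.members)

    def count_in(self, genome_id: str) -> int:
        return sum(1 for g, _ in self.members if g == genome_id)


def filter_hits(hits: Iterable[SimilarityHit],
                thresholds: OrthologyThresholds = OrthologyThresholds()
                ) -> list[SimilarityHit]:
    """Retain hits passing all thresholds; self-hits are removed."""
    return [
        h for h in hits
        if h.query_id != h.subject_id
        and h.evalue < thresholds.max_evalue
        and h.pct_identity > thresholds.min_identity
        and h.query_coverage >= thresholds.min_query_coverage
    ]


def reciprocal_best_hits(hits: Sequence[SimilarityHit],
                         genome_map: Mapping[str, str]
                         ) -> set[frozenset[str]]:
    """Unordered protein pairs that are mutual best hits between genomes.

    For each ordered genome pair and query, the best subject maximizes
    bitscore, then minimizes evalue, then takes the lexicographically
    smallest subject id.  Intra-genome hits are ignored.
    """
    best: dict[tuple[str, str, str], SimilarityHit] = {}
    for h in hits:
        try:
            gq, gs = genome_map[h.query_id], genome_map[h.subject_id]
        except KeyError as exc:
            raise ValueError(f"protein {exc.args[0]!r} missing from genome map") from exc
        if gq == gs:
            continue
        key = (gq, gs, h.query_id)
        cur = best.get(key)
        if cur is None or (
            (-h.bitscore, h.evalue, h.subject_id)
            < (-cur.bitscore, cur.evalue, cur.subject_id)
        ):
            best[key] = h
    pairs: set[frozenset[str]] = set()
    for (gq, gs, q), h in best.items():
        back = best.get((gs, gq, h.subject_id))
        if back is not None and back.subject_id == q:
            pairs.add(frozenset((q, h.subject_id)))
    return pairs


def cluster_ogs(pairs: Iterable[frozenset[str]],
                genome_map: Mapping[str, str],
                singletons: Iterable[str] = ()) -> list[OrthologGroup]:
    """Connected components of the reciprocal-pair graph.

    Groups are ordered by (size desc, smallest member id); singleton
    proteins are appended as singleton groups only when supplied.
    """
    graph = nx.Graph()
    for pair in pairs:
        a, b = sorted(pair)
        graph.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    for pid in sorted(set(singletons) - set(graph.nodes)):
        comps.append([pid])
    comps.sort(key=lambda c: (-len(c), c[0]))
    ogs = []
    for i, comp in enumerate(comps, start=1):
        members = frozenset((genome_map[p], p) for p in comp)
        ogs.append(OrthologGroup(og_id=f"OG{i:04d}", members=members))
    return ogs


def og_count_matrix(ogs: Sequence[OrthologGroup], genomes: Sequence[str],
                    cap: int | None = None) -> pd.DataFrame:
    """Genome x OG matrix of member counts; ``cap=2`` gives the bounded
    display view used for presence/dosage heatmaps."""
    data = {
        og.label or og.og_id: [og.count_in(g) for g in genomes] for og in ogs
    }
    df = pd.DataFrame(data, index=list(genomes), dtype=int)
    if cap is not None:
        df = df.clip(upper=cap)
    return df


def write_og_table(ogs: Sequence[OrthologGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("og_id\tlabel\tgenome_id\tprotein_id\n")
        for og in ogs:
            for genome_id, protein_id in sorted(og.members):
                fh.write(f"{og.og_id}\t{og.label or ''}\t{genome_id}\t{protein_id}\n")
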