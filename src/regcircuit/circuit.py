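"""Regulator -> transcriptional-unit network assembly and the end-to-end
pipeline.

Edges carry either binding-site evidence (an overlap-filtered PWM hit in
the target's upstream region, with its best p-value) or colocalization
evidence (a bEBP divergently oriented head-to-head with the target unit
within a configurable intergenic distance — the HupR/hupSL layout), or
both.  The pipeline runs orthology -> regulator classification -> TU
inference -> scanning -> network assembly and writes a machine-readable
manifest; identical config and inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__
from .io_formats import (GeneRecord, SequenceRecord, read_domain_table,
                         read_fasta, read_gff3, read_meme_motifs,
                         read_similarity_table, write_fasta, write_sites_bed)
from .motif import (MarkovBackground, PWM, SiteHit, filter_overlaps,
                    scan_sequences, train_markov_background)
from .orthology import (OrthologyThresholds, cluster_ogs, filter_hits,
                        og_count_matrix, reciprocal_best_hits, write_og_table)
from .regulator_classify import (RegulatorCall, TCSPair, build_architectures,
                                 classify_regulators, pair_tcs, write_calls,
                                 write_tcs_pairs)
from .synthetic_data import consensus_pwm
from .tu_infer import (TranscriptionalUnit, extract_upstream, infer_tus,
                       upstream_records, write_tu_table)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RegulatoryEdge:
    regulator_id: str
    regulator_class: str  # sigma_factor | bEBP
    target_tu_id: str
    evidence: str  # site_hit | colocalization | both
    best_site_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.evidence in ("site_hit", "both") and self.best_site_pvalue is None:
            raise ValueError("site evidence requires a p-value")


@dataclass
class PromoterCall:
    tu_id: str
    promoter_class: str  # sigma54_like | sigma70_like | none
    hit: SiteHit | None = None


# ---------------------------------------------------------------------------
# Promoter PWMs built from the canonical consensus elements


def sigma54_promoter_pwm(p: float = 0.9) -> PWM:
    """-24/-12 promoter: "GC" ending at -24 and "TGC" at -12.  Width 14
    covering -25..-12; only the five consensus positions are informative."""
    mat = np.full((14, 4), 0.25)
    for j, ch in ((0, "G"), (1, "C"), (11, "T"), (12, "G"), (13, "C")):
        mat[j] = (1.0 - p) / 3.0
        mat[j, "ACGT".index(ch)] = p
    return PWM(motif_id="sigma54_promoter", matrix=mat, nsites=0)


def sigma70_promoter_pwm(p: float = 0.9) -> PWM:
    """-35 "TTGACA" / -10 "TATAAT" promoter with a 17-nt spacer; width 29
    covering -35..-7."""
    mat = np.full((29, 4), 0.25)
    for start, word in ((0, "TTGACA"), (23, "TATAAT")):
        for k, ch in enumerate(word):
            mat[start + k] = (1.0 - p) / 3.0
            mat[start + k, "ACGT".index(ch)] = p
    return PWM(motif_id="sigma70_promoter", matrix=mat, nsites=0)


def call_promoter(tu: TranscriptionalUnit, sigma54_pwm: PWM,
                  sigma70_pwms: Sequence[PWM], background: MarkovBackground,
                  p_max: float = 1e-3, window: int = 60) -> PromoterCall:
    """Classify a TU's promoter by scanning sigma-class PWMs over the
    ``window`` nt immediately upstream of the leader (coding strand only).

    The default p_max is laxer than genome-wide scanning because a PWM with
    only the five -24/-12 consensus positions informative has an attainable
    p-value floor of 4^-5 ~ 9.8e-4.
    """
    if not tu.upstream_sequence:
        logger.info("TU %s has no upstream region; promoter call is none", tu.tu_id)
        return PromoterCall(tu.tu_id, "none")
    region = tu.upstream_sequence[-window:]
    best: tuple[float, float, str, SiteHit] | None = None
    for cls, pwms in (("sigma54_like", [sigma54_pwm]),
                      ("sigma70_like", list(sigma70_pwms))):
        for pwm in pwms:
            hits = scan_sequences(pwm, [(tu.tu_id, region)], background,
                                  p_max=p_max, both_strands=False)
            for h in hits:
                key = (h.pvalue, -h.score, cls, h)
                if best is None or key[:2] < best[:2]:
                    best = key
    if best is None:
        return PromoterCall(tu.tu_id, "none")
    return PromoterCall(tu.tu_id, best[2], best[3])


# ---------------------------------------------------------------------------
# Network assembly


def assemble_network(calls: Sequence[RegulatorCall],
                     tcs_pairs: Sequence[TCSPair],
                     site_hits: Sequence[SiteHit],
                     tus: Sequence[TranscriptionalUnit],
                     genes: Mapping[str, GeneRecord] | None = None,
                     colocalization_max_gap: int = 300,
                     regulator_class_of_motif: Mapping[str, str] | None = None
                     ) -> list[RegulatoryEdge]:
    """Build the regulator -> TU edge list.

    Site hits must already be overlap-filtered and carry the target
    ``tu_id`` as their ``seq_id``; each (motif, TU) pair yields one edge
    with the best p-value.  bEBPs whose unit is divergently head-to-head
    with a neighbour within ``colocalization_max_gap`` gain a
    colocalization edge; evidence kinds merge when both apply.
    """
    tu_ids = {tu.tu_id for tu in tus}
    edges: dict[tuple[str, str], RegulatoryEdge] = {}

    for h in sorted(site_hits, key=lambda h: (h.motif_id, h.seq_id, h.pvalue)):
        if h.seq_id not in tu_ids:
            raise ValueError(f"site hit references unknown TU {h.seq_id!r}")
        reg = h.motif_id or "motif"
        cls = (regulator_class_of_motif or {}).get(reg, "sigma_factor"
               if reg.startswith("sigma") else "bEBP")
        key = (reg, h.seq_id)
        cur = edges.get(key)
        if cur is None:
            edges[key] = RegulatoryEdge(reg, cls, h.seq_id, "site_hit", h.pvalue)
        elif cur.best_site_pvalue is None or h.pvalue < cur.best_site_pvalue:
            cur.best_site_pvalue = h.pvalue
            if cur.evidence == "colocalization":
                cur.evidence = "both"

    if genes is not None:
        bebps = {c.protein_id for c in calls if c.family == "bEBP"}
        tu_of_gene = {g: tu for tu in tus for g in tu.gene_ids}
        by_replicon: dict[str, list[TranscriptionalUnit]] = {}
        for tu in tus:
            by_replicon.setdefault(tu.replicon_id, []).append(tu)
        for lst in by_replicon.values():
            lst.sort(key=lambda t: min(genes[g].start for g in t.gene_ids))
            for t1, t2 in zip(lst, lst[1:]):
                end1 = max(genes[g].end for g in t1.gene_ids)
                start2 = min(genes[g].start for g in t2.gene_ids)
                gap = start2 - end1 - 1
                divergent = t1.strand == "-" and t2.strand == "+"
                if not divergent or gap > colocalization_max_gap:
                    continue
                for source, target in ((t1, t2), (t2, t1)):
                    for gid in source.gene_ids:
                        if gid not in bebps:
                            continue
                        key = (gid, target.tu_id)
                        cur = edges.get(key)
                        if cur is None:
                            edges[key] = RegulatoryEdge(
                                gid, "bEBP", target.tu_id, "colocalization")
                        elif cur.evidence == "site_hit":
                            cur.evidence = "both"

    return [edges[k] for k in sorted(edges)]


def collapse_edges_by_og(edges: Sequence[RegulatoryEdge],
                         og_of_regulator: Mapping[str, str]) -> list[RegulatoryEdge]:
    """Cross-genome summary view: one edge per (OG label, target)."""
    out: dict[tuple[str, str], RegulatoryEdge] = {}
    for e in edges:
        reg = og_of_regulator.get(e.regulator_id, e.regulator_id)
        key = (reg, e.target_tu_id)
        cur = out.get(key)
        if cur is None:
            out[key] = RegulatoryEdge(reg, e.regulator_class, e.target_tu_id,
                                      e.evidence, e.best_site_pvalue)
        else:
            if e.best_site_pvalue is not None and (
                    cur.best_site_pvalue is None
                    or e.best_site_pvalue < cur.best_site_pvalue):
                cur.best_site_pvalue = e.best_site_pvalue
            if cur.evidence != e.evidence:
                cur.evidence = "both"
    return [out[k] for k in sorted(out)]


def write_edges(edges: Sequence[RegulatoryEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator_id\tregulator_class\ttarget_tu_id\tevidence\tbest_site_pvalue\n")
        for e in edges:
            p = "" if e.best_site_pvalue is None else f"{e.best_site_pvalue:.6g}"
            fh.write(f"{e.regulator_id}\t{e.regulator_class}\t{e.target_tu_id}"
                     f"\t{e.evidence}\t{p}\n")


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class GenomeInput:
    genome_id: str
    fasta: Path
    gff: Path


@dataclass
class PipelineConfig:
    genomes: list[GenomeInput]
    domain_table: Path
    similarity_table: Path
    genome_map: Path
    outdir: Path
    motifs_meme: Path | None = None
    seed: int = 0
    p_max: float = 1e-4
    upstream_max: int = 300
    gap_threshold: int = 40
    background_order: int = 4
    colocalization_max_gap: int = 300
    thresholds: OrthologyThresholds = field(default_factory=OrthologyThresholds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def p(x):
            q = Path(x)
            return q if q.is_absolute() else base / q

        genomes = [GenomeInput(g["genome_id"], p(g["fasta"]), p(g["gff"]))
                   for g in raw["genomes"]]
        thr = OrthologyThresholds(**raw.get("thresholds", {}))
        return cls(
            genomes=genomes,
            domain_table=p(raw["domain_table"]),
            similarity_table=p(raw["similarity_table"]),
            genome_map=p(raw["genome_map"]),
            outdir=p(raw["outdir"]),
            motifs_meme=p(raw["motifs_meme"]) if raw.get("motifs_meme") else None,
            seed=int(raw.get("seed", 0)),
            p_max=float(raw.get("p_max", 1e-4)),
            upstream_max=int(raw.get("upstream_max", 300)),
            gap_threshold=int(raw.get("gap_threshold", 40)),
            background_order=int(raw.get("background_order", 4)),
            colocalization_max_gap=int(raw.get("colocalization_max_gap", 300)),
            thresholds=thr,
        )


@dataclass
class PipelineResult:
    ogs: list
    calls: list[RegulatorCall]
    tcs_pairs: list[TCSPair]
    tus: list[TranscriptionalUnit]
    site_hits: list[SiteHit]
    edges: list[RegulatoryEdge]
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute orthology -> classify -> tus -> scan -> network.

    Every intermediate is written under ``config.outdir`` together with a
    manifest (parameters, seed, input checksums, completed stages); any
    stage failure aborts with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def run_stage(name, fn):
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        stages.append(name)
        return result

    # --- stage: orthology
    def _orthology():
        genome_map = {}
        for line in Path(config.genome_map).read_text().splitlines():
            if line.strip():
                pid, gid = line.split("\t")
                genome_map[pid] = gid
        hits = read_similarity_table(config.similarity_table)
        kept = filter_hits(hits, config.thresholds)
        pairs = reciprocal_best_hits(kept, genome_map)
        ogs = cluster_ogs(pairs, genome_map)
        write_og_table(ogs, outdir / "ogs.tsv")
        counts = og_count_matrix(ogs, sorted({g.genome_id for g in config.genomes}))
        counts.to_csv(outdir / "og_counts.tsv", sep="\t")
        return genome_map, ogs

    genome_map, ogs = run_stage("orthology", _orthology)

    # --- stage: classify
    def _classify():
        hits = read_domain_table(config.domain_table)
        archs = build_architectures(hits)
        calls = classify_regulators(archs)
        write_calls(calls, outdir / "calls.tsv")
        return calls

    calls = run_stage("classify", _classify)

    # --- stage: tus
    def _tus():
        all_tus: list[TranscriptionalUnit] = []
        genes_by_id: dict[str, GeneRecord] = {}
        replicons: dict[str, SequenceRecord] = {}
        replicon_genome: dict[str, str] = {}
        tu_genome: dict[str, str] = {}
        for g in config.genomes:
            genes = read_gff3(g.gff)
            seqs = read_fasta(g.fasta)
            by_replicon: dict[str, list[GeneRecord]] = {}
            for gene in genes:
                genes_by_id[gene.gene_id] = gene
                by_replicon.setdefault(gene.replicon_id, []).append(gene)
            for rec in seqs:
                replicons[rec.id] = rec
                replicon_genome[rec.id] = g.genome_id
            for rid, rgenes in sorted(by_replicon.items()):
                if rid not in replicons:
                    raise ValueError(f"replicon {rid!r} missing from {g.fasta}")
                tus = infer_tus(rgenes, config.gap_threshold)
                for tu in tus:
                    extract_upstream(tu, replicons[rid], rgenes, config.upstream_max)
                    tu_genome[tu.tu_id] = g.genome_id
                all_tus.extend(tus)
        write_tu_table(all_tus, outdir / "tus.tsv")
        write_fasta(upstream_records(all_tus), outdir / "upstream.fna")
        return all_tus, genes_by_id, replicons, replicon_genome, tu_genome

    all_tus, genes_by_id, replicons, replicon_genome, tu_genome = \
        run_stage("tus", _tus)

    # --- stage: tcs pairing (part of classification outputs, needs TUs)
    def _tcs():
        bebps = [c.protein_id for c in calls
                 if c.family == "bEBP" and c.protein_id in genes_by_id]
        hks = [c.protein_id for c in calls
               if (c.family == "HKS" or c.hybrid_kinase)
               and c.protein_id in genes_by_id]
        pairs = pair_tcs(bebps, hks, all_tus, genes_by_id)
        write_tcs_pairs(pairs, outdir / "tcs_pairs.tsv")
        return pairs

    tcs_pairs = run_stage("tcs", _tcs)

    # --- stage: scan
    def _scan():
        if config.motifs_meme is None:
            (outdir / "sites.bed").write_text("")
            return []
        pwms, _ = read_meme_motifs(config.motifs_meme)
        hits: list[SiteHit] = []
        for g in config.genomes:
            bg_seqs = [r.sequence for r in replicons.values()
                       if replicon_genome.get(r.id) == g.genome_id]
            if not bg_seqs:
                bg_seqs = [r.sequence for r in replicons.values()]
            background = train_markov_background(bg_seqs, config.background_order)
            upstream = [(tu.tu_id, tu.upstream_sequence) for tu in all_tus
                        if tu.upstream_sequence
                        and tu_genome.get(tu.tu_id) == g.genome_id]
            for pwm in pwms:
                hits.extend(scan_sequences(pwm, upstream, background,
                                           p_max=config.p_max))
        hits = filter_overlaps(hits)
        write_sites_bed(hits, outdir / "sites.bed")
        return hits

    site_hits = run_stage("scan", _scan)

    # --- stage: network
    def _network():
        edges = assemble_network(
            calls, tcs_pairs, site_hits, all_tus, genes_by_id,
            colocalization_max_gap=config.colocalization_max_gap)
        write_edges(edges, outdir / "edges.tsv")
        return edges

    edges = run_stage("network", _network)

    inputs = {str(g.fasta): _sha256(g.fasta) for g in config.genomes}
    inputs.update({str(g.gff): _sha256(g.gff) for g in config.genomes})
    for p in (config.domain_table, config.similarity_table, config.genome_map,
              config.motifs_meme):
        if p is not None:
            inputs[str(p)] = _sha256(p)
    manifest = {
        "pipeline": "regcircuit",
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "parameters": {
            "p_max": config.p_max,
            "upstream_max": config.upstream_max,
            "gap_threshold": config.gap_threshold,
            "background_order": config.background_order,
            "colocalization_max_gap": config.colocalization_max_gap,
            "max_evalue": config.thresholds.max_evalue,
            "min_identity": config.thresholds.min_identity,
            "min_query_coverage": config.thresholds.min_query_coverage,
        },
        "inputs": {k: inputs[k] for k in sorted(inputs)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return PipelineResult(ogs=ogs, calls=calls, tcs_pairs=tcs_pairs,
                          tus=all_tus, site_hits=site_hits, edges=edges,
                          manifest=manifest, outdir=outdir)
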