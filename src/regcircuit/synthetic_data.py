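"""Synthetic genome bundles with planted ground truth.

The generator emits exactly the artifacts the pipeline consumes — replicon
FASTA, CDS GFF3, protein FASTA, a domain-hit table, an all-vs-all similarity
table — plus a truth bundle recording every planted operon, domain
architecture, ortholog group and binding site.  Operons follow the
intergenic-distance rule that drives transcriptional-unit inference
(intra-operon gaps <= 40 bp, inter-operon gaps > 40 bp), sites are sampled
column-wise from configurable PWMs and planted under a generative ZOOPS
regime (zero or one site per target region, occupancy gamma), and the
similarity table encodes the planted orthology as strong reciprocal hits
plus sub-threshold noise.

Proteins are random amino-acid strings and domain hits are asserted rather
than detected: the pipeline consumes domain tables, and upstream domain
detection is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (DomainHit, GeneRecord, SequenceRecord, SimilarityHit,
                         reverse_complement, write_domain_table, write_fasta,
                         write_gff3, write_similarity_table)
from .motif import (ALPHABET, MarkovBackground, PWM, sample_background_sequence)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Config


@dataclass(frozen=True)
class PlantedArchitecture:
    """An ordered Pfam domain architecture planted on one protein per copy.

    ``truth_family``/``truth_group`` state the expected regulator call;
    ``cotranscribed`` architectures are planted on the immediately following
    genes of the same operon (e.g. an HKS next to its bEBP).
    """

    label: str
    domains: tuple[tuple[str, str], ...]  # (pfam_acc, pfam_name), N-to-C order
    truth_family: str = "none"
    truth_group: str = "unclassified"
    copies: int = 1
    cotranscribed: tuple["PlantedArchitecture", ...] = ()


@dataclass(frozen=True)
class PlantedMotif:
    """A PWM planted upstream of ``n_targets`` operons per genome with
    per-target occupancy ``gamma`` (generative ZOOPS)."""

    motif_id: str
    pwm: PWM
    gamma: float = 1.0
    n_targets: int = 5
    regulator_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int
    n_genomes: int = 1
    n_operons_per_genome: int = 20
    genes_per_operon: tuple[int, int] = (2, 4)
    gene_length: tuple[int, int] = (300, 900)
    intra_operon_gap: tuple[int, int] = (1, 40)
    inter_operon_gap: tuple[int, int] = (150, 300)
    background_order: int = 0
    background: MarkovBackground | None = None
    planted_architectures: tuple[PlantedArchitecture, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    upstream_max: int = 300
    n_noise_similarity_hits: int = 30
    n_decoy_domains: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.intra_operon_gap[0] <= self.intra_operon_gap[1] <= 40:
            raise ValueError("intra-operon gaps must lie in [0, 40]")
        if self.inter_operon_gap[0] <= 40:
            raise ValueError("inter-operon gaps must exceed 40")
        if not 0 <= self.background_order <= 4:
            raise ValueError("background order must be in [0, 4]")


# ---------------------------------------------------------------------------
# Standard planted architectures (Pfam accessions of the diagnostic domains)

PF = {
    "Sigma54_AID": ("PF00309", "Sigma54_AID"),
    "Sigma54_CBD": ("PF04963", "Sigma54_CBD"),
    "Sigma54_DBD": ("PF04552", "Sigma54_DBD"),
    "Sigma70_r1_2": ("PF00140", "Sigma70_r1_2"),
    "Sigma70_r2": ("PF04542", "Sigma70_r2"),
    "Sigma70_r3": ("PF04539", "Sigma70_r3"),
    "Sigma70_r4_2": ("PF08281", "Sigma70_r4_2"),
    "Response_reg": ("PF00072", "Response_reg"),
    "Sigma_54_activat": ("PF00158", "Sigma_54_activat"),
    "HTH_8": ("PF02954", "HTH_8"),
    "HisKA": ("PF00512", "HisKA"),
    "HATPase_c": ("PF02518", "HATPase_c"),
    "PAS": ("PF00989", "PAS"),
    "HAMP": ("PF00672", "HAMP"),
    "Plug": ("PF07715", "Plug"),  # decoy, not a regulator domain
}


def _arch(label, names, family, group, **kw):
    return PlantedArchitecture(label, tuple(PF[n] for n in names),
                               truth_family=family, truth_group=group, **kw)


def standard_architectures() -> dict[str, PlantedArchitecture]:
    """Unambiguous reference architectures for every regulator class."""
    hks = _arch("HKS", ["HisKA", "HATPase_c"], "HKS", "HKS")
    hks_pas = _arch("HKS_PAS", ["PAS", "HisKA", "HATPase_c"], "HKS", "HKS")
    archs = [
        _arch("RpoN", ["Sigma54_AID", "Sigma54_CBD", "Sigma54_DBD"],
              "sigma54", "RpoN"),
        _arch("RpoD", ["Sigma70_r1_2", "Sigma70_r3"], "sigma70", "group1_2"),
        _arch("FliA", ["Sigma70_r3"], "sigma70", "group3_FliA-like"),
        _arch("RpoE", ["Sigma70_r2", "Sigma70_r4_2"], "sigma70", "group4_RpoE-like"),
        _arch("Sigma70_like6", ["Sigma70_r2"], "sigma70", "sigma70_like"),
        _arch("bEBP", ["Response_reg", "Sigma_54_activat", "HTH_8"], "bEBP", "bEBP"),
        hks,
        hks_pas,
        _arch("Decoy", ["Plug"], "none", "unclassified"),
    ]
    return {a.label: a for a in archs}


def consensus_pwm(consensus: str, p: float = 0.94, motif_id: str = "motif") -> PWM:
    """PWM putting probability ``p`` on the consensus base per column."""
    mat = np.full((len(consensus), 4), (1.0 - p) / 3.0)
    for j, ch in enumerate(consensus.upper()):
        mat[j, ALPHABET.index(ch)] = p
    return PWM(motif_id=motif_id, matrix=mat, nsites=0)


# ---------------------------------------------------------------------------
# Planting primitives


def plant_sites(sequences: Sequence[SequenceRecord], pwm: PWM, gamma: float,
                seed: int | np.random.Generator
                ) -> tuple[list[SequenceRecord], list[tuple[str, int, str]]]:
    """Plant zero or one PWM site per sequence (generative ZOOPS).

    Each sequence independently receives one site with probability gamma at
    a uniform offset and uniform strand; site letters are sampled column-wise
    from the PWM and overwrite the background.  Returns the modified records
    and a truth list of (seq_id, 1-based start, strand).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    width = pwm.width
    if any(len(s) <= width for s in sequences):
        raise ValueError("every sequence must be longer than the PWM width")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    truth: list[tuple[str, int, str]] = []
    for rec in sequences:
        seq = rec.sequence
        if rng.random() < gamma:
            offset = int(rng.integers(0, len(seq) - width + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            letters = "".join(ALPHABET[int(rng.choice(4, p=col))] for col in pwm.matrix)
            planted = letters if strand == "+" else reverse_complement(letters)
            seq = seq[:offset] + planted + seq[offset + width:]
            truth.append((rec.id, offset + 1, strand))
        out.append(SequenceRecord(rec.id, seq, rec.description))
    return out, truth


def plant_sigma54_promoter(upstream_sequence: str, tu_start_offset: int = 0) -> str:
    """Write the sigma54 promoter elements into an upstream region.

    "GC" ends at position -24 and "TGC" at -12 relative to the TU start;
    position -1 is the last character of the string when ``tu_start_offset``
    is 0.  Idempotent.
    """
    n = len(upstream_sequence)
    if n < 30:
        raise ValueError("upstream region too short for a sigma54 promoter (< 30 nt)")
    s = list(upstream_sequence)

    def put(rel_pos: int, ch: str) -> None:
        i = n + rel_pos + tu_start_offset
        if i < 0 or i >= n:
            raise ValueError(f"promoter position {rel_pos} outside the region")
        s[i] = ch

    for pos, ch in ((-25, "G"), (-24, "C"), (-14, "T"), (-13, "G"), (-12, "C")):
        put(pos, ch)
    return "".join(s)


def plant_sigma70_promoter(upstream_sequence: str, tu_start_offset: int = 0) -> str:
    """Write the sigma70 -35 "TTGACA" (at -35..-30) and -10 "TATAAT"
    (at -12..-7) elements into an upstream region.  Idempotent."""
    n = len(upstream_sequence)
    if n < 40:
        raise ValueError("upstream region too short for a sigma70 promoter (< 40 nt)")
    s = list(upstream_sequence)
    for start, word in ((-35, "TTGACA"), (-12, "TATAAT")):
        for k, ch in enumerate(word):
            i = n + start + k + tu_start_offset
            if i < 0 or i >= n:
                raise ValueError("promoter element outside the region")
            s[i] = ch
    return "".join(s)


# ---------------------------------------------------------------------------
# Truth bundle


@dataclass
class TruthOperon:
    genome_id: str
    replicon_id: str
    label: str
    strand: str
    gene_ids: tuple[str, ...]  # 5' -> 3'
    start: int
    end: int

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


@dataclass
class TruthSite:
    genome_id: str
    replicon_id: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str  # genomic strand the motif reads on
    motif_id: str
    operon_label: str
    letters: str  # motif-oriented letters


@dataclass
class TruthBundle:
    operons: list[TruthOperon] = field(default_factory=list)
    architectures: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    # protein_id -> (label, family, group)
    orthologs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    sites: list[TruthSite] = field(default_factory=list)
    colocalized_bebps: list[tuple[str, str]] = field(default_factory=list)
    # (bebp protein_id, divergent neighbour operon label)

    def operon_by_label(self, label: str) -> TruthOperon:
        for op in self.operons:
            if op.label == label:
                return op
        raise KeyError(label)

    def edge_truth(self) -> set[tuple[str, frozenset[str]]]:
        """Expected regulatory edges as (regulator id, target gene set)."""
        edges = {(s.motif_id, self.operon_by_label(s.operon_label).gene_set)
                 for s in self.sites}
        edges |= {(bebp, self.operon_by_label(lab).gene_set)
                  for bebp, lab in self.colocalized_bebps}
        return edges

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# section: operons\n")
            fh.write("genome\treplicon\tlabel\tstrand\tstart\tend\tgenes\n")
            for op in self.operons:
                fh.write("\t".join([op.genome_id, op.replicon_id, op.label,
                                    op.strand, str(op.start), str(op.end),
                                    ",".join(op.gene_ids)]) + "\n")
            fh.write("# section: architectures\n")
            fh.write("protein\tlabel\tfamily\tgroup\n")
            for pid in sorted(self.architectures):
                lab, fam, grp = self.architectures[pid]
                fh.write(f"{pid}\t{lab}\t{fam}\t{grp}\n")
            fh.write("# section: orthologs\n")
            fh.write("og_label\tmembers\n")
            for lab in sorted(self.orthologs):
                members = ";".join(f"{g}:{p}" for g, p in self.orthologs[lab])
                fh.write(f"{lab}\t{members}\n")
            fh.write("# section: sites\n")
            fh.write("genome\treplicon\tstart\tend\tstrand\tmotif\toperon\tletters\n")
            for s in self.sites:
                fh.write("\t".join([s.genome_id, s.replicon_id, str(s.start),
                                    str(s.end), s.strand, s.motif_id,
                                    s.operon_label, s.letters]) + "\n")
            fh.write("# section: colocalized_bebps\n")
            fh.write("protein\toperon\n")
            for pid, lab in self.colocalized_bebps:
                fh.write(f"{pid}\t{lab}\n")


@dataclass
class GenomeData:
    genome_id: str
    replicon: SequenceRecord
    genes: list[GeneRecord]
    proteins: list[SequenceRecord]


@dataclass
class SyntheticGenomeSet:
    config: SimulationConfig
    genomes: dict[str, GenomeData]
    domain_hits: list[DomainHit]
    similarity_hits: list[SimilarityHit]
    truth: TruthBundle

    @property
    def genome_map(self) -> dict[str, str]:
        return {p.id: g.genome_id for g in self.genomes.values() for p in g.proteins}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for gid, g in self.genomes.items():
            write_fasta([g.replicon], outdir / f"{gid}.fna")
            write_gff3(g.genes, outdir / f"{gid}.gff3")
            write_fasta(g.proteins, outdir / f"{gid}.faa")
            paths[f"{gid}.fna"] = outdir / f"{gid}.fna"
            paths[f"{gid}.gff3"] = outdir / f"{gid}.gff3"
            paths[f"{gid}.faa"] = outdir / f"{gid}.faa"
        write_domain_table(self.domain_hits, outdir / "domains.tsv")
        write_similarity_table(self.similarity_hits, outdir / "similarity.tsv")
        with open(outdir / "genome_map.tsv", "w") as fh:
            for pid, gid in sorted(self.genome_map.items()):
                fh.write(f"{pid}\t{gid}\n")
        self.truth.write(outdir / "truth.tsv")
        paths.update({
            "domains.tsv": outdir / "domains.tsv",
            "similarity.tsv": outdir / "similarity.tsv",
            "genome_map.tsv": outdir / "genome_map.tsv",
            "truth.tsv": outdir / "truth.tsv",
        })
        return paths


# ---------------------------------------------------------------------------
# Generator


def _make_background(config: SimulationConfig) -> MarkovBackground:
    if config.background is not None:
        return config.background
    if config.background_order == 0:
        return MarkovBackground.uniform(0)
    # mildly biased conditionals emulate compositional structure
    rng = np.random.default_rng([config.seed, 97])
    bg = MarkovBackground.uniform(config.background_order)
    probs = {ctx: rng.dirichlet(np.full(4, 8.0)) for ctx in bg.probs}
    return MarkovBackground(order=config.background_order, probs=probs)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=max(length, 50)))


def generate_genome_set(config: SimulationConfig) -> SyntheticGenomeSet:
    """Generate genomes, annotations, domain/similarity tables and truth.

    Deterministic given ``config.seed``: the same config yields byte-identical
    files from :meth:`SyntheticGenomeSet.write`.
    """
    background = _make_background(config)
    truth = TruthBundle()
    genomes: dict[str, GenomeData] = {}
    domain_hits: list[DomainHit] = []
    gmin, gmax = config.genes_per_operon
    lmin, lmax = config.gene_length
    imin, imax = config.intra_operon_gap
    omin, omax = config.inter_operon_gap

    # expand architecture placements: one operon per (entry, copy)
    placements: list[tuple[PlantedArchitecture, int]] = []
    for arch in config.planted_architectures:
        for copy in range(arch.copies):
            placements.append((arch, copy))
    if len(placements) > config.n_operons_per_genome:
        raise ValueError("more planted architecture copies than operons")

    for gi in range(config.n_genomes):
        gid = f"g{gi + 1}"
        replicon_id = f"{gid}_chr"
        rng = np.random.default_rng([config.seed, gi])
        # --- operon layout
        cursor = int(rng.integers(omin, omax + 1)) + config.upstream_max
        operon_genes: list[list[GeneRecord]] = []
        gene_count = 0
        for oi in range(config.n_operons_per_genome):
            strand = "+" if oi % 2 == 0 else "-"
            n_genes = int(rng.integers(gmin, gmax + 1))
            genes = []
            for j in range(n_genes):
                length = int(rng.integers(lmin, lmax + 1))
                start = cursor
                end = start + length - 1
                gene_count += 1
                genes.append(GeneRecord(
                    gene_id=f"{gid}_{gene_count:05d}", replicon_id=replicon_id,
                    start=start, end=end, strand=strand))
                if j < n_genes - 1:
                    gap = int(rng.integers(imin, imax + 1))
                else:
                    gap = int(rng.integers(omin, omax + 1))
                cursor = end + gap + 1
            operon_genes.append(genes)
        total_len = cursor + config.upstream_max
        seq = bytearray(sample_background_sequence(background, total_len, rng),
                        "ascii")

        all_genes = [g for op in operon_genes for g in op]
        gene_starts = [g.start for g in all_genes]
        gene_ends = [g.end for g in all_genes]

        # operon truth (gene ids 5'->3')
        operon_labels = []
        for oi, genes in enumerate(operon_genes):
            ordered = genes if genes[0].strand == "+" else list(reversed(genes))
            label = f"{gid}:op{oi + 1:03d}"
            operon_labels.append(label)
            truth.operons.append(TruthOperon(
                genome_id=gid, replicon_id=replicon_id, label=label,
                strand=genes[0].strand,
                gene_ids=tuple(g.gene_id for g in ordered),
                start=genes[0].start, end=genes[-1].end))

        # --- planted architectures: entry k occupies operon k's leading genes
        arch_by_gene: dict[str, tuple[PlantedArchitecture, str]] = {}
        for k, (arch, copy) in enumerate(placements):
            genes = operon_genes[k]
            chain = (arch,) + arch.cotranscribed
            if len(chain) > len(genes):
                raise ValueError(
                    f"operon {k} has {len(genes)} genes but architecture "
                    f"{arch.label} needs {len(chain)} cotranscribed slots")
            base = arch.label if arch.copies == 1 else f"{arch.label}_{copy + 1}"
            ordered = genes if genes[0].strand == "+" else list(reversed(genes))
            for slot, member in enumerate(chain):
                og_label = base if slot == 0 else f"{base}~{member.label}"
                arch_by_gene[ordered[slot].gene_id] = (member, og_label)

        proteins: list[SequenceRecord] = []
        for g in all_genes:
            prot = SequenceRecord(g.gene_id, _random_protein(rng, g.length // 3))
            proteins.append(prot)
            if g.gene_id in arch_by_gene:
                member, og_label = arch_by_gene[g.gene_id]
                truth.architectures[g.gene_id] = (
                    member.label, member.truth_family, member.truth_group)
                truth.orthologs.setdefault(og_label, []).append((gid, g.gene_id))
                ali = 10
                for di, (acc, name) in enumerate(member.domains):
                    domain_hits.append(DomainHit(
                        protein_id=g.gene_id, pfam_acc=f"{acc}.27",
                        pfam_name=name, ali_start=ali, ali_end=ali + 59,
                        bitscore=200.0 - 10.0 * di, evalue=1e-30))
                    ali += 80

        # decoy domains on unplanted proteins
        unplanted = [g.gene_id for g in all_genes if g.gene_id not in arch_by_gene]
        decoys = rng.choice(len(unplanted),
                            size=min(config.n_decoy_domains, len(unplanted)),
                            replace=False)
        for di in sorted(int(x) for x in decoys):
            pid = unplanted[di]
            acc, name = PF["Plug"]
            domain_hits.append(DomainHit(
                protein_id=pid, pfam_acc=acc, pfam_name=name,
                ali_start=5, ali_end=64, bitscore=80.0, evalue=1e-8))
            truth.architectures.setdefault(pid, ("Decoy", "none", "unclassified"))

        # --- planted binding sites in upstream regions of target operons
        occupied: list[tuple[int, int]] = []
        for pm in config.planted_motifs:
            n_targets = min(pm.n_targets, config.n_operons_per_genome)
            targets = sorted(int(t) for t in rng.choice(
                config.n_operons_per_genome, size=n_targets, replace=False))
            for oi in targets:
                if rng.random() >= pm.gamma:
                    continue
                genes = operon_genes[oi]
                strand = genes[0].strand
                if strand == "+":
                    leader_start = genes[0].start
                    prev_end = max([e for e in gene_ends if e < leader_start],
                                   default=0)
                    win_lo = max(prev_end + 1, leader_start - config.upstream_max)
                    win_hi = leader_start - 1
                else:
                    leader_end = genes[-1].end
                    next_start = min([s for s in gene_starts if s > leader_end],
                                     default=total_len + 1)
                    win_lo = leader_end + 1
                    win_hi = min(next_start - 1, leader_end + config.upstream_max)
                width = pm.pwm.width
                if win_hi - win_lo + 1 < width:
                    continue
                placed = False
                for _attempt in range(30):
                    gs = int(rng.integers(win_lo, win_hi - width + 2))
                    ge = gs + width - 1
                    if any(gs <= e and ge >= s for s, e in occupied):
                        continue
                    placed = True
                    break
                if not placed:
                    continue
                occupied.append((gs, ge))
                letters = "".join(ALPHABET[int(rng.choice(4, p=col))]
                                  for col in pm.pwm.matrix)
                gstrand = "+" if rng.random() < 0.5 else "-"
                genomic = letters if gstrand == "+" else reverse_complement(letters)
                seq[gs - 1:ge] = genomic.encode("ascii")
                truth.sites.append(TruthSite(
                    genome_id=gid, replicon_id=replicon_id, start=gs, end=ge,
                    strand=gstrand, motif_id=pm.motif_id,
                    operon_label=operon_labels[oi], letters=letters))

        # --- colocalization truth: planted bEBPs with a divergent neighbour
        for oi, genes in enumerate(operon_genes):
            ordered = genes if genes[0].strand == "+" else list(reversed(genes))
            for g in ordered:
                entry = arch_by_gene.get(g.gene_id)
                if entry is None or entry[0].truth_family != "bEBP":
                    continue
                # divergent neighbour: previous operon on "-" when ours is "+",
                # next operon on "+" when ours is "-", within 300 bp
                if genes[0].strand == "+" and oi > 0:
                    prev = operon_genes[oi - 1]
                    if prev[0].strand == "-" and \
                            genes[0].start - prev[-1].end - 1 <= 300:
                        truth.colocalized_bebps.append(
                            (g.gene_id, operon_labels[oi - 1]))
                if genes[0].strand == "-" and oi + 1 < len(operon_genes):
                    nxt = operon_genes[oi + 1]
                    if nxt[0].strand == "+" and \
                            nxt[0].start - genes[-1].end - 1 <= 300:
                        truth.colocalized_bebps.append(
                            (g.gene_id, operon_labels[oi + 1]))

        genomes[gid] = GenomeData(
            genome_id=gid,
            replicon=SequenceRecord(replicon_id, seq.decode("ascii")),
            genes=all_genes, proteins=proteins)

    # --- similarity table from planted orthology truth
    sim_hits: list[SimilarityHit] = []
    for og_label in sorted(truth.orthologs):
        members = truth.orthologs[og_label]
        for ga, pa in members:
            for gb, pb in members:
                if ga == gb:
                    continue
                sim_hits.append(SimilarityHit(
                    query_id=pa, subject_id=pb, pct_identity=90.0,
                    evalue=1e-50, bitscore=500.0, query_coverage=100.0))
    # sub-threshold noise hits
    rng = np.random.default_rng([config.seed, 10_007])
    all_proteins = sorted(p.id for g in genomes.values() for p in g.proteins)
    ortho_pairs = {(h.query_id, h.subject_id) for h in sim_hits}
    for _ in range(config.n_noise_similarity_hits):
        qi, si = rng.choice(len(all_proteins), size=2, replace=False)
        q, s = all_proteins[int(qi)], all_proteins[int(si)]
        if (q, s) in ortho_pairs:
            continue
        sim_hits.append(SimilarityHit(
            query_id=q, subject_id=s, pct_identity=35.0,
            evalue=1e-3, bitscore=45.0, query_coverage=50.0))

    return SyntheticGenomeSet(config=config, genomes=genomes,
                              domain_hits=domain_hits,
                              similarity_hits=sim_hits, truth=truth)


# ---------------------------------------------------------------------------
# Convenience generators used by tests and the acceptance run


def generate_planted_architectures(n: int, seed: int
                                   ) -> tuple[list[DomainHit], dict[str, tuple[str, str]]]:
    """n proteins cycling through the standard architecture set.

    Returns domain hits plus truth ``protein_id -> (family, group)``.
    """
    archs = list(standard_architectures().values())
    rng = np.random.default_rng(seed)
    hits: list[DomainHit] = []
    tr: dict[str, tuple[str, str]] = {}
    for i in range(n):
        arch = archs[i % len(archs)]
        pid = f"p{i + 1:04d}"
        tr[pid] = (arch.truth_family, arch.truth_group)
        ali = 10
        for di, (acc, name) in enumerate(arch.domains):
            hits.append(DomainHit(
                protein_id=pid, pfam_acc=f"{acc}.{int(rng.integers(1, 40))}",
                pfam_name=name, ali_start=ali, ali_end=ali + 59,
                bitscore=float(150 + rng.integers(0, 50)), evalue=1e-25))
            ali += 80
    return hits, tr


def reference_simulation(seed: int) -> SimulationConfig:
    """The reference study conditions for end-to-end recovery: 3 genomes of
    40 operons each, two planted 12-wide regulator motifs (NtrC- and
    TspR-style, ~1.6 bits/column) at occupancy 0.9, plus planted sigma and
    TCS architectures including a one-component HupR-style bEBP."""
    archs = standard_architectures()
    hks = archs["HKS"]
    ntrc = _arch("NtrC", ["Response_reg", "Sigma_54_activat", "HTH_8"],
                 "bEBP", "bEBP", cotranscribed=(hks,))
    tspr = _arch("TspR", ["Response_reg", "Sigma_54_activat", "HTH_8"],
                 "bEBP", "bEBP", cotranscribed=(hks,))
    hupr = _arch("HupR", ["Response_reg", "Sigma_54_activat", "HTH_8"],
                 "bEBP", "bEBP")
    # HupR sits between sigma-factor operons so no foreign kinase is within
    # the one-flanking-TU pairing window (the one-component layout)
    planted = (archs["RpoN"], hupr, archs["RpoD"], archs["RpoE"],
               ntrc, tspr, archs["FliA"])
    motifs = (
        PlantedMotif("NtrC_site", consensus_pwm("TGCACCATTGGT", p=0.94,
                                                motif_id="NtrC_site"),
                     gamma=0.9, n_targets=15, regulator_label="NtrC"),
        PlantedMotif("TspR_site", consensus_pwm("CACGTTAAGCGT", p=0.94,
                                                motif_id="TspR_site"),
                     gamma=0.9, n_targets=15, regulator_label="TspR"),
    )
    return SimulationConfig(
        seed=seed, n_genomes=3, n_operons_per_genome=40,
        genes_per_operon=(2, 4),
        # gaps wide enough that divergent neighbours' upstream windows
        # (<= 300 nt each) never overlap: a planted site then belongs to
        # exactly one transcriptional unit
        inter_operon_gap=(650, 900),
        planted_architectures=planted,
        planted_motifs=motifs)
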