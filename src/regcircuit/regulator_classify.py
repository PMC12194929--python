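"""Sigma-factor classification by Pfam domain architecture, and detection of
sigma54-dependent enhancer-binding proteins (bEBPs) and histidine-kinase
sensors (HKS), including their pairing into one-/two-component systems.

The sigma-factor rule cascade (first match wins):

1. all of Sigma54_AID (PF00309), Sigma54_CBD (PF04963), Sigma54_DBD
   (PF04552) -> sigma54 / RpoN;
2. Sigma70_r1_2 (PF00140) and Sigma70_r3 (PF04539) -> sigma70 groups 1-2
   (RpoD/RpoS/RpoH; sub-labels need orthology to references, not
   architecture);
3. Sigma70_r3 alone (no r1_2, r2 or r4_2) -> group 3, FliA-like;
4. Sigma70_r2 and Sigma70_r4_2 without r1_2/r3 -> group 4, RpoE-like;
5. any single remaining Sigma70-region domain -> sigma70-like;
6. otherwise unclassified.

bEBPs carry both the sigma54 activator (PF00158) and the response-regulator
receiver (PF00072) domain; HKS sensors carry HisKA (PF00512) plus the
catalytic HATPase_c domain.  Accessory sensory domains (PAS, HAMP, cache)
never block a call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit, GeneRecord
from .tu_infer import TranscriptionalUnit

logger = logging.getLogger(__name__)

SIGMA54_CORE = {"PF00309", "PF04963", "PF04552"}
SIGMA70_R1_2 = "PF00140"
SIGMA70_R3 = "PF04539"
SIGMA70_R2 = "PF04542"
SIGMA70_R4_2 = "PF08281"
BEBP_ACTIVATOR = "PF00158"
RESPONSE_REGULATOR = "PF00072"
HISKA = "PF00512"
HATPASE_C = "PF02518"

# accession -> canonical name, for tables that omit names
_KNOWN_NAMES = {
    "PF00309": "Sigma54_AID", "PF04963": "Sigma54_CBD", "PF04552": "Sigma54_DBD",
    "PF00140": "Sigma70_r1_2", "PF04539": "Sigma70_r3", "PF04542": "Sigma70_r2",
    "PF08281": "Sigma70_r4_2", "PF04545": "Sigma70_r4",
    "PF00158": "Sigma_54_activat", "PF00072": "Response_reg",
    "PF00512": "HisKA", "PF02518": "HATPase_c",
}


@dataclass
class DomainArchitecture:
    protein_id: str
    domains: tuple[tuple[str, str], ...]  # (pfam_acc, pfam_name), by ali_start

    @property
    def accessions(self) -> set[str]:
        return {acc for acc, _ in self.domains}

    def names(self) -> set[str]:
        out = set()
        for acc, name in self.domains:
            out.add(name or _KNOWN_NAMES.get(acc, ""))
        return out - {""}


@dataclass
class RegulatorCall:
    protein_id: str
    family: str  # sigma54 | sigma70 | bEBP | HKS | none
    group_label: str
    hybrid_kinase: bool = False

    def __post_init__(self) -> None:
        if (self.family == "none") != (self.group_label == "unclassified"):
            raise ValueError(
                f"{self.protein_id}: family none <=> group unclassified")


@dataclass
class TCSPair:
    bebp_id: str
    hks_id: str | None
    tu_id: str
    mode: str  # two_component | one_component

    def __post_init__(self) -> None:
        if (self.mode == "one_component") != (self.hks_id is None):
            raise ValueError("one_component <=> no HKS partner")


def resolve_domain_overlaps(hits: Sequence[DomainHit]) -> DomainArchitecture:
    """Greedy per-protein overlap resolution.

    Hits are taken in descending bitscore (ties: lower ali_start, then
    accession); a hit is kept iff it overlaps no kept hit by more than 50%
    of the shorter interval.  The result is ordered by ali_start.
    """
    if not hits:
        raise ValueError("resolve_domain_overlaps needs at least one hit")
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) != 1:
        raise ValueError(f"hits span several proteins: {sorted(protein_ids)}")
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.ali_start, h.pfam_acc))
    kept: list[DomainHit] = []
    for h in ranked:
        ok = True
        for k in kept:
            overlap = min(h.ali_end, k.ali_end) - max(h.ali_start, k.ali_start) + 1
            if overlap > 0.5 * min(h.length, k.length):
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.ali_start, h.pfam_acc))
    return DomainArchitecture(
        protein_id=hits[0].protein_id,
        domains=tuple((h.pfam_acc, h.pfam_name) for h in kept))


def build_architectures(hits: Iterable[DomainHit]) -> dict[str, DomainArchitecture]:
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return {pid: resolve_domain_overlaps(hl) for pid, hl in sorted(by_protein.items())}


def _sigma70_region_domains(arch: DomainArchitecture) -> set[str]:
    """Sigma70 region domains, matched by pinned accession or name prefix."""
    out = set()
    for acc, name in arch.domains:
        canonical = name or _KNOWN_NAMES.get(acc, "")
        if canonical.startswith("Sigma70_") or acc in {
                SIGMA70_R1_2, SIGMA70_R3, SIGMA70_R2, SIGMA70_R4_2}:
            out.add(acc)
    return out


def classify_sigma_factor(arch: DomainArchitecture) -> RegulatorCall:
    """Apply the sigma-factor rule cascade; total and deterministic."""
    accs = arch.accessions
    names = arch.names()
    if SIGMA54_CORE <= accs or {"Sigma54_AID", "Sigma54_CBD", "Sigma54_DBD"} <= names:
        return RegulatorCall(arch.protein_id, "sigma54", "RpoN")
    has = lambda acc, name: acc in accs or name in names
    r1_2 = has(SIGMA70_R1_2, "Sigma70_r1_2")
    r3 = has(SIGMA70_R3, "Sigma70_r3")
    r2 = has(SIGMA70_R2, "Sigma70_r2")
    r4_2 = has(SIGMA70_R4_2, "Sigma70_r4_2")
    if r1_2 and r3:
        return RegulatorCall(arch.protein_id, "sigma70", "group1_2")
    if r3 and not r1_2 and not r2 and not r4_2:
        return RegulatorCall(arch.protein_id, "sigma70", "group3_FliA-like")
    if r2 and r4_2 and not r1_2 and not r3:
        return RegulatorCall(arch.protein_id, "sigma70", "group4_RpoE-like")
    if _sigma70_region_domains(arch) or any(n.startswith("Sigma70_") for n in names):
        return RegulatorCall(arch.protein_id, "sigma70", "sigma70_like")
    return RegulatorCall(arch.protein_id, "none", "unclassified")


def detect_bebp(arch: DomainArchitecture) -> bool:
    """bEBP: sigma54 activator (PF00158) plus response regulator (PF00072)."""
    return {BEBP_ACTIVATOR, RESPONSE_REGULATOR} <= arch.accessions


def detect_hks(arch: DomainArchitecture) -> bool:
    """HKS: HisKA phosphoacceptor (PF00512) plus an HATPase_c catalytic
    domain; accessory domains are allowed."""
    accs = arch.accessions
    names = arch.names()
    has_hiska = HISKA in accs or "HisKA" in names
    has_atpase = HATPASE_C in accs or "HATPase_c" in names
    return has_hiska and has_atpase


def classify_regulator(arch: DomainArchitecture) -> RegulatorCall:
    """One call per protein.

    Precedence: defined sigma-factor groups, then bEBP, then HKS, then the
    generic sigma70-like fallback.  Hybrid sensors carrying all four
    bEBP+HKS domains are reported as bEBP with ``hybrid_kinase=True`` and a
    warning rather than forced into one class.
    """
    sigma = classify_sigma_factor(arch)
    if sigma.family == "sigma54" or (
            sigma.family == "sigma70" and sigma.group_label != "sigma70_like"):
        return sigma
    is_bebp = detect_bebp(arch)
    is_hks = detect_hks(arch)
    if is_bebp and is_hks:
        logger.warning("protein %s carries bEBP and HKS domains (hybrid kinase)",
                       arch.protein_id)
        return RegulatorCall(arch.protein_id, "bEBP", "bEBP", hybrid_kinase=True)
    if is_bebp:
        return RegulatorCall(arch.protein_id, "bEBP", "bEBP")
    if is_hks:
        return RegulatorCall(arch.protein_id, "HKS", "HKS")
    if sigma.family == "sigma70":
        return sigma
    return RegulatorCall(arch.protein_id, "none", "unclassified")


def classify_regulators(architectures: Mapping[str, DomainArchitecture]
                        ) -> list[RegulatorCall]:
    return [classify_regulator(architectures[p]) for p in sorted(architectures)]


def pair_tcs(bebps: Sequence[str], hks_list: Sequence[str],
             tus: Sequence[TranscriptionalUnit],
             genes: Mapping[str, GeneRecord],
             window_tus: int = 1) -> list[TCSPair]:
    """Pair each bEBP with its cognate HKS by genomic proximity.

    The search covers the bEBP's own transcriptional unit plus
    ``window_tus`` flanking units on each side (tandem or divergent).  The
    nearest HKS by gene distance wins; ties go to the downstream neighbour
    (relative to the bEBP gene's strand).  A bEBP with no HKS in the window
    is a one-component regulator.
    """
    hks_set = set(hks_list)
    tu_of_gene: dict[str, TranscriptionalUnit] = {}
    tus_by_replicon: dict[str, list[TranscriptionalUnit]] = {}
    for tu in tus:
        tus_by_replicon.setdefault(tu.replicon_id, []).append(tu)
        for gid in tu.gene_ids:
            tu_of_gene[gid] = tu
    for lst in tus_by_replicon.values():
        lst.sort(key=lambda t: min(genes[g].start for g in t.gene_ids))

    pairs: list[TCSPair] = []
    for bebp in sorted(bebps):
        if bebp not in tu_of_gene:
            raise ValueError(f"bEBP gene {bebp!r} absent from the TU map")
        tu = tu_of_gene[bebp]
        siblings = tus_by_replicon[tu.replicon_id]
        i = siblings.index(tu)
        window = siblings[max(0, i - window_tus): i + window_tus + 1]
        bgene = genes[bebp]

        def distance(hks_gid: str) -> int:
            h = genes[hks_gid]
            if h.start > bgene.end:
                return h.start - bgene.end
            if h.end < bgene.start:
                return bgene.start - h.end
            return 0

        def downstream(hks_gid: str) -> int:
            h = genes[hks_gid]
            if bgene.strand == "+":
                return 0 if h.start > bgene.end else 1
            return 0 if h.end < bgene.start else 1

        candidates = [g for t in window for g in t.gene_ids
                      if g in hks_set and g != bebp]
        if candidates:
            best = min(candidates, key=lambda g: (distance(g), downstream(g), g))
            pairs.append(TCSPair(bebp, best, tu.tu_id, "two_component"))
        else:
            pairs.append(TCSPair(bebp, None, tu.tu_id, "one_component"))
    return pairs


def write_calls(calls: Sequence[RegulatorCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily\tgroup_label\thybrid_kinase\n")
        for c in calls:
            fh.write(f"{c.protein_id}\t{c.family}\t{c.group_label}"
                     f"\t{int(c.hybrid_kinase)}\n")


def write_tcs_pairs(pairs: Sequence[TCSPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("bebp_id\thks_id\ttu_id\tmode\n")
        for p in pairs:
            fh.write(f"{p.bebp_id}\t{p.hks_id or ''}\t{p.tu_id}\t{p.mode}\n")
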