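import numpy as np
import pytest

from regcircuit.circuit import (GenomeInput, PipelineConfig, PipelineError,
                                assemble_network, call_promoter,
                                collapse_edges_by_og, run_pipeline,
                                sigma54_promoter_pwm, sigma70_promoter_pwm)
from regcircuit.io_formats import GeneRecord, write_meme_motifs
from regcircuit.motif import MarkovBackground, SiteHit, sample_background_sequence
from regcircuit.regulator_classify import RegulatorCall
from regcircuit.synthetic_data import (PlantedMotif, SimulationConfig,
                                       consensus_pwm, generate_genome_set,
                                       plant_sigma54_promoter,
                                       plant_sigma70_promoter,
                                       standard_architectures)
from regcircuit.tu_infer import TranscriptionalUnit, infer_tus


def tu(tu_id, genes, strand="+"):
    return TranscriptionalUnit(tu_id, "chr", strand, tuple(genes), genes[0])


class TestAssembleNetwork:
    def test_site_hits_become_edges_with_best_p(self):
        tus = [tu("T1", ["a"]), tu("T2", ["b"])]
        hits = [SiteHit("T1", 5, 16, "+", 12.0, 1e-6, "m1"),
                SiteHit("T1", 40, 51, "+", 10.0, 1e-5, "m1"),
                SiteHit("T2", 8, 19, "-", 11.0, 2e-6, "m1")]
        edges = assemble_network([], [], hits, tus)
        assert len(edges) == 2
        t1 = next(e for e in edges if e.target_tu_id == "T1")
        assert t1.evidence == "site_hit" and t1.best_site_pvalue == 1e-6

    def test_unknown_tu_errors(self):
        with pytest.raises(ValueError, match="unknown TU"):
            assemble_network([], [], [SiteHit("zz", 1, 12, "+", 1.0, 1e-5, "m")],
                             [tu("T1", ["a"])])

    def divergent_layout(self):
        genes = {"a": GeneRecord("a", "chr", 1000, 2000, "-"),
                 "b": GeneRecord("b", "chr", 2101, 3000, "+")}
        tus_ = infer_tus(sorted(genes.values(), key=lambda g: g.start))
        return genes, tus_

    def test_divergent_bebp_colocalization_edge(self):
        genes, tus_ = self.divergent_layout()
        calls = [RegulatorCall("a", "bEBP", "bEBP")]
        edges = assemble_network(calls, [], [], tus_, genes)
        assert len(edges) == 1
        e = edges[0]
        assert e.regulator_id == "a" and e.evidence == "colocalization"
        assert e.target_tu_id == next(t.tu_id for t in tus_ if "b" in t.gene_ids)

    def test_colocalization_respects_distance_cap(self):
        genes = {"a": GeneRecord("a", "chr", 1000, 2000, "-"),
                 "b": GeneRecord("b", "chr", 2700, 3600, "+")}
        tus_ = infer_tus(sorted(genes.values(), key=lambda g: g.start))
        calls = [RegulatorCall("a", "bEBP", "bEBP")]
        assert assemble_network(calls, [], [], tus_, genes) == []

    def test_both_evidence_kinds_merge(self):
        genes, tus_ = self.divergent_layout()
        target = next(t.tu_id for t in tus_ if "b" in t.gene_ids)
        calls = [RegulatorCall("a", "bEBP", "bEBP")]
        hits = [SiteHit(target, 3, 14, "+", 9.0, 1e-5, "a")]
        edges = assemble_network(calls, [], hits, tus_, genes)
        assert len(edges) == 1 and edges[0].evidence == "both"

    def test_empty_inputs_empty_network(self):
        assert assemble_network([], [], [], [tu("T1", ["a"])]) == []

    def test_og_collapse(self):
        tus_ = [tu("T1", ["a"]), tu("T2", ["b"])]
        hits = [SiteHit("T1", 1, 12, "+", 9.0, 1e-5, "p1"),
                SiteHit("T1", 30, 41, "+", 8.0, 1e-6, "p2")]
        edges = assemble_network([], [], hits, tus_)
        merged = collapse_edges_by_og(edges, {"p1": "NtrC", "p2": "NtrC"})
        assert len(merged) == 1
        assert merged[0].regulator_id == "NtrC"
        assert merged[0].best_site_pvalue == 1e-6


class TestCallPromoter:
    def setup_method(self):
        self.bg = MarkovBackground.uniform(0)
        self.up = sample_background_sequence(self.bg, 120, seed=9)
        self.s54 = sigma54_promoter_pwm()
        self.s70 = [sigma70_promoter_pwm()]

    def make_tu(self, upstream):
        return TranscriptionalUnit("T", "chr", "+", ("g",), "g",
                                   upstream_sequence=upstream)

    def test_sigma54_round_trip(self):
        call = call_promoter(self.make_tu(plant_sigma54_promoter(self.up)),
                             self.s54, self.s70, self.bg)
        assert call.promoter_class == "sigma54_like"

    def test_sigma70_round_trip(self):
        call = call_promoter(self.make_tu(plant_sigma70_promoter(self.up)),
                             self.s54, self.s70, self.bg)
        assert call.promoter_class == "sigma70_like"

    def test_scrambled_upstream_none(self):
        call = call_promoter(self.make_tu(self.up), self.s54, self.s70,
                             self.bg, p_max=1e-4)
        assert call.promoter_class == "none"

    def test_missing_upstream_none(self):
        call = call_promoter(self.make_tu(None), self.s54, self.s70, self.bg)
        assert call.promoter_class == "none"


class TestPipeline:
    @pytest.fixture()
    def bundle_dir(self, tmp_path):
        archs = standard_architectures()
        cfg = SimulationConfig(
            seed=55, n_genomes=2, n_operons_per_genome=8,
            planted_architectures=(archs["RpoN"], archs["bEBP"]),
            planted_motifs=(PlantedMotif(
                "m1", consensus_pwm("TGCACCATTGGT", motif_id="m1"),
                gamma=1.0, n_targets=3),),
            inter_operon_gap=(650, 900))
        gs = generate_genome_set(cfg)
        gs.write(tmp_path)
        write_meme_motifs([pm.pwm for pm in cfg.planted_motifs],
                          MarkovBackground.uniform(0), tmp_path / "m.meme")
        return tmp_path, gs

    def make_config(self, d, gs, outname="out", **kw):
        return PipelineConfig(
            genomes=[GenomeInput(g, d / f"{g}.fna", d / f"{g}.gff3")
                     for g in gs.genomes],
            domain_table=d / "domains.tsv",
            similarity_table=d / "similarity.tsv",
            genome_map=d / "genome_map.tsv",
            outdir=d / outname, motifs_meme=d / "m.meme",
            seed=1, background_order=0, **kw)

    def test_manifest_lists_completed_stages(self, bundle_dir):
        d, gs = bundle_dir
        res = run_pipeline(self.make_config(d, gs))
        assert res.manifest["stages"] == \
            ["orthology", "classify", "tus", "tcs", "scan", "network"]
        assert (d / "out" / "edges.tsv").exists()
        assert (d / "out" / "manifest.json").exists()

    def test_no_dangling_references(self, bundle_dir):
        d, gs = bundle_dir
        res = run_pipeline(self.make_config(d, gs))
        tu_ids = {t.tu_id for t in res.tus}
        motif_ids = {"m1"}
        regulators = {c.protein_id for c in res.calls} | motif_ids
        for e in res.edges:
            assert e.target_tu_id in tu_ids
            assert e.regulator_id in regulators

    def test_rerun_is_byte_identical(self, bundle_dir):
        d, gs = bundle_dir
        run_pipeline(self.make_config(d, gs, "o1"))
        run_pipeline(self.make_config(d, gs, "o2"))
        for name in ("edges.tsv", "tus.tsv", "sites.bed", "manifest.json"):
            assert (d / "o1" / name).read_bytes() == \
                (d / "o2" / name).read_bytes()

    def test_corrupt_gff_aborts_naming_tus_stage(self, bundle_dir):
        d, gs = bundle_dir
        bad = d / "g1.gff3"
        bad.write_text("chr\t.\tCDS\t9\t5\t.\t+\t0\tID=x\n")
        with pytest.raises(PipelineError, match="tus"):
            run_pipeline(self.make_config(d, gs, "o3"))
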