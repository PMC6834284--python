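"""Multi-granularity graph parsers, domain classification and the cascade."""

import pytest

from neep.mgg import (DDICatalog, DomainAssignment, GeneModel, MGGPath,
                      build_mgg, classify_domains, read_3did, read_biogrid,
                      read_domains, read_gene_model, read_mgg, write_mgg)
from neep.synthetic import simulate_interactome

BIOGRID_HEADER = ("#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
                  "Official Symbol Interactor B\tExperimental System Type\t"
                  "Organism ID Interactor A\tOrganism ID Interactor B\n")


class TestReadBiogrid:
    def _load(self, tmp_path, rows):
        p = tmp_path / "biogrid.tsv"
        p.write_text(BIOGRID_HEADER + "".join(rows))
        return read_biogrid(p)

    def test_physical_human_kept(self, tmp_path):
        inter = self._load(tmp_path, ["1\tA\tB\tphysical\t9606\t9606\n"])
        assert ("A", "B") in inter.edges

    def test_genetic_dropped(self, tmp_path):
        inter = self._load(tmp_path, ["1\tA\tB\tgenetic\t9606\t9606\n"])
        assert len(inter) == 0
        assert inter.report["n_physical"] == 0

    def test_non_human_dropped(self, tmp_path):
        inter = self._load(tmp_path, ["1\tA\tB\tphysical\t9606\t10090\n"])
        assert len(inter) == 0

    def test_unordered_dedup(self, tmp_path):
        inter = self._load(tmp_path, ["1\tA\tB\tphysical\t9606\t9606\n",
                                      "2\tB\tA\tphysical\t9606\t9606\n"])
        assert len(inter) == 1

    def test_missing_columns_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("geneA\tgeneB\nA\tB\n")
        with pytest.raises(ValueError, match="TAB2/TAB3"):
            read_biogrid(p)


class TestRead3did:
    def test_flat_file_symmetry(self, tmp_path):
        p = tmp_path / "3did.txt"
        p.write_text("#=ID\tfam1\tfam2\t(PF00001.12@Pfam\tPF00002.5@Pfam)\n"
                     "#=ID\tfam4\tfam4\t(PF00004.1@Pfam\tPF00004.1@Pfam)\n")
        ddi = read_3did(p)
        assert ("PF00001", "PF00002") in ddi
        assert ("PF00002", "PF00001") in ddi
        assert ("PF00004", "PF00004") in ddi

    def test_two_column_tsv_fallback_dedup(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("PF1\tPF2\nPF2\tPF1\nPF3\tPF3\n")
        ddi = read_3did(p)
        assert len(ddi) == 2

    def test_unparsable_errors(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("# nothing here\n")
        with pytest.raises(ValueError):
            read_3did(p)


DOMTBL_ROW = ("{acc}_dom {acc}.26 200 {tx} - 500 1e-40 100.0 0.1 1 1 "
              "1e-35 {ieval} 99.0 0.1 1 200 10 210 10 210 0.98 -\n")


class TestReadDomains:
    def test_domtblout_keeps_below_cutoff_and_strips_version(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text("# comment\n"
                     + DOMTBL_ROW.format(acc="PF00069", tx="T1", ieval="1e-30")
                     + DOMTBL_ROW.format(acc="PF00100", tx="T1", ieval="0.5"))
        dom = read_domains(p, e_value_cutoff=0.01)
        assert dom.get("T1") == {"PF00069"}
        assert dom.report["n_above_cutoff"] == 1

    def test_duplicate_hits_collapse(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBL_ROW.format(acc="PF00069", tx="T1", ieval="1e-30") * 2)
        assert dict(read_domains(p).domains) == {"T1": frozenset({"PF00069"})}

    def test_tsv_fallback(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("T1\tPF00069.2\nT2\tPF00100\n")
        dom = read_domains(p)
        assert dom.get("T1") == {"PF00069"} and dom.get("T2") == {"PF00100"}

    def test_malformed_row_skipped_with_warning(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBL_ROW.format(acc="PF00069", tx="T1", ieval="1e-30")
                     + "PFX_dom PF00200.1 200 T2 - 500 1e-40 100.0 0.1 1 1 "
                       "1e-35 not_a_number 99.0 0.1 1 200 10 210 10 210 0.98 -\n")
        with pytest.warns(UserWarning, match="malformed"):
            dom = read_domains(p)
        assert dom.report["n_malformed"] == 1


class TestClassifyDomains:
    dom = DomainAssignment({"V1": frozenset("AB"), "V2": frozenset("AC"),
                            "V3": frozenset({"A", "C", "D"})})

    def test_set_algebra(self):
        gained, ghost = classify_domains(["V1", "V2", "V3"], self.dom, "V1")
        assert gained == {"B"} and ghost == {"C", "D"}

    def test_identical_domain_sets_yield_nothing(self):
        dom = DomainAssignment({t: frozenset("AB") for t in ("V1", "V2")})
        gained, ghost = classify_domains(["V1", "V2"], dom, "V1")
        assert gained == ghost == frozenset()

    def test_single_isoform_gene_errors(self):
        with pytest.raises(ValueError, match="multiple"):
            classify_domains(["V1"], self.dom, "V1")

    def test_foreign_variant_errors(self):
        with pytest.raises(ValueError):
            classify_domains(["V2", "V3"], self.dom, "V1")

    def test_gained_and_ghost_disjoint(self):
        gained, ghost = classify_domains(["V1", "V2", "V3"], self.dom, "V2")
        assert not gained & ghost

    def test_multi_significant_classifies_against_insignificant_only(self):
        # V3 is itself significant, so only V2 defines the comparison set
        gained, ghost = classify_domains(["V1", "V2", "V3"], self.dom, "V1",
                                         significant={"V3"})
        assert gained == {"B"} and ghost == {"C"}


def _toy_universe(with_ddi=True):
    genes = GeneModel({"X": [("V1", True), ("V2", True)],
                       "Y": [("W1", True)]})
    # V1 (significant) lacks C which sibling V2 carries -> ghost C
    dom = DomainAssignment({"V1": frozenset("A"), "V2": frozenset("AC"),
                            "W1": frozenset("E")})
    from neep.mgg import Interactome
    inter = Interactome(frozenset({("X", "Y")}))
    ddi = DDICatalog([("C", "E")] if with_ddi else [("Q", "R")])
    return genes, dom, inter, ddi


class TestBuildMGG:
    def test_ghost_path_traced_through_cascade(self):
        genes, dom, inter, ddi = _toy_universe()
        paths, counts = build_mgg({"V1"}, genes, inter, dom, ddi)
        assert paths == [MGGPath("V1", "C", "ghost", "E", "W1", "Y")]
        assert paths[0].interpretation == "lost-interaction"
        assert counts["paths"] == 1

    def test_no_ddi_support_no_paths(self):
        genes, dom, inter, ddi = _toy_universe(with_ddi=False)
        paths, _ = build_mgg({"V1"}, genes, inter, dom, ddi)
        assert paths == []

    def test_self_domain_gained_path(self):
        from neep.mgg import Interactome
        genes = GeneModel({"X": [("V1", True), ("V2", True)],
                           "Y": [("W1", True)]})
        dom = DomainAssignment({"V1": frozenset("B"), "V2": frozenset(),
                                "W1": frozenset("B")})
        inter = Interactome(frozenset({("X", "Y")}))
        paths, _ = build_mgg({"V1"}, genes, inter, dom, DDICatalog([("B", "B")]))
        assert paths == [MGGPath("V1", "B", "gained", "B", "W1", "Y")]
        assert paths[0].interpretation == "gained-interaction"

    def test_insignificant_or_noncoding_left_variant_excluded(self):
        genes = GeneModel({"X": [("V1", False), ("V2", True)],
                           "Y": [("W1", True)]})
        _, dom, inter, ddi = _toy_universe()
        paths, _ = build_mgg({"V1"}, genes, inter, dom, ddi)
        assert paths == []  # significant but not protein-coding
        genes2, dom2, inter2, ddi2 = _toy_universe()
        paths2, _ = build_mgg(set(), genes2, inter2, dom2, ddi2)
        assert paths2 == []

    def test_cascade_counts_non_increasing(self):
        _, dom, inter, ddi = _toy_universe()
        genes = GeneModel({"X": [("V1", True), ("V2", True)],
                           "Y": [("W1", True)]})
        _, counts = build_mgg({"V1"}, genes, inter, dom, ddi)
        staged = [counts["ddi_supported_pairs"], counts["gained_or_ghost_pairs"],
                  counts["multi_isoform_pairs"]]
        assert staged == sorted(staged, reverse=True)

    def test_empty_interactome_warns_and_returns_nothing(self):
        from neep.mgg import Interactome
        genes, dom, _, ddi = _toy_universe()
        with pytest.warns(UserWarning, match="empty interactome"):
            paths, _ = build_mgg({"V1"}, genes, Interactome(frozenset()),
                                 dom, ddi)
        assert paths == []

    def test_synthetic_truth_recovered_exactly(self):
        gm, dom, inter, ddi, truth = simulate_interactome(
            n_planted_paths=5, seed=11)
        paths, counts = build_mgg(truth.significant_variants, gm, inter,
                                  dom, ddi)
        assert set(paths) == truth.expected_paths
        pair_stages = [counts["variant_pairs"], counts["left_significant_coding"],
                       counts["ddi_supported_pairs"],
                       counts["gained_or_ghost_pairs"],
                       counts["multi_isoform_pairs"]]
        assert pair_stages == sorted(pair_stages, reverse=True)


class TestWriteMGG:
    def test_empty_list_header_only(self, tmp_path):
        write_mgg([], tmp_path / "m.tsv")
        assert (tmp_path / "m.tsv").read_text().count("\n") == 1

    def test_round_trip_and_dedup(self, tmp_path):
        p = MGGPath("V1", "C", "ghost", "E", "W1", "Y")
        write_mgg([p, p], tmp_path / "m.tsv")
        assert read_mgg(tmp_path / "m.tsv") == [p]

    def test_graphml_export(self, tmp_path):
        import networkx as nx
        p = MGGPath("V1", "C", "ghost", "E", "W1", "Y")
        write_mgg([p], tmp_path / "m.tsv", graphml=tmp_path / "m.graphml")
        g = nx.read_graphml(tmp_path / "m.graphml")
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3


class TestGeneModelIO:
    def test_round_trip(self, tmp_path):
        from neep.synthetic import write_gene_model
        gm = GeneModel({"G1": [("T1", True), ("T2", False)]})
        write_gene_model(gm, tmp_path / "g.tsv")
        back = read_gene_model(tmp_path / "g.tsv")
        assert back.genes == gm.genes

    def test_duplicate_transcript_across_genes_rejected(self):
        with pytest.raises(ValueError):
            GeneModel({"G1": [("T1", True)], "G2": [("T1", True)]})
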