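"""Co-occurrence statistics, network export and tree annotation."""

import math

import numpy as np
import pytest

from helpers_oracles import brute_force_edge_weights
from ringscan.annotator import build_conservation_profile
from ringscan.core_model import (
    Cas10Annotation,
    EffectorAnnotation,
    GeneFeature,
    Locus,
    RNAnnotation,
)
from ringscan.cooccurrence_stats import (
    background_frequency,
    build_network,
    phage_family_counts,
    restricted_association,
    summarize,
    tree_annotation,
)
from ringscan.pipeline import annotate_genomes
from ringscan.synthetic_data import SimConfig, generate_dataset


def _gene(gene_id, genome="G1", length=100, start=1000):
    return GeneFeature(gene_id, genome, "c1", start, start + 3 * length - 1, "+", "M" * length)


def _locus(locus_id, genome="G1", rn_fams=(), eff_fams=(), subtype="III-A", cyclase=True, rn_status="pass"):
    anchor = _gene(f"{locus_id}_cas10", genome, 700, 10_000)
    loc = Locus(
        locus_id=locus_id,
        genome_id=genome,
        contig_id="c1",
        cas10=Cas10Annotation(anchor, cyclase, False),
        cas_span=(10_000, 14_000),
        neighborhood=(4_000, 20_000),
        subtype=subtype,
    )
    for i, f in enumerate(rn_fams):
        g = _gene(f"{locus_id}_rn{i}", genome, 150, 15_000 + 600 * i)
        loc.rns.append(
            RNAnnotation(
                f, g, 80.0, 1e-20,
                screen_status=rn_status,
                missing_positions=((0, "H"),) if rn_status == "fail" else (),
            )
        )
    for i, f in enumerate(eff_fams):
        g = _gene(f"{locus_id}_eff{i}", genome, 400, 17_000 + 1500 * i)
        loc.effectors.append(EffectorAnnotation(f, g, 90.0, 1e-25, signal="cA4"))
    loc.signals = {"cA4"} if eff_fams else set()
    return loc


class TestSummarize:
    def test_empty_input_all_zero(self):
        s = summarize([])
        assert s.n_loci == 0
        assert s.family_instances == {} and s.n_rn_positive_loci == 0
        assert math.isnan(s.frac_rn_instances_in_effector_loci)

    def test_two_family_locus_is_multi_rn(self):
        s = summarize([_locus("L1", rn_fams=("Crn1", "Csx15"))])
        assert s.n_multi_rn_loci == 1
        assert s.family_instances == {"Crn1": 1, "Csx15": 1}
        assert s.multi_rn_loci == [("L1", ("Crn1", "Csx15"))]

    def test_duplicate_family_counts_once_per_locus(self):
        s = summarize([_locus("L1", rn_fams=("Csx20", "Csx20"))])
        assert s.family_instances == {"Csx20": 2}
        assert s.family_loci == {"Csx20": 1}
        assert s.n_multi_rn_loci == 1  # two genes, even if one family

    def test_screen_failures_do_not_count(self):
        s = summarize([_locus("L1", rn_fams=("Crn1",), rn_status="fail")])
        assert s.n_rn_positive_loci == 0 and s.family_instances == {}

    def test_rn_without_effector_counted(self):
        s = summarize(
            [_locus("L1", rn_fams=("Crn3",)), _locus("L2", rn_fams=("Crn3",), eff_fams=("Csx1",))]
        )
        assert s.n_rn_loci_without_effector == 1
        assert s.frac_rn_instances_in_effector_loci == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_count_conservation_invariant(self, seed):
        ds = generate_dataset(SimConfig(n_genomes=30, seed=seed, p_multi_rn=0.3))
        profiles = {
            f: build_conservation_profile(sf.msa, family=f)
            for f, sf in ds.families.items()
        }
        res = annotate_genomes(ds.genomes, ds.hits, profiles)
        s = summarize(res.loci)
        lhs = sum(s.family_instances.values()) - s.n_rn_positive_loci
        rhs = sum(len(fams) - 1 for _, fams in s.multi_rn_loci)
        assert lhs == rhs

    def test_matches_truth_recount(self, noiseless_dataset, noiseless_result):
        s = summarize(noiseless_result.loci)
        truth = noiseless_dataset.truth
        rn_rows = truth[truth.role.str.startswith("rn:")]
        assert sum(s.family_instances.values()) == len(rn_rows)
        assert s.n_rn_positive_loci == rn_rows.locus_id.nunique()
        expected_per_family = rn_rows.family.value_counts().to_dict()
        assert s.family_instances == expected_per_family


class TestRestrictedAssociation:
    def test_two_effector_locus_excluded(self):
        loci = [
            _locus("L1", rn_fams=("Crn1",), eff_fams=("Csx1", "Can1")),
            _locus("L2", rn_fams=("Crn1",), eff_fams=("Csx1",)),
        ]
        assoc = restricted_association(loci)
        assert assoc["Csx1"] == (1, 1, 1.0)
        # Can1 appears only in the excluded locus: denominator 0, undefined
        k, n, p = assoc["Can1"]
        assert (k, n) == (0, 0) and math.isnan(p)

    def test_two_rn_locus_excluded(self):
        loci = [_locus("L1", rn_fams=("Crn1", "Csx15"), eff_fams=("Cam1",))]
        assoc = restricted_association(loci)
        assert assoc["Cam1"][1] == 0

    def test_proportion_arithmetic(self):
        loci = [
            _locus(f"L{i}", rn_fams=("Csx20",) if i < 8 else (), eff_fams=("Cam1",))
            for i in range(10)
        ]
        assert restricted_association(loci)["Cam1"] == (8, 10, 0.8)


class TestNetwork:
    def test_no_cooccurrence_empty_edges(self):
        net = build_network([_locus("L1", rn_fams=("Crn1",)), _locus("L2", eff_fams=("Csx1",))])
        assert net.edges == []
        assert {n.node_id for n in net.nodes} == {"Crn1", "Csx1"}

    def test_three_loci_one_edge_weight_three(self):
        loci = [_locus(f"L{i}", rn_fams=("Csx20",), eff_fams=("Csx1",)) for i in range(3)]
        net = build_network(loci)
        assert len(net.edges) == 1
        assert net.edges[0].weight == 3

    def test_weights_match_brute_force_on_random_loci(self, rng):
        rn_pool = ["Crn1", "Crn2", "Crn3", "Csx15", "Csx16", "Csx20"]
        eff_pool = ["Csx1", "Csm6", "Can1", "Cam1"]
        for _ in range(30):
            loci = []
            for i in range(int(rng.integers(0, 15))):
                loci.append(
                    _locus(
                        f"L{i}",
                        rn_fams=tuple(
                            rng.choice(rn_pool, size=int(rng.integers(0, 3)), replace=False)
                        ),
                        eff_fams=tuple(
                            rng.choice(eff_pool, size=int(rng.integers(0, 3)), replace=False)
                        ),
                    )
                )
            net = build_network(loci)
            got = {(e.rn, e.effector): e.weight for e in net.edges}
            assert got == brute_force_edge_weights(loci)

    def test_network_is_bipartite_by_construction(self, noiseless_result):
        net = build_network(noiseless_result.loci)
        kind = {n.node_id: n.kind for n in net.nodes}
        for e in net.edges:
            assert kind[e.rn] == "RN" and kind[e.effector] == "effector"


class TestBackgroundFrequency:
    @staticmethod
    def _rn(genome, fam="Csx15", status="pass"):
        g = _gene(f"{genome}_rn", genome, 150)
        return RNAnnotation(
            fam, g, 70.0, 1e-15, screen_status=status,
            missing_positions=((0, "H"),) if status == "fail" else (),
        )

    def test_family_only_inside_loci_gives_zero(self):
        loci = [_locus("L1", genome="G1", rn_fams=("Csx15",))]
        genome_rns = {"G1": [self._rn("G1")]}
        assert background_frequency(genome_rns, loci, "Csx15") == 0.0

    def test_one_in_four_carriers_lacks_locus(self):
        loci = [_locus(f"L{i}", genome=f"G{i}") for i in range(1, 4)]
        genome_rns = {f"G{i}": [self._rn(f"G{i}")] for i in range(1, 5)}
        assert background_frequency(genome_rns, loci, "Csx15") == pytest.approx(0.25)

    def test_absent_family_undefined(self):
        assert background_frequency({}, [], "Crn2") is None

    def test_screen_failures_not_carriers(self):
        genome_rns = {"G9": [self._rn("G9", status="fail")]}
        assert background_frequency(genome_rns, [], "Csx15") is None

    def test_planted_orphan_rate_recovered(self):
        ds = generate_dataset(
            SimConfig(n_genomes=120, seed=31, n_orphan_rns="auto")
        )
        profiles = {
            f: build_conservation_profile(sf.msa, family=f)
            for f, sf in ds.families.items()
        }
        res = annotate_genomes(ds.genomes, ds.hits, profiles)
        frac = background_frequency(res.genome_rns, res.loci, "Csx15")
        n_orphans = (ds.truth.role == "decoy:orphan_rn").sum()
        carriers = ds.truth[
            (ds.truth.family == "Csx15")
            & (ds.truth.expected_verdict != "rejected-by-screen")
        ].genome_id.nunique()
        assert frac == pytest.approx(n_orphans / carriers)


class TestPhageCounts:
    def test_empty(self):
        assert phage_family_counts({}) == {}

    def test_two_genes_one_phage_counts_once(self):
        g1 = _gene("P1_a", "P1", 150)
        g2 = _gene("P1_b", "P1", 150, start=2000)
        anns = {
            "P1": [
                RNAnnotation("Crn2", g1, 70.0, 1e-15, screen_status="pass"),
                RNAnnotation("Crn2", g2, 75.0, 1e-18, screen_status="pass"),
            ]
        }
        assert phage_family_counts(anns) == {"Crn2": 1}


class TestTreeAnnotation:
    def _write_tree(self, tmp_path, labels):
        nodes = list(labels)
        newick = nodes[0] if len(nodes) == 1 else ""
        while len(nodes) > 1:
            nodes = [f"({nodes[0]},{nodes[1]})"] + nodes[2:]
        path = tmp_path / "t.nwk"
        path.write_text((newick or nodes[0]) + ";\n")
        return path

    def test_presence_columns_and_red_dot(self, tmp_path):
        loci = [
            _locus("L1", rn_fams=("Crn3",), eff_fams=("Csx1",)),
            _locus("L2", cyclase=False, subtype="III-C"),
        ]
        path = self._write_tree(
            tmp_path, [loci[0].cas10.gene.gene_id, loci[1].cas10.gene.gene_id]
        )
        table = tree_annotation(path, loci)
        assert len(table) == 2
        r1 = table[table.leaf == loci[0].cas10.gene.gene_id].iloc[0]
        assert r1["Crn3"] == 1 and r1["Crn1"] == 0 and r1["cyclase_absent"] == 0
        r2 = table[table.leaf == loci[1].cas10.gene.gene_id].iloc[0]
        assert r2["cyclase_absent"] == 1 and r2["subtype"] == "III-C"

    def test_leaf_without_locus_gets_na_row(self, tmp_path):
        loci = [_locus("L1")]
        path = self._write_tree(tmp_path, [loci[0].cas10.gene.gene_id, "stray_leaf"])
        table = tree_annotation(path, loci)
        assert len(table) == 2
        stray = table[table.leaf == "stray_leaf"].iloc[0]
        assert stray[["subtype", "Crn1", "cyclase_absent"]].isna().all()

    def test_duplicate_leaves_abort(self, tmp_path):
        path = self._write_tree(tmp_path, ["x", "x", "y"])
        with pytest.raises(ValueError, match="duplicate.*x"):
            tree_annotation(path, [])

    def test_row_count_equals_leaf_count(self, tmp_path, noiseless_result, noiseless_dataset):
        path = tmp_path / "cas10.nwk"
        path.write_text(noiseless_dataset.tree_newick + "\n")
        table = tree_annotation(path, noiseless_result.loci)
        assert len(table) == len(noiseless_result.loci)
        assert not table.subtype.isna().any()
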