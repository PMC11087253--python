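"""CpG-to-gene mapping, moderated DE on log-CPM, restricted FDR, overlaps."""

import numpy as np
import pandas as pd
import pytest

import mechamethyl as mm
from mechamethyl.synthetic_data import CountMatrix


def meta_with_flags(probes, flags, b=0.01, q=0.001):
    return pd.DataFrame(
        {"dm_flag": flags, "b_meta": b, "q": q},
        index=pd.Index(probes, name="probe_id"),
    )


def annotation_rows(rows):
    ann = pd.DataFrame(
        rows, columns=["probe_id", "genes", "categories"]
    ).set_index("probe_id")
    ann["chrom"] = "chr1"
    ann["pos"] = np.arange(len(ann)) * 1000 + 1
    return ann


class TestMapCpgsToGenes:
    def test_body_only_mapping_is_excluded(self):
        meta = meta_with_flags(["p0"], [True])
        ann = annotation_rows([("p0", "GENEA", "Body")])
        assert mm.map_cpgs_to_genes(meta, ann).empty

    def test_single_tss200_pair(self):
        meta = meta_with_flags(["p0"], [True])
        ann = annotation_rows([("p0", "GENEA", "TSS200")])
        pairs = mm.map_cpgs_to_genes(meta, ann)
        assert len(pairs) == 1
        assert pairs.iloc[0]["gene"] == "GENEA"
        assert pairs.iloc[0]["categories"] == "TSS200"

    def test_multi_gene_explosion_matches_brute_force(self):
        rng = np.random.default_rng(0)
        cats = list(mm.expression_integration.QUALIFYING_CATEGORIES) + ["Body"]
        rows, expected = [], set()
        for i in range(1000):
            k = int(rng.integers(0, 3))
            genes = [f"G{rng.integers(0, 50):02d}" for _ in range(k)]
            cc = [str(rng.choice(cats)) for _ in range(k)]
            rows.append((f"p{i}", ";".join(genes), ";".join(cc)))
            for g, c in zip(genes, cc):
                if c != "Body":
                    expected.add((f"p{i}", g))
        meta = meta_with_flags([f"p{i}" for i in range(1000)], True)
        pairs = mm.map_cpgs_to_genes(meta, annotation_rows(rows))
        got = set(zip(pairs["probe_id"], pairs["gene"]))
        assert got == expected

    def test_non_dm_probes_never_mapped(self):
        meta = meta_with_flags(["p0", "p1"], [False, True])
        ann = annotation_rows([("p0", "GENEA", "TSS200"), ("p1", "GENEB", "TSS200")])
        pairs = mm.map_cpgs_to_genes(meta, ann)
        assert list(pairs["gene"]) == ["GENEB"]


def toy_counts(n_genes=30, nl=6, nc=6, seed=1, lfc_genes=()):
    rng = np.random.default_rng(seed)
    samples = pd.DataFrame(
        {"condition": ["loaded"] * nl + ["control"] * nc},
        index=[f"s{i}" for i in range(nl + nc)],
    )
    mean = rng.uniform(50, 500, n_genes)
    mu = np.tile(mean[:, None], (1, nl + nc))
    genes = [f"G{i:02d}" for i in range(n_genes)]
    for g in lfc_genes:
        mu[genes.index(g), :nl] *= 2
    counts = rng.poisson(mu)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        samples=samples,
    )


class TestDifferentialExpression:
    def test_identical_columns_give_zero_log2fc(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 500, 20)
        cm = toy_counts(20, 3, 3, seed=3)
        cm.counts.loc[:, :] = np.tile(col[:, None], (1, 6))
        de = mm.differential_expression(cm)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)

    def test_library_size_scaling_invariance(self):
        cm = toy_counts(seed=4)
        de1 = mm.differential_expression(cm)
        scaled = CountMatrix(counts=cm.counts.copy(), samples=cm.samples)
        scaled.counts.iloc[:, 0] *= 2  # CPM normalization must absorb this
        de2 = mm.differential_expression(scaled)
        np.testing.assert_allclose(de1["log2fc"], de2["log2fc"], atol=0.05)

    def test_planted_two_fold_genes_recovered(self):
        d = mm.StudyDesign(n_probes=600, n_genes=150, seed=31)
        ann = mm.generate_probe_annotation(d)
        spec = mm.EffectSpec(frac_dm=0.2, frac_linked_genes=0.8, expr_lfc=1.0,
                             nb_dispersion=0.1)
        datasets, truth = mm.generate_methylation_experiment(d, spec, ann)
        cm = mm.generate_expression_counts(d, spec, ann, truth)
        de = mm.differential_expression(cm)
        est = [de.loc[g, "log2fc"] * np.sign(l) for g, l in truth.linked_genes.items()]
        assert 0.8 <= np.mean(est) <= 1.2

    def test_all_zero_genes_dropped(self):
        cm = toy_counts(15, 3, 3, seed=5)
        cm.counts.iloc[0] = 0
        de = mm.differential_expression(cm)
        assert "G00" not in de.index
        assert len(de) == 14


class TestPrioritizeTcpgs:
    def test_restricted_bh_hand_example(self):
        pairs = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(4)],
                "gene": ["G1", "G2", "G3", "G4"],
                "categories": "TSS200",
                "meth_effect": 0.01,
                "meth_q": 0.001,
            }
        )
        de = pd.DataFrame(
            {"log2fc": 1.0, "p": [0.001, 0.01, 0.2, 0.9, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99]},
            index=[f"G{i}" for i in range(1, 11)],
        )
        out = mm.prioritize_tcpgs(pairs, de, expr_fdr=0.05)
        # BH within the 4 mapped genes only: q = 0.004, 0.02, 0.267, 0.9
        assert set(out["gene"]) == {"G1", "G2"}
        q = dict(zip(out["gene"], out["expr_q_restricted"]))
        assert q["G1"] == pytest.approx(0.004)
        assert q["G2"] == pytest.approx(0.02)

    def test_gene_above_threshold_drops_all_its_pairs(self):
        pairs = pd.DataFrame(
            {"probe_id": ["p0", "p1"], "gene": ["G1", "G1"],
             "categories": "TSS200", "meth_effect": 0.01, "meth_q": 0.001}
        )
        de = pd.DataFrame({"log2fc": [0.1], "p": [0.2]}, index=["G1"])
        assert mm.prioritize_tcpgs(pairs, de).empty

    def test_empty_pairs_give_empty_output(self):
        de = pd.DataFrame({"log2fc": [], "p": []})
        out = mm.prioritize_tcpgs(pd.DataFrame(columns=["probe_id", "gene"]), de)
        assert out.empty

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        pairs = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(20)],
                "gene": [f"G{rng.integers(0, 8)}" for _ in range(20)],
                "categories": "TSS1500",
                "meth_effect": 0.01,
                "meth_q": 0.001,
            }
        )
        de = pd.DataFrame(
            {"log2fc": rng.normal(0, 1, 8), "p": rng.uniform(0, 0.2, 8)},
            index=[f"G{i}" for i in range(8)],
        )
        a = mm.prioritize_tcpgs(pairs, de)
        b = mm.prioritize_tcpgs(pairs.sample(frac=1, random_state=7), de)
        key = lambda df: sorted(zip(df["probe_id"], df["gene"]))
        assert key(a) == key(b)


class TestSummariesAndOverlap:
    def test_category_proportions(self):
        tc = pd.DataFrame({"categories": ["TSS200", "TSS200", "3'UTR", "3'UTR"]})
        out = mm.region_category_summary(tc)
        assert out == {"3'UTR": 0.5, "TSS200": 0.5}
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_single_category(self):
        tc = pd.DataFrame({"categories": ["TSS200"] * 3})
        assert mm.region_category_summary(tc) == {"TSS200": 1.0}

    def test_overlap_counts_match_set_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ml_genes = [f"G{int(i)}" for i in rng.integers(0, 30, 15)]
            ext_genes = [f"g{int(i)}" for i in rng.integers(0, 30, 12)]
            ml = pd.DataFrame({"probe_id": [f"p{i}" for i in range(15)], "gene": ml_genes})
            out = mm.overlap_tcpg_sets(ml, ext_genes)
            expected = {g.upper() for g in ml_genes} & {g.upper() for g in ext_genes}
            assert out["n_overlap_genes"] == len(expected)

    def test_disjoint_and_identical(self):
        ml = pd.DataFrame({"probe_id": ["p1"], "gene": ["A"]})
        assert mm.overlap_tcpg_sets(ml, ["B"])["n_overlap_genes"] == 0
        ml5 = pd.DataFrame({"probe_id": [f"p{i}" for i in range(5)],
                            "gene": list("ABCDE")})
        assert mm.overlap_tcpg_sets(ml5, list("ABCDE"))["n_overlap_genes"] == 5
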