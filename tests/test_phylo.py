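"""Independent contrasts, contrast correlation, and Poisson log-linear fits."""

import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from socialte.phylo import (
    contrast_t_pvalue,
    loglinear_fit,
    lrt,
    pic_contrasts,
    pic_correlation,
    pic_correlation_test,
)


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def pic_oracle(node, trait):
    """Independent recursive pruning oracle over nested tuples.

    A node is either a (label, branch_length) leaf or
    ((left, right), branch_length). Returns (value, effective_length,
    contrasts).
    """
    children, bl = node
    if isinstance(children, str):
        return trait[children], bl, []
    left, right = children
    xv, vv, cl = pic_oracle(left, trait)
    yv, wv, cr = pic_oracle(right, trait)
    contrast = (xv - yv) / np.sqrt(vv + wv)
    value = (xv / vv + yv / wv) / (1 / vv + 1 / wv)
    return value, bl + vv * wv / (vv + wv), cl + cr + [contrast]


def L(name, bl=1):
    return (name, bl)


def N(a, b, bl=1):
    return ((a, b), bl)


UNIT_TREES = [
    # (newick with unit branches, nested-tuple mirror; root branch length 0)
    ("(A:1,B:1);", N(L("A"), L("B"), 0)),
    ("((A:1,B:1):1,C:1);", N(N(L("A"), L("B")), L("C"), 0)),
    ("((A:1,B:1):1,(C:1,D:1):1);", N(N(L("A"), L("B")), N(L("C"), L("D")), 0)),
    ("(((A:1,B:1):1,C:1):1,D:1);", N(N(N(L("A"), L("B")), L("C")), L("D"), 0)),
    (
        "((((A:1,B:1):1,C:1):1,D:1):1,E:1);",
        N(N(N(N(L("A"), L("B")), L("C")), L("D")), L("E"), 0),
    ),
    (
        "(((A:1,B:1):1,(C:1,D:1):1):1,E:1);",
        N(N(N(L("A"), L("B")), N(L("C"), L("D"))), L("E"), 0),
    ),
]


class TestPICContrasts:
    def test_two_tip_closed_form(self):
        tree = tree_from("(A:2,B:3);")
        c = pic_contrasts(tree, {"A": 5.0, "B": 1.0})
        assert c == pytest.approx([(5.0 - 1.0) / np.sqrt(5.0)])

    def test_constant_trait_zero_contrasts(self):
        tree = tree_from("((A:1,B:1):1,C:1);")
        assert np.allclose(pic_contrasts(tree, {"A": 2, "B": 2, "C": 2}), 0)

    def test_three_taxon_manual_pruning(self):
        tree = tree_from("((A:1,B:1):1,C:1);")
        x = {"A": 4.0, "B": 2.0, "C": 7.0}
        c = pic_contrasts(tree, x)
        # contrast 1: (4-2)/sqrt(2); node value 3, branch 1 + 1/2
        # contrast 2: (3-7)/sqrt(1.5 + 1)
        assert c == pytest.approx([2 / np.sqrt(2), -4 / np.sqrt(2.5)])

    @pytest.mark.parametrize("newick,nested", UNIT_TREES)
    def test_matches_recursive_oracle_on_unit_trees(self, newick, nested):
        rng = np.random.default_rng(hash(newick) % 2**31)
        labels = [ch for ch in "ABCDE" if ch in newick]
        for _ in range(5):
            trait = {l: float(rng.normal()) for l in labels}
            got = sorted(pic_contrasts(tree_from(newick), trait), key=abs)
            want = sorted(pic_oracle(nested, trait)[2], key=abs)
            assert np.allclose(got, want)

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="polytomy"):
            pic_contrasts(tree_from("(A:1,B:1,C:1);"), {"A": 1, "B": 2, "C": 3})

    def test_missing_tip_value_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pic_contrasts(tree_from("(A:1,B:1);"), {"A": 1})

    def test_zero_branch_rejected(self):
        with pytest.raises(ValueError):
            pic_contrasts(tree_from("(A:0,B:1);"), {"A": 1, "B": 2})

    def test_matches_ape_pic_oracle(self, tmp_path):
        """Cross-check against the reference implementation in R's ape."""
        newick = "(((A:1.2,B:0.7):0.5,C:2.0):0.8,(D:1.1,E:0.4):1.5);"
        trait = {"A": 3.1, "B": -0.5, "C": 2.2, "D": 7.9, "E": 0.3}
        ours = np.sort(pic_contrasts(tree_from(newick), trait))
        script = tmp_path / "pic.R"
        script.write_text(
            'library(ape); t <- read.tree(text="%s")\n'
            "x <- c(A=3.1, B=-0.5, C=2.2, D=7.9, E=0.3)\n"
            'cat(sort(pic(x[t$tip.label], t)), sep="\\n")\n' % newick
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        theirs = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(ours, theirs, atol=1e-8)


class TestContrastCorrelation:
    def test_reported_tail_probability(self):
        assert round(contrast_t_pvalue(1.382, 3), 3) == 0.261

    def test_perfect_correlation_flagged(self):
        cx = np.array([1.0, -2.0, 0.5, 3.0])
        res = pic_correlation(cx, cx)
        assert res.degenerate and res.p == 0.0 and res.r == 1.0

    def test_df_is_contrast_count_minus_two(self):
        rng = np.random.default_rng(0)
        res = pic_correlation(rng.normal(size=5), rng.normal(size=5))
        assert res.df == 3
        res_origin = pic_correlation(
            rng.normal(size=5), rng.normal(size=5), through_origin=True
        )
        assert res_origin.df == 4

    def test_type_one_error_under_independent_brownian_traits(self):
        from socialte.sim.traits import simulate_bm_traits

        newick = "((((A:1,B:1):1,C:2):1,(D:1,E:1):2):1,(F:2,G:2):1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rej = 0
        reps = 400
        for i in range(reps):
            traits, _ = simulate_bm_traits(tree, rho=0.0, sigma=1.0, seed=10_000 + i)
            res = pic_correlation_test(tree, traits, "trait_x", "trait_y")
            rej += res.p < 0.05
        # binomial 3-sigma band around 0.05 at 400 reps
        assert abs(rej / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestLogLinear:
    def test_saturated_model_fits_exactly(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"], "count": [10, 25, 5, 40]}
        )
        fit = loglinear_fit(df, "a * b")
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.fitted, df["count"])

    def test_independence_deviance_equals_g_statistic(self):
        obs = np.array([[12, 30], [8, 50]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        g = 2 * np.sum(obs * np.log(obs / expected))
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"],
             "count": obs.ravel().astype(int)}
        )
        fit = loglinear_fit(df, "a + b")
        assert fit.deviance == pytest.approx(g, abs=1e-6)

    def test_equal_counts_zero_interaction(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"], "count": [7, 7, 7, 7]}
        )
        fit = loglinear_fit(df, "a * b")
        assert abs(fit.coefficients.filter(like=":").iloc[0]) < 1e-8

    def test_deviance_non_increasing_with_terms(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "a": np.repeat(["x", "y"], 4),
                "b": np.tile(np.repeat(["u", "v"], 2), 2),
                "c": np.tile(["s", "t"], 4),
                "count": rng.poisson(20, 8),
            }
        )
        d1 = loglinear_fit(df, "a + b + c").deviance
        d2 = loglinear_fit(df, "a + b + c + a:b").deviance
        d3 = loglinear_fit(df, "a * b * c").deviance
        assert d1 >= d2 - 1e-10 >= d3 - 1e-10


class TestLRT:
    def test_identical_models_statistic_zero(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"], "count": [10, 25, 5, 40]}
        )
        fit = loglinear_fit(df, "a + b")
        stat, dof, p = lrt(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(2)
        mu = np.array([40.0, 10.0, 10.0, 40.0])  # strong a:b interaction
        hits = 0
        for _ in range(50):
            df = pd.DataFrame(
                {"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"],
                 "count": rng.poisson(mu)}
            )
            _, _, p = lrt(loglinear_fit(df, "a + b"), loglinear_fit(df, "a * b"))
            hits += p < 0.05
        assert hits / 50 > 0.95

    def test_non_nested_rejected(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"], "count": [10, 25, 5, 40]}
        )
        with pytest.raises(ValueError):
            lrt(loglinear_fit(df, "a * b"), loglinear_fit(df, "a + b"))


class TestExports:
    def test_model_tables_roundtrip_and_bias_codes(self, tmp_path):
        from socialte.phylo import export_model_tables

        table = pd.DataFrame(
            {
                "species": ["sp1"] * 6,
                "social_level": ["eusocial"] * 6,
                "bias": ["none", "none", "worker_nymph", "worker_nymph",
                         "queen_female", "queen_female"],
                "te_overlap": ["yes", "no"] * 3,
                "count": [5, 10, 4, 2, 3, 6],
            }
        )
        tree = dendropy.Tree.get(data="(sp1:1,sp2:1);", schema="newick")
        written = export_model_tables({"gene_te": table}, tree, tmp_path)
        back = pd.read_csv(written["gene_te"], sep="\t")
        assert back["count"].tolist() == table["count"].tolist()
        assert back["bias_code"].tolist() == [0, 0, 1, 1, 2, 2]
        assert (tmp_path / "species_tree.nwk").exists()
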