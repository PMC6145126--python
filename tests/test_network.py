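"""Pearson coexpression edges, significance and graph summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinome_evo.network import (
    build_network,
    degree_and_components,
    pcc,
    pcc_pvalue,
    CoexpressionEdge,
)


def test_pcc_known_values():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pcc(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert pcc(x, [-v for v in x]) == pytest.approx(-1.0)
    assert pcc(x, [5.0, 5.0, 5.0, 5.0]) is None  # constant vector


def test_pcc_matches_direct_formula():
    rng = np.random.default_rng(0)
    for _ in range(25):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        direct = float(np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std()))
        assert pcc(x, y) == pytest.approx(direct, abs=1e-12)


def test_pvalue_extremes_and_errors():
    assert pcc_pvalue(0.0, 14) == pytest.approx(1.0)
    assert pcc_pvalue(1.0, 14) == 0.0
    assert pcc_pvalue(-1.0, 14) == 0.0
    with pytest.raises(ValueError):
        pcc_pvalue(0.5, 2)


def test_pvalue_matches_scipy_reference():
    rng = np.random.default_rng(1)
    for n in (8, 14, 30):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        r, p_ref = stats.pearsonr(x, y)
        assert pcc_pvalue(float(r), n) == pytest.approx(p_ref, abs=1e-9)


def test_pvalue_strictly_decreasing_in_abs_r():
    ps = [pcc_pvalue(r, 14) for r in np.linspace(0.0, 0.99, 50)]
    assert all(b < a for a, b in zip(ps, ps[1:]))


def _edge_matrix():
    """Three correlated genes (one module) + two independent ones."""
    rng = np.random.default_rng(2)
    latent = rng.standard_normal(14) * 3
    rows = {
        f"mod{i}": latent + rng.standard_normal(14) * 0.1 for i in range(3)
    }
    rows["ind1"] = rng.standard_normal(14)
    rows["ind2"] = rng.standard_normal(14)
    return pd.DataFrame.from_dict(rows, orient="index")


def test_exact_threshold_value_excluded():
    # construct a pair with r exactly 0.8 via eigen-decomposition trick:
    # x and y = 0.8*x + sqrt(1-0.64)*z with z orthonormal to x, both unit
    n = 10
    x = np.zeros(n)
    x[0], x[1] = 1.0, -1.0
    z = np.zeros(n)
    z[2], z[3] = 1.0, -1.0
    y = 0.8 * x + np.sqrt(1 - 0.64) * z
    m = pd.DataFrame([x, y], index=["a", "b"])
    assert pcc(x, y) == pytest.approx(0.8, abs=1e-12)
    assert build_network(m, min_abs_pcc=0.8, alpha=0.5) == []
    assert len(build_network(m, min_abs_pcc=0.79, alpha=0.5)) == 1


def test_planted_module_forms_clique_without_spurious_edges():
    edges = build_network(_edge_matrix())
    names = {(e.node_a, e.node_b) for e in edges}
    assert names == {("mod0", "mod1"), ("mod0", "mod2"), ("mod1", "mod2")}
    assert all(e.sign == "positive" for e in edges)


def test_duplicated_profiles_positive_edge():
    rng = np.random.default_rng(3)
    row = rng.uniform(0, 50, 14)
    m = pd.DataFrame([row, row * 1.5 + 2], index=["a", "b"])
    edges = build_network(m)
    assert len(edges) == 1 and edges[0].sign == "positive"
    assert edges[0].p <= 1e-10


def test_raising_threshold_never_adds_edges():
    m = _edge_matrix()
    loose = {(e.node_a, e.node_b) for e in build_network(m, min_abs_pcc=0.5)}
    tight = {(e.node_a, e.node_b) for e in build_network(m, min_abs_pcc=0.9)}
    assert tight <= loose


def test_two_module_network_components():
    rng = np.random.default_rng(4)
    rows = {}
    for mod, scale in (("x", 1.0), ("y", -1.0)):
        latent = rng.standard_normal(14) * 3
        for i in range(3):
            rows[f"{mod}{i}"] = scale * latent + rng.standard_normal(14) * 0.1
    m = pd.DataFrame.from_dict(rows, orient="index")
    edges = build_network(m)
    degrees, components = degree_and_components(edges)
    assert len(components) == 2
    assert {frozenset(c) for c in components} == {
        frozenset({"x0", "x1", "x2"}),
        frozenset({"y0", "y1", "y2"}),
    }


def test_degrees_and_components_shapes():
    edges = [
        CoexpressionEdge("a", "b", 0.9, 0.001, "positive"),
        CoexpressionEdge("a", "c", 0.9, 0.001, "positive"),
        CoexpressionEdge("b", "c", 0.9, 0.001, "positive"),
        CoexpressionEdge("d", "e", -0.9, 0.001, "negative"),
    ]
    degrees, components = degree_and_components(edges)
    assert degrees == {"a": 2, "b": 2, "c": 2, "d": 1, "e": 1}
    assert sorted(len(c) for c in components) == [2, 3]
    assert degree_and_components([]) == ({}, [])


def test_gene_and_family_profiles_share_code_path():
    """The same builder serves gene-level and family-mean matrices."""
    from kinome_evo.expression import family_mean_expression

    m = _edge_matrix()
    fams = {name: f"F_{name[:3]}" for name in m.index}
    fam_matrix = family_mean_expression(m, fams)
    edges = build_network(fam_matrix)
    assert all(isinstance(e, CoexpressionEdge) for e in edges)
    mod_edges = [e for e in edges if "F_mod" in (e.node_a, e.node_b)]
    assert mod_edges == []  # the three module genes collapse to one family node
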