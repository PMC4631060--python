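"""Statistical tests for the comparative analysis, plus independent contrasts.

All tests are two-tailed.  Conventions chosen to match standard
comparative-genomics reporting:

* two-sample t statistics use the A - B sign convention;
* the variance-ratio F puts the larger variance in the numerator;
* the 2x2 chi-square is Pearson's, without Yates continuity correction;
* Welch degrees of freedom are Welch-Satterthwaite, with a rounded
  integer also provided for reporting;
* phylogenetically independent contrasts follow Felsenstein's recursion,
  with the contrast-contrast correlation computed through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collectable despite the name

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    variant: str
    tails: str = "two"

    @property
    def df_reported(self) -> int | tuple[int, int]:
        """Degrees of freedom rounded to integers, as customarily printed."""
        if isinstance(self.df, tuple):
            return tuple(int(round(d)) for d in self.df)
        return int(round(self.df))


def _as_arrays(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    return a, b


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sample t-test not assuming equal variances (Welch)."""
    a, b = _as_arrays(sample_a, sample_b)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def pooled_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sample t-test with pooled variance, df = n_a + n_b - 2."""
    a, b = _as_arrays(sample_a, sample_b)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue), "pooled_t")


def f_var(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Variance-ratio F-test; larger sample variance over smaller, two-tailed."""
    a, b = _as_arrays(sample_a, sample_b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance sample")
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = 2.0 * min(sps.f.sf(f, dfn, dfd), sps.f.cdf(f, dfn, dfd))
    return TestResult(float(f), (float(dfn), float(dfd)), min(float(p), 1.0), "f_var")


def chi2_2x2(a_success: int, a_total: int, b_success: int, b_total: int) -> TestResult:
    """Pearson chi-square on a 2x2 table of proportions, no continuity correction."""
    if a_total <= 0 or b_total <= 0 or a_success > a_total or b_success > b_total:
        raise ValueError("invalid table")
    obs = np.array([[a_success, a_total - a_success], [b_success, b_total - b_success]], float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return TestResult(chi2, 1.0, float(sps.chi2.sf(chi2, 1)), "chi2_2x2")


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, TestResult]:
    """Pearson correlation with its two-tailed t-based test (df = n - 2)."""
    x, y = _as_arrays(x, y)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    r, p = sps.pearsonr(x, y)
    return float(r), TestResult(float(r), float(len(x) - 2), float(p), "pearson")


def paired_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Paired two-tailed t-test of mean(a - b) = 0; zero-variance diffs give t = 0."""
    a, b = _as_arrays(sample_a, sample_b)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    d = a - b
    if np.allclose(np.var(d, ddof=1), 0.0):
        stat, p = (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf * np.sign(d.mean()), 0.0)
    else:
        stat, p = sps.ttest_rel(a, b)
    return TestResult(float(stat), float(len(a) - 1), float(p), "paired_t")


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts

@dataclass(frozen=True)
class ContrastSet:
    contrasts_x: np.ndarray  # standardized contrasts, one per internal node
    contrasts_y: np.ndarray
    r: float  # correlation through the origin
    test: TestResult


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=tree, schema="newick")


def pic_contrasts(tree: "dendropy.Tree | str", tip_values: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's standardized contrasts for one trait.

    At each internal node the contrast is (x_left - x_right) /
    sqrt(v_left + v_right); the node inherits the variance-weighted mean
    and its branch variance is inflated by v_l*v_r/(v_l + v_r).
    Polytomies are resolved into zero-length bifurcations first.
    """
    return _pic(_as_tree(tree), tip_values)[0]


def _pic(tree: dendropy.Tree, tip_values: Mapping[str, float]) -> tuple[np.ndarray, dict]:
    tree.resolve_polytomies()
    tree.suppress_unifurcations()
    node_state: dict = {}
    contrasts = []
    for node in tree.postorder_node_iter():
        edge_v = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            if name not in tip_values:
                raise KeyError(f"no trait value for tip {name!r}")
            if edge_v <= 0:
                raise ValueError(f"non-positive branch length at tip {name!r}")
            node_state[node] = (float(tip_values[name]), edge_v)
        else:
            children = node.child_nodes()
            if len(children) != 2:
                raise ValueError("tree not bifurcating after polytomy resolution")
            (x1, v1), (x2, v2) = node_state[children[0]], node_state[children[1]]
            if v1 + v2 <= 0:
                raise ValueError("zero combined branch variance at a contrast")
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            x_anc = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
            node_state[node] = (x_anc, edge_v + v1 * v2 / (v1 + v2))
    return np.asarray(contrasts), node_state


def corr_through_origin(cx: Sequence[float], cy: Sequence[float]) -> tuple[float, TestResult]:
    """Correlation constrained through the origin, df = n - 1.

    Contrast signs are arbitrary (child order), so the correlation must
    not be re-centred; significance via t = r*sqrt(df/(1-r^2)).
    """
    cx, cy = np.asarray(cx, float), np.asarray(cy, float)
    if len(cx) != len(cy) or len(cx) < 2:
        raise ValueError("need >= 2 paired contrasts")
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    if denom == 0:
        raise ValueError("all contrasts zero")
    r = float((cx * cy).sum() / denom)
    df = len(cx) - 1
    if abs(r) >= 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
    return r, TestResult(float(t), float(df), float(p), "pic_corr")


def pic(tree: "dendropy.Tree | str", tip_values_x: Mapping[str, float],
        tip_values_y: Mapping[str, float]) -> ContrastSet:
    """Independent contrasts for two traits on a shared tree, plus their
    through-origin correlation test.

    Both traits are propagated through the *same* resolved tree so the
    contrasts at each node refer to the same daughter pair.
    """
    tree = _as_tree(tree)
    tree.resolve_polytomies()
    tree.suppress_unifurcations()
    cx, _ = _pic(tree, tip_values_x)
    cy, _ = _pic(tree, tip_values_y)
    r, test = corr_through_origin(cx, cy)
    return ContrastSet(cx, cy, r, test)
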