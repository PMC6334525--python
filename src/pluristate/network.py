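"""Per-condition gene association networks and differential remodeling.

Two complementary association signals are computed for every unordered
gene pair in a condition:

* **binary** — a Fisher exact test on the 2×2 joint-detection table, with
  a Haldane–Anscombe +0.5 correction of the odds ratio when any cell is
  zero; captures coordinated on/off (dropout) structure.
* **correlation** — Spearman rank correlation over the cells detecting
  *both* genes (minimum co-detection count enforced), so level
  correlation is not driven by joint dropout, which the binary test
  already measures.

P values are Benjamini–Hochberg adjusted separately within each test
family across all pairs of a condition; an edge is kept when either
family's q-value clears alpha (an ``"both"`` conjunctive rule is
available).  Networks from two conditions are compared by partitioning
the edge union into common / condition-A-only / condition-B-only classes,
and remodeling is related to noise by contrasting the CV gains of the
genes each edge class recruits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .noise import ExpressionMatrix, NoiseComparison

__all__ = [
    "BinaryAssociation",
    "CorrelationAssociation",
    "Edge",
    "GeneNetwork",
    "EdgeComparison",
    "binary_association",
    "correlation_association",
    "build_network",
    "classify_edges",
    "target_subnetwork_degrees",
    "edge_cv_gain_comparison",
]


@dataclass
class BinaryAssociation:
    odds_ratio: float
    p: float
    table: np.ndarray
    defined: bool
    corrected: bool


@dataclass
class CorrelationAssociation:
    rho: float
    p: float
    n_codetected: int
    defined: bool


def binary_association(det_a, det_b) -> BinaryAssociation:
    """Odds ratio and Fisher exact p for the joint-detection 2×2 table.

    Table rows are (a detected, a undetected), columns (b detected, b
    undetected).  The +0.5 Haldane–Anscombe correction is applied to the
    odds ratio only when some cell is zero.  A gene detected in all or no
    cells has no binary contrast; the result is flagged undefined (not an
    error).
    """
    det_a = np.asarray(det_a, dtype=bool)
    det_b = np.asarray(det_b, dtype=bool)
    if det_a.shape != det_b.shape or det_a.ndim != 1:
        raise ValueError("detection vectors must be 1-D and equal length")
    if len(det_a) < 10:
        raise ValueError("binary association requires at least 10 cells")
    n11 = int(np.sum(det_a & det_b))
    n10 = int(np.sum(det_a & ~det_b))
    n01 = int(np.sum(~det_a & det_b))
    n00 = int(np.sum(~det_a & ~det_b))
    table = np.array([[n11, n10], [n01, n00]])
    defined = 0 < det_a.sum() < len(det_a) and 0 < det_b.sum() < len(det_b)
    corrected = bool(np.any(table == 0))
    t = table + 0.5 if corrected else table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return BinaryAssociation(
        odds_ratio=float(odds), p=float(p), table=table, defined=bool(defined), corrected=corrected
    )


def correlation_association(val_a, val_b, min_codetect: int = 10) -> CorrelationAssociation:
    """Spearman rank correlation (average-rank ties, two-sided p) over
    cells detecting both genes; flagged unavailable below ``min_codetect``
    co-detected cells or for a constant vector."""
    val_a = np.asarray(val_a, dtype=float)
    val_b = np.asarray(val_b, dtype=float)
    if val_a.shape != val_b.shape:
        raise ValueError("value vectors must have equal length")
    both = np.isfinite(val_a) & np.isfinite(val_b)
    n = int(both.sum())
    if n < min_codetect:
        return CorrelationAssociation(np.nan, np.nan, n, False)
    a, b = val_a[both], val_b[both]
    if np.all(a == a[0]) or np.all(b == b[0]):
        return CorrelationAssociation(np.nan, np.nan, n, False)
    rho, p = stats.spearmanr(a, b)
    return CorrelationAssociation(float(rho), float(p), n, True)


@dataclass(frozen=True)
class Edge:
    """A significant association between two genes in one condition; the
    pair is stored in canonical (sorted) order."""

    gene_a: str
    gene_b: str
    condition: str
    spearman_rho: float
    spearman_p: float
    spearman_q: float
    n_codetected: int
    odds_ratio: float
    or_p: float
    or_q: float
    significant_by: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-loops are not allowed")
        if self.gene_a > self.gene_b:
            raise ValueError("edge pair must be in canonical (sorted) order")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class GeneNetwork:
    """Significant associations among panel genes for one condition."""

    condition: str
    nodes: pd.DataFrame  # indexed by gene; boolean column is_h3k9ac_target
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes.index)
        pairs = set()
        for e in self.edges:
            if e.gene_a not in node_set or e.gene_b not in node_set:
                raise ValueError(f"edge endpoint outside node universe: {e.gene_a}-{e.gene_b}")
            if e.pair in pairs:
                raise ValueError(f"duplicate edge {e.gene_a}-{e.gene_b}")
            pairs.add(e.pair)

    @property
    def edge_pairs(self) -> set[frozenset]:
        return {e.pair for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "gene_a", "gene_b", "condition", "spearman_rho", "spearman_p", "spearman_q",
            "n_codetected", "odds_ratio", "or_p", "or_q", "significant_by",
        ]
        rows = [
            {c: (",".join(getattr(e, c)) if c == "significant_by" else getattr(e, c)) for c in cols}
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=cols)


def build_network(
    matrix: ExpressionMatrix,
    condition: str,
    alpha: float = 0.05,
    min_codetect: int = 10,
    edge_rule: str = "either",
) -> GeneNetwork:
    """Infer the association network for one condition.

    All unordered pairs of panel genes (spike-ins excluded) are scored by
    both association measures; BH adjustment runs separately per test
    family across the condition's pairs; an edge is retained when the
    ``edge_rule`` ("either" or "both") is met at q < alpha.
    """
    if edge_rule not in ("either", "both"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    sub = matrix.subset_condition(condition)
    genes = list(sub.genes)
    if len(genes) < 2:
        raise ValueError("panel must contain at least 2 genes")
    det = sub.detected[genes].to_numpy()
    vals = sub.values[genes].to_numpy()

    records = []
    for i, j in combinations(range(len(genes)), 2):
        ba = binary_association(det[:, i], det[:, j])
        ca = correlation_association(vals[:, i], vals[:, j], min_codetect=min_codetect)
        records.append((genes[i], genes[j], ba, ca))

    or_p = np.array([r[2].p if r[2].defined else np.nan for r in records])
    rho_p = np.array([r[3].p if r[3].defined else np.nan for r in records])
    or_q = _bh_with_nan(or_p)
    rho_q = _bh_with_nan(rho_p)

    edges = []
    for k, (ga, gb, ba, ca) in enumerate(records):
        sig = []
        if ba.defined and or_q[k] < alpha:
            sig.append("binary")
        if ca.defined and rho_q[k] < alpha:
            sig.append("correlation")
        keep = bool(sig) if edge_rule == "either" else len(sig) == 2
        if keep:
            ga, gb = sorted((ga, gb))
            edges.append(
                Edge(
                    gene_a=ga,
                    gene_b=gb,
                    condition=condition,
                    spearman_rho=ca.rho,
                    spearman_p=ca.p,
                    spearman_q=float(rho_q[k]),
                    n_codetected=ca.n_codetected,
                    odds_ratio=ba.odds_ratio,
                    or_p=ba.p,
                    or_q=float(or_q[k]),
                    significant_by=tuple(sig),
                )
            )
    node_flags = matrix.gene_meta.loc[genes, ["is_h3k9ac_target"]] if (
        "is_h3k9ac_target" in matrix.gene_meta.columns
    ) else pd.DataFrame({"is_h3k9ac_target": False}, index=genes)
    return GeneNetwork(condition=condition, nodes=node_flags, edges=edges)


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    """BH over the defined entries only; NaN passes through."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class EdgeComparison:
    """Partition of two networks' edge union into common / A-only / B-only."""

    network_a: GeneNetwork
    network_b: GeneNetwork
    common: set[frozenset]
    only_a: set[frozenset]
    only_b: set[frozenset]

    def class_of(self, pair: frozenset) -> str:
        if pair in self.common:
            return "common"
        if pair in self.only_a:
            return "only_a"
        if pair in self.only_b:
            return "only_b"
        raise KeyError(f"pair {set(pair)} not in either network")


def classify_edges(net_a: GeneNetwork, net_b: GeneNetwork) -> EdgeComparison:
    """Partition the union of both networks' edge pairs by identity
    (statistics ignored).  The node universes must agree."""
    nodes_a, nodes_b = set(net_a.nodes.index), set(net_b.nodes.index)
    if nodes_a != nodes_b:
        missing = sorted(nodes_a ^ nodes_b)
        raise ValueError(f"node universes differ; mismatched genes: {missing}")
    pa, pb = net_a.edge_pairs, net_b.edge_pairs
    return EdgeComparison(
        network_a=net_a,
        network_b=net_b,
        common=pa & pb,
        only_a=pa - pb,
        only_b=pb - pa,
    )


def target_subnetwork_degrees(comparison: EdgeComparison, target_flags: dict[str, bool] | pd.Series) -> pd.DataFrame:
    """Edge counts incident to target-flagged vs nontarget nodes, per
    condition.  An edge joining a target to a nontarget counts once in
    each group."""
    flags = pd.Series(target_flags)
    for net in (comparison.network_a, comparison.network_b):
        uncovered = set(net.nodes.index) - set(flags.index)
        if uncovered:
            raise ValueError(f"target flags missing for nodes: {sorted(uncovered)}")
    rows = []
    for net in (comparison.network_a, comparison.network_b):
        t = nt = 0
        for e in net.edges:
            incident = {e.gene_a, e.gene_b}
            if any(flags[g] for g in incident):
                t += 1
            if any(not flags[g] for g in incident):
                nt += 1
        rows.append({"condition": net.condition, "target_edges": t, "nontarget_edges": nt,
                     "total_edges": len(net.edges)})
    return pd.DataFrame(rows).set_index("condition")


@dataclass
class EdgeGainComparison:
    """CV-gain samples per edge class and the pairwise class contrasts."""

    gains: dict[str, np.ndarray]
    tests: pd.DataFrame
    mode: str


def edge_cv_gain_comparison(
    comparison: EdgeComparison,
    noise: NoiseComparison,
    mode: str = "partner",
    centers: set[str] | None = None,
) -> EdgeGainComparison:
    """Contrast CV gains recruited by common vs condition-unique edges.

    ``mode="partner"`` (default, for subnetworks centered on a set of
    ``centers`` genes): each edge contributes the CV gain of its non-center
    endpoint (mean of both if neither or both are centers).
    ``mode="mean"``: each edge contributes the mean gain of its two
    endpoints.  Classes with at least 2 usable gains are compared pairwise
    by two-sided Welch t test; classes too small are flagged skipped.
    """
    if mode not in ("partner", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "partner" and not centers:
        raise ValueError("mode='partner' requires a nonempty centers set")
    gain_by_gene = comparison.network_a.nodes.index.to_series().map(
        noise.per_gene["cv_gain"]
    )

    def edge_gain(pair: frozenset) -> float:
        a, b = sorted(pair)
        ga, gb = gain_by_gene.get(a, np.nan), gain_by_gene.get(b, np.nan)
        if mode == "partner":
            a_is_c, b_is_c = a in centers, b in centers
            if a_is_c and not b_is_c:
                return gb
            if b_is_c and not a_is_c:
                return ga
        return np.nanmean([ga, gb])

    gains = {}
    for cls, pairs in (("common", comparison.common), ("only_a", comparison.only_a),
                       ("only_b", comparison.only_b)):
        g = np.array([edge_gain(p) for p in pairs], dtype=float)
        gains[cls] = g[np.isfinite(g)]

    rows = []
    for ca, cb in (("only_b", "common"), ("only_a", "common"), ("only_b", "only_a")):
        ga, gb = gains[ca], gains[cb]
        if len(ga) < 2 or len(gb) < 2:
            rows.append({"class_a": ca, "class_b": cb, "n_a": len(ga), "n_b": len(gb),
                         "mean_diff": np.nan, "t": np.nan, "p": np.nan, "skipped": True})
            continue
        if np.ptp(ga) == 0 and np.ptp(gb) == 0:
            # degenerate: constant samples; no evidence either way at equal means
            t, p = (0.0, 1.0) if ga[0] == gb[0] else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(ga, gb, equal_var=False)
        rows.append({"class_a": ca, "class_b": cb, "n_a": len(ga), "n_b": len(gb),
                     "mean_diff": float(ga.mean() - gb.mean()), "t": float(t), "p": float(p),
                     "skipped": False})
    return EdgeGainComparison(gains=gains, tests=pd.DataFrame(rows), mode=mode)
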