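"""Subgroup co-expression networks, prognosis relevance values (PRV), and
the overlap + survival-filter feature selection.

For each anchor biomarker, patients are split into biomarker+ / biomarker-
subgroups (``prognet.stepminer``) and a co-expression network is built in
each subgroup by thresholding |Pearson r| over the pairs of a reference
interactome. A gene's PRV is the weighted symmetric-difference degree
between the two networks: genes whose interaction neighbourhood changes
with biomarker status score high. Candidates (top-k per anchor) are
intersected across all anchors and filtered by log-rank significance of
their own StepMiner split against overall survival.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stepminer
from . import survival as surv

__all__ = [
    "Interactome", "InteractionNetwork", "PRVTable", "BiomarkerPanel",
    "FeatureSelectionResult", "build_subgroup_network", "compute_prv",
    "select_candidates", "intersect_lists", "survival_filter",
    "run_feature_selection",
]

log = logging.getLogger(__name__)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair stored in lexicographic order."""
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Interactome:
    """Reference list of undirected gene-gene interaction pairs.

    Pairs are unique, self-loop free and stored canonically; optional
    confidence weights lie in [0, 1].
    """

    pairs: tuple[tuple[str, str], ...]
    weights: tuple[float, ...] | None = None

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]],
                   weights: Iterable[float] | None = None) -> "Interactome":
        seen: dict[tuple[str, str], float | None] = {}
        witer = iter(weights) if weights is not None else None
        for p in pairs:
            a, b = str(p[0]), str(p[1])
            w = next(witer) if witer is not None else None
            if a == b:
                raise ValueError(f"self-loop {a!r} not allowed in interactome")
            if w is not None and not 0.0 <= float(w) <= 1.0:
                raise ValueError(f"interactome weight {w} outside [0, 1]")
            seen.setdefault(canonical_pair(a, b), w)
        ordered = sorted(seen)
        ws = None
        if weights is not None:
            ws = tuple(float(seen[p]) for p in ordered)
        return cls(tuple(ordered), ws)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for p in self.pairs for g in p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in set(self.pairs)


@dataclass
class InteractionNetwork:
    """Correlation network of one biomarker subgroup.

    ``edges`` maps canonical interactome pairs to |Pearson r| weights
    (only pairs passing the threshold are present). ``nodes`` is the node
    universe: interactome genes measured in the expression matrix.
    """

    anchor: str
    subgroup: str  # "biomarker+" or "biomarker-"
    nodes: frozenset[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class PRVTable:
    """Per-gene prognosis relevance values for one anchor's network pair.

    ``table`` is indexed by gene symbol with columns ``prv`` (>= 0) and
    ``rank`` (1 = largest PRV; ties broken lexicographically by symbol).
    """

    anchor: str
    table: pd.DataFrame


@dataclass(frozen=True)
class BiomarkerPanel:
    """Literature anchors plus newly selected prognostic genes."""

    literature_genes: tuple[str, ...]
    novel_genes: tuple[str, ...]

    def __post_init__(self):
        if set(self.literature_genes) & set(self.novel_genes):
            raise ValueError("literature and novel gene lists must be disjoint")

    @property
    def combined(self) -> tuple[str, ...]:
        return self.literature_genes + self.novel_genes

    def __len__(self) -> int:
        return len(self.combined)


@dataclass
class FeatureSelectionResult:
    panel: BiomarkerPanel
    prv_tables: dict[str, PRVTable]
    candidate_lists: dict[str, list[str]]
    overlap: set[str]
    survival_pvalues: dict[str, float]


def build_subgroup_network(expression: pd.DataFrame,
                           sample_subset: Sequence[str],
                           interactome: Interactome,
                           r_threshold: float = 0.6,
                           anchor: str = "",
                           subgroup: str = "") -> InteractionNetwork:
    """Correlation-threshold network over interactome pairs in one subgroup.

    For each interactome pair with both genes measured, Pearson r is
    computed across ``sample_subset``; the edge is kept iff
    ``|r| >= r_threshold`` with weight |r|. Zero-variance genes contribute
    no edges (logged). Requires at least 3 samples and a threshold in (0, 1).
    """
    sample_subset = list(sample_subset)
    if len(sample_subset) < 3:
        raise ValueError("subgroup must contain at least 3 samples")
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must lie in (0, 1)")
    measured = set(expression.index)
    pairs = [p for p in interactome.pairs if p[0] in measured and p[1] in measured]
    nodes = frozenset(g for p in pairs for g in p)
    net = InteractionNetwork(anchor, subgroup, nodes)
    if not pairs:
        return net
    genes = sorted(nodes)
    sub = expression.loc[genes, sample_subset].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    gidx = {g: i for i, g in enumerate(genes)}
    flagged_zero_var = set(np.asarray(genes)[norm == 0.0])
    if flagged_zero_var:
        log.info("excluding %d zero-variance genes from %s/%s network",
                 len(flagged_zero_var), anchor, subgroup)
    for a, b in pairs:
        ia, ib = gidx[a], gidx[b]
        if norm[ia] == 0.0 or norm[ib] == 0.0:
            continue
        r = float(centered[ia] @ centered[ib] / (norm[ia] * norm[ib]))
        if abs(r) >= r_threshold:
            net.edges[(a, b)] = abs(r)
    return net


def compute_prv(net_plus: InteractionNetwork,
                net_minus: InteractionNetwork) -> PRVTable:
    """Weighted symmetric-difference degree between the two subgroup networks.

    PRV(g) = sum over pairs (g, .) of |w_plus - w_minus| where an absent
    edge has weight 0. Identical networks give all-zero PRV; swapping the
    two networks leaves every PRV unchanged.
    """
    if net_plus.nodes != net_minus.nodes:
        raise ValueError("subgroup networks must share the same node universe")
    prv: dict[str, float] = {g: 0.0 for g in net_plus.nodes}
    for pair in set(net_plus.edges) | set(net_minus.edges):
        d = abs(net_plus.edges.get(pair, 0.0) - net_minus.edges.get(pair, 0.0))
        prv[pair[0]] += d
        prv[pair[1]] += d
    genes = sorted(prv)
    tbl = pd.DataFrame({"prv": [prv[g] for g in genes]}, index=pd.Index(genes, name="gene"))
    order = sorted(genes, key=lambda g: (-prv[g], g))
    tbl.loc[order, "rank"] = np.arange(1, len(genes) + 1)
    tbl["rank"] = tbl["rank"].astype(int)
    anchor = net_plus.anchor or net_minus.anchor
    return PRVTable(anchor, tbl)


def select_candidates(prv: PRVTable, k: int = 30) -> list[str]:
    """Top-k genes by PRV rank for one anchor.

    The anchor gene itself is excluded before ranking, as are genes with
    PRV exactly 0 (no observed network difference carries no evidence;
    ranking zeros by the lexicographic tie rule would manufacture
    identical candidate lists from pure noise).
    """
    tbl = prv.table
    if k > len(tbl):
        raise ValueError(f"k={k} exceeds number of genes {len(tbl)}")
    keep = tbl[(tbl.index != prv.anchor) & (tbl["prv"] > 0.0)]
    order = keep.sort_values(["rank"]).index.tolist()
    return order[:k]


def intersect_lists(candidate_lists: Sequence[Iterable[str]]) -> set[str]:
    """Strict intersection of the per-anchor candidate lists."""
    lists = [set(lst) for lst in candidate_lists]
    if not lists:
        raise ValueError("need at least one candidate list")
    out = lists[0]
    for s in lists[1:]:
        out &= s
    return out


def survival_filter(genes: Iterable[str], expression: pd.DataFrame,
                    survival_table: pd.DataFrame, alpha: float = 0.01,
                    test: str = "logrank") -> tuple[list[str], dict[str, float]]:
    """Keep genes whose StepMiner split separates overall survival.

    Each gene's patients are dichotomized at its own step threshold and
    the two subgroups compared with a log-rank test (or univariate Cox
    when ``test='cox'``); genes with p < alpha survive. No multiplicity
    correction is applied (a raw per-gene threshold, default 0.01).
    Returns the retained genes (sorted) and all computed p-values.
    """
    ids = list(expression.columns)
    st = survival_table.loc[ids]
    times = st["time_months"].to_numpy(dtype=float)
    events = st["event"].to_numpy(dtype=int)
    kept, pvals = [], {}
    for g in sorted(set(genes)):
        try:
            plus = stepminer.dichotomize(expression, g).to_numpy()
        except ValueError:
            log.info("survival filter: dropping %s (degenerate step fit)", g)
            continue
        if test == "cox":
            res = surv.cox_univariate(plus.astype(int), times, events)
            p = res.p_value
        else:
            lr = surv.logrank(times[plus], events[plus], times[~plus], events[~plus])
            p = lr.p_value
        pvals[g] = float(p)
        if p < alpha:
            kept.append(g)
    return kept, pvals


def run_feature_selection(bundle, interactome: Interactome,
                          literature_genes: Sequence[str],
                          k: int = 30, r_threshold: float = 0.6,
                          alpha: float = 0.01) -> FeatureSelectionResult:
    """Full systems-level selector: dichotomize on each anchor, build the
    subgroup network pair, rank genes by PRV, intersect the per-anchor
    candidate lists, and keep overlap genes significant for survival.

    Returns a result whose ``panel`` combines the literature anchors with
    the surviving novel genes. An empty overlap yields an empty novel list
    (panel = literature only) with a warning.
    """
    expr = bundle.expression
    missing = [g for g in literature_genes if g not in expr.index]
    if missing:
        raise KeyError(f"literature genes missing from expression: {missing}")
    prv_tables: dict[str, PRVTable] = {}
    candidates: dict[str, list[str]] = {}
    for anchor in literature_genes:
        plus = stepminer.dichotomize(expr, anchor)
        ids_plus = list(plus.index[plus])
        ids_minus = list(plus.index[~plus])
        net_p = build_subgroup_network(expr, ids_plus, interactome, r_threshold,
                                       anchor, "biomarker+")
        net_m = build_subgroup_network(expr, ids_minus, interactome, r_threshold,
                                       anchor, "biomarker-")
        prv = compute_prv(net_p, net_m)
        prv_tables[anchor] = prv
        candidates[anchor] = select_candidates(prv, k=min(k, len(prv.table)))
    overlap = intersect_lists([candidates[a] for a in literature_genes])
    overlap -= set(literature_genes)
    if not overlap:
        log.warning("candidate overlap across anchors is empty; "
                    "panel falls back to literature genes only")
        novel, pvals = [], {}
    else:
        novel, pvals = survival_filter(overlap, expr, bundle.survival, alpha=alpha)
    panel = BiomarkerPanel(tuple(literature_genes), tuple(novel))
    return FeatureSelectionResult(panel, prv_tables, candidates, overlap, pvals)
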