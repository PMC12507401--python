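"""Thresholded co-abundance networks and guild-level connectivity metrics.

An edge joins two OTUs when the SparCC correlation passes |rho| > 0.4 and
permutation p < 0.05 (both strict).  Edge weight is |rho|, so negative
correlations contribute positively to the "weighted edges" totals; intra- vs
inter-guild connectivity splits the weighted total by whether both endpoints
share a guild.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, ValidationError
from .sparcc import SparccResult, estimate_correlations, sparcc_pvalues

EDGE_COLUMNS = ("otu_a", "otu_b", "rho", "pvalue", "weight")


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns EDGE_COLUMNS, otu_a < otu_b

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def weighted_edges(self) -> float:
        return float(self.edges["weight"].sum())


@dataclass
class ConnectivityReport:
    n_edges: int
    weighted_edges: float
    degree: pd.Series
    weighted_degree: pd.Series
    intra_weighted: float | None = None
    inter_weighted: float | None = None


def build_network(
    r: SparccResult, r_threshold: float = 0.4, p_threshold: float = 0.05
) -> CorrelationNetwork:
    """Keep pairs with |rho| strictly above and p strictly below threshold."""
    if not (0 < r_threshold < 1 and 0 < p_threshold < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    if r.pvalue is None:
        raise ValidationError("SparccResult has no p-values; run sparcc_pvalues")
    p = len(r.otu_ids)
    iu, ju = np.triu_indices(p, k=1)
    rho = r.rho[iu, ju]
    pval = r.pvalue[iu, ju]
    keep = (np.abs(rho) > r_threshold) & (pval < p_threshold)
    edges = pd.DataFrame(
        {
            "otu_a": np.asarray(r.otu_ids)[iu[keep]],
            "otu_b": np.asarray(r.otu_ids)[ju[keep]],
            "rho": rho[keep],
            "pvalue": pval[keep],
            "weight": np.abs(rho[keep]),
        }
    )
    # canonical ordering within a pair and across rows
    flip = edges["otu_a"] > edges["otu_b"]
    edges.loc[flip, ["otu_a", "otu_b"]] = edges.loc[flip, ["otu_b", "otu_a"]].values
    edges = edges.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)
    return CorrelationNetwork(nodes=list(r.otu_ids), edges=edges)


def connectivity(
    net: CorrelationNetwork, partition: dict[str, int] | None = None
) -> ConnectivityReport:
    """Edge totals, per-node (weighted) degree, and the intra/inter split."""
    degree = pd.Series(0.0, index=net.nodes)
    wdegree = pd.Series(0.0, index=net.nodes)
    for col in ("otu_a", "otu_b"):
        counts = net.edges[col].value_counts()
        if len(counts):
            degree += counts.reindex(degree.index, fill_value=0.0)
        wsum = net.edges.groupby(col)["weight"].sum()
        if len(wsum):
            wdegree += wsum.reindex(wdegree.index, fill_value=0.0)
    report = ConnectivityReport(
        n_edges=net.n_edges,
        weighted_edges=net.weighted_edges,
        degree=degree,
        weighted_degree=wdegree,
    )
    if partition is not None:
        missing = [n for n in net.nodes if n not in partition]
        if missing:
            raise ValidationError(
                f"partition does not cover node {missing[0]!r} "
                f"({len(missing)} missing)"
            )
        if net.n_edges:
            same = (
                net.edges["otu_a"].map(partition).to_numpy()
                == net.edges["otu_b"].map(partition).to_numpy()
            )
            w = net.edges["weight"].to_numpy()
            report.intra_weighted = float(w[same].sum())
            report.inter_weighted = float(w[~same].sum())
        else:
            report.intra_weighted = 0.0
            report.inter_weighted = 0.0
    return report


def group_connectivity_contrast(
    tables: dict[str, OtuTable],
    reference: str,
    partition: dict[str, int],
    r_threshold: float = 0.4,
    p_threshold: float = 0.05,
    n_permutations: int = 199,
    min_samples: int = 30,
    seed: int | None = None,
    pseudo: float = 0.5,
) -> dict[str, tuple[float, float]]:
    """Intra/inter weighted-edge differences of each group vs a reference.

    SparCC and the network are re-estimated per group on the shared OTU set
    with the cohort-level guild partition held fixed; the same permutation
    seed is used for every group so identical tables give identical networks.
    """
    if reference not in tables:
        raise ValidationError(f"reference group {reference!r} not among tables")
    shared = None
    for t in tables.values():
        shared = set(t.otu_ids) if shared is None else shared & set(t.otu_ids)
    shared = sorted(shared)

    def _report(t: OtuTable) -> ConnectivityReport | None:
        if t.n_samples < min_samples:
            return None
        sub = OtuTable(t.counts[shared].copy())
        res = estimate_correlations(sub, pseudo=pseudo)
        sparcc_pvalues(sub, res, n_permutations=n_permutations, seed=seed)
        net = build_network(res, r_threshold, p_threshold)
        return connectivity(net, partition)

    ref_report = _report(tables[reference])
    if ref_report is None:
        raise ValidationError(f"reference group {reference!r} below min_samples")
    out: dict[str, tuple[float, float]] = {}
    for label, t in tables.items():
        rep = _report(t)
        if rep is None:
            import warnings

            warnings.warn(f"group {label!r} below min_samples; skipped", stacklevel=2)
            continue
        out[label] = (
            rep.intra_weighted - ref_report.intra_weighted,
            rep.inter_weighted - ref_report.inter_weighted,
        )
    return out


def write_edge_list(net: CorrelationNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
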