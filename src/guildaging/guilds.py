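"""Guild construction: Ward clustering of 1 - rho and PERMANOVA tree cutting.

A guild is a clade of the Ward tree built on the correlation-derived
distance D = 1 - rho whose internal structure is *not* heterogeneous enough
to keep splitting: descending from the root, each split into two child
clades is tested by PERMANOVA (OTUs as observations, child membership as the
grouping factor, D restricted to the clade as the dissimilarity) and
accepted only while p < alpha and both children meet a size floor.  Rejected
nodes become guilds, so every OTU ends in exactly one guild.

Partitions are compared with the normalized variation of information
NVI = VI / log n in [0, 1]; 1 - NVI is the similarity reported downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .diversity import two_group_permanova_fast
from .io import OtuTable, ValidationError
from .network import CorrelationNetwork
from .sparcc import SparccResult


@dataclass
class GuildPartition:
    """OTU -> guild assignment (guild ids 1..K) with its provenance."""

    assignment: dict[str, int]
    dominant_otu: dict[int, str] = field(default_factory=dict)
    linkage: np.ndarray | None = None
    test_log: pd.DataFrame | None = None

    @property
    def n_guilds(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, guild_id: int) -> list[str]:
        return [o for o, g in self.assignment.items() if g == guild_id]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"otu_id": list(self.assignment), "guild_id": list(self.assignment.values())}
        ).sort_values(["guild_id", "otu_id"])
        dom = {v: k for k, v in self.dominant_otu.items()}
        df["is_dominant"] = df["otu_id"].map(lambda o: o in dom)
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GuildPartition":
        assignment = dict(zip(df["otu_id"].astype(str), df["guild_id"].astype(int)))
        dominant = {}
        if "is_dominant" in df.columns:
            for _, row in df[df["is_dominant"].astype(bool)].iterrows():
                dominant[int(row["guild_id"])] = str(row["otu_id"])
        return cls(assignment=assignment, dominant_otu=dominant)


def correlation_to_distance(r: SparccResult) -> pd.DataFrame:
    """D = 1 - rho; 0 on the diagonal, values in [0, 2]."""
    D = 1.0 - r.rho
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=r.otu_ids, columns=r.otu_ids)


def ward_tree(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward linkage on a precomputed distance matrix (condensed internally)."""
    A = np.asarray(D, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    return linkage(squareform(A, checks=False), method="ward")


def _tree_leaves(Z: np.ndarray) -> dict[int, list[int]]:
    """Leaf sets of every node of a scipy linkage matrix."""
    n = Z.shape[0] + 1
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, *_rest) in enumerate(Z):
        leaves[n + k] = leaves[int(a)] + leaves[int(b)]
    return leaves


def cut_by_permanova(
    tree: np.ndarray,
    D: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 999,
    min_guild_size: int = 3,
    seed: int | None = None,
) -> GuildPartition:
    """Top-down recursive PERMANOVA cut of a Ward tree into guilds.

    Splits are accepted while heterogeneous (p < alpha) and both children
    hold at least ``min_guild_size`` OTUs; each rejected node becomes one
    guild.  Guild ids are assigned 1..K in dendrogram (leftmost-leaf) order.
    """
    if min_guild_size < 2:
        raise ValidationError("min_guild_size must be >= 2")
    otu_ids = list(D.index)
    A = np.asarray(D, dtype=float)
    D2_full = A**2
    n = len(otu_ids)
    if tree.shape[0] != n - 1:
        raise ValidationError("tree and distance matrix disagree on OTU count")
    leaves = _tree_leaves(tree)
    rng = np.random.default_rng(seed)
    log_rows = []
    guild_nodes: list[int] = []

    def descend(node: int) -> None:
        if node < n:  # leaf
            guild_nodes.append(node)
            return
        a, b = int(tree[node - n, 0]), int(tree[node - n, 1])
        la, lb = leaves[a], leaves[b]
        if min(len(la), len(lb)) < min_guild_size:
            guild_nodes.append(node)
            return
        idx = np.asarray(la + lb)
        mask = np.zeros(len(idx), dtype=bool)
        mask[: len(la)] = True
        D2 = D2_full[np.ix_(idx, idx)]
        f, p = two_group_permanova_fast(D2, mask, n_permutations, rng)
        log_rows.append(
            {
                "node": node,
                "size_a": len(la),
                "size_b": len(lb),
                "pseudo_F": f,
                "p": p,
                "accepted": p < alpha,
            }
        )
        if p < alpha:
            descend(a)
            descend(b)
        else:
            guild_nodes.append(node)

    descend(2 * n - 2)

    # dendrogram order: sort guilds by their leftmost leaf position
    order: dict[int, int] = {}

    def leftmost(node: int) -> int:
        return min(leaves[node])

    guild_nodes.sort(key=leftmost)
    assignment: dict[str, int] = {}
    for gid, node in enumerate(guild_nodes, start=1):
        for leaf in leaves[node]:
            assignment[otu_ids[leaf]] = gid
        order[node] = gid
    return GuildPartition(
        assignment=assignment,
        linkage=tree,
        test_log=pd.DataFrame(log_rows),
    )


def dominant_otus(
    p: GuildPartition, net: CorrelationNetwork, t: OtuTable
) -> dict[int, str]:
    """Per guild: highest weighted degree, falling back to mean relative
    abundance when the guild has no edges; exact ties go to the
    lexicographically smaller OTU id."""
    missing = [node for node in net.nodes if node not in p.assignment]
    if missing:
        raise ValidationError(f"partition does not cover network node {missing[0]!r}")
    wdeg = pd.Series(0.0, index=sorted(p.assignment))
    for col in ("otu_a", "otu_b"):
        s = net.edges.groupby(col)["weight"].sum()
        if len(s):
            wdeg = wdeg.add(s.reindex(wdeg.index, fill_value=0.0), fill_value=0.0)
    mean_rel = t.relative_abundance().mean(axis=0)
    result: dict[int, str] = {}
    for gid in sorted(set(p.assignment.values())):
        members = sorted(p.members(gid))
        w = wdeg.reindex(members, fill_value=0.0).astype(float)
        if w.max() > 0:
            result[gid] = w.idxmax()  # first occurrence = lexicographic winner
        else:
            result[gid] = mean_rel.reindex(members).fillna(0.0).idxmax()
    p.dominant_otu = result
    return result


def nvi(p1: GuildPartition, p2: GuildPartition) -> float:
    """Normalized variation of information between two partitions.

    Computed on the shared OTU universe with natural logs:
    VI = H(P1) + H(P2) - 2 I(P1; P2), NVI = VI / log(n).  0 for identical
    partitions; 1 for maximally informative disagreement.
    """
    shared = sorted(set(p1.assignment) & set(p2.assignment))
    n = len(shared)
    if n < 2:
        raise ValidationError("need at least 2 shared OTUs to compare partitions")
    a = np.asarray([p1.assignment[o] for o in shared])
    b = np.asarray([p2.assignment[o] for o in shared])
    joint = pd.crosstab(a, b).to_numpy(dtype=float) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_a, h_b = entropy(pa), entropy(joint.sum(axis=0))
    nzi, nzj = np.nonzero(joint)
    mi = float(
        (
            joint[nzi, nzj]
            * np.log(joint[nzi, nzj] / (pa[nzi] * pb[nzj]))
        ).sum()
    )
    vi = h_a + h_b - 2.0 * mi
    return max(0.0, vi / math.log(n))


def guild_abundance(t: OtuTable, p: GuildPartition) -> pd.DataFrame:
    """Samples x guilds table of summed member counts (totals conserved)."""
    unassigned = [o for o in t.otu_ids if o not in p.assignment]
    if unassigned:
        raise ValidationError(f"OTU {unassigned[0]!r} not assigned to any guild")
    gids = pd.Series({o: p.assignment[o] for o in t.otu_ids})
    out = t.counts.T.groupby(gids).sum().T
    out.columns = [int(c) for c in out.columns]
    return out
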