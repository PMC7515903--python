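"""Amino-acid composition analysis of repetitive silk domains.

Silk mechanical classes track the residue economy of the repetitive domain
more than its exact sequence, so spidroins are compared here by their
20-dimensional amino-acid frequency vectors: a Pearson correlation matrix
across (species, family) rows and average-linkage hierarchical clustering
on the 1 - r distance.  Orthologs of one family across species should
cluster together before joining any other family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._seq import STANDARD_AA


def aa_frequencies(repeat_domain_aa: str) -> np.ndarray:
    """Frequency vector over the 20 canonical residues.

    Non-standard residues (X, B, Z, *, gaps...) are excluded from the
    denominator; the result sums to 1 for any sequence containing at least
    one canonical residue.
    """
    if not repeat_domain_aa:
        raise ValueError("empty amino-acid sequence")
    seq = repeat_domain_aa.upper()
    counts = np.array([seq.count(aa) for aa in STANDARD_AA], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical residues in sequence")
    return counts / total


@dataclass
class CompositionMatrix:
    labels: list[str]             # "(species, family)" row labels
    values: np.ndarray            # (n_rows, 20)

    @classmethod
    def from_sequences(cls, rows: list[tuple[str, str]]) -> "CompositionMatrix":
        labels = [lab for lab, _ in rows]
        values = np.vstack([aa_frequencies(seq) for _, seq in rows])
        return cls(labels, values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=list(STANDARD_AA))


def correlation_matrix(m: CompositionMatrix) -> pd.DataFrame:
    """Pearson r between all row pairs; symmetric with unit diagonal."""
    r = np.corrcoef(m.values)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.labels, columns=m.labels)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    flat_groups: dict[str, int]
    cut_height: float

    def newick(self) -> str:
        if len(self.labels) == 1:
            return self.labels[0] + ";"
        root = hierarchy.to_tree(self.linkage)
        return _tree_to_newick(root, self.labels) + ";"


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster(
    m: CompositionMatrix,
    method: str = "average",
    cut_height: float = 0.5,
) -> ClusterResult:
    """Hierarchical clustering on 1 - Pearson r.

    Average linkage by default; the dendrogram is deterministic given row
    order (scipy breaks distance ties by merge index).  Flat groups are
    reported at ``cut_height`` alongside the full dendrogram so the
    two-group reading is never the only output.
    """
    if len(m.labels) == 1:
        return ClusterResult(np.empty((0, 4)), list(m.labels), {m.labels[0]: 1}, cut_height)
    r = correlation_matrix(m).to_numpy()
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(d, checks=False), method=method)
    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    return ClusterResult(z, list(m.labels), dict(zip(m.labels, map(int, flat))), cut_height)


def family_coherence(result: ClusterResult, family_of: dict[str, str]) -> dict[str, bool]:
    """Whether each family's rows form a pure subtree of the dendrogram.

    True for a family iff some dendrogram node's leaf set equals exactly
    that family's rows — i.e. all orthologs merge with each other before
    any cross-family merge.
    """
    labels = result.labels
    fam_sets = {}
    for lab, fam in family_of.items():
        fam_sets.setdefault(fam, set()).add(lab)
    node_sets = []
    if len(labels) == 1:
        node_sets.append({labels[0]})
    else:
        root, nodes = hierarchy.to_tree(result.linkage, rd=True)
        for node in nodes:
            node_sets.append({labels[i] for i in node.pre_order(lambda n: n.id)})
    return {fam: members in node_sets for fam, members in fam_sets.items()}


def plot_heatmap(m: CompositionMatrix, path, method: str = "average") -> None:
    """Clustered correlation heatmap (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = correlation_matrix(m)
    res = cluster(m, method=method)
    if len(m.labels) > 1:
        order = hierarchy.leaves_list(res.linkage)
    else:
        order = [0]
    data = r.to_numpy()[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(data, vmin=-1, vmax=1, cmap="RdBu_r")
    ticks = [m.labels[i] for i in order]
    ax.set_xticks(range(len(ticks)), ticks, rotation=90, fontsize=5)
    ax.set_yticks(range(len(ticks)), ticks, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
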