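"""Terminal-domain gene trees and family monophyly.

The non-repetitive terminal domains are the only alignable parts of silk
genes, so trees are built from the first 90 N-terminal or last 80
C-terminal residues: MAFFT alignment, Poisson-corrected distances
(d = -ln(1 - p) on the mismatch proportion with pairwise gap deletion),
neighbor-joining with a deterministic tie-break, and nonparametric
bootstrap support from alignment-column resampling.  A family is
monophyletic when some edge bipartition of the tree separates exactly its
members from everything else.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# ----------------------------------------------------------------------
# terminal trimming
# ----------------------------------------------------------------------
N_TERM_LEN = 90
C_TERM_LEN = 80


@dataclass
class TerminalRecord:
    taxon: str
    family: str
    end: str                   # "N" | "C"
    sequence: str
    short: bool = False


@dataclass
class TerminalDomainSet:
    end: str
    records: list[TerminalRecord] = field(default_factory=list)


def trim_terminals(
    proteins: list[tuple[str, str, str]], end: str
) -> TerminalDomainSet:
    """Exact-slice terminal peptides: first 90 (N) or last 80 (C) residues.

    ``proteins`` rows are ``(taxon, family, aa_sequence)``.  Shorter source
    sequences are kept whole and flagged; empty sequences are an error.
    """
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    limit = N_TERM_LEN if end == "N" else C_TERM_LEN
    out = TerminalDomainSet(end=end)
    for taxon, family, seq in proteins:
        if not seq:
            raise ValueError(f"empty sequence for taxon {taxon}")
        trimmed = seq[:limit] if end == "N" else seq[-limit:]
        out.records.append(
            TerminalRecord(taxon, family, end, trimmed, short=len(seq) < limit)
        )
    return out


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------
@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        mat = np.array([list(r) for r in self.rows])
        return Alignment(list(self.ids), ["".join(row) for row in mat[:, cols]])


def align_terminals(terms: TerminalDomainSet) -> Alignment:
    """Multiple alignment of the trimmed terminals (MAFFT-backed).

    A single sequence is returned unchanged; otherwise MAFFT (--auto,
    case-preserving) produces the MSA.  Ungapping any row recovers its
    input sequence exactly.
    """
    ids = [r.taxon for r in terms.records]
    seqs = [r.sequence for r in terms.records]
    if len(seqs) <= 1:
        return Alignment(ids, seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        with open(fa, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", "--preservecase", "--anysymbol", str(fa)],
            capture_output=True, text=True, check=True,
        )
    aligned: dict[str, str] = {}
    key = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            key = line[1:].strip()
            aligned[key] = ""
        elif key is not None:
            aligned[key] += line.strip()
    rows = [aligned[f"s{i}"] for i in range(len(seqs))]
    return Alignment(ids, rows)


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------
def distance_matrix(
    msa: Alignment, model: str = "poisson", max_distance: float = 10.0
) -> pd.DataFrame:
    """Pairwise distances with pairwise gap deletion.

    ``poisson``: d = -ln(1 - p) on the mismatch proportion p over ungapped
    column pairs; ``p`` (raw proportion) also available.  Saturated pairs
    (p -> 1, or no comparable columns) are capped at ``max_distance``.
    """
    n = len(msa.ids)
    mat = np.array([list(r) for r in msa.rows])
    gap = (mat == "-") | (mat == ".")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = ok.sum()
            if m == 0:
                dist = max_distance
            else:
                p = float((mat[i, ok] != mat[j, ok]).mean())
                if model == "p":
                    dist = p
                elif model == "poisson":
                    dist = -np.log(1.0 - p) if p < 1.0 - 1e-12 else max_distance
                else:
                    raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = min(dist, max_distance)
    return pd.DataFrame(d, index=msa.ids, columns=msa.ids)


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class SupportTree:
    root: TreeNode               # unrooted tree stored with a basal multifurcation

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set on the child side."""
        all_leaves = self.root.leaf_names()
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_names()
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def newick(self) -> str:
        return self.root.newick()


def nj_tree(dist: pd.DataFrame) -> SupportTree:
    """Canonical neighbor joining; ties broken by the lowest (row, col) pair.

    On an additive distance matrix this recovers the generating topology
    and branch lengths exactly.  Supports are left unset.
    """
    ids = list(dist.index)
    d = dist.to_numpy().astype(float).copy()
    nodes = [TreeNode(name=i) for i in ids]
    if len(nodes) < 2:
        raise ValueError("need at least two taxa")
    if len(nodes) == 2:
        nodes[0].length = nodes[1].length = d[0, 1] / 2.0
        return SupportTree(TreeNode(children=nodes))
    active = list(range(len(nodes)))
    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        ai, aj = divmod(flat, n)   # argmin returns the first minimum in row order
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        li = sub[ai, aj] / 2.0 + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = sub[ai, aj] - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(nodes)] = new_d
        d[: len(nodes), -1] = new_d
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    for idx, l in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = l
    return SupportTree(TreeNode(children=[nodes[i], nodes[j], nodes[k]]))


def bootstrap(
    msa: Alignment,
    reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> SupportTree:
    """NJ tree with bootstrap supports from column resampling.

    Support on each internal edge is the percentage of replicate trees (on
    column-resampled alignments) containing the same bipartition;
    ``reps=0`` returns the tree with supports unset.  Deterministic under a
    fixed seed and invariant to taxon input order up to leaf labels.
    """
    tree = nj_tree(distance_matrix(msa, model=model))
    if reps <= 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(reps):
        rep_tree = nj_tree(distance_matrix(msa.resample_columns(rng), model=model))
        rep_bps = rep_tree.bipartitions()
        all_leaves = rep_tree.root.leaf_names()
        rep_full = rep_bps | {all_leaves - bp for bp in rep_bps}
        for bp in counts:
            if bp in rep_full:
                counts[bp] += 1
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf():
            continue
        bp = node.leaf_names()
        if bp in counts:
            node.support = 100.0 * counts[bp] / reps
    return tree


def monophyly_report(
    tree: SupportTree, labels: dict[str, str]
) -> pd.DataFrame:
    """Per-family monophyly on a gene tree.

    A family is monophyletic iff some edge bipartition separates exactly
    its members (singletons are trivially monophyletic).  Returns a table
    with the family, its size, the verdict and the supporting bipartition's
    bootstrap support where available.
    """
    all_leaves = tree.root.leaf_names()
    fams: dict[str, set[str]] = {}
    for taxon, fam in labels.items():
        fams.setdefault(fam, set()).add(taxon)
    support_of: dict[frozenset[str], float | None] = {}
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf():
            continue
        support_of[node.leaf_names()] = node.support
    rows = []
    for fam, members in sorted(fams.items()):
        mem = frozenset(members)
        if len(mem) == 1 or len(mem) == len(all_leaves):
            mono, sup = True, None
        else:
            comp = all_leaves - mem
            mono = mem in support_of or comp in support_of
            sup = support_of.get(mem, support_of.get(comp))
        rows.append(
            {"family": fam, "n_taxa": len(mem), "monophyletic": mono, "support": sup}
        )
    return pd.DataFrame(rows)


def read_newick(text: str) -> SupportTree:
    """Parse a newick string into a SupportTree (scikit-bio backed)."""
    import io

    from skbio import TreeNode as SkNode

    sk = SkNode.read(io.StringIO(text))

    def conv(n) -> TreeNode:
        node = TreeNode(
            name=n.name if n.is_tip() else None,
            length=n.length or 0.0,
            support=float(n.name) if (not n.is_tip() and n.name) else None,
        )
        node.children = [conv(c) for c in n.children]
        return node

    return SupportTree(conv(sk))
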