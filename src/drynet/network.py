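"""Differential network extraction and topological/entropic characterization.

The differential network D keeps the regulatory edges present in the
resistant network but absent from the sensitive one; its genes are the
candidates for resistance drivers.  Characterization covers degree tables,
a signed feedback-loop census (positive/negative 2-node loops and their
coupled 3-node combinations), and the local network entropy of each node —
the Shannon entropy of its normalized incoming interaction strengths,
higher when regulation is spread uniformly over many regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .grn import GRN

__all__ = [
    "DifferentialNetwork",
    "MotifCensus",
    "differential_network",
    "degree_table",
    "motif_census",
    "local_entropy",
    "entropies",
    "entropy_change",
]


@dataclass
class DifferentialNetwork:
    """Resistant-only edges over the induced node set V*.

    ``A_hat[i, j]`` is the resistant-network coefficient of the retained
    edge j -> i, restricted to the genes incident to at least one
    differential edge.
    """

    gene_ids: list[str]
    A_hat: np.ndarray
    resistant_genes: list[str] | None = None
    sensitive_genes: list[str] | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.A_hat))

    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "source": self.gene_ids[j],
                "target": self.gene_ids[i],
                "weight": self.A_hat[i, j],
                "sign": int(np.sign(self.A_hat[i, j])),
            }
            for i, j in np.argwhere(self.A_hat != 0)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
        return df.sort_values(["source", "target"], ignore_index=True)


def differential_network(
    resistant: GRN,
    sensitive: GRN,
    sign_flip_is_differential: bool = False,
) -> DifferentialNetwork:
    """Edges present in the resistant network and absent in the sensitive one.

    Edge identity is (source, target) presence; by default a sign or
    weight change of a shared edge does not make it differential
    (``sign_flip_is_differential`` switches that on).  Mismatched gene
    universes are intersected with a warning.  Weights are copied from
    the resistant network.
    """
    if resistant.gene_ids != sensitive.gene_ids:
        common = [g for g in resistant.gene_ids if g in set(sensitive.gene_ids)]
        warnings.warn(
            f"gene universes differ; intersecting to {len(common)} shared genes",
            stacklevel=2,
        )
        ri = [resistant.gene_ids.index(g) for g in common]
        si = [sensitive.gene_ids.index(g) for g in common]
        AR = resistant.A[np.ix_(ri, ri)]
        AS = sensitive.A[np.ix_(si, si)]
        genes = common
    else:
        AR, AS = resistant.A, sensitive.A
        genes = list(resistant.gene_ids)

    in_res = AR != 0
    in_sens = AS != 0
    if sign_flip_is_differential:
        shared = in_res & in_sens & (np.sign(AR) != np.sign(AS))
        keep = (in_res & ~in_sens) | shared
    else:
        keep = in_res & ~in_sens
    A_diff = np.where(keep, AR, 0.0)

    incident = (A_diff != 0).any(axis=0) | (A_diff != 0).any(axis=1)
    idx = np.flatnonzero(incident)
    sub = A_diff[np.ix_(idx, idx)]
    return DifferentialNetwork(
        [genes[i] for i in idx],
        sub,
        resistant_genes=list(resistant.gene_ids),
        sensitive_genes=list(sensitive.gene_ids),
    )


def _adjacency(net: GRN | DifferentialNetwork) -> tuple[list[str], np.ndarray]:
    if isinstance(net, GRN):
        return list(net.gene_ids), net.A
    return list(net.gene_ids), net.A_hat


def degree_table(net: GRN | DifferentialNetwork) -> pd.DataFrame:
    """Per-node in/out/total degree (edge counts, sign ignored)."""
    genes, A = _adjacency(net)
    nz = A != 0
    indeg = nz.sum(axis=1)  # regulators of i live along row i
    outdeg = nz.sum(axis=0)
    return pd.DataFrame(
        {"gene": genes, "in_degree": indeg, "out_degree": outdeg,
         "total_degree": indeg + outdeg}
    ).set_index("gene")


@dataclass
class MotifCensus:
    """Counts/percentages of signed feedback-loop classes.

    Two-node loops are reciprocal pairs i<->j: positive feedback (PF)
    when the two coefficients have the same sign, negative (NF) otherwise.
    Three-node classes are pairs of two-node loops sharing one gene,
    labelled by the two loop signs: PPF (both positive), PNF (mixed),
    NNF (both negative).
    """

    counts: dict[str, int]
    percentages: dict[str, float]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "MotifCensus":
        pct = {}
        two = counts["PF"] + counts["NF"]
        three = counts["PPF"] + counts["PNF"] + counts["NNF"]
        for k in ("PF", "NF"):
            pct[k] = 100.0 * counts[k] / two if two else 0.0
        for k in ("PPF", "PNF", "NNF"):
            pct[k] = 100.0 * counts[k] / three if three else 0.0
        return cls(dict(counts), pct)


def motif_census(net: GRN | DifferentialNetwork) -> MotifCensus:
    """Exhaustively enumerate signed 2-node and coupled 3-node feedback loops."""
    _, A = _adjacency(net)
    L = A.shape[0]
    loops: list[tuple[frozenset[int], int]] = []  # ({i, j}, loop sign)
    for i in range(L):
        for j in range(i + 1, L):
            if A[i, j] != 0 and A[j, i] != 0:
                sign = int(np.sign(A[i, j] * A[j, i]))
                loops.append((frozenset((i, j)), sign))
    counts = {"PF": 0, "NF": 0, "PPF": 0, "PNF": 0, "NNF": 0}
    for _, s in loops:
        counts["PF" if s > 0 else "NF"] += 1
    for (n1, s1), (n2, s2) in combinations(loops, 2):
        if len(n1 & n2) == 1:  # two loops coupled through one shared gene
            if s1 > 0 and s2 > 0:
                counts["PPF"] += 1
            elif s1 < 0 and s2 < 0:
                counts["NNF"] += 1
            else:
                counts["PNF"] += 1
    return MotifCensus.from_counts(counts)


def local_entropy(net: GRN | DifferentialNetwork, node: int | str) -> float:
    """Shannon entropy (bits) of a node's normalized incoming strengths.

    With incoming weights a_ij over regulators j, p_ij = |a_ij| / sum|a_ij|
    and S_i = -sum p log2 p.  A node with no regulators has entropy 0;
    the maximum log2(in-degree) is reached at uniform weights.
    """
    genes, A = _adjacency(net)
    i = genes.index(node) if isinstance(node, str) else node
    w = np.abs(A[i])
    w = w[w > 0]
    if w.size == 0:
        return 0.0
    p = w / w.sum()
    return float(-(p * np.log2(p)).sum())


def entropies(net: GRN | DifferentialNetwork) -> pd.Series:
    """Local entropy of every node, indexed by gene."""
    genes, _ = _adjacency(net)
    return pd.Series([local_entropy(net, g) for g in genes], index=genes,
                     name="entropy")


def entropy_change(
    resistant: GRN, sensitive: GRN, genes: list[str]
) -> pd.Series:
    """Delta S_i = S_i(resistant) - S_i(sensitive), in bits.

    A gene absent (or isolated) in either network contributes entropy 0
    on that side.
    """
    def side(net: GRN, g: str) -> float:
        return local_entropy(net, g) if g in net.gene_ids else 0.0

    return pd.Series(
        [side(resistant, g) - side(sensitive, g) for g in genes],
        index=list(genes),
        name="delta_entropy",
    )
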