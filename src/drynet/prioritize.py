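"""Node-importance scoring of differential-network genes.

Three complementary per-gene measures are combined: a hub score (principal
eigenvector of A·Aᵀ of the differential network's absolute adjacency,
oriented source->target as in HITS hub scoring), the local-entropy change
between resistant and sensitive networks, and an adaptation score built
from the relative expression response over the treatment window (0 -> T,
T = 48 h in the motivating experiment).  Each measure is ranked (average
ties) and the importance I_i is the normalized rank sum, so sum_i I_i = 1
and the index is invariant to monotone transforms of the raw measures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grn import GRN
from .network import DifferentialNetwork, entropy_change, entropies
from .preprocess import DenseTrajectories, TimeCourseMatrix

__all__ = [
    "hub_scores",
    "relative_response",
    "adaptation_scores",
    "node_metrics",
    "importance_scores",
]

_EPS = 1e-6


def hub_scores(diff: DifferentialNetwork) -> pd.Series:
    """Hub score per gene: principal eigenvector of M·Mᵀ, M = |Â| source-wise.

    M[u, v] = |weight of u -> v|, so M·Mᵀ measures shared out-targets and
    its principal eigenvector (the principal left singular vector of M)
    loads on genes that regulate many/strongly-regulated targets.  The
    vector is sign-fixed nonnegative and unit L2 norm.
    """
    if diff.n_genes == 0 or diff.n_edges == 0:
        raise ValueError("hub scores are undefined on an empty network")
    M = np.abs(diff.A_hat).T  # rows = sources
    U, s, _ = np.linalg.svd(M)
    h = U[:, 0]
    if h.sum() < 0:
        h = -h
    h = np.clip(h, 0.0, None)
    h = h / np.linalg.norm(h)
    return pd.Series(h, index=list(diff.gene_ids), name="hub")


def _endpoint_values(traj: TimeCourseMatrix | DenseTrajectories, gene: str,
                     T: float | None) -> tuple[float, float]:
    if isinstance(traj, TimeCourseMatrix):
        times, values = traj.times, traj.values
    else:
        times, values = traj.grid_times, traj.X
    i = traj.gene_ids.index(gene)
    t_final = times[-1] if T is None else T
    k = int(np.argmin(np.abs(times - t_final)))
    return float(values[i, 0]), float(values[i, k])


def relative_response(
    traj: TimeCourseMatrix | DenseTrajectories,
    gene: str,
    T: float | None = None,
) -> float:
    """R_i = (x_i(T) - x_i(0)) / x_i(0), guarded against zero baselines.

    ``T`` defaults to the final measured time (48 h in the motivating
    design); a baseline of 0 is replaced by the guard epsilon 1e-6.
    """
    x0, xT = _endpoint_values(traj, gene, T)
    return (xT - x0) / max(x0, _EPS)


def adaptation_scores(
    sens: TimeCourseMatrix | DenseTrajectories,
    res: TimeCourseMatrix | DenseTrajectories,
    genes: list[str],
    T: float | None = None,
) -> pd.DataFrame:
    """Adaptation D_i = R_i(resistant) / R_i(sensitive) per gene.

    Genes whose resistant-arm expression returns near baseline while the
    sensitive arm keeps changing get |D| near 0 — the adaptive signature.
    Zero sensitive responses are epsilon-guarded and flagged.
    """
    rows = []
    for g in genes:
        rS = relative_response(sens, g, T)
        rR = relative_response(res, g, T)
        guarded = abs(rS) < _EPS
        denom = rS if not guarded else np.copysign(_EPS, rS if rS != 0 else 1.0)
        D = rR / denom
        rows.append({"gene": g, "R_sensitive": rS, "R_resistant": rR,
                     "adaptation": D, "abs_adaptation": abs(D),
                     "guarded": guarded})
    return pd.DataFrame(rows).set_index("gene")


def node_metrics(
    diff: DifferentialNetwork,
    resistant: GRN,
    sensitive: GRN,
    sens_traj: TimeCourseMatrix | DenseTrajectories,
    res_traj: TimeCourseMatrix | DenseTrajectories,
    T: float | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene metric table for the differential network."""
    genes = list(diff.gene_ids)
    h = hub_scores(diff)
    dS = entropy_change(resistant, sensitive, genes)
    sS_all, sR_all = entropies(sensitive), entropies(resistant)
    sS = pd.Series({g: sS_all.get(g, 0.0) for g in genes})
    sR = pd.Series({g: sR_all.get(g, 0.0) for g in genes})
    ad = adaptation_scores(sens_traj, res_traj, genes, T)
    table = pd.DataFrame(
        {
            "hub": h,
            "entropy_sensitive": sS,
            "entropy_resistant": sR,
            "delta_entropy": dS,
            "R_sensitive": ad["R_sensitive"],
            "R_resistant": ad["R_resistant"],
            "adaptation": ad["adaptation"],
            "abs_adaptation": ad["abs_adaptation"],
        },
        index=genes,
    )
    table.index.name = "gene"
    return table


def importance_scores(
    metrics: pd.DataFrame,
    entropy_metric: str = "delta_entropy",
    adaptation_direction: str = "small_abs",
) -> pd.DataFrame:
    """Normalized rank-sum importance over the differential-network genes.

    Each metric is converted to ranks 1..L (average ties; L = most
    important): higher hub and higher entropy rank higher, and by default
    smaller |adaptation| ranks higher (an adaptive resistant gene moves
    little relative to its sensitive counterpart, so the literal response
    ratio is small; ``adaptation_direction='large_abs'`` flips this).
    I_i is the rank sum normalized to total 1; output is sorted
    descending by importance.
    """
    if len(metrics) < 2:
        raise ValueError("importance needs at least 2 genes")
    if entropy_metric not in ("delta_entropy", "entropy_resistant"):
        raise ValueError("entropy_metric must be 'delta_entropy' or 'entropy_resistant'")
    if adaptation_direction not in ("small_abs", "large_abs"):
        raise ValueError("adaptation_direction must be 'small_abs' or 'large_abs'")

    r_h = rankdata(metrics["hub"].to_numpy())
    r_s = rankdata(metrics[entropy_metric].to_numpy())
    a = metrics["abs_adaptation"].to_numpy()
    r_d = rankdata(-a) if adaptation_direction == "small_abs" else rankdata(a)

    rank_sum = r_h + r_s + r_d
    importance = rank_sum / rank_sum.sum()
    out = metrics.copy()
    out["rank_hub"] = r_h
    out["rank_entropy"] = r_s
    out["rank_adaptation"] = r_d
    out["importance"] = importance
    out = out.sort_values("importance", ascending=False, kind="mergesort")
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out
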