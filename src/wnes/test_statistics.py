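"""The five two-group network-difference statistics.

WNES (weighted nodes-and-edges statistic) is

    WNES = sum_k w_k * (xbar_Dk - xbar_Ck)^2 / (s2_Dk/n1 + s2_Ck/n2)
         + sum_m (betahat_Dm - betahat_Cm)^2 / (Var_Dm + Var_Cm)

over the K union nodes and M union edges of the merged structure, with
absent elements zero-filled.  Each node term U_k is the squared Welch
two-sample t statistic for that node; each edge term V_m standardizes the
difference of the per-group OLS edge strengths.  Companions: NES drops the
weights, NS keeps only the node sum, ES only the edge sum.

RT is an aligned-rank test: each column is aligned by subtracting the pooled
(combined-group) median, every subject's K aligned values are ranked within
the subject (midranks for ties), and RT is n1*n2/(n1+n2) times the squared
Euclidean distance between the two group mean rank vectors.  The leading
scalar is irrelevant under permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dag_core import (
    DirectedNetwork,
    MergedStructure,
    WeightScheme,
    merge_structures,
    merged_node_weights,
)
from .errors import DataInputError, DegenerateDataError
from .group_estimates import GroupData, GroupSummaries, summarize_group

STATISTIC_NAMES = ("wnes", "nes", "ns", "es", "rt")


def _safe_terms(num: np.ndarray, den: np.ndarray, labels, kind: str) -> np.ndarray:
    """num/den with the 0/0 -> 0 convention; 0 denominator with signal is an error."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = (den == 0) & (num != 0)
    if bad.any():
        where = labels[int(np.argmax(bad))]
        raise DegenerateDataError(
            f"{kind} {where!r}: zero variance in both groups but a nonzero difference"
        )
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def node_terms(
    summ_D: GroupSummaries, summ_C: GroupSummaries, n1: int, n2: int
) -> np.ndarray:
    """U_k = (mean_D,k - mean_C,k)^2 / (var_D,k/n1 + var_C,k/n2) per union node."""
    num = (summ_D.node_mean - summ_C.node_mean) ** 2
    den = summ_D.node_var / n1 + summ_C.node_var / n2
    return _safe_terms(num, den, summ_D.merged.union_nodes, "node")


def edge_terms(summ_D: GroupSummaries, summ_C: GroupSummaries) -> np.ndarray:
    """V_m = (beta_D,m - beta_C,m)^2 / (var_D,m + var_C,m) per union edge slot."""
    num = (summ_D.edge_beta - summ_C.edge_beta) ** 2
    den = summ_D.edge_var + summ_C.edge_var
    labels = ["->".join(s.representative) for s in summ_D.merged.slots]
    return _safe_terms(num, den, labels, "edge")


@dataclass
class StatisticResult:
    """Values of WNES/NES/NS/ES (and optionally RT) with their decomposition."""

    U: np.ndarray
    V: np.ndarray
    weights: np.ndarray
    ns: float
    es: float
    nes: float
    wnes: float
    rt: Optional[float] = None
    node_labels: tuple[str, ...] = ()
    edge_labels: tuple[tuple[str, str], ...] = ()
    n1: Optional[int] = None
    n2: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.U)

    @property
    def M(self) -> int:
        return len(self.V)

    def value(self, statistic: str) -> float:
        v = getattr(self, statistic.lower())
        if v is None:
            raise KeyError(f"statistic {statistic!r} was not computed")
        return float(v)

    def to_dict(self) -> dict:
        d = {
            "statistics": {s: self.value(s) for s in ("wnes", "nes", "ns", "es")},
            "node_terms": {
                l: {"U": float(u), "weight": float(w)}
                for l, u, w in zip(self.node_labels, self.U, self.weights)
            },
            "edge_terms": {
                "->".join(e): float(v) for e, v in zip(self.edge_labels, self.V)
            },
            "K": self.K,
            "M": self.M,
            "n1": self.n1,
            "n2": self.n2,
            "meta": dict(self.meta),
        }
        if self.rt is not None:
            d["statistics"]["rt"] = float(self.rt)
        return d


def combine_statistics(
    U: np.ndarray, V: np.ndarray, weights: np.ndarray, **extra
) -> StatisticResult:
    """Assemble NS, ES, NES and WNES from node terms, edge terms and weights."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if U.shape != weights.shape:
        raise DataInputError(
            f"length mismatch: {U.size} node terms vs {weights.size} weights"
        )
    ns = float(U.sum())
    es = float(V.sum())
    return StatisticResult(
        U=U,
        V=V,
        weights=weights,
        ns=ns,
        es=es,
        nes=ns + es,
        wnes=float(weights @ U) + es,
        **extra,
    )


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, GroupData):
        return data.values.to_numpy(dtype=float)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def aligned_ranks(pooled: np.ndarray, standardize: bool = False) -> np.ndarray:
    """Within-subject midranks of pooled-median-aligned (optionally scaled) data."""
    pooled = np.asarray(pooled, dtype=float)
    if standardize:
        sd = pooled.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DataInputError("cannot standardize a constant column for RT")
        pooled = (pooled - pooled.mean(axis=0)) / sd
    aligned = pooled - np.median(pooled, axis=0)
    return rankdata(aligned, axis=1)


def rt_statistic(data_D, data_C, standardize: bool = False) -> float:
    """Aligned-rank statistic RT = n1 n2/(n1+n2) * ||Wbar_D - Wbar_C||^2.

    Columns of the two matrices must be aligned to the same K variables
    (DataFrames are realigned by label); K >= 2 because within-subject ranks
    are undefined otherwise.  ``standardize`` scales each column over the
    pooled sample first, for panels mixing variables with different units.
    """
    if isinstance(data_D, (GroupData, pd.DataFrame)) and isinstance(
        data_C, (GroupData, pd.DataFrame)
    ):
        df_D = data_D.values if isinstance(data_D, GroupData) else data_D
        df_C = data_C.values if isinstance(data_C, GroupData) else data_C
        if set(df_D.columns) != set(df_C.columns):
            raise DataInputError("RT requires the same columns in both groups")
        df_C = df_C[df_D.columns]
        X_D, X_C = df_D.to_numpy(dtype=float), df_C.to_numpy(dtype=float)
    else:
        X_D, X_C = _as_matrix(data_D), _as_matrix(data_C)
        if X_D.shape[1] != X_C.shape[1]:
            raise DataInputError("RT requires the same number of columns in both groups")
    K = X_D.shape[1]
    if K < 2:
        raise DataInputError(f"RT needs at least 2 variables, got {K}")
    n1, n2 = len(X_D), len(X_C)
    R = aligned_ranks(np.vstack([X_D, X_C]), standardize=standardize)
    diff = R[:n1].mean(axis=0) - R[n1:].mean(axis=0)
    return float(n1 * n2 / (n1 + n2) * (diff @ diff))


def compute_all_statistics(
    data_D: GroupData,
    data_C: GroupData,
    net_D: DirectedNetwork,
    net_C: Optional[DirectedNetwork] = None,
    *,
    weight_scheme: Optional[WeightScheme] = None,
    count_mode: str = "descendants",
    collapse_reversed: bool = False,
    include_rt: bool = True,
    standardize_rt: bool = False,
    merged: Optional[MergedStructure] = None,
) -> StatisticResult:
    """Full modular pipeline: merge, summarize both groups, combine, plus RT.

    This is the reference (one-shot) path; the permutation engine re-derives
    the same quantities in batched form for all relabelings.
    """
    net_C = net_C if net_C is not None else net_D
    scheme = weight_scheme if weight_scheme is not None else WeightScheme()
    if merged is None:
        merged = merge_structures(net_D, net_C, collapse_reversed)
    summ_D = summarize_group(data_D, net_D, merged)
    summ_C = summarize_group(data_C, net_C, merged)
    U = node_terms(summ_D, summ_C, data_D.n, data_C.n)
    V = edge_terms(summ_D, summ_C)
    weights = merged_node_weights(merged, net_D, net_C, scheme, count_mode)
    rt = None
    if include_rt:
        rt = rt_statistic(
            data_D.values[list(merged.union_nodes)],
            data_C.values[list(merged.union_nodes)],
            standardize=standardize_rt,
        )
    return combine_statistics(
        U,
        V,
        weights,
        rt=rt,
        node_labels=merged.union_nodes,
        edge_labels=merged.union_edges,
        n1=data_D.n,
        n2=data_C.n,
        meta={
            "weight_family": scheme.family,
            "weight_tuning": scheme.tuning,
            "count_mode": count_mode,
            "collapse_reversed": collapse_reversed,
            "standardize_rt": standardize_rt,
        },
    )
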