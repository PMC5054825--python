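"""Batched recomputation of the five statistics across many group relabelings.

The permutation test recomputes the full pipeline (per-group node summaries,
per-child OLS, the combined statistics, and RT) for every relabeling of the
pooled subjects.  Doing this one permutation at a time is wasteful: for a
fixed pooled matrix, every per-group quantity is a linear functional of the
0/1 group-membership mask, so B permutations reduce to a handful of
matrix products:

* node sums and sums of squares: ``masks @ X`` and ``masks @ X**2``;
* per-child normal equations: precompute the rowwise outer products
  ``Z_n Z_n'`` of the child's design rows once, then ``masks @ O`` yields
  every permutation's X'X in one product, batched ``solve``/``inv`` finish
  the OLS;
* RT: within-subject ranks depend only on the pooled matrix (pooled-median
  alignment is permutation-invariant), so mean rank vectors are again mask
  products.

Results are bitwise-deterministic for a fixed mask matrix and agree with the
one-shot modular pipeline to rounding error (asserted in the test suite).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .dag_core import DirectedNetwork, MergedStructure
from .errors import EstimationError
from .test_statistics import STATISTIC_NAMES, aligned_ranks


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den; 0/0 -> 0, x/0 -> +inf (conservative under >=)."""
    out = np.full(num.shape, np.inf)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[(den == 0) & (num == 0)] = 0.0
    return out


class _ChildDesign:
    """Precomputed per-child regression pieces for one group's network."""

    __slots__ = ("child", "k", "O", "Zy", "y2", "slots")

    def __init__(self, child: str, Z: np.ndarray, y: np.ndarray, slots: Sequence[int]):
        n, k = Z.shape
        self.child = child
        self.k = k
        self.O = (Z[:, :, None] * Z[:, None, :]).reshape(n, k * k)
        self.Zy = Z * y[:, None]
        self.y2 = y * y
        self.slots = np.asarray(slots, dtype=int)


class BatchEvaluator:
    """Evaluate WNES/NES/NS/ES/RT for many group-membership masks at once.

    Parameters
    ----------
    pooled:
        (n1+n2) x K matrix, columns aligned to ``merged.union_nodes``,
        group-D subjects first.
    weights:
        Node weight vector over the union nodes.
    statistics:
        Subset of ``("wnes", "nes", "ns", "es", "rt")`` to compute.
    """

    def __init__(
        self,
        pooled: np.ndarray,
        n1: int,
        n2: int,
        merged: MergedStructure,
        net_D: DirectedNetwork,
        net_C: DirectedNetwork,
        weights: np.ndarray,
        statistics: Sequence[str] = STATISTIC_NAMES,
        standardize_rt: bool = False,
    ):
        self.X = np.ascontiguousarray(pooled, dtype=np.float64)
        self.X2 = self.X**2
        self.n1, self.n2 = n1, n2
        self.merged = merged
        self.weights = np.asarray(weights, dtype=float)
        self.statistics = tuple(s.lower() for s in statistics)
        self.node_present = {
            "D": np.array(merged.node_in_D, dtype=bool),
            "C": np.array(merged.node_in_C, dtype=bool),
        }
        self.edge_present = {
            g: np.array(merged.edge_presence(g), dtype=bool) for g in ("D", "C")
        }
        col = {l: i for i, l in enumerate(merged.union_nodes)}
        self.designs: dict[str, list[_ChildDesign]] = {}
        need_edges = any(s in self.statistics for s in ("wnes", "nes", "es"))
        for g, net in (("D", net_D), ("C", net_C)):
            designs: list[_ChildDesign] = []
            if need_edges:
                slot_of = {
                    s.edge_for(g): m
                    for m, s in enumerate(merged.slots)
                    if s.edge_for(g) is not None
                }
                for child in net.node_labels:
                    parents = net.parents(child)
                    if not parents:
                        continue
                    y = self.X[:, col[child]]
                    Z = np.column_stack(
                        [np.ones(len(self.X))] + [self.X[:, col[p]] for p in parents]
                    )
                    designs.append(
                        _ChildDesign(
                            child, Z, y, [slot_of[(p, child)] for p in parents]
                        )
                    )
            self.designs[g] = designs
        self.R: Optional[np.ndarray] = None
        if "rt" in self.statistics:
            self.R = aligned_ranks(self.X, standardize=standardize_rt)

    def observed_mask(self) -> np.ndarray:
        m = np.zeros(self.n1 + self.n2, dtype=bool)
        m[: self.n1] = True
        return m

    def _edge_arrays(self, Wg: np.ndarray, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-slot beta and var(beta) for one group across all masks."""
        B = Wg.shape[0]
        n_g = self.n1 if group == "D" else self.n2
        beta_out = np.zeros((B, self.merged.M))
        var_out = np.zeros((B, self.merged.M))
        for d in self.designs[group]:
            k = d.k
            xtx = (Wg @ d.O).reshape(B, k, k)
            xty = Wg @ d.Zy
            try:
                beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
            except np.linalg.LinAlgError:
                raise EstimationError(
                    f"child {d.child!r}: singular parent design in a permutation"
                ) from None
            rss = np.maximum(Wg @ d.y2 - np.einsum("bi,bi->b", beta, xty), 0.0)
            sigma2 = rss / (n_g - k)
            diag_inv = np.einsum("bii->bi", np.linalg.inv(xtx))
            beta_out[:, d.slots] = beta[:, 1:]
            var_out[:, d.slots] = sigma2[:, None] * diag_inv[:, 1:]
        return beta_out, var_out

    def evaluate(self, masks: np.ndarray) -> dict[str, np.ndarray]:
        """Statistic values for each row of ``masks`` (True = group D).

        Every row must contain exactly n1 True entries.
        """
        masks = np.atleast_2d(masks)
        if masks.shape[1] != self.n1 + self.n2:
            raise ValueError("mask width must equal the pooled sample size")
        Mf = masks.astype(np.float64)
        Cf = 1.0 - Mf
        out: dict[str, np.ndarray] = {}
        need_nodes = any(s in self.statistics for s in ("wnes", "nes", "ns"))
        need_edges = any(s in self.statistics for s in ("wnes", "nes", "es"))
        U = V = None
        if need_nodes:
            U = self._node_terms(Mf, Cf)
        if need_edges:
            bD, vD = self._edge_arrays(Mf, "D")
            bC, vC = self._edge_arrays(Cf, "C")
            bD[:, ~self.edge_present["D"]] = 0.0
            vD[:, ~self.edge_present["D"]] = 0.0
            bC[:, ~self.edge_present["C"]] = 0.0
            vC[:, ~self.edge_present["C"]] = 0.0
            V = _safe_ratio((bD - bC) ** 2, vD + vC)
        if "ns" in self.statistics:
            out["ns"] = U.sum(axis=1)
        if "es" in self.statistics:
            out["es"] = V.sum(axis=1)
        if "nes" in self.statistics:
            out["nes"] = U.sum(axis=1) + V.sum(axis=1)
        if "wnes" in self.statistics:
            out["wnes"] = U @ self.weights + V.sum(axis=1)
        if "rt" in self.statistics:
            diff = (Mf @ self.R) / self.n1 - (Cf @ self.R) / self.n2
            out["rt"] = self.n1 * self.n2 / (self.n1 + self.n2) * (diff**2).sum(axis=1)
        return out

    def _node_terms(self, Mf: np.ndarray, Cf: np.ndarray) -> np.ndarray:
        mD = (Mf @ self.X) / self.n1
        vD = (Mf @ self.X2 - self.n1 * mD**2) / (self.n1 - 1)
        mC = (Cf @ self.X) / self.n2
        vC = (Cf @ self.X2 - self.n2 * mC**2) / (self.n2 - 1)
        np.maximum(vD, 0.0, out=vD)
        np.maximum(vC, 0.0, out=vC)
        for arr in (mD, vD):
            arr[:, ~self.node_present["D"]] = 0.0
        for arr in (mC, vC):
            arr[:, ~self.node_present["C"]] = 0.0
        return _safe_ratio((mD - mC) ** 2, vD / self.n1 + vC / self.n2)
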