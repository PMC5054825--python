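"""Per-group node summaries and edge-strength estimates on the merged structure.

For each group the node part records sample means and unbiased variances; the
edge part records, for every union edge present in the group, the ordinary
least squares coefficient of the parent in the child's regression on its
*full* parent set plus an intercept, together with the usual OLS sampling
variance of that coefficient.  Elements absent from a group are zero-filled
(mean, variance, beta and its variance all 0), mirroring the convention the
statistics expect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag_core import DirectedNetwork, MergedStructure
from .errors import DataInputError, EstimationError


@dataclass
class GroupData:
    """One group's sample-by-variable data matrix.

    ``values`` rows are subjects, columns are node labels; no missing values
    (missingness is handled upstream), at least 3 subjects, unique columns.
    """

    values: pd.DataFrame
    group: str = "D"

    def __post_init__(self) -> None:
        if self.group not in ("D", "C"):
            raise DataInputError(f"group tag must be 'D' or 'C', got {self.group!r}")
        if self.values.columns.duplicated().any():
            raise DataInputError("duplicate column labels in data matrix")
        if self.values.isna().any().any():
            raise DataInputError("data matrix contains missing values; no imputation is done")
        if len(self.values) < 3:
            raise DataInputError(f"need at least 3 samples per group, got {len(self.values)}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataInputError(f"non-numeric data: {exc}") from None

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class GroupSummaries:
    """Node and edge summaries for one group, aligned to a merged structure."""

    group: str
    n: int
    merged: MergedStructure
    node_mean: np.ndarray
    node_var: np.ndarray
    node_present: np.ndarray
    edge_beta: np.ndarray
    edge_var: np.ndarray
    edge_present: np.ndarray


def summarize_nodes(
    data: GroupData, merged: MergedStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and unbiased (n-1) variance per union node; zeros where absent.

    Returns ``(mean, var, present)`` arrays of length K.
    """
    present = np.array(merged.node_presence(data.group), dtype=bool)
    mean = np.zeros(merged.K)
    var = np.zeros(merged.K)
    cols = set(data.values.columns)
    for k, label in enumerate(merged.union_nodes):
        if not present[k]:
            continue
        if label not in cols:
            raise DataInputError(
                f"node {label!r} is flagged present in group {data.group} "
                "but missing from its data matrix"
            )
        col = data.values[label].to_numpy()
        mean[k] = col.mean()
        var[k] = col.var(ddof=1)
    return mean, var, present


def _ols_child(y: np.ndarray, X: np.ndarray, child: str) -> tuple[np.ndarray, np.ndarray]:
    """Normal-equation OLS: coefficients and their sampling variances.

    ``X`` includes the intercept column.  sigma^2 uses the n - p - 1
    denominator (p = number of parents); the coefficient variance is
    sigma^2 * diag((X'X)^-1).
    """
    n, k = X.shape
    if n <= k:
        raise DataInputError(
            f"child {child!r}: {n} samples cannot support {k - 1} parents plus intercept"
        )
    xtx = X.T @ X
    # cond check surfaces collinear parents before solve returns garbage
    if np.linalg.cond(xtx) > 1e12:
        raise EstimationError(f"child {child!r}: collinear parent design")
    xty = X.T @ y
    beta = np.linalg.solve(xtx, xty)
    rss = max(float(y @ y - beta @ xty), 0.0)
    sigma2 = rss / (n - k)
    var = sigma2 * np.diag(np.linalg.inv(xtx))
    return beta, var


def estimate_edge_coefficients(
    data: GroupData, network: DirectedNetwork, merged: MergedStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS edge strengths for every union edge present in this group.

    For each child node the child column is regressed on *all* of its parent
    columns plus an intercept; the coefficient of parent i is the strength of
    edge i->child.  Absent edges are zero-filled.  Returns
    ``(beta, var_beta, present)`` arrays of length M.
    """
    group = data.group
    present = np.array(merged.edge_presence(group), dtype=bool)
    beta = np.zeros(merged.M)
    var = np.zeros(merged.M)
    slot_of: dict[tuple[str, str], int] = {}
    for m, slot in enumerate(merged.slots):
        e = slot.edge_for(group)
        if e is not None:
            slot_of[e] = m
    for child in network.node_labels:
        parents = network.parents(child)
        if not parents:
            continue
        y = data.values[child].to_numpy()
        X = np.column_stack(
            [np.ones(data.n)] + [data.values[p].to_numpy() for p in parents]
        )
        b, v = _ols_child(y, X, child)
        for i, p in enumerate(parents):
            m = slot_of[(p, child)]
            beta[m] = b[i + 1]
            var[m] = v[i + 1]
    return beta, var, present


def summarize_group(
    data: GroupData, network: DirectedNetwork, merged: MergedStructure
) -> GroupSummaries:
    """Full per-group summary (node and edge parts) on the merged structure."""
    mean, nvar, npres = summarize_nodes(data, merged)
    beta, evar, epres = estimate_edge_coefficients(data, network, merged)
    return GroupSummaries(
        group=data.group,
        n=data.n,
        merged=merged,
        node_mean=mean,
        node_var=nvar,
        node_present=npres,
        edge_beta=beta,
        edge_var=evar,
        edge_present=epres,
    )
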