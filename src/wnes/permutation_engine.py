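"""Empirical p-values by group-label permutation.

The permutation procedure: (1) compute the observed statistic; (2) randomly
re-assign subjects to the two groups keeping the group sizes fixed; (3)
recompute the statistic for each of B permutation samples; (4) the p-value
is the proportion of permuted statistics greater than or equal to the
observed one.  A conservative mode reporting (count+1)/(B+1) is available
because the plain proportion can be exactly 0.

``network_permutation_test`` is the main entry point: it runs any subset of
the five statistics on one *shared* permutation stream so their p-values are
comparable on identical relabelings, using the batched evaluator for speed.
``permutation_test`` is the generic engine for an arbitrary statistic
callable, and ``exhaustive_permutation_pvalue`` enumerates all label
arrangements for small samples (a test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._batch import BatchEvaluator
from .dag_core import (
    DirectedNetwork,
    MergedStructure,
    WeightScheme,
    merge_structures,
    merged_node_weights,
)
from .errors import DataInputError
from .group_estimates import GroupData
from .test_statistics import STATISTIC_NAMES, StatisticResult, compute_all_statistics

P_MODES = ("paper", "conservative")


@dataclass
class PermutationResult:
    """Observed value, permutation count, exceedance count and p-value."""

    statistic: str
    observed: float
    n_permutations: int
    count_ge: int
    p_value: float
    mode: str = "paper"
    seed: Optional[int] = None


def _pvalue(count_ge: int, B: int, mode: str) -> float:
    if mode not in P_MODES:
        raise DataInputError(f"p-mode must be one of {P_MODES}, got {mode!r}")
    if mode == "paper":
        return count_ge / B
    return (count_ge + 1) / (B + 1)


def _group_masks(labels: Sequence) -> tuple[np.ndarray, int, int]:
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise DataInputError(f"need exactly two group labels, got {uniq}")
    mask = labels == uniq[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if min(n1, n2) < 3:
        raise DataInputError(f"each group needs >= 3 subjects, got {n1} and {n2}")
    return mask, n1, n2


def sample_permutation_masks(
    n1: int, n2: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B random relabelings (rows) preserving the group sizes; True = group D."""
    base = np.zeros(n1 + n2, dtype=bool)
    base[:n1] = True
    return rng.permuted(np.tile(base, (B, 1)), axis=1)


def permutation_test(
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    pooled_data,
    labels: Sequence,
    B: int = 1000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    mode: str = "paper",
) -> PermutationResult:
    """Generic permutation test for ``stat_fn(pooled_data, mask) -> float``.

    ``mask`` is a boolean vector assigning each pooled row to the first
    group.  The observed arrangement is not included among the B draws.  If
    ``stat_fn`` exposes ``supports_batch = True`` it is called once with the
    full (B, n) mask matrix and must return a length-B vector.
    """
    if B < 1:
        raise DataInputError(f"need at least one permutation, got B={B}")
    obs_mask, n1, n2 = _group_masks(labels)
    observed = float(np.asarray(stat_fn(pooled_data, obs_mask)).reshape(()))
    rng = np.random.default_rng(seed)
    masks = sample_permutation_masks(n1, n2, B, rng)
    # restore the caller's row split: first-label rows may not be contiguous
    order = np.concatenate([np.flatnonzero(obs_mask), np.flatnonzero(~obs_mask)])
    full_masks = np.zeros((B, len(obs_mask)), dtype=bool)
    full_masks[:, order] = masks
    if getattr(stat_fn, "supports_batch", False):
        vals = np.asarray(stat_fn(pooled_data, full_masks))
    else:
        vals = np.array([stat_fn(pooled_data, m) for m in full_masks])
    count = int((vals >= observed).sum())
    return PermutationResult(
        statistic=getattr(stat_fn, "__name__", "stat"),
        observed=observed,
        n_permutations=B,
        count_ge=count,
        p_value=_pvalue(count, B, mode),
        mode=mode,
        seed=seed if isinstance(seed, int) else None,
    )


def exhaustive_permutation_pvalue(
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    pooled_data,
    labels: Sequence,
    mode: str = "paper",
) -> tuple[float, int]:
    """Exact p-value over all C(n, n1) label arrangements (n1+n2 <= 12 only).

    Every arrangement, including the observed one, counts once; returns
    ``(p_value, n_arrangements)``.  Intended as an oracle for the sampled
    test on tiny data.
    """
    obs_mask, n1, n2 = _group_masks(labels)
    n = n1 + n2
    if n > 12:
        raise DataInputError("exhaustive enumeration is limited to n1+n2 <= 12")
    observed = float(stat_fn(pooled_data, obs_mask))
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        m = np.zeros(n, dtype=bool)
        m[list(idx)] = True
        total += 1
        if float(stat_fn(pooled_data, m)) >= observed:
            count += 1
    return count / total, total


@dataclass
class NetworkTestResult:
    """Observed statistics with their permutation p-values and bookkeeping."""

    observed: StatisticResult
    permutation: dict[str, PermutationResult]
    merged: MergedStructure
    config: dict = field(default_factory=dict)

    def p_values(self) -> dict[str, float]:
        return {s: r.p_value for s, r in self.permutation.items()}

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.to_dict(),
            "p_values": self.p_values(),
            "permutation": {
                s: {
                    "observed": r.observed,
                    "n_permutations": r.n_permutations,
                    "count_ge": r.count_ge,
                    "p_value": r.p_value,
                    "mode": r.mode,
                }
                for s, r in self.permutation.items()
            },
            "config": dict(self.config),
        }


def network_permutation_test(
    data_D: GroupData,
    data_C: GroupData,
    net_D: DirectedNetwork,
    net_C: Optional[DirectedNetwork] = None,
    *,
    statistics: Sequence[str] = STATISTIC_NAMES,
    n_permutations: int = 1000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    weight_scheme: Optional[WeightScheme] = None,
    count_mode: str = "descendants",
    collapse_reversed: bool = False,
    standardize_rt: bool = False,
    p_mode: str = "paper",
    compute_decomposition: bool = True,
) -> NetworkTestResult:
    """Joint permutation test of the requested statistics on one stream.

    Each permutation re-runs the full pipeline (per-group summaries, edge
    OLS under each group's own structure, RT ranks) on the relabeled split.
    Identical ``(seed, data, n_permutations)`` give identical p-values.
    """
    if n_permutations < 1:
        raise DataInputError(f"need at least one permutation, got {n_permutations}")
    statistics = tuple(s.lower() for s in statistics)
    unknown = set(statistics) - set(STATISTIC_NAMES)
    if unknown:
        raise DataInputError(f"unknown statistics: {sorted(unknown)}")
    net_C = net_C if net_C is not None else net_D
    scheme = weight_scheme if weight_scheme is not None else WeightScheme()
    merged = merge_structures(net_D, net_C, collapse_reversed)
    cols = list(merged.union_nodes)
    for d in (data_D, data_C):
        missing = [c for c in cols if c not in d.values.columns]
        if missing:
            raise DataInputError(
                f"group {d.group} data lacks union-node columns {missing}; "
                "permutation needs every subject measured on every union node"
            )
    n1, n2 = data_D.n, data_C.n
    pooled = np.vstack(
        [data_D.values[cols].to_numpy(dtype=float), data_C.values[cols].to_numpy(dtype=float)]
    )
    weights = merged_node_weights(merged, net_D, net_C, scheme, count_mode)
    ev = BatchEvaluator(
        pooled, n1, n2, merged, net_D, net_C, weights,
        statistics=statistics, standardize_rt=standardize_rt,
    )
    obs = {s: float(v[0]) for s, v in ev.evaluate(ev.observed_mask()[None, :]).items()}
    rng = np.random.default_rng(seed)
    masks = sample_permutation_masks(n1, n2, n_permutations, rng)
    perm_vals = ev.evaluate(masks)
    permutation = {}
    for s in statistics:
        count = int((perm_vals[s] >= obs[s]).sum())
        permutation[s] = PermutationResult(
            statistic=s,
            observed=obs[s],
            n_permutations=n_permutations,
            count_ge=count,
            p_value=_pvalue(count, n_permutations, p_mode),
            mode=p_mode,
            seed=seed if isinstance(seed, int) else None,
        )
    if compute_decomposition:
        observed = compute_all_statistics(
            data_D,
            data_C,
            net_D,
            net_C,
            weight_scheme=scheme,
            count_mode=count_mode,
            collapse_reversed=collapse_reversed,
            include_rt="rt" in statistics,
            standardize_rt=standardize_rt,
            merged=merged,
        )
    else:
        K, M = merged.K, merged.M
        observed = StatisticResult(
            U=np.full(K, np.nan),
            V=np.full(M, np.nan),
            weights=weights,
            ns=obs.get("ns", np.nan),
            es=obs.get("es", np.nan),
            nes=obs.get("nes", np.nan),
            wnes=obs.get("wnes", np.nan),
            rt=obs.get("rt"),
            node_labels=merged.union_nodes,
            edge_labels=merged.union_edges,
            n1=n1,
            n2=n2,
        )
    config = {
        "statistics": statistics,
        "n_permutations": n_permutations,
        "seed": seed if isinstance(seed, int) else None,
        "weight_family": scheme.family,
        "weight_tuning": scheme.tuning,
        "count_mode": count_mode,
        "collapse_reversed": collapse_reversed,
        "standardize_rt": standardize_rt,
        "p_mode": p_mode,
        "n1": n1,
        "n2": n2,
        "K": merged.K,
        "M": merged.M,
    }
    return NetworkTestResult(
        observed=observed, permutation=permutation, merged=merged, config=config
    )
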