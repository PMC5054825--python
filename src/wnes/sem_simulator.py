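"""Linear Gaussian structural equation models on DAGs, and the study scenarios.

Each node is a linear function of its parents plus independent Gaussian
error: root nodes ~ Normal(delta, sigma^2), and every non-root node is
``delta + sum_parents beta * parent + Normal(0, sigma^2)``.  The module
provides exact implied moments (a test oracle for the sampler), *variance
rectification* — resetting error variances and intercepts after a scenario
perturbation so every untargeted node keeps its baseline marginal
distribution exactly (Gaussian, so matching mean and variance suffices) —
and builders for the power-study scenarios:

I    node-only mean shift (propagates downstream; covariances untouched)
II   edge-coefficient change, rectified so only edge strengths differ
III  scenario II plus a mean shift on a high-weight node (many descendants)
IV   scenario II plus a mean shift on a childless node (weight exactly 1)
dir-I/dir-II  one edge reversed in the control-group structure, keeping its
     coefficient magnitude; dir-II additionally compares the reversed pair
     in one collapsed union slot downstream.

Fixture topologies are documented synthetic stand-ins: ``upr12`` is a
three-branch signalling cascade (12 nodes, 15 edges, one root, depth >= 3 so
the node weights are heterogeneous), ``upr12_rev`` reverses its X4->X6 edge,
and ``wnt35`` is a seeded 35-node/79-edge DAG emulating a mid-sized
signalling pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dag_core import DirectedNetwork, Edge
from .errors import ConfigurationError, DataInputError, InfeasibleScenarioError
from .group_estimates import GroupData

SCENARIO_IDS = ("I", "II", "III", "IV", "dir-I", "dir-II")


@dataclass(frozen=True)
class LinearSEM:
    """A linear Gaussian SEM: coefficients per edge, intercepts and error variances per node."""

    network: DirectedNetwork
    coefficients: Mapping[Edge, float]
    error_variances: Mapping[str, float]
    mean_shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "error_variances", dict(self.error_variances))
        object.__setattr__(self, "mean_shifts", dict(self.mean_shifts))
        if set(self.coefficients) != set(self.network.edges):
            raise ConfigurationError("coefficients must be keyed exactly by the network edges")
        missing = set(self.network.node_labels) - set(self.error_variances)
        if missing:
            raise ConfigurationError(f"error variance missing for nodes {sorted(missing)}")
        for v, s2 in self.error_variances.items():
            if s2 < 0:
                raise ConfigurationError(f"negative error variance for node {v!r}")
        unknown = set(self.mean_shifts) - set(self.network.node_labels)
        if unknown:
            raise ConfigurationError(f"mean shift for unknown nodes {sorted(unknown)}")

    def delta(self, node: str) -> float:
        return float(self.mean_shifts.get(node, 0.0))


def homogeneous_sem(
    network: DirectedNetwork,
    beta: float = 0.5,
    sigma2: float = 1.0,
    mean_shifts: Optional[Mapping[str, float]] = None,
) -> LinearSEM:
    """SEM with one coefficient on every edge and one error variance everywhere."""
    return LinearSEM(
        network=network,
        coefficients={e: beta for e in network.edges},
        error_variances={v: sigma2 for v in network.node_labels},
        mean_shifts=dict(mean_shifts or {}),
    )


def simulate(
    sem: LinearSEM,
    n: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    group: str = "D",
) -> GroupData:
    """Draw n subjects; columns follow the network's node-label order.

    Noise is drawn node by node in topological order, so a fixed seed gives
    a bit-reproducible matrix.
    """
    if n < 1:
        raise DataInputError(f"need n >= 1 samples, got {n}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in sem.network.topological_order:
        x = rng.normal(0.0, np.sqrt(sem.error_variances[v]), size=n) + sem.delta(v)
        for p in sem.network.parents(v):
            x = x + sem.coefficients[(p, v)] * cols[p]
        cols[v] = x
    frame = pd.DataFrame({v: cols[v] for v in sem.network.node_labels})
    return GroupData(values=frame, group=group)


def implied_moments(sem: LinearSEM) -> tuple[pd.Series, pd.DataFrame]:
    """Exact model mean vector and covariance matrix.

    Accumulated in topological order: Cov(child, .) = sum_parents beta *
    Cov(parent, .), Var(child) = parent quadratic form + sigma^2 (equivalent
    to the (I - B)^-1 closed form).
    """
    order = sem.network.topological_order
    idx = {v: i for i, v in enumerate(order)}
    K = len(order)
    mu = np.zeros(K)
    S = np.zeros((K, K))
    for v in order:
        i = idx[v]
        ps = sem.network.parents(v)
        b = np.array([sem.coefficients[(p, v)] for p in ps])
        pi = [idx[p] for p in ps]
        mu[i] = sem.delta(v) + (b @ mu[pi] if ps else 0.0)
        if ps:
            row = b @ S[pi, :]
            S[i, :] = row
            S[:, i] = row
            S[i, i] = b @ S[np.ix_(pi, pi)] @ b + sem.error_variances[v]
        else:
            S[i, i] = sem.error_variances[v]
    labels = list(sem.network.node_labels)
    mu_s = pd.Series(mu, index=list(order)).reindex(labels)
    S_df = pd.DataFrame(S, index=list(order), columns=list(order)).reindex(
        index=labels, columns=labels
    )
    return mu_s, S_df


def implied_covariance(sem: LinearSEM) -> pd.DataFrame:
    """Exact K x K model covariance (see :func:`implied_moments`)."""
    return implied_moments(sem)[1]


def rectify_error_variances(
    sem_changed: LinearSEM,
    sem_baseline: LinearSEM,
    targeted_nodes: Optional[Sequence[str]] = None,
) -> LinearSEM:
    """Reset intercepts/error variances so untargeted nodes keep baseline marginals.

    Walks the nodes in topological order; for every node whose own equation
    was *not* targeted by the scenario (by default, targeted = nodes whose
    mean shift differs from baseline; children of changed edges are not
    targeted and hence are rectified), the error variance is reset to the
    baseline implied marginal variance minus the variance arriving through
    the parents under the changed upstream law, and the intercept is reset
    so the implied mean matches baseline.  An impossible requirement
    (sigma^2 <= 0) raises :class:`InfeasibleScenarioError` naming the node.
    """
    if set(sem_changed.network.node_labels) != set(sem_baseline.network.node_labels):
        raise ConfigurationError("rectification requires a shared node set")
    if targeted_nodes is None:
        targeted = {
            v
            for v in sem_changed.network.node_labels
            if sem_changed.delta(v) != sem_baseline.delta(v)
        }
    else:
        targeted = set(targeted_nodes)
    mu_b, S_b = implied_moments(sem_baseline)
    order = sem_changed.network.topological_order
    idx = {v: i for i, v in enumerate(order)}
    K = len(order)
    mu = np.zeros(K)
    S = np.zeros((K, K))
    new_delta: dict[str, float] = {}
    new_var: dict[str, float] = {}
    for v in order:
        i = idx[v]
        ps = sem_changed.network.parents(v)
        b = np.array([sem_changed.coefficients[(p, v)] for p in ps])
        pi = [idx[p] for p in ps]
        mean_par = float(b @ mu[pi]) if ps else 0.0
        var_par = float(b @ S[np.ix_(pi, pi)] @ b) if ps else 0.0
        if v in targeted:
            d, s2 = sem_changed.delta(v), sem_changed.error_variances[v]
        else:
            d = float(mu_b[v]) - mean_par
            s2 = float(S_b.loc[v, v]) - var_par
            if s2 <= 0:
                raise InfeasibleScenarioError(
                    f"node {v!r}: rectified error variance would be {s2:.6g} <= 0; "
                    "the scenario pushes more variance through the parents than the "
                    "baseline marginal allows"
                )
        new_delta[v] = d
        new_var[v] = s2
        mu[i] = d + mean_par
        if ps:
            row = b @ S[pi, :]
            S[i, :] = row
            S[:, i] = row
            S[i, i] = var_par + s2
        else:
            S[i, i] = s2
    return LinearSEM(
        network=sem_changed.network,
        coefficients=dict(sem_changed.coefficients),
        error_variances=new_var,
        mean_shifts={v: d for v, d in new_delta.items() if d != 0.0},
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of a two-group simulation scenario."""

    scenario_id: str
    node_shifts: Mapping[str, float] = field(default_factory=dict)
    edge_deltas: Mapping[Edge, float] = field(default_factory=dict)
    reversed_edges: tuple[Edge, ...] = ()
    rectify: bool = False
    collapse_reversed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_shifts", dict(self.node_shifts))
        object.__setattr__(self, "edge_deltas", dict(self.edge_deltas))
        object.__setattr__(
            self, "reversed_edges", tuple((p, c) for p, c in self.reversed_edges)
        )
        if self.scenario_id in ("II", "III", "IV") and not self.rectify:
            raise ConfigurationError(
                f"scenario {self.scenario_id} changes edges and must set rectify=True"
            )


def build_scenario(
    baseline: LinearSEM, spec: ScenarioSpec
) -> tuple[LinearSEM, LinearSEM]:
    """Instantiate ``(sem_D, sem_C)`` from a baseline SEM and a scenario spec.

    sem_C is the baseline (control) model; node shifts and edge deltas
    perturb sem_D, while designated edge reversals restructure sem_C keeping
    the reversed coefficient's magnitude.  With ``rectify`` on, sem_D's
    untargeted nodes (everything except the explicitly shifted nodes) are
    restored to baseline marginals.  Building twice from one spec yields
    identical models.
    """
    for v in spec.node_shifts:
        if v not in baseline.network.node_labels:
            raise ConfigurationError(f"scenario shifts unknown node {v!r}")
    for e in list(spec.edge_deltas) + list(spec.reversed_edges):
        if tuple(e) not in baseline.network.edges:
            raise ConfigurationError(f"scenario references unknown edge {tuple(e)!r}")
    coeffs = dict(baseline.coefficients)
    for e, d in spec.edge_deltas.items():
        coeffs[tuple(e)] = coeffs[tuple(e)] + d
    deltas = dict(baseline.mean_shifts)
    for v, d in spec.node_shifts.items():
        deltas[v] = deltas.get(v, 0.0) + d
    sem_D = LinearSEM(
        network=baseline.network,
        coefficients=coeffs,
        error_variances=dict(baseline.error_variances),
        mean_shifts=deltas,
    )
    if spec.rectify:
        sem_D = rectify_error_variances(sem_D, baseline, targeted_nodes=spec.node_shifts)
    sem_C = baseline
    if spec.reversed_edges:
        net_C = baseline.network
        coeffs_C = dict(baseline.coefficients)
        for e in spec.reversed_edges:
            net_C = net_C.reverse_edge(e)
            coeffs_C[(e[1], e[0])] = coeffs_C.pop(e)
        sem_C = LinearSEM(
            network=net_C,
            coefficients=coeffs_C,
            error_variances=dict(baseline.error_variances),
            mean_shifts=dict(baseline.mean_shifts),
        )
    return sem_D, sem_C


# ---------------------------------------------------------------------------
# Fixture networks (synthetic stand-ins) and default study conditions
# ---------------------------------------------------------------------------

_UPR12_EDGES = [
    ("X1", "X2"), ("X1", "X3"), ("X1", "X4"),
    ("X2", "X5"), ("X3", "X6"), ("X4", "X6"), ("X4", "X7"),
    ("X5", "X8"), ("X6", "X9"), ("X7", "X10"),
    ("X9", "X11"), ("X10", "X12"),
    ("X2", "X9"), ("X7", "X11"), ("X5", "X12"),
]
REVERSAL_EDGE: Edge = ("X4", "X6")


def _wnt35_network() -> DirectedNetwork:
    """Seeded synthetic 35-node/79-edge DAG emulating a mid-sized pathway.

    Nodes are ordered W01..W35 and every edge points from a lower to a
    higher index, so acyclicity holds by construction.  Each non-root node
    gets one backbone parent, then extra edges are added from a fixed
    shuffle subject to an in-degree cap of 6 (so edge OLS stays
    well-conditioned at n = 100 per group).  Deterministic.
    """
    rng = np.random.default_rng(3579)
    labels = [f"W{i + 1:02d}" for i in range(35)]
    edges: set[Edge] = set()
    indeg = {l: 0 for l in labels}
    for j in range(1, 35):
        i = int(rng.integers(0, j))
        edges.add((labels[i], labels[j]))
        indeg[labels[j]] += 1
    pairs = [
        (labels[i], labels[j]) for i in range(35) for j in range(i + 1, 35)
    ]
    rng.shuffle(pairs)
    for p, c in pairs:
        if len(edges) == 79:
            break
        if (p, c) in edges or indeg[c] >= 6:
            continue
        edges.add((p, c))
        indeg[c] += 1
    return DirectedNetwork(labels, sorted(edges))


def fixture_networks() -> dict[str, DirectedNetwork]:
    """Named study networks: ``upr12``, ``upr12_rev`` (X4->X6 reversed), ``wnt35``."""
    upr12 = DirectedNetwork([f"X{i + 1}" for i in range(12)], _UPR12_EDGES)
    return {
        "upr12": upr12,
        "upr12_rev": upr12.reverse_edge(REVERSAL_EDGE),
        "wnt35": _wnt35_network(),
    }


def fixture_sem(name: str = "upr12", beta: float = 0.5, sigma2: float = 1.0) -> LinearSEM:
    """Default generative model on a fixture network: beta on every edge,
    unit error variances, zero intercepts."""
    nets = fixture_networks()
    if name not in nets:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {sorted(nets)}")
    return homogeneous_sem(nets[name], beta=beta, sigma2=sigma2)


#: Default effect sizes for the power scenarios, calibrated so the leading
#: statistic sits in the 0.5-0.9 mid-range power band at n = 100 per group.
NODE_SHIFT = 0.4
EDGE_DELTA = 0.3


def default_scenarios() -> dict[str, ScenarioSpec]:
    """The six study scenarios on the upr12 fixture.

    X1 is the root (largest relative weight), X8 is childless (weight
    exactly 1), X2->X5 is the perturbed edge, and X4->X6 the reversed pair.
    """
    edge = ("X2", "X5")
    return {
        "I": ScenarioSpec("I", node_shifts={"X2": NODE_SHIFT}),
        "II": ScenarioSpec("II", edge_deltas={edge: EDGE_DELTA}, rectify=True),
        "III": ScenarioSpec(
            "III", edge_deltas={edge: EDGE_DELTA}, node_shifts={"X1": NODE_SHIFT},
            rectify=True,
        ),
        "IV": ScenarioSpec(
            "IV", edge_deltas={edge: EDGE_DELTA}, node_shifts={"X8": NODE_SHIFT},
            rectify=True,
        ),
        "dir-I": ScenarioSpec("dir-I", reversed_edges=(REVERSAL_EDGE,)),
        "dir-II": ScenarioSpec(
            "dir-II", reversed_edges=(REVERSAL_EDGE,), collapse_reversed=True
        ),
    }
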