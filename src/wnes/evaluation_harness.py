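"""Monte-Carlo type-I error and power estimation for the five statistics.

Each replicate draws both group samples from their generative models, runs
the joint permutation test (all requested statistics share one permutation
stream), and records whether each p-value falls at or below alpha.  The
default harness scale (500 replicates, 500 permutations) puts the
Monte-Carlo standard error near 0.01 under the null; the full-scale
1000/1000 design is configuration only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dag_core import WeightScheme
from .errors import ConfigurationError
from .permutation_engine import network_permutation_test
from .sem_simulator import (
    LinearSEM,
    ScenarioSpec,
    build_scenario,
    default_scenarios,
    fixture_sem,
    simulate,
)
from .test_statistics import STATISTIC_NAMES


@dataclass
class CalibrationReport:
    """Rejection proportions with their Monte-Carlo standard errors.

    ``table`` has one row per (statistic, configuration); ``p_values`` keeps
    the raw per-replicate p-values when requested.
    """

    table: pd.DataFrame
    alpha: float
    n_permutations: int
    reps: int
    seed: Optional[int] = None
    p_values: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "reps": self.reps,
            "seed": self.seed,
            "rows": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _mc_se(p: float, reps: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / reps))


def rejection_rate(
    sem_D: LinearSEM,
    sem_C: LinearSEM,
    *,
    n_per_group: Union[int, tuple[int, int]],
    reps: int = 500,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    statistics: Sequence[str] = STATISTIC_NAMES,
    weight_scheme: Optional[WeightScheme] = None,
    count_mode: str = "descendants",
    collapse_reversed: bool = False,
    standardize_rt: bool = False,
    keep_p_values: bool = False,
    label: str = "",
) -> CalibrationReport:
    """Empirical rejection proportion of each statistic at level alpha.

    Replicate r uses the deterministic stream ``default_rng(seed + r)`` for
    its two group draws and its permutation masks, so reruns reproduce the
    report exactly.
    """
    if reps < 1 or n_permutations < 1:
        raise ConfigurationError("reps and n_permutations must be >= 1")
    if isinstance(n_per_group, int):
        n1 = n2 = n_per_group
    else:
        n1, n2 = n_per_group
    statistics = tuple(s.lower() for s in statistics)
    rejections = {s: 0 for s in statistics}
    pvals: dict[str, list[float]] = {s: [] for s in statistics}
    for r in range(reps):
        rng = np.random.default_rng(seed + r)
        data_D = simulate(sem_D, n1, rng, group="D")
        data_C = simulate(sem_C, n2, rng, group="C")
        res = network_permutation_test(
            data_D,
            data_C,
            sem_D.network,
            sem_C.network,
            statistics=statistics,
            n_permutations=n_permutations,
            seed=rng,
            weight_scheme=weight_scheme,
            count_mode=count_mode,
            collapse_reversed=collapse_reversed,
            standardize_rt=standardize_rt,
            compute_decomposition=False,
        )
        for s, p in res.p_values().items():
            pvals[s].append(p)
            if p <= alpha:
                rejections[s] += 1
    rows = []
    for s in statistics:
        prop = rejections[s] / reps
        rows.append(
            {
                "label": label,
                "statistic": s,
                "n1": n1,
                "n2": n2,
                "rejection": prop,
                "se": _mc_se(prop, reps),
                "reps": reps,
                "n_permutations": n_permutations,
                "alpha": alpha,
                "seed": seed,
            }
        )
    return CalibrationReport(
        table=pd.DataFrame(rows),
        alpha=alpha,
        n_permutations=n_permutations,
        reps=reps,
        seed=seed,
        p_values={s: np.array(v) for s, v in pvals.items()} if keep_p_values else {},
    )


def type1_table(
    sample_sizes: Sequence[int] = (100, 200, 300, 400, 500),
    networks: Sequence[str] = ("upr12", "wnt35"),
    *,
    reps: int = 500,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    statistics: Sequence[str] = STATISTIC_NAMES,
    **kwargs,
) -> CalibrationReport:
    """Null rejection grid: both groups drawn from one fixture SEM.

    ``sample_sizes`` are per-group counts (the printed layout totals double
    them).  Rows cover every statistic x sample size x network cell.
    """
    frames = []
    offset = 0
    for net in networks:
        sem = fixture_sem(net)
        for n in sample_sizes:
            rep = rejection_rate(
                sem,
                sem,
                n_per_group=n,
                reps=reps,
                n_permutations=n_permutations,
                alpha=alpha,
                seed=seed + offset,
                statistics=statistics,
                label=net,
                **kwargs,
            )
            frames.append(rep.table)
            offset += reps
    return CalibrationReport(
        table=pd.concat(frames, ignore_index=True),
        alpha=alpha,
        n_permutations=n_permutations,
        reps=reps,
        seed=seed,
    )


def table1_layout(report: CalibrationReport) -> pd.DataFrame:
    """Pivot a type-I grid into the wide layout: one block of 5 statistic
    rows per network, one column per total sample size."""
    t = report.table.copy()
    t["total_n"] = t["n1"] + t["n2"]
    wide = t.pivot_table(
        index=["label", "statistic"], columns="total_n", values="rejection"
    )
    order = [s for s in STATISTIC_NAMES if s in set(t["statistic"])]
    wide = wide.reindex(
        pd.MultiIndex.from_product(
            [list(dict.fromkeys(t["label"])), order], names=["network", "statistic"]
        )
    )
    return wide.reset_index()


def power_curve(
    scenario: Union[str, ScenarioSpec],
    sample_sizes: Sequence[int] = (50, 100, 150, 200),
    *,
    baseline: Optional[LinearSEM] = None,
    reps: int = 500,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    statistics: Sequence[str] = STATISTIC_NAMES,
    plot_path: Optional[str] = None,
    **kwargs,
) -> CalibrationReport:
    """Per-statistic power against per-group sample size for one scenario.

    ``scenario`` is a :class:`ScenarioSpec` or the name of a default study
    scenario (I, II, III, IV, dir-I, dir-II) on the upr12 fixture.  The
    scenario's ``collapse_reversed`` flag is honoured in the analysis.
    Optionally writes a matplotlib figure.
    """
    if isinstance(scenario, str):
        spec = default_scenarios()[scenario]
    else:
        spec = scenario
    base = baseline if baseline is not None else fixture_sem("upr12")
    sem_D, sem_C = build_scenario(base, spec)
    frames = []
    offset = 0
    for n in sample_sizes:
        rep = rejection_rate(
            sem_D,
            sem_C,
            n_per_group=n,
            reps=reps,
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed + offset,
            statistics=statistics,
            collapse_reversed=spec.collapse_reversed,
            label=spec.scenario_id,
            **kwargs,
        )
        frames.append(rep.table)
        offset += reps
    report = CalibrationReport(
        table=pd.concat(frames, ignore_index=True),
        alpha=alpha,
        n_permutations=n_permutations,
        reps=reps,
        seed=seed,
    )
    if plot_path is not None:
        _plot_power(report, plot_path, spec.scenario_id)
    return report


def _plot_power(report: CalibrationReport, path: str, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = report.table
    for s, grp in t.groupby("statistic"):
        ax.plot(grp["n1"], grp["rejection"], marker="o", label=s.upper())
    ax.axhline(report.alpha, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("sample size per group")
    ax.set_ylabel(f"rejection rate at alpha={report.alpha}")
    ax.set_title(f"scenario {title}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
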