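"""Subsampled-network ensemble validation.

Repeated group subsampling → within-subsample filtering → inference →
topology / keystones / robustness, with aggregated per-group distributions
and cross-group rank tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gutnet.abundance import AbundanceTable
from gutnet.inference import InferenceConfig, infer_network
from gutnet.keystones import KeystoneConfig, ensemble_keystones, keystones_of_network
from gutnet.robustness import AttackSpec, run_attack_suite
from gutnet.topology import global_metrics

logger = logging.getLogger(__name__)

__all__ = ["EnsembleConfig", "EnsembleSummary", "run_ensemble", "summarize_distributions"]


@dataclass(frozen=True)
class EnsembleConfig:
    subsample_n: int = 100
    n_reps: int = 100
    seed: int = 0
    groups: Optional[tuple[str, ...]] = None
    group_column: str = "group"
    inference: InferenceConfig = InferenceConfig()
    keystone: KeystoneConfig = KeystoneConfig()
    attacks: tuple[AttackSpec, ...] = (AttackSpec(strategy="degree"),)
    run_robustness: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.subsample_n < 1:
            raise ValueError("subsample_n must be >= 1")


@dataclass
class EnsembleSummary:
    """Per-replicate results across groups."""

    global_metrics: pd.DataFrame  # index (group, rep)
    robustness: pd.DataFrame  # columns: group, rep, strategy, nr50, pc
    keystone_presence: pd.DataFrame
    keystone_set_sizes: pd.Series
    keystone_cores: dict[str, set[str]]
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_ensemble(table: AbundanceTable, config: EnsembleConfig) -> EnsembleSummary:
    """Run the subsampling validation loop.

    Each replicate subsamples ``subsample_n`` samples from a group without
    replacement, re-applies the prevalence/abundance filter *within the
    subsample* (inference does this internally), infers a network, and
    collects global metrics, keystones, and robustness. Failed replicates
    are logged and excluded, never imputed.
    """
    groups = table.groups(config.group_column)
    wanted = list(config.groups) if config.groups else sorted(groups)
    for g in wanted:
        if g not in groups:
            raise ValueError(f"group {g!r} not present in metadata")
        if groups[g].n_samples < config.subsample_n:
            raise ValueError(
                f"group {g!r} has {groups[g].n_samples} samples < subsample_n={config.subsample_n}"
            )
    root = np.random.SeedSequence(config.seed)
    gm_rows, rob_rows, fail_rows = [], [], []
    keysets: dict[str, list[set[str]]] = {g: [] for g in wanted}
    for gi, g in enumerate(wanted):
        sub_table = groups[g]
        seeds = np.random.SeedSequence((config.seed, gi)).spawn(config.n_reps)
        for rep in range(config.n_reps):
            rng = np.random.default_rng(seeds[rep])
            idx = rng.choice(sub_table.n_samples, size=config.subsample_n, replace=False)
            sample_ids = [sub_table.sample_ids[i] for i in sorted(idx)]
            rep_seed = int(rng.integers(2**31))
            try:
                sub = sub_table.subset_samples(sample_ids)
                inf_cfg = InferenceConfig(
                    **{
                        **config.inference.__dict__,
                        "seed": rep_seed,
                    }
                )
                net = infer_network(sub, inf_cfg)
                gm = global_metrics(net).to_series()
                gm["group"], gm["rep"] = g, rep
                gm_rows.append(gm)
                keysets[g].append(keystones_of_network(net, config.keystone))
                if config.run_robustness:
                    for strat, res in run_attack_suite(net, config.attacks).items():
                        rob_rows.append(
                            {
                                "group": g,
                                "rep": rep,
                                "strategy": strat,
                                "nr50": res.nr50,
                                "pc": res.pc,
                            }
                        )
            except Exception as exc:  # noqa: BLE001 - per-rep failures are data
                logger.warning("replicate (%s, %d) failed: %s", g, rep, exc)
                fail_rows.append({"group": g, "rep": rep, "error": str(exc)})
    if not gm_rows:
        raise RuntimeError("every ensemble replicate failed")
    gm_df = pd.DataFrame(gm_rows).set_index(["group", "rep"])
    rob_df = pd.DataFrame(rob_rows)
    presence, sizes, _inter, cores = ensemble_keystones(
        {g: s for g, s in keysets.items() if s}
    )
    return EnsembleSummary(
        global_metrics=gm_df,
        robustness=rob_df,
        keystone_presence=presence,
        keystone_set_sizes=sizes,
        keystone_cores=cores,
        failures=pd.DataFrame(fail_rows),
    )


def ranking_consistency(
    summary: EnsembleSummary, metric: str, ordering: Sequence[str]
) -> float:
    """Fraction of replicates in which ``ordering`` holds for ``metric``.

    Replicates are paired by index across groups. Each adjacent strict
    inequality must hold; a tie contributes a factor of 0.5 (so fully tied
    groups score 0.5 per pair).
    """
    gm = summary.global_metrics[metric].unstack(level="group")
    gm = gm[list(ordering)].dropna()
    score = 0.0
    for _, row in gm.iterrows():
        credit = 1.0
        for a, b in zip(ordering[:-1], ordering[1:]):
            if row[a] > row[b]:
                continue
            credit *= 0.5 if row[a] == row[b] else 0.0
        score += credit
    return score / len(gm) if len(gm) else float("nan")


def summarize_distributions(
    summary: EnsembleSummary,
    metrics: Sequence[str] = ("order", "size", "mean_degree", "mean_closeness"),
    ordering: Optional[Sequence[str]] = None,
) -> dict[str, pd.DataFrame]:
    """Medians/IQRs per group, cross-group rank tests with BH correction,
    and (optionally) the ranking-consistency score for a given ordering."""
    gm = summary.global_metrics
    groups = gm.index.get_level_values("group").unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    desc_rows = []
    test_rows = []
    for metric in metrics:
        for g in groups:
            vals = gm.loc[g, metric].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            desc_rows.append(
                {"metric": metric, "group": g, "median": med, "q1": q1, "q3": q3}
            )
        samples = [gm.loc[g, metric].to_numpy(dtype=float) for g in groups]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*samples)
        test_rows.append({"metric": metric, "statistic": float(stat), "pvalue": float(p)})
    tests = pd.DataFrame(test_rows).set_index("metric")
    tests["pvalue_adj"] = multipletests(tests["pvalue"], method="fdr_bh")[1]
    out = {
        "descriptives": pd.DataFrame(desc_rows).set_index(["metric", "group"]),
        "tests": tests,
    }
    if ordering is not None:
        out["ranking_consistency"] = pd.DataFrame(
            {
                "metric": list(metrics),
                "consistency": [
                    ranking_consistency(summary, m, list(ordering)) for m in metrics
                ],
            }
        ).set_index("metric")
    return out
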