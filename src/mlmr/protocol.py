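"""Benchmark protocol: repeated resampling over a labeling-rate sweep.

Each experimental cell (repetition x labeling rate) draws a fresh
train/test split (two thirds / one third by default), masks the labels of
all but a fraction ``eta`` of the training instances, fits each competing
learner on the partially labeled training set, predicts the held-out
third, and records average precision, micro-F1 and macro-F1.  Aggregated
per-rate means feed the Friedman / critical-difference analysis, with the
labeling-rate conditions playing the role of blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .exceptions import InvalidParameterError
from .graph import KernelConfig, SparsifierConfig, median_heuristic_sigma
from .model import HyperParams, fit_pipeline, predict_scores, threshold_labels
from .stats import FriedmanResult, PosthocResult, RankTable, friedman_test

__all__ = [
    "ProtocolConfig",
    "ALGORITHMS",
    "split_train_test",
    "mask_at_rate",
    "run_protocol",
    "aggregate_and_test",
    "EvalReport",
    "plot_metric_vs_rate",
]

DEFAULT_RATES = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))

# learner registry: name -> reliance weights (nu1, nu2); everything else
# is shared.  ml-mr is the unweighted model, ml-mrrw the recommended
# weighted setting.
ALGORITHMS: dict[str, tuple[float, float]] = {
    "ml-mr": (1.0, 1.0),
    "ml-mrrw": (1.0, 0.1),
}


@dataclass(frozen=True)
class ProtocolConfig:
    train_fraction: float = 2.0 / 3.0
    labeling_rates: tuple = DEFAULT_RATES
    repetitions: int = 100
    subsample_fraction: float = 1.0
    master_seed: int = 0
    algorithms: tuple = ("ml-mr", "ml-mrrw")
    gamma_A: float = 0.01
    gamma_I: float = 0.1
    sigma: float | None = None  # None -> median pairwise distance heuristic
    sparsifier: SparsifierConfig = field(default_factory=SparsifierConfig)
    weight_scheme: str = "distance"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise InvalidParameterError("train_fraction must lie in (0, 1)")
        if any(not 0 < r < 1 for r in self.labeling_rates):
            raise InvalidParameterError("labeling rates must lie in (0, 1)")
        if not 0 < self.subsample_fraction <= 1:
            raise InvalidParameterError("subsample_fraction must lie in (0, 1]")
        if self.repetitions < 1:
            raise InvalidParameterError("repetitions must be >= 1")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise InvalidParameterError(f"unknown algorithm {a!r}")


def _cell_seed(master_seed: int, rep: int, rate_idx: int) -> int:
    """Deterministic per-cell seed below 2**31, shared by all learners in a cell."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(rep, rate_idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def split_train_test(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive random split with ``round(train_fraction * n)`` training rows."""
    if n < 3:
        raise InvalidParameterError("need at least 3 instances to split")
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise InvalidParameterError(f"degenerate split: {n_train} train of {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def mask_at_rate(Y_train: np.ndarray, eta: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the full label vectors of ``max(1, round(eta * n_train))`` instances.

    All other rows are zeroed, marking them unlabeled.  Returns the
    partially observed label matrix and the sorted labeled index set.
    """
    if not 0 < eta < 1:
        raise InvalidParameterError("eta must lie in (0, 1)")
    Y_train = np.asarray(Y_train)
    n_train = Y_train.shape[0]
    l = max(1, int(round(eta * n_train)))
    labeled = np.sort(np.random.default_rng(seed).permutation(n_train)[:l])
    Y_partial = np.zeros_like(Y_train)
    Y_partial[labeled] = Y_train[labeled]
    return Y_partial, labeled


def run_protocol(X: np.ndarray, Y: np.ndarray, cfg: ProtocolConfig) -> pd.DataFrame:
    """Run the full sweep and return tidy records.

    One row per (repetition, labeling rate, algorithm, metric); learner
    failures are recorded with a NaN value and the run continues.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    n_all = X.shape[0]
    records = []
    for rep in range(cfg.repetitions):
        for rate_idx, eta in enumerate(cfg.labeling_rates):
            seed = _cell_seed(cfg.master_seed, rep, rate_idx)
            rng = np.random.default_rng(seed)
            if cfg.subsample_fraction < 1.0:
                m = max(3, int(round(cfg.subsample_fraction * n_all)))
                keep = np.sort(rng.permutation(n_all)[:m])
                Xs, Ys = X[keep], Y[keep]
            else:
                Xs, Ys = X, Y
            tr, te = split_train_test(Xs.shape[0], cfg.train_fraction, seed)
            Y_partial, _ = mask_at_rate(Ys[tr], eta, seed)
            sigma = cfg.sigma if cfg.sigma is not None else median_heuristic_sigma(Xs[tr])
            kernel_cfg = KernelConfig(sigma=sigma)
            for alg in cfg.algorithms:
                nu1, nu2 = ALGORITHMS[alg]
                hyper = HyperParams(
                    gamma_A=cfg.gamma_A, gamma_I=cfg.gamma_I, nu1=nu1, nu2=nu2
                )
                try:
                    model, _ = fit_pipeline(
                        Xs[tr],
                        Y_partial,
                        kernel_cfg=kernel_cfg,
                        sparsifier_cfg=cfg.sparsifier,
                        hyper=hyper,
                        weight_scheme=cfg.weight_scheme,
                    )
                    scores = predict_scores(model, Xs[te])
                    vals = M.compute_all(scores, threshold_labels(scores), Ys[te])
                except Exception as exc:  # record and continue per spec
                    vals = {m: np.nan for m in ("avgprec", "micro_f1", "macro_f1")}
                    vals["error"] = repr(exc)
                err = vals.pop("error", "")
                for metric, value in vals.items():
                    records.append(
                        {
                            "repetition": rep,
                            "labeling_rate": eta,
                            "algorithm": alg,
                            "metric": metric,
                            "value": value,
                            "seed": seed,
                            "error": err,
                        }
                    )
    return pd.DataFrame.from_records(records)


@dataclass
class EvalReport:
    """Per-metric aggregation: block tables, ranks, Friedman gate, post hoc."""

    blocks: dict[str, pd.DataFrame]
    ranks: dict[str, RankTable]
    friedman: dict[str, FriedmanResult]
    posthoc: dict[str, PosthocResult | None]
    alpha: float


def aggregate_and_test(
    records: pd.DataFrame,
    alpha: float = 0.05,
    cd_blocks: int = 1,
    rank_per: str = "rate",
) -> EvalReport:
    """Mean over repetitions within each rate, then Friedman + post hoc per metric.

    ``rank_per="rate"`` (default) treats the per-rate mean table as the
    N-blocks-by-K-algorithms input; ``rank_per="repetition"`` ranks every
    (repetition, rate) cell instead.
    """
    if records["algorithm"].nunique() < 2:
        raise InvalidParameterError("need at least 2 algorithms to compare")
    if records["labeling_rate"].nunique() < 2:
        raise InvalidParameterError("need at least 2 labeling rates (blocks)")
    blocks, ranks, fried, post = {}, {}, {}, {}
    for metric, sub in records.groupby("metric"):
        if rank_per == "rate":
            table = sub.pivot_table(
                index="labeling_rate", columns="algorithm", values="value", aggfunc="mean"
            ).sort_index()
        elif rank_per == "repetition":
            table = sub.pivot_table(
                index=["labeling_rate", "repetition"], columns="algorithm", values="value"
            ).sort_index()
        else:
            raise InvalidParameterError(f"unknown rank_per {rank_per!r}")
        rt, fr, ph = friedman_test(
            table.to_numpy(), higher_is_better=True, alpha=alpha, cd_blocks=cd_blocks
        )
        blocks[metric], ranks[metric], fried[metric], post[metric] = table, rt, fr, ph
    return EvalReport(blocks=blocks, ranks=ranks, friedman=fried, posthoc=post, alpha=alpha)


def plot_metric_vs_rate(records: pd.DataFrame, metric: str, path) -> None:
    """Mean +/- one standard deviation of ``metric`` against the labeling rate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    sub = records[records["metric"] == metric]
    for alg, g in sub.groupby("algorithm"):
        agg = g.groupby("labeling_rate")["value"].agg(["mean", "std"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["std"].fillna(0), label=alg, capsize=2)
    ax.set_xlabel("labeling rate")
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
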