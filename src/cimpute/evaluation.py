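"""MCAR injection, RMSE, and the replicated experiment harness.

The simulation protocol: take a fully observed matrix, delete a fixed
fraction of its data cells completely at random (never the class label),
impute, and score the imputed cells with root mean square error

    RMSE = sqrt( sum_i (x_i - x_i')^2 / n )

over the n injected cells, where x_i is the actual and x_i' the estimated
value.  RMSE is computed in z-score space (the space the estimator works
in), using the column statistics of the holed matrix — the statistics the
imputer actually sees.  Conditions (evaluation index, reduction rate,
missing rate) are replicated with derived seeds and averaged.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, UsageError
from .imputation import ImputationResult, ciimpute, iciimpute
from .matrix_io import LabeledMatrix
from .preprocess import DEFAULT_LEVELS, zscore_normalize
from .synthetic_data import SyntheticSpec, generate

logger = logging.getLogger(__name__)

# fixed offset separating generation seeds from injection seeds
_INJECT_SEED_OFFSET = 100_003


@dataclass(frozen=True)
class CellTruth:
    """Original content of one injected-missing cell."""

    row: int
    col: int
    raw: float
    normalized: float


@dataclass
class ExperimentReport:
    """Per-condition aggregates of a replicated imputation experiment."""

    table: pd.DataFrame
    base_seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, path, x: str = "reduction_rate") -> None:
        """Line plot of mean RMSE against a grid axis, one line per index."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for (index, rate), grp in self.table.groupby(["index", "missing_rate"]):
            grp = grp.sort_values(x)
            ax.plot(grp[x], grp["mean_rmse"], marker="o",
                    label=f"{index}, missing {rate}%")
        ax.set_xlabel(x.replace("_", " ") + " (%)")
        ax.set_ylabel("mean RMSE (normalized units)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def inject_mcar(
    matrix: LabeledMatrix, rate: float, seed: int
) -> tuple[LabeledMatrix, list[CellTruth]]:
    """Delete ``round(rate% * n * m)`` observed data cells uniformly at random.

    The class label column is never touched.  The recorded truth carries each
    deleted value in raw units and in the z-score space of the *holed*
    matrix, so estimates and truth live on the same scale.  Deterministic per
    seed.
    """
    if not 0 <= rate < 100:
        raise ParameterError(f"missing rate must be in [0, 100), got {rate}")
    n, m = matrix.values.shape
    n_remove = round(rate / 100.0 * n * m)
    holed = matrix.copy()
    if n_remove == 0:
        return holed, []
    obs_rows, obs_cols = np.where(~matrix.missing_mask)
    if n_remove > obs_rows.size:
        raise ParameterError(
            f"cannot remove {n_remove} cells: only {obs_rows.size} observed"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(obs_rows.size, size=n_remove, replace=False)
    for idx in pick:
        holed.values[obs_rows[idx], obs_cols[idx]] = np.nan
    for j in range(m):
        if np.isnan(holed.values[:, j]).all():
            logger.warning("column %d lost all observed values", j)
    stats = zscore_normalize(holed).col_stats
    truth = []
    for idx in sorted(pick):
        i, j = int(obs_rows[idx]), int(obs_cols[idx])
        raw = float(matrix.values[i, j])
        cs = stats[j]
        truth.append(CellTruth(i, j, raw, (raw - cs.raw_mean) / cs.raw_sd))
    return holed, truth


def rmse(truth: Sequence[float], estimates: Sequence[float]) -> float:
    """Root mean square error between matching value sequences."""
    a = np.asarray(truth, dtype=float)
    b = np.asarray(estimates, dtype=float)
    if a.shape != b.shape:
        raise UsageError("truth and estimates must have equal length")
    if a.size == 0:
        raise UsageError("rmse requires at least one value")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def knn_impute(matrix: LabeledMatrix, n_neighbors: int = 5) -> ImputationResult:
    """Distance-weighted K-nearest-neighbour baseline imputer.

    Neighbours by Euclidean distance over jointly observed attributes; used
    only as a comparison point and harness smoke test, never by CIimpute or
    ICIimpute themselves.
    """
    from sklearn.impute import KNNImputer

    imputer = KNNImputer(n_neighbors=n_neighbors, weights="distance")
    completed = matrix.copy()
    completed.values = imputer.fit_transform(matrix.values)
    return ImputationResult(completed, {}, {"method": "KNNimpute", "k": n_neighbors})


def _default_imputer(
    holed: LabeledMatrix, index: str, reduction_rate: float, theta: int, k: int
) -> ImputationResult:
    if reduction_rate == 0:
        return ciimpute(holed, theta=theta, k=k, index=index)
    return iciimpute(holed, theta=theta, k=k, index=index, reduction_rate=reduction_rate)


def run_experiment(
    data: LabeledMatrix | SyntheticSpec,
    *,
    indices: Sequence[str] = ("confidence",),
    reduction_rates: Sequence[float] = (0, 10, 20, 30, 40, 50),
    missing_rates: Sequence[float] = (10, 20, 30, 40, 50),
    replicates: int = 20,
    theta: int = 3,
    k: int = DEFAULT_LEVELS,
    base_seed: int = 0,
    imputer: Callable[..., ImputationResult] | None = None,
) -> ExperimentReport:
    """Replicated grid experiment over indices x reduction rates x missing rates.

    For each condition and replicate ``r``: draw the matrix (a fresh
    synthetic draw when ``data`` is a spec, seed ``base_seed + r``), inject
    MCAR missingness (seed ``base_seed + r`` plus a fixed offset), impute,
    and score RMSE in normalized units over the injected cells.  Reduction
    rate 0 denotes CIimpute; positive rates denote ICIimpute.  ``imputer``
    may replace the default driver (same keyword signature) for harness
    tests and baselines.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    impute = imputer or _default_imputer
    rows = []
    for index in indices:
        for red in reduction_rates:
            for miss in missing_rates:
                rmses, fb_rates, itemset_means, times = [], [], [], []
                for r in range(replicates):
                    if isinstance(data, SyntheticSpec):
                        matrix, _ = generate(
                            SyntheticSpec(**{**data.__dict__, "seed": base_seed + r})
                        )
                    else:
                        matrix = data
                    holed, truth = inject_mcar(
                        matrix, miss, base_seed + _INJECT_SEED_OFFSET + r
                    )
                    t0 = time.perf_counter()
                    result = impute(
                        holed, index=index, reduction_rate=red, theta=theta, k=k
                    )
                    times.append(time.perf_counter() - t0)
                    if truth:
                        stats = zscore_normalize(holed).col_stats
                        est = [
                            (float(result.completed.values[c.row, c.col])
                             - stats[c.col].raw_mean) / stats[c.col].raw_sd
                            for c in truth
                        ]
                        rmses.append(rmse([c.normalized for c in truth], est))
                        provs = [
                            result.provenance.get((c.row, c.col)) for c in truth
                        ]
                        known = [p for p in provs if p is not None]
                        fb_rates.append(
                            sum(p.fallback for p in known) / len(known)
                            if known else 0.0
                        )
                        counts = [p.n_itemsets for p in known]
                        itemset_means.append(
                            float(np.mean(counts)) if counts else np.nan
                        )
                rows.append(
                    {
                        "method": "CIimpute" if red == 0 else "ICIimpute",
                        "index": index,
                        "reduction_rate": red,
                        "missing_rate": miss,
                        "replicates": replicates,
                        "mean_rmse": float(np.mean(rmses)) if rmses else np.nan,
                        "sd_rmse": float(np.std(rmses, ddof=1))
                        if len(rmses) > 1 else np.nan,
                        "fallback_rate": float(np.mean(fb_rates)) if fb_rates else np.nan,
                        "mean_itemsets": float(np.nanmean(itemset_means))
                        if itemset_means and not np.all(np.isnan(itemset_means))
                        else np.nan,
                        "mean_time_s": float(np.mean(times)),
                    }
                )
    return ExperimentReport(pd.DataFrame(rows), base_seed)
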