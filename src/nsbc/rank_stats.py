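"""Classifier comparison across datasets: Friedman ranks and Holm post-hoc.

Given a datasets x algorithms matrix of balanced-accuracy scores, each
dataset row ranks the algorithms (rank 1 = best, ties averaged); the
Friedman test asks whether the mean ranks could have arisen from
exchangeable columns, and the Holm step-down procedure compares every
algorithm against the best-ranked control at familywise level alpha using

    z_i = (R_0 - R_i) / SE,   SE = sqrt(k (k + 1) / (6 N)),

with two-sided normal p-values and thresholds alpha / (m - i + 1) down the
p-sorted table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_results",
    "mean_ranks",
    "friedman_test",
    "holm_posthoc",
    "count_row_wins",
    "load_benchmark_matrix",
]


def validate_results(results: pd.DataFrame) -> pd.DataFrame:
    """Check a results matrix: numeric, no missing cells, scores in [0, 1]."""
    values = results.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 datasets (rows) and 2 algorithms (columns)")
    if np.isnan(values).any():
        bad = results.columns[np.isnan(values).any(axis=0)].tolist()
        raise ValueError(f"results matrix has missing cells in columns {bad}")
    if (values < 0).any() or (values > 1).any():
        raise ValueError("balanced-accuracy scores must lie in [0, 1]")
    return results


def mean_ranks(results: pd.DataFrame) -> pd.Series:
    """Mean rank per algorithm; rank 1 is the best score in a row, ties averaged."""
    validate_results(results)
    # rankdata ranks ascending, so rank the negated scores
    ranks = np.vstack([stats.rankdata(-row) for row in results.to_numpy(dtype=float)])
    return pd.Series(ranks.mean(axis=0), index=results.columns, name="mean_rank")


def friedman_test(results: pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square statistic (k - 1 df) and its upper-tail p-value.

    Classic sum-of-ranks form without tie correction: with average ranks for
    ties the statistic is 0 when all columns are identical.  The tie-corrected
    variant (as in scipy) is slightly larger in the presence of ties; the
    uncorrected form is the conservative choice.
    """
    validate_results(results)
    n, k = results.shape
    rbar = mean_ranks(results).to_numpy()
    chi2 = 12.0 * n / (k * (k + 1)) * float(((rbar - (k + 1) / 2.0) ** 2).sum())
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


def holm_posthoc(
    ranks: pd.Series,
    n_datasets: int,
    alpha: float = 0.05,
    control: str | None = None,
) -> pd.DataFrame:
    """Holm step-down comparisons of every algorithm against the control.

    The control defaults to the best-ranked (smallest mean rank) algorithm.
    Rows are sorted by |z| descending (equivalently raw p ascending); the
    i-th row's threshold is alpha / (m - i + 1) for m = k - 1 comparisons,
    and rejection stops at the first non-significant row.
    """
    if n_datasets < 2:
        raise ValueError("need at least two datasets")
    k = len(ranks)
    if k < 2:
        raise ValueError("need at least two algorithms")
    if control is None:
        control = str(ranks.idxmin())
    elif control not in ranks.index:
        raise ValueError(f"control {control!r} not among algorithms")
    r0 = float(ranks[control])
    se = np.sqrt(k * (k + 1) / (6.0 * n_datasets))
    rows = []
    for name, r in ranks.items():
        if name == control:
            continue
        z = (r0 - float(r)) / se
        rows.append((str(name), z, 2.0 * stats.norm.sf(abs(z))))
    table = pd.DataFrame(rows, columns=["algorithm", "z", "p"])
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    m = len(table)
    table["holm_threshold"] = [alpha / (m - i) for i in range(m)]
    reject, alive = [], True
    for p, thr in zip(table["p"], table["holm_threshold"]):
        alive = alive and (p <= thr)
        reject.append(alive)
    table["reject"] = reject
    table.attrs["control"] = control
    table.attrs["alpha"] = alpha
    return table


def count_row_wins(results: pd.DataFrame) -> pd.Series:
    """Per algorithm, the number of datasets where it attains the row maximum.

    Ties count as a win for every tied algorithm.
    """
    validate_results(results)
    values = results.to_numpy(dtype=float)
    wins = (values == values.max(axis=1, keepdims=True)).sum(axis=0)
    return pd.Series(wins, index=results.columns, name="row_wins")


def load_benchmark_matrix() -> pd.DataFrame:
    """Published balanced-accuracy scores of nine classifiers on 20 clinical datasets.

    Shipped as example input for the ranking tools (rows are datasets,
    columns algorithms; the two n-SBC presets are the last two columns).
    """
    with resources.files("nsbc.data").joinpath("benchmark_ba.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)
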