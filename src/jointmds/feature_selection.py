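"""Preprocessing filters for real feature matrices.

Three filters cover the typical situations:

* zero-variance removal (uninformative features);
* label-based selection by a two-sided Mann–Whitney U test with Bonferroni
  correction and an optional top-N truncation by corrected p-value, for
  matrices with a binary diagnosis (e.g. GBM vs LGG);
* a variance-to-mean-ratio filter for matrices without reliable labels
  (e.g. radiomic features with incomplete label assignment).

The Mann–Whitney test uses midranks with the tie-corrected normal
approximation; when both groups have at most 8 samples the exact two-sided
p-value is computed by full enumeration of group assignments, which remains
valid under heavy ties (ordinal data such as copy-number calls in
{−1, 0, 1}).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionReport",
    "drop_zero_variance",
    "exact_mannwhitney_p",
    "mannwhitney_select",
    "variance_mean_ratio_filter",
    "TOP_N_DEFAULTS",
]

# customary truncation sizes per sequencing modality
TOP_N_DEFAULTS = {"rnaseq": 5000, "methylation": 10000, "cnv": 4000}

_EXACT_LIMIT = 8  # both groups at most this size -> exact enumeration


@dataclass
class SelectionReport:
    """Per-feature test results of a label-based selection."""

    table: pd.DataFrame  # columns: U, p_raw, p_corrected, selected
    n_tested: int
    n_selected: int


def drop_zero_variance(F: pd.DataFrame) -> pd.DataFrame:
    """Remove features whose sample variance is exactly zero."""
    values = F.to_numpy(float)
    keep = values.var(axis=0) > 0.0
    if not keep.any():
        raise ValueError("all features have zero variance")
    return F.loc[:, keep]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of the first group, from midranks of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by enumerating all group assignments.

    Returns (U, p) with p = min(1, 2·min(P(U ≤ u), P(U ≥ u))) under the exact
    permutation null, computed on midranks so ties are handled correctly.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    total = math.comb(n1 + n2, n1)
    n_le = 0
    n_ge = 0
    tol = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - offset)
        if u <= u_obs + tol:
            n_le += 1
        if u >= u_obs - tol:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def _feature_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([x, y])) == 0.0:
        # all values identical: no evidence of a difference
        return _u_statistic(x, y), 1.0
    if len(x) <= _EXACT_LIMIT and len(y) <= _EXACT_LIMIT:
        return exact_mannwhitney_p(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mannwhitney_select(
    F: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    top_n: int | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Keep features that separate the two label groups after Bonferroni.

    Each feature is tested two-sided between the two groups; raw p-values are
    Bonferroni-corrected across all tested features (p_corr = min(1, m·p)),
    and features with p_corr < ``alpha`` are kept.  If more than ``top_n``
    survive, the ``top_n`` with the smallest corrected p-values are kept
    (ties broken by feature order).
    """
    labels = labels.reindex(F.index)
    if labels.isna().any():
        missing = F.index[labels.isna()].tolist()
        raise ValueError(f"samples without labels: {missing[:5]}")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 label groups, got {len(groups)}")
    mask = (labels == groups[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each label group needs at least 2 samples")
    values = F.to_numpy(float)
    stats = np.empty(F.shape[1])
    pvals = np.empty(F.shape[1])
    for j in range(F.shape[1]):
        stats[j], pvals[j] = _feature_test(values[mask, j], values[~mask, j])
    m = F.shape[1]
    p_corr = np.minimum(1.0, m * pvals)
    selected = p_corr < alpha
    table = pd.DataFrame(
        {"U": stats, "p_raw": pvals, "p_corrected": p_corr, "selected": selected},
        index=F.columns,
    )
    if top_n is not None and selected.sum() > top_n:
        order = np.argsort(p_corr, kind="stable")
        keep_idx = [j for j in order if selected[j]][:top_n]
        selected = np.zeros(m, dtype=bool)
        selected[keep_idx] = True
        table["selected"] = selected
    report = SelectionReport(table=table, n_tested=m, n_selected=int(selected.sum()))
    return F.loc[:, selected], report


def variance_mean_ratio_filter(F: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep features with (unbiased) variance / mean strictly above ``threshold``.

    The ratio is undefined for non-positive means; such features are dropped
    with a warning rather than erroring, since e.g. radiomic features can be
    negative-valued.
    """
    values = F.to_numpy(float)
    means = values.mean(axis=0)
    variances = values.var(axis=0, ddof=1)
    nonpos = means <= 0.0
    if nonpos.any():
        logger.warning(
            "dropping %d features with non-positive mean (ratio undefined)",
            int(nonpos.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = variances / means
    keep = (~nonpos) & (ratio > threshold)
    if not keep.any():
        raise ValueError("variance-to-mean filter removed every feature")
    return F.loc[:, keep]
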