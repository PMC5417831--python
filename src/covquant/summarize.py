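"""Protein abundance estimates from weighted peptide log-ratios.

The protein-level relative abundance for a group of samples is the weighted
geometric mean of its peptides' abundance ratios -- equivalently a weighted
arithmetic mean on the log2 scale:

    log2(z/z') = sum_i w_i * (log2(y_i) - log2(y'_i)) / sum_i w_i

with weights w from the factor-model loadings and missing measurements
simply omitted from both numerator and denominator. When most measurements
in a sample group are absent, absence itself is informative (concentration
below the detection limit), so missing entries in that group are filled
with half of the lowest registered abundance before averaging.

The module also provides the traditional per-sample summarizers used for
method comparison: Top-3 (mean of the three most abundant peptides), the
per-sample median, and a simplified peptide-correlation clustering
summarizer (largest complete-linkage cluster under correlation distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinQuant",
    "impute_group_missing",
    "weighted_group_abundance",
    "top3_summary",
    "median_summary",
    "pqpq_summary",
]


@dataclass
class ProteinQuant:
    """Per-condition weighted log2 abundance estimates for one protein."""

    group_id: str
    peptides: list[str]
    weights: np.ndarray
    abundance: pd.Series   # condition -> weighted mean log2 ratio (NaN if unquantified)
    n_used: pd.Series      # condition -> finite weighted observations used
    imputed: pd.Series     # condition -> whether group-missing imputation fired


def _conditions(group_labels, columns) -> pd.Series:
    labels = pd.Series(group_labels)
    if labels.index.equals(pd.RangeIndex(len(labels))) and len(labels) == len(columns):
        labels.index = columns
    return labels.reindex(columns)


def impute_group_missing(
    x: pd.DataFrame,
    group_labels,
    frac_threshold: float = 0.70,
    *,
    return_flags: bool = False,
):
    """Fill missing values in sample groups dominated by non-detections.

    Per sample group, if the fraction of missing peptide measurements
    exceeds ``frac_threshold``, the missing entries of that group are filled
    with the log2 of half the lowest registered abundance of the protein's
    peptide set, i.e. (min finite log2 value) - 1. With sparser input (e.g.
    MaxQuant-style tables) raise the threshold to 0.95 so that ordinary
    missingness does not trigger imputation.
    """
    if not 0.0 < frac_threshold <= 1.0:
        raise ValueError("frac_threshold must be in (0, 1]")
    labels = _conditions(group_labels, x.columns)
    out = x.copy()
    flags = {}
    finite_vals = x.to_numpy(dtype=float)
    if np.isfinite(finite_vals).any():
        fill = float(np.nanmin(finite_vals)) - 1.0  # log2(min / 2)
    else:
        fill = None
    for cond in pd.unique(labels.dropna()):
        cols = labels.index[labels == cond]
        block = out[cols]
        frac_missing = float(block.isna().to_numpy().mean())
        do_fill = frac_missing > frac_threshold and block.isna().to_numpy().any()
        if do_fill and fill is None:
            logger.warning(
                "group %r entirely missing with no registered minimum; left missing", cond
            )
            do_fill = False
        if do_fill:
            out[cols] = block.fillna(fill)
        flags[cond] = bool(do_fill)
    if return_flags:
        return out, pd.Series(flags, dtype=bool)
    return out


def weighted_group_abundance(
    x: pd.DataFrame,
    w,
    group_labels,
    *,
    group_id: str = "",
) -> ProteinQuant:
    """Weighted mean of finite peptide log2 ratios per sample group (Eq. above).

    Peptides with weight 0 are excluded; missing observations are omitted
    from numerator and denominator. A protein with all weights zero is
    reported unquantified (all-NaN abundances).
    """
    w = np.asarray(w, dtype=float)
    if w.shape[0] != x.shape[0]:
        raise ValueError("one weight per peptide row required")
    labels = _conditions(group_labels, x.columns)
    conds = list(pd.unique(labels.dropna()))
    use = w > 0
    abundance, n_used = {}, {}
    if not use.any():
        for cond in conds:
            abundance[cond] = np.nan
            n_used[cond] = 0
        return ProteinQuant(
            group_id=group_id,
            peptides=list(x.index),
            weights=w,
            abundance=pd.Series(abundance, dtype=float),
            n_used=pd.Series(n_used, dtype=int),
            imputed=pd.Series(False, index=conds, dtype=bool),
        )
    sub = x.loc[use].to_numpy(dtype=float)
    wsub = w[use]
    for cond in conds:
        mask = (labels == cond).to_numpy()
        block = sub[:, mask]
        finite = np.isfinite(block)
        wcell = np.broadcast_to(wsub[:, None], block.shape)
        den = float(wcell[finite].sum())
        if den > 0:
            num = float((wcell[finite] * block[finite]).sum())
            abundance[cond] = num / den
        else:
            abundance[cond] = np.nan
        n_used[cond] = int(finite.sum())
    return ProteinQuant(
        group_id=group_id,
        peptides=list(x.index),
        weights=w,
        abundance=pd.Series(abundance, dtype=float),
        n_used=pd.Series(n_used, dtype=int),
        imputed=pd.Series(False, index=conds, dtype=bool),
    )


def top3_summary(values: pd.DataFrame) -> pd.Series:
    """Per-sample arithmetic mean of the three globally most abundant
    peptides (or all peptides when fewer than three), ranking peptides by
    their overall mean abundance."""
    if values.shape[0] == 0:
        raise ValueError("need at least one peptide")
    order = values.mean(axis=1, skipna=True).sort_values(ascending=False, kind="stable")
    top = values.loc[order.index[:3]]
    return top.mean(axis=0, skipna=True)


def median_summary(values: pd.DataFrame) -> pd.Series:
    """Per-sample median over non-missing peptide measurements."""
    return values.median(axis=0, skipna=True)


def pqpq_summary(values: pd.DataFrame, *, distance_threshold: float = 0.4) -> pd.Series:
    """Largest-cluster summarization of log-transformed peptide abundances.

    Peptide rows (log2, missing filled with zeros) are clustered by
    complete-linkage hierarchical clustering under correlation distance
    (1 - Pearson r) and the tree is cut at ``distance_threshold``; the
    summary is the per-sample average of the largest cluster. Constant rows
    have undefined correlation and become singleton clusters. Returns
    log2-scale values.
    """
    if values.shape[0] < 1:
        raise ValueError("need at least one peptide")
    logged = np.log2(values.where(values > 0))
    Y = logged.fillna(0.0)
    if Y.shape[0] == 1:
        return Y.iloc[0]

    arr = Y.to_numpy(dtype=float)
    variable = arr.std(axis=1) > 0
    labels = np.zeros(arr.shape[0], dtype=int)
    next_label = 1
    idx = np.where(variable)[0]
    if idx.size >= 2:
        d = np.clip(pdist(arr[idx], metric="correlation"), 0.0, None)
        Z = linkage(d, method="complete")
        labels[idx] = fcluster(Z, t=distance_threshold, criterion="distance")
        next_label = labels.max() + 1
    elif idx.size == 1:
        labels[idx] = 1
        next_label = 2
    for j in np.where(~variable)[0]:  # undefined correlation -> singleton
        labels[j] = next_label
        next_label += 1

    counts = np.bincount(labels)
    counts[0] = 0
    best = int(np.argmax(counts))  # ties -> lowest label, deterministic
    return Y.iloc[labels == best].mean(axis=0)
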