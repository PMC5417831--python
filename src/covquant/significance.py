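"""Protein-level differential testing.

Three ingredients:

* a weighted one-way analysis of variance per protein, where the fitted
  per-condition values are the weighted peptide summaries (not per-condition
  least squares), yielding an explained sum of squares (ESS) and F statistic;
* a sequential Monte-Carlo permutation procedure: batches of sample-label
  shuffles, shared across proteins, recompute each protein's ESS; the
  permutation p-value is P_mc = (T + 1) / (N + 1) where T counts shuffles
  with ESS at least as large as observed; testing stops per protein once
  T reaches a cap, or globally once every remaining protein's q-value is
  below the FDR threshold. pi0 (proportion of true nulls) is estimated
  conservatively as min(1, 2 * mean(P_mc)) and q-values follow the standard
  step-up rule scaled by pi0;
* a PECA-style order-statistic test: an ordinary one-way ANOVA p-value per
  peptide, aggregated through the exact null distribution of the median of
  K uniform p-values, Beta((K+1)/2, (K+1)/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "McFdrResult",
    "PecaResult",
    "anova_ess",
    "mc_permutation_fdr",
    "qvalues",
    "peca_protein_p",
]


@dataclass
class AnovaResult:
    """Sums of squares and F statistic for one protein."""

    tss: float
    rss: float
    ess: float
    f_stat: float
    p_value: float
    df: tuple[int, int]
    n_conditions: int
    n_missing: int


@dataclass
class McFdrResult:
    """Sequential Monte-Carlo permutation outcome for a set of proteins."""

    ids: list[str]
    ess: np.ndarray      # observed ESS per protein
    t: np.ndarray        # permutations with ESS >= observed
    n: np.ndarray        # permutations performed per protein
    p_mc: np.ndarray     # (T + 1) / (N + 1)
    pi0_hat: float
    q: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ess": self.ess, "T": self.t, "N": self.n, "p_mc": self.p_mc, "q": self.q},
            index=pd.Index(self.ids, name="group_id"),
        )


@dataclass
class PecaResult:
    """Peptide-level ANOVA p-values aggregated through the beta order statistic."""

    peptides: list[str]
    f_stats: np.ndarray
    p_values: np.ndarray
    median_p: float
    protein_p: float
    n_tested: int


def _align_labels(group_labels, x):
    """Reorder a sample->condition Series to a DataFrame's column order."""
    if isinstance(group_labels, pd.Series) and isinstance(x, pd.DataFrame):
        if set(x.columns) <= set(group_labels.index):
            return group_labels.reindex(x.columns)
    return group_labels


def _label_codes(group_labels, n_samples: int) -> tuple[np.ndarray, list]:
    """Condition label per sample column -> (integer codes, condition order)."""
    labels = list(pd.Series(group_labels))
    if len(labels) != n_samples:
        raise ValueError(
            f"{len(labels)} group labels for {n_samples} sample columns"
        )
    conds = list(pd.unique(pd.Series(labels)))
    lookup = {c: i for i, c in enumerate(conds)}
    codes = np.array([lookup[v] for v in labels], dtype=int)
    return codes, conds


def anova_ess(
    x: pd.DataFrame | np.ndarray,
    w,
    group_labels,
    group_estimates: pd.Series | Mapping | None = None,
) -> AnovaResult:
    """Sums of squares and F for one protein, over finite entries of the
    weighted (w > 0) peptides.

    ``group_estimates`` are the fitted per-condition values x-hat (from the
    weighted summarization); if omitted they are recomputed here with the
    given weights. TSS/RSS are unweighted sums of squared deviations from
    the grand mean / from x-hat; each missing cell removes one residual
    degree of freedom.
    """
    group_labels = _align_labels(group_labels, x)
    X = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    codes, conds = _label_codes(group_labels, X.shape[1])
    I = len(conds)
    if I < 2:
        raise ValueError("ANOVA requires at least 2 conditions")

    use = w > 0
    sub = X[use]
    wsub = w[use]
    finite = np.isfinite(sub)
    n_cells = sub.size
    n_finite = int(finite.sum())
    n_missing = n_cells - n_finite
    if n_finite == 0:
        return AnovaResult(np.nan, np.nan, np.nan, np.nan, np.nan, (I - 1, 0), I, n_missing)

    vals = np.where(finite, sub, 0.0)
    xbar = vals.sum() / n_finite
    tss = float((((vals - xbar) ** 2) * finite).sum())

    if group_estimates is None:
        xhat = np.empty(I)
        for i in range(I):
            mask = finite[:, codes == i]
            block = vals[:, codes == i]
            wcell = np.broadcast_to(wsub[:, None], block.shape)
            den = float(wcell[mask].sum())
            xhat[i] = float((wcell[mask] * block[mask]).sum()) / den if den > 0 else np.nan
    else:
        est = pd.Series(group_estimates)
        xhat = np.array([est.get(c, np.nan) for c in conds], dtype=float)

    rss = 0.0
    for i in range(I):
        if not np.isfinite(xhat[i]):
            continue
        mask = finite[:, codes == i]
        block = vals[:, codes == i]
        rss += float((((block - xhat[i]) ** 2) * mask).sum())
    ess = tss - rss

    df2 = n_finite - I  # = I*J*K - I - m
    if df2 <= 0:
        f_stat, p_value = np.nan, np.nan
    elif rss <= 0:
        # constant data leaves float residue ~ eps * scale in TSS
        null_ess = ess <= 1e-9 * max(1.0, tss)
        f_stat = 0.0 if null_ess else np.inf
        p_value = 1.0 if null_ess else 0.0
    else:
        f_stat = max(ess, 0.0) / (I - 1) / (rss / df2)
        p_value = float(stats.f.sf(f_stat, I - 1, df2))
    return AnovaResult(tss, rss, ess, f_stat, p_value, (I - 1, df2), I, n_missing)


def qvalues(p, pi0_hat: float = 1.0) -> np.ndarray:
    """Step-up q-values: q(i) = min over j >= i of m * pi0 * p(j) / j,
    clipped to [0, 1], returned in the original order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0_hat * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _pi0(p_mc: np.ndarray) -> float:
    """Conservative estimate of the proportion of true nulls:
    min(1, 2/m * sum P_mc). Equals 1 in expectation for uniform p-values."""
    if p_mc.size == 0:
        return 1.0
    return float(min(1.0, 2.0 * p_mc.mean()))


class _PermStats:
    """Per-protein sufficient statistics for O(samples) ESS under any
    relabelling of the samples.

    For each protein (restricted to its w > 0 peptides) the per-sample
    column sums s (weighted values), v (weights over finite cells),
    u, q, c (unweighted value / squared-value / count sums) determine
    every condition's weighted mean and residual sum of squares.
    """

    def __init__(self, proteins: Mapping[str, tuple]):
        self.ids = list(proteins)
        mats = []
        for gid in self.ids:
            x, w = proteins[gid]
            X = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
            w = np.asarray(w, dtype=float)
            use = w > 0
            mats.append((X[use], w[use]))
        n_samples = {m[0].shape[1] for m in mats}
        if len(n_samples) != 1:
            raise ValueError("all proteins must share the same sample columns")
        S = n_samples.pop()
        P = len(mats)
        self.s = np.zeros((P, S))
        self.v = np.zeros((P, S))
        self.u = np.zeros((P, S))
        self.q = np.zeros((P, S))
        self.c = np.zeros((P, S))
        self.tss = np.zeros(P)
        for p_i, (X, w) in enumerate(mats):
            finite = np.isfinite(X)
            vals = np.where(finite, X, 0.0)
            wcol = w[:, None] * finite
            self.s[p_i] = (wcol * vals).sum(axis=0)
            self.v[p_i] = wcol.sum(axis=0)
            self.u[p_i] = vals.sum(axis=0)
            self.q[p_i] = (vals**2).sum(axis=0)
            self.c[p_i] = finite.sum(axis=0)
            n_fin = self.c[p_i].sum()
            if n_fin > 0:
                xbar = self.u[p_i].sum() / n_fin
                self.tss[p_i] = self.q[p_i].sum() - 2 * xbar * self.u[p_i].sum() \
                    + xbar**2 * n_fin

    def ess(self, codes: np.ndarray, n_conditions: int) -> np.ndarray:
        M = np.zeros((codes.size, n_conditions))
        M[np.arange(codes.size), codes] = 1.0
        SV = self.v @ M
        SS = self.s @ M
        with np.errstate(invalid="ignore", divide="ignore"):
            xhat = np.where(SV > 0, SS / np.where(SV > 0, SV, 1.0), 0.0)
        SU = self.u @ M
        SQ = self.q @ M
        SC = self.c @ M
        rss = (SQ - 2 * xhat * SU + xhat**2 * SC).sum(axis=1)
        return self.tss - rss


def mc_permutation_fdr(
    proteins: Mapping[str, tuple],
    group_labels,
    *,
    batch: int = 100,
    t_stop: int = 200,
    q_stop: float = 0.05,
    max_n: int = 10_000,
    seed: int = 0,
) -> McFdrResult:
    """Sequential Monte-Carlo permutation FDR over a set of proteins.

    ``proteins`` maps group_id -> (x, w): the peptides-by-samples log-ratio
    matrix and peptide weights (all sharing the same sample columns, aligned
    with ``group_labels``). Each batch draws ``batch`` label shuffles,
    applied identically to every protein (preserving between-protein
    dependence), and increments each still-active protein's T whenever the
    permuted ESS is >= the observed ESS (ties count). A protein stops at
    T >= t_stop; the whole procedure stops when no protein is active, all
    active proteins have q < q_stop, or max_n permutations are reached
    (logged, results returned at the achieved resolution). Deterministic
    given the seed.
    """
    if not proteins:
        raise ValueError("no proteins to test")
    first_x = next(iter(proteins.values()))[0]
    group_labels = _align_labels(group_labels, first_x)
    stats_ = _PermStats(proteins)
    n_samples = stats_.s.shape[1]
    codes, conds = _label_codes(group_labels, n_samples)
    if codes.size != n_samples:
        raise ValueError("group_labels must cover every sample column")
    I = len(conds)
    if I < 2:
        raise ValueError("permutation test requires at least 2 conditions")

    ess_obs = stats_.ess(codes, I)
    P = len(stats_.ids)
    T = np.zeros(P, dtype=int)
    N = np.zeros(P, dtype=int)
    active = np.ones(P, dtype=bool)
    rng = np.random.default_rng(seed)

    pi0 = 1.0
    q = np.ones(P)
    while active.any():
        for _ in range(batch):
            perm = rng.permutation(n_samples)
            ess_perm = stats_.ess(codes[perm], I)
            hits = ess_perm >= ess_obs
            T[active] += hits[active]
            N[active] += 1
        p_mc = (T + 1) / (N + 1)
        pi0 = _pi0(p_mc)
        q = qvalues(p_mc, pi0)
        active &= T < t_stop
        if active.any() and np.all(q[active] < q_stop):
            break
        if N[active].size and N[active].min() >= max_n:
            logging.getLogger(__name__).info(
                "permutation cap max_n=%d reached with %d proteins unresolved",
                max_n, int(active.sum()),
            )
            break

    p_mc = (T + 1) / (N + 1)
    pi0 = _pi0(p_mc)
    q = qvalues(p_mc, pi0)
    return McFdrResult(
        ids=stats_.ids, ess=ess_obs, t=T, n=N, p_mc=p_mc, pi0_hat=pi0, q=q
    )


def _peptide_anova(row: np.ndarray, codes: np.ndarray, I: int) -> tuple[float, float]:
    """Ordinary one-way ANOVA F and p for a single peptide's finite values."""
    finite = np.isfinite(row)
    vals = row[finite]
    grp = codes[finite]
    present = np.unique(grp)
    k = present.size
    n = vals.size
    if k < 2 or n - k < 1:
        return np.nan, np.nan
    grand = vals.mean()
    tss = float(((vals - grand) ** 2).sum())
    rss = 0.0
    for g in present:
        gv = vals[grp == g]
        rss += float(((gv - gv.mean()) ** 2).sum())
    ess = tss - rss
    df1, df2 = k - 1, n - k
    if rss <= 0:
        if ess <= 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ess / df1) / (rss / df2)
    return f, float(stats.f.sf(f, df1, df2))


def peca_protein_p(
    x: pd.DataFrame | np.ndarray,
    w,
    group_labels,
    *,
    peptides: Sequence[str] | None = None,
) -> PecaResult:
    """Protein-level p-value from the median of per-peptide ANOVA p-values.

    Each weighted (w > 0) peptide is tested by ordinary one-way ANOVA over
    its finite values; under the null the K peptide p-values are uniform and
    their median follows Beta((K+1)/2, (K+1)/2), whose CDF at the observed
    median is the protein p. For even K the lower of the two central order
    statistics is used, keeping integer beta parameters (exact for odd K,
    conservative for even K).
    """
    group_labels = _align_labels(group_labels, x)
    if isinstance(x, pd.DataFrame):
        peptides = list(x.index)
        X = x.to_numpy(dtype=float)
    else:
        X = np.asarray(x, dtype=float)
        peptides = list(peptides) if peptides is not None else [str(i) for i in range(X.shape[0])]
    w = np.asarray(w, dtype=float)
    codes, conds = _label_codes(group_labels, X.shape[1])
    I = len(conds)

    f_stats = np.full(X.shape[0], np.nan)
    p_values = np.full(X.shape[0], np.nan)
    for k in np.where(w > 0)[0]:
        f_stats[k], p_values[k] = _peptide_anova(X[k], codes, I)

    testable = p_values[np.isfinite(p_values)]
    if testable.size == 0:
        return PecaResult(peptides, f_stats, p_values, np.nan, np.nan, 0)
    K = testable.size
    median_p = float(np.sort(testable)[(K - 1) // 2])  # lower central order statistic
    a = (K + 1) / 2
    protein_p = float(stats.beta.cdf(median_p, a, a))
    return PecaResult(peptides, f_stats, p_values, median_p, protein_p, K)
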