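"""Non-negative MAP factor analysis of one protein's peptide log-ratios.

Model
-----
For a protein measured through K peptides across S samples, the zero-mean
log-ratio observations are assumed to share a single latent signal -- the
relative protein concentration z -- scaled by per-peptide responsiveness:

    x = lambda * z + eps,      x ~ N(0, lambda lambda^T + Psi)

with non-negative loadings ``lambda`` and diagonal noise covariance ``Psi``.
The loadings are estimated by expectation-maximization under a zero-mean
Gaussian prior (maximum a posteriori) with a non-negativity rectification:
a peptide whose trajectory anticorrelates with the shared signal cannot be
fit by a non-negative loading and is driven to zero. Fitting is performed
on per-peptide standardized rows (missing entries contribute zero to the
covariance, the null value on the centered scale, which is conservative);
the reported loadings are rescaled back to the observed log-ratio scale.

The summed signal-to-noise of the fitted model, in decibels, classifies the
peptide set as informative (S/N above a modest -20 dB, i.e. signal at least
1% of noise) or non-informative. Loadings below half of the maximum mark
peptides as unreliably quantified; they receive weight 0 downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAConfig",
    "FactorModel",
    "fit_farms",
    "signal_to_noise",
    "informative_call",
    "peptide_weights",
]

SNR_CAP_DB = 100.0


@dataclass
class FAConfig:
    """Hyperparameters of the factor-model fit and the downstream calls.

    prior_weight
        Strength of the zero-mean Gaussian prior on the loadings in the
        M-step (ridge shrinkage); 0 gives plain maximum likelihood.
    psi_floor
        Lower bound on each noise variance, keeping the E-step defined when
        peptides are (near-)duplicates.
    snr_threshold_db
        Informative/non-informative decision boundary: informative iff
        S/N > threshold. -20 dB corresponds to a 1% signal-to-noise ratio.
    weight_cutoff
        Peptides whose max-normalized loading is <= cutoff are excluded
        from summarization (the half-of-maximum rule).
    min_peptides
        Covariation is undefined below this; smaller groups are reported
        non-informative with unit weights.
    """

    prior_weight: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-6
    psi_floor: float = 1e-4
    snr_threshold_db: float = -20.0
    weight_cutoff: float = 0.5
    min_peptides: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FactorModel:
    """Fitted single-factor model for one protein group."""

    peptides: list[str]
    loadings: np.ndarray        # max-normalized, in [0, 1]
    loadings_raw: np.ndarray    # log-ratio scale, pre-normalization
    noise_var: np.ndarray       # diagonal noise variances, log-ratio scale
    factor_scores: np.ndarray   # posterior mean of z per sample
    snr_db: float
    informative: bool
    n_iter: int = 0


def _snr_db(loadings: np.ndarray, noise_var: np.ndarray, cap: float = SNR_CAP_DB) -> float:
    """S/N in decibels: total signal covariance over total noise variance.

    The signal covariance matrix is the rank-one lambda lambda^T, whose
    entries sum to (sum lambda)^2; the noise is the trace of Psi. Summing
    over the whole group makes the S/N grow with the number of coherent
    peptides, matching the observation that better peptide coverage gives
    more certain quantification.
    """
    lam = np.asarray(loadings, dtype=float)
    psi = np.asarray(noise_var, dtype=float)
    if not np.all(np.isfinite(lam)) or not np.all(np.isfinite(psi)):
        return float("nan")
    signal = lam.sum() ** 2
    noise = psi.sum()
    if noise <= 0:
        return cap
    if signal <= 0:
        return -cap
    return float(np.clip(10.0 * np.log10(signal / noise), -cap, cap))


def fit_farms(x, cfg: FAConfig | None = None, *, peptides=None) -> FactorModel:
    """Fit the non-negative MAP factor model to one protein group.

    Parameters
    ----------
    x
        Peptides-by-samples log-ratio matrix (DataFrame or array); NaN marks
        missing measurements. Every peptide needs at least one finite value,
        and at least 3 samples must carry data (the minimum to measure
        covariation).
    cfg
        See :class:`FAConfig`. The fit is deterministic given ``x`` and
        ``cfg``.
    """
    cfg = cfg or FAConfig()
    if isinstance(x, pd.DataFrame):
        peptides = list(x.index)
        X = x.to_numpy(dtype=float)
    else:
        X = np.asarray(x, dtype=float)
        if X.ndim != 2:
            raise ValueError("x must be 2-dimensional (peptides x samples)")
        peptides = list(peptides) if peptides is not None else [str(i) for i in range(X.shape[0])]

    K, S = X.shape
    finite = np.isfinite(X)
    if not finite.any(axis=1).all():
        raise ValueError("peptide row(s) with no finite measurements")
    if K < cfg.min_peptides:
        # covariation undefined: report unit weights, no informative call
        return FactorModel(
            peptides=peptides,
            loadings=np.ones(K),
            loadings_raw=np.full(K, np.nan),
            noise_var=np.full(K, np.nan),
            factor_scores=np.full(S, np.nan),
            snr_db=float("nan"),
            informative=False,
        )
    if int(finite.any(axis=0).sum()) < 3:
        raise ValueError("need at least 3 samples with finite data to measure covariation")

    mu = np.nanmean(np.where(finite, X, np.nan), axis=1)
    sd = np.nanstd(np.where(finite, X, np.nan), axis=1)
    sd = np.where(np.isfinite(sd), sd, 0.0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu[:, None]) / sd_safe[:, None]
    Xs[~finite] = 0.0  # missing -> null ratio on the centered scale
    Xs[sd == 0] = 0.0  # constant peptides carry no covariation signal

    C = Xs @ Xs.T / S
    C = 0.5 * (C + C.T)
    diagC = np.diag(C).copy()

    lam = np.sqrt(0.75 * np.clip(diagC, 1e-12, None))
    psi = np.maximum(diagC - lam**2, cfg.psi_floor)

    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        ipl = lam / psi
        xi = 1.0 / (1.0 + lam @ ipl)      # posterior variance of z
        a = ipl * xi                       # E[z | x] = a^T x
        Ca = C @ a
        Ezz = float(a @ Ca) + xi           # posterior second moment of z
        lam_new = np.maximum(Ca / (Ezz + cfg.prior_weight * psi), 0.0)
        psi = np.maximum(diagC - 2.0 * lam_new * Ca + lam_new**2 * Ezz, cfg.psi_floor)
        delta = float(np.max(np.abs(lam_new - lam)))
        lam = lam_new
        if delta < cfg.tol:
            break

    ipl = lam / psi
    xi = 1.0 / (1.0 + lam @ ipl)
    scores = (ipl * xi) @ Xs

    loadings_raw = lam * sd
    noise_var = psi * sd**2
    snr = _snr_db(loadings_raw, noise_var)
    lmax = loadings_raw.max()
    loadings = loadings_raw / lmax if lmax > 0 else np.zeros(K)

    return FactorModel(
        peptides=peptides,
        loadings=loadings,
        loadings_raw=loadings_raw,
        noise_var=noise_var,
        factor_scores=scores,
        snr_db=snr,
        informative=informative_call(snr, cfg),
        n_iter=n_iter,
    )


def signal_to_noise(model: FactorModel) -> float:
    """Recompute the model's S/N in decibels from its pre-normalization
    loadings and noise variances."""
    return _snr_db(model.loadings_raw, model.noise_var)


def informative_call(snr_db: float, cfg: FAConfig | None = None) -> bool:
    """True iff the S/N exceeds the informative threshold (NaN is never
    informative -- e.g. single-peptide groups, where covariation is
    undefined)."""
    cfg = cfg or FAConfig()
    if not np.isfinite(snr_db):
        return False
    return bool(snr_db > cfg.snr_threshold_db)


def peptide_weights(model: FactorModel, cfg: FAConfig | None = None) -> np.ndarray:
    """Summarization weights: max-normalized loadings, with peptides at or
    below the cutoff (half of the maximum by default) zeroed out as
    unreliably quantified."""
    cfg = cfg or FAConfig()
    w = np.asarray(model.loadings, dtype=float).copy()
    if len(w) >= cfg.min_peptides:
        w[w <= cfg.weight_cutoff] = 0.0
    return w
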