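"""Synthetic controlled-mixture data and the false quantification rate (FQR).

The generator emulates a controlled benchmark in which known protein
amounts are mixed at a series of ratios across samples and measured through
proteolytic peptides. Each peptide's readout follows the linear response
model y = alpha * z * exp(eps): an ionization efficiency alpha (log-uniform
over four decades, the span of the linear electrospray range), the protein
concentration z, and multiplicative log-normal measurement noise (the
log-scale Gaussian error assumed by the factor model and the ANOVA). A
configurable fraction of peptides is *incoherent* -- their trajectory does
not follow their protein's concentration, emulating mis-identified or
mis-extracted signals -- and a configurable fraction of measurements is
missing.

The FQR statistic scores a quantification method against the known design:
per protein, the Spearman rank correlation between all pairwise sample
abundance ratios of the estimates and of the true concentrations; proteins
with negative correlation are counted as false quantifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import PeptideTable

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDesign",
    "SyntheticPeptideModel",
    "SimulatedDataset",
    "simulate_design",
    "simulate_peptides",
    "pair_indices",
    "pairwise_ratio_correlations",
    "compute_fqr",
]

DESIGN_KINDS = ("constant", "linear", "exponential", "nonlinear", "mixed")
INCOHERENT_MODES = ("independent", "anticorrelated", "swap", "mixed")


@dataclass
class SyntheticDesign:
    """True protein concentrations z (proteins x samples, strictly positive)."""

    z: pd.DataFrame
    kinds: pd.Series  # protein -> curve family

    def __post_init__(self) -> None:
        if not (self.z.to_numpy() > 0).all():
            raise ValueError("design concentrations must be strictly positive")


@dataclass
class SyntheticPeptideModel:
    """Peptide-level generative settings.

    Defaults are the benchmark study conditions: log-scale noise sd 0.2,
    11% incoherent peptides, 12% missing values, ionization efficiencies
    spanning four orders of magnitude, anticorrelated incoherent
    trajectories (the canonical contradicting-peptide behavior).
    """

    noise_sd: float = 0.2
    missing_rate: float = 0.12
    incoherent_fraction: float = 0.11
    alpha_log10_range: tuple[float, float] = (0.0, 4.0)
    detection_floor: float = 1e-9
    incoherent_mode: str = "anticorrelated"

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.incoherent_fraction < 1:
            raise ValueError("incoherent_fraction must be in [0, 1)")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be > 0")
        if self.incoherent_mode not in INCOHERENT_MODES:
            raise ValueError(f"incoherent_mode must be one of {INCOHERENT_MODES}")


@dataclass
class SimulatedDataset:
    """A simulated peptide table plus its ground truth."""

    table: PeptideTable
    design: SyntheticDesign
    incoherent: pd.Series  # peptide -> bool


def _curve(kind: str, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_samples) / max(n_samples - 1, 1)
    z0 = 10.0 ** rng.uniform(0.0, 2.0)
    if kind == "constant":
        return np.full(n_samples, z0)
    if kind == "linear":
        # decreases linearly to 10% of the starting amount
        return z0 * (1.0 - 0.9 * t)
    if kind == "exponential":
        # increases exponentially over four orders of magnitude
        ratio = 10.0 ** (4.0 / max(n_samples - 1, 1))
        return z0 * ratio ** np.arange(n_samples)
    if kind == "nonlinear":
        # increases nonlinearly (quadratic ramp from 10% to 100%)
        return z0 * (0.1 + 0.9 * t**2)
    raise ValueError(f"unknown design kind {kind!r}")


def simulate_design(
    kind: str = "mixed",
    n_samples: int = 20,
    n_proteins: int = 500,
    seed: int = 0,
) -> SyntheticDesign:
    """Generate true concentration trajectories for ``n_proteins``.

    ``kind`` picks one curve family for every protein, or ``"mixed"`` for an
    even assignment over the three monotone families plus constant (null)
    proteins. Deterministic given the seed.
    """
    if kind not in DESIGN_KINDS:
        raise ValueError(f"kind must be one of {DESIGN_KINDS}")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    families = ("linear", "exponential", "nonlinear", "constant")
    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    kinds = [families[i % 4] if kind == "mixed" else kind for i in range(n_proteins)]
    z = np.vstack([_curve(k, n_samples, rng) for k in kinds])
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    return SyntheticDesign(
        z=pd.DataFrame(z, index=ids, columns=samples),
        kinds=pd.Series(kinds, index=ids, name="kind"),
    )


def _incoherent_trajectory(
    z: np.ndarray, mode: str, design_z: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if mode == "mixed":
        mode = rng.choice(("independent", "anticorrelated", "swap"))
    if mode == "independent":
        return rng.permutation(z)
    if mode == "anticorrelated":
        # geometric reflection: log z' = const - log z
        return z.max() * z.min() / z
    if mode == "swap":
        other = int(rng.integers(design_z.shape[0]))
        return design_z[other]
    raise ValueError(f"unknown incoherent mode {mode!r}")


def simulate_peptides(
    design: SyntheticDesign,
    model: SyntheticPeptideModel | None = None,
    n_peptides: int | tuple[int, int] = (3, 10),
    seed: int = 0,
) -> SimulatedDataset:
    """Draw a raw peptide abundance table from the linear response model.

    Each protein gets ``n_peptides`` peptides (an int, or an inclusive range
    sampled per protein). A peptide is incoherent with probability
    ``model.incoherent_fraction``, in which case its trajectory is replaced
    per ``model.incoherent_mode``. Deterministic given the seed.
    """
    model = model or SyntheticPeptideModel()
    rng = np.random.default_rng(seed)
    Z = design.z.to_numpy()
    n_prot, S = Z.shape
    rows, ids, prot_of, incoh_flags = [], [], [], []
    for p_i, gid in enumerate(design.z.index):
        if isinstance(n_peptides, tuple):
            k = int(rng.integers(n_peptides[0], n_peptides[1] + 1))
        else:
            k = int(n_peptides)
        z = Z[p_i]
        for j in range(k):
            alpha = 10.0 ** rng.uniform(*model.alpha_log10_range)
            incoherent = bool(rng.random() < model.incoherent_fraction)
            traj = _incoherent_trajectory(z, model.incoherent_mode, Z, rng) \
                if incoherent else z
            y = alpha * traj * np.exp(rng.normal(0.0, model.noise_sd, S))
            y[rng.random(S) < model.missing_rate] = np.nan
            y[y < model.detection_floor] = np.nan
            rows.append(y)
            ids.append(f"{gid}_pep{j + 1}")
            prot_of.append(gid)
            incoh_flags.append(incoherent)
    table = PeptideTable(
        pd.DataFrame(np.vstack(rows), index=ids, columns=design.z.columns),
        scale="raw",
        proteins=pd.Series(prot_of, index=ids, name="protein"),
    )
    return SimulatedDataset(
        table=table,
        design=design,
        incoherent=pd.Series(incoh_flags, index=ids, name="incoherent"),
    )


def pair_indices(n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of all C(n, 2) ordered sample pairs (a < b)."""
    pairs = np.array(list(combinations(range(n_samples), 2)), dtype=int)
    if pairs.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return pairs[:, 0], pairs[:, 1]


def pairwise_ratio_correlations(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    *,
    log_scale: bool = False,
) -> pd.Series:
    """Per-protein Spearman correlation between estimated and true pairwise
    sample ratios.

    ``estimates`` holds per-sample protein abundances (raw scale by default;
    pass ``log_scale=True`` for log-ratio estimates, where a pairwise ratio
    is a difference). ``truth`` holds the design concentrations on the raw
    scale. Pairs involving a missing estimate are excluded; proteins with
    fewer than 2 valid pairs, or a constant ratio vector (correlation
    undefined), return NaN.
    """
    common = estimates.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("estimates and truth share no proteins")
    est = estimates.loc[common, truth.columns].to_numpy(dtype=float)
    tru = truth.loc[common].to_numpy(dtype=float)
    ia, ib = pair_indices(est.shape[1])
    est_d = est[:, ia] - est[:, ib] if log_scale else est[:, ia] / est[:, ib]
    tru_d = np.log(tru[:, ia]) - np.log(tru[:, ib])  # monotone in the true ratio
    corr = np.full(len(common), np.nan)
    for i in range(len(common)):
        valid = np.isfinite(est_d[i])
        if valid.sum() < 2:
            continue
        e, t = est_d[i, valid], tru_d[i, valid]
        if np.ptp(e) == 0 or np.ptp(t) == 0:
            continue
        corr[i] = stats.spearmanr(e, t).statistic
    return pd.Series(corr, index=common, name="spearman")


def compute_fqr(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    threshold: float = 0.0,
    *,
    log_scale: bool = False,
) -> float:
    """Fraction of proteins whose pairwise-ratio Spearman correlation with
    the true design falls below ``threshold`` (default 0: negatively
    correlated, i.e. falsely quantified).

    Proteins with undefined correlation (too few valid pairs, constant
    design) are excluded from the denominator and logged.
    """
    corr = pairwise_ratio_correlations(estimates, truth, log_scale=log_scale)
    valid = corr.dropna()
    n_dropped = len(corr) - len(valid)
    if n_dropped:
        logger.info("FQR: %d protein(s) excluded with undefined correlation", n_dropped)
    if len(valid) == 0:
        raise ValueError("no protein with a defined ratio correlation")
    return float((valid < threshold).mean())
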