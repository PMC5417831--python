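"""Peptide abundance tables: parsing, normalization, and log-ratio matrices.

Label-free (and labelled-ratio) quantification arrives as a delimited text
table with one row per peptide and one column per sample. Raw ion
intensities are non-negative; a zero, negative, or empty cell means the
peptide was not detected in that run and is treated as missing. Downstream
modelling works on log2 ratios against a common reference, so this module
also covers peptide-to-protein mapping, per-run normalization, Gaussian
mixture zero-centering of clinical ratio data, and sample-coverage filters.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import parser as _parser

logger = logging.getLogger(__name__)

#: Column names recognised as a protein-mapping column when parsing tables.
PROTEIN_COLUMNS = {"protein", "proteins", "protein_id", "protein_ids", "gene", "genes"}

VALID_SCALES = ("raw", "log2", "ratio")


@dataclass
class PeptideTable:
    """A peptide-by-sample abundance table.

    Parameters
    ----------
    abundances
        DataFrame indexed by unique peptide keys, one column per sample.
        Missing measurements are ``NaN``. On the ``raw`` and ``ratio``
        scales, non-positive values are converted to missing on construction
        (zeros are non-detections, not measurements).
    scale
        ``"raw"`` (intensities), ``"log2"`` (already log-transformed), or
        ``"ratio"`` (pre-computed sample/reference ratios, e.g. H/L data).
    proteins
        Optional peptide -> protein id(s) mapping; multiple ids are
        semicolon-delimited.
    """

    abundances: pd.DataFrame
    scale: str = "raw"
    proteins: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.abundances.index.has_duplicates:
            dup = self.abundances.index[self.abundances.index.duplicated()][:3]
            raise ValueError(f"duplicate peptide keys, e.g. {list(dup)}")
        if self.abundances.shape[1] == 0:
            raise ValueError("peptide table has no sample columns")
        vals = self.abundances.astype(float)
        if self.scale in ("raw", "ratio"):
            vals = vals.where(vals > 0)
        self.abundances = vals
        if self.proteins is not None:
            self.proteins = self.proteins.reindex(self.abundances.index)

    @property
    def n_peptides(self) -> int:
        return self.abundances.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass
class ProteinGroup:
    """Peptides tentatively attributed to one protein (or gene) group."""

    group_id: str
    member_peptides: list[str]
    degenerate_peptides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_peptides:
            raise ValueError(f"protein group {self.group_id!r} has no member peptides")
        if len(set(self.member_peptides)) != len(self.member_peptides):
            raise ValueError(f"protein group {self.group_id!r} has duplicate members")


@dataclass
class AbundanceMatrix:
    """Log2-ratio matrix x = log2(y) - log2(y_ref), peptides by samples."""

    x: pd.DataFrame
    groups: pd.Series | None = None  # sample -> condition label

    def center_rows(self) -> "AbundanceMatrix":
        """Zero-center each peptide row over its finite entries."""
        centered = self.x.sub(self.x.mean(axis=1, skipna=True), axis=0)
        return AbundanceMatrix(centered, self.groups)


def read_peptide_table(
    path: str | Path,
    *,
    sep: str | None = None,
    scale: str = "raw",
    protein_col: str | None | bool = "auto",
) -> PeptideTable:
    """Read a delimited peptide table (column 1 = peptide key, header = samples).

    An optional second column holding protein identifiers (semicolon-delimited
    for shared peptides) is detected by name, or named explicitly via
    ``protein_col``; pass ``protein_col=None`` to force all non-index columns
    to be samples. Empty, non-numeric, zero and negative cells become missing.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    proteins = None
    if protein_col == "auto":
        protein_col = None
        if len(df.columns) and str(df.columns[0]).strip().lower() in PROTEIN_COLUMNS:
            protein_col = df.columns[0]
    if protein_col:
        if protein_col not in df.columns:
            raise ValueError(f"protein column {protein_col!r} not in table")
        proteins = df[protein_col].astype(str)
        df = df.drop(columns=[protein_col])
    values = df.apply(pd.to_numeric, errors="coerce")
    return PeptideTable(values, scale=scale, proteins=proteins)


def write_peptide_table(table: PeptideTable, path: str | Path, *, sep: str = "\t") -> None:
    """Write a table in the same layout accepted by :func:`read_peptide_table`."""
    out = table.abundances.copy()
    if table.proteins is not None:
        out.insert(0, "protein", table.proteins)
    out.index.name = "peptide"
    out.to_csv(path, sep=sep)


def read_sample_groups(path: str | Path, *, sep: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, group_label) file into a Series."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("sample file needs two columns: sample_id, group_label")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def _bare_sequence(peptide: str) -> str:
    # strip modification annotations: bracketed masses/names, lowercase tags,
    # terminal markers -- keep the uppercase residue string only
    stripped = re.sub(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}", "", peptide)
    return "".join(ch for ch in stripped if "A" <= ch <= "Z")


def map_peptides_to_proteins(
    table: PeptideTable,
    fasta_path: str | Path,
    *,
    method: str = "substring",
    enzyme: str = "trypsin",
    missed_cleavages: int = 1,
    min_length: int = 5,
    use_unique: bool = False,
) -> list[ProteinGroup]:
    """Assign each peptide to every protein whose sequence (or in-silico
    digest) contains it.

    ``method="substring"`` (default) matches the bare peptide sequence as a
    substring of the protein sequence, which is robust to missed-cleavage
    bookkeeping; ``method="digest"`` requires the peptide to appear in the
    enzymatic digest (default trypsin, one missed cleavage). Peptides that
    match more than one group are flagged degenerate, and dropped from all
    groups when ``use_unique`` is set.
    """
    if method not in ("substring", "digest"):
        raise ValueError("method must be 'substring' or 'digest'")
    entries = [(header.split()[0], seq.upper()) for header, seq in _fasta.read(str(fasta_path))]
    if not entries:
        raise ValueError(f"empty FASTA: {fasta_path}")

    bare = {pep: _bare_sequence(pep) for pep in table.abundances.index}
    assignments: dict[str, list[str]] = {pep: [] for pep in bare}
    for gid, seq in entries:
        if method == "digest":
            universe = _parser.cleave(
                seq, _parser.expasy_rules[enzyme], missed_cleavages=missed_cleavages,
                min_length=min_length,
            )
            hits = {pep for pep, b in bare.items() if b in universe}
        else:
            hits = {pep for pep, b in bare.items() if b and b in seq}
        for pep in hits:
            assignments[pep].append(gid)

    degenerate = {pep for pep, gids in assignments.items() if len(gids) > 1}
    members: dict[str, list[str]] = {}
    degen: dict[str, list[str]] = {}
    for pep, gids in assignments.items():
        for gid in gids:
            if pep in degenerate:
                degen.setdefault(gid, []).append(pep)
                if use_unique:
                    continue
            members.setdefault(gid, []).append(pep)
    if not any(assignments.values()):
        warnings.warn("no peptide mapped to any protein in the FASTA", stacklevel=2)
    return [
        ProteinGroup(gid, peps, degen.get(gid, []))
        for gid, peps in sorted(members.items())
    ]


def protein_groups_from_table(table: PeptideTable) -> list[ProteinGroup]:
    """Build protein groups from the table's own protein-id column.

    Semicolon-delimited ids mean the peptide is shared between groups and is
    recorded as degenerate in each.
    """
    if table.proteins is None:
        raise ValueError("table has no protein mapping column")
    members: dict[str, list[str]] = {}
    degen: dict[str, list[str]] = {}
    for pep, ids in table.proteins.items():
        gids = [g.strip() for g in str(ids).split(";") if g.strip()]
        for gid in gids:
            members.setdefault(gid, []).append(pep)
            if len(gids) > 1:
                degen.setdefault(gid, []).append(pep)
    return [
        ProteinGroup(gid, peps, degen.get(gid, []))
        for gid, peps in sorted(members.items())
    ]


def normalize_run_average(table: PeptideTable) -> PeptideTable:
    """Divide each sample column by the mean of its finite entries.

    This removes run-to-run differences in total ion current / injected
    amount; after normalization every column's finite mean is 1, so the
    operation is idempotent.
    """
    if table.scale != "raw":
        raise ValueError("run-average normalization applies to raw intensities")
    means = table.abundances.mean(axis=0, skipna=True)
    bad = means.index[~np.isfinite(means)]
    if len(bad):
        raise ValueError(f"sample(s) with no finite measurements: {list(bad)}")
    return PeptideTable(table.abundances.div(means, axis=1), scale="raw",
                        proteins=table.proteins)


def to_log_ratios(
    table: PeptideTable,
    reference: str | Sequence[str] | None = "mean",
    *,
    flip_sign: bool = False,
    groups: pd.Series | None = None,
) -> AbundanceMatrix:
    """Transform abundances to log2 ratios against a common reference.

    ``reference`` may name one or more reference sample columns (their
    per-peptide mean log2 abundance is subtracted and the columns dropped),
    be ``"mean"`` (each peptide compared with its own mean over samples), or
    ``None`` when the input is already relative (``ratio``/``log2`` scale).
    ``flip_sign`` reverses the direction of comparison, e.g. for tables
    recorded as reference-to-sample (H/L) ratios.
    """
    vals = table.abundances
    logx = vals if table.scale == "log2" else np.log2(vals)
    if isinstance(reference, str) and reference != "mean":
        reference = [reference]
    if reference is None:
        x = logx.copy()
    elif isinstance(reference, str):  # "mean"
        x = logx.sub(logx.mean(axis=1, skipna=True), axis=0)
    else:
        missing = [r for r in reference if r not in logx.columns]
        if missing:
            raise ValueError(f"reference column(s) absent: {missing}")
        ref = logx[list(reference)].mean(axis=1, skipna=True)
        x = logx.drop(columns=list(reference)).sub(ref, axis=0)
    if flip_sign:
        x = -x
    return AbundanceMatrix(x, groups)


def normalize_gmm_center(
    matrix: AbundanceMatrix,
    *,
    min_finite: int = 20,
    seed: int = 0,
    return_shifts: bool = False,
):
    """Zero-center each sample by the mean of the major Gaussian component.

    Per sample, a two-component Gaussian mixture is fit to the finite
    log-ratios and the mean of the larger-weight component is subtracted, so
    the unregulated bulk of peptides sits at ratio 0. Samples with fewer
    than ``min_finite`` finite entries, or where the mixture fit fails to
    converge, fall back to subtracting the sample median (logged).
    """
    from sklearn.mixture import GaussianMixture

    x = matrix.x.copy()
    shifts = {}
    for col in x.columns:
        v = x[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            shifts[col] = 0.0
            continue
        shift = None
        if v.size >= min_finite:
            gm = GaussianMixture(n_components=2, n_init=3, max_iter=500,
                                 random_state=seed)
            try:
                gm.fit(v[:, None])
                if gm.converged_:
                    shift = float(gm.means_[int(np.argmax(gm.weights_)), 0])
            except Exception:  # pragma: no cover - degenerate numerical input
                shift = None
        if shift is None:
            shift = float(np.median(v))
            logger.info("GMM centering fell back to median for sample %s", col)
        x[col] = x[col] - shift
        shifts[col] = shift
    out = AbundanceMatrix(x, matrix.groups)
    if return_shifts:
        return out, pd.Series(shifts)
    return out


def filter_min_samples(matrix: AbundanceMatrix, min_n: int) -> AbundanceMatrix:
    """Drop peptides quantified in strictly fewer than ``min_n`` samples.

    The "discard if quantified in no more than t samples" convention is
    reproduced by passing ``min_n = t + 1``.
    """
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    counts = matrix.x.notna().sum(axis=1)
    return AbundanceMatrix(matrix.x.loc[counts >= min_n], matrix.groups)


def filter_table_min_samples(table: PeptideTable, min_n: int) -> PeptideTable:
    """Same coverage filter applied directly to a :class:`PeptideTable`."""
    counts = table.abundances.notna().sum(axis=1)
    keep = counts >= min_n
    proteins = table.proteins.loc[keep] if table.proteins is not None else None
    return PeptideTable(table.abundances.loc[keep], scale=table.scale, proteins=proteins)
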