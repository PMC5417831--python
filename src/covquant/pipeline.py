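"""End-to-end orchestration: peptide table -> differential protein report.

The stages mirror how the method is meant to be run: normalize the raw
table, transform to log2 ratios against a common reference, group peptides
by protein, fit the factor model per group to weight (or exclude) peptides,
summarize per-condition protein abundances as weighted means, and test for
differential abundance with the Monte-Carlo permutation FDR and/or the
PECA-style order-statistic test. Everything is deterministic given the
configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factor import FAConfig, FactorModel, fit_farms, peptide_weights
from .io import (
    AbundanceMatrix,
    PeptideTable,
    ProteinGroup,
    filter_min_samples,
    map_peptides_to_proteins,
    normalize_gmm_center,
    normalize_run_average,
    protein_groups_from_table,
    read_peptide_table,
    read_sample_groups,
    to_log_ratios,
)
from .significance import mc_permutation_fdr, peca_protein_p, qvalues
from .summarize import (
    ProteinQuant,
    impute_group_missing,
    median_summary,
    pqpq_summary,
    top3_summary,
    weighted_group_abundance,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GroupQuantResult", "quantify_groups", "baseline_summaries",
           "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (echoed to the output directory)."""

    input: str
    out: str
    samples: str | None = None
    db: str | None = None                 # FASTA; otherwise the table's protein column
    reference: str | None = "mean"        # sample id(s, comma-separated) or "mean"
    log_input: str = "raw"                # raw | log2 | ratio
    flip_sign: bool = False
    normalize: bool = True                # run-average normalization (raw input only)
    gmm_center: bool = False
    min_samples: int = 0
    use_unique: bool = False
    mapping_method: str = "substring"     # substring | digest
    impute_threshold: float = 0.70
    test: str = "both"                    # mc | peca | both | none
    mc_batch: int = 100
    mc_tstop: int = 200
    max_permutations: int = 10_000
    q_stop: float = 0.05
    seed: int = 0
    include_singletons: bool = True
    fa: FAConfig = field(default_factory=FAConfig)


@dataclass
class GroupQuantResult:
    """Factor models, weights and per-condition abundances for all groups."""

    diagnostics: pd.DataFrame   # group_id -> n_peptides, n_used, snr_db, informative
    weights: pd.DataFrame       # peptide -> group_id, weight, loading
    abundance: pd.DataFrame     # group_id x condition (log2 ratios)
    models: dict
    quants: dict
    used_matrices: dict         # group_id -> (imputed x of used peptides, weights)


def quantify_groups(
    matrix: AbundanceMatrix,
    groups: list[ProteinGroup],
    fa_cfg: FAConfig | None = None,
    *,
    impute_threshold: float = 0.70,
    condition_of: pd.Series | None = None,
) -> GroupQuantResult:
    """Fit the factor model and summarize abundance for every protein group.

    ``condition_of`` maps sample -> condition; without it every sample is
    its own condition (per-sample estimates). Peptides absent from the
    matrix (e.g. removed by coverage filters) are ignored; groups left with
    no testable peptides are skipped.
    """
    fa_cfg = fa_cfg or FAConfig()
    x = matrix.x
    if condition_of is None:
        condition_of = matrix.groups
    if condition_of is None:
        condition_of = pd.Series(list(x.columns), index=x.columns)
    condition_of = condition_of.reindex(x.columns)

    diag_rows, weight_rows = [], []
    abundances = {}
    models, quants, used = {}, {}, {}
    for grp in groups:
        present = [p for p in grp.member_peptides if p in x.index]
        if not present:
            continue
        sub = x.loc[present]
        sub = sub.loc[sub.notna().any(axis=1)]
        if sub.shape[0] == 0:
            continue
        try:
            model = fit_farms(sub, fa_cfg)
        except ValueError as exc:
            logger.warning("group %s not fitted: %s", grp.group_id, exc)
            continue
        w = peptide_weights(model, fa_cfg)
        x_used = sub.loc[np.asarray(w) > 0]
        w_used = w[np.asarray(w) > 0]
        x_imp, imp_flags = impute_group_missing(
            x_used, condition_of, impute_threshold, return_flags=True
        ) if x_used.shape[0] else (x_used, pd.Series(dtype=bool))
        quant = weighted_group_abundance(
            x_imp, w_used, condition_of, group_id=grp.group_id
        )
        quant.imputed = imp_flags.reindex(quant.abundance.index).fillna(False)

        models[grp.group_id] = model
        quants[grp.group_id] = quant
        used[grp.group_id] = (x_imp, w_used)
        abundances[grp.group_id] = quant.abundance
        diag_rows.append(
            {
                "group_id": grp.group_id,
                "n_peptides": sub.shape[0],
                "n_used": int((np.asarray(w) > 0).sum()),
                "snr_db": model.snr_db,
                "informative": model.informative,
            }
        )
        for pep, lam, wi in zip(model.peptides, model.loadings, w):
            weight_rows.append(
                {"peptide": pep, "group_id": grp.group_id, "loading": lam, "weight": wi}
            )

    diagnostics = pd.DataFrame(diag_rows).set_index("group_id") if diag_rows \
        else pd.DataFrame(columns=["n_peptides", "n_used", "snr_db", "informative"])
    weights = pd.DataFrame(weight_rows).set_index("peptide") if weight_rows \
        else pd.DataFrame(columns=["group_id", "loading", "weight"])
    abundance = pd.DataFrame(abundances).T if abundances else pd.DataFrame()
    abundance.index.name = "group_id"
    return GroupQuantResult(diagnostics, weights, abundance, models, quants, used)


def baseline_summaries(
    table: PeptideTable,
    groups: list[ProteinGroup],
    method: str = "top3",
) -> pd.DataFrame:
    """Per-sample protein estimates with a traditional summarizer.

    ``method`` is one of ``top3`` / ``median`` (raw-scale output) or
    ``pqpq`` (log2-scale output). Used for benchmarking against the
    weighted factor-model summarization.
    """
    summarizers = {"top3": top3_summary, "median": median_summary, "pqpq": pqpq_summary}
    if method not in summarizers:
        raise ValueError(f"method must be one of {sorted(summarizers)}")
    fn = summarizers[method]
    rows = {}
    for grp in groups:
        present = [p for p in grp.member_peptides if p in table.abundances.index]
        if not present:
            continue
        rows[grp.group_id] = fn(table.abundances.loc[present])
    out = pd.DataFrame(rows).T
    out.index.name = "group_id"
    return out


def _load_groups(table: PeptideTable, cfg: RunConfig) -> list[ProteinGroup]:
    if cfg.db:
        return map_peptides_to_proteins(
            table, cfg.db, method=cfg.mapping_method, use_unique=cfg.use_unique
        )
    return protein_groups_from_table(table)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline and write the report tables under ``cfg.out``.

    Writes ``proteins.tsv`` (diagnostics, per-condition abundances and
    significance), ``peptide_weights.tsv`` and ``config.json``. Partial
    outputs are removed on failure. Returns the result tables in memory.
    """
    out_dir = Path(cfg.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, out_dir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(cfg: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    table = read_peptide_table(cfg.input, scale=cfg.log_input)
    logger.info("read %d peptides x %d samples", table.n_peptides, len(table.sample_ids))

    condition_of = read_sample_groups(cfg.samples) if cfg.samples else None

    if cfg.normalize and table.scale == "raw":
        table = normalize_run_average(table)

    reference = cfg.reference
    if reference and reference not in (None, "mean"):
        reference = [r.strip() for r in str(reference).split(",")]
    matrix = to_log_ratios(table, reference, flip_sign=cfg.flip_sign, groups=condition_of)
    if cfg.gmm_center:
        matrix = normalize_gmm_center(matrix, seed=cfg.seed)
    if cfg.min_samples:
        matrix = filter_min_samples(matrix, cfg.min_samples)

    groups = _load_groups(table, cfg)
    if not cfg.include_singletons:
        groups = [g for g in groups if len(g.member_peptides) > 1]
    logger.info("grouped peptides into %d proteins", len(groups))

    result = quantify_groups(
        matrix, groups, cfg.fa,
        impute_threshold=cfg.impute_threshold,
        condition_of=condition_of,
    )
    report = result.diagnostics.copy()
    if not result.abundance.empty:
        report = report.join(result.abundance.add_prefix("abundance."))
    n_informative = int(report["informative"].sum()) if len(report) else 0
    logger.info("%d of %d proteins informative", n_informative, len(report))

    # significance testing on informative proteins, needs >= 2 conditions
    testable = [
        gid for gid in report.index[report["informative"]]
        if gid in result.used_matrices
    ]
    n_conditions = condition_of.nunique() if condition_of is not None else 0
    if cfg.test != "none" and testable and n_conditions >= 2:
        labels = condition_of
        if cfg.test in ("mc", "both"):
            mc = mc_permutation_fdr(
                {gid: result.used_matrices[gid] for gid in testable},
                labels,
                batch=cfg.mc_batch,
                t_stop=cfg.mc_tstop,
                q_stop=cfg.q_stop,
                max_n=cfg.max_permutations,
                seed=cfg.seed,
            )
            report = report.join(
                mc.to_frame().rename(columns={"q": "q_mc", "N": "n_perm"})
            )
            report.attrs["pi0_mc"] = mc.pi0_hat
        if cfg.test in ("peca", "both"):
            peca_p = {}
            for gid in testable:
                x_used, w_used = result.used_matrices[gid]
                res = peca_protein_p(x_used, w_used, labels)
                peca_p[gid] = res.protein_p
            pvec = pd.Series(peca_p, name="p_peca")
            finite = pvec.dropna()
            qv = pd.Series(
                qvalues(finite.to_numpy(), 1.0), index=finite.index, name="q_peca"
            )
            report = report.join(pvec).join(qv)
    elif cfg.test != "none":
        logger.info("significance testing skipped (needs informative proteins "
                    "and >= 2 sample conditions)")

    report.index.name = "group_id"
    proteins_path = out_dir / "proteins.tsv"
    written.append(proteins_path)
    report.to_csv(proteins_path, sep="\t", float_format="%.8g")
    weights_path = out_dir / "peptide_weights.tsv"
    written.append(weights_path)
    result.weights.to_csv(weights_path, sep="\t", float_format="%.8g")
    config_path = out_dir / "config.json"
    written.append(config_path)
    config_path.write_text(json.dumps(asdict(cfg), indent=2, default=str) + "\n")

    return {
        "proteins": report,
        "weights": result.weights,
        "quant": result,
        "paths": {"proteins": proteins_path, "weights": weights_path,
                  "config": config_path},
    }
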