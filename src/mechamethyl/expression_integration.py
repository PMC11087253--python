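"""Positional integration of DM CpGs with differential expression (tCpG calling).

DM CpGs are mapped to genes through promoter/UTR/exon annotation categories
(TSS200, TSS1500, 5'UTR, 1stExon, ExonBnd, 3'UTR; gene-body links are
excluded).  Mapped genes are tested for differential expression with a
moderated t on log2 counts-per-million, and FDR correction for expression is
applied within the restricted family of genes that carry at least one mapped
DM CpG.  Pairs whose gene passes that restricted FDR are the
"transcriptionally active CpGs" (ML-tCpGs when loading-induced).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .synthetic_data import CountMatrix
from .differential_methylation import (
    adjust_bh,
    empirical_bayes_moderation,
    fit_linear_model,
)

logger = logging.getLogger(__name__)

QUALIFYING_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "ExonBnd", "3'UTR")


@dataclass
class TCpGPair:
    probe_id: str
    gene: str
    categories: str
    meth_effect: float
    meth_q: float
    expr_log2fc: float
    expr_p: float
    expr_q_restricted: float


def map_cpgs_to_genes(
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    categories: tuple[str, ...] = QUALIFYING_CATEGORIES,
) -> pd.DataFrame:
    """Explode DM CpG gene annotations into (probe, gene) pairs.

    Multi-gene / multi-category annotations become separate pairs; duplicate
    (probe, gene) pairs collapse with their categories ';'-joined.
    """
    dm = meta.index[meta["dm_flag"].to_numpy(dtype=bool)]
    records: dict[tuple[str, str], set[str]] = {}
    for probe in dm:
        row = annotation.loc[probe]
        if not row["genes"]:
            continue
        genes = row["genes"].split(";")
        cats = row["categories"].split(";")
        for g, c in zip(genes, cats):
            if c in categories:
                records.setdefault((probe, g), set()).add(c)
    rows = [
        {
            "probe_id": probe,
            "gene": gene,
            "categories": ";".join(sorted(cats)),
            "meth_effect": float(meta.loc[probe, "b_meta"]),
            "meth_q": float(meta.loc[probe, "q"]),
        }
        for (probe, gene), cats in sorted(records.items())
    ]
    return pd.DataFrame(
        rows, columns=["probe_id", "gene", "categories", "meth_effect", "meth_q"]
    )


def differential_expression(
    counts: CountMatrix, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Moderated-t differential expression on log2 counts-per-million.

    Library sizes are the per-sample count totals; genes with all-zero counts
    are dropped (and logged).  When ``covariates`` is None and the sample
    sheet has a ``model`` column, the model is included as a covariate so the
    two organoid models are analysed jointly (``~ loading + model``).
    """
    mat = counts.counts
    nonzero = mat.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("differential_expression: dropped %d all-zero genes", int((~nonzero).sum()))
    mat = mat.loc[nonzero]
    if mat.empty:
        raise EmptyInputError("no genes with non-zero counts")
    lib = mat.sum(axis=0).to_numpy(dtype=float)
    cpm = mat.to_numpy(dtype=float) / lib[None, :] * 1e6
    logcpm = pd.DataFrame(
        np.log2(cpm + 0.5), index=mat.index, columns=mat.columns
    )
    condition = counts.samples.loc[mat.columns, "condition"]
    if covariates is None and "model" in counts.samples.columns:
        if counts.samples.loc[mat.columns, "model"].nunique() > 1:
            covariates = counts.samples.loc[mat.columns, ["model"]]
    fits = fit_linear_model(logcpm, condition, covariates)
    mod = empirical_bayes_moderation(fits)
    out = mod.rename(columns={"b_g": "log2fc"})[["log2fc", "t_mod", "p"]]
    out.index.name = "gene"
    return out


def prioritize_tcpgs(
    pairs: pd.DataFrame, de_results: pd.DataFrame, expr_fdr: float = 0.05
) -> pd.DataFrame:
    """Restricted-family FDR: BH over the unique genes that carry >= 1 mapped
    DM CpG, then keep pairs whose gene's restricted q < ``expr_fdr``."""
    if pairs.empty:
        return pd.DataFrame(
            columns=list(pairs.columns) + ["expr_log2fc", "expr_p", "expr_q_restricted"]
        )
    genes = pd.Index(sorted(pairs["gene"].unique()))
    known = genes.intersection(de_results.index)
    dropped = len(genes) - len(known)
    if dropped:
        logger.info("prioritize_tcpgs: %d mapped genes absent from DE results", dropped)
    if len(known) == 0:
        return pd.DataFrame(
            columns=list(pairs.columns) + ["expr_log2fc", "expr_p", "expr_q_restricted"]
        )
    restricted = de_results.loc[known, ["log2fc", "p"]].copy()
    restricted["q_restricted"] = adjust_bh(restricted["p"].to_numpy())
    out = pairs.merge(
        restricted.rename(
            columns={"log2fc": "expr_log2fc", "p": "expr_p", "q_restricted": "expr_q_restricted"}
        ),
        left_on="gene",
        right_index=True,
        how="inner",
    )
    out = out[out["expr_q_restricted"] < expr_fdr].reset_index(drop=True)
    return out


def region_category_summary(tcpgs: pd.DataFrame) -> dict[str, float]:
    """Fraction of category occurrences per region category among tCpG pairs."""
    if tcpgs.empty:
        return {}
    counts: dict[str, int] = {}
    total = 0
    for cats in tcpgs["categories"]:
        for c in cats.split(";"):
            counts[c] = counts.get(c, 0) + 1
            total += 1
    return {c: counts[c] / total for c in sorted(counts)}


def overlap_tcpg_sets(
    ml: pd.DataFrame, external: "pd.DataFrame | list[str]"
) -> dict:
    """Overlap of ML-tCpG pairs with an external tCpG catalog.

    ``external`` is either a list of gene symbols or a DataFrame with a
    ``gene`` column and optionally a ``probe_id`` column (then exact
    probe-gene pairs are intersected as well).  Gene symbols are compared
    case-insensitively.
    """
    if isinstance(external, list):
        ext_genes = {g.strip().upper() for g in external if g.strip()}
        ext_pairs = None
    else:
        ext_genes = {str(g).strip().upper() for g in external["gene"]}
        ext_pairs = (
            {(str(p), str(g).strip().upper()) for p, g in zip(external["probe_id"], external["gene"])}
            if "probe_id" in external.columns
            else None
        )
    if not ext_genes:
        logger.warning("overlap_tcpg_sets: external list is empty")
    ml_genes = {str(g).upper() for g in ml["gene"]} if not ml.empty else set()
    shared_genes = sorted(ml_genes & ext_genes)
    n_pairs = 0
    if ext_pairs is not None and not ml.empty:
        ml_pairs = {(str(p), str(g).upper()) for p, g in zip(ml["probe_id"], ml["gene"])}
        n_pairs = len(ml_pairs & ext_pairs)
    return {
        "n_overlap_genes": len(shared_genes),
        "n_overlap_pairs": n_pairs,
        "overlapping_genes": shared_genes,
    }
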