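"""Gene-level expression aggregation and a documented effect-size stand-in.

The effect size beta is the natural-log fold change of pseudocounted mean
TPM (mutant vs control); significance comes from a Welch t-test on
ln(TPM + c) per replicate with BH adjustment. This deliberately simple model
preserves the downstream contract — every consumer reads only
(beta, p_adjusted, class) — without a bootstrap variance model. Biotype
summaries compare each biotype's betas against all other genes.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, welch_rows
from .annotation_io import GenomeAnnotation

__all__ = [
    "aggregate_gene_tpm",
    "estimate_beta_and_test",
    "beta_vs_delta_psi",
    "biotype_summary",
]

DEFAULT_PSEUDOCOUNT = 0.5
BETA_PLOT_CLIP_X = 0.275  # delta-psi axis clip, plotting only
BETA_PLOT_CLIP_Y = 1.0    # beta axis clip, plotting only


def aggregate_gene_tpm(abundance: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Sum member-transcript TPM per gene: genes x samples matrix.

    Transcripts absent from the annotation are excluded (their ids are kept
    on the result under ``.attrs['unassigned_transcripts']``).
    """
    tx2gene = {tid: t.gene_id for tid, t in annotation.transcripts.items()}
    df = abundance.copy()
    df["gene_id"] = df["transcript_id"].map(tx2gene)
    unassigned = sorted(df.loc[df["gene_id"].isna(), "transcript_id"].unique())
    df = df.dropna(subset=["gene_id"])
    mat = df.pivot_table(index="gene_id", columns="sample", values="tpm", aggfunc="sum").fillna(0.0)
    mat.attrs["unassigned_transcripts"] = unassigned
    return mat


def _keep_expressed(mat: pd.DataFrame, ctrl: list[str], mut: list[str], min_expr: float) -> pd.Series:
    ok_ctrl = (mat[ctrl] >= min_expr).all(axis=1)
    ok_mut = (mat[mut] >= min_expr).all(axis=1)
    return ok_ctrl | ok_mut


def estimate_beta_and_test(
    gene_matrix: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_expr: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene ln fold-change and Welch test on log TPM.

    beta = ln((mean mutant TPM + c) / (mean control TPM + c)). Genes below
    ``min_expr`` in at least one sample of both conditions, and all-zero
    genes, are excluded. Classes: up (beta > 0, BH p <= alpha), down
    (beta < 0, BH p <= alpha), else unchanged.
    """
    ctrl = design.loc[design["condition"] == "control", "sample_id"].tolist()
    mut = design.loc[design["condition"] == "mutant", "sample_id"].tolist()
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("differential expression requires >= 2 replicates per condition")
    mat = gene_matrix[(gene_matrix[ctrl + mut].sum(axis=1) > 0)]
    mat = mat[_keep_expressed(mat, ctrl, mut, min_expr)]
    x = np.log(mat[mut].to_numpy() + pseudocount)
    y = np.log(mat[ctrl].to_numpy() + pseudocount)
    p = welch_rows(x, y) if len(mat) else np.array([])
    mean_mut = mat[mut].to_numpy().mean(axis=1)
    mean_ctrl = mat[ctrl].to_numpy().mean(axis=1)
    beta = np.log(mean_mut + pseudocount) - np.log(mean_ctrl + pseudocount)
    out = pd.DataFrame({
        "gene_id": mat.index,
        "mean_tpm_control": mean_ctrl,
        "mean_tpm_mutant": mean_mut,
        "beta": beta,
        "p": p,
        "p_adjusted": bh_adjust(p),
    })
    sig = out["p_adjusted"] <= alpha
    out["de_class"] = np.where(sig & (out["beta"] > 0), "up",
                               np.where(sig & (out["beta"] < 0), "down", "unchanged"))
    return out.reset_index(drop=True)


def beta_vs_delta_psi(
    expression: pd.DataFrame, gene_results: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of beta with delta psi over significant-APA genes.

    Returns (rho, p, table); the table carries clipped plotting columns
    (delta psi at +/-0.275, beta at +/-1) while the correlation itself is
    computed on the unclipped values. (nan, nan) with < 3 genes.
    """
    sig = gene_results[(gene_results["p_adjusted"] <= alpha) & (gene_results["delta_psi"] != 0)]
    merged = sig.merge(expression, on="gene_id", how="inner", suffixes=("_apa", "_de"))
    table = merged[["gene_id", "delta_psi", "beta"]].copy()
    table["delta_psi_plot"] = np.clip(table["delta_psi"], -BETA_PLOT_CLIP_X, BETA_PLOT_CLIP_X)
    table["beta_plot"] = np.clip(table["beta"], -BETA_PLOT_CLIP_Y, BETA_PLOT_CLIP_Y)
    if len(table) < 3:
        return float("nan"), float("nan"), table
    rho, p = stats.spearmanr(table["delta_psi"], table["beta"])
    return float(rho), float(p), table


def biotype_summary(
    expression: pd.DataFrame, annotation: GenomeAnnotation, alpha: float = 0.05, min_genes: int = 3
) -> pd.DataFrame:
    """Per-biotype DE-class counts, median beta, and a shift test.

    Each biotype's betas are compared against those of all other tested
    genes with a two-sided Mann-Whitney test, BH-adjusted across biotypes;
    biotypes with fewer than ``min_genes`` tested genes are skipped.
    """
    bio = {gid: g.biotype for gid, g in annotation.genes.items()}
    df = expression.copy()
    df["biotype"] = df["gene_id"].map(bio).fillna("other")
    rows = []
    for biotype, sub in df.groupby("biotype"):
        if len(sub) < min_genes:
            continue
        rest = df[df["biotype"] != biotype]
        if len(rest) >= min_genes:
            _, p = stats.mannwhitneyu(sub["beta"], rest["beta"], alternative="two-sided")
        else:
            p = np.nan
        counts = sub["de_class"].value_counts()
        rows.append({
            "biotype": biotype,
            "n_genes": len(sub),
            "n_up": int(counts.get("up", 0)),
            "n_down": int(counts.get("down", 0)),
            "n_unchanged": int(counts.get("unchanged", 0)),
            "median_beta": float(sub["beta"].median()),
            "p": p,
        })
    out = pd.DataFrame(rows, columns=[
        "biotype", "n_genes", "n_up", "n_down", "n_unchanged", "median_beta", "p"])
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"])
        out["shifted"] = (out["p_adjusted"] <= alpha)
    return out
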