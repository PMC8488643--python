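"""Genomic context of PASs and genes.

Feature overlap of differentially used PASs (3'UTR / CDS / intron /
noncoding transcript, summarized as UpSet-style combination counts), an
independent per-site Fisher test for intronic PAS usage, gene
density/length descriptors with neighbor-orientation labels, and the
enrichment machinery (Fisher exact via hypergeometric summation) used to
ask, e.g., whether distal-shifted genes are enriched among DE genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, fisher_exact_two_sided
from .annotation_io import GenomeAnnotation
from .apa_quant import DEFAULT_DOWNSTREAM_EXTENSION, assign_pacs_to_genes
from .pac_calling import PAC

__all__ = [
    "FeatureOverlap",
    "EnrichmentResult",
    "overlap_features",
    "upset_counts",
    "intronic_pas_test",
    "neighbor_density",
    "neighbor_orientation",
    "context_vs_outcome",
    "fisher_enrichment",
]

DEFAULT_OVERLAP_WINDOW = 10
DEFAULT_NEIGHBOR_K = 10

FEATURE_KINDS = ("three_prime_utr", "cds", "intron", "noncoding_transcript")


@dataclass(frozen=True)
class FeatureOverlap:
    pas_id: str
    features: frozenset
    flagged_outside: bool = False

    @property
    def cds_or_intron_only(self) -> bool:
        """True when the PAS touches CDS and/or intron but neither a 3'UTR
        nor a noncoding transcript — the class expected to change protein
        output."""
        f = self.features
        return bool(f & {"cds", "intron"}) and not (f & {"three_prime_utr", "noncoding_transcript"})


def _overlaps(lo: int, hi: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s < hi and lo < e for s, e in intervals)


def overlap_features(
    pas_id: str,
    position: int,
    gene_id: str,
    annotation: GenomeAnnotation,
    window: int = DEFAULT_OVERLAP_WINDOW,
    downstream_extension: int = DEFAULT_DOWNSTREAM_EXTENSION,
) -> FeatureOverlap:
    """Feature kinds overlapped by the +/-``window`` nt around a PAS.

    Only the PAS's own gene is interrogated (strand-matched by
    construction). The union over the gene's transcripts is reported;
    ``noncoding_transcript`` is set when an exon of a noncoding-biotype
    transcript is overlapped. A PAS outside the gene span (plus the
    downstream extension) yields an empty set with ``flagged_outside``.
    """
    gene = annotation.genes[gene_id]
    lo, hi = position - window, position + window + 1
    span_lo, span_hi = gene.span_start, gene.span_end
    if gene.strand == "+":
        span_hi += downstream_extension
    else:
        span_lo -= downstream_extension
    if not (span_lo <= position < span_hi):
        return FeatureOverlap(pas_id=pas_id, features=frozenset(), flagged_outside=True)
    feats = annotation.feature_intervals(gene_id)
    hit = set()
    if _overlaps(lo, hi, feats["three_prime_utr"]):
        hit.add("three_prime_utr")
    if _overlaps(lo, hi, feats["cds"]):
        hit.add("cds")
    if _overlaps(lo, hi, feats["intron"]):
        hit.add("intron")
    if _overlaps(lo, hi, feats["noncoding_exon"]):
        hit.add("noncoding_transcript")
    return FeatureOverlap(pas_id=pas_id, features=frozenset(hit))


def upset_counts(overlaps: Iterable[FeatureOverlap]) -> pd.DataFrame:
    """Counts per exact feature-set combination (UpSet-plot tallies).

    The combination key lists features in the fixed kind order joined by
    '+'; an empty set is keyed 'none'. Also returns the cds_or_intron_only
    flag per combination; combination counts sum to the number of inputs.
    """
    counter: dict[frozenset, int] = {}
    for ov in overlaps:
        counter[ov.features] = counter.get(ov.features, 0) + 1
    rows = []
    for combo, count in counter.items():
        key = "+".join(k for k in FEATURE_KINDS if k in combo) or "none"
        only = bool(combo & {"cds", "intron"}) and not (combo & {"three_prime_utr", "noncoding_transcript"})
        rows.append({"combination": key, "count": count, "cds_or_intron_only": only})
    out = pd.DataFrame(rows, columns=["combination", "count", "cds_or_intron_only"])
    return out.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)


def intronic_pas_test(
    pacs: Iterable[PAC],
    annotation: GenomeAnnotation,
    design: pd.DataFrame,
    downstream_extension: int = DEFAULT_DOWNSTREAM_EXTENSION,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Independent per-site assessment of intronic PAS usage.

    Intronic sites are PACs lying fully inside an intron of *every*
    transcript of their assigned gene. For each site, a 2x2 table of
    (site reads vs the gene's other PAC reads) x (control vs mutant), with
    replicate counts pooled per condition, is tested with the two-sided
    Fisher exact test and BH-adjusted across sites. Sites of genes with zero
    non-site reads in both conditions are skipped.
    """
    pacs = list(pacs)
    assignment, _ = assign_pacs_to_genes(annotation, pacs, downstream_extension)
    ctrl = design.loc[design["condition"] == "control", "sample_id"].tolist()
    mut = design.loc[design["condition"] == "mutant", "sample_id"].tolist()

    def pooled(pac: PAC, samples: list[str]) -> int:
        return int(sum(pac.counts.get(s, 0) for s in samples))

    by_gene: dict[str, list[PAC]] = {}
    for pac in pacs:
        gid = assignment.get(pac.pac_id)
        if gid is not None:
            by_gene.setdefault(gid, []).append(pac)

    rows = []
    for gid, gene_pacs in sorted(by_gene.items()):
        gene = annotation.genes[gid]
        for pac in gene_pacs:
            in_all = all(
                any(s <= pac.start and pac.end <= e for s, e in t.introns)
                for t in gene.transcripts
            ) and bool(gene.transcripts)
            if not in_all:
                continue
            site_c, site_m = pooled(pac, ctrl), pooled(pac, mut)
            other_c = sum(pooled(p, ctrl) for p in gene_pacs if p is not pac)
            other_m = sum(pooled(p, mut) for p in gene_pacs if p is not pac)
            if other_c == 0 and other_m == 0:
                continue
            if site_c == 0 and site_m == 0:
                odds, p = 1.0, 1.0
            else:
                odds, p = fisher_exact_two_sided(site_c, site_m, other_c, other_m)
            rows.append({
                "pac_id": pac.pac_id, "gene_id": gid, "summit": pac.summit,
                "site_control": site_c, "site_mutant": site_m,
                "other_control": other_c, "other_mutant": other_m,
                "odds_ratio": odds, "p": p,
            })
    out = pd.DataFrame(rows, columns=[
        "pac_id", "gene_id", "summit", "site_control", "site_mutant",
        "other_control", "other_mutant", "odds_ratio", "p"])
    out["p_adjusted"] = bh_adjust(out["p"]) if len(out) else []
    out["differential"] = (out["p_adjusted"] <= alpha) if len(out) else []
    return out


def _edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two spans; 0 when they overlap or touch."""
    return max(0, b_start - a_end, a_start - b_end)


def neighbor_density(
    annotation: GenomeAnnotation,
    eligible_ids: Iterable[str],
    k: int = DEFAULT_NEIGHBOR_K,
    gene_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Mean edge-to-edge distance to the k nearest eligible neighbors.

    ``eligible_ids`` is the expressed-and-polyadenylated gene set that
    serves as the neighbor pool (the gene itself never counts as its own
    neighbor); distances are strand-agnostic and within-chromosome only.
    Genes with fewer than k eligible neighbors use all available and are
    flagged; a gene alone with no eligible neighbor on its chromosome gets
    NaN and is flagged.
    """
    eligible = set(eligible_ids)
    targets = list(gene_ids) if gene_ids is not None else list(annotation.genes)
    pool: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, genes in annotation.genes_by_chrom.items():
        el = [g for g in genes if g.id in eligible]
        pool[chrom] = (
            np.array([g.span_start for g in el], dtype=np.int64),
            np.array([g.span_end for g in el], dtype=np.int64),
            [g.id for g in el],
        )
    rows = []
    for gid in targets:
        g = annotation.genes[gid]
        starts, ends, ids = pool.get(g.chrom, (np.array([]), np.array([]), []))
        mask = np.array([i != gid for i in ids], dtype=bool)
        if mask.sum() == 0:
            rows.append({"gene_id": gid, "length": g.length, "mean_neighbor_distance": np.nan,
                         "n_neighbors": 0, "flagged": True})
            continue
        d = np.maximum(0, np.maximum(starts[mask] - g.span_end, g.span_start - ends[mask]))
        d = np.sort(d)[: k]
        rows.append({
            "gene_id": gid, "length": g.length,
            "mean_neighbor_distance": float(d.mean()),
            "n_neighbors": int(len(d)), "flagged": len(d) < k,
        })
    return pd.DataFrame(rows)


def neighbor_orientation(
    annotation: GenomeAnnotation, gene_id: str, eligible_ids: Iterable[str]
) -> pd.DataFrame:
    """Label the nearest eligible neighbor on each genomic side of a gene.

    ``side`` is upstream/downstream in the gene's own transcription
    direction; ``orientation`` is transcribed_toward / transcribed_away
    depending on whether the neighbor's transcription points at the gene.
    """
    g = annotation.genes[gene_id]
    eligible = set(eligible_ids) - {gene_id}
    same_chrom = [x for x in annotation.genes_by_chrom.get(g.chrom, []) if x.id in eligible]
    left = [x for x in same_chrom if x.span_start <= g.span_start]
    right = [x for x in same_chrom if x.span_start > g.span_start]
    rows = []
    for genomic_side, candidates in (("left", left), ("right", right)):
        if not candidates:
            continue
        nb = min(candidates, key=lambda x: (_edge_distance(g.span_start, g.span_end, x.span_start, x.span_end), x.id))
        if g.strand == "+":
            side = "downstream" if genomic_side == "right" else "upstream"
        else:
            side = "downstream" if genomic_side == "left" else "upstream"
        # neighbor transcribes toward the gene when it points at the gene's locus
        if genomic_side == "right":
            toward = nb.strand == "-"
        else:
            toward = nb.strand == "+"
        rows.append({
            "gene_id": gene_id, "neighbor_id": nb.id, "side": side,
            "orientation": "transcribed_toward" if toward else "transcribed_away",
            "distance": _edge_distance(g.span_start, g.span_end, nb.span_start, nb.span_end),
        })
    return pd.DataFrame(rows, columns=["gene_id", "neighbor_id", "side", "orientation", "distance"])


def context_vs_outcome(
    contexts: pd.DataFrame,
    outcomes: pd.DataFrame,
    value_col: str = "beta",
    class_col: str | None = None,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate gene context (length, density) to an outcome.

    Returns (correlations, comparisons). Correlations: Spearman rho of
    log10 length and log10 neighbor distance against ``value_col``, overall
    and within each optional named gene group. Comparisons: two-sided
    Mann-Whitney of each context variable between every pair of classes in
    ``class_col`` (when given); pairs with < 3 members on either side are
    skipped.
    """
    df = contexts.merge(outcomes, on="gene_id", how="inner")
    df = df[np.isfinite(df["mean_neighbor_distance"])]
    variables = {
        "log10_length": np.log10(df["length"].astype(float)),
        "log10_neighbor_distance": np.log10(df["mean_neighbor_distance"].astype(float) + 1.0),
    }
    for name, vals in variables.items():
        df = df.assign(**{name: vals})

    corr_rows = []
    group_sets = {"all": set(df["gene_id"])}
    if groups:
        group_sets.update({name: set(ids) for name, ids in groups.items()})
    for gname, ids in group_sets.items():
        sub = df[df["gene_id"].isin(ids)]
        for var in variables:
            if len(sub) < 3:
                corr_rows.append({"variable": var, "subset": gname, "rho": np.nan, "p": np.nan, "n": len(sub)})
                continue
            rho, p = stats.spearmanr(sub[var], sub[value_col])
            corr_rows.append({"variable": var, "subset": gname, "rho": float(rho), "p": float(p), "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    comp_rows = []
    if class_col is not None and class_col in df.columns:
        classes = sorted(df[class_col].dropna().unique())
        for i, ca in enumerate(classes):
            for cb in classes[i + 1:]:
                a = df[df[class_col] == ca]
                b = df[df[class_col] == cb]
                for var in variables:
                    if len(a) < 3 or len(b) < 3:
                        continue
                    u, p = stats.mannwhitneyu(a[var], b[var], alternative="two-sided")
                    comp_rows.append({
                        "variable": var, "class_a": ca, "class_b": cb,
                        "median_a": float(a[var].median()), "median_b": float(b[var].median()),
                        "u": float(u), "p": float(p), "n_a": len(a), "n_b": len(b),
                    })
    comparisons = pd.DataFrame(comp_rows, columns=[
        "variable", "class_a", "class_b", "median_a", "median_b", "u", "p", "n_a", "n_b"])
    return correlations, comparisons


@dataclass
class EnrichmentResult:
    """2x2 enrichment: table [[a, b], [c, d]], odds ratio, two-sided Fisher p."""

    table: np.ndarray
    odds_ratio: float
    p: float
    p_adjusted: float | None = None


def fisher_enrichment(set_a: Iterable, set_b: Iterable, universe: Iterable) -> EnrichmentResult:
    """Enrichment of set_a within set_b over a finite universe.

    Table cells: a = |A and B|, b = |A \\ B|, c = |B \\ A|, d = rest of the
    universe. Two-sided Fisher exact p by hypergeometric tail summation;
    odds ratio with Haldane correction when a cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A = set(set_a) & universe
    B = set(set_b) & universe
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    odds, p = fisher_exact_two_sided(a, b, c, d)
    return EnrichmentResult(table=np.array([[a, b], [c, d]]), odds_ratio=odds, p=p)
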