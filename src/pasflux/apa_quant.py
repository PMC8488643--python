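"""Per-gene APA isoform sets, PAS position scores, psi, and differential usage.

Evidence for poly(A) sites (reference transcript ends, optional assembled
ends, PAC summits) is merged into a per-gene ordered PAS list. Each PAS gets
a rank m in transcription direction and a PAS position score
PPS = m / (n - 1), so the most proximal site scores 0 and the most distal 1.
A gene's psi in a sample is the abundance-weighted mean PPS: 0 means fully
proximal usage, 1 fully distal. Differential usage is tested per gene (psi)
and per PAS (usage fraction) with Welch t-tests across replicates and
Benjamini-Hochberg adjustment; delta values reported for plotting are
additionally clipped at +/-0.2, never the statistics themselves.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, welch_rows
from .annotation_io import GenomeAnnotation
from .pac_calling import PAC

__all__ = [
    "PASite",
    "APAIsoformSet",
    "UsageMatrix",
    "assign_pacs_to_genes",
    "merge_pas_evidence",
    "build_isoform_sets",
    "quantify_usage",
    "test_differential_psi",
    "test_differential_usage_fractions",
    "classify_position",
    "usage_shift_vs_position",
]

DEFAULT_MERGE_WINDOW = 25
DEFAULT_DOWNSTREAM_EXTENSION = 5000
DEFAULT_MIN_EXPR = 1.0
DELTA_CLIP = 0.2  # reporting-only clip for delta-psi / delta-usage columns


@dataclass(frozen=True)
class PASite:
    """One merged poly(A) site of a gene."""

    gene_id: str
    position: int
    sources: frozenset
    pac_id: str | None = None

    @property
    def pas_id(self) -> str:
        return f"{self.gene_id}@{self.position}"


@dataclass
class APAIsoformSet:
    """A gene's >= 2 PASs ordered in transcription direction, with PPS."""

    gene_id: str
    chrom: str
    strand: str
    sites: list[PASite]

    @property
    def n(self) -> int:
        return len(self.sites)

    @property
    def pps(self) -> np.ndarray:
        return np.arange(self.n) / (self.n - 1)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"{self.gene_id}: an APA isoform set needs >= 2 PASs")
        positions = [s.position for s in self.sites]
        ordered = positions == sorted(positions) if self.strand == "+" else positions == sorted(positions, reverse=True)
        if not ordered:
            raise ValueError(f"{self.gene_id}: PASs not ordered in transcription direction")


def classify_position(m: int, n: int) -> str:
    """Most-proximal / middle / most-distal class of rank m among n PASs."""
    if n < 2:
        raise ValueError("position class needs n >= 2")
    if m == 0:
        return "most_proximal"
    if m == n - 1:
        return "most_distal"
    return "middle"


def _span_three_end(gene) -> int:
    return gene.span_end - 1 if gene.strand == "+" else gene.span_start


def assign_pacs_to_genes(
    annotation: GenomeAnnotation,
    pacs: Iterable[PAC],
    downstream_extension: int = DEFAULT_DOWNSTREAM_EXTENSION,
) -> tuple[dict[str, str], list[str]]:
    """Assign each PAC (by summit) to a gene on the same chromosome/strand.

    A PAC is assignable to a gene when its summit lies within the gene span
    extended ``downstream_extension`` nt past the 3' span end in
    transcription direction. Ambiguous summits (overlapping same-strand
    loci) go to the gene whose 3' span end is nearest; each such case is
    logged. Returns (pac_id -> gene_id, log messages).
    """
    assignment: dict[str, str] = {}
    log: list[str] = []
    for pac in pacs:
        candidates = []
        for gene in annotation.genes_by_chrom.get(pac.chrom, []):
            if gene.strand != pac.strand:
                continue
            lo, hi = gene.span_start, gene.span_end
            if gene.strand == "+":
                hi += downstream_extension
            else:
                lo -= downstream_extension
            if lo <= pac.summit < hi:
                candidates.append(gene)
        if not candidates:
            continue
        if len(candidates) > 1:
            candidates.sort(key=lambda g: (abs(pac.summit - _span_three_end(g)), g.id))
            log.append(
                f"PAC {pac.pac_id} summit {pac.chrom}:{pac.summit} assignable to "
                f"{[g.id for g in candidates]}; assigned to {candidates[0].id} (nearest span end)"
            )
        assignment[pac.pac_id] = candidates[0].id
    return assignment, log


def merge_pas_evidence(
    annotation: GenomeAnnotation,
    pacs: Iterable[PAC] = (),
    assembled_ends: pd.DataFrame | None = None,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    downstream_extension: int = DEFAULT_DOWNSTREAM_EXTENSION,
) -> tuple[dict[str, list[PASite]], list[str]]:
    """Merge PAS evidence per gene into deduplicated candidate sites.

    Candidates are annotated transcript 3' ends (source ``reference``),
    optional assembled 3' ends (source ``assembled``, same BED-of-ends frame
    convention as read input), and PAC summits (source ``pac``) assigned to
    genes by :func:`assign_pacs_to_genes`. Candidates within ``merge_window``
    nt of each other on the same gene collapse to one PAS whose
    representative position is the PAC summit when any member is a PAC
    (highest-count PAC wins, ties toward the distal one), else the most
    distal transcript end; the source set is the union.
    """
    pacs = list(pacs)
    log: list[str] = []
    assignment, assign_log = assign_pacs_to_genes(annotation, pacs, downstream_extension)
    log.extend(assign_log)
    pac_by_id = {p.pac_id: p for p in pacs}

    # raw per-gene candidates: (position, source, pac_id, pac_total)
    raw: dict[str, list[tuple[int, str, str | None, int]]] = {g: [] for g in annotation.genes}
    for gene in annotation.genes.values():
        for t in gene.transcripts:
            raw[gene.id].append((t.three_prime_end, "reference", None, 0))
    if assembled_ends is not None and len(assembled_ends):
        fake = [
            PAC(pac_id=f"ASM{i}", chrom=r.chrom, strand=r.strand,
                start=int(r.end), end=int(r.end) + 1, summit=int(r.end))
            for i, r in enumerate(assembled_ends.itertuples(index=False))
        ]
        asm_assign, asm_log = assign_pacs_to_genes(annotation, fake, downstream_extension)
        log.extend(asm_log)
        for f in fake:
            gid = asm_assign.get(f.pac_id)
            if gid is not None:
                raw[gid].append((f.summit, "assembled", None, 0))
    for pac in pacs:
        gid = assignment.get(pac.pac_id)
        if gid is not None:
            raw[gid].append((pac.summit, "pac", pac.pac_id, pac.total))

    merged: dict[str, list[PASite]] = {}
    for gid, cands in raw.items():
        if not cands:
            merged[gid] = []
            continue
        strand = annotation.genes[gid].strand
        cands.sort(key=lambda c: c[0])
        clusters: list[list[tuple[int, str, str | None, int]]] = [[cands[0]]]
        for c in cands[1:]:
            if c[0] - clusters[-1][-1][0] <= merge_window:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        sites = []
        for cl in clusters:
            sources = frozenset(src for _, src, _, _ in cl)
            pac_members = [c for c in cl if c[1] == "pac"]
            if pac_members:
                # highest-supported PAC summit represents the merged site
                distal_sign = 1 if strand == "+" else -1
                best = max(pac_members, key=lambda c: (c[3], distal_sign * c[0]))
                pos, pac_id = best[0], best[2]
            else:
                ends = [c[0] for c in cl if c[1] in ("reference", "assembled")]
                pos = max(ends) if strand == "+" else min(ends)
                pac_id = None
            sites.append(PASite(gene_id=gid, position=pos, sources=sources, pac_id=pac_id))
        sites.sort(key=lambda s: s.position, reverse=(strand == "-"))
        merged[gid] = sites
    return merged, log


def build_isoform_sets(
    candidates: Mapping[str, list[PASite]], annotation: GenomeAnnotation
) -> tuple[list[APAIsoformSet], list[str]]:
    """Keep genes with >= 2 merged PASs; return (sets, skipped gene ids)."""
    sets, skipped = [], []
    for gid, sites in candidates.items():
        gene = annotation.genes[gid]
        if len(sites) < 2:
            skipped.append(gid)
            continue
        sets.append(APAIsoformSet(gene_id=gid, chrom=gene.chrom, strand=gene.strand, sites=sites))
    sets.sort(key=lambda s: s.gene_id)
    return sets, sorted(skipped)


@dataclass
class UsageMatrix:
    """Quantified PAS usage: per-PAS abundances, usage fractions, per-gene psi."""

    pas_table: pd.DataFrame    # gene_id, pas_id, position, m, n, pps, sources, pac_id
    usage: pd.DataFrame        # gene_id, pas_id, sample, tpm, usage_fraction, pps, m, n
    psi: pd.DataFrame          # gene_id, sample, psi
    dropped_genes: list[str] = field(default_factory=list)
    excluded_transcripts: list[str] = field(default_factory=list)


def _condition_samples(design: pd.DataFrame) -> tuple[list[str], list[str]]:
    ctrl = design.loc[design["condition"] == "control", "sample_id"].tolist()
    mut = design.loc[design["condition"] == "mutant", "sample_id"].tolist()
    return ctrl, mut


def quantify_usage(
    isoform_sets: Iterable[APAIsoformSet],
    design: pd.DataFrame,
    abundance: pd.DataFrame | None = None,
    pac_counts: pd.DataFrame | None = None,
    mode: str = "transcript_tpm",
    annotation: GenomeAnnotation | None = None,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    min_expr: float = DEFAULT_MIN_EXPR,
) -> UsageMatrix:
    """Quantify per-PAS abundance, usage fractions, and per-gene psi.

    ``transcript_tpm`` mode sums member-transcript TPM per PAS after mapping
    each transcript to the PAS nearest its annotated 3' end (transcripts
    farther than ``merge_window`` from every PAS are excluded and logged).
    ``pac_counts`` mode uses per-sample PAC read counts instead.

    Only PASs measurable in the chosen mode are quantified: a PAS with no
    mapped transcript (transcript mode) or no PAC (PAC mode) has no
    observation, so it is removed and ranks/PPS are recomputed over the
    quantifiable sites; genes left with fewer than 2 quantifiable PASs are
    dropped. Genes whose total abundance falls below ``min_expr`` in at
    least one sample of *both* conditions are dropped (i.e., a gene is kept
    when at least one condition has all its samples at or above the
    threshold).
    """
    if mode not in ("transcript_tpm", "pac_counts"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = design["sample_id"].tolist()
    ctrl, mut = _condition_samples(design)
    isoform_sets = list(isoform_sets)

    tpm_lookup = None
    if mode == "transcript_tpm":
        if abundance is None or annotation is None:
            raise ValueError("transcript_tpm mode requires abundance and annotation")
        tpm_lookup = abundance.pivot_table(
            index="transcript_id", columns="sample", values="tpm", aggfunc="sum"
        ).reindex(columns=samples).fillna(0.0)
    else:
        if pac_counts is None:
            raise ValueError("pac_counts mode requires pac_counts")
        pac_counts = pac_counts.set_index("pac_id")

    pas_rows, usage_rows, psi_rows = [], [], []
    dropped, excluded_tx = [], []
    for iso in isoform_sets:
        values = np.zeros((iso.n, len(samples)))
        measurable = np.zeros(iso.n, dtype=bool)
        if mode == "transcript_tpm":
            positions = np.array([s.position for s in iso.sites])
            for t in annotation.genes[iso.gene_id].transcripts:
                dist = np.abs(positions - t.three_prime_end)
                j = int(dist.argmin())
                if dist[j] > merge_window:
                    excluded_tx.append(t.id)
                    continue
                measurable[j] = True
                if t.id in tpm_lookup.index:
                    values[j] += tpm_lookup.loc[t.id].to_numpy()
        else:
            for j, site in enumerate(iso.sites):
                if site.pac_id is not None and site.pac_id in pac_counts.index:
                    measurable[j] = True
                    values[j] = pac_counts.loc[site.pac_id, samples].to_numpy(dtype=float)

        # drop sites with no observation in this mode; ranks follow the
        # quantifiable set, mirroring usage analysis over observed isoforms
        if measurable.sum() < 2:
            dropped.append(iso.gene_id)
            continue
        sites = [s for s, keep in zip(iso.sites, measurable) if keep]
        values = values[measurable]
        n = len(sites)
        pps = np.arange(n) / (n - 1)

        totals = values.sum(axis=0)
        ok_ctrl = all(totals[samples.index(s)] >= min_expr for s in ctrl)
        ok_mut = all(totals[samples.index(s)] >= min_expr for s in mut)
        if not (ok_ctrl or ok_mut):
            dropped.append(iso.gene_id)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions = np.where(totals > 0, values / totals, np.nan)
        psi = np.where(totals > 0, (fractions * pps[:, None]).sum(axis=0), np.nan)
        for j, site in enumerate(sites):
            pas_rows.append({
                "gene_id": iso.gene_id, "pas_id": site.pas_id, "position": site.position,
                "m": j, "n": n, "pps": pps[j],
                "sources": ",".join(sorted(site.sources)), "pac_id": site.pac_id or "",
            })
            for k, s in enumerate(samples):
                usage_rows.append({
                    "gene_id": iso.gene_id, "pas_id": site.pas_id, "sample": s,
                    "tpm": values[j, k], "usage_fraction": fractions[j, k],
                    "pps": pps[j], "m": j, "n": n,
                })
        for k, s in enumerate(samples):
            psi_rows.append({"gene_id": iso.gene_id, "sample": s, "psi": psi[k]})

    return UsageMatrix(
        pas_table=pd.DataFrame(pas_rows),
        usage=pd.DataFrame(usage_rows),
        psi=pd.DataFrame(psi_rows),
        dropped_genes=dropped,
        excluded_transcripts=excluded_tx,
    )


def _clip(values: np.ndarray, bound: float = DELTA_CLIP) -> np.ndarray:
    return np.clip(values, -bound, bound)


def test_differential_psi(usage: UsageMatrix, design: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Gene-level differential PAS usage: Welch t on per-replicate psi.

    delta_psi = mean mutant psi - mean control psi; positive values indicate
    a distal shift in the mutant. ``delta_psi_clipped`` is the +/-0.2-clipped
    reporting column; p-values are BH-adjusted across tested genes.
    """
    ctrl, mut = _condition_samples(design)
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("differential testing requires >= 2 replicates per condition")
    wide = usage.psi.pivot(index="gene_id", columns="sample", values="psi")
    wide = wide.dropna(axis=0, how="any")
    x = wide[mut].to_numpy()
    y = wide[ctrl].to_numpy()
    if len(wide) == 0:
        return pd.DataFrame(columns=[
            "gene_id", "psi_control", "psi_mutant", "delta_psi", "delta_psi_clipped",
            "p", "p_adjusted", "significant"])
    p = welch_rows(x, y)
    delta = x.mean(axis=1) - y.mean(axis=1)
    out = pd.DataFrame({
        "gene_id": wide.index,
        "psi_control": y.mean(axis=1),
        "psi_mutant": x.mean(axis=1),
        "delta_psi": delta,
        "delta_psi_clipped": _clip(delta),
        "p": p,
        "p_adjusted": bh_adjust(p),
    })
    out["significant"] = (out["p_adjusted"] <= alpha) & (out["delta_psi"] != 0)
    return out.reset_index(drop=True)


def test_differential_usage_fractions(usage: UsageMatrix, design: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """PAS-level differential usage: Welch t on per-replicate usage fractions.

    Each PAS is labeled increased / decreased / unchanged in the mutant at
    BH-adjusted p <= alpha, and carries its position class
    (most_proximal / middle / most_distal).
    """
    ctrl, mut = _condition_samples(design)
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("differential testing requires >= 2 replicates per condition")
    wide = usage.usage.pivot_table(
        index=["gene_id", "pas_id", "m", "n", "pps"], columns="sample", values="usage_fraction"
    ).dropna(axis=0, how="any")
    if len(wide) == 0:
        return pd.DataFrame(columns=[
            "gene_id", "pas_id", "m", "n", "pps", "position_class", "usage_control",
            "usage_mutant", "delta_usage", "delta_usage_clipped", "p", "p_adjusted", "change"])
    x = wide[mut].to_numpy()
    y = wide[ctrl].to_numpy()
    p = welch_rows(x, y)
    idx = wide.index.to_frame(index=False)
    delta = x.mean(axis=1) - y.mean(axis=1)
    out = pd.DataFrame({
        "gene_id": idx["gene_id"], "pas_id": idx["pas_id"],
        "m": idx["m"].astype(int), "n": idx["n"].astype(int), "pps": idx["pps"],
        "usage_control": y.mean(axis=1), "usage_mutant": x.mean(axis=1),
        "delta_usage": delta, "delta_usage_clipped": _clip(delta),
        "p": p, "p_adjusted": bh_adjust(p),
    })
    out["position_class"] = [classify_position(m, n) for m, n in zip(out["m"], out["n"])]
    significant = (out["p_adjusted"] <= alpha) & (out["delta_usage"] != 0)
    out["change"] = np.where(
        significant & (out["delta_usage"] > 0), "increased",
        np.where(significant & (out["delta_usage"] < 0), "decreased", "unchanged"),
    )
    return out.reset_index(drop=True)


def usage_shift_vs_position(
    gene_results: pd.DataFrame, pas_results: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float]:
    """Spearman correlation of delta usage fraction with PAS position score.

    Restricted to PASs of genes with significant gene-level differential psi
    (delta_psi != 0, BH p <= alpha). Returns (rho, p); (nan, nan) when fewer
    than 3 points remain.
    """
    sig_genes = set(gene_results.loc[
        (gene_results["p_adjusted"] <= alpha) & (gene_results["delta_psi"] != 0), "gene_id"
    ])
    sub = pas_results[pas_results["gene_id"].isin(sig_genes)]
    if len(sub) < 3:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(sub["pps"], sub["delta_usage"])
    return float(rho), float(p)
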