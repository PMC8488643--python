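"""Sequence-level scans around PASs.

MicroRNA seed-site detection (canonical 8mer / 7mer-m8 / 7mer-A1 site types)
in the regions between proximal and distal PASs of shifted genes, with
presence/absence Fisher enrichment against a background of 3'UTRs of
non-shifted expressed genes; and exact k-mer motif enrichment in windows
around differentially used PASs versus unchanged PASs. DNA alphabet
internally; U and T are interchangeable on input.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._stats import bh_adjust, fisher_exact_two_sided
from .annotation_io import GenomeAnnotation, fetch_sequence, revcomp
from .apa_quant import APAIsoformSet, UsageMatrix

__all__ = [
    "InterPasRegion",
    "SeedHit",
    "read_mirna_fasta",
    "extract_interpas_regions",
    "scan_seed_sites",
    "mirna_target_summary",
    "mirna_enrichment",
    "kmer_enrichment",
    "pas_windows",
]

DEFAULT_K = 6
DEFAULT_FLANK = 50


@dataclass(frozen=True)
class InterPasRegion:
    """Sense-strand sequence between a proximal and a distal PAS of a gene."""

    gene_id: str
    chrom: str
    strand: str
    start: int   # genomic, half-open
    end: int
    sequence: str


@dataclass(frozen=True)
class SeedHit:
    mirna_id: str
    gene_id: str
    match_type: str  # 8mer | 7mer_m8 | 7mer_A1
    offset: int


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_mirna_fasta(path: str) -> dict[str, str]:
    """Mature microRNA sequences keyed by id, normalized to DNA alphabet."""
    return {rec.id: _dna(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}


def extract_interpas_regions(
    isoform_sets: Iterable[APAIsoformSet],
    gene_results: pd.DataFrame,
    pas_results: pd.DataFrame,
    genome,
    direction: str,
    alpha: float = 0.05,
) -> tuple[list[InterPasRegion], int, int]:
    """Regions between the most-used proximal PAS and a qualifying distal PAS.

    For ``distal_shifted``, genes with significant positive delta psi are
    taken and a specific distal PAS (rank m >= 1) with significantly
    *increased* usage is required; for ``proximal_shifted``, genes with
    significant negative delta psi and a distal PAS with *decreased* usage.
    The most distal qualifying PAS bounds the region; the proximal anchor is
    the most-used PAS upstream of it (mean usage over both conditions).
    Returns (regions, n_candidate_genes, n_excluded_for_no_specific_pas).
    """
    if direction not in ("distal_shifted", "proximal_shifted"):
        raise ValueError(f"unknown direction {direction!r}")
    sig = gene_results[(gene_results["p_adjusted"] <= alpha) & (gene_results["delta_psi"] != 0)]
    genes = set(sig.loc[sig["delta_psi"] > 0, "gene_id"]) if direction == "distal_shifted" \
        else set(sig.loc[sig["delta_psi"] < 0, "gene_id"])
    wanted_change = "increased" if direction == "distal_shifted" else "decreased"
    iso_by_gene = {iso.gene_id: iso for iso in isoform_sets}

    regions: list[InterPasRegion] = []
    excluded = 0
    for gid in sorted(genes):
        iso = iso_by_gene.get(gid)
        if iso is None:
            excluded += 1
            continue
        sub = pas_results[pas_results["gene_id"] == gid]
        qual = sub[(sub["m"] >= 1) & (sub["change"] == wanted_change)]
        if qual.empty:
            excluded += 1
            continue
        m_dist = int(qual["m"].max())
        upstream = sub[sub["m"] < m_dist].copy()
        if upstream.empty:
            excluded += 1
            continue
        upstream["mean_usage"] = (upstream["usage_control"] + upstream["usage_mutant"]) / 2
        m_prox = int(upstream.sort_values(["mean_usage", "m"], ascending=[False, True]).iloc[0]["m"])
        prox_pos = iso.sites[m_prox].position
        dist_pos = iso.sites[m_dist].position
        if iso.strand == "+":
            start, end = prox_pos, dist_pos
            seq = fetch_sequence(genome, iso.chrom, start, end)
        else:
            start, end = dist_pos + 1, prox_pos + 1
            seq = revcomp(fetch_sequence(genome, iso.chrom, start, end))
        if end <= start:
            excluded += 1
            continue
        regions.append(InterPasRegion(
            gene_id=gid, chrom=iso.chrom, strand=iso.strand, start=start, end=end, sequence=_dna(seq)
        ))
    return regions, len(genes), excluded


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def seed_sites(sequence: str, mirna_seq: str) -> list[tuple[str, int]]:
    """Canonical seed-match sites of one microRNA in one sense sequence.

    The seed is microRNA nucleotides 2-8. A 7mer-m8 site is the reverse
    complement of the full seed; a 7mer-A1 site is the reverse complement of
    nucleotides 2-7 followed by an A in the target; an 8mer satisfies both.
    One site per offset, strongest type wins.
    """
    seq = _dna(sequence)
    mir = _dna(mirna_seq)
    seed7 = mir[1:8]          # nt 2-8
    site_m8 = revcomp(seed7)  # 7 nt
    site_a1 = revcomp(mir[1:7]) + "A"  # 7 nt
    hits: dict[int, str] = {}
    for off in _find_all(seq, site_m8):
        if seq[off + 7: off + 8] == "A":
            hits[off] = "8mer"
        else:
            hits[off] = "7mer_m8"
    for off in _find_all(seq, site_a1):
        if off - 1 in hits and hits[off - 1] in ("8mer",):
            continue  # the A1 half of an 8mer already counted
        if off not in hits:
            hits[off] = "7mer_A1"
    return sorted(hits.items())


def scan_seed_sites(
    regions: Iterable[InterPasRegion], mirnas: Mapping[str, str]
) -> list[SeedHit]:
    """Scan every region for seed sites of every microRNA."""
    out: list[SeedHit] = []
    for mid, mseq in sorted(mirnas.items()):
        if len(_dna(mseq)) < 8:
            warnings.warn(f"microRNA {mid} shorter than 8 nt; skipped", stacklevel=2)
            continue
        for region in regions:
            for off, mtype in seed_sites(region.sequence, mseq):
                out.append(SeedHit(mirna_id=mid, gene_id=region.gene_id, match_type=mtype, offset=off))
    return out


def mirna_target_summary(
    hits: Iterable[SeedHit],
    regions: Iterable[InterPasRegion],
    expressed_mirnas: Iterable[str] | None = None,
) -> dict:
    """Counts of targeted regions, (gene, microRNA) pairs, and microRNAs."""
    hits = list(hits)
    if expressed_mirnas is not None:
        keep = set(expressed_mirnas)
        hits = [h for h in hits if h.mirna_id in keep]
    pairs = {(h.gene_id, h.mirna_id) for h in hits}
    per_mirna: dict[str, int] = {}
    for g, m in pairs:
        per_mirna[m] = per_mirna.get(m, 0) + 1
    return {
        "n_regions": len(list(regions)),
        "n_regions_with_site": len({h.gene_id for h in hits}),
        "n_pairs": len(pairs),
        "n_unique_mirnas": len(per_mirna),
        "targets_per_mirna": dict(sorted(per_mirna.items())),
    }


def mirna_enrichment(
    hits: Iterable[SeedHit],
    regions: Iterable[InterPasRegion],
    background_seqs: Mapping[str, str],
    mirnas: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-microRNA presence/absence Fisher enrichment vs background 3'UTRs.

    Foreground: inter-PAS regions of shifted genes; background: 3'UTR
    sequences of expressed non-shifted genes (id -> sense sequence). A
    sequence counts once no matter how many sites it holds.
    """
    background_seqs = dict(background_seqs)
    if not background_seqs:
        raise ValueError("empty background")
    regions = list(regions)
    n_fg = len(regions)
    n_bg = len(background_seqs)
    fg_with: dict[str, set] = {}
    for h in hits:
        fg_with.setdefault(h.mirna_id, set()).add(h.gene_id)
    rows = []
    for mid, mseq in sorted(mirnas.items()):
        if len(_dna(mseq)) < 8:
            continue
        a = len(fg_with.get(mid, ()))
        bg_hit = sum(1 for seq in background_seqs.values() if seed_sites(seq, mseq))
        odds, p = fisher_exact_two_sided(a, n_fg - a, bg_hit, n_bg - bg_hit)
        rows.append({
            "mirna_id": mid, "fg_with_site": a, "fg_total": n_fg,
            "bg_with_site": bg_hit, "bg_total": n_bg,
            "fg_fraction": a / n_fg if n_fg else np.nan,
            "bg_fraction": bg_hit / n_bg,
            "odds_ratio": odds, "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"])
        out["enriched"] = (out["p_adjusted"] <= alpha) & (out["fg_fraction"] > out["bg_fraction"])
        out = out.sort_values(["p_adjusted", "p", "mirna_id"], kind="stable").reset_index(drop=True)
    return out


def pas_windows(
    pas_frame: pd.DataFrame, annotation: GenomeAnnotation, genome, flank: int = DEFAULT_FLANK
) -> list[str]:
    """Sense-strand sequence windows of +/-``flank`` nt around PAS positions.

    ``pas_frame`` needs gene_id and position columns; the strand comes from
    the gene. Windows running off a chromosome end are truncated (padding
    N bases never match a k-mer).
    """
    seqs = []
    for r in pas_frame.itertuples(index=False):
        gene = annotation.genes[r.gene_id]
        window = fetch_sequence(genome, gene.chrom, r.position - flank, r.position + flank + 1)
        seqs.append(_dna(window if gene.strand == "+" else revcomp(window)))
    return seqs


def kmer_enrichment(
    foreground_seqs: Iterable[str],
    background_seqs: Iterable[str],
    k: int = DEFAULT_K,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Presence/absence k-mer enrichment in foreground vs background windows.

    Every k-mer observed in either set is Fisher-tested on the counts of
    windows containing it at least once; BH across k-mers; sorted by
    adjusted then raw p so the top row is the strongest motif.
    """
    fg = [_dna(s) for s in foreground_seqs]
    bg = [_dna(s) for s in background_seqs]

    def presence(seqs: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in seqs:
            seen = {s[i: i + k] for i in range(len(s) - k + 1)}
            for kmer in seen:
                if "N" not in kmer:
                    counts[kmer] = counts.get(kmer, 0) + 1
        return counts

    fg_counts = presence(fg)
    bg_counts = presence(bg)
    n_fg, n_bg = len(fg), len(bg)
    rows = []
    for kmer in sorted(set(fg_counts) | set(bg_counts)):
        a = fg_counts.get(kmer, 0)
        c = bg_counts.get(kmer, 0)
        odds, p = fisher_exact_two_sided(a, n_fg - a, c, n_bg - c)
        rows.append({
            "kmer": kmer, "fg_with": a, "fg_total": n_fg, "bg_with": c, "bg_total": n_bg,
            "fg_fraction": a / n_fg if n_fg else np.nan,
            "bg_fraction": c / n_bg if n_bg else np.nan,
            "odds_ratio": odds, "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"])
        out["enriched"] = (out["p_adjusted"] <= alpha) & (out["fg_fraction"] > out["bg_fraction"])
        out = out.sort_values(["p_adjusted", "p", "kmer"], kind="stable").reset_index(drop=True)
    return out
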