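"""Poly(A)-site cluster (PAC) calling from 3'-end reads.

The 3'READS-style workflow: deduplicate reads (UMI-aware), flag likely
internal-priming artifacts at genomic A-rich tracts, single-linkage cluster
the surviving cleavage positions per chromosome/strand, call a modal summit
per cluster, and count per-sample support. PACs are called on reads pooled
across samples and then counted per sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import fetch_sequence, reads_to_frame, revcomp

__all__ = [
    "PAC",
    "deduplicate",
    "filter_internal_priming",
    "cluster_ends",
    "count_pac_reads",
    "pacs_to_bed",
    "pac_count_matrix",
]

DEFAULT_MAX_GAP = 24
DEFAULT_MIN_READS = 2
IP_WINDOW = 10       # nt scanned immediately downstream of the cleavage site
IP_MIN_A = 7         # >= this many A in the window flags the read
IP_MIN_CONSECUTIVE_A = 6


@dataclass
class PAC:
    """A cluster of observed cleavage positions treated as one PAS locus."""

    pac_id: str
    chrom: str
    strand: str
    start: int
    end: int          # half-open cluster extent
    summit: int       # modal cleavage position
    total: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"{self.pac_id}: summit {self.summit} outside [{self.start}, {self.end})")


def deduplicate(reads) -> pd.DataFrame:
    """Collapse duplicate reads to one per distinct key.

    The key is (chromosome, strand, end position, UMI) when a UMI is present
    and (chromosome, strand, end position) otherwise; samples are
    deduplicated independently when more than one is present.
    """
    frame = reads_to_frame(reads)
    if frame.empty:
        return frame.copy()
    return frame.drop_duplicates(subset=["chrom", "strand", "end", "umi", "sample"]).reset_index(drop=True)


def _downstream_window(genome, chrom: str, strand: str, pos: int, window: int) -> str:
    """Genomic sequence immediately 3' of the cleavage site, read-strand sense."""
    if strand == "+":
        return fetch_sequence(genome, chrom, pos + 1, pos + 1 + window)
    return revcomp(fetch_sequence(genome, chrom, pos - window, pos))


def _is_a_rich(seq: str, min_a: int = IP_MIN_A, min_consecutive: int = IP_MIN_CONSECUTIVE_A) -> bool:
    if seq.count("A") >= min_a:
        return True
    run = best = 0
    for ch in seq:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best >= min_consecutive


def filter_internal_priming(
    reads, genome, window: int = IP_WINDOW,
    min_a: int = IP_MIN_A, min_consecutive: int = IP_MIN_CONSECUTIVE_A,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split reads into (kept, flagged) by the downstream A-content rule.

    A read is flagged as a likely internal-priming artifact when the
    ``window``-nt genomic stretch immediately downstream of its cleavage
    site, on the read's strand, contains >= ``min_a`` adenosines or a run of
    >= ``min_consecutive`` consecutive adenosines. Windows that run off the
    chromosome end are padded with non-A bases.
    """
    frame = reads_to_frame(reads)
    if frame.empty:
        return frame.copy(), frame.copy()
    sites = frame[["chrom", "strand", "end"]].drop_duplicates().copy()
    sites["_ip_flag"] = [
        _is_a_rich(_downstream_window(genome, r.chrom, r.strand, r.end, window), min_a, min_consecutive)
        for r in sites.itertuples(index=False)
    ]
    merged = frame.merge(sites, on=["chrom", "strand", "end"], how="left")
    mask = merged.pop("_ip_flag").to_numpy(dtype=bool)
    return frame[~mask].reset_index(drop=True), frame[mask].reset_index(drop=True)


def cluster_ends(reads, max_gap: int = DEFAULT_MAX_GAP, min_reads: int = DEFAULT_MIN_READS) -> list[PAC]:
    """Single-linkage cluster cleavage positions into PACs.

    Per (chromosome, strand), sorted distinct positions are chained while the
    gap to the previous position is <= ``max_gap`` (a gap of exactly
    ``max_gap`` still joins). The summit is the modal position, ties broken
    toward the most upstream position in transcription direction. Clusters
    supported by fewer than ``min_reads`` deduplicated reads are dropped.
    """
    frame = reads_to_frame(reads)
    pacs: list[PAC] = []
    if frame.empty:
        return pacs
    grouped = frame.groupby(["chrom", "strand"], sort=True)
    idx = 0
    for (chrom, strand), sub in grouped:
        pos, counts = np.unique(np.asarray(sub["end"], dtype=np.int64), return_counts=True)
        breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
        for seg_pos, seg_cnt in zip(np.split(pos, breaks), np.split(counts, breaks)):
            total = int(seg_cnt.sum())
            if total < min_reads:
                continue
            best = seg_cnt.max()
            tied = seg_pos[seg_cnt == best]
            summit = int(tied.min() if strand == "+" else tied.max())
            pacs.append(PAC(
                pac_id=f"PAC{idx:06d}", chrom=chrom, strand=strand,
                start=int(seg_pos[0]), end=int(seg_pos[-1]) + 1,
                summit=summit, total=total,
            ))
            idx += 1
    return pacs


def count_pac_reads(pacs: list[PAC], reads_by_sample: Mapping[str, object]) -> dict[str, int]:
    """Fill per-sample read counts on the PACs; returns unassigned totals.

    A deduplicated read is assigned to the PAC whose [start, end) contains
    its cleavage position on the matching strand (PACs on one strand never
    overlap by construction). Reads outside every PAC count as unassigned.
    """
    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[PAC]]] = {}
    for pac in pacs:
        pac.counts = {}
        pac.total = 0
        by_key.setdefault((pac.chrom, pac.strand), ([], [], []))
    tmp: dict[tuple[str, str], list[PAC]] = {}
    for pac in pacs:
        tmp.setdefault((pac.chrom, pac.strand), []).append(pac)
    for key, plist in tmp.items():
        plist.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in plist], dtype=np.int64)
        ends = np.array([p.end for p in plist], dtype=np.int64)
        by_key[key] = (starts, ends, plist)

    unassigned: dict[str, int] = {}
    for sample, reads in reads_by_sample.items():
        frame = reads_to_frame(reads)
        unassigned[sample] = 0
        if frame.empty:
            continue
        for (chrom, strand), sub in frame.groupby(["chrom", "strand"]):
            ends_arr = np.asarray(sub["end"], dtype=np.int64)
            if (chrom, strand) not in by_key:
                unassigned[sample] += len(ends_arr)
                continue
            starts, ends, plist = by_key[(chrom, strand)]
            pos_idx = np.searchsorted(starts, ends_arr, side="right") - 1
            inside = (pos_idx >= 0) & (ends_arr < ends[np.clip(pos_idx, 0, len(ends) - 1)])
            unassigned[sample] += int((~inside).sum())
            hit_idx, hit_n = np.unique(pos_idx[inside], return_counts=True)
            for i, n in zip(hit_idx, hit_n):
                pac = plist[i]
                pac.counts[sample] = pac.counts.get(sample, 0) + int(n)
                pac.total += int(n)
    return unassigned


def pacs_to_bed(pacs: Iterable[PAC]) -> pd.DataFrame:
    """BED6 frame for pacs.bed: name = pac_id, score = total count."""
    rows = [(p.chrom, p.start, p.end, p.pac_id, p.total, p.strand) for p in pacs]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def pac_count_matrix(pacs: Iterable[PAC], samples: Iterable[str]) -> pd.DataFrame:
    """pac_id x sample count matrix (long-friendly wide TSV)."""
    samples = list(samples)
    rows = [
        {"pac_id": p.pac_id, "chrom": p.chrom, "strand": p.strand, "summit": p.summit,
         **{s: p.counts.get(s, 0) for s in samples}}
        for p in pacs
    ]
    cols = ["pac_id", "chrom", "strand", "summit", *samples]
    return pd.DataFrame(rows, columns=cols)
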