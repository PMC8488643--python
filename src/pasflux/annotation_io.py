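"""Genomic annotation I/O and the shared data model.

Houses the gene/transcript containers used by every downstream stage and the
readers/writers for the standard formats the pipeline consumes: GTF 2.2
(annotation), BED6 (3'-end read positions), TSV (transcript abundances and
sample design). All coordinates are 0-based half-open **internally**;
conversion to and from 1-based-inclusive GTF and 0-based BED happens only at
the format boundary.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "Transcript",
    "GenomeAnnotation",
    "ThreePrimeRead",
    "BIOTYPES",
    "read_gtf",
    "write_gtf",
    "read_end_reads",
    "reads_to_frame",
    "read_design",
    "read_abundance",
    "write_results",
    "fetch_sequence",
    "revcomp",
]

#: the biotype vocabulary used throughout; anything else maps to "other"
BIOTYPES = ("protein_coding", "antisense", "lincRNA", "processed_pseudogene", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    pass


@dataclass
class Transcript:
    """One transcript: exon structure plus optional CDS and 3'UTR intervals.

    Intervals are 0-based half-open, sorted by genomic coordinate.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr3 = sorted(self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (transcript span minus exons)."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def three_prime_end(self) -> int:
        """0-based coordinate of the last transcribed base (the PAS proxy)."""
        return self.end - 1 if self.strand == "+" else self.start

    def derived_utr3(self) -> list[tuple[int, int]]:
        """Exonic region strictly 3' of the CDS, when a CDS is annotated."""
        if self.utr3:
            return self.utr3
        if not self.cds:
            return []
        out = []
        if self.strand == "+":
            cds_end = max(e for _, e in self.cds)
            for s, e in self.exons:
                if e > cds_end:
                    out.append((max(s, cds_end), e))
        else:
            cds_start = min(s for s, _ in self.cds)
            for s, e in self.exons:
                if s < cds_start:
                    out.append((s, min(e, cds_start)))
        return out


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    biotype: str = "other"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span_start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def span_end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def length(self) -> int:
        return self.span_end - self.span_start

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1


@dataclass(frozen=True)
class ThreePrimeRead:
    """A single 3'-end read reduced to its cleavage-site coordinate."""

    chrom: str
    strand: str
    end_position: int
    umi: str | None = None
    sample: str | None = None


class GenomeAnnotation:
    """Gene-centric annotation with per-gene feature interval lookups."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValueError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
            for t in g.transcripts:
                self.transcripts[t.id] = t

    def __len__(self) -> int:
        return len(self.genes)

    @cached_property
    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        by: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            by.setdefault(g.chrom, []).append(g)
        for lst in by.values():
            lst.sort(key=lambda g: (g.span_start, g.span_end, g.id))
        return by

    def feature_intervals(self, gene_id: str) -> dict[str, list[tuple[int, int]]]:
        """Union-of-transcripts intervals per feature kind for one gene.

        Kinds: exon, cds, intron, three_prime_utr, noncoding_exon (exons of
        transcripts whose gene biotype is not protein_coding).
        """
        g = self.genes[gene_id]
        feats: dict[str, list[tuple[int, int]]] = {
            "exon": [], "cds": [], "intron": [], "three_prime_utr": [], "noncoding_exon": []
        }
        noncoding = g.biotype != "protein_coding"
        for t in g.transcripts:
            feats["exon"].extend(t.exons)
            feats["cds"].extend(t.cds)
            feats["intron"].extend(t.introns)
            feats["three_prime_utr"].extend(t.derived_utr3())
            if noncoding:
                feats["noncoding_exon"].extend(t.exons)
        return {k: sorted(set(v)) for k, v in feats.items()}


def _normalize_biotype(raw: str | None) -> str:
    if raw in BIOTYPES:
        return raw
    aliases = {"lncRNA": "lincRNA", "lincrna": "lincRNA", "antisense_RNA": "antisense"}
    return aliases.get(raw, "other")


def _prevalidate_gtf(path: str) -> None:
    """Line-level validation so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise GtfParseError(f"line {lineno}: end ({end}) < start ({start})")
            if fields[6] not in "+-":
                raise GtfParseError(f"line {lineno}: strand must be + or -, got {fields[6]!r}")
            if "gene_id" not in fields[8]:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute: {line.strip()!r}")
            if fields[2] != "gene" and "transcript_id" not in fields[8]:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute: {line.strip()!r}")


_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR", "3UTR"}


def read_gtf(path: str, include_biotypes: Iterable[str] | None = None) -> GenomeAnnotation:
    """Parse a GTF 2.2 file into a :class:`GenomeAnnotation`.

    1-based inclusive coordinates are converted to 0-based half-open.
    Transcript introns are derived from exon gaps. ``gene_biotype`` (or
    ``gene_type``) outside the fixed vocabulary maps to ``"other"``; with
    ``include_biotypes`` the annotation is restricted to those labels after
    normalization.
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    tx_info: dict[str, dict] = {}
    gene_bio: dict[str, str] = {}
    gene_meta: dict[str, tuple[str, str]] = {}

    def attr1(feat, key):
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    for feat in db.all_features():
        gid = attr1(feat, "gene_id")
        bio = _normalize_biotype(attr1(feat, "gene_biotype") or attr1(feat, "gene_type"))
        if gid is not None:
            if gid not in gene_bio or bio != "other":
                gene_bio[gid] = bio
            gene_meta.setdefault(gid, (feat.seqid, feat.strand))
        if feat.featuretype in ("gene", "transcript"):
            if feat.featuretype == "transcript":
                tid = attr1(feat, "transcript_id")
                tx_info.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid,
                                         "strand": feat.strand, "exon": [], "cds": [], "utr3": []})
            continue
        tid = attr1(feat, "transcript_id")
        if tid is None:
            continue
        rec = tx_info.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid,
                                       "strand": feat.strand, "exon": [], "cds": [], "utr3": []})
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            rec["exon"].append(iv)
        elif feat.featuretype == "CDS":
            rec["cds"].append(iv)
        elif feat.featuretype in _UTR3_TYPES:
            rec["utr3"].append(iv)

    genes: dict[str, Gene] = {}
    for tid, rec in tx_info.items():
        if not rec["exon"]:
            continue
        gid = rec["gene_id"]
        bio = gene_bio.get(gid, "other")
        if include_biotypes is not None and bio not in set(include_biotypes):
            continue
        if gid not in genes:
            genes[gid] = Gene(id=gid, chrom=rec["chrom"], strand=rec["strand"], biotype=bio)
        genes[gid].transcripts.append(
            Transcript(id=tid, gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                       exons=rec["exon"], cds=rec["cds"], utr3=rec["utr3"])
        )
    return GenomeAnnotation(genes.values())


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write the annotation back to GTF 2.2 (round-trip partner of read_gtf)."""
    with open(path, "w") as fh:
        for g in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.span_start, g.id)):
            attrs = f'gene_id "{g.id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\tpasflux\tgene\t{g.span_start + 1}\t{g.span_end}\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                ta = f'gene_id "{g.id}"; transcript_id "{t.id}"; gene_biotype "{g.biotype}";'
                fh.write(f"{g.chrom}\tpasflux\ttranscript\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t{ta}\n")
                for s, e in t.exons:
                    fh.write(f"{g.chrom}\tpasflux\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{ta}\n")
                for s, e in t.cds:
                    fh.write(f"{g.chrom}\tpasflux\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{ta}\n")
                for s, e in t.utr3:
                    fh.write(f"{g.chrom}\tpasflux\tthree_prime_utr\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{ta}\n")


# ---------------------------------------------------------------------------
# 3'-end reads (BED6). Bulk read sets travel as DataFrames with columns
# chrom, strand, end, umi, sample — cheap at millions of rows, and every
# pac_calling operation is vectorized over them.
# ---------------------------------------------------------------------------

READ_COLUMNS = ["chrom", "strand", "end", "umi", "sample"]


def reads_to_frame(reads: Iterable[ThreePrimeRead] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    rows = [(r.chrom, r.strand, r.end_position, r.umi, r.sample) for r in reads]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def read_end_reads(path_bed: str, sample: str | None = None) -> pd.DataFrame:
    """Read 3'-end read positions from BED6.

    The cleavage coordinate is chromEnd-1 on the + strand and chromStart on
    the - strand. A UMI is taken from the name field after the last ":" when
    one is present.
    """
    chroms, strands, ends, umis = [], [], [], []
    with open(path_bed) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path_bed} line {lineno}: BED6 requires 6 fields")
            strand = f[5]
            if strand not in "+-":
                raise ValueError(f"{path_bed} line {lineno}: unknown strand {strand!r}")
            start, end = int(f[1]), int(f[2])
            chroms.append(f[0])
            strands.append(strand)
            ends.append(end - 1 if strand == "+" else start)
            name = f[3]
            umis.append(name.rsplit(":", 1)[1] if ":" in name else None)
    return pd.DataFrame({
        "chrom": chroms, "strand": strands,
        "end": np.asarray(ends, dtype=np.int64),
        "umi": umis, "sample": sample,
    })


# ---------------------------------------------------------------------------
# abundance + design tables
# ---------------------------------------------------------------------------

def read_design(path: str) -> pd.DataFrame:
    """Sample design TSV: columns sample_id, condition, replicate."""
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(design.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    bad = set(design["condition"]) - {"control", "mutant"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return design


def read_abundance(path_tsv: str, design: pd.DataFrame) -> pd.DataFrame:
    """Read a wide per-transcript abundance table into long format.

    Expects a ``transcript_id`` column plus ``<sample>_est_counts`` /
    ``<sample>_tpm`` column pairs. Returns rows of
    (transcript_id, sample, est_counts, tpm). Negative values are rejected;
    a per-sample TPM total off 10^6 by more than 1% triggers a warning only.
    """
    wide = pd.read_csv(path_tsv, sep="\t")
    if "transcript_id" not in wide.columns:
        raise ValueError("abundance table must have a transcript_id column")
    samples = sorted({c[: -len("_tpm")] for c in wide.columns if c.endswith("_tpm")})
    if not samples:
        raise ValueError("abundance table has no <sample>_tpm columns")
    known = set(design["sample_id"])
    unknown = [s for s in samples if s not in known]
    if unknown:
        raise ValueError(f"samples absent from design: {unknown}")
    frames = []
    for s in samples:
        cols = {f"{s}_est_counts": "est_counts", f"{s}_tpm": "tpm"}
        missing = [c for c in cols if c not in wide.columns]
        if missing:
            raise ValueError(f"missing abundance columns: {missing}")
        sub = wide[["transcript_id", *cols]].rename(columns=cols)
        sub.insert(1, "sample", s)
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    if (long[["est_counts", "tpm"]] < 0).any().any():
        raise ValueError("negative est_counts/tpm values are not allowed")
    totals = long.groupby("sample")["tpm"].sum()
    off = totals[(totals - 1e6).abs() > 1e4]
    for s, tot in off.items():
        warnings.warn(f"sample {s}: TPM column sums to {tot:.1f}, not 1e6", stacklevel=2)
    return long


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str) -> dict[str, str]:
    """Write result tables as TSV (or BED for keys ending in ``.bed``).

    Keys are file names; values DataFrames. Floats use a fixed %.10g format
    so reruns with identical inputs are byte-identical. Returns name->path.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, name)
        if name.endswith(".bed"):
            df.to_csv(path, sep="\t", index=False, header=False)
        else:
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[name] = path
    return written


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) as an upper-case string, padding out-of-bounds
    positions with 'N'. Accepts a pyfaidx.Fasta or any Mapping[str, str]."""
    start, end = int(start), int(end)
    if end <= start:
        return ""
    try:
        ref = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    length = len(ref)
    lo, hi = max(0, start), min(length, end)
    core = str(ref[lo:hi]).upper() if hi > lo else ""
    return "N" * (lo - start) + core + "N" * (end - hi)
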