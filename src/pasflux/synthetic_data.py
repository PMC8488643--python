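"""Self-contained synthetic dataset with ground truth for every statistic.

Generates a toy genome (FASTA), a matching annotation (GTF, one transcript
per PAS so the transcript-to-PAS mapping is exact), per-sample transcript
abundance tables, 3'-end read BEDs, a mature microRNA FASTA, and a truth
table. The generator's defaults define the study conditions the pipeline is
validated against: 500 genes in density strata on two chromosomes, 3 vs 3
replicates, 100 genes with a planted delta psi of +0.15 (85% distal-
directed) preferentially drawn from short/dense genes, biotype and
density/length couplings on expression, canonical AATAAA signals planted
upstream of PASs (80% at shifted-gene PASs vs 5% elsewhere), a planted
microRNA, internal-priming decoy tracts, and Normal(sigma=10) read scatter
around true cleavage sites.

All randomness flows from a single seed through per-stage generators, so
the abundance tables can be re-simulated without materializing the genome
and every output is byte-identical under a fixed seed.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation_io import Gene, GenomeAnnotation, Transcript, revcomp, write_gtf

__all__ = [
    "SimConfig",
    "SimGene",
    "Truth",
    "simulate_truth",
    "materialize_genome",
    "simulate_abundances",
    "simulate_end_reads",
    "simulate_dataset",
    "to_annotation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the reference study conditions."""

    seed: int = 0
    n_genes: int = 500
    n_chromosomes: int = 2
    frac_multi_pas: float = 0.8
    n_pas_min: int = 2
    n_pas_max: int = 5
    # planted APA shifts
    n_shifted: int = 100
    delta_psi: float = 0.15
    frac_distal: float = 0.85
    shift_selection_weight: float = 1.0   # bias toward short/dense genes
    # replicates and noise
    replicates: int = 3
    sigma_psi: float = 0.02               # per-replicate jitter of the target psi
    dirichlet_concentration: float = 2000.0  # residual compositional noise; keeps
    # the total replicate psi noise ~sigma_psi so sigma_psi is the condition that matters
    log_tpm_sd: float = 1.0
    expr_rep_cv: float = 0.10             # sd of per-replicate log expression noise
    # planted expression effects
    biotype_fracs: dict = field(default_factory=lambda: {
        "protein_coding": 0.70, "antisense": 0.10, "lincRNA": 0.10,
        "processed_pseudogene": 0.05, "other": 0.05})
    biotype_beta: dict = field(default_factory=lambda: {
        "protein_coding": 0.10, "antisense": -0.20, "lincRNA": -0.20,
        "processed_pseudogene": -0.20, "other": 0.0})
    length_beta_coeff: float = 0.25       # beta per SD of log10 gene length
    density_beta_coeff: float = 0.25      # beta per SD of log10 intergenic gap
    # 3'-end reads
    reads_per_sample: int = 100_000
    read_sigma: float = 10.0
    internal_priming_rate: float = 0.05   # artifact fraction of emitted reads
    umi_length: int = 8
    # sequence plants
    pas_signal_prob_shifted: float = 0.80
    pas_signal_prob_background: float = 0.05
    pas_signal_offset: int = 21           # hexamer starts this far upstream of the PAS
    n_mirnas: int = 20
    mirna_site_prob_shifted: float = 0.50
    mirna_site_prob_background: float = 0.05
    # intronic PASs (unannotated read signal inside introns)
    frac_intronic_pas: float = 0.15
    intronic_read_frac: float = 0.05
    intronic_delta_frac: float = 0.0      # condition effect on intronic usage (0 = null)
    # internal-priming decoys
    n_decoys: int = 200
    decoy_len: int = 15
    # gene geometry (nt)
    exon1_len: int = 200
    cds_lead: int = 30
    cds_len: int = 300
    utr_lead: int = 150
    min_pas_spacing: int = 200
    max_pas_spacing: int = 800
    block_size: int = 25                  # genes per shared-density stratum
    gap_log10_range: tuple = (2.2, 4.3)
    gap_log10_jitter: float = 0.15
    intron_log10_range: tuple = (2.3, 3.7)


@dataclass
class SimGene:
    """One simulated gene; offsets are transcription coordinates from the TSS."""

    gene_id: str
    chrom: str
    strand: str
    anchor: int                 # genomic coordinate of the TSS
    biotype: str
    exon1_len: int
    intron_len: int
    cds_len: int                # 0 for noncoding biotypes
    cds_lead: int
    pas_offsets: list[int]      # offset of the last transcribed base per PAS
    gap_log10: float
    intronic_pas_offset: int | None = None
    rel_expr: float = 1.0
    true_beta: float = 0.0
    planted_shift: bool = False
    shift_direction: str | None = None
    frac_control: np.ndarray | None = None
    frac_mutant: np.ndarray | None = None
    pas_signal: list[bool] = field(default_factory=list)
    mirna_planted: bool = False
    mirna_site_offset: int | None = None

    @property
    def n_pas(self) -> int:
        return len(self.pas_offsets)

    @property
    def length(self) -> int:
        return self.pas_offsets[-1] + 1

    def genomic(self, offset: int) -> int:
        return self.anchor + offset if self.strand == "+" else self.anchor - offset

    def interval(self, x: int, y: int) -> tuple[int, int]:
        """Transcription-coordinate [x, y) to genomic half-open interval."""
        if self.strand == "+":
            return self.anchor + x, self.anchor + y
        return self.anchor - y + 1, self.anchor - x + 1

    @property
    def span(self) -> tuple[int, int]:
        return self.interval(0, self.length)

    @property
    def pas_positions(self) -> list[int]:
        return [self.genomic(o) for o in self.pas_offsets]

    @property
    def pps(self) -> np.ndarray:
        if self.n_pas < 2:
            return np.array([np.nan])
        return np.arange(self.n_pas) / (self.n_pas - 1)

    def psi(self, fracs: np.ndarray) -> float:
        if self.n_pas < 2:
            return float("nan")
        return float((fracs * self.pps).sum())

    def transcripts(self) -> list[Transcript]:
        exon_break = self.exon1_len + self.intron_len
        out = []
        for k, off in enumerate(self.pas_offsets):
            exons = [self.interval(0, self.exon1_len), self.interval(exon_break, off + 1)]
            cds = []
            if self.cds_len > 0:
                cds = [self.interval(self.cds_lead, self.exon1_len),
                       self.interval(exon_break, exon_break + self.cds_len)]
            out.append(Transcript(
                id=f"{self.gene_id}.t{k}", gene_id=self.gene_id, chrom=self.chrom,
                strand=self.strand, exons=exons, cds=cds,
            ))
        return out


@dataclass
class Truth:
    config: SimConfig
    genes: list[SimGene]
    decoys: list[tuple[str, int, str]]   # (chrom, tract start, strand)
    mirnas: dict[str, str]               # id -> mature sequence (RNA alphabet)
    chrom_lengths: dict[str, int]
    design: pd.DataFrame
    table: pd.DataFrame


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,)))


def _sample_names(config: SimConfig) -> tuple[list[str], list[str]]:
    ctrl = [f"control_{i + 1}" for i in range(config.replicates)]
    mut = [f"mutant_{i + 1}" for i in range(config.replicates)]
    return ctrl, mut


def _design_frame(config: SimConfig) -> pd.DataFrame:
    ctrl, mut = _sample_names(config)
    rows = [{"sample_id": s, "condition": "control", "replicate": i + 1} for i, s in enumerate(ctrl)]
    rows += [{"sample_id": s, "condition": "mutant", "replicate": i + 1} for i, s in enumerate(mut)]
    return pd.DataFrame(rows)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_truth(config: SimConfig) -> Truth:
    """Draw gene structures, planted shifts and expression effects.

    Purely combinatorial/statistical: no genome sequence is materialized, so
    repeated truth+abundance simulation (e.g., for calibration studies) is
    cheap. Gene placement walks each chromosome in blocks that share a
    density stratum; planted APA shifts are drawn preferentially from
    short/dense genes; target usage fractions per condition encode the
    planted delta psi exactly as a proximal-to-distal mass shift.
    """
    rng = _rng(config, 0)
    cfg = config
    biotypes = list(cfg.biotype_fracs)
    bio_p = np.array([cfg.biotype_fracs[b] for b in biotypes], dtype=float)
    bio_p = bio_p / bio_p.sum()

    genes: list[SimGene] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    gene_idx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 1000
        n_here = min(per_chrom, cfg.n_genes - gene_idx)
        block_centers = rng.uniform(*cfg.gap_log10_range, size=int(np.ceil(n_here / cfg.block_size)))
        for j in range(n_here):
            center = block_centers[j // cfg.block_size]
            gap = int(round(10 ** (center + rng.normal(0, cfg.gap_log10_jitter)))) + 50
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = biotypes[rng.choice(len(biotypes), p=bio_p)]
            intron_len = int(round(10 ** rng.uniform(*cfg.intron_log10_range)))
            multi = rng.random() < cfg.frac_multi_pas
            n_pas = int(rng.integers(cfg.n_pas_min, cfg.n_pas_max + 1)) if multi else 1
            cds_len = cfg.cds_len if biotype == "protein_coding" else 0
            first = cfg.exon1_len + intron_len + cds_len + cfg.utr_lead
            spacings = rng.integers(cfg.min_pas_spacing, cfg.max_pas_spacing + 1, size=n_pas - 1)
            pas_offsets = (first + np.concatenate([[0], np.cumsum(spacings)])).astype(int).tolist()
            intronic = None
            if rng.random() < cfg.frac_intronic_pas:
                intronic = cfg.exon1_len + int(round(rng.uniform(0.25, 0.75) * intron_len))
            cursor += gap
            length = pas_offsets[-1] + 1
            anchor = cursor if strand == "+" else cursor + length - 1
            genes.append(SimGene(
                gene_id=f"G{gene_idx:04d}", chrom=chrom, strand=strand, anchor=anchor,
                biotype=biotype, exon1_len=cfg.exon1_len, intron_len=intron_len,
                cds_len=cds_len, cds_lead=cfg.cds_lead, pas_offsets=pas_offsets,
                gap_log10=float(np.log10(gap)), intronic_pas_offset=intronic,
            ))
            cursor += length
            gene_idx += 1

    # expression levels and planted beta couplings
    log_len = np.log10([g.length for g in genes])
    gap10 = np.array([g.gap_log10 for g in genes])
    z_len, z_gap = _zscore(log_len), _zscore(gap10)
    rel = np.exp(rng.normal(0.0, cfg.log_tpm_sd, size=len(genes)))
    for i, g in enumerate(genes):
        g.rel_expr = float(rel[i])
        g.true_beta = float(
            cfg.biotype_beta.get(g.biotype, 0.0)
            + cfg.length_beta_coeff * z_len[i]
            + cfg.density_beta_coeff * z_gap[i]
        )

    # planted APA shifts, biased toward short/dense genes
    multi_idx = [i for i, g in enumerate(genes) if g.n_pas >= 2]
    n_shift = min(cfg.n_shifted, len(multi_idx))
    if n_shift:
        score = z_len[multi_idx] + z_gap[multi_idx]
        w = np.exp(-cfg.shift_selection_weight * score)
        w = w / w.sum()
        chosen = rng.choice(len(multi_idx), size=n_shift, replace=False, p=w)
        chosen_ids = [multi_idx[c] for c in chosen]
        # exact composition: frac_distal of the planted shifts are distal-directed
        n_distal = int(round(cfg.frac_distal * n_shift))
        order = rng.permutation(n_shift)
        direction_of = {chosen_ids[j]: ("distal" if rank < n_distal else "proximal")
                        for rank, j in enumerate(order)}
        shifted = set(chosen_ids)
    else:
        direction_of = {}
        shifted = set()

    margin = cfg.delta_psi + 4 * cfg.sigma_psi + 0.05
    for i, g in enumerate(genes):
        if g.n_pas < 2:
            g.frac_control = np.array([1.0])
            g.frac_mutant = np.array([1.0])
            continue
        raw = rng.dirichlet(np.full(g.n_pas, 3.0))
        f = (raw + 0.15) / (1.0 + 0.15 * g.n_pas)
        if i in shifted:
            g.planted_shift = True
            g.shift_direction = direction_of[i]
            anchor_idx = 0 if g.shift_direction == "distal" else g.n_pas - 1
            if f[anchor_idx] < margin:
                deficit = margin - f[anchor_idx]
                scale = (1.0 - margin) / (1.0 - f[anchor_idx])
                f = f * scale
                f[anchor_idx] = margin
                f = f / f.sum()
            fm = f.copy()
            if g.shift_direction == "distal":
                fm[0] -= cfg.delta_psi
                fm[-1] += cfg.delta_psi
            else:
                fm[-1] -= cfg.delta_psi
                fm[0] += cfg.delta_psi
        else:
            fm = f.copy()
        g.frac_control = f
        g.frac_mutant = fm

    # sequence plants: PAS signal hexamers and microRNA sites
    rng_seq = _rng(config, 1)
    mirnas = {}
    for k in range(cfg.n_mirnas):
        seq = "".join("ACGU"[b] for b in rng_seq.integers(0, 4, size=22))
        mirnas[f"syn-mir-{k + 1:03d}"] = seq
    planted_mirna = next(iter(mirnas)) if mirnas else None
    for g in genes:
        p_sig = cfg.pas_signal_prob_shifted if g.planted_shift else cfg.pas_signal_prob_background
        g.pas_signal = [bool(rng_seq.random() < p_sig) for _ in g.pas_offsets]
        if g.n_pas >= 2 and planted_mirna is not None:
            p_site = cfg.mirna_site_prob_shifted if g.planted_shift else cfg.mirna_site_prob_background
            if rng_seq.random() < p_site:
                g.mirna_planted = True
                g.mirna_site_offset = g.pas_offsets[-1] - int(rng_seq.integers(60, 150))

    # internal-priming decoy tracts in intergenic space
    decoys: list[tuple[str, int, str]] = []
    chrom_lengths: dict[str, int] = {}
    by_chrom: dict[str, list[SimGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        spans = sorted(g.span for g in by_chrom.get(chrom, []))
        end = (spans[-1][1] if spans else 1000) + 1000
        chrom_lengths[chrom] = end
        gaps = []
        prev = 100
        for s, e in spans:
            if s - prev > cfg.decoy_len + 40:
                gaps.append((prev + 20, s - 20 - cfg.decoy_len))
            prev = e
        n_here = cfg.n_decoys // cfg.n_chromosomes
        for _ in range(n_here):
            if not gaps:
                break
            lo, hi = gaps[int(rng_seq.integers(0, len(gaps)))]
            if hi <= lo:
                continue
            pos = int(rng_seq.integers(lo, hi))
            strand = "+" if rng_seq.random() < 0.5 else "-"
            decoys.append((chrom, pos, strand))

    table = pd.DataFrame([{
        "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
        "span_start": g.span[0], "span_end": g.span[1], "length": g.length,
        "biotype": g.biotype, "n_pas": g.n_pas,
        "pas_positions": ",".join(str(p) for p in g.pas_positions),
        "psi_control": g.psi(g.frac_control), "psi_mutant": g.psi(g.frac_mutant),
        "delta_psi": g.psi(g.frac_mutant) - g.psi(g.frac_control) if g.n_pas >= 2 else np.nan,
        "planted_shift": g.planted_shift, "shift_direction": g.shift_direction or "",
        "true_beta": g.true_beta, "rel_expr": g.rel_expr, "gap_log10": g.gap_log10,
        "intronic_pas": g.genomic(g.intronic_pas_offset) if g.intronic_pas_offset is not None else -1,
        "mirna_planted": g.mirna_planted,
        "pas_signals": ",".join("1" if s else "0" for s in g.pas_signal),
    } for g in genes])

    return Truth(config=config, genes=genes, decoys=decoys, mirnas=mirnas,
                 chrom_lengths=chrom_lengths, design=_design_frame(config), table=table)


def to_annotation(truth: Truth) -> GenomeAnnotation:
    """The truth's gene structures as a GenomeAnnotation (what the GTF holds)."""
    return GenomeAnnotation(
        Gene(id=g.gene_id, chrom=g.chrom, strand=g.strand, biotype=g.biotype,
             transcripts=g.transcripts())
        for g in truth.genes
    )


def materialize_genome(truth: Truth) -> dict[str, str]:
    """Random background sequence with all planted elements written in.

    AATAAA hexamers go ``pas_signal_offset`` nt upstream of flagged PASs on
    the sense strand; the planted microRNA's 8mer site goes between the
    PASs of flagged genes; poly(A)/poly(T) decoy tracts go into intergenic
    gaps. Deterministic given the config seed.
    """
    cfg = truth.config
    rng = _rng(cfg, 2)
    arrays: dict[str, np.ndarray] = {}
    for chrom, length in truth.chrom_lengths.items():
        arrays[chrom] = _BASES[rng.integers(0, 4, size=length)]

    def write_sense(gene: SimGene, off_start: int, motif: str) -> None:
        lo, hi = gene.interval(off_start, off_start + len(motif))
        seq = motif if gene.strand == "+" else revcomp(motif)
        arrays[gene.chrom][lo:hi] = np.frombuffer(seq.encode(), dtype=np.uint8)

    planted_mirna = next(iter(truth.mirnas)) if truth.mirnas else None
    site = None
    if planted_mirna is not None:
        mseq = truth.mirnas[planted_mirna].upper().replace("U", "T")
        site = revcomp(mseq[1:8]) + "A"  # 8mer site of the planted microRNA
    for g in truth.genes:
        for off, flagged in zip(g.pas_offsets, g.pas_signal):
            if flagged:
                write_sense(g, off - cfg.pas_signal_offset, "AATAAA")
        if g.mirna_planted and site is not None:
            write_sense(g, g.mirna_site_offset, site)
    for chrom, pos, strand in truth.decoys:
        tract = b"A" * cfg.decoy_len if strand == "+" else b"T" * cfg.decoy_len
        arrays[chrom][pos: pos + cfg.decoy_len] = np.frombuffer(tract, dtype=np.uint8)
    return {chrom: arr.tobytes().decode() for chrom, arr in arrays.items()}


def simulate_abundances(truth: Truth) -> pd.DataFrame:
    """Per-sample transcript abundances (wide TSV layout, TPM-normalized).

    Per replicate, a gene's expression is its relative level times the
    condition effect e^beta (mutant only) times log-normal replicate noise;
    its usage fractions are a Dirichlet draw around the condition target
    after a Normal(0, sigma_psi) proximal/distal jitter of the target psi.
    """
    cfg = truth.config
    rng = _rng(cfg, 3)
    ctrl, mut = _sample_names(cfg)
    samples = [(s, "control") for s in ctrl] + [(s, "mutant") for s in mut]
    tx_ids = [f"{g.gene_id}.t{k}" for g in truth.genes for k in range(g.n_pas)]
    wide = pd.DataFrame({"transcript_id": tx_ids})
    for sample, condition in samples:
        raw = np.zeros(len(tx_ids))
        pos = 0
        for g in truth.genes:
            expr = g.rel_expr * np.exp(rng.normal(0, cfg.expr_rep_cv))
            if condition == "mutant":
                expr *= np.exp(g.true_beta)
            target = (g.frac_control if condition == "control" else g.frac_mutant).copy()
            if g.n_pas >= 2:
                jitter = rng.normal(0, cfg.sigma_psi)
                jitter = float(np.clip(jitter, -(target[-1] - 0.01), target[0] - 0.01))
                target[0] -= jitter
                target[-1] += jitter
                fracs = rng.dirichlet(cfg.dirichlet_concentration * target)
            else:
                fracs = np.array([1.0])
            raw[pos: pos + g.n_pas] = expr * fracs
            pos += g.n_pas
        tpm = raw / raw.sum() * 1e6
        wide[f"{sample}_est_counts"] = tpm * 0.25
        wide[f"{sample}_tpm"] = tpm
    return wide


def abundance_to_long(design: pd.DataFrame, wide: pd.DataFrame) -> pd.DataFrame:
    """Wide per-sample abundance layout -> long (transcript, sample) rows."""
    frames = []
    for s in design["sample_id"]:
        frames.append(pd.DataFrame({
            "transcript_id": wide["transcript_id"], "sample": s,
            "est_counts": wide[f"{s}_est_counts"], "tpm": wide[f"{s}_tpm"],
        }))
    return pd.concat(frames, ignore_index=True)


def _random_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length)).astype(np.uint8)
    return _BASES[codes].view(f"S{length}").ravel().astype(str)


def simulate_end_reads(truth: Truth, abundance: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-sample 3'-end reads around true PASs, plus artifact reads.

    Read counts per PAS are Poisson(reads_per_sample x TPM / 1e6) from the
    realized abundances; positions are round(Normal(PAS, read_sigma)).
    Intronic-PAS genes additionally emit reads at the intronic position, and
    internal-priming artifacts are emitted immediately upstream of decoy
    A-tracts at the configured rate. Returns sample -> read frame.
    """
    cfg = truth.config
    rng = _rng(cfg, 4)
    ctrl, mut = _sample_names(cfg)
    out: dict[str, pd.DataFrame] = {}
    tx_index = {tid: i for i, tid in enumerate(abundance["transcript_id"])}
    for sample in ctrl + mut:
        condition = "control" if sample in ctrl else "mutant"
        tpm = abundance[f"{sample}_tpm"].to_numpy()
        chroms: list[str] = []
        strands: list[str] = []
        ends: list[np.ndarray] = []
        meta: list[tuple[str, str, int]] = []  # chrom, strand, count appended below
        for g in truth.genes:
            lam_gene = 0.0
            for k, pas in enumerate(g.pas_positions):
                lam = cfg.reads_per_sample * tpm[tx_index[f"{g.gene_id}.t{k}"]] / 1e6
                lam_gene += lam
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                pos = np.rint(rng.normal(pas, cfg.read_sigma, size=n)).astype(np.int64)
                pos = np.clip(pos, 1, truth.chrom_lengths[g.chrom] - 2)
                ends.append(pos)
                meta.append((g.chrom, g.strand, n))
            if g.intronic_pas_offset is not None and lam_gene > 0:
                frac = cfg.intronic_read_frac
                if condition == "mutant":
                    frac = max(0.0, frac + cfg.intronic_delta_frac)
                n = int(rng.poisson(lam_gene * frac))
                if n:
                    pos = np.rint(rng.normal(g.genomic(g.intronic_pas_offset), cfg.read_sigma, size=n))
                    pos = np.clip(pos.astype(np.int64), 1, truth.chrom_lengths[g.chrom] - 2)
                    ends.append(pos)
                    meta.append((g.chrom, g.strand, n))
        n_true = int(sum(m[2] for m in meta))
        rate = cfg.internal_priming_rate
        if truth.decoys and rate > 0 and n_true:
            n_art = int(rng.poisson(n_true * rate / (1.0 - rate)))
            if n_art:
                picks = rng.integers(0, len(truth.decoys), size=n_art)
                art_pos = np.empty(n_art, dtype=np.int64)
                art_chrom = []
                art_strand = []
                for i, di in enumerate(picks):
                    chrom, tpos, strand = truth.decoys[di]
                    art_pos[i] = tpos - 1 if strand == "+" else tpos + cfg.decoy_len
                    art_chrom.append(chrom)
                    art_strand.append(strand)
                ends.append(art_pos)
                for chrom, strand, n in zip(art_chrom, art_strand, np.ones(n_art, dtype=int)):
                    meta.append((chrom, strand, 1))
        for chrom, strand, n in meta:
            chroms.extend([chrom] * n)
            strands.extend([strand] * n)
        all_ends = np.concatenate(ends) if ends else np.array([], dtype=np.int64)
        frame = pd.DataFrame({
            "chrom": chroms, "strand": strands, "end": all_ends,
            "umi": _random_umis(rng, len(all_ends), cfg.umi_length),
            "sample": sample,
        })
        out[sample] = frame
    return out


def _write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def _write_reads_bed(frame: pd.DataFrame, path: str) -> None:
    # length-1 records: cleavage = chromEnd-1 on +, chromStart on - (both = end)
    with open(path, "w") as fh:
        for i, r in enumerate(frame.itertuples(index=False)):
            fh.write(f"{r.chrom}\t{r.end}\t{r.end + 1}\tr{i}:{r.umi}\t0\t{r.strand}\n")


def simulate_dataset(config: SimConfig, out_dir: str) -> dict[str, object]:
    """Generate and write the full input file set; returns paths and objects.

    Files: genome.fa, annotation.gtf, abundance.tsv, design.tsv,
    reads_<sample>.bed, mirnas.fa, truth.tsv.
    """
    os.makedirs(out_dir, exist_ok=True)
    truth = simulate_truth(config)
    genome = materialize_genome(truth)
    abundance = simulate_abundances(truth)
    reads = simulate_end_reads(truth, abundance)

    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "gtf": os.path.join(out_dir, "annotation.gtf"),
        "abundance": os.path.join(out_dir, "abundance.tsv"),
        "design": os.path.join(out_dir, "design.tsv"),
        "mirnas": os.path.join(out_dir, "mirnas.fa"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    _write_fasta(genome, paths["genome"])
    write_gtf(to_annotation(truth), paths["gtf"])
    abundance.to_csv(paths["abundance"], sep="\t", index=False, float_format="%.10g")
    truth.design.to_csv(paths["design"], sep="\t", index=False)
    _write_fasta({k: v for k, v in truth.mirnas.items()}, paths["mirnas"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    read_paths = {}
    for sample, frame in reads.items():
        p = os.path.join(out_dir, f"reads_{sample}.bed")
        _write_reads_bed(frame, p)
        read_paths[sample] = p
    paths["reads"] = read_paths
    return {"paths": paths, "truth": truth, "genome": genome,
            "abundance": abundance, "reads": reads}
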