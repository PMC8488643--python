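"""End-to-end orchestration of the APA analysis stages.

Stage order follows the analysis: PAC calling from 3'-end reads -> PAS
evidence merge and isoform sets -> usage quantification and differential
psi / usage-fraction tests -> feature overlap and the intronic-site test ->
gene context (density/length) and enrichment -> sequence scans (microRNA
seeds, k-mer motifs) -> differential expression and cross-analyses. Every
stage is a plain function over in-memory objects; :func:`run` composes them
from a :class:`PipelineConfig` and writes the result TSVs plus a manifest.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    GenomeAnnotation, fetch_sequence, read_abundance, read_design, read_end_reads,
    read_gtf, revcomp, write_results,
)
from .pac_calling import (
    PAC, cluster_ends, count_pac_reads, deduplicate, filter_internal_priming,
    pac_count_matrix, pacs_to_bed,
)
from .apa_quant import (
    build_isoform_sets, merge_pas_evidence, quantify_usage, test_differential_psi,
    test_differential_usage_fractions, usage_shift_vs_position,
)
from .genomic_context import (
    context_vs_outcome, fisher_enrichment, intronic_pas_test, neighbor_density,
    overlap_features, upset_counts,
)
from .seq_scan import (
    extract_interpas_regions, kmer_enrichment, mirna_enrichment, pas_windows,
    read_mirna_fasta, scan_seed_sites,
)
from .diffexpr import aggregate_gene_tpm, beta_vs_delta_psi, biotype_summary, estimate_beta_and_test

logger = logging.getLogger("pasflux")

__all__ = ["PipelineConfig", "PipelineError", "run", "load_pacs"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run (flat YAML on disk)."""

    gtf: str = ""
    genome: str = ""
    end_read_beds: dict = field(default_factory=dict)  # sample -> BED path
    abundance: str = ""
    design: str = ""
    mirnas: str = ""
    # parameters (each default documented in its module)
    max_gap: int = 24
    min_reads: int = 2
    internal_priming_filter: bool = True
    merge_window: int = 25
    downstream_extension: int = 5000
    min_expr: float = 1.0
    alpha: float = 0.05
    k: int = 6
    flank: int = 50
    pseudocount: float = 0.5
    neighbor_k: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate_paths(self) -> None:
        missing = [p for p in [self.gtf, self.genome, self.abundance, self.design,
                               *self.end_read_beds.values()]
                   if p and not os.path.exists(p)]
        if self.mirnas and not os.path.exists(self.mirnas):
            missing.append(self.mirnas)
        if missing:
            raise PipelineError(f"missing input paths: {missing}")
        if not 0 < self.alpha < 1:
            raise PipelineError(f"alpha must be in (0, 1), got {self.alpha}")


def _load_genome(path: str):
    import pyfaidx

    return pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)


def load_pacs(out_dir: str) -> list[PAC]:
    """Rehydrate PACs from a previous call-pacs stage (pacs.bed + counts)."""
    bed = pd.read_csv(os.path.join(out_dir, "pacs.bed"), sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    counts = pd.read_csv(os.path.join(out_dir, "pac_counts.tsv"), sep="\t")
    samples = [c for c in counts.columns if c not in ("pac_id", "chrom", "strand", "summit")]
    counts = counts.set_index("pac_id")
    pacs = []
    for r in bed.itertuples(index=False):
        row = counts.loc[r.name]
        cdict = {s: int(row[s]) for s in samples if row[s] > 0}
        pacs.append(PAC(pac_id=r.name, chrom=r.chrom, strand=r.strand, start=int(r.start),
                        end=int(r.end), summit=int(row["summit"]), total=int(r.score),
                        counts=cdict))
    return pacs


# ---------------------------------------------------------------------------
# stages (in-memory)
# ---------------------------------------------------------------------------

def stage_call_pacs(config: PipelineConfig, genome, reads_by_sample: dict) -> dict:
    dedup = {s: deduplicate(frame) for s, frame in reads_by_sample.items()}
    n_dedup = sum(len(f) for f in dedup.values())
    if config.internal_priming_filter:
        filtered, n_flagged = {}, 0
        for s, frame in dedup.items():
            kept, flagged = filter_internal_priming(frame, genome)
            filtered[s] = kept
            n_flagged += len(flagged)
    else:
        filtered, n_flagged = dedup, 0
    pooled = pd.concat(filtered.values(), ignore_index=True) if filtered else pd.DataFrame()
    pacs = cluster_ends(pooled, max_gap=config.max_gap, min_reads=config.min_reads)
    unassigned = count_pac_reads(pacs, filtered)
    logger.info("call_pacs: %d dedup reads, %d flagged as internal priming, %d PACs",
                n_dedup, n_flagged, len(pacs))
    return {"pacs": pacs, "reads": filtered, "unassigned": unassigned,
            "n_dedup": n_dedup, "n_flagged": n_flagged}


def stage_quantify(config: PipelineConfig, annotation: GenomeAnnotation, pacs: list[PAC],
                   abundance: pd.DataFrame, design: pd.DataFrame) -> dict:
    candidates, merge_log = merge_pas_evidence(
        annotation, pacs, merge_window=config.merge_window,
        downstream_extension=config.downstream_extension)
    isoform_sets, skipped = build_isoform_sets(candidates, annotation)
    usage = quantify_usage(
        isoform_sets, design, abundance=abundance, annotation=annotation,
        mode="transcript_tpm", merge_window=config.merge_window, min_expr=config.min_expr)
    gene_results = test_differential_psi(usage, design, alpha=config.alpha)
    pas_results = test_differential_usage_fractions(usage, design, alpha=config.alpha)
    rho, p = usage_shift_vs_position(gene_results, pas_results, alpha=config.alpha)
    logger.info("quantify: %d isoform sets (%d single-PAS genes skipped), "
                "%d genes tested, usage-vs-position rho=%.3f", len(isoform_sets),
                len(skipped), len(gene_results), rho if np.isfinite(rho) else float("nan"))
    return {"isoform_sets": isoform_sets, "skipped": skipped, "usage": usage,
            "gene_results": gene_results, "pas_results": pas_results,
            "usage_position_rho": rho, "usage_position_p": p, "merge_log": merge_log}


def _shift_class(gene_results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    sig = (gene_results["p_adjusted"] <= alpha) & (gene_results["delta_psi"] != 0)
    cls = np.where(sig & (gene_results["delta_psi"] > 0), "distal_shifted",
                   np.where(sig & (gene_results["delta_psi"] < 0), "proximal_shifted", "unchanged"))
    return pd.DataFrame({"gene_id": gene_results["gene_id"], "shift_class": cls})


def stage_context(config: PipelineConfig, annotation: GenomeAnnotation, pacs: list[PAC],
                  quant: dict, expression: pd.DataFrame, design: pd.DataFrame) -> dict:
    alpha = config.alpha
    gene_results, pas_results = quant["gene_results"], quant["pas_results"]
    sig_genes = set(gene_results.loc[
        (gene_results["p_adjusted"] <= alpha) & (gene_results["delta_psi"] != 0), "gene_id"])
    pas_sig = pas_results[(pas_results["gene_id"].isin(sig_genes))
                          & (pas_results["change"] != "unchanged")]
    pas_lookup = quant["usage"].pas_table.set_index("pas_id")

    overlap_rows, upsets = [], {}
    for direction in ("increased", "decreased"):
        sub = pas_sig[pas_sig["change"] == direction]
        ovs = []
        for r in sub.itertuples(index=False):
            position = int(pas_lookup.loc[r.pas_id, "position"])
            ov = overlap_features(r.pas_id, position, r.gene_id, annotation,
                                  downstream_extension=config.downstream_extension)
            ovs.append(ov)
            overlap_rows.append({
                "pas_id": r.pas_id, "gene_id": r.gene_id, "direction": direction,
                "features": "+".join(sorted(ov.features)) or "none",
                "cds_or_intron_only": ov.cds_or_intron_only,
                "flagged_outside": ov.flagged_outside,
            })
        up = upset_counts(ovs)
        up.insert(0, "direction", direction)
        upsets[direction] = up
    feature_overlap = pd.DataFrame(overlap_rows, columns=[
        "pas_id", "gene_id", "direction", "features", "cds_or_intron_only", "flagged_outside"])
    upset = pd.concat(upsets.values(), ignore_index=True) if upsets else pd.DataFrame()

    intronic = intronic_pas_test(pacs, annotation, design,
                                 downstream_extension=config.downstream_extension, alpha=alpha)

    # expressed-and-polyadenylated neighbor pool
    from .apa_quant import assign_pacs_to_genes

    assignment, _ = assign_pacs_to_genes(annotation, pacs, config.downstream_extension)
    with_pac = set(assignment.values())
    expressed = set(expression["gene_id"])
    eligible = expressed & with_pac
    contexts = neighbor_density(annotation, eligible, k=config.neighbor_k)
    classes = _shift_class(gene_results, alpha)
    ctx_out = contexts.merge(classes, on="gene_id", how="left")
    ctx_out["shift_class"] = ctx_out["shift_class"].fillna("not_tested")

    outcome = expression[["gene_id", "beta"]].merge(classes, on="gene_id", how="left")
    outcome["shift_class"] = outcome["shift_class"].fillna("not_tested")
    outcome = outcome[outcome["shift_class"] != "not_tested"]
    coding = {g.id for g in annotation.genes.values() if g.biotype == "protein_coding"}
    noncoding = {g.id for g in annotation.genes.values() if g.biotype != "protein_coding"}
    correlations, comparisons = context_vs_outcome(
        contexts, outcome, value_col="beta", class_col="shift_class",
        groups={"protein_coding": coding, "noncoding": noncoding})

    # enrichment of DE classes among shifted genes, over the expressed universe
    universe = expressed
    enr_rows = []
    for shift in ("distal_shifted", "proximal_shifted"):
        shifted_ids = set(classes.loc[classes["shift_class"] == shift, "gene_id"]) & universe
        for de_class in ("up", "down"):
            de_ids = set(expression.loc[expression["de_class"] == de_class, "gene_id"])
            res = fisher_enrichment(shifted_ids, de_ids, universe)
            enr_rows.append({
                "shift_class": shift, "de_class": de_class,
                "n_overlap": int(res.table[0, 0]), "n_shifted": len(shifted_ids),
                "n_de": len(de_ids & universe), "n_universe": len(universe),
                "odds_ratio": res.odds_ratio, "p": res.p,
            })
    enrichment = pd.DataFrame(enr_rows)
    logger.info("context: %d intronic sites tested, %d eligible neighbor genes",
                len(intronic), len(eligible))
    return {"feature_overlap": feature_overlap, "upset": upset, "intronic": intronic,
            "gene_context": ctx_out, "correlations": correlations,
            "comparisons": comparisons, "enrichment": enrichment, "classes": classes}


def _utr3_sequence(gene, genome) -> str:
    """Sense-strand 3'UTR of the gene's most distal transcript."""
    tx = max(gene.transcripts, key=lambda t: t.end if gene.strand == "+" else -t.start)
    utr = tx.derived_utr3()
    if not utr:
        return ""
    parts = [fetch_sequence(genome, gene.chrom, s, e) for s, e in utr]
    seq = "".join(parts)
    return seq if gene.strand == "+" else revcomp(seq)


def stage_scan(config: PipelineConfig, annotation: GenomeAnnotation, genome,
               quant: dict, mirnas: dict, expression: pd.DataFrame) -> dict:
    alpha = config.alpha
    gene_results, pas_results = quant["gene_results"], quant["pas_results"]
    isoform_sets = quant["isoform_sets"]
    classes = _shift_class(gene_results, alpha)
    shifted = set(classes.loc[classes["shift_class"] != "unchanged", "gene_id"])

    hits_frames, summaries, enrich_frames = [], {}, []
    background = {}
    expressed = set(expression["gene_id"])
    for gid in sorted(expressed - shifted):
        gene = annotation.genes.get(gid)
        if gene is None or gene.biotype != "protein_coding":
            continue
        seq = _utr3_sequence(gene, genome)
        if seq:
            background[gid] = seq
    for direction in ("distal_shifted", "proximal_shifted"):
        regions, n_genes, n_excluded = extract_interpas_regions(
            isoform_sets, gene_results, pas_results, genome, direction, alpha=alpha)
        hits = scan_seed_sites(regions, mirnas)
        summaries[direction] = {
            **mirna_target_summary_compat(hits, regions),
            "n_candidate_genes": n_genes, "n_excluded": n_excluded,
        }
        hits_frames.append(pd.DataFrame(
            [{"direction": direction, "mirna_id": h.mirna_id, "gene_id": h.gene_id,
              "match_type": h.match_type, "offset": h.offset} for h in hits],
            columns=["direction", "mirna_id", "gene_id", "match_type", "offset"]))
        if regions and background:
            enr = mirna_enrichment(hits, regions, background, mirnas, alpha=alpha)
            enr.insert(0, "direction", direction)
            enrich_frames.append(enr)
    mirna_hits = pd.concat(hits_frames, ignore_index=True)
    mirna_enr = (pd.concat(enrich_frames, ignore_index=True)
                 if enrich_frames else pd.DataFrame())

    pas_lookup = quant["usage"].pas_table[["pas_id", "gene_id", "position"]]
    sig_pas = pas_results[(pas_results["gene_id"].isin(shifted))
                          & (pas_results["change"] != "unchanged")]
    bg_pas = pas_results[pas_results["change"] == "unchanged"]
    fg_frame = sig_pas.merge(pas_lookup, on=["pas_id", "gene_id"])
    bg_frame = bg_pas.merge(pas_lookup, on=["pas_id", "gene_id"])
    kmers = pd.DataFrame()
    if len(fg_frame) and len(bg_frame):
        fg_seqs = pas_windows(fg_frame, annotation, genome, flank=config.flank)
        bg_seqs = pas_windows(bg_frame, annotation, genome, flank=config.flank)
        kmers = kmer_enrichment(fg_seqs, bg_seqs, k=config.k, alpha=alpha)
    logger.info("scan: %d microRNA hits, %d k-mers tested", len(mirna_hits), len(kmers))
    return {"mirna_hits": mirna_hits, "mirna_enrichment": mirna_enr,
            "mirna_summaries": summaries, "kmer_enrichment": kmers}


def mirna_target_summary_compat(hits, regions) -> dict:
    from .seq_scan import mirna_target_summary

    summary = mirna_target_summary(hits, regions)
    summary.pop("targets_per_mirna", None)
    return summary


def stage_diffexpr(config: PipelineConfig, annotation: GenomeAnnotation,
                   abundance: pd.DataFrame, design: pd.DataFrame) -> dict:
    gene_matrix = aggregate_gene_tpm(abundance, annotation)
    expression = estimate_beta_and_test(
        gene_matrix, design, pseudocount=config.pseudocount,
        min_expr=config.min_expr, alpha=config.alpha)
    biotypes = biotype_summary(expression, annotation, alpha=config.alpha)
    logger.info("diffexpr: %d genes tested, %d up / %d down",
                len(expression), int((expression["de_class"] == "up").sum()),
                int((expression["de_class"] == "down").sum()))
    return {"gene_matrix": gene_matrix, "expression": expression, "biotypes": biotypes}


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def run(config: PipelineConfig, out_dir: str) -> dict:
    """Run every stage and write all result tables plus a manifest.

    Raises :class:`PipelineError` naming the failed stage; outputs of
    completed stages stay on disk, and files of the failed stage are
    renamed with a ``.partial`` suffix.
    """
    os.makedirs(out_dir, exist_ok=True)
    config.validate_paths()
    t0 = time.time()
    logger.info("pasflux %s, seed %d, out %s", __version__, config.seed, out_dir)

    annotation = read_gtf(config.gtf)
    genome = _load_genome(config.genome)
    design = read_design(config.design)
    abundance = read_abundance(config.abundance, design)
    reads = {s: read_end_reads(p, sample=s) for s, p in sorted(config.end_read_beds.items())}
    mirnas = read_mirna_fasta(config.mirnas) if config.mirnas else {}
    samples = design["sample_id"].tolist()

    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": asdict(config), "outputs": {}, "stages": {}}
    written_by_stage: dict[str, list[str]] = {}

    def emit(stage: str, tables: dict) -> None:
        paths = write_results(tables, out_dir)
        written_by_stage.setdefault(stage, []).extend(paths.values())
        for name, df in tables.items():
            manifest["outputs"][name] = int(len(df))

    def run_stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception as exc:
            for path in written_by_stage.get(name, []):
                if os.path.exists(path):
                    os.replace(path, path + ".partial")
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        manifest["stages"][name] = round(time.time() - t, 3)
        logger.info("stage %s done in %.2fs", name, time.time() - t)
        return result

    def _call_pacs():
        res = stage_call_pacs(config, genome, reads)
        emit("call_pacs", {"pacs.bed": pacs_to_bed(res["pacs"]),
                           "pac_counts.tsv": pac_count_matrix(res["pacs"], samples)})
        return res

    pac_res = run_stage("call_pacs", _call_pacs)

    def _quantify():
        res = stage_quantify(config, annotation, pac_res["pacs"], abundance, design)
        usage = res["usage"]
        emit("quantify", {
            "apa_isoforms.tsv": usage.pas_table,
            "psi_per_gene.tsv": usage.psi,
            "usage_per_pas.tsv": usage.usage,
            "differential_psi.tsv": res["gene_results"],
            "differential_usage.tsv": res["pas_results"],
        })
        return res

    quant = run_stage("quantify", _quantify)

    def _diffexpr():
        res = stage_diffexpr(config, annotation, abundance, design)
        emit("diffexpr", {"expression_results.tsv": res["expression"],
                          "biotype_summary.tsv": res["biotypes"]})
        return res

    de = run_stage("diffexpr", _diffexpr)

    def _context():
        res = stage_context(config, annotation, pac_res["pacs"], quant, de["expression"], design)
        emit("context", {
            "feature_overlap.tsv": res["feature_overlap"],
            "upset_counts.tsv": res["upset"],
            "intronic_sites.tsv": res["intronic"],
            "gene_context.tsv": res["gene_context"],
            "context_correlations.tsv": res["correlations"],
            "context_comparisons.tsv": res["comparisons"],
            "enrichment.tsv": res["enrichment"],
        })
        return res

    ctx = run_stage("context", _context)

    def _scan():
        res = stage_scan(config, annotation, genome, quant, mirnas, de["expression"])
        emit("scan", {
            "mirna_hits.tsv": res["mirna_hits"],
            "mirna_enrichment.tsv": res["mirna_enrichment"],
            "kmer_enrichment.tsv": res["kmer_enrichment"],
        })
        return res

    scan = run_stage("scan", _scan) if mirnas else {"mirna_summaries": {},
                                                   "kmer_enrichment": pd.DataFrame()}

    rho_beta, p_beta, _ = beta_vs_delta_psi(de["expression"], quant["gene_results"], config.alpha)
    summary = {
        "n_genes": len(annotation),
        "n_pacs": len(pac_res["pacs"]),
        "n_isoform_sets": len(quant["isoform_sets"]),
        "n_genes_tested": int(len(quant["gene_results"])),
        "n_significant_apa": int(quant["gene_results"]["significant"].sum()) if len(quant["gene_results"]) else 0,
        "usage_position_rho": quant["usage_position_rho"],
        "usage_position_p": quant["usage_position_p"],
        "beta_vs_delta_psi_rho": rho_beta,
        "beta_vs_delta_psi_p": p_beta,
        "n_de_up": int((de["expression"]["de_class"] == "up").sum()),
        "n_de_down": int((de["expression"]["de_class"] == "down").sum()),
        "mirna_summaries": scan["mirna_summaries"],
    }
    manifest["summary"] = summary
    manifest["runtime_s"] = round(time.time() - t0, 3)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return {"manifest": manifest, "pacs": pac_res, "quant": quant, "context": ctx,
            "scan": scan, "diffexpr": de, "summary": summary}


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
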