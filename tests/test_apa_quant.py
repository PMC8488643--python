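"""PAS merging, PPS/psi computation, and differential usage testing."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pasflux.apa_quant import (
    APAIsoformSet, PASite, build_isoform_sets, classify_position, merge_pas_evidence,
    quantify_usage, usage_shift_vs_position,
)
from pasflux.apa_quant import test_differential_psi as differential_psi
from pasflux.apa_quant import test_differential_usage_fractions as differential_usage
from pasflux.annotation_io import GenomeAnnotation
from pasflux.pac_calling import PAC
from pasflux.synthetic_data import SimConfig, simulate_abundances, simulate_truth, to_annotation
from conftest import abundance_long, make_gene, two_by_two_design


def single_exon_gene(gene_id, strand, ends, chrom="c", tss=None):
    """One transcript per 3' end; + strand TSS at 100, - strand TSS high."""
    if strand == "+":
        start = tss if tss is not None else 100
        exon_sets = [[(start, e + 1)] for e in ends]
    else:
        stop = (tss if tss is not None else max(ends) + 100) + 1
        exon_sets = [[(e, stop)] for e in ends]
    return make_gene(gene_id, chrom, strand, exon_sets)


def iso_set(gene_id, strand, positions, chrom="c"):
    order = sorted(positions, reverse=(strand == "-"))
    sites = [PASite(gene_id=gene_id, position=p, sources=frozenset({"reference"})) for p in order]
    return APAIsoformSet(gene_id=gene_id, chrom=chrom, strand=strand, sites=sites)


# ---------------------------------------------------------------------------
# PPS
# ---------------------------------------------------------------------------

def test_pps_plus_strand_three_sites():
    iso = iso_set("g", "+", [1000, 1500, 2000])
    assert iso.pps.tolist() == [0.0, 0.5, 1.0]
    assert [s.position for s in iso.sites] == [1000, 1500, 2000]


def test_pps_minus_strand_most_proximal_is_highest_coordinate():
    iso = iso_set("g", "-", [500, 300, 100])
    assert [s.position for s in iso.sites] == [500, 300, 100]
    assert iso.pps.tolist() == [0.0, 0.5, 1.0]  # PAS at 500 is proximal on -


@pytest.mark.parametrize("n,m,expected", [(5, 3, 0.75), (2, 0, 0.0), (2, 1, 1.0), (4, 2, 2 / 3)])
def test_pps_formula(n, m, expected):
    iso = iso_set("g", "+", [100 * (i + 1) for i in range(n)])
    assert iso.pps[m] == pytest.approx(expected)


@pytest.mark.parametrize("n,m,expected", [
    (4, 0, "most_proximal"), (4, 3, "most_distal"), (4, 1, "middle"),
    (2, 0, "most_proximal"), (2, 1, "most_distal"),
])
def test_position_classes(n, m, expected):
    assert classify_position(m, n) == expected


# ---------------------------------------------------------------------------
# merging evidence
# ---------------------------------------------------------------------------

def pac(pac_id, summit, strand="+", chrom="c", total=10):
    return PAC(pac_id=pac_id, chrom=chrom, strand=strand, start=summit - 2,
               end=summit + 3, summit=summit, total=total)


def test_merge_collapses_reference_and_pac_within_window():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000])])
    merged, _ = merge_pas_evidence(ann, [pac("P1", 1010)], merge_window=25)
    sites = merged["g"]
    assert len(sites) == 1
    assert sites[0].position == 1010  # PAC summit represents the merged site
    assert sites[0].sources == frozenset({"reference", "pac"})


def test_merge_keeps_distant_reference_ends_apart():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500])])
    merged, _ = merge_pas_evidence(ann, [])
    assert [s.position for s in merged["g"]] == [1000, 1500]


def test_pac_within_downstream_extension_is_assigned():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000])])
    merged, _ = merge_pas_evidence(ann, [pac("P1", 4000)], downstream_extension=5000)
    assert [s.position for s in merged["g"]] == [1000, 4000]
    merged, _ = merge_pas_evidence(ann, [pac("P1", 7000)], downstream_extension=5000)
    assert [s.position for s in merged["g"]] == [1000]


def test_ambiguous_pac_goes_to_nearest_span_end():
    g1 = single_exon_gene("g1", "+", [1000])
    g2 = single_exon_gene("g2", "+", [3000], tss=2000)
    ann = GenomeAnnotation([g1, g2])
    # summit 2500 is inside g2's span and within g1's 5 kb extension
    merged, log = merge_pas_evidence(ann, [pac("P1", 2500)])
    assert any(s.pac_id == "P1" for s in merged["g2"])
    assert all(s.pac_id != "P1" for s in merged["g1"])
    assert any("P1" in line for line in log)


def test_single_pas_genes_are_skipped():
    ann = GenomeAnnotation([single_exon_gene("g1", "+", [1000]),
                            single_exon_gene("g2", "+", [1000, 1500], tss=50)])
    merged, _ = merge_pas_evidence(ann, [])
    sets, skipped = build_isoform_sets(merged, ann)
    assert [s.gene_id for s in sets] == ["g2"]
    assert skipped == ["g1"]


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantified(ann, tpm_by_transcript, design=None):
    design = design if design is not None else two_by_two_design()
    rows = []
    for tid, tpms in tpm_by_transcript.items():
        for sample, v in zip(design["sample_id"], tpms):
            rows.append((tid, sample, v))
    merged, _ = merge_pas_evidence(ann, [])
    sets, _ = build_isoform_sets(merged, ann)
    return quantify_usage(sets, design, abundance=abundance_long(rows), annotation=ann)


def test_psi_hand_computed_fixture():
    """TPM (3, 1, 4) at PPS (0, 0.5, 1) -> psi = 0.5625, the weighted mean."""
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500, 2000])])
    um = quantified(ann, {"g.t0": [3] * 4, "g.t1": [1] * 4, "g.t2": [4] * 4})
    psi = um.psi["psi"].unique()
    assert psi == pytest.approx([0.5625])
    # independent oracle: direct weighted mean
    assert np.average([0, 0.5, 1], weights=[3, 1, 4]) == pytest.approx(0.5625)


def test_psi_equal_split_and_all_distal():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500])])
    um = quantified(ann, {"g.t0": [10] * 4, "g.t1": [10] * 4})
    assert um.psi["psi"].unique() == pytest.approx([0.5])
    um = quantified(ann, {"g.t0": [0] * 4, "g.t1": [5] * 4})
    assert um.psi["psi"].unique() == pytest.approx([1.0])


def test_usage_fractions_sum_to_one():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500, 2000])])
    um = quantified(ann, {"g.t0": [3, 2, 1, 5], "g.t1": [1, 1, 1, 1], "g.t2": [4, 2, 1, 3]})
    sums = um.usage.groupby(["gene_id", "sample"])["usage_fraction"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_low_expression_gene_dropped():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500])])
    # both conditions have a sample below min_expr=1
    um = quantified(ann, {"g.t0": [0.2, 5, 0.2, 5], "g.t1": [0.2, 5, 0.2, 5]})
    assert um.dropped_genes == ["g"]
    # one condition fully >= min_expr -> kept
    um = quantified(ann, {"g.t0": [2, 5, 0.1, 5], "g.t1": [2, 5, 0.1, 5]})
    assert um.dropped_genes == []


def test_far_transcript_excluded():
    gene = make_gene("g", "c", "+", exon_sets=[[(100, 1001)], [(100, 1501)], [(100, 1101)]])
    ann = GenomeAnnotation([gene])
    merged, _ = merge_pas_evidence(ann, [], merge_window=25)
    # ends 1000, 1100, 1500 -> three PASs; map a transcript exactly
    sets, _ = build_isoform_sets(merged, ann)
    um = quantify_usage(sets, two_by_two_design(),
                        abundance=abundance_long([(f"g.t{i}", s, 1.0)
                                                  for i in range(3)
                                                  for s in two_by_two_design()["sample_id"]]),
                        annotation=ann, merge_window=25)
    assert um.excluded_transcripts == []  # all ends coincide with PASs


# ---------------------------------------------------------------------------
# differential tests
# ---------------------------------------------------------------------------

def test_identical_replicates_give_p_one_and_zero_delta():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500])])
    um = quantified(ann, {"g.t0": [3] * 4, "g.t1": [7] * 4})
    res = differential_psi(um, two_by_two_design())
    assert res["delta_psi"].tolist() == [0.0]
    assert res["p"].tolist() == [1.0]
    pas = differential_usage(um, two_by_two_design())
    assert (pas["change"] == "unchanged").all()
    assert np.allclose(pas["delta_usage"], 0.0)


def test_delta_clipping_affects_report_column_only():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500])])
    # control fully proximal, mutant mostly distal: delta psi = +0.8
    um = quantified(ann, {"g.t0": [10, 10, 2, 2], "g.t1": [0.01, 0.01, 8, 8]})
    res = differential_psi(um, two_by_two_design())
    assert res["delta_psi"].iloc[0] > 0.2
    assert res["delta_psi_clipped"].iloc[0] == pytest.approx(0.2)
    pas = differential_usage(um, two_by_two_design())
    distal = pas[pas["m"] == 1].iloc[0]
    assert distal["delta_usage"] > 0.2
    assert distal["delta_usage_clipped"] == pytest.approx(0.2)


def test_zero_variance_unequal_means_uses_permutation_fallback():
    ann = GenomeAnnotation([single_exon_gene("g", "+", [1000, 1500])])
    um = quantified(ann, {"g.t0": [10, 10, 5, 5], "g.t1": [10, 10, 15, 15]})
    res = differential_psi(um, two_by_two_design())
    # exact enumeration of C(4,2)=6 labelings; both extremes reach |diff|
    assert res["p"].iloc[0] == pytest.approx(2 / 6)


def test_two_pas_sign_consistency():
    """For two-PAS genes, sign(delta psi) == sign(delta usage of distal PAS)."""
    rng = np.random.default_rng(3)
    design = two_by_two_design()
    ann = GenomeAnnotation([single_exon_gene(f"g{i}", "+", [1000, 1500], tss=10)
                            for i in range(20)])
    rows = []
    for i in range(20):
        for s in design["sample_id"]:
            a, b = rng.uniform(1, 10, size=2)
            rows.append((f"g{i}.t0", s, a))
            rows.append((f"g{i}.t1", s, b))
    merged, _ = merge_pas_evidence(ann, [])
    sets, _ = build_isoform_sets(merged, ann)
    um = quantify_usage(sets, design, abundance=abundance_long(rows), annotation=ann)
    gene = differential_psi(um, design).set_index("gene_id")
    pas = differential_usage(um, design)
    distal = pas[pas["m"] == 1].set_index("gene_id")
    for gid in gene.index:
        assert np.sign(gene.loc[gid, "delta_psi"]) == np.sign(distal.loc[gid, "delta_usage"])
        # fractions of a two-PAS gene mirror exactly
        prox = pas[(pas["gene_id"] == gid) & (pas["m"] == 0)]["delta_usage"].iloc[0]
        assert prox == pytest.approx(-distal.loc[gid, "delta_usage"])


def test_planted_shift_recovery_with_tight_noise():
    """delta psi = +0.15 at n = 3 vs 3, sigma_psi = 0.02: detected with the
    correct sign for >= 90% of planted genes."""
    cfg = SimConfig(seed=11, n_genes=150, n_shifted=60, frac_distal=1.0)
    truth = simulate_truth(cfg)
    ann = to_annotation(truth)
    wide = simulate_abundances(truth)
    rows = []
    for s in truth.design["sample_id"]:
        for tid, tpm in zip(wide["transcript_id"], wide[f"{s}_tpm"]):
            rows.append((tid, s, tpm))
    merged, _ = merge_pas_evidence(ann, [])
    sets, _ = build_isoform_sets(merged, ann)
    um = quantify_usage(sets, truth.design, abundance=abundance_long(rows), annotation=ann)
    res = differential_psi(um, truth.design)
    planted = set(truth.table.loc[truth.table["planted_shift"], "gene_id"])
    hits = res[res["gene_id"].isin(planted)]
    detected = hits[hits["significant"]]
    assert len(detected) / len(planted) >= 0.9
    assert (detected["delta_psi"] > 0).mean() >= 0.9


# ---------------------------------------------------------------------------
# usage shift vs position
# ---------------------------------------------------------------------------

def _fake_results(delta_by_pps):
    gene = pd.DataFrame({"gene_id": ["g"], "delta_psi": [0.2], "p_adjusted": [0.01]})
    pas = pd.DataFrame({
        "gene_id": "g", "pas_id": [f"g@{i}" for i in range(len(delta_by_pps))],
        "pps": list(delta_by_pps), "delta_usage": [delta_by_pps[p] for p in delta_by_pps],
    })
    return gene, pas


def test_usage_shift_monotone_extremes():
    pps = np.linspace(0, 1, 8)
    gene, pas = _fake_results({p: p * 0.1 for p in pps})
    assert usage_shift_vs_position(gene, pas)[0] == pytest.approx(1.0)
    gene, pas = _fake_results({p: -p * 0.1 for p in pps})
    assert usage_shift_vs_position(gene, pas)[0] == pytest.approx(-1.0)


def test_usage_shift_matches_rank_oracle():
    rng = np.random.default_rng(4)
    pps = np.linspace(0, 1, 40)
    deltas = rng.permutation(np.linspace(-0.1, 0.1, 40))
    gene, pas = _fake_results(dict(zip(pps, deltas)))
    rho, _ = usage_shift_vs_position(gene, pas)
    # independent oracle: Pearson correlation of average ranks
    ranks_x = stats.rankdata(pps)
    ranks_y = stats.rankdata(deltas)
    oracle = np.corrcoef(ranks_x, ranks_y)[0, 1]
    assert abs(rho - oracle) < 1e-12
    assert abs(rho) < 0.5


def test_usage_shift_undefined_below_three_points():
    gene, pas = _fake_results({0.0: 0.1, 1.0: -0.1})
    rho, p = usage_shift_vs_position(gene, pas)
    assert np.isnan(rho) and np.isnan(p)
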