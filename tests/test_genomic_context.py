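"""Feature overlap, intronic-site testing, neighbor density, enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pasflux.annotation_io import GenomeAnnotation
from pasflux.genomic_context import (
    FeatureOverlap, context_vs_outcome, fisher_enrichment, intronic_pas_test,
    neighbor_density, neighbor_orientation, overlap_features, upset_counts,
)
from pasflux._stats import fisher_exact_two_sided
from pasflux.pac_calling import PAC
from conftest import make_gene, two_by_two_design


@pytest.fixture
def coding_gene_annotation():
    # exon1 [100,300), intron [300,600), exon2 [600,1200); CDS to 800 -> 3'UTR [800,1200)
    gene = make_gene("g", "c", "+",
                     exon_sets=[[(100, 300), (600, 1200)]],
                     cds=[[(150, 300), (600, 800)]])
    return GenomeAnnotation([gene])


def test_overlap_utr_cds_intron(coding_gene_annotation):
    ann = coding_gene_annotation
    assert overlap_features("p1", 1000, "g", ann).features == frozenset({"three_prime_utr"})
    ov = overlap_features("p2", 700, "g", ann)
    assert ov.features == frozenset({"cds"})
    assert ov.cds_or_intron_only
    ov = overlap_features("p3", 450, "g", ann)
    assert ov.features == frozenset({"intron"})
    assert ov.cds_or_intron_only
    # window straddling the CDS/UTR border picks up both
    ov = overlap_features("p4", 805, "g", ann)
    assert ov.features == frozenset({"cds", "three_prime_utr"})
    assert not ov.cds_or_intron_only


def test_overlap_noncoding_transcript():
    gene = make_gene("ng", "c", "+", exon_sets=[[(100, 500)]], biotype="lincRNA")
    ann = GenomeAnnotation([gene])
    ov = overlap_features("p", 300, "ng", ann)
    assert ov.features == frozenset({"noncoding_transcript"})
    assert not ov.cds_or_intron_only


def test_overlap_outside_span_is_flagged(coding_gene_annotation):
    ov = overlap_features("p", 50_000, "g", coding_gene_annotation, downstream_extension=5000)
    assert ov.features == frozenset()
    assert ov.flagged_outside


def test_upset_counts_conserve_total():
    overlaps = [
        FeatureOverlap("a", frozenset({"three_prime_utr"})),
        FeatureOverlap("b", frozenset({"three_prime_utr"})),
        FeatureOverlap("c", frozenset({"three_prime_utr"})),
        FeatureOverlap("d", frozenset({"cds", "intron"})),
        FeatureOverlap("e", frozenset()),
    ]
    counts = upset_counts(overlaps)
    assert counts["count"].sum() == 5
    assert counts.set_index("combination").loc["three_prime_utr", "count"] == 3
    assert bool(counts.set_index("combination").loc["cds+intron", "cds_or_intron_only"])
    assert len(upset_counts([])) == 0


def _intron_gene(gene_id="g", chrom="c"):
    return make_gene(gene_id, chrom, "+", exon_sets=[[(100, 300), (900, 1500)]])


def _pac(pac_id, start, end, summit, counts, chrom="c", strand="+"):
    total = sum(counts.values())
    return PAC(pac_id=pac_id, chrom=chrom, strand=strand, start=start, end=end,
               summit=summit, total=total, counts=counts)


def test_intronic_site_symmetric_table_p_one():
    ann = GenomeAnnotation([_intron_gene()])
    design = two_by_two_design()
    intronic = _pac("I", 500, 520, 510, {"control_1": 3, "control_2": 2, "mutant_1": 3, "mutant_2": 2})
    terminal = _pac("T", 1480, 1500, 1490, {"control_1": 3, "control_2": 2, "mutant_1": 3, "mutant_2": 2})
    res = intronic_pas_test([intronic, terminal], ann, design)
    assert len(res) == 1
    assert res["p"].iloc[0] == pytest.approx(1.0)
    assert not res["differential"].iloc[0]


def test_intronic_site_zero_reads_not_differential():
    ann = GenomeAnnotation([_intron_gene()])
    design = two_by_two_design()
    intronic = _pac("I", 500, 520, 510, {})
    terminal = _pac("T", 1480, 1500, 1490, {"control_1": 5, "mutant_1": 5})
    res = intronic_pas_test([intronic, terminal], ann, design)
    assert res["p"].iloc[0] == 1.0


def test_intronic_null_simulation_controls_discoveries():
    """200 Poisson-null intronic sites yield (almost) no BH discoveries."""
    rng = np.random.default_rng(5)
    genes, pacs = [], []
    design = two_by_two_design()
    samples = design["sample_id"].tolist()
    for i in range(200):
        base = 10_000 * i
        genes.append(make_gene(f"g{i}", "c", "+",
                               exon_sets=[[(base + 100, base + 300), (base + 900, base + 1500)]]))
        site = {s: int(rng.poisson(5)) for s in samples}
        other = {s: int(rng.poisson(50)) for s in samples}
        pacs.append(_pac(f"I{i}", base + 500, base + 520, base + 510, site))
        pacs.append(_pac(f"T{i}", base + 1480, base + 1500, base + 1490, other))
    res = intronic_pas_test(pacs, GenomeAnnotation(genes), design)
    assert len(res) == 200
    assert res["differential"].sum() <= 2


def _spaced_annotation(spans, strands=None):
    genes = []
    for i, (s, e) in enumerate(spans):
        strand = strands[i] if strands else "+"
        if strand == "+":
            genes.append(make_gene(f"g{i}", "c", "+", exon_sets=[[(s, e)]]))
        else:
            genes.append(make_gene(f"g{i}", "c", "-", exon_sets=[[(s, e)]]))
    return GenomeAnnotation(genes)


def test_neighbor_density_worked_example():
    ann = _spaced_annotation([(0, 100), (200, 300), (1000, 1100)])
    res = neighbor_density(ann, ["g0", "g1", "g2"], k=2).set_index("gene_id")
    assert res.loc["g1", "mean_neighbor_distance"] == pytest.approx((100 + 700) / 2)
    # k = 1 reduces to nearest neighbor
    res1 = neighbor_density(ann, ["g0", "g1", "g2"], k=1).set_index("gene_id")
    assert res1.loc["g1", "mean_neighbor_distance"] == pytest.approx(100)


def test_neighbor_density_overlap_counts_zero_and_flags():
    ann = _spaced_annotation([(0, 100), (50, 150)])
    res = neighbor_density(ann, ["g0", "g1"], k=10).set_index("gene_id")
    assert res.loc["g0", "mean_neighbor_distance"] == 0.0
    assert bool(res.loc["g0", "flagged"])  # fewer than k neighbors available
    lonely = neighbor_density(ann, ["g0"], k=2).set_index("gene_id")
    assert np.isnan(lonely.loc["g0", "mean_neighbor_distance"])


def test_neighbor_density_matches_all_pairs_oracle():
    rng = np.random.default_rng(6)
    starts = np.sort(rng.choice(np.arange(0, 500_000, 50), size=200, replace=False))
    spans = [(int(s), int(s + rng.integers(100, 5000))) for s in starts]
    ann = _spaced_annotation(spans)
    ids = [f"g{i}" for i in range(200)]
    res = neighbor_density(ann, ids, k=10).set_index("gene_id")
    for i, (s, e) in enumerate(spans):
        dists = sorted(
            max(0, s2 - e, s - e2) for j, (s2, e2) in enumerate(spans) if j != i
        )[:10]
        assert res.loc[f"g{i}", "mean_neighbor_distance"] == pytest.approx(np.mean(dists))
    # symmetry of the metric
    d01 = max(0, spans[1][0] - spans[0][1], spans[0][0] - spans[1][1])
    d10 = max(0, spans[0][0] - spans[1][1], spans[1][0] - spans[0][1])
    assert d01 == d10


@pytest.mark.parametrize("gene_strand,neighbor_strand,expect_side,expect_orient", [
    ("+", "-", "downstream", "transcribed_toward"),
    ("+", "+", "downstream", "transcribed_away"),
    ("-", "+", "upstream", "transcribed_away"),
])
def test_neighbor_orientation_geometry(gene_strand, neighbor_strand, expect_side, expect_orient):
    ann = _spaced_annotation([(0, 100), (500, 600)], strands=[gene_strand, neighbor_strand])
    res = neighbor_orientation(ann, "g0", ["g1"]).iloc[0]
    assert res["side"] == expect_side
    assert res["orientation"] == expect_orient


def test_neighbor_orientation_mirrored_configuration():
    plus = _spaced_annotation([(0, 100), (500, 600)], strands=["+", "-"])
    minus = _spaced_annotation([(500, 600), (0, 100)], strands=["-", "+"])
    a = neighbor_orientation(plus, "g0", ["g1"]).iloc[0]
    b = neighbor_orientation(minus, "g0", ["g1"]).iloc[0]
    assert (a["side"], a["orientation"]) == (b["side"], b["orientation"])


def test_context_correlation_extremes():
    n = 50
    lengths = np.linspace(1000, 100_000, n)
    contexts = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "length": lengths,
        "mean_neighbor_distance": np.linspace(100, 5000, n),
    })
    outcomes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "beta": np.log10(lengths),   # strictly increasing with log length
        "cls": ["a"] * 25 + ["b"] * 25,
    })
    corr, comp = context_vs_outcome(contexts, outcomes, class_col="cls")
    rho = corr.set_index(["variable", "subset"]).loc[("log10_length", "all"), "rho"]
    assert rho == pytest.approx(1.0)
    # identical length distributions in both classes -> MW p near 1
    contexts2 = contexts.copy()
    contexts2["length"] = np.tile(np.linspace(1e3, 1e4, 25), 2)
    _, comp2 = context_vs_outcome(contexts2, outcomes, class_col="cls")
    p = comp2.set_index("variable").loc["log10_length", "p"]
    assert p > 0.9


def test_fisher_examples_and_oracle():
    _, p = fisher_exact_two_sided(5, 5, 5, 5)
    assert p == pytest.approx(1.0)
    rng = np.random.default_rng(7)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 26, 4))
        mine = fisher_exact_two_sided(a, b, c, d)[1]
        oracle = sps.fisher_exact([[a, b], [c, d]])[1]
        assert abs(mine - oracle) < 1e-12


def test_fisher_enrichment_nested_sets_reach_minimal_p():
    universe = [f"x{i}" for i in range(20)]
    half = universe[:10]
    res = fisher_enrichment(half, half, universe)
    # hypergeometric oracle: both extreme tables (a=10 and a=0) are equally
    # likely under these symmetric margins, so the two-sided p sums both
    oracle = sps.hypergeom.pmf(10, 20, 10, 10) + sps.hypergeom.pmf(0, 20, 10, 10)
    assert res.p == pytest.approx(oracle, abs=1e-12)
    assert res.table.tolist() == [[10, 0], [0, 10]]
    with pytest.raises(ValueError):
        fisher_enrichment(half, half, [])


def test_fisher_null_calibration():
    """Independent random sets: rejection rate at 0.05 stays near nominal."""
    rng = np.random.default_rng(8)
    universe = list(range(200))
    rejections = 0
    reps = 300
    for _ in range(reps):
        a = set(rng.choice(universe, 50, replace=False).tolist())
        b = set(rng.choice(universe, 50, replace=False).tolist())
        if fisher_enrichment(a, b, universe).p <= 0.05:
            rejections += 1
    assert rejections / reps <= 0.08  # Fisher is conservative; never anti-conservative
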