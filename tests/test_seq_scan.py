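"""MicroRNA seed scanning and k-mer enrichment."""
import numpy as np
import pytest

from pasflux.annotation_io import revcomp
from pasflux.seq_scan import (
    InterPasRegion, extract_interpas_regions, kmer_enrichment, mirna_enrichment,
    mirna_target_summary, scan_seed_sites, seed_sites,
)
from pasflux.apa_quant import APAIsoformSet, PASite
import pandas as pd

MIR = "UGAGGUAGUAGGUUGUAUAGUU"  # 22-nt let-7-like sequence
SEED7 = MIR.replace("U", "T")[1:8]          # GAGGTAG
SITE_M8 = revcomp(SEED7)                    # CTACCTC
SITE_A1 = revcomp(MIR.replace("U", "T")[1:7]) + "A"


def region(seq, gene_id="g"):
    return InterPasRegion(gene_id=gene_id, chrom="c", strand="+", start=0,
                          end=len(seq), sequence=seq)


def test_seed_match_types():
    pad = "GCGCGCGCGC"
    assert seed_sites(pad + SITE_M8 + "G" + pad, MIR) == [(10, "7mer_m8")]
    assert seed_sites(pad + SITE_M8 + "A" + pad, MIR) == [(10, "8mer")]
    # pad must not end in C, which would complete the full seed match
    assert seed_sites("G" * 10 + SITE_A1 + pad, MIR) == [(10, "7mer_A1")]
    assert seed_sites("GCGC" * 10, MIR) == []


def test_seed_sites_count_once_per_offset():
    seq = "GC" + SITE_M8 + "A" + "GC" + SITE_M8 + "G" + "GC"
    hits = seed_sites(seq, MIR)
    assert [t for _, t in hits] == ["8mer", "7mer_m8"]


def test_antisense_plant_produces_no_hits():
    """A site planted only on the antisense strand must not match: the scan
    is strand-aware because regions are sense-strand sequences."""
    sense_site = SITE_M8
    antisense_seq = revcomp("GCGC" + sense_site + "GCGC")
    assert seed_sites(antisense_seq, MIR) == []


def test_scan_matches_naive_oracle():
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))
    for _ in range(100):
        seq = "".join(rng.choice(bases, size=200))
        mir = "".join(rng.choice(bases, size=22))
        got = dict(seed_sites(seq, mir))
        # naive oracle: test every offset against the site definitions
        m8 = revcomp(mir[1:8])
        a1 = revcomp(mir[1:7]) + "A"
        expected = {}
        for off in range(len(seq) - 6):
            window7 = seq[off: off + 7]
            if window7 == m8:
                expected[off] = "8mer" if seq[off + 7: off + 8] == "A" else "7mer_m8"
        for off in range(len(seq) - 6):
            if seq[off: off + 7] == a1 and off not in expected:
                if not (off - 1 in expected and expected[off - 1] == "8mer"):
                    expected[off] = "7mer_A1"
        assert got == expected


def test_short_mirna_skipped_with_warning():
    with pytest.warns(UserWarning, match="shorter"):
        hits = scan_seed_sites([region("ACGT" * 30)], {"tiny": "ACGUACG"})
    assert hits == []


def test_target_summary_counts():
    regions = [region("GC" + SITE_M8 + "G" + "GC" * 20, "g1"),
               region("GC" + SITE_M8 + "G" + "GC" * 20, "g2")]
    hits = scan_seed_sites(regions, {"m1": MIR})
    summary = mirna_target_summary(hits, regions)
    assert summary["n_pairs"] == 2
    assert summary["n_unique_mirnas"] == 1
    assert summary["n_regions_with_site"] == 2
    assert mirna_target_summary([], regions)["n_pairs"] == 0
    filtered = mirna_target_summary(hits, regions, expressed_mirnas=[])
    assert filtered["n_pairs"] == 0


def test_mirna_enrichment_recovers_planted_mirna():
    """Planted sites in 50% of foreground vs 5% of background regions put the
    planted microRNA first after BH."""
    rng = np.random.default_rng(10)
    bases = np.array(list("ACGT"))
    mirnas = {"planted": MIR}
    for i in range(9):
        mirnas[f"m{i}"] = "".join(rng.choice(bases, size=22)).replace("T", "U")

    def rand_seq(n=150):
        return "".join(rng.choice(bases, size=n))

    fg = []
    for i in range(100):
        seq = rand_seq()
        if i < 50:
            seq = seq[:40] + SITE_M8 + "A" + seq[48:]
        fg.append(region(seq, f"fg{i}"))
    bg = {}
    for i in range(1000):
        seq = rand_seq()
        if i < 50:
            seq = seq[:40] + SITE_M8 + "A" + seq[48:]
        bg[f"bg{i}"] = seq
    hits = scan_seed_sites(fg, mirnas)
    res = mirna_enrichment(hits, fg, bg, mirnas)
    assert res.iloc[0]["mirna_id"] == "planted"
    assert res.iloc[0]["p_adjusted"] <= 0.05
    with pytest.raises(ValueError, match="background"):
        mirna_enrichment(hits, fg, {}, mirnas)


def test_kmer_enrichment_recovers_planted_hexamer_and_null_is_quiet():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))

    def windows(n, plant_frac):
        out = []
        for i in range(n):
            seq = "".join(rng.choice(bases, size=101))
            if i < plant_frac * n:
                seq = seq[:30] + "AATAAA" + seq[36:]
            out.append(seq)
        return out

    fg = windows(100, 0.8)
    bg = windows(400, 0.05)
    res = kmer_enrichment(fg, bg, k=6)
    assert res.iloc[0]["kmer"] == "AATAAA"
    assert res.iloc[0]["p_adjusted"] < 1e-10
    # identical foreground and background: nothing passes BH
    same = windows(100, 0.0)
    res_null = kmer_enrichment(same[:50], same[50:], k=6)
    assert not res_null["enriched"].any()


def test_kmer_k1_reduces_to_alphabet_presence():
    res = kmer_enrichment(["AAAA", "CCCC"], ["GGGG", "TTTT"], k=1)
    a_row = res.set_index("kmer").loc["A"]
    assert a_row["fg_with"] == 1 and a_row["bg_with"] == 0


def _iso(gene_id, strand, positions):
    sites = [PASite(gene_id=gene_id, position=p, sources=frozenset({"reference"}))
             for p in positions]
    return APAIsoformSet(gene_id=gene_id, chrom="c", strand=strand, sites=sites)


def _results(gene_id, delta_psi, usage_rows):
    gene = pd.DataFrame({"gene_id": [gene_id], "delta_psi": [delta_psi],
                         "p_adjusted": [0.01]})
    pas = pd.DataFrame(usage_rows)
    return gene, pas


@pytest.mark.parametrize("strand,positions,expected_span,expect_rc", [
    ("+", [1000, 1400], (1000, 1400), False),
    ("-", [1400, 1000], (1001, 1401), True),
])
def test_interpas_region_extraction_conventions(strand, positions, expected_span, expect_rc):
    genome = {"c": "".join(np.random.default_rng(12).choice(list("ACGT"), size=2000))}
    iso = _iso("g", strand, positions)
    gene, pas = _results("g", +0.2, [
        {"gene_id": "g", "pas_id": f"g@{positions[0]}", "m": 0, "n": 2, "pps": 0.0,
         "usage_control": 0.6, "usage_mutant": 0.4, "change": "decreased"},
        {"gene_id": "g", "pas_id": f"g@{positions[1]}", "m": 1, "n": 2, "pps": 1.0,
         "usage_control": 0.4, "usage_mutant": 0.6, "change": "increased"},
    ])
    regions, n_genes, n_excl = extract_interpas_regions([iso], gene, pas, genome, "distal_shifted")
    assert n_genes == 1 and n_excl == 0
    r = regions[0]
    assert (r.start, r.end) == expected_span
    raw = genome["c"][r.start: r.end]
    assert r.sequence == (revcomp(raw) if expect_rc else raw)


def test_interpas_region_requires_specific_significant_distal_pas():
    genome = {"c": "A" * 2000}
    iso = _iso("g", "+", [1000, 1400])
    gene, pas = _results("g", +0.2, [
        {"gene_id": "g", "pas_id": "g@1000", "m": 0, "n": 2, "pps": 0.0,
         "usage_control": 0.6, "usage_mutant": 0.4, "change": "unchanged"},
        {"gene_id": "g", "pas_id": "g@1400", "m": 1, "n": 2, "pps": 1.0,
         "usage_control": 0.4, "usage_mutant": 0.6, "change": "unchanged"},
    ])
    regions, n_genes, n_excl = extract_interpas_regions([iso], gene, pas, genome, "distal_shifted")
    assert regions == [] and n_genes == 1 and n_excl == 1
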