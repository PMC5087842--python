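"""Seed sites, complementarity scoring, intersection, filter, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirnaome._seq import revcomp
from mirnaome.targets import (ALIGN_THRESHOLD, TargetPredictions, TargetSite,
                              anticorrelation_filter, enrich, find_seed_sites,
                              intersect_targets, perfect_complement_score,
                              predict_targets, score_complementarity)
from oracles import oracle_hypergeom_mc, oracle_hypergeom_upper

MIR = "TGGAATGTAAAGAAGTATGTAT"  # 22 nt, canonical-style mature


def test_seed_site_classes_constructed():
    m8 = revcomp(MIR[1:8])
    m7 = revcomp(MIR[1:7])
    utr_8mer = "CCCCC" + m8 + "A" + "CCCCC"
    sites = find_seed_sites("m", MIR, "g", utr_8mer)
    assert [s.site_class for s in sites] == ["8mer"]
    assert sites[0].position == 6
    utr_7m8 = "CCCCC" + m8 + "G" + "CCCCC"
    assert [s.site_class for s in find_seed_sites("m", MIR, "g", utr_7m8)] \
        == ["7mer-m8"]
    utr_7a1 = "CCCCC" + m7 + "A" + "CCCCC"
    assert [s.site_class for s in find_seed_sites("m", MIR, "g", utr_7a1)] \
        == ["7mer-A1"]


def test_seed_scan_no_sites_and_short_mirna():
    assert find_seed_sites("m", MIR, "g", "C" * 60) == []
    with pytest.raises(ValueError):
        find_seed_sites("m", "ACGTACG", "g", "C" * 30)


def test_seed_scan_equals_naive_scan(rng):
    """All occurrences found; counts match an independent re-scan."""
    m8 = revcomp(MIR[1:8])
    m7 = revcomp(MIR[1:7])
    for _ in range(50):
        utr = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 300))
        if rng.random() < 0.5:  # plant a site at a random position
            pos = int(rng.integers(0, 280))
            utr = utr[:pos] + m8 + "A" + utr[pos + 8:]
        sites = find_seed_sites("m", MIR, "g", utr)
        expected = 0
        for i in range(len(utr) - 6):
            is_m8 = utr[i:i + 7] == m8
            a1_7 = (utr[i:i + 6] == m7 and i + 6 < len(utr)
                    and utr[i + 6] == "A")
            nested = i >= 1 and utr[i - 1:i + 6] == m8
            if is_m8 or (a1_7 and not is_m8 and not nested):
                expected += 1
        assert len(sites) == expected


def test_alignment_closed_form_and_seed_weighting():
    site = revcomp(MIR)
    assert score_complementarity(MIR, site) \
        == pytest.approx(perfect_complement_score(len(MIR)))
    assert perfect_complement_score(22) == 145.0
    # a seed mismatch costs strictly more than a 3' mismatch
    seed_mm = list(site)
    pos_seed = len(site) - 4   # pairs miRNA position 4 (seed)
    seed_mm[pos_seed] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
        seed_mm[pos_seed]]
    three_mm = list(site)
    three_mm[2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[three_mm[2]]
    s_seed = score_complementarity(MIR, "".join(seed_mm))
    s_three = score_complementarity(MIR, "".join(three_mm))
    assert s_seed < s_three


def test_alignment_empty_window():
    assert score_complementarity(MIR, "") == 0.0


def test_intersection_requires_all_three_methods():
    preds = TargetPredictions(
        seed_genes={"m": {"g1", "g2", "g3"}},
        align_genes={"m": {"g1", "g2"}},
        energy_genes={"m": {"g1", "g3"}},
        sites=[])
    assert intersect_targets(preds) == {("m", "g1")}
    empty = TargetPredictions({"m": set()}, {"m": {"g1"}}, {"m": {"g1"}}, [])
    assert intersect_targets(empty) == set()


def test_planted_strong_site_retained(rng):
    """A full-complement 8mer site passes all three predictors."""
    utr = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 300))
    site = revcomp(MIR[1:]) + "A"
    utr = utr[:100] + site + utr[100 + len(site):]
    preds = predict_targets({"m": MIR}, {"g": utr, "empty": "C" * 200})
    assert intersect_targets(preds) == {("m", "g")}


def test_anticorrelation_sign_rule():
    de = pd.DataFrame([
        {"mirna": "m-up", "comparison": "E45_vs_B3", "log2fc": 2.0,
         "call": "up"},
        {"mirna": "m-dn", "comparison": "E45_vs_B3", "log2fc": -2.0,
         "call": "down"},
        {"mirna": "m-low", "comparison": "E45_vs_B3", "log2fc": 2.0,
         "call": "up"},
    ])
    pairs = {("m-up", "g1"), ("m-up", "g2"), ("m-dn", "g3"),
             ("m-low", "g4"), ("m-up", "g-missing")}
    fc = {("g1", "E45_vs_B3"): -1.2,   # opposite: retained
          ("g2", "E45_vs_B3"): 0.8,    # same direction: dropped
          ("g3", "E45_vs_B3"): 0.5,    # opposite of down: retained
          ("g4", "E45_vs_B3"): -1.0}
    rpm = {"m-up": 500.0, "m-dn": 150.0, "m-low": 80.0}
    out = anticorrelation_filter(pairs, de, fc, "E45_vs_B3", rpm)
    kept = set(zip(out["mirna"], out["gene"]))
    assert kept == {("m-up", "g1"), ("m-dn", "g3")}
    assert out.attrs["n_missing_gene"] == 1


def test_anticorrelation_antisymmetry(rng):
    """Flipping every mRNA sign swaps retained and dropped pairs."""
    de = pd.DataFrame([{"mirna": "m", "comparison": "C", "log2fc": 1.5,
                        "call": "up"}])
    genes = [f"g{i}" for i in range(20)]
    fc = {(g, "C"): float(rng.normal()) for g in genes}
    fc = {k: v for k, v in fc.items() if v != 0}
    pairs = {("m", g) for g in genes}
    rpm = {"m": 500.0}
    kept1 = set(anticorrelation_filter(pairs, de, fc, "C", rpm)["gene"])
    flipped = {k: -v for k, v in fc.items()}
    kept2 = set(anticorrelation_filter(pairs, de, flipped, "C", rpm)["gene"])
    assert kept1 | kept2 == set(genes)
    assert kept1 & kept2 == set()


def test_enrichment_closed_form_and_ease():
    sets = {"S": [f"g{i}" for i in range(5)]}
    bg = [f"g{i}" for i in range(20)]
    out = enrich([f"g{i}" for i in range(5)], bg, sets).set_index("gene_set")
    assert out.loc["S", "pvalue"] == pytest.approx(1 / 15504)
    assert out.loc["S", "pvalue"] == pytest.approx(
        oracle_hypergeom_upper(5, 20, 5, 5))
    # zero overlap -> p = 1
    out0 = enrich(["g10", "g11"], bg, {"S": ["g0", "g1"]})
    assert out0["pvalue"].iloc[0] == pytest.approx(1.0)
    # EASE decrements a singleton overlap to zero
    oute = enrich(["g0", "g10"], bg, {"S": ["g0", "g1"]}, mode="EASE")
    assert oute["pvalue"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        enrich(["g0"], [], sets)
    with pytest.raises(ValueError):
        enrich(["not-there"], bg, sets)


def test_enrichment_matches_monte_carlo(rng):
    """Hypergeometric p within 3 SE of a resampling estimate."""
    N, K, n, k = 60, 18, 15, 8
    bg = [f"g{i}" for i in range(N)]
    members = bg[:K]
    query = bg[:k] + bg[K:K + (n - k)]
    out = enrich(query, bg, {"S": members}).set_index("gene_set")
    p = out.loc["S", "pvalue"]
    draws = 20_000
    mc = oracle_hypergeom_mc(k, N, K, n, draws, rng)
    se = np.sqrt(p * (1 - p) / draws)
    assert abs(p - mc) <= 3 * se + 1e-12


def test_pipeline_recovers_planted_targets(small_pipeline, small_study):
    """Planted full-complement targets survive intersection and filtering."""
    _, truth, _ = small_study
    planted = set(zip(truth.targets["mirna"], truth.targets["gene"]))
    assert planted <= small_pipeline.target_pairs
    kept = set()
    for comp, df in small_pipeline.filtered_targets.items():
        kept.update(zip(df["mirna"], df["gene"]))
    assert planted <= kept
    # final targets are contained in each method's prediction set
    assert small_pipeline.enrichment is not None
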