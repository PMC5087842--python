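"""RPM arithmetic, tiers, correlations, clusters, heatmap ordering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirnaome.datasets import TOP19_ABUNDANCE
from mirnaome.quantify import (ExpressionMatrix, detect_genomic_clusters,
                               filter_and_tier, hierarchical_order,
                               overall_average_from_stage_means,
                               pairwise_correlation, summarize_abundance)


def _matrix(counts: dict, denoms: dict, kinds=None) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(counts).T, denoms, kinds=kinds)


LIBS = ["E45-1", "E45-2", "E60-1", "E60-2"]


def test_rpm_unit_case_and_scale_invariance():
    m = _matrix({"miR-a": {"E45-1": 9}}, {"E45-1": 9_000_000})
    assert m.rpm.loc["miR-a", "E45-1"] == pytest.approx(1.0)
    base = {"miR-a": dict(zip(LIBS, [10, 20, 30, 40]))}
    denoms = dict(zip(LIBS, [1e6, 2e6, 1e6, 4e6]))
    doubled = {"miR-a": {k: 2 * v for k, v in base["miR-a"].items()}}
    d2 = {k: 2 * v for k, v in denoms.items()}
    assert np.allclose(_matrix(base, denoms).rpm, _matrix(doubled, d2).rpm)


def test_zero_denominator_rejected():
    with pytest.raises(ValueError, match="denominator"):
        _matrix({"miR-a": {"E45-1": 1}}, {"E45-1": 0})


def test_tier_boundaries_and_retention():
    counts = {f"m{i}": dict(zip(LIBS, [c] * 4))
              for i, c in enumerate([0, 1, 99, 100, 999, 1000, 10500])}
    m = _matrix(counts, dict(zip(LIBS, [1e6] * 4)))
    tiers = filter_and_tier(m)
    assert not tiers.loc["m0", "retained"]          # 0 RPM
    assert not tiers.loc["m1", "retained"]          # exactly 1 RPM: not > 1
    assert tiers.loc["m2", "tier"] == "low"         # 99 RPM
    assert tiers.loc["m3", "tier"] == "moderate"    # boundary inclusive at 100
    assert tiers.loc["m4", "tier"] == "moderate"
    assert tiers.loc["m5", "tier"] == "high"        # boundary inclusive at 1000
    assert tiers.loc["m6", "tier"] == "high"


def test_tier_is_monotone_step_function():
    rpm = np.sort(np.concatenate([[0.5, 1.0, 100.0, 1000.0],
                                  np.random.default_rng(0).uniform(
                                      0, 5000, 50)]))
    counts = {f"m{i:03d}": dict(zip(LIBS, [int(v)] * 4))
              for i, v in enumerate(rpm)}
    m = _matrix(counts, dict(zip(LIBS, [1e6] * 4)))
    tiers = filter_and_tier(m).sort_values("overall_average_rpm")
    order = {"low": 0, "moderate": 1, "high": 2}
    seq = [order[t] for t in tiers["tier"]]
    assert seq == sorted(seq)


def test_published_table_overall_averages():
    """The printed overall averages equal the mean of the stage values."""
    for mirna, row in TOP19_ABUNDANCE.iterrows():
        stage_values = [row["E45"], row["E60"], row["E105"], row["B3"]]
        assert overall_average_from_stage_means(stage_values) \
            == pytest.approx(row["overall_average_rpm"], abs=0.005), mirna


def test_percent_of_total_single_mirna():
    m = _matrix({"m1": dict(zip(LIBS, [50] * 4))},
                dict(zip(LIBS, [1e6] * 4)))
    out = summarize_abundance(m, filter_and_tier(m))
    assert out["percent_of_total"].iloc[0] == pytest.approx(100.0)


def test_stage_mean_identity(small_pipeline):
    """Sum over stage means x replicates equals sum of per-library RPM."""
    m = small_pipeline.matrix
    stage = m.stage_means()
    reps = m.stages.value_counts()
    lhs = (stage * reps[stage.columns]).sum(axis=1)
    rhs = m.rpm.sum(axis=1)
    assert np.allclose(lhs, rhs)


def test_correlation_trivial_and_scale_invariance():
    counts = {"m1": dict(zip(LIBS, [10, 20, 5, 40])),
              "m2": dict(zip(LIBS, [100, 200, 50, 400])),
              "m3": dict(zip(LIBS, [7, 14, 3, 28]))}
    m = _matrix(counts, dict(zip(LIBS, [1e6] * 4)))
    r = pairwise_correlation(m)
    assert np.allclose(np.diag(r), 1.0)
    assert np.allclose(r, r.T)
    # E45-2 = 2x E45-1 -> r = 1
    assert r.loc["E45-1", "E45-2"] == pytest.approx(1.0)


def test_correlation_zero_variance_is_missing():
    counts = {"m1": dict(zip(LIBS, [5, 5, 10, 20])),
              "m2": dict(zip(LIBS, [5, 9, 10, 21]))}
    m = _matrix(counts, dict(zip(LIBS, [1e6] * 4)))
    r = pairwise_correlation(m)
    assert np.isnan(r.loc["E45-1", "E60-1"])  # library E45-1 has no variance
    assert r.loc["E45-1", "E45-1"] == 1.0


def test_correlation_same_vs_disjoint_composition(rng):
    """Libraries from identical proportions correlate near 1; disjoint near 0."""
    p = rng.dirichlet(np.ones(50) * 0.3)
    a = rng.multinomial(200_000, p)
    b = rng.multinomial(200_000, p)
    ids = [f"m{i:02d}" for i in range(50)]
    counts = pd.DataFrame({"L-1": a, "L-2": b}, index=ids)
    m = ExpressionMatrix(counts, {"L-1": 2e5, "L-2": 2e5})
    r = pairwise_correlation(m)
    assert r.loc["L-1", "L-2"] > 0.95
    disjoint = pd.DataFrame(
        {"L-1": np.concatenate([a[:25], np.zeros(25, int)]),
         "L-2": np.concatenate([np.zeros(25, int), b[:25]])}, index=ids)
    m2 = ExpressionMatrix(disjoint, {"L-1": 2e5, "L-2": 2e5})
    r2 = pairwise_correlation(m2)
    assert abs(r2.loc["L-1", "L-2"]) < 0.3


# ===================================================================== clusters

def _tiers_for(ids, rpm):
    return pd.DataFrame({"overall_average_rpm": rpm,
                         "tier": "high", "retained": True, "kind": "known"},
                        index=ids)


def test_cluster_of_50_within_1mb_window():
    coords = {f"m{i:02d}": ("chr21", 62_000_000 + i * 20_000,
                            62_000_000 + i * 20_000 + 80, "+")
              for i in range(50)}
    tiers = _tiers_for(list(coords), [500.0] * 50)
    out = detect_genomic_clusters(coords, tiers, window=100_000, min_size=3)
    assert len(out) == 1
    assert out.iloc[0]["n_members"] == 50
    assert out.iloc[0]["end"] - out.iloc[0]["start"] < 1_000_000


def test_genes_spaced_beyond_window_do_not_cluster():
    coords = {f"m{i}": ("chr1", 1 + i * 200_000, 80 + i * 200_000, "+")
              for i in range(5)}
    tiers = _tiers_for(list(coords), [500.0] * 5)
    out = detect_genomic_clusters(coords, tiers, window=100_000, min_size=3)
    assert len(out) == 0


def test_infinite_window_one_cluster_per_chromosome():
    coords = {}
    for c, chrom in enumerate(["chr1", "chr2"]):
        for i in range(4):
            coords[f"m{c}{i}"] = (chrom, 1 + i * 10_000_000,
                                  80 + i * 10_000_000, "+")
    tiers = _tiers_for(list(coords), [500.0] * 8)
    out = detect_genomic_clusters(coords, tiers, window=10**12, min_size=3)
    assert len(out) == 2
    assert set(out["chrom"]) == {"chr1", "chr2"}


def test_cluster_detection_translation_and_order_invariant():
    base = {f"m{i}": ("chr9", 100 + i * 1_000, 180 + i * 1_000, "+")
            for i in range(6)}
    tiers = _tiers_for(list(base), [500.0] * 6)
    a = detect_genomic_clusters(base, tiers, window=5_000, min_size=3)
    shifted = {k: (c, s + 777_777, e + 777_777, st)
               for k, (c, s, e, st) in base.items()}
    b = detect_genomic_clusters(shifted, tiers, window=5_000, min_size=3)
    assert a["n_members"].tolist() == b["n_members"].tolist()
    assert a["members"].tolist() == b["members"].tolist()
    scrambled = dict(reversed(list(base.items())))
    c = detect_genomic_clusters(scrambled, tiers, window=5_000, min_size=3)
    assert a.equals(c)


def test_low_rpm_members_excluded_from_clusters():
    coords = {f"m{i}": ("chr3", 1 + i * 1_000, 80 + i * 1_000, "+")
              for i in range(5)}
    tiers = _tiers_for(list(coords), [500, 500, 50, 500, 500])
    out = detect_genomic_clusters(coords, tiers, window=5_000, min_size=3)
    assert out.iloc[0]["n_members"] == 4
    assert "m2" not in out.iloc[0]["members"]


# ===================================================================== heatmap

def test_hierarchical_split_recovers_two_programs(rng):
    """Two planted co-expression programs split at the dendrogram root."""
    rising = np.array([1.0, 2.0, 4.0, 8.0])
    falling = rising[::-1]
    rows = {}
    for i in range(10):
        noise = rng.normal(1.0, 0.05, 4)
        rows[f"up{i}"] = rising * noise * rng.uniform(10, 1000)
    for i in range(10):
        noise = rng.normal(1.0, 0.05, 4)
        rows[f"dn{i}"] = falling * noise * rng.uniform(10, 1000)
    df = pd.DataFrame(rows, index=["E45", "E60", "E105", "B3"]).T
    order, groups = hierarchical_order(df)
    ups = {groups[f"up{i}"] for i in range(10)}
    dns = {groups[f"dn{i}"] for i in range(10)}
    assert len(ups) == 1 and len(dns) == 1 and ups != dns


def test_hierarchical_two_rows_and_identical_rows():
    df = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]],
                      index=["a", "b"], columns=list("wxyz"))
    order, groups = hierarchical_order(df)
    assert sorted(order) == ["a", "b"] and groups["a"] != groups["b"]
    same = pd.DataFrame([[1, 2, 3, 4]] * 3, index=["a", "b", "c"],
                        columns=list("wxyz"))
    o1, _ = hierarchical_order(same)
    o2, _ = hierarchical_order(same.iloc[::-1])
    assert o1 == o2  # determinism enforced by id order
    with pytest.raises(ValueError):
        hierarchical_order(df.iloc[:1])
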