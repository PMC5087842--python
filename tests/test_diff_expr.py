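"""UQ factors, dispersion recovery, exact test vs enumeration, DE calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirnaome.diff_expr import (DispersionEstimate, call_de,
                                estimate_common_dispersion, exact_test,
                                uq_factors, scale_to_common_size,
                                effective_sizes, venn_partition)
from mirnaome.quantify import ExpressionMatrix
from oracles import oracle_exact_test_p

LIBS = ["E45-1", "E45-2", "B3-1", "B3-2"]


# ===================================================================== UQ

def test_uq_identical_libraries_unit_factors(rng):
    col = rng.integers(0, 500, 100)
    counts = pd.DataFrame({l: col for l in LIBS})
    assert np.allclose(uq_factors(counts), 1.0)


def test_uq_doubling_closed_form(rng):
    a = rng.integers(1, 500, 200)
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    f = uq_factors(counts)
    assert f["A"] == pytest.approx(1 / np.sqrt(2))
    assert f["B"] == pytest.approx(np.sqrt(2))


def test_uq_row_permutation_invariant(rng):
    counts = pd.DataFrame(rng.integers(0, 300, (50, 4)), columns=LIBS)
    f1 = uq_factors(counts)
    f2 = uq_factors(counts.sample(frac=1.0, random_state=0))
    assert np.allclose(f1, f2)


def test_uq_all_zero_library_errors():
    counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
    with pytest.raises(ValueError, match="B"):
        uq_factors(counts)


# ===================================================================== dispersion

def test_dispersion_poisson_recovery(rng):
    mu = rng.uniform(20, 200, 2000)
    counts = pd.DataFrame({l: rng.poisson(mu) for l in LIBS})
    est = estimate_common_dispersion(counts, {"E45": LIBS[:2], "B3": LIBS[2:]})
    assert est.phi <= 0.05


def test_dispersion_nb_recovery(rng):
    phi = 0.2
    mu = rng.uniform(50, 500, 2000)
    r = 1 / phi
    counts = pd.DataFrame(
        {l: rng.negative_binomial(r, r / (r + mu)) for l in LIBS})
    est = estimate_common_dispersion(counts, {"E45": LIBS[:2], "B3": LIBS[2:]})
    assert 0.1 <= est.phi <= 0.3


def test_dispersion_identical_replicates_hits_lower_bound():
    col = np.arange(1, 101)
    counts = pd.DataFrame({l: col for l in LIBS})
    est = estimate_common_dispersion(counts, {"E45": LIBS[:2], "B3": LIBS[2:]})
    assert est.phi == 0.0


def test_dispersion_requires_replication():
    counts = pd.DataFrame({"A": [1, 2], "B": [3, 4]})
    with pytest.raises(ValueError, match="dispersion"):
        estimate_common_dispersion(counts, {"g1": ["A"], "g2": ["B"]})
    with pytest.raises(ValueError):
        DispersionEstimate(phi=-0.1)


# ===================================================================== exact test

def test_exact_test_symmetry_and_trivial_cases():
    p, lfc = exact_test([5, 7], [5, 7], phi=0.1)
    assert lfc == 0.0 and p == pytest.approx(1.0)
    p1, l1 = exact_test([1, 3], [20, 30], phi=0.1)
    p2, l2 = exact_test([20, 30], [1, 3], phi=0.1)
    assert p1 == pytest.approx(p2)
    assert l1 == pytest.approx(-l2)
    with pytest.raises(ValueError):
        exact_test([1], [1], phi=-1)


def test_exact_test_strong_signal_direction():
    p, lfc = exact_test([0, 0], [100, 100], phi=0.1)
    assert p < 0.05 and lfc > 1


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
def test_exact_test_equals_enumeration(phi, rng):
    """Exact p equals brute-force conditional enumeration, totals <= 50."""
    for _ in range(40):
        t = int(rng.integers(1, 51))
        sa = int(rng.integers(0, t + 1))
        sb = t - sa
        # split sums into replicate vectors arbitrarily
        a = [sa // 2, sa - sa // 2]
        b = [sb // 2, sb - sb // 2]
        p, _ = exact_test(a, b, phi)
        assert p == pytest.approx(
            oracle_exact_test_p(sa, sb, 2, 2, phi), rel=1e-9), (sa, sb, phi)


# ===================================================================== calling

def _matrix_from_counts(counts: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(counts, {l: 1_000_000 for l in counts.columns})


def test_call_de_recall_and_type_one_error(rng):
    """phi=0.1, 2v2, base ~500 RPM, 4-fold: recall >= 0.9, null calls <= 5%."""
    n_de, n_null = 100, 900
    phi = 0.1
    r = 1 / phi
    base = rng.uniform(300, 800, n_de + n_null)
    mu_a = base.copy()
    mu_b = base.copy()
    mu_b[:n_de // 2] *= 4.0
    mu_a[n_de // 2:n_de] *= 4.0

    def draw(mu):
        return rng.negative_binomial(r, r / (r + mu))

    counts = pd.DataFrame({
        "E45-1": draw(mu_a), "E45-2": draw(mu_a),
        "B3-1": draw(mu_b), "B3-2": draw(mu_b)},
        index=[f"m{i:04d}" for i in range(n_de + n_null)])
    m = _matrix_from_counts(counts)
    de = call_de(m, comparisons=[("E45", "B3")])
    de = de.set_index("mirna")
    called = de["call"] != "ns"
    recall = called.iloc[:n_de].mean()
    fpr = called.iloc[n_de:].mean()
    assert recall >= 0.9
    assert fpr <= 0.05
    # directions match the planted changes
    up = de.iloc[:n_de // 2]
    dn = de.iloc[n_de // 2:n_de]
    assert (up.loc[up["call"] != "ns", "call"] == "up").all()
    assert (dn.loc[dn["call"] != "ns", "call"] == "down").all()


def test_call_boundary_fold_change_is_ns(rng):
    """|log2FC| just under 1 is not called, however small the FDR."""
    null = rng.integers(100, 5000, 100)
    shift = 2 ** 0.99
    a = np.concatenate([null, [10_000, 10_000]])
    b = np.concatenate([null, [int(10_000 * shift)] * 2])
    ids = [f"n{i}" for i in range(100)] + ["m1", "m2"]
    counts = pd.DataFrame({"E45-1": a, "E45-2": a, "B3-1": b, "B3-2": b},
                          index=ids)
    m = _matrix_from_counts(counts)
    de = call_de(m, comparisons=[("E45", "B3")], phi=0.0).set_index("mirna")
    assert (de.loc[["m1", "m2"], "pvalue"] < 1e-6).all()
    assert abs(de.loc["m1", "log2fc"]) < 1.0
    assert (de.loc[["m1", "m2"], "call"] == "ns").all()


def test_call_de_unknown_stage_errors(small_pipeline):
    with pytest.raises(ValueError, match="unknown stage"):
        call_de(small_pipeline.matrix, comparisons=[("E45", "XXX")])


def test_bh_fdr_monotone_in_rank(small_pipeline):
    de = small_pipeline.de_table
    for comp, grp in de.groupby("comparison"):
        g = grp.sort_values("pvalue")
        # BH-adjusted values are monotone non-decreasing in p-value rank
        assert (np.diff(g["fdr"]) >= -1e-12).all()
        assert (g["fdr"] >= g["pvalue"] - 1e-12).all()


def test_swapping_groups_negates_lfc(small_pipeline):
    m = small_pipeline.matrix
    d1 = call_de(m, comparisons=[("E45", "B3")]).set_index("mirna")
    d2 = call_de(m, comparisons=[("B3", "E45")]).set_index("mirna")
    assert np.allclose(d1["log2fc"], -d2["log2fc"])
    assert np.allclose(d1["pvalue"], d2["pvalue"])


def test_venn_partition_counts():
    de = pd.DataFrame([
        {"mirna": "m1", "comparison": "A_vs_B", "call": "up"},
        {"mirna": "m1", "comparison": "A_vs_C", "call": "up"},
        {"mirna": "m2", "comparison": "A_vs_B", "call": "up"},
        {"mirna": "m3", "comparison": "A_vs_C", "call": "down"},
    ])
    out = venn_partition(de, ["A_vs_B", "A_vs_C"], "up")
    row = out.set_index("comparisons")
    assert row.loc["A_vs_B", "n"] == 1            # m2 only
    assert row.loc["A_vs_B&A_vs_C", "n"] == 1     # m1 common
    assert row.loc["A_vs_C", "n"] == 0


def test_scaled_counts_have_common_effective_size(small_pipeline):
    m = small_pipeline.matrix
    tiers = small_pipeline.tiers
    counts = m.counts.loc[tiers.index[tiers["retained"]]]
    eff = effective_sizes(counts, m.denominators)
    scaled = scale_to_common_size(counts, eff)
    assert (scaled >= 0).all().all()
    assert scaled.dtypes.unique().tolist() == [np.dtype("int64")]
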