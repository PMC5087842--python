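"""Differential expression between stages: UQ scaling + NB exact test.

Between-library normalization uses upper-quartile (UQ) scaling: the 75th
percentile of each library's nonzero counts, rescaled so the geometric
mean of the factors is 1; the effective library size is the mapped-read
denominator times the factor. A common negative-binomial dispersion phi is
estimated by maximizing the conditional (on per-group totals) NB
log-likelihood summed over miRNAs — the conditional distribution does not
depend on the mean, so phi is identified from replicate variability alone.
The per-miRNA test is the two-sided conditional NB exact test: given the
pooled total (after quantile-scaling counts to a common effective size),
the probability of every group-A total as likely or less likely than the
observed one is summed. Calls require |log2FC| >= 1 (from UQ-scaled
pseudo-counts, +0.5 stabilizer) and Benjamini-Hochberg FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

from mirnaome.quantify import ExpressionMatrix, filter_and_tier

FC_THRESHOLD = 1.0     # |log2 fold change| cutoff
FDR_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5
PHI_BOUNDS = (0.0, 5.0)


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "conditional-ML"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


# ===================================================================== UQ

def uq_factors(counts: pd.DataFrame) -> pd.Series:
    """Upper-quartile scale factor per library (geometric mean 1)."""
    raw = {}
    for lib in counts.columns:
        col = counts[lib].to_numpy()
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"library {lib} has no nonzero counts")
        raw[lib] = float(np.percentile(nz, 75))
    s = pd.Series(raw)
    return s / np.exp(np.log(s).mean())


def effective_sizes(counts: pd.DataFrame,
                    denominators: Mapping[str, float]) -> pd.Series:
    f = uq_factors(counts)
    return pd.Series({lib: denominators[lib] * f[lib] for lib in counts.columns})


def scale_to_common_size(counts: pd.DataFrame, eff_sizes: pd.Series,
                         ) -> pd.DataFrame:
    """Quantile-scale counts to the geometric-mean effective size.

    Counts are multiplied by (common size / library size) and rounded half
    away from zero, giving integer pseudo-counts comparable across
    libraries (required by the conditional exact test).
    """
    common = float(np.exp(np.log(eff_sizes).mean()))
    scaled = counts.mul(common / eff_sizes, axis=1)
    return np.floor(scaled + 0.5).astype(np.int64)


# ===================================================================== dispersion

def _group_cond_loglik(y: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood of one gene's replicate counts.

    Conditioning on the replicate total removes the mean: the counts are
    Dirichlet-multinomial-like with size r per replicate.
    """
    n = y.size
    t = y.sum()
    return float(gammaln(y + r).sum() - n * gammaln(r)
                 - gammaln(y + 1).sum()
                 - gammaln(t + n * r) + gammaln(n * r) + gammaln(t + 1))


def estimate_common_dispersion(counts: pd.DataFrame,
                               groups: Mapping[str, Sequence[str]],
                               ) -> DispersionEstimate:
    """Common phi maximizing the summed conditional log-likelihood.

    ``groups`` maps group label to replicate column names; groups with a
    single replicate contribute nothing (their conditional likelihood is
    constant). Counts should already be scaled to a common effective size.
    """
    blocks = []
    for label, cols in groups.items():
        if len(cols) >= 2:
            blocks.append(counts[list(cols)].to_numpy(dtype=float))
    if not blocks:
        raise ValueError(
            "no group has replication; supply a dispersion estimate directly")

    def neg_ll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        total = 0.0
        for block in blocks:
            for row in block:
                if row.sum() > 0:
                    total += _group_cond_loglik(row, r)
        return -total

    res = minimize_scalar(neg_ll, bounds=(np.log(1e-6), np.log(PHI_BOUNDS[1])),
                          method="bounded",
                          options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    # fold numerically-zero overdispersion onto the Poisson boundary
    if phi <= 2e-6 or neg_ll(np.log(1e-6)) <= res.fun:
        phi = 0.0
    return DispersionEstimate(phi=phi)


# ===================================================================== exact test

def exact_test(counts_a: Sequence[int], counts_b: Sequence[int],
               phi: float) -> tuple[float, float]:
    """Two-sided conditional NB exact test on equal-size scaled counts.

    Returns (p-value, log2 fold change B vs A). Counts must already be
    scaled to a common effective library size; phi is the common NB
    dispersion (phi = 0 reduces the model to Poisson and the conditional
    law to a binomial).
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    na, nb = a.size, b.size
    sa, sb = int(a.sum()), int(b.sum())
    t = sa + sb
    log2fc = float(np.log2((b.mean() + PSEUDOCOUNT) / (a.mean() + PSEUDOCOUNT)))
    if t == 0:
        return 1.0, log2fc
    k = np.arange(t + 1)
    if phi == 0.0:
        logp = binom.logpmf(k, t, na / (na + nb))
    else:
        # sum of n iid NB(mean mu, dispersion phi) is NB(n*mu, phi/n)
        mu = t / (na + nb)
        ra, rb = na / phi, nb / phi
        la = nbinom.logpmf(k, ra, ra / (ra + na * mu))
        lb = nbinom.logpmf(t - k, rb, rb / (rb + nb * mu))
        logp = la + lb
        logp -= _logsumexp(logp)
    obs = logp[sa]
    mask = logp <= obs + 1e-12
    p = float(np.exp(_logsumexp(logp[mask]) - _logsumexp(logp)))
    return min(p, 1.0), log2fc


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.exp(x - m).sum()))


# ===================================================================== calling

def call_de(matrix: ExpressionMatrix,
            comparisons: Sequence[tuple[str, str]] | None = None,
            fc_threshold: float = FC_THRESHOLD,
            fdr_threshold: float = FDR_THRESHOLD,
            phi: float | None = None,
            tiers: pd.DataFrame | None = None) -> pd.DataFrame:
    """DE results for every stage pair on retained miRNAs.

    log2FC > 0 means higher in the later stage (group B). Benjamini-
    Hochberg FDR is applied within each comparison; a call requires
    |log2FC| >= fc_threshold and FDR <= fdr_threshold.
    """
    if tiers is None:
        tiers = filter_and_tier(matrix)
    keep = tiers.index[tiers["retained"]]
    counts = matrix.counts.loc[keep]
    stages = matrix.stage_order
    if comparisons is None:
        comparisons = list(combinations(stages, 2))
    for a, b in comparisons:
        if a not in stages or b not in stages:
            raise ValueError(f"unknown stage label in comparison {a} vs {b}")
    libs_of = {s: [lib for lib in matrix.libraries if matrix.stages[lib] == s]
               for s in stages}
    eff = effective_sizes(counts, matrix.denominators)
    scaled = scale_to_common_size(counts, eff)
    if phi is None:
        phi = estimate_common_dispersion(scaled, libs_of).phi
    rows = []
    for a, b in comparisons:
        cols_a, cols_b = libs_of[a], libs_of[b]
        pvals, lfcs = [], []
        for mid in counts.index:
            p, lfc = exact_test(scaled.loc[mid, cols_a].to_numpy(),
                                scaled.loc[mid, cols_b].to_numpy(), phi)
            pvals.append(p)
            lfcs.append(lfc)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for mid, p, lfc, q in zip(counts.index, pvals, lfcs, fdr):
            call = "ns"
            if abs(lfc) >= fc_threshold and q <= fdr_threshold:
                call = "up" if lfc > 0 else "down"
            rows.append({"mirna": mid, "comparison": f"{a}_vs_{b}",
                         "log2fc": lfc, "pvalue": p, "fdr": q, "call": call})
    out = pd.DataFrame(rows)
    out.attrs["phi"] = phi
    out.attrs["pseudocount"] = PSEUDOCOUNT
    return out


def venn_partition(de_table: pd.DataFrame,
                   comparisons: Sequence[str],
                   direction: str) -> pd.DataFrame:
    """Set-algebra partition of DE calls across comparisons.

    For each non-empty subset of ``comparisons``, the number of miRNAs
    called in ``direction`` in exactly that subset (the Venn-diagram
    region counts).
    """
    sets = {
        c: set(de_table.loc[(de_table["comparison"] == c)
                            & (de_table["call"] == direction), "mirna"])
        for c in comparisons}
    universe = set().union(*sets.values())
    rows = []
    for r in range(1, len(comparisons) + 1):
        for combo in combinations(comparisons, r):
            inside = set(universe)
            for c in combo:
                inside &= sets[c]
            for c in comparisons:
                if c not in combo:
                    inside -= sets[c]
            rows.append({"comparisons": "&".join(combo),
                         "direction": direction, "n": len(inside),
                         "mirnas": ",".join(sorted(inside))})
    return pd.DataFrame(rows)
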