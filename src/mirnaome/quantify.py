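"""miRNA expression matrix, RPM normalization and descriptive analyses.

Raw counts aggregate every tag assigned to a mature miRNA (isomiRs within
+/-2 nt and single-mismatch edited tags are counted under their miRNA).
RPM = count x 10^6 / per-library genome-mapped clean reads; the denominator
is recorded with the matrix for auditability. Retention requires an overall
average (unweighted mean over libraries) above 1 RPM; retained miRNAs tier
into low (<100), moderate ([100, 1000)) and high (>=1000 RPM). Descriptive
analyses mirror a staged small-RNA study: stage means and percent-of-total
for the most abundant miRNAs, pairwise library Pearson correlations,
genomic cluster detection, and hierarchical ordering of cluster-member
expression rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

TIER_LOW_MAX = 100.0     # low: < 100 RPM
TIER_HIGH_MIN = 1000.0   # high: >= 1000 RPM
RETENTION_RPM = 1.0      # keep miRNAs with overall average > 1 RPM


class ExpressionMatrix:
    """miRNA x library raw counts with RPM normalization.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, rows = mature miRNA ids, columns =
        library labels.
    denominators : mapping
        Per-library genome-mapped clean-read totals (the RPM denominator).
    kinds : mapping, optional
        Row id -> {"known", "homolog", "novel"}; defaults to "known".
    stage_of : callable or mapping, optional
        Library label -> stage label; defaults to label.rsplit("-", 1)[0].
    """

    def __init__(self, counts: pd.DataFrame, denominators: Mapping[str, int],
                 kinds: Mapping[str, str] | None = None,
                 stage_of=None):
        self.counts = counts.astype(np.int64)
        denom = pd.Series({lib: denominators[lib] for lib in counts.columns},
                          dtype=float)
        if (denom <= 0).any():
            bad = denom[denom <= 0].index.tolist()
            raise ValueError(f"zero mapped-read denominator for libraries {bad}")
        self.denominators = denom
        self.rpm = counts.div(denom, axis=1) * 1e6
        kinds = kinds or {}
        self.kinds = pd.Series({i: kinds.get(i, "known") for i in counts.index})
        if stage_of is None:
            stage_of = lambda lib: lib.rsplit("-", 1)[0]
        if isinstance(stage_of, Mapping):
            mapping = dict(stage_of)
            stage_of = mapping.__getitem__
        self.stages = pd.Series({lib: stage_of(lib) for lib in counts.columns})

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def stage_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for lib in self.libraries:
            seen.setdefault(self.stages[lib], None)
        return list(seen)

    def overall_average(self) -> pd.Series:
        """Unweighted mean RPM over all libraries, per miRNA."""
        return self.rpm.mean(axis=1)

    def stage_means(self) -> pd.DataFrame:
        """Mean RPM over each stage's replicate libraries."""
        return self.rpm.T.groupby(self.stages).mean().T[self.stage_order]


def build_expression_matrix(counts_per_mirna: Mapping[str, Mapping[str, int]],
                            denominators: Mapping[str, int],
                            libraries: Sequence[str],
                            kinds: Mapping[str, str] | None = None,
                            ) -> ExpressionMatrix:
    """Assemble the matrix from per-miRNA per-library count dicts."""
    ids = sorted(counts_per_mirna)
    data = {lib: [counts_per_mirna[i].get(lib, 0) for i in ids]
            for lib in libraries}
    counts = pd.DataFrame(data, index=ids)
    return ExpressionMatrix(counts, denominators, kinds=kinds)


# ===================================================================== tiers

def filter_and_tier(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Retention (>1 RPM overall average) and abundance tiers per miRNA."""
    avg = matrix.overall_average()
    tier = pd.cut(avg, bins=[-np.inf, TIER_LOW_MAX, TIER_HIGH_MIN, np.inf],
                  labels=["low", "moderate", "high"], right=False)
    return pd.DataFrame({
        "overall_average_rpm": avg,
        "tier": tier.astype(str),
        "retained": avg > RETENTION_RPM,
        "kind": matrix.kinds,
    })


def summarize_abundance(matrix: ExpressionMatrix, tiers: pd.DataFrame,
                        top_n: int = 19) -> pd.DataFrame:
    """Stage means, overall average and percent-of-total; top-N table.

    Percent-of-total is computed over retained known miRNAs only. Under
    equal replication the overall average (mean of per-library RPM) equals
    the mean of the stage means.
    """
    known = tiers.index[(tiers["kind"] == "known") & tiers["retained"]]
    stage = matrix.stage_means().loc[known]
    overall = matrix.overall_average().loc[known]
    pct = 100.0 * overall / overall.sum()
    out = stage.copy()
    out["overall_average_rpm"] = overall
    out["percent_of_total"] = pct
    out = out.sort_values("overall_average_rpm", ascending=False)
    return out.head(top_n) if top_n else out


def overall_average_from_stage_means(stage_values: Sequence[float]) -> float:
    """Overall-average RPM as the unweighted mean of the stage means."""
    return float(np.mean(stage_values))


# ===================================================================== correlation

def pairwise_correlation(matrix: ExpressionMatrix,
                         tiers: pd.DataFrame | None = None) -> pd.DataFrame:
    """Library x library Pearson r on retained known-miRNA RPM vectors."""
    if tiers is None:
        tiers = filter_and_tier(matrix)
    keep = tiers.index[(tiers["kind"] == "known") & tiers["retained"]]
    data = matrix.rpm.loc[keep]
    libs = matrix.libraries
    if len(libs) < 2:
        raise ValueError("need at least two libraries")
    out = pd.DataFrame(np.nan, index=libs, columns=libs)
    sd = data.std(axis=0, ddof=0)
    for i, a in enumerate(libs):
        for b in libs[i:]:
            if a == b:
                out.loc[a, b] = 1.0
                continue
            if sd[a] == 0 or sd[b] == 0:
                continue  # undefined r stays missing
            r = float(np.corrcoef(data[a], data[b])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


# ===================================================================== clusters

def detect_genomic_clusters(coordinates: Mapping[str, tuple[str, int, int, str]],
                            tiers: pd.DataFrame,
                            window: int = 100_000,
                            min_size: int = 3,
                            min_rpm: float = 100.0) -> pd.DataFrame:
    """Maximal runs of co-located miRNA genes with gaps <= window.

    Only miRNAs with overall average RPM above ``min_rpm`` are considered.
    Returns one row per reported cluster (>= min_size members) with span
    and member ids; detection is invariant to input order and coordinate
    translation.
    """
    avg = tiers["overall_average_rpm"]
    entries = [(chrom, start, end, mid)
               for mid, (chrom, start, end, strand) in coordinates.items()
               if mid in avg.index and avg[mid] > min_rpm]
    entries.sort()
    rows = []
    i = 0
    while i < len(entries):
        chrom = entries[i][0]
        members = [entries[i]]
        j = i + 1
        while (j < len(entries) and entries[j][0] == chrom
               and entries[j][1] - members[-1][2] <= window):
            members.append(entries[j])
            j += 1
        if len(members) >= min_size:
            rows.append({
                "chrom": chrom,
                "start": members[0][1],
                "end": max(m[2] for m in members),
                "n_members": len(members),
                "members": ",".join(sorted(m[3] for m in members)),
            })
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members",
                                       "members"])


def chromosome_distribution(coordinates: Mapping[str, tuple[str, int, int, str]],
                            mirna_ids: Sequence[str]) -> pd.Series:
    """Known-miRNA counts per chromosome (genomic-distribution figure)."""
    counts: dict[str, int] = {}
    for mid in mirna_ids:
        if mid in coordinates:
            chrom = coordinates[mid][0]
            counts[chrom] = counts.get(chrom, 0) + 1
    return pd.Series(counts).sort_index()


# ===================================================================== heatmap

def hierarchical_order(stage_rpm: pd.DataFrame,
                       ) -> tuple[list[str], dict[str, int]]:
    """Agglomerative ordering of expression rows; two top-level groups.

    Average-linkage clustering on correlation distance between per-stage
    RPM rows. Returns the leaf order and a {miRNA: group} map where the
    groups are the two children of the dendrogram root. Rows are sorted by
    id first so ties break deterministically.
    """
    if len(stage_rpm) < 2:
        raise ValueError("need at least two rows")
    data = stage_rpm.sort_index()
    ids = list(data.index)
    if len(ids) == 2:
        return ids, {ids[0]: 0, ids[1]: 1}
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=1)
    dist = pdist(x, metric="correlation")
    # zero-variance rows make correlation distance undefined; treat any
    # NaN distance as maximal so identical-flat rows still cluster stably
    dist = np.where(np.isnan(dist), 1.0, dist)
    Z = hierarchy.linkage(dist, method="average")
    order = [ids[k] for k in hierarchy.leaves_list(Z)]
    # the root's two children partition the leaves
    n = len(ids)
    root_left = int(Z[-1, 0])
    members_left = _leaf_members(Z, root_left, n)
    groups = {mid: (0 if k in members_left else 1)
              for k, mid in enumerate(ids)}
    return order, groups


def _leaf_members(Z: np.ndarray, node: int, n: int) -> set[int]:
    if node < n:
        return {node}
    left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
    return _leaf_members(Z, left, n) | _leaf_members(Z, right, n)
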