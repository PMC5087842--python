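"""miRNA target prediction, anti-correlation filtering and enrichment.

Three archetypal site-finding methods are intersected at the gene level:

* seed scan — canonical 8mer / 7mer-m8 / 7mer-A1 sites (reverse-complement
  matches to miRNA positions 2-8 in the 3'UTR, with or without the
  A opposite position 1);
* weighted local alignment — Smith-Waterman-style complementarity with
  G:U wobbles and doubled seed-position weights;
* duplex energy — minimum-energy miRNA:site hybridization under the
  stacking model.

Only genes predicted by all three methods are kept. Pairs are then
filtered to DE miRNAs with overall average expression above 100 RPM whose
target mRNA moved in the opposite direction in the same comparison.
Gene-set enrichment is an upper-tail hypergeometric test (optional EASE
variant decrementing the overlap) with BH FDR across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from mirnaome._seq import revcomp
from mirnaome.folding import duplex_energy

ALIGN_THRESHOLD = 140.0
ENERGY_THRESHOLD = -15.0
SITE_CONTEXT = 30          # nt of UTR context on each side of a seed site
RPM_FOCUS = 100.0          # DE miRNAs above this overall average are analyzed

MATCH, WOBBLE, MISMATCH = 5.0, 1.0, -3.0
GAP_OPEN, GAP_EXTEND = -8.0, -2.0
SEED_WEIGHT = 2.0          # multiplier on miRNA positions 2-8


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    gene: str
    position: int          # 1-based site start in the UTR
    site_class: str        # 8mer | 7mer-m8 | 7mer-A1


# ===================================================================== seed scan

def find_seed_sites(mirna_id: str, mirna_seq: str, gene_id: str,
                    utr: str) -> list[TargetSite]:
    """Canonical seed sites of a miRNA in one 3'UTR (sense orientation).

    7mer-m8: reverse complement of miRNA positions 2-8; 7mer-A1: reverse
    complement of positions 2-7 followed by an A opposite position 1;
    8mer: both. All occurrences are reported.
    """
    if len(mirna_seq) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    m8 = revcomp(mirna_seq[1:8])       # 7 nt, pairs positions 2-8
    m7 = revcomp(mirna_seq[1:7])       # 6 nt, pairs positions 2-7
    sites = []
    n = len(utr)
    for i in range(n - 6):
        has_m8 = utr[i:i + 7] == m8
        a1_after_m8 = has_m8 and i + 7 < n and utr[i + 7] == "A"
        if a1_after_m8:
            sites.append(TargetSite(mirna_id, gene_id, i + 1, "8mer"))
        elif has_m8:
            sites.append(TargetSite(mirna_id, gene_id, i + 1, "7mer-m8"))
        elif (utr[i:i + 6] == m7 and i + 6 < n and utr[i + 6] == "A"
                and not (i >= 1 and utr[i - 1:i + 6] == m8)):
            # the guard avoids re-reporting the 7mer-A1 nested in an 8mer
            sites.append(TargetSite(mirna_id, gene_id, i + 1, "7mer-A1"))
    return sites


# ===================================================================== alignment

def score_complementarity(mirna_seq: str, window: str) -> float:
    """Weighted local-alignment complementarity score.

    The miRNA is aligned reversed (3'->5') against the window (5'->3') so
    aligned columns are potential base pairs: +5 complement, +1 G:U
    wobble, -3 mismatch, affine gaps -8/-2; scores at miRNA seed positions
    2-8 are doubled. Returns the best local score (0 if none positive).
    """
    if not window or not mirna_seq:
        return 0.0
    m = mirna_seq[::-1]
    L = len(m)
    # weight by original miRNA position (2-8)
    weights = [SEED_WEIGHT if 2 <= (L - k) <= 8 else 1.0 for k in range(L)]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
    n = len(window)
    H = np.zeros((L + 1, n + 1))
    E = np.full((L + 1, n + 1), -np.inf)
    F = np.full((L + 1, n + 1), -np.inf)
    best = 0.0
    for i in range(1, L + 1):
        mi = m[i - 1]
        w = weights[i - 1]
        for j in range(1, n + 1):
            uj = window[j - 1]
            if comp.get(mi) == uj:
                s = MATCH * w
            elif (mi, uj) in (("G", "T"), ("T", "G"), ("G", "U"), ("U", "G")):
                s = WOBBLE * w
            else:
                s = MISMATCH * w
            E[i, j] = max(E[i, j - 1] + GAP_EXTEND, H[i, j - 1] + GAP_OPEN)
            F[i, j] = max(F[i - 1, j] + GAP_EXTEND, H[i - 1, j] + GAP_OPEN)
            h = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best = h
    return float(best)


def perfect_complement_score(length: int) -> float:
    """Closed-form alignment score of a full-length perfect complement."""
    n_seed = len([k for k in range(length) if 2 <= k + 1 <= 8])
    return MATCH * (SEED_WEIGHT * n_seed + (length - n_seed))


# ===================================================================== prediction

@dataclass
class TargetPredictions:
    """Per-method gene-level prediction sets and merged site records."""

    seed_genes: dict[str, set[str]]
    align_genes: dict[str, set[str]]
    energy_genes: dict[str, set[str]]
    sites: list[TargetSite]

    def intersected(self) -> set[tuple[str, str]]:
        pairs = set()
        for mirna, genes in self.seed_genes.items():
            inter = (genes & self.align_genes.get(mirna, set())
                     & self.energy_genes.get(mirna, set()))
            pairs.update((mirna, g) for g in inter)
        return pairs


def predict_targets(mirnas: Mapping[str, str],
                    utrs: Mapping[str, str],
                    align_threshold: float = ALIGN_THRESHOLD,
                    energy_threshold: float = ENERGY_THRESHOLD,
                    context: int = SITE_CONTEXT) -> TargetPredictions:
    """Run the three predictors over all miRNA x UTR combinations.

    The alignment and duplex predictors evaluate windows of ``context`` nt
    around each seed site (the seed scan proposes loci; the other two
    score them independently against their thresholds).
    """
    seed_genes: dict[str, set[str]] = {}
    align_genes: dict[str, set[str]] = {}
    energy_genes: dict[str, set[str]] = {}
    all_sites: list[TargetSite] = []
    for mirna_id, mseq in mirnas.items():
        seed_genes[mirna_id] = set()
        align_genes[mirna_id] = set()
        energy_genes[mirna_id] = set()
        for gene_id, utr in utrs.items():
            sites = find_seed_sites(mirna_id, mseq, gene_id, utr)
            if not sites:
                continue
            seed_genes[mirna_id].add(gene_id)
            all_sites.extend(sites)
            if (gene_id in align_genes[mirna_id]
                    and gene_id in energy_genes[mirna_id]):
                continue
            for site in sites:
                lo = max(0, site.position - 1 - context)
                hi = min(len(utr), site.position - 1 + 8 + context)
                window = utr[lo:hi]
                if gene_id not in align_genes[mirna_id] and \
                        score_complementarity(mseq, window) >= align_threshold:
                    align_genes[mirna_id].add(gene_id)
                if gene_id not in energy_genes[mirna_id] and \
                        duplex_energy(mseq, window) <= energy_threshold:
                    energy_genes[mirna_id].add(gene_id)
                if (gene_id in align_genes[mirna_id]
                        and gene_id in energy_genes[mirna_id]):
                    break
    return TargetPredictions(seed_genes, align_genes, energy_genes, all_sites)


def intersect_targets(predictions: TargetPredictions) -> set[tuple[str, str]]:
    """(miRNA, gene) pairs predicted by all three methods."""
    return predictions.intersected()


# ===================================================================== filter

def anticorrelation_filter(target_pairs: set[tuple[str, str]],
                           de_table: pd.DataFrame,
                           mrna_fc: Mapping[tuple[str, str], float],
                           comparison: str,
                           overall_rpm: Mapping[str, float],
                           rpm_focus: float = RPM_FOCUS,
                           min_mrna_abs_lfc: float = 0.0) -> pd.DataFrame:
    """Keep pairs whose mRNA moved opposite to the DE miRNA.

    Only miRNAs called DE in ``comparison`` with overall average RPM above
    ``rpm_focus`` are considered; a pair is retained when the mRNA
    log2 fold change is nonzero (and at least ``min_mrna_abs_lfc`` in
    magnitude — sign-only by default) with the opposite sign. Pairs whose
    gene is missing from the mRNA table are dropped (counted in the log).
    """
    de = de_table[(de_table["comparison"] == comparison)
                  & (de_table["call"] != "ns")]
    lfc_of = dict(zip(de["mirna"], de["log2fc"]))
    rows = []
    n_missing = 0
    for mirna, gene in sorted(target_pairs):
        if mirna not in lfc_of:
            continue
        if overall_rpm.get(mirna, 0.0) <= rpm_focus:
            continue
        key = (gene, comparison)
        if key not in mrna_fc:
            n_missing += 1
            continue
        m_lfc = mrna_fc[key]
        if abs(m_lfc) > 0 and abs(m_lfc) >= min_mrna_abs_lfc \
                and np.sign(m_lfc) == -np.sign(lfc_of[mirna]):
            rows.append({"mirna": mirna, "gene": gene,
                         "comparison": comparison,
                         "mirna_log2fc": lfc_of[mirna],
                         "mrna_log2fc": m_lfc})
    out = pd.DataFrame(rows, columns=["mirna", "gene", "comparison",
                                      "mirna_log2fc", "mrna_log2fc"])
    out.attrs["n_missing_gene"] = n_missing
    return out


# ===================================================================== enrichment

def enrich(gene_list: Sequence[str],
           background: Sequence[str],
           gene_sets: Mapping[str, Sequence[str]],
           mode: str = "hypergeometric",
           alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric (or EASE) enrichment against gene sets.

    Sets are intersected with the background; the EASE variant decrements
    the overlap by one (floor 0), penalizing singleton overlaps. BH FDR is
    computed across sets; rows with p < alpha are flagged significant.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    query = set(gene_list) & bg
    if not set(gene_list) <= bg:
        raise ValueError("gene list must be a subset of the background")
    N, n = len(bg), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & bg
        K = len(members)
        k = len(query & members)
        k_eff = max(k - 1, 0) if mode == "EASE" else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append({"gene_set": name, "overlap": k, "list_size": n,
                     "set_size": K, "background": N, "pvalue": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["pvalue"] < alpha
    return out
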