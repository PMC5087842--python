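"""Novel miRNA discovery from unannotated genome-mapped tags.

Read stacks at unannotated loci are merged into clusters, candidate
precursor windows are excised around each cluster, folded with the
simplified stacking-energy model, and scored by two complementary
detectors whose intersection defines the final calls:

* detector A (score-based): a composite score over read-stack consistency,
  star-arm support, minimum free energy and mature-in-stem pairing must
  reach 5, and the structure must be more stable than dinucleotide
  shuffles (randomization p < 0.05);
* detector B (rule-based): MFE < -18 kcal/mol, the mature arm fully inside
  one stem arm, read 5'-end variability <= 4 nt, precursor 60-110 nt.

Duplicate calls of the same mature sequence from different genomic copies
collapse to one mature with all precursor records; final names are
assigned ``chi-miR-new-N`` by descending total raw count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mirnaome._seq import revcomp
from mirnaome.annotate import TagAnnotation
from mirnaome.folding import fold, shuffled_mfe_pvalue

MFE_THRESHOLD = -18.0          # kcal/mol, rule shared by both detectors
SCORE_THRESHOLD = 5.0          # detector A composite-score cutoff
SHUFFLE_P_THRESHOLD = 0.05     # structure-randomization cutoff
PRECURSOR_MIN, PRECURSOR_MAX = 60, 110
MIN_MATURE_PAIRED = 14         # stem-pairing requirement on the mature arm
MAX_OVERHANG_VARIABILITY = 4   # nt spread of mature-read 5' ends

# composite-score weights (documented; max attainable score 7.0)
W_READ_FRACTION = 2.5
W_STAR_SUPPORT = 1.5
W_MFE = 1.5
W_MATURE_IN_STEM = 1.5


@dataclass
class HairpinCandidate:
    chrom: str
    start: int              # 1-based inclusive window on the plus strand
    end: int
    strand: str
    precursor: str          # window sequence in read orientation
    structure: str = ""
    mfe: float = 0.0
    mature: str | None = None
    mature_pos: int | None = None       # 0-based within precursor
    star: str | None = None
    star_pos: int | None = None
    read_stack: list[tuple[int, str, int]] = field(default_factory=list)
    # (offset of tag 5' end within window, tag sequence, total count)
    score: float = 0.0
    detector_a: bool = False
    detector_b: bool = False
    shuffle_p: float = 1.0
    total_count: int = 0


@dataclass
class NovelCall:
    name: str
    mature: str
    total_count: int
    candidates: list[HairpinCandidate]


# ===================================================================== excision

def excise_candidates(annotations: dict[str, TagAnnotation],
                      tag_counts: dict[str, int],
                      genome: dict[str, str],
                      flank: int = 70,
                      merge_gap: int = 30,
                      min_reads: int = 5) -> list[HairpinCandidate]:
    """Excise candidate precursor windows around unannotated read clusters.

    Tags with ``novel-miRNA-candidate`` annotation are grouped per strand
    into clusters (gap <= merge_gap); each cluster with >= min_reads total
    reads yields two windows: the read block extended upstream and the
    block extended downstream, each capped at the maximum precursor length.
    Windows running off a contig end are truncated.
    """
    placements: dict[tuple[str, str], list[tuple[int, int, str, int]]] = {}
    for seq, ann in annotations.items():
        if ann.category != "novel-miRNA-candidate":
            continue
        n = tag_counts.get(seq, 0)
        if n == 0:
            continue
        for chrom, pos, strand in ann.loci:
            key = (chrom, strand)
            placements.setdefault(key, []).append(
                (pos, pos + len(seq) - 1, seq, n))
    out: list[HairpinCandidate] = []
    for (chrom, strand), items in sorted(placements.items()):
        items.sort()
        clusters: list[list[tuple[int, int, str, int]]] = []
        for it in items:
            if clusters and it[0] - max(e for _, e, _, _ in clusters[-1]) \
                    <= merge_gap:
                clusters[-1].append(it)
            else:
                clusters.append([it])
        glen = len(genome[chrom])
        for cl in clusters:
            total = sum(n for _, _, _, n in cl)
            if total < min_reads:
                continue
            bstart = min(s for s, _, _, _ in cl)
            bend = max(e for _, e, _, _ in cl)
            windows = []
            up_start = max(1, bend - min(PRECURSOR_MAX,
                                         bend - bstart + 1 + flank) + 1)
            windows.append((up_start, bend))
            down_end = min(glen, bstart + min(PRECURSOR_MAX,
                                              bend - bstart + 1 + flank) - 1)
            windows.append((bstart, down_end))
            for wstart, wend in dict.fromkeys(windows):
                seq = genome[chrom][wstart - 1:wend]
                if strand == "-":
                    seq = revcomp(seq)
                stack = []
                for s, e, t, n in cl:
                    if strand == "+":
                        off = s - wstart
                    else:
                        off = wend - e
                    stack.append((off, t, n))
                out.append(HairpinCandidate(
                    chrom=chrom, start=wstart, end=wend, strand=strand,
                    precursor=seq, read_stack=sorted(stack),
                    total_count=total))
    return out


# ===================================================================== scoring

def score_candidate(candidate: HairpinCandidate,
                    n_shuffles: int = 100,
                    seed: int = 0) -> HairpinCandidate:
    """Fold, score and flag one candidate under both detectors."""
    cand = candidate
    cand.structure, cand.mfe = fold(cand.precursor)
    pairs = _pairs_from_dotbracket(cand.structure)
    partner = {}
    for i, j in pairs:
        partner[i], partner[j] = j, i

    n = len(cand.precursor)
    stack = [(off, t, c) for off, t, c in cand.read_stack
             if 0 <= off and off + len(t) <= n]
    total = sum(c for _, _, c in stack)
    if total == 0:
        cand.score = 0.0
        return cand

    # dominant mature arm = the highest-count tag's placement
    dom = max(stack, key=lambda x: (x[2], -x[0]))
    m_off, m_seq = dom[0], dom[1]
    m_end = m_off + len(m_seq)
    cand.mature = m_seq
    cand.mature_pos = m_off

    consistent = [(off, t, c) for off, t, c in stack
                  if abs(off - m_off) <= 2
                  and abs((off + len(t)) - m_end) <= 2]
    frac = sum(c for _, _, c in consistent) / total

    # star arm = the region pairing with the mature arm
    partners = sorted(partner[k] for k in range(m_off, m_end) if k in partner)
    n_paired = len(partners)
    in_stem = (
        n_paired >= MIN_MATURE_PAIRED
        and (not partners or partners[-1] < m_off or partners[0] >= m_end)
    )
    star_support = False
    if partners and (partners[-1] < m_off or partners[0] >= m_end):
        s_lo, s_hi = partners[0], partners[-1] + 1
        cand.star = cand.precursor[s_lo:s_hi]
        cand.star_pos = s_lo
        for off, t, c in stack:
            if (off, t, c) in consistent:
                continue
            if abs(off - s_lo) <= 2 and abs(off + len(t) - s_hi) <= 2:
                star_support = True
                break

    mfe_ok = cand.mfe < MFE_THRESHOLD
    cand.score = (W_READ_FRACTION * frac
                  + W_STAR_SUPPORT * star_support
                  + W_MFE * mfe_ok
                  + W_MATURE_IN_STEM * in_stem)

    five_prime_spread = (max(off for off, _, _ in consistent)
                         - min(off for off, _, _ in consistent)
                         if consistent else 0)

    # shuffle p-value only when the score gate is otherwise reachable
    if cand.score >= SCORE_THRESHOLD or (
            mfe_ok and in_stem
            and five_prime_spread <= MAX_OVERHANG_VARIABILITY):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(seed, cand.start, cand.end)))
        cand.shuffle_p = shuffled_mfe_pvalue(cand.precursor, cand.mfe,
                                             n_shuffles, rng)
    else:
        cand.shuffle_p = 1.0

    cand.detector_a = (cand.score >= SCORE_THRESHOLD
                       and cand.shuffle_p < SHUFFLE_P_THRESHOLD)
    cand.detector_b = (
        mfe_ok and in_stem
        and five_prime_spread <= MAX_OVERHANG_VARIABILITY
        and PRECURSOR_MIN <= len(cand.precursor) <= PRECURSOR_MAX)
    return cand


def _pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            pairs.append((stack.pop(), k))
    return sorted(pairs)


# ===================================================================== calling

def call_novel(candidates: list[HairpinCandidate],
               prefix: str = "chi-miR-new") -> list[NovelCall]:
    """Intersect the detectors and collapse duplicate matures.

    A mature sequence is called when at least one of its candidate
    precursors passes both detectors; all passing precursor records are
    kept (the same mature can be processed from several genomic copies).
    Names are assigned by descending total raw count.
    """
    passed = [c for c in candidates
              if c.detector_a and c.detector_b and c.mature]
    by_mature: dict[str, list[HairpinCandidate]] = {}
    for c in passed:
        by_mature.setdefault(c.mature, []).append(c)
    calls = []
    for mature, cands in by_mature.items():
        total = max(c.total_count for c in cands)
        calls.append((mature, total, sorted(
            cands, key=lambda c: (c.chrom, c.start))))
    calls.sort(key=lambda x: (-x[1], x[0]))
    return [NovelCall(name=f"{prefix}-{k + 1}", mature=m, total_count=t,
                      candidates=cs)
            for k, (m, t, cs) in enumerate(calls)]


def discover_novel(annotations: dict[str, TagAnnotation],
                   tag_counts: dict[str, int],
                   genome: dict[str, str],
                   flank: int = 70,
                   n_shuffles: int = 100,
                   seed: int = 0,
                   min_reads: int = 5) -> tuple[list[NovelCall],
                                                list[HairpinCandidate]]:
    """Excise, score and call novel miRNAs; returns (calls, all candidates)."""
    candidates = excise_candidates(annotations, tag_counts, genome,
                                   flank=flank, min_reads=min_reads)
    scored = [score_candidate(c, n_shuffles=n_shuffles, seed=seed)
              for c in candidates]
    return call_novel(scored), scored
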