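"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or a closed
form, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from math import lgamma, comb, exp, log

import numpy as np

from mirnaome._seq import revcomp
from mirnaome.annotate import (EditHit, HomologHit, KnownHit, MiRNARegistry,
                               _edit_key, _homolog_key, _known_key)
from mirnaome.folding import energy_of_structure, pair_energy

MAXOFF = 2


# ----------------------------------------------------------- tolerant matchers

def oracle_known(tag: str, registry: MiRNARegistry) -> KnownHit | None:
    """Brute-force scan over all (mature, d5, d3) windows, 0 mismatches."""
    best = None
    for m in registry.own_matures:
        prec = registry.precursors[m.precursor_id].seq
        for d5 in range(-MAXOFF, MAXOFF + 1):
            for d3 in range(-MAXOFF, MAXOFF + 1):
                start = m.offset + d5
                end = m.offset + len(m.seq) + d3
                if start < 0 or end > len(prec) or end - start < 1:
                    continue
                if prec[start:end] == tag:
                    hit = KnownHit(m.id, d5, d3)
                    if best is None or _known_key(hit) < _known_key(best):
                        best = hit
    return best


def oracle_edited(tag: str, registry: MiRNARegistry) -> EditHit | None:
    """Brute-force scan, exactly one mismatch."""
    best = None
    for m in registry.own_matures:
        prec = registry.precursors[m.precursor_id].seq
        for d5 in range(-MAXOFF, MAXOFF + 1):
            for d3 in range(-MAXOFF, MAXOFF + 1):
                start = m.offset + d5
                end = m.offset + len(m.seq) + d3
                if start < 0 or end > len(prec) or end - start != len(tag):
                    continue
                var = prec[start:end]
                mism = [k for k in range(len(tag)) if var[k] != tag[k]]
                if len(mism) == 1:
                    k = mism[0]
                    hit = EditHit(m.id, k + d5 + 1, var[k], tag[k], d5, d3)
                    if best is None or _edit_key(hit) < _edit_key(best):
                        best = hit
    return best


def oracle_homolog(tag: str, registry: MiRNARegistry) -> HomologHit | None:
    """Brute-force scan over homolog entities, <=2 mismatches."""
    best = None
    for name, seq, _ in registry.homolog_entities():
        Lt, Lm = len(tag), len(seq)
        for d5 in range(-MAXOFF, MAXOFF + 1):
            d3 = d5 + Lt - Lm
            if abs(d3) > MAXOFF:
                continue
            lo, hi = max(0, -d5), min(Lt, Lm - d5)
            if hi - lo < 1:
                continue
            mm = sum(1 for k in range(lo, hi) if tag[k] != seq[k + d5])
            if mm <= 2:
                hit = HomologHit(name, mm, d5, d3)
                if best is None or _homolog_key(hit) < _homolog_key(best):
                    best = hit
    return best


def oracle_genome_scan(tag: str, genome: dict[str, str]) -> list:
    """Naive full scan for exact occurrences on both strands."""
    loci = []
    rc = revcomp(tag)
    for chrom in sorted(genome):
        s = genome[chrom]
        for query, strand in ((tag, "+"), (rc, "-")):
            start = 0
            while True:
                k = s.find(query, start)
                if k < 0:
                    break
                loci.append((chrom, k + 1, strand))
                start = k + 1
    return sorted(loci)


# ----------------------------------------------------------- NB exact test

def _nb_logpmf(k: int, r: float, mean: float) -> float:
    """Hand-rolled NB log pmf (size r, mean), independent of scipy."""
    p = r / (r + mean)
    return (lgamma(k + r) - lgamma(r) - lgamma(k + 1)
            + r * log(p) + k * log(1 - p))


def oracle_exact_test_p(sa: int, sb: int, na: int, nb: int,
                        phi: float) -> float:
    """Conditional two-sided exact p by explicit enumeration of splits."""
    t = sa + sb
    if t == 0:
        return 1.0
    mu = t / (na + nb)
    logs = []
    for k in range(t + 1):
        if phi == 0.0:
            # Poisson sums condition to a binomial
            lp = (log(comb(t, k)) + k * log(na / (na + nb))
                  + (t - k) * log(nb / (na + nb)))
        else:
            ra, rb = na / phi, nb / phi
            lp = (_nb_logpmf(k, ra, na * mu)
                  + _nb_logpmf(t - k, rb, nb * mu))
        logs.append(lp)
    mx = max(logs)
    probs = [exp(x - mx) for x in logs]
    z = sum(probs)
    obs = probs[sa]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)) / z)


# ----------------------------------------------------------- folding

def oracle_mfe(seq: str) -> float:
    """Exhaustive minimum energy over all nested structures (short seqs)."""
    n = len(seq)
    pairable = [[pair_energy(seq[i], seq[j]) < 0 for j in range(n)]
                for i in range(n)]
    best = [0.0]

    def rec(intervals: list[tuple[int, int]], pairs: list[tuple[int, int]]):
        if not intervals:
            if pairs:
                try:
                    e = energy_of_structure(seq, pairs)
                except ValueError:
                    return
                if e < best[0]:
                    best[0] = e
            return
        (i, j), rest = intervals[0], intervals[1:]
        if i >= j:
            rec(rest, pairs)
            return
        # i unpaired
        rec([(i + 1, j)] + rest, pairs)
        # i paired with k (hairpin loop >= 3)
        for k in range(i + 4, j + 1):
            if pairable[i][k]:
                rec([(i + 1, k - 1), (k + 1, j)] + rest, pairs + [(i, k)])

    rec([(0, n - 1)], [])
    return best[0]


# ----------------------------------------------------------- duplex

def oracle_duplex(seq_a: str, seq_b: str, max_loop: int = 30) -> float:
    """Exhaustive minimum over antiparallel intermolecular pair chains."""
    na, nb = len(seq_a), len(seq_b)
    pairs = [(i, j) for i in range(na) for j in range(nb)
             if pair_energy(seq_a[i], seq_b[j]) < 0]
    best = [0.0]

    def score(chain: list[tuple[int, int]]) -> float:
        e = 0.0
        for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
            if i2 == i1 + 1 and j2 == j1 - 1:
                e += 0.5 * (pair_energy(seq_a[i1], seq_b[j1])
                            + pair_energy(seq_a[i2], seq_b[j2]))
            else:
                e += 2.0
        return e

    def rec(chain: list[tuple[int, int]]):
        if chain:
            e = score(chain)
            if e < best[0]:
                best[0] = e
        last = chain[-1] if chain else None
        for (i, j) in pairs:
            if last is not None:
                i0, j0 = last
                if not (i > i0 and j < j0):
                    continue
                if (i - i0 - 1) + (j0 - j - 1) > max_loop:
                    continue
            rec(chain + [(i, j)])

    rec([])
    return best[0]


# ----------------------------------------------------------- hypergeometric

def oracle_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """Closed-form upper-tail hypergeometric from binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def oracle_hypergeom_mc(k: int, N: int, K: int, n: int, draws: int,
                        rng: np.random.Generator) -> float:
    """Monte-Carlo resampling estimate of the upper-tail probability."""
    pool = np.zeros(N, dtype=int)
    pool[:K] = 1
    hits = 0
    for _ in range(draws):
        take = rng.choice(N, size=n, replace=False)
        if pool[take].sum() >= k:
            hits += 1
    return hits / draws
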