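"""Simplified nested RNA secondary-structure folding.

A stacking-only nearest-neighbor-lite energy model: stacked base pairs
contribute the mean of the two pair energies (GC/CG -3.0, AU/UA -2.0,
GU/UG -1.0 kcal/mol); a hairpin closure costs +3.0 (loop >= 3 unpaired),
an interior loop or bulge +2.0 (total unpaired <= 30), a multiloop +3.0.
Isolated pairs contribute nothing, so the minimum free energy of any
sequence is <= 0 and the empty structure scores exactly 0.

The solver is an exact dynamic program over nested structures (no
pseudoknots) with deterministic traceback; :func:`energy_of_structure`
scores an explicit pair set under the same model, which lets exhaustive
enumeration at short lengths act as an independent oracle.

:func:`duplex_energy` applies the same stacking model to intermolecular
miRNA:target duplexes (no intramolecular pairs).
"""

from __future__ import annotations

import numpy as np
from numba import njit

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
HAIRPIN_PENALTY = 3.0
INTERIOR_PENALTY = 2.0
MULTILOOP_PENALTY = 3.0
MIN_HAIRPIN_LOOP = 3       # unpaired nt enclosed by a hairpin-closing pair
MAX_INTERIOR_UNPAIRED = 30  # model constraint on interior/bulge loop size

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_INF = 1e30

# 4x4 pair-energy table in encoded space (A,C,G,U)
_PAIR_TABLE = np.zeros((4, 4))
_PAIR_TABLE[2, 1] = _PAIR_TABLE[1, 2] = -3.0
_PAIR_TABLE[0, 3] = _PAIR_TABLE[3, 0] = -2.0
_PAIR_TABLE[2, 3] = _PAIR_TABLE[3, 2] = -1.0


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-ACGU symbol in sequence: {e}") from None


def pair_energy(a: str, b: str) -> float:
    """Energy of an (a, b) base pair; 0.0 means not pairable."""
    return PAIR_ENERGY.get((a.upper().replace("U", "T"),
                            b.upper().replace("U", "T")), 0.0)


@njit(cache=True)
def _fill(enc, pair_table, hp, ip, mp, min_loop, max_int):  # pragma: no cover
    n = enc.shape[0]
    V = np.full((n, n), _INF)
    W = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            e_ij = pair_table[enc[i], enc[j]]
            if e_ij < 0.0:
                best = _INF
                if j - i - 1 >= min_loop:
                    best = hp
                # stack on the directly enclosed pair
                if j - i - 1 >= 2:
                    e_in = pair_table[enc[i + 1], enc[j - 1]]
                    if e_in < 0.0 and V[i + 1, j - 1] < _INF / 2:
                        cand = V[i + 1, j - 1] + 0.5 * (e_ij + e_in)
                        if cand < best:
                            best = cand
                # interior loop / bulge
                kmax = min(i + 1 + max_int, j - 1)
                for k in range(i + 1, kmax + 1):
                    left = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_int - left))
                    for l in range(lmin, j):
                        if left + (j - l - 1) < 1:
                            continue
                        if V[k, l] < _INF / 2:
                            cand = V[k, l] + ip
                            if cand < best:
                                best = cand
                # multiloop: two strictly stabilizing halves
                for k in range(i + 2, j - 1):
                    wl = W[i + 1, k]
                    wr = W[k + 1, j - 1]
                    if wl < 0.0 and wr < 0.0:
                        cand = wl + wr + mp
                        if cand < best:
                            best = cand
                V[i, j] = best
            # W
            w = W[i + 1, j] if i + 1 <= j else 0.0
            if V[i, j] < w:
                w = V[i, j]
            for k in range(i + 1, j):
                if V[i, k] < _INF / 2:
                    cand = V[i, k] + W[k + 1, j]
                    if cand < w:
                        w = cand
            if w < 0.0:
                W[i, j] = w
            else:
                W[i, j] = 0.0
    return V, W


def fold(seq: str) -> tuple[str, float]:
    """Minimum-free-energy nested structure of a sequence.

    Returns (dot-bracket string, mfe in kcal/mol). Deterministic: ties in
    the dynamic program resolve by a fixed traceback order.
    """
    enc = encode(seq)
    n = len(enc)
    if n < 2:
        return "." * n, 0.0
    V, W = _fill(enc, _PAIR_TABLE, HAIRPIN_PENALTY, INTERIOR_PENALTY,
                 MULTILOOP_PENALTY, MIN_HAIRPIN_LOOP, MAX_INTERIOR_UNPAIRED)
    pairs = _traceback(enc, V, W)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), float(W[0, n - 1])


def _traceback(enc, V, W) -> list[tuple[int, int]]:
    eps = 1e-9
    pt = _PAIR_TABLE
    pairs: list[tuple[int, int]] = []
    n = len(enc)
    stack = [(0, n - 1, "W")]
    while stack:
        i, j, which = stack.pop()
        if i >= j:
            continue
        if which == "W":
            w = W[i, j]
            if w >= -eps:
                continue
            if i + 1 <= j and abs(W[i + 1, j] - w) < eps:
                stack.append((i + 1, j, "W"))
                continue
            if abs(V[i, j] - w) < eps:
                stack.append((i, j, "V"))
                continue
            for k in range(i + 1, j):
                if V[i, k] < _INF / 2 and abs(V[i, k] + W[k + 1, j] - w) < eps:
                    stack.append((i, k, "V"))
                    stack.append((k + 1, j, "W"))
                    break
            continue
        # V
        v = V[i, j]
        pairs.append((i, j))
        e_ij = pt[enc[i], enc[j]]
        if j - i - 1 >= MIN_HAIRPIN_LOOP and abs(v - HAIRPIN_PENALTY) < eps:
            continue
        if j - i - 1 >= 2:
            e_in = pt[enc[i + 1], enc[j - 1]]
            if (e_in < 0 and V[i + 1, j - 1] < _INF / 2
                    and abs(V[i + 1, j - 1] + 0.5 * (e_ij + e_in) - v) < eps):
                stack.append((i + 1, j - 1, "V"))
                continue
        found = False
        kmax = min(i + 1 + MAX_INTERIOR_UNPAIRED, j - 1)
        for k in range(i + 1, kmax + 1):
            left = k - i - 1
            lmin = max(k + 1, j - 1 - (MAX_INTERIOR_UNPAIRED - left))
            for l in range(lmin, j):
                if left + (j - l - 1) < 1:
                    continue
                if V[k, l] < _INF / 2 and abs(V[k, l] + INTERIOR_PENALTY - v) < eps:
                    stack.append((k, l, "V"))
                    found = True
                    break
            if found:
                break
        if found:
            continue
        for k in range(i + 2, j - 1):
            if (W[i + 1, k] < 0 and W[k + 1, j - 1] < 0
                    and abs(W[i + 1, k] + W[k + 1, j - 1]
                            + MULTILOOP_PENALTY - v) < eps):
                stack.append((i + 1, k, "W"))
                stack.append((k + 1, j - 1, "W"))
                break
    return sorted(pairs)


def energy_of_structure(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Score an explicit nested pair set under the folding energy model.

    Raises ValueError for non-nested structures, unpairable bases,
    hairpin loops under the minimum size, or interior loops above the
    model's size cap.
    """
    n = len(seq)
    partner = {}
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError("pair out of range")
        if i in partner or j in partner:
            raise ValueError("base in two pairs")
        partner[i], partner[j] = j, i
    for i, j in pairs:
        for k, l in pairs:
            if i < k < j < l:
                raise ValueError("pseudoknotted pairs")
    total = 0.0
    spairs = sorted(pairs)
    for i, j in spairs:
        if pair_energy(seq[i], seq[j]) >= 0:
            raise ValueError(f"unpairable bases at {(i, j)}")
        children = [(k, l) for k, l in spairs
                    if i < k < l < j
                    and not any(i < a < k and l < b < j for a, b in spairs)]
        if not children:
            if j - i - 1 < MIN_HAIRPIN_LOOP:
                raise ValueError("hairpin loop too small")
            total += HAIRPIN_PENALTY
        elif len(children) == 1:
            k, l = children[0]
            if (k, l) == (i + 1, j - 1):
                total += 0.5 * (pair_energy(seq[i], seq[j])
                                + pair_energy(seq[k], seq[l]))
            else:
                unpaired = (k - i - 1) + (j - l - 1)
                if unpaired > MAX_INTERIOR_UNPAIRED:
                    raise ValueError("interior loop above model cap")
                total += INTERIOR_PENALTY
        else:
            total += MULTILOOP_PENALTY
    return total


# ===================================================================== shuffle

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving the dinucleotide composition.

    Altschul–Erickson style: the sequence is an Eulerian walk on the
    first-order transition multigraph; a random walk with a valid
    last-edge tree reproduces the exact dinucleotide counts.
    """
    n = len(seq)
    if n < 3:
        return seq
    chars = sorted(set(seq))
    if len(chars) == 1:
        return seq
    adj: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        adj[a].append(b)
    last = seq[-1]
    vertices = [c for c in chars if adj[c]]
    for _ in range(200):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = adj[v][int(rng.integers(0, len(adj[v])))]
        # the chosen last edges must lead every vertex to the final vertex
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return seq
    walk_adj: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(adj[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        edges = [edges[k] for k in perm]
        if v in last_edge:
            edges.append(last_edge[v])
        walk_adj[v] = edges
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = walk_adj[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffled_mfe_pvalue(seq: str, mfe: float, n_shuffles: int,
                        rng: np.random.Generator) -> float:
    """Fraction of dinucleotide-shuffled sequences with mfe <= observed."""
    hits = 0
    for _ in range(n_shuffles):
        s = dinucleotide_shuffle(seq, rng)
        _, m = fold(s)
        if m <= mfe:
            hits += 1
    return hits / n_shuffles


# ===================================================================== duplex

def duplex_energy(seq_a: str, seq_b: str,
                  max_loop: int = 30) -> float:
    """Minimum-energy intermolecular duplex under the stacking model.

    ``seq_a`` (miRNA, 5'->3') pairs antiparallel with ``seq_b`` (target
    window, 5'->3'): pairs (i, j) chain with increasing i and decreasing j.
    Adjacent pairs stack (mean of the two pair energies); interrupted
    chains pay the interior-loop penalty. No intramolecular pairs. The
    empty duplex scores 0.
    """
    a = encode(seq_a)
    b = encode(seq_b)
    na, nb = len(a), len(b)
    if na > 80 or nb > 80:
        raise ValueError("duplex sequences must be <= 80 nt")
    pt = _PAIR_TABLE
    D = np.full((na, nb), _INF)
    best = 0.0
    for i in range(na):
        for j in range(nb):
            e_ij = pt[a[i], b[j]]
            if e_ij >= 0.0:
                continue
            d = 0.0  # chain starting at this pair
            # extend from a previous pair (i' < i, j' > j)
            for ip in range(max(0, i - max_loop - 1), i):
                gap_a = i - ip - 1
                for jp in range(j + 1, min(nb, j + max_loop + 2 - gap_a)):
                    if D[ip, jp] >= _INF / 2:
                        continue
                    e_prev = pt[a[ip], b[jp]]
                    if gap_a == 0 and jp == j + 1:
                        cand = D[ip, jp] + 0.5 * (e_ij + e_prev)
                    else:
                        cand = D[ip, jp] + INTERIOR_PENALTY
                    if cand < d:
                        d = cand
            D[i, j] = d
            if d < best:
                best = d
    return float(best)
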