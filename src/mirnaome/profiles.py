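"""Short time-series clustering against model expression profiles.

Candidate integer profiles start at 0 and change by at most c units
between consecutive stages; if the (2c+1)^(T-1) candidates exceed the
profile budget m, a greedy max-min-distance subset seeded from the flat
profile is kept. Each miRNA's stage-mean log2(RPM+1) trajectory is
assigned to the profile maximizing Pearson correlation. Per-profile
significance compares the observed assignment count with its expectation
under all T! stage-order permutations (upper-tail binomial, Bonferroni
corrected over profiles) — the permutation scheme of short time-series
expression-miner methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy.stats import binom

MAX_UNIT_CHANGE = 1
MAX_PROFILES = 30
ALPHA = 0.05


@dataclass(frozen=True)
class ModelProfile:
    id: int
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.values[0] != 0:
            raise ValueError("profiles start at 0")


def enumerate_profiles(T: int, c: int = MAX_UNIT_CHANGE,
                       m: int = MAX_PROFILES) -> list[ModelProfile]:
    """All (2c+1)^(T-1) candidate profiles, reduced to m if needed.

    Reduction keeps a greedy maximally-distinct subset (max-min Euclidean
    distance), deterministically seeded from the flat profile.
    """
    if T < 2 or c < 1 or m < 1:
        raise ValueError("need T >= 2, c >= 1, m >= 1")
    deltas = range(-c, c + 1)
    values = []
    for diffs in product(deltas, repeat=T - 1):
        v = [0]
        for d in diffs:
            v.append(v[-1] + d)
        values.append(tuple(v))
    values.sort()
    if len(values) > m:
        flat = tuple([0] * T)
        chosen = [flat]
        rest = [v for v in values if v != flat]
        arr = {v: np.array(v, dtype=float) for v in values}
        while len(chosen) < m and rest:
            best, best_d = None, -1.0
            for v in rest:
                d = min(float(np.linalg.norm(arr[v] - arr[u])) for u in chosen)
                if d > best_d + 1e-12 or (abs(d - best_d) <= 1e-12
                                          and best is not None and v < best):
                    best, best_d = v, d
            chosen.append(best)
            rest.remove(best)
        values = sorted(chosen)
    return [ModelProfile(i, v) for i, v in enumerate(values)]


# ===================================================================== assignment

def _correlation_matrix(traj: np.ndarray, profs: np.ndarray) -> np.ndarray:
    """Pearson r between each trajectory row and each profile row.

    Zero-variance rows on either side yield NaN columns/rows.
    """
    tz = traj - traj.mean(axis=1, keepdims=True)
    pz = profs - profs.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tz, axis=1)
    pn = np.linalg.norm(pz, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tz @ pz.T) / np.outer(tn, pn)
    return r


def assign_profiles(trajectories: pd.DataFrame,
                    profiles: list[ModelProfile]) -> pd.DataFrame:
    """Assign each trajectory to its maximally correlated profile.

    ``trajectories``: rows = miRNAs, columns = stages in temporal order
    (stage-mean log2(RPM+1)). Flat trajectories (undefined r) go to the
    flat profile; ties break toward the lower profile id.
    """
    if len(trajectories) == 0:
        return pd.DataFrame(columns=["profile", "correlation"],
                            index=pd.Index([], name="mirna"))
    profs = np.array([p.values for p in profiles], dtype=float)
    traj = trajectories.to_numpy(dtype=float)
    r = _correlation_matrix(traj, profs)
    flat_id = _flat_profile_id(profiles)
    rows = []
    for k, mid in enumerate(trajectories.index):
        rk = r[k]
        if np.all(np.isnan(rk)):
            pid, rbest = flat_id, np.nan
        else:
            rbest = np.nanmax(rk)
            pid = int(np.nanargmax(rk))  # argmax returns first (lowest id) tie
        rows.append({"mirna": mid, "profile": profiles[pid].id,
                     "correlation": rbest})
    return pd.DataFrame(rows).set_index("mirna")


def _flat_profile_id(profiles: list[ModelProfile]) -> int:
    for p in profiles:
        if all(v == 0 for v in p.values):
            return p.id
    return profiles[0].id


# ===================================================================== significance

def profile_significance(trajectories: pd.DataFrame,
                         profiles: list[ModelProfile],
                         assignments: pd.DataFrame | None = None,
                         alpha: float = ALPHA) -> pd.DataFrame:
    """Permutation-expected counts and binomial p per profile.

    The expected assignment count of each profile is the average over all
    T! stage-order permutations of the number of miRNAs assigned to it;
    p is the upper-tail binomial probability of >= the observed count in n
    trials at rate expected/n, Bonferroni corrected over profiles.
    """
    if assignments is None:
        assignments = assign_profiles(trajectories, profiles)
    n = len(trajectories)
    prof_ids = [p.id for p in profiles]
    if n == 0:
        return pd.DataFrame(columns=["profile", "observed", "expected",
                                     "pvalue", "corrected_pvalue",
                                     "significant"]).set_index("profile")
    observed = assignments["profile"].value_counts().reindex(
        prof_ids, fill_value=0)
    T = trajectories.shape[1]
    profs = np.array([p.values for p in profiles], dtype=float)
    traj = trajectories.to_numpy(dtype=float)
    flat_id = _flat_profile_id(profiles)
    id_index = {pid: k for k, pid in enumerate(prof_ids)}
    exp_counts = np.zeros(len(profiles))
    perms = list(permutations(range(T)))
    for perm in perms:
        r = _correlation_matrix(traj[:, perm], profs)
        for k in range(n):
            rk = r[k]
            if np.all(np.isnan(rk)):
                exp_counts[id_index[flat_id]] += 1
            else:
                exp_counts[int(np.nanargmax(rk))] += 1
    expected = exp_counts / len(perms)
    rows = []
    m = len(profiles)
    for pid in prof_ids:
        k = id_index[pid]
        e = expected[k]
        obs = int(observed[pid])
        p0 = min(e / n, 1.0)
        p = float(binom.sf(obs - 1, n, p0)) if p0 > 0 else float(obs > 0) * 0.0
        if p0 == 0.0:
            p = 0.0 if obs > 0 else 1.0
        corrected = min(1.0, p * m)
        rows.append({"profile": pid, "observed": obs, "expected": e,
                     "pvalue": p, "corrected_pvalue": corrected,
                     "significant": corrected < alpha})
    return pd.DataFrame(rows).set_index("profile")


def stage_trajectories(stage_rpm: pd.DataFrame) -> pd.DataFrame:
    """log2(RPM+1) trajectories from a stage-mean RPM table."""
    return np.log2(stage_rpm + 1.0)
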