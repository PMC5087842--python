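"""Read cleaning, tag collapsing and length distributions.

Raw 50 bp single-end reads are filtered by whole-read rules applied in a
fixed order — too many N bases, too many low-quality bases, 5'-adapter
contamination, missing 3' adapter, empty insert (adapter dimer), poly(A)
insert, and insert-length bounds — then trimmed to the insert and collapsed
to unique tags with per-library counts. No base-level quality trimming is
performed; a read passes or fails whole.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: rejection reasons, in the order the rules are tested
REASONS = (
    "too-many-N",
    "low-quality",
    "has-5'-adapter",
    "no-3'-adapter",
    "no-insert",
    "polyA",
    "too-short",
    "too-long",
)


@dataclass
class QCParams:
    """Whole-read filtering parameters.

    A read is rejected when it has more than ``max_n`` N bases, more than
    ``max_low_quality_bases`` bases under ``quality_threshold`` (Phred), a
    5'-adapter prefix, no ``adapter_match_min``-nt prefix of the 3' adapter,
    an empty insert, a poly(A) insert (A fraction >= ``polya_fraction``), or
    an insert outside [``min_insert_length``, ``max_insert_length``].
    """

    adapter3: str
    adapter5: str
    max_n: int = 1
    quality_threshold: int = 20
    max_low_quality_bases: int = 1
    min_insert_length: int = 16
    max_insert_length: int = 35
    polya_fraction: float = 0.9
    adapter_match_min: int = 8

    def __post_init__(self) -> None:
        if self.min_insert_length < 1:
            raise ValueError("min_insert_length must be >= 1")
        if min(self.max_n, self.quality_threshold,
               self.max_low_quality_bases) < 0:
            raise ValueError("thresholds must be non-negative")


class FastqParseError(ValueError):
    """Malformed FASTQ record (sequence/quality length mismatch)."""


def filter_read(seq: str, qual: str, params: QCParams,
                record_index: int | None = None,
                ) -> tuple[bool, str]:
    """Apply the rejection rules to one read.

    Returns ``(True, insert)`` for a kept read (3'-adapter-trimmed insert)
    or ``(False, reason)`` with the first failing rule's reason.
    """
    if len(seq) != len(qual):
        idx = "" if record_index is None else f" at record {record_index}"
        raise FastqParseError(
            f"sequence/quality length mismatch{idx}: "
            f"{len(seq)} vs {len(qual)}")
    if seq.count("N") > params.max_n:
        return False, "too-many-N"
    thresh = chr(params.quality_threshold + 33)
    n_low = sum(1 for c in qual if c < thresh)
    if n_low > params.max_low_quality_bases:
        return False, "low-quality"
    a5_probe = params.adapter5[-params.adapter_match_min:]
    if seq.startswith(a5_probe):
        return False, "has-5'-adapter"
    a3_probe = params.adapter3[: params.adapter_match_min]
    pos = seq.find(a3_probe)
    if pos < 0:
        return False, "no-3'-adapter"
    insert = seq[:pos]
    if not insert:
        return False, "no-insert"
    if insert.count("A") / len(insert) >= params.polya_fraction:
        return False, "polyA"
    if len(insert) < params.min_insert_length:
        return False, "too-short"
    if len(insert) > params.max_insert_length:
        return False, "too-long"
    return True, insert


# ===================================================================== tags

@dataclass
class UniqueTag:
    """A collapsed clean-insert sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def collapse_reads(clean_inserts: Mapping[str, Iterable[str]],
                   ) -> list[UniqueTag]:
    """Collapse clean inserts per library into unique tags.

    ``clean_inserts`` maps library label to an iterable of kept inserts.
    One tag per distinct sequence; per-library counts sum to the
    per-library clean-read totals. Output is ordered by descending total
    count, then sequence (stable under input read order).
    """
    per_lib = {lib: Counter(inserts) for lib, inserts in clean_inserts.items()}
    tags: dict[str, UniqueTag] = {}
    for lib in per_lib:
        for seq, n in per_lib[lib].items():
            tags.setdefault(seq, UniqueTag(seq)).counts[lib] = n
    return sorted(tags.values(), key=lambda t: (-t.total, t.sequence))


@dataclass
class QCResult:
    """Per-library QC bookkeeping: kept/rejected counts and the tags."""

    tags: list[UniqueTag]
    summary: pd.DataFrame       # rows: libraries; columns: raw, clean, reasons
    libraries: list[str]

    def length_distribution(self, library: str) -> dict[int, float]:
        return length_distribution(self.tags, library)


def run_qc(reads_per_library: Mapping[str, Iterable[tuple[str, str, str]]],
           params: QCParams) -> QCResult:
    """Filter and collapse all libraries.

    ``reads_per_library`` maps library label to (name, seq, qual) reads.
    Identical (sequence, quality) pairs are filtered once and their counts
    pooled, which leaves the result invariant to read order.
    """
    libraries = list(reads_per_library)
    clean: dict[str, dict[str, int]] = {}
    rows = []
    for lib in libraries:
        groups: Counter[tuple[str, str]] = Counter()
        raw = 0
        for rec_idx, (_, seq, qual) in enumerate(reads_per_library[lib]):
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"sequence/quality length mismatch at record {rec_idx} "
                    f"of library {lib}")
            groups[(seq, qual)] += 1
            raw += 1
        kept: dict[str, int] = {}
        reject = dict.fromkeys(REASONS, 0)
        for (seq, qual), n in groups.items():
            ok, result = filter_read(seq, qual, params)
            if ok:
                kept[result] = kept.get(result, 0) + n
            else:
                reject[result] += n
        clean[lib] = kept
        row = {"library": lib, "raw_reads": raw,
               "clean_reads": sum(kept.values())}
        row.update(reject)
        rows.append(row)
    # collapse directly from count dicts (avoids re-expanding reads)
    tags: dict[str, UniqueTag] = {}
    for lib, kept in clean.items():
        for seq, n in kept.items():
            tags.setdefault(seq, UniqueTag(seq)).counts[lib] = n
    tag_list = sorted(tags.values(), key=lambda t: (-t.total, t.sequence))
    summary = pd.DataFrame(rows).set_index("library")
    return QCResult(tags=tag_list, summary=summary, libraries=libraries)


def length_distribution(tags: Sequence[UniqueTag], library: str,
                        ) -> dict[int, float]:
    """Count-weighted insert-length histogram for one library (sums to 1)."""
    hist: Counter[int] = Counter()
    for t in tags:
        n = t.counts.get(library, 0)
        if n:
            hist[t.length] += n
    total = sum(hist.values())
    if total == 0:
        return {}
    return {L: hist[L] / total for L in sorted(hist)}


def length_distribution_table(tags: Sequence[UniqueTag],
                              libraries: Sequence[str]) -> pd.DataFrame:
    """Length x library fraction table (for the clean-read length figure)."""
    dists = {lib: length_distribution(tags, lib) for lib in libraries}
    lengths = sorted({L for d in dists.values() for L in d})
    return pd.DataFrame(
        {lib: [dists[lib].get(L, 0.0) for L in lengths] for lib in libraries},
        index=pd.Index(lengths, name="length"))
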