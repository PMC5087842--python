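"""Hierarchical annotation of unique small-RNA tags.

Each collapsed tag is assigned to exactly one category following the
priority hierarchy used in small-RNA annotation:

    ncRNA (rRNA/tRNA/snRNA/snoRNA) > known miRNA (incl. edited)
        > repeat > exon > novel-miRNA candidate > intron > unannotated

Known-miRNA matching is tolerant of isomiR end variation: a tag matches a
mature arm if it aligns inside the precursor with zero mismatches and both
ends within +/-2 nt of the annotated mature ends. A single internal
mismatch under the same end window is reported as an edited miRNA
(RNA editing or SNP). Tags failing both are compared against mature arms of
other species (<=2 mismatches, same +/-2 nt end windows) and reported as
cross-species homologs. Remaining tags are mapped exactly to the genome and
classified by feature overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from mirnaome import io
from mirnaome._seq import revcomp

logger = logging.getLogger(__name__)

DNA = "ACGT"

#: categories a tag can receive, in priority order
CATEGORIES = (
    "ncRNA",
    "known-miRNA",
    "edited-miRNA",
    "repeat",
    "exon",
    "novel-miRNA-candidate",
    "intron",
    "unannotated",
)

MAX_END_OFFSET = 2  # +/- nt window on each end for tolerant matching
MAX_HOMOLOG_MISMATCHES = 2


# ===================================================================== registry

@dataclass(frozen=True)
class PrecursorRecord:
    id: str
    seq: str
    chrom: str | None  # None for foreign-species entries without coordinates
    start: int | None  # 1-based inclusive
    end: int | None
    strand: str | None
    species: str
    own: bool


@dataclass(frozen=True)
class MatureRecord:
    id: str
    seq: str
    precursor_id: str
    offset: int  # 0-based offset of the mature 5' end within the precursor
    species: str
    own: bool


class MiRNARegistry:
    """miRBase-like registry of precursors and mature arms.

    Own-species entries carry genomic coordinates; foreign-species entries
    are used only for homolog matching (identical foreign mature sequences
    across species collapse to one homolog entity, named without the
    species prefix).
    """

    def __init__(self, precursors: Sequence[PrecursorRecord],
                 matures: Sequence[MatureRecord]):
        self.precursors = {p.id: p for p in precursors}
        self.matures = list(matures)
        self.validate()

    # ------------------------------------------------------------- invariants
    def validate(self) -> None:
        for m in self.matures:
            prec = self.precursors[m.precursor_id]
            sub = prec.seq[m.offset:m.offset + len(m.seq)]
            if sub != m.seq:
                raise ValueError(
                    f"mature {m.id} does not map into precursor "
                    f"{m.precursor_id} at offset {m.offset}"
                )
            if not 19 <= len(m.seq) <= 25:
                raise ValueError(f"mature {m.id} length {len(m.seq)} outside 19-25")

    # ------------------------------------------------------------- accessors
    @property
    def own_matures(self) -> list[MatureRecord]:
        return [m for m in self.matures if m.own]

    @property
    def foreign_matures(self) -> list[MatureRecord]:
        return [m for m in self.matures if not m.own]

    def homolog_entities(self) -> list[tuple[str, str, tuple[str, ...]]]:
        """Collapse identical foreign mature sequences to one entity.

        Returns (entity name, sequence, species tuple); the name drops the
        species prefix (reporting style of cross-species homolog tables) and
        ties between distinct ids with identical sequence resolve to the
        lexicographically smallest stripped name.
        """
        by_seq: dict[str, list[MatureRecord]] = {}
        for m in self.foreign_matures:
            by_seq.setdefault(m.seq, []).append(m)
        entities = []
        for seq, recs in by_seq.items():
            names = sorted(_strip_species_prefix(r.id) for r in recs)
            species = tuple(sorted({r.species for r in recs}))
            entities.append((names[0], seq, species))
        entities.sort(key=lambda e: e[0])
        return entities

    # ------------------------------------------------------------- on-disk
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(outdir / "precursors.fa",
                       [(p.id, p.seq) for p in self.precursors.values()])
        io.write_fasta(outdir / "matures.fa", [(m.id, m.seq) for m in self.matures])
        rows = []
        for p in self.precursors.values():
            chrom = p.chrom if p.chrom is not None else "unplaced"
            start = p.start if p.start is not None else 1
            end = p.end if p.end is not None else len(p.seq)
            strand = p.strand if p.strand is not None else "+"
            rows.append((chrom, "mirnaome", "miRNA_primary_transcript", start, end,
                         strand, f"ID={p.id};species={p.species};own={int(p.own)}"))
        for m in self.matures:
            p = self.precursors[m.precursor_id]
            chrom = p.chrom if p.chrom is not None else "unplaced"
            if p.chrom is not None and p.strand == "-":
                m_end = p.end - m.offset
                m_start = m_end - len(m.seq) + 1
            elif p.chrom is not None:
                m_start = p.start + m.offset
                m_start, m_end = m_start, m_start + len(m.seq) - 1
            else:
                m_start, m_end = m.offset + 1, m.offset + len(m.seq)
            strand = p.strand if p.strand is not None else "+"
            rows.append((chrom, "mirnaome", "miRNA", m_start, m_end, strand,
                         f"ID={m.id};Parent={m.precursor_id};offset={m.offset};"
                         f"species={m.species};own={int(m.own)}"))
        io.write_gff3(outdir / "registry.gff3", rows)

    @classmethod
    def load(cls, indir: str | Path) -> "MiRNARegistry":
        indir = Path(indir)
        prec_seqs = io.read_fasta(indir / "precursors.fa")
        mat_seqs = io.read_fasta(indir / "matures.fa")
        gff = io.read_gff3(indir / "registry.gff3")
        precursors, matures = [], []
        for _, row in gff.iterrows():
            a = row["attributes"]
            own = bool(int(a.get("own", "1")))
            placed = row["chrom"] != "unplaced"
            if row["type"] == "miRNA_primary_transcript":
                precursors.append(PrecursorRecord(
                    id=a["ID"], seq=prec_seqs[a["ID"]],
                    chrom=row["chrom"] if placed else None,
                    start=int(row["start"]) if placed else None,
                    end=int(row["end"]) if placed else None,
                    strand=row["strand"] if placed else None,
                    species=a["species"], own=own))
            else:
                matures.append(MatureRecord(
                    id=a["ID"], seq=mat_seqs[a["ID"]], precursor_id=a["Parent"],
                    offset=int(a["offset"]), species=a["species"], own=own))
        return cls(precursors, matures)

    def mature_coordinates(self) -> dict[str, tuple[str, int, int, str]]:
        """Genomic coordinates (chrom, start, end, strand) of own matures."""
        coords = {}
        for m in self.own_matures:
            p = self.precursors[m.precursor_id]
            if p.chrom is None:
                continue
            if p.strand == "-":
                end = p.end - m.offset
                start = end - len(m.seq) + 1
            else:
                start = p.start + m.offset
                end = start + len(m.seq) - 1
            coords[m.id] = (p.chrom, start, end, p.strand)
        return coords


def _strip_species_prefix(mid: str) -> str:
    parts = mid.split("-", 1)
    if len(parts) == 2 and len(parts[0]) <= 4 and parts[0].islower():
        return parts[1]
    return mid


# ===================================================================== hits

@dataclass(frozen=True)
class KnownHit:
    mature_id: str
    offset5: int  # tag 5' start minus mature 5' start (precursor coords)
    offset3: int  # tag 3' end minus mature 3' end


@dataclass(frozen=True)
class EditHit:
    mature_id: str
    position: int  # 1-based position in mature coordinates
    from_base: str
    to_base: str
    offset5: int
    offset3: int


@dataclass(frozen=True)
class HomologHit:
    entity: str
    mismatches: int
    offset5: int
    offset3: int


@dataclass
class TagAnnotation:
    sequence: str
    category: str
    assigned_mirna: str | None = None
    variant: tuple | None = None  # (offset5, offset3, n_mismatch, detail)
    homolog_of: str | None = None
    loci: list[tuple[str, int, str]] = field(default_factory=list)


# ===================================================================== indexes

class NcRNAIndex:
    """Exact-substring index over a contaminant ncRNA reference set."""

    def __init__(self, ncrna_set: Iterable[tuple[str, str, str]],
                 min_len: int = 16, max_len: int = 35):
        self._index: dict[str, tuple[str, str]] = {}
        for name, seq, cls in ncrna_set:
            n = len(seq)
            for L in range(min_len, min(max_len, n) + 1):
                for i in range(n - L + 1):
                    sub = seq[i:i + L]
                    if sub not in self._index:
                        self._index[sub] = (name, cls)

    def match(self, tag: str) -> tuple[str, str] | None:
        return self._index.get(tag)


def match_ncrna(tag: str, index: NcRNAIndex) -> tuple[str, str] | None:
    """Exact-substring hit against the ncRNA set, or None."""
    return index.match(tag)


class RegistryIndex:
    """Precomputed tolerant-matching indexes over a miRNA registry."""

    def __init__(self, registry: MiRNARegistry):
        self.registry = registry
        self._known: dict[str, KnownHit] = {}
        for m in sorted(registry.own_matures, key=lambda m: m.id):
            prec = registry.precursors[m.precursor_id].seq
            for d5 in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
                start = m.offset + d5
                if start < 0:
                    continue
                for d3 in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
                    end = m.offset + len(m.seq) + d3
                    if end > len(prec) or end - start < 1:
                        continue
                    var = prec[start:end]
                    hit = KnownHit(m.id, d5, d3)
                    prev = self._known.get(var)
                    if prev is None or _known_key(hit) < _known_key(prev):
                        self._known[var] = hit
        # homolog entities with a 7-mer prefilter
        self.entities = registry.homolog_entities()
        self._seed7: dict[str, set[int]] = {}
        for idx, (_, seq, _) in enumerate(self.entities):
            for i in range(len(seq) - 6):
                self._seed7.setdefault(seq[i:i + 7], set()).add(idx)

    # ------------------------------------------------------------- known
    def match_known(self, tag: str) -> KnownHit | None:
        """Zero-mismatch isomiR match (ends within +/-2 nt), or None."""
        return self._known.get(tag)

    # ------------------------------------------------------------- edited
    def detect_edited(self, tag: str) -> EditHit | None:
        """Exactly-one-mismatch match under the same end windows, or None."""
        best: EditHit | None = None
        for i, base in enumerate(tag):
            for b in DNA:
                if b == base:
                    continue
                cand = tag[:i] + b + tag[i + 1:]
                hit = self._known.get(cand)
                if hit is None:
                    continue
                edit = EditHit(hit.mature_id, i + hit.offset5 + 1, b, base,
                               hit.offset5, hit.offset3)
                if best is None or _edit_key(edit) < _edit_key(best):
                    best = edit
        return best

    # ------------------------------------------------------------- homolog
    def match_homolog(self, tag: str) -> HomologHit | None:
        """Best foreign-mature match (<=2 mismatches, ends within +/-2 nt)."""
        cand_ids: set[int] = set()
        for i in range(len(tag) - 6):
            hits = self._seed7.get(tag[i:i + 7])
            if hits:
                cand_ids.update(hits)
        best: HomologHit | None = None
        for idx in sorted(cand_ids):
            name, seq, _ = self.entities[idx]
            hit = _align_homolog(tag, seq, name)
            if hit is not None and (best is None or _homolog_key(hit) < _homolog_key(best)):
                best = hit
        return best


def _known_key(h: KnownHit):
    return (abs(h.offset5) + abs(h.offset3), h.mature_id)


def _edit_key(e: EditHit):
    return (abs(e.offset5) + abs(e.offset3), e.mature_id, e.position)


def _homolog_key(h: HomologHit):
    return (h.mismatches, abs(h.offset5) + abs(h.offset3), h.entity)


def _align_homolog(tag: str, mature: str, name: str) -> HomologHit | None:
    """Best end-anchored alignment of tag against a bare mature sequence.

    Overhanging tag bases beyond the mature (no precursor context is
    available for foreign entries) are unconstrained; mismatches are
    counted over the overlapped positions only.
    """
    Lt, Lm = len(tag), len(mature)
    best: HomologHit | None = None
    for d5 in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
        d3 = d5 + Lt - Lm
        if abs(d3) > MAX_END_OFFSET:
            continue
        lo = max(0, -d5)
        hi = min(Lt, Lm - d5)
        if hi - lo < 1:
            continue
        mm = sum(1 for i in range(lo, hi) if tag[i] != mature[i + d5])
        if mm <= MAX_HOMOLOG_MISMATCHES:
            hit = HomologHit(name, mm, d5, d3)
            if best is None or _homolog_key(hit) < _homolog_key(best):
                best = hit
    return best


# ===================================================================== genome

class GenomeIndex:
    """Exact full-length mapping of many short tags in one genome pass."""

    SEED = 16

    def __init__(self, genome: dict[str, str]):
        self.genome = genome

    def map_many(self, tags: Sequence[str]) -> dict[str, list[tuple[str, int, str]]]:
        """All exact occurrences of each tag on either strand.

        Loci are (chrom, 1-based start on the plus strand, strand), in
        deterministic (chrom, pos, strand) order.
        """
        k = self.SEED
        seeds: dict[str, list[tuple[int, str]]] = {}
        uniq = list(dict.fromkeys(tags))
        for idx, t in enumerate(uniq):
            if len(t) < k:
                continue
            seeds.setdefault(t[:k], []).append((idx, "+"))
            seeds.setdefault(revcomp(t)[:k], []).append((idx, "-"))
        loci: dict[str, list[tuple[str, int, str]]] = {t: [] for t in uniq}
        for chrom in sorted(self.genome):
            s = self.genome[chrom]
            n = len(s)
            get = seeds.get
            for pos in range(n - k + 1):
                cands = get(s[pos:pos + k])
                if not cands:
                    continue
                for idx, strand in cands:
                    t = uniq[idx]
                    q = t if strand == "+" else revcomp(t)
                    if s[pos:pos + len(q)] == q:
                        loci[t].append((chrom, pos + 1, strand))
        for t in loci:
            loci[t].sort()
        return loci

    def map_one(self, tag: str) -> list[tuple[str, int, str]]:
        return self.map_many([tag])[tag]


def map_to_genome(tag: str, genome: dict[str, str]) -> list[tuple[str, int, str]]:
    """All exact full-length loci of a tag on both strands."""
    return GenomeIndex(genome).map_one(tag)


# ===================================================================== features

class FeatureIndex:
    """Interval lookup over repeat/exon/intron annotation."""

    def __init__(self, features: Iterable[tuple[str, int, int, str, str]]):
        from intervaltree import IntervalTree

        self._trees: dict[tuple[str, str], "IntervalTree"] = {}
        for chrom, start, end, strand, cls in features:
            key = (cls, chrom)
            self._trees.setdefault(key, IntervalTree())
            self._trees[key][start:end + 1] = strand

    def overlaps(self, cls: str, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get((cls, chrom))
        return bool(tree is not None and tree.overlap(start, end + 1))


# ===================================================================== classify

def classify_tag(tag: str,
                 ncrna_index: NcRNAIndex,
                 reg_index: RegistryIndex,
                 loci: list[tuple[str, int, str]],
                 feature_index: FeatureIndex) -> TagAnnotation:
    """Assign a tag to exactly one category via the priority hierarchy.

    The returned category for genome-mapped tags outside repeats/exons is
    the provisional ``novel-miRNA-candidate``; after novel-miRNA calling
    uncalled candidates demote to ``intron`` (if an intron locus exists) or
    ``unannotated`` (see :func:`finalize_category`).
    """
    nc = ncrna_index.match(tag)
    if nc is not None:
        return TagAnnotation(tag, "ncRNA", assigned_mirna=None, loci=loci,
                             variant=(None, None, 0, nc))
    known = reg_index.match_known(tag)
    if known is not None:
        return TagAnnotation(tag, "known-miRNA", assigned_mirna=known.mature_id,
                             variant=(known.offset5, known.offset3, 0, None),
                             loci=loci)
    edit = reg_index.detect_edited(tag)
    if edit is not None:
        return TagAnnotation(tag, "edited-miRNA", assigned_mirna=edit.mature_id,
                             variant=(edit.offset5, edit.offset3, 1,
                                      (edit.position, edit.from_base, edit.to_base)),
                             loci=loci)
    hom = reg_index.match_homolog(tag)
    if hom is not None:
        return TagAnnotation(tag, "known-miRNA", assigned_mirna=hom.entity,
                             homolog_of=hom.entity,
                             variant=(hom.offset5, hom.offset3, hom.mismatches, None),
                             loci=loci)
    if not loci:
        return TagAnnotation(tag, "unannotated", loci=loci)
    L = len(tag)
    for cls in ("repeat", "exon"):
        for chrom, pos, strand in loci:
            if feature_index.overlaps(cls, chrom, pos, pos + L - 1):
                return TagAnnotation(tag, cls, loci=loci)
    return TagAnnotation(tag, "novel-miRNA-candidate", loci=loci)


def finalize_category(ann: TagAnnotation, called: bool,
                      feature_index: FeatureIndex) -> str:
    """Demote uncalled novel candidates to intron or unannotated."""
    if ann.category != "novel-miRNA-candidate":
        return ann.category
    if called:
        return "novel-miRNA-candidate"
    L = len(ann.sequence)
    for chrom, pos, strand in ann.loci:
        if feature_index.overlaps("intron", chrom, pos, pos + L - 1):
            return "intron"
    return "unannotated"


# ===================================================================== driver

def annotate_tags(tags: Sequence[str],
                  registry: MiRNARegistry,
                  ncrna_set: Iterable[tuple[str, str, str]],
                  genome: dict[str, str],
                  features: Iterable[tuple[str, int, int, str, str]],
                  ) -> dict[str, TagAnnotation]:
    """Annotate unique tag sequences; returns {sequence: TagAnnotation}."""
    ncrna_index = NcRNAIndex(ncrna_set)
    reg_index = RegistryIndex(registry)
    feature_index = FeatureIndex(features)
    loci = GenomeIndex(genome).map_many(list(tags))
    out = {}
    for t in tags:
        out[t] = classify_tag(t, ncrna_index, reg_index, loci[t], feature_index)
    return out
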