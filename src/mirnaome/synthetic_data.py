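"""Synthetic reference bundle and stage-structured small-RNA libraries.

Emulates a four-stage (three prenatal, one neonatal) muscle small-RNA study
design with two replicate libraries per stage: a toy genome carrying
miRNA precursor genes (including a 50-member co-expressed cluster in a 1 Mb
window of one chromosome, mimicking an imprinted-locus miRNA cluster),
repeat/exon/intron annotation, contaminant ncRNAs, plantable novel
hairpins, 3'UTRs with plantable target sites, gene sets and an mRNA
fold-change table. Libraries are 50 bp single-end reads: insert + 3'
adapter + padding, with isomiR end variation (templated +/-2 nt shifts),
single-base edit events, cross-species homolog reads, and separable
contaminant classes (adapter dimers, low-quality reads, poly(A) reads,
N-containing reads, 5'-adapter contamination).

Every random choice derives from one master seed; the planted parameters
are recorded in a :class:`TruthTable` so downstream recovery can be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirnaome import io
from mirnaome._seq import revcomp
from mirnaome.annotate import MatureRecord, MiRNARegistry, PrecursorRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
_PAD = "ATCTCGTATGCCGTCTTCTGCTTGAAACCGCTCTTCCGATCTACGTACGT"

COMPARISONS = [
    ("E45", "E60"), ("E45", "E105"), ("E45", "B3"),
    ("E60", "E105"), ("E60", "B3"), ("E105", "B3"),
]


class SizingError(ValueError):
    """A chromosome is too short to host the requested features."""


# ===================================================================== config

@dataclass
class GeneratorConfig:
    """Parameters of the synthetic reference and read model.

    Defaults are the package's standard benchmark conditions: ~300 mature
    miRNAs of which 50 form one genomic cluster inside a 1 Mb window,
    foreign-species homolog donors, 10 plantable novel hairpins, and the
    contaminant fractions listed in ``class_fractions``.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {
        "chr1": 400_000, "chr2": 400_000, "chr3": 400_000,
        "chr21": 1_600_000, "chrX": 400_000,
    })
    n_mirna: int = 300              # own-species mature arms (one per precursor)
    n_cluster: int = 50             # clustered subset, placed on cluster_chrom
    cluster_chrom: str = "chr21"
    cluster_window: tuple[int, int] = (200_000, 1_200_000)
    n_foreign_sub: int = 30         # foreign donors differing by 2 substitutions
    n_foreign_near: int = 15        # registry-only donors differing by 1 substitution
    n_foreign_ext: int = 8          # donors = own mature + 3 nt non-templated 3' addition
    n_novel: int = 10               # planted novel hairpins
    n_decoy: int = 25               # intergenic degradation loci (no hairpin)
    n_ncrna: int = 24
    n_genes: int = 40               # exon/intron gene models in the annotation
    n_repeats: int = 60
    n_utr_genes: int = 150          # genes with 3'UTR sequences
    n_gene_sets: int = 12
    n_de_pairs: int = 30            # planted 4-fold DE miRNAs come in balanced pairs
    n_edited: int = 5               # miRNAs with a planted single-base edit event
    edit_rate: float = 0.15
    de_fold: float = 4.0
    precursor_len: int = 82
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "mirna": 0.70, "ncrna": 0.08, "homolog": 0.03, "feature": 0.06,
        "intergenic": 0.03, "novel": 0.02, "adapter_dimer": 0.04,
        "low_quality": 0.02, "polya": 0.015, "many_n": 0.005,
        "adapter5": 0.01,
    })
    isomir5: dict[int, float] = field(default_factory=lambda: {
        0: 0.85, -1: 0.05, 1: 0.05, -2: 0.025, 2: 0.025})
    isomir3: dict[int, float] = field(default_factory=lambda: {
        0: 0.50, 1: 0.20, -1: 0.15, 2: 0.10, -2: 0.05})


@dataclass
class StudyDesign:
    """Sequencing design: stage labels, replication, read model."""

    stages: tuple[str, ...] = ("E45", "E60", "E105", "B3")
    replicates: int = 2
    reads_per_library: int = 200_000
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    read_length: int = 50

    @property
    def libraries(self) -> list[str]:
        return [f"{s}-{r + 1}" for s in self.stages for r in range(self.replicates)]

    def stage_of(self, library: str) -> str:
        return library.rsplit("-", 1)[0]


# ===================================================================== bundle

@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    registry: MiRNARegistry
    ncrna_set: list[tuple[str, str, str]]               # (name, seq, class)
    feature_annotation: list[tuple[str, int, int, str, str]]  # chrom,start,end,strand,class
    utr_set: list[tuple[str, str]]                      # (gene id, 3'UTR seq)
    gene_sets: dict[str, list[str]]
    mrna_fc_table: dict[tuple[str, str], float]         # (gene, comparison) -> log2fc

    def validate(self) -> None:
        self.registry.validate()
        for p in self.registry.precursors.values():
            if p.chrom is None:
                continue
            glen = len(self.genome[p.chrom])
            if not (1 <= p.start <= p.end <= glen):
                raise ValueError(f"precursor {p.id} outside genome bounds")
            sub = self.genome[p.chrom][p.start - 1:p.end]
            expect = p.seq if p.strand == "+" else revcomp(p.seq)
            if sub != expect:
                raise ValueError(f"precursor {p.id} != genomic substring")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(outdir / "genome.fa", sorted(self.genome.items()))
        self.registry.write(outdir / "registry")
        io.write_fasta(outdir / "ncrna.fa",
                       [(f"{name}|{cls}", seq) for name, seq, cls in self.ncrna_set])
        io.write_gff3(outdir / "features.gff3",
                      [(c, "mirnaome", cls, s, e, st, f"ID={cls}_{i}")
                       for i, (c, s, e, st, cls) in enumerate(self.feature_annotation)])
        io.write_fasta(outdir / "utrs.fa", self.utr_set)
        io.write_gmt(outdir / "gene_sets.gmt", self.gene_sets)
        rows = [{"gene": g, "comparison": c, "log2fc": v}
                for (g, c), v in sorted(self.mrna_fc_table.items())]
        io.write_tsv(outdir / "mrna_fc.tsv", pd.DataFrame(rows))

    @classmethod
    def load(cls, indir: str | Path) -> "ReferenceBundle":
        indir = Path(indir)
        genome = io.read_fasta(indir / "genome.fa")
        registry = MiRNARegistry.load(indir / "registry")
        ncrna = []
        for name, seq in io.read_fasta(indir / "ncrna.fa").items():
            base, nc_class = name.rsplit("|", 1)
            ncrna.append((base, seq, nc_class))
        gff = io.read_gff3(indir / "features.gff3")
        feats = [(r["chrom"], r["start"], r["end"], r["strand"], r["type"])
                 for _, r in gff.iterrows()]
        utrs = list(io.read_fasta(indir / "utrs.fa").items())
        gene_sets = io.read_gmt(indir / "gene_sets.gmt")
        fc = io.read_tsv(indir / "mrna_fc.tsv")
        table = {(r["gene"], r["comparison"]): float(r["log2fc"])
                 for _, r in fc.iterrows()}
        return cls(genome, registry, ncrna, feats, utrs, gene_sets, table)


# ===================================================================== truth

@dataclass
class TruthTable:
    """Planted parameters of one synthetic dataset (the recovery oracle)."""

    mirna: pd.DataFrame          # id, kind, weight per stage, expected RPM per stage
    de_truth: pd.DataFrame       # mirna, comparison, true_lfc, is_de
    edits: pd.DataFrame          # mirna, position, from_base, to_base, rate
    novel: pd.DataFrame          # id, chrom, start, end, strand, mature, star
    targets: pd.DataFrame        # mirna, gene, comparison
    isomir5: dict[int, float]
    isomir3: dict[int, float]
    class_fractions: dict[str, float]
    mapped_fraction: dict[str, float]   # per stage: mapped / raw reads
    clean_fraction: float

    def expected_rpm(self, mirna_id: str, stage: str) -> float:
        row = self.mirna.set_index("id").loc[mirna_id]
        return float(row[f"rpm_{stage}"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_tsv(outdir / "truth_mirna.tsv", self.mirna)
        io.write_tsv(outdir / "truth_de.tsv", self.de_truth)
        io.write_tsv(outdir / "truth_edits.tsv", self.edits)
        io.write_tsv(outdir / "truth_novel.tsv", self.novel)
        io.write_tsv(outdir / "truth_targets.tsv", self.targets)
        meta = pd.DataFrame(
            [{"key": f"mapped_fraction_{s}", "value": v}
             for s, v in self.mapped_fraction.items()]
            + [{"key": "clean_fraction", "value": self.clean_fraction}])
        io.write_tsv(outdir / "truth_meta.tsv", meta)


# ===================================================================== helpers

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_dna_clean(rng: np.random.Generator, n: int, forbidden: str) -> str:
    """Random DNA avoiding a forbidden substring (adapter seed)."""
    for _ in range(100):
        s = _random_dna(rng, n)
        if forbidden not in s and forbidden not in revcomp(s):
            return s
    raise RuntimeError("could not generate clean random sequence")


class _Placer:
    """Greedy non-overlapping interval placement on one chromosome."""

    def __init__(self, length: int, margin: int = 50):
        self.length = length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, rng: np.random.Generator, size: int,
              lo: int | None = None, hi: int | None = None,
              what: str = "feature") -> int:
        lo = 1 if lo is None else lo
        hi = self.length - size if hi is None else min(hi, self.length - size)
        if hi < lo:
            raise SizingError(
                f"chromosome too short to host {what}: need {size} nt in "
                f"[{lo}, {hi}] of length {self.length}")
        for _ in range(2000):
            start = int(rng.integers(lo, hi + 1))
            if all(start + size + self.margin <= s or start >= e + self.margin
                   for s, e in self.taken):
                self.taken.append((start, start + size))
                return start
        raise SizingError(
            f"chromosome of length {self.length} cannot host {what} "
            f"({size} nt): {len(self.taken)} intervals already placed")


def _substitute(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


# ===================================================================== build

def build_reference(config: GeneratorConfig | None = None,
                    seed: int = 0) -> ReferenceBundle:
    """Deterministically build the toy reference bundle for one seed."""
    bundle, _ = generate(config, None, seed)
    return bundle


def plant_truth(config: GeneratorConfig | None = None,
                design: StudyDesign | None = None,
                seed: int = 0) -> TruthTable:
    """The TruthTable matching :func:`build_reference` at the same seed."""
    _, truth = generate(config, design, seed)
    return truth


def generate(config: GeneratorConfig | None = None,
             design: StudyDesign | None = None,
             seed: int = 0) -> tuple[ReferenceBundle, TruthTable]:
    """Build the reference bundle and its planted TruthTable together."""
    config = config or GeneratorConfig()
    design = design or StudyDesign()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xB10)))
    adapter_seed = ADAPTER3[:8]

    # ----------------------------------------------------------- genome
    genome_arr = {c: _BASES[rng.integers(0, 4, n)].copy()
                  for c, n in config.chrom_sizes.items()}
    placers = {c: _Placer(n) for c, n in config.chrom_sizes.items()}

    # ----------------------------------------------------------- registry
    n_scattered = config.n_mirna - config.n_cluster
    if n_scattered < 0:
        raise ValueError("n_cluster exceeds n_mirna")
    chroms = sorted(config.chrom_sizes)
    precursors: list[PrecursorRecord] = []
    matures: list[MatureRecord] = []
    plen = config.precursor_len

    def _make_precursor(idx: int, chrom: str, start: int, strand: str,
                        ) -> tuple[PrecursorRecord, MatureRecord]:
        pseq = _random_dna_clean(rng, plen, adapter_seed)
        # mature lengths centered on the canonical 22 nt
        mlen = int(rng.choice([20, 21, 22, 23], p=[0.15, 0.25, 0.45, 0.15]))
        arm = rng.choice(["5p", "3p"])
        offset = int(rng.integers(4, 12)) if arm == "5p" else \
            plen - int(rng.integers(4, 12)) - mlen
        pid = f"chi-mir-{idx}"
        mid = f"chi-miR-{idx}-{arm}"
        prec = PrecursorRecord(pid, pseq, chrom, start, start + plen - 1,
                               strand, "chi", True)
        mat = MatureRecord(mid, pseq[offset:offset + mlen], pid, offset, "chi", True)
        return prec, mat

    # clustered subset: jittered grid inside the 1 Mb window (max gap << window);
    # the whole window is reserved so nothing else lands inside it
    lo, hi = config.cluster_window
    cluster_member_ids: list[str] = []
    if config.n_cluster:
        span = hi - lo
        step = span // config.n_cluster
        if step < plen + 200:
            raise SizingError(
                f"cluster window of {span} nt too small for "
                f"{config.n_cluster} precursors")
        # reserve a margin beyond the window so nothing chains onto the cluster
        placers[config.cluster_chrom].taken.append((lo - 110_000, hi + 110_000))
        for i in range(config.n_cluster):
            start = lo + i * step + int(rng.integers(0, max(1, step - plen - 100)))
            strand = "+" if rng.random() < 0.7 else "-"
            prec, mat = _make_precursor(i + 1, config.cluster_chrom, start, strand)
            precursors.append(prec)
            matures.append(mat)
            cluster_member_ids.append(mat.id)
    for j in range(n_scattered):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = placers[chrom].place(rng, plen, what="miRNA precursor")
        strand = "+" if rng.random() < 0.5 else "-"
        prec, mat = _make_precursor(config.n_cluster + j + 1, chrom, start, strand)
        precursors.append(prec)
        matures.append(mat)

    # embed precursors into the genome (reverse-complemented on minus strand)
    for p in precursors:
        seg = p.seq if p.strand == "+" else revcomp(p.seq)
        genome_arr[p.chrom][p.start - 1:p.end] = np.frombuffer(
            seg.encode(), dtype="S1")

    # ----------------------------------------------------- foreign donors
    own_by_idx = list(matures)
    foreign_species = ["mmu", "hsa", "bta"]
    read_sourced_foreign: list[str] = []  # entity names that source homolog reads

    def _add_foreign(fidx: int, seq: str, species: str, stem: str) -> str:
        pseq = _random_dna_clean(rng, 12, adapter_seed) + seq + \
            _random_dna_clean(rng, 12, adapter_seed)
        pid = f"{species}-mir-h{fidx}"
        mid = f"{species}-{stem}"
        precursors.append(PrecursorRecord(pid, pseq, None, None, None, None,
                                          species, False))
        matures.append(MatureRecord(mid, seq, pid, 12, species, False))
        return mid

    fidx = 0
    for i in range(config.n_foreign_sub):
        donor = own_by_idx[int(rng.integers(0, len(own_by_idx)))]
        seq = _substitute(rng, donor.seq, 2)
        species = foreign_species[i % len(foreign_species)]
        stem = f"miR-h{fidx}-{donor.id.rsplit('-', 1)[1]}"
        _add_foreign(fidx, seq, species, stem)
        if i % 5 == 0 and len(foreign_species) > 1:
            # identical sequence recorded under a second species: collapses
            other = foreign_species[(i + 1) % len(foreign_species)]
            _add_foreign(fidx, seq, other, stem)
        read_sourced_foreign.append(stem)
        fidx += 1
    for i in range(config.n_foreign_near):
        donor = own_by_idx[int(rng.integers(0, len(own_by_idx)))]
        seq = _substitute(rng, donor.seq, 1)
        species = foreign_species[i % len(foreign_species)]
        _add_foreign(fidx, seq, species, f"miR-h{fidx}-near")
        fidx += 1
    for i in range(config.n_foreign_ext):
        donor = own_by_idx[int(rng.integers(0, len(own_by_idx)))]
        ext = "".join(rng.choice(list("ACGT"), 3))
        seq = (donor.seq if len(donor.seq) <= 22 else donor.seq[:22]) + ext
        species = foreign_species[i % len(foreign_species)]
        stem = f"miR-h{fidx}-ext"
        _add_foreign(fidx, seq, species, stem)
        read_sourced_foreign.append(stem)
        fidx += 1

    registry = MiRNARegistry(precursors, matures)

    # ----------------------------------------------------------- ncRNA set
    ncrna_classes = (["rRNA"] * 6 + ["tRNA"] * 8 + ["snRNA"] * 5 + ["snoRNA"] * 5)
    ncrna_classes = (ncrna_classes * (config.n_ncrna // len(ncrna_classes) + 1)
                     )[: config.n_ncrna]
    lengths = {"rRNA": (500, 1500), "tRNA": (70, 90),
               "snRNA": (100, 200), "snoRNA": (60, 150)}
    ncrna_set = []
    for i, cls in enumerate(ncrna_classes):
        lo_n, hi_n = lengths[cls]
        L = int(rng.integers(lo_n, hi_n + 1))
        ncrna_set.append((f"{cls}_{i + 1}", _random_dna_clean(rng, L, adapter_seed), cls))

    # ----------------------------------------------------------- features
    features: list[tuple[str, int, int, str, str]] = []
    for g in range(config.n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        e1 = int(rng.integers(150, 401))
        intron = int(rng.integers(200, 801))
        e2 = int(rng.integers(150, 401))
        start = placers[chrom].place(rng, e1 + intron + e2, what="gene model")
        strand = "+" if rng.random() < 0.5 else "-"
        features.append((chrom, start, start + e1 - 1, strand, "exon"))
        features.append((chrom, start + e1, start + e1 + intron - 1, strand, "intron"))
        features.append((chrom, start + e1 + intron,
                         start + e1 + intron + e2 - 1, strand, "exon"))
    for r in range(config.n_repeats):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = int(rng.integers(150, 501))
        start = placers[chrom].place(rng, L, what="repeat")
        features.append((chrom, start, start + L - 1, "+", "repeat"))

    # ----------------------------------------------------------- novel hairpins
    novel_rows = []
    for i in range(config.n_novel):
        arm = _random_dna_clean(rng, 28, adapter_seed)
        loop = _random_dna_clean(rng, 8, adapter_seed)
        hp = arm + loop + revcomp(arm)  # perfect 28-bp stem hairpin
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = placers[chrom].place(rng, len(hp), what="novel hairpin")
        genome_arr[chrom][start - 1:start + len(hp) - 1] = np.frombuffer(
            hp.encode(), dtype="S1")
        mature = hp[3:25]                      # 22 nt on the 5' arm
        # star = the exact pairing partner of the mature inside the stem
        star = revcomp(mature)
        novel_rows.append({"id": f"planted-novel-{i + 1}", "chrom": chrom,
                           "start": start, "end": start + len(hp) - 1,
                           "strand": "+", "mature": mature, "star": star,
                           "precursor": hp})
    novel_df = pd.DataFrame(novel_rows)

    # ----------------------------------------------------------- decoy loci
    decoys = []
    for i in range(config.n_decoy):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = 120
        start = placers[chrom].place(rng, L, what="decoy locus")
        decoys.append((chrom, start, L))

    genome = {c: a.tobytes().decode() for c, a in genome_arr.items()}

    # ----------------------------------------------------------- stage weights
    stages = list(design.stages)
    own_ids = [m.id for m in registry.own_matures]
    n_own = len(own_ids)
    base = np.exp(rng.normal(np.log(30.0), 1.2, n_own))  # lognormal base weights
    weights = {s: base.copy() for s in stages}
    kind = ["known"] * n_own

    cluster_ids = set(cluster_member_ids)
    cluster_list = list(cluster_member_ids)
    # two co-expression programs among cluster members (rising / falling),
    # adjacent-stage ratio 3 so planted DE sits clear of the 2-fold cutoff
    prog_a = [1.0, 3.0, 9.0, 27.0]
    prog_b = prog_a[::-1]
    idx_of = {mid: k for k, mid in enumerate(own_ids)}
    cluster_base = 18.0
    for k, mid in enumerate(cluster_list):
        prog = prog_a if k % 2 == 0 else prog_b
        for s, mult in zip(stages, prog):
            weights[s][idx_of[mid]] = cluster_base * mult

    # balanced 4-fold step DE pairs among non-cluster miRNAs
    non_cluster = [m for m in own_ids if m not in cluster_ids]
    rng.shuffle(non_cluster)
    de_ids: list[str] = []
    fold = config.de_fold
    pair_base = np.exp(rng.normal(np.log(120.0), 0.5, config.n_de_pairs))
    for p in range(config.n_de_pairs):
        up, down = non_cluster[2 * p], non_cluster[2 * p + 1]
        switch = 1 + p % (len(stages) - 1)  # step occurs entering this stage
        b = pair_base[p]
        for t, s in enumerate(stages):
            mult_up = fold if t >= switch else 1.0
            mult_down = 1.0 if t >= switch else fold
            weights[s][idx_of[up]] = b * mult_up
            weights[s][idx_of[down]] = b * mult_down
        de_ids += [up, down]

    # planted edits on non-DE, non-cluster miRNAs with decent abundance
    edit_candidates = [m for m in non_cluster[2 * config.n_de_pairs:]
                       if base[idx_of[m]] > 20]
    edit_rows = []
    mature_by_id = {m.id: m for m in registry.own_matures}
    for m in edit_candidates[: config.n_edited]:
        mlen = len(mature_by_id[m].seq)
        pos = int(rng.integers(6, mlen - 4))  # internal, 1-based
        from_base = mature_by_id[m].seq[pos - 1]
        to_base = rng.choice([b for b in "ACGT" if b != from_base])
        edit_rows.append({"mirna": m, "position": pos, "from_base": from_base,
                          "to_base": str(to_base), "rate": config.edit_rate})
    edits_df = pd.DataFrame(edit_rows,
                            columns=["mirna", "position", "from_base",
                                     "to_base", "rate"])

    # homolog and novel stage weights (constant across stages)
    hom_names = sorted(set(read_sourced_foreign))
    hom_w = np.exp(rng.normal(np.log(40.0), 0.8, len(hom_names)))
    nov_w = np.exp(rng.normal(np.log(50.0), 0.4, config.n_novel)) \
        if config.n_novel else np.array([])

    # ----------------------------------------------------------- proportions
    frac = dict(config.class_fractions)
    for key in ("mirna", "ncrna", "homolog", "feature", "intergenic", "novel",
                "adapter_dimer", "low_quality", "polya", "many_n", "adapter5"):
        frac.setdefault(key, 0.0)
    total_frac = sum(frac.values())
    if abs(total_frac - 1.0) > 1e-9:
        frac = {k: v / total_frac for k, v in frac.items()}
    clean_classes = ("mirna", "ncrna", "homolog", "feature", "intergenic", "novel")
    clean_fraction = sum(frac[c] for c in clean_classes)

    per_stage_rpm: dict[str, np.ndarray] = {}
    mapped_fraction: dict[str, float] = {}
    edit_rate_by_idx = np.zeros(n_own)
    for r in edit_rows:
        edit_rate_by_idx[idx_of[r["mirna"]]] = r["rate"]
    for s in stages:
        w = weights[s]
        p_mirna = frac["mirna"] * w / w.sum()       # fraction of raw reads, per miRNA
        # edited reads stay in the miRNA count but do not map to the genome
        p_mapped = (p_mirna * (1 - edit_rate_by_idx)).sum() \
            + frac["feature"] + frac["intergenic"] + frac["novel"]
        mapped_fraction[s] = p_mapped
        per_stage_rpm[s] = 1e6 * p_mirna / p_mapped

    hom_rpm = {}
    for s in stages:
        p_hom = frac["homolog"] * hom_w / hom_w.sum() if len(hom_names) else hom_w
        hom_rpm[s] = 1e6 * p_hom / mapped_fraction[s]
    nov_rpm = {}
    for s in stages:
        p_nov = frac["novel"] * nov_w / nov_w.sum() if config.n_novel else nov_w
        nov_rpm[s] = 1e6 * p_nov / mapped_fraction[s]

    mirna_rows = []
    for k, mid in enumerate(own_ids):
        row = {"id": mid, "kind": "known",
               "cluster": mid in cluster_ids}
        for s in stages:
            row[f"weight_{s}"] = weights[s][k]
            row[f"rpm_{s}"] = per_stage_rpm[s][k]
        mirna_rows.append(row)
    for k, name in enumerate(hom_names):
        row = {"id": name, "kind": "homolog", "cluster": False}
        for s in stages:
            row[f"weight_{s}"] = hom_w[k]
            row[f"rpm_{s}"] = hom_rpm[s][k]
        mirna_rows.append(row)
    for k in range(config.n_novel):
        row = {"id": f"planted-novel-{k + 1}", "kind": "novel", "cluster": False}
        for s in stages:
            row[f"weight_{s}"] = nov_w[k]
            row[f"rpm_{s}"] = nov_rpm[s][k]
        mirna_rows.append(row)
    mirna_df = pd.DataFrame(mirna_rows)

    de_rows = []
    for mid in own_ids:
        k = idx_of[mid]
        for a, b in COMPARISONS:
            lfc = float(np.log2(weights[b][k] / weights[a][k]))
            de_rows.append({"mirna": mid, "comparison": f"{a}_vs_{b}",
                            "true_lfc": lfc, "is_de": abs(lfc) >= 1.0})
    de_df = pd.DataFrame(de_rows)

    # ----------------------------------------------------------- UTRs, sets, mRNA fc
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_utr_genes)]
    utr_seqs = {g: _random_dna_clean(rng, int(rng.integers(300, 801)), adapter_seed)
                for g in gene_ids}
    # plant 8mer target sites for abundant planted-DE miRNAs; the mRNA table
    # gives those genes the opposite fold-change sign
    overall_rpm = {mid: np.mean([per_stage_rpm[s][idx_of[mid]] for s in stages])
                   for mid in own_ids}
    # target planting needs 22-nt matures: a full-complement site then clears
    # the alignment predictor's threshold as well as seed and duplex rules
    focus = [m for m in de_ids
             if overall_rpm[m] > 100 and len(mature_by_id[m].seq) == 22][:10]
    target_rows = []
    mrna_fc: dict[tuple[str, str], float] = {}
    for g in gene_ids:
        for a, b in COMPARISONS:
            mrna_fc[(g, f"{a}_vs_{b}")] = float(rng.normal(0.0, 1.0))
    for j, mid in enumerate(focus):
        mseq = mature_by_id[mid].seq
        # full-complement site with an A opposite position 1 (8mer class)
        site8 = revcomp(mseq[1:]) + "A"
        genes = gene_ids[3 * j: 3 * j + 3]
        for g in genes:
            utr = utr_seqs[g]
            pos = int(rng.integers(40, len(utr) - 40))
            utr_seqs[g] = utr[:pos] + site8 + utr[pos + len(site8):]
            for a, b in COMPARISONS:
                comp = f"{a}_vs_{b}"
                lfc = float(np.log2(weights[b][idx_of[mid]]
                                    / weights[a][idx_of[mid]]))
                if abs(lfc) >= 1.0:
                    mag = 0.8 + abs(rng.normal(0.0, 0.5))
                    mrna_fc[(g, comp)] = -np.sign(lfc) * mag
            target_rows.append({"mirna": mid, "gene": g})
    targets_df = pd.DataFrame(target_rows, columns=["mirna", "gene"])

    hi_size = max(2, min(40, len(gene_ids) // 2))
    lo_size = min(15, hi_size)
    set_rng_sizes = rng.integers(lo_size, hi_size + 1, config.n_gene_sets)
    gene_sets = {}
    for i in range(config.n_gene_sets):
        members = rng.choice(gene_ids, size=int(set_rng_sizes[i]), replace=False)
        gene_sets[f"SET_{i + 1:02d}"] = sorted(members.tolist())

    bundle = ReferenceBundle(
        genome=genome, registry=registry, ncrna_set=ncrna_set,
        feature_annotation=features, utr_set=sorted(utr_seqs.items()),
        gene_sets=gene_sets, mrna_fc_table=mrna_fc)
    bundle.validate()

    truth = TruthTable(
        mirna=mirna_df, de_truth=de_df, edits=edits_df, novel=novel_df,
        targets=targets_df, isomir5=dict(config.isomir5),
        isomir3=dict(config.isomir3), class_fractions=frac,
        mapped_fraction=mapped_fraction, clean_fraction=clean_fraction)
    # decoy loci ride along for the generator (not part of the truth contract)
    truth._decoys = decoys  # type: ignore[attr-defined]
    truth._weights = weights  # type: ignore[attr-defined]
    truth._hom = (hom_names, hom_w)  # type: ignore[attr-defined]
    truth._nov_w = nov_w  # type: ignore[attr-defined]
    return bundle, truth


# ===================================================================== simulate

def simulate_libraries(bundle: ReferenceBundle,
                       design: StudyDesign,
                       truth: TruthTable,
                       seed: int = 0,
                       outdir: str | Path | None = None,
                       ) -> dict[str, list[tuple[str, str, str]]]:
    """Simulate per-library reads; optionally write gzipped FASTQ + truth.

    Returns {library label: [(name, sequence, quality), ...]}. Read counts
    per discrete outcome are multinomial around the planted proportions;
    per-library seeds derive deterministically from the master seed and the
    library index.
    """
    config_frac = truth.class_fractions
    stages = list(design.stages)
    registry = bundle.registry
    mature_by_id = {m.id: m for m in registry.own_matures}
    own_ids = [m.id for m in registry.own_matures]
    weights = truth._weights  # type: ignore[attr-defined]
    hom_names, hom_w = truth._hom  # type: ignore[attr-defined]
    nov_w = truth._nov_w  # type: ignore[attr-defined]
    decoys = truth._decoys  # type: ignore[attr-defined]
    edit_by_mirna = {r["mirna"]: r for _, r in truth.edits.iterrows()}
    hom_seq = {name: seq for name, seq, _ in registry.homolog_entities()}

    read_len = design.read_length
    a3, a5 = design.adapter3, design.adapter5

    def _read_of(insert: str) -> str:
        return (insert + a3 + _PAD * 3)[:read_len]

    # -------- discrete outcome table (identical across libraries; only
    # the per-stage probability vector changes)
    outcome_seq: list[str] = []
    outcome_lowq: list[bool] = []
    outcome_prob: dict[str, list[float]] = {s: [] for s in stages}

    def _add(seq: str, probs: dict[str, float], lowq: bool = False) -> None:
        outcome_seq.append(seq)
        outcome_lowq.append(lowq)
        for s in stages:
            outcome_prob[s].append(probs.get(s, 0.0))

    p5 = truth.isomir5
    p3 = truth.isomir3
    for k, mid in enumerate(own_ids):
        m = mature_by_id[mid]
        prec = registry.precursors[m.precursor_id].seq
        e = edit_by_mirna.get(mid)
        p_mirna_stage = {
            s: config_frac["mirna"] * weights[s][k] / weights[s].sum()
            for s in stages}
        for d5, w5 in p5.items():
            for d3, w3 in p3.items():
                start = m.offset + d5
                end = m.offset + len(m.seq) + d3
                if start < 0 or end > len(prec):
                    start = m.offset
                    end = m.offset + len(m.seq)
                var = prec[start:end]
                pw = w5 * w3
                if e is None:
                    _add(_read_of(var),
                         {s: p_mirna_stage[s] * pw for s in stages})
                else:
                    rate = e["rate"]
                    _add(_read_of(var),
                         {s: p_mirna_stage[s] * pw * (1 - rate) for s in stages})
                    vpos = e["position"] - 1 - (start - m.offset)
                    if 0 <= vpos < len(var):
                        edited = var[:vpos] + e["to_base"] + var[vpos + 1:]
                    else:
                        edited = var
                    _add(_read_of(edited),
                         {s: p_mirna_stage[s] * pw * rate for s in stages})
    hom_total = hom_w.sum() if len(hom_names) else 1.0
    for k, name in enumerate(hom_names):
        _add(_read_of(hom_seq[name]),
             {s: config_frac["homolog"] * hom_w[k] / hom_total for s in stages})
    nov_total = nov_w.sum() if len(nov_w) else 1.0
    for k in range(len(truth.novel)):
        row = truth.novel.iloc[k]
        p_nov = config_frac["novel"] * nov_w[k] / nov_total
        hp = row["precursor"]
        mat = row["mature"]
        mstart = hp.index(mat)
        # 90% mature reads with slight 3' jitter, 10% star reads
        for d3, wj in ((0, 0.6), (1, 0.25), (-1, 0.15)):
            var = hp[mstart:mstart + len(mat) + d3]
            _add(_read_of(var), {s: p_nov * 0.9 * wj for s in stages})
        star_start = hp.index(row["star"])
        _add(_read_of(row["star"]), {s: p_nov * 0.10 for s in stages})
    # contaminant discrete outcomes
    _add(_read_of(""), {s: config_frac["adapter_dimer"] for s in stages})
    _add(_read_of("A" * 24), {s: config_frac["polya"] for s in stages})
    first_own = mature_by_id[own_ids[0]].seq
    n_insert = first_own[:8] + "NN" + first_own[10:]
    _add(_read_of(n_insert), {s: config_frac["many_n"] for s in stages})
    _add((a5[-8:] + _read_of(first_own))[:read_len],
         {s: config_frac["adapter5"] for s in stages})
    _add(_read_of(first_own), {s: config_frac["low_quality"] for s in stages},
         lowq=True)

    discrete_p = {s: np.array(outcome_prob[s]) for s in stages}
    n_outcomes = len(outcome_seq)

    # continuous classes sampled per read: ncrna, feature, intergenic
    ncrna_seqs = [seq for _, seq, _ in bundle.ncrna_set]
    exon_ivals = [(c, s0, e0) for c, s0, e0, _, cls in bundle.feature_annotation
                  if cls == "exon"]
    repeat_ivals = [(c, s0, e0) for c, s0, e0, _, cls in bundle.feature_annotation
                    if cls == "repeat"]

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    results_paths = {}
    for lib_index, lib in enumerate(design.libraries):
        stage = design.stage_of(lib)
        lrng = np.random.default_rng(
            np.random.SeedSequence(entropy=(seed, 1000 + lib_index)))
        n = design.reads_per_library
        if n == 0:
            logger.warning("library %s requested 0 reads; writing empty FASTQ", lib)
            libraries[lib] = []
            continue
        qual_base = (35 + lrng.integers(0, 6, read_len)).astype(np.int64)
        qual_hi = "".join(chr(q + 33) for q in qual_base)
        lowq_scores = qual_base.copy()
        lowq_scores[[5, 9, 17]] = 10
        qual_lo = "".join(chr(q + 33) for q in lowq_scores)

        p = discrete_p[stage].copy()
        p_disc_total = p.sum()
        p_nc = config_frac["ncrna"]
        p_feat = config_frac["feature"]
        p_int = config_frac["intergenic"]
        p_rest = 1.0 - p_disc_total - p_nc - p_feat - p_int
        # numerical slack spread over discrete outcomes
        full = np.concatenate([p, [p_nc, p_feat, p_int, max(p_rest, 0.0)]])
        full = full / full.sum()
        counts = lrng.multinomial(n, full)
        reads: list[tuple[str, bool]] = []
        for i in range(n_outcomes):
            if counts[i]:
                reads.extend([(outcome_seq[i], outcome_lowq[i])] * counts[i])
        for _ in range(counts[n_outcomes]):       # ncRNA fragments
            src = ncrna_seqs[int(lrng.integers(0, len(ncrna_seqs)))]
            L = int(lrng.integers(18, 31))
            st = int(lrng.integers(0, max(1, len(src) - L + 1)))
            reads.append((_read_of(src[st:st + L]), False))
        for _ in range(counts[n_outcomes + 1]):   # repeat/exon degradation
            ivals = repeat_ivals if lrng.random() < 0.5 else exon_ivals
            c, s0, e0 = ivals[int(lrng.integers(0, len(ivals)))]
            L = int(lrng.integers(18, 31))
            st = int(lrng.integers(s0 - 1, max(s0, e0 - L)))
            frag = bundle.genome[c][st:st + L]
            reads.append((_read_of(frag), False))
        for _ in range(counts[n_outcomes + 2]):   # intergenic degradation (decoys)
            c, s0, L0 = decoys[int(lrng.integers(0, len(decoys)))]
            L = int(lrng.integers(18, 29))
            st = int(s0 - 1 + lrng.integers(0, L0 - L))
            frag = bundle.genome[c][st:st + L]
            reads.append((_read_of(frag), False))
        for _ in range(counts[n_outcomes + 3]):   # numerical remainder
            reads.append((_read_of(first_own), False))
        order = lrng.permutation(len(reads))
        out = []
        for ridx, j in enumerate(order):
            seq, lowq = reads[j]
            qual = (qual_lo if lowq else qual_hi)[:len(seq)]
            out.append((f"{lib}.{ridx + 1}", seq, qual))
        libraries[lib] = out

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, reads in libraries.items():
            path = outdir / f"{lib}.fastq.gz"
            io.write_fastq_gz(path, reads)
            results_paths[lib] = path
        truth.write(outdir)
    return libraries
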