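"""Tolerant matchers vs brute-force oracles; priority classification."""

from __future__ import annotations

import numpy as np
import pytest

from mirnaome._seq import revcomp
from mirnaome.annotate import (FeatureIndex, GenomeIndex, MiRNARegistry,
                               NcRNAIndex, RegistryIndex, classify_tag,
                               map_to_genome, match_ncrna)
from oracles import (oracle_edited, oracle_genome_scan, oracle_homolog,
                     oracle_known)


@pytest.fixture(scope="module")
def registry(small_study_module):
    return small_study_module[0].registry


@pytest.fixture(scope="module")
def small_study_module(request):
    return request.getfixturevalue("small_study")


@pytest.fixture(scope="module")
def index(registry):
    return RegistryIndex(registry)


def _random_tags(registry, rng, n):
    """Tags exercising hits and misses: shifted/edited/extended matures,
    foreign matures, and pure random sequences."""
    own = registry.own_matures
    tags = []
    for _ in range(n):
        kind = rng.integers(0, 5)
        if kind <= 1 and own:
            m = own[int(rng.integers(0, len(own)))]
            prec = registry.precursors[m.precursor_id].seq
            d5 = int(rng.integers(-3, 4))
            d3 = int(rng.integers(-3, 4))
            start = max(0, m.offset + d5)
            end = min(len(prec), m.offset + len(m.seq) + d3)
            tag = prec[start:end]
            if kind == 1 and len(tag) > 4:  # sprinkle mismatches
                n_mm = int(rng.integers(1, 4))
                tag = list(tag)
                for p in rng.choice(len(tag), size=n_mm, replace=False):
                    tag[p] = "ACGT"[int(rng.integers(0, 4))]
                tag = "".join(tag)
        elif kind == 2 and registry.foreign_matures:
            f = registry.foreign_matures[
                int(rng.integers(0, len(registry.foreign_matures)))]
            tag = f.seq
        else:
            tag = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 22))
        if len(tag) >= 16:
            tags.append(tag)
    return tags


def test_matchers_equal_bruteforce_enumeration(registry, index):
    """Each tolerant matcher equals enumeration over (offset, mismatch)."""
    rng = np.random.default_rng(42)
    tags = _random_tags(registry, rng, 500)
    n_known = n_edit = n_hom = 0
    for tag in tags:
        k = index.match_known(tag)
        assert k == oracle_known(tag, registry), tag
        n_known += k is not None
        if k is None:
            e = index.detect_edited(tag)
            assert e == oracle_edited(tag, registry), tag
            n_edit += e is not None
            if e is None:
                h = index.match_homolog(tag)
                assert h == oracle_homolog(tag, registry), tag
                n_hom += h is not None
    # the tag mix must actually exercise every matcher
    assert n_known > 20 and n_edit > 10 and n_hom > 3


def test_known_match_identity_and_offsets(registry, index):
    m = registry.own_matures[0]
    prec = registry.precursors[m.precursor_id].seq
    hit = index.match_known(m.seq)
    assert hit is not None and (hit.offset5, hit.offset3) == (0, 0)
    # templated 3' extension by 2 nt -> offsets (0, +2)
    ext = prec[m.offset:m.offset + len(m.seq) + 2]
    hit = index.match_known(ext)
    assert hit is not None and (hit.offset5, hit.offset3) == (0, 2)
    # a 3 nt 5' shift falls outside the window
    shifted = prec[m.offset + 3:m.offset + len(m.seq) + 2]
    hit = index.match_known(shifted)
    assert hit is None or hit.mature_id != m.id or hit.offset5 != 3


def test_edited_hit_position_and_two_mismatch_fallthrough(registry, index):
    m = registry.own_matures[1]
    tag = list(m.seq)
    pos = 9  # 0-based
    tag[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[tag[pos]]
    edited = "".join(tag)
    hit = index.detect_edited(edited)
    assert hit is not None and hit.mature_id == m.id
    assert hit.position == pos + 1
    assert (hit.from_base, hit.to_base) == (m.seq[pos], edited[pos])
    # two substitutions: not an edit (falls through to homolog matching)
    tag[4] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[4]]
    assert index.detect_edited("".join(tag)) is None


def test_homolog_three_mismatches_rejected(registry, index):
    ents = index.entities
    assert ents, "registry must carry foreign entries"
    name, seq, _ = ents[0]
    tag = list(seq)
    for p in (2, 8, 14):
        tag[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[p]]
    hit = index.match_homolog("".join(tag))
    assert hit is None or hit.mismatches <= 2 and hit.entity != name \
        or hit is None


def test_identical_foreign_sequences_collapse(registry):
    by_seq = {}
    for m in registry.foreign_matures:
        by_seq.setdefault(m.seq, set()).add(m.species)
    multi = [s for s, sp in by_seq.items() if len(sp) > 1]
    assert multi, "generator plants cross-species duplicates"
    ents = registry.homolog_entities()
    for seq in multi:
        matches = [e for e in ents if e[1] == seq]
        assert len(matches) == 1 and len(matches[0][2]) > 1


def test_genome_mapping_equals_naive_scan(small_study_module):
    bundle = small_study_module[0]
    genome = bundle.genome
    rng = np.random.default_rng(7)
    tags = []
    # random 22-mers plus genuine genomic substrings on both strands
    for _ in range(30):
        tags.append("".join("ACGT"[int(b)] for b in rng.integers(0, 4, 22)))
    chroms = sorted(genome)
    for _ in range(30):
        c = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, len(genome[c]) - 22))
        frag = genome[c][pos:pos + 22]
        tags.append(frag if rng.random() < 0.5 else revcomp(frag))
    loci = GenomeIndex(genome).map_many(tags)
    for tag in tags:
        assert loci[tag] == oracle_genome_scan(tag, genome), tag


def test_absent_tag_maps_nowhere():
    genome = {"chr1": "ACGT" * 100}
    assert map_to_genome("TTTTTTTTTTTTTTTTTT", genome) == []


def test_minus_strand_locus():
    core = "ATCGGATCCGTTAGGCACAT"
    genome = {"chr1": "CCCC" + revcomp(core) + "GGGG"}
    loci = map_to_genome(core, genome)
    assert loci == [("chr1", 5, "-")]


# ===================================================================== priority

def _mini_world():
    """A tiny handcrafted world with overlapping annotations."""
    from mirnaome.annotate import MatureRecord, PrecursorRecord

    prec_seq = "GGCAT" + "ACGTTGCAACGTAGCTAGCAT" + "TTGCA"
    registry = MiRNARegistry(
        [PrecursorRecord("pre-1", prec_seq, "chr1", 11, 10 + len(prec_seq),
                         "+", "chi", True)],
        [MatureRecord("miR-1-5p", prec_seq[5:26], "pre-1", 5, "chi", True)])
    genome = {"chr1": "A" * 10 + prec_seq + "A" * 30}
    ncrna = [("rRNA_1", prec_seq[5:26] + "GGGGCCCC", "rRNA")]
    features = [("chr1", 1, 60, "+", "repeat"), ("chr1", 1, 60, "+", "exon")]
    return registry, genome, ncrna, features


def test_priority_ncrna_over_known_over_repeat():
    registry, genome, ncrna, features = _mini_world()
    tag = registry.own_matures[0].seq
    nc_index = NcRNAIndex(ncrna)
    reg_index = RegistryIndex(registry)
    feats = FeatureIndex(features)
    loci = GenomeIndex(genome).map_many([tag])[tag]
    # matches rRNA, a mature miRNA and overlaps a repeat: ncRNA wins
    ann = classify_tag(tag, nc_index, reg_index, loci, feats)
    assert ann.category == "ncRNA"
    # without the ncRNA hit: known-miRNA beats repeat
    ann = classify_tag(tag, NcRNAIndex([]), reg_index, loci, feats)
    assert ann.category == "known-miRNA"
    assert ann.assigned_mirna == "miR-1-5p"


def test_exon_only_overlap_and_unmapped_tag():
    registry, genome, ncrna, features = _mini_world()
    feats = FeatureIndex([("chr1", 40, 60, "+", "exon")])
    tag = genome["chr1"][40:60]
    loci = GenomeIndex(genome).map_many([tag])[tag]
    ann = classify_tag(tag, NcRNAIndex([]), RegistryIndex(registry), loci,
                       feats)
    assert ann.category == "exon"
    missing = "TTGGCCAATTGGCCAATT"
    ann = classify_tag(missing, NcRNAIndex([]), RegistryIndex(registry), [],
                       feats)
    assert ann.category == "unannotated"


def test_ncrna_substring_identity(small_study_module):
    bundle = small_study_module[0]
    index = NcRNAIndex(bundle.ncrna_set)
    name, seq, cls = bundle.ncrna_set[0]
    assert match_ncrna(seq[5:25], index) == (name, cls)
    assert match_ncrna("ACGT" * 5, index) is None


def test_priority_monotone_partition(small_pipeline):
    """Every tag gets exactly one category; counts reconcile."""
    anns = small_pipeline.annotations
    cats = {a.category for a in anns.values()}
    from mirnaome.annotate import CATEGORIES
    assert cats <= set(CATEGORIES)
    assert "novel-miRNA-candidate" not in cats or all(
        a.category != "novel-miRNA-candidate" or a.loci
        for a in anns.values())
    total = small_pipeline.category_counts.sum(axis=1)
    clean = small_pipeline.qc.summary["clean_reads"]
    assert (total == clean).all()
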