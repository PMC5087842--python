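"""End-to-end pipeline: reads -> tags -> annotation -> quantification ->
novel calls -> differential expression -> temporal profiles -> targets.

`run_pipeline` wires the stage modules together on in-memory objects (a
reference bundle plus per-library reads); the CLI exposes the same flow on
files. The result object keeps every intermediate table so tests and the
acceptance script can audit each stage against the generator's truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import pandas as pd

from mirnaome import annotate, diff_expr, novel_mirna, profiles, quantify, targets
from mirnaome.read_qc import QCParams, QCResult, run_qc
from mirnaome.synthetic_data import ReferenceBundle, StudyDesign


@dataclass
class PipelineResult:
    qc: QCResult
    annotations: dict[str, annotate.TagAnnotation]
    category_counts: pd.DataFrame          # library x category read counts
    denominators: dict[str, int]
    matrix: quantify.ExpressionMatrix
    tiers: pd.DataFrame
    summary: pd.DataFrame                  # top-N abundance table
    correlations: pd.DataFrame
    clusters: pd.DataFrame
    novel_calls: list[novel_mirna.NovelCall]
    novel_candidates: list[novel_mirna.HairpinCandidate]
    de_table: pd.DataFrame
    profile_assignments: pd.DataFrame
    profile_significance: pd.DataFrame
    target_pairs: set[tuple[str, str]] = field(default_factory=set)
    filtered_targets: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None


def run_pipeline(bundle: ReferenceBundle,
                 reads_per_library: Mapping[str, list[tuple[str, str, str]]],
                 design: StudyDesign,
                 qc_params: QCParams | None = None,
                 novel_seed: int = 0,
                 n_shuffles: int = 100,
                 run_targets: bool = True) -> PipelineResult:
    """Run every stage on in-memory reads against a reference bundle."""
    qc_params = qc_params or QCParams(adapter3=design.adapter3,
                                      adapter5=design.adapter5)
    qc = run_qc(reads_per_library, qc_params)
    libraries = qc.libraries

    tag_seqs = [t.sequence for t in qc.tags]
    anns = annotate.annotate_tags(
        tag_seqs, bundle.registry, bundle.ncrna_set, bundle.genome,
        bundle.feature_annotation)
    counts_of = {t.sequence: t.counts for t in qc.tags}
    totals_of = {t.sequence: t.total for t in qc.tags}

    # ------------------------------------------------------------- novel
    novel_calls, novel_candidates = novel_mirna.discover_novel(
        anns, totals_of, bundle.genome, seed=novel_seed,
        n_shuffles=n_shuffles)
    called_tags: dict[str, str] = {}
    for call in novel_calls:
        for cand in call.candidates:
            m_off = cand.mature_pos
            m_end = m_off + len(cand.mature)
            for off, tseq, _ in cand.read_stack:
                if (abs(off - m_off) <= 2
                        and abs(off + len(tseq) - m_end) <= 2):
                    called_tags.setdefault(tseq, call.name)

    feature_index = annotate.FeatureIndex(bundle.feature_annotation)
    for seq, ann in anns.items():
        ann.category = annotate.finalize_category(
            ann, seq in called_tags, feature_index)

    # ------------------------------------------------------- denominators
    denominators = {lib: 0 for lib in libraries}
    for seq, ann in anns.items():
        if ann.loci:
            for lib, n in counts_of[seq].items():
                denominators[lib] += n

    # -------------------------------------------------- category partition
    cat_rows = {lib: dict.fromkeys(annotate.CATEGORIES, 0) for lib in libraries}
    for seq, ann in anns.items():
        for lib, n in counts_of[seq].items():
            cat_rows[lib][ann.category] += n
    category_counts = pd.DataFrame(
        [{"library": lib, **cat_rows[lib]} for lib in libraries]
    ).set_index("library")

    # ------------------------------------------------------------- counts
    mirna_counts: dict[str, dict[str, int]] = {}
    kinds: dict[str, str] = {}

    def _bump(mid: str, seq: str, kind: str) -> None:
        kinds.setdefault(mid, kind)
        slot = mirna_counts.setdefault(mid, {})
        for lib, n in counts_of[seq].items():
            slot[lib] = slot.get(lib, 0) + n

    for seq, ann in anns.items():
        if ann.category in ("known-miRNA", "edited-miRNA") and ann.assigned_mirna:
            kind = "homolog" if ann.homolog_of else "known"
            _bump(ann.assigned_mirna, seq, kind)
        elif seq in called_tags:
            _bump(called_tags[seq], seq, "novel")
    # every registry own mature appears as a row even at zero counts
    for m in bundle.registry.own_matures:
        mirna_counts.setdefault(m.id, {})
        kinds.setdefault(m.id, "known")

    matrix = quantify.build_expression_matrix(
        mirna_counts, denominators, libraries, kinds=kinds)
    tiers = quantify.filter_and_tier(matrix)
    summary = quantify.summarize_abundance(matrix, tiers)
    correlations = quantify.pairwise_correlation(matrix, tiers)
    coords = bundle.registry.mature_coordinates()
    clusters = quantify.detect_genomic_clusters(coords, tiers)

    # ------------------------------------------------------------- DE
    de_table = diff_expr.call_de(matrix, tiers=tiers)

    # ------------------------------------------------------------- profiles
    de_known = sorted(set(
        de_table.loc[de_table["call"] != "ns", "mirna"])
        & set(tiers.index[tiers["kind"] == "known"]))
    stage_rpm = matrix.stage_means().loc[de_known]
    profs = profiles.enumerate_profiles(len(matrix.stage_order))
    if len(de_known):
        traj = profiles.stage_trajectories(stage_rpm)
        assignments = profiles.assign_profiles(traj, profs)
        significance = profiles.profile_significance(traj, profs, assignments)
    else:
        assignments = pd.DataFrame(columns=["profile", "correlation"])
        significance = pd.DataFrame()

    result = PipelineResult(
        qc=qc, annotations=anns, category_counts=category_counts,
        denominators=denominators, matrix=matrix, tiers=tiers,
        summary=summary, correlations=correlations, clusters=clusters,
        novel_calls=novel_calls, novel_candidates=novel_candidates,
        de_table=de_table, profile_assignments=assignments,
        profile_significance=significance)

    # ------------------------------------------------------------- targets
    if run_targets:
        mature_by_id = {m.id: m.seq for m in bundle.registry.own_matures}
        overall = tiers["overall_average_rpm"]
        focus = {mid: mature_by_id[mid] for mid in de_known
                 if mid in mature_by_id and overall[mid] > targets.RPM_FOCUS}
        utrs = dict(bundle.utr_set)
        preds = targets.predict_targets(focus, utrs)
        pairs = targets.intersect_targets(preds)
        result.target_pairs = pairs
        retained_genes: set[str] = set()
        overall_map = overall.to_dict()
        for a, b in combinations(matrix.stage_order, 2):
            comp = f"{a}_vs_{b}"
            kept = targets.anticorrelation_filter(
                pairs, de_table, bundle.mrna_fc_table, comp, overall_map)
            result.filtered_targets[comp] = kept
            retained_genes.update(kept["gene"])
        if retained_genes:
            result.enrichment = targets.enrich(
                sorted(retained_genes), [g for g, _ in bundle.utr_set],
                bundle.gene_sets)
    return result
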