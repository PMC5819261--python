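"""Taxonomic assignment: thresholded 1-NN with topological evaluation.

A query is assigned the group of its most similar reference genome
(1-nearest neighbour on CGJ similarity).  The candidate is then
validated in two steps: (1) the CGJ score must reach the group-specific
threshold, estimated as the SVM decision boundary between the group's
intra- and inter-group similarity score distributions (balanced class
weights, at most 10,000 samples per side); (2) the query's placement in
a joint UPGMA dendrogram of references and queries must put it next to
the candidate group — its sister clade, its immediate outgroup, or one
of the two basal branches of its sister clade must consist entirely of
candidate-group references.  A query rejected by every sub-pipeline
(one per Baltimore group) is "unclassified"; when several sub-pipelines
accept, the highest CGJ similarity wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import SignatureTable, annotate, annotate_references
from .dendro import Node, upgma
from .genome_io import GenomeRecord
from .profiles import BuildConfig, ProfileDatabase, baltimore_key, build_database
from .similarity import DistanceMatrix, cgj_matrix

logger = logging.getLogger(__name__)

SAMPLE_CAP = 10_000

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ThresholdModel:
    group: str
    threshold: float
    n_intra: int
    n_inter: int

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateAssignment:
    query_id: str
    group: str
    neighbour_id: str
    cgj: float


@dataclass
class ClassificationResult:
    query_id: str
    label: str  # group name or "unclassified"
    sub_pipeline: str = ""
    cgj: float = 0.0
    neighbour_id: str = ""
    trace: dict = field(default_factory=dict)


def nearest_neighbour(
    query_id: str,
    similarities: np.ndarray,
    ref_table: SignatureTable,
    rank: str = "family",
) -> CandidateAssignment:
    """Candidate group = group of the reference with the highest CGJ.

    Ties are broken by the smallest reference accession.
    """
    if not len(ref_table):
        raise ValueError("reference table is empty")
    best_cgj = float(np.max(similarities))
    tied = [i for i in range(len(ref_table)) if similarities[i] >= best_cgj]
    best = min(tied, key=lambda i: ref_table.accessions[i])
    return CandidateAssignment(
        query_id, ref_table.label(best, rank), ref_table.accessions[best], best_cgj
    )


def fit_group_threshold(
    intra: Sequence[float],
    inter: Sequence[float],
    cap: int = SAMPLE_CAP,
    seed: int = 0,
    group: str = "",
) -> ThresholdModel:
    """CGJ threshold separating intra- from inter-group similarities.

    A linear SVM with balanced class weights is fitted on the (1-D)
    scores; the threshold is its decision boundary, which for separable
    classes is the midpoint of the margin.  Degenerate cases: no inter
    scores -> threshold 0 (accept all); no intra scores (single-member
    group) -> the largest observed inter score, capped at 1.
    """
    rng = np.random.default_rng(seed)
    intra = np.asarray(list(intra), dtype=float)
    inter = np.asarray(list(inter), dtype=float)
    if intra.size > cap:
        intra = rng.choice(intra, size=cap, replace=False)
    if inter.size > cap:
        inter = rng.choice(inter, size=cap, replace=False)
    if inter.size == 0:
        if intra.size == 0:
            raise ValueError("no similarity scores to fit a threshold")
        warnings.warn(f"group {group!r}: no inter-group scores; threshold 0",
                      RuntimeWarning)
        return ThresholdModel(group, 0.0, int(intra.size), 0)
    if intra.size == 0:
        thr = min(1.0, float(inter.max()))
        return ThresholdModel(group, thr, 0, int(inter.size))
    from sklearn.svm import SVC

    X = np.concatenate([intra, inter])[:, None]
    y = np.concatenate([np.ones(intra.size), np.zeros(inter.size)])
    if np.ptp(X) == 0:  # all scores identical; SVC cannot fit
        thr = float(X[0, 0])
    else:
        clf = SVC(kernel="linear", class_weight="balanced")
        clf.fit(X, y)
        w = float(clf.coef_[0, 0])
        if w <= 0:
            thr = 0.5 * (float(intra.mean()) + float(inter.mean()))
        else:
            thr = -float(clf.intercept_[0]) / w
    thr = float(np.clip(thr, 0.0, 1.0))
    return ThresholdModel(group, thr, int(intra.size), int(inter.size))


def fit_thresholds(
    ref_table: SignatureTable, rank: str = "family", cap: int = SAMPLE_CAP, seed: int = 0
) -> dict[str, ThresholdModel]:
    """One threshold model per group in a reference signature table."""
    S = cgj_matrix(ref_table)
    labels = np.array(ref_table.labels(rank))
    models: dict[str, ThresholdModel] = {}
    iu = np.triu_indices(len(ref_table), k=1)
    pair_labels = (labels[iu[0]], labels[iu[1]])
    scores = S[iu]
    for g in sorted(set(labels)):
        in_a = pair_labels[0] == g
        in_b = pair_labels[1] == g
        intra = scores[in_a & in_b]
        inter = scores[in_a ^ in_b]
        models[g] = fit_group_threshold(intra, inter, cap=cap, seed=seed, group=g)
    return models


def threshold_check(candidate: CandidateAssignment, model: ThresholdModel) -> bool:
    """True when the candidate passes (cgj >= threshold)."""
    return candidate.cgj >= model.threshold


def topological_evaluate(
    tree: Node,
    query_leaf: str,
    candidate_group: str,
    ref_labels: dict[str, str],
) -> tuple[bool, str]:
    """Accept a candidate when the query's neighbourhood matches the group.

    Conditions (any suffices): (i) the sister clade, (ii) the immediate
    outgroup, or (iii) one of the two basal branches of the sister
    clade, is composed entirely of candidate-group references.
    Co-analysed queries carry no group label yet, so they are ignored:
    the neighbourhood is read off the joint tree restricted to the
    reference leaves plus this query (other query leaves pruned,
    single-child nodes collapsed).  A condition needs at least one
    reference leaf to fire.
    Returns (accepted, name of the condition that fired or "").
    """
    if tree.find_leaf(query_leaf) is None:
        raise ValueError(f"query {query_leaf!r} not in the tree")
    tree = _restrict_tree(tree, set(ref_labels) | {query_leaf})
    leaf = tree.find_leaf(query_leaf)

    def group_only(node: Node) -> bool:
        refs = [l for l in node.leaves() if l in ref_labels]
        return bool(refs) and all(ref_labels[l] == candidate_group for l in refs)

    parent = tree.parent_of(leaf)
    if parent is None:
        return False, ""
    sister = next((c for c in parent.children if c is not leaf), None)
    if sister is not None and group_only(sister):
        return True, "sister"
    grand = tree.parent_of(parent)
    if grand is not None:
        outgroup = next((c for c in grand.children if c is not parent), None)
        if outgroup is not None and group_only(outgroup):
            return True, "outgroup"
    if sister is not None and not sister.is_leaf:
        for basal in sister.children:
            if group_only(basal):
                return True, "sister-basal"
    return False, ""


def _restrict_tree(tree: Node, keep: set[str]) -> Node:
    """Copy of the tree with only ``keep`` leaves; unary nodes collapse."""

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                out = Node(name=node.name, height=node.height)
                return out
            return None
        kept = [c2 for c2 in (rec(c) for c in node.children) if c2 is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(children=kept, height=node.height, support=node.support)

    out = rec(tree)
    if out is None:
        raise ValueError("restriction removed every leaf")
    return out


@dataclass
class SubPipeline:
    """One Baltimore group's annotator + classifier state."""

    name: str
    db: ProfileDatabase
    ref_table: SignatureTable
    goms: list
    thresholds: dict[str, ThresholdModel]
    rank: str = "family"


def build_sub_pipeline(
    ref_genomes: Sequence[GenomeRecord],
    config: BuildConfig = BuildConfig(),
    rank: str = "family",
    seed: int = 0,
) -> SubPipeline:
    """Build database, reference annotations and thresholds for one group."""
    db = build_database(ref_genomes, config)
    table, goms = annotate_references(ref_genomes, db, rank=rank)
    thresholds = fit_thresholds(table, rank=rank, seed=seed)
    return SubPipeline(db.baltimore_group, db, table, goms, thresholds, rank)


def classify(
    queries: Sequence[GenomeRecord],
    pipelines: Sequence[SubPipeline],
) -> list[ClassificationResult]:
    """Run queries through every sub-pipeline and arbitrate by CGJ.

    Per pipeline: annotate, 1-NN, threshold check, then topological
    evaluation on one joint dendrogram holding all references and all
    queries.  Accepted candidates from different pipelines compete on
    CGJ; queries with no accepted candidate are "unclassified".
    """
    if not pipelines:
        raise ValueError("at least one sub-pipeline required")
    results = {
        q.accession: ClassificationResult(q.accession, UNCLASSIFIED)
        for q in queries
    }
    for pipe in pipelines:
        if not queries:
            continue
        q_table = annotate(queries, pipe.db, pipe.goms)
        S = cgj_matrix(q_table, pipe.ref_table)  # (n_queries, n_refs)
        candidates = {}
        for qi, qacc in enumerate(q_table.accessions):
            cand = nearest_neighbour(qacc, S[qi], pipe.ref_table, pipe.rank)
            model = pipe.thresholds.get(cand.group)
            passed = model is not None and threshold_check(cand, model)
            candidates[qacc] = (cand, model, passed)
        joint_tree = None
        if any(passed for _, _, passed in candidates.values()):
            joint_tree = upgma(_joint_distance_matrix(pipe.ref_table, q_table))
        ref_labels = dict(zip(pipe.ref_table.accessions,
                              pipe.ref_table.labels(pipe.rank)))
        for qacc, (cand, model, passed) in candidates.items():
            trace = {
                "pipeline": pipe.name,
                "candidate": cand.group,
                "neighbour": cand.neighbour_id,
                "cgj": cand.cgj,
                "threshold": model.threshold if model else None,
                "threshold_pass": passed,
                "condition": "",
            }
            accepted = False
            if passed:
                accepted, condition = topological_evaluate(
                    joint_tree, qacc, cand.group, ref_labels
                )
                trace["condition"] = condition
            res = results[qacc]
            res.trace[pipe.name] = trace
            if accepted and (res.label == UNCLASSIFIED or cand.cgj > res.cgj):
                res.label = cand.group
                res.sub_pipeline = pipe.name
                res.cgj = cand.cgj
                res.neighbour_id = cand.neighbour_id
    return [results[q.accession] for q in queries]


def _joint_distance_matrix(ref_table: SignatureTable, q_table: SignatureTable) -> DistanceMatrix:
    S_rr = cgj_matrix(ref_table)
    S_qq = cgj_matrix(q_table)
    S_qr = cgj_matrix(q_table, ref_table)
    n_r, n_q = len(ref_table), len(q_table)
    S = np.zeros((n_r + n_q, n_r + n_q))
    S[:n_r, :n_r] = S_rr
    S[n_r:, n_r:] = S_qq
    S[n_r:, :n_r] = S_qr
    S[:n_r, n_r:] = S_qr.T
    D = np.clip(1.0 - S, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(list(ref_table.accessions) + list(q_table.accessions), D)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldMetrics:
    fold: int
    n_known: int
    n_known_correct: int
    n_unknown: int
    n_unknown_unclassified: int

    @property
    def sensitivity(self) -> float:
        """% of test viruses from represented groups assigned correctly."""
        return 100.0 * self.n_known_correct / self.n_known if self.n_known else float("nan")

    @property
    def specificity(self) -> float:
        """% of test viruses from unrepresented groups left unclassified."""
        return (100.0 * self.n_unknown_unclassified / self.n_unknown
                if self.n_unknown else float("nan"))


def split_reference_test(
    genomes: Sequence[GenomeRecord],
    rng: np.random.Generator,
    rank: str = "family",
    ref_fraction: float = 0.67,
    always_test: Sequence[str] = (),
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Random per-group 67/33 split; groups with <3 members go all to test."""
    by_group: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_group.setdefault(g.taxonomy.label(rank), []).append(g)
    refs: list[GenomeRecord] = []
    tests: list[GenomeRecord] = []
    for group in sorted(by_group):
        members = by_group[group]
        if group in always_test or len(members) < 3:
            tests.extend(members)
            continue
        order = rng.permutation(len(members))
        n_ref = int(round(ref_fraction * len(members)))
        refs.extend(members[i] for i in order[:n_ref])
        tests.extend(members[i] for i in order[n_ref:])
    return refs, tests


def cross_validate(
    genomes: Sequence[GenomeRecord],
    seed: int = 0,
    n_folds: int = 3,
    rank: str = "family",
    always_test_families: Sequence[str] = (),
    config: BuildConfig = BuildConfig(),
) -> list[FoldMetrics]:
    """Repeated random-split evaluation of the whole pipeline.

    Each fold draws an independent 67/33 reference/test split per
    group, rebuilds the databases and thresholds from the reference
    side only, classifies the test side, and scores sensitivity over
    test viruses whose group is represented among the references and
    specificity over those whose group is not.
    """
    rng = np.random.default_rng(seed)
    metrics: list[FoldMetrics] = []
    for fold in range(n_folds):
        refs, tests = split_reference_test(
            genomes, rng, rank=rank, always_test=list(always_test_families)
        )
        by_balt: dict[str, list[GenomeRecord]] = {}
        for g in refs:
            by_balt.setdefault(baltimore_key(g.taxonomy.baltimore_group), []).append(g)
        pipelines = [
            build_sub_pipeline(members, config=config, rank=rank, seed=seed + fold)
            for _, members in sorted(by_balt.items())
        ]
        represented = {
            lab for p in pipelines for lab in p.ref_table.labels(rank)
        }
        results = classify(tests, pipelines)
        n_known = n_known_correct = n_unknown = n_unknown_uncl = 0
        for g, res in zip(tests, results):
            truth = g.taxonomy.label(rank)
            if truth in represented:
                n_known += 1
                n_known_correct += res.label == truth
            else:
                n_unknown += 1
                n_unknown_uncl += res.label == UNCLASSIFIED
        metrics.append(FoldMetrics(fold, n_known, n_known_correct,
                                   n_unknown, n_unknown_uncl))
        logger.info("fold %d: sensitivity %.2f%% specificity %.2f%%",
                    fold, metrics[-1].sensitivity, metrics[-1].specificity)
    return metrics


# ---------------------------------------------------------------------------
# metagenomic helpers


def metagenomic_length_filter(
    queries: Sequence[GenomeRecord],
    provisional_groups: dict[str, str],
    reference_genomes: Sequence[GenomeRecord],
    rank: str = "family",
) -> list[GenomeRecord]:
    """Drop assembled queries shorter than the smallest reference of their group.

    The group-specific threshold is the genome length of the smallest
    reference virus in the query's provisionally assigned group; a
    query exactly at the threshold is retained.  Queries whose group
    has no reference member are retained with a warning.
    """
    min_len: dict[str, int] = {}
    for g in reference_genomes:
        lab = g.taxonomy.label(rank)
        if lab:
            min_len[lab] = min(min_len.get(lab, g.length), g.length)
    retained = []
    for q in queries:
        group = provisional_groups.get(q.accession, "")
        if group not in min_len:
            warnings.warn(
                f"query {q.accession}: no reference lengths for group {group!r}; retained",
                RuntimeWarning,
            )
            retained.append(q)
        elif q.length >= min_len[group]:
            retained.append(q)
    return retained


def update_database(
    reference_genomes: Sequence[GenomeRecord],
    new_genomes: Sequence[GenomeRecord],
    config: BuildConfig = BuildConfig(),
    baltimore_group: str | None = None,
) -> ProfileDatabase:
    """Rebuild a group's database with genes from new (e.g. unclassified) genomes.

    The new genomes' proteins are pooled with the existing reference
    proteins before clustering, so novel gene families become new
    profiles; genomes that failed the assembly length filter may still
    contribute genes here.
    """
    pooled = list(reference_genomes) + list(new_genomes)
    if baltimore_group is None and reference_genomes:
        baltimore_group = baltimore_key(
            reference_genomes[0].taxonomy.baltimore_group
        )
    return build_database(pooled, config, baltimore_group=baltimore_group)
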