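"""Mutual information of profile scores with taxonomy, and gene categories.

Mutual information (MI) between a profile's score column and the virus
group labels measures how predictive that gene family is of the
current taxonomy.  The estimate is stochastic (k-nearest-neighbour
estimator for continuous scores), so it is averaged over repeated
subsamples that draw at most two viruses per group, which keeps large
groups from dominating.  Profiles are also bucketed into broad gene
categories by keyword matching on their member descriptions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import mutual_info_score

from .annotation import SignatureTable

DEFAULT_REPS = 100
DEFAULT_MAX_PER_GROUP = 2
DISPLAY_THRESHOLD = 0.1  # nats; profiles below this are background
_DISCRETE_MAX_UNIQUE = 8

CATEGORIES = (
    "nonstructural_replication",
    "nonstructural_other",
    "structural_capsid_gag",
    "structural_other",
    "unknown",
)


@dataclass(frozen=True)
class MIResult:
    profile_id: str
    mean_mi: float  # nats
    category: str
    n_reps: int


def mutual_information(
    feature: np.ndarray, labels: Sequence[str], seed: int = 0
) -> float:
    """MI (nats) between one numeric feature and categorical labels.

    Continuous features use the kNN estimator (k=3); features with few
    unique values use the discrete plug-in formula.  A single label
    class carries no information (0).
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.size != labels.size:
        raise ValueError("feature and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        return 0.0
    uniq, codes = np.unique(feature, return_inverse=True)
    # plug-in only for genuinely discrete features: few unique values that
    # are each observed repeatedly (a fresh value per sample is continuous)
    if uniq.size <= min(_DISCRETE_MAX_UNIQUE, feature.size // 2):
        return float(mutual_info_score(labels, codes))
    mi = mutual_info_classif(
        feature[:, None], labels, n_neighbors=3, random_state=seed,
        discrete_features=False,
    )
    return float(max(mi[0], 0.0))


def mi_profile(
    table: SignatureTable,
    rank: str = "family",
    reps: int = DEFAULT_REPS,
    max_per_group: int = DEFAULT_MAX_PER_GROUP,
    seed: int = 0,
    annotations: dict[str, str] | None = None,
) -> list[MIResult]:
    """Mean MI per profile over repeated per-group subsamples."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = np.array(table.labels(rank))
    rng = np.random.default_rng(seed)
    sums = np.zeros(len(table.profile_ids))
    for r in range(reps):
        rows = _subsample_rows(labels, max_per_group, rng)
        sub_scores = table.pphmm[rows]
        sub_labels = labels[rows]
        for j in range(sub_scores.shape[1]):
            sums[j] += mutual_information(
                sub_scores[:, j], sub_labels, seed=int(rng.integers(2**31))
            )
    means = sums / reps
    annotations = annotations or {}
    return [
        MIResult(pid, float(means[j]),
                 categorize_profile(annotations.get(pid, "")), reps)
        for j, pid in enumerate(table.profile_ids)
    ]


def _subsample_rows(
    labels: np.ndarray, max_per_group: int, rng: np.random.Generator
) -> np.ndarray:
    rows: list[int] = []
    for g in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == g)
        if idx.size > max_per_group:
            idx = rng.choice(idx, size=max_per_group, replace=False)
        rows.extend(int(i) for i in idx)
    return np.array(sorted(rows))


def family_shared_features(
    families: Sequence[str],
    table: SignatureTable,
    rank: str = "family",
    reps: int = DEFAULT_REPS,
    max_per_group: int = DEFAULT_MAX_PER_GROUP,
    seed: int = 0,
    annotations: dict[str, str] | None = None,
) -> list[MIResult]:
    """MI after relabelling the families of interest as one class.

    Viruses of the investigated families become one group, everything
    else another; profiles with no hit in the investigated families
    are removed before scoring.
    """
    families = set(families)
    labels = np.array(table.labels(rank))
    member = np.isin(labels, sorted(families))
    keep = np.flatnonzero((table.pphmm[member] != 0).any(axis=0)) if member.any() \
        else np.array([], dtype=int)
    relabelled = SignatureTable(
        list(table.accessions),
        [_binary_taxonomy(t.label(rank) in families) for t in table.taxonomies],
        table.pphmm[:, keep], table.locations[:, keep],
        table.gom_sig, [table.profile_ids[i] for i in keep], list(table.gom_labels),
    )
    return mi_profile(relabelled, rank="family", reps=reps,
                      max_per_group=max_per_group, seed=seed, annotations=annotations)


def _binary_taxonomy(in_set: bool):
    from .genome_io import Taxonomy

    return Taxonomy(family="investigated" if in_set else "other")


# ---------------------------------------------------------------------------
# gene categorisation

_REPLICATION = ("polymerase", "replicase", "replication", "transcription",
                "helicase", "primase")
_CAPSID = ("capsid", "gag", "coat", "shell", "core", "nucleocapsid")
_NONSTRUCTURAL = ("nonstructural", "non-structural", "non structural")
_STRUCTURAL = ("glycoprotein", "matrix", "tegument", "envelope", "surface",
               "membrane", "structural")
_NS_RE = re.compile(r"\bns\d*\b", re.IGNORECASE)


def categorize_profile(annotation: str) -> str:
    """Keyword gene category with precedence replication > capsid/gag >
    other non-structural > other structural > unknown.

    "structural" must not fire on "non-structural"/"nonstructural".
    """
    text = annotation.lower()
    if any(k in text for k in _REPLICATION):
        return "nonstructural_replication"
    if any(k in text for k in _CAPSID):
        return "structural_capsid_gag"
    if any(k in text for k in _NONSTRUCTURAL) or _NS_RE.search(annotation):
        return "nonstructural_other"
    masked = text.replace("non-structural", "").replace("nonstructural", "") \
                 .replace("non structural", "")
    if any(k in masked for k in _STRUCTURAL):
        return "structural_other"
    return "unknown"


def write_mi_report(results: Sequence[MIResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("profile_id\tmean_mi\tcategory\tn_reps\n")
        for r in sorted(results, key=lambda r: -r.mean_mi):
            fh.write(f"{r.profile_id}\t{r.mean_mi:.6f}\t{r.category}\t{r.n_reps}\n")
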