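"""Genome annotation against a profile database.

Each genome (segments concatenated largest-to-smallest) is six-frame
translated and scanned against the profile HMM database.  Retained hits
(conditional E-value <= 0.001, positive score) yield two vectors per
genome: the profile score vector (the PPHMM signature, 0 = no hit) and
a signed gene-location vector holding the nucleotide midpoint of each
profile's best hit, negative when the gene lies on the complementary
strand.  Stacking the location vectors of a family's members gives its
genome-organisation model (GOM); the distance correlation between a
genome's location vector and each family GOM forms its GOM signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pyhmmer

from .genome_io import GenomeRecord, Taxonomy, canonical_orientation, six_frame_translate
from .profiles import ProfileDatabase

logger = logging.getLogger(__name__)

_AMINO = pyhmmer.easel.Alphabet.amino()

DEFAULT_MAX_C_EVALUE = 0.001

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ProfileHit:
    """Aggregated hit of one profile on one genome.

    ``score`` is the overall evidence across the whole query (sum of
    retained per-domain bit scores over all six frames); ``span`` is
    the best single domain's amino-acid envelope within its frame's
    translation (1-based, inclusive), used for the gene location.
    """

    profile_id: str
    score: float
    c_evalue: float
    span: tuple[int, int]
    frame: int


def scan_genome(
    seq: str,
    db: ProfileDatabase,
    max_c_evalue: float = DEFAULT_MAX_C_EVALUE,
) -> list[ProfileHit]:
    """Scan one nucleotide sequence against the profile database.

    The six frame translations are scanned with pyhmmer's hmmscan with
    the bias-composition filter disabled.  Domains with conditional
    E-value above the cutoff or non-positive score are discarded; at
    most one aggregated hit per profile is returned.
    """
    if not seq or not len(db):
        raise ValueError("empty sequence or database")
    frames = six_frame_translate(seq)
    queries = []
    for f in FRAME_ORDER:
        aa = frames[f].replace("*", "X")  # stops are non-residues for the scanner
        queries.append(
            pyhmmer.easel.TextSequence(name=str(f).encode(), sequence=aa).digitize(_AMINO)
        )
    best: dict[str, dict] = {}
    results = pyhmmer.hmmer.hmmscan(queries, db.hmms(), cpus=1, bias_filter=False)
    for frame, tophits in zip(FRAME_ORDER, results):
        for hit in tophits:
            pid = hit.name if isinstance(hit.name, str) else hit.name.decode()
            for dom in hit.domains:
                if dom.c_evalue > max_c_evalue or dom.score <= 0:
                    continue
                rec = best.setdefault(
                    pid, {"score": 0.0, "best": None}
                )
                rec["score"] += dom.score
                key = (dom.score, -frame)  # deterministic best-domain choice
                if rec["best"] is None or key > rec["best"][0]:
                    rec["best"] = (key, dom.c_evalue, (dom.env_from, dom.env_to), frame)
    hits = []
    for pid in db.profile_ids:
        if pid not in best:
            continue
        rec = best[pid]
        _, c_evalue, span, frame = rec["best"]
        hits.append(ProfileHit(pid, rec["score"], c_evalue, span, frame))
    return hits


def gene_locations(
    hits: Iterable[ProfileHit], genome_length: int, db: ProfileDatabase
) -> np.ndarray:
    """Signed nucleotide midpoints of the best hit per profile (0 = absent).

    A protein position p in forward frame f maps to nucleotide
    (f-1) + 3(p-1) + 2 (the codon midpoint, 1-based).  Reverse frames
    map through the reverse-complement coordinate and are negated.
    """
    loc = np.zeros(len(db))
    order = {pid: i for i, pid in enumerate(db.profile_ids)}
    for h in hits:
        p_mid = 0.5 * (h.span[0] + h.span[1])
        f = abs(h.frame)
        nt = (f - 1) + 3.0 * (p_mid - 1) + 2
        if h.frame < 0:
            nt = genome_length - nt + 1
        if not (1 <= nt <= genome_length):
            raise ValueError(
                f"profile {h.profile_id}: mapped midpoint {nt} outside [1, {genome_length}]"
            )
        loc[order[h.profile_id]] = nt if h.frame > 0 else -nt
    return loc


@dataclass
class GenomeOrganisationModel:
    """Per-family matrix of signed gene locations (rows = member genomes)."""

    label: str
    matrix: np.ndarray  # (n_members, n_profiles)
    member_accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))


def build_gom(
    location_vectors: Sequence[np.ndarray],
    label: str,
    member_accessions: Sequence[str] = (),
) -> GenomeOrganisationModel:
    if not len(location_vectors):
        raise ValueError("GOM needs at least one member")
    lengths = {len(v) for v in location_vectors}
    if len(lengths) > 1:
        raise ValueError("inconsistent location vector lengths")
    return GenomeOrganisationModel(label, np.vstack(location_vectors), list(member_accessions))


def distance_correlation(x: np.ndarray, Y: np.ndarray) -> float:
    """Szekely's distance correlation between paired observations.

    ``x`` holds one scalar observation per index and ``Y`` one vector
    per index (rows).  Distance matrices of both samples are double
    centred; dCor = dCov / sqrt(dVar_x * dVar_y), which lies in [0, 1]
    and is invariant to negating x (so to the choice of input strand).
    Degenerate inputs (fewer than 2 indices, or zero variance) give 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != x.size:
        raise ValueError("x and Y must have the same number of observations")
    n = x.size
    if n < 2:
        warnings.warn("distance correlation needs >= 2 observations; returning 0",
                      RuntimeWarning)
        return 0.0
    a = np.abs(x[:, None] - x[None, :])
    d = Y[:, None, :] - Y[None, :, :]
    b = np.sqrt((d * d).sum(axis=2))
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    r2 = dcov2 / np.sqrt(dvarx * dvary)
    return float(np.clip(r2, 0.0, 1.0) ** 0.5)


def gom_signature(
    locations: np.ndarray, goms: Sequence[GenomeOrganisationModel]
) -> np.ndarray:
    """Distance correlation of a location vector against each family GOM.

    Profile indices where the gene is absent both from the query and
    from every GOM member are ignored; if fewer than two usable indices
    remain the entry is 0.
    """
    locations = np.asarray(locations, dtype=float)
    sig = np.zeros(len(goms))
    for j, gom in enumerate(goms):
        usable = (locations != 0) | (gom.matrix != 0).any(axis=0)
        if usable.sum() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sig[j] = distance_correlation(locations[usable], gom.matrix.T[usable])
    return sig


@dataclass
class SignatureTable:
    """Per-genome signature rows with consistent profile/GOM indexing."""

    accessions: list[str]
    taxonomies: list[Taxonomy]
    pphmm: np.ndarray      # (n, P) profile scores, >= 0
    locations: np.ndarray  # (n, P) signed midpoints
    gom_sig: np.ndarray    # (n, G) distance correlations in [0, 1]
    profile_ids: list[str]
    gom_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.accessions)
        self.pphmm = np.atleast_2d(np.asarray(self.pphmm, dtype=float))
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.gom_sig = np.atleast_2d(np.asarray(self.gom_sig, dtype=float))
        if not (self.pphmm.shape[0] == self.locations.shape[0] == self.gom_sig.shape[0] == n):
            raise ValueError("row count mismatch")
        if self.pphmm.shape[1] != len(self.profile_ids):
            raise ValueError("profile column mismatch")
        if self.gom_sig.shape[1] != len(self.gom_labels):
            raise ValueError("GOM column mismatch")

    def __len__(self) -> int:
        return len(self.accessions)

    def index_of(self, accession: str) -> int:
        return self.accessions.index(accession)

    def label(self, i: int, rank: str = "family") -> str:
        return self.taxonomies[i].label(rank)

    def labels(self, rank: str = "family") -> list[str]:
        return [t.label(rank) for t in self.taxonomies]

    def subset(self, rows: Sequence[int]) -> "SignatureTable":
        rows = list(rows)
        return SignatureTable(
            [self.accessions[i] for i in rows],
            [self.taxonomies[i] for i in rows],
            self.pphmm[rows], self.locations[rows], self.gom_sig[rows],
            list(self.profile_ids), list(self.gom_labels),
        )

    # -- plumbing: TSV round trip -------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        from .genome_io import TAXONOMY_RANKS

        with open(path, "w") as fh:
            fh.write(f"#profiles\t{','.join(self.profile_ids)}\n")
            fh.write(f"#goms\t{','.join(self.gom_labels)}\n")
            cols = (["accession", *TAXONOMY_RANKS]
                    + [f"score:{p}" for p in self.profile_ids]
                    + [f"loc:{p}" for p in self.profile_ids]
                    + [f"gom:{g}" for g in self.gom_labels])
            fh.write("\t".join(cols) + "\n")
            for i, acc in enumerate(self.accessions):
                t = self.taxonomies[i]
                vals = ([acc] + [t.label(r) for r in TAXONOMY_RANKS]
                        + [repr(float(v)) for v in self.pphmm[i]]
                        + [repr(float(v)) for v in self.locations[i]]
                        + [repr(float(v)) for v in self.gom_sig[i]])
                fh.write("\t".join(vals) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureTable":
        from .genome_io import TAXONOMY_RANKS

        with open(path) as fh:
            profile_ids = fh.readline().rstrip("\n").split("\t")[1].split(",")
            gom_line = fh.readline().rstrip("\n").split("\t")
            gom_labels = gom_line[1].split(",") if len(gom_line) > 1 and gom_line[1] else []
            fh.readline()  # header
            accs, taxa, scores, locs, gsig = [], [], [], [], []
            P, G = len(profile_ids), len(gom_labels)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                accs.append(f[0])
                taxa.append(Taxonomy(**dict(zip(TAXONOMY_RANKS, f[1:6]))))
                vals = [float(v) for v in f[6:]]
                scores.append(vals[:P])
                locs.append(vals[P:2 * P])
                gsig.append(vals[2 * P:2 * P + G])
        return cls(accs, taxa, np.array(scores), np.array(locs),
                   np.array(gsig) if G else np.zeros((len(accs), 0)),
                   profile_ids, gom_labels)


def build_goms(
    accessions: Sequence[str],
    taxonomies: Sequence[Taxonomy],
    locations: np.ndarray,
    rank: str = "family",
) -> list[GenomeOrganisationModel]:
    """Group location rows by taxonomic label into GOMs (sorted by label)."""
    by_label: dict[str, list[int]] = {}
    for i, t in enumerate(taxonomies):
        lab = t.label(rank)
        if lab:
            by_label.setdefault(lab, []).append(i)
    return [
        build_gom([locations[i] for i in idx], lab, [accessions[i] for i in idx])
        for lab, idx in sorted(by_label.items())
    ]


def annotate(
    genomes: Sequence[GenomeRecord],
    db: ProfileDatabase,
    goms: Sequence[GenomeOrganisationModel],
    max_c_evalue: float = DEFAULT_MAX_C_EVALUE,
) -> SignatureTable:
    """Annotate genomes against an existing database and GOM set.

    Each genome's segments are concatenated largest-to-smallest and the
    result is scanned in its canonical orientation, so the signatures do
    not depend on the strand on which the genome was submitted.
    """
    scores = np.zeros((len(genomes), len(db)))
    locs = np.zeros((len(genomes), len(db)))
    order = {pid: i for i, pid in enumerate(db.profile_ids)}
    for i, g in enumerate(genomes):
        seq = canonical_orientation(g.sequence())
        hits = scan_genome(seq, db, max_c_evalue=max_c_evalue)
        for h in hits:
            scores[i, order[h.profile_id]] = h.score
        locs[i] = gene_locations(hits, len(seq), db)
    gsig = np.vstack([gom_signature(locs[i], goms) for i in range(len(genomes))]) \
        if len(genomes) and len(goms) else np.zeros((len(genomes), len(goms)))
    return SignatureTable(
        [g.accession for g in genomes], [g.taxonomy for g in genomes],
        scores, locs, gsig, list(db.profile_ids), [g.label for g in goms],
    )


def annotate_references(
    genomes: Sequence[GenomeRecord],
    db: ProfileDatabase,
    rank: str = "family",
    max_c_evalue: float = DEFAULT_MAX_C_EVALUE,
) -> tuple[SignatureTable, list[GenomeOrganisationModel]]:
    """Annotate the reference set itself, building GOMs from its own rows.

    Two passes: scan everything to get score/location vectors, build
    one GOM per family, then fill in the GOM signatures.
    """
    empty = annotate(genomes, db, goms=[], max_c_evalue=max_c_evalue)
    goms = build_goms(empty.accessions, empty.taxonomies, empty.locations, rank=rank)
    gsig = np.vstack([gom_signature(empty.locations[i], goms) for i in range(len(genomes))]) \
        if len(genomes) else np.zeros((0, len(goms)))
    table = SignatureTable(
        empty.accessions, empty.taxonomies, empty.pphmm, empty.locations,
        gsig, empty.profile_ids, [g.label for g in goms],
    )
    return table, goms
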