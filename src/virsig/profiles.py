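"""Protein-profile database construction.

The database for one Baltimore group is built from the proteins of its
reference genomes in five steps: all-versus-all protein search, hit
filtering, best-hit reduction to one weight per protein pair, Markov
clustering (MCL) of the resulting similarity graph, and per-cluster
multiple alignment from which a profile hidden Markov model (HMM) is
trained.  Downstream code only consumes (score, E-value, location)
triples, so the search and alignment engines are pluggable: BLASTp and
MAFFT are used when available, with native fallbacks (Smith-Waterman
via Biopython plus Karlin-Altschul bit scores; star alignment) that
expose the same fields.  Profile HMMs are always built with pyhmmer.
"""

from __future__ import annotations

import json
import logging
import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pyhmmer
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genome_io import DEFAULT_MIN_PROTEIN_LEN, GenomeRecord, ProteinRecord, extract_proteins

logger = logging.getLogger(__name__)

_AMINO = pyhmmer.easel.Alphabet.amino()

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1),
# as used by BLASTp for its bit-score conversion.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class SimilarityEdge:
    """One directed protein-vs-protein hit."""

    query_id: str
    subject_id: str
    bit_score: float
    e_value: float
    pct_identity: float
    query_coverage: float
    subject_coverage: float


@dataclass(frozen=True)
class HitFilter:
    """Retention thresholds for pairwise protein hits."""

    max_evalue: float = 0.001
    min_identity: float = 30.0
    min_coverage: float = 75.0


@dataclass
class ProteinCluster:
    cluster_id: str
    member_ids: list[str]
    alignment: list[str]  # one gapped row per member, equal lengths

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        lengths = {len(r) for r in self.alignment}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")


class ProteinProfile:
    """A protein family profile: a pyhmmer HMM plus bookkeeping.

    ``annotation`` concatenates the descriptions of the member proteins
    and is what the gene categoriser later inspects.
    """

    def __init__(self, profile_id: str, hmm: pyhmmer.plan7.HMM, annotation: str = "",
                 member_ids: Sequence[str] = ()):
        self.profile_id = profile_id
        self.hmm = hmm
        self.annotation = annotation
        self.member_ids = list(member_ids)

    @property
    def length(self) -> int:
        return self.hmm.M

    def __repr__(self) -> str:
        return f"ProteinProfile({self.profile_id!r}, M={self.length})"


@dataclass
class ProfileDatabase:
    """An ordered collection of protein profiles for one Baltimore group.

    Signature vectors index into ``profiles`` by position, so the order
    is part of the database identity and is preserved on disk.
    """

    baltimore_group: str
    profiles: list[ProteinProfile]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.profile_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("profile ids must be unique")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def profile_ids(self) -> list[str]:
        return [p.profile_id for p in self.profiles]

    def hmms(self) -> list[pyhmmer.plan7.HMM]:
        return [p.hmm for p in self.profiles]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "profiles.hmm", "wb") as fh:
            for p in self.profiles:
                p.hmm.write(fh, binary=False)
        meta = {
            "baltimore_group": self.baltimore_group,
            "profiles": [
                {"profile_id": p.profile_id, "annotation": p.annotation,
                 "member_ids": p.member_ids}
                for p in self.profiles
            ],
            "metadata": self.metadata,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ProfileDatabase":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        with pyhmmer.plan7.HMMFile(directory / "profiles.hmm") as fh:
            hmms = list(fh)
        if len(hmms) != len(meta["profiles"]):
            raise ValueError("profile count mismatch between HMM file and metadata")
        profiles = [
            ProteinProfile(m["profile_id"], hmm, m["annotation"], m["member_ids"])
            for m, hmm in zip(meta["profiles"], hmms)
        ]
        return cls(meta["baltimore_group"], profiles, meta.get("metadata", {}))


def baltimore_key(group: str) -> str:
    """Database key for a Baltimore group; groups VI and VII are pooled."""
    g = group.strip().upper()
    return "VI+VII" if g in {"VI", "VII"} else g


# ---------------------------------------------------------------------------
# pairwise protein search


def pairwise_protein_search(
    proteins: Sequence[ProteinRecord], engine: str = "auto"
) -> list[SimilarityEdge]:
    """All-versus-all protein comparison.

    ``engine`` is "blast", "native" or "auto" (BLASTp when on PATH,
    native Smith-Waterman otherwise).  Self hits are excluded.
    """
    if len(proteins) < 2:
        return []
    if engine == "auto":
        engine = "blast" if shutil.which("blastp") else "native"
    if engine == "blast":
        return _blast_search(proteins)
    if engine == "native":
        return _native_search(proteins)
    raise ValueError(f"unknown search engine {engine!r}")


_OUTFMT = "6 qseqid sseqid pident length evalue bitscore qstart qend sstart send qlen slen"


def _blast_search(proteins: Sequence[ProteinRecord]) -> list[SimilarityEdge]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "prot.faa"
        with open(fasta, "w") as fh:
            for p in proteins:
                fh.write(f">{p.id}\n{p.sequence}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot", "-out", str(tmp / "db")],
            check=True, capture_output=True,
        )
        res = subprocess.run(
            ["blastp", "-query", str(fasta), "-db", str(tmp / "db"),
             "-outfmt", _OUTFMT, "-max_target_seqs", "1000000"],
            check=True, capture_output=True, text=True,
        )
        return parse_tabular_hits(res.stdout.splitlines())


def parse_tabular_hits(lines: Iterable[str]) -> list[SimilarityEdge]:
    """Parse tabular (outfmt-6 style) search results into edges.

    Expected columns: qseqid sseqid pident length evalue bitscore
    qstart qend sstart send qlen slen.
    """
    edges: list[SimilarityEdge] = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"expected 12 tab-separated columns, got {len(f)}: {line!r}")
        q, s = f[0], f[1]
        if q == s:
            continue
        qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
        qlen, slen = int(f[10]), int(f[11])
        edges.append(
            SimilarityEdge(
                query_id=q, subject_id=s,
                bit_score=float(f[5]), e_value=float(f[4]), pct_identity=float(f[2]),
                query_coverage=100.0 * (abs(qend - qstart) + 1) / qlen,
                subject_coverage=100.0 * (abs(send - sstart) + 1) / slen,
            )
        )
    return edges


def _kmer_sets(seqs: Sequence[str], k: int = 4) -> list[set[str]]:
    return [{s[i:i + k] for i in range(len(s) - k + 1)} for s in seqs]


def _native_search(
    proteins: Sequence[ProteinRecord], min_shared_kmers: int = 3
) -> list[SimilarityEdge]:
    """Smith-Waterman all-vs-all with a shared-k-mer prefilter.

    Raw BLOSUM62 scores are converted to bits with the standard
    Karlin-Altschul scaling; the E-value uses the m*n search-space of
    the pair.  Coverage is the aligned span over the full length.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"

    seqs = [p.sequence for p in proteins]
    kmers = _kmer_sets(seqs)
    edges: list[SimilarityEdge] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if len(kmers[i] & kmers[j]) < min_shared_kmers:
                continue
            aln = aligner.align(seqs[i], seqs[j])[0]
            bits = (_KA_LAMBDA * aln.score - math.log(_KA_K)) / math.log(2)
            evalue = len(seqs[i]) * len(seqs[j]) * 2.0 ** (-bits)
            counts = aln.counts()
            ncols = counts.identities + counts.mismatches + counts.gaps
            pident = 100.0 * counts.identities / max(ncols, 1)
            qspan = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
            sspan = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
            common = dict(bit_score=bits, e_value=evalue, pct_identity=pident)
            edges.append(SimilarityEdge(
                query_id=proteins[i].id, subject_id=proteins[j].id,
                query_coverage=100.0 * qspan / len(seqs[i]),
                subject_coverage=100.0 * sspan / len(seqs[j]), **common))
            edges.append(SimilarityEdge(
                query_id=proteins[j].id, subject_id=proteins[i].id,
                query_coverage=100.0 * sspan / len(seqs[j]),
                subject_coverage=100.0 * qspan / len(seqs[i]), **common))
    return edges


def filter_edges(
    edges: Iterable[SimilarityEdge], thresholds: HitFilter = HitFilter()
) -> list[SimilarityEdge]:
    """Discard weak hits.

    An edge survives iff E-value <= 0.001, identity >= 30% and both
    query and subject coverage >= 75% (defaults; configurable).
    """
    t = thresholds
    return [
        e for e in edges
        if e.e_value <= t.max_evalue
        and e.pct_identity >= t.min_identity
        and e.query_coverage >= t.min_coverage
        and e.subject_coverage >= t.min_coverage
    ]


def best_hit_reduction(
    edges: Iterable[SimilarityEdge],
) -> dict[tuple[str, str], float]:
    """One weight per unordered protein pair: the best surviving bit score."""
    weights: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.query_id == e.subject_id:
            continue
        pair = (min(e.query_id, e.subject_id), max(e.query_id, e.subject_id))
        if e.bit_score > weights.get(pair, -math.inf):
            weights[pair] = e.bit_score
    return weights


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    weights: dict[tuple[str, str], float],
    inflation: float = 2.0,
    nodes: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[set[str]]:
    """Markov clustering of a weighted undirected similarity graph.

    The stochastic flow matrix alternates expansion (self-multiplication)
    and inflation (elementwise power and column renormalisation) until
    the change drops below ``tol``.  Self-loops are set to the maximum
    incident weight, which damps spurious splitting of tight cliques.
    Every node ends up in exactly one cluster; clusters always refine
    the connected components, so each component is clustered separately.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    node_list = sorted(nodes) if nodes is not None else sorted({n for e in weights for n in e})
    index = {n: i for i, n in enumerate(node_list)}
    n = len(node_list)
    if n == 0:
        return []
    A = np.zeros((n, n))
    for (a, b), w in weights.items():
        if a == b:
            continue
        if w < 0:
            raise ValueError("edge weights must be nonnegative")
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = max(A[i, j], w)
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(A, loop)

    ncomp, labels = connected_components(csr_matrix(A > 0), directed=False)
    clusters: list[set[str]] = []
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        if len(members) == 1:
            clusters.append({node_list[members[0]]})
            continue
        for part in _mcl_dense(A[np.ix_(members, members)], inflation, tol, max_iter):
            clusters.append({node_list[members[i]] for i in part})
    return sorted(clusters, key=lambda s: min(s))


def _mcl_dense(A: np.ndarray, inflation: float, tol: float, max_iter: int) -> list[set[int]]:
    M = A / A.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        M2 = M @ M
        np.power(M2, inflation, out=M2)
        M2[M2 < 1e-12] = 0.0
        colsum = M2.sum(axis=0)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        change = np.abs(M2 - M).max()
        M = M2
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within the iteration cap; "
                      "returning the current clustering", RuntimeWarning)
    attractors = np.flatnonzero(M.diagonal() > 1e-6)
    if attractors.size == 0:  # degenerate; treat the component as one cluster
        return [set(range(A.shape[0]))]
    clusters: list[set[int]] = []
    for i in attractors:
        support = set(np.flatnonzero(M[i] > 1e-6))
        support.add(int(i))
        clusters.append(support)
    clusters = _merge_overlapping(clusters)
    covered = set().union(*clusters)
    for j in range(A.shape[0]):
        if j in covered:
            continue
        best = attractors[int(np.argmax(M[attractors, j]))]
        for cl in clusters:
            if best in cl:
                cl.add(j)
                break
    return clusters


def _merge_overlapping(sets: list[set[int]]) -> list[set[int]]:
    merged: list[set[int]] = []
    for s in sets:
        hits = [m for m in merged if m & s]
        for m in hits:
            s |= m
            merged.remove(m)
        merged.append(s)
    return merged


# ---------------------------------------------------------------------------
# cluster alignment


def align_cluster(sequences: Sequence[str], engine: str = "auto") -> list[str]:
    """Multiple alignment of one protein cluster.

    Uses MAFFT when available; otherwise a star alignment around the
    longest member built from pairwise global alignments.  Singletons
    are returned as a one-row alignment.
    """
    if not sequences:
        raise ValueError("empty cluster")
    if len(sequences) == 1:
        return [sequences[0]]
    if engine == "auto":
        engine = "mafft" if shutil.which("mafft") else "native"
    if engine == "mafft":
        try:
            return _mafft_align(sequences)
        except (subprocess.CalledProcessError, OSError) as exc:
            logger.warning("MAFFT failed (%s); falling back to star alignment", exc)
            return _star_align(sequences)
    if engine == "native":
        return _star_align(sequences)
    raise ValueError(f"unknown alignment engine {engine!r}")


def _mafft_align(sequences: Sequence[str]) -> list[str]:
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.faa"
        with open(infile, "w") as fh:
            for i, s in enumerate(sequences):
                fh.write(f">s{i}\n{s}\n")
        res = subprocess.run(
            ["mafft", "--quiet", "--anysymbol", str(infile)],
            check=True, capture_output=True, text=True,
        )
    rows: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        elif name is not None:
            rows[name] += line.strip()
    return [rows[f"s{i}"].upper() for i in range(len(sequences))]


def _star_align(sequences: Sequence[str]) -> list[str]:
    """Star alignment: merge pairwise global alignments against a centre.

    The centre is the longest sequence (ties: first).  Insertions
    relative to the centre are reconciled by taking, between each pair
    of centre columns, the maximum insertion length over members.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"

    centre_idx = max(range(len(sequences)), key=lambda i: len(sequences[i]))
    centre = sequences[centre_idx]
    L = len(centre)
    pairs: list[tuple[str, str] | None] = []
    # inserts[slot] = residues inserted before centre position `slot` (0..L)
    max_ins = [0] * (L + 1)
    for i, seq in enumerate(sequences):
        if i == centre_idx:
            pairs.append(None)
            continue
        aln = aligner.align(centre, seq)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        pairs.append((c_row, s_row))
        slot = 0
        run = 0
        for c_ch in c_row:
            if c_ch == "-":
                run += 1
            else:
                max_ins[slot] = max(max_ins[slot], run)
                run = 0
                slot += 1
        max_ins[L] = max(max_ins[L], run)

    def expand(c_row: str, s_row: str) -> str:
        out: list[str] = []
        slot = 0
        run: list[str] = []
        for c_ch, s_ch in zip(c_row, s_row):
            if c_ch == "-":
                run.append(s_ch)
            else:
                out.append("-" * (max_ins[slot] - len(run)))
                out.extend(run)
                out.append(s_ch)
                run = []
                slot += 1
        out.append("-" * (max_ins[L] - len(run)))
        out.extend(run)
        return "".join(out)

    centre_expanded = expand(centre, centre)
    rows = []
    for i, pair in enumerate(pairs):
        if pair is None:
            rows.append(centre_expanded)
        else:
            rows.append(expand(*pair))
    return rows


# ---------------------------------------------------------------------------
# profile construction


def build_profile(
    alignment: Sequence[str],
    profile_id: str,
    annotation: str = "",
    member_ids: Sequence[str] = (),
) -> ProteinProfile:
    """Train a profile HMM from a cluster alignment (pyhmmer Builder)."""
    if not alignment:
        raise ValueError("empty alignment")
    if all(set(row) <= {"-", "."} for row in alignment):
        raise ValueError("all-gap alignment")
    builder = pyhmmer.plan7.Builder(_AMINO)
    background = pyhmmer.plan7.Background(_AMINO)
    name = profile_id.encode()
    if len(alignment) == 1:
        seq = pyhmmer.easel.TextSequence(
            name=name, sequence=alignment[0].replace("-", "")
        ).digitize(_AMINO)
        hmm, _, _ = builder.build(seq, background)
    else:
        texts = [
            pyhmmer.easel.TextSequence(name=f"m{i}".encode(), sequence=row)
            for i, row in enumerate(alignment)
        ]
        msa = pyhmmer.easel.TextMSA(name=name, sequences=texts)
        hmm, _, _ = builder.build_msa(msa.digitize(_AMINO), background)
    hmm.name = name
    return ProteinProfile(profile_id, hmm, annotation, member_ids)


# ---------------------------------------------------------------------------
# full chain


@dataclass(frozen=True)
class BuildConfig:
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN
    hit_filter: HitFilter = HitFilter()
    inflation: float = 2.0
    search_engine: str = "auto"
    align_engine: str = "auto"


def build_database(
    genomes: Sequence[GenomeRecord],
    config: BuildConfig = BuildConfig(),
    baltimore_group: str | None = None,
) -> ProfileDatabase:
    """Extract -> search -> filter -> best-hit -> MCL -> align -> profiles.

    All genomes must belong to one Baltimore group (VI and VII pool).
    Deterministic for a fixed input order.
    """
    groups = {baltimore_key(g.taxonomy.baltimore_group) for g in genomes}
    if baltimore_group is None:
        if len(groups) > 1:
            raise ValueError(f"genomes span multiple Baltimore groups: {sorted(groups)}")
        baltimore_group = next(iter(groups)) if groups else ""
    proteins: list[ProteinRecord] = []
    for g in genomes:
        proteins.extend(extract_proteins(g, min_len=config.min_protein_len))
    if not proteins:
        raise ValueError("no proteins survive the length filter")
    by_id = {p.id: p for p in proteins}
    edges = pairwise_protein_search(proteins, engine=config.search_engine)
    weights = best_hit_reduction(filter_edges(edges, config.hit_filter))
    member_sets = mcl_cluster(weights, inflation=config.inflation,
                              nodes=[p.id for p in proteins])
    profiles = []
    for k, members in enumerate(member_sets):
        ids = sorted(members)
        alignment = align_cluster([by_id[i].sequence for i in ids],
                                  engine=config.align_engine)
        annotation = "; ".join(
            dict.fromkeys(by_id[i].description for i in ids if by_id[i].description)
        )
        profiles.append(
            build_profile(alignment, f"PPHMM_{k:04d}", annotation, ids)
        )
    meta = {
        "n_genomes": len(genomes),
        "n_proteins": len(proteins),
        "hit_filter": vars(config.hit_filter),
        "inflation": config.inflation,
    }
    return ProfileDatabase(baltimore_group, profiles, meta)
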