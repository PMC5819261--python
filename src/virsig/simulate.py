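"""Synthetic family-structured virus genomes and signature tables.

The generator emulates the structure the classifier assumes: each
family owns a private repertoire of protein-coding genes in a conserved
order (optionally with some genes shared between designated family
pairs), members of a family carry independently mutated copies of the
ancestral proteins, and genomes are assembled by back-translating the
proteins with random synonymous codons, separated by random intergenic
spacers.  A stop cassette with stops in all six reading frames flanks
every gene so that ORF prediction recovers exactly the planted genes.
Genes may sit on the reverse strand (strand chosen per gene slot, so
the organisation is conserved within a family) and genomes may be
split into two segments.

A second, sequence-free generator emits signature tables directly
(block scores plus noise) for fast tests of the similarity, dendrogram
and classification layers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .annotation import SignatureTable, build_goms, gom_signature
from .genome_io import GenomeRecord, Taxonomy, reverse_complement

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")
# TTAA repeats are their own reverse complement and contain a stop codon
# in every forward and reverse frame: ORFs never run across a spacer.
_STOP_CASSETTE = "TTAA" * 3

# standard-code synonymous codons per amino acid
_CODONS: dict[str, list[str]] = {}
for _c in ("".join(x) for x in itertools.product("TCAG", repeat=3)):
    _a = str(Seq(_c).translate())
    if _a != "*":
        _CODONS.setdefault(_a, []).append(_c)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic reference set."""

    n_families: int = 12
    genomes_per_family: int = 8
    genes_per_genome: int = 6
    gene_length_range: tuple[int, int] = (120, 250)  # aa, >= extraction filter
    family_divergence: float = 0.15  # per-site aa substitution probability
    cross_family_shared_genes: int = 0
    segmented_fraction: float = 0.0
    reverse_strand_fraction: float = 0.25
    spacer_length_range: tuple[int, int] = (10, 30)  # nt on each side of the cassette
    baltimore_group: str = "I"
    seed: int = 0


@dataclass(frozen=True)
class FamilyModel:
    """Ancestral gene repertoire and organisation of one synthetic family.

    The ancestor of each gene is fixed at the nucleotide level (codon
    usage is inherited), so member genomes differ only through their
    amino-acid substitutions and their intergenic spacers.
    """

    name: str
    gene_ids: tuple[str, ...]
    ancestors: tuple[str, ...]     # ancestral aa sequences, order = gene order
    ancestors_nt: tuple[str, ...]  # ancestral codons incl. stop, same order
    strands: tuple[int, ...]       # +1 / -1 per gene slot


@dataclass
class ReferenceSet:
    genomes: list[GenomeRecord]
    truth: "object"  # pandas DataFrame: accession, family, gene_id, start, end, strand
    families: list[FamilyModel]
    config: SimulationConfig


def _random_gene(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(_AA), size=length - 1)
    return "M" + "".join(body)


def _back_translate(aa: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aa]
    return "".join(codons) + _STOPS[rng.integers(3)]


def _mutate_gene(
    ancestor_nt: str, rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Substitute amino acids at the given per-site rate.

    Unmutated positions keep the ancestral codon; mutated positions get
    a random synonymous codon of the new residue.  The initial
    methionine and the stop codon are preserved.  Returns (aa, nt).
    """
    codons = [ancestor_nt[i:i + 3] for i in range(0, len(ancestor_nt) - 3, 3)]
    stop = ancestor_nt[-3:]
    aa_out = [str(Seq(c).translate()) for c in codons]
    for i in range(1, len(codons)):  # position 0 stays M
        if rng.random() < rate:
            choices = [c for c in _AA if c != aa_out[i]]
            new_aa = choices[rng.integers(len(choices))]
            aa_out[i] = new_aa
            codons[i] = _CODONS[new_aa][rng.integers(len(_CODONS[new_aa]))]
    return "".join(aa_out), "".join(codons) + stop


def _spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    """Random intergenic DNA flanked by all-frame stop cassettes.

    The cassettes sit directly against the genes on both sides (the
    cassette is its own reverse complement), so an ORF in any frame and
    on either strand always starts at a planted gene's methionine.
    """
    n = int(rng.integers(lo, hi + 1))
    return _STOP_CASSETTE + "".join(rng.choice(list("ACGT"), size=n)) + _STOP_CASSETTE


def draw_families(config: SimulationConfig, rng: np.random.Generator,
                  n_families: int | None = None, prefix: str = "Fam") -> list[FamilyModel]:
    """Draw ancestral repertoires; optionally share leading genes between pairs."""
    lo, hi = config.gene_length_range
    families: list[FamilyModel] = []
    n = n_families if n_families is not None else config.n_families
    for f in range(n):
        genes = []
        genes_nt = []
        ids = []
        for g in range(config.genes_per_genome):
            shared = (
                config.cross_family_shared_genes > 0
                and f % 2 == 1
                and g < config.cross_family_shared_genes
            )
            if shared:  # copy from the preceding (paired) family
                genes.append(families[f - 1].ancestors[g])
                genes_nt.append(families[f - 1].ancestors_nt[g])
                ids.append(families[f - 1].gene_ids[g])
            else:
                aa = _random_gene(rng, int(rng.integers(lo, hi + 1)))
                genes.append(aa)
                genes_nt.append(_back_translate(aa, rng))
                ids.append(f"{prefix}{f:02d}_g{g}")
        strands = tuple(
            -1 if rng.random() < config.reverse_strand_fraction else 1
            for _ in range(config.genes_per_genome)
        )
        families.append(FamilyModel(f"{prefix}{f:02d}", tuple(ids), tuple(genes),
                                    tuple(genes_nt), strands))
    return families


def synthesize_genome(
    family: FamilyModel,
    accession: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenomeRecord, list[dict]]:
    """One genome of a family: mutated genes, spacers, optional segmentation."""
    lo, hi = config.spacer_length_range
    parts: list[str] = [_spacer(rng, lo, hi)]
    truth_rows: list[dict] = []
    boundaries: list[int] = []  # candidate split points (between genes)
    for gid, ancestor_nt, strand in zip(
        family.gene_ids, family.ancestors_nt, family.strands
    ):
        _, nt = _mutate_gene(ancestor_nt, config.family_divergence, rng)
        if strand < 0:
            nt = reverse_complement(nt)
        start = sum(len(p) for p in parts) + 1
        parts.append(nt)
        truth_rows.append({
            "accession": accession, "family": family.name, "gene_id": gid,
            "start": start, "end": start + len(nt) - 1, "strand": strand,
        })
        parts.append(_spacer(rng, lo, hi))
        boundaries.append(sum(len(p) for p in parts))
    sequence = "".join(parts)
    segments = [sequence]
    if config.segmented_fraction > 0 and rng.random() < config.segmented_fraction:
        cut = boundaries[len(boundaries) // 2 - 1] if len(boundaries) > 1 else boundaries[0]
        segments = [sequence[:cut], sequence[cut:]]
    record = GenomeRecord(
        accession=accession,
        segments=segments,
        taxonomy=Taxonomy(baltimore_group=config.baltimore_group, family=family.name,
                          species=accession),
    )
    return record, truth_rows


def simulate_reference_set(config: SimulationConfig = SimulationConfig()) -> ReferenceSet:
    """Family-structured reference genomes with a per-gene truth table."""
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    families = draw_families(config, rng)
    genomes: list[GenomeRecord] = []
    truth_rows: list[dict] = []
    for fam in families:
        for k in range(config.genomes_per_family):
            acc = f"{fam.name}_v{k:02d}"
            rec, rows = synthesize_genome(fam, acc, config, rng)
            genomes.append(rec)
            truth_rows.extend(rows)
    return ReferenceSet(genomes, pd.DataFrame(truth_rows), families, config)


def simulate_queries(
    ref_set: ReferenceSet,
    mode: str = "known",
    n_queries: int = 10,
    seed: int = 1,
    novel_prefix: str = "Novel",
) -> tuple[list[GenomeRecord], "object"]:
    """Query genomes: fresh draws from known families and/or novel families.

    "known" queries come from the reference families; "unknown" queries
    from freshly drawn families with disjoint repertoires; "mixed"
    alternates between the two.
    """
    import pandas as pd

    if mode not in {"known", "unknown", "mixed"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    config = ref_set.config
    n_unknown = {"known": 0, "unknown": n_queries, "mixed": n_queries // 2}[mode]
    novel = draw_families(
        config, rng, n_families=max(1, (n_unknown + 1) // 2), prefix=novel_prefix
    ) if n_unknown else []
    genomes: list[GenomeRecord] = []
    truth_rows: list[dict] = []
    for q in range(n_queries):
        unknown = q < n_unknown
        if unknown:
            fam = novel[q % len(novel)]
        else:
            fam = ref_set.families[int(rng.integers(len(ref_set.families)))]
        acc = f"Q{q:03d}_{fam.name}"
        rec, rows = synthesize_genome(fam, acc, config, rng)
        genomes.append(rec)
        truth_rows.extend(rows)
    return genomes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# sequence-free signature tables


@dataclass(frozen=True)
class TableConfig:
    """Conditions for directly simulated signature tables."""

    n_families: int = 4
    genomes_per_family: int = 4
    profiles_per_family: int = 6
    score_mean: float = 50.0
    score_noise_sd: float = 0.0
    location_spacing: float = 500.0
    location_jitter_sd: float = 0.0
    seed: int = 0


def simulate_signature_table(
    config: TableConfig = TableConfig(),
) -> tuple[SignatureTable, list]:
    """Block-structured signature table plus matching GOMs.

    Family f's genomes score ~``score_mean`` on its private block of
    profile columns and 0 elsewhere; gene locations follow a conserved
    order with optional jitter.  GOM signatures are computed with the
    real distance-correlation machinery, so the table behaves exactly
    like an annotated one.
    """
    rng = np.random.default_rng(config.seed)
    F, n, P = config.n_families, config.genomes_per_family, config.profiles_per_family
    total = F * n
    cols = F * P
    pphmm = np.zeros((total, cols))
    locations = np.zeros((total, cols))
    accessions, taxonomies = [], []
    for f in range(F):
        fam = f"Fam{f:02d}"
        for k in range(n):
            i = f * n + k
            accessions.append(f"{fam}_v{k:02d}")
            taxonomies.append(Taxonomy(baltimore_group="I", family=fam))
            for j in range(P):
                col = f * P + j
                score = config.score_mean + rng.normal(0, config.score_noise_sd) \
                    if config.score_noise_sd else config.score_mean
                pphmm[i, col] = max(score, 1e-3)
                loc = (j + 1) * config.location_spacing
                if config.location_jitter_sd:
                    loc += rng.normal(0, config.location_jitter_sd)
                locations[i, col] = max(loc, 1.0)
    goms = build_goms(accessions, taxonomies, locations)
    gsig = np.vstack([gom_signature(locations[i], goms) for i in range(total)])
    table = SignatureTable(
        accessions, taxonomies, pphmm, locations, gsig,
        [f"PPHMM_{c:04d}" for c in range(cols)], [g.label for g in goms],
    )
    return table, goms


# ---------------------------------------------------------------------------
# plumbing: write the generated inputs in pipeline formats


def write_reference_set(ref_set: ReferenceSet, directory) -> None:
    """FASTA + taxonomy TSV + truth TSV, the formats the pipeline reads."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "genomes.fasta", "w") as fh:
        for g in ref_set.genomes:
            if len(g.segments) == 1:
                fh.write(f">{g.accession}\n{g.segments[0]}\n")
            else:
                for si, seg in enumerate(g.segments, 1):
                    fh.write(f">{g.accession}.seg{si}\n{seg}\n")
    with open(directory / "taxonomy.tsv", "w") as fh:
        fh.write("accession\tbaltimore_group\torder\tfamily\tgenus\tspecies\n")
        for g in ref_set.genomes:
            t = g.taxonomy
            fh.write(f"{g.accession}\t{t.baltimore_group}\t{t.order}\t{t.family}"
                     f"\t{t.genus}\t{t.species}\n")
    ref_set.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
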