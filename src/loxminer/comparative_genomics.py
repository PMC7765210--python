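"""Pairwise identity/similarity matrices, exon-intron structure with intron
phases, and tandem/segmental duplication classification.

Alignment is optimal global Needleman-Wunsch with affine gaps (Biopython's
PairwiseAligner engine). Defaults mirror the EMBOSS tools commonly used for
this job: BLOSUM62 with gap open 12 / extend 2 for proteins, +5/-4 with gap
open 16 / extend 4 for nucleotides. A gap of length L costs
open + (L-1) * extend. Nucleotide ambiguity codes score as mismatches and
never count toward identity.

Duplication rules follow the standard plant gene-family convention: a tandem
array is 2-5 paralogs spanning at most 100 kb on one scaffold, and any
remaining pair above 90% similarity is called a segmental duplicate, with
tandem membership taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneModel, SequenceRecord

PROTEIN_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_STANDARD = set("ACGT")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global alignment."""

    matrix_name: str
    gap_open: float
    gap_extend: float
    alphabet: str

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @classmethod
    def protein_default(cls) -> "AlignmentParams":
        return cls("BLOSUM62", 12.0, 2.0, "protein")

    @classmethod
    def nucleotide_default(cls) -> "AlignmentParams":
        return cls("NUC+5/-4", 16.0, 4.0, "nucleotide")

    def substitution_matrix(self):
        if self.alphabet == "protein":
            return substitution_matrices.load(self.matrix_name.upper()
                                              if self.matrix_name.lower().startswith("blosum")
                                              else self.matrix_name)
        # simple match/mismatch over the full IUPAC nucleotide alphabet;
        # any pair involving an ambiguity code scores as a mismatch
        alphabet = "ACGTUNRYSWKMBDHV"
        mat = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                same = a == b and a in NUCLEOTIDE_STANDARD
                mat[a, b] = 5.0 if same else -4.0
        return mat


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.substitution_matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(a: SequenceRecord, b: SequenceRecord,
                 params: AlignmentParams | None = None
                 ) -> tuple[float, float, int]:
    """Optimal global alignment of two sequences.

    Returns (identity %, similarity %, alignment length). Identity counts
    columns with identical unambiguous residues; similarity counts columns
    whose substitution score is positive; both are percentages of the total
    alignment length (gap columns included in the denominator).
    """
    if a.alphabet != b.alphabet:
        raise ValueError(
            f"mixed alphabets: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}"
        )
    if params is None:
        params = (AlignmentParams.protein_default() if a.alphabet == "protein"
                  else AlignmentParams.nucleotide_default())
    aligner = _make_aligner(params)
    alignment = aligner.align(a.sequence, b.sequence)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix
    unambiguous = (PROTEIN_STANDARD if params.alphabet == "protein"
                   else NUCLEOTIDE_STANDARD)
    length = len(row_a)
    ident = simil = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if x == y and x in unambiguous:
            ident += 1
        if matrix[x, y] > 0:
            simil += 1
    return (100.0 * ident / length, 100.0 * simil / length, length)


def alignment_score(a: str, b: str, params: AlignmentParams) -> float:
    """Optimal global alignment score (used for oracle comparisons)."""
    aligner = _make_aligner(params)
    return float(aligner.score(a, b))


# ---------------------------------------------------------------------------
# Identity matrices
# ---------------------------------------------------------------------------

@dataclass
class IdentityMatrix:
    """Symmetric pairwise identity and similarity percentages."""

    ids: list[str]
    identity: pd.DataFrame
    similarity: pd.DataFrame
    lengths: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for df in (self.identity, self.similarity):
            vals = df.to_numpy(dtype=float)
            if not np.allclose(vals, vals.T):
                raise ValueError("matrix must be symmetric")
            if (vals < 0).any() or (vals > 100).any():
                raise ValueError("percentages must lie in [0, 100]")

    @classmethod
    def from_pairs(cls, ids: list[str],
                   identity_pairs: dict[tuple[str, str], float],
                   similarity_pairs: dict[tuple[str, str], float] | None = None,
                   fill: float = 0.0) -> "IdentityMatrix":
        """Build a matrix from sparse pair values (unlisted pairs -> *fill*)."""
        def build(pairs):
            df = pd.DataFrame(fill, index=ids, columns=ids, dtype=float)
            np.fill_diagonal(df.values, 100.0)
            for (a, b), v in pairs.items():
                df.loc[a, b] = df.loc[b, a] = v
            return df
        ident = build(identity_pairs)
        simil = build(similarity_pairs if similarity_pairs is not None
                      else identity_pairs)
        return cls(ids=list(ids), identity=ident, similarity=simil)


def identity_matrix(records: list[SequenceRecord],
                    params: AlignmentParams | None = None) -> IdentityMatrix:
    """All-against-all global alignment identity/similarity matrix."""
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    ids = [r.id for r in records]
    n = len(records)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    alen = np.zeros((n, n))
    for i in range(n):
        alen[i, i] = len(records[i])
        for j in range(i + 1, n):
            pid, psim, length = global_align(records[i], records[j], params)
            ident[i, j] = ident[j, i] = pid
            simil[i, j] = simil[j, i] = psim
            alen[i, j] = alen[j, i] = length
    return IdentityMatrix(
        ids=ids,
        identity=pd.DataFrame(ident, index=ids, columns=ids),
        similarity=pd.DataFrame(simil, index=ids, columns=ids),
        lengths=pd.DataFrame(alen, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# Gene structure / intron phases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneStructure:
    """CDS-projected exon lengths, intron lengths and intron phases."""

    gene_id: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    intron_phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if len(self.intron_phases) != len(self.intron_lengths):
            raise ValueError("one phase per intron")


def intron_phases(model: GeneModel) -> GeneStructure:
    """Exon/intron layout with intron phases recomputed from CDS lengths.

    The phase of intron i is the cumulative coding length of exons 1..i
    modulo 3, walking 5'->3' on the coding strand — i.e. how many
    nucleotides into a codon the intron interrupts. Stored GFF3 phase
    columns are ignored; CDS arithmetic is authoritative.
    """
    if not model.exons:
        raise ValueError(f"gene {model.gene_id}: no exons")
    cds = model.cds_parts or model.exons
    if model.cds_length % 3 != 0:
        raise ValueError(
            f"gene {model.gene_id}: CDS length {model.cds_length} not a multiple of 3"
        )
    # project CDS onto each exon (coding order)
    exon_cds_lengths = []
    for es, ee in model.exons:
        contrib = sum(
            max(0, min(ee, ce) - max(es, cs) + 1) for cs, ce in cds
        )
        exon_cds_lengths.append(contrib)
    phases = []
    cumulative = 0
    for contrib in exon_cds_lengths[:-1]:
        cumulative += contrib
        phases.append(cumulative % 3)
    return GeneStructure(
        gene_id=model.gene_id,
        exon_lengths=tuple(exon_cds_lengths),
        intron_lengths=tuple(model.intron_lengths),
        intron_phases=tuple(phases),
    )


# ---------------------------------------------------------------------------
# Duplication classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationCall:
    """A tandem array or segmental duplicate pair."""

    kind: str                     # {"tandem", "segmental"}
    members: tuple[str, ...]
    scaffold: str
    span: int                     # bp from first start to last end (tandem)
    supporting_identity: float    # % (min pairwise identity / similarity)


def detect_duplications(members: list[GeneModel],
                        identities: IdentityMatrix,
                        tandem_min_identity: float = 70.0,
                        window: int = 100_000,
                        max_genes: int = 5,
                        segmental_min_similarity: float = 90.0
                        ) -> list[DuplicationCall]:
    """Classify tandem arrays and segmental duplicates among family members.

    Per scaffold, genes sorted by start are greedily clustered: a gene joins
    the open cluster while the total span stays within *window*, the cluster
    holds at most *max_genes*, and the gene shares at least
    *tandem_min_identity* % identity with some cluster member. Clusters of
    two or more genes are tandem arrays. Remaining pairs above
    *segmental_min_similarity* % similarity are segmental duplicates; a pair
    already inside one tandem array is never double-reported.
    """
    for m in members:
        if m.gene_id not in identities.identity.index:
            raise ValueError(f"gene {m.gene_id} missing from identity matrix")

    calls: list[DuplicationCall] = []
    tandem_pairs: set[frozenset] = set()
    by_scaffold: dict[str, list[GeneModel]] = {}
    for m in members:
        by_scaffold.setdefault(m.scaffold, []).append(m)

    for scaffold, genes in sorted(by_scaffold.items()):
        genes = sorted(genes, key=lambda g: g.start)
        cluster: list[GeneModel] = []
        def close_cluster():
            if len(cluster) >= 2:
                ids = [g.gene_id for g in cluster]
                span = cluster[-1].end - cluster[0].start + 1
                min_ident = min(
                    identities.identity.loc[a, b]
                    for i, a in enumerate(ids) for b in ids[i + 1:]
                )
                calls.append(DuplicationCall(
                    kind="tandem", members=tuple(ids), scaffold=scaffold,
                    span=span, supporting_identity=float(min_ident)))
                for i, a in enumerate(ids):
                    for b in ids[i + 1:]:
                        tandem_pairs.add(frozenset((a, b)))
        for gene in genes:
            if not cluster:
                cluster = [gene]
                continue
            span = gene.end - cluster[0].start + 1
            linked = any(
                identities.identity.loc[gene.gene_id, g.gene_id]
                >= tandem_min_identity for g in cluster
            )
            if span <= window and len(cluster) < max_genes and linked:
                cluster.append(gene)
            else:
                close_cluster()
                cluster = [gene]
        close_cluster()

    ids = [m.gene_id for m in members]
    scaffold_of = {m.gene_id: m.scaffold for m in members}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if frozenset((a, b)) in tandem_pairs:
                continue
            sim = float(identities.similarity.loc[a, b])
            if sim > segmental_min_similarity:
                scaf = (scaffold_of[a] if scaffold_of[a] == scaffold_of[b]
                        else f"{scaffold_of[a]};{scaffold_of[b]}")
                calls.append(DuplicationCall(
                    kind="segmental", members=(a, b), scaffold=scaf,
                    span=0, supporting_identity=sim))
    return calls
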