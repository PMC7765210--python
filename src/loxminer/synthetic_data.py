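"""Deterministic synthetic genome bundles and qPCR tables with planted,
manifest-recorded ground truth.

The generator emulates the study design this pipeline targets: a small
annotated genome holding a known LOX family (every true member carries a
PLAT-like block, a complete LOX-like block, and a correctly spaced
5-histidine signature inside it), decoy candidates that each violate exactly
one leg of the bona-fide rule, tandem clusters of near-identical paralogs
within a bounded genomic window, two subfamily sequence archetypes for
distance-based classification, and replicated Ct measurements with planted
treatment effects under Gaussian noise.

Sequence backgrounds are i.i.d. uniform residues/nucleotides outside the
planted features — the simplest null that keeps false motif hits rare and
quantifiable. All randomness flows from one seed; the same configuration
always yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .family_identification import (
    AA_ORDER, FIVE_HIS_OFFSETS, LOX_FIVE_HIS_OFFSET, packaged_motifs,
    scan_five_his,
)
from .io_formats import (
    GeneModel, SequenceRecord, reverse_complement, write_fasta, write_gff3,
    write_tsv,
)

DECOY_MODES = ("missing-LOX-domain", "truncated-LOX", "missing-5His")

# fixed codon per amino acid (synthetic genomes make no claim to codon usage)
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
STOP_CODON = "TAA"


class PlacementError(RuntimeError):
    """Gene placement cannot satisfy the configured constraints."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the duckweed LOX study design: a nine-member family with
    two 9-LOX and seven 13-LOX genes (six of the seven plastid-targeted,
    type II), six decoy candidates lacking a complete LOX domain, one
    two-gene and one three-gene tandem cluster, and a qPCR design of
    control/treated conditions sampled at 0, 1, 3, 6 and 12 h in
    triplicate against two reference genes.
    """

    seed: int = 0
    n_scaffolds: int = 8
    scaffold_length: int = 120_000
    n_true_family: int = 9
    n_decoys: int = 6
    decoy_modes: tuple = ("missing-LOX-domain",)
    tandem_clusters: tuple = ((2, 40_000), (3, 40_000))
    subfamily_split: dict = field(
        default_factory=lambda: {"9-LOX": 2, "13-LOX": 7})
    type2_fraction: float = 6.0 / 7.0
    exon_count_range: tuple = (4, 9)
    intron_length_range: tuple = (80, 500)
    mutation_rate: float = 0.10        # per-site archetype/member divergence
    cluster_divergence: float = 0.10   # expected pairwise divergence in a cluster
    # qPCR design
    conditions: tuple = ("control", "treated")
    timepoints: tuple = (0, 1, 3, 6, 12)
    replicates: int = 3
    reference_genes: tuple = ("SpACT", "Sp18S")
    reference_gene_ct: float = 20.0
    baseline_ct: float = 25.0
    ct_noise_sd: float = 0.2
    planted_fold_changes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for size, max_span in self.tandem_clusters:
            if not 2 <= size <= 5:
                raise ValueError(f"tandem cluster size {size} outside [2, 5]")
            if max_span <= 0:
                raise ValueError("tandem max_span must be positive")
        if sum(self.subfamily_split.values()) != self.n_true_family:
            raise ValueError("subfamily_split must sum to n_true_family")
        if sum(s for s, _ in self.tandem_clusters) > self.n_true_family:
            raise ValueError("tandem clusters need more genes than n_true_family")
        for mode in self.decoy_modes:
            if mode not in DECOY_MODES:
                raise ValueError(f"unknown decoy mode {mode!r}")
        if not 0.0 <= self.type2_fraction <= 1.0:
            raise ValueError("type2_fraction must be in [0, 1]")
        for gene, cells in self.planted_fold_changes.items():
            for key, fold in cells.items():
                if fold <= 0:
                    raise ValueError(
                        f"planted fold for {gene}/{key} must be positive")


@dataclass
class GenomeBundle:
    """A generated genome plus its ground-truth manifest."""

    genome: list      # scaffold SequenceRecords
    genes: list       # GeneModels
    proteins: list    # protein SequenceRecords
    cds: list         # CDS SequenceRecords (stop codon included)
    manifest: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length))


def subfamily_archetypes() -> dict[str, str]:
    """Two fixed 60-aa discriminative blocks with zero mutual identity.

    The 13-LOX block is a derangement of the 9-LOX block (every position
    differs), making distance-based classification unambiguous.
    """
    rng = np.random.default_rng(24681357)
    arch9 = _random_protein(rng, 60)
    arch13 = "".join(
        AA_ORDER[(AA_ORDER.index(aa) + 1 + int(rng.integers(0, 19))) % 20]
        for aa in arch9
    )
    return {"9-LOX": arch9, "13-LOX": arch13}


def _transit_peptide(rng: np.random.Generator) -> str:
    """Ser/Thr-rich, acid-free, net-positive N-terminal extension.

    Exact residue counts (59 aa: 16 S, 9 T, 9 A, 6 L, 6 V, 5 P, 4 R, 4 K)
    are shuffled, so together with the initial Met the extension fills the
    transit-peptide predictor's N-terminal window and satisfies its
    composition rules by construction, as real plastid-targeting peptides
    satisfy the predictors trained on them.
    """
    residues = list("S" * 16 + "T" * 9 + "A" * 9 + "L" * 6 + "V" * 6
                    + "P" * 5 + "R" * 4 + "K" * 4)
    return "".join(rng.permutation(residues))


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: set[int] | None = None) -> str:
    """Substitute residues i.i.d. at *rate*, never touching protected sites
    (planted histidines, transit peptides, the initial Met)."""
    protected = protected or set()
    out = list(seq)
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = AA_ORDER.replace(out[i], "")
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


@dataclass
class _ProteinDesign:
    sequence: str
    protected: set          # 0-based indices excluded from mutation
    lox_start: int          # 0-based start of the LOX block, -1 if absent


def _design_protein(rng: np.random.Generator, role: str, subfamily: str,
                    lox13_type: str, decoy_mode: str | None,
                    archetypes: dict, motifs: dict) -> _ProteinDesign:
    plat = motifs["PLAT"].consensus
    lox = motifs["LOX"].consensus
    parts: list[str] = ["M"]
    protected: set[int] = {0}
    pos = 1

    def add(segment: str, protect: bool = False):
        nonlocal pos
        parts.append(segment)
        if protect:
            protected.update(range(pos, pos + len(segment)))
        pos += len(segment)

    if role == "true" and lox13_type == "II":
        add(_transit_peptide(rng), protect=True)
    add(_random_protein(rng, 20))
    add(plat)
    add(_random_protein(rng, 30))
    if role == "true":
        add(archetypes[subfamily])
    add(_random_protein(rng, 10))
    lox_start = -1
    if role == "true":
        lox_start = pos
        add(lox)
        # keep the planted 5-His signature intact under mutation
        protected.update(lox_start + LOX_FIVE_HIS_OFFSET + off
                         for off in FIVE_HIS_OFFSETS)
    elif decoy_mode == "truncated-LOX":
        add(lox[:240])
        add(_random_protein(rng, 240))
    elif decoy_mode == "missing-5His":
        broken = list(lox)
        for off in FIVE_HIS_OFFSETS:
            broken[LOX_FIVE_HIS_OFFSET + off] = "L"
        add("".join(broken))
    else:  # missing-LOX-domain
        add(_random_protein(rng, 480))
    add(_random_protein(rng, 20))
    return _ProteinDesign("".join(parts), protected, lox_start)


def _strip_stray_signatures(seq: str, rng: np.random.Generator,
                            keep_interval: tuple[int, int] | None) -> str:
    """Disrupt accidental 5-His windows outside the planted signature so
    decoy modes violate exactly their contract."""
    out = list(seq)
    while True:
        hits = scan_five_his(SequenceRecord("tmp", "".join(out), "protein"))
        stray = [
            h for h in hits
            if keep_interval is None
            or not (keep_interval[0] <= h.aa_start and h.aa_end <= keep_interval[1])
        ]
        if not stray:
            return "".join(out)
        first = stray[0]
        out[first.his_positions[0] - 1] = "A"


# ---------------------------------------------------------------------------
# Gene model construction
# ---------------------------------------------------------------------------

def _reverse_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein) + STOP_CODON


def _split_exons(rng: np.random.Generator, cds_len: int,
                 exon_range: tuple[int, int], min_exon: int = 30) -> list[int]:
    lo, hi = exon_range
    n = int(rng.integers(lo, hi + 1))
    n = max(1, min(n, cds_len // min_exon))
    spare = cds_len - n * min_exon
    if n == 1:
        return [cds_len]
    weights = rng.dirichlet(np.ones(n))
    extras = np.floor(weights * spare).astype(int)
    extras[0] += spare - int(extras.sum())
    return [min_exon + int(e) for e in extras]


@dataclass
class _GeneDraft:
    gene_id: str
    role: str
    decoy_mode: str | None
    subfamily: str
    lox13_type: str
    transit_peptide: bool
    cluster_id: str | None
    protein: str
    cds: str
    exon_lengths: list
    intron_lengths: list
    strand: str

    @property
    def genomic_span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def genomic_sequence(self) -> str:
        """Sense-strand (coding orientation) genomic sequence."""
        chunks = []
        offset = 0
        for i, elen in enumerate(self.exon_lengths):
            chunks.append(self.cds[offset:offset + elen])
            offset += elen
            if i < len(self.intron_lengths):
                chunks.append(self._introns[i])
        return "".join(chunks)


def _draft_gene(rng, gene_id, role, decoy_mode, subfamily, lox13_type,
                cluster_id, protein, config) -> _GeneDraft:
    cds = _reverse_translate(protein)
    exon_lengths = _split_exons(rng, len(cds), config.exon_count_range)
    lo, hi = config.intron_length_range
    intron_lengths = [int(rng.integers(lo, hi + 1))
                      for _ in range(len(exon_lengths) - 1)]
    strand = "+" if rng.random() < 0.5 else "-"
    draft = _GeneDraft(
        gene_id=gene_id, role=role, decoy_mode=decoy_mode,
        subfamily=subfamily, lox13_type=lox13_type,
        transit_peptide=(lox13_type == "II"), cluster_id=cluster_id,
        protein=protein, cds=cds, exon_lengths=exon_lengths,
        intron_lengths=intron_lengths, strand=strand,
    )
    nts = "ACGT"
    draft._introns = [
        "".join(nts[i] for i in rng.integers(0, 4, size=n))
        for n in intron_lengths
    ]
    return draft


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def _allocate_labels(config: SimulationConfig):
    """Assign subfamily/type labels and cluster membership to true genes.

    Clusters are homogeneous in subfamily (a tandem array is a set of recent
    paralogs); type I is assigned preferentially to singleton 13-LOX genes.
    """
    remaining = dict(config.subfamily_split)
    units: list[dict] = []  # {"size": s, "max_span": sp or None, "label": l}
    for size, max_span in sorted(config.tandem_clusters, key=lambda c: -c[0]):
        fitting = [l for l, n in remaining.items() if n >= size]
        if not fitting:
            raise PlacementError(
                f"no subfamily has {size} unassigned members for a tandem cluster"
            )
        label = min(fitting, key=lambda l: (remaining[l], l))
        remaining[label] -= size
        units.append({"size": size, "max_span": max_span, "label": label})
    for label in sorted(remaining):
        for _ in range(remaining[label]):
            units.append({"size": 1, "max_span": None, "label": label})

    n13 = config.subfamily_split.get("13-LOX", 0)
    n_type2 = int(round(config.type2_fraction * n13))
    n_type1 = n13 - n_type2
    # spend type-I quota on singletons first, then whole clusters
    for unit in sorted((u for u in units if u["label"] == "13-LOX"),
                       key=lambda u: u["size"]):
        if n_type1 >= unit["size"]:
            unit["type"] = "I"
            n_type1 -= unit["size"]
        else:
            unit["type"] = "II"
    for unit in units:
        unit.setdefault("type", "n/a")
    return units


def generate_genome_bundle(config: SimulationConfig) -> GenomeBundle:
    """Generate a genome FASTA + GFF3 + protein/CDS FASTA + manifest.

    True members carry the PLAT-like and LOX-like planted blocks and a
    correctly spaced 5-His signature inside the LOX block; each decoy
    violates exactly its decoy mode; tandem clusters sit on one scaffold
    within their maximum span; every CDS is a multiple of 3 ending in a stop
    codon; GFF3 coordinates are 1-based inclusive and consistent with the
    FASTA. Same config and seed give byte-identical output files.
    """
    rng = np.random.default_rng(config.seed)
    archetypes = subfamily_archetypes()
    motifs = packaged_motifs()
    units = _allocate_labels(config)

    drafts: list[_GeneDraft] = []
    placement_units: list[tuple[list[_GeneDraft], int | None]] = []
    gene_no = 0
    for uidx, unit in enumerate(units):
        group: list[_GeneDraft] = []
        design = _design_protein(rng, "true", unit["label"], unit["type"],
                                 None, archetypes, motifs)
        # tandem copies diverge independently from the shared ancestral
        # design, giving ~cluster_divergence pairwise divergence while each
        # copy stays close to the planted domain consensus
        rate = (config.cluster_divergence / 2.0 if unit["size"] > 1
                else config.mutation_rate)
        for m in range(unit["size"]):
            gene_no += 1
            gid = f"SpLOX{gene_no}"
            protein = _mutate(design.sequence, rate, rng, design.protected)
            cluster_id = f"cluster{uidx + 1}" if unit["size"] > 1 else None
            group.append(_draft_gene(rng, gid, "true", None, unit["label"],
                                     unit["type"], cluster_id, protein, config))
        drafts.extend(group)
        placement_units.append((group, unit["max_span"]))

    modes = config.decoy_modes
    for d in range(config.n_decoys):
        mode = modes[d % len(modes)]
        design = _design_protein(rng, "decoy", "unassigned", "n/a", mode,
                                 archetypes, motifs)
        protein = _mutate(design.sequence, config.mutation_rate, rng,
                          design.protected)
        keep = None
        if mode == "truncated-LOX":
            # the truncated block may retain the signature — that is fine,
            # its violation is the incomplete domain, not the signature
            hits = scan_five_his(SequenceRecord("tmp", protein, "protein"))
            if hits:
                keep = (hits[0].aa_start, hits[0].aa_end)
        protein = _strip_stray_signatures(protein, rng, keep)
        draft = _draft_gene(rng, f"DECOY{d + 1}", "decoy", mode, "unassigned",
                            "n/a", None, protein, config)
        drafts.append(draft)
        placement_units.append(([draft], None))

    # sanity: planted signatures survive in true members
    for draft in drafts:
        if draft.role == "true":
            hits = scan_five_his(SequenceRecord(draft.gene_id, draft.protein,
                                                "protein"))
            if not hits:
                raise RuntimeError("planted 5-His signature lost — generator bug")

    # --- placement ---------------------------------------------------------
    intergenic = 2_000
    scaffold_parts: list[list[str]] = [[] for _ in range(config.n_scaffolds)]
    cursors = [0] * config.n_scaffolds
    models: list[GeneModel] = []
    nts = "ACGT"

    def pad(scaffold_idx: int, n: int):
        scaffold_parts[scaffold_idx].append(
            "".join(nts[i] for i in rng.integers(0, 4, size=n)))
        cursors[scaffold_idx] += n

    scaffold_idx = 0
    for group, max_span in placement_units:
        spans = [g.genomic_span for g in group]
        if len(group) > 1:
            gap_budget = max_span - sum(spans)
            if gap_budget < (len(group) - 1):
                raise PlacementError(
                    f"cluster of {len(group)} genes (total {sum(spans)} bp) "
                    f"cannot fit inside max_span {max_span} bp"
                )
            gap = min(intergenic, gap_budget // (len(group) - 1))
        else:
            gap = intergenic

        total_needed = sum(spans) + gap * (len(group) - 1) + 2 * intergenic
        placed = False
        for _ in range(config.n_scaffolds):
            if cursors[scaffold_idx] + total_needed <= config.scaffold_length:
                placed = True
                break
            scaffold_idx = (scaffold_idx + 1) % config.n_scaffolds
        if not placed:
            raise PlacementError(
                f"scaffold_length {config.scaffold_length} x {config.n_scaffolds} "
                f"scaffolds cannot hold all genes without overlap"
            )
        pad(scaffold_idx, intergenic)
        for k, draft in enumerate(group):
            offset = cursors[scaffold_idx]  # 0-based start of gene
            sense = draft.genomic_sequence()
            segment = (sense if draft.strand == "+"
                       else reverse_complement(sense))
            scaffold_parts[scaffold_idx].append(segment)
            cursors[scaffold_idx] += len(segment)
            total = len(sense)
            exons = []
            pos = 0
            for i, elen in enumerate(draft.exon_lengths):
                s_sense, e_sense = pos + 1, pos + elen
                if draft.strand == "+":
                    exons.append((offset + s_sense, offset + e_sense))
                else:
                    exons.append((offset + total - e_sense + 1,
                                  offset + total - s_sense + 1))
                pos += elen
                if i < len(draft.intron_lengths):
                    pos += draft.intron_lengths[i]
            models.append(GeneModel(
                gene_id=draft.gene_id,
                scaffold=f"scaffold_{scaffold_idx + 1}",
                start=offset + 1, end=offset + total, strand=draft.strand,
                exons=exons, cds_parts=exons,
                attributes={"ID": draft.gene_id, "role": draft.role},
            ))
            if k < len(group) - 1:
                pad(scaffold_idx, gap)
        pad(scaffold_idx, intergenic)
        scaffold_idx = (scaffold_idx + 1) % config.n_scaffolds

    for idx in range(config.n_scaffolds):
        if cursors[idx] < config.scaffold_length:
            pad(idx, config.scaffold_length - cursors[idx])

    genome = [
        SequenceRecord(f"scaffold_{i + 1}", "".join(parts), "nucleotide")
        for i, parts in enumerate(scaffold_parts)
    ]
    proteins = [SequenceRecord(d.gene_id, d.protein, "protein") for d in drafts]
    cds = [SequenceRecord(d.gene_id, d.cds, "nucleotide") for d in drafts]

    model_by_id = {m.gene_id: m for m in models}
    rows = []
    for d in drafts:
        m = model_by_id[d.gene_id]
        rows.append({
            "gene_id": d.gene_id, "role": d.role,
            "decoy_mode": d.decoy_mode or "n/a",
            "subfamily": d.subfamily, "lox13_type": d.lox13_type,
            "transit_peptide": d.transit_peptide,
            "cluster_id": d.cluster_id or "n/a",
            "scaffold": m.scaffold, "start": m.start, "end": m.end,
            "strand": m.strand, "n_exons": len(m.exons),
            "cds_length": m.cds_length, "orf_length": len(d.cds),
            "protein_length": len(d.protein), "seed": config.seed,
        })
    manifest = pd.DataFrame(rows)
    return GenomeBundle(genome=genome, genes=models, proteins=proteins,
                        cds=cds, manifest=manifest, config=config)


def write_bundle(bundle: GenomeBundle, outdir) -> dict[str, Path]:
    """Write genome.fasta, genes.gff3, proteins.fasta, cds.fasta and
    manifest.tsv under *outdir*; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "proteins": outdir / "proteins.fasta",
        "cds": outdir / "cds.fasta",
        "manifest": outdir / "manifest.tsv",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gff3(bundle.genes, paths["gff3"])
    write_fasta(bundle.proteins, paths["proteins"])
    write_fasta(bundle.cds, paths["cds"])
    write_tsv(bundle.manifest, paths["manifest"])
    return paths


def reference_panel() -> list[SequenceRecord]:
    """Labelled subfamily reference proteins for nearest-reference
    classification; identical except for their archetype block."""
    rng = np.random.default_rng(1122334455)
    motifs = packaged_motifs()
    archetypes = subfamily_archetypes()
    bg1 = _random_protein(rng, 20)
    bg2 = _random_protein(rng, 30)
    bg3 = _random_protein(rng, 10)
    bg4 = _random_protein(rng, 20)
    refs = []
    for label in ("9-LOX", "13-LOX"):
        seq = ("M" + bg1 + motifs["PLAT"].consensus + bg2
               + archetypes[label] + bg3 + motifs["LOX"].consensus + bg4)
        refs.append(SequenceRecord(f"REF{label.split('-')[0]}|{label}",
                                   seq, "protein"))
    return refs


# ---------------------------------------------------------------------------
# qPCR table generation
# ---------------------------------------------------------------------------

def generate_ct_table(config: SimulationConfig,
                      target_genes: list[str] | None = None) -> pd.DataFrame:
    """Long-format Ct table with planted treatment effects.

    Each target gene gets a per-gene baseline Ct; a planted fold change f at
    (condition, timepoint) shifts the Ct by -log2(f); Gaussian noise of sd
    ``ct_noise_sd`` is added per measurement. Reference genes sit at
    ``reference_gene_ct`` and never respond to treatment.
    """
    if config.replicates < 2:
        raise ValueError("need at least 2 replicates per cell")
    if not config.reference_genes:
        raise ValueError("need at least one reference gene")
    for gene, cells in config.planted_fold_changes.items():
        for key, fold in cells.items():
            if fold <= 0:
                raise ValueError(f"planted fold for {gene}/{key} must be > 0")
    rng = np.random.default_rng([config.seed, 7_777])
    if target_genes is None:
        target_genes = [f"SpLOX{i + 1}" for i in range(config.n_true_family)]
    baselines = {
        g: config.baseline_ct + float(rng.uniform(-2.0, 2.0))
        for g in target_genes
    }
    ref_offsets = {
        g: float(rng.uniform(-1.0, 1.0)) for g in config.reference_genes
    }
    rows = []
    for cond in config.conditions:
        for tp in config.timepoints:
            for rep in range(1, config.replicates + 1):
                sample = f"{cond}_t{tp}_r{rep}"
                for gene in target_genes:
                    fold = (config.planted_fold_changes
                            .get(gene, {}).get((cond, tp), 1.0))
                    noise = (float(rng.standard_normal()) * config.ct_noise_sd
                             if config.ct_noise_sd > 0 else 0.0)
                    rows.append((sample, gene, cond, tp, rep,
                                 baselines[gene] - np.log2(fold) + noise))
                for gene in config.reference_genes:
                    noise = (float(rng.standard_normal()) * config.ct_noise_sd
                             if config.ct_noise_sd > 0 else 0.0)
                    rows.append((sample, gene, cond, tp, rep,
                                 config.reference_gene_ct
                                 + ref_offsets[gene] + noise))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "condition",
                                       "timepoint", "replicate", "ct"])
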