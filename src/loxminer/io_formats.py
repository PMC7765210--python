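"""Readers and writers for the formats the pipeline touches.

Coordinate convention: 1-based inclusive everywhere, matching the way plant
genome browsers and annotation tables print gene loci (a gene spanning
5245164..5249140 has genomic length 5249140 - 5245164 + 1 = 3977 bp).
Half-open intervals are never exposed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_CHARS = set("ACGTUNRYSWKMBDHV-")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
DOMAIN_NAMES = ("PLAT", "LOX", "5HIS")


class FormatError(ValueError):
    """Malformed input file or record."""


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an explicit alphabet.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    sequence : str
        Residue string, upper case. Nucleotide ambiguity codes are allowed.
    alphabet : {"nucleotide", "protein"}
    """

    id: str
    sequence: str
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record must have a non-empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} is empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.alphabet not in ("nucleotide", "protein"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        allowed = NUCLEOTIDE_CHARS if self.alphabet == "nucleotide" else PROTEIN_CHARS
        bad = set(self.sequence) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def guess_alphabet(sequence: str) -> str:
    """Call a sequence nucleotide if every character is a nucleotide code."""
    return "nucleotide" if set(sequence.upper()) <= NUCLEOTIDE_CHARS else "protein"


def read_fasta(path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Duplicate ids and empty sequences are errors. If *alphabet* is None it is
    guessed per record (all-ACGTN... -> nucleotide).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        alpha = alphabet or guess_alphabet(seq)
        records.append(SequenceRecord(rec.id, seq, alpha))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA wrapped at *width* columns."""
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene models and GFF3
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene locus with its exon/CDS layout.

    Coordinates are 1-based inclusive genomic positions. ``exons`` and
    ``cds_parts`` are ordered 5'->3' on the coding strand, i.e. by ascending
    start on '+' genes and descending start on '-' genes.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds_parts: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = _order_intervals(self.exons, self.strand, self.gene_id)
        if self.cds_parts:
            self.cds_parts = _order_intervals(self.cds_parts, self.strand, self.gene_id)

    @property
    def genomic_length(self) -> int:
        return self.end - self.start + 1

    @property
    def cds_length(self) -> int:
        parts = self.cds_parts or self.exons
        return sum(e - s + 1 for s, e in parts)

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def intron_lengths(self) -> list[int]:
        spans = sorted(self.exons)
        gaps = [spans[i + 1][0] - spans[i][1] - 1 for i in range(len(spans) - 1)]
        return gaps[::-1] if self.strand == "-" else gaps

    def reversed(self) -> "GeneModel":
        """The same locus viewed on the opposite strand."""
        flipped = "-" if self.strand == "+" else "+"
        return replace(
            self,
            strand=flipped,
            exons=list(self.exons),
            cds_parts=list(self.cds_parts),
            warnings=list(self.warnings),
        )


def _order_intervals(intervals, strand, gene_id):
    ivs = [(int(s), int(e)) for s, e in intervals]
    for s, e in ivs:
        if s > e:
            raise FormatError(f"gene {gene_id}: interval {s}..{e} inverted")
    ivs.sort()
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise FormatError(
                f"gene {gene_id}: overlapping intervals {s1}..{e1} and {s2}..{e2}"
            )
    return ivs[::-1] if strand == "-" else ivs


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, val = part.split("=", 1)
            attrs[key] = val
    return attrs


def read_gff3(path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    The stored GFF3 phase column is read but ignored downstream: intron phases
    are recomputed from CDS lengths, which are authoritative. A CDS total that
    is not a multiple of 3 yields a warning on the model, not an error; a
    Parent attribute pointing at an unknown feature is an error.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    deferred: list[tuple[str, str, int, int]] = []  # (type, parent, start, end)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_text = cols
            attrs = _parse_gff_attributes(attr_text)
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "scaffold": seqid, "start": start, "end": end,
                    "strand": strand, "exons": [], "cds": [], "attrs": attrs,
                }
            elif ftype == "mRNA":
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: mRNA Parent {parent!r} is not a known gene"
                    )
                mid = attrs.get("ID", f"{parent}.t1")
                # first transcript wins; extra isoforms are ignored
                mrna_to_gene.setdefault(mid, parent)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: {ftype} without Parent")
                deferred.append((ftype, parent, start, end))

    for ftype, parent, start, end in deferred:
        gid = mrna_to_gene.get(parent, parent if parent in genes else None)
        if gid is None:
            raise FormatError(f"{ftype} Parent {parent!r} matches no gene or mRNA")
        genes[gid]["exons" if ftype == "exon" else "cds"].append((start, end))

    models = []
    for gid, g in genes.items():
        model = GeneModel(
            gene_id=gid, scaffold=g["scaffold"], start=g["start"], end=g["end"],
            strand=g["strand"], exons=g["exons"] or g["cds"],
            cds_parts=g["cds"], attributes=g["attrs"],
        )
        if model.cds_length % 3 != 0:
            model.warnings.append(
                f"CDS length {model.cds_length} not a multiple of 3"
            )
        models.append(model)
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene/mRNA/exon/CDS rows, 1-based inclusive, phases populated."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.scaffold}\tloxminer\t"
            fh.write(base + f"gene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            mid = f"{m.gene_id}.t1"
            fh.write(base + f"mRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={mid};Parent={m.gene_id}\n")
            for s, e in m.exons:
                fh.write(base + f"exon\t{s}\t{e}\t.\t{m.strand}\t.\tParent={mid}\n")
            done = 0
            for s, e in (m.cds_parts or m.exons):
                phase = (3 - done % 3) % 3
                fh.write(base + f"CDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\tParent={mid}\n")
                done += e - s + 1


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_cds(scaffold_seq: str, model: GeneModel) -> str:
    """Splice a gene's CDS out of its scaffold sequence (coding orientation)."""
    parts = model.cds_parts or model.exons
    spans = sorted(parts)
    spliced = "".join(scaffold_seq[s - 1:e] for s, e in spans)
    return reverse_complement(spliced) if model.strand == "-" else spliced


# ---------------------------------------------------------------------------
# Tabular inputs: domain tables, Ct tables, gene summary tables
# ---------------------------------------------------------------------------

_LOCUS_RE = re.compile(r"^\s*(\d+)\s*:\s*(\d+)\s*\(\s*([+\-−])\s*\)\s*$")


def parse_locus(text: str) -> tuple[int, int, str]:
    """Parse a printed locus string like ``5245164:5249140 (-)``.

    Unicode minus signs are accepted. Returns (start, end, strand).
    """
    m = _LOCUS_RE.match(str(text))
    if not m:
        raise FormatError(f"cannot parse locus {text!r}")
    start, end = int(m.group(1)), int(m.group(2))
    strand = "-" if m.group(3) in "-−" else "+"
    if start > end:
        raise FormatError(f"locus {text!r}: start > end")
    return start, end, strand


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene summary table (Table-1 style TSV).

    Requires columns ``gene`` and ``coordinates`` (``start:end (strand)``);
    any further columns are carried through. Adds parsed ``start``, ``end``,
    ``strand`` and computed ``genomic_length`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "coordinates"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    parsed = df["coordinates"].map(parse_locus)
    df["start"] = [p[0] for p in parsed]
    df["end"] = [p[1] for p in parsed]
    df["strand"] = [p[2] for p in parsed]
    df["genomic_length"] = df["end"] - df["start"] + 1
    for col in ("orf_bp", "protein_aa"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


def read_domain_table(path) -> pd.DataFrame:
    """Read a per-protein domain interval table.

    TSV columns: gene_id, domain (PLAT | LOX | 5HIS), aa_start, aa_end
    [, source]. Coordinates are 1-based inclusive amino-acid positions.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "domain": str})
    required = {"gene_id", "domain", "aa_start", "aa_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    if len(df) == 0:
        return df
    df["aa_start"] = df["aa_start"].astype(int)
    df["aa_end"] = df["aa_end"].astype(int)
    for idx, row in df.iterrows():
        if row["domain"] not in DOMAIN_NAMES:
            raise FormatError(
                f"{path} row {idx + 2}: unknown domain {row['domain']!r}"
            )
        if row["aa_start"] > row["aa_end"]:
            raise FormatError(
                f"{path} row {idx + 2}: aa_start {row['aa_start']} > "
                f"aa_end {row['aa_end']}"
            )
        if row["aa_start"] < 1:
            raise FormatError(f"{path} row {idx + 2}: coordinates are 1-based")
    return df


def validate_domain_containment(domains: pd.DataFrame) -> list[str]:
    """Check that every 5HIS interval lies inside its gene's LOX interval.

    Returns a list of violation messages (empty when all genes pass).
    """
    problems = []
    for gid, sub in domains.groupby("gene_id"):
        lox = sub[sub["domain"] == "LOX"]
        his = sub[sub["domain"] == "5HIS"]
        for _, h in his.iterrows():
            inside = any(
                l["aa_start"] <= h["aa_start"] and h["aa_end"] <= l["aa_end"]
                for _, l in lox.iterrows()
            )
            if not inside:
                problems.append(
                    f"{gid}: 5HIS {h['aa_start']}-{h['aa_end']} not inside a LOX interval"
                )
    return problems


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table.

    TSV columns: sample_id, gene_id, condition, timepoint, replicate, ct.
    Ct values must be positive. Cells with fewer than two replicates load but
    are flagged in ``df.attrs['insufficient_replication']`` since group
    statistics need replication.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_id", "condition", "timepoint", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["ct"] = df["ct"].astype(float)
    if (df["ct"].dropna() <= 0).any():
        bad = df.index[df["ct"] <= 0][0]
        raise FormatError(f"{path} row {bad + 2}: Ct must be positive")
    counts = df.groupby(["gene_id", "condition", "timepoint"])["replicate"].nunique()
    df.attrs["insufficient_replication"] = [
        key for key, n in counts.items() if n < 2
    ]
    return df


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.2f") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
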