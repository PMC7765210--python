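"""Bona-fide lipoxygenase calling.

A plant LOX gene is accepted into the family only when its protein carries
(1) an N-terminal PLAT/LH2 beta-sandwich domain, (2) a complete catalytic
LOX domain, and (3) the conserved 38-residue 5-histidine iron-coordination
signature, His-(X)4-His-(X)4-His-(X)17-His-(X)8-His, inside the LOX domain.
Candidates failing any leg of this co-occurrence rule are rejected with an
explicit reason, mirroring the curation step that trims keyword-search
candidate sets down to the true family.

Domain evidence comes either from a user-supplied interval table (e.g. the
output of HMMER/InterProScan run elsewhere) or from the packaged toy profile
motifs, which score candidate proteins with position-frequency log-odds at
desk scale. Full profile-HMM Forward/Viterbi scoring is deliberately out of
scope: the decision rule, not the scanner, is what this module pins down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# His offsets within the 38-aa signature window (0-based):
# His-(X)4-His-(X)4-His-(X)17-His-(X)8-His
FIVE_HIS_OFFSETS = (0, 5, 10, 28, 37)
FIVE_HIS_SPAN = 38


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in 1-based inclusive amino-acid coordinates."""

    gene_id: str
    motif: str
    aa_start: int
    aa_end: int
    score: float = 0.0
    his_positions: tuple[int, ...] | None = None

    @property
    def width(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass
class FamilyMember:
    """A candidate gene with its family call and characterization columns."""

    gene_id: str
    bona_fide: bool = False
    rejection_reason: str | None = None
    subfamily: str = "unassigned"       # {9-LOX, 13-LOX, unassigned}
    lox13_type: str = "n/a"             # {I, II, n/a}
    transit_peptide: bool = False
    protein_length: int | None = None
    orf_length: int | None = None
    genomic_length: int | None = None
    mw_kda: float | None = None
    pi: float | None = None
    domain_hits: list[MotifHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# 5-histidine signature scanning
# ---------------------------------------------------------------------------

def scan_five_his(protein: SequenceRecord) -> list[MotifHit]:
    """Report every 38-aa window with His at relative positions 1,6,11,29,38.

    Overlapping matches are all reported; the spacer (X) positions are
    unconstrained. An empty list means no signature.
    """
    seq = protein.sequence
    hits = []
    for i in range(len(seq) - FIVE_HIS_SPAN + 1):
        if all(seq[i + off] == "H" for off in FIVE_HIS_OFFSETS):
            hits.append(MotifHit(
                gene_id=protein.id, motif="5HIS",
                aa_start=i + 1, aa_end=i + FIVE_HIS_SPAN,
                his_positions=tuple(i + 1 + off for off in FIVE_HIS_OFFSETS),
            ))
    return hits


# ---------------------------------------------------------------------------
# Profile-motif scanning
# ---------------------------------------------------------------------------

@dataclass
class ProfileMotif:
    """Position-frequency matrix motif scored as log2 odds against background.

    ``pfm`` has shape (L, 20) over :data:`AA_ORDER`, rows summing to 1.
    ``threshold`` is in bits; when None, 0.6 x the consensus score is used.
    """

    name: str
    pfm: np.ndarray
    background: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 20:
            raise ValueError("pfm must be (L, 20)")
        if self.pfm.shape[0] < 8:
            raise ValueError("motif length must be >= 8")
        if not np.allclose(self.pfm.sum(axis=1), 1.0):
            raise ValueError("pfm rows must sum to 1")
        if self.background is None:
            self.background = np.full(20, 1.0 / 20.0)
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return self.pfm.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.pfm / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[j] for j in self.pfm.argmax(axis=1))

    @property
    def consensus_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 0.6 * self.consensus_score


def motif_from_consensus(name: str, consensus: str, match_prob: float = 0.7,
                         threshold: float | None = None) -> ProfileMotif:
    """Build a toy motif placing ``match_prob`` on the consensus residue and
    spreading the rest uniformly over the other 19 amino acids."""
    L = len(consensus)
    pfm = np.full((L, 20), (1.0 - match_prob) / 19.0)
    for i, aa in enumerate(consensus):
        pfm[i, AA_INDEX[aa]] = match_prob
    return ProfileMotif(name=name, pfm=pfm, threshold=threshold)


def scan_profile(protein: SequenceRecord, motif: ProfileMotif) -> list[MotifHit]:
    """Score every window of the protein against the motif.

    Window score = sum over columns of log2(p_col(residue)/background).
    Residues outside the 20-letter alphabet contribute 0 bits. Hits are all
    windows scoring at or above the motif's effective threshold.
    """
    seq = protein.sequence
    L = len(motif)
    if L > len(seq):
        return []
    lod = np.vstack([motif.log_odds.T, np.zeros(L)]).T  # extra row idx 20 = unknown
    idx = np.fromiter((AA_INDEX.get(aa, 20) for aa in seq), dtype=np.intp,
                      count=len(seq))
    cols = np.arange(L)
    thr = motif.effective_threshold
    hits = []
    for s in range(len(seq) - L + 1):
        score = float(lod[cols, idx[s:s + L]].sum())
        if score >= thr:
            hits.append(MotifHit(gene_id=protein.id, motif=motif.name,
                                 aa_start=s + 1, aa_end=s + L, score=score))
    return hits


def best_nonoverlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy best-scoring set of mutually non-overlapping hits."""
    chosen: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.aa_start)):
        if all(hit.aa_end < c.aa_start or hit.aa_start > c.aa_end for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.aa_start)


# ---------------------------------------------------------------------------
# Packaged toy domain motifs
# ---------------------------------------------------------------------------

PLAT_MOTIF_LENGTH = 100
LOX_MOTIF_LENGTH = 480
# 0-based offset of the 5-His signature inside the LOX motif consensus
LOX_FIVE_HIS_OFFSET = 200


def _random_consensus(length: int, rng: np.random.Generator) -> str:
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length))


def packaged_motifs(match_prob: float = 0.7) -> dict[str, ProfileMotif]:
    """The toy PLAT-like and LOX-like profile motifs used on synthetic data.

    Consensus strings are generated from a fixed seed so the motifs are
    identical on every run. The LOX consensus embeds a correctly spaced
    5-histidine signature, as real catalytic LOX domains do.
    """
    rng = np.random.default_rng(987654321)
    plat = _random_consensus(PLAT_MOTIF_LENGTH, rng)
    lox = list(_random_consensus(LOX_MOTIF_LENGTH, rng))
    for off in FIVE_HIS_OFFSETS:
        lox[LOX_FIVE_HIS_OFFSET + off] = "H"
    return {
        "PLAT": motif_from_consensus("PLAT", plat, match_prob),
        "LOX": motif_from_consensus("LOX", "".join(lox), match_prob),
    }


# ---------------------------------------------------------------------------
# Bona-fide co-occurrence filter
# ---------------------------------------------------------------------------

REASON_NO_PLAT = "missing PLAT domain"
REASON_NO_LOX = "missing or incomplete LOX domain"
REASON_NO_5HIS = "missing 5-His signature within LOX domain"

DEFAULT_MIN_LOX_WIDTH = 450


def _domain_intervals(gene_id: str, domains: pd.DataFrame, name: str):
    sub = domains[(domains["gene_id"] == gene_id) & (domains["domain"] == name)]
    return [
        MotifHit(gene_id=gene_id, motif=name,
                 aa_start=int(r["aa_start"]), aa_end=int(r["aa_end"]))
        for _, r in sub.iterrows()
    ]


def bona_fide_filter(candidates: list[str],
                     proteins: dict[str, SequenceRecord] | None = None,
                     domains: pd.DataFrame | None = None,
                     motifs: dict[str, ProfileMotif] | None = None,
                     min_lox_width: int = DEFAULT_MIN_LOX_WIDTH) -> list[FamilyMember]:
    """Apply the PLAT + complete-LOX + 5-His-in-LOX co-occurrence rule.

    Evidence resolution per candidate: rows in *domains* win when present;
    otherwise the candidate's protein is scanned with *motifs* (packaged toy
    motifs by default). A candidate with neither a domain-table entry nor a
    protein sequence is an error. "Complete" LOX means an interval of width
    >= *min_lox_width* amino acids.

    Returns one :class:`FamilyMember` per candidate, flagged bona fide or
    carrying its rejection reason; removing evidence can only ever move a
    candidate from accepted to rejected, never the other way.
    """
    proteins = proteins or {}
    members: list[FamilyMember] = []
    for gid in candidates:
        in_table = domains is not None and (domains["gene_id"] == gid).any()
        protein = proteins.get(gid)
        if not in_table and protein is None:
            raise ValueError(
                f"candidate {gid!r} has no protein sequence and no domain table entry"
            )
        if in_table:
            plat_hits = _domain_intervals(gid, domains, "PLAT")
            lox_hits = _domain_intervals(gid, domains, "LOX")
            his_hits = _domain_intervals(gid, domains, "5HIS")
            if not his_hits and protein is not None:
                his_hits = scan_five_his(protein)
        else:
            if motifs is None:
                motifs = packaged_motifs()
            plat_hits = best_nonoverlapping(scan_profile(protein, motifs["PLAT"]))
            lox_hits = best_nonoverlapping(scan_profile(protein, motifs["LOX"]))
            his_hits = scan_five_his(protein)

        member = FamilyMember(gene_id=gid,
                              domain_hits=plat_hits + lox_hits + his_hits)
        if protein is not None:
            member.protein_length = len(protein)
        complete_lox = [h for h in lox_hits if h.width >= min_lox_width]
        if not plat_hits:
            member.rejection_reason = REASON_NO_PLAT
        elif not complete_lox:
            member.rejection_reason = REASON_NO_LOX
        else:
            his_in_lox = [
                h for h in his_hits
                if any(l.aa_start <= h.aa_start and h.aa_end <= l.aa_end
                       for l in complete_lox)
            ]
            if not his_in_lox:
                member.rejection_reason = REASON_NO_5HIS
            else:
                member.bona_fide = True
        members.append(member)
    return members


def rejection_report(members: list[FamilyMember]) -> pd.DataFrame:
    """Tabulate rejected candidates and their reasons."""
    rows = [(m.gene_id, m.rejection_reason) for m in members if not m.bona_fide]
    return pd.DataFrame(rows, columns=["gene_id", "reason"])


# ---------------------------------------------------------------------------
# Plastid transit peptide heuristic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitPeptideCall:
    positive: bool
    st_fraction: float
    de_fraction: float
    net_charge: int
    short: bool = False


def predict_transit_peptide(protein: SequenceRecord, window: int = 60,
                            min_st: float = 0.25, max_de: float = 0.08,
                            min_net_charge: int = 0) -> TransitPeptideCall:
    """Heuristic plastid transit-peptide call on the N-terminal window.

    Chloroplast transit peptides are serine/threonine-rich, depleted in
    acidic residues, and not net negative; the call is positive only
    when all three hold over the first *window* residues. Proteins shorter
    than the window are evaluated over their full length and flagged short.
    All thresholds are exposed because no single published predictor defines
    this classification.
    """
    seq = protein.sequence
    short = len(seq) < window
    nterm = seq[: min(window, len(seq))]
    n = len(nterm)
    st = sum(nterm.count(a) for a in "ST") / n
    de = sum(nterm.count(a) for a in "DE") / n
    charge = (sum(nterm.count(a) for a in "RKH")
              - sum(nterm.count(a) for a in "DE"))
    positive = st >= min_st and de <= max_de and charge >= min_net_charge
    return TransitPeptideCall(positive=positive, st_fraction=st,
                              de_fraction=de, net_charge=charge, short=short)


# ---------------------------------------------------------------------------
# Subfamily assignment
# ---------------------------------------------------------------------------

def parse_reference_label(ref_id: str) -> tuple[str, str]:
    """Split a reference panel id of the form ``name|label``."""
    if "|" not in ref_id:
        raise ValueError(f"reference id {ref_id!r} lacks a '|label' suffix")
    name, label = ref_id.rsplit("|", 1)
    return name, label


def assign_subfamily(member: FamilyMember, protein: SequenceRecord,
                     references: list[SequenceRecord],
                     transit: bool | None = None) -> FamilyMember:
    """Label a member 9-LOX or 13-LOX by its nearest labelled reference.

    Nearest = highest global-alignment identity; ties broken by higher
    similarity, then lexicographic reference id. 13-LOX members split into
    type II (plastid transit peptide predicted) and type I (none).
    """
    from .comparative_genomics import AlignmentParams, global_align

    if not references:
        raise ValueError("no reference sequences supplied")
    params = AlignmentParams.protein_default()
    best = None
    for ref in references:
        name, label = parse_reference_label(ref.id)
        ident, simil, _ = global_align(protein, ref, params)
        key = (-ident, -simil, ref.id)
        if best is None or key < best[0]:
            best = (key, label)
    label = best[1]
    if transit is None:
        transit = predict_transit_peptide(protein).positive
    member = replace(member, subfamily=label, transit_peptide=bool(transit))
    member.lox13_type = ("II" if transit else "I") if label == "13-LOX" else "n/a"
    return member


def subfamily_ratio(counts: dict[str, int]) -> float | None:
    """13-LOX : 9-LOX count ratio, to 2 decimals; None when undefined.

    A family with no 9-LOX members has no finite ratio and returns None
    rather than raising.
    """
    for label, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {label!r}")
    n9 = counts.get("9-LOX", 0)
    n13 = counts.get("13-LOX", 0)
    if n9 == 0:
        return None
    return round(n13 / n9, 2)
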