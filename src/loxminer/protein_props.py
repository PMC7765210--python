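"""Physicochemical protein properties: molecular weight, isoelectric point,
and ORF/protein length consistency.

Molecular weight uses average (not monoisotopic) residue masses, following
the ExPASy "Compute pI/Mw" convention. The isoelectric point solver is a
Henderson-Hasselbalch bisection over the net-charge function with an
EMBOSS-style pKa set; both tables are plain dataclasses and can be swapped
for other published constant sets (constant-set choice shifts pI by roughly
+/- 0.2 pH units, so cross-tool comparisons should allow for that).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import SequenceRecord

# Average residue masses (Da): amino-acid residue = free amino acid - water.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class MassTable:
    """Average residue masses in daltons plus the mass of one water."""

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASSES)
    )
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        if self.water <= 0 or any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("all masses must be positive")


@dataclass(frozen=True)
class PkaTable:
    """pKa constants per ionizable group (EMBOSS-style defaults).

    ``basic`` groups carry positive charge below their pKa, ``acidic``
    groups negative charge above theirs. N/C termini are counted once per
    chain; side chains once per matching residue.
    """

    c_term: float = 3.55
    n_term: float = 7.50
    asp: float = 4.05
    glu: float = 4.45
    cys: float = 9.00
    tyr: float = 10.00
    his: float = 5.98
    lys: float = 10.00
    arg: float = 12.00

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {name}={value} outside (0, 14)")

    @property
    def acidic(self) -> dict[str, float]:
        return {"C-term": self.c_term, "D": self.asp, "E": self.glu,
                "C": self.cys, "Y": self.tyr}

    @property
    def basic(self) -> dict[str, float]:
        return {"N-term": self.n_term, "H": self.his, "K": self.lys,
                "R": self.arg}


def molecular_weight(protein: SequenceRecord | str, masses: MassTable | None = None) -> float:
    """Average molecular weight of a protein in daltons.

    Raises on empty sequences and on residues missing from the mass table
    (ambiguity codes carry no defined average mass).
    """
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    masses = masses or MassTable()
    total = masses.water
    for pos, aa in enumerate(seq, start=1):
        try:
            total += masses.residue_masses[aa]
        except KeyError:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos}"
            ) from None
    return total


def molecular_weight_kda(protein: SequenceRecord | str,
                         masses: MassTable | None = None) -> float:
    """Molecular weight in kDa, rounded to 2 decimals (report convention)."""
    return round(molecular_weight(protein, masses) / 1000.0, 2)


def net_charge(seq: str, ph: float, pkas: PkaTable) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch).

    Strictly decreasing in pH, so the isoelectric point is the unique root.
    """
    counts: dict[str, int] = {"N-term": 1, "C-term": 1}
    for aa in seq:
        if aa in "DECYHKR":
            counts[aa] = counts.get(aa, 0) + 1
    charge = 0.0
    for group, pka in pkas.basic.items():
        n = counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka))
    for group, pka in pkas.acidic.items():
        n = counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(protein: SequenceRecord | str,
                      pkas: PkaTable | None = None,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Converges unconditionally because the charge function is strictly
    decreasing. The returned pH is unrounded; report at 2 decimals.
    """
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    pkas = pkas or PkaTable()
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pkas)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def length_consistency(orf_length: int) -> int:
    """Protein length implied by an ORF length: orf/3 - 1 (stop excluded).

    E.g. a 2763 bp ORF encodes a 920 aa protein.
    """
    if orf_length < 6:
        raise ValueError(f"ORF length {orf_length} too short (minimum 6 bp)")
    if orf_length % 3 != 0:
        raise ValueError(f"ORF length {orf_length} is not a multiple of 3")
    return orf_length // 3 - 1
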