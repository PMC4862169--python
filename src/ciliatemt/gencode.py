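"""Translation under the ciliate nuclear genetic code and codon statistics.

Ciliates read UAA and UAG as glutamine, leaving UGA as the only stop codon
(NCBI translation table 6, the Ciliate/Dasycladacean nuclear code).  The
standard code (table 1) is included for contrast analyses.  DNA spelling
(T) is used for sequences; codons are reported in RNA spelling (UAA etc.)
in outputs to match the field's notation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

from Bio.Data import CodonTable

from .seq_io import RegionAnnotation, SequenceRecord

GLN_CODONS_RNA = ("CAA", "UAA", "UAG", "CAG")
CANONICAL_GLN = ("CAA", "CAG")
NONCANONICAL_GLN = ("UAA", "UAG")


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


def _dna(codon: str) -> str:
    return codon.replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table (DNA spelling)."""

    name: str
    id: str
    codon_map: dict  # codon -> one-letter amino acid
    stop_codons: frozenset

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        ident = {1: "standard", 6: "ciliate"}.get(table_id, str(table_id))
        return cls(
            name=table.names[0],
            id=ident,
            codon_map=dict(table.forward_table),
            stop_codons=frozenset(table.stop_codons),
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi(1)

    @classmethod
    def ciliate(cls) -> "GeneticCode":
        return cls.from_ncbi(6)

    def codons_for(self, aa: str) -> list[str]:
        return sorted(c for c, a in self.codon_map.items() if a == aa)


def get_code(name: str) -> GeneticCode:
    if name == "ciliate":
        return GeneticCode.ciliate()
    if name == "standard":
        return GeneticCode.standard()
    raise ValueError(f"unknown genetic code {name!r}")


@dataclass
class CodonTally:
    """Per-residue codon counts; for Gln the keys are CAA/UAA/UAG/CAG."""

    residue: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GlnRatio:
    """Non-canonical (UAA+UAG) over canonical (CAA+CAG) Gln codon usage."""

    numerator: int
    denominator: int

    @property
    def ratio(self) -> float | None:
        if self.denominator == 0:
            return None  # undefined, not an error
        return self.numerator / self.denominator

    @property
    def inverse(self) -> float | None:
        if self.numerator == 0:
            return None
        return self.denominator / self.numerator

    @property
    def rational(self) -> Fraction | None:
        if self.denominator == 0:
            return None
        return Fraction(self.numerator, self.denominator)


@dataclass
class CompositionStats:
    """Residue census of one sequence plus the derived summary numbers."""

    counts: dict
    length: int
    at_fraction: float | None = None  # dna only
    lys: int = 0
    arg: int = 0
    his: int = 0


def translate(orf: str, code: GeneticCode, require_start: bool = True) -> str:
    """Translate an ORF, excluding the terminal stop codon if present.

    Codons containing N translate to X; an internal stop raises ValueError
    reporting the 0-based codon index.
    """
    orf = orf.upper()
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} is not a multiple of 3")
    if require_start and not orf.startswith("ATG"):
        raise ValueError("ORF does not start with ATG")
    codons = [orf[i:i + 3] for i in range(0, len(orf), 3)]
    protein = []
    last = len(codons) - 1
    for idx, codon in enumerate(codons):
        if "N" in codon:
            protein.append("X")
        elif codon in code.stop_codons:
            if idx != last:
                raise ValueError(
                    f"internal stop codon {_rna(codon)} at codon {idx}"
                )
        else:
            protein.append(code.codon_map[codon])
    return "".join(protein)


def find_orf(
    record: SequenceRecord,
    code: GeneticCode,
    min_len: int = 60,
    annotate: bool = True,
) -> RegionAnnotation:
    """Longest forward-strand ATG..stop frame (stop codon included).

    Equal-length candidates resolve to the 5'-most start.  The flanks are
    annotated utr5/utr3 on the record when ``annotate`` is true.
    """
    if record.alphabet != "dna":
        raise ValueError("find_orf requires a dna record")
    seq = record.residues
    best: tuple[int, int] | None = None
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos:pos + 3] in code.stop_codons:
                length = pos + 3 - start
                if best is None or length > best[1] - best[0]:
                    best = (start, pos + 3)
                break
    if best is None or best[1] - best[0] < min_len:
        raise ValueError(
            f"record {record.id!r}: no ORF of at least {min_len} nt found"
        )
    orf = RegionAnnotation("orf", best[0], best[1])
    if annotate:
        if best[0] > 0:
            record.regions.append(RegionAnnotation("utr5", 0, best[0]))
        record.regions.append(orf)
        if best[1] < len(seq):
            record.regions.append(RegionAnnotation("utr3", best[1], len(seq)))
    return orf


def tally_gln_codons(orf: str, code: GeneticCode,
                     require_start: bool = True) -> CodonTally:
    """Count the codons encoding glutamine in an ORF (RNA-spelled keys)."""
    protein = translate(orf, code, require_start=require_start)
    counts = {c: 0 for c in GLN_CODONS_RNA}
    for idx, aa in enumerate(protein):
        if aa == "Q":
            codon = _rna(orf.upper()[3 * idx:3 * idx + 3])
            if codon not in counts:  # unreachable under either code
                raise ValueError(f"codon {codon} translated to Q unexpectedly")
            counts[codon] += 1
    return CodonTally(residue="Q", counts=counts)


def noncanonical_ratio(tally: CodonTally | dict) -> GlnRatio:
    """(UAA+UAG)/(CAA+CAG) for a Gln tally or an aggregated count mapping."""
    counts = tally.counts if isinstance(tally, CodonTally) else dict(tally)
    num = sum(counts.get(c, 0) for c in NONCANONICAL_GLN)
    den = sum(counts.get(c, 0) for c in CANONICAL_GLN)
    return GlnRatio(numerator=num, denominator=den)


def composition(record: SequenceRecord) -> CompositionStats:
    """Full residue census; A+T fraction for DNA, K/R/H counts for protein."""
    counts = dict(Counter(record.residues))
    n = len(record.residues)
    if record.alphabet == "dna":
        at = (counts.get("A", 0) + counts.get("T", 0)) / n if n else 0.0
        return CompositionStats(counts=counts, length=n, at_fraction=at)
    return CompositionStats(
        counts=counts,
        length=n,
        lys=counts.get("K", 0),
        arg=counts.get("R", 0),
        his=counts.get("H", 0),
    )


def cys_adjacent_lys_fraction(protein: str) -> float:
    """Fraction of Cys residues with a Lys at position +-1 (0 if no Cys)."""
    protein = protein.upper()
    cys = [i for i, aa in enumerate(protein) if aa == "C"]
    if not cys:
        return 0.0
    hits = sum(
        1 for i in cys
        if (i > 0 and protein[i - 1] == "K")
        or (i + 1 < len(protein) and protein[i + 1] == "K")
    )
    return hits / len(cys)
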