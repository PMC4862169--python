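"""Synthetic MT-like genes with known ground truth.

Every pipeline stage is testable without downloading the real cDNAs: the
generator assembles proteins from the canonical module/repeat templates
(CdMT: sm1+sm1+sm2 modules ending in a CXCCX terminator, 2-9 aa linkers;
CuMT: CKC X2-5 CXC repeats with Lys next to Cys), back-translates them
under the ciliate code with glutamine codons drawn from the per-subfamily
biased distributions, and wraps the ORF in UTRs whose backgrounds are
rejection-sampled to be free of the default regulatory motifs before the
requested motifs are planted at recorded positions.

Defaults are the observed study conditions: Gln codon biases
(CAA/UAA/UAG/CAG) of 0.29/0.54/0.15/0.02 for CdMTs and 0.61/0.29/0.08/0.02
for CuMTs, terminator finals K/Q/E/N at 0.55/0.36/0.07/0.02, ~3 TATA and
~5 (Cd) or ~3 (Cu) MTCM1 motifs per 5'UTR, ~3 polyadenylation signals and
~2 ARE per 3'UTR, and an A+T-rich (~66 %) UTR background.

Substitution mutations are applied at non-Cys protein positions (the
start Met excluded, so the ORF stays recoverable) before back-translation;
there is no indel model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gencode import GeneticCode, find_orf
from .seq_io import RegionAnnotation, SequenceRecord
from .utr_motifs import DEFAULT_MOTIFS, count_hits, motifs_for_region, scan_motifs

X_POOL = "KSTGEQDNA"  # Cys-free background pool, MT-like composition
_MUT_POOL = "ADEFGHIKLMNPQRSTVWY"  # every standard residue except Cys

GLN_BIAS = {
    "CdMT": {"CAA": 0.29, "UAA": 0.54, "UAG": 0.15, "CAG": 0.02},
    "CuMT": {"CAA": 0.61, "UAA": 0.29, "UAG": 0.08, "CAG": 0.02},
}
_TERM_FINALS = ("K", "Q", "E", "N")
_TERM_PROBS = (0.55, 0.36, 0.07, 0.02)

_UTR5_DEFAULTS = {"CdMT": {"TATA": 3, "MTCM1": 5},
                  "CuMT": {"TATA": 3, "MTCM1": 3}}
_UTR3_DEFAULTS = {"CdMT": {"polyA1": 2, "polyA2": 1, "ARE": 2},
                  "CuMT": {"polyA1": 2, "polyA2": 2, "ARE": 2}}

_BASES = np.array(list("ACGT"))
_BASE_PROBS = (0.33, 0.17, 0.17, 0.33)  # A+T-rich UTR background

_CLUSTER_OF_RUN = {1: "XXCXX", 2: "XCCX", 3: "CCC"}


@dataclass
class SyntheticSpec:
    subfamily: str = "CdMT"
    n_modules: int = 3    # CdMT
    n_repeats: int = 8    # CuMT
    gln_codon_bias: dict | None = None
    utr5_len: int = 150
    utr3_len: int = 120
    utr5_motifs: dict | None = None
    utr3_motifs: dict | None = None
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subfamily not in ("CdMT", "CuMT"):
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if self.subfamily == "CdMT" and not 2 <= self.n_modules <= 5:
            raise ValueError("n_modules must be in 2..5")
        if not 0.0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation_rate must be in [0, 0.2]")
        if self.gln_codon_bias is not None:
            if abs(sum(self.gln_codon_bias.values()) - 1.0) > 1e-9:
                raise ValueError("gln_codon_bias must sum to 1")

    @property
    def bias(self) -> dict:
        return self.gln_codon_bias or GLN_BIAS[self.subfamily]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated gene."""

    protein: str
    orf: tuple  # (start, end) on the cDNA
    module_regions: list = field(default_factory=list)     # protein coords
    submodule_types: list = field(default_factory=list)    # per module
    repeat_regions: list = field(default_factory=list)     # CuMT, protein coords
    cluster_multiset: dict = field(default_factory=dict)   # implied by templates
    gln_codons: list = field(default_factory=list)         # (protein pos, RNA codon)
    utr5_motif_positions: dict = field(default_factory=dict)
    utr3_motif_positions: dict = field(default_factory=dict)
    breakpoints: tuple | None = None


def _draw(rng: np.random.Generator, pool: str, k: int) -> str:
    return "".join(rng.choice(list(pool), size=k)) if k else ""


def _add_clusters(multiset: dict, *types: str) -> None:
    for t in types:
        multiset[t] = multiset.get(t, 0) + 1


def _sm1(rng, multiset) -> str:
    # CCC starts dominate real sm1 instances (CCC is the most abundant
    # CdMT cluster type); a uniform draw would leave synthetic CdMTs
    # CCC-poor relative to the family they emulate
    c1 = 3 if rng.random() < 0.75 else 2
    c2 = int(rng.integers(1, 3))
    _add_clusters(multiset, _CLUSTER_OF_RUN[c1], _CLUSTER_OF_RUN[c2])
    return "C" * c1 + _draw(rng, X_POOL, 6) + "C" * c2 + _draw(rng, X_POOL, 6)


def _sm2(rng, multiset) -> str:
    xp = int(rng.integers(6, 9))
    a = int(rng.integers(1, 3))
    b = int(rng.integers(1, 3))
    final = rng.choice(_TERM_FINALS, p=_TERM_PROBS)
    _add_clusters(multiset, "XCCX", "CXC",
                  _CLUSTER_OF_RUN[a], _CLUSTER_OF_RUN[b], "CXCC")
    return ("CC" + _draw(rng, X_POOL, xp)
            + "C" + _draw(rng, X_POOL, 1) + "C" + _draw(rng, X_POOL, 2)
            + "C" * a + _draw(rng, X_POOL, 2)
            + "C" * b + _draw(rng, X_POOL, 2)
            + "C" + _draw(rng, X_POOL, 1) + "CC" + str(final))


def _cd_protein(rng, spec, truth) -> str:
    parts = ["M" + _draw(rng, X_POOL, int(rng.integers(1, 4)))]
    pos = len(parts[0])
    for _ in range(spec.n_modules):
        module = _sm1(rng, truth.cluster_multiset) \
            + _sm1(rng, truth.cluster_multiset) \
            + _sm2(rng, truth.cluster_multiset)
        truth.module_regions.append((pos, pos + len(module)))
        truth.submodule_types.append(["sm1", "sm1", "sm2"])
        parts.append(module)
        pos += len(module)
        linker = _draw(rng, X_POOL, int(rng.integers(2, 10)))
        parts.append(linker)
        pos += len(linker)
    parts[-1] = parts[-1][:int(rng.integers(0, 4))]  # short C-terminal tail
    return "".join(parts)


def _cu_protein(rng, spec, truth) -> str:
    parts = ["M" + _draw(rng, X_POOL, int(rng.integers(1, 4)))]
    pos = len(parts[0])
    for _ in range(spec.n_repeats):
        gap = int(rng.integers(2, 6))
        repeat = "CKC" + _draw(rng, X_POOL, gap) + "C" + _draw(rng, X_POOL, 1) + "C"
        truth.repeat_regions.append((pos, pos + len(repeat)))
        _add_clusters(truth.cluster_multiset, "CXC", "CXC")
        parts.append(repeat)
        pos += len(repeat)
        # Lys-flanked spacers (>=6 aa so repeats cannot chain into
        # spurious cross-boundary matches)
        spacer = "K" + _draw(rng, X_POOL, int(rng.integers(4, 8))) + "K"
        parts.append(spacer)
        pos += len(spacer)
    parts[-1] = parts[-1][:int(rng.integers(0, 4))]
    return "".join(parts)


def _mutate_protein(rng, protein: str, rate: float) -> str:
    if rate <= 0:
        return protein
    out = list(protein)
    for i in range(1, len(out)):  # keep the start Met and all Cys
        if out[i] != "C" and rng.random() < rate:
            choices = [aa for aa in _MUT_POOL if aa != out[i]]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _backtranslate(rng, protein: str, bias: dict,
                   code: GeneticCode, truth: SyntheticTruth) -> str:
    gln_codons = ["CAA", "UAA", "UAG", "CAG"]
    gln_p = [bias[c] for c in gln_codons]
    codons = []
    for i, aa in enumerate(protein):
        if aa == "Q":
            codon_rna = str(rng.choice(gln_codons, p=gln_p))
            truth.gln_codons.append((i, codon_rna))
            codons.append(codon_rna.replace("U", "T"))
        else:
            options = code.codons_for(aa)
            codons.append(options[int(rng.integers(0, len(options)))])
    codons.append("TGA")
    return "".join(codons)


def _background(rng, length: int, defs) -> str:
    seq = list(rng.choice(_BASES, size=length, p=_BASE_PROBS))
    for _ in range(200):
        hits = scan_motifs("".join(seq), defs)
        if not hits:
            return "".join(seq)
        for h in hits:
            for k in range(h.start, h.start + len(h.matched)):
                seq[k] = str(rng.choice(_BASES, p=_BASE_PROBS))
    raise RuntimeError("could not build a motif-free UTR background")


def _concrete(rng, pattern: str) -> str:
    from .utr_motifs import _IUPAC
    return "".join(
        sym if sym in "ACGT" else str(rng.choice(sorted(_IUPAC[sym])))
        for sym in pattern.upper()
    )


def _plant(rng, background: str, wanted: dict, defs) -> tuple[str, dict]:
    """Plant non-overlapping motif instances; verify exact recoverability."""
    wanted = {k: v for k, v in (wanted or {}).items() if v > 0}
    by_name = {d.name: d for d in defs}
    unknown = set(wanted) - set(by_name)
    if unknown:
        raise ValueError(f"unknown motifs requested: {sorted(unknown)}")
    if sum(len(by_name[n].pattern) * c for n, c in wanted.items()) > len(background):
        raise ValueError("planted motifs exceed UTR length")
    if not wanted:
        return background, {}
    for _ in range(100):
        seq = list(background)
        occupied: list[tuple[int, int]] = []
        positions: dict[str, list[int]] = {n: [] for n in wanted}
        feasible = True
        for name, count in wanted.items():
            width = len(by_name[name].pattern)
            for _ in range(count):
                for _ in range(200):
                    start = int(rng.integers(0, len(seq) - width + 1))
                    if all(start + width <= s or start >= e
                           for s, e in occupied):
                        break
                else:
                    feasible = False
                    break
                instance = _concrete(rng, by_name[name].pattern)
                seq[start:start + width] = instance
                occupied.append((start, start + width))
                positions[name].append(start)
            if not feasible:
                break
        if not feasible:
            continue
        found = count_hits(scan_motifs("".join(seq), defs))
        if found == wanted:
            for v in positions.values():
                v.sort()
            return "".join(seq), positions
    raise RuntimeError("could not plant motifs without spurious matches")


def generate_mt_gene(spec: SyntheticSpec) -> tuple[SequenceRecord, SyntheticTruth]:
    """Generate one MT-like cDNA with full planted ground truth.

    The same spec (including seed) always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.ciliate()
    truth = SyntheticTruth(protein="", orf=(0, 0))
    protein = (_cd_protein if spec.subfamily == "CdMT" else _cu_protein)(
        rng, spec, truth)
    protein = _mutate_protein(rng, protein, spec.mutation_rate)
    truth.protein = protein
    cds = _backtranslate(rng, protein, spec.bias, code, truth)

    utr5_defs = motifs_for_region("utr5", DEFAULT_MOTIFS)
    utr3_defs = motifs_for_region("utr3", DEFAULT_MOTIFS)
    utr5_wanted = spec.utr5_motifs if spec.utr5_motifs is not None \
        else _UTR5_DEFAULTS[spec.subfamily]
    utr3_wanted = spec.utr3_motifs if spec.utr3_motifs is not None \
        else _UTR3_DEFAULTS[spec.subfamily]
    # Rebuild the UTRs until the planted CDS is the unambiguous longest
    # reading frame (a random UTR can otherwise harbour an in-frame ATG
    # with no stop before the CDS, shifting the recovered ORF).
    for _ in range(50):
        utr5, pos5 = _plant(rng, _background(rng, spec.utr5_len, utr5_defs),
                            utr5_wanted, utr5_defs)
        utr3, pos3 = _plant(rng, _background(rng, spec.utr3_len, utr3_defs),
                            utr3_wanted, utr3_defs)
        cdna = utr5 + cds + utr3
        probe = SequenceRecord(id="probe", residues=cdna, alphabet="dna")
        found = find_orf(probe, code, min_len=30, annotate=False)
        if (found.start, found.end) == (len(utr5), len(utr5) + len(cds)):
            break
    else:
        raise RuntimeError("could not build UTRs compatible with the ORF")
    truth.utr5_motif_positions = pos5
    truth.utr3_motif_positions = pos3
    truth.orf = (len(utr5), len(utr5) + len(cds))
    regions = [RegionAnnotation("orf", *truth.orf)]
    if utr5:
        regions.insert(0, RegionAnnotation("utr5", 0, len(utr5)))
    if utr3:
        regions.append(RegionAnnotation("utr3", truth.orf[1], len(cdna)))
    record = SequenceRecord(
        id=f"syn{spec.subfamily}-{spec.seed}",
        residues=cdna,
        alphabet="dna",
        description=f"synthetic {spec.subfamily} gene",
        regions=regions,
    )
    return record, truth


def generate_duplication(
    parent_spec: SyntheticSpec | None = None,
    junction_len: int = 9,
    divergence: float = 0.06,
    truncations: tuple = (0, 29, 40, 0),
    seed: int = 0,
) -> tuple[SequenceRecord, SequenceRecord, SyntheticTruth]:
    """Build a parent gene and a derived semi-duplicated gene.

    The parent is the ORF of a generated CdMT gene; the derived sequence
    is copy1 (parent truncated by ``truncations[0]`` nt at 5' and
    ``truncations[1]`` nt at 3') + a random junction + copy2 (truncated by
    ``truncations[2]``/``truncations[3]``), each copy independently
    mutated at the ``divergence`` substitution rate.  Truth records the
    derived-sequence breakpoints.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    spec = parent_spec or SyntheticSpec(
        subfamily="CdMT", n_modules=2, utr5_len=0, utr3_len=0,
        utr5_motifs={}, utr3_motifs={},
        seed=int(rng.integers(0, 2**31 - 1)))
    gene, gene_truth = generate_mt_gene(spec)
    orf = gene.region("orf")
    parent_seq = gene.subseq(orf)
    L = len(parent_seq)
    t15, t13, t25, t23 = truncations
    if min(truncations) < 0 or t15 + t13 >= L or t25 + t23 >= L:
        raise ValueError("truncations exceed parent length")

    def mutate_dna(seq: str) -> str:
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < divergence:
                others = [b for b in "ACGT" if b != out[i]]
                out[i] = others[int(rng.integers(0, 3))]
        return "".join(out)

    copy1 = mutate_dna(parent_seq[t15:L - t13])
    copy2 = mutate_dna(parent_seq[t25:L - t23])
    junction = _draw(rng, "ACGT", junction_len)
    derived_seq = copy1 + junction + copy2

    parent = SequenceRecord(id="synParent", residues=parent_seq,
                            alphabet="dna", description="synthetic parent gene")
    derived = SequenceRecord(id="synDerived", residues=derived_seq,
                             alphabet="dna",
                             description="synthetic semi-duplicated gene")
    truth = SyntheticTruth(
        protein=gene_truth.protein,
        orf=(0, L),
        breakpoints=(len(copy1), len(copy1) + junction_len),
    )
    return parent, derived, truth
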