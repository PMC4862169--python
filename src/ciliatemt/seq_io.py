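"""Sequence records, FASTA/GFF-style I/O and the packaged census tables.

Coordinates are 0-based half-open everywhere in memory and converted to
1-based inclusive only when written in the GFF3-style annotation format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_LETTERS = frozenset("ACGTN")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

REGION_KINDS = frozenset(
    {"utr5", "orf", "utr3", "module", "submodule", "linker", "motif", "segment"}
)

CLUSTER_TYPES = ("CCC", "CXCC", "CXCXC", "XCCX", "CXC", "XXCXX")

#: Cys residues contributed by one cluster of each type.
CYS_PER_CLUSTER = {"CCC": 3, "CXCC": 3, "CXCXC": 3, "XCCX": 2, "CXC": 2, "XXCXX": 1}

# Embedded column checksums for the packaged census tables (per-type Cys
# residue totals and grand totals per subfamily).
_TABLE2_CHECKSUMS = {
    "CdMT": {"CCC": 351, "CXCC": 183, "CXCXC": 9, "XCCX": 378, "CXC": 116,
             "XXCXX": 45, "total": 1082, "rows": 26},
    "CuMT": {"CCC": 0, "CXCC": 3, "CXCXC": 0, "XCCX": 14, "CXC": 518,
             "XXCXX": 26, "total": 561, "rows": 17},
}
_TABLE3_CHECKSUMS = {
    "CdMT": {"caa": 52, "uaa": 96, "uag": 27, "cag": 3, "total": 178},
    "CuMT": {"caa": 65, "uaa": 31, "uag": 8, "cag": 2, "total": 106},
}


class FixtureError(RuntimeError):
    """A packaged census table failed its embedded checksum."""


@dataclass
class RegionAnnotation:
    """A typed half-open interval on a sequence, with free-form attributes."""

    kind: str
    start: int
    end: int
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for kind {self.kind}"
            )

    def validate(self, seq_len: int) -> None:
        if self.end > seq_len:
            raise ValueError(
                f"{self.kind} region [{self.start}, {self.end}) exceeds "
                f"sequence length {seq_len}"
            )
        if self.kind == "orf" and (self.end - self.start) % 3 != 0:
            raise ValueError("orf region length must be a multiple of 3")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with region annotations."""

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""
    regions: list[RegionAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper().replace("U", "T") \
            if self.alphabet == "dna" else self.residues.upper()
        legal = DNA_LETTERS if self.alphabet == "dna" else PROTEIN_LETTERS
        for pos, ch in enumerate(self.residues):
            if ch not in legal:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )
        for region in self.regions:
            region.validate(len(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def region(self, kind: str) -> RegionAnnotation | None:
        """First annotated region of the given kind, or None."""
        for r in self.regions:
            if r.kind == kind:
                return r
        return None

    def subseq(self, region: RegionAnnotation) -> str:
        return self.residues[region.start:region.end]


def read_fasta(path: str | Path, alphabet: str = "dna",
               errors: str = "raise") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Lowercase input is normalized to uppercase; an illegal residue raises
    ValueError naming the record and 0-based position (or skips the record
    with a warning when ``errors="skip"``). An empty file yields an empty
    list with a warning.
    """
    if errors not in ("raise", "skip"):
        raise ValueError("errors must be 'raise' or 'skip'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(SequenceRecord(
                id=rec.id,
                description=rec.description[len(rec.id):].strip(),
                alphabet=alphabet,
                residues=str(rec.seq),
            ))
        except ValueError:
            if errors == "raise":
                raise
            warnings.warn(f"skipping invalid record {rec.id!r}", stacklevel=2)
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.residues), id=r.id, description=r.description)
         for r in records],
        str(path),
        "fasta",
    )


def _escape(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D")


def _unescape(value: str) -> str:
    return value.replace("%3B", ";").replace("%3D", "=")


def write_annotations(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write region annotations as 9-column GFF3-style lines.

    Coordinates are converted to 1-based inclusive on output; the paired
    :func:`read_annotations` restores the in-memory convention losslessly.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            for region in rec.regions:
                attrs = ";".join(
                    f"{_escape(k)}={_escape(v)}"
                    for k, v in sorted(region.attributes.items())
                ) or "."
                fh.write(
                    "\t".join(
                        [rec.id, "ciliatemt", region.kind,
                         str(region.start + 1), str(region.end),
                         ".", "+", ".", attrs]
                    ) + "\n"
                )


def read_annotations(path: str | Path) -> dict[str, list[RegionAnnotation]]:
    """Read the GFF3-style files written by :func:`write_annotations`."""
    out: dict[str, list[RegionAnnotation]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed annotation line: {line!r}")
            seqid, _, kind, start, end, _, _, _, attrs = cols
            attributes = {}
            if attrs != ".":
                for item in attrs.split(";"):
                    key, _, value = item.partition("=")
                    attributes[_unescape(key)] = _unescape(value)
            out.setdefault(seqid, []).append(
                RegionAnnotation(kind, int(start) - 1, int(end), attributes)
            )
    return out


def _data_path(name: str):
    return resources.files("ciliatemt.data").joinpath(name)


def load_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged per-sequence census tables.

    Returns ``(clusters, gln_codons)``:

    * ``clusters`` — one row per MT with cluster counts per type (a CCC,
      CXCC or CXCXC cluster holds 3 Cys; XCCX and CXC hold 2; XXCXX 1),
      total Cys, the printed Cys percentage, and protein length.  Boolean
      ``pct_consistent`` flags rows whose printed percentage disagrees with
      ``100 * total_cys / length`` by more than rounding (two CuMT rows).
    * ``gln_codons`` — one row per MT with Gln codon counts (CAA, UAA,
      UAG, CAG) and their total.

    Both tables are verified against embedded column checksums; a mismatch
    raises :class:`FixtureError`.
    """
    with resources.as_file(_data_path("table2_clusters.tsv")) as p:
        clusters = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("table3_gln_codons.tsv")) as p:
        gln = pd.read_csv(p, sep="\t")

    # Per-row arithmetic consistency: counts must reproduce total Cys.
    implied = sum(
        clusters[t.lower()] * CYS_PER_CLUSTER[t] for t in CLUSTER_TYPES
    )
    bad = clusters.loc[implied != clusters["total_cys"], "id"].tolist()
    if bad:
        raise FixtureError(f"cluster counts do not reproduce total Cys for {bad}")
    clusters["pct_consistent"] = (
        (100.0 * clusters["total_cys"] / clusters["length"])
        .round(2)
        .sub(clusters["pct_cys"])
        .abs()
        < 0.011
    )

    for sub, expect in _TABLE2_CHECKSUMS.items():
        grp = clusters[clusters["subfamily"] == sub]
        if len(grp) != expect["rows"]:
            raise FixtureError(f"{sub}: expected {expect['rows']} rows, got {len(grp)}")
        for t in CLUSTER_TYPES:
            got = int((grp[t.lower()] * CYS_PER_CLUSTER[t]).sum())
            if got != expect[t]:
                raise FixtureError(f"{sub} {t}: Cys checksum {got} != {expect[t]}")
        if int(grp["total_cys"].sum()) != expect["total"]:
            raise FixtureError(f"{sub}: total Cys checksum failed")

    for sub, expect in _TABLE3_CHECKSUMS.items():
        grp = gln[gln["subfamily"] == sub]
        for col in ("caa", "uaa", "uag", "cag", "total"):
            if int(grp[col].sum()) != expect.get(col, expect["total"]):
                raise FixtureError(f"{sub} {col}: Gln codon checksum failed")
    if not (gln["caa"] + gln["uaa"] + gln["uag"] + gln["cag"]).equals(gln["total"]):
        raise FixtureError("per-row Gln codon totals inconsistent")

    return clusters, gln
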