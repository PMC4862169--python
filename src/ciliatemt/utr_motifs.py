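"""Regulatory motif scanning in 5'/3' UTRs.

The default motif set covers the elements recurrently found around
Tetrahymena MT genes: an AT-rich TATA box variant (TAATAA), the AP-1-like
core of the MTCM1 promoter element (TGANTCA), the two standard eukaryotic
polyadenylation signals (AATAAA, ATTAAA) and the AU-rich mRNA instability
element (ATTTA).  Patterns are IUPAC nucleotide strings; every window is
tested on the forward strand and overlapping hits are all counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

_IUPAC = {sym: frozenset(bases) for sym, bases in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str  # IUPAC nucleotide string, N = any
    max_mismatch: int = 0
    region: str = "any"  # utr5 | utr3 | any

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError(f"motif {self.name}: pattern shorter than 4")
        if not 0 <= self.max_mismatch < len(self.pattern):
            raise ValueError(f"motif {self.name}: bad max_mismatch")
        for sym in self.pattern.upper():
            if sym not in _IUPAC:
                raise ValueError(
                    f"motif {self.name}: unknown IUPAC symbol {sym!r}")
        if self.region not in ("utr5", "utr3", "any"):
            raise ValueError(f"motif {self.name}: bad region {self.region!r}")


DEFAULT_MOTIFS = (
    MotifDef("TATA", "TAATAA", region="utr5"),
    MotifDef("MTCM1", "TGANTCA", region="utr5"),
    MotifDef("polyA1", "AATAAA", region="utr3"),
    MotifDef("polyA2", "ATTAAA", region="utr3"),
    MotifDef("ARE", "ATTTA", region="utr3"),
)


def motifs_for_region(region: str,
                      defs: tuple = DEFAULT_MOTIFS) -> list[MotifDef]:
    return [d for d in defs if d.region in ("any", region)]


@dataclass
class MotifHit:
    motif: str
    start: int  # 0-based within the scanned region
    matched: str
    mismatches: int


def scan_motifs(region_seq: str, defs) -> list[MotifHit]:
    """Every matching window for every motif, sorted by (motif, start)."""
    seq = region_seq.upper()
    hits: list[MotifHit] = []
    for motif in defs:
        pattern = motif.pattern.upper()
        m = len(pattern)
        for start in range(len(seq) - m + 1):
            window = seq[start:start + m]
            mismatches = sum(
                1 for base, sym in zip(window, pattern)
                if base not in _IUPAC[sym]
            )
            if mismatches <= motif.max_mismatch:
                hits.append(MotifHit(motif.name, start, window, mismatches))
    hits.sort(key=lambda h: (h.motif, h.start))
    return hits


@dataclass
class MotifSummary:
    per_gene: pd.DataFrame    # genes x motifs, counts
    group_means: pd.DataFrame  # groups x motifs, means to 1 decimal
    convention: str = "overlapping matches counted; forward strand only"


def motif_summary(counts_by_gene: dict, groups: dict | None = None) -> MotifSummary:
    """Per-gene motif counts and per-group means.

    ``counts_by_gene`` maps gene id -> {motif name -> count}; ``groups``
    maps gene id -> group label (one group named "all" when omitted).
    Means are reported to 1 decimal; an empty group would simply have no
    row, and genes absent from ``groups`` are skipped with NaN-free output.
    """
    per_gene = pd.DataFrame.from_dict(counts_by_gene, orient="index").fillna(0)
    per_gene = per_gene.astype(int).sort_index(axis=1)
    if groups is None:
        labels = pd.Series("all", index=per_gene.index)
    else:
        labels = pd.Series({g: groups[g] for g in per_gene.index})
    means = per_gene.groupby(labels).mean().round(1)
    return MotifSummary(per_gene=per_gene, group_means=means)


def count_hits(hits: list[MotifHit]) -> dict:
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.motif] = counts.get(h.motif, 0) + 1
    return counts
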