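"""Cysteine-cluster tokenization, classification and censuses.

A cluster is a maximal run of Cys residues in which consecutive Cys are
separated by at most one other residue (X).  Six canonical types are
recognised — CCC, CXCC, CXCXC, XCCX, CXC and XXCXX (an isolated Cys) —
and longer chains are decomposed into canonical sub-clusters.  The type is
determined solely by the internal C/X pattern: the flanking X context in
the names XCCX/XXCXX is not required, so clusters at sequence termini
classify normally.  CCXC is folded into CXCC (orientation-insensitive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq_io import CLUSTER_TYPES, CYS_PER_CLUSTER

#: internal pattern -> canonical type
_CANONICAL = {
    "C": "XXCXX",
    "CC": "XCCX",
    "CXC": "CXC",
    "CCC": "CCC",
    "CXCC": "CXCC",
    "CCXC": "CXCC",
    "CXCXC": "CXCXC",
}

_TRIPLE_TYPES = ("CCC", "CXCC", "CXCXC")


@dataclass
class CysCluster:
    """One tokenized cysteine cluster on a protein."""

    start: int  # index of first Cys
    end: int    # exclusive index past last Cys
    pattern: str
    type: str
    n_cys: int
    decomposed: bool = False


@dataclass
class ClusterProfile:
    """Per-sequence cluster census (one Table-2-style row)."""

    seq_id: str
    cluster_counts: dict
    cys_counts: dict
    total_cys: int
    pct_cys: float
    length: int
    clusters: list = field(default_factory=list)

    @classmethod
    def from_counts(cls, seq_id: str, cluster_counts: dict, length: int,
                    pct_cys: float | None = None) -> "ClusterProfile":
        """Build a profile from cluster counts alone (no sequence needed)."""
        counts = {t: int(cluster_counts.get(t, 0)) for t in CLUSTER_TYPES}
        cys = {t: counts[t] * CYS_PER_CLUSTER[t] for t in CLUSTER_TYPES}
        total = sum(cys.values())
        if pct_cys is None:
            pct_cys = round(100.0 * total / length, 2) if length else 0.0
        return cls(seq_id, counts, cys, total, pct_cys, length)


def _pattern(positions: list[int]) -> str:
    first, last = positions[0], positions[-1]
    pos = set(positions)
    return "".join("C" if i in pos else "X" for i in range(first, last + 1))


def classify_cluster(pattern: str) -> list[str]:
    """Classify an internal C/X pattern into one or more canonical types.

    Canonical patterns map to a single type.  Longer chains are decomposed
    into consecutive canonical blocks, preferring the fewest blocks and
    then the longest leading blocks; OTHER is returned only when no
    decomposition exists (impossible for gap-<=1 chains, but kept for
    malformed input tolerance).
    """
    if not pattern or pattern[0] != "C" or pattern[-1] != "C":
        raise ValueError(f"malformed cluster pattern {pattern!r}")
    if set(pattern) - {"C", "X"}:
        raise ValueError(f"cluster pattern must be over {{C,X}}: {pattern!r}")
    if pattern in _CANONICAL:
        return [_CANONICAL[pattern]]
    positions = [i for i, ch in enumerate(pattern) if ch == "C"]
    blocks = _decompose(positions)
    if blocks is None:
        return ["OTHER"]
    return [_CANONICAL[_pattern(block)] for block in blocks]


def _decompose(positions: list[int]) -> list[list[int]] | None:
    """Split a Cys-position chain into canonical blocks.

    Among all splits into consecutive blocks with canonical patterns,
    returns the one with the fewest blocks, breaking ties toward longer
    earlier blocks (lexicographically).  Chains are short, so exhaustive
    recursion is fine.
    """
    best: tuple | None = None
    best_blocks: list[list[int]] | None = None

    def rec(idx: int, blocks: list[list[int]]) -> None:
        nonlocal best, best_blocks
        if idx == len(positions):
            key = (len(blocks), tuple(-len(b) for b in blocks))
            if best is None or key < best:
                best, best_blocks = key, [list(b) for b in blocks]
            return
        if best is not None and len(blocks) >= best[0]:
            return  # cannot improve on fewest-blocks
        for stop in range(idx + 1, min(idx + 3, len(positions)) + 1):
            block = positions[idx:stop]
            if _pattern(block) in _CANONICAL:
                blocks.append(block)
                rec(stop, blocks)
                blocks.pop()

    rec(0, [])
    return best_blocks


def tokenize_clusters(protein: str) -> list[CysCluster]:
    """Tokenize a protein into ordered, non-overlapping Cys clusters.

    Every Cys belongs to exactly one cluster; maximal chains whose
    consecutive Cys are <=1 residue apart become clusters, split into
    canonical sub-clusters when longer than the recognised types.
    """
    protein = protein.upper()
    cys = [i for i, aa in enumerate(protein) if aa == "C"]
    chains: list[list[int]] = []
    for i in cys:
        if chains and i - chains[-1][-1] <= 2:
            chains[-1].append(i)
        else:
            chains.append([i])
    clusters: list[CysCluster] = []
    for chain in chains:
        pattern = _pattern(chain)
        if pattern in _CANONICAL:
            clusters.append(CysCluster(
                start=chain[0], end=chain[-1] + 1, pattern=pattern,
                type=_CANONICAL[pattern], n_cys=len(chain)))
            continue
        blocks = _decompose(chain)
        if blocks is None:
            clusters.append(CysCluster(
                start=chain[0], end=chain[-1] + 1, pattern=pattern,
                type="OTHER", n_cys=len(chain)))
            continue
        for block in blocks:
            sub = _pattern(block)
            clusters.append(CysCluster(
                start=block[0], end=block[-1] + 1, pattern=sub,
                type=_CANONICAL[sub], n_cys=len(block), decomposed=True))
    return clusters


def cluster_profile(protein: str, seq_id: str = "") -> ClusterProfile:
    """Census of cluster types, Cys residues and Cys percentage."""
    protein = protein.upper()
    clusters = tokenize_clusters(protein)
    cluster_counts = {t: 0 for t in CLUSTER_TYPES}
    cys_counts = {t: 0 for t in CLUSTER_TYPES}
    cluster_counts["OTHER"] = 0
    cys_counts["OTHER"] = 0
    for c in clusters:
        cluster_counts[c.type] += 1
        cys_counts[c.type] += c.n_cys
    total = protein.count("C")
    length = len(protein)
    pct = round(100.0 * total / length, 2) if length else 0.0
    return ClusterProfile(seq_id, cluster_counts, cys_counts, total, pct,
                          length, clusters)


def aggregate_profiles(profiles: list[ClusterProfile],
                       labels: list[str] | None = None) -> pd.DataFrame:
    """Per-type Cys totals and percentages, optionally per group label.

    Returns one row per group (plus nothing else); columns are the Cys
    residue totals per cluster type, their percentages of the group grand
    total, and the grand total itself.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if labels is None:
        labels = ["all"] * len(profiles)
    rows = {}
    for profile, label in zip(profiles, labels, strict=True):
        row = rows.setdefault(label, {t: 0 for t in CLUSTER_TYPES})
        for t in CLUSTER_TYPES:
            row[t] += profile.cys_counts.get(t, 0)
    out = []
    for label, row in rows.items():
        grand = sum(row.values())
        entry = {"group": label, "total_cys": grand}
        for t in CLUSTER_TYPES:
            entry[f"{t}_cys"] = row[t]
            entry[f"{t}_pct"] = round(100.0 * row[t] / grand, 2) if grand else 0.0
        out.append(entry)
    return pd.DataFrame(out).set_index("group")


@dataclass
class SubfamilyCall:
    label: str  # CdMT, CuMT or ambiguous
    triple_fraction: float  # Cys share in CCC+CXCC+CXCXC clusters
    cxc_fraction: float
    warning: str | None = None


def classify_subfamily(profile: ClusterProfile,
                       threshold_cd: float = 0.25,
                       threshold_cu: float = 0.50,
                       cu_max_triple: float = 0.05) -> SubfamilyCall:
    """Call CdMT vs CuMT from the cluster census.

    CdMTs are rich in CCC/CXCC/CXCXC clusters, which are almost absent in
    CuMTs where CXC dominates; the thresholds operationalise that contrast
    and are configurable.
    """
    if profile.total_cys == 0:
        return SubfamilyCall("ambiguous", 0.0, 0.0,
                             warning="no Cys residues; cannot classify")
    triple = sum(profile.cys_counts.get(t, 0) for t in _TRIPLE_TYPES)
    triple_frac = triple / profile.total_cys
    cxc_frac = profile.cys_counts.get("CXC", 0) / profile.total_cys
    if triple_frac >= threshold_cd:
        return SubfamilyCall("CdMT", triple_frac, cxc_frac)
    if cxc_frac >= threshold_cu and triple_frac <= cu_max_triple:
        return SubfamilyCall("CuMT", triple_frac, cxc_frac)
    return SubfamilyCall("ambiguous", triple_frac, cxc_frac)
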