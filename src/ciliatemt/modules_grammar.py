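"""Modular/submodular grammar of CdMTs and the CuMT repeat motif.

CdMT proteins are concatenations of 2-5 modules (32-63 aa) separated by
2-9 aa linkers.  Each module ends in a CXCCX terminator whose final
residue is typically K, Q, E or N, and canonically decomposes into two
type-1 submodules (sm1 = C2-3 X6 C1-2 X6) followed by one type-2
submodule (sm2 = C2 X6-8 + CXCXX C1-2 XX C1-2 X1-2, optionally carrying
the CXCCX terminator as its tail).  CuMTs instead repeat the consensus
CKC X2-5 CXC, where the Lys is occasionally substituted.

Module boundaries are chosen by dynamic programming over candidate
terminator sites, maximizing first the number of modules with in-range
lengths and linkers, then the number of canonical (K/Q/E/N-ending)
terminators, then the module count, with leftmost boundaries on ties.
Terminator candidates accept any non-Cys final residue — a strict
K/Q/E/N matcher would drop every module whose final residue has mutated —
and the canonical set is recorded per module instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

TERMINATOR_FINALS = "KQEN"
_TERMINATOR_RE = re.compile(r"(?=(C[^C]CC([^C])))")

_SM1_RE = re.compile(r"C{2,3}[^C]{6}C{1,2}[^C]{6}")
_SM2_RE = re.compile(
    r"C{2}[^C]{6,8}C[^C]C[^C]{2}C{1,2}[^C]{2}C{1,2}[^C]{1,2}(?:C[^C]CC[^C])?"
)
_SM2_CTERM_RE = re.compile(r"C[^C]C[^C]{2}C{1,2}[^C]{2}C{1,2}[^C]{1,2}(?:C[^C]CC[^C])?")
_HALF_SM1_RE = re.compile(r"C{2,3}[^C]{6}")


@dataclass
class ModuleConfig:
    module_len: tuple = (32, 63)
    linker_len: tuple = (2, 9)
    terminator_finals: str = TERMINATOR_FINALS


@dataclass
class SubmoduleAnn:
    type: str  # sm1, sm2, half_sm1, sm2_cterm
    start: int
    end: int
    complete: bool
    matched_pattern: str


@dataclass
class ModuleAnn:
    index: int  # 1-based
    start: int
    end: int
    terminator_motif: str | None
    terminator_final: str | None
    terminator_canonical: bool
    in_range: bool
    submodules: list = field(default_factory=list)
    completeness: str = "incomplete"  # canonical | incomplete
    warning: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ModularityResult:
    seq_id: str
    n_modules: int
    klass: str  # bi, tri, tetra, penta, other
    linker_lengths: list
    fraction_canonical_modules: float


@dataclass
class CuRepeatHit:
    start: int
    end: int
    pattern: str
    position2_residue: str
    is_canonical_K: bool


_CLASS_BY_COUNT = {2: "bi", 3: "tri", 4: "tetra", 5: "penta"}


def _terminator_candidates(protein: str):
    """(end, canonical) for every CXCC+non-Cys window; end is exclusive."""
    out = []
    for m in _TERMINATOR_RE.finditer(protein):
        end = m.start() + 5
        out.append((end, m.group(2) in TERMINATOR_FINALS))
    return out


def find_module_boundaries(protein: str,
                           config: ModuleConfig | None = None) -> list[ModuleAnn]:
    """Segment a (CdMT-like) protein into terminator-ending modules.

    Returns modules in order; residues before the first and after the last
    module, and between modules, are linkers (reported by
    :func:`classify_modularity`).  With no terminator candidate at all the
    whole protein is returned as a single flagged module.
    """
    config = config or ModuleConfig()
    protein = protein.upper()
    n = len(protein)
    lo_m, hi_m = config.module_len
    lo_l, hi_l = config.linker_len
    cands = _terminator_candidates(protein)
    if not cands:
        return [ModuleAnn(1, 0, n, None, None, False, in_range=False,
                          warning="no terminator motif found")]

    def first_module(end: int) -> tuple[int, bool]:
        # Module start for a first module ending at `end`: in-range length
        # if possible, else the whole prefix; leading residues are linker.
        if end >= lo_m:
            return end - min(end, hi_m), True
        return 0, False

    def interior_module(prev_end: int, end: int) -> tuple[int, bool] | None:
        gap = end - prev_end
        if gap < lo_l + 5:  # linker + at least the terminator itself
            return None
        # smallest in-range linker whose module length lands in range
        linker = max(lo_l, gap - hi_m)
        if linker <= hi_l and lo_m <= gap - linker <= hi_m:
            return prev_end + linker, True
        linker = min(max(lo_l, gap - hi_m), hi_l)
        return prev_end + linker, False

    # DP over candidates: value = (#in-range, #canonical, #modules)
    k = len(cands)
    best_val: list[tuple | None] = [None] * k
    best_prev: list[int | None] = [None] * k
    best_start: list[int] = [0] * k
    for i, (end_i, canon_i) in enumerate(cands):
        start, ok = first_module(end_i)
        best_val[i] = (int(ok), int(canon_i), 1)
        best_prev[i] = None
        best_start[i] = start
        for j in range(i):
            if best_val[j] is None:
                continue
            placed = interior_module(cands[j][0], end_i)
            if placed is None:
                continue
            start_j, ok_j = placed
            val = tuple(
                a + b for a, b in zip(
                    best_val[j], (int(ok_j), int(canon_i), 1))
            )
            if val > best_val[i]:
                best_val[i] = val
                best_prev[i] = j
                best_start[i] = start_j
    # best final candidate; ties resolve to the earliest end (leftmost)
    final = max(range(k), key=lambda i: (best_val[i], -cands[i][0]))
    chain = []
    node: int | None = final
    while node is not None:
        chain.append(node)
        node = best_prev[node]
    chain.reverse()
    modules = []
    for idx, ci in enumerate(chain, start=1):
        end, canon = cands[ci]
        start = best_start[ci]
        length = end - start
        modules.append(ModuleAnn(
            index=idx, start=start, end=end,
            terminator_motif=protein[end - 5:end],
            terminator_final=protein[end - 1],
            terminator_canonical=canon,
            in_range=lo_m <= length <= hi_m,
        ))
    return modules


def annotate_submodules(module: ModuleAnn, protein: str) -> list[SubmoduleAnn]:
    """Left-to-right sm1/sm2 decomposition of one module.

    Unmatched stretches are left as gaps.  A module made of two complete
    sm1 and one complete sm2 is marked canonical.
    """
    protein = protein.upper()
    segment = protein[module.start:module.end]
    anns: list[SubmoduleAnn] = []
    pos = 0
    order = (("sm1", _SM1_RE), ("sm2", _SM2_RE),
             ("sm2_cterm", _SM2_CTERM_RE), ("half_sm1", _HALF_SM1_RE))
    while pos < len(segment):
        for name, pattern in order:
            m = pattern.match(segment, pos)
            if m:
                anns.append(SubmoduleAnn(
                    type=name,
                    start=module.start + m.start(),
                    end=module.start + m.end(),
                    complete=name in ("sm1", "sm2"),
                    matched_pattern=m.group(0),
                ))
                pos = m.end()
                break
        else:
            pos += 1
    module.submodules = anns
    types = [a.type for a in anns]
    module.completeness = "canonical" if types == ["sm1", "sm1", "sm2"] \
        else "incomplete"
    return anns


def classify_modularity(modules: list[ModuleAnn], seq_id: str = "",
                        seq_len: int | None = None) -> ModularityResult:
    """Modularity class (bi..penta) and inter-module linker lengths."""
    n = len(modules)
    linkers = [
        b.start - a.end for a, b in zip(modules, modules[1:])
    ]
    canonical = sum(1 for m in modules if m.completeness == "canonical")
    return ModularityResult(
        seq_id=seq_id,
        n_modules=n,
        klass=_CLASS_BY_COUNT.get(n, "other"),
        linker_lengths=linkers,
        fraction_canonical_modules=canonical / n if n else 0.0,
    )


def find_cump_repeats(protein: str) -> list[CuRepeatHit]:
    """All (overlapping) CKC X2-5 CXC repeat hits, ordered by start.

    Position 2 may be any residue; hits are flagged canonical when it is
    the consensus Lys.
    """
    protein = protein.upper()
    n = len(protein)
    hits = []
    for start in range(n):
        if protein[start] != "C":
            continue
        for gap in range(2, 6):
            end = start + 6 + gap
            if end > n:
                break
            window = protein[start:end]
            if (window[2] == "C"
                    and "C" not in window[3:3 + gap]
                    and window[3 + gap] == "C"
                    and window[4 + gap] != "C"
                    and window[5 + gap] == "C"):
                hits.append(CuRepeatHit(
                    start=start, end=end, pattern=window,
                    position2_residue=window[1],
                    is_canonical_K=window[1] == "K",
                ))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits
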