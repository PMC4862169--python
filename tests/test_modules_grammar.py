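"""CdMT module/submodule grammar and CuMT repeats."""

import numpy as np
import pytest

from ciliatemt.modules_grammar import (
    ModuleConfig,
    annotate_submodules,
    classify_modularity,
    find_cump_repeats,
    find_module_boundaries,
)
from ciliatemt.synth import SyntheticSpec, generate_mt_gene, _sm1, _sm2


def _module(rng):
    multiset = {}
    return _sm1(rng, multiset) + _sm1(rng, multiset) + _sm2(rng, multiset)


class TestModuleBoundaries:
    def test_three_planted_modules_recovered_at_boundaries(self):
        rng = np.random.default_rng(1)
        mods = [_module(rng) for _ in range(3)]
        linker = "ASKG"
        protein = linker.join(mods)
        found = find_module_boundaries(protein)
        starts = [0]
        for m in mods[:-1]:
            starts.append(starts[-1] + len(m) + len(linker))
        expected = [(s, s + len(m)) for s, m in zip(starts, mods)]
        # module ends are pinned by the terminators; starts may extend a
        # few residues into the preceding linker when still in range
        assert [m.end for m in found] == [e for _, e in expected]
        assert len(found) == 3
        for got, (s, _) in zip(found, expected):
            assert got.start <= s and s - got.start <= 7
        assert all(m.in_range and m.terminator_canonical for m in found)

    def test_decoy_terminator_rejected_for_in_range_segmentation(self):
        # a decoy CXCCK early in the module would split it into two
        # out-of-range pieces; the DP must keep the single in-range module
        rng = np.random.default_rng(2)
        module = _module(rng)
        decoy = "CKCCK"
        protein = decoy + module[len(decoy):]
        assert module[-1] in "KQEN"
        found = find_module_boundaries(protein)
        in_range = [m for m in found if m.in_range]
        assert len(in_range) == 1
        assert in_range[0].end == len(protein)
        # exhaustive check: no candidate subset yields more in-range modules
        assert _best_in_range_bruteforce(protein) == 1

    def test_no_terminator_falls_back_to_single_module(self):
        found = find_module_boundaries("MASKGSTE" * 5)
        assert len(found) == 1 and found[0].warning

    def test_segmentation_tiles_the_sequence(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            protein = generate_mt_gene(
                SyntheticSpec(n_modules=int(rng.integers(2, 6)),
                              utr5_len=0, utr3_len=0,
                              utr5_motifs={}, utr3_motifs={},
                              seed=seed))[1].protein
            found = find_module_boundaries(protein)
            for a, b in zip(found, found[1:]):
                assert a.end <= b.start
            assert found[0].start >= 0 and found[-1].end <= len(protein)


def _best_in_range_bruteforce(protein, config=ModuleConfig()):
    """Max number of in-range modules over all terminator subsets."""
    import itertools
    import re

    ends = [m.start() + 5
            for m in re.finditer(r"(?=C[^C]CC[^C])", protein)]
    lo_m, hi_m = config.module_len
    lo_l, hi_l = config.linker_len
    best = 0
    for r in range(1, len(ends) + 1):
        for subset in itertools.combinations(ends, r):
            count = 0
            prev = None
            ok = True
            for e in subset:
                if prev is None:
                    count += int(e >= lo_m)
                else:
                    gap = e - prev
                    if gap < lo_l + 5:
                        ok = False
                        break
                    count += int(any(lo_m <= gap - l <= hi_m
                                     for l in range(lo_l, hi_l + 1)))
                prev = e
            if ok:
                best = max(best, count)
    return best


class TestSubmodules:
    def test_canonical_module(self):
        rng = np.random.default_rng(4)
        module = _module(rng)
        found = find_module_boundaries(module)
        assert len(found) == 1
        anns = annotate_submodules(found[0], module)
        assert [a.type for a in anns] == ["sm1", "sm1", "sm2"]
        assert found[0].completeness == "canonical"

    def test_sm2_cterm_when_n_half_missing(self):
        rng = np.random.default_rng(5)
        multiset = {}
        sm1 = _sm1(rng, multiset)
        sm2 = _sm2(rng, multiset)
        # strip the C2 X6-8 N-terminal half of sm2 (CC + spacer)
        cterm = sm2[2:]
        while cterm and cterm[0] != "C":
            cterm = cterm[1:]
        module = sm1 + sm1 + cterm
        found = find_module_boundaries(module)
        anns = annotate_submodules(found[0], module)
        assert [a.type for a in anns] == ["sm1", "sm1", "sm2_cterm"]
        assert found[0].completeness == "incomplete"

    def test_random_sequence_is_incomplete(self):
        rng = np.random.default_rng(6)
        pool = "ASKGTE"
        protein = "".join(pool[int(rng.integers(0, 6))] for _ in range(50))
        found = find_module_boundaries(protein)
        annotate_submodules(found[0], protein)
        assert found[0].completeness == "incomplete"


class TestModularity:
    @pytest.mark.parametrize("n,klass", [
        (2, "bi"), (3, "tri"), (4, "tetra"), (5, "penta")])
    def test_class_names(self, n, klass):
        protein = generate_mt_gene(
            SyntheticSpec(n_modules=n, utr5_len=0, utr3_len=0,
                          utr5_motifs={}, utr3_motifs={},
                          seed=100 + n))[1].protein
        modules = find_module_boundaries(protein)
        result = classify_modularity(modules, seq_id="x")
        assert result.n_modules == n and result.klass == klass
        assert all(2 <= l <= 9 for l in result.linker_lengths)


class TestCuRepeats:
    def test_canonical_hit(self):
        hits = find_cump_repeats("CKCAACAC")
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.end) == (0, 8)
        assert hit.is_canonical_K and hit.position2_residue == "K"

    def test_noncanonical_substitution(self):
        (hit,) = find_cump_repeats("CRCAACAC")
        assert not hit.is_canonical_K and hit.position2_residue == "R"

    def test_matches_bruteforce_on_random_sequences(self, rng):
        pool = "CKAGS"
        for _ in range(20):
            protein = "".join(pool[int(rng.integers(0, 5))]
                              for _ in range(200))
            got = [(h.start, h.end) for h in find_cump_repeats(protein)]
            expect = []
            for start in range(len(protein)):
                for gap in range(2, 6):
                    w = protein[start:start + 6 + gap]
                    if len(w) < 6 + gap:
                        continue
                    if (w[0] == "C" and w[2] == "C"
                            and all(c != "C" for c in w[3:3 + gap])
                            and w[3 + gap] == "C" and w[4 + gap] != "C"
                            and w[5 + gap] == "C"):
                        expect.append((start, start + 6 + gap))
            expect.sort()
            assert got == expect
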