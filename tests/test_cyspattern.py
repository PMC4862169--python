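"""Cys-cluster tokenization, classification and censuses."""

import itertools

import pytest

from ciliatemt.cyspattern import (
    ClusterProfile,
    aggregate_profiles,
    classify_cluster,
    classify_subfamily,
    cluster_profile,
    tokenize_clusters,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: literal canonical-pattern set, full
# partition enumeration (no pruning), fewest blocks then longest-first.

_ORACLE_CANONICAL = {
    "C": "XXCXX", "CC": "XCCX", "CXC": "CXC", "CCC": "CCC",
    "CXCC": "CXCC", "CCXC": "CXCC", "CXCXC": "CXCXC",
}


def _oracle_chains(protein):
    cys = [i for i, aa in enumerate(protein) if aa == "C"]
    chains = []
    for i in cys:
        if chains and i - chains[-1][-1] <= 2:
            chains[-1].append(i)
        else:
            chains.append([i])
    return chains


def _chain_pattern(chain):
    return "".join("C" if i in set(chain) else "X"
                   for i in range(chain[0], chain[-1] + 1))


def _oracle_partitions(chain):
    """All splits of a Cys chain into consecutive canonical blocks."""
    if not chain:
        yield []
        return
    for cut in range(1, len(chain) + 1):
        head = chain[:cut]
        if _chain_pattern(head) in _ORACLE_CANONICAL:
            for rest in _oracle_partitions(chain[cut:]):
                yield [head] + rest


def _oracle_types(protein):
    types = []
    for chain in _oracle_chains(protein):
        parts = sorted(
            _oracle_partitions(chain),
            key=lambda blocks: (len(blocks),
                                tuple(-len(b) for b in blocks)))
        assert parts, f"no canonical decomposition for {protein}"
        types.extend(_ORACLE_CANONICAL[_chain_pattern(b)] for b in parts[0])
    return types


class TestTokenize:
    @pytest.mark.parametrize("protein,expected", [
        ("AKCCCKA", [("CCC", "CCC")]),
        ("MCKCM", [("CXC", "CXC")]),
        ("ACCAACGC", [("CC", "XCCX"), ("CXC", "CXC")]),
        ("AAAA", []),
    ])
    def test_examples(self, protein, expected):
        got = [(c.pattern, c.type) for c in tokenize_clusters(protein)]
        assert got == expected

    def test_gap_of_two_splits_chains(self):
        clusters = tokenize_clusters("ACCAACGC")
        assert [(c.start, c.end) for c in clusters] == [(1, 3), (5, 8)]

    def test_every_cys_in_exactly_one_cluster(self, rng):
        pool = "ACKGSE"
        for _ in range(300):
            protein = "".join(pool[int(rng.integers(0, len(pool)))]
                              for _ in range(int(rng.integers(0, 60))))
            clusters = tokenize_clusters(protein)
            assert sum(c.n_cys for c in clusters) == protein.count("C")
            covered = sorted(
                i for c in clusters
                for i in range(c.start, c.end) if protein[i] == "C")
            assert covered == [i for i, aa in enumerate(protein) if aa == "C"]

    def test_exhaustive_oracle_equivalence_short_ac_strings(self):
        for n in range(1, 13):
            for tup in itertools.product("AC", repeat=n):
                protein = "".join(tup)
                got = [c.type for c in tokenize_clusters(protein)]
                assert got == _oracle_types(protein), protein


class TestClassify:
    @pytest.mark.parametrize("pattern,expected", [
        ("C", ["XXCXX"]), ("CC", ["XCCX"]), ("CXC", ["CXC"]),
        ("CCC", ["CCC"]), ("CXCC", ["CXCC"]), ("CCXC", ["CXCC"]),
        ("CXCXC", ["CXCXC"]), ("CCCC", ["CCC", "XXCXX"]),
    ])
    def test_examples(self, pattern, expected):
        assert classify_cluster(pattern) == expected

    def test_super_cluster_decomposition_matches_enumerator(self):
        for pattern in ("CCCC", "CCXCC", "CCCXC", "CXCCXCC", "CCCCCC"):
            chain = [i for i, ch in enumerate(pattern) if ch == "C"]
            parts = sorted(
                _oracle_partitions(chain),
                key=lambda blocks: (len(blocks),
                                    tuple(-len(b) for b in blocks)))
            expected = [_ORACLE_CANONICAL[_chain_pattern(b)]
                        for b in parts[0]]
            assert classify_cluster(pattern) == expected

    def test_malformed_pattern_is_an_error(self):
        with pytest.raises(ValueError):
            classify_cluster("XCC")
        with pytest.raises(ValueError):
            classify_cluster("CAC")


class TestProfile:
    def test_small_peptide(self):
        profile = cluster_profile("CCC" + "A" * 17)
        assert profile.cluster_counts["CCC"] == 1
        assert profile.total_cys == 3 and profile.pct_cys == 15.0

    def test_no_cys(self):
        profile = cluster_profile("A" * 10)
        assert profile.total_cys == 0 and profile.pct_cys == 0.0

    def test_tpyr2_from_counts(self):
        profile = ClusterProfile.from_counts(
            "TpyrMT-2",
            {"CCC": 6, "CXCC": 5, "CXCXC": 0, "XCCX": 6, "CXC": 4,
             "XXCXX": 1},
            length=181)
        assert profile.total_cys == 54
        assert profile.pct_cys == 29.83


class TestAggregate:
    def test_two_groups(self):
        p1 = ClusterProfile.from_counts("a", {"CCC": 2}, 20)
        p2 = ClusterProfile.from_counts("b", {"CXC": 3}, 20)
        table = aggregate_profiles([p1, p2], ["g1", "g2"])
        assert table.loc["g1", "CCC_pct"] == 100.0
        assert table.loc["g2", "CXC_cys"] == 6

    def test_requires_profiles(self):
        with pytest.raises(ValueError):
            aggregate_profiles([])


class TestSubfamilyCall:
    def test_ccc_rich_is_cdmt(self):
        profile = ClusterProfile.from_counts("x", {"CCC": 3, "CXC": 1}, 50)
        assert classify_subfamily(profile).label == "CdMT"

    def test_cxc_dominated_is_cumt(self):
        profile = ClusterProfile.from_counts("x", {"CXC": 12, "XXCXX": 2}, 100)
        assert classify_subfamily(profile).label == "CuMT"

    def test_isolated_cys_only_is_ambiguous(self):
        profile = ClusterProfile.from_counts("x", {"XXCXX": 5}, 50)
        assert classify_subfamily(profile).label == "ambiguous"

    def test_no_cys_warns_ambiguous(self):
        profile = ClusterProfile.from_counts("x", {}, 50)
        call = classify_subfamily(profile)
        assert call.label == "ambiguous" and call.warning
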