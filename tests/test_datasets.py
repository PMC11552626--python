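import numpy as np
import pytest

from ptmtok.alphabet import LabelChannel, build_alphabet, vectorize
from ptmtok.datasets import (
    DatasetError,
    DatasetSplit,
    SiteRecord,
    balance_negatives,
    enumerate_candidates,
    identity_filter,
    monte_carlo_resample,
    split_dataset,
    split_manifest_rows,
)
from conftest import make_window, toy_records


class TestEnumerateCandidates:
    def test_direct_count(self, phospho_alphabet):
        proteins = {"p": "ASTSA"}
        recs = enumerate_candidates(proteins, {"S", "T"}, {("p", 2)}, [], 5,
                                    phospho_alphabet)
        assert [(r.position, r.label) for r in recs] == [(2, 1), (3, 0), (4, 0)]

    def test_empty_positives_all_negative(self, phospho_alphabet):
        recs = enumerate_candidates({"p": "ASTSA"}, {"S", "T"}, set(), [], 5,
                                    phospho_alphabet)
        assert all(r.label == 0 for r in recs)

    def test_positive_on_non_target_error(self, phospho_alphabet):
        with pytest.raises(DatasetError, match="p:1"):
            enumerate_candidates({"p": "ASTSA"}, {"S", "T"}, {("p", 1)}, [], 5,
                                 phospho_alphabet)

    def test_count_matches_bruteforce_scan(self, small_simulation):
        spec, sim = small_simulation
        alphabet = build_alphabet([sim.known_channel])
        recs = enumerate_candidates(sim.proteins, set(spec.residue_targets),
                                    sim.positives, [sim.known_channel], 9,
                                    alphabet)
        # independent oracle: character scan over the raw sequences
        expected = sum(
            seq.count("S") + seq.count("T") for seq in sim.proteins.values()
        )
        assert len(recs) == expected
        assert sum(r.label for r in recs) == len(sim.positives)

    def test_windows_respect_labels_and_masking(self, phospho_alphabet):
        ch = LabelChannel("phospho-ST", frozenset("ST"), {"p": {2, 4}})
        recs = enumerate_candidates({"p": "ASDTK"}, {"S", "T"},
                                    {("p", 2), ("p", 4)}, [ch], 5,
                                    phospho_alphabet)
        by_pos = {r.position: r for r in recs}
        assert by_pos[2].window.tokens == "-ASD&"   # own site masked
        assert by_pos[4].window.tokens == "@DTK-"   # neighbor token visible


class TestBalanceNegatives:
    def test_forced_counts(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=40)
        # toy_records alternates labels; drop negatives to build imbalance
        pos = [r for r in recs if r.label == 1][:10]
        neg = [r for r in recs if r.label == 0]
        out = balance_negatives(pos + neg, seed=0)
        assert sum(r.label for r in out) == 10
        assert sum(1 - r.label for r in out) == 10

    def test_degenerate_branch_keeps_all_negatives(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=28)
        pos = [r for r in recs if r.label == 1]  # 14
        neg = [r for r in recs if r.label == 0][:4]
        out = balance_negatives(pos + neg, seed=0)
        assert len(out) == 18

    def test_deterministic(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=200)
        a = balance_negatives(recs, seed=42)
        b = balance_negatives(recs, seed=42)
        assert [r.key for r in a] == [r.key for r in b]

    def test_zero_positives_error(self, phospho_alphabet):
        neg = [r for r in toy_records(phospho_alphabet, n=20) if r.label == 0]
        with pytest.raises(DatasetError, match="positive"):
            balance_negatives(neg, seed=0)

    def test_skip_flag(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=40)
        assert balance_negatives(recs, seed=0, skip=True) == recs

    def test_prevalence_exactly_half(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=300)
        out = balance_negatives(recs[:10] + recs, seed=1)
        labels = [r.label for r in out]
        assert sum(labels) * 2 == len(labels)


class TestSplitDataset:
    def test_sizes(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=1000)
        split = split_dataset(recs, seed=3)
        n = split.n_total
        assert abs(len(split.validation) - 0.1 * n) <= 2
        assert abs(len(split.test) - 0.1 * n) <= 2
        assert len(split.train) + len(split.validation) + len(split.test) == n

    def test_disjoint_keys(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=300)
        split = split_dataset(recs, seed=3)
        parts = [set(r.key for r in p) for p in split.partitions().values()]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_bad_ratios(self, phospho_alphabet):
        with pytest.raises(DatasetError, match="sum"):
            split_dataset(toy_records(phospho_alphabet, n=50), ratios=(0.7, 0.1, 0.1))

    def test_too_few_records(self, phospho_alphabet):
        with pytest.raises(DatasetError, match="at least"):
            split_dataset(toy_records(phospho_alphabet, n=5))

    def test_no_identical_test_window(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=100)
        # duplicate every window so exact-identity filtering must act
        split = split_dataset(recs + recs, seed=0)
        ref = {r.window.tokens for r in split.train + split.validation}
        assert all(r.window.tokens not in ref for r in split.test)


class TestIdentityFilter:
    def _split_of(self, train, test, alphabet):
        return DatasetSplit(
            train=train, validation=[], test=test, seed=0,
        )

    def _rec(self, tokens, alphabet, pid="p", pos=1, label=0):
        return SiteRecord(pid, pos, tokens[len(tokens) // 2], label,
                          make_window(tokens, alphabet, origin=(pid, pos)))

    def test_exact_duplicate_removed(self, phospho_alphabet):
        r = self._rec("AASAA", phospho_alphabet)
        split = self._split_of([r], [self._rec("AASAA", phospho_alphabet, "q")],
                               phospho_alphabet)
        out = identity_filter(split, 1.0)
        assert out.test == [] and out.n_test_removed_identity == 1

    def test_hand_counted_identity_below_cutoff_retained(self, phospho_alphabet):
        # 53-mer pair differing at 32 positions: identity 21/53 = 0.396 < 0.40
        base = ("ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNA")
        other = list(base)
        for i in range(32):
            other[i] = "W" if base[i] != "W" else "Y"
        other = "".join(other)
        assert sum(a == b for a, b in zip(base, other)) == 21
        split = self._split_of([self._rec(base, phospho_alphabet)],
                               [self._rec(other, phospho_alphabet, "q")],
                               phospho_alphabet)
        out = identity_filter(split, 0.40)
        assert len(out.test) == 1

    def test_quadratic_oracle_agreement(self, phospho_alphabet):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        k = 21
        base = rng.choice(aas, size=k)

        def mutate(n_mut):
            s = base.copy()
            idx = rng.choice(k, size=n_mut, replace=False)
            for i in idx:
                s[i] = rng.choice(aas)
            return "".join(s)

        train = [self._rec(mutate(rng.integers(0, k)), phospho_alphabet, f"t{i}")
                 for i in range(100)]
        test = [self._rec(mutate(rng.integers(0, k)), phospho_alphabet, f"x{i}")
                for i in range(100)]
        split = self._split_of(train, test, phospho_alphabet)
        cutoff = 0.40
        out = identity_filter(split, cutoff)

        # independent O(n^2) python-loop oracle
        def ident(a, b):
            return sum(x == y for x, y in zip(a, b)) / k

        expected = [
            r for r in test
            if all(ident(r.window.tokens, t.window.tokens) < cutoff for t in train)
        ]
        assert [r.key for r in out.test] == [r.key for r in expected]

    def test_monotone_in_cutoff(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=300, k=9)
        split = split_dataset(recs, seed=1)
        kept = []
        for cutoff in (0.3, 0.5, 0.8, 1.0):
            out = identity_filter(split, cutoff)
            kept.append({r.key for r in out.test})
        for smaller, larger in zip(kept, kept[1:]):
            assert smaller <= larger  # lower cutoff removes a superset

    def test_mod_tokens_distinct_in_identity(self, phospho_alphabet):
        a = self._rec("AA@AA", phospho_alphabet, "a", label=1)
        b = self._rec("AASAA", phospho_alphabet, "b")
        split = self._split_of([a], [b], phospho_alphabet)
        # 4/5 = 0.8 identity: removed at 0.8, kept at 0.9
        assert identity_filter(split, 0.9).test == [b]
        assert identity_filter(split, 0.8).test == []

    def test_bad_cutoff(self, phospho_alphabet):
        split = self._split_of([], [], phospho_alphabet)
        for c in (0.0, 1.5, -1):
            with pytest.raises(DatasetError):
                identity_filter(split, c)


class TestMonteCarlo:
    def test_folds_differ(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=400)
        folds = monte_carlo_resample(recs, n_folds=2, seeds=[0, 1])
        t0 = {r.key for r in folds[0].test}
        t1 = {r.key for r in folds[1].test}
        assert t0 != t1

    def test_each_fold_passes_invariants(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=400)
        folds = monte_carlo_resample(recs, n_folds=10)
        for split in folds:
            labels = [r.label for r in split.train + split.validation + split.test]
            assert sum(labels) * 2 == len(labels)  # balanced
            ref = {r.window.tokens for r in split.train + split.validation}
            assert all(r.window.tokens not in ref for r in split.test)

    def test_seed_count_mismatch(self, phospho_alphabet):
        with pytest.raises(DatasetError, match="seeds"):
            monte_carlo_resample(toy_records(phospho_alphabet, n=100),
                                 n_folds=3, seeds=[1])

    def test_manifest_rows(self, phospho_alphabet):
        recs = toy_records(phospho_alphabet, n=100)
        folds = monte_carlo_resample(recs, n_folds=2)
        rows = split_manifest_rows(folds)
        assert {r["fold"] for r in rows} == {0, 1}
        assert {r["partition"] for r in rows} == {"train", "validation", "test"}
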