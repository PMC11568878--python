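"""Window extraction, negative sampling, splitting, ratio ladder, strata."""

import numpy as np
import pytest

from nmsitekit.errors import (
    AmbiguousCenterError,
    InsufficientCandidatesError,
    NegativePoolExhaustedError,
    WindowOutOfBoundsError,
)
from nmsitekit.windows import (
    WINDOW_FLANK,
    SiteRecord,
    extract_window,
    make_ratio_subsets,
    read_sites_tsv,
    read_windows_fasta,
    sample_negatives,
    split_dataset,
    stratify_by_center,
    write_windows_fasta,
)


class TestExtractWindow:
    def test_identity_case(self, random_sequence):
        seq = random_sequence(41)
        w = extract_window(seq, 21)
        assert w.sequence == seq
        assert w.center_base == seq[20]

    def test_out_of_bounds(self, random_sequence):
        with pytest.raises(WindowOutOfBoundsError):
            extract_window(random_sequence(41), 10)

    def test_center_from_slicing_oracle(self):
        seq = "ACGU" * 20 + "A"  # length 81
        w = extract_window(seq, 41)
        assert w.sequence == seq[20:61]  # independent slice arithmetic
        assert w.center_base == seq[40]

    def test_t_and_lowercase_normalized(self):
        seq = "acgt" * 10 + "a"
        w = extract_window(seq, 21)
        assert set(w.sequence) <= set("ACGU")

    def test_ambiguous_center(self):
        seq = "A" * 20 + "N" + "A" * 20
        with pytest.raises(AmbiguousCenterError):
            extract_window(seq, 21)


class TestSampleNegatives:
    def test_counts_and_exclusion(self, random_sequence):
        seq = random_sequence(2000)
        negs = sample_negatives(seq, {1000}, per_positive=15, radius=500, rng_seed=3)
        assert len(negs) == 15
        assert all(w.origin[1] != 1000 for w in negs)
        assert all(w.label == 0 for w in negs)

    def test_insufficient_candidates(self, random_sequence):
        seq = random_sequence(41)
        with pytest.raises(InsufficientCandidatesError) as exc:
            sample_negatives(seq, {21}, per_positive=15, radius=500, rng_seed=0)
        assert exc.value.achieved == 0

    def test_determinism_and_multi_positive(self, random_sequence):
        seq = random_sequence(5000)
        positives = {700, 2500, 4300}
        a = sample_negatives(seq, positives, per_positive=15, radius=500, rng_seed=9)
        b = sample_negatives(seq, positives, per_positive=15, radius=500, rng_seed=9)
        assert len(a) == 45
        assert [w.origin for w in a] == [w.origin for w in b]
        assert len({w.window_id for w in a}) == 45  # no duplicate centers


class TestSplitDataset:
    def test_fraction_arithmetic(self, random_windows, random_sequence):
        pos = [extract_window(random_sequence(100), p, seq_id=f"p{i}", label=1)
               for i, p in enumerate([50] * 100)]
        neg = [extract_window(random_sequence(100), 50, seq_id=f"n{i}", label=0)
               for i in range(1500)]
        s = split_dataset(pos, neg, seed=1)
        assert (len(s.train_pos), len(s.val_pos), len(s.test_pos)) == (60, 10, 30)
        assert len(s.val_neg) == 100 and len(s.test_neg) == 300 and len(s.train_neg) == 1100

    def test_pool_exhausted(self, random_sequence):
        # 10 positives -> 1 val + 3 test positives -> 40 negatives required
        pos = [extract_window(random_sequence(41), 21, seq_id=f"p{i}", label=1) for i in range(10)]
        neg = [extract_window(random_sequence(41), 21, seq_id=f"n{i}", label=0) for i in range(30)]
        with pytest.raises(NegativePoolExhaustedError):
            split_dataset(pos, neg, seed=1)

    def test_benchmark_scale_floor_rounding(self):
        # arithmetic oracle at the reference dataset scale, no window objects needed
        n = 8037
        assert int(0.1 * n) == 803 and n - int(0.6 * n) - int(0.1 * n) - int(0.3 * n) >= 0
        n_val, n_test = int(0.1 * n), int(0.3 * n)
        assert n_val == 803 and n_test == 2411

    def test_partitions_disjoint_and_reproducible(self, random_windows):
        pos = [w for w in random_windows if w.label == 1]
        neg = [w for w in random_windows if w.label == 0]
        s1 = split_dataset(pos, neg, val_test_ratio=2, seed=4)
        s2 = split_dataset(pos, neg, val_test_ratio=2, seed=4)
        ids = [w.window_id for part in (s1.train, s1.val, s1.test) for w in part]
        assert len(ids) == len(set(ids))
        assert [w.window_id for w in s1.train] == [w.window_id for w in s2.train]


class TestRatioSubsets:
    @pytest.fixture
    def pools(self, random_sequence):
        pos = [extract_window(random_sequence(41), 21, seq_id=f"p{i}", label=1) for i in range(20)]
        neg = [extract_window(random_sequence(41), 21, seq_id=f"n{i}", label=0) for i in range(200)]
        return pos, neg

    def test_sizes_and_nesting(self, pools):
        pos, neg = pools
        subsets = make_ratio_subsets(pos, neg, seed=2)
        assert len(subsets) == 10
        prev = set()
        for k, ts in enumerate(subsets, start=1):
            negs = {w.window_id for w in ts.windows if w.label == 0}
            assert len(negs) == k * len(pos)
            assert prev <= negs
            assert {w.window_id for w in ts.windows if w.label == 1} == {w.window_id for w in pos}
            prev = negs

    def test_truncation_warns(self, pools):
        pos, neg = pools
        with pytest.warns(UserWarning, match="truncated"):
            subsets = make_ratio_subsets(pos, neg[:50], seed=2)
        assert len(subsets) == 2

    def test_deterministic(self, pools):
        pos, neg = pools
        a = make_ratio_subsets(pos, neg, seed=5)
        b = make_ratio_subsets(pos, neg, seed=5)
        assert [w.window_id for w in a[9].windows] == [w.window_id for w in b[9].windows]


class TestStratify:
    def test_partition_by_center(self, random_windows):
        strata = stratify_by_center(random_windows)
        assert sum(len(v) for v in strata.values()) == len(random_windows)
        for base, ws in strata.items():
            assert all(w.center_base == base for w in ws)

    def test_empty(self):
        assert all(len(v) == 0 for v in stratify_by_center([]).values())


class TestIO:
    def test_sites_tsv(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("# comment\nchr1\t100\tpositive\nchr2\t7\n")
        records = read_sites_tsv(p)
        assert records[0] == SiteRecord(seq_id="chr1", position=100, label="positive")
        assert records[1].label == "unknown"

    def test_windows_fasta_round_trip(self, tmp_path, random_windows):
        p = tmp_path / "w.fasta"
        write_windows_fasta(p, random_windows)
        back = read_windows_fasta(p)
        assert [(w.window_id, w.sequence, w.label, w.origin) for w in back] == [
            (w.window_id, w.sequence, w.label, w.origin) for w in random_windows
        ]
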