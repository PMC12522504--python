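import numpy as np
import pandas as pd
import pytest

import tfekit as tk
from tfekit.core import SampleSheet
from tfekit.quant import build_count_matrix, call_tfes, dedup_events, extract_five_prime


def make_events(rows):
    """rows: (chrom, pos, strand, umi, sample) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "umi", "sample"])
    df["is_spikein"] = df["chrom"].str.startswith("spike_")
    df["read_id"] = [f"r{i}" for i in range(len(df))]
    return df


class TestExtractFivePrime:
    @pytest.mark.parametrize(
        "blocks,strand,expected",
        [
            ([(100, 150)], "+", 100),
            ([(100, 150)], "-", 149),
            ([(100, 120), (180, 200)], "-", 199),  # spliced: max aligned base
            ([(180, 200), (100, 120)], "+", 100),  # unsorted blocks tolerated
        ],
    )
    def test_strand_convention(self, blocks, strand, expected):
        # oracle: enumerate every aligned base, take the strand-aware extreme
        aligned = [p for s, e in blocks for p in range(s, e)]
        oracle = min(aligned) if strand == "+" else max(aligned)
        assert extract_five_prime(blocks, strand) == expected == oracle

    def test_zero_length_alignment_raises(self):
        with pytest.raises(ValueError):
            extract_five_prime([], "+")
        with pytest.raises(ValueError):
            extract_five_prime([(5, 5)], "+")


class TestDedup:
    def test_exact_copies_collapse(self):
        ev = make_events([("chr1", 100, "+", "ACGT", "s1")] * 3)
        assert len(dedup_events(ev)) == 1

    def test_distinct_umis_survive(self):
        ev = make_events(
            [("chr1", 100, "+", "ACGT", "s1"), ("chr1", 100, "+", "ACGA", "s1")]
        )
        assert len(dedup_events(ev)) == 2

    def test_no_cross_sample_collapse(self):
        ev = make_events(
            [("chr1", 100, "+", "ACGT", "s1"), ("chr1", 100, "+", "ACGT", "s2")]
        )
        out = dedup_events(ev)
        # oracle: the set of distinct key tuples
        key = {tuple(r) for r in ev[["sample", "chrom", "strand", "pos", "umi"]].itertuples(index=False)}
        assert len(out) == len(key) == 2

    def test_order_independence(self, rng):
        rows = [
            ("chr1", int(rng.integers(0, 50)), rng.choice(["+", "-"]),
             rng.choice(["AA", "CC"]), rng.choice(["s1", "s2"]))
            for _ in range(300)
        ]
        ev = make_events(rows)
        shuffled = ev.sample(frac=1, random_state=1).reset_index(drop=True)
        a = dedup_events(ev)[["sample", "chrom", "strand", "pos", "umi"]]
        b = dedup_events(shuffled)[["sample", "chrom", "strand", "pos", "umi"]]
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


def brute_force_clusters(positions, max_gap):
    """Independent oracle: union positions whose pairwise gap <= max_gap,
    transitively (union-find over all pairs)."""
    pos = sorted(positions)
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if abs(pos[i] - pos[j]) <= max_gap:
                pi, pj = find(i), find(j)
                parent[pi] = pj
    groups: dict = {}
    for i, p in enumerate(pos):
        groups.setdefault(find(i), []).append(p)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestCallTfes:
    def test_worked_example(self):
        ev = make_events(
            [("chr1", 100, "+", f"u{i}", "s1") for i in range(3)]
            + [("chr1", 130, "+", f"v{i}", "s1") for i in range(2)]
            + [("chr1", 400, "+", "w0", "s1")]
        )
        regions = call_tfes(ev, min_count=2, max_gap=50)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start"], r["end"], r["summit"], r["count"]) == (100, 131, 100, 5)

    def test_single_event_min_count_one(self):
        ev = make_events([("chr1", 42, "-", "AA", "s1")])
        regions = call_tfes(ev, min_count=1, max_gap=10)
        assert len(regions) == 1
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (42, 43)

    def test_strands_call_separately(self):
        rows = [("chr1", p, st, f"u{p}{st}", "s1")
                for st in "+-" for p in (10, 20, 30)]
        regions = call_tfes(make_events(rows), min_count=2, max_gap=15)
        assert len(regions) == 2
        assert set(regions["strand"]) == {"+", "-"}

    def test_summit_tie_breaks_toward_five_prime(self):
        # equal counts at 10 and 20
        for strand, expected in [("+", 10), ("-", 20)]:
            rows = [("chr1", 10, strand, "a", "s1"), ("chr1", 20, strand, "b", "s1")]
            regions = call_tfes(make_events(rows), min_count=1, max_gap=60)
            assert regions.iloc[0]["summit"] == expected

    def test_empty_input_empty_catalogue(self):
        regions = call_tfes(make_events([]).iloc[:0], min_count=2, max_gap=60)
        assert len(regions) == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(1000):
            n = int(rng.integers(1, 25))
            max_gap = int(rng.integers(0, 8))
            positions = rng.integers(0, 60, size=n)
            rows = [("chr1", int(p), "+", f"u{i}", "s1")
                    for i, p in enumerate(positions)]
            regions = call_tfes(make_events(rows), min_count=1, max_gap=max_gap)
            expected = brute_force_clusters(positions, max_gap)
            got = sorted(
                (int(r["start"]), int(r["end"])) for _, r in regions.iterrows()
            )
            want = sorted((g[0], g[-1] + 1) for g in expected)
            assert got == want, f"trial {trial}"

    def test_permutation_invariance(self, rng):
        rows = [("chr1", int(rng.integers(0, 300)), "+", f"u{i}", "s1")
                for i in range(120)]
        ev = make_events(rows)
        shuffled = ev.sample(frac=1, random_state=2).reset_index(drop=True)
        a = call_tfes(dedup_events(ev))
        b = call_tfes(dedup_events(shuffled))
        pd.testing.assert_frame_equal(a, b)


class TestBuildCountMatrix:
    sheet = SampleSheet({"s1": "GV", "s2": "MII"}, stage_order=("GV", "MII"))

    def _regions(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "summit",
                           "is_spikein", "count"],
        )
        df.index = pd.Index([f"TFE{i+1}" for i in range(len(df))], name="tfe_id")
        return df

    def test_in_region_events_counted(self):
        regions = self._regions([("chr1", 100, 131, "+", 100, False, 4)])
        ev = make_events([("chr1", p, "+", f"u{i}", "s1")
                          for i, p in enumerate((100, 110, 120, 130))])
        matrix, unassigned = build_count_matrix(regions, ev, self.sheet)
        assert matrix.counts.loc["TFE1", "s1"] == 4
        assert unassigned == 0

    def test_half_open_boundary(self):
        regions = self._regions([("chr1", 100, 131, "+", 100, False, 1)])
        ev = make_events([("chr1", 131, "+", "u", "s1")])  # 1 bp past end
        matrix, unassigned = build_count_matrix(regions, ev, self.sheet)
        assert matrix.counts.to_numpy().sum() == 0
        assert unassigned == 1

    def test_unknown_sample_raises(self):
        regions = self._regions([("chr1", 0, 10, "+", 0, False, 1)])
        ev = make_events([("chr1", 5, "+", "u", "sX")])
        with pytest.raises(ValueError, match="sX"):
            build_count_matrix(regions, ev, self.sheet)

    def test_matches_double_loop_oracle(self, rng):
        regions = self._regions(
            [("chr1", s, s + 20, "+", s, False, 0) for s in (0, 50, 100, 150)]
            + [("chr1", 50, 80, "-", 50, False, 0)]
        )
        rows = [
            ("chr1", int(rng.integers(0, 200)), rng.choice(["+", "-"]),
             f"u{i}", rng.choice(["s1", "s2"]))
            for i in range(200)
        ]
        ev = make_events(rows)
        matrix, unassigned = build_count_matrix(regions, ev, self.sheet)
        # O(n*m) oracle
        oracle = np.zeros((len(regions), 2), dtype=int)
        n_out = 0
        for _, e in ev.iterrows():
            hit = False
            for i, (_, r) in enumerate(regions.iterrows()):
                if (e["chrom"] == r["chrom"] and e["strand"] == r["strand"]
                        and r["start"] <= e["pos"] < r["end"]):
                    oracle[i, 0 if e["sample"] == "s1" else 1] += 1
                    hit = True
                    break  # regions are disjoint per strand
            n_out += not hit
        assert (matrix.counts.to_numpy() == oracle).all()
        assert unassigned == n_out

    def test_conservation_of_events(self, small_bundle):
        deduped = dedup_events(small_bundle.events)
        regions = call_tfes(deduped)
        matrix, unassigned = build_count_matrix(regions, deduped,
                                                small_bundle.sheet)
        assert matrix.counts.to_numpy().sum() + unassigned == len(deduped)

    def test_recovers_true_tss_loci(self, small_bundle):
        """With jitter << max_gap, >= 99% of expressed true TSS loci come
        back as exactly one TFE."""
        from conftest import match_tfe

        deduped = dedup_events(small_bundle.events)
        regions = call_tfes(deduped)
        truth = small_bundle.truth
        expressed = truth.genes[truth.stage_means.max(axis=1) > 5]
        hits = [len(match_tfe(regions, row)) for _, row in expressed.iterrows()]
        assert np.mean([h >= 1 for h in hits]) >= 0.99
        assert np.mean([h == 1 for h in hits]) >= 0.99
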