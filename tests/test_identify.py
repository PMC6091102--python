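"""Leave-one-out identification criteria and their summaries."""

import math

import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix
from barcodekit.errors import ThresholdError
from barcodekit.identify import (
    all_species_barcodes,
    best_close_match,
    best_match,
    intraspecific_threshold,
    run_criterion,
    summarize_identification,
)
from oracles import best_match_bruteforce


def make_dm(species, pairs):
    ids = list(species)
    n = len(ids)
    idx = {x: i for i, x in enumerate(ids)}
    v = np.zeros((n, n))
    for (a, b), d in pairs.items():
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = d
    return DistanceMatrix(ids, v, species)


@pytest.fixture
def clean_dm():
    """2 species x 2 identical-within, well separated between."""
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    pairs = {("a1", "a2"): 0.0, ("b1", "b2"): 0.0}
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            pairs[(a, b)] = 0.10
    return make_dm(species, pairs)


class TestBestMatch:
    def test_clean_dataset_all_correct(self, clean_dm):
        outcomes = run_criterion(clean_dm, "best_match")
        s = summarize_identification(outcomes)
        assert (s.pct_correct, s.pct_ambiguous, s.pct_incorrect) == (100.0, 0.0, 0.0)

    def test_heterospecific_nearest_is_incorrect(self):
        dm = make_dm({"a1": "A", "a2": "A", "b1": "B"},
                     {("a1", "a2"): 0.10, ("a1", "b1"): 0.01, ("a2", "b1"): 0.10})
        assert best_match("a1", dm).verdict == "incorrect"

    def test_exact_tie_between_species_is_ambiguous(self):
        dm = make_dm({"q": "A", "a": "A", "b": "B"},
                     {("q", "a"): 0.05, ("q", "b"): 0.05, ("a", "b"): 0.2})
        out = best_match("q", dm)
        assert out.verdict == "ambiguous"
        assert out.nearest_ids == ("a", "b")

    def test_all_undefined_excluded(self):
        dm = make_dm({"q": "A", "a": "A"}, {("q", "a"): math.nan})
        assert best_match("q", dm) is None

    def test_agreement_with_bruteforce_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            ids = [f"r{i}" for i in range(n)]
            species = {i: f"S{rng.integers(0, 4)}" for i in ids}
            pairs = {}
            for i in range(n):
                for j in range(i + 1, n):
                    # coarse grid so exact ties actually occur
                    pairs[(ids[i], ids[j])] = float(rng.integers(1, 6)) / 100.0
            dm = make_dm(species, pairs)
            for q in ids:
                expected = best_match_bruteforce(q, pairs, species)
                got = best_match(q, dm)
                assert (got.verdict if got else "excluded") == expected


class TestThreshold:
    def test_all_zero_intra_gives_zero(self, clean_dm):
        assert intraspecific_threshold(clean_dm) == 0.0

    def test_linear_interpolation_on_1_to_100(self):
        species = {}
        pairs = {}
        # 100 intraspecific distances 1%..100%: 50 species of 2 + padding pair values
        for k in range(100):
            a, b = f"s{k}x", f"s{k}y"
            species[a] = species[b] = f"S{k}"
            pairs[(a, b)] = (k + 1) / 100.0
        # fill unspecified (interspecific) pairs with a constant
        dm_ids = list(species)
        for i in range(len(dm_ids)):
            for j in range(i + 1, len(dm_ids)):
                pairs.setdefault((dm_ids[i], dm_ids[j]), 2.0)
        dm = make_dm(species, pairs)
        assert intraspecific_threshold(dm, 95) == pytest.approx(95.05)
        assert intraspecific_threshold(dm, 100) == pytest.approx(100.0)

    def test_no_intra_pairs_raises(self):
        dm = make_dm({"a": "A", "b": "B"}, {("a", "b"): 0.1})
        with pytest.raises(ThresholdError):
            intraspecific_threshold(dm)


class TestBestCloseMatch:
    def test_conspecific_below_threshold_correct(self, clean_dm):
        assert best_close_match("a1", clean_dm, threshold=5.0).verdict == "correct"

    def test_beyond_threshold_is_no_match(self):
        dm = make_dm({"a1": "A", "a2": "A", "b1": "B"},
                     {("a1", "a2"): 0.08, ("a1", "b1"): 0.2, ("a2", "b1"): 0.2})
        assert best_close_match("a1", dm, threshold=5.0).verdict == "no_match"

    def test_verdict_flips_as_threshold_crosses_distance(self):
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        pairs = {("a1", "a2"): 0.03, ("b1", "b2"): 0.01, ("c1", "c2"): 0.01}
        for x in ("a1", "a2"):
            for y in ("b1", "b2", "c1", "c2"):
                pairs[(x, y)] = 0.2
        for x in ("b1", "b2"):
            for y in ("c1", "c2"):
                pairs[(x, y)] = 0.2
        dm = make_dm(species, pairs)
        assert best_close_match("a1", dm, threshold=4.0).verdict == "correct"
        assert best_close_match("a1", dm, threshold=2.0).verdict == "no_match"

    def test_infinite_threshold_equals_best_match(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 10))
            ids = [f"r{i}" for i in range(n)]
            species = {i: f"S{rng.integers(0, 3)}" for i in ids}
            pairs = {(ids[i], ids[j]): float(rng.integers(0, 8)) / 50.0
                     for i in range(n) for j in range(i + 1, n)}
            dm = make_dm(species, pairs)
            for q in ids:
                bm = best_match(q, dm)
                bcm = best_close_match(q, dm, threshold=math.inf)
                assert (bm is None) == (bcm is None)
                if bm is not None:
                    assert bcm.verdict == bm.verdict

    def test_raising_threshold_recovers_best_match_verdict(self):
        dm = make_dm({"a1": "A", "a2": "A", "b1": "B"},
                     {("a1", "a2"): 0.08, ("a1", "b1"): 0.2, ("a2", "b1"): 0.2})
        verdicts = [best_close_match("a1", dm, t).verdict for t in (1.0, 8.0, 50.0)]
        assert verdicts == ["no_match", "correct", "correct"]


class TestAllSpeciesBarcodes:
    def test_coherent_species_cluster_correct(self):
        species = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        pairs = {("a1", "a2"): 0.0, ("a1", "a3"): 0.0, ("a2", "a3"): 0.0}
        for a in ("a1", "a2", "a3"):
            pairs[(a, "b1")] = 0.3
        dm = make_dm(species, pairs)
        assert all_species_barcodes("a1", dm, threshold=50.0).verdict == "correct"

    def test_straggler_conspecific_makes_incorrect(self):
        # a2 is farther from the query than the heterospecific b1
        species = {"a1": "A", "a2": "A", "b1": "B"}
        pairs = {("a1", "a2"): 0.15, ("a1", "b1"): 0.05, ("a2", "b1"): 0.2}
        dm = make_dm(species, pairs)
        assert all_species_barcodes("a1", dm, threshold=50.0).verdict == "incorrect"

    def test_singleton_species_excluded(self):
        dm = make_dm({"a1": "A", "b1": "B", "b2": "B"},
                     {("a1", "b1"): 0.1, ("a1", "b2"): 0.1, ("b1", "b2"): 0.0})
        assert all_species_barcodes("a1", dm, threshold=50.0) is None

    def test_decisive_tie_is_ambiguous(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        pairs = {("a1", "a2"): 0.05, ("a1", "b1"): 0.05, ("a2", "b1"): 0.2}
        dm = make_dm(species, pairs)
        assert all_species_barcodes("a1", dm, threshold=50.0).verdict == "ambiguous"


class TestSummaries:
    def test_hand_tally(self, clean_dm):
        outcomes = run_criterion(clean_dm, "best_close_match", threshold=50.0)
        s = summarize_identification(outcomes)
        assert s.n_queried == 4
        assert s.pct_correct + s.pct_ambiguous + s.pct_incorrect + s.pct_no_match == pytest.approx(100.0)

    def test_all_no_match(self):
        dm = make_dm({"a1": "A", "a2": "A"}, {("a1", "a2"): 0.4})
        s = summarize_identification(run_criterion(dm, "best_close_match", threshold=1.0))
        assert (s.pct_correct, s.pct_no_match) == (0.0, 100.0)

    def test_percentages_always_sum_to_100(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            ids = [f"r{i}" for i in range(n)]
            species = {i: f"S{rng.integers(0, 3)}" for i in ids}
            pairs = {(ids[i], ids[j]): float(rng.uniform(0, 0.2))
                     for i in range(n) for j in range(i + 1, n)}
            dm = make_dm(species, pairs)
            for crit in ("best_match", "best_close_match"):
                try:
                    s = summarize_identification(run_criterion(dm, crit, threshold=5.0))
                except ValueError:
                    continue
                total = s.pct_correct + s.pct_ambiguous + s.pct_incorrect + s.pct_no_match
                assert total == pytest.approx(100.0)
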