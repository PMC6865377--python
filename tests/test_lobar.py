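"""Cluster extraction, overlap rules, and cohort rates."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from mp2vbm.lobar import (FindingRecord, apply_brain_rule, classify_findings,
                          concordant_discordant_ratio, concordant_rate,
                          corrected_specificity, discordant_rate,
                          extract_clusters, lobe_concordance_census, specificity)


def _offsets(connectivity):
    out = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(x) for x in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        out.append(d)
    return out


def flood_fill_components(binary, connectivity):
    """Brute-force BFS connected components, the oracle for extract_clusters."""
    offsets = _offsets(connectivity)
    seen = np.zeros(binary.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        queue, comp = deque([start]), []
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for d in offsets:
                w = tuple(a + b for a, b in zip(v, d))
                if all(0 <= x < s for x, s in zip(w, binary.shape)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestExtractClusters:
    def test_empty_below_threshold(self, rng):
        t = rng.normal(0, 1, (6, 6, 6))
        assert extract_clusters(t, threshold=10.0) == []

    def test_cube_is_single_cluster(self):
        t = np.zeros((7, 7, 7))
        t[2:5, 2:5, 2:5] = 5.0
        clusters = extract_clusters(t, threshold=4.0)
        assert len(clusters) == 1 and clusters[0].size == 27
        assert clusters[0].peak_t == 5.0

    def test_diagonal_pair_depends_on_connectivity(self):
        t = np.zeros((5, 5, 5))
        t[1, 1, 1] = t[2, 2, 2] = 3.0
        assert len(extract_clusters(t, 2.0, connectivity=26)) == 1
        assert len(extract_clusters(t, 2.0, connectivity=6)) == 2

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError):
            extract_clusters(np.zeros((3, 3, 3)), 1.0, connectivity=10)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        field = rng.random((8, 8, 8))
        threshold = 0.7
        clusters = extract_clusters(field, threshold, connectivity)
        got = {frozenset(map(tuple, c.indices)) for c in clusters}
        want = flood_fill_components(field >= threshold, connectivity)
        assert got == want

    def test_monotone_suppression_without_brain_rule(self, rng):
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.normal(0, 1, (12, 12, 12)), 1.5)
        sizes_prev = None
        for threshold in np.linspace(0.0, 0.15, 6):
            total = sum(c.size for c in extract_clusters(field, threshold))
            if sizes_prev is not None:
                assert total <= sizes_prev
            sizes_prev = total


class TestBrainRule:
    def _cluster_with_fraction(self, n_inside, n_total):
        t = np.zeros((40, 3, 3))
        t[:n_total, 1, 1] = 5.0
        brain = np.zeros_like(t, dtype=bool)
        brain[:n_inside, 1, 1] = True
        clusters = extract_clusters(t, 4.0, connectivity=6)
        assert len(clusters) == 1
        return apply_brain_rule(clusters, brain)

    def test_fully_inside_kept(self):
        assert len(self._cluster_with_fraction(30, 30)) == 1

    def test_boundary_exactly_one_third_kept(self):
        assert len(self._cluster_with_fraction(10, 30)) == 1

    def test_below_one_third_dropped(self):
        assert len(self._cluster_with_fraction(9, 30)) == 0

    def test_empty_input(self):
        assert apply_brain_rule([], np.ones((3, 3, 3), dtype=bool)) == []


@pytest.fixture(scope="module")
def atlas32():
    from mp2vbm.phantom import make_atlas

    return make_atlas((32, 36, 32), voxel_size=2.0)


def _cluster_in(atlas, lobes_with_counts, peak=5.0):
    """Build a t-field whose single cluster covers given per-lobe voxel counts."""
    t = np.zeros(atlas.labels.shape)
    chunks = []
    for lobe, count in lobes_with_counts.items():
        coords = np.argwhere(atlas.labels == lobe)[:count]
        assert len(coords) == count
        chunks.append(coords)
    for c in np.concatenate(chunks):
        t[tuple(c)] = peak
    return extract_clusters(t, 4.0, connectivity=26)


class TestClassifyFindings:
    def test_cluster_inside_hypothesis_lobe(self, atlas32):
        # a compact in-lobe blob: carve from one lobe only
        t = np.zeros(atlas32.labels.shape)
        coords = np.argwhere(atlas32.labels == 3)
        t[tuple(coords[:40].T)] = 6.0
        clusters = extract_clusters(t, 4.0)
        rec = classify_findings(clusters, atlas32, {3})
        assert rec.concordant and rec.any_finding
        # every cluster lies wholly in lobe 3, so nothing is discordant
        assert not rec.discordant

    def test_split_cluster_sets_both_flags(self, atlas32):
        # one artificial cluster with 40%/60% of voxels in two lobes would
        # need adjacency; equivalent: two clusters, one per rule
        t = np.zeros(atlas32.labels.shape)
        t[tuple(np.argwhere(atlas32.labels == 1)[:30].T)] = 5.0
        t[tuple(np.argwhere(atlas32.labels == 6)[:30].T)] = 5.0
        clusters = extract_clusters(t, 4.0)
        rec = classify_findings(clusters, atlas32, {1})
        assert rec.concordant and rec.discordant

    def test_control_any_cluster_is_discordant(self, atlas32):
        t = np.zeros(atlas32.labels.shape)
        t[tuple(np.argwhere(atlas32.labels == 5)[:20].T)] = 5.0
        rec = classify_findings(extract_clusters(t, 4.0), atlas32, frozenset())
        assert rec.discordant and not rec.concordant and rec.any_finding

    def test_unknown_lobe_rejected(self, atlas32):
        with pytest.raises(ValueError):
            classify_findings([], atlas32, {12})

    def test_lobe_fractions_sum_to_one(self, atlas32):
        t = np.zeros(atlas32.labels.shape)
        t[tuple(np.argwhere(atlas32.labels == 2)[:25].T)] = 5.0
        rec = classify_findings(extract_clusters(t, 4.0), atlas32, {2})
        for cl in rec.clusters:
            total = sum(cl.lobe_fractions.values()) + cl.out_of_atlas_fraction
            assert total == pytest.approx(1.0)


def _records(flags):
    return [FindingRecord(str(i), c, d, c or d or a)
            for i, (c, d, a) in enumerate(flags)]


class TestRates:
    def test_concordant_rate_table_granularity(self):
        recs = _records([(True, False, False)] * 10 + [(False, False, False)] * 6)
        assert concordant_rate(recs) == 62.5

    def test_extremes(self):
        none = _records([(False, False, False)] * 5)
        assert concordant_rate(none) == 0.0
        assert discordant_rate(_records([(False, True, False)] * 16)) == 100.0

    def test_discordant_rounding(self):
        recs = _records([(False, True, False)] * 15 + [(False, False, False)])
        assert discordant_rate(recs) == 93.8

    def test_rates_invariant_to_order(self, rng):
        flags = [(bool(rng.integers(2)), bool(rng.integers(2)), False)
                 for _ in range(20)]
        recs = _records(flags)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert concordant_rate(recs) == concordant_rate(shuffled)
        assert discordant_rate(recs) == discordant_rate(shuffled)

    def test_specificity_31_controls(self):
        clean = [FindingRecord(str(i), False, False, False) for i in range(14)]
        dirty = [FindingRecord(str(i), False, True, True) for i in range(17)]
        assert specificity(clean + dirty) == 45.2

    def test_specificity_extremes(self):
        assert specificity(_records([(False, False, False)] * 3)) == 100.0
        assert specificity(_records([(False, True, False)] * 31)) == 0.0

    def test_empty_rejected(self):
        for fn in (concordant_rate, discordant_rate, specificity):
            with pytest.raises(ValueError):
                fn([])


class TestCorrectedSpecificity:
    @pytest.mark.parametrize("unclear, expected",
                             [(48.4, 51.6), (64.5, 35.5), (0.0, 100.0)])
    def test_values(self, unclear, expected):
        assert corrected_specificity(unclear) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            corrected_specificity(120.0)


class TestLobeCensus:
    def test_published_cohort_counts(self):
        assert concordant_discordant_ratio(27, 101) == 0.27

    def test_single_lobe_hypotheses(self):
        n_con, n_disc, ratio = lobe_concordance_census([{1}] * 16)
        assert (n_con, n_disc, ratio) == (16, 112, 0.14)

    def test_all_lobes_hypothesized_is_degenerate(self):
        with pytest.raises(ValueError):
            lobe_concordance_census([set(range(1, 9))] * 4)

    def test_unknown_lobe_rejected(self):
        with pytest.raises(ValueError):
            lobe_concordance_census([{11}])
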