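"""ROC biomarker selection, spread extension, correlation."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from epiremodel import biomarker as bm
from epiremodel import simulate as sim
from epiremodel.io import SampleSheet
from epiremodel.stats import auc_mann_whitney


@pytest.fixture(scope="module")
def candidate_regions(genome, probe_layout):
    regions = []
    for isl in genome.islands:
        member = bm.probes_in_region(probe_layout.probe_ids,
                                     probe_layout.probes, isl)
        if member:
            regions.append((isl, member))
    return regions


class TestDifferentialProbes:
    def test_null_calibration(self, probe_layout):
        truth0 = sim.SimulationTruth()
        betas, sheet = sim.simulate_beta_matrix(probe_layout, truth0,
                                                seed=31)
        res = bm.differential_probes(betas, sheet, ("group", "tumour"),
                                     ("group", "normal"))
        raw = float((res["p"] < 0.05).mean())
        assert 0.01 <= raw <= 0.10
        assert (res["padj"] < 0.05).mean() <= 0.01

    def test_recovers_implanted_marker_probes(self, beta_data, truth,
                                              probe_layout):
        betas, sheet = beta_data
        res = bm.differential_probes(betas, sheet, ("group", "tumour"),
                                     ("group", "normal"))
        marker_probes = bm.probes_in_region(
            probe_layout.probe_ids, probe_layout.probes,
            truth.tumour_markers[0])
        for iv in truth.tumour_markers[1:]:
            marker_probes += bm.probes_in_region(
                probe_layout.probe_ids, probe_layout.probes, iv)
        frac = float(res.loc[marker_probes, "hyper"].mean())
        assert frac >= 0.9

    def test_extreme_betas_finite(self):
        m = bm.beta_to_m(np.array([0.0, 1.0, 0.5]))
        assert np.all(np.isfinite(m))

    def test_requires_four_per_class(self, probe_layout):
        truth0 = sim.SimulationTruth()
        betas, sheet = sim.simulate_beta_matrix(probe_layout, truth0, seed=1)
        small = SampleSheet(sheet.table.iloc[:6].copy())
        with pytest.raises(ValueError):
            bm.differential_probes(betas[small.ids()], small,
                                   ("group", "tumour"), ("group", "normal"))


class TestRegionScore:
    def test_single_probe_passthrough(self, beta_data):
        betas, _ = beta_data
        pid = betas.index[0]
        score = bm.region_score(betas, [pid])
        assert np.allclose(score.to_numpy(), betas.loc[pid].to_numpy())

    def test_mean_of_two(self):
        betas = pd.DataFrame({"s": [0.2, 0.4]}, index=["p1", "p2"])
        assert bm.region_score(betas, ["p1", "p2"])["s"] == pytest.approx(0.3)

    def test_matches_brute_force(self, beta_data):
        betas, _ = beta_data
        probes = list(betas.index[5:12])
        score = bm.region_score(betas, probes)
        assert np.allclose(score.to_numpy(),
                           betas.loc[probes].to_numpy().mean(axis=0))


class TestStratifiedSplit:
    def test_deterministic(self, beta_data):
        _, sheet = beta_data
        labels = sheet.table.set_index("sample_id")["group"]
        assert bm.stratified_split(labels, seed=3) == \
            bm.stratified_split(labels, seed=3)
        assert bm.stratified_split(labels, seed=3) != \
            bm.stratified_split(labels, seed=4)

    def test_degenerate_fraction_rejected(self, beta_data):
        _, sheet = beta_data
        labels = sheet.table.set_index("sample_id")["group"]
        with pytest.raises(ValueError):
            bm.stratified_split(labels, train_fraction=1.0)

    def test_both_classes_in_both_cohorts(self, beta_data):
        _, sheet = beta_data
        labels = sheet.table.set_index("sample_id")["group"]
        train, test = bm.stratified_split(labels, seed=0)
        for cohort in (train, test):
            assert {"tumour", "normal"} <= set(labels[cohort])


class TestRocSelect:
    def test_markers_selected_nulls_not(self, beta_data, truth,
                                        candidate_regions):
        betas, sheet = beta_data
        cands = bm.roc_select(betas, sheet, candidate_regions, seed=5)
        spread = set(truth.spread_probes)
        marker_found = {
            i for i, m in enumerate(truth.tumour_markers)
            if any(c.region.overlaps(m) for c in cands)
        }
        assert len(marker_found) == len(truth.tumour_markers)
        for c in cands:
            assert c.test_auc >= 0.95
            is_marker = any(c.region.overlaps(m)
                            for m in truth.tumour_markers)
            assert is_marker or (set(c.probes) & spread)

    def test_deterministic_under_seed(self, beta_data, candidate_regions):
        betas, sheet = beta_data
        c1 = bm.roc_select(betas, sheet, candidate_regions, seed=6)
        c2 = bm.roc_select(betas, sheet, candidate_regions, seed=6)
        assert [(str(c.region), c.test_auc) for c in c1] == \
            [(str(c.region), c.test_auc) for c in c2]

    def test_basal_path_requires_basal_hypermethylation(self, beta_data,
                                                        truth,
                                                        candidate_regions):
        betas, sheet = beta_data
        cands = bm.roc_select(betas, sheet, candidate_regions,
                              comparison="basal_vs_other_tumours", seed=7)
        assert cands, "implanted basal markers should be found"
        for c in cands:
            assert c.test_auc >= 0.7
        found = {i for i, m in enumerate(truth.basal_markers)
                 if any(c.region.overlaps(m) for c in cands)}
        assert len(found) == len(truth.basal_markers)

    def test_region_auc_matches_oracle(self, beta_data, candidate_regions):
        betas, sheet = beta_data
        labels = sheet.table.set_index("sample_id")["group"]
        region, probes = candidate_regions[0]
        score = bm.region_score(betas, probes)
        pos = score[labels[labels == "tumour"].index]
        neg = score[labels[labels == "normal"].index]
        auc = auc_mann_whitney(pos.to_numpy(), neg.to_numpy())
        brute = np.mean([
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg])
        assert auc == pytest.approx(brute)

    def test_no_information_leak_from_test_cohort(self, beta_data,
                                                  candidate_regions, truth):
        betas, sheet = beta_data
        labels = sheet.table.set_index("sample_id")["group"]
        train, test = bm.stratified_split(labels, seed=8)

        def train_state(frame):
            sub = SampleSheet(
                sheet.table[sheet.table["sample_id"].isin(train)].copy())
            stats = bm.differential_probes(frame[train], sub,
                                           ("group", "tumour"),
                                           ("group", "normal"))
            scored = []
            for region, probes in candidate_regions:
                score = bm.region_score(frame[train], probes)
                pos = score[[s for s in train if labels[s] == "tumour"]]
                neg = score[[s for s in train if labels[s] == "normal"]]
                scored.append((str(region),
                               auc_mann_whitney(pos.to_numpy(),
                                                neg.to_numpy())))
            blob = repr((stats.round(12).to_dict(), scored)).encode()
            return hashlib.sha256(blob).hexdigest()

        scrambled = betas.copy()
        rng = np.random.default_rng(9)
        scrambled[test] = rng.uniform(size=scrambled[test].shape)
        assert train_state(betas) == train_state(scrambled)


class TestSpreadExtend:
    def _stats_and_cohorts(self, betas, sheet, seed=10):
        labels = sheet.table.set_index("sample_id")["group"]
        train, test = bm.stratified_split(labels, seed=seed)
        sub = SampleSheet(
            sheet.table[sheet.table["sample_id"].isin(train)].copy())
        stats = bm.differential_probes(betas[train], sub,
                                       ("group", "tumour"),
                                       ("group", "normal"))
        return stats, train, test

    def test_captures_implanted_spread_and_is_idempotent(
            self, beta_data, truth, probe_layout, candidate_regions):
        betas, sheet = beta_data
        stats, train, test = self._stats_and_cohorts(betas, sheet)
        cands = bm.roc_select(betas, sheet, candidate_regions, seed=10)
        marker_cands = [c for c in cands if any(
            c.region.overlaps(m) for m in truth.tumour_markers)]
        captured = set()
        for c in marker_cands:
            ext = bm.spread_extend(c, betas, probe_layout.probe_ids,
                                   probe_layout.probes, stats, sheet,
                                   train, test)
            again = bm.spread_extend(ext, betas, probe_layout.probe_ids,
                                     probe_layout.probes, stats, sheet,
                                     train, test)
            assert ext.extended_probes == again.extended_probes
            assert ext.extended_test_auc >= c.test_auc - 0.05
            captured |= set(ext.extended_probes) - set(c.probes)
        assert captured & set(truth.spread_probes)

    def test_gap_rule(self):
        # significant at index 0..2 (region), 3 (adjacent), then a 2-gap,
        # then 6: with max_gap 1 only probe 3 is captured
        from epiremodel.intervals import GenomicInterval, IntervalSet

        n = 8
        ids = [f"p{i}" for i in range(n)]
        probes = IntervalSet([GenomicInterval("c", 100 * i, 100 * i + 2)
                              for i in range(n)])
        stats = pd.DataFrame({
            "padj": [0.001] * 4 + [0.9, 0.9, 0.001, 0.9],
            "delta_beta": [0.4] * 4 + [0.0, 0.0, 0.4, 0.0],
        }, index=ids)
        rng = np.random.default_rng(0)
        cols = {}
        rows = []
        for i in range(20):
            rows.append((f"T{i}", "NA", "NA", "NA", "tumour", "NA"))
        for i in range(10):
            rows.append((f"N{i}", "NA", "NA", "NA", "normal", "NA"))
        sheet = SampleSheet(pd.DataFrame(
            rows, columns=["sample_id", "donor", "condition", "timepoint",
                           "group", "subtype"]))
        for sid in sheet.ids():
            cols[sid] = rng.uniform(0, 1, n)
        betas = pd.DataFrame(cols, index=ids)
        cand = bm.RocCandidate(GenomicInterval("c", 0, 202),
                               ["p0", "p1", "p2"], 1.0, 1.0,
                               "tumour_vs_normal")
        train = sheet.ids(group="tumour")[:15] + sheet.ids(group="normal")[:7]
        test = sheet.ids(group="tumour")[15:] + sheet.ids(group="normal")[7:]
        ext = bm.spread_extend(cand, betas, ids, probes, stats, sheet,
                               train, test, max_gap_probes=1)
        assert ext.extended_probes == ["p0", "p1", "p2", "p3"]

    def test_no_adjacent_significant_region_unchanged(
            self, beta_data, probe_layout, candidate_regions):
        betas, sheet = beta_data
        stats, train, test = self._stats_and_cohorts(betas, sheet)
        # a background region: no neighbouring probe is hypermethylated
        null_stats = stats.copy()
        null_stats["padj"] = 1.0
        region, probes = candidate_regions[0]
        cand = bm.RocCandidate(region, probes, 0.5, 0.5, "tumour_vs_normal")
        ext = bm.spread_extend(cand, betas, probe_layout.probe_ids,
                               probe_layout.probes, null_stats, sheet,
                               train, test)
        assert set(ext.extended_probes) == set(probes)


class TestCorrelation:
    def test_exact_linear_relation_r2_one(self, beta_data):
        betas, _ = beta_data
        probes = list(betas.index[:3])
        score = bm.region_score(betas, probes)
        expr = 2.0 * score + 1.0
        _, r2 = bm.methylation_expression_correlation(betas, expr, probes)
        assert r2 == pytest.approx(1.0)

    def test_independent_near_zero(self, beta_data):
        betas, _ = beta_data
        rng = np.random.default_rng(12)
        r2s = []
        for i in range(100):
            pid = betas.index[i]
            expr = pd.Series(rng.normal(size=betas.shape[1]),
                             index=betas.columns)
            per_probe, _ = bm.methylation_expression_correlation(
                betas, expr, [pid])
            r2s.append(per_probe[pid])
        assert np.mean(r2s) <= 0.05

    def test_constant_expression_zero(self, beta_data):
        betas, _ = beta_data
        expr = pd.Series(1.0, index=betas.columns)
        _, r2 = bm.methylation_expression_correlation(
            betas, expr, [betas.index[0]])
        assert r2 == 0.0
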