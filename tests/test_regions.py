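"""Region-wise scanning: per-region scores, argmax assignment, selections."""

import math

import numpy as np
import pandas as pd
import pytest

from fpfinder import (ConfigError, PresenceMatrix, RegionScoreTable,
                      SampleManifest, ScoringConfig, assign_enriched_region,
                      compare_enriched_groups, score_by_region, score_sites,
                      select_region_specific, trim_low_specificity)

FULL = ScoringConfig(background_mode="full-cohort")


def region_manifest(sizes: dict[str, int]) -> SampleManifest:
    samples, regions = [], {}
    for lab, n in sizes.items():
        for i in range(n):
            name = f"{lab}{i}"
            samples.append(name)
            regions[name] = lab
    return SampleManifest(samples=samples,
                          roles={s: "background" for s in samples},
                          regions=regions)


def matrix_from_rows(rows, samples):
    n = len(rows)
    sites = pd.DataFrame({"chrom": "A01", "pos": range(10, 10 * (n + 1), 10),
                          "ref": "A", "alt": "G"})
    return PresenceMatrix(sites=sites, samples=list(samples),
                          values=np.array(rows, dtype=bool))


class TestScoreByRegion:
    def test_region_exclusive_site_scores_only_there(self):
        manifest = region_manifest({"A": 2, "B": 2, "C": 2})
        m = matrix_from_rows([[1, 1, 0, 0, 0, 0],  # only region A
                              [1, 1, 1, 1, 1, 1],  # everywhere
                              [0, 0, 0, 0, 0, 0]], manifest.samples)
        table = score_by_region(m, manifest, FULL)
        expected_a = 1.0 * math.log10(7 / 3)  # tf 1 in A, idf over 6-sample cohort
        assert table.scores.loc[0, "A"] == pytest.approx(expected_a)
        assert table.scores.loc[0, "B"] == 0.0
        assert table.enriched_region[0] == "A"
        # ubiquitous and absent rows score 0 in every region
        assert (table.scores.loc[1] == 0.0).all()
        assert (table.scores.loc[2] == 0.0).all()

    def test_matches_single_population_scoring_per_region(self):
        # each region column must equal a full-cohort score_sites run with
        # that region's samples as the target set
        rng = np.random.default_rng(3)
        manifest = region_manifest({"N": 4, "S": 3, "YZ": 5})
        m = matrix_from_rows(rng.random((30, 12)) < 0.4, manifest.samples)
        table = score_by_region(m, manifest, FULL)
        for lab in table.regions:
            roles = {s: ("target" if manifest.regions.get(s) == lab else "background")
                     for s in manifest.samples}
            single = score_sites(m, SampleManifest(samples=manifest.samples, roles=roles),
                                 FULL)
            np.testing.assert_allclose(table.scores[lab], single["score"], atol=1e-12)

    def test_region_label_permutation_permutes_columns(self):
        rng = np.random.default_rng(4)
        manifest = region_manifest({"A": 3, "B": 3})
        vals = rng.random((20, 6)) < 0.5
        m = matrix_from_rows(vals, manifest.samples)
        t1 = score_by_region(m, manifest, FULL)
        swapped = SampleManifest(
            samples=manifest.samples, roles=manifest.roles,
            regions={s: {"A": "B", "B": "A"}[r] for s, r in manifest.regions.items()})
        t2 = score_by_region(m, swapped, FULL)
        np.testing.assert_allclose(t1.scores["A"], t2.scores["B"], atol=0)
        np.testing.assert_allclose(t1.scores["B"], t2.scores["A"], atol=0)

    def test_single_region_rejected(self):
        manifest = region_manifest({"A": 4})
        m = matrix_from_rows([[1, 0, 0, 1]], manifest.samples)
        with pytest.raises(ConfigError):
            score_by_region(m, manifest, FULL)


class TestEnrichedRegion:
    def make_table(self, score_rows, regions=("N", "YZ")):
        n = len(score_rows)
        sites = pd.DataFrame({"chrom": "A01", "pos": range(1, n + 1),
                              "ref": "A", "alt": "G"})
        return RegionScoreTable(sites=sites,
                                scores=pd.DataFrame(score_rows, columns=list(regions)))

    def test_argmax_and_tie_flag(self):
        table = self.make_table([[0.1, 0.3], [0.2, 0.2], [0.0, 0.0]])
        out = assign_enriched_region(table)
        assert list(out["enriched_region"]) == ["YZ", "N", "N"]  # ties lexicographic
        assert list(out["tied"]) == [False, True, True]
        assert list(out["max_score"]) == [0.3, 0.2, 0.0]


class TestTrimAndSelect:
    def test_trim_boundary_inclusive(self):
        t = TestEnrichedRegion().make_table([[0.05, 0.01], [0.1, 0.0], [0.25, 0.2]])
        kept = trim_low_specificity(t, 0.1)
        assert len(kept.sites) == 2
        assert trim_low_specificity(t, 0.0).sites.shape == t.sites.shape

    def test_trim_above_global_max_warns_and_empties(self):
        t = TestEnrichedRegion().make_table([[0.05, 0.01]])
        with pytest.warns(UserWarning):
            assert len(trim_low_specificity(t, 1.0).sites) == 0

    def test_select_top_fraction_nearest_rank(self):
        rng = np.random.default_rng(8)
        scores = rng.permutation(1000) / 1000.0
        t = TestEnrichedRegion().make_table(
            np.column_stack([scores, scores]).tolist())
        sel = select_region_specific(t, 0.001)
        for lab in ("N", "YZ"):
            assert len(sel[lab]) == 1
            assert sel[lab]["score"].iloc[0] == scores.max()
        # identical columns -> identical selections
        pd.testing.assert_frame_equal(sel["N"], sel["YZ"])

    def test_boundary_ties_all_included(self):
        col = [0.9] * 3 + [0.1] * 97  # top 1% boundary is tied three ways
        t = TestEnrichedRegion().make_table(np.column_stack([col, col]).tolist())
        sel = select_region_specific(t, 0.01)
        assert len(sel["N"]) == 3

    def test_at_least_ceil_fraction_per_region(self):
        rng = np.random.default_rng(12)
        for frac in (0.001, 0.01, 0.13):
            n = int(rng.integers(50, 400))
            t = TestEnrichedRegion().make_table(rng.random((n, 2)).tolist())
            sel = select_region_specific(t, frac)
            for lab in ("N", "YZ"):
                assert len(sel[lab]) >= math.ceil(frac * n)


class TestGroupComparison:
    def make_table(self):
        sites = pd.DataFrame({"chrom": "A01", "pos": range(1, 7),
                              "ref": "A", "alt": "G"})
        scores = pd.DataFrame({"A": [0.5, 0.6, 0.7, 0.1, 0.1, 0.1],
                               "B": [0.1, 0.1, 0.1, 0.5, 0.6, 0.7]})
        return RegionScoreTable(sites=sites, scores=scores)

    def functional(self, effects=(1, 2, 3, 4, 5, 6)):
        return pd.DataFrame({"chrom": "A01", "pos": range(1, 7),
                             "ref": "A", "alt": "G", "effect": effects})

    def test_group_means(self):
        gc = compare_enriched_groups(self.functional(), self.make_table(), pair=("A", "B"))
        summary = gc.summary.set_index("region")
        assert summary.loc["A", "mean_effect"] == 2.0
        assert summary.loc["B", "mean_effect"] == 5.0
        assert summary.loc["A", "n"] == 3
        assert gc.pvalue is not None and 0 <= gc.pvalue <= 1

    def test_unresolved_sites_reported_not_dropped_silently(self):
        func = self.functional()
        func.loc[0, "pos"] = 999
        gc = compare_enriched_groups(func, self.make_table())
        assert len(gc.unresolved) == 1
        assert gc.summary["n"].sum() == 5

    def test_positive_effect_filter(self):
        gc = compare_enriched_groups(self.functional((-1, -2, 3, 4, 5, 6)),
                                     self.make_table(), positive_effects_only=True)
        assert gc.summary["n"].sum() == 4

    def test_unknown_region_in_pair_rejected(self):
        with pytest.raises(ConfigError, match="XX"):
            compare_enriched_groups(self.functional(), self.make_table(),
                                    pair=("A", "XX"))
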