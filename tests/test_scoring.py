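"""Score arithmetic, filters, anchored normalization, categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from mave_scorer import constants as C
from mave_scorer.scoring import (
    abundance_raw,
    aggregate_to_variants,
    annotate_variants,
    categorize,
    competitive_index,
    exclude_drug_residues,
    filter_low_coverage,
    function_raw,
    merge_replicates,
    normalize_replicate,
    score_assay,
    zone_of,
)
from tests.conftest import make_variant_counts


class TestAggregate:
    BARCODE_MAP = pd.DataFrame(
        {"barcode": ["AAA", "AAC", "AAG"], "variant": ["A2C", "A2C", "A3G"],
         "support": [5, 5, 5]}
    )

    def test_pooling_sums_barcodes(self):
        counts = make_variant_counts(
            {"AAA": {"bin1": 5.0}, "AAC": {"bin1": 7.0}, "AAG": {"bin1": 8.0}}
        )
        out = aggregate_to_variants(counts, self.BARCODE_MAP)
        wide = out.set_index("entity_id")["rpm"]
        # 12 and 8 RPM pooled, then renormalized to a million total
        assert np.isclose(wide["A2C"], 1e6 * 12 / 20)
        assert np.isclose(wide["A3G"], 1e6 * 8 / 20)

    def test_single_variant_gets_full_million(self):
        counts = make_variant_counts({"AAA": {"bin1": 3.0, "bin2": 9.0}})
        out = aggregate_to_variants(counts, self.BARCODE_MAP.iloc[:1])
        assert np.allclose(out["rpm"], 1e6)

    def test_matches_groupby_oracle(self, default_barcodes, default_truth,
                                    default_config):
        from mave_scorer.simulate import simulate_facs

        counts = simulate_facs(
            default_truth.head(50),
            default_config.with_(n_cells=100_000, reads_per_sample=200_000),
            replicate_seed=3,
            barcodes=default_barcodes[
                default_barcodes["variant"].isin(default_truth.head(50)["variant"])
            ].reset_index(drop=True),
        )
        counts["replicate"] = 1
        bc_map = default_barcodes.rename(columns={"weight": "support"})
        out = aggregate_to_variants(counts, bc_map)
        # brute-force oracle: python-dict accumulation then renormalize
        lookup = dict(zip(bc_map["barcode"], bc_map["variant"]))
        acc: dict = {}
        for row in counts.itertuples(index=False):
            v = lookup.get(row.entity_id)
            if v is not None:
                acc[(v, row.sample)] = acc.get((v, row.sample), 0.0) + row.rpm
        totals: dict = {}
        for (v, s), rpm in acc.items():
            totals[s] = totals.get(s, 0.0) + rpm
        for row in out.itertuples(index=False):
            expected = 1e6 * acc[(row.entity_id, row.sample)] / totals[row.sample]
            assert np.isclose(row.rpm, expected)

    def test_empty_intersection_errors(self):
        counts = make_variant_counts({"TTT": {"bin1": 5.0}})
        with pytest.raises(ValueError):
            aggregate_to_variants(counts, self.BARCODE_MAP)


class TestAbundanceRaw:
    @pytest.mark.parametrize(
        "bins, expected",
        [
            ((10, 0, 0, 0), 0.0),
            ((0, 0, 0, 10), 3.0),
            ((1, 2, 3, 4), 2.0),
            ((5, 5, 5, 5), 1.5),
        ],
    )
    def test_weighted_bin_examples(self, bins, expected):
        counts = make_variant_counts(
            {"A2C": dict(zip(("bin1", "bin2", "bin3", "bin4"), bins))}
        )
        out = abundance_raw(counts)
        assert np.isclose(out.iloc[0]["raw"], expected)
        assert np.isclose(out.iloc[0]["mean_rpm"], sum(bins) / 4)

    def test_all_zero_variant_dropped(self):
        counts = make_variant_counts(
            {"A2C": {"bin1": 0.0, "bin2": 0.0, "bin3": 0.0, "bin4": 0.0},
             "A3C": {"bin1": 1.0, "bin2": 0.0, "bin3": 0.0, "bin4": 0.0}}
        )
        out = abundance_raw(counts)
        assert list(out["variant"]) == ["A3C"]

    def test_negative_counts_rejected(self):
        counts = make_variant_counts(
            {"A2C": {"bin1": -1.0, "bin2": 0.0, "bin3": 0.0, "bin4": 1.0}}
        )
        with pytest.raises(ValueError):
            abundance_raw(counts)

    def test_matches_bruteforce_on_random_tables(self, rng):
        f = rng.uniform(0, 1000, size=(500, 4))
        rows = []
        for i in range(500):
            for k in range(4):
                rows.append(
                    {"entity_id": f"A{i+2}C", "sample": f"bin{k+1}",
                     "replicate": 1, "rpm": f[i, k]}
                )
        out = abundance_raw(pd.DataFrame(rows)).set_index("variant")
        for i in range(500):
            expected = sum(k * f[i, k] for k in range(4)) / f[i].sum()
            assert np.isclose(out.loc[f"A{i+2}C", "raw"], expected)

    def test_monotone_under_upward_mass_shift(self, rng):
        # moving reads from a lower bin to a higher bin never decreases W
        base = rng.uniform(1, 100, size=4)
        counts = make_variant_counts(
            {"A2C": dict(zip(("bin1", "bin2", "bin3", "bin4"), base))}
        )
        w0 = abundance_raw(counts).iloc[0]["raw"]
        shifted = base.copy()
        shifted[0] -= 0.5
        shifted[3] += 0.5
        counts2 = make_variant_counts(
            {"A2C": dict(zip(("bin1", "bin2", "bin3", "bin4"), shifted))}
        )
        assert abundance_raw(counts2).iloc[0]["raw"] >= w0


class TestFunctionRaw:
    @pytest.mark.parametrize(
        "f0, f28, expected",
        [
            (100.0, 100.0, 0.0),
            (0.0, 0.0, 0.0),       # pseudocount symmetry
            (30.0, 150.0, 2.0),    # log2(160/40)
        ],
    )
    def test_log_ratio_examples(self, f0, f28, expected):
        counts = make_variant_counts({"A2C": {"day0": f0, "day28": f28}})
        out = function_raw(counts)
        assert np.isclose(out.iloc[0]["raw"], expected)
        assert np.isclose(out.iloc[0]["mean_rpm"], f0)

    def test_matches_bruteforce_on_random_tables(self, rng):
        f = rng.uniform(0, 2000, size=(500, 2))
        rows = []
        for i in range(500):
            rows.append({"entity_id": f"A{i+2}C", "sample": "day0",
                         "replicate": 1, "rpm": f[i, 0]})
            rows.append({"entity_id": f"A{i+2}C", "sample": "day28",
                         "replicate": 1, "rpm": f[i, 1]})
        out = function_raw(pd.DataFrame(rows)).set_index("variant")
        for i in range(500):
            expected = np.log2((f[i, 1] + 10) / (f[i, 0] + 10))
            assert np.isclose(out.loc[f"A{i+2}C", "raw"], expected)


class TestFilters:
    def test_abundance_strictly_below_25_removed(self):
        raw = pd.DataFrame(
            {"variant": ["A2C", "A3C", "A4C"], "replicate": [1, 1, 1],
             "raw": [1.0, 1.0, 1.0], "mean_rpm": [24.9, 25.0, 26.0]}
        )
        out = filter_low_coverage(raw, "abundance")
        assert list(out["variant"]) == ["A3C", "A4C"]

    def test_function_less_than_15_removed_15_retained(self):
        raw = pd.DataFrame(
            {"variant": ["A2C", "A3C"], "replicate": [1, 1],
             "raw": [0.0, 0.0], "mean_rpm": [14.99, 15.0]}
        )
        out = filter_low_coverage(raw, "function")
        assert list(out["variant"]) == ["A3C"]

    def test_mixed_table_matches_oracle(self, rng):
        raw = pd.DataFrame(
            {
                "variant": [f"A{i+2}C" for i in range(200)],
                "replicate": rng.integers(1, 4, 200),
                "raw": rng.normal(size=200),
                "mean_rpm": rng.uniform(0, 50, 200),
            }
        )
        out = filter_low_coverage(raw, "abundance")
        expected = {
            (r.variant, r.replicate)
            for r in raw.itertuples()
            if not r.mean_rpm < 25.0
        }
        got = set(zip(out["variant"], out["replicate"]))
        assert got == expected


def _raw_table(values: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": list(values),
            "replicate": 1,
            "raw": list(values.values()),
            "mean_rpm": 100.0,
        }
    )


class TestNormalize:
    # synonymous raws around 2.4, early-nonsense raws around 0.3
    BASE = {
        "A2=": 2.4, "A3=": 2.5, "A4=": 2.3,
        "A5*": 0.3, "A6*": 0.2, "A7*": 0.4,
        "A8C": 1.35,
    }

    def test_anchor_examples(self):
        out = normalize_replicate(_raw_table(self.BASE), "function")
        scores = out.set_index("variant")["score"]
        assert np.isclose(scores["A5*"], 0.0)   # at nonsense median
        assert np.isclose(scores["A2="], 1.0)   # at synonymous median
        assert np.isclose(scores["A8C"], 0.5)   # (1.35-0.3)/(2.4-0.3)

    def test_het_abundance_anchors_zero_raw(self):
        out = normalize_replicate(_raw_table(self.BASE), "het_abundance")
        scores = out.set_index("variant")["score"]
        assert np.isclose(scores["A2="], 1.0)
        assert np.isclose(scores["A8C"], 1.35 / 2.4)

    def test_affine_invariance(self):
        # any positive affine transform of raw scores normalizes identically
        base = normalize_replicate(_raw_table(self.BASE), "function")
        shifted = {k: 3.7 * v + 11.0 for k, v in self.BASE.items()}
        other = normalize_replicate(_raw_table(shifted), "function")
        assert np.allclose(
            base.sort_values("variant")["score"],
            other.sort_values("variant")["score"],
        )

    def test_function_assay_excludes_mid_gene_nonsense_anchor(self):
        # a nonsense variant inside the excluded 239-307 window must not
        # move the anchor in the function assays
        values = dict(self.BASE)
        values["A250*"] = 99.0  # wild outlier inside excluded window
        out = normalize_replicate(_raw_table(values), "function")
        scores = out.set_index("variant")["score"]
        assert np.isclose(scores["A5*"], 0.0)
        out_ab = normalize_replicate(_raw_table(values), "abundance")
        # in the abundance assay the outlier does shift the nonsense median
        assert not np.isclose(
            out_ab.set_index("variant")["score"]["A5*"], 0.0
        )

    def test_missing_anchor_class_errors(self):
        no_syn = {k: v for k, v in self.BASE.items() if not k.endswith("=")}
        with pytest.raises(ValueError, match="synonymous"):
            normalize_replicate(_raw_table(no_syn), "function")
        no_nons = {k: v for k, v in self.BASE.items() if not k.endswith("*")}
        with pytest.raises(ValueError, match="nonsense"):
            normalize_replicate(_raw_table(no_nons), "function")

    def test_zone_wise_normalization(self):
        # two zones with different raw scales converge after zone-wise anchors
        zone1 = {"A2=": 2.0, "A3=": 2.0, "A5*": 0.5, "A10C": 1.25}
        zone2 = {"A300=": 4.0, "A301=": 4.0, "A302*": 1.0, "A310C": 2.5}
        raw = _raw_table({**zone1, **zone2})
        out = normalize_replicate(raw, "abundance", by_zone=True)
        scores = out.set_index("variant")["score"]
        assert np.isclose(scores["A10C"], 0.5)
        assert np.isclose(scores["A310C"], 0.5)


class TestMerge:
    def test_mean_and_sem(self):
        norm = pd.DataFrame(
            {
                "variant": ["A2C", "A2C"] + ["A3=", "A3="] * 6 + ["A5*", "A5*"],
                "replicate": [1, 2] * 8,
                "score": [0.9, 1.1] + [1.0, 1.0] * 6 + [0.0, 0.0],
            }
        )
        out = merge_replicates(norm, "function", sem_cutoff=None)
        row = out.set_index("variant").loc["A2C"]
        assert np.isclose(row["score"], 1.0)
        assert np.isclose(row["sem"], 0.1)
        assert row["n_reps"] == 2

    def test_sem_cutoff_removes_noisy(self):
        norm = pd.DataFrame(
            {
                "variant": ["A2C", "A2C"] + ["A3=", "A3="] * 6 + ["A5*", "A5*"],
                "replicate": [1, 2] * 8,
                "score": [0.0, 2.0] + [1.0, 1.0] * 6 + [0.0, 0.0],
            }
        )
        out = merge_replicates(norm, "function", sem_cutoff=0.5)
        assert "A2C" not in set(out["variant"])

    def test_final_anchoring_exact(self, default_scoresets):
        # after merge + renormalization the medians sit exactly on (0, 1)
        for assay, result in default_scoresets.items():
            df = result.scores
            syn = df.loc[df["consequence"] == "synonymous", "score"]
            assert abs(syn.median() - 1.0) < 1e-9, assay
            if assay == "het_abundance":
                continue
            lo, hi = C.EARLY_NONSENSE_RANGE
            nons = df[(df["consequence"] == "nonsense")
                      & df["position"].between(lo, hi)]
            if assay in ("function", "het_function"):
                xlo, xhi = C.FUNCTION_NONSENSE_EXCLUDED_RANGE
                nons = nons[~nons["position"].between(xlo, xhi)]
            assert abs(nons["score"].median()) < 1e-9, assay


class TestCategorize:
    def _scores(self, extra: dict[str, float]) -> pd.DataFrame:
        rng = np.random.default_rng(1)
        syn = {f"A{i}=": s for i, s in
               enumerate(rng.normal(1.0, 0.12, 40), start=2)}
        return pd.DataFrame(
            {"variant": list(syn) + list(extra),
             "score": list(syn.values()) + list(extra.values())}
        )

    def test_rule_examples(self):
        df, (lower, upper) = categorize(
            self._scores({"A100C": 1.0, "A101C": 2.0, "A102C": 0.5,
                          "A103C": 0.1, "A104C": 0.25})
        )
        cat = df.set_index("variant")["category"]
        assert 0.25 < lower < 1.0 < upper < 2.0
        assert cat["A100C"] == "normal"
        assert cat["A101C"] == "gain"
        assert cat["A102C"] == "partial_loss"
        assert cat["A103C"] == "loss"
        assert cat["A104C"] == "partial_loss"  # boundary: exactly 0.25

    def test_matches_bruteforce_oracle(self, rng):
        extra = {f"A{i}C": s for i, s in
                 enumerate(rng.uniform(-0.2, 1.8, 150), start=100)}
        df, (lower, upper) = categorize(self._scores(extra))
        for row in df.itertuples():
            s = row.score
            if s > upper:
                expected = "gain"
            elif s >= lower:
                expected = "normal"
            elif s >= 0.25:
                expected = "partial_loss"
            else:
                expected = "loss"
            assert row.category == expected

    def test_too_few_synonymous_errors(self):
        df = pd.DataFrame({"variant": ["A2=", "A3C"], "score": [1.0, 0.5]})
        with pytest.raises(ValueError, match="synonymous"):
            categorize(df)

    def test_degenerate_bounds_error(self):
        rng = np.random.default_rng(0)
        syn = {f"A{i}=": s for i, s in
               enumerate(rng.normal(0.3, 0.3, 40), start=2)}
        df = pd.DataFrame({"variant": list(syn), "score": list(syn.values())})
        with pytest.raises(ValueError, match="degenerate"):
            categorize(df)


class TestDrugResidues:
    SCORES = pd.DataFrame(
        {"variant": ["W248L", "F335=", "W248*", "A100C"],
         "score": [0.1, 1.0, 0.0, 1.0]}
    )

    def test_missense_at_drug_residues_removed_from_function(self):
        out = exclude_drug_residues(self.SCORES, "function")
        assert set(out["variant"]) == {"F335=", "W248*", "A100C"}

    def test_abundance_untouched(self):
        out = exclude_drug_residues(self.SCORES, "abundance")
        assert set(out["variant"]) == set(self.SCORES["variant"])


class TestCompetitiveIndex:
    @pytest.mark.parametrize(
        "args, expected",
        [((100, 100, 50, 50), 100.0),
         ((100, 50, 50, 50), 50.0),
         ((200, 60, 100, 90), 100 * 0.3 / 0.9)],
    )
    def test_examples(self, args, expected):
        assert np.isclose(competitive_index(*args), expected)

    def test_zero_day0_errors(self):
        with pytest.raises(ValueError):
            competitive_index(0, 10, 100, 90)


class TestZones:
    def test_partition(self):
        assert zone_of(1) == 1
        assert zone_of(236) == 1
        assert zone_of(237) == 2
        assert zone_of(394) == 2
        assert zone_of(395) == 3
        assert zone_of(676) == 3


class TestPipelineRecovery:
    def test_function_scores_recover_latents(self, default_scoresets,
                                             default_truth):
        sc = default_scoresets["function"].scores.merge(default_truth,
                                                        on="variant")
        rho = spearmanr(sc["score"], sc["latent_function"]).statistic
        assert rho >= 0.9

    def test_lof_near_zero_synonymous_near_one(self, default_scoresets,
                                               default_truth):
        sc = default_scoresets["function"].scores.merge(default_truth,
                                                        on="variant")
        by = sc.groupby("archetype")["score"].mean()
        assert abs(by["synonymous-like"] - 1.0) < 0.1
        assert by["missense-LOF"] < 0.15
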