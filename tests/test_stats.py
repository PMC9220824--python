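import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from isletpulse.stats import (
    abundance_screen, anova_posthoc, column_normalize, scale_rows_to_100,
    sidak_adjust,
)
from isletpulse.synthetic import channel_groups, make_abundance_table


class TestSidak:
    def test_closed_form(self):
        p = np.array([0.001, 0.01, 0.05, 0.5])
        adj = sidak_adjust(p, 6)
        assert np.allclose(adj, 1.0 - (1.0 - p) ** 6)

    def test_scalar_and_clamping(self):
        assert sidak_adjust(0.5, 10) == pytest.approx(1.0 - 0.5**10)
        assert sidak_adjust(1.0, 3) == 1.0
        assert sidak_adjust(0.0, 3) == 0.0
        with pytest.raises(ValueError):
            sidak_adjust(0.1, 0)

    def test_never_below_raw(self):
        p = 1e-300
        assert sidak_adjust(p, 12) >= p


def _two_way_records(seed=0, effect=0.3):
    rng = np.random.default_rng(seed)
    rows = []
    for g, delta in (("control", 0.0), ("knockout", effect)):
        for conc in (3.0, 6.0, 9.0):
            for i in range(8):
                rows.append({
                    "group": g, "concentration": conc,
                    "value": conc / 10 + delta + rng.normal(0, 0.1),
                })
    return pd.DataFrame(rows)


class TestAnovaPosthoc:
    def test_two_way_sidak_structure(self):
        res = anova_posthoc(_two_way_records(), "value",
                            ["group", "concentration"], posthoc="sidak")
        comp = res.comparisons
        assert len(comp) == 3  # one comparison per concentration
        m = 3
        assert np.allclose(comp["p_adj"],
                           1.0 - (1.0 - comp["p_raw"]) ** m)
        assert {"C(Q('group'))", "C(Q('concentration'))"} <= {
            ix.strip() for ix in res.anova_table.index
        }

    def test_two_way_detects_group_effect(self):
        res = anova_posthoc(_two_way_records(effect=0.5), "value",
                            ["group", "concentration"])
        assert (res.comparisons["p_adj"] < 0.01).all()

    def test_tukey_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 12),
            "value": np.concatenate([
                rng.normal(0.0, 1.0, 12),
                rng.normal(0.8, 1.0, 12),
                rng.normal(0.3, 1.0, 12),
            ]),
        })
        res = anova_posthoc(df, "value", ["g"], posthoc="tukey")
        ref = pairwise_tukeyhsd(df["value"], df["g"])
        assert np.allclose(
            np.sort(res.comparisons["p_adj"].to_numpy()),
            np.sort(np.asarray(ref.pvalues, dtype=float)),
            atol=1e-6,
        )

    def test_tukey_requires_one_factor(self):
        with pytest.raises(ValueError, match="one-way"):
            anova_posthoc(_two_way_records(), "value",
                          ["group", "concentration"], posthoc="tukey")

    def test_empty_cell_raises(self):
        df = _two_way_records()
        df = df[~((df.group == "knockout") & (df.concentration == 9.0))]
        with pytest.raises(ValueError, match="empty design cells"):
            anova_posthoc(df, "value", ["group", "concentration"])


class TestNormalisation:
    def test_column_sums_equalised(self, abundance_fixture):
        table, _ = abundance_fixture
        norm = column_normalize(table)
        sums = norm.sum(axis=0).to_numpy()
        assert np.allclose(sums, sums[0])

    def test_row_scaling_exact(self, abundance_fixture):
        table, _ = abundance_fixture
        scaled = scale_rows_to_100(column_normalize(table))
        assert np.allclose(scaled.sum(axis=1).to_numpy(), 100.0)

    def test_nonpositive_rejected(self):
        bad = pd.DataFrame({"c1": [1.0, -2.0], "c2": [1.0, 1.0]})
        with pytest.raises(ValueError, match="positive"):
            column_normalize(bad)


class TestScreen:
    def test_hits_recover_planted_directions(self, abundance_fixture):
        table, truth = abundance_fixture
        result = abundance_screen(table, channel_groups(table))
        planted_up = set(truth.loc[truth.direction == "up", "protein"])
        planted_down = set(truth.loc[truth.direction == "down", "protein"])
        # no cross-direction mistakes
        assert not planted_up & set(result.down)
        assert not planted_down & set(result.up)
        # false positives among nulls controlled by BH at 5%
        nulls = set(truth.loc[truth.direction == "null", "protein"])
        fp = (set(result.up) | set(result.down)) & nulls
        assert len(fp) <= 0.05 * len(truth) + 3

    def test_requires_two_groups(self, abundance_fixture):
        table, _ = abundance_fixture
        groups = {c: "a" for c in table.columns}
        with pytest.raises(ValueError, match="two groups"):
            abundance_screen(table, groups)

    def test_unmapped_channel_rejected(self, abundance_fixture):
        table, _ = abundance_fixture
        groups = channel_groups(table)
        groups.pop(table.columns[0])
        with pytest.raises(ValueError, match="without a group"):
            abundance_screen(table, groups)

    def test_fold_change_orientation(self):
        table, truth = make_abundance_table(
            80, planted_up=8, planted_down=8, seed=9, noise_sd=0.02
        )
        result = abundance_screen(table, channel_groups(table))
        merged = result.results.merge(truth, on="protein")
        up = merged[merged.direction == "up"]
        down = merged[merged.direction == "down"]
        assert (up.fold_change > 1).all()
        assert (down.fold_change < 1).all()
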