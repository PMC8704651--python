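import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from brainlayers.group_stats import (
    StatReport,
    bh_adjust,
    electrode_posthoc,
    games_howell,
    key_electrodes,
    manova_electrodes,
    metrics_to_table,
    paired_t_fdr,
    pooled_anova,
)
from brainlayers.single_layer import NodeMetrics


def make_table(rng, n_rec=18, n_classes=4, electrodes=8, metric="x",
               band="beta", shift=None):
    """Long metric table of iid normal values; ``shift`` maps
    (electrode_index, class) -> mean offset."""
    rows = []
    for r in range(n_rec):
        for c in range(1, n_classes + 1):
            vals = rng.standard_normal(electrodes)
            if shift:
                for (e_idx, cls), d in shift.items():
                    if cls == c:
                        vals[e_idx] += d
            for e in range(electrodes):
                rows.append(
                    dict(recording_id=r, class_label=c, band=band,
                         electrode=f"e{e:02d}", metric=metric, value=vals[e])
                )
    return pd.DataFrame(rows)


class TestMetricsToTable:
    def test_long_format_columns_and_values(self):
        nm = NodeMetrics(values=np.array([1.0, 2.0]), metric="degree",
                         band="beta", class_label=2, recording_id=7,
                         channel_labels=("C3", "Cz"))
        table = metrics_to_table([nm])
        assert list(table.columns) == [
            "recording_id", "class_label", "band", "electrode", "metric", "value"
        ]
        assert table.loc[table.electrode == "Cz", "value"].item() == 2.0


class TestPooledAnova:
    def test_identical_class_distributions_give_f0_p1(self, rng):
        vals = rng.standard_normal(20)
        rows = [
            dict(recording_id=i, class_label=c, band="multilayer",
                 electrode="e", metric="x", value=v)
            for c in range(1, 5) for i, v in enumerate(vals)
        ]
        rep = pooled_anova(pd.DataFrame(rows), "x")
        assert rep.statistic == 0.0
        assert rep.p == 1.0

    def test_strong_shift_detected(self, rng):
        table = make_table(rng, shift={(e, 1): 5.0 for e in range(8)})
        rep = pooled_anova(table, "x")
        assert rep.p < 1e-6
        assert rep.significant

    def test_undersized_class_rejected(self, rng):
        table = make_table(rng, n_rec=1, electrodes=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            pooled_anova(table, "x")


class TestManova:
    def test_planted_effect_detected(self, rng):
        table = make_table(rng, shift={(3, 1): 2.5})
        rep = manova_electrodes(table, "x", "beta")
        assert rep.test == "manova"
        assert rep.significant
        assert rep.p < 0.01

    def test_null_data_mostly_accepted(self, rng):
        rejections = sum(
            manova_electrodes(make_table(rng), "x", "beta").significant
            for _ in range(30)
        )
        assert rejections <= 6  # ~alpha = 0.05

    def test_constant_data_rejected_as_singular(self):
        rows = [
            dict(recording_id=r, class_label=c, band="beta", electrode=f"e{e}",
                 metric="x", value=1.0)
            for r in range(10) for c in (1, 2) for e in range(3)
        ]
        with pytest.raises(ValueError, match="singular"):
            manova_electrodes(pd.DataFrame(rows), "x", "beta")

    def test_compositional_metric_reduced_not_rejected(self, rng):
        """A metric normalized across electrodes (rows sum to 1, like
        PageRank) has an exactly singular covariance; the test must still
        run on a reduced response set."""
        table = make_table(rng, electrodes=6)
        wide = table.pivot_table(index=["recording_id", "class_label"],
                                 columns="electrode", values="value")
        wide = wide.sub(wide.min(axis=1), axis=0)
        wide = wide.div(wide.sum(axis=1), axis=0)
        long = wide.stack().reset_index().rename(columns={0: "value"})
        long["band"] = "multilayer"
        long["metric"] = "pr"
        rep = manova_electrodes(long, "pr", "multilayer")
        assert "linear dependency" in rep.note
        assert np.isfinite(rep.p)

    def test_error_df_must_exceed_responses(self, rng):
        table = make_table(rng, n_rec=3, electrodes=20)
        with pytest.raises(ValueError, match="degrees of freedom"):
            manova_electrodes(table, "x", "beta")


class TestGamesHowell:
    def test_two_groups_equal_welch_t_test(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(20) * 2.0 + 0.8
        (_, t, df, p, _), = games_howell([a, b])
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(abs(t_ref), abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_identical_pair_not_significant(self, rng):
        g = rng.standard_normal(18)
        out = games_howell([g, g.copy(), g + 3.0, g - 3.0])
        p12 = next(p for (pair, t, df, p, _) in out if pair == (1, 2))
        assert p12 > 0.999

    def test_matches_pingouin_reference(self, rng):
        groups = [rng.standard_normal(18) + mu for mu in (0.0, 0.4, 1.0, 1.1)]
        ours = games_howell(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat([1, 2, 3, 4], 18),
        })
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for (pair, t, dof, p, _), (_, row) in zip(ours, ref.iterrows()):
            assert pair == (row["A"], row["B"])
            assert t == pytest.approx(abs(row["T"]), abs=1e-9)
            assert dof == pytest.approx(row["df"], abs=1e-9)
            assert p == pytest.approx(row["pval"], abs=1e-6)

    def test_degenerate_groups_raise_by_default(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            games_howell([np.ones(5), np.full(5, 2.0)])

    def test_degenerate_groups_resolved_on_request(self):
        out = games_howell([np.ones(5), np.full(5, 2.0), np.ones(5)],
                           on_degenerate="resolve")
        by_pair = {pair: (p, note) for pair, _, _, p, note in out}
        assert by_pair[(1, 2)][0] == 0.0
        assert by_pair[(1, 3)][0] == 1.0


class TestElectrodePosthoc:
    def test_planted_electrode_flagged_with_correct_pair(self, rng):
        table = make_table(rng, shift={(2, 1): 3.0})
        reports = electrode_posthoc(table, "x", "beta")
        gh_sig = [r for r in reports if r.test == "games_howell" and r.significant]
        assert gh_sig, "no significant pairwise comparisons found"
        assert "e02" in {r.scope["electrode"] for r in gh_sig}
        e02 = [r for r in gh_sig if r.scope["electrode"] == "e02"]
        assert all(1 in r.comparison for r in e02)
        # the planted electrode carries the strongest evidence
        assert min(r.p for r in e02) == min(r.p for r in gh_sig)

    def test_gate_blocks_chain_when_manova_null(self, rng):
        table = make_table(rng)
        reports = electrode_posthoc(table, "x", "beta")
        if not reports[0].significant:  # typical case under the null
            assert len(reports) == 1


class TestPairedTFdr:
    def test_bh_stepup_textbook_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_equal_inputs_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_bh_adjusted_dominates_raw_and_preserves_order(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_paired_chain_flags_shifted_class(self, rng):
        table = make_table(rng, band="multilayer",
                           shift={(e, 2): 1.5 for e in range(8)})
        reports = paired_t_fdr(table, "x", "multilayer")
        assert len(reports) == 6
        sig = {r.comparison for r in reports if r.significant}
        assert {(1, 2), (2, 3), (2, 4)} <= sig
        for r in reports:
            assert r.p_adjusted >= r.p - 1e-12

    def test_zero_variance_pair_reported_with_warning(self, rng):
        table = make_table(rng)
        # class 2 duplicates class 1 exactly -> zero-variance differences
        dup = table[table.class_label == 1].copy()
        dup["class_label"] = 2
        table = pd.concat([table[table.class_label != 2], dup])
        with pytest.warns(UserWarning, match="zero-variance"):
            reports = paired_t_fdr(table, "x")
        p12 = next(r for r in reports if r.comparison == (1, 2))
        assert p12.p == 1.0

    def test_unpairable_observations_rejected(self, rng):
        table = make_table(rng)
        table = table[~((table.recording_id == 0) & (table.class_label == 3)
                        & (table.electrode == "e00"))]
        with pytest.raises(ValueError, match="unpairable|missing"):
            paired_t_fdr(table, "x")


class TestKeyElectrodes:
    @staticmethod
    def _gh(electrode, metric, significant):
        return StatReport(
            test="games_howell",
            scope={"metric": metric, "band": "beta", "electrode": electrode},
            statistic=3.0, df=(30.0,), p=0.01 if significant else 0.5,
            significant=significant, comparison=(1, 2),
        )

    def test_two_metric_rule(self):
        reports = [
            self._gh("C3", "degree", True),
            self._gh("C3", "eigenvector", True),
            self._gh("Cz", "degree", True),
            self._gh("POz", "degree", False),
        ]
        assert key_electrodes(reports) == ["C3"]

    def test_repeated_hits_in_one_metric_do_not_count_twice(self):
        reports = [self._gh("C3", "degree", True)] * 5
        assert key_electrodes(reports) == []
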