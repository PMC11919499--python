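"""Normalization ladder, Mann-Whitney U, stars and correlation profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from slowcodon.stats import (
    correlation_profile,
    fold_change,
    mannwhitney_u,
    normalize_per_cell,
    rnai_relative_fc,
    significance_stars,
    summarize,
)


def fit_row(cell, channel, delta, m0ktl=10.0, construct="eGFP",
            sirna="siCtrl", converged=True, non_expressing=False):
    return {
        "cell_id": cell, "channel": channel, "delta_hat": delta,
        "m0ktl_hat": m0ktl, "converged": converged,
        "non_expressing": non_expressing, "construct": construct,
        "sirna": sirna, "cell_line": "A549", "experiment": "e1",
    }


class TestNormalizePerCell:
    def test_identical_channels_give_unity(self):
        fits = pd.DataFrame([
            fit_row("c1", "eGFP", 0.2), fit_row("c1", "CayRFP", 0.2),
        ])
        cells, dropped = normalize_per_cell(fits)
        assert cells["tau_n"].iloc[0] == pytest.approx(1.0)
        assert cells["k_n"].iloc[0] == pytest.approx(1.0)
        assert sum(dropped.values()) == 0

    def test_tau_ratio(self):
        # eGFP tau 5 h (delta 0.2), CayRFP tau 10 h (delta 0.1) -> 0.5
        fits = pd.DataFrame([
            fit_row("c1", "eGFP", 0.2), fit_row("c1", "CayRFP", 0.1),
        ])
        cells, _ = normalize_per_cell(fits)
        assert cells["tau_n"].iloc[0] == pytest.approx(0.5)

    def test_failed_channel_dropped_and_counted(self):
        fits = pd.DataFrame([
            fit_row("c1", "eGFP", 0.2, converged=False),
            fit_row("c1", "CayRFP", 0.1),
            fit_row("c2", "eGFP", 0.2),
        ])
        cells, dropped = normalize_per_cell(fits)
        assert cells.empty
        assert dropped["failed_fit"] == 1
        assert dropped["missing_channel"] == 1


class TestFoldChange:
    def make_cells(self, taus_by_construct, sirna="siCtrl"):
        rows = []
        for construct, taus in taus_by_construct.items():
            for i, t in enumerate(taus):
                rows.append({
                    "cell_id": f"{construct}{i}", "construct": construct,
                    "sirna": sirna, "cell_line": "A549", "experiment": "e1",
                    "tau_n": t, "k_n": 1.0,
                })
        return pd.DataFrame(rows)

    def test_reference_median_is_one(self):
        cells = fold_change(self.make_cells({"eGFP": [1.0, 2.0, 3.0]}))
        assert cells["fc_tau"].median() == pytest.approx(1.0)

    def test_planted_ratio(self):
        cells = fold_change(self.make_cells(
            {"eGFP": [1.0, 2.0, 3.0], "v": [1.32, 1.32]}
        ))
        assert np.allclose(cells[cells["construct"] == "v"]["fc_tau"], 0.66)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference construct"):
            fold_change(self.make_cells({"v": [1.0]}))

    def test_norm_fc_ladder(self):
        ctrl = self.make_cells({"eGFP": [2.0, 2.0], "v": [1.0, 1.0]}, "siCtrl")
        si = self.make_cells({"eGFP": [0.2, 0.2], "v": [0.2, 0.2]}, "siRNA1")
        cells = rnai_relative_fc(fold_change(pd.concat([ctrl, si])))
        # under siCtrl: fc(v) = 0.5; under siRNA1: fc(v) = 1.0 -> norm 2.0
        v_si = cells[(cells["construct"] == "v") & (cells["sirna"] == "siRNA1")]
        assert np.allclose(v_si["norm_fc_tau"], 2.0)
        # siCtrl rows through the same formula have median 1 per construct
        ctrl_rows = cells[cells["sirna"] == "siCtrl"]
        for _, g in ctrl_rows.groupby("construct"):
            assert g["norm_fc_tau"].median() == pytest.approx(1.0)

    def test_missing_sictrl_raises(self):
        si = self.make_cells({"eGFP": [1.0], "v": [1.0]}, "siRNA1")
        with pytest.raises(ValueError, match="siCtrl"):
            rnai_relative_fc(fold_change(si))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mannwhitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = mannwhitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_all_small_splits(self):
        """Exhaustive relabeling enumeration for every tie-free split with
        n_a, n_b <= 6."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                pooled = rng.normal(size=n1 + n2)
                a, b = pooled[:n1], pooled[n1:]
                u_impl, p_impl = mannwhitney_u(a, b)
                us = []
                for comb in itertools.combinations(range(n1 + n2), n1):
                    aa = pooled[list(comb)]
                    bb = np.delete(pooled, list(comb))
                    us.append(float(sum((x > bb).sum() for x in aa)))
                us = np.array(us)
                p_enum = min(
                    1.0,
                    2.0 * min((us <= u_impl).mean(), (us >= u_impl).mean()),
                )
                assert u_impl == float(sum((x > b).sum() for x in a))
                assert p_impl == pytest.approx(p_enum)

    def test_approximation_close_to_exact(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(0.8, 1.0, size=8)
        _, p_exact = mannwhitney_u(a, b)
        _, p_approx = mannwhitney_u(a, b, exact_max_n=0)
        assert abs(p_exact - p_approx) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_u([], [1.0])


class TestStars:
    @pytest.mark.parametrize("p,label", [
        (0.3, "ns"), (5e-5, "****"), (0.05, "ns"), (0.049, "*"),
        (1e-2, "*"), (9e-3, "**"), (1e-3, "**"), (9e-4, "***"),
        (1e-4, "***"), (9e-5, "****"), (0.0, "****"), (1.0, "ns"),
    ])
    def test_mapping_with_boundary_rule(self, p, label):
        assert significance_stars(p) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestCorrelationProfile:
    def test_perfect_correlation_at_matching_position(self):
        profiles = {
            "a": np.array([0.1, 0.5]), "b": np.array([0.2, 0.5]),
            "c": np.array([0.3, 0.5]),
        }
        stats_ = {"a": 1.0, "b": 2.0, "c": 3.0}
        corr = correlation_profile(stats_, profiles)
        assert corr.r[0] == pytest.approx(1.0)
        assert not corr.defined[1]          # zero density variance
        assert np.isnan(corr.r[1])

    def test_constant_stability_everywhere_undefined(self):
        profiles = {
            "a": np.array([0.1, 0.2]), "b": np.array([0.2, 0.1]),
            "c": np.array([0.3, 0.4]),
        }
        corr = correlation_profile({"a": 1.0, "b": 1.0, "c": 1.0}, profiles)
        assert not corr.defined.any()

    def test_sign_structure_recovered(self):
        """Stability decreasing in early density yields negative early r
        and positive r where density tracks stability."""
        rng = np.random.default_rng(0)
        profiles, stats_ = {}, {}
        for i, name in enumerate(["a", "b", "c", "d"]):
            early = 0.1 + 0.05 * i
            late = 0.3 - 0.05 * i
            profiles[name] = np.array([early, late]) + rng.normal(0, 1e-4, 2)
            stats_[name] = 1.0 - early           # decreasing in early density
        corr = correlation_profile(stats_, profiles)
        assert corr.r[0] < -0.9
        assert corr.r[1] > 0.9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st_.floats(0.1, 50), offset=st_.floats(-5, 5))
    def test_affine_invariance(self, scale, offset):
        profiles = {
            "a": np.array([0.1, 0.4]), "b": np.array([0.25, 0.2]),
            "c": np.array([0.15, 0.35]),
        }
        stats_ = {"a": 1.0, "b": 0.4, "c": 0.8}
        base = correlation_profile(stats_, profiles)
        scaled = correlation_profile(
            {k: scale * v + offset for k, v in stats_.items()}, profiles
        )
        assert np.allclose(base.r, scaled.r)

    def test_too_few_constructs(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_profile({"a": 1.0, "b": 2.0},
                                {"a": np.zeros(2), "b": np.zeros(2)})

    def test_mismatched_grids(self):
        with pytest.raises(ValueError, match="mismatched"):
            correlation_profile(
                {"a": 1.0, "b": 2.0, "c": 3.0},
                {"a": np.zeros(2), "b": np.zeros(3), "c": np.zeros(2)},
            )


class TestSummarize:
    def test_median_and_unscaled_mad(self):
        cells = pd.DataFrame({
            "construct": "x", "sirna": "siCtrl", "cell_line": "A549",
            "experiment": "e1", "tau_n": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        s = summarize(cells)
        pooled = s[s["experiment"] == "<pooled>"].iloc[0]
        assert pooled["median"] == 3.0
        assert pooled["mad"] == 1.0

    def test_single_cell_mad_zero(self):
        cells = pd.DataFrame({
            "construct": "x", "sirna": "siCtrl", "cell_line": "A549",
            "experiment": "e1", "tau_n": [2.0],
        })
        s = summarize(cells)
        assert (s["mad"] == 0.0).all()

    def test_per_experiment_rows(self):
        cells = pd.DataFrame({
            "construct": "x", "sirna": "siCtrl", "cell_line": "A549",
            "experiment": ["e1"] * 3 + ["e2"] * 3 + ["e3"] * 3,
            "tau_n": [1, 1, 1, 2, 2, 2, 3, 3, 3.0],
        })
        s = summarize(cells)
        per_exp = s[s["experiment"] != "<pooled>"]
        assert sorted(per_exp["median"]) == [1.0, 2.0, 3.0]
        pooled = s[s["experiment"] == "<pooled>"]["median"].iloc[0]
        assert pooled == 2.0
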