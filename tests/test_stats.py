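"""Abundance weighting, Spearman/BH machinery and the correlation screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from stonescreen import (
    benjamini_hochberg,
    build_weighted_entries,
    correlation_screen,
    normalize_abundance,
    spearman,
    summarize_fractions,
)
from stonescreen.ingest import FractionTable
from stonescreen.stats import ENTRY_PROPERTIES, SCREEN_ORDER, screen_matrix


def make_table(entries):
    df = pd.DataFrame(entries, columns=["protein_id", "fraction_id", "intensity"])
    return FractionTable(fraction_ids=sorted(df["fraction_id"].unique()), entries=df)


class TestNormalize:
    def test_weights_are_within_fraction_shares(self):
        table = normalize_abundance(
            make_table([("a", "F1", 2.0), ("b", "F1", 3.0), ("c", "F1", 5.0)])
        )
        assert table.entries["weight"].tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_singleton_fraction_weight_one(self):
        table = normalize_abundance(make_table([("a", "F1", 7.0)]))
        assert table.entries["weight"].tolist() == [1.0]

    def test_zero_total_fraction_named(self):
        with pytest.raises(ValueError, match="F2"):
            normalize_abundance(make_table([("a", "F1", 1.0), ("b", "F2", 0.0)]))

    def test_weight_conservation(self, small_dataset):
        table = normalize_abundance(small_dataset.proteome.fraction_table)
        sums = table.entries.groupby("fraction_id")["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [2, 4, 6]).rs == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rs == pytest.approx(-1.0)

    def test_midrank_tie_handling_by_hand(self):
        # x = (1,2,2,4) -> ranks (1, 2.5, 2.5, 4); y = (1,3,2,4) -> (1,3,2,4)
        res = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.rs == pytest.approx(expected)

    def test_matches_scipy_on_tied_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert res.rs == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)), min_size=4, max_size=30
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        base = spearman(x, y).rs
        assert spearman(np.exp(x / 20), y**3 + 5).rs == pytest.approx(base, abs=1e-12)

    def test_exact_permutation_small_n(self):
        res = spearman([1, 2, 3], [10, 20, 30], method="exact")
        assert res.p == pytest.approx(2 / 6)  # only the two perfect orderings
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], method="exact")
        # oracle: full enumeration happens inside; cross-check against scipy exact
        ref = sps.spearmanr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert abs(res.rs - ref.statistic) < 1e-12
        assert 0 < res.p <= 1

    def test_constant_vector_flagged_not_raised(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.ok and np.isnan(res.rs)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [1, 2])


class TestBenjaminiHochberg:
    def test_step_up_hand_values(self):
        assert benjamini_hochberg([0.01, 0.04]).tolist() == pytest.approx([0.02, 0.04])
        assert benjamini_hochberg([0.05, 0.05]).tolist() == pytest.approx([0.05, 0.05])
        assert benjamini_hochberg([0.3]).tolist() == pytest.approx([0.3])

    def test_independent_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 25)))
            m = p.size
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            assert benjamini_hochberg(p) == pytest.approx(adj)

    @given(p=st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_pointwise_bounds_and_order_preservation(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_domain_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            benjamini_hochberg(bad)


def _toy_inputs():
    """Three fractions, four proteins, hand-buildable weighted entries."""
    profiles = pd.DataFrame(
        {
            "protein_id": ["a", "b", "c", "d"],
            "mw_da": [10_000.0, 100_000.0, 40_000.0, 70_000.0],
            "instability_index": [30.0, 50.0, 45.0, 20.0],
            "gravy": [-1.0, -0.5, 0.5, -0.2],
            "pi": [5.0, 6.0, 7.0, 8.0],
            "n_ca_sites": [0, 2, 0, 1],
            "n_ox_motifs": [1, 4, 0, 2],
            "frac_aromatic": [0.1, 0.2, 0.15, 0.05],
            "frac_polar": [0.3, 0.3, 0.3, 0.3],
            "frac_nonpolar": [0.4, 0.3, 0.35, 0.45],
            "frac_positive": [0.2, 0.2, 0.15, 0.1],
            "frac_negative": [0.1, 0.2, 0.2, 0.15],
            "ss_helix": [0.25, 0.4, 0.3, 0.2],
            "ss_strand": [0.25, 0.2, 0.2, 0.3],
            "ss_turn": [0.25, 0.2, 0.2, 0.2],
            "ss_coil": [0.25, 0.2, 0.3, 0.3],
        }
    ).set_index("protein_id")
    table = normalize_abundance(
        make_table(
            [("a", "F1", 1.0), ("b", "F1", 1.0), ("c", "F2", 2.0), ("d", "F3", 3.0)]
        )
    )
    panel = pd.concat(
        {
            "aggregation": pd.DataFrame(
                {"activity_pct": {"F1": 200.0, "F2": 100.0, "F3": 150.0},
                 "sem_pct": 1.0, "n": 3}
            )
        },
        axis=1,
    )
    return table, profiles, panel


class TestWeightedEntries:
    def test_definition_by_hand(self):
        table, profiles, panel = _toy_inputs()
        entries = build_weighted_entries(table, profiles, panel)
        row = entries.set_index("protein_id").loc["a"]
        assert row["weight"] == pytest.approx(0.5)
        assert row["aw_mw_da"] == pytest.approx(0.5 * 10_000)
        assert row["aw_act_aggregation"] == pytest.approx(0.5 * 200.0)
        assert len(entries) == 4

    def test_uniform_weights_constant_property(self):
        table = normalize_abundance(
            make_table([("a", "F1", 1.0), ("b", "F1", 1.0)])
        )
        _, profiles, panel = _toy_inputs()
        profiles = profiles.copy()
        profiles["mw_da"] = 5_000.0
        entries = build_weighted_entries(table, profiles, panel)
        assert entries["aw_mw_da"].nunique() == 1

    def test_missing_profile_listed(self):
        table, profiles, panel = _toy_inputs()
        with pytest.raises(ValueError, match=r"without profiles: \['a'\]"):
            build_weighted_entries(table, profiles.drop(index="a"), panel)


class TestSummaries:
    def test_threshold_splits_by_hand(self):
        table, profiles, panel = _toy_inputs()
        summary = summarize_fractions(profiles, table)
        # F1 holds a (10 kDa) and b (100 kDa): one low, one high
        assert summary.loc["F1", "pct_low_mw"] == pytest.approx(50.0)
        assert summary.loc["F1", "pct_high_mw"] == pytest.approx(50.0)
        # gravy in F1: -1.0 and -0.5, both hydrophilic
        assert summary.loc["F1", "pct_hydrophilic"] == pytest.approx(100.0)
        # c in F2 has gravy 0.5
        assert summary.loc["F2", "pct_hydrophobic"] == pytest.approx(100.0)
        assert summary.loc["F1", "pct_ca_binding"] == pytest.approx(50.0)

    def test_single_protein_sem_undefined(self):
        table, profiles, panel = _toy_inputs()
        summary = summarize_fractions(profiles, table)
        assert np.isnan(summary.loc["F3", "sem_mw_da"])
        assert summary.loc["F3", "n_proteins"] == 1

    def test_hand_counted_hydrophilic_share(self):
        _, profiles, panel = _toy_inputs()
        profiles = profiles.copy()
        profiles["gravy"] = [-1.0, -1.0, -1.0, 1.0]
        table = normalize_abundance(
            make_table([(p, "F1", 1.0) for p in "abcd"])
        )
        summary = summarize_fractions(profiles, table)
        assert summary.loc["F1", "pct_hydrophilic"] == pytest.approx(75.0)


class TestScreen:
    def test_monotone_construction_is_significant(self, rng):
        # many proteins, weights and MW arranged so aw_MW orders exactly with
        # aw_aggregation: rs = 1 and the cell must be flagged
        n = 40
        pids = [f"p{i}" for i in range(n)]
        fracs = [f"F{i % 4 + 1}" for i in range(n)]
        table = normalize_abundance(
            make_table([(p, f, float(rng.uniform(1, 10))) for p, f in zip(pids, fracs)])
        )
        base = pd.DataFrame(
            {c: rng.uniform(0.1, 0.9, size=n) for c in ENTRY_PROPERTIES},
            index=pd.Index(pids, name="protein_id"),
        )
        base["pi"] = 7.0
        act = {f: 100.0 + 50 * int(f[1]) for f in set(fracs)}
        w = table.entries.set_index("protein_id")["weight"]
        aw_act = {
            p: w[p] * act[f] for p, f in zip(pids, fracs)
        }
        # choose mw so that weight*mw reproduces the aw activity ordering
        base["mw_da"] = [aw_act[p] * 1000.0 / w[p] for p in pids]
        panel = pd.concat(
            {
                "aggregation": pd.DataFrame(
                    {"activity_pct": act, "sem_pct": 1.0, "n": 3}
                )
            },
            axis=1,
        )
        screen = correlation_screen(table, base, panel)
        cell = screen[(screen["property"] == "mw_da") & (screen["assay"] == "aggregation")]
        assert cell["rs"].iloc[0] == pytest.approx(1.0)
        assert bool(cell["significant"].iloc[0])

    def test_shuffled_activities_not_significant(self, rng):
        table, profiles, panel = _toy_inputs()
        screen = correlation_screen(table, profiles, panel)
        # only 3 fractions / 4 entries: nothing can clear BH at these sizes
        assert screen["significant"].sum() == 0

    def test_constant_property_reported_na_and_excluded(self):
        table, profiles, panel = _toy_inputs()
        profiles = profiles.copy()
        profiles["frac_polar"] = 0.3  # aw values still vary via weight; use ss_turn
        profiles["ss_turn"] = 0.0
        screen = correlation_screen(table, profiles, panel)
        cell = screen[(screen["property"] == "ss_turn") & (screen["assay"] == "aggregation")]
        assert not bool(cell["ok"].iloc[0])
        assert np.isnan(cell["p_adj"].iloc[0])
        assert not bool(cell["significant"].iloc[0])

    def test_row_order_and_matrix_shape(self):
        table, profiles, panel = _toy_inputs()
        screen = correlation_screen(table, profiles, panel)
        assert list(screen["property"].unique()) == list(SCREEN_ORDER)
        mat = screen_matrix(screen)
        assert list(mat.index) == list(SCREEN_ORDER)

    def test_fraction_unit_sensitivity_mode(self):
        table, profiles, panel = _toy_inputs()
        screen = correlation_screen(table, profiles, panel, unit="fraction")
        assert (screen["n"] == 3).all()  # 3 fractions everywhere
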