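"""Equity adjustment of CERs, league-table ranking, and rank comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equicea.league import (
    adjust_cer,
    build_league,
    compare_rankings,
    intervention_equity,
)
from equicea.panel_io import ReferentialError, SchemaError


def equity_table(weights: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"condition_id": list(weights), "equity_weight": list(weights.values())}
    )


def interventions_table(rows: list[tuple[str, tuple[str, ...], float]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intervention_id": [r[0] for r in rows],
            "name": [r[0] for r in rows],
            "condition_ids": [r[1] for r in rows],
            "cer": [r[2] for r in rows],
        }
    )


def kendall_tau_b_bruteforce(x: list[int], y: list[int]) -> float:
    """Exhaustive pairwise concordance count (tau-b, tie corrected)."""
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = len(x) * (len(x) - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


class TestInterventionEquity:
    def test_single_condition_inheritance(self):
        iv = interventions_table([("I1", ("C1",), 10.0)])
        w = intervention_equity(iv, equity_table({"C1": 2.0}))
        assert w["I1"] == 2.0

    @pytest.mark.parametrize(
        "mode,expected", [("mean", 1.5), ("max", 2.0), ("min", 1.0)]
    )
    def test_multi_condition_modes(self, mode, expected):
        iv = interventions_table([("I1", ("C1", "C2"), 10.0)])
        w = intervention_equity(
            iv, equity_table({"C1": 1.0, "C2": 2.0}), multi_mode=mode
        )
        assert w["I1"] == expected

    def test_unmapped_condition_raises(self):
        iv = interventions_table([("I1", ("C9",), 10.0)])
        with pytest.raises(ReferentialError, match="C9"):
            intervention_equity(iv, equity_table({"C1": 1.0}))


class TestAdjustCer:
    def test_halving_and_identity(self):
        assert adjust_cer(100.0, 2.0) == 50.0
        assert adjust_cer(100.0, 1.0) == 100.0
        assert adjust_cer(60.0, 1.5) == pytest.approx(40.0)

    @pytest.mark.parametrize("cer,weight", [(-1.0, 1.5), (0.0, 1.5), (10.0, 0.9), (10.0, 2.1)])
    def test_domain_errors(self, cer, weight):
        with pytest.raises(ValueError):
            adjust_cer(cer, weight)

    @given(
        st.floats(min_value=0.01, max_value=1e6),
        st.floats(min_value=1.0, max_value=2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_adjusted_bounded_by_half_and_full_cer(self, cer, weight):
        adjusted = adjust_cer(cer, weight)
        assert cer / 2 - 1e-9 <= adjusted <= cer + 1e-9


class TestBuildLeague:
    def test_neutral_weights_preserve_ordering(self):
        iv = interventions_table(
            [("I1", ("C1",), 10.0), ("I2", ("C1",), 20.0), ("I3", ("C1",), 30.0)]
        )
        w = pd.Series([1.0, 1.0, 1.0], index=pd.Index(["I1", "I2", "I3"], name="intervention_id"))
        league = build_league(iv, w)
        assert (league["rank_cer"] == league["rank_adjusted"]).all()
        assert (league["rank_delta"] == 0).all()

    def test_tie_broken_by_id(self):
        iv = interventions_table([("I1", ("C1",), 10.0), ("I2", ("C1",), 20.0)])
        w = pd.Series([1.0, 2.0], index=pd.Index(["I1", "I2"], name="intervention_id"))
        league = build_league(iv, w).set_index("intervention_id")
        # adjusted CERs are both 10; lexicographically smaller id wins
        assert league.loc["I1", "adjusted_cer"] == league.loc["I2", "adjusted_cer"] == 10.0
        assert league.loc["I1", "rank_adjusted"] == 1
        assert league.loc["I2", "rank_adjusted"] == 2

    def test_duplicate_intervention_id_rejected(self):
        iv = interventions_table([("I1", ("C1",), 10.0), ("I1", ("C1",), 20.0)])
        w = pd.Series([1.0], index=pd.Index(["I1"], name="intervention_id"))
        with pytest.raises(SchemaError):
            build_league(iv, w)

    def test_ranks_match_brute_force_sort(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            ids = [f"I{i}" for i in range(n)]
            cers = np.round(rng.lognormal(3, 1, size=n), 1)
            weights = np.round(rng.uniform(1, 2, size=n), 2)
            iv = interventions_table(
                [(ids[i], ("C1",), float(cers[i])) for i in range(n)]
            )
            w = pd.Series(weights, index=pd.Index(ids, name="intervention_id"))
            league = build_league(iv, w).set_index("intervention_id")
            brute = sorted(ids, key=lambda i: (cers[ids.index(i)] / weights[ids.index(i)], i))
            for rank, iid in enumerate(brute, start=1):
                assert league.loc[iid, "rank_adjusted"] == rank
            assert sorted(league["rank_cer"]) == list(range(1, n + 1))
            assert sorted(league["rank_adjusted"]) == list(range(1, n + 1))

    def test_raising_one_weight_never_worsens_its_rank(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = 8
            ids = [f"I{i}" for i in range(n)]
            cers = rng.lognormal(3, 1, size=n)
            weights = rng.uniform(1, 1.8, size=n)
            iv = interventions_table(
                [(ids[i], ("C1",), float(cers[i])) for i in range(n)]
            )
            target = int(rng.integers(n))
            bumped = weights.copy()
            bumped[target] = min(2.0, bumped[target] + 0.2)
            base = build_league(
                iv, pd.Series(weights, index=pd.Index(ids, name="intervention_id"))
            ).set_index("intervention_id")
            after = build_league(
                iv, pd.Series(bumped, index=pd.Index(ids, name="intervention_id"))
            ).set_index("intervention_id")
            assert (
                after.loc[ids[target], "rank_adjusted"]
                <= base.loc[ids[target], "rank_adjusted"]
            )


class TestCompareRankings:
    def make_league(self, cers: list[float], weights: list[float]) -> pd.DataFrame:
        ids = [f"I{i}" for i in range(len(cers))]
        iv = interventions_table(
            [(ids[i], ("C1",), cers[i]) for i in range(len(cers))]
        )
        return build_league(
            iv, pd.Series(weights, index=pd.Index(ids, name="intervention_id"))
        )

    def test_identical_rankings(self):
        league = self.make_league([10, 20, 30], [1.0, 1.0, 1.0])
        cmp = compare_rankings(league, k=2)
        assert cmp.rank_correlation == pytest.approx(1.0)
        assert not cmp.entered_top_k and not cmp.exited_top_k

    def test_exactly_reversed_rankings(self):
        league = pd.DataFrame(
            {
                "intervention_id": ["I1", "I2", "I3", "I4"],
                "rank_cer": [1, 2, 3, 4],
                "rank_adjusted": [4, 3, 2, 1],
            }
        )
        cmp = compare_rankings(league, k=2)
        assert cmp.rank_correlation == pytest.approx(-1.0)
        assert cmp.entered_top_k == {"I3", "I4"}
        assert cmp.exited_top_k == {"I1", "I2"}

    def test_five_intervention_jump_at_k3(self):
        # I3 (cer 50, weight 2 -> adjusted 25) jumps from rank 5 to rank 2,
        # displacing I4 (cer 29, weight 1) from the top 3.
        league = self.make_league(
            [10, 30, 28, 50, 29], [1.0, 1.0, 1.0, 2.0, 1.0]
        )
        by_id = league.set_index("intervention_id")
        assert by_id.loc["I3", "rank_cer"] == 5
        assert by_id.loc["I3", "rank_adjusted"] == 2
        cmp = compare_rankings(league, k=3)
        assert cmp.entered_top_k == {"I3"}
        assert cmp.exited_top_k == {"I4"}

    def test_entered_and_exited_always_balance_and_deltas_sum_to_zero(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            league = self.make_league(
                list(rng.lognormal(3, 1, size=n)), list(rng.uniform(1, 2, size=n))
            )
            k = int(rng.integers(1, n + 1))
            cmp = compare_rankings(league, k=k)
            assert len(cmp.entered_top_k) == len(cmp.exited_top_k)
            assert cmp.rank_delta.sum() == 0

    def test_k_out_of_range(self):
        league = self.make_league([10, 20], [1.0, 1.0])
        with pytest.raises(ValueError):
            compare_rankings(league, k=3)

    def test_kendall_matches_exhaustive_oracle_small_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            # draw CERs/weights from coarse grids so ties actually occur
            cers = list(rng.choice([10.0, 20.0, 20.0, 40.0], size=n))
            weights = list(rng.choice([1.0, 1.0, 2.0], size=n))
            league = self.make_league(cers, weights)
            cmp = compare_rankings(league, k=n)
            brute = kendall_tau_b_bruteforce(
                list(league["rank_cer"]), list(league["rank_adjusted"])
            )
            assert cmp.rank_correlation == pytest.approx(brute, abs=1e-12)
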