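"""Interaction-table ingestion, effect estimation and synthetic networks."""

import gzip

import numpy as np
import pandas as pd
import pytest

from epistasim.network import (
    COSTANZO_2016_COLUMNS,
    EpistasisNetwork,
    KnockoutRecord,
    SyntheticNetworkSpec,
    effect_correlation,
    estimate_effects,
    filter_complete,
    generate_synthetic,
    load_interaction_table,
    mean_interaction_profile,
)

CMAP = {
    "query_id": "query",
    "array_id": "array",
    "w_query": "wq",
    "w_array": "wa",
    "w_double": "wd",
}


def _write_table(path, rows):
    df = pd.DataFrame(rows, columns=["query", "array", "wq", "wa", "wd"])
    df.to_csv(path, sep="\t", index=False)


class TestLoading:
    def test_concatenates_files_in_order(self, tmp_path):
        f1 = tmp_path / "a.tsv"
        f2 = tmp_path / "b.tsv"
        _write_table(f1, [("q1", "a1", 0.9, 0.8, 0.7),
                          ("q2", "a2", 1.0, 1.0, 1.0),
                          ("q3", "a3", 0.5, 0.5, 0.3)])
        _write_table(f2, [("q4", "a4", 0.9, 0.9, 0.9),
                          ("q5", "a5", 0.8, 0.8, 0.8)])
        records = load_interaction_table([f1, f2], CMAP)
        assert len(records) == 5
        assert [r.query_id for r in records] == ["q1", "q2", "q3", "q4", "q5"]

    def test_unparseable_fitness_is_absent(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("query\tarray\twq\twa\twd\nq1\ta1\t0.9\t0.8\t\n"
                     "q2\ta2\t0.9\tnot_a_number\t0.5\n")
        records = load_interaction_table([f], CMAP)
        assert records[0].w_double is None
        assert records[1].w_array is None
        assert records[1].w_double == 0.5

    def test_gzip_input_accepted(self, tmp_path):
        f = tmp_path / "a.tsv.gz"
        with gzip.open(f, "wt") as fh:
            fh.write("query\tarray\twq\twa\twd\nq1\ta1\t0.9\t0.8\t0.7\n")
        records = load_interaction_table([f], CMAP)
        assert len(records) == 1 and records[0].w_query == 0.9

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_interaction_table([tmp_path / "absent.tsv"], CMAP)

    def test_bad_column_map_lists_columns(self, tmp_path):
        f = tmp_path / "a.tsv"
        _write_table(f, [("q1", "a1", 0.9, 0.8, 0.7)])
        bad = dict(CMAP, w_double="no_such_col")
        with pytest.raises(ValueError, match="no_such_col"):
            load_interaction_table([f], bad)

    def test_default_column_map_is_sga_layout(self):
        assert "query_id" in COSTANZO_2016_COLUMNS


class TestFilterComplete:
    def _records(self):
        return [
            KnockoutRecord("a", "b", 0.9, 0.8, 0.7),
            KnockoutRecord("a", "c", 0.9, None, 0.7),
            KnockoutRecord("b", "c", 0.8, 0.9, None),
            KnockoutRecord("a", "d", 1.0, 1.0, 1.0),
            KnockoutRecord("b", "d", 0.8, 1.0, 0.8),
        ]

    def test_drops_incomplete(self):
        kept = filter_complete(self._records())
        assert len(kept) == 3
        assert all(r.complete for r in kept)

    def test_empty_input(self):
        assert filter_complete([]) == []

    def test_identity_on_complete_and_idempotent(self):
        recs = [r for r in self._records() if r.complete]
        once = filter_complete(recs)
        assert once == recs
        assert filter_complete(once) == once


class TestEstimateEffects:
    REC = KnockoutRecord("i", "j", 0.9, 0.8, 0.684)

    @pytest.mark.parametrize(
        "measure,expected_eps",
        [
            ("multiplicative", 0.684 / 0.72 - 1),   # -0.05
            ("additive", 0.684 - 0.9 - 0.8 + 1),    # -0.016
            ("costanzo", 0.684 - 0.72),             # -0.036
        ],
    )
    def test_measures(self, measure, expected_eps):
        net = estimate_effects([self.REC], measure=measure)
        assert net.s[net.index("i")] == pytest.approx(-0.1)
        assert net.s[net.index("j")] == pytest.approx(-0.2)
        assert net.epsilon_of("i", "j") == pytest.approx(expected_eps, abs=1e-12)

    def test_unknown_measure_fatal(self):
        with pytest.raises(ValueError, match="unknown measure"):
            estimate_effects([self.REC], measure="geometric")

    def test_zero_fitness_pair_dropped_and_counted(self):
        recs = [self.REC, KnockoutRecord("k", "l", 0.0, 0.8, 0.0)]
        net = estimate_effects(recs, measure="multiplicative")
        assert net.epsilon_of("k", "l") == 0.0
        assert net.metadata["dropped_zero_fitness_pairs"] == 1

    def test_orientation_duplicates_averaged(self):
        recs = [
            KnockoutRecord("i", "j", 0.9, 0.8, 0.72 * 1.1),
            KnockoutRecord("j", "i", 0.8, 0.9, 0.72 * 0.9),
        ]
        net = estimate_effects(recs)
        assert net.epsilon_of("i", "j") == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_single_fitness_warns(self):
        recs = [
            KnockoutRecord("i", "j", 0.9, 0.8, 0.72),
            KnockoutRecord("i", "k", 0.7, 0.8, 0.56),
        ]
        with pytest.warns(UserWarning, match="spread"):
            net = estimate_effects(recs)
        assert net.s[net.index("i")] == pytest.approx(0.8 - 1)

    def test_reconstruction_recovers_double_fitness(self):
        """Multiplicative fits invert exactly: (1+s_i)(1+s_j)(1+eps) = W_ij."""
        rng = np.random.default_rng(42)
        recs = []
        w_single = {f"g{k}": rng.uniform(0.2, 1.2) for k in range(8)}
        for a in range(8):
            for b in range(a + 1, 8):
                qi, ai = f"g{a}", f"g{b}"
                wd = w_single[qi] * w_single[ai] * rng.uniform(0.5, 1.5)
                recs.append(KnockoutRecord(qi, ai, w_single[qi], w_single[ai], wd))
        net = estimate_effects(recs, measure="multiplicative")
        for r in recs:
            w_ij = (
                (1 + net.s[net.index(r.query_id)])
                * (1 + net.s[net.index(r.array_id)])
                * (1 + net.epsilon_of(r.query_id, r.array_id))
            )
            assert w_ij == pytest.approx(r.w_double, rel=1e-12)


class TestProfileAndCorrelation:
    def test_profile_mean_and_flag(self):
        net = EpistasisNetwork(
            ["a", "b", "c", "d"], s=np.zeros(4),
            epsilon={("a", "b"): 0.1, ("a", "c"): -0.3},
        )
        prof = mean_interaction_profile(net).set_index("locus_id")
        assert prof.loc["a", "mean_epsilon"] == pytest.approx(-0.1)
        assert prof.loc["d", "mean_epsilon"] == 0.0
        assert prof.loc["d", "n_pairs"] == 0

    def test_profile_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        ids = ["x", "y", "z"]
        eps = {("x", "y"): 0.2, ("x", "z"): -0.4, ("y", "z"): 0.1}
        net = EpistasisNetwork(ids, s=rng.normal(size=3), epsilon=eps)
        prof = mean_interaction_profile(net).set_index("locus_id")
        for locus in ids:
            vals = [v for (a, b), v in eps.items() if locus in (a, b)]
            assert prof.loc[locus, "mean_epsilon"] == pytest.approx(np.mean(vals))

    def test_exactly_linear_profiles_give_r2_one(self):
        # eps_ij = s_i + s_j makes each profile linear in s with slope 1
        n = 10
        ids = [f"L{k}" for k in range(n)]
        s = np.linspace(-0.3, 0.3, n)
        eps = {
            (ids[a], ids[b]): s[a] + s[b]
            for a in range(n) for b in range(a + 1, n)
        }
        net = EpistasisNetwork(ids, s=s, epsilon=eps)
        fit = effect_correlation(net)
        assert fit["adjusted_R2"] == pytest.approx(1.0, abs=1e-9)

    def test_uncoupled_network_has_near_zero_r2(self):
        spec = SyntheticNetworkSpec(
            n_loci=2000, coupling=0.0, pair_density=0.05, seed=11
        )
        fit = effect_correlation(generate_synthetic(spec))
        assert fit["adjusted_R2"] < 0.01

    def test_too_few_loci_fatal(self):
        net = EpistasisNetwork(["a", "b"], s=[0, 0], epsilon={("a", "b"): 0.1})
        with pytest.raises(ValueError, match="at least 3"):
            effect_correlation(net)


class TestSynthetic:
    def test_same_seed_bit_identical(self):
        spec = SyntheticNetworkSpec(n_loci=50, seed=5)
        assert generate_synthetic(spec) == generate_synthetic(spec)

    def test_two_loci_full_density_single_pair(self):
        spec = SyntheticNetworkSpec(n_loci=2, pair_density=1.0, seed=0)
        net = generate_synthetic(spec)
        assert net.n_pairs == 1

    def test_positive_coupling_gives_positive_slope_every_seed(self):
        for seed in range(20):
            spec = SyntheticNetworkSpec(
                n_loci=2000, coupling=0.2, pair_density=0.02, seed=seed
            )
            assert effect_correlation(generate_synthetic(spec))["slope"] > 0

    def test_zero_coupling_correlation_small(self):
        for seed in range(5):
            spec = SyntheticNetworkSpec(
                n_loci=2000, coupling=0.0, pair_density=0.05, seed=seed
            )
            net = generate_synthetic(spec)
            prof = mean_interaction_profile(net)
            keep = prof["n_pairs"] > 0
            r = np.corrcoef(net.s[keep.to_numpy()],
                            prof.loc[keep, "mean_epsilon"])[0, 1]
            assert abs(r) < 0.05

    def test_invalid_specs_fatal(self):
        with pytest.raises(ValueError):
            SyntheticNetworkSpec(n_loci=1)
        with pytest.raises(ValueError):
            SyntheticNetworkSpec(pair_density=1.5)
        with pytest.raises(ValueError):
            SyntheticNetworkSpec(s_weights=(0.5, 0.2, 0.2))


class TestNetworkStructure:
    def test_symmetry_of_lookup(self, two_locus_net):
        assert two_locus_net.epsilon_of("i", "j") == two_locus_net.epsilon_of("j", "i")

    def test_absent_pair_is_exactly_zero(self, two_locus_net):
        net = EpistasisNetwork(["a", "b", "c"], s=np.zeros(3),
                               epsilon={("a", "b"): 0.1})
        assert net.epsilon_of("a", "c") == 0.0

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            EpistasisNetwork(["a", "b"], s=[0, 0], epsilon={("a", "a"): 0.1})

    def test_roundtrip_serialization(self, tmp_path):
        spec = SyntheticNetworkSpec(n_loci=40, seed=3)
        net = generate_synthetic(spec)
        net.save(tmp_path / "net")
        loaded = EpistasisNetwork.load(tmp_path / "net")
        assert loaded == net
        assert loaded.measure == net.measure
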