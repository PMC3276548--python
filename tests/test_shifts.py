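"""ECDFs, two-sample KS, set partitioning, and shift analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirderep import (ExpressionMatrix, differential_expression, ecdf_eval,
                      ecdf_coordinates, ks_two_sample, partition_target_sets,
                      shift_analysis, absolute_expression_shift,
                      signature_shift, import_site_predictions)
from mirderep.shifts import shift_results_frame
from mirderep.sites import gene_site_summary, scan_utrs

from oracles import ks_D_bruteforce

floats = st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=40)


class TestEcdf:
    def test_basic_fraction(self):
        assert ecdf_eval([1, 2, 3], 2) == pytest.approx(2 / 3)

    def test_extremes(self):
        assert ecdf_eval([1, 2, 3], 0.5) == 0.0
        assert ecdf_eval([1, 2, 3], 3) == 1.0
        assert ecdf_eval([1, 2, 3], 99) == 1.0

    def test_ties_counted_with_leq(self):
        assert ecdf_eval([1, 1, 2], 1) == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf_eval([], 0)

    def test_coordinates_step_to_one(self):
        coords = ecdf_coordinates([3, 1, 1])
        assert list(coords["x"]) == [1, 3]
        assert list(coords["F"]) == [pytest.approx(2 / 3), 1.0]

    @given(vals=floats, x=st.floats(-60, 60, allow_nan=False))
    def test_matches_direct_count(self, vals, x):
        arr = np.array(vals)
        assert ecdf_eval(vals, x) == pytest.approx(np.mean(arr <= x))


class TestKsTwoSample:
    def test_identical_samples(self):
        D, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert D == 0.0

    def test_interleaved_third(self):
        D, _ = ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
        assert D == pytest.approx(1 / 3)

    def test_disjoint_supports(self):
        D, p = ks_two_sample([0, 0.1], [5, 6])
        assert D == 1.0
        assert 0 < p <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_matches_breakpoint_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(2000):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            D, _ = ks_two_sample(a, b)
            assert D == pytest.approx(ks_D_bruteforce(a, b), abs=1e-12)

    @given(vals=floats, shift=st.floats(-10, 10, allow_nan=False))
    def test_scale_invariance_under_constant_shift(self, vals, shift):
        """Adding a constant to both samples leaves D unchanged."""
        a = np.array(vals)
        b = a[::-1] * 0.5 + 1.0
        D1, _ = ks_two_sample(a, b)
        D2, _ = ks_two_sample(a + shift, b + shift)
        assert D1 == pytest.approx(D2, abs=1e-12)


def summary_of(mapping):
    df = pd.DataFrame.from_dict(
        {g: {"site_class": c, "conservation": "unassessed", "n_sites": 1}
         for g, c in mapping.items()}, orient="index",
        columns=["site_class", "conservation", "n_sites"])
    df.index.name = "gene_id"
    return df


class TestPartition:
    def test_class_partition(self):
        part = partition_target_sets(summary_of({"g1": "seed7", "g2": "seed6"}),
                                     {"g1", "g2", "g3", "g4"}, "class")
        assert part["seed7"] == {"g1"}
        assert part["seed6"] == {"g2"}
        assert part["noncanonical"] == set()
        assert part["background"] == {"g3", "g4"}

    def test_no_sites_all_background(self):
        part = partition_target_sets(summary_of({}), {"a", "b"}, "class")
        assert part["background"] == {"a", "b"}

    def test_gene_outside_universe_in_no_set(self):
        part = partition_target_sets(summary_of({"g5": "seed7"}),
                                     {"g1", "g2"}, "class")
        assert all("g5" not in s for s in part.values())

    def test_sets_partition_universe(self):
        part = partition_target_sets(
            summary_of({"g1": "seed7", "g2": "noncanonical"}),
            {"g1", "g2", "g3"}, "class")
        union = set().union(*part.values())
        assert union == {"g1", "g2", "g3"}
        all_sets = list(part.values())
        for i in range(len(all_sets)):
            for j in range(i + 1, len(all_sets)):
                assert not all_sets[i] & all_sets[j]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            partition_target_sets(summary_of({}), set(), "class")


def de_frame(values: dict[str, float]):
    return pd.DataFrame({"log2fc": pd.Series(values)})


class TestShiftAnalysis:
    def test_complete_separation(self):
        de = de_frame({"t1": 1.0, "t2": 1.0, "b1": 0.0, "b2": 0.0})
        res = shift_analysis(de, {"targets": {"t1", "t2"},
                                  "background": {"b1", "b2"}})
        assert res[0].D == 1.0
        assert res[0].direction == "up"

    def test_empty_set_skipped(self, caplog):
        de = de_frame({"b1": 0.0, "b2": 1.0})
        res = shift_analysis(de, {"empty": set(), "background": {"b1", "b2"}})
        assert res == []

    def test_constant_offset_leaves_D_unchanged(self):
        rng = np.random.default_rng(3)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=60))}
        part = {"set": {f"g{i}" for i in range(20)},
                "background": {f"g{i}" for i in range(20, 60)}}
        res1 = shift_analysis(de_frame(vals), part)
        shifted = {g: v + 7.5 for g, v in vals.items()}
        res2 = shift_analysis(de_frame(shifted), part)
        assert res1[0].D == pytest.approx(res2[0].D, abs=1e-12)

    def test_default_dataset_class_ordering(self, default_dataset):
        """Site-class stratified shifts: seed7 shifts harder than seed6,
        both upward."""
        sites = scan_utrs(default_dataset.utrs) + \
            import_site_predictions(default_dataset.site_table)
        summary = gene_site_summary(sites)
        matrix = ExpressionMatrix(default_dataset.expression,
                                  default_dataset.samples)
        de = differential_expression(matrix)
        part = partition_target_sets(summary, set(de.index), "class")
        res = {r.set_name: r for r in shift_analysis(de, part)}
        assert res["seed7"].D > res["seed6"].D
        assert res["seed7"].direction == "up"
        assert res["seed6"].direction == "up"


class TestAbsoluteShift:
    def test_toy_separation(self, ):
        cols = ["wt_1", "wt_2", "mut_1", "mut_2"]
        df = pd.DataFrame([[5, 6, 5, 6], [5.5, 6.5, 5, 6],
                           [1, 2, 1, 2], [1.5, 2.5, 1, 2]],
                          columns=cols, index=["t1", "t2", "b1", "b2"])
        samples = pd.DataFrame({"sample": cols,
                                "genotype": ["wildtype", "wildtype",
                                             "mutant", "mutant"],
                                "replicate": [1, 2, 1, 2]})
        m = ExpressionMatrix(df, samples)
        res = absolute_expression_shift(m, {"targets": {"t1", "t2"},
                                            "background": {"b1", "b2"}})
        assert res[0].D == 1.0
        assert res[0].direction == "up"

    def test_targets_high_in_both_genotypes(self, default_dataset):
        """With a positive baseline offset, target transcripts sit above the
        background in wildtype AND mutant cells."""
        sites = scan_utrs(default_dataset.utrs) + \
            import_site_predictions(default_dataset.site_table)
        summary = gene_site_summary(sites)
        m = ExpressionMatrix(default_dataset.expression,
                             default_dataset.samples)
        part = partition_target_sets(summary, set(m.values.index), "any_site")
        for genotype in ("wildtype", "mutant"):
            res = absolute_expression_shift(m, part, genotype)
            assert res[0].direction == "up"
            assert res[0].p < 1e-6


class TestSignatureShift:
    def test_signature_scenario_directions(self):
        from mirderep import generate_dataset, scenario
        ds = generate_dataset(scenario("signature", seed=21, n_genes=800,
                                       with_alignments=False))
        m = ExpressionMatrix(ds.expression, ds.samples)
        de = differential_expression(m)
        res = {r.set_name: r for r in
               signature_shift(de, ds.nb_set, ds.neuron_set, set(de.index))}
        assert res["nb"].direction == "up"
        assert res["neuron"].direction == "down"

    def test_identical_to_background_gives_zero_D(self):
        de = de_frame({"n1": 1.0, "n2": 2.0, "m1": 5.0, "m2": 6.0,
                       "b1": 1.0, "b2": 2.0})
        res = {r.set_name: r for r in
               signature_shift(de, {"n1", "n2"}, {"m1", "m2"},
                               set(de.index))}
        assert res["nb"].D == 0.0
        assert res["nb"].direction == "none"

    def test_empty_background_rejected(self):
        de = de_frame({"n1": 1.0, "m1": 2.0})
        with pytest.raises(ValueError):
            signature_shift(de, {"n1"}, {"m1"}, {"n1", "m1"})

    def test_overlap_removed_from_both(self, caplog):
        de = de_frame({"x": 1.0, "n1": 1.0, "m1": 2.0, "b1": 0.0, "b2": 0.0})
        res = signature_shift(de, {"n1", "x"}, {"m1", "x"}, set(de.index))
        sizes = {r.set_name: r.n_set for r in res}
        assert sizes == {"nb": 1, "neuron": 1}


def test_D_monotone_in_planted_effect():
    """Raising the planted derepression (same seed) never decreases the
    observed target-set D, by majority vote over repeats."""
    from mirderep import generate_dataset, scenario
    from mirderep.experiments import _dataset_summary, _log2fc

    wins = 0
    reps = 10
    for r in range(reps):
        Ds = []
        for eff in (0.1, 0.4, 0.8):
            ds = generate_dataset(scenario(
                "default", seed=100 + r, n_genes=500, with_alignments=False,
                effect_7mer=eff, effect_6mer=eff, effect_nc=eff))
            summary = _dataset_summary(ds)
            part = partition_target_sets(summary, set(ds.expression.index),
                                         "any_site")
            fc = _log2fc(ds)
            D, _ = ks_two_sample(fc.loc[sorted(part["target"])],
                                 fc.loc[sorted(part["background"])])
            Ds.append(D)
        wins += Ds[0] < Ds[1] < Ds[2]
    assert wins >= 8


def test_shift_results_frame_round_trip():
    de = de_frame({"t1": 1.0, "b1": 0.0, "b2": 0.1})
    res = shift_analysis(de, {"s": {"t1"}, "background": {"b1", "b2"}})
    frame = shift_results_frame(res)
    assert list(frame.columns) == ["set_name", "background_name", "n_set",
                                   "n_background", "D", "p", "direction"]
    assert frame.loc[0, "n_background"] == 2
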