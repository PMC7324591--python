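"""Normalization, flags, P50, the three DE statistics and consensus/Venn logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tregpipe import simulate
from tregpipe.deg import (
    CountMatrix,
    classify_pattern,
    compute_flags,
    consensus,
    de_test_moderated_t,
    de_test_nb_wald,
    de_test_rank,
    normalize_mean_coverage,
    p50_list,
    run_tissue_comparison,
    signature_counts,
    venn_signatures,
)


def _cm(counts, n_a=3, n_b=3, tissue="NI"):
    samples = [f"{tissue}_Treg_{i}" for i in range(n_a)] + [f"{tissue}_Tconv_{i}" for i in range(n_b)]
    meta = pd.DataFrame(
        {"patient": [f"P{i}" for i in range(n_a + n_b)], "tissue": tissue,
         "subset": ["Treg"] * n_a + ["Tconv"] * n_b},
        index=samples,
    )
    return CountMatrix(counts=pd.DataFrame(counts, columns=samples), metadata=meta)


class TestNormalization:
    def test_hand_computed_scale_factors(self):
        cm = _cm(np.array([[40, 120], [60, 180]]), n_a=1, n_b=1)
        norm = normalize_mean_coverage(cm)
        # totals 100 and 300 -> mean 200 -> factors 2.0 and 2/3
        np.testing.assert_allclose(norm.counts.iloc[:, 0], [80, 120])
        np.testing.assert_allclose(norm.counts.iloc[:, 1], [80, 120])
        np.testing.assert_allclose(norm.counts.sum(axis=0), [200, 200])

    def test_equal_totals_is_identity(self):
        cm = _cm(np.array([[10, 20], [30, 20]]), n_a=1, n_b=1)
        norm = normalize_mean_coverage(cm)
        np.testing.assert_allclose(norm.counts.to_numpy(), cm.counts.to_numpy())

    def test_preserves_within_sample_ratios(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.integers(1, 1000, size=(20, 6)))
        norm = normalize_mean_coverage(cm)
        for s in cm.samples:
            ratio = norm.counts[s] / cm.counts[s]
            np.testing.assert_allclose(ratio, ratio.iloc[0])

    def test_zero_total_sample_names_sample(self):
        cm = _cm(np.array([[0, 5], [0, 5]]), n_a=1, n_b=1)
        with pytest.raises(ValueError, match="NI_Treg_0"):
            normalize_mean_coverage(cm)


class TestFlagsAndP50:
    def test_flag_boundary_is_inclusive_at_threshold(self):
        cm = _cm(np.array([[20.0, 19.9], [80.0, 80.1]]), n_a=1, n_b=1)
        # equal totals -> identity normalization, so values hit the boundary exactly
        flags = compute_flags(normalize_mean_coverage(cm))
        assert flags.flags.iloc[0, 0] == 1   # exactly 20 -> signal
        assert flags.flags.iloc[0, 1] == 0   # 19.9 -> background
        assert flags.threshold == 20.0

    def test_all_zero_gene_flags_zero(self, toy_counts):
        flags = compute_flags(normalize_mean_coverage(toy_counts))
        assert (flags.flags.loc["G_ZERO"] == 0).all()

    @pytest.mark.parametrize(
        "flag_row,n,included",
        [
            ((1, 1, 0, 0), 4, True),    # 2 of 4: at least half
            ((1, 0, 0, 0), 4, False),
            ((1, 1, 0, 0, 0), 5, False),  # 2 < 2.5
            ((1, 1, 1, 0, 0), 5, True),
            ((1, 1, 1, 1), 4, True),
        ],
    )
    def test_at_least_half_rule_exact_rationals(self, flag_row, n, included):
        from tregpipe.deg import FlagMatrix

        samples = [f"s{i}" for i in range(n)]
        fm = FlagMatrix(flags=pd.DataFrame([flag_row], index=["g"], columns=samples))
        assert (["g"] == p50_list(fm, samples)) is included

    def test_unknown_sample_is_error(self, toy_counts):
        flags = compute_flags(normalize_mean_coverage(toy_counts))
        with pytest.raises(ValueError, match="unknown"):
            p50_list(flags, ["nope"])


class TestDEStatistics:
    def _null_cm(self, seed=0, n_genes=300, n=4):
        cm, _ = simulate.gen_counts(n_genes, (n, n), frac_de=0.0, seed=seed)
        return cm

    @pytest.mark.parametrize("test_fn", [de_test_nb_wald, de_test_moderated_t, de_test_rank])
    def test_identical_groups_are_null(self, test_fn):
        """The same samples relabeled as two groups give fold 1 and p ~ 1."""
        base = np.tile([[100], [40], [250]], (1, 3)).astype(float)
        counts = np.concatenate([base, base], axis=1)
        cm = _cm(counts, n_a=3, n_b=3)
        res = test_fn(cm, cm.samples_for(subset="Treg"), cm.samples_for(subset="Tconv"))
        np.testing.assert_allclose(res["fold"], 1.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_all_zero_gene_reported_missing(self, toy_counts):
        res = de_test_nb_wald(toy_counts, toy_counts.samples_for(subset="Treg"), toy_counts.samples_for(subset="Tconv"))
        assert np.isnan(res.loc["G_ZERO", "p"]) and np.isnan(res.loc["G_ZERO", "fold"])

    def test_group_too_small_is_error(self, toy_counts):
        with pytest.raises(ValueError, match="at least 2"):
            de_test_nb_wald(toy_counts, ["NI_Treg_1"], toy_counts.samples_for(subset="Tconv"))

    def test_nb_wald_recovers_planted_fold(self):
        """True fold 4 at n=10 per group, dispersion 0.1: median estimate in [3, 5]."""
        medians = []
        for s in range(20):
            cm, gt = simulate.gen_counts(200, (10, 10), frac_de=0.2, true_fold=4.0, dispersion=0.1, seed=400 + s)
            res = de_test_nb_wald(cm, cm.samples_for(subset="Treg"), cm.samples_for(subset="Tconv"))
            up = [g for g, d in gt.params["de_direction"].items() if d == 1]
            medians.append(res.loc[up, "fold"].median())
        assert 3.0 <= np.median(medians) <= 5.0

    def test_moderated_t_smaller_variance_smaller_p(self):
        """Equal mean difference, unequal variance: tighter gene wins."""
        tight_a, tight_b = [100, 101, 99, 100], [120, 121, 119, 120]
        loose_a, loose_b = [80, 120, 100, 100], [100, 140, 120, 120]
        counts = np.array([tight_a + tight_b, loose_a + loose_b])
        cm = _cm(counts, n_a=4, n_b=4)
        res = de_test_moderated_t(
            cm, cm.samples_for(subset="Treg"), cm.samples_for(subset="Tconv"), normalized=True
        )
        assert res["p"].iloc[0] < res["p"].iloc[1]

    def test_moderated_t_type1_error_calibrated(self):
        """Under an NB null (2000 genes, 5v5) the p<=0.05 rate is in [0.03, 0.07]."""
        cm = self._null_cm(seed=77, n_genes=2000, n=5)
        res = de_test_moderated_t(cm, cm.samples_for(subset="Treg"), cm.samples_for(subset="Tconv"))
        rate = (res["p"].dropna() <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_rank_exact_p_for_complete_separation(self):
        """3v3 fully separated: two-sided exact p = 2/C(6,3) = 0.1."""
        counts = np.array([[10, 11, 12, 20, 21, 22]], dtype=float)
        cm = _cm(counts, n_a=3, n_b=3)
        res = de_test_rank(
            cm, cm.samples_for(subset="Treg"), cm.samples_for(subset="Tconv"), normalized=True
        )
        assert res["p"].iloc[0] == pytest.approx(0.1)

    def test_rank_constant_gene_p_one(self):
        counts = np.array([[7, 7, 7, 7, 7, 7]], dtype=float)
        cm = _cm(counts, n_a=3, n_b=3)
        res = de_test_rank(cm, cm.samples_for(subset="Treg"), cm.samples_for(subset="Tconv"))
        assert res["p"].iloc[0] == 1.0


class TestConsensus:
    def _results(self, ps, folds):
        genes = pd.Index(["g"])
        return {
            name: pd.DataFrame({"fold": [f], "p": [p]}, index=genes)
            for name, p, f in zip(("nb_wald", "moderated_t", "rank"), ps, folds)
        }

    @pytest.mark.parametrize(
        "ps,folds,expected",
        [
            ((0.01, 0.04, 0.05), (1.3, 1.25, 1.21), "U"),   # boundary p=0.05 inclusive
            ((0.01, 0.051, 0.01), (1.3, 1.3, 1.3), "N"),
            ((0.01, 0.01, 0.01), (1.3, 1.3, 0.7), "N"),      # direction conflict
            ((0.01, 0.01, 0.01), (1.2, 1.2, 1.2), "U"),      # fold boundary inclusive
            ((0.01, 0.01, 0.01), (0.8, 0.75, 1 / 1.2), "D"),
            ((0.01, 0.01, 0.01), (1.3, 1.19, 1.3), "N"),
        ],
    )
    def test_rule_application(self, ps, folds, expected):
        table = consensus(self._results(ps, folds))
        assert table["call"].iloc[0] == expected
        if expected != "N":
            assert table["fold"].iloc[0] == pytest.approx(np.median(folds))

    def test_missing_gene_in_one_method_is_N(self):
        res = self._results((0.01, 0.01, 0.01), (2.0, 2.0, 2.0))
        res["rank"].loc["g", "p"] = np.nan
        assert consensus(res)["call"].iloc[0] == "N"

    def test_monotone_in_thresholds(self):
        """Relaxing p_max or fold_min never removes a U/D call."""
        rng = np.random.default_rng(1)
        genes = pd.Index([f"g{i}" for i in range(200)])
        res = {
            name: pd.DataFrame(
                {"fold": np.exp(rng.normal(0, 0.5, 200)), "p": rng.uniform(0, 1, 200)},
                index=genes,
            )
            for name in ("nb_wald", "moderated_t", "rank")
        }
        strict = consensus(res, p_max=0.05, fold_min=1.3)["call"]
        loose = consensus(res, p_max=0.10, fold_min=1.1)["call"]
        called = strict != "N"
        assert (strict[called] == loose[called]).all()


class TestVenn:
    def test_signature_classes(self):
        assert classify_pattern(("U", "U", "U")) == "common_treg"
        assert classify_pattern(("D", "D", "D")) == "common_tconv"
        assert classify_pattern(("N", "N", "N")) == "unclassified"
        assert classify_pattern(("U", "N", "N")) == "NI_unique_treg"
        assert classify_pattern(("N", "N", "D")) == "T_unique_tconv"
        assert classify_pattern(("U", "D", "N")) == "other"

    def test_every_triple_has_exactly_one_class(self):
        for triple in itertools.product("UDN", repeat=3):
            assert isinstance(classify_pattern(triple), str)

    def test_venn_partitions_gene_set(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(100)]
        tables = {
            t: pd.DataFrame(
                {"call": rng.choice(["U", "D", "N"], size=100)},
                index=pd.Index(genes),
            )
            for t in ("NI", "I", "T")
        }
        venn = venn_signatures(tables)
        assert len(venn) == 100
        assert signature_counts(venn).sum() == 100  # one class per gene

    def test_genes_missing_from_a_tissue_are_N_there(self):
        tables = {
            "NI": pd.DataFrame({"call": ["U"]}, index=pd.Index(["g1"])),
            "I": pd.DataFrame({"call": ["U"]}, index=pd.Index(["g2"])),
            "T": pd.DataFrame({"call": ["N"]}, index=pd.Index(["g1"])),
        }
        venn = venn_signatures(tables)
        assert venn.loc["g1", "signature"] == "NI_unique_treg"
        assert venn.loc["g2", "signature"] == "I_unique_treg"


class TestEndToEndComparison:
    def test_toy_matrix_exact_pipeline_behavior(self, toy_counts):
        comp = run_tissue_comparison(toy_counts, "NI")
        # G_LOW (normalized ~5) and G_ZERO fail the P50 flag universe
        assert set(comp.p50_genes) == {"G_UP", "G_FLAT"}
        assert comp.table.loc["G_FLAT", "call"] == "N"
        assert comp.table.loc["G_UP", "fold"] > 1.2

    def test_null_consensus_below_each_single_test(self):
        cm, _ = simulate.gen_counts(1000, (5, 5), frac_de=0.0, seed=31)
        comp = run_tissue_comparison(cm, "NI")
        t = comp.table
        cons_rate = (t["call"] != "N").mean()
        for pcol in ("p_nb_wald", "p_moderated_t", "p_rank"):
            single = ((t[pcol] <= 0.05) & ((t["fold"] >= 1.2) | (t["fold"] <= 1 / 1.2))).mean()
            assert cons_rate <= single + 1e-12

    def test_planted_recovery_sensitivity_and_fdp(self):
        """10% planted fold-4 genes (6v6, dispersion 0.1): sensitivity >= 0.7;
        the false-discovery proportion stays within the simulation-derived
        bound for three correlated calibrated tests."""
        sens, fdp = [], []
        for s in range(3):
            cm, gt = simulate.gen_counts(1000, (6, 6), frac_de=0.1, true_fold=4.0, dispersion=0.1, seed=500 + s)
            comp = run_tissue_comparison(cm, "NI")
            called = set(comp.table.index[comp.table["call"] != "N"])
            true = set(gt.params["de_genes"]) & set(comp.table.index)
            sens.append(len(called & true) / len(true))
            fdp.append(len(called - true) / max(len(called), 1))
        assert min(sens) >= 0.7
        assert max(fdp) <= 0.25
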