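"""Phospho-response analysis: normalization, testing, counting, dependence, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hsdquant.phospho import (
    count_changes,
    dedupe_proteins,
    dependent_set,
    enrichment,
    insulin_response,
    normalize_channels,
    site_anova,
    venn_overlap,
)
from hsdquant.synthetic import PhosphoSimParams, sim_phospho


def tiny_design(genotypes=("control",), n_rep=3):
    rows = []
    ch = 0
    for g in genotypes:
        for tr in ("mock", "insulin"):
            for r in range(1, n_rep + 1):
                ch += 1
                rows.append({"channel": f"ch{ch:02d}", "genotype": g,
                             "treatment": tr, "replicate": r})
    return pd.DataFrame(rows)


def table_from_fold_changes(fcs, design, genotype="control", base=100.0):
    """Abundance table whose insulin/mock replicate-mean ratio equals fcs exactly.

    Channel totals are deliberately unbalanced by the planted ratios, so tests
    built on it call insulin_response(..., normalized=True) to exercise the
    direction rule in isolation."""
    n = len(fcs)
    data = {"site_id": [f"s{i}" for i in range(n)],
            "protein_id": [f"p{i}" for i in range(n)]}
    fcs = np.asarray(fcs, dtype=float)
    # scale each channel's site values so ratios hold and totals match
    mock_vals = np.full(n, base)
    ins_vals = base * fcs
    for _, row in design.iterrows():
        v = ins_vals if row["treatment"] == "insulin" else mock_vals
        data[row["channel"]] = v.copy()
    df = pd.DataFrame(data)
    return df


class TestNormalize:
    def test_equal_totals_unchanged(self):
        design = tiny_design()
        t = table_from_fold_changes([1.0, 1.0], design)
        out = normalize_channels(t, design)
        pd.testing.assert_frame_equal(out, t)

    def test_totals_equalized_and_ratios_preserved(self):
        rng = np.random.default_rng(0)
        design = tiny_design()
        cols = design["channel"].tolist()
        t = pd.DataFrame({"site_id": [f"s{i}" for i in range(20)],
                          "protein_id": ["p0"] * 20,
                          **{c: rng.uniform(1, 100, 20) for c in cols}})
        out = normalize_channels(t, design)
        totals = out[cols].sum()
        assert np.allclose(totals, totals.iloc[0], rtol=1e-9)
        for c in cols:  # within-channel ratios preserved
            np.testing.assert_allclose(
                out[c] / out[c].iloc[0], t[c] / t[c].iloc[0], rtol=1e-12
            )

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        design = tiny_design()
        cols = design["channel"].tolist()
        t = pd.DataFrame({"site_id": ["s0", "s1"], "protein_id": ["p0", "p1"],
                          **{c: rng.uniform(1, 10, 2) for c in cols}})
        once = normalize_channels(t, design)
        twice = normalize_channels(once, design)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_total_channel_rejected(self):
        design = tiny_design()
        t = table_from_fold_changes([1.0], design)
        t["ch01"] = 0.0
        with pytest.raises(ValueError):
            normalize_channels(t, design)


class TestSiteAnova:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        design = tiny_design(("control", "KD1", "KD2"))
        cols = design["channel"].tolist()
        t = pd.DataFrame({"site_id": [f"s{i}" for i in range(1000)],
                          "protein_id": ["p0"] * 1000,
                          **{c: 2.0 ** rng.normal(10, 1, 1000) for c in cols}})
        p = site_anova(t, design)
        assert abs((p < 0.05).mean() - 0.05) <= 0.02

    def test_planted_shift_detected(self):
        design = tiny_design()
        t = table_from_fold_changes([4.0], design)
        rng = np.random.default_rng(4)
        cols = design["channel"].tolist()
        t[cols] = t[cols] * 2.0 ** rng.normal(0, 0.05, (1, len(cols)))
        p = site_anova(t, design, group_cols=("treatment",))
        assert p.iloc[0] < 0.01

    def test_degenerate_equal_means_p_one(self):
        design = tiny_design()
        t = table_from_fold_changes([1.0], design)
        assert site_anova(t, design, group_cols=("treatment",)).iloc[0] == 1.0

    def test_matches_scipy_oneway(self):
        rng = np.random.default_rng(5)
        design = tiny_design(("control", "KD1"))
        cols = design["channel"].tolist()
        t = pd.DataFrame({"site_id": ["s0"], "protein_id": ["p0"],
                          **{c: [float(rng.uniform(10, 100))] for c in cols}})
        p = site_anova(t, design).iloc[0]
        key = design.set_index("channel")
        groups = {}
        for c in cols:
            groups.setdefault((key.loc[c, "genotype"], key.loc[c, "treatment"]), []).append(
                np.log2(t[c].iloc[0])
            )
        _, p_ref = sps.f_oneway(*groups.values())
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        design = tiny_design(n_rep=1)
        t = table_from_fold_changes([1.0], design)
        with pytest.raises(ValueError):
            site_anova(t, design)


class TestInsulinResponse:
    @pytest.mark.parametrize(
        "fc,expected",
        [
            (1.31, "up"), (1.30, "up"), (1.29, "none"),
            (0.769, "down"), (0.78, "none"), (1.0, "none"),
        ],
    )
    def test_threshold_boundaries_reciprocal(self, fc, expected):
        design = tiny_design()
        t = table_from_fold_changes([fc], design)
        out = insulin_response(t, design, "control", normalized=True)
        assert out["direction"].iloc[0] == expected

    def test_linear_down_rule(self):
        design = tiny_design()
        t = table_from_fold_changes([0.72, 0.70], design)
        out = insulin_response(t, design, "control", down_rule="linear", normalized=True)
        assert list(out["direction"]) == ["none", "down"]

    def test_missing_treatment_arm_rejected(self):
        design = tiny_design()
        design = design[design["treatment"] == "mock"]
        t = table_from_fold_changes([1.0], tiny_design())
        with pytest.raises(ValueError, match="treatment arm|not in design"):
            insulin_response(t, design, "control")

    def test_noiseless_truth_recovered(self, phospho_noiseless):
        table, design, truth = phospho_noiseless
        rs = count_changes(insulin_response(table, design, "control"), "control")
        assert rs.up_sites == frozenset(truth["responsive"]["control"]["up"])
        assert rs.down_sites == frozenset(truth["responsive"]["control"]["down"])


class TestCountsAndDependence:
    def test_empty_counts(self):
        rs = count_changes(pd.DataFrame(columns=["site_id", "direction"]))
        assert (rs.n_up, rs.n_down, rs.n_total) == (0, 0, 0)

    def test_partition_invariant(self):
        design = tiny_design()
        rng = np.random.default_rng(6)
        t = table_from_fold_changes(rng.uniform(0.4, 2.5, 200), design)
        rs = count_changes(insulin_response(t, design, "control", normalized=True))
        assert rs.n_total == rs.n_up + rs.n_down
        assert not (rs.up_sites & rs.down_sites)

    def test_kd_identical_to_control_gives_empty_set(self):
        design = tiny_design()
        resp = insulin_response(table_from_fold_changes([2.0, 0.5, 1.0], design), design, "control", normalized=True)
        dep = dependent_set(resp, [resp.copy(), resp.copy()])
        assert dep.n_total == 0 and dep.fraction_pct == 0

    def test_full_blunting_recovers_whole_truth_set(self, phospho_noiseless):
        table, design, truth = phospho_noiseless
        ctrl = insulin_response(table, design, "control")
        kds = [insulin_response(table, design, g) for g in ("KD1", "KD2")]
        dep = dependent_set(ctrl, kds)
        expected = set(truth["responsive"]["control"]["up"]) | set(
            truth["responsive"]["control"]["down"]
        )
        assert dep.sites == frozenset(expected)
        assert dep.fraction_pct == 100

    def test_differing_universes_rejected(self):
        design = tiny_design()
        a = insulin_response(table_from_fold_changes([2.0, 1.0], design), design, "control", normalized=True)
        b = a.iloc[:1]
        with pytest.raises(ValueError, match="universes"):
            dependent_set(a, [b])

    def test_any_mode_is_superset_of_all_mode(self):
        design = tiny_design()
        ctrl = insulin_response(table_from_fold_changes([2.0, 0.5, 2.0], design), design, "control", normalized=True)
        kd1 = ctrl.copy(); kd1["direction"] = ["none", "down", "up"]
        kd2 = ctrl.copy(); kd2["direction"] = ["none", "none", "up"]
        dep_all = dependent_set(ctrl, [kd1, kd2], mode="all")
        dep_any = dependent_set(ctrl, [kd1, kd2], mode="any")
        assert dep_all.sites <= dep_any.sites
        assert dep_all.sites == {"s0"} and dep_any.sites == {"s0", "s1"}


class TestProteinOps:
    def test_dedupe(self):
        mapping = {"s1": "pA", "s2": "pA", "s3": "pA", "s4": "pB"}
        assert dedupe_proteins(["s1", "s2", "s3"], mapping) == {"pA"}
        assert dedupe_proteins([], mapping) == set()
        with pytest.raises(KeyError):
            dedupe_proteins(["sX"], mapping)

    def test_dedupe_matches_set_oracle(self):
        rng = np.random.default_rng(7)
        sites = [f"s{i}" for i in range(50)]
        mapping = {s: f"p{rng.integers(0, 12)}" for s in sites}
        sub = rng.choice(sites, 30, replace=False).tolist()
        assert dedupe_proteins(sub, mapping) == {mapping[s] for s in sub}

    def test_venn_trivial(self):
        assert venn_overlap({"A": {"a"}, "B": {"b"}}) == {
            ("A",): 1, ("B",): 1, ("A", "B"): 0,
        }
        out = venn_overlap({"A": {"x", "y"}, "B": {"x", "y"}})
        assert out[("A", "B")] == 2 and out[("A",)] == 0 and out[("B",)] == 0

    def test_venn_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        universe = [f"e{i}" for i in range(40)]
        sets = {n: {e for e in universe if rng.random() < 0.4} for n in ("A", "B", "C")}
        out = venn_overlap(sets)
        # brute-force membership enumeration
        for e in set().union(*sets.values()):
            key = tuple(n for n in ("A", "B", "C") if e in sets[n])
        # region counts sum to |union| and match per-element tally
        tally = {}
        for e in set().union(*sets.values()):
            key = tuple(n for n in ("A", "B", "C") if e in sets[n])
            tally[key] = tally.get(key, 0) + 1
        for key, n in out.items():
            assert n == tally.get(key, 0)
        assert sum(out.values()) == len(set().union(*sets.values()))


class TestEnrichment:
    def test_exact_p_small_table(self):
        # 2x2 table (3,1 / 1,3): two-sided hypergeometric p = 34/70
        bg = {f"b{i}" for i in range(8)}
        hits = {"b0", "b1", "b2", "b3"}
        path = {"b0", "b1", "b2", "b4"}
        out = enrichment(hits, bg, {"P": path})
        assert out["p"].iloc[0] == pytest.approx(34 / 70, rel=1e-9)

    def test_hits_equal_background_p_one(self):
        bg = {f"b{i}" for i in range(10)}
        out = enrichment(bg, bg, {"P": {"b0", "b1"}})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_pathway_skipped_with_warning(self):
        bg = {"a", "b"}
        with pytest.warns(UserWarning, match="skipped"):
            out = enrichment({"a"}, bg, {"P": {"zzz"}})
        assert out.empty

    def test_matches_hypergeometric_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            r1, r2 = rng.integers(1, 12, 2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            b, d = r1 - a, r2 - c
            _, p_impl = sps.fisher_exact([[a, b], [c, d]])
            p_oracle = fisher_oracle(a, b, c, d)
            assert p_impl == pytest.approx(p_oracle, rel=1e-9, abs=1e-12)

    def test_empty_background_and_bad_hits_rejected(self):
        with pytest.raises(ValueError):
            enrichment({"a"}, set(), {})
        with pytest.raises(ValueError):
            enrichment({"a"}, {"b"}, {})


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration over all
    tables with the same margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-12)))
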