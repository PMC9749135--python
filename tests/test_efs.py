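import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ftstab import efs, preprocess
from ftstab.simulate import (GeneContentMatrix, gene_content_matrix,
                             generate_functions, generate_taxa, sample_frame,
                             small_config)
from ftstab.tables import AbundanceTable


def _rel(values, prefix="f", domain="function"):
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(values.shape[1])])
    return AbundanceTable(data=data, domain=domain, scale="relative")


def brute_force_euclidean(values):
    n = values.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(values.shape[1]):
                acc += (values[i, k] - values[j, k]) ** 2
            D[i, j] = np.sqrt(acc)
    return D


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        t = _rel([[0.5, 0.5], [0.5, 0.5]])
        D = efs.euclidean_distance_matrix(t)
        np.testing.assert_allclose(D.D, 0.0, atol=1e-15)

    def test_three_four_five(self):
        t = AbundanceTable(
            data=pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"],
                              columns=["x", "y"]),
            domain="function", scale="counts")
        D = efs.euclidean_distance_matrix(t)
        assert D.D[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            raw = rng.random((8, 6))
            t = _rel(raw / raw.sum(axis=1, keepdims=True))
            D = efs.euclidean_distance_matrix(t)
            np.testing.assert_allclose(D.D, brute_force_euclidean(t.values),
                                       atol=1e-12)


class TestMeanOffdiag:
    def test_two_samples(self):
        D = efs.DistanceMatrix(["a", "b"], np.array([[0.0, 2.5], [2.5, 0.0]]), "f")
        m = efs.mean_offdiag(D)
        np.testing.assert_allclose(m, [2.5, 2.5])

    def test_hand_computed_three_samples(self):
        M = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        m = efs.mean_offdiag(efs.DistanceMatrix(["a", "b", "c"], M, "f"))
        np.testing.assert_allclose(m, [2.0, 1.5, 2.5])

    def test_symmetric_configuration(self):
        # equilateral: all pairwise distances equal -> all means equal
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        t = AbundanceTable(data=pd.DataFrame(pts, index=list("abc"),
                                             columns=["x", "y"]),
                           domain="function", scale="counts")
        m = efs.mean_offdiag(efs.euclidean_distance_matrix(t))
        assert m.std() == pytest.approx(0.0, abs=1e-12)


class TestConcat:
    def test_block_concatenation(self):
        bac = _rel([[0.2, 0.3, 0.5]] * 2, prefix="b", domain="bacteria")
        arc = _rel([[0.4, 0.6]] * 2, prefix="a", domain="archaea")
        mic = efs.concat_domains(bac, arc)
        assert len(mic.feature_ids) == 5
        np.testing.assert_allclose(mic.data.sum(axis=1), 2.0)

    def test_order_does_not_change_distances(self, rng):
        raw_b, raw_a = rng.random((4, 3)), rng.random((4, 2))
        bac = _rel(raw_b / raw_b.sum(1, keepdims=True), "b", "bacteria")
        arc = _rel(raw_a / raw_a.sum(1, keepdims=True), "a", "archaea")
        d1 = efs.euclidean_distance_matrix(efs.concat_domains(bac, arc)).D
        # swap the roles: Euclidean distance ignores column order
        bac2 = _rel(raw_a / raw_a.sum(1, keepdims=True), "a", "bacteria")
        arc2 = _rel(raw_b / raw_b.sum(1, keepdims=True), "b", "archaea")
        d2 = efs.euclidean_distance_matrix(efs.concat_domains(bac2, arc2)).D
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_empty_archaea_reduces_to_bacteria(self, rng):
        raw = rng.random((5, 4))
        bac = _rel(raw / raw.sum(1, keepdims=True), "b", "bacteria")
        s = efs.distance_summaries(bac, bac, arc=None)
        np.testing.assert_allclose(s["T_mic"], s["T_bac"], atol=1e-15)


class TestFtRatio:
    def test_identity_table_gives_one(self, relative_table):
        ratios = efs.ft_identity_check(relative_table)
        np.testing.assert_allclose(ratios, 1.0, atol=1e-12)

    def test_identical_function_and_taxa_tables(self, rng):
        raw = rng.random((6, 5))
        rel = raw / raw.sum(1, keepdims=True)
        func = _rel(rel, "p", "function")
        bac = _rel(rel, "p", "bacteria")
        s = efs.distance_summaries(func, bac)
        r = efs.ft_ratio(s)
        np.testing.assert_allclose(r["ft_mic"], 1.0, atol=1e-12)
        assert (r["stability_class"] == "synchronous").all()

    def test_halved_function_distances(self):
        s = pd.DataFrame({"F": [0.5, 0.7], "T_bac": [1.0, 1.4],
                          "T_arc": [1.0, 1.4], "T_mic": [1.0, 1.4]},
                         index=["a", "b"])
        r = efs.ft_ratio(s)
        np.testing.assert_allclose(r["ft_mic"], 0.5)
        assert (r["stability_class"] == "stable").all()

    def test_zero_denominator_flagged(self):
        s = pd.DataFrame({"F": [0.5], "T_bac": [0.0], "T_arc": [1.0],
                          "T_mic": [0.0]}, index=["a"])
        r = efs.ft_ratio(s)
        assert np.isnan(r["ft_mic"].iloc[0])
        assert r["stability_class"].iloc[0] == "undefined"

    def test_invariant_to_sample_order_and_common_scaling(self, rng):
        raw_f, raw_b = rng.random((6, 4)), rng.random((6, 7))
        func = _rel(raw_f / raw_f.sum(1, keepdims=True), "p", "function")
        bac = _rel(raw_b / raw_b.sum(1, keepdims=True), "b", "bacteria")
        r = efs.ft_ratio(efs.distance_summaries(func, bac))
        order = list(reversed(func.sample_ids))
        r_perm = efs.ft_ratio(efs.distance_summaries(
            func.subset_samples(order), bac.subset_samples(order)))
        np.testing.assert_allclose(r.loc[order, "ft_mic"], r_perm["ft_mic"],
                                   atol=1e-12)
        # scaling both spaces by the same constant cancels in the ratio
        s = efs.distance_summaries(func, bac)
        r_scaled = efs.ft_ratio(s * 3.7)
        np.testing.assert_allclose(r["ft_mic"], r_scaled["ft_mic"], atol=1e-12)
        # scaling F alone does not cancel (documented asymmetry)
        s_f = s.copy()
        s_f["F"] *= 2.0
        assert not np.allclose(efs.ft_ratio(s_f)["ft_mic"], r["ft_mic"])


class TestGeneratorCoupling:
    def test_identity_gene_content_gives_exact_unity(self):
        """redundancy 1, no noise, one gene per taxon: F:T_mic = 1 exactly."""
        cfg = small_config(seed=3, noise_sigma=0.0, redundancy=1)
        meta = sample_frame(cfg)
        bac, arc = generate_taxa(cfg, meta)
        taxa_ids = list(bac.feature_ids) + list(arc.feature_ids)
        incidence = pd.DataFrame(np.eye(len(taxa_ids)), index=taxa_ids,
                                 columns=[f"gene{i:03d}" for i in range(len(taxa_ids))])
        G = GeneContentMatrix(incidence=incidence,
                              pathway_of_gene={c: "N" for c in incidence.columns})
        genes = generate_functions(bac, arc, G, 0.0, cfg)
        func_rel = preprocess.to_relative(genes)
        bac_rel = preprocess.to_relative(bac)
        arc_rel = preprocess.to_relative(arc)
        s = efs.distance_summaries(func_rel, bac_rel, arc_rel, tmic_norm="joint")
        r = efs.ft_ratio(s)
        np.testing.assert_allclose(r["ft_mic"], 1.0, atol=1e-12)

    def test_median_ft_decreases_with_redundancy(self):
        """Monotone at redundancy 1 > 5 > 20 on matched seeds."""
        medians = {}
        for red in (1, 5, 20):
            vals = []
            for seed in range(5):
                cfg = small_config(seed=seed, redundancy=red, noise_sigma=0.2)
                meta = sample_frame(cfg)
                bac, arc = generate_taxa(cfg, meta)
                G = gene_content_matrix(list(bac.feature_ids) + list(arc.feature_ids), cfg)
                genes = generate_functions(bac, arc, G, cfg.noise_sigma, cfg)
                func_rel = preprocess.to_relative(preprocess.map_genes_to_pathways(genes))
                bac_rel = preprocess.aggregate_dominant(preprocess.to_relative(bac), 0.01)
                arc_rel = preprocess.aggregate_dominant(preprocess.to_relative(arc), 0.01)
                r = efs.ft_ratio(efs.distance_summaries(func_rel, bac_rel, arc_rel))
                vals.append(r["ft_mic"].median())
            medians[red] = np.median(vals)
        assert medians[20] < medians[5] < medians[1]


class TestGroupContrast:
    def test_identical_groups(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        g = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        res = efs.group_contrast(v, g, labels=("x", "y"))
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_constant_separated_groups(self):
        v = pd.Series([0.0] * 4 + [1.0] * 4, index=list("abcdefgh"))
        g = pd.Series(["x"] * 4 + ["y"] * 4, index=list("abcdefgh"))
        res = efs.group_contrast(v, g, labels=("x", "y"), variant="student")
        # permutation oracle: only 1 of C(8,4)=70 labelings is this extreme
        # (two-sided: 2/70); the epsilon-guarded t must report p below that
        assert res.p < 2 / 70
        assert res.t != 0

    def test_welch_hand_computed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        v = pd.Series(np.concatenate([a, b]))
        g = pd.Series(["a"] * 4 + ["b"] * 3)
        res = efs.group_contrast(v, g, labels=("a", "b"))
        assert res.t == pytest.approx(t_hand, abs=1e-6)
        assert res.df == pytest.approx(df_hand, abs=1e-6)
        assert res.p == pytest.approx(p_hand, abs=1e-6)


class TestPairedWaterRatio:
    def _frame(self, inflow_vals, res_vals):
        rows, data = [], {}
        i = 0
        for r, (iw, rw) in enumerate(zip(inflow_vals, res_vals)):
            for v, wt in ((iw, "inflow"), (rw, "reservoir"), (rw, "reservoir")):
                sid = f"s{i}"; i += 1
                rows.append({"sample_id": sid, "reservoir": f"R{r}",
                             "water_type": wt, "season": "August",
                             "depth_m": 0.0})
                data[sid] = v
        meta = pd.DataFrame(rows).set_index("sample_id")
        per_sample = pd.DataFrame({"F": pd.Series(data)})
        per_sample["T_mic"] = per_sample["F"]
        per_sample["ft_mic"] = 1.0
        return per_sample, meta

    def test_identity_gives_unit_ratio(self):
        per_sample, meta = self._frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = efs.paired_water_ratio(per_sample, meta)
        assert out.loc["F", "mean_ratio"] == pytest.approx(1.0)
        assert out.loc["F", "p"] == pytest.approx(1.0)

    def test_constant_ratios_use_sign_test(self):
        per_sample, meta = self._frame([1.2, 2.4, 3.6, 4.8], [1.0, 2.0, 3.0, 4.0])
        out = efs.paired_water_ratio(per_sample, meta)
        assert out.loc["F", "mean_ratio"] == pytest.approx(1.2)
        # all four ratios above 1: two-sided sign test p = 2 * (1/2)^4
        assert out.loc["F", "p"] == pytest.approx(0.125, abs=1e-12)

    def test_inflow_turnover_raises_mean_ratio(self):
        """Extra inflow turnover in the generator pushes the F ratio above 1."""
        wins = 0
        for seed in range(20):
            cfg = small_config(seed=seed, inflow_turnover_factor=3.0)
            meta = sample_frame(cfg)
            bac, arc = generate_taxa(cfg, meta)
            G = gene_content_matrix(list(bac.feature_ids) + list(arc.feature_ids), cfg)
            genes = generate_functions(bac, arc, G, cfg.noise_sigma, cfg)
            func_rel = preprocess.to_relative(preprocess.map_genes_to_pathways(genes))
            bac_rel = preprocess.to_relative(bac)
            arc_rel = preprocess.to_relative(arc)
            r = efs.ft_ratio(efs.distance_summaries(func_rel, bac_rel, arc_rel))
            out = efs.paired_water_ratio(r, meta)
            wins += out.loc["F", "mean_ratio"] > 1.0
        assert wins >= 18
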