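import numpy as np
import pandas as pd
import pytest

from meqaxis import (
    AxisCandidate,
    FunnelThresholds,
    MeqtlRecord,
    correlation_filter,
    expression_filter,
    intersect_meqtl,
    ld_prune,
    ld_r2,
    m_to_beta,
    run_funnel,
    simulate_cohort,
    simulate_meqtl_tables,
)
from meqaxis.simulate import SimulationConfig

from conftest import funnel_config
from oracles import pearson_r2


def _rec(snp, cpg, sign, p, source):
    return MeqtlRecord(snp, cpg, sign, p, min(1.0, p * 2), source)


class TestIntersect:
    def test_reported_pair_retained(self):
        # rs939408-cg09596674: signs (-,-), p 1.75e-5 tissue / 6.89e-8 blood
        recs = [
            _rec("rs939408", "cg09596674", "-", 1.75e-5, "tissue"),
            _rec("rs939408", "cg09596674", "-", 6.89e-8, "blood"),
        ]
        out = intersect_meqtl({"cg09596674"}, recs)
        assert len(out) == 1
        cand = out[0]
        assert (cand.beta_sign_tissue, cand.beta_sign_blood) == ("-", "-")

    def test_sign_clash_excluded_by_default_but_configurable(self):
        recs = [
            _rec("s1", "c1", "+", 1e-8, "tissue"),
            _rec("s1", "c1", "-", 1e-8, "blood"),
        ]
        assert intersect_meqtl({"c1"}, recs) == []
        assert len(intersect_meqtl({"c1"}, recs, require_sign_agreement=False)) == 1

    def test_single_source_pair_excluded(self):
        assert intersect_meqtl({"c1"}, [_rec("s1", "c1", "+", 1e-8, "tissue")]) == []

    def test_output_subset_of_consensus(self):
        consensus = {"c1", "c2", "c3"}
        recs = []
        for cpg in ["c1", "c2", "c3", "c4", "c5"]:
            recs += [_rec("s_" + cpg, cpg, "+", 1e-8, "tissue"),
                     _rec("s_" + cpg, cpg, "+", 1e-8, "blood")]
        out = intersect_meqtl(consensus, recs)
        assert {c.cpg_id for c in out} <= consensus and len(out) == 3


class TestCorrelationFilter:
    def _frames(self, m_vals, e_vals):
        idx = [f"S{i}" for i in range(len(m_vals))]
        meth = pd.DataFrame({"c1": m_to_beta(np.asarray(m_vals))}, index=idx)
        expr = pd.DataFrame({"g1": e_vals}, index=idx)
        return meth, expr

    def test_self_correlation_is_one(self):
        m = np.linspace(-2, 2, 20)
        meth, expr = self._frames(m, 2.0**m - 2.0 ** m.min() + 0.1)
        # expression chosen so log2(e+1) is monotone in m but not affine;
        # replace with exact affine map for the identity check
        expr["g1"] = 2.0 ** (m + 3) - 1.0  # log2(e+1) = m+3, exactly linear in M
        out = correlation_filter(meth, expr, [AxisCandidate("s1", "c1")], {"c1": "g1"})
        assert out[0].correlation_r == pytest.approx(1.0, abs=1e-12)

    def test_threshold_is_strict(self):
        # sample r constructed to be exactly 0.29: significant p (n=2000)
        # but below the strict |r| > 0.3 gate
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.normal(size=n)
        u = rng.normal(size=n)
        x -= x.mean()
        u -= u.mean()
        u -= (u @ x) / (x @ x) * x  # orthogonal to x
        y = 0.29 * x / np.linalg.norm(x) + np.sqrt(1 - 0.29**2) * u / np.linalg.norm(u)
        y = 3.0 + y  # keep expression positive; correlation unchanged
        meth = pd.DataFrame({"c1": m_to_beta(x)}, index=[f"S{i}" for i in range(n)])
        expr = pd.DataFrame({"g1": 2.0**y - 1.0}, index=meth.index)  # log2(e+1) == y
        r_check = np.corrcoef(x, np.log2(expr["g1"] + 1))[0, 1]
        assert r_check == pytest.approx(0.29, abs=1e-9)
        out = correlation_filter(meth, expr, [AxisCandidate("s1", "c1")], {"c1": "g1"})
        assert out == []

    def test_planted_negative_slope_retained_with_sign(self, small_cohort):
        cfg, c = small_cohort
        tumor = c.tumor_samples
        out = correlation_filter(
            c.methylation_beta, c.expression, [AxisCandidate("snp0001", "cpg00001")],
            c.cpg_gene_map, samples=tumor,
        )
        assert len(out) == 1 and out[0].correlation_r < -0.3

    def test_constant_expression_dropped_with_warning(self):
        meth, expr = self._frames(np.linspace(-1, 1, 10), np.full(10, 5.0))
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_filter(meth, expr, [AxisCandidate("s1", "c1")], {"c1": "g1"})
        assert out == []


class TestExpressionFilter:
    def _frame(self, tumor_mean, normal_mean, n=30, sd=0.3, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.normal(tumor_mean, sd, size=n), rng.normal(normal_mean, sd, size=n)
        ])
        labels = ["tumor"] * n + ["normal"] * n
        df = pd.DataFrame({"g1": np.maximum(vals, 0.0)},
                          index=[f"S{i}" for i in range(2 * n)])
        return df, labels

    def test_low_gene_kept_with_direction(self):
        df, labels = self._frame(10.0, 40.0)
        kept = expression_filter(df, labels)
        fc, p_fdr, direction = kept["g1"]
        assert fc == pytest.approx(0.25, abs=0.02) and direction == "Low" and p_fdr < 0.05

    def test_fc_between_bounds_excluded(self):
        df, labels = self._frame(18.0, 10.0)  # FC 1.8, highly significant
        assert expression_filter(df, labels) == {}

    def test_planted_low_gene_recovered_across_seeds(self):
        from meqaxis import PlantedAxis

        hits = 0
        for seed in range(10):
            ax = PlantedAxis(0, 0, 0, meqtl_beta=0.0, tumor_meth_shift=2.0,
                             meth_expr_slope=-1.0, per_allele_log_or=0.0)
            cfg = SimulationConfig(n_cases=2, n_controls=2, n_tumor_tissue=50,
                                   n_normal_tissue=50, n_snps=2, n_cpgs=5, n_genes=5,
                                   planted_axes=(ax,), seed=seed)
            c = simulate_cohort(cfg)
            ts = c.tissue_samples
            kept = expression_filter(c.expression.loc[ts], c.tissue_labels)
            if "gene001" in kept and kept["gene001"][2] == "Low":
                hits += 1
        assert hits >= 9

    def test_zero_normal_mean_dropped(self):
        df = pd.DataFrame({"g1": [1.0, 2.0, 0.0, 0.0]}, index=list("abcd"))
        with pytest.warns(UserWarning, match="zero normal"):
            kept = expression_filter(df, ["tumor", "tumor", "normal", "normal"])
        assert kept == {}


class TestLdR2:
    def test_self_and_flip(self):
        a = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        low = 0
        rng_master = np.random.default_rng(77)
        for _ in range(20):
            seed = rng_master.integers(2**31)
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, 0.3, size=2000)
            b = rng.binomial(2, 0.3, size=2000)
            if ld_r2(a, b) < 0.01:
                low += 1
        assert low >= 18

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(10, 60)
            a = rng.binomial(2, rng.uniform(0.1, 0.5), size=n)
            b = rng.binomial(2, rng.uniform(0.1, 0.5), size=n)
            if np.var(a) == 0 or np.var(b) == 0:
                continue
            assert ld_r2(a, b) == pytest.approx(pearson_r2(a, b), abs=1e-10)

    def test_zero_variance_names_snp(self):
        with pytest.raises(ValueError, match="rsX"):
            ld_r2(np.zeros(10), np.array([0, 1, 2] * 3 + [1]), snp_a="rsX")


def _cand(snp, p):
    return AxisCandidate(snp_id=snp, cpg_id="c_" + snp, meqtl_p_tissue=p)


class TestLdPrune:
    def test_smallest_p_snp_dominates_cluster(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=100)
        ref = pd.DataFrame({"s1": g, "s2": g})  # perfectly correlated
        pruned, missing, _ = ld_prune([_cand("s1", 1e-4), _cand("s2", 1e-8)], ref)
        assert [c.snp_id for c in pruned] == ["s2"] and missing == []

    def test_maf_gate(self):
        g = np.zeros(100, dtype=int)
        g[:8] = 1  # MAF 0.04
        ref = pd.DataFrame({"s1": g})
        pruned, _, stages = ld_prune([_cand("s1", 1e-8)], ref)
        assert pruned == [] and stages[0].n_out == 0

    def test_missing_snp_reported_not_fatal(self):
        ref = pd.DataFrame({"s1": np.random.default_rng(0).binomial(2, 0.3, 50)})
        pruned, missing, _ = ld_prune([_cand("s1", 1e-6), _cand("sX", 1e-9)], ref)
        assert missing == ["sX"] and [c.snp_id for c in pruned] == ["s1"]

    def test_kept_set_pairwise_below_threshold_and_maximal(self):
        # greedy output: all kept pairs r2 < 0.8, and every dropped SNP
        # conflicts with an earlier-kept SNP (maximality under the order)
        rng = np.random.default_rng(9)
        base = rng.binomial(1, 0.5, size=(300, 10))
        cols, cands = {}, []
        for i in range(50):
            src = base[:, i % 10]
            flip = rng.random(300) < 0.1
            cols[f"s{i:02d}"] = np.clip(src + flip + rng.binomial(1, 0.2, 300), 0, 2)
            cands.append(_cand(f"s{i:02d}", float(rng.uniform(1e-9, 1e-3))))
        ref = pd.DataFrame(cols)
        pruned, _, _ = ld_prune(cands, ref)
        kept = [c.snp_id for c in pruned]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld_r2(ref[a], ref[b]) < 0.8
        order = sorted({c.snp_id for c in cands}, key=lambda s: (
            min(c.meqtl_p_tissue for c in cands if c.snp_id == s), s))
        mafs = {s: min(ref[s].mean() / 2, 1 - ref[s].mean() / 2) for s in order}
        for snp in order:
            if mafs[snp] <= 0.05 or snp in kept:
                continue
            earlier = [k for k in kept if order.index(k) < order.index(snp)]
            assert any(ld_r2(ref[snp], ref[k]) >= 0.8 for k in earlier)

    def test_invariant_to_sample_relabeling(self):
        rng = np.random.default_rng(4)
        ref = pd.DataFrame({f"s{i}": rng.binomial(2, 0.3, 200) for i in range(6)})
        cands = [_cand(f"s{i}", 10.0 ** -(i + 3)) for i in range(6)]
        out1, _, _ = ld_prune(cands, ref)
        shuffled = ref.sample(frac=1.0, random_state=1)
        out2, _, _ = ld_prune(cands, shuffled)
        assert [c.snp_id for c in out1] == [c.snp_id for c in out2]


def _run(cfg, seed_b, seed_meqtl, thresholds=FunnelThresholds()):
    ca = simulate_cohort(cfg)
    cb = simulate_cohort(SimulationConfig(**{**cfg.__dict__, "seed": seed_b}))
    tis, blo = simulate_meqtl_tables(cfg, seed=seed_meqtl)
    ts = ca.tissue_samples
    return run_funnel(
        ca.methylation_beta.loc[ts], ca.phenotype.loc[ts, "tissue"],
        cb.methylation_beta.loc[cb.tissue_samples], cb.phenotype.loc[cb.tissue_samples, "tissue"],
        tis, blo, ca.expression.loc[ts], ca.phenotype.loc[ts, "tissue"],
        ca.cpg_gene_map, ca.genotypes.loc[ts], thresholds,
    )


class TestRunFunnel:
    def test_empty_consensus_yields_empty_report(self):
        cfg = funnel_config(seed=0, planted=False, n_cpgs=200)
        cands, report = _run(cfg, 10_000, 20_000)
        assert cands == []
        frame = report.to_frame()
        assert frame.loc[frame.stage == "consensus_diff_methylation", "items_out"].item() == 0

    def test_counts_non_increasing_after_intersection(self):
        cfg = funnel_config(seed=1, n_cpgs=600)
        _, report = _run(cfg, 10_001, 20_001)
        outs = [s.n_out for s in report.stages[1:]]
        assert all(a >= b for a, b in zip(outs, outs[1:]))
        assert all(s.n_out <= s.n_in for s in report.stages)

    def test_permissive_thresholds_keep_all_intersected_pairs(self):
        cfg = funnel_config(seed=2, n_cpgs=600)
        loose = FunnelThresholds(r_threshold=-1.0, r_p_threshold=1.1, fc_low=1.0,
                                 fc_high=1.0, expr_fdr=1.1, maf_threshold=0.0,
                                 r2_threshold=1.1)
        cands, report = _run(cfg, 10_002, 20_002, loose)
        frame = report.to_frame().set_index("stage")
        assert len(cands) == frame.loc["meqtl_intersection", "items_out"]

    def test_monotone_in_correlation_threshold(self):
        cfg = funnel_config(seed=3, n_cpgs=600)
        loose, _ = _run(cfg, 10_003, 20_003, FunnelThresholds(r_threshold=0.1))
        tight, _ = _run(cfg, 10_003, 20_003, FunnelThresholds(r_threshold=0.6))
        loose_ids = {(c.snp_id, c.cpg_id) for c in loose}
        tight_ids = {(c.snp_id, c.cpg_id) for c in tight}
        assert tight_ids <= loose_ids
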