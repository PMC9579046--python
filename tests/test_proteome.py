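"""Label-free roll-up, normalization, imputation and moderated statistics."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radpep.proteome import (
    classify_volcano,
    foreground_from_de,
    impute_mle,
    moderated_de,
    normalize_scalar,
    over_representation,
    rollup_top3,
    twoway_anova,
)
from radpep.types import QuantMatrix


def _meta(samples, condition="control", tp=24):
    rows = []
    for i, s in enumerate(samples):
        if isinstance(s, tuple):
            sid, cond, t = s
        else:
            sid, cond, t = s, condition, tp
        rows.append({"sample_id": sid, "condition": cond, "timepoint_h": t,
                     "replicate": i + 1})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Top-3 roll-up


def _pep_frame(mapping, samples=("s1",)):
    """mapping: {(protein, peptide): [values per sample]}"""
    idx = pd.MultiIndex.from_tuples(list(mapping), names=["protein", "peptide"])
    return pd.DataFrame(list(mapping.values()), index=idx, columns=list(samples))


def test_rollup_examples():
    vals = _pep_frame(
        {
            ("A", "p1"): [10.0],
            ("A", "p2"): [5.0],
            ("A", "p3"): [2.0],
            ("A", "p4"): [1.0],
            ("B", "q1"): [10.0],
            ("B", "q2"): [5.0],
        }
    )
    qm = rollup_top3(vals, _meta(["s1"]))
    assert qm.values.loc["A", "s1"] == 17.0  # top-3 sum
    assert qm.values.loc["B", "s1"] == 15.0  # all available when < 3


def test_rollup_excludes_shared_peptides():
    vals = _pep_frame(
        {
            ("A", "shared"): [100.0],
            ("B", "shared"): [100.0],
            ("A", "pa"): [10.0],
            ("B", "pb"): [20.0],
        }
    )
    qm = rollup_top3(vals, _meta(["s1"]))
    assert qm.values.loc["A", "s1"] == 10.0
    assert qm.values.loc["B", "s1"] == 20.0


def test_rollup_protein_without_unique_peptides_omitted():
    vals = _pep_frame({("A", "shared"): [5.0], ("B", "shared"): [5.0]})
    qm = rollup_top3(vals, _meta(["s1"]))
    assert list(qm.values.index) == []


def test_rollup_permutation_invariant_and_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n_prot = rng.integers(1, 5)
        entries = {}
        for p in range(n_prot):
            for q in range(rng.integers(1, 6)):
                entries[(f"P{p}", f"P{p}_pep{q}")] = [float(rng.uniform(0, 100))]
        vals = _pep_frame(entries)
        qm = rollup_top3(vals, _meta(["s1"]))
        perm = vals.sample(frac=1, random_state=int(rng.integers(1e6)))
        qm2 = rollup_top3(perm, _meta(["s1"]))
        pd.testing.assert_frame_equal(qm.values, qm2.values)
        # brute-force oracle: sort each protein's values, sum largest 3
        for p in qm.values.index:
            vv = sorted(
                (v[0] for (pp, _), v in entries.items() if pp == p), reverse=True
            )
            assert qm.values.loc[p, "s1"] == pytest.approx(sum(vv[:3]))


# ---------------------------------------------------------------------------
# Scalar normalization


def _qm(values, samples):
    return QuantMatrix(
        pd.DataFrame(values, columns=list(samples)), _meta(list(samples))
    )


def test_normalize_factor_half_for_doubled_sample():
    rng = np.random.default_rng(0)
    base = rng.lognormal(10, 1, size=50)
    qm = _qm({"s1": base, "s2": base, "s3": 4 * base}, ["s1", "s2", "s3"])
    _, factors = normalize_scalar(qm)
    # reference = geometric mean; s3 is 4x the others, ref = cbrt(4)x base
    assert factors["s3"] / factors["s1"] == pytest.approx(0.25, rel=1e-9)


def test_normalize_identity_for_identical_samples():
    base = np.linspace(1, 100, 40)
    qm = _qm({"s1": base, "s2": base}, ["s1", "s2"])
    normed, factors = normalize_scalar(qm)
    assert np.allclose(factors, 1.0)
    assert np.allclose(normed.values, qm.values)


def test_normalize_recovers_injected_scales_and_is_idempotent():
    rng = np.random.default_rng(7)
    base = rng.lognormal(12, 1.5, size=200)
    scales = {"s1": 1.0, "s2": 2.5, "s3": 0.4}
    qm = _qm({s: base * c for s, c in scales.items()}, list(scales))
    normed, factors = normalize_scalar(qm)
    # factors recover inverse of injected per-sample scale (up to common ref)
    rel = factors / factors["s1"]
    for s, c in scales.items():
        assert rel[s] == pytest.approx(1.0 / c, rel=1e-9)
    _, factors2 = normalize_scalar(normed)
    assert np.allclose(factors2, 1.0, atol=1e-9)


def test_normalize_too_few_shared_features_errors():
    qm = _qm({"s1": [1.0, np.nan], "s2": [1.0, 2.0]}, ["s1", "s2"])
    with pytest.raises(ValueError, match="shared"):
        normalize_scalar(qm)


# ---------------------------------------------------------------------------
# ML imputation


def test_impute_fixed_point_is_group_mean():
    meta = _meta(["a1", "a2", "a3"])
    qm = QuantMatrix(
        pd.DataFrame({"a1": [5.0], "a2": [np.nan], "a3": [7.0]},
                     index=["f1"]), meta, log_scale=True)
    out, flags = impute_mle(qm)
    assert out.values.loc["f1", "a2"] == pytest.approx(6.0)
    assert flags == []


def test_impute_no_missing_is_identity_and_all_missing_flagged():
    meta = _meta([("a1", "control", 24), ("a2", "control", 24),
                  ("b1", "irradiated", 24), ("b2", "irradiated", 24)])
    df = pd.DataFrame(
        {"a1": [1.0, np.nan], "a2": [2.0, np.nan], "b1": [3.0, 4.0],
         "b2": [5.0, 6.0]},
        index=["f1", "f2"],
    )
    out, flags = impute_mle(QuantMatrix(df, meta, log_scale=True))
    assert out.values.loc["f1"].tolist() == [1.0, 2.0, 3.0, 5.0]
    assert np.isnan(out.values.loc["f2", "a1"])  # left missing
    assert ("f2", ("control", 24)) in flags
    assert out.values.loc["f2", ["b1", "b2"]].tolist() == [4.0, 6.0]


# ---------------------------------------------------------------------------
# Moderated DE


def _two_group_qm(a, b):
    na, nb = a.shape[1], b.shape[1]
    samples = [(f"a{i}", "control", 24) for i in range(na)] + [
        (f"b{i}", "irradiated", 24) for i in range(nb)
    ]
    df = pd.DataFrame(
        np.hstack([a, b]), columns=[s[0] for s in samples],
        index=[f"f{i}" for i in range(a.shape[0])],
    )
    return QuantMatrix(df, _meta(samples), log_scale=True)


def test_moderated_null_p_uniform():
    rng = np.random.default_rng(1)
    a = rng.normal(10, 1, size=(2000, 3))
    b = rng.normal(10, 1, size=(2000, 3))
    qm = _two_group_qm(a, b)
    de = moderated_de(qm, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
    ks = stats.kstest(de["p"], "uniform")
    assert ks.pvalue > 0.01


def test_moderated_infinite_prior_df_is_z_test():
    # identical within-feature deviations -> zero dispersion of log s2 ->
    # infinite prior df; the moderated test converges to the pooled z-test
    # (total df is capped at the pooled residual df, so the match tightens
    # as features grow)
    n = 1000
    mus = np.linspace(10.0, 20.0, n)
    dev = np.array([-1.0, 0.0, 1.0])
    a = mus[:, None] + dev[None, :]
    b = mus[:, None] + dev[None, :] + np.linspace(0, 2, n)[:, None]
    qm = _two_group_qm(a, b)
    de = moderated_de(qm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    assert np.isinf(de["prior_df"]).all()
    assert (de["df_total"] == 4 * n).all()
    s2 = a.var(axis=1, ddof=1)  # identical across features
    z = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(s2 * (2 / 3))
    expected = 2 * stats.norm.sf(np.abs(z))
    assert np.allclose(de["p"], expected, rtol=5e-3, atol=1e-12)


def test_moderated_exact_recovery_in_no_noise_limit():
    mus = np.full((50, 3), 10.0)
    jitter = np.tile([0.0, 1e-9, -1e-9], (50, 1))
    a = mus + jitter
    b = mus + 1.0 + jitter
    qm = _two_group_qm(a, b)
    de = moderated_de(qm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    assert np.allclose(de["log2fc"], 1.0)
    assert (de["p"] < 1e-10).all()


def test_moderated_small_group_errors():
    qm = _two_group_qm(np.ones((3, 1)), np.ones((3, 2)))
    with pytest.raises(ValueError, match="at least 2"):
        moderated_de(qm, ["a0"], ["b0", "b1"])


def test_moderated_matches_limma_oracle(tmp_path):
    """Cross-check prior estimation and moderated p against Bioconductor
    limma's squeezeVar/eBayes on a small matrix."""
    rng = np.random.default_rng(3)
    a = rng.normal(8, 1, size=(60, 3))
    effects = rng.normal(0, 1, size=60)
    b = rng.normal(8, 1, size=(60, 3)) + effects[:, None]
    qm = _two_group_qm(a, b)
    de = moderated_de(qm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    mat = tmp_path / "m.tsv"
    qm.values.to_csv(mat, sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(
        textwrap.dedent(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            m <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(Intercept=1, Diff=c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(p=fit$p.value[,"Diff"], lfc=fit$coefficients[,"Diff"],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, args[2], sep="\\t", quote=FALSE)
            """
        )
    )
    out = tmp_path / "limma.tsv"
    subprocess.run(
        ["Rscript", str(script), str(mat), str(out)], check=True,
        capture_output=True,
    )
    ref = pd.read_csv(out, sep="\t")
    assert np.allclose(de["log2fc"], ref["lfc"], atol=1e-8)
    assert de["prior_df"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-3)
    assert np.allclose(de["p"], ref["p"], rtol=1e-4)


# ---------------------------------------------------------------------------
# Two-way ANOVA


def _anova_qm(y, timepoints=(0, 24), reps=3):
    samples = []
    for cond in ("control", "irradiated"):
        for tp in timepoints:
            for r in range(1, reps + 1):
                samples.append((f"{cond}{tp}_r{r}", cond, tp))
    df = pd.DataFrame(y, columns=[s[0] for s in samples],
                      index=[f"f{i}" for i in range(y.shape[0])])
    return QuantMatrix(df, _meta(samples), log_scale=True)


def test_anova_matches_statsmodels_oracle():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, size=(4, 12))
    qm = _anova_qm(y)
    res = twoway_anova(qm)
    meta = qm.sample_meta
    for i, fid in enumerate(qm.values.index):
        df = pd.DataFrame(
            {
                "y": qm.values.loc[fid].to_numpy(),
                "trt": meta["condition"].to_numpy(),
                "tp": meta["timepoint_h"].astype(str).to_numpy(),
            }
        )
        fit = ols("y ~ C(trt) * C(tp)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.loc[fid, "F"] == pytest.approx(
            tab.loc["C(trt):C(tp)", "F"], rel=1e-8
        )
        assert res.loc[fid, "p"] == pytest.approx(
            tab.loc["C(trt):C(tp)", "PR(>F)"], rel=1e-8
        )


def test_anova_detects_injected_interaction():
    rng = np.random.default_rng(6)
    y = rng.normal(0, 0.05, size=(1, 12))
    # effect grows with time only under treatment: classic interaction
    y[0, 9:12] += 3.0  # irradiated, tp=24
    res = twoway_anova(_anova_qm(y))
    assert res["p"].iloc[0] < 1e-4


def test_anova_single_replicate_flagged():
    y = np.zeros((2, 4))
    res = twoway_anova(_anova_qm(y, reps=1))
    assert (res["flag"] == "no_residual_df").all()
    assert res["p"].isna().all()


def test_anova_missing_cell_flagged():
    rng = np.random.default_rng(8)
    y = rng.normal(0, 1, size=(2, 12))
    y[1, 0] = np.nan
    res = twoway_anova(_anova_qm(y))
    assert res["flag"].iloc[1] == "missing_cell" and np.isnan(res["p"].iloc[1])
    assert np.isfinite(res["p"].iloc[0])


# ---------------------------------------------------------------------------
# Volcano classification


def test_volcano_classes_and_conservation():
    de = pd.DataFrame(
        {
            "log2fc": [1.2, 1.2, -1.5, 0.5, -0.2],
            "p": [1e-6, 1e-4, 1e-7, 1e-9, 0.5],
        },
        index=list("abcde"),
    )
    cls, counts = classify_volcano(de)
    assert cls["a"] == "up"
    assert cls["b"] == "ns"  # p above the 1e-5 cutoff
    assert cls["c"] == "down"
    assert cls["d"] == "ns"  # fold change below cutoff
    assert counts["n_up"] + counts["n_down"] + counts["n_ns"] == len(de)


# ---------------------------------------------------------------------------
# Over-representation


def test_fisher_matches_hypergeometric_tail():
    fg = [f"g{i}" for i in range(100)]
    bg = [f"g{i}" for i in range(1000)]
    gene_set = {"set1": fg[:10] + [f"g{i}" for i in range(900, 905)]}
    res = over_representation(fg, bg, gene_set)
    # brute-force hypergeometric tail: 15 set members, 100 drawn, >=10 hits
    M, n, N, k = 1000, 15, 100, 10
    expected = stats.hypergeom.sf(k - 1, M, n, N)
    assert res.loc["set1", "p"] == pytest.approx(expected, rel=1e-9)


def test_over_representation_extremes_and_null():
    fg = [f"g{i}" for i in range(20)]
    bg = [f"g{i}" for i in range(2000)]
    res = over_representation(fg, bg, {"exact": fg})
    assert res.loc["exact", "p"] < 1e-30
    rng = np.random.default_rng(11)
    sets = {
        f"s{j}": [f"g{i}" for i in rng.choice(2000, 30, replace=False)]
        for j in range(200)
    }
    null_fg = [f"g{i}" for i in rng.choice(2000, 50, replace=False)]
    res = over_representation(null_fg, bg, sets)
    assert (res["q"] < 0.05).sum() <= 2


def test_foreground_selection_cutoffs():
    de = pd.DataFrame(
        {"log2fc": [0.6, 0.5, -0.7, 0.9], "p": [0.01, 0.01, 0.02, 0.2]},
        index=list("abcd"),
    )
    assert foreground_from_de(de) == ["a", "c"]
    assert foreground_from_de(de, direction="up") == ["a"]
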