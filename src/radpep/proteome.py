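"""Label-free quantitation and differential expression.

Implements the quantitative proteome workflow: Hi-3-style roll-up of the
three most abundant unique peptides per protein, scalar-factor
normalization against a geometric-mean pseudo-reference, maximum-likelihood
imputation of missing values within condition groups, an empirical-Bayes
moderated t-test (variances shrunk toward a scaled-inverse-chi-square prior
fitted by method of moments), balanced two-way ANOVA across
treatment x time, volcano classification, and a Fisher-exact
over-representation stand-in for pathway analysis.

All statistics operate on log2-scale matrices; roll-up and normalization
operate on linear-scale abundances.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import QuantMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Top-3 roll-up


def rollup_top3(
    peptide_values: pd.DataFrame,
    sample_meta: pd.DataFrame,
    unique_only: bool = True,
    agg: str = "sum",
) -> QuantMatrix:
    """Roll peptide abundances up to proteins by the top-3 rule.

    ``peptide_values`` is indexed by a (protein, peptide) MultiIndex.
    Protein abundance per sample is the sum (or mean, ``agg='mean'``) of its
    three largest peptide abundances in that sample — all available if fewer
    than three.  With ``unique_only`` (the default) peptides mapping to more
    than one protein are excluded entirely.  Proteins left with zero usable
    peptides are omitted and logged.  Missing peptide values do not count
    toward the top three.
    """
    if peptide_values.index.nlevels != 2:
        raise ValueError("expected a (protein, peptide) MultiIndex")
    df = peptide_values
    if unique_only:
        pep_counts = df.index.to_frame(index=False).groupby(df.index.names[1])[
            df.index.names[0]
        ].nunique()
        shared = set(pep_counts.index[pep_counts > 1])
        if shared:
            df = df[~df.index.get_level_values(1).isin(shared)]

    def top3(group: pd.DataFrame) -> pd.Series:
        out = {}
        for col in group.columns:
            vals = group[col].dropna().nlargest(3)
            if len(vals) == 0:
                out[col] = np.nan
            else:
                out[col] = vals.sum() if agg == "sum" else vals.mean()
        return pd.Series(out)

    rolled = df.groupby(level=0, sort=True).apply(top3)
    dropped = set(peptide_values.index.get_level_values(0)) - set(rolled.index)
    for p in sorted(dropped):
        log.info("protein %s omitted: no unique peptides", p)
    return QuantMatrix(rolled, sample_meta)


# ---------------------------------------------------------------------------
# Scalar normalization


def normalize_scalar(qm: QuantMatrix, min_shared: int = 10) -> tuple[QuantMatrix, pd.Series]:
    """Scalar-factor normalization of every sample to a geometric-mean
    pseudo-reference.

    The reference is the feature-wise geometric mean over samples, computed
    on features observed in all samples.  Each sample is multiplied by one
    scalar ``exp(median_f(log ref_f - log x_fs))`` so that afterwards the
    median log-ratio of every sample to the reference is 0.  Returns the
    normalized matrix and the per-sample factors.
    """
    vals = qm.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        lv = np.log(vals)
    shared = np.isfinite(lv).all(axis=1)
    if shared.sum() < min_shared:
        raise ValueError(
            f"only {int(shared.sum())} features shared across all samples "
            f"(need >= {min_shared})"
        )
    ref = lv[shared].mean(axis=1)
    d = np.median(ref[:, None] - lv[shared], axis=0)
    factors = pd.Series(np.exp(d), index=qm.sample_ids, name="factor")
    out = qm.values * factors
    return QuantMatrix(out, qm.sample_meta.copy()), factors


# ---------------------------------------------------------------------------
# ML imputation


def impute_mle(
    qm: QuantMatrix,
    group_cols: tuple[str, ...] = ("condition", "timepoint_h"),
) -> tuple[QuantMatrix, list[tuple[str, tuple]]]:
    """Maximum-likelihood imputation of a log-scale matrix.

    Under a per-feature Gaussian across the samples of each condition group
    the EM fixed point sets each missing entry to the converged conditional
    mean, which for independent samples is the observed within-group mean.
    Features fully missing in a group are left missing and flagged; returns
    the imputed matrix and the flags as (feature, group-key) tuples.
    Imputation is within condition groups, not global, so true treatment
    effects are not shrunk.
    """
    if np.nanmax(qm.values.to_numpy(dtype=float)) > 50:
        log.warning("matrix maximum > 50; input may not be log-scale")
    values = qm.values.copy()
    flags: list[tuple[str, tuple]] = []
    groups = qm.sample_meta.groupby(list(group_cols), sort=True).groups
    for key, samples in groups.items():
        block = values.loc[:, list(samples)]
        means = block.mean(axis=1)
        all_missing = block.isna().all(axis=1)
        for feat in values.index[all_missing]:
            flags.append((feat, key if isinstance(key, tuple) else (key,)))
        fill = block.apply(lambda col: col.fillna(means))
        values.loc[:, list(samples)] = fill
    return QuantMatrix(values, qm.sample_meta.copy(), log_scale=True), flags


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t-test


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_inverse_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior for
    residual variances, on the log scale: returns (prior df d0, prior
    variance s0^2).  d0 may be inf when observed variances are no more
    dispersed than chi-square sampling alone explains."""
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(s2[ok].mean()) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    ebar = e.mean()
    evar = e.var(ddof=1)
    resid = evar - special.polygamma(1, df / 2)
    if resid <= 0:
        # no excess dispersion beyond chi-square sampling: one common
        # variance, estimated by the arithmetic mean of the sample variances
        return math.inf, float(s2[ok].mean())
    d0 = 2 * trigamma_inverse(resid)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2) - math.log(d0 / 2)))
    return float(d0), s0_sq


def moderated_de(
    qm: QuantMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Moderated two-group comparison on a log2-scale matrix.

    ``log2fc = mean(B) - mean(A)``.  Per-feature residual variances are
    shrunk toward a prior fitted by method of moments on the scaled
    inverse-chi-square model; the moderated t statistic has
    ``d0 + dfA + dfB`` degrees of freedom.  Features with missing values in
    either group get NaN results.  Returns columns log2fc, t, p, q,
    s2, s2_post, df_total.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = qm.values[group_a].to_numpy(dtype=float)
    b = qm.values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    complete = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    df_resid = na + nb - 2
    pooled = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / df_resid
    d0, s0_sq = fit_inverse_chisq_prior(pooled[complete], df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(pooled, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df_resid * pooled) / (d0 + df_resid)
    # total df capped at the pooled residual df: the prior cannot contribute
    # more information than the data it was estimated from
    df_pooled = df_resid * int(complete.sum())
    df_total = min(d0 + df_resid, df_pooled)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    zero_noise = se == 0
    p = np.where(zero_noise, np.where(lfc == 0, 1.0, 0.0), p)
    p = np.where(complete, p, np.nan)
    lfc = np.where(complete, lfc, np.nan)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "t": np.where(complete, t, np.nan),
            "p": p,
            "q": q,
            "s2": pooled,
            "s2_post": s2_post,
            "df_total": df_total,
            "prior_df": d0,
        },
        index=qm.values.index,
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA


def twoway_anova(
    qm: QuantMatrix,
    treatment_col: str = "condition",
    time_col: str = "timepoint_h",
) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA per feature (treatment x time).

    Returns interaction F and p per feature (vectorized closed form over the
    cell-mean decomposition).  Features with any missing cell value, or
    designs with a single replicate per cell (no residual degrees of
    freedom), yield NaN with ``flag`` set.
    """
    meta = qm.sample_meta
    treatments = sorted(meta[treatment_col].unique())
    times = sorted(meta[time_col].unique())
    a, t = len(treatments), len(times)
    cells = {}
    r = None
    for trt in treatments:
        for tp in times:
            cols = list(
                meta.index[(meta[treatment_col] == trt) & (meta[time_col] == tp)]
            )
            if not cols:
                raise ValueError(f"empty design cell ({trt}, {tp})")
            if r is None:
                r = len(cols)
            elif len(cols) != r:
                raise ValueError("unbalanced design: unequal replicates per cell")
            cells[(trt, tp)] = qm.values[cols].to_numpy(dtype=float)
    assert r is not None
    n_feat = len(qm.values.index)
    if r == 1:
        return pd.DataFrame(
            {"F": np.nan, "p": np.nan, "flag": "no_residual_df"},
            index=qm.values.index,
        )
    y = np.empty((n_feat, a, t, r))
    for i, trt in enumerate(treatments):
        for j, tp in enumerate(times):
            y[:, i, j, :] = cells[(trt, tp)]
    complete = np.isfinite(y).all(axis=(1, 2, 3))
    m_ij = y.mean(axis=3)
    m_i = m_ij.mean(axis=2)
    m_j = m_ij.mean(axis=1)
    m = m_ij.mean(axis=(1, 2))
    inter = m_ij - m_i[:, :, None] - m_j[:, None, :] + m[:, None, None]
    ss_int = r * (inter**2).sum(axis=(1, 2))
    df_int = (a - 1) * (t - 1)
    sse = ((y - m_ij[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))
    dfe = a * t * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_int / df_int) / (sse / dfe)
    p = stats.f.sf(f, df_int, dfe)
    f = np.where(complete, f, np.nan)
    p = np.where(complete, p, np.nan)
    flag = np.where(complete, "", "missing_cell")
    return pd.DataFrame({"F": f, "p": p, "flag": flag}, index=qm.values.index)


# ---------------------------------------------------------------------------
# Volcano classification


def classify_volcano(
    de: pd.DataFrame,
    p_cut: float = 1e-5,
    lfc_cut: float = 1.0,
) -> tuple[pd.Series, dict[str, int]]:
    """Classify features as up / down / ns.

    ``up`` requires ``log2fc > lfc_cut`` and ``p < p_cut`` (the study's
    volcano cutoffs: -log10 p of 5 and |log2FC| of 1); ``down`` is
    symmetric.  Returns the per-feature class plus counts.
    """
    lfc, p = de["log2fc"], de["p"]
    cls = pd.Series("ns", index=de.index, name="volcano_class")
    cls[(lfc > lfc_cut) & (p < p_cut)] = "up"
    cls[(lfc < -lfc_cut) & (p < p_cut)] = "down"
    counts = {
        "n_up": int((cls == "up").sum()),
        "n_down": int((cls == "down").sum()),
        "n_ns": int((cls == "ns").sum()),
    }
    return cls, counts


# ---------------------------------------------------------------------------
# Over-representation (generic pathway stand-in)


def foreground_from_de(
    de: pd.DataFrame, lfc_cut: float = 0.58, p_cut: float = 0.05,
    direction: str = "both",
) -> list[str]:
    """Select a pathway-analysis foreground from DE results using the
    |log2FC| > 0.58 (fold-change 1.5) and p < 0.05 convention."""
    p_ok = de["p"] < p_cut
    if direction == "up":
        m = (de["log2fc"] > lfc_cut) & p_ok
    elif direction == "down":
        m = (de["log2fc"] < -lfc_cut) & p_ok
    else:
        m = (de["log2fc"].abs() > lfc_cut) & p_ok
    return list(de.index[m.fillna(False)])


def over_representation(
    foreground: Iterable[str],
    background: Iterable[str],
    gene_sets: dict[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of each gene set in the
    foreground relative to the background universe; BH-adjusted q-values
    reported alongside."""
    fg = set(foreground)
    bg = set(background) | fg
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & bg
        a = len(fg & s)
        b = len(fg - s)
        c = len(s - fg)
        d = len(bg) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"gene_set": name, "n_set": len(s), "n_overlap": a, "p": p}
        )
    df = pd.DataFrame(rows).set_index("gene_set")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
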