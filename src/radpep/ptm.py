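"""Posttranslational-modification analytics on the immunopeptidome.

Modification burden is expressed as the ratio of unique modified
peptidoforms to unique unmodified peptides within each sample, overall,
per 9-mer position, and per modification type.  Condition comparisons use
paired two-sided t-tests across replicate pairs, with BH adjustment across
positions.  The denominator is the global unmodified-peptide count of the
relevant length class; a pseudocount of 0.5 replaces zero cells and is
flagged.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import PeptideRecord

PSEUDOCOUNT = 0.5


def _sample_groups(records: list[PeptideRecord]) -> dict[tuple, list[PeptideRecord]]:
    groups: dict[tuple, list[PeptideRecord]] = defaultdict(list)
    for r in records:
        if not r.is_decoy:
            groups[(r.condition, r.timepoint_h, r.sample_id)].append(r)
    return groups


def _counts(recs: list[PeptideRecord], length: int | None = None) -> tuple[int, int]:
    """(unique modified peptidoforms, unique unmodified peptides)."""
    modified = set()
    unmodified = set()
    for r in recs:
        if length is not None and len(r.sequence) != length:
            continue
        if r.is_modified:
            modified.add((r.sequence, tuple(sorted(r.modifications))))
        else:
            unmodified.add(r.sequence)
    return len(modified), len(unmodified)


def ptm_ratio(
    records: Iterable[PeptideRecord], by: str = "condition"
) -> pd.DataFrame:
    """Modified/unmodified ratio per replicate per group.

    ``by`` is ``"condition"`` or ``"condition_timepoint"``.  A replicate
    with zero unmodified peptides gets a NaN ratio and is flagged.
    """
    groups = _sample_groups(list(records))
    rows = []
    for (cond, tp, sid), recs in sorted(groups.items()):
        n_mod, n_unmod = _counts(recs)
        ratio = n_mod / n_unmod if n_unmod else np.nan
        rows.append(
            {
                "group": cond if by == "condition" else f"{cond}_{tp}",
                "condition": cond,
                "timepoint_h": tp,
                "sample_id": sid,
                "n_modified": n_mod,
                "n_unmodified": n_unmod,
                "ratio": ratio,
                "flag": "" if n_unmod else "no_unmodified",
            }
        )
    return pd.DataFrame(rows)


def _paired_vectors(
    per_sample: pd.DataFrame, value_col: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pair control and irradiated replicates by (timepoint order, replicate
    order) and return matched value vectors."""
    ctrl = per_sample[per_sample["condition"] == "control"].sort_values(
        ["timepoint_h", "sample_id"]
    )
    irr = per_sample[per_sample["condition"] == "irradiated"].sort_values(
        ["timepoint_h", "sample_id"]
    )
    n = min(len(ctrl), len(irr))
    return (
        ctrl[value_col].to_numpy(dtype=float)[:n],
        irr[value_col].to_numpy(dtype=float)[:n],
    )


def positional_ratio(
    records: Iterable[PeptideRecord], length: int = 9
) -> pd.DataFrame:
    """Per-position modification ratio on ``length``-mers with a paired
    test per position.

    For each position i the per-sample ratio is (# unique length-mer
    peptidoforms modified at i) / (# unique unmodified length-mers in that
    sample).  Control and irradiated replicates are paired in timepoint /
    replicate order for a two-sided paired t-test; p-values are BH-adjusted
    across the ``length`` positions.  Non-length-mers contribute to neither
    numerator nor denominator.
    """
    recs = [r for r in records if not r.is_decoy and len(r.sequence) == length]
    groups = _sample_groups(recs)
    rows = []
    for (cond, tp, sid), rr in sorted(groups.items()):
        _, n_unmod = _counts(rr, length)
        mod_at = defaultdict(set)
        for r in rr:
            if r.is_modified:
                form = (r.sequence, tuple(sorted(r.modifications)))
                for _, pos in r.modifications:
                    mod_at[pos].add(form)
        for pos in range(1, length + 1):
            ratio = len(mod_at[pos]) / n_unmod if n_unmod else np.nan
            rows.append(
                {
                    "position": pos,
                    "condition": cond,
                    "timepoint_h": tp,
                    "sample_id": sid,
                    "ratio": ratio,
                }
            )
    per_sample = pd.DataFrame(rows)
    out = []
    for pos in range(1, length + 1):
        sub = per_sample[per_sample["position"] == pos]
        c, i = _paired_vectors(sub, "ratio")
        if len(c) >= 2 and np.isfinite(c).all() and np.isfinite(i).all():
            if np.allclose(i - c, (i - c)[0]):
                # constant paired difference: zero variance, t undefined
                p = 1.0 if np.allclose(i, c) else 0.0
            else:
                p = float(stats.ttest_rel(i, c).pvalue)
        else:
            p = np.nan
        out.append(
            {
                "position": pos,
                "mean_control": float(np.nanmean(c)) if len(c) else np.nan,
                "mean_irradiated": float(np.nanmean(i)) if len(i) else np.nan,
                "p": p,
            }
        )
    df = pd.DataFrame(out)
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df


def per_ptm_compare(records: Iterable[PeptideRecord]) -> pd.DataFrame:
    """Per-modification-name condition comparison of modification ratios.

    The per-sample ratio for one modification name is (# unique peptidoforms
    carrying it) / (# unique unmodified peptides).  Zero cells receive the
    0.5 pseudocount and are flagged.  Multi-modified peptidoforms count once
    per distinct modification name they carry.
    """
    rec_list = [r for r in records if not r.is_decoy]
    groups = _sample_groups(rec_list)
    names = sorted({name for r in rec_list for name, _ in r.modifications})
    rows = []
    for (cond, tp, sid), rr in sorted(groups.items()):
        _, n_unmod = _counts(rr)
        by_name = defaultdict(set)
        for r in rr:
            if r.is_modified:
                form = (r.sequence, tuple(sorted(r.modifications)))
                for name, _ in r.modifications:
                    by_name[name].add(form)
        for name in names:
            n_mod = len(by_name[name])
            flagged = n_mod == 0 or n_unmod == 0
            num = n_mod if n_mod else PSEUDOCOUNT
            den = n_unmod if n_unmod else PSEUDOCOUNT
            rows.append(
                {
                    "modification": name,
                    "condition": cond,
                    "timepoint_h": tp,
                    "sample_id": sid,
                    "n_modified": n_mod,
                    "ratio": num / den,
                    "pseudocount": flagged,
                }
            )
    per_sample = pd.DataFrame(rows)
    out = []
    for name in names:
        sub = per_sample[per_sample["modification"] == name]
        c, i = _paired_vectors(sub, "ratio")
        if len(c) >= 2:
            diff = i - c
            if np.allclose(diff, diff[0]):
                p = 1.0 if np.allclose(i, c) else 0.0
            else:
                p = float(stats.ttest_rel(i, c).pvalue)
        else:
            p = np.nan
        out.append(
            {
                "modification": name,
                "mean_control": float(np.mean(c)) if len(c) else np.nan,
                "mean_irradiated": float(np.mean(i)) if len(i) else np.nan,
                "diff": float(np.mean(i) - np.mean(c)) if len(c) else np.nan,
                "p": p,
                "pseudocount_used": bool(sub["pseudocount"].any()),
            }
        )
    return pd.DataFrame(out)
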