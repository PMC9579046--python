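"""Proteome vs immunopeptidome cross-correlation.

Joins per-protein differential-expression results from the proteome with
per-source-protein results from the immunopeptidome roll-up, classifies
each protein by significance in either axis (p < 0.05, unadjusted, as in
scatter-plot practice; BH q-values reported additionally) and by
fold-change sign quadrant.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

P_CUT = 0.05


def join_ratios(
    proteome_de: pd.DataFrame,
    ipp_de: pd.DataFrame,
    ipp_peptides: Optional[dict[str, set[str]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Inner-join proteome and immunopeptidome DE tables on accession.

    Inputs need ``log2fc`` and ``p`` columns indexed by accession.  Returns
    the joined records (columns proteome_log2fc/p, ipp_log2fc/p plus BH
    q-values) and a summary with the overlap count, the number of
    immunopeptidome-only proteins, and (when ``ipp_peptides`` maps protein
    to its peptide sequences) the count of unique immunopeptidome-only
    peptides, each sequence counted once.
    """
    joined = proteome_de[["log2fc", "p"]].join(
        ipp_de[["log2fc", "p"]], how="inner", lsuffix="_proteome", rsuffix="_ipp"
    )
    joined = joined.rename(
        columns={
            "log2fc_proteome": "proteome_log2fc",
            "p_proteome": "proteome_p",
            "log2fc_ipp": "ipp_log2fc",
            "p_ipp": "ipp_p",
        }
    )
    for axis in ("proteome", "ipp"):
        p = joined[f"{axis}_p"].to_numpy(dtype=float)
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        joined[f"{axis}_q"] = q
    ipp_only = sorted(set(ipp_de.index) - set(proteome_de.index))
    summary = {
        "n_overlap": len(joined),
        "n_ipp_only_proteins": len(ipp_only),
    }
    if ipp_peptides is not None:
        peps = set()
        for prot in ipp_only:
            peps |= set(ipp_peptides.get(prot, ()))
        summary["n_ipp_only_unique_peptides"] = len(peps)
    return joined, summary


def classify_quadrants(
    records: pd.DataFrame, p_cut: float = P_CUT
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign significance class and fold-change quadrant to joined records.

    ``sig_class``: both / proteome_only / ipp_only / neither by p < p_cut in
    each axis.  ``quadrant``: sign pair of (proteome_log2fc, ipp_log2fc);
    zero fold-change on either axis leaves the quadrant unset (a
    measure-zero tie is not forced to a side).  Returns the annotated
    records and per-quadrant counts.
    """
    rec = records.copy()
    psig = rec["proteome_p"] < p_cut
    isig = rec["ipp_p"] < p_cut
    sig = np.select(
        [psig & isig, psig & ~isig, ~psig & isig],
        ["both", "proteome_only", "ipp_only"],
        default="neither",
    )
    rec["sig_class"] = sig
    px, ix = rec["proteome_log2fc"], rec["ipp_log2fc"]
    quadrant = np.select(
        [
            (px > 0) & (ix > 0),
            (px > 0) & (ix < 0),
            (px < 0) & (ix > 0),
            (px < 0) & (ix < 0),
        ],
        ["up_up", "up_down", "down_up", "down_down"],
        default="",
    )
    rec["quadrant"] = quadrant
    counts = {
        q: int((rec["quadrant"] == q).sum())
        for q in ("up_up", "up_down", "down_up", "down_down")
    }
    return rec, counts
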