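"""High-level composition of the proteome differential-expression stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .proteome import (
    classify_volcano,
    impute_mle,
    moderated_de,
    normalize_scalar,
    twoway_anova,
)
from .types import QuantMatrix


def log2_matrix(qm: QuantMatrix) -> QuantMatrix:
    """Linear -> log2 scale, preserving missingness (and mapping exact zeros
    to missing: a zero area is below quantitation)."""
    vals = qm.values.to_numpy(dtype=float).copy()
    vals[vals == 0] = np.nan
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(np.log2(vals), index=qm.values.index, columns=qm.values.columns)
    return QuantMatrix(out, qm.sample_meta.copy(), log_scale=True)


def proteome_de_by_timepoint(
    qm: QuantMatrix,
    p_cut: float = 1e-5,
    lfc_cut: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Normalize, log2-transform, impute, then per-timepoint moderated DE
    of irradiated vs control, with volcano classes and the two-way-ANOVA
    interaction p appended.

    Returns a wide table: log2fc_<tp>, p_<tp>, class_<tp> per time point,
    plus anova_interaction_p.
    """
    if normalize:
        qm, _ = normalize_scalar(qm)
    logm = log2_matrix(qm)
    imputed, _ = impute_mle(logm)
    meta = imputed.sample_meta
    out = pd.DataFrame(index=imputed.values.index)
    for tp in sorted(meta["timepoint_h"].unique()):
        ctrl = imputed.samples_for("control", tp)
        irr = imputed.samples_for("irradiated", tp)
        de = moderated_de(imputed, ctrl, irr)
        cls, _ = classify_volcano(de, p_cut=p_cut, lfc_cut=lfc_cut)
        out[f"log2fc_{tp}"] = de["log2fc"]
        out[f"p_{tp}"] = de["p"]
        out[f"q_{tp}"] = de["q"]
        out[f"class_{tp}"] = cls
    anova = twoway_anova(imputed)
    out["anova_interaction_p"] = anova["p"]
    return out
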