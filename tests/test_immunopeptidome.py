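"""FDR filtering, allele assignment, set algebra and motif summaries."""

import numpy as np
import pytest

from radpep import io as rio
from radpep.immunopeptidome import (
    MockRankScorer,
    assign_alleles,
    condition_sets,
    fdr_filter,
    length_distribution,
    motif_matrix,
    multi_peptide_proteins,
    radiation_antigen_table,
    rollup_all_peptides,
)
from radpep.simulate import DEFAULT_MOTIFS, SimConfig, gen_immunopeptidome
from radpep.types import PeptideRecord


def _rec(seq, score=10.0, decoy=False, **kw):
    base = dict(
        sequence=seq,
        sample_id="s1",
        condition="control",
        timepoint_h=24,
        intensity=1.0,
        search_score=score,
        is_decoy=decoy,
    )
    base.update(kw)
    return PeptideRecord(**base)


# ---------------------------------------------------------------------------
# FDR


def test_fdr_worked_example():
    # targets {10, 9, 8, 7}, decoy {7.5}: at t=7 the decoy/target ratio hits
    # 1/4 which is not strictly below 0.25, so the threshold is 8
    records = [
        _rec("AAAAAAAA", 10), _rec("CCCCCCCC", 9), _rec("DDDDDDDD", 8),
        _rec("EEEEEEEE", 7), _rec("FFFFFFFF", 7.5, decoy=True),
    ]
    kept, threshold = fdr_filter(records, alpha=0.25)
    assert threshold == 8
    assert {r.sequence for r in kept} == {"AAAAAAAA", "CCCCCCCC", "DDDDDDDD"}


def test_fdr_alpha_one_keeps_all_targets():
    records = [
        _rec("AAAAAAAA", 10), _rec("CCCCCCCC", 1),
        _rec("FFFFFFFF", 5, decoy=True),
    ]
    kept, _ = fdr_filter(records, alpha=1.0)
    assert {r.sequence for r in kept} == {"AAAAAAAA", "CCCCCCCC"}


def test_fdr_collapses_duplicate_sequences_to_best_score():
    # the low-scoring observation of AAAA... must not count separately
    records = [
        _rec("AAAAAAAA", 10), _rec("AAAAAAAA", 1, sample_id="s2"),
        _rec("CCCCCCCC", 9),
        _rec("FFFFFFFF", 5, decoy=True),
    ]
    kept, threshold = fdr_filter(records, alpha=0.4)
    # both observations of the accepted sequence are returned
    assert sum(r.sequence == "AAAAAAAA" for r in kept) == 2
    assert not any(r.is_decoy for r in kept)


def test_fdr_zero_decoys_errors():
    with pytest.raises(ValueError, match="decoy"):
        fdr_filter([_rec("AAAAAAAA")], alpha=0.01)


def _seq(i: int, prefix: str = "") -> str:
    """Deterministic unique peptide-like sequence for an integer."""
    digits = "ACDEFGHIKL"
    body = "".join(digits[int(c)] for c in f"{i:04d}")
    return (prefix + body + "VVVVV")[:9]


def test_fdr_monotone_in_alpha():
    rng = np.random.default_rng(4)
    records = [
        _rec(_seq(i), float(rng.normal(5, 2)), decoy=bool(i % 3 == 0))
        for i in range(120)
    ]
    sizes = []
    for alpha in (0.01, 0.05, 0.2, 0.5, 1.0):
        kept, _ = fdr_filter(records, alpha=alpha)
        sizes.append(len({r.sequence for r in kept}))
    assert sizes == sorted(sizes)  # lowering alpha never adds peptides


def test_fdr_controls_fdp_on_average():
    """Realized false-discovery proportion stays below 1.5x alpha averaged
    over repeated simulations with known true/false targets."""
    rng = np.random.default_rng(17)
    alpha = 0.05
    fdps = []
    for _ in range(100):
        records = []
        for i in range(200):  # true targets: well-separated scores
            records.append(_rec(_seq(i, "T"), float(rng.normal(4.0, 1))))
        for i in range(200):  # false targets: null-distributed scores
            records.append(_rec(_seq(i, "F"), float(rng.normal(0.0, 1))))
        for i in range(200):  # decoys: same null distribution
            records.append(_rec(_seq(i, "D"), float(rng.normal(0.0, 1)),
                                decoy=True))
        kept, _ = fdr_filter(records, alpha=alpha)
        kept_seqs = {r.sequence for r in kept}
        n_false = sum(1 for s in kept_seqs if s.startswith("F"))
        fdps.append(n_false / max(len(kept_seqs), 1))
    assert np.mean(fdps) <= 1.5 * alpha


# ---------------------------------------------------------------------------
# Allele assignment


def test_assignment_from_rank_table():
    recs = [
        _rec("AYSSLVTSL", allele_ranks={"H-2-Kd": 0.0029, "H-2-Dd": 1.5}),
        _rec("CCCCCCCCC", allele_ranks={"H-2-Kd": 3.0, "H-2-Dd": 2.0}),
        _rec("DDDDDDDDD", allele_ranks={"H-2-Kd": 0.5, "H-2-Dd": 5.0}),
    ]
    out = {a.sequence: a for a in assign_alleles(recs, ["H-2-Kd", "H-2-Dd"])}
    a = out["AYSSLVTSL"]
    assert (a.best_allele, a.best_rank, a.binder_class) == ("H-2-Kd", 0.0029, "strong")
    b = out["CCCCCCCCC"]
    assert (b.best_allele, b.binder_class) == (None, "non-binder")
    # boundary is strict: rank exactly 0.5 is a binder, not strong
    assert out["DDDDDDDDD"].binder_class == "binder"


def test_mock_scorer_calibration():
    scorer = MockRankScorer(DEFAULT_MOTIFS, seed=3, n_ref=20000)
    rng = np.random.default_rng(9)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    random_ranks = [
        scorer.percent_rank("".join(rng.choice(list(aas), 9)), "H-2-Kd")
        for _ in range(300)
    ]
    # random peptides get roughly uniform ranks on [0, 100]
    assert 30 < np.mean(random_ranks) < 70
    # a motif-perfect peptide sits at the top of the score distribution
    assert scorer.percent_rank("YYYYYYYYL", "H-2-Kd") < 0.5
    # matching both anchors puts any peptide within the top ~1%
    assert scorer.percent_rank("AYAAAAAAL", "H-2-Kd") < 1.5
    assert scorer.percent_rank("AYAAAAAAL", "H-2-Kd") < scorer.percent_rank(
        "AAAAAAAAQ", "H-2-Kd"
    )


# ---------------------------------------------------------------------------
# Length distribution


def test_length_distribution_windowing():
    recs = [
        _rec("A" * 9), _rec("C" * 9), _rec("D" * 13), _rec("E" * 7),
    ]
    ld = length_distribution(recs)
    assert set(ld["length"]) == {9}
    assert ld["n_unique"].sum() == 2
    wide = length_distribution(recs, max_len=14)
    assert set(wide["length"]) == {9, 13}


def test_length_distribution_generator_mode_is_nine(transcriptome):
    _, _, proteome = transcriptome
    records, _ = gen_immunopeptidome(SimConfig(seed=21), proteome)
    ld = length_distribution(records)
    per_len = ld.groupby("length")["n_unique"].sum()
    assert per_len.idxmax() == 9


# ---------------------------------------------------------------------------
# All-peptide roll-up


def test_rollup_all_peptides_sums_and_flags_ambiguity():
    recs = [
        _rec("AAAAAAAAA", intensity=1e5, source_proteins=["P1"]),
        _rec("CCCCCCCCC", intensity=2e5, source_proteins=["P1"]),
        _rec("DDDDDDDDD", intensity=7e4, source_proteins=["P1", "P2"]),
        _rec("EEEEEEEEE", intensity=1e4, source_proteins=["P3"]),
    ]
    values, ambiguous = rollup_all_peptides(recs)
    assert values.loc["P1", "s1"] == pytest.approx(3.7e5)
    assert values.loc["P2", "s1"] == pytest.approx(7e4)
    assert ambiguous == {"P1", "P2"}
    # conservation: protein total >= peptide total, equal iff no ambiguity
    total_peptide = sum(r.intensity for r in recs)
    assert values["s1"].sum() >= total_peptide
    unambiguous = [r for r in recs if len(r.source_proteins) == 1]
    v2, amb2 = rollup_all_peptides(unambiguous)
    assert amb2 == set()
    assert v2["s1"].sum() == pytest.approx(sum(r.intensity for r in unambiguous))


# ---------------------------------------------------------------------------
# Condition sets


def _set_records():
    return [
        _rec("AAAAAAAAA", condition="irradiated", sample_id="irr1"),
        _rec("AAAAAAAAA", condition="control", sample_id="pool1"),
        _rec("CCCCCCCCC", condition="irradiated", sample_id="irr1"),
        _rec("CCCCCCCCC", condition="irradiated", sample_id="irr2"),
        _rec("DDDDDDDDD", condition="control", sample_id="ctl1"),
    ]


def test_condition_sets_radiation_specific():
    cs = condition_sets(_set_records())
    # AAA... is in the control pool, so not radiation-specific
    assert cs.radiation_specific == {"CCCCCCCCC"}


def test_condition_sets_monotone_in_control_pool():
    recs = _set_records()
    cs = condition_sets(recs)
    extra = [_rec("CCCCCCCCC", condition="control", sample_id="pool9")]
    cs2 = condition_sets(recs, expanded_controls=extra)
    assert cs2.radiation_specific <= cs.radiation_specific
    assert cs2.radiation_specific == set()


def test_condition_sets_recover_injected_radiation_only(transcriptome):
    _, _, proteome = transcriptome
    cfg = SimConfig(seed=31)
    records, truth = gen_immunopeptidome(cfg, proteome)
    cs = condition_sets(records)
    rad = set(truth["radiation_only"])
    observed = {r.sequence for r in records if not r.is_decoy}
    assert cs.radiation_specific == rad & observed


def test_replicate_overlap_counts():
    recs = [
        _rec("AAAAAAAAA", condition="irradiated", sample_id="r1"),
        _rec("CCCCCCCCC", condition="irradiated", sample_id="r1"),
        _rec("AAAAAAAAA", condition="irradiated", sample_id="r2"),
    ]
    cs = condition_sets(recs)
    mat = cs.replicate_overlap[("irradiated", 24)]
    assert mat.loc["r1", "r2"] == 1 and mat.loc["r1", "r1"] == 2


# ---------------------------------------------------------------------------
# Antigen table (packaged fixture)


def test_table1_multi_peptide_source_proteins():
    df = rio.load_table1_fixture()
    assert multi_peptide_proteins(df) == ["ADCY7_MOUSE", "S14L1_MOUSE"]


def test_table1_rank_extremes():
    df = rio.load_table1_fixture()
    assert df.loc[df["rank"].idxmin(), "peptide"] == "AYSSLVTSL"
    assert df["rank"].min() == pytest.approx(0.0029)
    assert (df["rank"] < 0.5).all()  # strong binders only


def test_radiation_antigen_table_sorted_and_flags():
    asn = assign_alleles(
        [
            _rec("AAAAAAAAA", allele_ranks={"K": 0.3}, source_proteins=["P1"]),
            _rec("CCCCCCCCC", allele_ranks={"K": 0.1}, source_proteins=["P1"]),
            _rec("DDDDDDDDD", allele_ranks={"K": 0.9}, source_proteins=["P2"]),
            _rec("EEEEEEEEE", allele_ranks={"K": 0.05}, source_proteins=["P3"]),
        ],
        ["K"],
    )
    table, multi = radiation_antigen_table(
        {"AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD"}, asn
    )
    # DDD... fails the 0.5 cut; EEE... is not radiation-specific
    assert list(table["peptide"]) == ["CCCCCCCCC", "AAAAAAAAA"]
    assert multi == ["P1"]


def test_radiation_antigen_table_empty():
    table, multi = radiation_antigen_table(set(), [])
    assert len(table) == 0 and multi == []


# ---------------------------------------------------------------------------
# Motif matrix


def test_motif_matrix_one_hot_and_normalized():
    asn = assign_alleles(
        [_rec("AYSSLVTSL", allele_ranks={"K": 0.1}),
         _rec("AYSSLVTSL", allele_ranks={"K": 0.1}, sample_id="s2")],
        ["K"],
    )
    mat = motif_matrix(asn, "K")
    assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
    assert mat.loc[2, "Y"] == 1.0 and mat.loc[1, "A"] == 1.0


def test_motif_matrix_recovers_configured_anchor(transcriptome):
    _, _, proteome = transcriptome
    cfg = SimConfig(seed=41, anchor_fidelity=0.95)
    records, _ = gen_immunopeptidome(cfg, proteome)
    scorer = MockRankScorer(cfg.allele_motifs, seed=41, n_ref=20000)
    asn = assign_alleles(records, list(cfg.allele_motifs), scorer)
    mat = motif_matrix(asn, "H-2-Kd")
    assert mat.loc[2].idxmax() == "Y"  # configured P2 anchor
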