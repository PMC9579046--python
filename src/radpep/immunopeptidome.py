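"""Immunopeptidome analytics: target-decoy peptide-level FDR, MHC allele
assignment at the strong-binder (<0.5) and binder (<2) %rank thresholds,
length distributions, per-source-protein intensity roll-up over all
associated peptides, condition set algebra against an expanded control
pool, radiation-specific antigen tables, and binding-motif frequency
matrices.

Peptide identity throughout is the bare sequence (modifications are ignored
for set algebra, matching unique-peptide counting practice); pass
``modified_identity=True`` where supported to distinguish peptidoforms.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import AA_ALPHABET, PeptideRecord

STRONG_RANK = 0.5
BINDER_RANK = 2.0


# ---------------------------------------------------------------------------
# Target-decoy FDR


def fdr_filter(
    records: Sequence[PeptideRecord], alpha: float = 0.01
) -> tuple[list[PeptideRecord], float]:
    """Filter identifications to a peptide-level false discovery rate.

    Peptide-level means scores are first collapsed to the best score per
    distinct sequence (targets and decoys separately).  The score threshold
    is the smallest score at which the decoy/target ratio among peptides at
    or above it stays below ``alpha``; ties at the boundary are resolved
    conservatively (a threshold where the ratio equals ``alpha`` is not
    accepted).  Decoy records are removed from the output.  Lowering
    ``alpha`` never admits additional peptides.

    Returns (accepted target records, score threshold).  Raises ValueError
    when no decoys are present (the FDR cannot be estimated).
    """
    target_best: dict[str, float] = {}
    decoy_best: dict[str, float] = {}
    for r in records:
        d = decoy_best if r.is_decoy else target_best
        prev = d.get(r.sequence)
        if prev is None or r.search_score > prev:
            d[r.sequence] = r.search_score
    if not decoy_best:
        raise ValueError("cannot estimate FDR: no decoy records")
    t_scores = np.sort(np.array(list(target_best.values())))
    d_scores = np.sort(np.array(list(decoy_best.values())))
    # candidate thresholds: unique target scores, descending
    candidates = np.unique(t_scores)[::-1]
    n_t = len(t_scores) - np.searchsorted(t_scores, candidates, side="left")
    n_d = len(d_scores) - np.searchsorted(d_scores, candidates, side="left")
    fdp = n_d / np.maximum(n_t, 1)
    ok = fdp < alpha
    if not ok.any():
        return [], float("inf")
    threshold = float(candidates[ok][-1])  # smallest accepted score
    accepted = {s for s, sc in target_best.items() if sc >= threshold}
    kept = [r for r in records if not r.is_decoy and r.sequence in accepted]
    return kept, threshold


# ---------------------------------------------------------------------------
# Mock %rank scorer (stand-in for an external binding predictor)


_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
# small fixed per-residue background weights so scores are near-continuous
_BG = np.linspace(0.0, 1e-3, len(AA_ALPHABET))


class MockRankScorer:
    """Position-weight log-odds scorer calibrated to an empirical %rank.

    For each allele, anchor positions carry preferred residues; a peptide
    scores one unit per matched anchor plus a tiny fixed residue background
    to break ties.  The %rank of a peptide is the percentage of ``n_ref``
    random peptides (uniform residues, same length) that score strictly
    higher — so 0 is the strongest possible rank, matching predictor
    conventions where <0.5 marks strong binders.
    """

    def __init__(
        self,
        motifs: dict[str, dict[int, str]],
        seed: int = 0,
        n_ref: int = 100_000,
        lengths: tuple[int, ...] = (8, 9, 10, 11, 12),
    ):
        self.motifs = motifs
        self.lengths = lengths
        self._ref: dict[tuple[str, int], np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for allele in sorted(motifs):
            for L in lengths:
                codes = rng.integers(0, len(AA_ALPHABET), size=(n_ref, L))
                scores = self._score_codes(codes, allele)
                self._ref[(allele, L)] = np.sort(scores)

    def _score_codes(self, codes: np.ndarray, allele: str) -> np.ndarray:
        L = codes.shape[1]
        scores = _BG[codes].sum(axis=1)
        for pos, residues in self.motifs[allele].items():
            idx = pos - 1 if pos > 0 else L + pos
            if not 0 <= idx < L:
                continue
            match = np.isin(codes[:, idx], [_AA_INDEX[r] for r in residues])
            scores += match.astype(float)
        return scores

    def score(self, peptide: str, allele: str) -> float:
        codes = np.array([[_AA_INDEX[a] for a in peptide]])
        return float(self._score_codes(codes, allele)[0])

    def percent_rank(self, peptide: str, allele: str) -> float:
        """Empirical quantile of the peptide's score among random peptides
        of the same length; in [0, 100], smaller is stronger."""
        L = min(max(len(peptide), min(self.lengths)), max(self.lengths))
        ref = self._ref[(allele, L)]
        if len(peptide) in self.lengths:
            ref = self._ref[(allele, len(peptide))]
        s = self.score(peptide, allele)
        n_higher = len(ref) - np.searchsorted(ref, s, side="right")
        return 100.0 * n_higher / len(ref)


# ---------------------------------------------------------------------------
# Allele assignment


@dataclass
class AlleleAssignment:
    """Best-allele call for one peptide sequence."""

    sequence: str
    best_allele: Optional[str]
    best_rank: float
    binder_class: str  # strong | binder | non-binder
    source_proteins: list[str] = field(default_factory=list)


def _binder_class(rank: float) -> str:
    if rank < STRONG_RANK:
        return "strong"
    if rank < BINDER_RANK:
        return "binder"
    return "non-binder"


def assign_alleles(
    records: Iterable[PeptideRecord],
    alleles: Sequence[str],
    rank_source: str | MockRankScorer = "table",
) -> list[AlleleAssignment]:
    """Assign each distinct peptide sequence its minimum-%rank allele.

    ``rank_source`` is either ``"table"`` (use the per-record
    ``allele_ranks`` carried in from an external predictor's output) or a
    :class:`MockRankScorer`.  Class boundaries are strict: rank < 0.5 is a
    strong binder, < 2 a binder; at or above 2 the peptide is a non-binder
    and gets no best allele.
    """
    by_seq: dict[str, PeptideRecord] = {}
    for r in records:
        if not r.is_decoy and r.sequence not in by_seq:
            by_seq[r.sequence] = r
    out = []
    for seq, rec in by_seq.items():
        if isinstance(rank_source, MockRankScorer):
            ranks = {a: rank_source.percent_rank(seq, a) for a in alleles}
        else:
            ranks = {a: v for a, v in rec.allele_ranks.items() if a in alleles}
        if not ranks:
            out.append(AlleleAssignment(seq, None, float("inf"), "non-binder",
                                        rec.source_proteins))
            continue
        best = min(ranks, key=lambda a: (ranks[a], a))
        rank = ranks[best]
        cls = _binder_class(rank)
        out.append(
            AlleleAssignment(
                seq,
                best if cls != "non-binder" else None,
                rank,
                cls,
                rec.source_proteins,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Length distribution


def length_distribution(
    records: Iterable[PeptideRecord], min_len: int = 8, max_len: int = 12
) -> pd.DataFrame:
    """Per length x condition counts of unique sequences and summed
    intensity, over peptides inside the [min_len, max_len] window."""
    rows = defaultdict(lambda: {"sequences": set(), "intensity": 0.0})
    for r in records:
        if r.is_decoy or not (min_len <= len(r.sequence) <= max_len):
            continue
        key = (len(r.sequence), r.condition)
        rows[key]["sequences"].add(r.sequence)
        rows[key]["intensity"] += r.intensity
    out = [
        {
            "length": L,
            "condition": cond,
            "n_unique": len(v["sequences"]),
            "intensity": v["intensity"],
        }
        for (L, cond), v in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["length", "condition", "n_unique", "intensity"])


# ---------------------------------------------------------------------------
# Per-source-protein roll-up (all associated peptides)


def rollup_all_peptides(
    records: Iterable[PeptideRecord],
) -> tuple[pd.DataFrame, set[str]]:
    """Sum intensities per source protein per sample using ALL associated
    peptides (unlike the proteome's top-3 rule).  Peptides with multiple
    source proteins contribute to each; such proteins are returned in the
    ambiguity set.  Returns (protein x sample intensity table, ambiguous
    proteins)."""
    sums: dict[tuple[str, str], float] = defaultdict(float)
    ambiguous: set[str] = set()
    samples: list[str] = []
    for r in records:
        if r.is_decoy:
            continue
        if r.sample_id not in samples:
            samples.append(r.sample_id)
        for p in r.source_proteins:
            sums[(p, r.sample_id)] += r.intensity
            if len(r.source_proteins) > 1:
                ambiguous.add(p)
    proteins = sorted({p for p, _ in sums})
    values = pd.DataFrame(0.0, index=proteins, columns=samples)
    for (p, s), v in sums.items():
        values.loc[p, s] = v
    return values, ambiguous


# ---------------------------------------------------------------------------
# Condition set algebra


@dataclass
class ConditionSets:
    by_condition: dict[str, set[str]]
    by_group: dict[tuple[str, int], set[str]]
    radiation_specific: set[str]
    replicate_overlap: dict[tuple[str, int], pd.DataFrame]


def condition_sets(
    records: Iterable[PeptideRecord],
    expanded_controls: Optional[Iterable[PeptideRecord]] = None,
    modified_identity: bool = False,
) -> ConditionSets:
    """Unique-peptide sets per condition and per condition x timepoint,
    pairwise replicate overlap counts, and the radiation-specific set:
    sequences seen in at least one irradiated sample and absent from ALL
    control samples including the expanded control pool.  Enlarging the
    pool can only shrink the radiation-specific set."""

    def ident(r: PeptideRecord):
        if modified_identity:
            return (r.sequence, tuple(sorted(r.modifications)))
        return r.sequence

    by_condition: dict[str, set] = defaultdict(set)
    by_group: dict[tuple[str, int], set] = defaultdict(set)
    by_sample: dict[tuple[str, int], dict[str, set]] = defaultdict(
        lambda: defaultdict(set)
    )
    all_records = list(records) + (list(expanded_controls) if expanded_controls else [])
    for r in all_records:
        if r.is_decoy:
            continue
        key = ident(r)
        by_condition[r.condition].add(key)
        by_group[(r.condition, r.timepoint_h)].add(key)
        by_sample[(r.condition, r.timepoint_h)][r.sample_id].add(key)
    radiation_specific = by_condition.get("irradiated", set()) - by_condition.get(
        "control", set()
    )
    overlap = {}
    for group, persample in by_sample.items():
        sids = sorted(persample)
        mat = pd.DataFrame(
            [[len(persample[a] & persample[b]) for b in sids] for a in sids],
            index=sids,
            columns=sids,
        )
        overlap[group] = mat
    return ConditionSets(
        by_condition=dict(by_condition),
        by_group=dict(by_group),
        radiation_specific=radiation_specific,
        replicate_overlap=overlap,
    )


# ---------------------------------------------------------------------------
# Radiation-specific antigen table


def radiation_antigen_table(
    radiation_specific: Iterable[str],
    assignments: Iterable[AlleleAssignment],
    rank_cut: float = STRONG_RANK,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank the radiation-specific strong binders.

    Keeps peptides in the radiation-specific set with best %rank strictly
    below ``rank_cut``, sorted ascending by rank; returns the table plus
    source proteins represented by two or more distinct peptides."""
    spec = set(radiation_specific)
    rows = []
    for a in assignments:
        if a.sequence in spec and a.best_rank < rank_cut:
            rows.append(
                {
                    "peptide": a.sequence,
                    "allele": a.best_allele,
                    "rank": a.best_rank,
                    "source_proteins": ";".join(a.source_proteins),
                }
            )
    df = pd.DataFrame(rows, columns=["peptide", "allele", "rank", "source_proteins"])
    df = df.sort_values("rank", kind="mergesort").reset_index(drop=True)
    counts: dict[str, set] = defaultdict(set)
    for _, row in df.iterrows():
        for p in row["source_proteins"].split(";"):
            if p:
                counts[p].add(row["peptide"])
    multi = sorted(p for p, peps in counts.items() if len(peps) >= 2)
    return df, multi


def multi_peptide_proteins(table: pd.DataFrame, protein_col: str = "entry",
                           peptide_col: str = "peptide") -> list[str]:
    """Source proteins with two or more distinct peptides in a ranked
    antigen table (e.g. the packaged fixture)."""
    counts = table.groupby(protein_col)[peptide_col].nunique()
    return sorted(counts.index[counts >= 2])


# ---------------------------------------------------------------------------
# Motif frequency matrix


def motif_matrix(
    assignments: Iterable[AlleleAssignment],
    allele: str,
    length: int = 9,
    rank_cut: float = BINDER_RANK,
) -> pd.DataFrame:
    """Position x residue frequency matrix over ``length``-mers assigned to
    ``allele`` with rank below ``rank_cut``.  Each position's frequencies
    sum to 1."""
    seqs = [
        a.sequence
        for a in assignments
        if a.best_allele == allele and len(a.sequence) == length
        and a.best_rank < rank_cut
    ]
    mat = pd.DataFrame(0.0, index=range(1, length + 1), columns=list(AA_ALPHABET))
    if not seqs:
        return mat
    for seq in seqs:
        for i, aa in enumerate(seq, start=1):
            mat.loc[i, aa] += 1.0
    return mat.div(mat.sum(axis=1), axis=0)
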