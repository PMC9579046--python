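"""Core domain types shared by all pipeline stages.

External coordinate conventions follow the source formats: VCF positions and
protein positions are 1-based inclusive.  All internal interval arithmetic
(exon geometry, CDS slicing) is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

PROTEIN_CODING = "protein_coding"
NMD_BIOTYPE = "NMD_mediated_decay"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's genomic geometry plus biotype annotation.

    ``exons`` are (start, end) 0-based half-open intervals in genomic order
    (ascending start), regardless of strand; transcript-orientation handling
    is a pure function applied at extraction/translation time.  ``cds_start``
    and ``cds_end`` delimit the coding span in genomic coordinates (0-based
    half-open over the genome; the spliced CDS is the exonic sequence inside
    that span).
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    gene_biotype: str = PROTEIN_CODING
    transcript_biotypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("exons overlap or are unordered")
            prev_end = e
        if not (self.cds_start < self.cds_end):
            raise ValueError("cds_start must be < cds_end")

    @property
    def is_coding_eligible(self) -> bool:
        """True unless the gene biotype is non-protein-coding or any
        transcript biotype flags nonsense-mediated decay."""
        return (
            self.gene_biotype == PROTEIN_CODING
            and NMD_BIOTYPE not in self.transcript_biotypes
        )


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant (one ALT allele) as read from a Strelka-style VCF."""

    contig: str
    pos: int  # 1-based genomic position of the first REF base
    ref: str
    alt: str
    filter: str = "PASS"
    depth: Optional[int] = None  # DP for SNVs, DPI for indels; None if absent
    max_pop_af: Optional[float] = None

    def __post_init__(self) -> None:
        for name, seq in (("ref", self.ref), ("alt", self.alt)):
            if not seq or set(seq) - set(DNA_ALPHABET):
                raise ValueError(f"{name} must be non-empty over ACGT, got {seq!r}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def vtype(self) -> str:
        nr, na = len(self.ref), len(self.alt)
        if nr == na:
            return "SNV" if nr == 1 else "MNV"
        return "insertion" if na > nr else "deletion"

    @property
    def variant_id(self) -> str:
        return f"{self.contig}_{self.pos}_{self.ref}_{self.alt}"


@dataclass
class PeptideRecord:
    """One identified MHC-associated peptide observation in one sample."""

    sequence: str
    sample_id: str
    condition: str  # 'control' or 'irradiated'
    timepoint_h: int
    intensity: float
    modifications: list[tuple[str, int]] = field(default_factory=list)
    source_proteins: list[str] = field(default_factory=list)
    is_decoy: bool = False
    search_score: float = 0.0
    allele_ranks: dict[str, float] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sequence) - set(AA_ALPHABET):
            raise ValueError(f"peptide {self.sequence!r} has non-standard residues")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        for name, pos in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(
                    f"modification {name}@{pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )
        for allele, rank in self.allele_ranks.items():
            if rank < 0:
                raise ValueError(f"%rank for {allele} must be >= 0")

    @property
    def is_modified(self) -> bool:
        return bool(self.modifications)


@dataclass(frozen=True)
class ConsequenceCall:
    """Protein-level consequence of a variant on one transcript."""

    variant_id: str
    transcript_id: str
    consequence: str  # synonymous | missense | stop_gained | stop_lost |
    #                   frameshift | inframe_insertion | inframe_deletion | non_coding
    protein_pos: int = 0  # 1-based first affected residue; 0 for non_coding
    ref_aa: str = ""
    alt_aa: str = ""

    @property
    def aa_change(self) -> str:
        if self.consequence == "non_coding":
            return ""
        if self.consequence == "frameshift":
            return f"{self.ref_aa}{self.protein_pos}fs"
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"


@dataclass
class ContextPair:
    """Paired normal/mutant protein context window around a somatic variant."""

    variant_id: str
    gene_id: str
    aa_change: str
    normal_seq: str
    mutant_seq: str
    desired_len: int = 31
    max_pop_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.normal_seq == self.mutant_seq:
            raise ValueError("normal and mutant context sequences are identical")


class QuantMatrix:
    """A feature x sample abundance table with explicit missing values.

    Missingness is encoded as NaN, which is distinct from 0 (a legal
    abundance).  ``sample_meta`` is indexed by sample id with columns
    ``condition``, ``timepoint_h`` and ``replicate``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_meta: pd.DataFrame,
        log_scale: bool = False,
    ):
        if list(values.columns) != list(sample_meta.index):
            raise ValueError("sample_meta index must match value columns")
        missing = {"condition", "timepoint_h", "replicate"} - set(sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta lacks columns: {sorted(missing)}")
        if not log_scale:  # log-scale matrices may legitimately go negative
            with np.errstate(invalid="ignore"):
                if (values.to_numpy(dtype=float) < 0).any():
                    raise ValueError("abundances must be non-negative")
        self.values = values
        self.sample_meta = sample_meta
        self.log_scale = log_scale

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str, timepoint_h: Optional[int] = None) -> list[str]:
        m = self.sample_meta
        mask = m["condition"] == condition
        if timepoint_h is not None:
            mask &= m["timepoint_h"] == timepoint_h
        return list(m.index[mask])

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.sample_meta.copy(), self.log_scale)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"QuantMatrix({len(self.feature_ids)} features x "
            f"{len(self.sample_ids)} samples)"
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear light/heavy-ratio standard curve for one PRM peptide."""

    peptide: str
    slope: float  # ratio per fmol
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]
    slope_se: float = float("nan")
    intercept_warning: bool = False

    def predict_ratio(self, fmol: float) -> float:
        return self.intercept + self.slope * fmol


@dataclass(frozen=True)
class CopiesPerCellResult:
    """Absolute quantitation of an endogenous peptide."""

    sample: str
    light_heavy_ratio: float
    endogenous_fmol: float
    n_cells: float
    copies_per_cell: float
    extrapolated: bool = False

    @property
    def copies_per_cell_rounded(self) -> int:
        return int(round(self.copies_per_cell))
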