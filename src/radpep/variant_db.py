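"""Somatic-variant filtering, protein consequence calling, and paired
normal/mutant context-sequence generation.

This is the proteogenomic database stage: somatic variants from a
Strelka-style VCF are filtered (FILTER == PASS, read depth >= 10), mapped
through transcript models to protein-level consequences, turned into
centered 31-aa normal/mutant context windows, filtered on population allele
frequency (< 1%), and written as a paired FASTA ready for search-engine
consumption.  Variant annotation is a simplified consequence caller over
explicit transcript models: transcripts of non-protein-coding gene biotype,
or carrying the nonsense-mediated-decay transcript biotype, are excluded by
label.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional

from Bio.Seq import Seq

from .io import read_vcf_strelka, write_paired_fasta
from .types import ConsequenceCall, ContextPair, TranscriptModel, VariantRecord

log = logging.getLogger(__name__)

DEFAULT_DESIRED_LEN = 31
DEFAULT_MIN_DEPTH = 10
DEFAULT_MAX_AF = 0.01
MIN_MUTANT_CONTEXT = 8  # minimum MHC ligand length


# ---------------------------------------------------------------------------
# Transcript sequence arithmetic (0-based half-open internally)


def cds_exon_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    """Exon intervals clipped to the CDS span, in genomic order."""
    out = []
    for s, e in t.exons:
        s2, e2 = max(s, t.cds_start), min(e, t.cds_end)
        if s2 < e2:
            out.append((s2, e2))
    return out


def spliced_cds(t: TranscriptModel, contig_seq: str) -> str:
    """The coding sequence in transcript orientation (reverse-complemented
    for '-' strand transcripts)."""
    parts = [contig_seq[s:e] for s, e in cds_exon_intervals(t)]
    seq = "".join(parts).upper()
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def genomic_to_cds(t: TranscriptModel, gpos: int) -> Optional[int]:
    """Map a 0-based genomic position to its 0-based index in the spliced
    CDS (transcript orientation), or None if non-exonic / outside the CDS."""
    offset = 0
    plus_index = None
    intervals = cds_exon_intervals(t)
    for s, e in intervals:
        if s <= gpos < e:
            plus_index = offset + (gpos - s)
            break
        offset += e - s
    if plus_index is None:
        return None
    if t.strand == "+":
        return plus_index
    total = sum(e - s for s, e in intervals)
    return total - 1 - plus_index


def translate_cds(cds: str) -> str:
    """Translate a spliced CDS, truncating trailing partial codons, and cut
    at the first stop codon."""
    usable = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:usable]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def _translate_full(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


# ---------------------------------------------------------------------------
# Filters


def filter_variants(
    variants: Iterable[VariantRecord], min_depth: int = DEFAULT_MIN_DEPTH
) -> list[VariantRecord]:
    """Keep variants with FILTER == PASS and read depth >= ``min_depth``.

    Variants with absent depth are rejected (logged).  Order is preserved;
    the filter is idempotent.
    """
    kept, _ = filter_variants_report(variants, min_depth)
    return kept


def filter_variants_report(
    variants: Iterable[VariantRecord], min_depth: int = DEFAULT_MIN_DEPTH
) -> tuple[list[VariantRecord], Counter]:
    kept: list[VariantRecord] = []
    reasons: Counter = Counter()
    for v in variants:
        if v.filter != "PASS":
            reasons["filter_fail"] += 1
        elif v.depth is None:
            log.info("rejecting %s: no read depth recorded", v.variant_id)
            reasons["no_depth"] += 1
        elif v.depth < min_depth:
            reasons["low_depth"] += 1
        else:
            kept.append(v)
    return kept, reasons


def apply_af_filter(
    pairs: Iterable[ContextPair], max_af: float = DEFAULT_MAX_AF
) -> list[ContextPair]:
    """Keep pairs whose variant is absent from population surveys or seen at
    a highest population allele frequency strictly below ``max_af``."""
    return [p for p in pairs if p.max_pop_af is None or p.max_pop_af < max_af]


# ---------------------------------------------------------------------------
# Consequence calling


def _edit_cds(
    v: VariantRecord, t: TranscriptModel, contig_seq: str, cds: str
) -> str:
    """Apply the variant's edit to the spliced CDS (transcript orientation)."""
    span = range(v.pos - 1, v.pos - 1 + len(v.ref))
    if contig_seq[span.start : span.stop].upper() != v.ref:
        raise ValueError(
            f"reference mismatch at {v.contig}:{v.pos}: expected {v.ref}, "
            f"contig has {contig_seq[span.start:span.stop].upper()}"
        )
    indices = [genomic_to_cds(t, g) for g in span]
    if any(i is None for i in indices):
        raise ValueError(
            f"variant {v.variant_id} spans non-exonic or non-CDS sequence"
        )
    if t.strand == "+":
        start = indices[0]
        ref_txt, alt_txt = v.ref, v.alt
    else:
        start = indices[-1]
        ref_txt = str(Seq(v.ref).reverse_complement())
        alt_txt = str(Seq(v.alt).reverse_complement())
    assert cds[start : start + len(ref_txt)] == ref_txt
    return cds[:start] + alt_txt + cds[start + len(ref_txt) :]


def call_consequence(
    v: VariantRecord, t: TranscriptModel, contigs: dict[str, str]
) -> ConsequenceCall:
    """Call the protein-level consequence of one variant on one transcript.

    Transcripts with a non-protein-coding gene biotype or the
    NMD_mediated_decay transcript biotype yield ``non_coding`` (excluded
    downstream).  SNVs/MNVs are mapped through splicing and strand to their
    codon; indels are classified by length difference mod 3.  The mutant
    protein is obtained by editing the spliced CDS and re-translating, so
    all consequence classes share one code path.
    """
    if t.contig != v.contig:
        raise ValueError(f"variant {v.variant_id} is not on contig {t.contig}")
    if not t.is_coding_eligible:
        return ConsequenceCall(v.variant_id, t.transcript_id, "non_coding")
    contig_seq = contigs[t.contig]
    cds = spliced_cds(t, contig_seq)
    mutant_cds = _edit_cds(v, t, contig_seq, cds)

    normal = translate_cds(cds)
    mutant = translate_cds(mutant_cds)
    d = len(v.alt) - len(v.ref)

    if d == 0:
        if normal == mutant:
            i = genomic_to_cds(t, v.pos - 1)
            assert i is not None
            p = i // 3
            aa = normal[p] if p < len(normal) else ""
            return ConsequenceCall(
                v.variant_id, t.transcript_id, "synonymous", p + 1, aa, aa
            )
        p = _first_diff(normal, mutant)
        if len(mutant) < len(normal) and normal[: len(mutant)] == mutant:
            return ConsequenceCall(
                v.variant_id, t.transcript_id, "stop_gained",
                len(mutant) + 1, normal[len(mutant)], "*",
            )
        if len(mutant) > len(normal) and mutant[: len(normal)] == normal:
            return ConsequenceCall(
                v.variant_id, t.transcript_id, "stop_lost",
                len(normal) + 1, "*", mutant[len(normal)],
            )
        return ConsequenceCall(
            v.variant_id, t.transcript_id, "missense", p + 1, normal[p], mutant[p]
        )

    p = _first_diff(normal, mutant)
    ref_aa = normal[p] if p < len(normal) else ""
    alt_aa = mutant[p] if p < len(mutant) else ""
    if d % 3 != 0:
        return ConsequenceCall(
            v.variant_id, t.transcript_id, "frameshift", p + 1, ref_aa, alt_aa
        )
    if normal == mutant:
        # in-frame edit silent at protein level (e.g. within a repeat)
        return ConsequenceCall(
            v.variant_id, t.transcript_id, "synonymous", p + 1, ref_aa, alt_aa
        )
    kind = "inframe_insertion" if d > 0 else "inframe_deletion"
    if len(mutant) < len(normal) and normal[: len(mutant)] == mutant:
        return ConsequenceCall(
            v.variant_id, t.transcript_id, "stop_gained",
            len(mutant) + 1, normal[len(mutant)], "*",
        )
    return ConsequenceCall(
        v.variant_id, t.transcript_id, kind, p + 1, ref_aa, alt_aa
    )


def _first_diff(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


# ---------------------------------------------------------------------------
# Context pairs


def build_context_pair(
    call: ConsequenceCall,
    protein_seq: str,
    mutant_protein_seq: str,
    desired_len: int = DEFAULT_DESIRED_LEN,
    gene_id: str = "",
    max_pop_af: Optional[float] = None,
) -> Optional[ContextPair]:
    """Build the paired normal/mutant context window for a coding call.

    Substitutions get a ``desired_len`` window centered on the mutated
    residue ((desired_len-1)//2 flanking residues each side), truncated at
    protein termini without padding.  Frameshift and stop-lost contexts run
    from 15 residues of wild-type left flank through the new stop;
    stop-gained contexts keep the left flank up to the new C terminus and
    are emitted only when at least 8 mutant residues remain (the minimum
    MHC ligand length), otherwise None is returned.

    Raises ValueError for synonymous or non-coding calls (no peptide-level
    change).
    """
    if call.consequence in ("synonymous", "non_coding"):
        raise ValueError("no peptide-level change")
    flank = (desired_len - 1) // 2
    p0 = call.protein_pos - 1  # 0-based first affected residue

    if call.consequence == "missense":
        start = max(0, p0 - flank)
        end = min(len(protein_seq), p0 + flank + 1)
        normal = protein_seq[start:end]
        mutant = mutant_protein_seq[start:end]
    elif call.consequence == "stop_gained":
        start = max(0, p0 - flank)
        mutant = mutant_protein_seq[start:]
        if len(mutant) < MIN_MUTANT_CONTEXT:
            return None
        normal = protein_seq[start : start + desired_len]
    else:  # frameshift, stop_lost, inframe insertion/deletion
        start = max(0, p0 - flank)
        mutant = mutant_protein_seq[start:]
        end = min(len(protein_seq), max(start + len(mutant), start + desired_len))
        normal = protein_seq[start:end]

    return ContextPair(
        variant_id=call.variant_id,
        gene_id=gene_id,
        aa_change=call.aa_change,
        normal_seq=normal,
        mutant_seq=mutant,
        desired_len=desired_len,
        max_pop_af=max_pop_af,
    )


def locate_peptide_variant(
    protein_seq: str, normal_pep: str, mutant_pep: str
) -> tuple[int, int]:
    """Locate a wild-type peptide in a protein and identify the mutated
    residue by diffing against its variant form.

    Returns (1-based protein position of the substituted residue, 1-based
    position within the peptide).  Requires equal-length peptides differing
    at exactly one residue and an unambiguous single match of the wild-type
    peptide in the protein.
    """
    if len(normal_pep) != len(mutant_pep):
        raise ValueError("peptides must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(normal_pep, mutant_pep)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"expected exactly one substitution, found {len(diffs)}")
    start = protein_seq.find(normal_pep)
    if start < 0:
        raise ValueError("wild-type peptide not found in protein")
    if protein_seq.find(normal_pep, start + 1) >= 0:
        raise ValueError("wild-type peptide matches the protein more than once")
    return start + diffs[0] + 1, diffs[0] + 1


# ---------------------------------------------------------------------------
# Pipeline composition


def build_database(
    vcf_path: str | Path,
    transcripts: list[TranscriptModel],
    contigs: dict[str, str],
    out_fasta: str | Path,
    desired_len: int = DEFAULT_DESIRED_LEN,
    max_af: float = DEFAULT_MAX_AF,
    min_depth: int = DEFAULT_MIN_DEPTH,
    pop_af: Optional[dict[str, float]] = None,
) -> dict:
    """Run filter -> consequence -> context -> AF-filter -> paired FASTA.

    Each input variant lands in exactly one report bucket, so
    ``input == kept + sum(rejected-by-reason)``.  ``pop_af`` optionally
    overrides per-variant population allele frequencies by variant id.
    """
    variants = read_vcf_strelka(vcf_path)
    report: Counter = Counter()
    report["input"] = len(variants)
    kept, reasons = filter_variants_report(variants, min_depth)
    report.update(reasons)

    by_contig: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_contig.setdefault(t.contig, []).append(t)

    pairs: list[ContextPair] = []
    for v in kept:
        span = (v.pos - 1, v.pos - 1 + len(v.ref))
        overlapping = [
            t
            for t in by_contig.get(v.contig, [])
            if any(s < span[1] and span[0] < e for s, e in t.exons)
        ]
        if not overlapping:
            report["no_transcript"] += 1
            continue
        t = overlapping[0]
        call = call_consequence(v, t, contigs)
        if call.consequence == "non_coding":
            report["non_coding_biotype"] += 1
            continue
        if call.consequence == "synonymous":
            report["synonymous"] += 1
            continue
        af = v.max_pop_af
        if pop_af is not None and v.variant_id in pop_af:
            af = pop_af[v.variant_id]
        cds = spliced_cds(t, contigs[t.contig])
        pair = build_context_pair(
            call,
            translate_cds(cds),
            translate_cds(_edit_cds(v, t, contigs[t.contig], cds)),
            desired_len=desired_len,
            gene_id=t.gene_id,
            max_pop_af=af,
        )
        if pair is None:
            report["short_mutant_context"] += 1
            continue
        if not apply_af_filter([pair], max_af):
            report["population_af"] += 1
            continue
        pairs.append(pair)
        report["kept"] += 1

    write_paired_fasta(pairs, out_fasta)
    return {"pairs": pairs, "report": dict(report)}
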