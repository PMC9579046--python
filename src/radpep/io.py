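"""Readers and writers for the pipeline's file formats.

FASTA via Biopython, VCF via cyvcf2 (Strelka dialect: FILTER "PASS", read
depth in DP for SNVs and DPI for indels, FORMAT preferred over INFO), and
documented TSV layouts for peptide tables, transcript models and quant
matrices.  Missing values in quant tables are empty fields, never 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .types import ContextPair, PeptideRecord, QuantMatrix, TranscriptModel, VariantRecord

PEPTIDE_TABLE_COLUMNS = [
    "sequence",
    "sample_id",
    "condition",
    "timepoint_h",
    "intensity",
    "modifications",
    "source_proteins",
    "allele_ranks",
    "is_decoy",
    "search_score",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` mapping.

    Raises ``ValueError`` on duplicate ids or empty records.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate id {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id}")
        out[rec.id] = seq
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_paired_fasta(pairs: Iterable[ContextPair], path: str | Path) -> None:
    """Write paired normal/mutant context entries, normal first.

    Header grammar: ``>{variant_id}|{gene}|{aa_change}|{normal|mutant}``.
    Round-trips through :func:`read_fasta`.
    """
    records: dict[str, str] = {}
    for p in pairs:
        for label, seq in (("normal", p.normal_seq), ("mutant", p.mutant_seq)):
            header = f"{p.variant_id}|{p.gene_id}|{p.aa_change}|{label}"
            if header in records:
                raise ValueError(f"id collision: {header}")
            records[header] = seq
    write_fasta(records, path)


# ---------------------------------------------------------------------------
# VCF (Strelka dialect)


def _format_depth(variant, field: str) -> Optional[int]:
    """Per-sample FORMAT depth, summed over samples (tumor+normal)."""
    try:
        arr = variant.format(field)
    except KeyError:
        return None
    if arr is None:
        return None
    vals = np.asarray(arr).ravel()
    vals = vals[(vals >= 0) & (vals < np.iinfo(np.int32).max)]
    if vals.size == 0:
        return None
    return int(vals.sum())


def read_vcf_strelka(path: str | Path) -> list[VariantRecord]:
    """Parse a Strelka-style VCF into one :class:`VariantRecord` per ALT allele.

    Multi-allelic lines are split, sharing CHROM/POS/REF.  Depth comes from
    DP for SNVs and DPI for indels, FORMAT (summed over samples) preferred
    over INFO; an absent depth is recorded as ``None``, not 0.
    """
    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for i, v in enumerate(vcf, start=1):
            filt = v.FILTER or "PASS"  # cyvcf2 reports PASS as None
            info = dict(v.INFO)
            af = info.get("MAX_AF")
            for alt in v.ALT:
                try:
                    rec_is_indel = len(v.REF) != len(alt)
                    field = "DPI" if rec_is_indel else "DP"
                    depth = _format_depth(v, field)
                    if depth is None and field in info:
                        depth = int(info[field])
                    out.append(
                        VariantRecord(
                            contig=v.CHROM,
                            pos=v.POS,
                            ref=v.REF.upper(),
                            alt=str(alt).upper(),
                            filter=filt,
                            depth=depth,
                            max_pop_af=float(af) if af is not None else None,
                        )
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"malformed variant at record {i} ({v.CHROM}:{v.POS}): {exc}"
                    ) from exc
    finally:
        vcf.close()
    return out


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=DPI,Number=1,Type=Integer,Description="Read depth for indels">
##INFO=<ID=MAX_AF,Number=1,Type=Float,Description="Highest allele frequency observed in any population">
##FILTER=<ID=LowEVS,Description="Low empirical variant score">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: Iterable[VariantRecord], path: str | Path,
              contigs: Optional[dict[str, str]] = None) -> None:
    """Write variants as a minimal Strelka-dialect VCF (depths in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, seq in contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        for line in VCF_HEADER.splitlines()[1:]:
            fh.write(line + "\n")
        for v in variants:
            info = []
            if v.depth is not None:
                key = "DPI" if v.vtype in ("insertion", "deletion") else "DP"
                info.append(f"{key}={v.depth}")
            if v.max_pop_af is not None:
                info.append(f"MAX_AF={v.max_pop_af:g}")
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter}\t"
                f"{';'.join(info) or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Peptide tables


def _encode_mods(mods: list[tuple[str, int]]) -> str:
    return ";".join(f"{name}@{pos}" for name, pos in mods)


def _decode_mods(text: str) -> list[tuple[str, int]]:
    if not text:
        return []
    out = []
    for item in text.split(";"):
        name, _, pos = item.rpartition("@")
        if not name:
            raise ValueError(f"bad modification spec {item!r}")
        out.append((name, int(pos)))
    return out


def _encode_ranks(ranks: dict[str, float]) -> str:
    return ";".join(f"{r:g}@{a}" for a, r in ranks.items())


def _decode_ranks(text: str) -> dict[str, float]:
    if not text:
        return {}
    out = {}
    for item in text.split(";"):
        rank, _, allele = item.partition("@")
        out[allele] = float(rank)
    return out


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a TSV of peptide identifications into typed records.

    Required columns: sequence, sample_id, condition, timepoint_h, intensity.
    Optional: modifications (``name@pos;...``), source_proteins (``;``-joined),
    allele_ranks (``rank@allele;...``), is_decoy, search_score.  Unknown
    columns are preserved as opaque string metadata on ``record.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sequence", "sample_id", "condition", "timepoint_h", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    known = set(PEPTIDE_TABLE_COLUMNS)
    extra_cols = [c for c in df.columns if c not in known]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            PeptideRecord(
                sequence=d["sequence"],
                sample_id=d["sample_id"],
                condition=d["condition"],
                timepoint_h=int(d["timepoint_h"]),
                intensity=float(d["intensity"]) if d["intensity"] else 0.0,
                modifications=_decode_mods(d.get("modifications", "")),
                source_proteins=[p for p in d.get("source_proteins", "").split(";") if p],
                allele_ranks=_decode_ranks(d.get("allele_ranks", "")),
                is_decoy=d.get("is_decoy", "").lower() in ("1", "true", "yes"),
                search_score=float(d["search_score"]) if d.get("search_score") else 0.0,
                extra={c: d[c] for c in extra_cols},
            )
        )
    return records


def write_peptide_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sequence": r.sequence,
                "sample_id": r.sample_id,
                "condition": r.condition,
                "timepoint_h": r.timepoint_h,
                "intensity": f"{r.intensity:g}",
                "modifications": _encode_mods(r.modifications),
                "source_proteins": ";".join(r.source_proteins),
                "allele_ranks": _encode_ranks(r.allele_ranks),
                "is_decoy": "1" if r.is_decoy else "0",
                "search_score": f"{r.search_score:g}",
                **r.extra,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript models (documented TSV; one row per transcript, exons inline)


def read_transcript_table(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from TSV.

    Columns: transcript_id, gene_id, contig, strand, exons (``start-end;...``
    1-based inclusive), cds_start, cds_end (1-based inclusive), gene_biotype,
    transcript_biotypes (comma-joined, may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        exons = tuple(
            (int(s) - 1, int(e))
            for s, e in (iv.split("-") for iv in row.exons.split(";"))
        )
        out.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                contig=row.contig,
                strand=row.strand,
                exons=exons,
                cds_start=int(row.cds_start) - 1,
                cds_end=int(row.cds_end),
                gene_biotype=row.gene_biotype,
                transcript_biotypes=frozenset(
                    b for b in row.transcript_biotypes.split(",") if b
                ),
            )
        )
    return out


def write_transcript_table(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "contig": t.contig,
                "strand": t.strand,
                "exons": ";".join(f"{s + 1}-{e}" for s, e in t.exons),
                "cds_start": t.cds_start + 1,
                "cds_end": t.cds_end,
                "gene_biotype": t.gene_biotype,
                "transcript_biotypes": ",".join(sorted(t.transcript_biotypes)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quant matrices


def read_quant_matrix(values_path: str | Path, meta_path: str | Path) -> QuantMatrix:
    """Read a feature x sample abundance TSV plus a sample metadata TSV.

    Empty fields are missing values (NaN); 0 is a legal abundance.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return QuantMatrix(values, meta)


def write_quant_matrix(qm: QuantMatrix, values_path: str | Path, meta_path: str | Path) -> None:
    qm.values.to_csv(values_path, sep="\t", na_rep="")
    qm.sample_meta.to_csv(meta_path, sep="\t")


def load_table1_fixture() -> pd.DataFrame:
    """The packaged table of radiation-specific strong-binder peptides
    (sequence, allele, %rank, SwissProt entry, protein name, annotation flags)."""
    path = Path(__file__).parent / "data" / "table1_ct26.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["rank"] = df["rank"].astype(float)
    return df
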