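"""Synthetic dataset generation with the statistical structure the analyses
assume, so every pipeline stage is testable without external downloads.

Each generator emulates one input of the study design: a small spliced
transcriptome with biotype labels; a somatic VCF with known-truth
missense/synonymous/stop-gained/frameshift variants straddling the
depth-filter boundary; an MHC immunopeptidome with allele anchor motifs,
an 8-12-mer length distribution peaking at 9, condition/time-structured
intensities, injected radiation-only peptides and reversed-sequence decoys;
a label-free proteome matrix with injected log2 fold-changes and
abundance-dependent missingness; and linear light/heavy PRM calibration
series.  Every generator emits a machine-readable truth object so
downstream recovery tests consume only truth + outputs.

All randomness derives from ``SimConfig.seed`` through named substreams,
so stages re-run independently are reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as rio
from .types import (
    NMD_BIOTYPE,
    PROTEIN_CODING,
    PeptideRecord,
    QuantMatrix,
    TranscriptModel,
    VariantRecord,
)
from .variant_db import translate_cds

AA = "ACDEFGHIKLMNPQRSTVWY"
STOPS = {"TAA", "TAG", "TGA"}

# Allele-like anchor motifs: position (1-based; -1 = C terminus) -> preferred
# residues.  Kd-like prefers Tyr at P2, Dd-like Gly/Pro at P2/P3, Ld-like Pro
# at P2; all prefer aliphatic C-terminal anchors, mirroring H-2d motifs.
DEFAULT_MOTIFS: dict[str, dict[int, str]] = {
    "H-2-Kd": {2: "Y", -1: "LI"},
    "H-2-Dd": {2: "G", 3: "P", -1: "FLI"},
    "H-2-Ld": {2: "P", -1: "LF"},
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions (triplicate biological replicates, 24/48 h immunopeptidome
    time points, 0/24/48/72 h proteome time points, seven-point PRM series
    with a 100 fmol heavy spike)."""

    seed: int = 0

    # transcriptome
    n_transcripts: int = 12
    codons_range: tuple[int, int] = (80, 200)
    noncoding_fraction: float = 0.25  # split between non-coding biotype and NMD
    two_exon_fraction: float = 0.5

    # variants
    n_missense: int = 6
    n_synonymous: int = 2
    n_stop_gained: int = 2
    n_frameshift: int = 2
    dp_range: tuple[int, int] = (5, 20)
    lowqual_fraction: float = 0.2
    af_present_fraction: float = 0.3  # drawn uniform on [0, 0.05]

    # immunopeptidome
    allele_motifs: dict[str, dict[int, str]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIFS.items()}
    )
    n_replicates: int = 3
    ipp_timepoints: tuple[int, ...] = (24, 48)
    n_catalog_peptides: int = 300
    length_weights: dict[int, float] = field(
        default_factory=lambda: {8: 0.15, 9: 0.50, 10: 0.20, 11: 0.10, 12: 0.05}
    )
    anchor_fidelity: float = 0.9
    detection_prob: float = 0.7
    intensity_sigma: float = 0.5  # ln-scale multiplicative noise
    # summed-intensity boosts under irradiation, per time point (study scale)
    intensity_boost: dict[int, float] = field(
        default_factory=lambda: {24: 1.49, 48: 3.17}
    )
    n_radiation_only: int = 30
    decoy_fraction: float = 0.5
    target_score: tuple[float, float] = (10.0, 2.0)  # mean, sd
    decoy_score: tuple[float, float] = (5.0, 2.0)
    ptm_rate: float = 0.10
    ptm_pos7_boost: float = 3.0  # extra odds of position 7 on irradiated 9-mers
    ptm_names: tuple[str, ...] = ("Oxidation", "Deamidation", "Phospho")
    n_extra_controls: int = 2  # expanded control pool size (study leaves it open)

    # proteome quant
    n_proteins: int = 400
    n_de_proteins: int = 40
    # |log2FC| magnitudes drawn uniformly: real DE spans a wide FC range
    de_log2fc_range: tuple[float, float] = (0.5, 2.5)
    proteome_timepoints: tuple[int, ...] = (0, 24, 48, 72)
    proteome_sigma: float = 0.25  # log2-scale residual sd
    missing_midpoint: float = 16.0  # log2 abundance of 50% missingness
    missing_steepness: float = 1.5

    # PRM
    calibration_amounts: tuple[float, ...] = (0, 5, 10, 25, 50, 100, 150)
    heavy_spike_fmol: float = 100.0
    prm_noise: float = 0.05
    n_cells: float = 3e8
    # endogenous amounts chosen to sit at the study's copies-per-cell scale
    truth_endogenous_fmol: dict[str, float] = field(
        default_factory=lambda: {"control": 51.31, "irradiated": 99.63}
    )


def _rng(cfg: SimConfig, name: str) -> np.random.Generator:
    """Named substream: reproducible per stage regardless of call order."""
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# Transcriptome


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop."""
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def gen_transcriptome(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], dict[str, str]]:
    """Generate contig sequences, transcript models and the translated
    proteome.  Every coding transcript translates without internal stops;
    ``noncoding_fraction`` of transcripts carry a non-protein-coding gene
    biotype or the NMD transcript biotype (alternating)."""
    rng = _rng(cfg, "transcriptome")
    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    proteome: dict[str, str] = {}
    n_nc = int(round(cfg.noncoding_fraction * cfg.n_transcripts))
    for i in range(cfg.n_transcripts):
        tid = f"T{i:03d}"
        n_codons = int(rng.integers(cfg.codons_range[0], cfg.codons_range[1] + 1))
        cds = _random_cds(rng, n_codons)
        flank5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
        flank3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
        strand = "+" if rng.random() < 0.5 else "-"
        # forward-layout plan: flank5 | exon1 [| intron | exon2] | flank3
        if rng.random() < cfg.two_exon_fraction and len(cds) > 60:
            split = int(rng.integers(30, len(cds) - 30))
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=40)) + "AG"
            layout = flank5 + cds[:split] + intron + cds[split:] + flank3
            fwd_exons = [
                (len(flank5), len(flank5) + split),
                (len(flank5) + split + len(intron), len(layout) - len(flank3)),
            ]
        else:
            layout = flank5 + cds + flank3
            fwd_exons = [(len(flank5), len(layout) - len(flank3))]
        cds_span = (fwd_exons[0][0], fwd_exons[-1][1])
        if strand == "-":
            m = len(layout)
            contig_seq = str(Seq(layout).reverse_complement())
            exons = tuple(sorted((m - e, m - s) for s, e in fwd_exons))
            cds_span = (m - cds_span[1], m - cds_span[0])
        else:
            contig_seq = layout
            exons = tuple(fwd_exons)
        if i < n_nc:
            gene_biotype = "lincRNA" if i % 2 == 0 else PROTEIN_CODING
            tbio = frozenset() if i % 2 == 0 else frozenset({NMD_BIOTYPE})
        else:
            gene_biotype, tbio = PROTEIN_CODING, frozenset()
        contig = f"ctg{i:03d}"
        contigs[contig] = contig_seq
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{i:03d}",
            contig=contig,
            strand=strand,
            exons=exons,
            cds_start=cds_span[0],
            cds_end=cds_span[1],
            gene_biotype=gene_biotype,
            transcript_biotypes=tbio,
        )
        transcripts.append(t)
        proteome[tid] = translate_cds(cds)
    return contigs, transcripts, proteome


# ---------------------------------------------------------------------------
# Variants


def _cds_genomic_positions(t: TranscriptModel) -> list[int]:
    """Genomic positions (0-based) of spliced-CDS bases in transcript order."""
    pos: list[int] = []
    for s, e in t.exons:
        s2, e2 = max(s, t.cds_start), min(e, t.cds_end)
        if s2 < e2:
            pos.extend(range(s2, e2))
    if t.strand == "-":
        pos.reverse()
    return pos


_COMP = str.maketrans("ACGT", "TGCA")


def gen_variants(
    cfg: SimConfig,
    transcripts: list[TranscriptModel],
    contigs: dict[str, str],
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Inject known-truth variants into coding transcripts.

    Returns the variant records plus a truth table with the designed
    consequence, amino-acid change, and expected survival of the
    PASS / depth>=10 / population-AF filters.
    """
    rng = _rng(cfg, "variants")
    coding = [t for t in transcripts if t.is_coding_eligible]
    plan = (
        ["missense"] * cfg.n_missense
        + ["synonymous"] * cfg.n_synonymous
        + ["stop_gained"] * cfg.n_stop_gained
        + ["frameshift"] * cfg.n_frameshift
    )
    variants: list[VariantRecord] = []
    rows = []
    used_pos: set[tuple[str, int]] = set()
    for kind in plan:
        for _ in range(200):  # retry until a valid injection site is found
            t = coding[int(rng.integers(len(coding)))]
            cds_pos = _cds_genomic_positions(t)
            cds = "".join(contigs[t.contig][g] for g in cds_pos)
            if t.strand == "-":
                cds = cds.translate(_COMP)
            prot = translate_cds(cds)
            made = _inject(rng, kind, t, cds, cds_pos, contigs, prot)
            if made is None:
                continue
            v0, protein_pos, ref_aa, alt_aa = made
            if (v0[0], v0[1]) in used_pos:
                continue
            used_pos.add((v0[0], v0[1]))
            break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place a {kind} variant")
        dp = int(rng.integers(cfg.dp_range[0], cfg.dp_range[1] + 1))
        filt = "PASS" if rng.random() >= cfg.lowqual_fraction else "LowEVS"
        af = float(rng.uniform(0, 0.05)) if rng.random() < cfg.af_present_fraction else None
        v = VariantRecord(
            contig=v0[0], pos=v0[1], ref=v0[2], alt=v0[3],
            filter=filt, depth=dp, max_pop_af=af,
        )
        variants.append(v)
        coding_change = kind in ("missense", "stop_gained", "frameshift")
        survives = (
            filt == "PASS"
            and dp >= 10
            and (af is None or af < 0.01)
            and coding_change
            and not (kind == "stop_gained" and protein_pos <= 8)
        )
        if kind == "frameshift":
            aa_change = f"{ref_aa}{protein_pos}fs"
        elif kind == "stop_gained":
            aa_change = f"{ref_aa}{protein_pos}*"
        else:
            aa_change = f"{ref_aa}{protein_pos}{alt_aa}"
        rows.append(
            {
                "variant_id": v.variant_id,
                "kind": kind,
                "transcript_id": t.transcript_id,
                "protein_pos": protein_pos,
                "aa_change": aa_change,
                "depth": dp,
                "filter": filt,
                "max_pop_af": af if af is not None else "",
                "expected_in_db": survives,
            }
        )
    variants = sorted(variants, key=lambda v: (v.contig, v.pos))
    truth = pd.DataFrame(rows)
    return variants, truth


def _inject(rng, kind, t, cds, cds_pos, contigs, prot):
    """Design one edit of the requested kind; returns ((contig,pos,ref,alt),
    protein_pos, ref_aa, alt_aa) in VCF 1-based coordinates, or None if the
    sampled site cannot host the edit."""
    n_codons = len(cds) // 3
    contig_seq = contigs[t.contig]
    if kind in ("missense", "synonymous", "stop_gained"):
        ci = int(rng.integers(10, n_codons - 2))  # avoid start/stop neighborhood
        codon = cds[3 * ci : 3 * ci + 3]
        old_aa = str(Seq(codon).translate())
        offsets = rng.permutation(3)
        bases = rng.permutation(list("ACGT"))
        for off in offsets:
            for b in bases:
                if b == codon[off]:
                    continue
                new = codon[:off] + b + codon[off + 1 :]
                new_aa = str(Seq(new).translate())
                ok = (
                    (kind == "missense" and new_aa != old_aa and new_aa != "*")
                    or (kind == "synonymous" and new_aa == old_aa)
                    or (kind == "stop_gained" and new_aa == "*")
                )
                if not ok:
                    continue
                tx_index = 3 * ci + int(off)
                g = cds_pos[tx_index]
                ref = contig_seq[g]
                alt = b if t.strand == "+" else b.translate(_COMP)
                if alt == ref:
                    continue
                return (t.contig, g + 1, ref, alt), ci + 1, old_aa, new_aa
        return None
    # frameshift: delete 1 or 2 bases after an anchor, all within spliced CDS
    k = int(rng.integers(1, 3))
    ci = int(rng.integers(10, n_codons - 5))
    tx_index = 3 * ci
    idxs = list(range(tx_index, tx_index + k + 1))
    gs = [cds_pos[i] for i in idxs]
    if t.strand == "-":
        gs = sorted(gs)
    if gs != list(range(gs[0], gs[0] + k + 1)):
        return None  # spans a splice junction
    g0 = gs[0]
    ref = contig_seq[g0 : g0 + k + 1]
    alt = ref[0]
    old_aa = prot[ci] if ci < len(prot) else ""
    return (t.contig, g0 + 1, ref, alt), ci + 1, old_aa, ""


# ---------------------------------------------------------------------------
# Immunopeptidome


def _sample_peptide(rng, cfg, proteome_items, allele) -> tuple[str, str]:
    lengths = sorted(cfg.length_weights)
    probs = np.array([cfg.length_weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    for _ in range(100):
        L = int(rng.choice(lengths, p=probs))
        pid, seq = proteome_items[int(rng.integers(len(proteome_items)))]
        if len(seq) <= L:
            continue
        start = int(rng.integers(0, len(seq) - L))
        pep = list(seq[start : start + L])
        for pos, residues in cfg.allele_motifs[allele].items():
            if rng.random() < cfg.anchor_fidelity:
                idx = pos - 1 if pos > 0 else L + pos
                pep[idx] = residues[int(rng.integers(len(residues)))]
        return "".join(pep), pid
    raise RuntimeError("could not sample a peptide")  # pragma: no cover


def reverse_decoy(seq: str) -> str:
    """Sequence reversal keeping the terminal residue, mirroring common
    search-engine decoy construction."""
    return seq[:-1][::-1] + seq[-1]


def gen_immunopeptidome(
    cfg: SimConfig, proteome: dict[str, str]
) -> tuple[list[PeptideRecord], dict]:
    """Generate per-sample peptide observations plus a truth object.

    The catalog of target peptides is shared across samples; irradiated
    samples get a summed-intensity multiplier per time point, a set of
    radiation-only peptides is injected (absent from every control sample,
    including the expanded control pool), and reversed decoys are appended
    with a lower score distribution.
    """
    rng = _rng(cfg, "immunopeptidome")
    alleles = list(cfg.allele_motifs)
    items = sorted(proteome.items())
    catalog: list[tuple[str, str, str]] = []  # (sequence, source protein, allele)
    seen: set[str] = set()
    while len(catalog) < cfg.n_catalog_peptides:
        allele = alleles[int(rng.integers(len(alleles)))]
        pep, pid = _sample_peptide(rng, cfg, items, allele)
        if pep not in seen:
            seen.add(pep)
            catalog.append((pep, pid, allele))
    rad_only: list[tuple[str, str, str]] = []
    while len(rad_only) < cfg.n_radiation_only:
        allele = alleles[int(rng.integers(len(alleles)))]
        pep, pid = _sample_peptide(rng, cfg, items, allele)
        if pep not in seen:
            seen.add(pep)
            rad_only.append((pep, pid, allele))

    base_mu = rng.normal(np.log(1e6), 1.0, size=len(catalog) + len(rad_only))

    samples: list[tuple[str, str, int]] = []
    for cond in ("control", "irradiated"):
        for tp in cfg.ipp_timepoints:
            for r in range(1, cfg.n_replicates + 1):
                samples.append((f"{cond}{tp}_r{r}", cond, tp))
    for i in range(1, cfg.n_extra_controls + 1):
        samples.append((f"pool_r{i}", "control", 0))

    records: list[PeptideRecord] = []
    all_peps = catalog + rad_only
    for sid, cond, tp in samples:
        boost = cfg.intensity_boost.get(tp, 1.0) if cond == "irradiated" else 1.0
        for j, (pep, pid, allele) in enumerate(all_peps):
            is_rad_only = j >= len(catalog)
            if is_rad_only and cond != "irradiated":
                continue
            if rng.random() >= cfg.detection_prob:
                continue
            intensity = float(
                np.exp(base_mu[j] + rng.normal(0, cfg.intensity_sigma)) * boost
            )
            mods: list[tuple[str, int]] = []
            if rng.random() < cfg.ptm_rate:
                L = len(pep)
                w = np.ones(L)
                if cond == "irradiated" and L == 9:
                    w[6] *= cfg.ptm_pos7_boost
                pos = int(rng.choice(np.arange(1, L + 1), p=w / w.sum()))
                name = cfg.ptm_names[int(rng.integers(len(cfg.ptm_names)))]
                mods.append((name, pos))
            records.append(
                PeptideRecord(
                    sequence=pep,
                    sample_id=sid,
                    condition=cond,
                    timepoint_h=tp,
                    intensity=intensity,
                    modifications=mods,
                    source_proteins=[pid],
                    is_decoy=False,
                    search_score=float(rng.normal(*cfg.target_score)),
                    extra={"true_allele": allele},
                )
            )
        n_decoys = int(round(cfg.decoy_fraction * cfg.n_catalog_peptides))
        for _ in range(n_decoys):
            pep, pid, allele = catalog[int(rng.integers(len(catalog)))]
            records.append(
                PeptideRecord(
                    sequence=reverse_decoy(pep),
                    sample_id=sid,
                    condition=cond,
                    timepoint_h=tp,
                    intensity=float(np.exp(rng.normal(np.log(1e5), 1.0))),
                    is_decoy=True,
                    search_score=float(rng.normal(*cfg.decoy_score)),
                )
            )
    truth = {
        "radiation_only": sorted(p for p, _, _ in rad_only),
        "catalog": [
            {"sequence": p, "protein": pid, "allele": a} for p, pid, a in catalog
        ],
        "intensity_boost": {str(k): v for k, v in cfg.intensity_boost.items()},
        "samples": [
            {"sample_id": s, "condition": c, "timepoint_h": t} for s, c, t in samples
        ],
    }
    return records, truth


# ---------------------------------------------------------------------------
# Proteome quant


def gen_proteome_quant(cfg: SimConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Log-normal protein abundances with injected per-timepoint log2
    effects under irradiation and abundance-dependent missingness
    (logistic: low-abundance values are more often missing)."""
    rng = _rng(cfg, "proteome")
    n = cfg.n_proteins
    proteins = [f"P{i:04d}" for i in range(n)]
    base = rng.normal(20.0, 2.0, size=n)  # log2 abundance
    de_idx = rng.choice(n, size=cfg.n_de_proteins, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de_proteins)
    magnitudes = rng.uniform(*cfg.de_log2fc_range, size=cfg.n_de_proteins)
    # effect ramps with time: none at 0 h, half at 24 h, full at 48/72 h
    ramp = {0: 0.0, 24: 0.5, 48: 1.0, 72: 1.0}
    effects = np.zeros((n, len(cfg.proteome_timepoints)))
    for j, tp in enumerate(cfg.proteome_timepoints):
        effects[de_idx, j] = signs * magnitudes * ramp.get(tp, 1.0)

    cols, meta_rows = [], []
    data = {}
    for cond in ("control", "irradiated"):
        for j, tp in enumerate(cfg.proteome_timepoints):
            for r in range(1, cfg.n_replicates + 1):
                sid = f"{cond}{tp}_r{r}"
                mu = base + (effects[:, j] if cond == "irradiated" else 0.0)
                vals = mu + rng.normal(0, cfg.proteome_sigma, size=n)
                p_missing = 1.0 / (
                    1.0 + np.exp(cfg.missing_steepness * (vals - cfg.missing_midpoint))
                )
                miss = rng.random(n) < p_missing
                linear = np.power(2.0, vals)
                linear[miss] = np.nan
                data[sid] = linear
                cols.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "condition": cond, "timepoint_h": tp,
                     "replicate": r}
                )
    values = pd.DataFrame(data, index=proteins)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth_rows = []
    for i in range(n):
        for j, tp in enumerate(cfg.proteome_timepoints):
            if effects[i, j] != 0.0:
                truth_rows.append(
                    {"protein": proteins[i], "timepoint_h": tp,
                     "log2fc": effects[i, j]}
                )
    return QuantMatrix(values, meta), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# PRM series


def gen_prm_series(
    cfg: SimConfig, peptide: str = "KYLSVQSQL"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Light/heavy calibration series plus per-sample measured ratios.

    Measured ratio = amount / heavy_spike x (1 + eps), eps ~ N(0, prm_noise).
    The default series is the seven-point 0-150 fmol design with a constant
    100 fmol heavy spike.
    """
    rng = _rng(cfg, "prm")
    cal_rows = []
    for amt in cfg.calibration_amounts:
        eps = rng.normal(0, cfg.prm_noise) if cfg.prm_noise > 0 else 0.0
        cal_rows.append(
            {"peptide": peptide, "fmol": amt,
             "ratio": amt / cfg.heavy_spike_fmol * (1.0 + eps)}
        )
    sample_rows = []
    for cond, fmol in sorted(cfg.truth_endogenous_fmol.items()):
        for r in range(1, cfg.n_replicates + 1):
            eps = rng.normal(0, cfg.prm_noise) if cfg.prm_noise > 0 else 0.0
            sample_rows.append(
                {"peptide": peptide, "sample": f"{cond}_r{r}", "condition": cond,
                 "ratio": fmol / cfg.heavy_spike_fmol * (1.0 + eps),
                 "true_fmol": fmol}
            )
    return pd.DataFrame(cal_rows), pd.DataFrame(sample_rows)


# ---------------------------------------------------------------------------
# Dataset directory


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write a self-contained dataset directory: contig FASTA, transcript
    TSV, somatic VCF + truth table, peptide TSV + truth JSON, proteome
    matrices + truth, PRM tables, and an echo of the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs, transcripts, proteome = gen_transcriptome(cfg)
    rio.write_fasta(contigs, out / "contigs.fa")
    rio.write_fasta(proteome, out / "proteome.fa")
    rio.write_transcript_table(transcripts, out / "transcripts.tsv")

    variants, vtruth = gen_variants(cfg, transcripts, contigs)
    rio.write_vcf(variants, out / "variants.vcf", contigs)
    vtruth.to_csv(out / "variant_truth.tsv", sep="\t", index=False)

    records, ipp_truth = gen_immunopeptidome(cfg, proteome)
    rio.write_peptide_table(records, out / "peptides.tsv")
    (out / "ipp_truth.json").write_text(json.dumps(ipp_truth, indent=1))

    qm, ptruth = gen_proteome_quant(cfg)
    rio.write_quant_matrix(qm, out / "proteome_values.tsv", out / "proteome_meta.tsv")
    ptruth.to_csv(out / "proteome_truth.tsv", sep="\t", index=False)

    cal, samp = gen_prm_series(cfg)
    cal.to_csv(out / "prm_calibration.tsv", sep="\t", index=False)
    samp.to_csv(out / "prm_samples.tsv", sep="\t", index=False)

    cfg_echo = asdict(cfg)
    (out / "config.json").write_text(json.dumps(cfg_echo, indent=1, default=str))
    return {
        "contigs": contigs,
        "transcripts": transcripts,
        "proteome": proteome,
        "variants": variants,
        "variant_truth": vtruth,
        "peptides": records,
        "ipp_truth": ipp_truth,
        "proteome_quant": qm,
        "proteome_truth": ptruth,
        "prm_calibration": cal,
        "prm_samples": samp,
    }
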