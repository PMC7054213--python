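"""Readers and writers for the toolkit's file formats.

Variant input comes from VCF (one sample per file, or an explicit sample
id) or a MAF-like tab-delimited table with a configurable column map.
Matrices (catalogues, signatures, exposures) are plain UTF-8 CSV with the
class/signature labels in the first column, so that everything round-trips
through ``pandas`` unchanged.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from .catalogue import (
    GenomicMutation,
    MutationKind,
    mutation_kind,
    normalise_alleles,
)

MAF_DEFAULT_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}


def _to_mutation(sample: str, chrom: str, pos: int, ref: str, alt: str) -> GenomicMutation | None:
    pos, ref, alt = normalise_alleles(pos, ref.upper(), alt.upper())
    kind = mutation_kind(ref, alt)
    if kind is None:
        return None
    return GenomicMutation(sample, chrom, pos, ref, alt, kind)


def read_vcf(path: str, sample_id: str | None = None) -> list[GenomicMutation]:
    """Read somatic variants from a VCF; multi-allelic records are split.

    ``sample_id`` defaults to the file's basename without extension.
    Records that are neither SBS, true DBS nor simple indel after allele
    normalisation (e.g. 3-bp substitutions) are dropped here; kind-vs-schema
    filtering with logging happens in catalogue construction.
    """
    from cyvcf2 import VCF

    if sample_id is None:
        sample_id = os.path.basename(path)
        for suffix in (".gz", ".vcf"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
    muts: list[GenomicMutation] = []
    for record in VCF(path):
        for alt in record.ALT:
            if set(record.REF + alt) - set("ACGTN"):
                continue  # symbolic / breakend alleles
            m = _to_mutation(sample_id, record.CHROM, record.POS, record.REF, alt)
            if m is not None:
                muts.append(m)
    return muts


def read_vcf_dir(directory: str) -> list[GenomicMutation]:
    """Read every ``*.vcf`` in a directory, one sample per file."""
    muts: list[GenomicMutation] = []
    for name in sorted(os.listdir(directory)):
        if name.endswith((".vcf", ".vcf.gz")):
            muts.extend(read_vcf(os.path.join(directory, name)))
    return muts


def read_maf(path: str, columns: Mapping[str, str] | None = None) -> list[GenomicMutation]:
    """Read a MAF-like TSV; ``columns`` remaps the required field names."""
    cols = dict(MAF_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file lacks columns: {missing}")
    muts: list[GenomicMutation] = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        ref = rec[cols["ref"]].replace("-", "")
        alt = rec[cols["alt"]].replace("-", "")
        m = _to_mutation(
            rec[cols["sample"]], rec[cols["chrom"]], int(rec[cols["pos"]]), ref, alt
        )
        if m is not None:
            muts.append(m)
    return muts


def write_vcf(path: str, mutations: Sequence[GenomicMutation], contigs: Mapping[str, int], fetch) -> None:
    """Write mutations as a minimal VCF v4.2 with proper anchor bases.

    ``fetch(chrom, start, end)`` supplies reference sequence (0-based,
    half-open) for indel anchors.
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = sorted(mutations, key=lambda m: (m.chrom, m.pos))
    for m in ordered:
        if m.kind in (MutationKind.SBS, MutationKind.DBS):
            pos, ref, alt = m.pos, m.ref, m.alt
        elif m.kind is MutationKind.DEL:
            anchor = fetch(m.chrom, m.pos - 2, m.pos - 1)
            pos, ref, alt = m.pos - 1, anchor + m.ref, anchor
        else:  # INS between pos-1 and pos
            anchor = fetch(m.chrom, m.pos - 2, m.pos - 1)
            pos, ref, alt = m.pos - 1, anchor, anchor + m.alt
        lines.append(f"{m.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(path: str, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_matrix_csv(path: str) -> pd.DataFrame:
    """Read a labelled matrix CSV (first column = row labels)."""
    return pd.read_csv(path, index_col=0)


def write_matrix_csv(df: pd.DataFrame, path: str, index_label: str = "MutationType") -> None:
    df.rename_axis(index_label).to_csv(path, float_format="%.10g")
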