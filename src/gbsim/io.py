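"""Readers and writers for the standard interchange formats.

FASTA/FASTQ go through Biopython (gzip handled transparently by filename),
VCF reading through pysam, tabular formats through pandas.  Genotypes are
written as minimal VCF 4.2 with FORMAT ``GT:DP:GQ`` and 1-based positions;
all other coordinates in the package are 0-based half-open.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gbsim.config import InputError
from gbsim.sim.reads import FastqRead, ReadSet
from gbsim.sim.reference import ReferenceGenome
from gbsim.tables import (ABH_CHARS, ABH_CODES, GT_HET, GT_HOM_ALT,
                          GT_HOM_REF, GT_MISSING, GenotypeTable, MarkerMatrix)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(reads: ReadSet | list[FastqRead], path: str | Path) -> None:
    items = reads.reads if isinstance(reads, ReadSet) else reads
    with _open_text(path, "w") as fh:
        for r in items:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path) -> ReadSet:
    reads = []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33)
                           for q in rec.letter_annotations["phred_quality"])
            reads.append(FastqRead(rec.id, str(rec.seq), qual))
    return ReadSet(reads)


# ----------------------------------------------------------------------- VCF

def write_vcf(table: GenotypeTable, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeTable as VCF 4.2 (GT:DP:GQ, 1-based positions)."""
    gt_strings = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1",
                  GT_MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=gbsim\n')
        contigs = (contig_lengths or
                   {c: None for c in dict.fromkeys(table.sites["contig"])})
        for name, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            contig = table.sites["contig"].iat[i]
            pos = int(table.sites["pos"].iat[i]) + 1
            ref = table.sites["ref"].iat[i]
            alt = table.sites["alt"].iat[i]
            cells = []
            for j in range(len(table.samples)):
                cells.append(f"{gt_strings[int(table.gt[i, j])]}:"
                             f"{int(table.dp[i, j])}:{int(table.gq[i, j])}")
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\t"
                     f"GT:DP:GQ\t" + "\t".join(cells) + "\n")


def read_vcf(path: str | Path, provenance: str = "") -> GenotypeTable:
    """Read a GT:DP:GQ VCF back into a GenotypeTable (via pysam)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, gt_rows, dp_rows, gq_rows = [], [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
        gts, dps, gqs = [], [], []
        for s in samples:
            call = rec.samples[s]
            alleles = call.get("GT", (None, None))
            if alleles is None or None in alleles:
                gts.append(GT_MISSING)
            else:
                gts.append(int(sum(alleles)))
            dps.append(int(call.get("DP") or 0))
            gqs.append(int(call.get("GQ") or 0))
        gt_rows.append(gts)
        dp_rows.append(dps)
        gq_rows.append(gqs)
    vf.close()
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    shape = (len(rows), len(samples))
    return GenotypeTable(
        sites, samples,
        np.array(gt_rows, dtype=np.int8).reshape(shape),
        np.array(dp_rows, dtype=np.int32).reshape(shape),
        np.array(gq_rows, dtype=np.int16).reshape(shape),
        provenance=provenance)


# ----------------------------------------------------------------------- TSV

def write_barcodes(barcodes: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(list(barcodes.items()),
                 columns=["sample_id", "barcode"]).to_csv(
        path, sep="\t", index=False)


def read_barcodes(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "barcode"} <= set(df.columns):
        raise InputError("barcode table needs sample_id and barcode columns")
    return dict(zip(df["sample_id"], df["barcode"]))


def write_anchors(ref: ReferenceGenome, path: str | Path) -> None:
    ref.anchor_frame().to_csv(path, sep="\t", index=False)


def read_anchors(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"contig_id", "chrom", "start", "end", "cM"}
    if not need <= set(df.columns):
        raise InputError(f"anchor table needs columns {sorted(need)}")
    return df


def write_marker_matrix(matrix: MarkerMatrix, path: str | Path) -> None:
    chars = np.vectorize(ABH_CHARS.get)(matrix.calls)
    df = pd.DataFrame(chars, index=pd.Index(matrix.ids, name="marker_id"),
                      columns=matrix.samples)
    df.to_csv(path, sep="\t")


def read_marker_matrix(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls = np.vectorize(lambda c: ABH_CODES.get(c, -1))(
        df.to_numpy()).astype(np.int8)
    return MarkerMatrix(df.index.to_numpy(), calls, list(df.columns))


def write_map(gmap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path):
    from gbsim.mapbuilder import GeneticMap

    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
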