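"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; GFF3 read via gffutils (1-based closed coordinates on
disk, converted to 0-based half-open in memory); BED6 / bedGraph / TSV / CSV
via pandas.  Writers are deterministic so seeded runs are byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragnorm import FRAGMENT_COLUMNS, CoverageTrack, FragmentSet
from .peakcall import PeakSet


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sorted(genome.items())]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Emit gene models as GFF3 (gene + five_prime_UTR + CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            fh.write(f"{row.chrom}\tzeitshift\tgene\t{row.start + 1}\t"
                     f"{row.end}\t.\t{row.strand}\t.\t{attrs}\n")
            fh.write(f"{row.chrom}\tzeitshift\tfive_prime_UTR\t"
                     f"{row.utr5_start + 1}\t{row.utr5_end}\t.\t{row.strand}"
                     f"\t.\tParent={row.gene_id}\n")
            fh.write(f"{row.chrom}\tzeitshift\tCDS\t{row.cds_start + 1}\t"
                     f"{row.cds_end}\t.\t{row.strand}\t0\tParent={row.gene_id}\n")


def read_gff3(path) -> pd.DataFrame:
    """Gene-model table from a GFF3 file (gffutils-backed)."""
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for gene in db.features_of_type("gene"):
        start0, end = gene.start - 1, gene.end
        strand = gene.strand
        utr = next(db.children(gene, featuretype="five_prime_UTR"), None)
        cds = next(db.children(gene, featuretype="CDS"), None)
        tss, tes = (start0, end) if strand == "+" else (end, start0)
        rows.append({
            "gene_id": gene.id, "chrom": gene.seqid, "start": start0,
            "end": end, "strand": strand, "tss": tss, "tes": tes,
            "utr5_start": (utr.start - 1) if utr else start0,
            "utr5_end": utr.end if utr else start0,
            "cds_start": (cds.start - 1) if cds else start0,
            "cds_end": cds.end if cds else end,
        })
    return pd.DataFrame(rows)


def write_bed(fs: FragmentSet, path) -> None:
    df = fs.fragments.copy()
    df["name"] = fs.sample_id
    df["score"] = 0
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path, sample_id: str = "", genotype: str = "", zt: str = "",
             replicate: int = 1, treatment: str = "ChIP") -> FragmentSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, [0, 1, 2, 5] if df.shape[1] >= 6 else [0, 1, 2]]
    if df.shape[1] == 3:
        df["strand"] = "+"
    df.columns = FRAGMENT_COLUMNS
    return FragmentSet(sample_id=sample_id or str(path), genotype=genotype,
                       zt=zt, replicate=replicate, treatment=treatment,
                       fragments=df)


def write_bedgraph(track: CoverageTrack, path) -> None:
    import numpy as np
    vals = np.asarray(track.values, dtype=float)
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                if vals[run_start] != 0:
                    fh.write(f"{track.chrom}\t{run_start * track.bin_size}\t"
                             f"{i * track.bin_size}\t{vals[run_start]:g}\n")
                run_start = i


def write_narrowpeak(peaks: PeakSet, path) -> None:
    import math
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            neglog = -math.log10(p.p_value) if p.p_value > 0 else 999.0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t"
                     f"{min(int(10 * neglog), 1000)}\t.\t"
                     f"{p.fold_enrichment:.4f}\t{neglog:.4f}\t-1\t"
                     f"{p.summit - p.start}\n")


def write_sample_sheet(samples: dict, path) -> None:
    rows = [{"sample_id": fs.sample_id, "genotype": fs.genotype, "zt": fs.zt,
             "replicate": fs.replicate, "treatment": fs.treatment,
             "bed": f"{fs.sample_id}.bed"} for fs in samples.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
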