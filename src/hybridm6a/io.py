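"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; bedGraph and BED are 0-based half-open per the UCSC
conventions; tables are plain TSV.  bedGraph runs of equal coverage are
collapsed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: dict, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_bedgraph(tracks: dict, path: str) -> None:
    """Write {chrom: per-base array} as bedGraph, collapsing equal runs and
    omitting zero intervals."""
    with open(path, "w") as fh:
        for chrom in tracks:
            values = np.asarray(tracks[chrom])
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str, lengths: dict) -> dict:
    tracks = {chrom: np.zeros(int(n)) for chrom, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in tracks:
                tracks[chrom][int(start):int(end)] = float(value)
    return tracks


def write_fragments_bed(fragments: dict, path: str) -> None:
    """Write {chrom: (n, 2) interval array} as BED3."""
    with open(path, "w") as fh:
        for chrom in fragments:
            for start, end in np.asarray(fragments[chrom]):
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_fragments_bed(path: str) -> dict:
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end = line.split()[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return {chrom: np.asarray(v) for chrom, v in out.items()}


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_experiment(exp, outdir: str) -> None:
    """Write a simulated experiment to a directory in the standard formats."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta(exp.genomes.sequences_a, os.path.join(outdir, "genomeA.fa"))
    write_fasta(exp.genomes.sequences_b, os.path.join(outdir, "genomeB.fa"))
    write_tsv(exp.genomes.gene_models, os.path.join(outdir, "genes.tsv"))
    write_tsv(exp.genomes.variants, os.path.join(outdir, "variants.tsv"))
    write_tsv(exp.truth, os.path.join(outdir, "truth.tsv"))
    for key in exp.sample_keys():
        stem = f"{key.background}_{key.genotype}_{key.fraction}_rep{key.replicate + 1}"
        write_bedgraph(exp.coverage[key], os.path.join(outdir, stem + ".bedGraph"))
        write_fragments_bed(exp.fragments[key], os.path.join(outdir, stem + ".bed"))
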