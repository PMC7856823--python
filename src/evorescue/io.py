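"""File-format plumbing: FASTA alignments, haploid VCF, newick, TSV tables."""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import GeneAlignment

__all__ = [
    "write_alignment_fasta",
    "read_alignment_fasta",
    "read_alignment_dir",
    "write_dataset",
    "write_vcf",
    "read_vcf_genotypes",
    "write_presence_tsv",
    "read_presence_tsv",
    "read_annotations_tsv",
]

_DECODE = {0: "A", 1: "C", 2: "G", 3: "T", 255: "N"}


def write_alignment_fasta(aln: GeneAlignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(_DECODE[b] for b in row)), id=sid, description="")
        for sid, row in zip(aln.ids, aln.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path, gene_id: str | None = None) -> GeneAlignment:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if gene_id is None:
        gene_id = path.stem
    return GeneAlignment.from_sequences(gene_id, [r.id for r in records],
                                        [str(r.seq) for r in records])


def read_alignment_dir(directory, pattern: str = "*.fasta") -> list:
    """One alignment per file; the cluster id is the file stem."""
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files under {directory}")
    return [read_alignment_fasta(f) for f in files]


def write_vcf(dataset, path) -> None:
    """Merged haploid VCF (1-based positions, one contig per gene)."""
    n = dataset.n
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for g in dataset.genealogies:
        lines.append(f"##contig=<ID={g.gene_id},length={dataset.locus_len}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.sample_ids))
    for g in dataset.genealogies:
        tip_seqs = np.stack([g.node_sequence(t, dataset.locus_len) for t in range(n)])
        seg = np.flatnonzero((tip_seqs.sum(axis=0) > 0) & (tip_seqs.sum(axis=0) < n))
        for site in seg:
            gts = "\t".join(str(int(b)) for b in tip_seqs[:, site])
            lines.append(f"{g.gene_id}\t{site + 1}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_genotypes(path):
    """(sites x samples) 0/1 haploid genotype matrix from a VCF (missing = -1)."""
    import pysam

    rows, samples = [], None
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            row = []
            for s in samples:
                alleles = rec.samples[s].allele_indices
                a = alleles[0] if alleles else None
                row.append(-1 if a is None else int(a))
            rows.append(row)
    return np.array(rows, dtype=int), samples


def write_dataset(dataset, outdir, mu_scale_newick: float | None = None) -> dict:
    """Write FASTA per gene, merged VCF, newick genealogies and the truth record.

    Returns the paths written.  ``mu_scale_newick`` optionally rescales
    newick branch lengths from generations to expected substitutions/site.
    """
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    os.makedirs(aln_dir, exist_ok=True)
    for aln in dataset.alignments():
        write_alignment_fasta(aln, aln_dir / f"{aln.gene_id}.fasta")
    vcf_path = outdir / "variants.vcf"
    write_vcf(dataset, vcf_path)
    scale = mu_scale_newick if mu_scale_newick is not None else 1.0
    nwk_path = outdir / "genealogies.nwk"
    with open(nwk_path, "w") as fh:
        for g in dataset.genealogies:
            fh.write(g.newick(dataset.sample_ids, lengths_scale=scale) + "\n")
    truth_path = outdir / "truth.json"
    truth_path.write_text(dataset.truth_record().to_json() + "\n")
    return {"alignments": str(aln_dir), "vcf": str(vcf_path),
            "newick": str(nwk_path), "truth": str(truth_path)}


def write_presence_tsv(matrix, path) -> None:
    """Rows = clusters, columns = genomes; a second header row carries groups."""
    df = matrix.to_frame()
    with open(path, "w") as fh:
        fh.write("cluster\t" + "\t".join(df.columns) + "\n")
        fh.write("#group\t" + "\t".join(matrix.groups[g] for g in df.columns) + "\n")
        for cid, row in df.iterrows():
            fh.write(cid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_presence_tsv(path):
    from .pangenome import PresenceMatrix

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_line = fh.readline().rstrip("\n").split("\t")
        genome_ids = tuple(header[1:])
        groups = dict(zip(genome_ids, group_line[1:]))
        cluster_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cluster_ids.append(parts[0])
            rows.append([bool(int(v)) for v in parts[1:]])
    return PresenceMatrix(genome_ids=genome_ids, groups=groups,
                          cluster_ids=tuple(cluster_ids), matrix=np.array(rows, dtype=bool))


def read_annotations_tsv(path) -> dict:
    """cluster -> (annotated flag, category) from a 3-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["cluster", "annotated", "category"])
    return {r.cluster: (bool(int(r.annotated)), None if pd.isna(r.category) else str(r.category))
            for r in df.itertuples()}


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (frozenset, set)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
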