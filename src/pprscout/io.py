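"""File-format plumbing: FASTA transcripts/peptides, plastid FASTA+GFF3,
and the packaged TSV gene-table dialect."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .orf_processing import TranscriptRecord
from .target_prediction import PlastidGene

_GENE_FEATURE_TYPES = {"CDS", "intron", "exon", "tRNA", "rRNA"}


def read_transcripts(path):
    return [
        TranscriptRecord(transcript_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_protein_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_peptides(orfs, path):
    """Peptide FASTA; header carries orf|transcript|strand|frame|coords|completeness
    with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f">{o.orf_id}|{o.transcript_id}|{o.strand}|{o.frame}"
                f"|{o.nt_start + 1}-{o.nt_end}|{o.completeness}\n{o.aa_sequence}\n"
            )


def load_plastid_genes(fasta_path, gff3_path):
    """Plastid gene set from a genome FASTA + GFF3.

    Gene features define the RNA span (reverse-complemented to the sense
    strand for minus-strand genes); child CDS/intron/exon/tRNA/rRNA features
    are mapped to 1-based gene-relative coordinates.  A second gene with the
    same Name, or an ``ir_duplicate=true`` attribute, marks an
    inverted-repeat duplicate.
    """
    import gffutils

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    seen_names = set()
    for gene in db.features_of_type("gene", order_by="start"):
        name = gene.attributes.get("Name", [gene.id])[0]
        seq = genome[gene.seqid][gene.start - 1: gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        rna = seq.replace("T", "U")
        feats = []
        for child in db.children(gene.id):
            if child.featuretype not in _GENE_FEATURE_TYPES:
                continue
            if gene.strand == "-":
                start = gene.end - child.end + 1
                end = gene.end - child.start + 1
            else:
                start = child.start - gene.start + 1
                end = child.end - gene.start + 1
            feats.append((child.featuretype, start, end))
        feats.sort(key=lambda f: f[1])
        ir_attr = gene.attributes.get("ir_duplicate", ["false"])[0].lower() == "true"
        genes.append(
            PlastidGene(
                gene_name=name,
                rna_sequence=rna,
                features=tuple(feats),
                ir_duplicate=ir_attr or name in seen_names,
            )
        )
        seen_names.add(name)
    return genes


def load_gene_table(path):
    """Packaged single-file gene-table dialect: TSV with columns gene_name,
    rna_sequence, features (semicolon-separated ``type:start-end``),
    ir_duplicate (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = []
    for row in df.itertuples(index=False):
        feats = []
        for item in str(row.features).split(";"):
            ftype, _, span = item.partition(":")
            a, _, b = span.partition("-")
            feats.append((ftype.strip(), int(a), int(b)))
        genes.append(
            PlastidGene(
                gene_name=str(row.gene_name),
                rna_sequence=str(row.rna_sequence),
                features=tuple(feats),
                ir_duplicate=bool(int(getattr(row, "ir_duplicate", 0))),
            )
        )
    return genes
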