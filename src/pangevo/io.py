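"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; tables are TSV via pandas; trees are Newick.
Pan-matrices are TSV with the genome id in the first column and cluster ids
as the header.  Protein FASTA headers follow the ``genomeID|geneID``
convention.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pangenome import GeneRecord
from .trees import Tree

__all__ = ["read_fasta", "write_fasta", "read_gene_records",
           "write_gene_records", "read_pan_matrix", "write_pan_matrix",
           "read_tree", "write_tree", "read_table", "write_table",
           "read_annotation_hits"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_records(path) -> list[GeneRecord]:
    """Protein FASTA with ``>genomeID|geneID`` headers."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"header {rec.id!r} is not genomeID|geneID")
        genome, gene = rec.id.split("|", 1)
        records.append(GeneRecord(genome_id=genome, gene_id=gene,
                                  protein=str(rec.seq)))
    return records


def write_gene_records(records: list[GeneRecord], path) -> None:
    write_fasta({f"{r.genome_id}|{r.gene_id}": r.protein for r in records}, path)


def read_pan_matrix(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", index_col=0)
    pm.index = pm.index.map(str)
    return pm.astype(int)


def write_pan_matrix(pan_matrix: pd.DataFrame, path) -> None:
    pan_matrix.rename_axis("genome").to_csv(path, sep="\t")


def read_tree(path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


def write_tree(tree: Tree, path, supports: bool = False) -> None:
    Path(path).write_text(tree.to_newick(supports=supports) + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_annotation_hits(path):
    """Hits TSV (gene_id, category, pident, qcov, evalue, bitscore)."""
    from .enrichment import AnnotationHit

    df = pd.read_csv(path, sep="\t")
    return [AnnotationHit(gene_id=str(r.gene_id), category=str(r.category),
                          percent_identity=float(r.pident),
                          query_coverage=float(r.qcov),
                          e_value=float(r.evalue), bitscore=float(r.bitscore))
            for r in df.itertuples()]
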