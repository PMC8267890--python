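"""Ortholog clustering and pan-matrix construction.

Proteins are clustered greedily, CD-HIT style: sequences are processed
longest-first and each either joins the first existing cluster whose
representative aligns at >=50% identity with >=50% coverage of BOTH sequences,
or seeds a new cluster.  The genomes x clusters abundance table (pan-matrix)
is then partitioned into core (present in every genome), unique (one genome)
and mosaic (the rest), and core calls can be intersected between two
clusterings by majority member overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["GeneRecord", "OrthologCluster", "PanPartition",
           "pairwise_identity", "cluster_proteins", "consensus_core",
           "dedup_core", "build_pan_matrix", "partition"]

_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX")


@dataclass(frozen=True)
class GeneRecord:
    genome_id: str
    gene_id: str
    protein: str
    cds: str | None = None

    def __post_init__(self):
        if not self.protein:
            raise ValueError(f"{self.genome_id}|{self.gene_id}: empty protein")


@dataclass
class OrthologCluster:
    cluster_id: str
    members: list[tuple[str, str]]            # (genome_id, gene_id)
    representative: tuple[str, str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("cluster needs at least one member")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class PanPartition:
    core: set[str] = field(default_factory=set)
    mosaic: set[str] = field(default_factory=set)
    unique: set[str] = field(default_factory=set)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    """Global protein aligner: BLOSUM62, gap open 11 / extend 1, free end gaps.

    The scoring scheme is fixed here so results are reproducible; it is
    reported in the partition/cluster TSV metadata by the CLI.
    """
    aln = Align.PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    try:
        aln.end_insertion_score = 0.0
        aln.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aln.target_end_gap_score = 0.0
        aln.query_end_gap_score = 0.0
    aln.mode = "global"
    return aln


def pairwise_identity(a: str, b: str) -> tuple[float, float, float]:
    """(identity, coverage_a, coverage_b) from a global affine alignment.

    Identity is exact matches over aligned columns after trimming terminal-gap
    overhang; coverage of each sequence is its aligned span over its length.
    Exactly symmetric in its arguments.
    """
    for s in (a, b):
        if not s:
            raise ValueError("empty sequence")
        bad = set(s.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    swapped = (len(b), b) < (len(a), a)
    x, y = (b, a) if swapped else (a, b)
    identity, cov_x, cov_y = _identity_core(x.upper(), y.upper())
    return (identity, cov_y, cov_x) if swapped else (identity, cov_x, cov_y)


def _identity_core(a: str, b: str) -> tuple[float, float, float]:
    alignment = _aligner().align(a, b)[0]
    coords = alignment.coordinates      # 2 x (k+1) path vertices
    segs = []
    for i in range(coords.shape[1] - 1):
        da = coords[0, i + 1] - coords[0, i]
        db = coords[1, i + 1] - coords[1, i]
        segs.append((coords[0, i], coords[1, i], da, db))
    # trim terminal overhang (gap-only segments at either end)
    while segs and (segs[0][2] == 0 or segs[0][3] == 0):
        segs.pop(0)
    while segs and (segs[-1][2] == 0 or segs[-1][3] == 0):
        segs.pop()
    if not segs:
        return 0.0, 0.0, 0.0
    columns = matches = 0
    for a0, b0, da, db in segs:
        columns += max(da, db)
        if da and db:
            matches += sum(1 for k in range(da) if a[a0 + k] == b[b0 + k])
    span_a = segs[-1][0] + segs[-1][2] - segs[0][0]
    span_b = segs[-1][1] + segs[-1][3] - segs[0][1]
    return matches / columns, span_a / len(a), span_b / len(b)


def cluster_proteins(records: list[GeneRecord], identity_min: float = 0.5,
                     coverage_min: float = 0.5) -> list[OrthologCluster]:
    """Greedy incremental clustering against cluster representatives.

    Sequences are processed longest-first (ties by genome then gene id); each
    joins the first cluster whose representative passes both thresholds, else
    seeds a new cluster.  Every gene lands in exactly one cluster.
    """
    if not records:
        raise ValueError("no records")
    seen = set()
    for r in records:
        key = (r.genome_id, r.gene_id)
        if key in seen:
            raise ValueError(f"duplicate gene {key}")
        seen.add(key)
    ordered = sorted(records,
                     key=lambda r: (-len(r.protein), r.genome_id, r.gene_id))
    clusters: list[OrthologCluster] = []
    reps: list[str] = []
    for rec in ordered:
        placed = False
        for cluster, rep_seq in zip(clusters, reps):
            ident, cov_a, cov_b = pairwise_identity(rep_seq, rec.protein)
            if ident >= identity_min and cov_a >= coverage_min and cov_b >= coverage_min:
                cluster.members.append((rec.genome_id, rec.gene_id))
                placed = True
                break
        if not placed:
            cid = f"C{len(clusters) + 1:04d}"
            clusters.append(OrthologCluster(
                cluster_id=cid,
                members=[(rec.genome_id, rec.gene_id)],
                representative=(rec.genome_id, rec.gene_id)))
            reps.append(rec.protein)
    return clusters


def consensus_core(partition_a: PanPartition, clusters_a: list[OrthologCluster],
                   partition_b: PanPartition, clusters_b: list[OrthologCluster],
                   min_overlap: float = 0.5) -> list[OrthologCluster]:
    """Core clusters of method A confirmed by method B.

    A core cluster of A is retained iff some core cluster of B shares at least
    ``min_overlap`` of A's members.  Both clusterings must cover the same gene
    universe; returned clusters are A's.
    """
    universe_a = {m for c in clusters_a for m in c.members}
    universe_b = {m for c in clusters_b for m in c.members}
    if universe_a != universe_b:
        raise ValueError("clusterings cover different gene universes")
    core_b = [set(c.members) for c in clusters_b
              if c.cluster_id in partition_b.core]
    out = []
    for cluster in clusters_a:
        if cluster.cluster_id not in partition_a.core:
            continue
        members = set(cluster.members)
        if any(len(members & cb) >= min_overlap * len(members) for cb in core_b):
            out.append(cluster)
    return out


def dedup_core(cluster: OrthologCluster,
               lengths: dict[tuple[str, str], int]) -> OrthologCluster:
    """One member per genome: keep the longest paralog, ties to the smallest
    gene id.  ``lengths`` maps (genome_id, gene_id) to protein length."""
    by_genome: dict[str, list[tuple[str, str]]] = {}
    for member in cluster.members:
        by_genome.setdefault(member[0], []).append(member)
    kept = []
    for genome in sorted(by_genome):
        kept.append(min(by_genome[genome],
                        key=lambda m: (-lengths[m], m[1])))
    rep = cluster.representative if cluster.representative in kept else kept[0]
    return OrthologCluster(cluster_id=cluster.cluster_id, members=kept,
                           representative=rep)


def build_pan_matrix(clusters: list[OrthologCluster],
                     genomes: list[str]) -> pd.DataFrame:
    """Genomes x clusters abundance table (member counts)."""
    known = set(genomes)
    pm = pd.DataFrame(0, index=list(genomes),
                      columns=[c.cluster_id for c in clusters], dtype=int)
    for cluster in clusters:
        for genome, _ in cluster.members:
            if genome not in known:
                raise ValueError(f"unknown genome id {genome!r}")
            pm.loc[genome, cluster.cluster_id] += 1
    return pm


def partition(pan_matrix: pd.DataFrame) -> PanPartition:
    """Core (all genomes), unique (exactly one genome) and mosaic clusters.

    With a single genome every cluster is literally present in all genomes, so
    core takes precedence over unique.
    """
    present = pan_matrix > 0
    if (present.sum(axis=0) == 0).any():
        raise ValueError("pan-matrix has an all-zero column")
    out = PanPartition()
    n = pan_matrix.shape[0]
    for cid, col in present.items():
        k = int(col.sum())
        if k == n:
            out.core.add(cid)
        elif k == 1:
            out.unique.add(cid)
        else:
            out.mosaic.add(cid)
    return out
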