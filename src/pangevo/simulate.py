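"""Synthetic-data generators with known ground truth.

Three generators cover the inputs of the analysis pipeline:

* gene-family content evolving on a rooted tree under a Gillespie process of
  family gain (innovation), family loss and copy-number duplication;
* codon alignments under a Goldman-Yang style substitution model with site
  classes of distinct omega and optional foreground branches;
* mosaic (recombinant) nucleotide alignments with known breakpoints plus
  clonal controls.

Every generator takes an integer seed and draws all randomness from a single
``numpy.random.Generator``; identical seeds give identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codons
from .trees import Tree

__all__ = [
    "GeneContentSimConfig", "GeneContentSimResult", "simulate_gene_content",
    "CodonSimConfig", "CodonSimResult", "simulate_codon_alignment",
    "RecombSimConfig", "RecombSimResult", "simulate_recombinant_set",
    "simulate_protein_families",
]


# ===================================================== gene-content evolution
@dataclass
class GeneContentSimConfig:
    """Parameters of the gene gain/loss/duplication process.

    Branch lengths are in expected-event units: along a branch of length t a
    genome with n families accrues gains at rate ``gain_rate * n``, each family
    is lost at rate ``loss_rate`` and duplicated at rate ``dup_rate`` (copy
    number capped at ``max_copies``).  Gains always create brand-new families,
    never re-gains, so the ground truth stays unambiguous.
    """

    tree: Tree
    root_size: int = 100
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    dup_rate: float = 0.0
    seed: int = 0
    max_copies: int = 9

    def validate(self) -> None:
        if self.root_size < 1:
            raise ValueError("root_size must be >= 1")
        if min(self.gain_rate, self.loss_rate, self.dup_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not self.tree.root.children:
            raise ValueError("tree must be rooted with children at the root")
        for node in self.tree.internal_nodes():
            if len(node.children) != 2:
                raise ValueError(
                    "gene-content simulation requires a rooted binary tree")


@dataclass
class GeneContentSimResult:
    pan_matrix: pd.DataFrame          # leaves x families surviving in >=1 leaf
    states: pd.DataFrame              # every node x every family (copy number)
    events: pd.DataFrame              # per branch (child node): gains/losses/dups
    config: GeneContentSimConfig


def simulate_gene_content(config: GeneContentSimConfig) -> GeneContentSimResult:
    """Evolve gene-family content down the tree; returns leaf pan-matrix and
    the true ancestral states plus per-branch event counts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    tree.label_internal()

    counter = [0]

    def new_family() -> str:
        counter[0] += 1
        return f"F{counter[0]:05d}"

    root_state = {new_family(): 1 for _ in range(config.root_size)}
    states: dict[str, dict[str, int]] = {tree.root.label: root_state}
    events: list[dict] = []

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[node.parent.label]
        state = dict(parent_state)
        t = node.length if node.length is not None else 0.0
        gains = losses = dups = 0
        clock = 0.0
        while True:
            n = len(state)
            r_gain = config.gain_rate * n
            r_loss = config.loss_rate * n
            r_dup = config.dup_rate * n
            total = r_gain + r_loss + r_dup
            if total <= 0:
                break
            clock += rng.exponential(1.0 / total)
            if clock > t:
                break
            u = rng.random() * total
            if u < r_gain:
                state[new_family()] = 1
                gains += 1
            elif u < r_gain + r_loss:
                victim = list(state)[rng.integers(n)]
                del state[victim]
                losses += 1
            else:
                victim = list(state)[rng.integers(n)]
                if state[victim] < config.max_copies:
                    state[victim] += 1
                dups += 1
        states[node.label] = state
        events.append({"node": node.label, "parent": node.parent.label,
                       "branch_length": t, "gains": gains, "losses": losses,
                       "duplications": dups,
                       "families_parent": len(parent_state),
                       "families_child": len(state)})

    families = [f"F{i + 1:05d}" for i in range(counter[0])]
    node_order = [n.label for n in tree.preorder()]
    full = pd.DataFrame(0, index=node_order, columns=families, dtype=int)
    for label, state in states.items():
        for fam, copies in state.items():
            full.loc[label, fam] = copies

    leaf_labels = tree.leaf_labels()
    leaf_rows = full.loc[leaf_labels]
    surviving = leaf_rows.columns[(leaf_rows > 0).any(axis=0)]
    pan = leaf_rows[surviving].copy()

    events_df = pd.DataFrame(events).set_index("node")
    return GeneContentSimResult(pan_matrix=pan, states=full,
                                events=events_df, config=config)


# ======================================================== codon substitution
@dataclass
class CodonSimConfig:
    """Codon alignment evolved on a tree with site classes of distinct omega.

    ``site_classes`` is a list of (proportion, omega) pairs (proportions sum
    to 1).  Branches named in ``foreground_branches`` substitute
    ``foreground_omega`` for the class omega at the sites of the classes in
    ``foreground_classes`` (default: the last class only, the usual
    branch-site reading).
    """

    tree: Tree
    n_codons: int = 300
    kappa: float = 2.0
    site_classes: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 1.0)])
    foreground_branches: frozenset[str] = frozenset()
    foreground_omega: float | None = None
    foreground_classes: frozenset[int] | None = None
    codon_frequencies: np.ndarray | str = "uniform"
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        props = [p for p, _ in self.site_classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("site-class proportions must sum to 1")
        if any(w < 0 for _, w in self.site_classes):
            raise ValueError("omega must be non-negative")
        if self.foreground_branches and self.foreground_omega is None:
            raise ValueError("foreground branches given without foreground_omega")
        if len(self.tree.leaves()) < 2:
            raise ValueError("tree needs at least two leaves")

    def pi(self) -> np.ndarray:
        if isinstance(self.codon_frequencies, str):
            if self.codon_frequencies != "uniform":
                raise ValueError("named frequency schemes: 'uniform' "
                                 "(or pass an explicit 61-vector)")
            return np.full(codons.N_CODONS, 1.0 / codons.N_CODONS)
        pi = np.asarray(self.codon_frequencies, dtype=float)
        if pi.shape != (codons.N_CODONS,) or pi.min() < 0:
            raise ValueError("codon_frequencies must be a non-negative 61-vector")
        return pi / pi.sum()


@dataclass
class CodonSimResult:
    sequences: dict[str, str]     # leaf label -> ungapped CDS (3*n_codons)
    site_classes: np.ndarray      # per-codon class index
    config: CodonSimConfig
    ancestral_sequences: dict[str, str] | None = None   # internal nodes (truth)


def simulate_codon_alignment(config: CodonSimConfig) -> CodonSimResult:
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    tree.label_internal()
    pi = config.pi()
    n = config.n_codons

    n_classes = len(config.site_classes)
    props = np.array([p for p, _ in config.site_classes])
    labels = rng.choice(n_classes, size=n, p=props)
    fg_classes = (config.foreground_classes
                  if config.foreground_classes is not None
                  else frozenset({n_classes - 1}))

    root_seq = rng.choice(codons.N_CODONS, size=n, p=pi)
    seqs = {tree.root.label: root_seq}
    leaf_seqs: dict[str, str] = {}

    qcache: dict[float, np.ndarray] = {}

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent = seqs[node.parent.label]
        child = parent.copy()
        t = node.length if node.length is not None else 0.0
        if t > 0:
            for ci, (_, omega) in enumerate(config.site_classes):
                if node.label in config.foreground_branches and ci in fg_classes:
                    omega = config.foreground_omega
                if omega not in qcache:
                    qcache[omega] = codons.rate_matrix(config.kappa, omega, pi)
                p = codons.transition_probs(qcache[omega], pi, np.array([t]))[0]
                sites = np.flatnonzero(labels == ci)
                for codon in np.unique(parent[sites]):
                    here = sites[parent[sites] == codon]
                    child[here] = rng.choice(codons.N_CODONS, size=here.size,
                                             p=p[codon])
        seqs[node.label] = child
        if node.is_leaf():
            leaf_seqs[node.label] = codons.decode(child)

    ancestral = {lab: codons.decode(arr) for lab, arr in seqs.items()
                 if lab not in leaf_seqs}
    return CodonSimResult(sequences=leaf_seqs, site_classes=labels,
                          config=config, ancestral_sequences=ancestral)


# ========================================================= mosaic sequences
@dataclass
class RecombSimConfig:
    """One recombinant mosaic of two diverged parents plus clonal controls.

    Segments between breakpoints follow the 0-based half-open convention
    [start, end); even-numbered segments copy parent A, odd-numbered copy B.
    """

    parent_divergence: float = 0.1
    breakpoints: tuple[int, ...] = ()
    length: int = 1000
    n_clonal_controls: int = 2
    seed: int = 0

    def validate(self) -> None:
        bps = list(self.breakpoints)
        if bps != sorted(set(bps)):
            raise ValueError("breakpoints must be strictly increasing")
        if bps and (bps[0] <= 0 or bps[-1] >= self.length):
            raise ValueError("breakpoints must lie within (0, length)")
        if not 0 <= self.parent_divergence <= 1:
            raise ValueError("parent_divergence is a per-site proportion")


@dataclass
class RecombSimResult:
    alignment: dict[str, str]       # parentA, parentB, recombinant, control*
    breakpoints: tuple[int, ...]
    config: RecombSimConfig


_NT = np.frombuffer(b"ACGT", dtype="S1")


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < p)
    for i in hits:
        choices = _NT[_NT != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def simulate_recombinant_set(config: RecombSimConfig,
                             min_length: int | None = None) -> RecombSimResult:
    config.validate()
    if min_length is not None and config.length < min_length:
        warnings.warn("alignment shorter than twice the downstream window")
    rng = np.random.default_rng(config.seed)
    a = _NT[rng.integers(4, size=config.length)]
    b = _mutate(a, config.parent_divergence, rng)

    bounds = [0, *config.breakpoints, config.length]
    rec = a.copy()
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if k % 2 == 1:
            rec[lo:hi] = b[lo:hi]

    aln = {
        "parentA": a.tobytes().decode(),
        "parentB": b.tobytes().decode(),
        "recombinant": rec.tobytes().decode(),
    }
    for i in range(config.n_clonal_controls):
        ctrl = _mutate(a, config.parent_divergence / 2.0, rng)
        aln[f"control{i + 1}"] = ctrl.tobytes().decode()
    return RecombSimResult(alignment=aln, breakpoints=tuple(config.breakpoints),
                           config=config)


# ================================================== protein family sequences
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_protein_families(n_families: int, genome_ids: list[str],
                              seed: int = 0, length_range=(80, 200),
                              within_divergence: float = 0.1) -> list[tuple[str, str, str]]:
    """Unrelated random protein families copied into every genome with
    point-mutation noise; returns (genome_id, gene_id, protein) records.

    Families drawn independently sit near random-background identity (<10%),
    copies within a family at ~(1 - within_divergence) identity, so threshold
    clustering at 50% identity should recover them exactly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for f in range(n_families):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = rng.integers(20, size=length)
        for g in genome_ids:
            prot = ancestor.copy()
            hits = np.flatnonzero(rng.random(length) < within_divergence)
            for i in hits:
                prot[i] = (prot[i] + 1 + rng.integers(19)) % 20
            seq = "".join(_AA20[i] for i in prot)
            records.append((g, f"{g}_g{f + 1:03d}", seq))
    return records
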