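"""Pairwise dN/dS estimation and branch-site positive-selection testing.

Two counting estimators are provided per sequence pair of a codon alignment:

* ``ng86_pair`` — Nei-Gojobori (1986): per-codon synonymous-site fractions,
  equal-weight averaging over minimal substitution pathways, Jukes-Cantor
  correction of both proportions;
* ``yn00_pair`` — a transition/transversion- and codon-frequency-aware
  variant: kappa is estimated from fourfold-degenerate third positions (K80),
  site counting weights each possible change by kappa and the F3x4 target
  frequency, and reduces to NG86 at kappa = 1 with uniform frequencies.

Pairs with dS < 0.1 or omega >= 99 (or an undefined correction) are marked
invalid and excluded from group averages — the standard saturation filter.
Positive-selection triage keeps clusters with at least one valid pair with
dN > dS; candidate clusters can then be tested with a branch-site codon model
(site classes omega0 <= 1, omega1 = 1, and a foreground class with omega2
free and >= 1, versus a null with omega2 pinned at 1) via the likelihood-ratio
test Delta = 2(lnL1 - lnL0) against chi-squared with one degree of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import codons
from .trees import Tree

__all__ = ["PairwiseOmega", "BranchSiteFit", "back_translate", "ng86_pair",
           "yn00_pair", "pair_schedule", "pairwise_scan", "group_average",
           "triage_positive", "branch_site_lnL", "branch_site_test", "lrt"]

DS_MIN = 0.1        # saturation filter: dS below this is unreliable
OMEGA_MAX = 99.0    # and so is a ratio at or beyond this


@dataclass
class PairwiseOmega:
    cluster_id: str
    genome_a: str
    genome_b: str
    dN: float
    dS: float
    omega: float          # NaN when undefined
    valid: bool
    method: str
    converged: bool = True


def _validity(dn: float, ds: float) -> tuple[float, bool]:
    if not np.isfinite(ds) or not np.isfinite(dn):
        return float("nan"), False
    omega = dn / ds if ds > 0 else float("nan")
    valid = np.isfinite(omega) and ds >= DS_MIN and omega < OMEGA_MAX
    return omega, bool(valid)


# -------------------------------------------------------------- back-translate
def back_translate(protein_alignment: dict[str, str],
                   cds: dict[str, str]) -> dict[str, str]:
    """Expand a protein alignment to codons using each gene's CDS.

    Each CDS (terminal stop trimmed) must translate exactly to its ungapped
    protein row; protein gaps become '---'.
    """
    from Bio.Seq import Seq

    out = {}
    for name, row in protein_alignment.items():
        if name not in cds:
            raise ValueError(f"{name}: no CDS provided")
        nt = cds[name].upper()
        if len(nt) % 3:
            raise ValueError(f"{name}: CDS length not a multiple of 3")
        if nt[-3:] in codons.STOP_CODONS:
            nt = nt[:-3]
        aa = str(Seq(nt).translate())
        ungapped = row.replace("-", "")
        if len(aa) != len(ungapped):
            raise ValueError(f"{name}: CDS translates to {len(aa)} residues, "
                             f"alignment row has {len(ungapped)}")
        for pos, (x, y) in enumerate(zip(aa, ungapped)):
            if x != y and x != "*":
                raise ValueError(f"{name}: translation mismatch at residue "
                                 f"{pos + 1} ({x} vs {y})")
            if x == "*":
                raise ValueError(f"{name}: internal stop at residue {pos + 1}")
        chunks, k = [], 0
        for ch in row:
            if ch == "-":
                chunks.append("---")
            else:
                chunks.append(nt[3 * k:3 * k + 3])
                k += 1
        out[name] = "".join(chunks)
    return out


# --------------------------------------------------------------------- NG86
def _comparable(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = codons.encode(a), codons.encode(b)
    if ia.size != ib.size:
        raise ValueError("sequences differ in length")
    mask = (ia >= 0) & (ib >= 0)
    if not mask.any():
        raise ValueError("no comparable codons")
    return ia[mask], ib[mask]


def ng86_pair(a: str, b: str, cluster_id: str = "", genome_a: str = "a",
              genome_b: str = "b") -> PairwiseOmega:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction."""
    ia, ib = _comparable(a, b)
    s_sites = codons.ng86_site_counts()
    big_s = float((s_sites[ia] + s_sites[ib]).sum()) / 2.0
    big_n = 3.0 * ia.size - big_s
    sd_tab, nd_tab = codons.ng86_diff_counts()
    sd = float(sd_tab[ia, ib].sum())
    nd = float(nd_tab[ia, ib].sum())
    ds = codons.jukes_cantor(sd / big_s) if big_s > 0 else float("nan")
    dn = codons.jukes_cantor(nd / big_n) if big_n > 0 else float("nan")
    omega, valid = _validity(dn, ds)
    return PairwiseOmega(cluster_id, genome_a, genome_b, dN=dn, dS=ds,
                         omega=omega, valid=valid, method="NG86")


# --------------------------------------------------------------------- YN00
from functools import lru_cache


@lru_cache(maxsize=1)
def _degeneracy_masks() -> tuple[np.ndarray, np.ndarray]:
    """Per codon x position: fourfold-degenerate and nondegenerate flags."""
    four = np.zeros((codons.N_CODONS, 3), dtype=bool)
    zero = np.zeros((codons.N_CODONS, 3), dtype=bool)
    for i, codon in enumerate(codons.CODONS):
        for p in range(3):
            syn = 0
            for nt in "ACGT":
                if nt == codon[p]:
                    continue
                alt = codon[:p] + nt + codon[p + 1:]
                j = codons.CODON_INDEX.get(alt)
                if j is not None and codons.AA[j] == codons.AA[i]:
                    syn += 1
            four[i, p] = syn == 3
            zero[i, p] = syn == 0
    return four, zero


def _k80_distances(n: int, ti: int, tv: int) -> tuple[float, float] | None:
    """K80 transition/transversion distance components; None if unusable."""
    if n < 10:
        return None
    p, q = ti / n, tv / n
    a1, a2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if a1 <= 0 or a2 <= 0:
        return None
    d_ts = -0.5 * np.log(a1) + 0.25 * np.log(a2)
    d_tv = -0.5 * np.log(a2)
    return d_ts, d_tv


def _kappa_fourfold(ia: np.ndarray, ib: np.ndarray) -> float:
    """Kappa from fourfold-degenerate and nondegenerate positions (K80 on
    each class, site-weighted average) — the degeneracy class must agree
    between the two codons at that position."""
    four, zero = _degeneracy_masks()
    pos_a = np.array([[codons.CODONS[x][p] for p in range(3)] for x in ia])
    pos_b = np.array([[codons.CODONS[x][p] for p in range(3)] for x in ib])
    ts_sum = tv_sum = 0.0
    for mask in (four, zero):
        use = mask[ia] & mask[ib]          # n_codons x 3
        n = int(use.sum())
        if n == 0:
            continue
        na, nb = pos_a[use], pos_b[use]
        diff = na != nb
        pur_a = np.isin(na, list("AG"))
        pur_b = np.isin(nb, list("AG"))
        ti = int((diff & (pur_a == pur_b)).sum())
        tv = int((diff & (pur_a != pur_b)).sum())
        dists = _k80_distances(n, ti, tv)
        if dists is not None:
            ts_sum += n * dists[0]         # site-weighted pooled distances
            tv_sum += n * dists[1]
    if tv_sum <= 0:
        return 1.0 if ts_sum <= 0 else 20.0
    return float(np.clip(2.0 * ts_sum / tv_sum, 0.1, 20.0))


def _f3x4(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Position-specific nucleotide frequencies (3 x 4, order ACGT) of a pair."""
    freqs = np.zeros((3, 4))
    lookup = {nt: k for k, nt in enumerate("ACGT")}
    for idx in itertools.chain(ia, ib):
        codon = codons.CODONS[idx]
        for p in range(3):
            freqs[p, lookup[codon[p]]] += 1
    freqs /= freqs.sum(axis=1, keepdims=True)
    return freqs


def _weighted_site_counts(kappa: float, f3x4: np.ndarray) -> np.ndarray:
    """Per-codon synonymous potential sites with kappa- and frequency-weighted
    changes (changes to stops count as nonsynonymous); 3 sites per codon."""
    lookup = {nt: k for k, nt in enumerate("ACGT")}
    s = np.zeros(codons.N_CODONS)
    for i, codon in enumerate(codons.CODONS):
        w_syn = w_tot = 0.0
        for p in range(3):
            for nt in "ACGT":
                if nt == codon[p]:
                    continue
                w = (kappa if codons.is_transition(codon[p], nt) else 1.0)
                w *= f3x4[p, lookup[nt]]
                w_tot += w
                alt = codon[:p] + nt + codon[p + 1:]
                j = codons.CODON_INDEX.get(alt)
                if j is not None and codons.AA[j] == codons.AA[i]:
                    w_syn += w
        s[i] = 3.0 * w_syn / w_tot if w_tot > 0 else 0.0
    return s


def yn00_pair(a: str, b: str, cluster_id: str = "", genome_a: str = "a",
              genome_b: str = "b", tol: float = 1e-6,
              max_iter: int = 100) -> PairwiseOmega:
    """Transition/transversion- and frequency-weighted counting dN/dS.

    Iterates the kappa estimate and weighted site counts until dN and dS
    change by less than ``tol`` (non-convergence is flagged, last iterate
    kept).  With kappa = 1 and uniform codon usage this reduces to NG86.
    """
    ia, ib = _comparable(a, b)
    f3x4 = _f3x4(ia, ib)
    sd_tab, nd_tab = codons.ng86_diff_counts()
    sd = float(sd_tab[ia, ib].sum())
    nd = float(nd_tab[ia, ib].sum())

    kappa = 1.0
    dn = ds = float("nan")
    converged = False
    for _ in range(max_iter):
        s_sites = _weighted_site_counts(kappa, f3x4)
        big_s = float((s_sites[ia] + s_sites[ib]).sum()) / 2.0
        big_n = 3.0 * ia.size - big_s
        new_ds = codons.jukes_cantor(sd / big_s) if big_s > 0 else float("nan")
        new_dn = codons.jukes_cantor(nd / big_n) if big_n > 0 else float("nan")
        done = (np.isfinite(new_ds) == np.isfinite(ds)
                and np.isfinite(new_dn) == np.isfinite(dn)
                and (not np.isfinite(new_ds) or abs(new_ds - ds) < tol)
                and (not np.isfinite(new_dn) or abs(new_dn - dn) < tol))
        dn, ds = new_dn, new_ds
        kappa = _kappa_fourfold(ia, ib)
        if done:
            converged = True
            break
    omega, valid = _validity(dn, ds)
    return PairwiseOmega(cluster_id, genome_a, genome_b, dN=dn, dS=ds,
                         omega=omega, valid=valid, method="YN00",
                         converged=converged)


# ------------------------------------------------------------- pairwise scan
def pair_schedule(genomes: list[str],
                  cluster_ids: list[str]) -> list[tuple[str, str, str]]:
    """The full evaluation schedule: every cluster x unordered genome pair.

    len == C(n_genomes, 2) * n_clusters exactly (225,765 for 30 genomes and
    519 clusters)."""
    pairs = list(itertools.combinations(genomes, 2))
    return [(cid, a, b) for cid in cluster_ids for a, b in pairs]


def pairwise_scan(cluster_alignments: dict[str, dict[str, str]],
                  genomes: list[str], method: str = "NG86") -> pd.DataFrame:
    """dN/dS for every cluster x genome pair; one record each.

    Each cluster alignment must hold exactly one row per genome (deduplicated
    core clusters)."""
    est = {"NG86": ng86_pair, "YN00": yn00_pair}[method.upper()]
    for cid, aln in cluster_alignments.items():
        if sorted(aln) != sorted(genomes):
            raise ValueError(f"cluster {cid!r}: rows do not match genome list "
                             "(missing or duplicated genome)")
    rows = []
    for cid, a, b in pair_schedule(genomes, list(cluster_alignments)):
        aln = cluster_alignments[cid]
        res = est(aln[a], aln[b], cluster_id=cid, genome_a=a, genome_b=b)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def group_average(table: pd.DataFrame,
                  grouping: dict[str, str]) -> pd.DataFrame:
    """Mean dN, dS and dN/dS over valid pairs for every group combination.

    Groups with no valid pair report NaN means with n_valid = 0 (undefined,
    not zero)."""
    for col in ("genome_a", "genome_b"):
        unknown = set(table[col]) - set(grouping)
        if unknown:
            raise ValueError(f"genomes missing from grouping: {sorted(unknown)}")
    ga = table["genome_a"].map(grouping)
    gb = table["genome_b"].map(grouping)
    swap = ga > gb
    work = table.assign(group_a=ga.where(~swap, gb), group_b=gb.where(~swap, ga))
    rows = []
    for (g1, g2), sub in work.groupby(["group_a", "group_b"]):
        valid = sub[sub["valid"]]
        rows.append({
            "group_a": g1, "group_b": g2, "n_pairs": len(sub),
            "n_valid": len(valid),
            "mean_dN": valid["dN"].mean() if len(valid) else float("nan"),
            "mean_dS": valid["dS"].mean() if len(valid) else float("nan"),
            "mean_omega": valid["omega"].mean() if len(valid) else float("nan"),
        })
    return pd.DataFrame(rows)


def triage_positive(table: pd.DataFrame) -> set[str]:
    """Clusters with at least one valid pair where dN strictly exceeds dS."""
    hits = table[table["valid"] & (table["dN"] > table["dS"])]
    return set(hits["cluster_id"])


# -------------------------------------------------------- branch-site model
@dataclass
class BranchSiteFit:
    lnL0: float
    lnL1: float
    delta: float
    p: float
    foreground: frozenset[str]
    params_null: dict = field(default_factory=dict)
    params_alt: dict = field(default_factory=dict)


def lrt(lnL0: float, lnL1: float) -> tuple[float, float]:
    """Likelihood-ratio statistic Delta = 2(lnL1 - lnL0) and its chi2(1)
    upper-tail P; small negative Delta (numerical) is clamped to zero."""
    if not (np.isfinite(lnL0) and np.isfinite(lnL1)):
        raise ValueError("log-likelihoods must be finite")
    if lnL1 < lnL0 - 1e-3:
        raise ValueError(f"lnL1 ({lnL1}) below lnL0 ({lnL0}): "
                         "optimization inconsistency")
    delta = 2.0 * (lnL1 - lnL0)
    if delta < 0:
        delta = 0.0
    return delta, float(stats.chi2.sf(delta, df=1))


class _BranchSiteLikelihood:
    """Pruning likelihood over the 61-codon state space with three site
    classes; mixture proportions are profiled out by EM at each evaluation."""

    def __init__(self, alignment: dict[str, str], tree: Tree,
                 foreground: frozenset[str]):
        self.tree = tree.copy()
        self.tree.label_internal()
        leaves = self.tree.leaf_labels()
        if set(leaves) != set(alignment):
            raise ValueError("alignment rows do not match tree leaves")
        if len(leaves) < 3:
            raise ValueError("need at least 3 taxa")
        rows = {t: codons.encode(alignment[t]) for t in leaves}
        keep = np.ones(len(next(iter(rows.values()))), dtype=bool)
        for arr in rows.values():
            keep &= arr >= 0
        if keep.sum() < 10:
            raise ValueError("fewer than 10 gap-free codon columns")
        data = np.vstack([rows[t][keep] for t in leaves])
        patterns, inverse, counts = np.unique(
            data.T, axis=0, return_inverse=True, return_counts=True)
        self.leaves = leaves
        self.patterns = patterns.T          # n_leaves x n_patterns
        self.weights = counts.astype(float)
        self.pi = np.full(codons.N_CODONS, 1.0 / codons.N_CODONS)
        self.nodes = list(self.tree.postorder())
        self.branches = [n for n in self.nodes if n is not self.tree.root]
        self.is_fg = {n.label: (n.label in foreground) for n in self.branches}
        missing = foreground - {n.label for n in self.branches}
        if missing:
            raise ValueError(f"foreground branches not in tree: {sorted(missing)}")

    def _probs(self, kappa: float, omegas: set[float]) -> dict[float, dict[str, np.ndarray]]:
        times = np.array([n.length if n.length is not None else 0.0
                          for n in self.branches])
        out: dict[float, dict[str, np.ndarray]] = {}
        for w in omegas:
            q = codons.rate_matrix(kappa, w, self.pi)
            mats = codons.transition_probs(q, self.pi, times)
            out[w] = {n.label: mats[k] for k, n in enumerate(self.branches)}
        return out

    def _class_loglik(self, probs, w_bg: float, w_fg: float) -> np.ndarray:
        """Per-pattern log-likelihood for one site class."""
        leaf_row = {t: i for i, t in enumerate(self.leaves)}
        npat = self.patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        scale = np.zeros(npat)
        for node in self.nodes:
            if node.is_leaf():
                continue
            acc = np.ones((codons.N_CODONS, npat))
            for child in node.children:
                p = probs[w_fg if self.is_fg[child.label] else w_bg][child.label]
                if child.is_leaf():
                    acc *= p[:, self.patterns[leaf_row[child.label]]]
                else:
                    acc *= p @ partial[id(child)]
            top = acc.max(axis=0)
            top = np.where(top > 0, top, 1.0)
            acc /= top
            scale += np.log(top)
            partial[id(node)] = acc
        site = self.pi @ partial[id(self.tree.root)]
        with np.errstate(divide="ignore"):
            return np.log(site) + scale

    def loglik(self, kappa: float, omega0: float,
               omega2: float) -> tuple[float, np.ndarray]:
        """Maximised-over-proportions log-likelihood and the proportions.

        Classes: (omega0 everywhere), (1 everywhere), (omega0 background with
        omega2 on foreground branches).
        """
        probs = self._probs(kappa, {omega0, 1.0, omega2})
        ls = np.vstack([
            self._class_loglik(probs, omega0, omega0),
            self._class_loglik(probs, 1.0, 1.0),
            self._class_loglik(probs, omega0, omega2),
        ])
        p = np.full(3, 1.0 / 3.0)
        top = ls.max(axis=0)
        lik = np.exp(ls - top)              # 3 x npat, safe
        for _ in range(200):
            mix = p @ lik
            resp = (p[:, None] * lik) / mix
            new = (resp * self.weights).sum(axis=1) / self.weights.sum()
            if np.abs(new - p).max() < 1e-10:
                p = new
                break
            p = new
        lnl = float((self.weights * (np.log(p @ lik) + top)).sum())
        return lnl, p


def branch_site_lnL(alignment: dict[str, str], tree: Tree,
                    foreground: set[str], null: bool, seed: int = 0,
                    n_restarts: int = 3,
                    starts: list[tuple[float, float, float]] | None = None,
                    ) -> tuple[float, dict]:
    """Maximised branch-site log-likelihood (one arm of the LRT).

    ``null=True`` pins the foreground omega2 at 1; otherwise omega2 >= 1 is
    free.  kappa and omega0 are optimized by L-BFGS-B from ``n_restarts``
    seeded starting points (plus any explicit ``starts``); class proportions
    are profiled out analytically at each evaluation.  Branch lengths are
    taken from the tree as given.
    """
    model = _BranchSiteLikelihood(alignment, tree, frozenset(foreground))
    rng = np.random.default_rng(seed)
    pts = list(starts or [])
    pts.append((2.0, 0.5, 1.0 if null else 2.0))
    while len(pts) < n_restarts + len(starts or []):
        pts.append((float(rng.uniform(0.5, 8.0)), float(rng.uniform(0.05, 0.95)),
                    1.0 if null else float(rng.uniform(1.0, 6.0))))

    def objective(x):
        kappa, omega0 = x[0], x[1]
        omega2 = 1.0 if null else x[2]
        lnl, _ = model.loglik(kappa, omega0, omega2)
        return -lnl

    bounds = [(0.2, 20.0), (1e-4, 1.0)] + ([] if null else [(1.0, 50.0)])
    best = None
    failures = []
    for kappa0, w0, w2 in pts:
        x0 = [kappa0, w0] + ([] if null else [w2])
        try:
            res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": 60, "ftol": 1e-9})
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"optimizer failed on all restarts: {failures}")
    kappa, omega0 = best.x[0], best.x[1]
    omega2 = 1.0 if null else best.x[2]
    lnl, props = model.loglik(kappa, omega0, omega2)
    params = {"kappa": float(kappa), "omega0": float(omega0),
              "omega2": float(omega2),
              "proportions": tuple(float(v) for v in props)}
    return lnl, params


def branch_site_test(alignment: dict[str, str], tree: Tree,
                     foreground: set[str], seed: int = 0) -> BranchSiteFit:
    """Null and alternative fits plus the chi2(1) LRT.

    The alternative search additionally starts from the fitted null (with
    omega2 = 1), so the nesting inequality lnL1 >= lnL0 holds by construction
    of the search."""
    lnl0, p0 = branch_site_lnL(alignment, tree, foreground, null=True,
                               seed=seed)
    warm = [(p0["kappa"], p0["omega0"], 1.0)]
    lnl1, p1 = branch_site_lnL(alignment, tree, foreground, null=False,
                               seed=seed + 1, starts=warm)
    delta, p = lrt(lnl0, lnl1)
    return BranchSiteFit(lnL0=lnl0, lnL1=lnl1, delta=delta, p=p,
                         foreground=frozenset(foreground),
                         params_null=p0, params_alt=p1)
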