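"""Codon-level machinery shared by the simulators and the dN/dS estimators.

Standard genetic code only.  The 61 sense codons are indexed in a fixed
lexicographic order; substitution models are Goldman-Yang style with a single
transition/transversion ratio kappa and nonsynonymous factor omega, scaled so
that one branch-length unit equals one expected substitution per codon site.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS = tuple(sorted(c for c in ("".join(p) for p in product("ACGT", repeat=3))
                      if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA = tuple(_TABLE.forward_table[c] for c in CODONS)
N_CODONS = len(CODONS)  # 61

_PURINES = frozenset("AG")


def is_transition(x: str, y: str) -> bool:
    return x != y and ((x in _PURINES) == (y in _PURINES))


@lru_cache(maxsize=1)
def _structure():
    """Pairwise structural masks over the 61x61 codon space."""
    ndiff = np.zeros((N_CODONS, N_CODONS), dtype=np.int8)
    ti = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    syn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            ndiff[i, j] = len(diffs)
            if len(diffs) == 1:
                p = diffs[0]
                ti[i, j] = is_transition(ci[p], cj[p])
                syn[i, j] = AA[i] == AA[j]
    return ndiff, ti, syn


def rate_matrix(kappa: float, omega: float, pi: np.ndarray | None = None,
                reference_omega: float | None = 1.0) -> np.ndarray:
    """61x61 codon substitution generator.

    With ``reference_omega`` set (default 1), the matrix is scaled so that one
    branch-length unit equals one expected substitution per codon at sites
    with the reference omega — a common scale across site classes, so classes
    with omega above the reference genuinely substitute faster.  Pass
    ``reference_omega=None`` to self-normalise to mean rate one.
    """
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    ndiff, ti, syn = _structure()

    def build(w: float) -> np.ndarray:
        q = np.where(ndiff == 1, pi[None, :], 0.0)
        q = q * np.where(ti, kappa, 1.0) * np.where(syn, 1.0, w)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    q = build(omega)
    ref = omega if reference_omega is None else reference_omega
    scale = -(pi * np.diag(build(ref))).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (all rates zero)")
    return q / scale


def transition_probs(q: np.ndarray, pi: np.ndarray, times: np.ndarray) -> np.ndarray:
    """P(t) for each t, via symmetrised eigendecomposition (reversible q)."""
    sq = np.sqrt(pi)
    b = (sq[:, None] * q) / sq[None, :]
    w, u = np.linalg.eigh((b + b.T) / 2.0)
    left = u / sq[:, None]
    right = (u * sq[:, None]).T
    out = np.empty((len(times), q.shape[0], q.shape[0]))
    for k, t in enumerate(np.asarray(times, dtype=float)):
        p = (left * np.exp(w * t)) @ right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        out[k] = p
    return out


# --------------------------------------------------------------- NG86 tables
@lru_cache(maxsize=1)
def ng86_site_counts() -> np.ndarray:
    """Synonymous potential sites per codon (mutations to stops = nonsynonymous)."""
    s = np.zeros(N_CODONS)
    for i, codon in enumerate(CODONS):
        for p in range(3):
            for nt in "ACGT":
                if nt == codon[p]:
                    continue
                alt = codon[:p] + nt + codon[p + 1:]
                if alt in CODON_INDEX and AA[CODON_INDEX[alt]] == AA[i]:
                    s[i] += 1.0 / 3.0
    return s


@lru_cache(maxsize=1)
def ng86_diff_counts() -> tuple[np.ndarray, np.ndarray]:
    """(syn, nonsyn) substitution counts per codon pair, averaged over all
    minimal substitution pathways that avoid stop codons."""
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    from itertools import permutations

    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if not diffs:
                continue
            path_syn, path_non, n_paths = 0.0, 0.0, 0
            for order in permutations(diffs):
                cur = ci
                syn = non = 0
                ok = True
                for p in order:
                    nxt = cur[:p] + cj[p] + cur[p + 1:]
                    if nxt in STOP_CODONS:
                        ok = False
                        break
                    if AA[CODON_INDEX[cur]] == AA[CODON_INDEX[nxt]]:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                if ok:
                    path_syn += syn
                    path_non += non
                    n_paths += 1
            if n_paths == 0:  # all pathways hit a stop; fall back to direct tally
                sd[i, j] = 0.0
                nd[i, j] = len(diffs)
            else:
                sd[i, j] = path_syn / n_paths
                nd[i, j] = path_non / n_paths
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when the proportion is saturated (argument <= 0)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan")
    return -0.75 * float(np.log(arg))


FOURFOLD_CODONS = frozenset(
    c for c in CODONS
    if all((c[:2] + nt) in CODON_INDEX and AA[CODON_INDEX[c[:2] + nt]] == AA[CODON_INDEX[c]]
           for nt in "ACGT")
)


def encode(seq: str) -> np.ndarray:
    """Codon-index array for an ungapped CDS; -1 marks gapped/ambiguous codons."""
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        out[k // 3] = CODON_INDEX.get(seq[k:k + 3].upper(), -1)
    return out


def decode(idx: np.ndarray) -> str:
    return "".join(CODONS[i] if i >= 0 else "---" for i in idx)
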