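"""Recombination screening of core clusters.

One detector is implemented natively: the maximum chi-squared (MaxChi) scan,
which for every sequence pair slides a split window over the polymorphic
columns and contrasts the match/mismatch counts on the two sides of the split
with a 2x2 chi-squared statistic.  Significance comes from a column
permutation null, Bonferroni-corrected over pairs.  Calls from external
detectors enter through a TSV importer, and a cluster is flagged as
recombinant when at least ``k_min`` distinct methods report P < alpha (the
k-of-n consensus rule; defaults 3 of n at alpha = 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RecombinationCall", "ConsensusRule", "maxchi_scan", "import_calls",
           "write_calls", "consensus_flag", "filter_nonrecombinant",
           "default_window"]


@dataclass
class RecombinationCall:
    cluster_id: str
    method: str
    p_value: float
    breakpoint: int | None = None
    sequences: tuple[str, ...] = ()
    statistic: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ConsensusRule:
    alpha: float = 0.05
    k_min: int = 3

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")


def default_window(n_polymorphic: int) -> int:
    """2 * ceil(sqrt(m)) rounded up to even — the scan's default split window."""
    w = 2 * math.ceil(math.sqrt(max(n_polymorphic, 1)))
    return w + (w % 2)


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Plain (uncorrected) chi-squared of [[a, b], [c, d]], vectorised; zero
    where a margin vanishes."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return out


def _max_stat(diff: np.ndarray, half: int) -> tuple[float, int]:
    """Maximum split-window chi-squared over a 0/1 mismatch vector.

    Returns (statistic, split index in polymorphic-site coordinates).
    """
    m = diff.size
    cums = np.concatenate([[0], np.cumsum(diff)])
    ks = np.arange(half, m - half + 1)
    left_mis = cums[ks] - cums[ks - half]
    right_mis = cums[ks + half] - cums[ks]
    stat = _chi2_2x2(half - left_mis, left_mis, half - right_mis, right_mis)
    best = int(np.argmax(stat))
    return float(stat[best]), int(ks[best])


def maxchi_scan(alignment: dict[str, str], window: int | None = None,
                n_permutations: int = 1000, seed: int = 0,
                cluster_id: str = "") -> list[RecombinationCall]:
    """MaxChi scan of every sequence pair of an alignment.

    Reports, per pair, the maximum split-window chi-squared with a permutation
    p-value (alignment columns permuted), Bonferroni-corrected over pairs.
    ``window`` is the full (even) split-window width in polymorphic sites;
    the default is ``default_window``.  No polymorphic sites -> no calls.
    """
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    length = len(alignment[names[0]])
    if any(len(alignment[n]) != length for n in names):
        raise ValueError("sequences must have equal length")
    mat = np.array([list(alignment[n]) for n in names])
    poly = np.flatnonzero((mat != mat[0]).any(axis=0))
    if poly.size == 0:
        return []
    m = poly.size
    if window is None:
        window = default_window(m)
    if window % 2 or window < 2:
        raise ValueError("window must be a positive even integer")
    if window > m:
        raise ValueError(f"window {window} exceeds {m} polymorphic sites")
    half = window // 2
    rng = np.random.default_rng(seed)
    n_pairs = len(names) * (len(names) - 1) // 2
    calls = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = (mat[i, poly] != mat[j, poly]).astype(np.int64)
            obs, split = _max_stat(diff, half)
            exceed = 0
            for _ in range(n_permutations):
                perm_stat, _ = _max_stat(rng.permutation(diff), half)
                if perm_stat >= obs:
                    exceed += 1
            p = (1 + exceed) / (n_permutations + 1)
            p_adj = min(1.0, p * n_pairs)
            calls.append(RecombinationCall(
                cluster_id=cluster_id, method="maxchi", p_value=p_adj,
                breakpoint=int(poly[split]) if split < m else None,
                sequences=(names[i], names[j]), statistic=obs,
                metadata={"p_raw": p, "window": window,
                          "n_polymorphic": int(m)}))
    return calls


def import_calls(table: pd.DataFrame | str) -> list[RecombinationCall]:
    """Parse external detector calls from a TSV (or DataFrame) with columns
    cluster_id, method, p_value; extra columns become metadata."""
    df = pd.read_csv(table, sep="\t", dtype=str) if isinstance(table, str) else table.copy()
    required = {"cluster_id", "method", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in required and c != "breakpoint"]
    calls = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            p = float(row["p_value"])
        except (TypeError, ValueError):
            raise ValueError(f"row {pos}: malformed p_value {row['p_value']!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"row {pos}: p_value {p} outside [0, 1]")
        bp = row.get("breakpoint")
        bp = None if bp is None or (isinstance(bp, float) and np.isnan(bp)) \
            or bp in ("", "NA", "nan") else int(float(bp))
        calls.append(RecombinationCall(
            cluster_id=str(row["cluster_id"]), method=str(row["method"]),
            p_value=p, breakpoint=bp,
            metadata={k: row[k] for k in extra}))
    return calls


def write_calls(calls: list[RecombinationCall], path: str) -> None:
    rows = []
    for c in calls:
        rows.append({"cluster_id": c.cluster_id, "method": c.method,
                     "p_value": c.p_value,
                     "breakpoint": "" if c.breakpoint is None else c.breakpoint,
                     **c.metadata})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def consensus_flag(calls: list[RecombinationCall],
                   rule: ConsensusRule = ConsensusRule()) -> set[str]:
    """Clusters with significant calls (P < alpha) from >= k_min distinct methods."""
    methods: dict[str, set[str]] = {}
    for call in calls:
        if call.p_value < rule.alpha:
            methods.setdefault(call.cluster_id, set()).add(call.method)
    return {cid for cid, ms in methods.items() if len(ms) >= rule.k_min}


def filter_nonrecombinant(core_ids: list[str], flagged: set[str]) -> list[str]:
    """Order-preserving removal of flagged clusters from the core list."""
    stray = flagged - set(core_ids)
    if stray:
        import warnings
        warnings.warn(f"{len(stray)} flagged clusters are not in the core set")
    return [cid for cid in core_ids if cid not in flagged]
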