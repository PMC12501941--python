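"""Gene-set statistics: hypergeometric ORA (+BH) and weighted GSEA.

The over-representation p-value is the exact upper-tail hypergeometric
sum computed with integer arithmetic.  The GSEA statistic is the classical
weighted Kolmogorov-Smirnov running sum (hits weighted by |score|^exponent
normalized to one; misses decremented uniformly), with a seeded
gene-label-permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# gene-set collections (GMT)


def read_gmt(path) -> dict[str, dict]:
    """GMT: one set per line — name, description, then members."""
    sets: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, members = parts[0], parts[1], parts[2:]
        sets[name] = {"description": desc, "members": set(m for m in members if m)}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for name, entry in sets.items():
            members = "\t".join(sorted(entry["members"]))
            fh.write(f"{name}\t{entry.get('description', '')}\t{members}\n")


# ---------------------------------------------------------------------------
# over-representation


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact summation."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError("inconsistent hypergeometric parameters")
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, hi + 1))
    return float(Fraction(num, math.comb(N, n)))


def ora_test(query: set[str], gene_set: set[str], universe: set[str]) -> dict:
    """Upper-tail hypergeometric test of one query against one set.

    The query must be a subset of the universe; the set is intersected
    with the universe before testing.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    hits = gene_set & universe
    N, K, n = len(universe), len(hits), len(query)
    k = len(query & hits)
    return {"N": N, "K": K, "n": n, "k": k, "p": hypergeom_upper_tail(N, K, n, k)}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def ora_collection(
    query: set[str], collection: dict[str, dict], universe: set[str]
) -> pd.DataFrame:
    """ORA over a whole collection, BH-adjusted; disjoint sets are skipped."""
    rows, names = [], []
    for name, entry in collection.items():
        if not (entry["members"] & set(universe)):
            continue
        res = ora_test(query, entry["members"], universe)
        res["description"] = entry.get("description", "")
        rows.append(res)
        names.append(name)
    out = pd.DataFrame(rows, index=pd.Index(names, name="set"))
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p")
    return out


# ---------------------------------------------------------------------------
# GSEA


def _ranked(ranking: pd.Series) -> pd.Series:
    if ranking.isna().any():
        raise ValueError("ranking contains NA scores")
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate accessions")
    return ranking.sort_values(ascending=False, kind="stable")


def gsea_score(
    ranking: pd.Series, gene_set: set[str], weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score.

    ``ranking`` maps accession -> score (e.g. log2 3D/2D); it is sorted
    descending internally.  Returns ``(ES, running_sum)`` where ES is the
    signed maximum deviation of the running sum from zero.
    """
    ranked = _ranked(ranking)
    hit = ranked.index.isin(gene_set)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == len(ranked):
        raise ValueError("gene set covers the entire ranking")
    running = _running_sum(ranked.to_numpy(), hit, weight_exponent)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _running_sum(scores: np.ndarray, hit: np.ndarray, exponent: float) -> np.ndarray:
    weights = np.abs(scores) ** exponent
    nr = weights[hit].sum()
    n_miss = len(scores) - int(hit.sum())
    steps = np.where(hit, (weights / nr) if nr > 0 else 0.0, -1.0 / n_miss)
    return np.cumsum(steps)


def gsea_permutation_p(
    ranking: pd.Series,
    gene_set: set[str],
    B: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> dict:
    """Gene-label-permutation p-value and normalized ES for one set.

    The tail is evaluated within the same-sign portion of the null (the
    standard two-tailed ES convention): for a nonnegative observed ES,
    ``p = (1 + #{perm ES >= observed, among perm ES >= 0}) /
    (1 + #{perm ES >= 0})``, mirrored for a negative one — this keeps p
    uniform under a random-set null.  NES divides by the mean
    |permutation ES| of matching sign.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    es, running = gsea_score(ranking, gene_set, weight_exponent)
    ranked = _ranked(ranking)
    scores = ranked.to_numpy()
    hit = ranked.index.isin(gene_set)
    n, n_hit = len(scores), int(hit.sum())

    rng = np.random.default_rng(seed)
    weights = np.abs(scores) ** weight_exponent
    perm_es = np.empty(B)
    # vectorized permutation null: random hit positions, shared score grid
    positions = np.argsort(rng.random((B, n)), axis=1)[:, :n_hit]
    for b in range(B):
        h = np.zeros(n, dtype=bool)
        h[positions[b]] = True
        r = _running_sum(scores, h, weight_exponent)
        perm_es[b] = r[np.argmax(np.abs(r))]

    if es >= 0:
        same = perm_es[perm_es >= 0]
        p = (1 + int(np.sum(same >= es))) / (1 + len(same))
    else:
        same = perm_es[perm_es < 0]
        p = (1 + int(np.sum(same <= es))) / (1 + len(same))
    nes = es / np.mean(np.abs(same)) if len(same) else float("nan")

    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = ranked.index[: peak + 1][hit[: peak + 1]]
    else:
        leading = ranked.index[peak:][hit[peak:]]
    return {
        "es": es,
        "nes": nes,
        "p": p,
        "n_hit": n_hit,
        "n_null_same_sign": int(len(same)),
        "leading_edge": list(leading),
    }


def gsea_collection(
    ranking: pd.Series,
    collection: dict[str, dict],
    B: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    rows, names = [], []
    for i, (name, entry) in enumerate(collection.items()):
        members = entry["members"] & set(ranking.index)
        if not members or len(members) == len(ranking):
            continue
        res = gsea_permutation_p(ranking, members, B=B, seed=seed + i, weight_exponent=weight_exponent)
        res["description"] = entry.get("description", "")
        res["leading_edge"] = ";".join(res["leading_edge"])
        rows.append(res)
        names.append(name)
    out = pd.DataFrame(rows, index=pd.Index(names, name="set"))
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p")
    return out
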