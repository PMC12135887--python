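"""Gene-set enrichment: hypergeometric over-representation and preranked GSEA.

Two complementary views of the same question — is a pathway's membership
concentrated among the proteins that change?

* :func:`fisher_ora` tests a discrete hit list (e.g. the differentially
  abundant proteins of one contrast) against each set with the one-sided
  hypergeometric (Fisher's exact) upper tail, BH-adjusted across sets. The
  background defaults to the post-filter protein universe, not the genome.
* :func:`gsea_preranked` runs classical preranked GSEA on a continuous
  ranking (here the bootstrapped median log2 fold change): weighted
  Kolmogorov-Smirnov running-sum enrichment score with weight exponent 1,
  gene-set permutation null, sign-matched permutation p-values and
  NES = ES / mean(|permutation ES| of matching sign).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import bh_adjust, protein_rng
from .types import GeneSetCollection

__all__ = [
    "ORAResult",
    "GSEAResult",
    "fisher_ora",
    "gsea_es",
    "gsea_preranked",
    "rank_genes",
]


@dataclass
class ORAResult:
    set_name: str
    overlap: int
    set_size: int       # after intersection with the background
    hit_size: int
    background_size: int
    odds_ratio: float
    p: float
    q_bh: float = float("nan")
    overlap_genes: tuple[str, ...] = ()


@dataclass
class GSEAResult:
    set_name: str
    size: int           # after restriction to the ranked universe
    es: float
    nes: float
    p_perm: float
    q_bh: float = float("nan")
    leading_edge: tuple[str, ...] = ()


def fisher_ora(
    hits: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    q_threshold: float = 0.05,
) -> list[ORAResult]:
    """One-sided hypergeometric over-representation of each set in the hits.

    2x2 table per set (restricted to the background): overlap, hits outside
    the set, set members not hit, and the rest. p = P(X >= overlap) under the
    hypergeometric null; BH across all tested sets; sorted by (q, p).
    """
    background = list(dict.fromkeys(background))
    hit_set = set(hits)
    if not background:
        raise ValueError("empty background")
    if not hit_set:
        raise ValueError("empty hit list")
    stray = hit_set - set(background)
    if stray:
        raise ValueError(f"hits not in background: {sorted(stray)[:5]}")
    M = len(background)
    n_hits = len(hit_set)
    results = []
    for gs in sets:
        members = set(gs.members) & set(background)
        if not members:
            continue
        k = len(members & hit_set)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_hits))
        a, b = k, n_hits - k
        c, d = K - k, M - K - (n_hits - k)
        odds = float("inf") if (b * c) == 0 and a * d > 0 else (
            (a * d) / (b * c) if (b * c) else float("nan")
        )
        results.append(
            ORAResult(
                set_name=gs.name, overlap=k, set_size=K, hit_size=n_hits,
                background_size=M, odds_ratio=odds, p=p,
                overlap_genes=tuple(sorted(members & hit_set)),
            )
        )
    qs = bh_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q_bh = float(q)
    results.sort(key=lambda r: (r.q_bh, r.p, r.set_name))
    return results


def rank_genes(genes: Sequence[str], metric: Sequence[float]) -> tuple[list[str], np.ndarray]:
    """Deduplicate and sort genes by metric, descending.

    Duplicate symbols keep the entry with the largest |metric|; ties in the
    metric preserve input order (stable sort).
    """
    metric = np.asarray(metric, dtype=float)
    if not np.all(np.isfinite(metric)):
        raise ValueError("ranking metric must be finite")
    best: dict[str, int] = {}
    for i, g in enumerate(genes):
        if g not in best or abs(metric[i]) > abs(metric[best[g]]):
            best[g] = i
    idx = np.array(sorted(best.values()))
    g2 = [genes[i] for i in idx]
    m2 = metric[idx]
    order = np.argsort(-m2, kind="stable")
    return [g2[i] for i in order], m2[order]


def _es_positions(pos: np.ndarray, absr: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enrichment scores for many same-size hit-position sets at once.

    ``pos``: (R, s) 0-based hit positions, sorted along axis 1. Returns
    (es, argext, is_positive): the ES per row, the index (into the row's hit
    list) of the extremum hit, and the sign indicator.
    """
    if pos.ndim == 1:
        pos = pos[None, :]
    R, s = pos.shape
    if s >= N:
        # every gene is a hit: running sum climbs to exactly 1
        return np.ones(R), np.full(R, s - 1), np.ones(R, dtype=bool)
    w = absr[pos]                         # (R, s) hit weights
    tot = w.sum(axis=1, keepdims=True)
    miss = 1.0 / (N - s)
    if np.any(tot == 0):
        # all-zero metric inside the set: hits contribute equal zero weight;
        # fall back to equal weights so the score stays defined
        w = np.where(tot == 0, 1.0, w)
        tot = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / tot       # running sum just after each hit
    ranks = np.arange(1, s + 1)
    after = cw - (pos + 1 - ranks) * miss
    before = cw - w / tot - (pos - (ranks - 1)) * miss
    i_max = np.argmax(after, axis=1)
    i_min = np.argmin(before, axis=1)
    best_pos = after[np.arange(R), i_max]
    best_neg = before[np.arange(R), i_min]
    # tie (|max deviation| == |min deviation|) resolves to the positive side;
    # the small tolerance keeps the tie-break stable under float summation order
    positive = best_pos >= -best_neg - 1e-12 * np.maximum(best_pos, -best_neg)
    es = np.where(positive, best_pos, best_neg)
    argext = np.where(positive, i_max, i_min)
    return es, argext, positive


def gsea_es(
    ranked_genes: Sequence[str],
    metric: Sequence[float],
    gene_set: Iterable[str],
) -> tuple[float, list[str]]:
    """Enrichment score and leading edge of one set against a ranked list.

    Weighted KS running sum (weight exponent 1): each hit adds
    |r_g| / sum_set |r|, each miss subtracts 1/(N - |set|); ES is the running
    sum's maximal absolute deviation. The leading edge is the hits at or
    before the extremum (at or after it for negative ES).
    """
    metric = np.asarray(metric, dtype=float)
    N = len(ranked_genes)
    index = {g: i for i, g in enumerate(ranked_genes)}
    if len(index) != N:
        raise ValueError("ranked gene list contains duplicates")
    pos = np.array(sorted(index[g] for g in set(gene_set) if g in index))
    if pos.size == 0:
        raise ValueError("gene set has no genes in the ranked universe")
    es, argext, positive = _es_positions(pos[None, :], np.abs(metric), N)
    i = int(argext[0])
    if positive[0]:
        le = [ranked_genes[p] for p in pos[: i + 1]]
    else:
        le = [ranked_genes[p] for p in pos[i:]]
    return float(es[0]), le


def gsea_preranked(
    genes: Sequence[str],
    metric: Sequence[float],
    sets: GeneSetCollection,
    nperm: int = 10_000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> list[GSEAResult]:
    """Classical gene-set-permutation preranked GSEA.

    For each retained set, the null is ``nperm`` uniformly drawn same-size
    gene subsets of the ranked universe. ``p_perm`` is the add-one-smoothed
    one-sided tail frequency among permutation scores of matching sign, and
    NES divides ES by the mean |permutation ES| of that sign. BH across
    retained sets.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    ranked, m = rank_genes(genes, metric)
    N = len(ranked)
    if N < min_size:
        raise ValueError(f"ranked universe ({N}) smaller than min_size ({min_size})")
    absr = np.abs(m)
    index = {g: i for i, g in enumerate(ranked)}
    # null subsets are drawn as gene identities (indices into a canonical
    # name-sorted order) and mapped to ranking positions, so negating the
    # metric mirrors every permutation score exactly
    pos_of_input = np.array([index[g] for g in sorted(index)])

    results = []
    for gs in sets:
        pos = np.array(sorted(index[g] for g in set(gs.members) if g in index))
        s = pos.size
        if not (min_size <= s <= max_size):
            continue
        es, argext, positive = _es_positions(pos[None, :], absr, N)
        es = float(es[0])
        rng = protein_rng(seed, gs.name, stream=1)
        perm_es = np.empty(nperm)
        done = 0
        chunk = max(1, min(2000, int(2e7 // max(N, 1))))
        while done < nperm:
            c = min(chunk, nperm - done)
            keys = rng.random((c, N))
            sub = np.argpartition(keys, s - 1, axis=1)[:, :s]
            sub = pos_of_input[sub]
            sub.sort(axis=1)
            perm_es[done:done + c] = _es_positions(sub, absr, N)[0]
            done += c
        sign = 1.0 if es >= 0 else -1.0
        side = perm_es * sign >= 0
        n_side = int(side.sum())
        n_extreme = int(np.sum(perm_es[side] * sign >= es * sign))
        p_perm = (1 + n_extreme) / (1 + n_side) if n_side else 1.0
        denom = np.abs(perm_es[side]).mean() if n_side else float("nan")
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        i = int(argext[0])
        le = ([ranked[p] for p in pos[: i + 1]] if positive[0]
              else [ranked[p] for p in pos[i:]])
        results.append(
            GSEAResult(set_name=gs.name, size=s, es=es, nes=float(nes),
                       p_perm=float(min(p_perm, 1.0)), leading_edge=tuple(le))
        )
    qs = bh_adjust(np.array([r.p_perm for r in results]))
    for r, q in zip(results, qs):
        r.q_bh = float(q)
    results.sort(key=lambda r: (r.q_bh, r.p_perm, r.set_name))
    return results


def ora_frame(results: Sequence[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
             "hit_size": r.hit_size, "background_size": r.background_size,
             "odds_ratio": r.odds_ratio, "p": r.p, "q_bh": r.q_bh}
            for r in results
        ]
    )


def gsea_frame(results: Sequence[GSEAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set_name": r.set_name, "size": r.size, "es": r.es, "nes": r.nes,
             "p_perm": r.p_perm, "q_bh": r.q_bh,
             "leading_edge": ";".join(r.leading_edge)}
            for r in results
        ]
    )
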