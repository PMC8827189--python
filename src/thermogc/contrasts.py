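"""Sister-pair contrasts and resampling sensitivity analysis.

Phylogenetically independent pairs of tips (or pooled tip sets) with
different growth-temperature ranks are extracted from a rooted tree; GC
differences between pair members are tested with an exact two-sided
Wilcoxon signed-rank test; and the stability of PGLS conclusions under
reduced sample size is tallied over repeated random subsampling of tips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phylo import PhyloTree
from .stats import pgls

logger = logging.getLogger(__name__)


@dataclass
class RankPair:
    """One phylogenetically independent high-rank vs low-rank contrast.

    Members sharing a rank under the pairing node are pooled; the pooled
    value is the arithmetic mean of their trait values.
    """

    high_members: tuple[str, ...]
    low_members: tuple[str, ...]
    high_rank: int
    low_rank: int
    high_value: float
    low_value: float

    @property
    def difference(self) -> float:
        return self.high_value - self.low_value

    @property
    def tips(self) -> frozenset[str]:
        return frozenset(self.high_members) | frozenset(self.low_members)


@dataclass
class ResampleTally:
    """Sign x significance tallies over resampling rounds, per trait pair."""

    counts: pd.DataFrame  # index: trait pair; columns: negative/ns/positive
    rounds: int
    m: int
    alpha: float
    seed: int


# --------------------------------------------------------- pair extraction

def extract_rank_pairs(tree: PhyloTree, ranks: dict[str, int],
                       values: dict[str, float]) -> list[RankPair]:
    """Closely related pairs with different growth-temperature ranks.

    Post-order traversal, so the shallowest qualifying clades pair first;
    an internal node yields a pair iff all tips below it are still unused
    and carry exactly two distinct ranks.  Tips of a shared rank pool into
    one member with the mean trait value.  Each tip joins at most one
    pair, making pairs disjoint and phylogenetically independent.  Clades
    with three or more ranks never pair at that node but their sub-clades
    may already have paired.
    """
    for lab, r in ranks.items():
        if r not in (1, 2, 3, 4):
            raise ValueError(f"rank for {lab!r} must be in 1..4, got {r}")
    used: set[str] = set()
    pairs: list[RankPair] = []
    for nd in tree._tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        tips = [tree.tip_labels[i] for i in nd._tgc_tips]
        if any(t in used for t in tips):
            continue
        if any(t not in ranks for t in tips):
            continue
        by_rank: dict[int, list[str]] = {}
        for t in tips:
            by_rank.setdefault(ranks[t], []).append(t)
        if len(by_rank) != 2:
            continue
        (r_lo, lo), (r_hi, hi) = sorted(by_rank.items())
        pairs.append(RankPair(
            high_members=tuple(hi), low_members=tuple(lo),
            high_rank=r_hi, low_rank=r_lo,
            high_value=float(np.mean([values[t] for t in hi])),
            low_value=float(np.mean([values[t] for t in lo])),
        ))
        used.update(tips)
    return pairs


def pairs_to_frame(pairs: list[RankPair]) -> pd.DataFrame:
    return pd.DataFrame([
        {"high_members": ";".join(p.high_members),
         "low_members": ";".join(p.low_members),
         "high_rank": p.high_rank, "low_rank": p.low_rank,
         "high_value": p.high_value, "low_value": p.low_value,
         "difference": p.difference}
        for p in pairs])


# ------------------------------------------------------- Wilcoxon exact

def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact P over all sign assignments.

    ``ranks2`` are tie-averaged ranks doubled to integers; the null
    distribution of the doubled positive-rank sum is built by dynamic-
    programming convolution (equivalent to enumerating all 2^n sign
    vectors).
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2i = int(round(w2))
    cdf = dist[: w2i + 1].sum()
    sf = dist[w2i:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(differences: Sequence[float],
                         exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (W, P).

    Zero differences are dropped; tied absolute values get averaged
    ranks.  P is exact (full sign-assignment enumeration via DP) for
    n <= ``exact_max_n`` nonzero differences, and otherwise a normal
    approximation with tie and continuity corrections.  W is the
    positive-rank sum.
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(np.round(2.0 * ranks), 2.0 * W)
        return W, p
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var <= 0:
        raise ValueError("degenerate rank variance")
    z = (W - mu - 0.5 * np.sign(W - mu)) / math.sqrt(var)
    return W, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ------------------------------------------------------------- resampling

def resample_pgls(tree: PhyloTree, traits: pd.DataFrame,
                  trait_pairs: Sequence[tuple[str, str]],
                  m: int = 155, rounds: int = 1000, alpha: float = 0.05,
                  model: str = "BM", seed: int = 0) -> ResampleTally:
    """Tally PGLS slope sign x significance over random tip subsamples.

    Each round draws ``m`` tips without replacement (its own counter-based
    RNG substream keyed (seed, round), so individual rounds are
    reproducible and independent of ``rounds``), prunes the tree, and runs
    ``pgls`` of the first trait on the second for every (response,
    predictor) name pair in ``trait_pairs``.
    """
    labels = [lab for lab in tree.tip_labels if lab in traits.index]
    n = len(labels)
    if m > n:
        raise ValueError(f"m = {m} exceeds usable tips n = {n}")
    if m < 5:
        raise ValueError("m too small for PGLS")
    keys = [f"{y}~{x}" for y, x in trait_pairs]
    counts = pd.DataFrame(0, index=keys,
                          columns=["negative", "nonsignificant", "positive"])
    for rnd in range(rounds):
        rng = np.random.default_rng([seed, rnd])
        chosen = list(np.array(labels)[rng.choice(n, size=m, replace=False)])
        sub = tree.prune_to(chosen)
        for (ycol, xcol), key in zip(trait_pairs, keys):
            fit = pgls(sub, traits[ycol], traits[xcol], model=model, names=[xcol])
            slope = fit.coef[xcol]
            pval = fit.pvals[xcol]
            if pval < alpha:
                counts.loc[key, "negative" if slope < 0 else "positive"] += 1
            else:
                counts.loc[key, "nonsignificant"] += 1
    return ResampleTally(counts, rounds, m, alpha, seed)
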