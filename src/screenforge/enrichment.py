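"""Preranked GSEA core: weighted Kolmogorov-Smirnov enrichment score and
permutation null.  Shared by the CRISPR gene-aggregation step and the
proteomics hallmark analysis.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "enrichment_score",
    "permutation_p",
    "read_gmt",
    "EXHAUSTIVE_LIMIT",
]

# below this many distinct member placements the permutation null is
# enumerated exactly instead of sampled
EXHAUSTIVE_LIMIT = 10_000


def _es_from_membership(scores: np.ndarray, member_mask: np.ndarray,
                        weight_exp: float) -> float:
    """Weighted-KS running-sum extreme for one membership mask.

    A hit at rank i adds |score_i|^weight_exp normalized by the sum over hits;
    a miss subtracts 1/(N - n_members).  The enrichment score is the running
    sum's most extreme deviation from zero, keeping its sign; an exact tie
    between the positive and negative extremes resolves positive.
    """
    n = scores.size
    n_mem = int(member_mask.sum())
    w = np.abs(scores) ** weight_exp
    hit_norm = w[member_mask].sum()
    if n_mem == n:
        # internal all-hits case: running sum peaks at exactly 1
        return 1.0
    if hit_norm == 0:
        raise ValueError("all member scores are zero: hit weights undefined")
    steps = np.where(member_mask, w / hit_norm, -1.0 / (n - n_mem))
    running = np.cumsum(steps)
    hi = running.max()
    lo = running.min()
    return float(hi) if hi >= -lo else float(lo)


def enrichment_score(scores, member_mask=None, members=None, items=None,
                     weight_exp: float = 1.0) -> float:
    """Enrichment score of a member set within a descending-ranked list.

    ``scores`` must already be ordered by descending score (ties keep their
    original order).  Membership is given either as a boolean ``member_mask``
    aligned with ``scores`` or as a ``members`` set over ``items``.
    """
    scores = np.asarray(scores, dtype=float)
    if member_mask is None:
        if members is None or items is None:
            raise ValueError("provide member_mask, or members together with items")
        member_set = set(members)
        member_mask = np.array([it in member_set for it in items])
    else:
        member_mask = np.asarray(member_mask, dtype=bool)
    if member_mask.size != scores.size:
        raise ValueError("membership mask length mismatch")
    n_mem = int(member_mask.sum())
    if n_mem == 0:
        raise ValueError("member set is empty")
    return _es_from_membership(scores, member_mask, weight_exp)


def permutation_p(scores, member_mask=None, members=None, items=None,
                  n_perm: int = 1000, seed: int | None = None,
                  weight_exp: float = 1.0) -> tuple[float, float]:
    """One-sided permutation p for an observed enrichment score.

    The null reassigns the member labels to uniformly random positions of the
    same set size.  When the number of distinct placements C(N, k) is at most
    `EXHAUSTIVE_LIMIT` the null is enumerated exactly (p = fraction of
    placements at least as extreme, including the observed one); otherwise
    ``n_perm`` random placements are drawn and p = (1 + #extreme)/(1 + n_perm).
    For a positive observed ES the extreme tail is ES_null >= ES_obs; for a
    negative one it is ES_null <= ES_obs.

    Returns (es_observed, p).
    """
    scores = np.asarray(scores, dtype=float)
    if member_mask is None:
        member_set = set(members)
        member_mask = np.array([it in member_set for it in items])
    else:
        member_mask = np.asarray(member_mask, dtype=bool)
    n = scores.size
    k = int(member_mask.sum())
    es_obs = enrichment_score(scores, member_mask=member_mask,
                              weight_exp=weight_exp)
    if k == n:
        return es_obs, 1.0

    def _tail(es_null: float) -> bool:
        return es_null >= es_obs if es_obs >= 0 else es_null <= es_obs

    if comb(n, k) <= EXHAUSTIVE_LIMIT:
        extreme = total = 0
        mask = np.zeros(n, dtype=bool)
        for combo in combinations(range(n), k):
            mask[:] = False
            mask[list(combo)] = True
            total += 1
            if _tail(_es_from_membership(scores, mask, weight_exp)):
                extreme += 1
        return es_obs, extreme / total
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    extreme = 0
    mask = np.zeros(n, dtype=bool)
    for _ in range(n_perm):
        mask[:] = False
        mask[rng.choice(n, size=k, replace=False)] = True
        if _tail(_es_from_membership(scores, mask, weight_exp)):
            extreme += 1
    return es_obs, (1 + extreme) / (1 + n_perm)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT: name <tab> description <tab> member...."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {f for f in fields[2:] if f}
    return sets
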