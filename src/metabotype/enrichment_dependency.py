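"""Set enrichment over ranked lists and dependency/drug group comparisons.

Three complementary views of how the two metabolic types differ:

* hypergeometric enrichment of pathway/gene sets in the top and bottom
  tails of a ranked list (e.g. metabolites ranked by type-1-minus-type-2
  fractional difference), BH-adjusted per tail family;
* per-item two-sample comparisons of gene-dependency (CERES scale) or
  drug-response scores between the types;
* pre-ranked GSEA: weighted Kolmogorov-Smirnov running-sum enrichment
  score with a gene-label permutation null, NES normalized by the mean
  same-sign permuted ES, add-one permutation p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _as_ranked(ranked) -> pd.Series:
    """Coerce to a descending-sorted Series (index = item id, value = score)."""
    if isinstance(ranked, pd.DataFrame):
        s = ranked.set_index(ranked.columns[0])[ranked.columns[1]]
    else:
        s = pd.Series(ranked)
    if not s.index.is_unique:
        raise ValueError("ranked list ids must be unique")
    # descending score, ties broken by id for reproducibility
    order = sorted(s.index, key=lambda i: (-s[i], str(i)))
    return s.loc[order].astype(float)


# ---------------------------------------------------------------------------
# tail enrichment
# ---------------------------------------------------------------------------


def tail_enrichment(
    ranked, sets: dict[str, set], tail_fraction: float = 0.25
) -> pd.DataFrame:
    """Hypergeometric enrichment of sets in both tails of a ranked list.

    Tails are the top and bottom ``ceil(tail_fraction * N)`` items of the
    descending ranking (top tail = positive scores = "type 1" direction,
    bottom = "type 2"). Per set and tail an upper-tail hypergeometric
    p-value on the overlap is computed and BH-adjusted within each tail
    family. Sets with no members in the universe are skipped; full ties
    in the scores are resolved by item id and flagged with a warning.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5]")
    s = _as_ranked(ranked)
    N = len(s)
    n_tail = math.ceil(tail_fraction * N)
    boundary_tied = (
        (N > n_tail)
        and (s.iloc[n_tail - 1] == s.iloc[n_tail] or s.iloc[-n_tail] == s.iloc[-n_tail - 1])
    )
    if boundary_tied:
        warnings.warn("tied scores at a tail boundary; tails resolved by item id")
    universe = set(s.index)
    tails = {
        "type1": set(s.index[:n_tail]),
        "type2": set(s.index[-n_tail:]),
    }
    rows = []
    for set_id, members in sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        if K == 0:
            continue  # skipped: no members measured
        for tail, tail_ids in tails.items():
            k = len(in_universe & tail_ids)
            p = float(stats.hypergeom.sf(k - 1, N, K, n_tail))
            rows.append(
                {"set_id": set_id, "tail": tail, "k": k, "K": K,
                 "n": n_tail, "N": N, "p": min(max(p, 1e-300), 1.0),
                 "tie_warning": bool(boundary_tied)}
            )
    out = pd.DataFrame(rows)
    if len(out):
        for tail in tails:
            mask = out["tail"] == tail
            out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# group comparisons and ranking
# ---------------------------------------------------------------------------


def _item_scores(effects: pd.DataFrame, item: str) -> pd.Series:
    sub = effects[effects.iloc[:, 0] == item]
    if len(sub) == 0:
        raise KeyError(f"no scores for item {item!r}")
    return sub.set_index("cell_line")["score"].astype(float)


def compare_groups(
    effects: pd.DataFrame, labels: pd.Series, item: str
) -> dict:
    """Classical two-sided unpaired (pooled-variance) t-test for one item.

    ``effects`` is long-format (gene_or_drug, cell_line, score); ``labels``
    maps cell line to type. Returns group means, the mean difference
    (type 1 minus type 2), t and p.
    """
    scores = _item_scores(effects, item)
    types = labels.reindex(scores.index)
    x = scores[types == 1].to_numpy()
    y = scores[types == 2].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 cell lines per group")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {
        "item": item,
        "mean_type1": float(x.mean()),
        "mean_type2": float(y.mean()),
        "mean_difference": float(x.mean() - y.mean()),
        "t": float(t),
        "p": float(p),
        "n_type1": len(x),
        "n_type2": len(y),
    }


def rank_genes_by_type(effects: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Genes ranked by point-biserial correlation with the type labels.

    The binary coding is type 1 = 1, type 2 = 0, so positive scores mean
    a higher (less negative) dependency score in type 1. Genes with
    constant scores get correlation 0 with a warning. Returns a
    descending-sorted Series (gene -> correlation).
    """
    wide = effects.pivot_table(index="cell_line", columns=effects.columns[0],
                               values="score")
    types = labels.reindex(wide.index)
    keep = types.isin([1, 2])
    wide, types = wide[keep], types[keep]
    if not ((types == 1).any() and (types == 2).any()):
        raise ValueError("both types must be represented")
    y = (types == 1).astype(float).to_numpy()
    X = wide.to_numpy(dtype=float)
    yc = y - y.mean()
    Xc = X - np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(Xc), 0.0, Xc)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    if (sx == 0).any():
        warnings.warn("constant dependency scores for some genes; correlation set to 0")
        r = np.where(sx == 0, 0.0, r)
    s = pd.Series(r, index=wide.columns)
    return _as_ranked(s)


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------


def enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score of a set in a ranking.

    ``scores`` are the ranking statistics in descending rank order;
    ``hit_mask`` marks set members. Hits increment the running sum by
    |score|^weight (normalized over hits), misses decrement by 1/(N-K);
    the ES is the maximal signed deviation of the running sum.
    """
    N = len(scores)
    K = int(hit_mask.sum())
    if K == 0 or K == N:
        raise ValueError("set must be a proper non-empty subset of the universe")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores zero: fall back to unweighted hits
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~hit_mask) / (N - K))
    return float(running[np.argmax(np.abs(running))])


@dataclass
class GSEAResult:
    set_id: str
    es: float
    nes: float
    p: float
    q: float
    size: int


def preranked_gsea(
    ranked,
    sets: dict[str, set],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over gene sets with a gene-label permutation null.

    For each set the ES is computed on the observed ranking; the null is
    generated by permuting the gene labels (equivalently, drawing random
    member positions of the same size). NES = ES / mean(|same-sign
    permuted ES|); permutation p-values use the add-one rule so they are
    never 0; BH q-values are computed within each sign family.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    s = _as_ranked(ranked)
    N = len(s)
    scores = s.to_numpy()
    universe = set(s.index)
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(s.index)}
    rows = []
    for set_id, members in sets.items():
        extra = set(members) - universe
        if extra:
            raise ValueError(f"set {set_id!r} contains items outside the universe")
        idx = np.array([pos[g] for g in members], dtype=int)
        K = len(idx)
        if K == 0:
            continue
        hit = np.zeros(N, dtype=bool)
        hit[idx] = True
        es = enrichment_score(scores, hit, weight)
        perm_es = np.empty(n_perm)
        for r in range(n_perm):
            mask = np.zeros(N, dtype=bool)
            mask[rng.choice(N, size=K, replace=False)] = True
            perm_es[r] = enrichment_score(scores, mask, weight)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        mean_same = np.abs(perm_es[same_sign]).mean() if n_same else np.nan
        nes = es / mean_same if n_same else np.nan
        extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same) if n_same else 1.0
        rows.append({"set_id": set_id, "es": es, "nes": nes, "p": p, "size": K})
    out = pd.DataFrame(rows)
    if len(out):
        for sign_mask in (out["es"] >= 0, out["es"] < 0):
            if sign_mask.any():
                out.loc[sign_mask, "q"] = multipletests(
                    out.loc[sign_mask, "p"], method="fdr_bh"
                )[1]
    return out


def read_gmt_sets(path) -> dict[str, set]:
    """Plain GMT reader: set name, description, members."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


__all__ = [
    "GSEAResult",
    "compare_groups",
    "enrichment_score",
    "preranked_gsea",
    "rank_genes_by_type",
    "read_gmt_sets",
    "tail_enrichment",
]
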