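"""Metabolic typing and the dendrogram-branch association scan.

Cell lines are clustered by Ward's method on their pathway-activity
scores (Euclidean distance). Rather than testing only the final cut, the
association scan iterates over every internal branch of the dendrogram
covering at least a minimum fraction of the cohort (default 10%, i.e. 18
of 180 cell lines) and tests each (branch, trait) pair: a one-sided
upper-tail hypergeometric test per level for categorical traits and a
two-tailed pooled-variance t-test (branch versus rest of the tree) for
continuous traits. All p-values are pooled into one global
Storey-Tibshirani q-value computation, and each q-value is extended with
a sign indicating whether the trait is higher/enriched (+1) or
lower/depleted (-1) in the branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.interpolate import make_smoothing_spline

_P_FLOOR = 1e-300  # keep pooled p-values inside (0, 1]
_TRUTHY_LEVELS = {"1", "true", "yes", "y", "pos", "positive"}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    id: str
    node_id: int
    leaves: frozenset[str]
    height: float

    @property
    def size(self) -> int:
        return len(self.leaves)


@dataclass
class ClusterTree:
    """Ward dendrogram over cell lines with enumerable internal branches."""

    linkage: np.ndarray
    labels: list[str]
    data: pd.DataFrame | None = None
    _branches: dict[int, Branch] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("linkage heights must be non-decreasing")
        self._collect_branches()

    def _collect_branches(self) -> None:
        root = hierarchy.to_tree(self.linkage)
        labels = self.labels

        def visit(node):
            leaves = frozenset(labels[i] for i in node.pre_order(lambda x: x.id))
            self._branches[node.id] = Branch(
                f"b{node.id}", node.id, leaves, float(node.dist)
            )
            if not node.is_leaf():
                visit(node.left)
                visit(node.right)

        visit(root)
        self._root_id = root.id

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def branch(self, branch_id: str) -> Branch:
        return self._branches[int(branch_id.lstrip("b"))]

    def internal_branches(self) -> list[Branch]:
        n = self.n_leaves
        return [
            b
            for node_id, b in sorted(self._branches.items())
            if node_id >= n  # internal nodes only
        ]

    def major_types(self, k: int = 2) -> pd.Series:
        """Cut into k major types; type numbers ordered by descending size
        (ties broken by smallest leaf id)."""
        assign = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        raw = pd.Series(assign, index=self.labels)
        order = sorted(
            raw.unique(), key=lambda c: (-(raw == c).sum(), min(raw.index[raw == c]))
        )
        remap = {c: i + 1 for i, c in enumerate(order)}
        return raw.map(remap)

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_dist):
            bl = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right})b{node.id}:{bl:.6g}"

        return fmt(root, root.dist) + ";"


def cluster_cell_lines(scores) -> ClusterTree:
    """Ward linkage over cell lines on their pathway scores.

    Accepts a :class:`~metabotype.pathway_scoring.PathwayScoreMatrix` or a
    plain cell-line x pathway DataFrame. Cell lines are sorted
    lexicographically before linkage so the result is deterministic for a
    given score matrix regardless of input order.
    """
    df = getattr(scores, "scores", scores)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 cell lines")
    if df.isna().any().any():
        raise ValueError(
            "missing pathway scores; impute or drop cell lines upstream before clustering"
        )
    df = df.sort_index()
    Z = hierarchy.linkage(df.to_numpy(dtype=float), method="ward")
    return ClusterTree(Z, list(df.index), df)


def branch_size_threshold(n_total: int, min_fraction: float = 0.10) -> int:
    """Minimum branch size implied by the fraction-of-cohort inclusion rule."""
    return math.ceil(min_fraction * n_total)


def enumerate_branches(
    tree: ClusterTree, n_total: int | None = None, min_fraction: float = 0.10
) -> list[Branch]:
    """All internal branches with size >= ceil(min_fraction * n_total).

    The root is excluded (its complement is empty); both children of the
    root qualify if they meet the size rule.
    """
    if n_total is None:
        n_total = tree.n_leaves
    threshold = branch_size_threshold(n_total, min_fraction)
    return [
        b
        for b in tree.internal_branches()
        if b.size >= threshold and b.node_id != tree._root_id
    ]


# ---------------------------------------------------------------------------
# branch-trait tests
# ---------------------------------------------------------------------------


def _positive_level(levels: list) -> object | None:
    """For two-level traits, the level to treat as the trait's presence."""
    if len(levels) != 2:
        return None
    for lv in levels:
        if str(lv).strip().lower() in _TRUTHY_LEVELS:
            return lv
    return max(levels, key=str)  # deterministic fallback


def test_branch_trait(
    branch: Iterable[str], values: pd.Series, modality: str
) -> tuple[float, int, dict]:
    """p-value, direction and effect summary for one (branch, trait) pair.

    Categorical: one-sided upper-tail hypergeometric P(X >= k) per trait
    level against the branch, keeping the minimal-p level. For two-level
    traits the direction is +1 when the "positive" level is the enriched
    one and -1 otherwise; multi-level traits always report +1 for the
    winning level. Continuous: two-tailed pooled-variance t-test of branch
    versus complement, direction = sign of the mean difference.
    """
    values = values.dropna()
    background = set(values.index)
    in_branch = values.index.isin(set(branch))
    n = int(in_branch.sum())
    if n == 0:
        raise ValueError("branch has no cell lines with trait data")
    N = len(background)

    if modality == "categorical":
        levels = sorted(values.unique(), key=str)
        if len(levels) < 2:
            raise ValueError("categorical trait needs >= 2 levels among non-missing")
        best = None
        for lv in levels:
            is_lv = (values == lv).to_numpy()
            K = int(is_lv.sum())
            k = int((is_lv & in_branch).sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            if best is None or p < best[0]:
                best = (p, lv, k, K)
        p, lv, k, K = best
        pos = _positive_level(levels)
        direction = 1 if pos is None or lv == pos else -1
        effect = {"level": lv, "k": k, "K": K, "n": n, "N": N}
        return max(min(p, 1.0), _P_FLOOR), direction, effect

    if modality == "continuous":
        x = values[in_branch].to_numpy(dtype=float)
        y = values[~in_branch].to_numpy(dtype=float)
        if len(y) < 2 or len(x) < 2:
            raise ValueError("need >= 2 values in branch and complement for a t-test")
        if np.ptp(np.concatenate([x, y])) == 0:
            return 1.0, 1, {"mean_branch": float(x.mean()), "mean_rest": float(y.mean())}
        t, p = stats.ttest_ind(x, y, equal_var=True)
        diff = float(x.mean() - y.mean())
        direction = 1 if diff >= 0 else -1
        if np.isnan(p):
            p = 1.0
        effect = {"mean_branch": float(x.mean()), "mean_rest": float(y.mean()),
                  "mean_difference": diff}
        return max(min(float(p), 1.0), _P_FLOOR), direction, effect

    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# Storey-Tibshirani q-values
# ---------------------------------------------------------------------------


def qvalues_storey(
    pvals: np.ndarray, lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """q-values and pi0 per the smoothing-spline pi0 estimator.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    lambda in {0, 0.05, ..., 0.90}, smoothed by a cubic smoothing spline;
    pi0 is the fitted value at 0.90, clipped into (0, 1].
    q_i = min_{t >= p_i} pi0 * m * t / #{p <= t}, monotone in p.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.0, 0.95, 0.05)
    pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if m < 100 or np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = float(min(1.0, pi0_lam[-1] if m >= 100 else 1.0))
    else:
        spline = make_smoothing_spline(lambdas, pi0_lam)
        pi0 = float(spline(lambdas[-1]))
    pi0 = min(1.0, max(pi0, 1.0 / m))

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = pi0 * m * ranked / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


@dataclass
class AssociationRecord:
    branch_id: str
    trait_id: str
    test: str
    p: float
    q: float
    direction: int
    effect: dict
    significant: bool

    @property
    def signed_q(self) -> float:
        return self.direction * self.q


@dataclass
class ScanResult:
    records: list[AssociationRecord]
    pi0: float
    skipped: list[dict]
    fdr: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "branch_id": r.branch_id,
                "trait_id": r.trait_id,
                "test": r.test,
                "p": r.p,
                "q": r.q,
                "direction": r.direction,
                "signed_q": r.signed_q,
                "significant": r.significant,
                **{f"effect_{k}": v for k, v in r.effect.items()},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def significant_records(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.significant]


def association_scan(
    tree: ClusterTree,
    traits,
    fdr: float = 0.10,
    min_fraction: float = 0.10,
) -> ScanResult:
    """Test every qualifying (branch, trait) pair with one global FDR pool.

    ``traits`` is a :class:`~metabotype.synthetic_data.TraitTable`.
    Continuous tests are vectorized across traits per branch; categorical
    tests are vectorized across branches per trait level. Pairs that
    cannot be tested (branch entirely missing, complement too small,
    single trait level) are skipped with a machine-readable reason.
    """
    branches = enumerate_branches(tree, min_fraction=min_fraction)
    lines = pd.Index(tree.labels)
    skipped: list[dict] = []
    entries: list[tuple[str, str, str, float, int, dict]] = []

    # continuous traits: vectorize over traits for each branch
    cont = traits.continuous.reindex(lines)
    if cont.shape[1]:
        V = cont.to_numpy(dtype=float)
        valid = ~np.isnan(V)
        for br in branches:
            b = lines.isin(br.leaves)
            n1 = (valid & b[:, None]).sum(axis=0)
            n2 = (valid & ~b[:, None]).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sum1 = np.nansum(np.where(b[:, None], V, 0.0), axis=0)
                sum2 = np.nansum(np.where(~b[:, None], V, 0.0), axis=0)
                mean1, mean2 = sum1 / n1, sum2 / n2
                sq1 = np.nansum(np.where(b[:, None], V**2, 0.0), axis=0)
                sq2 = np.nansum(np.where(~b[:, None], V**2, 0.0), axis=0)
                ss1 = sq1 - n1 * mean1**2
                ss2 = sq2 - n2 * mean2**2
                df = n1 + n2 - 2
                pooled = (ss1 + ss2) / df
                t = (mean1 - mean2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
                p = 2.0 * stats.t.sf(np.abs(t), df)
            for j, trait_id in enumerate(cont.columns):
                if n1[j] < 2 or n2[j] < 2:
                    skipped.append(
                        {"branch_id": br.id, "trait_id": trait_id,
                         "reason": "insufficient_nonmissing"}
                    )
                    continue
                pj = p[j]
                if np.isnan(pj):  # zero pooled variance
                    pj = 1.0 if (mean1[j] - mean2[j]) == 0 else _P_FLOOR
                direction = 1 if (mean1[j] - mean2[j]) >= 0 else -1
                entries.append(
                    (br.id, trait_id, "t", max(min(float(pj), 1.0), _P_FLOOR),
                     direction,
                     {"mean_branch": float(mean1[j]), "mean_rest": float(mean2[j])})
                )

    # categorical traits: vectorize over branches for each trait level
    cat = traits.categorical.reindex(lines)
    if cat.shape[1]:
        branch_masks = np.array([lines.isin(br.leaves) for br in branches])
        for trait_id in cat.columns:
            values = cat[trait_id]
            present = values.notna().to_numpy()
            levels = sorted(values.dropna().unique(), key=str)
            if len(levels) < 2:
                for br in branches:
                    skipped.append({"branch_id": br.id, "trait_id": trait_id,
                                    "reason": "single_level"})
                continue
            N = int(present.sum())
            n_arr = (branch_masks & present).sum(axis=1)
            best_p = np.full(len(branches), np.inf)
            best = [None] * len(branches)
            pos = _positive_level(levels)
            for lv in levels:
                is_lv = (values == lv).to_numpy()
                K = int(is_lv.sum())
                k_arr = (branch_masks & is_lv).sum(axis=1)
                p_arr = stats.hypergeom.sf(k_arr - 1, N, K, n_arr)
                better = p_arr < best_p
                for bi in np.nonzero(better)[0]:
                    best_p[bi] = p_arr[bi]
                    best[bi] = (lv, int(k_arr[bi]), K)
            for bi, br in enumerate(branches):
                if n_arr[bi] == 0:
                    skipped.append({"branch_id": br.id, "trait_id": trait_id,
                                    "reason": "branch_all_missing"})
                    continue
                lv, k, K = best[bi]
                direction = 1 if pos is None or lv == pos else -1
                # Sidak-adjust the minimal-p level for the number of levels
                # tested, so the pooled family is not anticonservative
                p_min = max(min(float(best_p[bi]), 1.0), _P_FLOOR)
                p_adj = float(-np.expm1(len(levels) * np.log1p(-min(p_min, 1 - 1e-16))))
                entries.append(
                    (br.id, trait_id, "hypergeometric",
                     max(min(p_adj, 1.0), _P_FLOOR), direction,
                     {"level": lv, "k": k, "K": K, "n": int(n_arr[bi]), "N": N,
                      "p_min_level": p_min})
                )

    if not entries:
        raise ValueError("no testable (branch, trait) pairs")
    pvals = np.array([e[3] for e in entries])
    qvals, pi0 = qvalues_storey(pvals)
    records = [
        AssociationRecord(bid, tid, test, p, float(q), direction, effect, bool(q <= fdr))
        for (bid, tid, test, p, direction, effect), q in zip(entries, qvals)
    ]
    return ScanResult(records, pi0, skipped, fdr)


__all__ = [
    "AssociationRecord",
    "Branch",
    "ClusterTree",
    "ScanResult",
    "association_scan",
    "branch_size_threshold",
    "cluster_cell_lines",
    "enumerate_branches",
    "qvalues_storey",
    "test_branch_trait",
]
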