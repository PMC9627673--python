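"""Five reproducibility criteria for scoring normalization methods.

Each criterion exploits the QC cell lines replicated across all batches:

* **batch scoring FC** — the 95th percentile of pooled per-ion |log2
  fold-changes| between random disjoint subsets of one QC line's
  replicates (zero for perfectly reproducible data);
* **FC reproducibility** — the mean pairwise Euclidean distance between
  the per-batch log2 fold-change vectors of two QC lines (optionally
  restricted to ions matching the 20 proteinogenic amino acids);
* **interbatch distance** — mean pairwise Bhattacharyya distance between
  per-batch Gaussian clouds in the first principal components;
* **KS rate** — fraction of significant two-sample Kolmogorov-Smirnov
  tests of one QC line's intensities between batch pairs.

All criteria are non-negative; for benchmarking they are scaled so the
un-normalized table equals 1 exactly and values below 1 mean improved
reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iontable import IonTable
from .normalization import NormalizationStack, apply_stack

# monoisotopic formulas of the 20 proteinogenic amino acids (isomer pairs
# such as leucine/isoleucine collapse to the same formula)
AMINO_ACID_FORMULAS: dict[str, str] = {
    "glycine": "C2H5NO2",
    "alanine": "C3H7NO2",
    "serine": "C3H7NO3",
    "proline": "C5H9NO2",
    "valine": "C5H11NO2",
    "threonine": "C4H9NO3",
    "cysteine": "C3H7NO2S",
    "leucine": "C6H13NO2",
    "isoleucine": "C6H13NO2",
    "asparagine": "C4H8N2O3",
    "aspartate": "C4H7NO4",
    "glutamine": "C5H10N2O3",
    "lysine": "C6H14N2O2",
    "glutamate": "C5H9NO4",
    "methionine": "C5H11NO2S",
    "histidine": "C6H9N3O2",
    "phenylalanine": "C9H11NO2",
    "arginine": "C6H14N4O2",
    "tyrosine": "C9H11NO3",
    "tryptophan": "C11H12N2O2",
}

CRITERIA = (
    "batch_scoring_fc",
    "fc_reproducibility",
    "fc_reproducibility_aa",
    "interbatch_distance",
    "ks_rate",
)


def batch_scoring_fc(
    table: IonTable,
    qc_line: str,
    set_size: int = 6,
    n_resample: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
    return_sd: bool = False,
) -> float | tuple[float, float]:
    """Resampled fold-change threshold between replicate subsets of a QC line.

    Repeatedly draws two disjoint ``set_size`` subsets of the QC line's
    replicate measurements, forms per-ion |log2 FC| between the subset
    means, and returns the (1 - ``fdr``) quantile of the pooled
    distribution. ``return_sd`` adds a Monte-Carlo block sd of the
    quantile (10 blocks of resamples).
    """
    qc_samples = table.samples_of_line(qc_line)
    vals = table.intensities.loc[qc_samples].to_numpy(dtype=float)
    n = vals.shape[0]
    if n < 2 * set_size:
        raise ValueError(
            f"QC line {qc_line!r} has {n} replicates; need >= {2 * set_size}"
        )
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_resample, vals.shape[1]))
    for r in range(n_resample):
        perm = rng.permutation(n)
        mean_a = vals[perm[:set_size]].mean(axis=0)
        mean_b = vals[perm[set_size: 2 * set_size]].mean(axis=0)
        pooled[r] = np.abs(np.log2(mean_a / mean_b))
    value = float(np.quantile(pooled, 1.0 - fdr))
    if not return_sd:
        return value
    n_blocks = min(10, n_resample)
    blocks = np.array_split(pooled, n_blocks, axis=0)
    block_q = [np.quantile(b, 1.0 - fdr) for b in blocks]
    return value, float(np.std(block_q, ddof=1) / np.sqrt(n_blocks))


def amino_acid_ion_subset(ions: pd.DataFrame) -> pd.Index:
    """Ions with at least one candidate formula matching a proteinogenic AA."""
    targets = set(AMINO_ACID_FORMULAS.values())
    mask = [
        bool(targets.intersection(str(f).split(";"))) for f in ions["formulas"]
    ]
    return ions.index[mask]


def fc_reproducibility(
    table: IonTable, qc_a: str, qc_b: str, ion_subset: str = "all"
) -> float:
    """Mean pairwise distance of per-batch QC-line log2 fold-change vectors."""
    if ion_subset == "amino_acids":
        cols = amino_acid_ion_subset(table.ions)
        if len(cols) == 0:
            raise ValueError("no ions match the amino-acid formula list")
    elif ion_subset == "all":
        cols = table.intensities.columns
    else:
        raise ValueError("ion_subset must be 'all' or 'amino_acids'")
    intens = table.intensities[cols]
    fc_vectors = []
    for b in table.batches:
        in_batch = table.samples["batch"] == b
        a_rows = in_batch & (table.samples["cell_line"] == qc_a)
        b_rows = in_batch & (table.samples["cell_line"] == qc_b)
        if a_rows.sum() == 0 or b_rows.sum() == 0:
            continue
        fc = np.log2(
            intens.loc[a_rows].mean(axis=0).to_numpy()
            / intens.loc[b_rows].mean(axis=0).to_numpy()
        )
        fc_vectors.append(fc)
    if len(fc_vectors) < 2:
        raise ValueError("need both QC lines in at least 2 common batches")
    dists = [
        float(np.linalg.norm(u - v)) for u, v in combinations(fc_vectors, 2)
    ]
    return float(np.mean(dists))


def _bhattacharyya(mu1, cov1, mu2, cov2) -> float:
    cov_bar = (cov1 + cov2) / 2.0
    diff = mu1 - mu2
    term1 = 0.125 * diff @ np.linalg.solve(cov_bar, diff)
    _, ld_bar = np.linalg.slogdet(cov_bar)
    _, ld1 = np.linalg.slogdet(cov1)
    _, ld2 = np.linalg.slogdet(cov2)
    term2 = 0.5 * (ld_bar - 0.5 * (ld1 + ld2))
    return float(term1 + term2)


def interbatch_distance(table: IonTable, n_pcs: int = 2) -> float:
    """Mean pairwise Bhattacharyya distance of batch clouds in PC space.

    PCA on log intensities (ion-centered); per batch a Gaussian is fitted
    to the first ``n_pcs`` scores. Near-singular covariances are
    regularized by adding a small diagonal.
    """
    batches = table.samples["batch"].to_numpy()
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValueError("need at least 2 batches")
    for b in uniq:
        if (batches == b).sum() <= n_pcs:
            raise ValueError(f"batch {b!r} needs more than {n_pcs} samples")
    from .normalization import _log_with_imputation

    log_vals, _ = _log_with_imputation(table.values())
    centered = log_vals - log_vals.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    params = []
    for b in uniq:
        pts = scores[batches == b]
        cov = np.cov(pts, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        eps = 1e-9 * max(np.trace(cov) / n_pcs, 1.0)
        if np.linalg.cond(cov) > 1e10 or np.linalg.det(cov) <= 0:
            cov = cov + eps * np.eye(n_pcs)
        if np.linalg.det(cov) <= 0 or np.linalg.det((cov + cov) / 2) <= 0:
            raise ValueError(f"singular covariance for batch {b!r} after regularization")
        params.append((pts.mean(axis=0), cov))
    dists = [
        _bhattacharyya(m1, c1, m2, c2)
        for (m1, c1), (m2, c2) in combinations(params, 2)
    ]
    return float(np.mean(dists))


def ks_batch_effect_rate(
    table: IonTable, qc_line: str, alpha: float = 0.05
) -> float:
    """Fraction of significant KS tests of QC intensities between batches."""
    qc_mask = table.samples["cell_line"] == qc_line
    batches = table.samples.loc[qc_mask, "batch"]
    usable = []
    for b in sorted(batches.unique()):
        rows = table.intensities.index[qc_mask & (table.samples["batch"] == b)]
        if len(rows) < 2:
            warnings.warn(f"batch {b!r} skipped: fewer than 2 QC replicates")
            continue
        usable.append(table.intensities.loc[rows].to_numpy(dtype=float))
    if len(usable) < 2:
        raise ValueError("fewer than 2 batches with enough QC replicates")
    n_sig = n_tot = 0
    for x, y in combinations(usable, 2):
        for j in range(x.shape[1]):
            p = stats.ks_2samp(x[:, j], y[:, j]).pvalue
            n_tot += 1
            n_sig += p < alpha
    return n_sig / n_tot


@dataclass
class QualityReport:
    """Raw and baseline-scaled criteria values for one normalization stack."""

    label: str
    raw: dict[str, float]
    scaled: dict[str, float]
    mc_sd: dict[str, float] = field(default_factory=dict)

    @property
    def mean_scaled(self) -> float:
        return float(np.mean(list(self.scaled.values())))


def compute_criteria(
    table: IonTable,
    qc_line: str,
    qc_pair: tuple[str, str],
    seed: int = 0,
    set_size: int = 6,
    n_resample: int = 1000,
    n_pcs: int = 2,
    alpha: float = 0.05,
) -> dict[str, float]:
    """All five criteria on one table (raw values)."""
    return {
        "batch_scoring_fc": batch_scoring_fc(
            table, qc_line, set_size=set_size, n_resample=n_resample, seed=seed
        ),
        "fc_reproducibility": fc_reproducibility(table, *qc_pair, ion_subset="all"),
        "fc_reproducibility_aa": fc_reproducibility(
            table, *qc_pair, ion_subset="amino_acids"
        ),
        "interbatch_distance": interbatch_distance(table, n_pcs=n_pcs),
        "ks_rate": ks_batch_effect_rate(table, qc_line, alpha=alpha),
    }


def score_stacks(
    table: IonTable,
    stacks: Sequence[NormalizationStack],
    qc_line: str,
    qc_pair: tuple[str, str],
    seed: int = 0,
    **criteria_kwargs,
) -> list[QualityReport]:
    """Benchmark normalization stacks against the un-normalized baseline.

    The baseline report (label ``not_normalized``) has every scaled value
    equal to 1 by definition; stacks are ranked by mean scaled criterion
    (ascending, best first). The same resampling seed is reused for every
    table so Monte-Carlo criteria are directly comparable.
    """
    baseline = compute_criteria(table, qc_line, qc_pair, seed=seed, **criteria_kwargs)
    reports = [
        QualityReport(
            "not_normalized", baseline, {k: 1.0 for k in baseline}
        )
    ]
    for stack in stacks:
        normalized = apply_stack(table, stack)
        raw = compute_criteria(normalized, qc_line, qc_pair, seed=seed, **criteria_kwargs)
        scaled = {
            k: (raw[k] / baseline[k]) if baseline[k] > 0 else np.nan for k in raw
        }
        reports.append(QualityReport(stack.label, raw, scaled))
    reports[1:] = sorted(reports[1:], key=lambda r: r.mean_scaled)
    return reports


def reports_to_frame(reports: Sequence[QualityReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"stack": r.label}
        row.update({f"raw_{k}": v for k, v in r.raw.items()})
        row.update({f"scaled_{k}": v for k, v in r.scaled.items()})
        row["mean_scaled"] = r.mean_scaled
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "AMINO_ACID_FORMULAS",
    "CRITERIA",
    "QualityReport",
    "amino_acid_ion_subset",
    "batch_scoring_fc",
    "compute_criteria",
    "fc_reproducibility",
    "interbatch_distance",
    "ks_batch_effect_rate",
    "reports_to_frame",
    "score_stacks",
]
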