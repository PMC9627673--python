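"""Injection QC and the three classes of normalization methods.

Large flow-injection metabolomics screens accumulate multiplicative
artifacts: per-sample scale differences (cell amount, pipetting,
injection), chronological signal drift (source contamination, detector
sensitivity), and batch effects between growth/measurement batches.
The corrections here are organized in three classes that compose into
ordered stacks (sample_variance -> signal_drift -> batch_effect):

* sample variance: quantile, geometric-mean, median, std, MAD, TIC,
  probabilistic-quotient (PQN) and confluency scaling;
* signal drift: moving median (default window 120 min), LOESS and
  robust LOESS trendlines over injection time;
* batch effect: ComBat-style parametric empirical-Bayes location/scale
  adjustment, optionally estimated on QC samples only.

All corrections treat artifacts as multiplicative: they operate on
log-transformed intensities internally and exponentiate on output. Zero
intensities are treated as missing, imputed per ion with half the
minimum positive value for the correction, and restored afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .iontable import IonTable

CLASS_ORDER = ("sample_variance", "signal_drift", "batch_effect")

SAMPLE_VARIANCE_METHODS = (
    "quantile", "mean", "median", "std", "mad", "tic", "pqn", "confluency",
)
DRIFT_METHODS = ("moving_median", "loess", "robust_loess")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _log_with_imputation(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform with zeros treated as missing (half-minimum imputed).

    Returns the log matrix and the mask of imputed entries so callers can
    restore zeros after correction.
    """
    vals = values.copy()
    zero_mask = vals <= 0
    if zero_mask.any():
        col_min = np.where(
            (~zero_mask).any(axis=0),
            np.min(np.where(zero_mask, np.inf, vals), axis=0),
            1.0,
        )
        fill = np.broadcast_to(col_min / 2.0, vals.shape)
        vals = np.where(zero_mask, fill, vals)
    return np.log(vals), zero_mask


def _restore_zeros(values: np.ndarray, zero_mask: np.ndarray) -> np.ndarray:
    out = values.copy()
    out[zero_mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# TIC-based injection QC
# ---------------------------------------------------------------------------


def filter_abnormal_tic(table: IonTable, k: float = 4.0) -> tuple[IonTable, list[str]]:
    """Drop injections whose log-TIC is a robust outlier.

    A sample is removed when its log total ion current deviates from the
    cohort median by more than ``k`` robust standard deviations
    (MAD x 1.4826). Cell lines whose replicates are all removed are
    dropped entirely and reported in the output provenance.
    """
    if table.n_samples == 0:
        raise ValueError("empty table")
    if k <= 0:
        raise ValueError("k must be > 0")
    tic = table.values().sum(axis=1)
    if (tic <= 0).any():
        raise ValueError("samples with zero TIC present; remove them first")
    log_tic = np.log(tic)
    med = np.median(log_tic)
    dev = np.abs(log_tic - med)
    mad = np.median(dev) * 1.4826
    if mad == 0:
        # degenerate spread: any deviation at all is infinitely many robust sds
        removed = dev > 0
    else:
        removed = dev / mad > k
    removed_ids = table.intensities.index[removed].tolist()
    if removed.all():
        raise ValueError("TIC filter removed every sample")
    kept = table.subset_samples(table.intensities.index[~removed])
    before = set(table.samples["cell_line"])
    after = set(kept.samples["cell_line"])
    dropped_lines = sorted(before - after)
    kept.provenance.append(
        {"step": "filter_abnormal_tic", "k": k, "removed_samples": removed_ids,
         "dropped_cell_lines": dropped_lines}
    )
    return kept, removed_ids


# ---------------------------------------------------------------------------
# sample-variance normalization
# ---------------------------------------------------------------------------


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    n_samples, n_ions = values.shape
    profile = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values, dtype=float)
    grid = np.arange(1, n_ions + 1, dtype=float)
    for s in range(n_samples):
        ranks = rankdata(values[s], method="average")
        out[s] = np.interp(ranks, grid, profile)  # tied ranks -> averaged profile
    return out


def normalize_sample_variance(table: IonTable, method: str) -> IonTable:
    """Correct per-sample scale differences.

    Scaling methods divide each sample by its statistic (geometric mean,
    median, sd, MAD, TIC sum or confluency) and re-multiply by the cohort
    median of that statistic; ``quantile`` replaces each sample's sorted
    intensities by the across-sample mean quantile profile; ``pqn``
    divides each sample by the median of its ion-wise quotients versus
    the median reference spectrum.
    """
    if method not in SAMPLE_VARIANCE_METHODS:
        raise ValueError(f"unknown sample-variance method {method!r}")
    vals = table.values()

    if method == "quantile":
        out = _quantile_normalize(vals)
        return table.with_values(out, {"step": "sample_variance", "method": method})

    if method == "pqn":
        ref = np.median(vals, axis=0)
        usable = ref > 0
        if not usable.any():
            raise ValueError("PQN reference spectrum is all zero")
        quot = vals[:, usable] / ref[usable]
        factors = np.median(quot, axis=1)
        if (factors <= 0).any():
            raise ValueError("zero PQN quotient for at least one sample")
        out = vals / factors[:, None]
        return table.with_values(out, {"step": "sample_variance", "method": method})

    if method == "confluency":
        conf = table.samples.get("confluency")
        if conf is None or conf.isna().all():
            raise ValueError("confluency metadata required for confluency scaling")
        stat = conf.to_numpy(dtype=float)
        suspension = table.samples.get("is_suspension")
        scale_mask = np.ones(len(stat), dtype=bool)
        if suspension is not None and suspension.fillna(False).any():
            scale_mask = ~suspension.fillna(False).to_numpy(dtype=bool)
            warnings.warn("suspension samples left unscaled by confluency normalization")
        if np.isnan(stat[scale_mask]).any() or (stat[scale_mask] <= 0).any():
            raise ValueError("confluency must be present and > 0 for adherent samples")
        med = np.median(stat[scale_mask])
        out = vals.copy()
        out[scale_mask] = vals[scale_mask] * (med / stat[scale_mask, None])
        return table.with_values(out, {"step": "sample_variance", "method": method})

    log_vals, _ = _log_with_imputation(vals)
    if method == "mean":
        stat = np.exp(log_vals.mean(axis=1))  # geometric mean
    elif method == "median":
        stat = np.median(vals, axis=1)
    elif method == "std":
        stat = vals.std(axis=1, ddof=1)
    elif method == "mad":
        stat = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1)
    elif method == "tic":
        stat = vals.sum(axis=1)
    if (stat <= 0).any() or np.isnan(stat).any():
        raise ValueError(f"zero or undefined {method} statistic for at least one sample")
    out = vals * (np.median(stat) / stat)[:, None]
    return table.with_values(out, {"step": "sample_variance", "method": method})


# ---------------------------------------------------------------------------
# signal-drift correction
# ---------------------------------------------------------------------------


def correct_drift(
    table: IonTable, method: str = "moving_median", window_min: float = 120.0
) -> IonTable:
    """Remove chronological drift over injection time, per ion.

    ``moving_median`` estimates a robust trendline as the running median of
    log intensity within +-``window_min``/2 of each injection; ``loess``
    and ``robust_loess`` use locally weighted regression (0 and 4
    robustifying iterations). Intensities are divided by the trend and
    re-multiplied by the ion's overall median. Ions whose trend is not
    finite are left uncorrected and logged in the provenance.
    """
    if method not in DRIFT_METHODS:
        raise ValueError(f"unknown drift method {method!r}")
    t = table.samples["injection_order"].to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("injection_order must be present and finite")
    if len(np.unique(t)) < 5:
        raise ValueError("need at least 5 distinct injection times to estimate drift")
    vals = table.values()
    log_vals, zero_mask = _log_with_imputation(vals)
    out_log = log_vals.copy()
    uncorrected = []

    if method == "moving_median":
        half = window_min / 2.0
        order = np.argsort(t, kind="stable")
        ts = t[order]
        # mirror-pad one window at both ends so a monotone trend is
        # estimated without bias at the run boundaries
        left = ts[0] - (ts[1:][ts[1:] <= ts[0] + half] - ts[0])[::-1]
        right = ts[-1] + (ts[-1] - ts[:-1][ts[:-1] >= ts[-1] - half])[::-1]
        ts_pad = np.concatenate([left, ts, right])
        lo = np.searchsorted(ts_pad, ts - half, side="left")
        hi = np.searchsorted(ts_pad, ts + half, side="right")
        n_left = len(left)
        for j in range(vals.shape[1]):
            y = log_vals[order, j]
            y_pad = np.concatenate([y[1: n_left + 1][::-1], y, y[-len(right) - 1: -1][::-1]])
            trend = np.array([np.median(y_pad[lo[i]: hi[i]]) for i in range(len(ts))])
            if not np.all(np.isfinite(trend)):
                uncorrected.append(table.intensities.columns[j])
                continue
            corrected = y - trend + np.median(y)
            out_log[order, j] = corrected
    else:
        it = 0 if method == "loess" else 4
        span = max(t.max() - t.min(), 1e-9)
        frac = float(np.clip(window_min / span, 10.0 / len(t), 1.0))
        for j in range(vals.shape[1]):
            y = log_vals[:, j]
            trend = lowess(y, t, frac=frac, it=it, return_sorted=False)
            if not np.all(np.isfinite(trend)):
                uncorrected.append(table.intensities.columns[j])
                continue
            out_log[:, j] = y - trend + np.median(y)

    out = _restore_zeros(np.exp(out_log), zero_mask)
    step = {"step": "signal_drift", "method": method, "window_min": window_min,
            "uncorrected_ions": uncorrected}
    return table.with_values(out, step)


# ---------------------------------------------------------------------------
# ComBat batch correction
# ---------------------------------------------------------------------------


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def correct_batch_combat(
    table: IonTable,
    use_qc_only_for_estimation: bool = False,
    empirical_bayes: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> IonTable:
    """Empirical-Bayes location/scale batch adjustment on log intensities.

    Per ion the data are standardized against the batch-size-weighted
    grand mean and pooled variance; per-batch locations and scales are
    estimated and shrunk by parametric empirical Bayes (normal prior on
    locations, inverse-gamma on scales, moment-matched hyperparameters);
    the batch-adjusted data are returned on the original intensity scale.
    With ``empirical_bayes=False`` the raw per-batch estimates are used
    (no shrinkage: every batch is matched exactly in mean and variance).
    With ``use_qc_only_for_estimation`` the batch parameters come from QC
    samples only but are applied to all samples.
    """
    batches = table.samples["batch"].to_numpy()
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    est_mask = np.ones(len(batches), dtype=bool)
    if use_qc_only_for_estimation:
        est_mask = table.samples["is_qc"].to_numpy(dtype=bool)
        if not est_mask.any():
            raise ValueError("no QC samples available for estimation")
    for b in uniq:
        if ((batches == b) & est_mask).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples for estimation")

    vals = table.values()
    log_vals, zero_mask = _log_with_imputation(vals)
    n_ions = log_vals.shape[1]

    est = log_vals[est_mask]
    est_batches = batches[est_mask]
    sizes = np.array([(est_batches == b).sum() for b in uniq], dtype=float)
    batch_means = np.vstack([est[est_batches == b].mean(axis=0) for b in uniq])
    grand_mean = (sizes[:, None] * batch_means).sum(axis=0) / sizes.sum()
    resid = est - batch_means[np.searchsorted(uniq, est_batches)]
    var_pooled = (resid**2).sum(axis=0) / est.shape[0]
    var_pooled = np.where(var_pooled <= 0, np.finfo(float).tiny, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    z_est = (est - grand_mean) / sd_pooled
    gamma_hat = np.vstack([z_est[est_batches == b].mean(axis=0) for b in uniq])
    delta_hat = np.vstack([z_est[est_batches == b].var(axis=0, ddof=1) for b in uniq])
    delta_hat = np.where(delta_hat <= 0, 1e-8, delta_hat)

    if empirical_bayes and n_ions >= 2:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for bi, b in enumerate(uniq):
            zb = z_est[est_batches == b]
            n_b = zb.shape[0]
            g_bar = gamma_hat[bi].mean()
            t2 = gamma_hat[bi].var(ddof=1)
            a_pr, b_pr = _aprior(delta_hat[bi]), _bprior(delta_hat[bi])
            g_new, d_new = gamma_hat[bi].copy(), delta_hat[bi].copy()
            for _ in range(max_iter):
                g_old, d_old = g_new, d_new
                g_new = (n_b * t2 * gamma_hat[bi] + d_old * g_bar) / (n_b * t2 + d_old)
                sse = ((zb - g_new) ** 2).sum(axis=0)
                d_new = (b_pr + 0.5 * sse) / (n_b / 2.0 + a_pr - 1.0)
                if max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max()) < tol:
                    break
            gamma_star[bi], delta_star[bi] = g_new, d_new
    else:
        gamma_star, delta_star = gamma_hat, delta_hat

    z_all = (log_vals - grand_mean) / sd_pooled
    idx = np.searchsorted(uniq, batches)
    adjusted = (z_all - gamma_star[idx]) / np.sqrt(delta_star[idx])
    out_log = adjusted * sd_pooled + grand_mean
    out = _restore_zeros(np.exp(out_log), zero_mask)
    step = {"step": "batch_effect", "method": "combat",
            "use_qc_only_for_estimation": use_qc_only_for_estimation,
            "empirical_bayes": empirical_bayes}
    return table.with_values(out, step)


# ---------------------------------------------------------------------------
# plug-in slots and stacks
# ---------------------------------------------------------------------------

# published normalizers benchmarked via an external implementation can be
# registered here; RUV (2 variants) and QC-SVR are declared but not bundled
NORMALIZER_PLUGINS: dict[str, Callable[..., IonTable]] = {}
PLUGIN_SLOTS = {
    "ruv2": "batch_effect",
    "ruv4": "batch_effect",
    "qc_svr": "signal_drift",
}


def register_normalizer(name: str, fn: Callable[..., IonTable]) -> None:
    NORMALIZER_PLUGINS[name] = fn


@dataclass
class NormalizationStack:
    """Ordered list of method descriptors, at most one per class.

    Each step is a mapping with keys ``class`` (one of
    ``sample_variance``, ``signal_drift``, ``batch_effect``), ``method``
    and optional ``params``. Methods are applied in fixed class order.
    """

    steps: list[dict[str, Any]] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self) -> None:
        seen = set()
        for step in self.steps:
            cls = step.get("class")
            if cls not in CLASS_ORDER:
                raise ValueError(f"unknown normalization class {cls!r}")
            if cls in seen:
                raise ValueError(f"stack has more than one {cls} method")
            seen.add(cls)
        if self.label is None:
            self.label = "+".join(s["method"] for s in self.ordered_steps()) or "identity"

    def ordered_steps(self) -> list[dict[str, Any]]:
        return sorted(self.steps, key=lambda s: CLASS_ORDER.index(s["class"]))

    @classmethod
    def from_config(cls, config: dict[str, Any], label: str | None = None) -> "NormalizationStack":
        return cls(list(config["stack"]), label=label)


def apply_stack(table: IonTable, stack: NormalizationStack) -> IonTable:
    """Apply a normalization stack in class order, recording provenance."""
    out = table
    for step in stack.ordered_steps():
        cls, method = step["class"], step["method"]
        params = step.get("params", {})
        if method in PLUGIN_SLOTS:
            fn = NORMALIZER_PLUGINS.get(method)
            if fn is None:
                raise NotImplementedError(
                    f"{method} is a plug-in slot; register an implementation with "
                    "register_normalizer()"
                )
            out = fn(out, **params)
        elif cls == "sample_variance":
            out = normalize_sample_variance(out, method, **params)
        elif cls == "signal_drift":
            out = correct_drift(out, method, **params)
        elif cls == "batch_effect":
            if method != "combat":
                raise ValueError(f"unknown batch-effect method {method!r}")
            out = correct_batch_combat(out, **params)
    if not stack.steps:
        out = table.with_values(table.values(), {"step": "identity"})
    return out


__all__ = [
    "CLASS_ORDER",
    "DRIFT_METHODS",
    "NormalizationStack",
    "SAMPLE_VARIANCE_METHODS",
    "apply_stack",
    "correct_batch_combat",
    "correct_drift",
    "filter_abnormal_tic",
    "normalize_sample_variance",
    "register_normalizer",
]
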