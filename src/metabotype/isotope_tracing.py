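"""13C isotopologue processing and lipidomics summary statistics.

Covers natural-abundance correction of raw isotopologue intensity vectors
(non-negative least-squares deconvolution against the binomial correction
matrix), mass distribution vectors (MDV), fractional contribution
FC = (sum_i i*m_i)/n, type-wise fractional differences, and the targeted
lipidomics summaries (class totals, concentration-weighted unsaturation
index per acyl chain, chain-length profiles) with group tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

P_NAT_13C = 0.0107  # natural 13C abundance


# ---------------------------------------------------------------------------
# mass distribution vectors
# ---------------------------------------------------------------------------


def natural_abundance_matrix(n_carbons: int, p_nat: float = P_NAT_13C) -> np.ndarray:
    """(n+1)x(n+1) matrix C with C[j, i] = P(observe M+j | true M+i).

    Tracer-labeled positions are assumed fully 13C; the remaining
    ``n - i`` positions each carry a 13C with probability ``p_nat``,
    so observed = C @ true_mdv.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        C[i:, i] = stats.binom.pmf(np.arange(n - i + 1), n - i, p_nat)
    return C


def forward_natural_abundance(mdv: np.ndarray, p_nat: float = P_NAT_13C) -> np.ndarray:
    """Convolve a true MDV with the natural-abundance binomial."""
    mdv = np.asarray(mdv, dtype=float)
    return natural_abundance_matrix(len(mdv) - 1, p_nat) @ mdv


def natural_abundance_correction(
    raw: np.ndarray, n_carbons: int, p_nat: float = P_NAT_13C
) -> np.ndarray:
    """Correct a raw isotopologue vector for natural 13C abundance.

    Solves the non-negative least-squares deconvolution against the
    binomial correction matrix and renormalizes to unit sum. With
    ``p_nat = 0`` the correction reduces to normalization.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) != n_carbons + 1:
        raise ValueError(f"expected vector of length {n_carbons + 1}, got {len(raw)}")
    if (raw < 0).any():
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("raw vector is all zero")
    if p_nat == 0:
        return raw / total
    C = natural_abundance_matrix(n_carbons, p_nat)
    sol, _ = optimize.nnls(C, raw / total)
    s = sol.sum()
    if s == 0:
        raise ValueError("deconvolution collapsed to the zero vector")
    return sol / s


def fractional_contribution(mdv: np.ndarray) -> float:
    """FC = (sum_i i*m_i) / n: fraction of carbon derived from the tracer."""
    mdv = np.asarray(mdv, dtype=float)
    n = len(mdv) - 1
    if n == 0:
        raise ValueError("fractional contribution undefined for a single-entry MDV")
    return float(np.arange(n + 1) @ mdv / n)


def mixture_mdv(fc_star: float, n_carbons: int, enrichment: float = 0.99) -> np.ndarray:
    """True MDV of a two-population labeling mixture with FC exactly ``fc_star``.

    A labeled fraction f carries binomially distributed label with
    per-position enrichment e; the rest is unlabeled. FC = f*e, so
    f = fc_star / e. When ``fc_star`` exceeds ``e`` the whole population
    is labeled at enrichment ``fc_star`` instead (f = 1).
    """
    if not 0 <= fc_star <= 1:
        raise ValueError("fc_star must lie in [0, 1]")
    if fc_star >= enrichment:
        f, e = 1.0, fc_star
    else:
        f, e = fc_star / enrichment, enrichment
    mdv = f * stats.binom.pmf(np.arange(n_carbons + 1), n_carbons, e)
    mdv[0] += 1.0 - f
    return mdv


# ---------------------------------------------------------------------------
# MDV tables
# ---------------------------------------------------------------------------


def _intensity_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("I") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def correct_mdv_table(
    mdv_table: pd.DataFrame, p_nat: float = P_NAT_13C, correct: bool = True
) -> pd.DataFrame:
    """Add corrected fraction columns m0..mN to a long raw MDV table.

    Expects columns metabolite, n_carbons, tracer, cell_line, replicate,
    I0..Imax. Natural-abundance correction can be disabled with
    ``correct=False`` (plain normalization to unit sum).
    """
    icols = _intensity_columns(mdv_table)
    out = mdv_table.copy()
    max_n = len(icols) - 1
    mcols = [f"m{i}" for i in range(max_n + 1)]
    for c in mcols:
        out[c] = np.nan
    for idx, row in mdv_table.iterrows():
        n = int(row["n_carbons"])
        raw = row[icols[: n + 1]].to_numpy(dtype=float)
        mdv = natural_abundance_correction(raw, n, p_nat if correct else 0.0)
        out.loc[idx, mcols[: n + 1]] = mdv
    return out


@dataclass
class FCRecord:
    """Fractional contribution of one metabolite in one cell line."""

    metabolite: str
    tracer: str
    cell_line: str
    fc: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.fc <= 1 + 1e-9:
            raise ValueError("fractional contribution must lie in [0, 1]")


def fc_table(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per (metabolite, tracer, cell line) mean FC over replicates."""
    mcols = [c for c in corrected.columns if c.startswith("m") and c[1:].isdigit()]
    mcols = sorted(mcols, key=lambda c: int(c[1:]))
    recs = []
    for (_, row) in corrected.iterrows():
        n = int(row["n_carbons"])
        mdv = row[mcols[: n + 1]].to_numpy(dtype=float)
        recs.append(
            {
                "metabolite": row["metabolite"],
                "tracer": row["tracer"],
                "cell_line": row["cell_line"],
                "replicate": row["replicate"],
                "fc": fractional_contribution(mdv),
            }
        )
    df = pd.DataFrame.from_records(recs)
    return (
        df.groupby(["metabolite", "tracer", "cell_line"], as_index=False)["fc"].mean()
    )


def fractional_difference(
    fc: pd.DataFrame, type_labels: pd.Series
) -> pd.DataFrame:
    """Ranked type-1-minus-type-2 fractional differences per metabolite.

    ``fc`` has columns metabolite, tracer, cell_line, fc. Type means are
    taken over cell-line means so every line weighs equally. Metabolites
    missing in one type are excluded (listed in the ``excluded`` attr).
    Sorted descending by delta, ties broken by metabolite id.
    """
    fc = fc.copy()
    fc["type"] = fc["cell_line"].map(type_labels)
    rows, excluded = [], []
    for (met, tracer), grp in fc.groupby(["metabolite", "tracer"]):
        m1 = grp.loc[grp["type"] == 1, "fc"]
        m2 = grp.loc[grp["type"] == 2, "fc"]
        if len(m1) == 0 or len(m2) == 0:
            excluded.append((met, tracer))
            continue
        rows.append({"metabolite": met, "tracer": tracer,
                     "delta": float(m1.mean() - m2.mean()),
                     "mean_fc_type1": float(m1.mean()), "mean_fc_type2": float(m2.mean())})
    out = pd.DataFrame.from_records(rows)
    if len(out):
        out = out.sort_values(["delta", "metabolite"], ascending=[False, True]).reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# lipidomics summaries
# ---------------------------------------------------------------------------

# acyl-chain count per lipid class: lyso species carry one chain, diacyl
# glycerophospholipids and sphingolipids (long-chain base + N-acyl) two,
# triacylglycerols three, cardiolipins four
ACYL_CHAINS_PER_CLASS: dict[str, int] = {
    "HexCer": 2,
    "SM": 2,
    "CL": 4,
    "PC": 2,
    "LPC": 1,
    "ether PC": 2,
    "PE": 2,
    "LPE": 1,
    "PS": 2,
    "PG": 2,
    "TAG": 3,
}


def lipid_summaries(
    lipids: pd.DataFrame,
    groups: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Class totals, unsaturation index and chain-length profile per sample.

    ``lipids`` is long-format: species, class, carbons, double_bonds,
    ether (bool), sample, concentration. The unsaturation index is the
    concentration-weighted mean of double bonds per acyl chain (class
    chain counts per :data:`ACYL_CHAINS_PER_CLASS`), computed per class and
    overall. With ``groups`` (sample -> group label) two-sided pooled
    t-tests compare class totals between the two groups, and the
    per-species panel is BH-adjusted.
    """
    df = lipids.copy()
    if (df["concentration"] < 0).any():
        raise ValueError("concentrations must be non-negative")
    bad = df[df["double_bonds"] > df["carbons"]]
    if len(bad):
        raise ValueError("double bonds cannot exceed total acyl carbons")
    df["chains"] = df["class"].map(ACYL_CHAINS_PER_CLASS)
    if df["chains"].isna().any():
        unknown = sorted(df.loc[df["chains"].isna(), "class"].unique())
        raise ValueError(f"unknown lipid classes: {unknown}")
    df["db_per_chain"] = df["double_bonds"] / df["chains"]

    class_totals = df.pivot_table(
        index="sample", columns="class", values="concentration", aggfunc="sum"
    )  # absent class stays NaN (missing, not zero)

    def _ui(sub: pd.DataFrame) -> float:
        w = sub["concentration"].to_numpy()
        if w.sum() == 0:
            return np.nan
        return float(np.average(sub["db_per_chain"], weights=w))

    ui_class = (
        df.groupby(["sample", "class"]).apply(_ui, include_groups=False).unstack("class")
    )
    ui_overall = df.groupby("sample").apply(_ui, include_groups=False).rename("overall")
    unsaturation = ui_class.join(ui_overall)

    chain_profile = df.pivot_table(
        index="sample", columns="carbons", values="concentration", aggfunc="sum", fill_value=0.0
    )
    chain_profile = chain_profile.div(chain_profile.sum(axis=1), axis=0)

    out = {
        "class_totals": class_totals,
        "unsaturation": unsaturation,
        "chain_profile": chain_profile,
    }

    if groups is not None:
        g = groups.reindex(class_totals.index)
        levels = sorted(g.dropna().unique())
        if len(levels) != 2:
            raise ValueError("group tests need exactly two groups")
        a, b = (g == levels[0]), (g == levels[1])
        recs = []
        for cls in class_totals.columns:
            x = class_totals.loc[a, cls].dropna()
            y = class_totals.loc[b, cls].dropna()
            if len(x) < 2 or len(y) < 2:
                recs.append({"class": cls, "t": np.nan, "p": np.nan})
                continue
            if np.ptp(np.concatenate([x, y])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(x, y, equal_var=True)
            recs.append({"class": cls, "t": float(t), "p": float(p),
                         "mean_" + str(levels[0]): float(x.mean()),
                         "mean_" + str(levels[1]): float(y.mean())})
        out["class_tests"] = pd.DataFrame.from_records(recs)

        species_conc = df.pivot_table(
            index="sample", columns="species", values="concentration", aggfunc="sum"
        )
        sp = []
        for s in species_conc.columns:
            x = species_conc.loc[a, s].dropna()
            y = species_conc.loc[b, s].dropna()
            if len(x) < 2 or len(y) < 2:
                continue
            t, p = stats.ttest_ind(x, y, equal_var=True)
            sp.append({"species": s, "t": float(t), "p": float(p)})
        sp_df = pd.DataFrame.from_records(sp)
        if len(sp_df):
            sp_df["q"] = multipletests(sp_df["p"], method="fdr_bh")[1]
        out["species_tests"] = sp_df
    return out


__all__ = [
    "ACYL_CHAINS_PER_CLASS",
    "FCRecord",
    "P_NAT_13C",
    "correct_mdv_table",
    "fc_table",
    "forward_natural_abundance",
    "fractional_contribution",
    "fractional_difference",
    "lipid_summaries",
    "mixture_mdv",
    "natural_abundance_correction",
    "natural_abundance_matrix",
]
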