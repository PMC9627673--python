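"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate a multi-batch untargeted metabolomics screen of
cancer cell lines: metabolite ion levels driven monotonically by latent
pathway fluxes (power-law link, as expected when enzymes operate near
their Michaelis-Menten affinity), two planted metabolic types, seven
growth/measurement batches with two QC cell lines replicated in every
batch, multiplicative batch and injection-order drift artifacts,
per-sample size factors, trait tables with planted branch associations,
and binomial-mixture 13C isotopologue distributions convolved with
natural abundance.

Every generator is deterministic given its ``seed`` and returns the ground
truth alongside the data so downstream modules can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iontable import IonTable
from .isotope_tracing import forward_natural_abundance, mixture_mdv
from .pathway_scoring import Pathway, PathwayCollection, Reaction
from .quality_metrics import AMINO_ACID_FORMULAS


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class FluxPanelTruth:
    """Ground truth of the flux/metabolite validation panel."""

    condition_ids: list[str]
    pathway_ids: list[str]
    fluxes: pd.DataFrame  # condition x pathway, > 0
    ion_pathway: pd.Series  # ion id -> pathway id
    gamma: pd.Series  # ion id -> response exponent
    sigma: float  # log-scale noise sd

    def __post_init__(self) -> None:
        if (self.fluxes.to_numpy() <= 0).any():
            raise ValueError("fluxes must be positive")


@dataclass
class ScreenTruth:
    """Ground truth of the synthetic cell-line screen."""

    type_labels: pd.Series  # cell line -> {1, 2}
    batch_of_sample: pd.Series
    batch_effects: pd.DataFrame  # batch x ion multiplicative factors
    drift_factors: pd.DataFrame  # sample x ion multiplicative factors
    size_factors: pd.Series  # sample -> factor
    qc_lines: tuple[str, str]
    ion_pathway: pd.Series  # ion -> pathway id
    fluxes: pd.DataFrame  # cell line x pathway
    gamma: pd.Series
    biology: pd.DataFrame  # sample x ion, artifact-free expected level x noise


@dataclass
class TracerTruth:
    """Planted fractional contributions for a 13C labeling experiment."""

    carbon_counts: Mapping[str, int]  # metabolite -> n carbons
    fc: pd.DataFrame  # rows metabolite, columns (type, tracer) or type label
    cell_line_types: Mapping[str, int]  # cell line -> {1, 2}
    p_nat: float = 0.0107
    enrichment: float = 0.99

    def __post_init__(self) -> None:
        for met, n in self.carbon_counts.items():
            if n < 1:
                raise ValueError(f"carbon count of {met} must be >= 1")
        vals = self.fc.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("true fractional contributions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# flux / metabolite panel
# ---------------------------------------------------------------------------


def _synthetic_formula(i: int) -> str:
    """Unique, inert formula-like label for a synthetic ion."""
    return f"C{6 + i}H{8 + 2 * i}O{3 + i % 7}"


def generate_flux_metabolite_panel(
    n_conditions: int = 25,
    pathway_sizes: Sequence[int] = (8, 8, 8, 8, 8),
    seed: int = 0,
    sigma: float = 0.2,
    fluxes: np.ndarray | None = None,
    gammas: np.ndarray | None = None,
    negative_fraction: float = 0.15,
    n_replicates: int = 1,
) -> tuple[IonTable, FluxPanelTruth]:
    """Metabolite panel whose ion levels follow latent pathway fluxes.

    Each ion i belongs to exactly one pathway p(i) and its level in
    condition c is ``a_i * v[p(i), c] ** gamma_i * exp(eps)`` with
    ``eps ~ Normal(0, sigma^2)``. Exponents are drawn Uniform(0.3, 1.0)
    with a minority (``negative_fraction`` <= 20% per pathway) negated to
    emulate incoherent intermediates.

    Returns the table and the truth needed for score validation.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    for s in pathway_sizes:
        if s < 4:
            raise ValueError("each pathway needs >= 4 ions (downstream scoreability rule)")
    if not 0 <= negative_fraction <= 0.2:
        raise ValueError("negative_fraction must be in [0, 0.2]")
    rng = np.random.default_rng(seed)

    conditions = [f"cond{c:02d}" for c in range(n_conditions)]
    pathways = [f"PW{p + 1}" for p in range(len(pathway_sizes))]
    if fluxes is None:
        # diverse flux distributions across conditions, as a validation
        # panel needs: ~e^3 dynamic range
        flux = np.exp(rng.normal(0.0, 1.5, size=(n_conditions, len(pathways))))
    else:
        flux = np.asarray(fluxes, dtype=float)
        if flux.ndim == 1:
            flux = np.tile(flux[:, None], (1, len(pathways)))
        if flux.shape != (n_conditions, len(pathways)):
            raise ValueError("fluxes must have shape (n_conditions, n_pathways)")
    if (flux <= 0).any():
        raise ValueError("fluxes must be positive")
    flux_df = pd.DataFrame(flux, index=conditions, columns=pathways)

    ion_ids, ion_pw, gam = [], [], []
    for p, size in zip(pathways, pathway_sizes):
        g = rng.uniform(0.3, 1.0, size=size)
        n_neg = int(np.floor(negative_fraction * size))
        if n_neg:
            neg_idx = rng.choice(size, size=n_neg, replace=False)
            g[neg_idx] *= -1.0
        for j in range(size):
            ion_ids.append(f"{p}_ion{j:02d}")
            ion_pw.append(p)
        gam.extend(g.tolist())
    if gammas is not None:
        gam = list(np.asarray(gammas, dtype=float))
        if len(gam) != len(ion_ids):
            raise ValueError("gammas must have one entry per ion")
    gamma = pd.Series(gam, index=ion_ids)
    ion_pathway = pd.Series(ion_pw, index=ion_ids)

    base = np.exp(rng.normal(np.log(1e4), 0.5, size=len(ion_ids)))
    sample_ids, cond_of_sample, rep_of_sample = [], [], []
    for c in conditions:
        for r in range(n_replicates):
            sample_ids.append(f"{c}_r{r}" if n_replicates > 1 else c)
            cond_of_sample.append(c)
            rep_of_sample.append(r)

    v = flux_df.loc[cond_of_sample, ion_pathway.to_numpy()].to_numpy()
    level = base[None, :] * np.power(v, gamma.to_numpy()[None, :])
    noise = np.exp(rng.normal(0.0, sigma, size=level.shape)) if sigma > 0 else 1.0
    intens = level * noise

    samples = pd.DataFrame(
        {
            "cell_line": cond_of_sample,
            "batch": 1,
            "injection_order": np.arange(len(sample_ids), dtype=float) * 5.0,
            "confluency": 0.7,
            "is_qc": False,
            "replicate": rep_of_sample,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ions = pd.DataFrame(
        {
            "mz": 100.0 + np.arange(len(ion_ids)) * 1.0,
            "formulas": [_synthetic_formula(i) for i in range(len(ion_ids))],
        },
        index=pd.Index(ion_ids, name="ion_id"),
    )
    table = IonTable(pd.DataFrame(intens, index=samples.index, columns=ions.index), samples, ions)
    truth = FluxPanelTruth(conditions, pathways, flux_df, ion_pathway, gamma, sigma)
    return table, truth


def pathway_collection_from_truth(
    ion_pathway: pd.Series, ions: pd.DataFrame
) -> PathwayCollection:
    """Build pathway definitions matching a generated truth's ion->pathway map."""
    pws = []
    for pid in sorted(ion_pathway.unique()):
        members = ion_pathway.index[ion_pathway == pid]
        formulas = [str(ions.loc[i, "formulas"]).split(";")[0] for i in members]
        reactions = [
            Reaction(f"{pid}_r{k}", substrates=(formulas[k],), products=(formulas[(k + 1) % len(formulas)],))
            for k in range(len(formulas))
        ]
        pws.append(Pathway(pid, pid, "synthetic", reactions))
    return PathwayCollection(pws)


# ---------------------------------------------------------------------------
# cell-line screen
# ---------------------------------------------------------------------------


def generate_cell_line_screen(
    n_lines: int = 180,
    n_batches: int = 7,
    n_ions: int = 300,
    qc_replicates_per_batch: int = 6,
    seed: int = 0,
    n_replicates: int = 6,
    n_pathways: int = 10,
    type_effect: float = 1.0,
    sigma: float = 0.25,
    batch_effect_range: tuple[float, float] = (2.0, 3.0),
    batch_ion_sd: float = 0.5,
    batch_effects: np.ndarray | None = None,
    drift_amplitude: float = 2.0,
    size_factor_sd: float = 0.25,
    injection_spacing_min: float = 5.0,
) -> tuple[IonTable, ScreenTruth]:
    """Multi-batch screen with planted metabolic types and acquisition artifacts.

    The observed intensity is ``biology x batch_effect x drift x size_factor``
    where biology follows the same power-law flux link as
    :func:`generate_flux_metabolite_panel`, with pathway fluxes shifted
    between the two planted types by ``type_effect`` log-units in half of
    the pathways. Batch effects are per-batch, per-ion multiplicative
    factors whose batch-level magnitude falls in ``batch_effect_range``
    (set to ``(1.0, 1.0)`` with ``batch_ion_sd=0`` for an artifact-free
    screen). Drift is a smooth cubic of injection time with per-ion
    amplitude up to ``drift_amplitude`` fold. Two QC cell lines (``QC_A``,
    ``QC_B``) are measured ``qc_replicates_per_batch`` times in every batch.
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    if qc_replicates_per_batch < 1:
        raise ValueError("quality metrics are undefined without QC replicates; "
                         "qc_replicates_per_batch must be >= 1")
    rng = np.random.default_rng(seed)

    lines = [f"CL{i:03d}" for i in range(n_lines)]
    qc_lines = ("QC_A", "QC_B")
    # balanced type labels (within +-20% by construction: exact split)
    labels = np.ones(n_lines, dtype=int)
    labels[rng.permutation(n_lines)[: n_lines // 2]] = 2
    type_labels = pd.Series(labels, index=lines)
    qc_types = {"QC_A": 1, "QC_B": 2}

    pathways = [f"PW{p + 1}" for p in range(n_pathways)]
    ion_ids = [f"ion{i:04d}" for i in range(n_ions)]
    ion_pathway = pd.Series([pathways[i % n_pathways] for i in range(n_ions)], index=ion_ids)

    # type-differential fluxes in alternating half of pathways
    delta = np.zeros(n_pathways)
    delta[::2] = type_effect * np.resize([1.0, -1.0], len(delta[::2]))
    all_lines = lines + list(qc_lines)
    all_types = np.array([type_labels.get(l, qc_types.get(l)) for l in all_lines])
    centered = np.where(all_types == 1, 0.5, -0.5)
    flux = np.exp(
        centered[:, None] * delta[None, :] + rng.normal(0.0, 0.25, size=(len(all_lines), n_pathways))
    )
    flux_df = pd.DataFrame(flux, index=all_lines, columns=pathways)

    gamma = np.array(
        [g if rng.random() > 0.15 else -g for g in rng.uniform(0.3, 1.0, size=n_ions)]
    )
    gamma_s = pd.Series(gamma, index=ion_ids)
    base = np.exp(rng.normal(np.log(1e4), 0.6, size=n_ions))

    # batch assignment: non-QC lines split across batches; QC lines everywhere
    batch_of_line = {l: 1 + (i % n_batches) for i, l in enumerate(lines)}
    rows = []  # (sample_id, cell_line, batch, replicate)
    for b in range(1, n_batches + 1):
        for l in lines:
            if batch_of_line[l] == b:
                for r in range(n_replicates):
                    rows.append((f"{l}_b{b}_r{r}", l, b, r))
        for q in qc_lines:
            for r in range(qc_replicates_per_batch):
                rows.append((f"{q}_b{b}_r{r}", q, b, r))
    sample_ids = [r[0] for r in rows]
    line_of_sample = [r[1] for r in rows]
    batch_of_sample = pd.Series([r[2] for r in rows], index=sample_ids)
    rep_of_sample = [r[3] for r in rows]

    # injection order: sequential within the full run, batch blocks contiguous,
    # order shuffled within batch
    order = np.empty(len(rows), dtype=float)
    pos = 0
    for b in range(1, n_batches + 1):
        idx = [i for i, r in enumerate(rows) if r[2] == b]
        perm = rng.permutation(len(idx))
        for k, i in enumerate(np.array(idx)[perm]):
            order[i] = (pos + k) * injection_spacing_min
        pos += len(idx)
    injection_order = pd.Series(order, index=sample_ids)

    # biology
    v = flux_df.loc[line_of_sample, ion_pathway.to_numpy()].to_numpy()
    biology = base[None, :] * np.power(v, gamma[None, :])
    biology *= np.exp(rng.normal(0.0, sigma, size=biology.shape))
    biology_df = pd.DataFrame(biology, index=sample_ids, columns=ion_ids)

    # batch effects: per-batch mean magnitude in batch_effect_range, random
    # sign, per-ion jitter so sample-level scaling alone cannot remove them
    lo, hi = batch_effect_range
    if lo < 1 or hi < lo:
        raise ValueError("batch_effect_range must satisfy 1 <= lo <= hi")
    if batch_effects is not None:
        be = np.asarray(batch_effects, dtype=float)
        if be.ndim == 1:
            be = np.tile(be[:, None], (1, n_ions))
        if be.shape != (n_batches, n_ions):
            raise ValueError("batch_effects must have shape (n_batches,) or (n_batches, n_ions)")
        if (be <= 0).any():
            raise ValueError("batch effects must be > 0")
    else:
        be = np.empty((n_batches, n_ions))
        for b in range(n_batches):
            if hi == 1.0 and batch_ion_sd == 0.0:
                be[b] = 1.0
                continue
            mag = np.log(rng.uniform(lo, hi)) * rng.choice([-1.0, 1.0])
            be[b] = np.exp(rng.normal(mag, batch_ion_sd, size=n_ions))
    batch_effects = pd.DataFrame(be, index=range(1, n_batches + 1), columns=ion_ids)

    # smooth cubic drift of injection time, per-ion amplitude
    t = injection_order.to_numpy()
    tt = (t - t.min()) / max(t.max() - t.min(), 1.0)
    coeffs = rng.normal(0.0, 1.0, size=(n_ions, 3))
    shape = (
        coeffs[:, 0][None, :] * tt[:, None]
        + coeffs[:, 1][None, :] * tt[:, None] ** 2
        + coeffs[:, 2][None, :] * tt[:, None] ** 3
    )
    rngs = shape.max(axis=0) - shape.min(axis=0)
    rngs[rngs == 0] = 1.0
    shape = (shape - shape.mean(axis=0)) / rngs  # unit peak-to-peak, zero mean
    amp = np.log(rng.uniform(1.0, max(drift_amplitude, 1.0), size=n_ions))
    drift = np.exp(shape * amp[None, :])
    drift_df = pd.DataFrame(drift, index=sample_ids, columns=ion_ids)

    size_factors = pd.Series(
        np.exp(rng.normal(0.0, size_factor_sd, size=len(sample_ids))), index=sample_ids
    )

    intens = biology * be[batch_of_sample.to_numpy() - 1] * drift * size_factors.to_numpy()[:, None]

    confluency = rng.uniform(0.5, 0.8, size=len(sample_ids))
    samples = pd.DataFrame(
        {
            "cell_line": line_of_sample,
            "batch": batch_of_sample.to_numpy(),
            "injection_order": injection_order.to_numpy(),
            "confluency": confluency,
            "is_qc": [l in qc_lines for l in line_of_sample],
            "replicate": rep_of_sample,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # first ions carry proteinogenic amino-acid formulas so the amino-acid
    # reproducibility subset is non-empty; remaining ions get unique labels
    aa = list(dict.fromkeys(AMINO_ACID_FORMULAS.values()))
    formulas = [aa[i] if i < len(aa) else _synthetic_formula(i) for i in range(n_ions)]
    ions = pd.DataFrame(
        {"mz": 80.0 + np.arange(n_ions) * 0.7, "formulas": formulas},
        index=pd.Index(ion_ids, name="ion_id"),
    )
    table = IonTable(pd.DataFrame(intens, index=samples.index, columns=ions.index), samples, ions)
    truth = ScreenTruth(
        type_labels=type_labels,
        batch_of_sample=batch_of_sample,
        batch_effects=batch_effects,
        drift_factors=drift_df,
        size_factors=size_factors,
        qc_lines=qc_lines,
        ion_pathway=ion_pathway,
        fluxes=flux_df,
        gamma=gamma_s,
        biology=biology_df,
    )
    return table, truth


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Per-cell-line trait values, mixed categorical and continuous.

    ``continuous`` and ``categorical`` are cell-line x trait frames (NaN /
    None mark missing values); ``source`` tags each trait's origin.
    """

    continuous: pd.DataFrame
    categorical: pd.DataFrame
    source: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def trait_ids(self) -> list[str]:
        return list(self.continuous.columns) + list(self.categorical.columns)

    @property
    def n_traits(self) -> int:
        return self.continuous.shape[1] + self.categorical.shape[1]

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: trait_id, modality, cell_line, value, source."""
        parts = []
        for df, modality in ((self.continuous, "continuous"), (self.categorical, "categorical")):
            if df.shape[1] == 0:
                continue
            long = df.reset_index(names="cell_line").melt(
                id_vars="cell_line", var_name="trait_id", value_name="value"
            )
            long["modality"] = modality
            parts.append(long)
        out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["cell_line", "trait_id", "value", "modality"]
        )
        out["source"] = out["trait_id"].map(self.source).fillna("synthetic")
        return out[["trait_id", "modality", "cell_line", "value", "source"]]

    def write(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TraitTable":
        long = pd.read_csv(path, sep="\t")
        cont = long[long["modality"] == "continuous"].pivot(
            index="cell_line", columns="trait_id", values="value"
        ).astype(float)
        cat = long[long["modality"] == "categorical"].pivot(
            index="cell_line", columns="trait_id", values="value"
        )
        idx = cont.index.union(cat.index)
        src = long.drop_duplicates("trait_id").set_index("trait_id")["source"]
        return cls(cont.reindex(idx), cat.reindex(idx), src)


def generate_trait_table(
    type_labels: pd.Series,
    n_null_categorical: int = 50,
    n_null_continuous: int = 50,
    n_planted: int = 2,
    effect: float = 2.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> TraitTable:
    """Trait table with null traits and traits planted on the type labels.

    Planted continuous traits are mean-shifted by ``effect`` sd units in
    type 1; planted categorical traits have the "pos" level over-represented
    in type 1 with log-odds shift ``effect`` (``effect=np.inf`` makes the
    trait a deterministic copy of the type membership). Null traits are
    independent of the labels.
    """
    if n_planted > 0 and not effect > 0:
        raise ValueError("effect must be > 0 for planted traits")
    rng = np.random.default_rng(seed)
    lines = type_labels.index
    n = len(lines)
    is_type1 = (type_labels == 1).to_numpy()

    cont = {}
    cat = {}
    for j in range(n_null_continuous):
        cont[f"null_cont{j:04d}"] = rng.normal(0.0, 1.0, size=n)
    levels = np.array(["A", "B", "C"])
    for j in range(n_null_categorical):
        cat[f"null_cat{j:04d}"] = levels[rng.integers(0, 3, size=n)]
    for j in range(n_planted):
        if j % 2 == 0:
            base_logit = np.log(0.3 / 0.7)
            shift = base_logit + np.where(is_type1, effect, 0.0)
            p = 1.0 / (1.0 + np.exp(-shift))
            if np.isinf(effect):
                p = np.where(is_type1, 1.0, 0.0)
            vals = np.where(rng.random(n) < p, "pos", "neg")
            cat[f"planted_cat{j:04d}"] = vals
        else:
            cont[f"planted_cont{j:04d}"] = rng.normal(0.0, 1.0, size=n) + np.where(
                is_type1, effect, 0.0
            )
    cont_df = pd.DataFrame(cont, index=lines, dtype=float)
    cat_df = pd.DataFrame(cat, index=lines, dtype=object)
    if missing_rate > 0:
        cont_df = cont_df.mask(rng.random(cont_df.shape) < missing_rate)
        cat_df = cat_df.mask(rng.random(cat_df.shape) < missing_rate)
    source = pd.Series("synthetic", index=list(cont_df.columns) + list(cat_df.columns))
    return TraitTable(cont_df, cat_df, source)


# ---------------------------------------------------------------------------
# 13C isotopologue data
# ---------------------------------------------------------------------------


def default_tracer_truth(
    n_metabolites: int = 12,
    lines_per_type: int = 3,
    seed: int = 0,
    type_gap: float = 0.3,
) -> TracerTruth:
    """Tracer truth with metabolites whose labeling differs between types."""
    rng = np.random.default_rng(seed)
    mets = [f"met{m:02d}" for m in range(n_metabolites)]
    carbons = {m: int(rng.integers(3, 7)) for m in mets}
    base = rng.uniform(0.15, 0.6, size=n_metabolites)
    sign = np.resize([1.0, -1.0], n_metabolites)
    fc1 = np.clip(base + sign * type_gap / 2, 0.0, 0.99)
    fc2 = np.clip(base - sign * type_gap / 2, 0.0, 0.99)
    fc = pd.DataFrame({1: fc1, 2: fc2}, index=mets)
    cl = {f"T1_L{k}": 1 for k in range(lines_per_type)}
    cl.update({f"T2_L{k}": 2 for k in range(lines_per_type)})
    return TracerTruth(carbons, fc, cl)


def generate_mdv_set(
    truth: TracerTruth,
    n_replicates: int = 3,
    noise: float = 0.0,
    seed: int = 0,
    tracer: str = "glucose-U13C",
) -> pd.DataFrame:
    """Raw isotopologue intensity vectors from a binomial labeling mixture.

    Per metabolite the true mass distribution vector is a two-population
    mixture (labeled fraction with per-position enrichment 0.99, unlabeled
    fraction) whose fractional contribution equals the planted FC* exactly;
    it is convolved with the natural-abundance binomial (``p_nat``) and
    multiplied by log-normal noise of sd ``noise`` per isotopologue.

    Returns a long table with columns metabolite, n_carbons, tracer,
    cell_line, replicate, I0..Imax (NaN beyond each metabolite's carbon
    count). All intensities are non-negative.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    max_n = max(truth.carbon_counts.values())
    records = []
    for met, n in truth.carbon_counts.items():
        for line, typ in truth.cell_line_types.items():
            fc_star = float(truth.fc.loc[met, typ])
            true_mdv = mixture_mdv(fc_star, n, enrichment=truth.enrichment)
            observed = forward_natural_abundance(true_mdv, truth.p_nat)
            for r in range(n_replicates):
                scale = np.exp(rng.normal(np.log(1e5), 0.3)) if noise > 0 else 1e5
                vec = observed * scale
                if noise > 0:
                    vec = vec * np.exp(rng.normal(0.0, noise, size=n + 1))
                row = {
                    "metabolite": met,
                    "n_carbons": n,
                    "tracer": tracer,
                    "cell_line": line,
                    "replicate": r,
                }
                for i in range(max_n + 1):
                    row[f"I{i}"] = vec[i] if i <= n else np.nan
                records.append(row)
    return pd.DataFrame.from_records(records)


__all__ = [
    "AMINO_ACID_FORMULAS",
    "FluxPanelTruth",
    "ScreenTruth",
    "TracerTruth",
    "TraitTable",
    "default_tracer_truth",
    "generate_cell_line_screen",
    "generate_flux_metabolite_panel",
    "generate_mdv_set",
    "generate_trait_table",
    "pathway_collection_from_truth",
]
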