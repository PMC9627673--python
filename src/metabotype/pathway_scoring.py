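"""Pathway curation, ion mapping and PC1 pathway-activity scoring.

When the flux through a pathway changes, most of its intermediates shift
in a coherent direction (enzymes typically operate near their
Michaelis-Menten affinity, far from saturation), so the dominant shared
axis of variation of a pathway's member ions serves as a qualitative
proxy for pathway activity. That axis is extracted as the first
principal component of the log-transformed, per-ion standardized member
intensities; replicate scores are averaged per cell line, the component
sign is fixed (majority-positive loadings), and scores are scaled to
[-1, 1] for comparability across pathways.

Pathway definitions are curated before mapping: any reaction shared by
two or more pathways is deleted from all of them, together with its
substrates and products, yielding memberships more specific to a single
pathway. Only pathways with at least four mapped ions of unique m/z are
scoreable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_IONS_PER_PATHWAY = 4


# ---------------------------------------------------------------------------
# pathway definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]

    @property
    def metabolites(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)


@dataclass
class Pathway:
    id: str
    name: str
    pathway_class: str
    reactions: list[Reaction] = field(default_factory=list)
    extra_metabolites: frozenset[str] = frozenset()

    @property
    def metabolites(self) -> frozenset[str]:
        mets = set(self.extra_metabolites)
        for r in self.reactions:
            mets |= r.metabolites
        return frozenset(mets)


class PathwayCollection:
    """Ordered collection of pathways, addressable by id."""

    def __init__(self, pathways: Iterable[Pathway]):
        self.pathways: dict[str, Pathway] = {}
        for p in pathways:
            if p.id in self.pathways:
                raise ValueError(f"duplicate pathway id {p.id}")
            self.pathways[p.id] = p

    def __iter__(self):
        return iter(self.pathways.values())

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> Pathway:
        return self.pathways[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    # -- I/O: extended GMT (name <tab> class <tab> members) and reaction TSV
    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for p in self:
                members = "\t".join(sorted(p.metabolites))
                fh.write(f"{p.name}\t{p.pathway_class}\t{members}\n")

    @classmethod
    def read_gmt(cls, path) -> "PathwayCollection":
        pws = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, pclass, members = parts[0], parts[1], parts[2:]
                pws.append(Pathway(name, name, pclass, [], frozenset(m for m in members if m)))
        return cls(pws)

    @classmethod
    def read_reactions_tsv(cls, path) -> "PathwayCollection":
        """reaction_id, pathway_id, substrates (;-sep), products (;-sep)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        pws: dict[str, list[Reaction]] = {}
        for _, row in df.iterrows():
            rxn = Reaction(
                row["reaction_id"],
                tuple(s for s in str(row["substrates"]).split(";") if s),
                tuple(s for s in str(row["products"]).split(";") if s),
            )
            pws.setdefault(row["pathway_id"], []).append(rxn)
        return cls(Pathway(pid, pid, "unknown", rxns) for pid, rxns in pws.items())


def curate_pathways(collection: PathwayCollection) -> PathwayCollection:
    """Remove reactions shared by >= 2 pathways, with their metabolites.

    A metabolite attached to a removed reaction is retained in a pathway
    only if some surviving reaction of that pathway still touches it.
    Pathways left without metabolites are dropped.
    """
    counts: dict[str, int] = {}
    for p in collection:
        for r in p.reactions:
            counts[r.id] = counts.get(r.id, 0) + 1
    curated = []
    for p in collection:
        keep = [r for r in p.reactions if counts[r.id] == 1]
        new = Pathway(p.id, p.name, p.pathway_class, keep, p.extra_metabolites)
        if new.metabolites:
            curated.append(new)
    return PathwayCollection(curated)


# ---------------------------------------------------------------------------
# ion -> pathway mapping
# ---------------------------------------------------------------------------


@dataclass
class IonPathwayMap:
    """Formula-level ion-to-pathway assignment.

    ``ion_hits`` maps ion id to the set of (metabolite formula, pathway id)
    pairs it matches; structural isomers are all retained, so one ion may
    feed several pathways. A pathway is scoreable iff it has at least
    :data:`MIN_IONS_PER_PATHWAY` mapped ions with distinct m/z.
    """

    ion_hits: dict[str, set[tuple[str, str]]]
    pathway_ions: dict[str, list[str]]
    scoreable: dict[str, bool]

    def scoreable_pathways(self) -> list[str]:
        return [p for p, ok in self.scoreable.items() if ok]


def map_ions_to_pathways(ions: pd.DataFrame, collection: PathwayCollection) -> IonPathwayMap:
    """Match ion candidate formulas to curated pathway memberships."""
    formula_to_pathways: dict[str, set[str]] = {}
    for p in collection:
        for m in p.metabolites:
            formula_to_pathways.setdefault(m, set()).add(p.id)

    ion_hits: dict[str, set[tuple[str, str]]] = {}
    pathway_ions: dict[str, list[str]] = {p.id: [] for p in collection}
    for ion_id, row in ions.iterrows():
        hits = set()
        for f in str(row["formulas"]).split(";"):
            for pid in formula_to_pathways.get(f, ()):
                hits.add((f, pid))
        if hits:
            ion_hits[str(ion_id)] = hits
            for pid in {pid for _, pid in hits}:
                pathway_ions[pid].append(str(ion_id))

    scoreable = {}
    for pid, members in pathway_ions.items():
        n_unique_mz = ions.loc[members, "mz"].nunique() if members else 0
        scoreable[pid] = n_unique_mz >= MIN_IONS_PER_PATHWAY
    return IonPathwayMap(ion_hits, pathway_ions, scoreable)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass
class PathwayScoreMatrix:
    """Cell line x pathway activity scores in [-1, 1] plus PCA diagnostics."""

    scores: pd.DataFrame  # cell line x pathway
    loadings: dict[str, pd.Series]
    explained_variance: dict[str, float]
    orientation: dict[str, int]

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if np.nanmax(np.abs(vals)) > 1 + 1e-9:
            raise ValueError("scores must lie in [-1, 1]")

    def write(self, scores_path, loadings_path=None) -> None:
        self.scores.to_csv(scores_path, sep="\t", index_label="cell_line")
        if loadings_path is not None:
            payload = {
                p: {
                    "loadings": self.loadings[p].to_dict(),
                    "explained_variance": self.explained_variance[p],
                    "orientation": self.orientation[p],
                }
                for p in self.scores.columns
            }
            Path(loadings_path).write_text(json.dumps(payload, indent=1))


def _pc1(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a samples x ions standardized matrix."""
    u, s, vt = np.linalg.svd(z - z.mean(axis=0, keepdims=True), full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    var = s**2
    explained = float(var[0] / var.sum()) if var.sum() > 0 else 0.0
    return scores, loadings, explained


def pathway_score(
    table, ion_map: IonPathwayMap, log_transform: bool = True
) -> PathwayScoreMatrix:
    """PC1 pathway-activity scores per cell line.

    Member-ion intensities are log-transformed and z-scored per ion across
    all replicate-level samples, PCA is fitted jointly on replicates, the
    component is oriented so the sum of its loadings is positive (tie:
    positive correlation of scores with the mean member-ion level),
    replicate scores are averaged per cell line, and each pathway's
    cell-line scores are divided by their max absolute value.
    """
    intens = table.intensities
    cell_lines = table.samples["cell_line"]
    scores_by_pathway = {}
    loadings, explained, orientation = {}, {}, {}
    for pid in ion_map.scoreable_pathways():
        members = ion_map.pathway_ions[pid]
        x = intens[members].to_numpy(dtype=float)
        if log_transform:
            if (x <= 0).any():
                x = np.where(x <= 0, np.nan, x)
                mins = np.nanmin(x, axis=0)
                x = np.where(np.isnan(x), mins / 2, x)
            x = np.log(x)
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        if keep.sum() < 2:
            warnings.warn(f"pathway {pid} dropped: fewer than 2 variable ions")
            continue
        z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        pc_scores, pc_load, ev = _pc1(z)
        if pc_load.sum() > 0:
            sign = 1
        elif pc_load.sum() < 0:
            sign = -1
        else:  # tie: orient with the mean member-ion level
            r = np.corrcoef(pc_scores, z.mean(axis=1))[0, 1]
            sign = 1 if r >= 0 else -1
        pc_scores = sign * pc_scores
        pc_load = sign * pc_load
        per_line = pd.Series(pc_scores, index=intens.index).groupby(cell_lines).mean()
        m = per_line.abs().max()
        if m == 0:
            warnings.warn(f"pathway {pid} dropped: zero-variance scores")
            continue
        scores_by_pathway[pid] = per_line / m
        loadings[pid] = pd.Series(pc_load, index=np.array(members)[keep])
        explained[pid] = ev
        orientation[pid] = sign
    if not scores_by_pathway:
        raise ValueError("no scoreable pathway produced a score")
    scores = pd.DataFrame(scores_by_pathway).sort_index()
    return PathwayScoreMatrix(scores, loadings, explained, orientation)


def validate_against_flux(scores: PathwayScoreMatrix, truth) -> pd.DataFrame:
    """Pearson correlation of pathway scores against planted fluxes.

    ``truth`` is a :class:`~metabotype.synthetic_data.FluxPanelTruth`.
    Reports r, its sign and whether the pathway's ion response was
    majority-negative (sign-indeterminate direction).
    """
    if len(truth.condition_ids) < 3:
        raise ValueError("need at least 3 conditions to correlate")
    recs = []
    for pid in scores.scores.columns:
        if pid not in truth.fluxes.columns:
            continue
        common = scores.scores.index.intersection(truth.fluxes.index)
        s = scores.scores.loc[common, pid]
        f = truth.fluxes.loc[common, pid]
        r, _ = stats.pearsonr(s, np.log(f))
        gam = truth.gamma[truth.ion_pathway == pid]
        recs.append(
            {
                "pathway": pid,
                "r": float(r),
                "sign": int(np.sign(r)) if r != 0 else 0,
                "majority_negative_response": bool((gam < 0).mean() > 0.5),
            }
        )
    return pd.DataFrame.from_records(recs).set_index("pathway")


__all__ = [
    "IonPathwayMap",
    "MIN_IONS_PER_PATHWAY",
    "Pathway",
    "PathwayCollection",
    "PathwayScoreMatrix",
    "Reaction",
    "curate_pathways",
    "map_ions_to_pathways",
    "pathway_score",
    "validate_against_flux",
]
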