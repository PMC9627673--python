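"""End-to-end orchestration with provenance and reproducible seeds.

Two entry points: :func:`run_screen_pipeline` (simulate or ingest a
screen, TIC-filter, normalize, score pathways, cluster, run the branch
association scan) and :func:`run_tracing_pipeline` (natural-abundance
correction, fractional contributions, type-wise fractional differences,
tail enrichment). Every stage writes its artifact plus a provenance
JSON (stage, parameters, input hashes, seed); deterministic stages are
byte-identical on re-run with the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import normalization
from .iontable import IonTable
from .isotope_tracing import correct_mdv_table, fc_table, fractional_difference
from .enrichment_dependency import read_gmt_sets, tail_enrichment
from .pathway_scoring import (
    PathwayCollection,
    curate_pathways,
    map_ions_to_pathways,
    pathway_score,
)
from .synthetic_data import (
    TraitTable,
    generate_cell_line_screen,
    generate_trait_table,
    pathway_collection_from_truth,
)
from .typing_association import association_scan, cluster_cell_lines


@dataclass
class RunConfig:
    """Configuration of a full screen or tracing run."""

    out_dir: str
    seed: int = 0
    # screen inputs: either simulate=True or a directory with screen TSVs
    simulate: bool = True
    screen_dir: str | None = None
    screen_params: dict[str, Any] = field(default_factory=dict)
    stack: list[dict[str, Any]] = field(default_factory=lambda: [
        {"class": "sample_variance", "method": "quantile"},
        {"class": "batch_effect", "method": "combat"},
    ])
    tic_k: float = 4.0
    pathways_gmt: str | None = None
    reactions_tsv: str | None = None
    traits_tsv: str | None = None
    trait_params: dict[str, Any] = field(default_factory=dict)
    min_fraction: float = 0.10
    fdr: float = 0.10
    # tracing inputs
    mdv_csv: str | None = None
    labels_tsv: str | None = None
    sets_gmt: str | None = None
    p_nat: float = 0.0107
    tail_fraction: float = 0.25

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        for attr in ("screen_dir", "pathways_gmt", "reactions_tsv", "traits_tsv",
                     "mdv_csv", "labels_tsv", "sets_gmt"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, seed: int):
        self.out_dir = out_dir
        self.seed = seed
        self.stages: list[dict[str, Any]] = []

    def record(self, stage: str, params: dict, outputs: list[Path], inputs: list[Path] = ()):
        self.stages.append(
            {
                "stage": stage,
                "parameters": params,
                "seed": self.seed,
                "inputs": {str(p): _sha256(Path(p)) for p in inputs},
                "outputs": [str(p) for p in outputs],
            }
        )
        (self.out_dir / "provenance.json").write_text(json.dumps(self.stages, indent=1))


def run_screen_pipeline(config: RunConfig) -> dict[str, Any]:
    """simulate/ingest -> TIC filter -> normalize -> score -> cluster -> scan."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.seed)

    # stage: input
    truth = None
    if config.simulate:
        table, truth = generate_cell_line_screen(seed=config.seed, **config.screen_params)
        table.write(out, "raw")
        manifest.record("simulate_screen", config.screen_params,
                        [out / "raw_intensities.tsv"])
    else:
        if config.screen_dir is None:
            raise ValueError("screen_dir required when simulate is false")
        table = IonTable.read(config.screen_dir, "screen")
        manifest.record("ingest", {"screen_dir": config.screen_dir}, [])

    # stage: TIC QC
    table, removed = normalization.filter_abnormal_tic(table, k=config.tic_k)
    manifest.record("filter_abnormal_tic", {"k": config.tic_k, "removed": removed}, [])

    # stage: normalization
    stack = normalization.NormalizationStack(config.stack)
    table = normalization.apply_stack(table, stack)
    table.write(out, "normalized")
    manifest.record("normalize", {"stack": config.stack},
                    [out / "normalized_intensities.tsv"])

    # stage: pathway scoring
    if config.pathways_gmt is not None:
        collection = PathwayCollection.read_gmt(config.pathways_gmt)
    elif config.reactions_tsv is not None:
        collection = PathwayCollection.read_reactions_tsv(config.reactions_tsv)
    elif truth is not None:
        collection = pathway_collection_from_truth(truth.ion_pathway, table.ions)
    else:
        raise ValueError("no pathway definitions available")
    collection = curate_pathways(collection)
    ion_map = map_ions_to_pathways(table.ions, collection)
    # score on non-QC biological samples
    bio = table.subset_samples(table.samples.index[~table.samples["is_qc"]])
    scores = pathway_score(bio, ion_map)
    scores.write(out / "pathway_scores.tsv", out / "pathway_loadings.json")
    manifest.record("pathway_score", {"n_pathways": scores.scores.shape[1]},
                    [out / "pathway_scores.tsv"])

    # stage: clustering
    tree = cluster_cell_lines(scores)
    (out / "tree.nwk").write_text(tree.to_newick())
    types = tree.major_types()
    types.rename("type").to_csv(out / "types.tsv", sep="\t", index_label="cell_line")
    manifest.record("cluster", {}, [out / "tree.nwk", out / "types.tsv"])

    # stage: association scan
    if config.traits_tsv is not None:
        traits = TraitTable.read(config.traits_tsv)
    else:
        traits = generate_trait_table(types, seed=config.seed, **config.trait_params)
    scan = association_scan(tree, traits, fdr=config.fdr, min_fraction=config.min_fraction)
    scan.to_frame().to_csv(out / "associations.tsv", sep="\t", index=False)
    (out / "associations.json").write_text(json.dumps(
        {"pi0": scan.pi0, "fdr": scan.fdr,
         "n_records": len(scan.records),
         "n_significant": len(scan.significant_records()),
         "skipped": scan.skipped}, indent=1))
    manifest.record("association_scan",
                    {"fdr": config.fdr, "min_fraction": config.min_fraction},
                    [out / "associations.tsv"])

    return {
        "table": table,
        "scores": scores,
        "tree": tree,
        "types": types,
        "scan": scan,
        "manifest": manifest.stages,
    }


def run_tracing_pipeline(config: RunConfig) -> dict[str, Any]:
    """correction -> FC -> fractional differences -> tail enrichment."""
    if config.mdv_csv is None or config.labels_tsv is None:
        raise ValueError("tracing pipeline needs mdv_csv and labels_tsv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.seed)

    mdv = pd.read_csv(config.mdv_csv)
    labels = pd.read_csv(config.labels_tsv, sep="\t", index_col="cell_line")["type"]
    corrected = correct_mdv_table(mdv, p_nat=config.p_nat)
    corrected.to_csv(out / "mdv_corrected.csv", index=False)
    manifest.record("natural_abundance_correction", {"p_nat": config.p_nat},
                    [out / "mdv_corrected.csv"], [Path(config.mdv_csv)])

    fc = fc_table(corrected)
    fc.to_csv(out / "fractional_contributions.tsv", sep="\t", index=False)
    manifest.record("fractional_contribution", {}, [out / "fractional_contributions.tsv"])

    results = {"fc": fc, "manifest": manifest.stages}
    # stratify per tracer, never pooled
    deltas = {}
    enrich = {}
    for tracer, sub in fc.groupby("tracer"):
        delta = fractional_difference(sub, labels)
        delta.to_csv(out / f"fractional_difference_{tracer}.tsv", sep="\t", index=False)
        deltas[tracer] = delta
        if config.sets_gmt is not None and len(delta):
            sets = read_gmt_sets(config.sets_gmt)
            ranked = delta.set_index("metabolite")["delta"]
            res = tail_enrichment(ranked, sets, tail_fraction=config.tail_fraction)
            res.to_csv(out / f"tail_enrichment_{tracer}.tsv", sep="\t", index=False)
            enrich[tracer] = res
    manifest.record("fractional_difference", {"tracers": sorted(deltas)}, [])
    results["deltas"] = deltas
    results["enrichment"] = enrich
    return results


__all__ = ["RunConfig", "run_screen_pipeline", "run_tracing_pipeline"]
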