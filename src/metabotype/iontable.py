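"""Sample x ion intensity container for flow-injection metabolomics screens.

An :class:`IonTable` bundles the intensity matrix with the two metadata
tables the downstream analysis needs: per-sample acquisition metadata
(cell line, growth/measurement batch, injection time, confluency, QC flag,
replicate index) and per-ion annotation (m/z, candidate molecular formulas).
All normalizers and quality metrics operate on this container and preserve
its shape and identities.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["cell_line", "batch", "injection_order", "confluency", "is_qc", "replicate"]
ION_COLUMNS = ["mz", "formulas"]


@dataclass
class IonTable:
    """Intensity matrix (samples x ions) plus sample and ion metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with one column per ion id.
        Values are non-negative intensities in arbitrary units; zero is
        allowed only as a missing-value sentinel prior to QC filtering.
    samples
        DataFrame indexed by sample id. Expected columns: ``cell_line``,
        ``batch``, ``injection_order`` (minutes), ``confluency`` (fraction,
        may be NaN), ``is_qc`` (bool), ``replicate`` (int).
    ions
        DataFrame indexed by ion id. Expected columns: ``mz`` (Da) and
        ``formulas`` (semicolon-separated candidate formulas).
    provenance
        Ordered record of processing steps already applied.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    ions: pd.DataFrame
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not self.intensities.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.intensities.columns.is_unique:
            raise ValueError("ion ids must be unique")
        if not self.intensities.index.equals(self.samples.index):
            raise ValueError("intensity rows and sample metadata are out of sync")
        if not self.intensities.columns.equals(self.ions.index):
            raise ValueError("intensity columns and ion metadata are out of sync")
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if (vals < 0).any():
            raise ValueError("intensities must be non-negative")
        if "batch" not in self.samples.columns or self.samples["batch"].isna().any():
            raise ValueError("every sample needs a batch assignment")

    # -- conveniences ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ions(self) -> int:
        return self.intensities.shape[1]

    @property
    def batches(self) -> list:
        return sorted(self.samples["batch"].unique().tolist())

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def copy(self) -> "IonTable":
        return IonTable(
            self.intensities.copy(),
            self.samples.copy(),
            self.ions.copy(),
            _copy.deepcopy(self.provenance),
        )

    def with_values(self, values: np.ndarray, step: dict[str, Any] | None = None) -> "IonTable":
        """Return a new table with replaced intensities and appended provenance."""
        new = pd.DataFrame(values, index=self.intensities.index, columns=self.intensities.columns)
        prov = _copy.deepcopy(self.provenance)
        if step is not None:
            prov.append(step)
        return IonTable(new, self.samples.copy(), self.ions.copy(), prov)

    def subset_samples(self, sample_ids) -> "IonTable":
        idx = pd.Index(sample_ids)
        return IonTable(
            self.intensities.loc[idx],
            self.samples.loc[idx],
            self.ions.copy(),
            _copy.deepcopy(self.provenance),
        )

    def samples_of_line(self, cell_line: str) -> pd.Index:
        return self.samples.index[self.samples["cell_line"] == cell_line]

    # -- I/O ------------------------------------------------------------
    def write(self, directory: str | Path, prefix: str = "screen") -> None:
        """Write intensity + metadata TSVs (``<prefix>_intensities.tsv`` etc.)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.intensities.to_csv(directory / f"{prefix}_intensities.tsv", sep="\t", index_label="sample_id")
        self.samples.to_csv(directory / f"{prefix}_samples.tsv", sep="\t", index_label="sample_id")
        self.ions.to_csv(directory / f"{prefix}_ions.tsv", sep="\t", index_label="ion_id")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "screen") -> "IonTable":
        directory = Path(directory)
        intens = pd.read_csv(directory / f"{prefix}_intensities.tsv", sep="\t", index_col="sample_id")
        samples = pd.read_csv(directory / f"{prefix}_samples.tsv", sep="\t", index_col="sample_id")
        ions = pd.read_csv(directory / f"{prefix}_ions.tsv", sep="\t", index_col="ion_id")
        if "is_qc" in samples.columns:
            samples["is_qc"] = samples["is_qc"].astype(bool)
        ions.index = ions.index.astype(str)
        intens.columns = intens.columns.astype(str)
        return cls(intens, samples, ions)
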