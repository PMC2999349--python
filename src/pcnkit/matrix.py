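"""Expression-matrix container and tab-separated text I/O.

The :class:`ExpressionMatrix` carries probe-by-sample fluorescence
intensities together with per-entry present/absent detection flags and a
per-sample dose-group label.  A ``scale_state`` field records where the
matrix sits in the preprocessing chain so that stages can refuse
out-of-order application.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed scale states, in the order the preprocessing chain produces them.
SCALE_STATES = ("raw", "floored", "chip_normalized", "gene_normalized", "log2")

PRESENT = "P"
ABSENT = "A"


@dataclass
class ExpressionMatrix:
    """Probe × sample intensities with flags and dose-group labels.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Rows are probes, columns are samples.  Strictly positive until the
        log2 stage.
    flags : pandas.DataFrame
        Same shape/labels as ``intensities``; values ``"P"`` (present) or
        ``"A"`` (absent).
    dose_group : pandas.Series
        One label per sample (index = sample ids), e.g. ``"control"``,
        ``"49.8"``.
    scale_state : str
        One of :data:`SCALE_STATES`.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    dose_group: pd.Series
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        if not self.intensities.index.equals(self.flags.index) or not (
            self.intensities.columns.equals(self.flags.columns)
        ):
            raise ValueError("flags and intensities must share probe/sample labels")
        if not set(self.intensities.columns) == set(self.dose_group.index):
            raise ValueError("dose_group index must match sample ids")
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    # -- convenience ------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_probes(self) -> int:
        return len(self.intensities.index)

    @property
    def n_samples(self) -> int:
        return len(self.intensities.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.dose_group.index[self.dose_group == group])

    def with_intensities(self, values: pd.DataFrame, scale_state: str) -> "ExpressionMatrix":
        """Return a copy with new intensity values and scale state."""
        return ExpressionMatrix(
            intensities=values,
            flags=self.flags.copy(),
            dose_group=self.dose_group.copy(),
            scale_state=scale_state,
        )

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=self.intensities.loc[probes].copy(),
            flags=self.flags.loc[probes].copy(),
            dose_group=self.dose_group.copy(),
            scale_state=self.scale_state,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            intensities=self.intensities[samples].copy(),
            flags=self.flags[samples].copy(),
            dose_group=self.dose_group.loc[samples].copy(),
            scale_state=self.scale_state,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=self.intensities.copy(),
            flags=self.flags.copy(),
            dose_group=self.dose_group.copy(),
            scale_state=self.scale_state,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.scale_state == other.scale_state
            and self.intensities.equals(other.intensities)
            and self.flags.equals(other.flags)
            and self.dose_group.equals(other.dose_group)
        )


def write_expression(m: ExpressionMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write intensities, flags and sample sheet as tab-separated text.

    Produces ``<prefix>.expr.tsv`` (first column probe id, one column per
    sample), ``<prefix>.flags.tsv`` (identical layout, P/A values) and
    ``<prefix>.samples.tsv`` (sample id, dose group).
    """
    prefix = Path(prefix)
    paths = {
        "expr": prefix.with_suffix(".expr.tsv"),
        "flags": prefix.with_suffix(".flags.tsv"),
        "samples": prefix.with_suffix(".samples.tsv"),
    }
    m.intensities.to_csv(paths["expr"], sep="\t", index_label="probe_id")
    m.flags.to_csv(paths["flags"], sep="\t", index_label="probe_id")
    sheet = pd.DataFrame({"sample_id": m.dose_group.index, "dose_group": m.dose_group.values})
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    return paths


def read_expression(
    expr_path: str | Path,
    flags_path: str | Path,
    samples_path: str | Path,
    scale_state: str = "raw",
) -> ExpressionMatrix:
    """Read the three-file tab-separated expression format."""
    intens = pd.read_csv(expr_path, sep="\t", index_col="probe_id")
    flags = pd.read_csv(flags_path, sep="\t", index_col="probe_id")
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    dose_group = pd.Series(
        sheet["dose_group"].values, index=pd.Index(sheet["sample_id"], name="sample_id")
    )
    return ExpressionMatrix(intens, flags, dose_group, scale_state=scale_state)
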