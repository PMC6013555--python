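"""Tab-separated input/output for expression matrices, sample sheets and probe maps.

All on-disk formats are plain TSV so that runs diff cleanly:

* expression matrix — first column ``probe_id``, remaining columns array ids,
  linear-scale intensities;
* sample sheet — columns ``array_id``, ``genotype``, ``region``, ``age_months``;
* probe map — two columns ``probe_id``, ``gene_symbol``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

SAMPLE_SHEET_COLUMNS = ("array_id", "genotype", "region", "age_months")

# Fixed float format for all written TSVs so identical runs are byte-identical.
FLOAT_FORMAT = "%.10g"


@dataclass
class ExpressionMatrix:
    """Probe-level intensities plus the sample sheet describing each array.

    ``values`` is a probes x arrays DataFrame of linear-scale intensities with
    the probe id as index; ``samples`` is indexed by array id with columns
    ``genotype``, ``region`` and ``age_months``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"arrays absent from sample sheet: {missing}")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def arrays_for(self, genotype: str, region: str, age_months: int) -> list[str]:
        """Array ids of one (genotype, region, age) group, in sheet order."""
        s = self.samples
        mask = (
            (s["genotype"] == genotype)
            & (s["region"] == region)
            & (s["age_months"] == age_months)
        )
        return list(s.index[mask])

    def write(self, expression_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(
            expression_path, sep="\t", index_label="probe_id", float_format=FLOAT_FORMAT
        )
        self.samples.to_csv(samples_path, sep="\t", index_label="array_id")

    @classmethod
    def read(cls, expression_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expression_path, sep="\t", index_col="probe_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="array_id")
        return cls(values=values, samples=samples)


def write_probe_map(probe_map: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        {"probe_id": list(probe_map.keys()), "gene_symbol": list(probe_map.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["probe_id", "gene_symbol"]:
        raise ValueError(
            f"probe map {path} must have columns probe_id, gene_symbol; got {list(df.columns)}"
        )
    return dict(zip(df["probe_id"], df["gene_symbol"]))
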