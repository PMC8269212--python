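"""Bundled benchmark fixtures and static pathway definitions."""

from __future__ import annotations

import json
import warnings
from importlib import resources

import pandas as pd

#: Cells sorted per experiment replicate in the mock-community benchmark:
#: 20 by morphology, 11 by C-D band, 11 by carotenoid band, each in triplicate.
SORTED_COUNTS = {
    "A-1": 20, "A-2": 20, "A-3": 20,
    "B-1": 11, "B-2": 11, "B-3": 11,
    "C-1": 11, "C-2": 11, "C-3": 11,
}

#: Reference labels of the four mock-community members.
MOCK_REFERENCES = ("Hp", "Se", "Sc", "Ec")


def _path(name: str):
    return resources.files(__name__).joinpath(name)


def mock_benchmark_table() -> pd.DataFrame:
    """Per-cell QC rows of the four-species mock-community benchmark."""
    with resources.as_file(_path("mock_benchmark_qc.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def mock_benchmark_records():
    """The mock benchmark as :class:`~ramansort.seqqc.CellSeqRecord` objects."""
    df = mock_benchmark_table()
    with warnings.catch_warnings():
        # a handful of published rows sum outside [99, 101]; known and accepted
        warnings.filterwarnings("ignore", message=".*rounding slack.*")
        records = _build_records(df)
    return records


def _build_records(df):
    from ramansort.seqqc import CellSeqRecord

    records = []
    for row in df.itertuples(index=False):
        is_nc = row.is_negative_control == "yes"
        records.append(
            CellSeqRecord(
                sample_id=row.sample_id,
                experiment_id=row.experiment_id,
                mapped_pct={ref: float(getattr(row, f"mapped_{ref}")) for ref in MOCK_REFERENCES},
                hit_no_genomes_pct=float(row.hit_no_genomes_pct),
                taxonomy_bin=None if is_nc else str(row.taxonomy_bin),
                completeness_pct=None if pd.isna(row.completeness_pct) else float(row.completeness_pct),
                contaminant_bins_pct_bound=None
                if pd.isna(row.contaminant_bound_pct)
                else float(row.contaminant_bound_pct),
                is_negative_control=is_nc,
                consistent_with_sort=row.consistent_with_sort == "yes",
            )
        )
    return records


def soil_cell_table() -> pd.DataFrame:
    """Marker-gene completeness / GC of genomes from sorted soil cells."""
    with resources.as_file(_path("soil_cell_qc.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def success_counts() -> dict[str, dict[str, int]]:
    """Validated-cell and sorted-cell counts for the benchmark experiments."""
    return json.loads(_path("success_counts.json").read_text())
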