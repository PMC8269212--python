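"""Plain-text I/O: spectra TSVs with JSON sidecars, FASTA, QC tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqqc import CellSeqRecord
from .spectra import ProcessingState, RamanSpectrum
from .synthetic import SyntheticTruth

SPECTRUM_HEADER = ("wavenumber_cm1", "intensity")


def write_spectrum_tsv(
    path: str | Path,
    spectrum: RamanSpectrum,
    truth: SyntheticTruth | None = None,
) -> Path:
    """Write one spectrum as a two-column TSV plus a JSON sidecar.

    The sidecar (<name>.json) records the processing state and, when given,
    the synthetic ground truth.
    """
    path = Path(path)
    df = pd.DataFrame(
        {SPECTRUM_HEADER[0]: spectrum.wavenumbers, SPECTRUM_HEADER[1]: spectrum.intensities}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {"processing_state": spectrum.state.name.lower()}
    if truth is not None:
        sidecar["truth"] = dataclasses.asdict(truth)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_spectrum_tsv(path: str | Path) -> tuple[RamanSpectrum, SyntheticTruth | None]:
    """Read a spectrum TSV and its JSON sidecar (if present)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ValueError(f"{path}: unreadable spectrum TSV ({exc})") from exc
    missing = [c for c in SPECTRUM_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: line 1: missing column(s) {missing}")
    bad = df[df[list(SPECTRUM_HEADER)].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: line {int(bad.index[0]) + 2}: malformed row")
    state = ProcessingState.RAW
    truth = None
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        state = ProcessingState[sidecar.get("processing_state", "raw").upper()]
        if "truth" in sidecar:
            t = sidecar["truth"]
            t["baseline_params"] = tuple(t.get("baseline_params", ()))
            truth = SyntheticTruth(**t)
    spectrum = RamanSpectrum(
        df[SPECTRUM_HEADER[0]].to_numpy(), df[SPECTRUM_HEADER[1]].to_numpy(), state
    )
    return spectrum, truth


def write_fasta(path: str | Path, contigs: Iterable[tuple[str, str]]) -> Path:
    """Write contigs as wrapped FASTA (60 columns)."""
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


_RECORD_COLUMNS = (
    "experiment_id",
    "sample_id",
    "hit_no_genomes_pct",
    "taxonomy_bin",
    "completeness_pct",
    "contaminant_bound_pct",
    "consistent_with_sort",
    "is_negative_control",
)


def write_seq_records(path: str | Path, records: Sequence[CellSeqRecord]) -> Path:
    """Write QC records as a TSV with one mapped_<ref> column per reference."""
    path = Path(path)
    refs = sorted({ref for r in records for ref in r.mapped_pct})
    rows = []
    for r in records:
        row = {
            "experiment_id": r.experiment_id,
            "sample_id": r.sample_id,
            **{f"mapped_{ref}": r.mapped_pct.get(ref, 0.0) for ref in refs},
            "hit_no_genomes_pct": r.hit_no_genomes_pct,
            "taxonomy_bin": r.taxonomy_bin or "",
            "completeness_pct": r.completeness_pct,
            "contaminant_bound_pct": r.contaminant_bins_pct_bound,
            "consistent_with_sort": "yes" if r.consistent_with_sort else "no",
            "is_negative_control": "yes" if r.is_negative_control else "no",
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_seq_records(path: str | Path) -> list[CellSeqRecord]:
    """Read a QC record TSV (the inverse of :func:`write_seq_records`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    map_cols = [c for c in df.columns if c.startswith("mapped_")]
    required = {"experiment_id", "sample_id", "hit_no_genomes_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        is_nc = str(getattr(row, "is_negative_control", "no")) == "yes"
        tax = getattr(row, "taxonomy_bin", "")
        tax = None if (is_nc or pd.isna(tax) or tax == "") else str(tax)
        compl = getattr(row, "completeness_pct", None)
        contam = getattr(row, "contaminant_bound_pct", None)
        records.append(
            CellSeqRecord(
                sample_id=str(row.sample_id),
                experiment_id=str(row.experiment_id),
                mapped_pct={c.removeprefix("mapped_"): float(getattr(row, c)) for c in map_cols},
                hit_no_genomes_pct=float(row.hit_no_genomes_pct),
                taxonomy_bin=tax,
                completeness_pct=None if compl is None or pd.isna(compl) else float(compl),
                contaminant_bins_pct_bound=None if contam is None or pd.isna(contam) else float(contam),
                is_negative_control=is_nc,
                consistent_with_sort=str(getattr(row, "consistent_with_sort", "yes")) == "yes",
            )
        )
    return records
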