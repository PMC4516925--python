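"""Readers and writers for the formats the pipeline exchanges.

Peak lists travel as MGF (via pyteomics) or whitespace-delimited two-column
text; sequences and contigs as FASTA (via Biopython); pharmacology tables
as CSV (via pandas); reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .denovo import PeakList
from .fragments import IonSeries
from .transcriptome import Contig, OrfRecord

__all__ = [
    "read_peaklist",
    "write_mgf",
    "read_mgf",
    "read_contigs_fasta",
    "write_fasta",
    "read_proteins_fasta",
    "write_ion_series_csv",
    "read_dose_response_csv",
    "read_iv_csv",
    "write_json_report",
]


def read_mgf(path) -> list[PeakList]:
    """All BEGIN IONS/END IONS blocks of an MGF file as peak lists."""
    out = []
    with _mgf.read(str(path)) as reader:
        for i, spectrum in enumerate(reader):
            title = str(spectrum.get("params", {}).get("title", f"spectrum{i}"))
            out.append(
                PeakList.from_pairs(
                    zip(spectrum["m/z array"], spectrum["intensity array"]),
                    source=title,
                )
            )
    return out


def write_mgf(peaklists: Iterable[PeakList], path, pepmass: float | None = None) -> None:
    spectra = []
    for i, pl in enumerate(peaklists):
        params = {"title": pl.source or f"spectrum{i}"}
        if pepmass is not None:
            params["pepmass"] = pepmass
        spectra.append(
            {"params": params, "m/z array": pl.mz, "intensity array": pl.intensity}
        )
    _mgf.write(spectra, str(path), file_mode="w")


def read_peaklist(path) -> PeakList:
    """One peak list from MGF or two-column (m/z, intensity) text."""
    path = Path(path)
    head = path.read_text().lstrip()
    if head.startswith("BEGIN IONS") or head.startswith("MASS") or "BEGIN IONS" in head[:2000]:
        lists = read_mgf(path)
        if len(lists) != 1:
            raise ValueError(f"{path}: expected a single spectrum, found {len(lists)}")
        return lists[0]
    pairs = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            mz = float(parts[0])
            inten = float(parts[1]) if len(parts) > 1 else 1.0
        except ValueError:
            raise ValueError(f"{path}:{ln}: cannot parse peak line {line!r}") from None
        pairs.append((mz, inten))
    return PeakList.from_pairs(pairs, source=path.stem)


def read_contigs_fasta(path) -> list[Contig]:
    return [
        Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_proteins_fasta(path) -> list[OrfRecord]:
    return [
        OrfRecord(rec.id, 1, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_ion_series_csv(series_list: Iterable[IonSeries], path) -> None:
    rows = [
        {"series": s.series, "index": i, "mz": mz}
        for s in series_list
        for i, mz in s.ions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _read_csv_checked(path, required: set[str], kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse {kind} CSV ({exc})") from None
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: {kind} CSV missing columns {sorted(missing)}")
    return df


def read_dose_response_csv(path) -> pd.DataFrame:
    return _read_csv_checked(path, {"conc_nM", "fraction"}, "dose-response")


def read_iv_csv(path) -> pd.DataFrame:
    return _read_csv_checked(
        path, {"potential_mV", "current", "condition", "replicate"}, "I-V"
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        return super().default(o)


def write_json_report(obj, path) -> None:
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
    tmp.replace(path)  # atomic: partial reports are never left behind
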