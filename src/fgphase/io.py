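"""Readers and writers for the CSV dialects, Sparky peak lists, and FASTA.

The canonical tabular dialect is headered CSV, UTF-8, '.' decimal separator.
Readers validate the header against a schema and report offending columns and
rows by name/line number rather than raising bare pandas errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phase_assay import AssayPoint
from .spectra import Peak, ShiftTable
from .tract import RelaxationSeries

__all__ = [
    "read_table",
    "read_tract_csv",
    "write_tract_csv",
    "read_frap_csv",
    "read_profile_csv",
    "read_ramp_csv",
    "read_assay_csv",
    "read_shift_table_csv",
    "write_shift_table_csv",
    "read_sparky_peaklist",
    "write_sparky_peaklist",
    "read_fasta",
    "write_fasta",
]


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """CSV reader with header and cell validation.

    ``schema`` maps required column names to the dtype each must coerce to;
    extra columns pass through untouched.  Missing columns and unparsable
    cells are reported by name and 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [col for col in schema if col not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                row = int(bad[0]) + 1
                raise ValueError(
                    f"{path.name}: column '{col}', row {row}: "
                    f"cannot parse {df[col].iloc[bad[0]]!r} as {typ.__name__}"
                )
            df[col] = coerced
        else:
            df[col] = df[col].astype(str)
    return df


# --- TRACT ------------------------------------------------------------------

_TRACT_SCHEMA = {"residue": str, "state": str, "delay_s": float, "intensity": float}


def read_tract_csv(path: str | Path) -> tuple[dict[str, RelaxationSeries], dict[str, RelaxationSeries]]:
    """Long-format decay table -> per-residue alpha and beta series."""
    df = read_table(path, _TRACT_SCHEMA)
    alpha: dict[str, RelaxationSeries] = {}
    beta: dict[str, RelaxationSeries] = {}
    for (residue, state), grp in df.groupby(["residue", "state"], sort=False):
        grp = grp.sort_values("delay_s")
        series = RelaxationSeries(residue, state,
                                  grp["delay_s"].to_numpy(), grp["intensity"].to_numpy())
        (alpha if state == "alpha" else beta)[residue] = series
    return alpha, beta


def write_tract_csv(path: str | Path,
                    alpha: dict[str, RelaxationSeries],
                    beta: dict[str, RelaxationSeries]) -> None:
    rows = []
    for store in (alpha, beta):
        for series in store.values():
            for t, y in zip(series.delays, series.intensities):
                rows.append({"residue": series.residue_label, "state": series.state,
                             "delay_s": t, "intensity": y})
    pd.DataFrame(rows).to_csv(path, index=False)


# --- FRAP / DLS / assay ------------------------------------------------------


def read_frap_csv(path: str | Path) -> pd.DataFrame:
    """FRAP curve CSV with columns time_s, roi[, reference]."""
    return read_table(path, {"time_s": float, "roi": float})


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    return read_table(path, {"distance_um": float, "intensity": float})


def read_ramp_csv(path: str | Path) -> pd.DataFrame:
    return read_table(path, {"temperature_c": float, "radius_nm": float})


def read_assay_csv(path: str | Path) -> list[AssayPoint]:
    df = read_table(path, {"total_um": float, "supernatant_um": float,
                           "temp_c": float, "nacl_mm": float})
    return [
        AssayPoint(total_conc=row.total_um, supernatant_conc=row.supernatant_um,
                   temperature=row.temp_c, nacl=row.nacl_mm)
        for row in df.itertuples()
    ]


# --- shift tables ------------------------------------------------------------


def read_shift_table_csv(path: str | Path, condition: str = "") -> ShiftTable:
    df = read_table(path, {"position": int, "atom": str, "shift_ppm": float})
    shifts = {(int(row.position), row.atom): float(row.shift_ppm) for row in df.itertuples()}
    return ShiftTable(shifts, condition=condition)


def write_shift_table_csv(path: str | Path, table: ShiftTable) -> None:
    rows = [{"position": pos, "atom": atom, "shift_ppm": value}
            for (pos, atom), value in sorted(table.shifts.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- Sparky peak lists --------------------------------------------------------


def read_sparky_peaklist(path: str | Path) -> list[Peak]:
    """Parse 'Assignment  w1  w2  [Height]' lines; '?' marks unassigned peaks."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected 'Assignment w1 w2 [Height]'")
            assignment = None if fields[0] == "?" else fields[0]
            try:
                w1, w2 = float(fields[1]), float(fields[2])
                height = float(fields[3]) if len(fields) > 3 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: unparsable number: {exc}") from exc
            peaks.append(Peak(w1=w1, w2=w2, intensity=height, assignment=assignment))
    return peaks


def write_sparky_peaklist(path: str | Path, peaks: list[Peak]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{'Assignment':<20}{'w1':>10}{'w2':>10}{'Height':>14}\n")
        for peak in peaks:
            label = peak.assignment or "?"
            handle.write(f"{label:<20}{peak.w1:>10.3f}{peak.w2:>10.3f}{peak.intensity:>14.4g}\n")


# --- FASTA --------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
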