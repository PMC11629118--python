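"""Delimited-text spectra tables and the bundled reference dataset.

Two table families share one reader:

* property tables — ``wavelength_nm, mu_a[, mu_a_sd], mu_sp[, mu_sp_sd]``
* measurement tables — ``wavelength_nm, Rd, Tt, thickness_mm[, replicate,
  sample_id]``

Delimiter (comma or tab) is sniffed from the header line. Validation
errors carry the 1-based line number of the offending row.

The package ships a transcription of published mean +/- SD optical
properties of six upper-urinary-tract tissue types (human/porcine ureter
and fatty tissue, ureteral and renal pelvic carcinoma) at the 11
therapeutic wavelengths between 410 and 690 nm; its integrity is pinned
by a sha256 checksum.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraParseError",
    "read_spectra",
    "write_spectra",
    "load_reference_table",
    "REFERENCE_TISSUES",
]

REFERENCE_TISSUES = (
    "human_ureter",
    "human_fat",
    "ureteral_carcinoma",
    "renal_pelvic_carcinoma",
    "porcine_ureter",
    "porcine_fat",
)

_REFERENCE_SHA256 = "ec305386af1fb733611f1f8f8fb8c6699f792d77dc66a796712eb17d4ee054e8"

_COEFF_COLUMNS = ("mu_a", "mu_a_sd", "mu_sp", "mu_sp_sd")


class SpectraParseError(ValueError):
    """Malformed spectra table; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _group_keys(df: pd.DataFrame) -> list[str]:
    return [c for c in ("sample_id", "replicate") if c in df.columns]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if "wavelength_nm" not in df.columns:
        raise SpectraParseError("missing required column 'wavelength_nm'")
    lines = df.index.to_numpy() + 2  # header is line 1

    def fail(mask: np.ndarray, message: str):
        if mask.any():
            raise SpectraParseError(message, line=int(lines[mask][0]))

    wl = df["wavelength_nm"].to_numpy(dtype=float)
    fail(~np.isfinite(wl), "non-numeric wavelength")

    keys = _group_keys(df)
    groups = df.groupby(keys, sort=False) if keys else [(None, df)]
    for _, grp in groups:
        w = grp["wavelength_nm"].to_numpy(dtype=float)
        bad = np.zeros(len(df), dtype=bool)
        not_increasing = np.where(np.diff(w) <= 0)[0]
        if not_increasing.size:
            bad[grp.index[not_increasing[0] + 1]] = True
            fail(bad, "wavelengths must be strictly increasing "
                      "(duplicate or unsorted wavelength)")

    for col in _COEFF_COLUMNS:
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            fail(vals < 0, f"negative value in column '{col}'")
    for col in ("Rd", "Tt"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            fail((vals < 0) | (vals > 1), f"'{col}' outside [0, 1]")
    if "Rd" in df.columns and "Tt" in df.columns:
        s = df["Rd"].to_numpy(dtype=float) + df["Tt"].to_numpy(dtype=float)
        fail(s >= 1, "Rd + Tt must be < 1 for a physical measurement")
    if "thickness_mm" in df.columns:
        vals = df["thickness_mm"].to_numpy(dtype=float)
        fail(vals <= 0, "'thickness_mm' must be > 0")
    return df


def read_spectra(path: str | Path) -> pd.DataFrame:
    """Read and validate a delimited spectra table (comma or tab)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path),
                     float_precision="round_trip")
    return _validate(df)


def write_spectra(path: str | Path, table: pd.DataFrame) -> None:
    """Write a spectra table as delimited text, full float precision."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    table.to_csv(path, sep=sep, index=False, float_format="%.17g")


def _reference_path():
    return resources.files("tissuelight") / "data" / "uut_reference_properties.csv"


def load_reference_table(tissue: str | None = None) -> pd.DataFrame:
    """Bundled tissue optical-property reference (mean +/- SD).

    Columns: tissue, wavelength_nm, mu_a, mu_a_sd, mu_sp, mu_sp_sd; 11
    wavelengths per tissue. Verifies the transcription checksum on load.
    """
    ref = _reference_path()
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise RuntimeError(
            "bundled reference table failed its transcription checksum: "
            f"{digest}"
        )
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    if tissue is not None:
        if tissue not in REFERENCE_TISSUES:
            raise KeyError(
                f"unknown tissue {tissue!r}; choose from {REFERENCE_TISSUES}"
            )
        df = df[df["tissue"] == tissue].reset_index(drop=True)
    return df
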