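"""Readers and writers for the plain-text formats used by the pipeline.

SAXS profiles use the three-column ASCII dialect of SASBDB/ATSAS deposits:
comment/header lines (anything that does not parse as 2-3 numbers) followed
by ``Q  I(Q)  [sigma]`` rows.  Q units are auto-detected — a maximum Q below
1 suggests inverse angstroms (converted to nm^-1) — and can be overridden.

CD melting matrices are delimited text with wavelengths in the first column
and one column per temperature, temperatures in the header row.  A
two-column file parses as a single spectrum.

Readers reject silently-corrupting inputs (non-monotone Q, ragged matrices)
rather than repairing them.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cd_melting import CDMeltingMatrix, CDSpectrum
from .scattering import SAXSProfile

__all__ = ["read_saxs_dat", "write_saxs_dat", "read_cd_matrix",
           "write_cd_matrix", "read_cd_spectrum", "write_cd_spectrum"]


def read_saxs_dat(path, unit_hint: str | None = None) -> SAXSProfile:
    """Parse a SASBDB/ATSAS-style .dat file into a :class:`SAXSProfile`.

    ``unit_hint`` may be 'nm^-1' or 'A^-1'; when omitted the unit is
    guessed from max(Q).  The returned profile is always in nm^-1.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.replace(",", " ").split()
            if len(parts) not in (2, 3):
                continue
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue
            rows.append(vals)
    if len(rows) < 10:
        raise ValueError(f"{path}: fewer than 10 numeric data rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    q = data[:, 0]
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: Q column is not strictly increasing")
    intensity = data[:, 1]
    sigma = data[:, 2] if ncol >= 3 else None
    if sigma is not None and np.any(sigma <= 0):
        sigma = None

    unit = unit_hint
    if unit is None:
        unit = "A^-1" if q.max() < 1.0 else "nm^-1"
    if unit not in ("nm^-1", "A^-1"):
        raise ValueError("unit_hint must be 'nm^-1' or 'A^-1'")
    if np.any(intensity < 0):
        warnings.warn(f"{path}: negative intensities present (kept)", stacklevel=2)
    return SAXSProfile(q=q, intensity=intensity, sigma=sigma, q_unit=unit).to_nm()


def write_saxs_dat(path, profile: SAXSProfile, header: str = "") -> None:
    prof = profile.to_nm()
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# Q[nm^-1]  I(Q)  sigma\n")
        for i in range(len(prof.q)):
            if prof.sigma is not None:
                fh.write(f"{prof.q[i]:.8e} {prof.intensity[i]:.8e} {prof.sigma[i]:.8e}\n")
            else:
                fh.write(f"{prof.q[i]:.8e} {prof.intensity[i]:.8e}\n")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_cd_matrix(path) -> CDMeltingMatrix | CDSpectrum:
    """Read a CD melting matrix (wavelength rows x temperature columns); a
    single-column file is returned as a :class:`CDSpectrum`."""
    df = _read_table(path)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or non-numeric CD table")
    lam = df.index.to_numpy(dtype=float)
    if df.shape[1] == 1:
        return CDSpectrum(wavelengths=lam,
                          ellipticity=df.iloc[:, 0].to_numpy(dtype=float))
    try:
        temps = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: temperature header row is not numeric") from exc
    return CDMeltingMatrix(wavelengths=lam, temperatures=temps,
                           ellipticity=df.to_numpy(dtype=float))


def write_cd_matrix(path, mat: CDMeltingMatrix) -> None:
    df = pd.DataFrame(mat.ellipticity,
                      index=pd.Index(mat.wavelengths, name="wavelength_nm"),
                      columns=[f"{t:g}" for t in mat.temperatures])
    df.to_csv(path)


def read_cd_spectrum(path) -> CDSpectrum:
    out = read_cd_matrix(path)
    if isinstance(out, CDMeltingMatrix):
        raise ValueError(f"{path}: expected a single-spectrum file")
    return out


def write_cd_spectrum(path, spec: CDSpectrum) -> None:
    df = pd.DataFrame({"ellipticity_mdeg": spec.ellipticity},
                      index=pd.Index(spec.wavelengths, name="wavelength_nm"))
    df.to_csv(path)
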