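"""Spectrum and FID serialisation.

Two plain-text formats are supported:

* **JCAMP-DX** (NMR spectrum dialect, AFFN ``(X++(Y..Y))`` tables, one
  block per part).  Real-only spectra carry a single ``##XYDATA`` block;
  spectra with an imaginary part carry two ``##XYDATA`` blocks tagged by
  a ``##$PART`` record.  Acquisition parameters are stored in standard
  (``##.OBSERVE FREQUENCY``) and private (``##$...``) records so the
  scheme survives a round trip.
* **Columnar**: whitespace-separated ``ppm real [imag]`` rows preceded
  by ``# key: value`` header comments.

Both readers normalise the ppm axis to descending order.
"""

from __future__ import annotations

import io as _io
from typing import Optional, TextIO, Union

import numpy as np

from .types import AcquisitionScheme, FidRecord, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_fid_columnar",
    "write_fid_columnar",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed spectrum file; message carries line context."""


_SCHEME_KEYS = {
    "spectrometer_frequency": float,
    "spectral_width": float,
    "n_points": int,
    "n_scans": int,
    "flip_angle": float,
    "relaxation_delay": float,
    "temperature_label": str,
}


def _scheme_header_lines(scheme: AcquisitionScheme, prefix: str) -> list[str]:
    return [
        f"{prefix}spectrometer_frequency: {scheme.spectrometer_frequency!r}",
        f"{prefix}spectral_width: {scheme.spectral_width!r}",
        f"{prefix}n_points: {scheme.n_points}",
        f"{prefix}n_scans: {scheme.n_scans}",
        f"{prefix}flip_angle: {scheme.flip_angle!r}",
        f"{prefix}relaxation_delay: {scheme.relaxation_delay!r}",
        f"{prefix}temperature_label: {scheme.temperature_label}",
    ]


def _scheme_from_dict(d: dict) -> AcquisitionScheme:
    kwargs = {}
    for key, conv in _SCHEME_KEYS.items():
        if key in d:
            kwargs[key] = conv(d[key])
    kwargs.setdefault("spectrometer_frequency", 400.13)
    kwargs.setdefault("spectral_width", 8000.0)
    kwargs.setdefault("n_points", max(1024, int(d.get("npoints_axis", 1024))))
    return AcquisitionScheme(**kwargs)


def _normalise_descending(ppm, real, imag):
    ppm = np.asarray(ppm, dtype=float)
    real = np.asarray(real, dtype=float)
    imag = None if imag is None else np.asarray(imag, dtype=float)
    if ppm.size >= 2 and ppm[0] < ppm[-1]:
        ppm = ppm[::-1].copy()
        real = real[::-1].copy()
        imag = None if imag is None else imag[::-1].copy()
    return ppm, real, imag


# ---------------------------------------------------------------- columnar


def write_spectrum_columnar(spec: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("# citrusnmr spectrum v1\n")
        fh.write(f"# sample_id: {spec.sample_id}\n")
        fh.write(f"# variety_id: {spec.variety_id}\n")
        fh.write(f"# replicate: {spec.replicate}\n")
        for line in _scheme_header_lines(spec.scheme, "# "):
            fh.write(line + "\n")
        fh.write("# columns: ppm real" + (" imag" if spec.imag_part is not None else "") + "\n")
        imag = spec.imag_part
        for i in range(spec.n_points):
            if imag is None:
                fh.write(f"{spec.ppm_axis[i]:.8e} {spec.real_part[i]:.10e}\n")
            else:
                fh.write(
                    f"{spec.ppm_axis[i]:.8e} {spec.real_part[i]:.10e} {imag[i]:.10e}\n"
                )


def read_spectrum_columnar(path) -> Spectrum:
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    imag = arr[:, 2] if arr.shape[1] == 3 else None
    ppm, real, imag = _normalise_descending(arr[:, 0], arr[:, 1], imag)
    return Spectrum(
        ppm_axis=ppm,
        real_part=real,
        imag_part=imag,
        scheme=_scheme_from_dict({**meta, "npoints_axis": arr.shape[0]}),
        history=[{"step": "read", "format": "columnar", "path": str(path)}],
        sample_id=meta.get("sample_id", ""),
        variety_id=meta.get("variety_id", ""),
        replicate=int(meta.get("replicate", 0) or 0),
    )


# ---------------------------------------------------------------- JCAMP-DX


def _write_xydata(fh: TextIO, x: np.ndarray, y: np.ndarray, per_line: int = 6) -> None:
    fh.write("##XYDATA=(X++(Y..Y))\n")
    for i in range(0, x.size, per_line):
        ys = " ".join(f"{v:.10e}" for v in y[i : i + per_line])
        fh.write(f"{x[i]:.8e} {ys}\n")


def write_spectrum_jcamp(spec: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"##TITLE={spec.sample_id or 'citrusnmr spectrum'}\n")
        fh.write("##JCAMP-DX=5.00\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##DATA CLASS=XYDATA\n")
        fh.write("##ORIGIN=citrusnmr\n")
        fh.write("##OWNER=\n")
        fh.write("##.OBSERVE NUCLEUS=^1H\n")
        fh.write(f"##.OBSERVE FREQUENCY={spec.scheme.spectrometer_frequency!r}\n")
        fh.write(f"##$SAMPLEID={spec.sample_id}\n")
        fh.write(f"##$VARIETYID={spec.variety_id}\n")
        fh.write(f"##$REPLICATE={spec.replicate}\n")
        fh.write(f"##$SPECTRALWIDTH={spec.scheme.spectral_width!r}\n")
        fh.write(f"##$TDPOINTS={spec.scheme.n_points}\n")
        fh.write(f"##$NSCANS={spec.scheme.n_scans}\n")
        fh.write(f"##$FLIPANGLE={spec.scheme.flip_angle!r}\n")
        fh.write(f"##$RELAXATIONDELAY={spec.scheme.relaxation_delay!r}\n")
        fh.write(f"##$TEMPERATURELABEL={spec.scheme.temperature_label}\n")
        fh.write("##XUNITS=PPM\n##YUNITS=ARBITRARY UNITS\n")
        fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={spec.ppm_axis[0]:.8e}\n")
        fh.write(f"##LASTX={spec.ppm_axis[-1]:.8e}\n")
        fh.write(f"##NPOINTS={spec.n_points}\n")
        fh.write("##$PART=REAL\n")
        _write_xydata(fh, spec.ppm_axis, spec.real_part)
        if spec.imag_part is not None:
            fh.write("##$PART=IMAG\n")
            _write_xydata(fh, spec.ppm_axis, spec.imag_part)
        fh.write("##END=\n")


def _parse_jcamp(path) -> tuple[dict, dict]:
    """Return (records, {part: (x, y)}) from our JCAMP dialect.

    Tolerates ascending or descending X and plain AFFN tables only
    (no compressed DIF/DUP forms).
    """
    records: dict = {}
    tables: dict = {}
    current_part = "REAL"
    in_table = False
    xs: list[float] = []
    ys: list[float] = []

    def flush():
        nonlocal xs, ys, in_table
        if in_table and ys:
            tables[current_part] = (np.array(xs), np.array(ys))
        xs, ys, in_table = [], [], False

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                flush()
                if "=" not in line:
                    raise ParseError(f"{path}:{ln}: malformed label record")
                key, val = line[2:].split("=", 1)
                key, val = key.strip().upper(), val.strip()
                if key == "$PART":
                    current_part = val.upper()
                elif key == "XYDATA":
                    in_table = True
                else:
                    records[key] = val
                continue
            if in_table:
                parts = line.split()
                try:
                    vals = [float(p) for p in parts]
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: bad numeric value ({exc})") from None
                if len(vals) < 2:
                    raise ParseError(f"{path}:{ln}: XYDATA row needs X plus >=1 Y")
                xs.append(vals[0])
                ys.extend(vals[1:])
            else:
                raise ParseError(f"{path}:{ln}: data outside an XYDATA block")
    flush()
    if not tables:
        raise ParseError(f"{path}: no XYDATA block found")
    return records, tables


def read_spectrum_jcamp(path) -> Spectrum:
    records, tables = _parse_jcamp(path)
    if "REAL" not in tables:
        raise ParseError(f"{path}: missing REAL part")
    try:
        firstx = float(records["FIRSTX"])
        lastx = float(records["LASTX"])
        npoints = int(records["NPOINTS"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing required record {exc}") from None
    yfactor = float(records.get("YFACTOR", 1.0))
    ppm = np.linspace(firstx, lastx, npoints)
    real = tables["REAL"][1] * yfactor
    if real.size != npoints:
        raise ParseError(
            f"{path}: NPOINTS={npoints} but REAL table has {real.size} values"
        )
    imag = None
    if "IMAG" in tables:
        imag = tables["IMAG"][1] * yfactor
        if imag.size != npoints:
            raise ParseError(f"{path}: IMAG table length mismatch")
    ppm, real, imag = _normalise_descending(ppm, real, imag)
    meta = {
        "spectrometer_frequency": records.get(".OBSERVE FREQUENCY", 400.13),
        "spectral_width": records.get("$SPECTRALWIDTH", 8000.0),
        "n_points": records.get("$TDPOINTS", max(1024, npoints)),
        "n_scans": records.get("$NSCANS", 1),
        "flip_angle": records.get("$FLIPANGLE", 90.0),
        "relaxation_delay": records.get("$RELAXATIONDELAY", 1.0),
        "temperature_label": records.get("$TEMPERATURELABEL", ""),
    }
    return Spectrum(
        ppm_axis=ppm,
        real_part=real,
        imag_part=imag,
        scheme=_scheme_from_dict(meta),
        history=[{"step": "read", "format": "jcamp", "path": str(path)}],
        sample_id=records.get("$SAMPLEID", records.get("TITLE", "")),
        variety_id=records.get("$VARIETYID", ""),
        replicate=int(records.get("$REPLICATE", 0) or 0),
    )


# ---------------------------------------------------------------- dispatch


def write_spectrum(spec: Spectrum, path, format: str = "jcamp") -> None:
    """Write a spectrum as ``jcamp`` or ``columnar`` text."""
    if format == "jcamp":
        write_spectrum_jcamp(spec, path)
    elif format == "columnar":
        write_spectrum_columnar(spec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_spectrum(path, format: Optional[str] = None) -> Spectrum:
    """Read a spectrum; format sniffed from the first line if not given."""
    if format is None:
        with open(path) as fh:
            first = fh.readline()
        format = "jcamp" if first.startswith("##") else "columnar"
    if format == "jcamp":
        return read_spectrum_jcamp(path)
    if format == "columnar":
        return read_spectrum_columnar(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------- FIDs


def write_fid_columnar(fid: FidRecord, path) -> None:
    """Time-domain record: ``time_s real imag`` rows plus scheme header."""
    with open(path, "w") as fh:
        fh.write("# citrusnmr fid v1\n")
        fh.write(f"# sample_id: {fid.sample_id}\n")
        fh.write(f"# variety_id: {fid.variety_id}\n")
        fh.write(f"# replicate: {fid.replicate}\n")
        fh.write(f"# seed: {fid.seed}\n")
        for line in _scheme_header_lines(fid.scheme, "# "):
            fh.write(line + "\n")
        fh.write("# columns: time_s real imag\n")
        dwell = fid.scheme.dwell_time
        for i, z in enumerate(fid.complex_signal):
            fh.write(f"{i * dwell:.10e} {z.real:.10e} {z.imag:.10e}\n")


def read_fid_columnar(path) -> FidRecord:
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 columns")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows)
    scheme = _scheme_from_dict({**meta, "npoints_axis": arr.shape[0]})
    return FidRecord(
        complex_signal=arr[:, 1] + 1j * arr[:, 2],
        scheme=scheme,
        sample_id=meta.get("sample_id", ""),
        variety_id=meta.get("variety_id", ""),
        replicate=int(meta.get("replicate", 0) or 0),
        seed=int(meta.get("seed", 0) or 0),
    )
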