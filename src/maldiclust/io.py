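"""Peak-table and manifest IO.

Peak tables are plain two-column TSV/CSV files (``mz``, ``intensity``) as
exported from acquisition software; the manifest is a CSV with columns
``strain_id,species,genus,file``.  On read, m/z is rounded to one decimal
place, peaks colliding after rounding have their intensities summed (total
ion signal is conserved), and peaks outside the 2-20 kDa detection window
are dropped with a logged count.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DenoiseParams, SpectrumPreprocessor
from .spectra import (
    MZ_MAX,
    MZ_MIN,
    GridSpec,
    GridSpectrum,
    RawSpectrum,
    SpectrumSet,
    StrainManifest,
)

__all__ = ["read_peak_table", "write_peak_table", "load_spectrum_set"]

logger = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}


def _sniff_dialect(path: Path) -> str:
    return "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"


def read_peak_table(
    path,
    dialect: str | None = None,
    strain_id: str = "",
    replicate_id: str = "",
    mz_range: tuple[float, float] = (MZ_MIN, MZ_MAX),
) -> RawSpectrum:
    """Read a two-column (m/z, intensity) table into a :class:`RawSpectrum`."""
    path = Path(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect not in _DELIMS:
        raise ValueError(f"dialect must be one of {sorted(_DELIMS)}, got {dialect!r}")

    mz, intensity = [], []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=_DELIMS[dialect]), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if lineno == 1 and not _is_numeric(row[0]):
                continue  # header
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(row)}")
            try:
                mz.append(float(row[0]))
                intensity.append(float(row[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell in {row!r}") from exc
    if not mz:
        raise ValueError(f"{path}: no peaks found")

    mz_arr = np.round(np.asarray(mz), 1)
    int_arr = np.asarray(intensity)
    if np.any(int_arr < 0):
        raise ValueError(f"{path}: negative intensity")

    lo, hi = mz_range
    in_range = (mz_arr >= lo) & (mz_arr <= hi)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("%s: dropped %d peak(s) outside [%g, %g] Da", path, n_dropped, lo, hi)
    mz_arr, int_arr = mz_arr[in_range], int_arr[in_range]
    if mz_arr.size == 0:
        raise ValueError(f"{path}: all peaks outside [{lo}, {hi}] Da")

    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    uniq, inverse, counts = np.unique(mz_arr, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        logger.warning(
            "%s: %d duplicate m/z value(s) after rounding; intensities summed",
            path,
            int((counts > 1).sum()),
        )
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, int_arr)
    return RawSpectrum(uniq, summed, strain_id=strain_id, replicate_id=replicate_id)


def _is_numeric(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_peak_table(spectrum, path, dialect: str | None = None) -> None:
    """Write a spectrum as a two-column table (one-decimal m/z, full-precision
    intensity).  Zero-intensity grid points of a GridSpectrum are omitted."""
    path = Path(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if isinstance(spectrum, GridSpectrum):
        idx = spectrum.support
        mz = spectrum.grid.centers[idx]
        intensity = spectrum.intensity[idx]
    else:
        mz, intensity = spectrum.mz, spectrum.intensity
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_DELIMS[dialect], lineterminator="\n")
        writer.writerow(["mz", "intensity"])
        for m, i in zip(mz, intensity):
            writer.writerow([f"{m:.1f}", repr(float(i))])


def load_spectrum_set(
    manifest_path,
    spectra_dir,
    grid: GridSpec = GridSpec(),
    denoise_params: DenoiseParams = DenoiseParams(),
    order: str = "log_then_denoise",
) -> SpectrumSet:
    """Read every manifest-listed peak table, preprocess and label it.

    The manifest's ``file`` column may hold a comma-free path per replicate
    row, or ``;``-separated paths for multiple replicates of one strain.
    """
    manifest_path = Path(manifest_path)
    spectra_dir = Path(spectra_dir)
    table = pd.read_csv(manifest_path, dtype=str)
    if "file" not in table.columns:
        raise ValueError(f"{manifest_path}: manifest needs a 'file' column")
    manifest = StrainManifest(table[["strain_id", "species", "genus"]].drop_duplicates())

    jobs: list[tuple[str, str, Path]] = []
    missing: list[str] = []
    for _, row in table.iterrows():
        for rep_no, fname in enumerate(str(row["file"]).split(";"), start=1):
            fpath = spectra_dir / fname.strip()
            if not fpath.exists():
                missing.append(row["strain_id"])
            else:
                jobs.append((row["strain_id"], f"r{rep_no}", fpath))
    if missing:
        raise FileNotFoundError(f"no peak table for strain(s): {sorted(set(missing))}")

    pre = SpectrumPreprocessor(
        start=grid.start,
        stop=grid.stop,
        grid_step=grid.step,
        window_width=denoise_params.window_width,
        keep_fraction=denoise_params.keep_fraction,
        denoise_step=denoise_params.step,
        combine_rule=denoise_params.combine_rule,
        order=order,
    )
    raws = [
        read_peak_table(fpath, strain_id=sid, replicate_id=rid, mz_range=(grid.start, grid.stop))
        for sid, rid, fpath in jobs
    ]
    return SpectrumSet(pre.transform_spectra(raws), manifest, grid)
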