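"""Core spectrum containers.

A whole-cell MALDI-TOF protein mass fingerprint is a sparse list of
(m/z, intensity) peaks in the 2-20 kDa range.  Downstream similarity and
ordination need point-wise comparable vectors, so peaks are resampled onto
a shared fixed-step m/z grid (:class:`GridSpec`) producing a
:class:`GridSpectrum`.  A :class:`SpectrumSet` bundles the gridded spectra
of one study with the strain/species/genus manifest that labels them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RawSpectrum",
    "GridSpectrum",
    "StrainManifest",
    "SpectrumSet",
]

MZ_MIN = 2000.0
MZ_MAX = 20000.0


@dataclass(frozen=True)
class GridSpec:
    """Fixed m/z grid: ``start, start+step, ..., stop`` (inclusive), in Da."""

    start: float = MZ_MIN
    stop: float = MZ_MAX
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        span = self.stop - self.start
        if abs(span / self.step - round(span / self.step)) > 1e-9:
            raise ValueError("(stop - start) must be divisible by step")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def centers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def index_of(self, mz: np.ndarray) -> np.ndarray:
        """Round-half-up bin index for each m/z value."""
        return np.floor((np.asarray(mz, float) - self.start) / self.step + 0.5).astype(int)


@dataclass
class RawSpectrum:
    """Centroided peak list as exported: m/z to one decimal, intensity >= 0."""

    mz: np.ndarray
    intensity: np.ndarray
    strain_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return self.mz.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
            and self.strain_id == other.strain_id
            and self.replicate_id == other.replicate_id
        )


@dataclass
class GridSpectrum:
    """Intensity vector on a fixed grid, with processing-state flags."""

    grid: GridSpec
    intensity: np.ndarray
    strain_id: str = ""
    replicate_id: str = ""
    resampled: bool = False
    log_transformed: bool = False
    denoised: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity length {self.intensity.size} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def with_intensity(self, intensity: np.ndarray, **flag_updates) -> "GridSpectrum":
        out = replace(self, intensity=np.asarray(intensity, float))
        for name, value in flag_updates.items():
            setattr(out, name, value)
        return out

    @property
    def support(self) -> np.ndarray:
        """Indices of nonzero grid points."""
        return np.flatnonzero(self.intensity)


class StrainManifest:
    """Strain -> (species, genus) labels; one row per strain."""

    REQUIRED = ("strain_id", "species", "genus")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if table["strain_id"].duplicated().any():
            dups = table.loc[table["strain_id"].duplicated(), "strain_id"].tolist()
            raise ValueError(f"duplicate strain_id in manifest: {dups}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "StrainManifest":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    @classmethod
    def read_csv(cls, path) -> "StrainManifest":
        return cls(pd.read_csv(path, dtype=str))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def strain_ids(self) -> list[str]:
        return self.table["strain_id"].tolist()

    def species_of(self, strain_id: str) -> str:
        return self._lookup(strain_id, "species")

    def genus_of(self, strain_id: str) -> str:
        return self._lookup(strain_id, "genus")

    def _lookup(self, strain_id: str, col: str) -> str:
        rows = self.table.loc[self.table["strain_id"] == strain_id, col]
        if rows.empty:
            raise KeyError(f"strain {strain_id!r} not in manifest")
        return rows.iloc[0]

    @property
    def species_map(self) -> dict[str, str]:
        return dict(zip(self.table["strain_id"], self.table["species"]))

    @property
    def genus_map(self) -> dict[str, str]:
        return dict(zip(self.table["strain_id"], self.table["genus"]))

    def strains_of_species(self, species: str) -> list[str]:
        return self.table.loc[self.table["species"] == species, "strain_id"].tolist()

    @property
    def species_list(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SpectrumSet:
    """Gridded spectra of one study sharing a grid, plus their manifest."""

    spectra: list[GridSpectrum]
    manifest: StrainManifest
    grid: GridSpec

    def __post_init__(self) -> None:
        known = set(self.manifest.strain_ids)
        for s in self.spectra:
            if s.grid != self.grid:
                raise ValueError(f"spectrum {s.strain_id} on a different grid")
            if s.strain_id not in known:
                raise ValueError(f"spectrum strain {s.strain_id!r} not in manifest")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def spectrum_labels(self) -> list[str]:
        """One label per spectrum: ``strain`` or ``strain/replicate``."""
        labels = []
        for s in self.spectra:
            labels.append(f"{s.strain_id}/{s.replicate_id}" if s.replicate_id else s.strain_id)
        return labels

    @property
    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_grid_points) stacked intensities."""
        return np.vstack([s.intensity for s in self.spectra])

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        return SpectrumSet([self.spectra[i] for i in indices], self.manifest, self.grid)
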