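"""Spectral relatedness: composite correlation index (CCI) and Bray-Curtis.

The CCI scores a pair of preprocessed fingerprints by splitting the m/z
grid into ``n_intervals`` equal-width contiguous blocks, computing the
Pearson correlation within each block, and averaging the block
correlations.  Blocks where either spectrum is flat (zero variance) carry
no information about relatedness and are excluded from the mean rather
than scored zero.  The mean is clamped to [0, 1] by default so the index
matches the usual heat-map scale (1 = highly related, 0 = unrelated);
``n_intervals=1`` reduces the CCI to plain clamped Pearson correlation
over the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrices import DistanceMatrix, SimilarityMatrix
from .spectra import GridSpectrum, SpectrumSet, StrainManifest

__all__ = [
    "CCIParams",
    "ZeroVarianceError",
    "pearson",
    "cci",
    "cci_matrix",
    "strain_level_matrix",
    "bray_curtis_matrix",
    "cci_summary",
]


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class CCIParams:
    n_intervals: int = 10
    clamp_negative: bool = True
    min_points_per_interval: int = 2

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.min_points_per_interval < 2:
            raise ValueError("min_points_per_interval must be >= 2")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises :class:`ZeroVarianceError` when
    either input is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("zero variance input")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def _interval_slices(n_points: int, n_intervals: int) -> list[slice]:
    """Equal-width contiguous blocks covering the grid (widths differ by at
    most one point when n_points is not divisible by n_intervals)."""
    bounds = np.linspace(0, n_points, n_intervals + 1).round().astype(int)
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def cci(a: GridSpectrum, b: GridSpectrum, params: CCIParams = CCIParams()) -> float:
    if a.grid != b.grid:
        raise ValueError("spectra must share one grid")
    rs = []
    for sl in _interval_slices(a.grid.n_points, params.n_intervals):
        x, y = a.intensity[sl], b.intensity[sl]
        if x.size < params.min_points_per_interval:
            continue
        try:
            rs.append(pearson(x, y))
        except ZeroVarianceError:
            continue
    if not rs:
        raise ValueError(
            f"no informative interval between {a.strain_id!r} and {b.strain_id!r}"
        )
    value = float(np.mean(rs))
    if params.clamp_negative:
        value = min(max(value, 0.0), 1.0)
    return value


def cci_matrix(spectrum_set: SpectrumSet, params: CCIParams = CCIParams()) -> SimilarityMatrix:
    """All pairwise CCI values over a spectrum set (spectrum level).

    Vectorised per interval: within each block every spectrum is
    standardised, so the block correlation matrix is a single matrix
    product.  Agrees with pairwise :func:`cci` (asserted in tests).
    """
    if len(spectrum_set) < 2:
        raise ValueError("need at least two spectra")
    X = spectrum_set.intensity_matrix()
    n = X.shape[0]
    r_sum = np.zeros((n, n))
    r_cnt = np.zeros((n, n))
    for sl in _interval_slices(spectrum_set.grid.n_points, params.n_intervals):
        sub = X[:, sl]
        m = sub.shape[1]
        if m < params.min_points_per_interval:
            continue
        centered = sub - sub.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        valid = norms > 0
        Z = np.zeros_like(centered)
        Z[valid] = centered[valid] / norms[valid, None]
        R = np.clip(Z @ Z.T, -1.0, 1.0)
        pair_ok = np.outer(valid, valid)
        r_sum += np.where(pair_ok, R, 0.0)
        r_cnt += pair_ok
    if np.any(r_cnt[~np.eye(n, dtype=bool)] == 0):
        i, j = np.argwhere((r_cnt == 0) & ~np.eye(n, dtype=bool))[0]
        labels = spectrum_set.spectrum_labels
        raise ValueError(f"no informative interval between {labels[i]!r} and {labels[j]!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(r_cnt > 0, r_sum / np.maximum(r_cnt, 1), 0.0)
    if params.clamp_negative:
        values = np.clip(values, 0.0, 1.0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(spectrum_set.spectrum_labels, values)


def strain_level_matrix(m: SimilarityMatrix, strain_ids: list[str]) -> SimilarityMatrix:
    """Aggregate a spectrum-level matrix to strain level.

    The (A, B) entry is the mean CCI over all replicate pairs of strains A
    and B; the diagonal is 1 by definition of the index.
    """
    if len(strain_ids) != len(m):
        raise ValueError("one strain_id per matrix row required")
    strains = list(dict.fromkeys(strain_ids))
    groups = {s: [i for i, sid in enumerate(strain_ids) if sid == s] for s in strains}
    k = len(strains)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            block = m.values[np.ix_(groups[strains[i]], groups[strains[j]])]
            out[i, j] = out[j, i] = block.mean()
    return SimilarityMatrix(strains, out)


def _upper(n: int):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _pair_values(m: SimilarityMatrix, pairs) -> float:
    if not pairs:
        raise ValueError("no pairs in this category")
    return float(np.mean([m.values[i, j] for i, j in pairs]))


def cci_group_means(
    m: SimilarityMatrix, strain_ids: list[str], manifest: StrainManifest
) -> dict[str, float]:
    """Mean CCI split by pair category: intra-strain replicate pairs,
    intra-genus inter-species pairs, and inter-genus pairs."""
    species = [manifest.species_of(s) for s in strain_ids]
    genus = [manifest.genus_of(s) for s in strain_ids]
    cats: dict[str, list[tuple[int, int]]] = {
        "intra_strain": [],
        "intra_species": [],
        "intra_genus_inter_species": [],
        "inter_genus": [],
    }
    for i, j in _upper(len(m)):
        if strain_ids[i] == strain_ids[j]:
            cats["intra_strain"].append((i, j))
        elif species[i] == species[j]:
            cats["intra_species"].append((i, j))
        elif genus[i] == genus[j]:
            cats["intra_genus_inter_species"].append((i, j))
        else:
            cats["inter_genus"].append((i, j))
    return {k: _pair_values(m, v) for k, v in cats.items() if v}


def bray_curtis_matrix(spectrum_set: SpectrumSet) -> DistanceMatrix:
    """BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) over all spectrum pairs."""
    X = spectrum_set.intensity_matrix()
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        bad = [spectrum_set.spectrum_labels[i] for i in zero]
        raise ValueError(f"all-zero spectrum for: {bad}")
    values = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(spectrum_set.spectrum_labels, values)


def cci_summary(m: SimilarityMatrix, thresholds: list[float] = (0.1, 0.5)) -> pd.DataFrame:
    """Bin the n(n-1) off-diagonal entries (both orientations, matching the
    usual whole-matrix accounting) into left-closed threshold bins."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    vals = m.off_diagonal()
    if vals.size == 0:
        raise ValueError("matrix has no off-diagonal entries")
    edges = [-np.inf] + thresholds + [np.inf]
    names = (
        [f"< {thresholds[0]}"]
        + [f"[{a}, {b})" for a, b in zip(thresholds[:-1], thresholds[1:])]
        + [f">= {thresholds[-1]}"]
    )
    counts = np.histogram(vals, bins=edges)[0]
    return pd.DataFrame(
        {"bin": names, "count": counts, "fraction": counts / vals.size}
    )
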