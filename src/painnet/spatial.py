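"""Spatial and correlation analyses: distances, 2-D embedding, profiles.

Covers the distance-related parts of the analysis: Euclidean distances
between injection coordinates, classical (Torgerson) multidimensional
scaling to a 2-D layout, per-source-area correlation of log strength with
distance, and area-by-area correlation of outgoing (source) and incoming
(target) projection profiles.

Projection strengths span far more than five orders of magnitude, so all
correlation analyses operate on log10 strength with a small floor
(``LOG_FLOOR``) added before taking logs; pairs with zero strength are
excluded from the distance fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import BrainAreaCatalog, ProjectionTable

__all__ = [
    "DistanceMatrix",
    "CorrelationMatrices",
    "pairwise_distances",
    "mds_embed_2d",
    "strength_distance_correlation",
    "projection_profile_correlations",
    "LOG_FLOOR",
]

LOG_FLOOR = 1e-6


@dataclass
class DistanceMatrix:
    """Symmetric area-by-area Euclidean distances, zero diagonal."""

    areas: list[str]
    d: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.areas), len(self.areas)):
            raise ValueError("distance matrix shape does not match area list")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")

    def normalize(self) -> "DistanceMatrix":
        """Scale so the maximum distance is 1."""
        peak = self.d.max()
        if peak == 0:
            raise ValueError("cannot normalize an all-zero distance matrix")
        return DistanceMatrix(self.areas, self.d / peak, normalized=True)

    def lookup(self, a: str, b: str) -> float:
        i, j = self.areas.index(a), self.areas.index(b)
        return float(self.d[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.areas, columns=self.areas).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class CorrelationMatrices:
    """Pearson correlations of outgoing (source) / incoming (target) profiles."""

    areas: list[str]
    source_corr: np.ndarray
    target_corr: np.ndarray


def pairwise_distances(catalog: BrainAreaCatalog, normalize: bool = False) -> DistanceMatrix:
    """Euclidean distances between injection coordinates."""
    frame = catalog.frame
    coords = frame[["x", "y", "z"]].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        raise ValueError(
            f"missing coordinates for areas: {frame.loc[bad, 'acronym'].tolist()}"
        )
    dm = DistanceMatrix(frame["acronym"].tolist(), cdist(coords, coords))
    return dm.normalize() if normalize else dm


def mds_embed_2d(dm: DistanceMatrix) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling to two dimensions.

    Double-centers -D^2/2, eigendecomposes, and returns the coordinates
    along the top two eigenvectors scaled by the square roots of their
    eigenvalues.  Configurations that are exactly 1- or 2-D embeddable are
    reconstructed to numerical tolerance (up to rotation/reflection).
    """
    D = dm.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n < 2 or evals[1] <= 1e-12 * max(1.0, abs(evals[0])):
        warnings.warn(
            "fewer than 2 positive eigenvalues: embedding is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    top = np.clip(evals[:2], 0.0, None)
    return evecs[:, :2] * np.sqrt(top)


def strength_distance_correlation(
    table: ProjectionTable,
    dm: DistanceMatrix,
    hemisphere: str = "ipsi",
    min_targets: int = 3,
) -> pd.DataFrame:
    """Per source area: Pearson r of log10 strength vs distance to targets.

    Zero-strength pairs are excluded; areas with fewer than ``min_targets``
    positive connections in the requested hemisphere get NaN (flagged).
    Also reports the least-squares slope and intercept of log10 strength on
    distance, as in a scatter-plot regression.
    """
    if not table.is_aggregated:
        raise ValueError("aggregate the table first")
    rec = table.records
    rec = rec[(rec["hemisphere"] == hemisphere) & (rec["volume"] > 0)]
    rows = []
    for area in dm.areas:
        sub = rec[(rec["source"] == area) & (rec["target"] != area)]
        dists = np.array([dm.lookup(area, t) for t in sub["target"]])
        logs = np.log10(sub["volume"].to_numpy(dtype=float) + LOG_FLOOR)
        if len(sub) < min_targets or np.ptp(logs) == 0 or np.ptp(dists) == 0:
            rows.append((area, np.nan, np.nan, np.nan, len(sub)))
            continue
        r = float(np.corrcoef(dists, logs)[0, 1])
        slope, intercept = np.polyfit(dists, logs, 1)
        rows.append((area, r, float(slope), float(intercept), len(sub)))
    return pd.DataFrame(
        rows, columns=["area", "correlation", "slope", "intercept", "n_targets"]
    ).set_index("area")


def _strength_matrix(table: ProjectionTable) -> tuple[list[str], np.ndarray, np.ndarray]:
    """areas x (areas*2) log10 strength matrix (ipsi then contra columns).

    The boolean mask marks self-entries, which are excluded from profile
    correlations.
    """
    areas = table.catalog.acronyms
    index = {a: i for i, a in enumerate(areas)}
    n = len(areas)
    M = np.zeros((n, 2 * n))
    for row in table.records.itertuples():
        j = index[row.target] + (0 if row.hemisphere == "ipsi" else n)
        M[index[row.source], j] = row.volume
    M = np.log10(M + LOG_FLOOR)
    mask = np.zeros((n, 2 * n), dtype=bool)
    for i in range(n):
        mask[i, i] = mask[i, n + i] = True
    return areas, M, mask


def _masked_row_correlations(M: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between rows of a masked matrix."""
    n = M.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            keep = ~(mask[i] | mask[j])
            xi, xj = M[i, keep], M[j, keep]
            if keep.sum() < 2 or np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue  # undefined, stays NaN (flagged)
            out[i, j] = out[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return out


def projection_profile_correlations(table: ProjectionTable) -> CorrelationMatrices:
    """Similarity of areas as projection sources and as projection targets.

    ``source_corr[i, j]`` correlates the outgoing log-strength profiles of
    areas i and j (both hemispheres concatenated, self-entries masked);
    ``target_corr`` does the same for incoming profiles.  Zero-variance
    profiles yield NaN entries.
    """
    if not table.is_aggregated:
        raise ValueError("aggregate the table first")
    areas, M, mask = _strength_matrix(table)
    n = len(areas)
    source_corr = _masked_row_correlations(M, mask)
    # incoming profiles: stack the ipsi and contra target columns
    Mt = np.concatenate([M[:, :n].T, M[:, n:].T], axis=1)
    mask_t = np.concatenate([mask[:, :n].T, mask[:, n:].T], axis=1)
    target_corr = _masked_row_correlations(Mt, mask_t)
    return CorrelationMatrices(areas, source_corr, target_corr)
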