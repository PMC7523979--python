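"""Genetic distance (1 - IBS), principal coordinates, and the Evanno ΔK summary.

Identity by state between two lines at a locus is the probability that
one allele drawn from each is the same: 1 for identical homozygotes, 0
for opposite homozygotes, 1/2 whenever either call is heterozygous (the
latter cannot occur in fully inbred material but the convention is fixed
here because upstream tools differ).  The panel distance is 1 minus the
mean IBS over markers called in both lines.

The ΔK summary consumes a plain (K, run, logL) table from externally
produced model-based clustering runs; the clustering itself is out of
scope for this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


class PopgenError(ValueError):
    """Raised on invalid diversity-analysis input."""


# ================================================================= distances
@dataclass
class DistanceMatrix:
    """Symmetric 1-IBS distance matrix with per-pair marker counts."""

    line_ids: list[str]
    values: np.ndarray  # (n, n), NaN where no shared markers
    n_shared: np.ndarray  # (n, n) int, markers compared per pair

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise PopgenError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise PopgenError("distance diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise PopgenError("distance matrix must be symmetric")
        finite = self.values[np.isfinite(self.values)]
        if ((finite < -1e-12) | (finite > 1 + 1e-12)).any():
            raise PopgenError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def ibs_distance(geno: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - mean(IBS) over markers non-missing in both lines.

    A pair with zero shared markers gets NaN (flagged missing).
    Invariant to swapping the ref/alt labelling of any marker.
    """
    if geno.n_lines < 2:
        raise PopgenError("need at least two lines")
    calls = geno.calls.astype(float)
    calls[geno.calls == MISSING] = np.nan
    n = geno.n_lines
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            m = int(ok.sum())
            shared[i, j] = shared[j, i] = m
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            gi, gj = calls[i, ok], calls[j, ok]
            # match prob per locus: 1 - |gi-gj|/2, with het-het fixed at 1/2
            ibs = 1.0 - np.abs(gi - gj) / 2.0
            both_het = (gi == 1) & (gj == 1)
            ibs[both_het] = 0.5
            d = 1.0 - ibs.mean()
            dist[i, j] = dist[j, i] = d
    shared[np.arange(n), np.arange(n)] = (~np.isnan(calls)).sum(axis=1)
    return DistanceMatrix(list(geno.line_ids), dist, shared)


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    dist.to_frame().to_csv(path, sep="\t", index_label="line")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line")
    ids = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != ids:
        raise PopgenError("distance file rows and columns disagree")
    values = df.to_numpy(dtype=float)
    n = len(ids)
    shared = np.zeros((n, n), dtype=int)  # counts are not serialized
    return DistanceMatrix(ids, values, shared)


# ===================================================================== PCoA
@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` is lines x axes (centered columns); ``eigenvalues``
    holds the full descending spectrum of the double-centered matrix
    (negative values reported but carrying no axis);
    ``proportion_explained`` is relative to the positive eigenvalue sum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix, n_axes: int | None = None,
         standardize: bool = False) -> PcoaResult:
    """Principal coordinate analysis (Gower's classical metric scaling).

    Squares the distances, double-centers (-1/2 J D2 J), eigendecomposes,
    and scales eigenvectors by the square root of their (positive)
    eigenvalues.  ``standardize`` optionally divides the distances by
    their largest value first — an option because range-standardization
    conventions differ between ordination tools; the embedding geometry
    is unchanged up to scale.
    """
    D = np.asarray(dist.values, dtype=float)
    if np.isnan(D).any():
        raise PopgenError(
            "distance matrix has missing entries; complete the pairs "
            "(e.g. restrict to lines with shared markers) before ordination"
        )
    if standardize:
        mx = D.max()
        if mx > 0:
            D = D / mx
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = evals[pos].sum()
    prop = np.where(pos, evals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dist.line_ids, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ================================================================ Evanno ΔK
def read_likelihood_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"K", "run", "logL"} - set(df.columns)
    if missing:
        raise PopgenError(f"likelihood table lacks columns {sorted(missing)}")
    return df


def evanno_delta_k(tab: pd.DataFrame) -> pd.DataFrame:
    """Evanno's ΔK from replicate log-likelihoods over consecutive K.

    ΔK(K) = mean over replicate runs of |L_r(K+1) - 2 L_r(K) + L_r(K-1)|
    divided by the standard deviation of L(K) across runs.  Endpoints of
    the K range get no value; a K whose replicates are all equal (zero
    standard deviation) is flagged undefined rather than crashing.

    ``tab`` needs columns K, run, logL with >= 3 consecutive K values and
    >= 2 run-aligned replicates per K.
    """
    missing = {"K", "run", "logL"} - set(tab.columns)
    if missing:
        raise PopgenError(f"likelihood table lacks columns {sorted(missing)}")
    wide = tab.pivot_table(index="run", columns="K", values="logL")
    ks = sorted(int(k) for k in wide.columns)
    if len(ks) < 3:
        raise PopgenError("ΔK needs at least three consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise PopgenError("K values must be consecutive integers")
    if wide.isna().any().any() or len(wide) < 2:
        raise PopgenError("ΔK needs >= 2 run-aligned replicates at every K")
    rows = []
    for k in ks:
        col = wide[k]
        if k == ks[0] or k == ks[-1]:
            rows.append((k, col.mean(), col.std(ddof=1), np.nan, False))
            continue
        sd = col.std(ddof=1)
        second = (wide[k + 1] - 2.0 * wide[k] + wide[k - 1]).abs().mean()
        if sd == 0:
            rows.append((k, col.mean(), 0.0, np.nan, True))
        else:
            rows.append((k, col.mean(), sd, second / sd, False))
    return pd.DataFrame(
        rows, columns=["K", "mean_logL", "sd_logL", "delta_k", "undefined"]
    )
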