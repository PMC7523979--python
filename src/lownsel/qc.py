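"""Marker quality control: call-rate/MAF filtering and window LD pruning.

Thresholds follow array-panel convention: a marker is kept when its call
rate and minor-allele frequency are at or above the thresholds
(inclusive), and a window pair is pruned when its squared allele-count
correlation is strictly above the LD threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypeMatrix


@dataclass
class QcReport:
    markers_in: int
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_ld: int = 0
    markers_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        removed = self.removed_call_rate + self.removed_maf + self.removed_ld
        if self.markers_out != self.markers_in - removed:
            raise ValueError("QcReport counts do not reconcile")

    def to_text(self) -> str:
        rows = [
            ("markers_in", self.markers_in),
            ("removed_call_rate", self.removed_call_rate),
            ("removed_maf", self.removed_maf),
            ("removed_ld", self.removed_ld),
            ("markers_out", self.markers_out),
        ]
        head = "\t".join(f"{k}={v}" for k, v in sorted(self.thresholds.items()))
        return "# " + head + "\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def filter_markers(
    geno: GenotypeMatrix, min_call_rate: float = 0.90, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep markers with call rate >= min_call_rate and MAF >= min_maf.

    MAF is computed on non-missing homozygous calls (each inbred line
    contributes one allele draw).  Marker order is preserved;
    idempotent by construction.
    """
    for name, t in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    cr = geno.call_rate()
    maf = geno.maf()
    # compare in counts to dodge float representation at the boundary
    n = geno.n_lines
    pass_cr = (cr * n) >= (min_call_rate * n) - 1e-9
    with np.errstate(invalid="ignore"):
        pass_maf = maf >= min_maf - 1e-12
    pass_maf = np.where(np.isnan(maf), False, pass_maf)
    keep = pass_cr & pass_maf
    report = QcReport(
        markers_in=geno.n_markers,
        removed_call_rate=int((~pass_cr).sum()),
        removed_maf=int((pass_cr & ~pass_maf).sum()),
        markers_out=int(keep.sum()),
        thresholds={"min_call_rate": min_call_rate, "min_maf": min_maf},
    )
    if report.markers_out == 0:
        warnings.warn("all markers removed by QC filters", stacklevel=2)
    return geno.subset_markers(keep), report


def _pairwise_r2(geno: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of allele-count codes over pairwise-complete lines."""
    sub = geno.calls[:, idx].astype(float)
    sub[geno.calls[:, idx] == -1] = np.nan
    k = len(idx)
    r2 = np.zeros((k, k))
    valid = ~np.isnan(sub)
    for a in range(k):
        for b in range(a + 1, k):
            ok = valid[:, a] & valid[:, b]
            if ok.sum() < 2:
                continue
            x, y = sub[ok, a], sub[ok, b]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return r2


def _prune_window(
    geno: GenotypeMatrix, window_idx: list[int], r2_threshold: float,
    maf: np.ndarray, pos: np.ndarray, removed: set[int],
) -> None:
    """Greedy within-window pruning; mutates ``removed``.

    Repeatedly finds the live pair with the largest r^2 above the
    threshold (ties resolved by position order) and removes the member
    with the lower MAF, breaking ties toward the later position.
    """
    idx = np.array([i for i in window_idx if i not in removed])
    if len(idx) < 2:
        return
    r2 = _pairwise_r2(geno, idx)
    alive = np.ones(len(idx), dtype=bool)
    while True:
        r2a = np.where(np.outer(alive, alive), r2, 0.0)
        np.fill_diagonal(r2a, 0.0)
        mx = r2a.max()
        if mx <= r2_threshold:
            break
        a, b = np.unravel_index(np.argmax(r2a), r2a.shape)
        a, b = min(a, b), max(a, b)
        i, j = idx[a], idx[b]
        if maf[i] < maf[j]:
            drop_local = a
        elif maf[j] < maf[i]:
            drop_local = b
        else:  # MAF tie: drop the later position
            drop_local = b if pos[j] >= pos[i] else a
        alive[drop_local] = False
        removed.add(int(idx[drop_local]))


def ld_prune(
    geno: GenotypeMatrix,
    r2_threshold: float = 0.13,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sliding-window LD pruning within chromosomes.

    Windows of ``window`` markers advance by ``step``; in each window any
    surviving pair with r^2 strictly above ``r2_threshold`` loses one
    member (the lower-MAF marker; position tie-break).  Deterministic for
    a given input.  Markers must be position-sorted within chromosome
    (use :meth:`GenotypeMatrix.sorted_by_position` first if unsure).
    """
    if window < 2:
        raise ValueError("window must be >= 2 markers")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in [0, 1]")
    geno = geno.sorted_by_position()
    maf = geno.maf()
    pos = geno.marker_map["pos"].to_numpy()
    chrom = geno.marker_map["chrom"].to_numpy()
    removed: set[int] = set()
    # sweep until a fixpoint: after removals, surviving markers shift into
    # shared windows, so the output carries no within-window violating pair
    while True:
        before = len(removed)
        for c in dict.fromkeys(chrom):
            cidx = [int(i) for i in np.flatnonzero(chrom == c) if i not in removed]
            start = 0
            while start < len(cidx):
                win = cidx[start : start + window]
                _prune_window(geno, win, r2_threshold, maf, pos, removed)
                if start + window >= len(cidx):
                    break
                start += step
        if len(removed) == before:
            break
    keep = np.array([i for i in range(geno.n_markers) if i not in removed])
    report = QcReport(
        markers_in=geno.n_markers,
        removed_ld=len(removed),
        markers_out=geno.n_markers - len(removed),
        thresholds={"r2_threshold": r2_threshold, "window": window, "step": step},
    )
    return geno.subset_markers(keep), report
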