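"""Per-SNP Weir-Cockerham Fst contrast scan and favorable-allele scoring.

The scan contrasts two phenotypically defined groups of inbred lines
(high vs low low-N tolerance) marker by marker.  Because the lines are
fully homozygous, each contributes a single independent allele draw, so
the moment estimator used is the haploid-sample Weir & Cockerham theta:
with r groups of sizes n_i and alternate-allele frequencies p_i,

    nbar = mean(n_i)
    n_c  = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
    pbar = sum n_i p_i / sum n_i
    s2   = sum n_i (p_i - pbar)^2 / ((r - 1) nbar)
    T1   = s2 - [pbar(1-pbar) - s2 (r-1)/r] / (nbar - 1)
    T2   = pbar(1-pbar) (n_c - 1)/(nbar - 1)
           + [1 + (r-1)(nbar - n_c)/(nbar - 1)] s2 / r
    theta = T1 / T2

Small-sample theta can be negative; values are reported as computed
(optionally clamped at zero).  Markers monomorphic across both groups
have theta undefined and are flagged.

Downstream, markers above a fixed theta threshold (0.2 by convention
for this contrast design) are called under directional selection; at
each such marker the favorable allele is the one enriched in the
high-tolerance group, and each line's NFA is the number of outlier loci
at which it is homozygous for the favorable allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix
from .pheno import GroupAssignment


class SelscanError(ValueError):
    """Raised on invalid selection-scan input."""


# ========================================================= theta estimator
def theta_wc(n, p):
    """Haploid-sample Weir-Cockerham theta from group sizes and frequencies.

    Parameters
    ----------
    n : array-like, shape (r,) or (r, m)
        Allele-draw counts per group (one per inbred line).
    p : array-like, matching shape
        Alternate (or favorable) allele frequency per group.

    Returns a scalar (1-D input) or an array over markers; NaN where the
    pooled frequency is monomorphic.  Invariant to relabelling the
    alleles (p -> 1-p in every group).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if n.shape != p.shape:
        raise SelscanError("n and p must have matching shapes")
    scalar = n.ndim == 1
    if scalar:
        n, p = n[:, None], p[:, None]
    r = n.shape[0]
    if r < 2:
        raise SelscanError("need at least two groups")
    if np.any((p < 0) | (p > 1)):
        raise SelscanError("frequencies must lie in [0, 1]")
    if np.any(n < 2):
        raise SelscanError("each group needs >= 2 allele draws")
    nsum = n.sum(axis=0)
    nbar = nsum / r
    nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
        t2 = pbar * (1 - pbar) * (nc - 1) / (nbar - 1) + (
            1 + (r - 1) * (nbar - nc) / (nbar - 1)
        ) * s2 / r
        theta = np.where(t2 != 0, t1 / np.where(t2 != 0, t2, 1.0), np.nan)
    mono = (pbar == 0) | (pbar == 1)
    theta = np.where(mono, np.nan, theta)
    return float(theta[0]) if scalar else theta


def _two_groups(groups, high=None) -> tuple[pd.Series, str, str]:
    """Normalize a grouping input into (labels, high label, low label)."""
    if isinstance(groups, GroupAssignment):
        labels = groups.labels.astype(str)
        uniq = sorted(labels.unique(), key=lambda s: int(s))
        if len(uniq) != 2:
            raise SelscanError(
                f"the contrast scan needs exactly two groups, got {len(uniq)}"
            )
        return labels, uniq[0], uniq[1]  # group 1 = highest mean
    labels = pd.Series(groups).astype(str)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise SelscanError(
            f"the contrast scan needs exactly two groups, got {len(uniq)}"
        )
    if high is None:
        if set(uniq) == {"H", "L"}:
            return labels, "H", "L"
        raise SelscanError("ambiguous grouping: pass high=<label of the high group>")
    high = str(high)
    if high not in uniq:
        raise SelscanError(f"high label {high!r} not among groups {uniq}")
    low = uniq[0] if uniq[1] == high else uniq[1]
    return labels, high, low


# ================================================================= Fst scan
def wc_fst(
    geno: GenotypeMatrix, groups, high=None, clamp_negative: bool = False
) -> pd.DataFrame:
    """Per-marker haploid Weir-Cockerham theta between two line groups.

    ``groups`` is a :class:`~lownsel.pheno.GroupAssignment` (group 1 =
    high-mean group) or a line-indexed Series of two labels with ``high``
    naming the high group.  Returns a marker-ordered DataFrame with
    chromosome, position, alleles, per-group called-line counts and
    alternate-allele frequencies, theta (``fst``), and a ``flag`` column:
    empty, "monomorphic", or "insufficient" (a group with < 2 called
    lines — reported, never silently dropped).
    """
    labels, hi_lab, lo_lab = _two_groups(groups, high)
    missing_lines = set(labels.index) - set(geno.line_ids)
    if missing_lines:
        raise SelscanError(f"group labels for unknown lines: {sorted(missing_lines)[:5]}")
    lab = labels.reindex(geno.line_ids)
    if lab.isna().any():
        raise SelscanError(
            f"{int(lab.isna().sum())} lines lack a group label"
        )
    hi_rows = np.flatnonzero((lab == hi_lab).to_numpy())
    lo_rows = np.flatnonzero((lab == lo_lab).to_numpy())

    called = geno.calls != MISSING
    alt = geno.calls == 2
    n1 = called[hi_rows].sum(axis=0).astype(float)
    n2 = called[lo_rows].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, alt[hi_rows].sum(axis=0) / np.maximum(n1, 1), np.nan)
        p2 = np.where(n2 > 0, alt[lo_rows].sum(axis=0) / np.maximum(n2, 1), np.nan)

    theta = np.full(geno.n_markers, np.nan)
    ok = (n1 >= 2) & (n2 >= 2)
    if ok.any():
        theta[ok] = theta_wc(
            np.vstack([n1[ok], n2[ok]]), np.vstack([p1[ok], p2[ok]])
        )
    if clamp_negative:
        theta = np.where(np.isnan(theta), np.nan, np.maximum(theta, 0.0))

    flag = np.where(~ok, "insufficient", "")
    pbar_mono = np.zeros(geno.n_markers, dtype=bool)
    with np.errstate(invalid="ignore"):
        pbar = (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1)
    pbar_mono[ok] = (pbar[ok] == 0) | (pbar[ok] == 1)
    flag = np.where(pbar_mono, "monomorphic", flag)

    m = geno.marker_map
    return pd.DataFrame(
        {
            "marker": geno.marker_ids,
            "chrom": m["chrom"].to_numpy(),
            "pos": m["pos"].to_numpy(),
            "ref": m["ref"].to_numpy(),
            "alt": m["alt"].to_numpy(),
            "n_high": n1.astype(int),
            "n_low": n2.astype(int),
            "p_high": p1,
            "p_low": p2,
            "fst": theta,
            "flag": flag,
        }
    )


def outlier_scan(fst: pd.DataFrame, threshold: float = 0.2) -> tuple[pd.DataFrame, float]:
    """Markers with theta strictly above ``threshold``.

    Returns the outlier subset sorted by (chromosome, position) plus the
    genome-wide mean theta over defined values.  An empty result is
    legitimate (warned for the all-undefined case).
    """
    defined = fst["fst"].notna()
    if not defined.any():
        warnings.warn("no marker has a defined Fst (all monomorphic?)", stacklevel=2)
        return fst.iloc[0:0].copy(), float("nan")
    mean_fst = float(fst.loc[defined, "fst"].mean())
    out = fst[defined & (fst["fst"] > threshold)].copy()
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out, mean_fst


# ======================================================== favorable alleles
def favorable_alleles(
    geno: GenotypeMatrix, groups, outliers: pd.DataFrame, high=None
) -> pd.DataFrame:
    """Favorable allele and its group frequencies at each outlier marker.

    The favorable allele is the one enriched in the high-tolerance group
    relative to the low group (it may well be a minority allele in both),
    so FFA_high >= FFA_low by construction.  An exact between-group
    frequency tie yields no favorable allele and the marker is excluded
    (warned).
    """
    labels, hi_lab, lo_lab = _two_groups(groups, high)
    fst_by_marker = outliers.set_index("marker")
    mindex = {mid: j for j, mid in enumerate(geno.marker_ids)}
    rows, dropped = [], []
    for mid, row in fst_by_marker.iterrows():
        j = mindex.get(mid)
        if j is None:
            raise SelscanError(f"outlier marker {mid} absent from genotype matrix")
        p_hi, p_lo = row["p_high"], row["p_low"]
        if np.isnan(p_hi) or np.isnan(p_lo):
            dropped.append(mid)
            continue
        if p_hi == p_lo:
            dropped.append(mid)
            continue
        if p_hi > p_lo:  # alt allele enriched in the high group
            fa, ffa_h, ffa_l = geno.marker_map.iloc[j]["alt"], p_hi, p_lo
        else:
            fa, ffa_h, ffa_l = geno.marker_map.iloc[j]["ref"], 1 - p_hi, 1 - p_lo
        rows.append(
            (
                mid,
                row["chrom"],
                row["pos"],
                f"{geno.marker_map.iloc[j]['ref']}/{geno.marker_map.iloc[j]['alt']}",
                fa,
                ffa_h,
                ffa_l,
            )
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} outlier marker(s) with a tied or undefined favorable "
            f"allele excluded: {dropped[:5]}",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["marker", "chrom", "pos", "alleles", "favorable_allele",
                 "ffa_high", "ffa_low"],
    )


def nfa_scores(
    geno: GenotypeMatrix, fav: pd.DataFrame, lnae: pd.Series | None = None,
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Per-line count of outlier loci homozygous for the favorable allele.

    ``missing_policy``: "zero" (default) counts a missing call as not
    carrying the allele; "scale" rescales the count by
    n_outliers / n_called so lines with missing calls are not penalized
    (non-integer scores).  NFA counts loci (0/1 each), not allele dosage.
    """
    if fav.empty:
        raise SelscanError("no favorable alleles defined")
    if missing_policy not in ("zero", "scale"):
        raise SelscanError(f"unknown missing_policy {missing_policy!r}")
    mindex = {mid: j for j, mid in enumerate(geno.marker_ids)}
    cols, fav_is_alt = [], []
    for _, row in fav.iterrows():
        j = mindex[row["marker"]]
        cols.append(j)
        fav_is_alt.append(row["favorable_allele"] == geno.marker_map.iloc[j]["alt"])
    sub = geno.calls[:, cols]
    fav_is_alt = np.asarray(fav_is_alt)
    carries = np.where(fav_is_alt[None, :], sub == 2, sub == 0)
    called = sub != MISSING
    nfa = carries.sum(axis=1).astype(float)
    if missing_policy == "scale":
        k = len(cols)
        ncalled = called.sum(axis=1)
        nfa = np.where(ncalled > 0, nfa * k / np.maximum(ncalled, 1), 0.0)
    out = pd.DataFrame({"line": geno.line_ids, "nfa": nfa})
    if missing_policy == "zero":
        out["nfa"] = out["nfa"].astype(int)
    if lnae is not None:
        out["lnae"] = out["line"].map(pd.Series(lnae))
    return out


# ============================================================== association
@dataclass
class Association:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def nfa_lnae_association(nfa: pd.DataFrame, lnae: pd.Series | None = None) -> Association:
    """Pearson correlation and simple regression of LNAE on NFA.

    For the simple regression R^2 equals the squared correlation; this
    identity is asserted internally.  Zero variance in NFA makes the
    correlation undefined (raises with a clear message).
    """
    df = nfa.copy()
    if lnae is not None:
        df["lnae"] = df["line"].map(pd.Series(lnae))
    if "lnae" not in df.columns:
        raise SelscanError("no LNAE values supplied")
    df = df.dropna(subset=["nfa", "lnae"])
    if len(df) < 3:
        raise SelscanError("association needs >= 3 lines with both NFA and LNAE")
    x = df["nfa"].to_numpy(dtype=float)
    y = df["lnae"].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise SelscanError("NFA has zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    r2 = reg.rvalue**2
    assert abs(r2 - r * r) < 1e-12, "simple-regression identity violated"
    return Association(
        pearson_r=float(r), p_value=float(p), slope=float(reg.slope),
        intercept=float(reg.intercept), r_squared=float(r2), n=len(df),
    )


# ==================================================================== plots
def manhattan_fst(fst: pd.DataFrame, path, threshold: float = 0.2) -> None:
    """Fst by genome position, one color band per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset, ticks, labels = 0.0, [], []
    chroms = list(dict.fromkeys(fst["chrom"]))
    for k, c in enumerate(chroms):
        sub = fst[fst["chrom"] == c]
        x = sub["pos"].to_numpy(dtype=float) + offset
        ax.scatter(x, sub["fst"], s=4, color="C0" if k % 2 == 0 else "C1",
                   rasterized=True)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(c))
        offset += sub["pos"].max() * 1.02
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("Fst")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def lnae_vs_nfa_plot(nfa: pd.DataFrame, assoc: Association, path) -> None:
    """Scatter of LNAE against NFA with the fitted regression line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(nfa["nfa"], nfa["lnae"], s=14)
    xs = np.linspace(nfa["nfa"].min(), nfa["nfa"].max(), 20)
    ax.plot(xs, assoc.intercept + assoc.slope * xs, color="red", lw=1)
    ax.set_xlabel("number of favorable alleles (NFA)")
    ax.set_ylabel("LNAE (kg/ha)")
    ax.set_title(f"r = {assoc.pearson_r:.2f}, R² = {assoc.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
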