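"""I/O for genotype matrices, marker maps, and plot-level phenotype tables.

Genotypes are held as a lines x markers matrix of alternate-allele copy
counts.  Because the material is fully inbred, the call alphabet is
{0, 2, MISSING}: homozygous reference, homozygous alternate, or no call.
Alleles are stored exactly as given by the upstream source; orientation
("minor", "favorable") is a downstream concept and no strand flipping is
ever applied here.

Positions are 1-based base pairs, as conventional for SNP array annotation.
Missing cells are never imputed at I/O time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1
NUCLEOTIDES = frozenset("ACGT")
N_LEVELS = ("IN", "LN")

PHENO_COLUMNS = ["line", "environment", "n_level", "rep", "block", "grain_yield"]
PHENO_KEY = ["line", "environment", "n_level", "rep"]


class GenioError(ValueError):
    """Raised on malformed genotype/phenotype input."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a panel of inbred lines.

    Parameters
    ----------
    line_ids
        Ordered line identifiers (rows of ``calls``).
    marker_ids
        Ordered marker identifiers (columns of ``calls``).
    calls
        ``(n_lines, n_markers)`` int8 array of alternate-allele copy
        counts in {0, 2} with ``MISSING`` (-1) for no-calls.
    marker_map
        DataFrame indexed by marker id with columns
        ``chrom`` (str), ``pos`` (1-based bp), ``ref``, ``alt``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenioError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.calls, (0, 2, MISSING))
        if bad.any():
            raise GenioError(
                f"{bad.sum()} genotype calls outside the inbred alphabet {{0, 2, {MISSING}}}"
            )
        m = self.marker_map
        missing_cols = {"chrom", "pos", "ref", "alt"} - set(m.columns)
        if missing_cols:
            raise GenioError(f"marker map lacks columns {sorted(missing_cols)}")
        if list(m.index) != self.marker_ids:
            raise GenioError("marker map index does not match marker_ids order")
        for col in ("ref", "alt"):
            alle = m[col].astype(str)
            if not alle.isin(list(NUCLEOTIDES)).all():
                bad_m = m.index[~alle.isin(list(NUCLEOTIDES))][0]
                raise GenioError(f"marker {bad_m}: allele {col!r} not a single nucleotide")
        if (m["ref"] == m["alt"]).any():
            bad_m = m.index[m["ref"] == m["alt"]][0]
            raise GenioError(f"marker {bad_m}: ref and alt alleles identical")
        # positions must be sortable strictly increasing within chromosome
        for chrom, sub in m.groupby("chrom", sort=False):
            pos = np.sort(sub["pos"].to_numpy())
            if len(pos) > 1 and (np.diff(pos) <= 0).any():
                raise GenioError(f"duplicate positions on chromosome {chrom}")

    # ------------------------------------------------------------------ views
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing lines.

        Inbred lines contribute a single allele draw each (calls/2), so
        the frequency is the mean of calls/2 over called lines.  Markers
        with no calls at all yield NaN.
        """
        ok = ~self.missing_mask()
        with np.errstate(invalid="ignore"):
            num = np.where(ok, self.calls, 0).sum(axis=0) / 2.0
            den = ok.sum(axis=0)
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # --------------------------------------------------------------- subsets
    def subset_markers(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.marker_ids[i] for i in keep]
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=ids,
            calls=self.calls[:, keep].copy(),
            marker_map=self.marker_map.iloc[keep].copy(),
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Markers reordered by (chromosome label, position)."""
        order = np.lexsort(
            (self.marker_map["pos"].to_numpy(), self.marker_map["chrom"].to_numpy())
        )
        if np.array_equal(order, np.arange(self.n_markers)):
            return self
        return self.subset_markers(order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and self.marker_map.reset_index(drop=True).equals(
                other.marker_map.reset_index(drop=True)
            )
        )


# ====================================================================== VCF
_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write as VCF 4.2 with homozygous diploid GT fields (0/0, 1/1, ./.)."""
    path = Path(path)
    gt_str = {0: "0/0", 2: "1/1", MISSING: "./."}
    m = geno.marker_map
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(m["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.line_ids)
            + "\n"
        )
        for j, mid in enumerate(geno.marker_ids):
            row = m.iloc[j]
            gts = "\t".join(gt_str[int(c)] for c in geno.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: str | Path, het_policy: str = "missing") -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Heterozygous calls cannot occur in fully inbred material; under the
    default policy ``"missing"`` they are set missing with a warning,
    under ``"strict"`` they raise.  Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "strict"):
        raise GenioError(f"unknown heterozygote policy {het_policy!r}")
    path = Path(path)
    if not path.exists():
        raise GenioError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports its own diagnostics
        raise GenioError(f"cannot parse VCF {path}: {exc}") from exc
    lines = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids, chroms, poss, refs, alts = [], [], [], [], []
    n_het = 0
    for rec_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise GenioError(
                f"{path}: record {rec_no} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        col = np.full(len(lines), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 2
        het = gt == 1
        if het.any():
            if het_policy == "strict":
                raise GenioError(
                    f"{path}: heterozygous call at record {rec_no} "
                    f"({var.CHROM}:{var.POS}) under strict policy"
                )
            n_het += int(het.sum())
        cols.append(col)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(str(var.REF))
        alts.append(str(var.ALT[0]))
    if n_het:
        warnings.warn(f"{n_het} heterozygous calls set to missing", stacklevel=2)
    if not cols:
        raise GenioError(f"{path}: VCF contains no variant records")
    marker_map = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}, index=ids
    )
    return GenotypeMatrix(lines, ids, np.column_stack(cols), marker_map)


# ============================================================== tabular dialect
def write_genotypes_table(
    geno: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None
) -> None:
    """Write the tab-delimited genotype dialect plus its map sidecar.

    The matrix file has a header row of marker ids and one row per line;
    cells are nucleotide pairs ("AA", "GG") with "NN" for missing.  The
    sidecar (default ``<path>.map``) holds marker, chrom, pos, ref, alt.
    """
    path = Path(path)
    map_path = Path(map_path) if map_path is not None else path.with_suffix(path.suffix + ".map")
    m = geno.marker_map
    ref = m["ref"].to_numpy(dtype=object)
    alt = m["alt"].to_numpy(dtype=object)
    with open(path, "w") as fh:
        fh.write("line\t" + "\t".join(geno.marker_ids) + "\n")
        for i, lid in enumerate(geno.line_ids):
            row = geno.calls[i]
            cells = np.where(row == 0, ref + ref, np.where(row == 2, alt + alt, "NN"))
            fh.write(lid + "\t" + "\t".join(cells) + "\n")
    m.reset_index(names="marker").to_csv(map_path, sep="\t", index=False)


def read_genotypes_table(
    path: str | Path, map_path: str | Path | None = None
) -> GenotypeMatrix:
    path = Path(path)
    map_path = Path(map_path) if map_path is not None else path.with_suffix(path.suffix + ".map")
    for p in (path, map_path):
        if not p.exists():
            raise GenioError(f"file not found: {p}")
    marker_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str}).set_index("marker")
    tab = pd.read_csv(path, sep="\t", dtype=str).set_index("line")
    if list(tab.columns) != list(marker_map.index):
        raise GenioError("matrix header markers do not match the map sidecar")
    ref = marker_map["ref"].to_numpy(dtype=object)
    alt = marker_map["alt"].to_numpy(dtype=object)
    cells = tab.to_numpy(dtype=object)
    calls = np.full(cells.shape, MISSING, dtype=np.int8)
    calls[cells == ref + ref] = 0
    calls[cells == alt + alt] = 2
    unknown = (cells != ref + ref) & (cells != alt + alt) & (cells != "NN")
    if unknown.any():
        j = int(np.argwhere(unknown)[0, 1])
        raise GenioError(
            f"marker {marker_map.index[j]}: cell {cells[np.argwhere(unknown)[0,0], j]!r} "
            f"does not match alleles {ref[j]}/{alt[j]}"
        )
    return GenotypeMatrix(list(tab.index), list(marker_map.index), calls, marker_map)


# ================================================================= phenotypes
def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a plot-level phenotype table.

    Requires columns line, environment, n_level, rep, block, grain_yield;
    N level must be IN or LN, yields non-negative, and the key
    (line, environment, n_level, rep) unique.
    """
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise GenioError(f"phenotype table lacks columns {sorted(missing)}")
    out = df.loc[:, PHENO_COLUMNS].copy()
    for col in ("line", "environment", "n_level", "block"):
        out[col] = out[col].astype(str)
    out["rep"] = out["rep"].astype(int)
    out["grain_yield"] = pd.to_numeric(out["grain_yield"], errors="raise").astype(float)
    bad_level = ~out["n_level"].isin(N_LEVELS)
    if bad_level.any():
        raise GenioError(
            f"unknown N level token(s): {sorted(out.loc[bad_level, 'n_level'].unique())}"
        )
    if (out["grain_yield"] < 0).any():
        raise GenioError("negative grain yield encountered")
    if not np.isfinite(out["grain_yield"]).all():
        raise GenioError("non-finite grain yield encountered")
    dup = out.duplicated(subset=PHENO_KEY)
    if dup.any():
        first = out.loc[dup, PHENO_KEY].iloc[0].tolist()
        raise GenioError(f"duplicate phenotype key {tuple(first)}")
    return out.reset_index(drop=True)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a delimited phenotype file (delimiter sniffed) and validate it."""
    path = Path(path)
    if not path.exists():
        raise GenioError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)
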