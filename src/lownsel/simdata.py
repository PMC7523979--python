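"""Synthetic genotypes and phenotypes for a low-N tolerance contrast panel.

The generator emulates the structure the downstream analysis assumes: a
panel of fully homozygous inbred lines genotyped at biallelic SNPs spread
over ten chromosomes, split a priori into a high-tolerance (H) and a
low-tolerance (L) group.  Most loci are neutral — one shared allele
frequency for both groups — while a handful of "planted" loci carry a
large favorable-allele frequency differential between the groups (the
kind of contrast a directional-selection scan should recover, e.g. 0.45
in H vs 0.05 in L).

Phenotypes are plot-level grain yields from paired optimal-N (IN) and
low-N (LN) fields laid out as incomplete blocks within replicates.  The
genetic signal enters only through the low-N yield: each favorable
allele a line carries adds a fixed number of kg/ha to its LN plots, so
the derived low-N agronomic efficiency index correlates with the
planted favorable-allele count.

Every draw flows from the single ``SimConfig.seed`` through independent
child streams, so genotype and phenotype simulation are individually
reproducible and phenotypes can be re-simulated on fixed genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

_NUC = np.array(list("ACGT"))


class SimError(ValueError):
    """Raised on invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the field-trial design the package targets: 64 inbred
    lines (29 high-tolerance, 35 low-tolerance), ~12,050 SNPs over 10
    chromosomes, three environments each with two replicates of an 8x8
    incomplete-block layout under paired IN/LN nitrogen regimes
    (150/60 and 100/35 kg N per ha).

    ``effect_per_favorable_allele`` is the kg/ha added to a line's low-N
    yield per favorable allele carried; the default of 150 targets an
    NFA-LNAE correlation of roughly 0.7 at panel scale.
    """

    n_lines: int = 64
    n_high_lines: int = 29
    n_snps: int = 12050
    n_chromosomes: int = 10
    chromosome_length_bp: int = 240_000_000
    n_selected_loci: int = 4
    freq_high_group: float | tuple[float, ...] = 0.45
    freq_low_group: float | tuple[float, ...] = 0.05
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    selected_sampling: str = "exact"  # "exact" or "binomial"
    effect_per_favorable_allele: float = 150.0
    n_environments: int = 3
    n_reps: int = 2
    n_doses: tuple[tuple[float, float], ...] = ((150.0, 60.0), (100.0, 35.0))
    baseline_in: float = 5500.0
    baseline_ln: float = 2800.0
    env_effect_span: float = 500.0
    block_size: int = 8
    residual_sd: float = 350.0
    block_sd: float = 250.0
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_lines": self.n_lines,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_environments": self.n_environments,
            "n_reps": self.n_reps,
            "block_size": self.block_size,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise SimError(f"{name} must be a positive integer, got {v!r}")
        if not 0 < self.n_high_lines < self.n_lines:
            raise SimError("n_high_lines must be strictly between 0 and n_lines")
        if self.n_selected_loci < 0 or self.n_selected_loci >= self.n_snps:
            raise SimError("require 0 <= n_selected_loci < n_snps")
        for name, p in (
            ("missing_rate", self.missing_rate),
            *(("freq_high_group", f) for f in self._freqs(self.freq_high_group)),
            *(("freq_low_group", f) for f in self._freqs(self.freq_low_group)),
            *(("background_freq_range", f) for f in self.background_freq_range),
        ):
            if not 0.0 <= p <= 1.0:
                raise SimError(f"{name} must lie in [0, 1], got {p}")
        if self.background_freq_range[0] > self.background_freq_range[1]:
            raise SimError("background_freq_range must be (low, high)")
        if self.selected_sampling not in ("exact", "binomial"):
            raise SimError(f"unknown selected_sampling {self.selected_sampling!r}")
        if self.residual_sd <= 0:
            raise SimError("residual_sd must be positive")
        if self.block_sd < 0:
            raise SimError("block_sd must be non-negative")
        if self.baseline_in <= 0 or self.baseline_ln <= 0:
            raise SimError("baseline yields must be positive")

    def _freqs(self, f) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(f, dtype=float))
        if self.n_selected_loci == 0:
            return arr[:0] if arr.size == 1 else arr
        if arr.size == 1:
            arr = np.repeat(arr, self.n_selected_loci)
        if arr.size != self.n_selected_loci:
            raise SimError(
                f"per-locus frequency list has length {arr.size}, "
                f"expected {self.n_selected_loci}"
            )
        return arr

    @property
    def freqs_high(self) -> np.ndarray:
        return self._freqs(self.freq_high_group)

    @property
    def freqs_low(self) -> np.ndarray:
        return self._freqs(self.freq_low_group)


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated panel.

    ``selected`` has one row per planted locus (marker id, favorable
    allele, configured H/L favorable-allele frequencies); ``lines`` has
    one row per line (true H/L group, true favorable-allele count
    computed before any missingness is applied).
    """

    selected: pd.DataFrame  # marker, favorable_allele, freq_high, freq_low
    lines: pd.DataFrame  # line, group, true_nfa

    @property
    def selected_locus_ids(self) -> list[str]:
        return list(self.selected["marker"])

    @property
    def true_nfa(self) -> pd.Series:
        return self.lines.set_index("line")["true_nfa"]

    @property
    def group_labels(self) -> pd.Series:
        return self.lines.set_index("line")["group"]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted 1-based positions on a chromosome of given length."""
    if n > length:
        raise SimError("more markers than base pairs on a chromosome")
    pos: np.ndarray = np.array([], dtype=np.int64)
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=2 * (n - pos.size) + 16)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _exact_count_column(
    rng: np.random.Generator, n: int, freq: float
) -> np.ndarray:
    """0/1 carrier vector with exactly round(n*freq) ones, randomly placed."""
    k = int(round(n * freq))
    col = np.zeros(n, dtype=np.int8)
    col[rng.choice(n, size=k, replace=False)] = 1
    return col


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a fully homozygous biallelic panel with planted contrasts.

    Neutral loci draw every line's single allele from one shared per-locus
    frequency (uniform on ``background_freq_range``).  Planted loci use
    group-specific favorable-allele frequencies; under the default
    ``"exact"`` sampling the realized group counts equal
    ``round(n_group * freq)`` so the configured contrast is what the panel
    actually carries, while ``"binomial"`` draws each line independently.
    Missing calls are masked uniformly at ``missing_rate`` after the
    ground-truth favorable-allele counts are recorded.
    """
    config.validate()
    rng = _rng(config, 0)
    n, m = config.n_lines, config.n_snps

    line_ids = [f"L{i + 1:03d}" for i in range(n)]
    is_high = np.zeros(n, dtype=bool)
    is_high[rng.choice(n, size=config.n_high_lines, replace=False)] = True

    # marker map: markers spread over chromosomes, sorted positions
    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chroms = np.concatenate(
        [np.repeat(str(c + 1), len(idx)) for c, idx in enumerate(per_chrom)]
    )
    positions = np.concatenate(
        [_draw_positions(rng, len(idx), config.chromosome_length_bp) for idx in per_chrom]
    )
    marker_ids = [f"SNP{i + 1:05d}" for i in range(m)]
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    marker_map = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": _NUC[ref_idx], "alt": _NUC[alt_idx]},
        index=marker_ids,
    )

    # neutral loci: one shared frequency per locus
    lo, hi = config.background_freq_range
    p_neutral = rng.uniform(lo, hi, size=m)
    carrier = (rng.random((n, m)) < p_neutral[None, :]).astype(np.int8)

    # planted loci: group-specific favorable-allele frequencies
    sel = np.sort(rng.choice(m, size=config.n_selected_loci, replace=False))
    fav_is_alt = rng.random(config.n_selected_loci) < 0.5
    f_high, f_low = config.freqs_high, config.freqs_low
    hi_rows, lo_rows = np.flatnonzero(is_high), np.flatnonzero(~is_high)
    for k, j in enumerate(sel):
        fav = np.zeros(n, dtype=np.int8)
        if config.selected_sampling == "exact":
            fav[hi_rows] = _exact_count_column(rng, hi_rows.size, f_high[k])
            fav[lo_rows] = _exact_count_column(rng, lo_rows.size, f_low[k])
        else:
            fav[hi_rows] = rng.random(hi_rows.size) < f_high[k]
            fav[lo_rows] = rng.random(lo_rows.size) < f_low[k]
        # fav counts the favorable allele; re-express as alt-allele carrier
        carrier[:, j] = fav if fav_is_alt[k] else 1 - fav

    calls = (2 * carrier).astype(np.int8)

    fav_allele = np.where(
        fav_is_alt, marker_map["alt"].to_numpy()[sel], marker_map["ref"].to_numpy()[sel]
    )
    fav_carrier = np.where(fav_is_alt[None, :], carrier[:, sel], 1 - carrier[:, sel])
    true_nfa = fav_carrier.sum(axis=1).astype(int)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        calls[mask] = MISSING

    truth = SimTruth(
        selected=pd.DataFrame(
            {
                "marker": [marker_ids[j] for j in sel],
                "favorable_allele": fav_allele,
                "freq_high": f_high,
                "freq_low": f_low,
            }
        ),
        lines=pd.DataFrame(
            {
                "line": line_ids,
                "group": np.where(is_high, "H", "L"),
                "true_nfa": true_nfa,
            }
        ),
    )
    return GenotypeMatrix(line_ids, marker_ids, calls, marker_map), truth


def env_baselines(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-environment baselines and N doses.

    Environment offsets are evenly spaced over ``env_effect_span`` so the
    environment main effect is nonzero without adding another random
    stream; dose pairs cycle through ``n_doses`` (first environment gets
    the first pair, later ones the last, mirroring a two-season trial).
    """
    n_env = config.n_environments
    offsets = (
        np.linspace(0.5, -0.5, n_env) * config.env_effect_span
        if n_env > 1
        else np.zeros(1)
    )
    doses = [config.n_doses[min(i, len(config.n_doses) - 1)] for i in range(n_env)]
    return pd.DataFrame(
        {
            "environment": [f"E{i + 1}" for i in range(n_env)],
            "offset": offsets,
            "dose_in": [d[0] for d in doses],
            "dose_ln": [d[1] for d in doses],
        }
    )


def simulate_phenotypes(
    geno: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Simulate plot-level grain yields for every line x env x N level x rep.

    yield = baseline(N level) + environment offset
            + effect_per_favorable_allele * true NFA   (low-N plots only)
            + block effect ~ N(0, block_sd^2) + residual ~ N(0, residual_sd^2)

    Lines are partitioned afresh into blocks of ``block_size`` within each
    (environment, N level, replicate), emulating a resolvable
    incomplete-block layout.
    """
    config.validate()
    if list(geno.line_ids) != list(truth.lines["line"]):
        raise SimError("line ids in genotypes and truth disagree")
    rng = _rng(config, 1)
    n = geno.n_lines
    nfa = truth.lines["true_nfa"].to_numpy(dtype=float)
    envs = env_baselines(config)
    n_blocks = int(np.ceil(n / config.block_size))

    recs = []
    for _, env in envs.iterrows():
        for n_level, base in (("IN", config.baseline_in), ("LN", config.baseline_ln)):
            for rep in range(1, config.n_reps + 1):
                order = rng.permutation(n)
                block_of = np.empty(n, dtype=int)
                block_of[order] = np.arange(n) // config.block_size
                block_eff = rng.normal(0.0, config.block_sd, size=n_blocks)
                resid = rng.normal(0.0, config.residual_sd, size=n)
                y = base + env["offset"] + block_eff[block_of] + resid
                if n_level == "LN":
                    y = y + config.effect_per_favorable_allele * nfa
                y = np.maximum(y, 0.0)
                for i, lid in enumerate(geno.line_ids):
                    recs.append(
                        (
                            lid,
                            env["environment"],
                            n_level,
                            rep,
                            f"R{rep}B{block_of[i] + 1}",
                            y[i],
                        )
                    )
    return pd.DataFrame(
        recs, columns=["line", "environment", "n_level", "rep", "block", "grain_yield"]
    )


# ----------------------------------------------------------------- sidecars
def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write the ground-truth sidecar (two sections in one TSV)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#selected\n")
        truth.selected.to_csv(fh, sep="\t", index=False)
        fh.write("#lines\n")
        truth.lines.to_csv(fh, sep="\t", index=False)


def read_truth(path: str | Path) -> SimTruth:
    text = Path(path).read_text().splitlines()
    i_sel = text.index("#selected")
    i_lin = text.index("#lines")
    from io import StringIO

    selected = pd.read_csv(StringIO("\n".join(text[i_sel + 1 : i_lin])), sep="\t")
    lines = pd.read_csv(StringIO("\n".join(text[i_lin + 1 :])), sep="\t")
    return SimTruth(selected=selected, lines=lines)
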