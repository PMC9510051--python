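"""Chromosome-scale summaries: binned heterozygous-SNP density,
homozygous-run detection, read-fraction and elimination-efficiency
ratios, and the MLPA aneuploidy decision rule.

The run scan is the recombination test: a first-meiosis crossover between
the two maternal homologs makes them identical over a terminal segment,
so the dP line (which retains only M1 and M2) loses every heterozygous
site there — a run of empty 10-kb bins flanked by normally dense ones.
An empty run list is a "no recombination" call for that sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .variantio import BaseSetProfile

__all__ = [
    "TRISOMY",
    "NEGATIVE",
    "BinCounts",
    "HomozygousRun",
    "MlpaProfile",
    "bin_het_density",
    "detect_homozygous_runs",
    "chr21_read_fraction",
    "elimination_efficiency",
    "round_percent",
    "mlpa_call",
    "write_bin_tsv",
    "write_runs_tsv",
]

TRISOMY = "TRISOMY"
NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class BinCounts:
    """Heterozygous-site counts per fixed-width genomic bin per sample.

    Bins are 1-based closed intervals of exactly ``bin_size`` bp starting
    at 1, 1+bin_size, ...; empty bins are reported explicitly (the run
    detector needs them).
    """

    chrom: str
    bin_size: int
    bin_starts: np.ndarray
    het_counts: Mapping[str, np.ndarray]

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    def totals(self) -> dict[str, int]:
        return {s: int(c.sum()) for s, c in self.het_counts.items()}


class HomozygousRun(NamedTuple):
    start: int  # 1-based start of the first empty bin
    end: int  # 1-based end of the last empty bin (inclusive)
    n_bins: int


def bin_het_density(
    profiles: Sequence[BaseSetProfile],
    chrom_length: int,
    bin_size: int = 10_000,
    samples: Sequence[str] | None = None,
) -> BinCounts:
    """Count per-sample heterozygous sites (present set of >= 2 bases) in
    ``bin_size`` bins covering [1, chrom_length]."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = -(-chrom_length // bin_size)  # ceil
    bin_starts = 1 + bin_size * np.arange(n_bins, dtype=np.int64)
    chrom = profiles[0].chrom if profiles else "?"
    if samples is None:
        samples = sorted(profiles[0].present) if profiles else []
    positions = np.array([p.pos for p in profiles], dtype=np.int64)
    if len(positions) and positions.max() > chrom_length:
        raise ValueError(
            f"position {positions.max()} beyond chrom_length {chrom_length}"
        )
    idx = (positions - 1) // bin_size
    het_counts: dict[str, np.ndarray] = {}
    for s in samples:
        het = np.array([len(p.present[s]) >= 2 for p in profiles], dtype=bool)
        het_counts[s] = np.bincount(idx[het], minlength=n_bins).astype(np.int64)
    return BinCounts(
        chrom=chrom, bin_size=bin_size, bin_starts=bin_starts, het_counts=het_counts
    )


def detect_homozygous_runs(
    bins: BinCounts,
    sample: str,
    min_run_bins: int = 5,
    min_flank_density: float = 1.0,
) -> list[HomozygousRun]:
    """Maximal runs of empty bins bounded by normally dense flanks.

    A run is >= ``min_run_bins`` consecutive bins with zero heterozygous
    sites; on each side where flanking bins exist, the nearest
    ``min_run_bins`` of them must average >= ``min_flank_density``
    heterozygous sites per bin (guarding against sparse-data false
    positives).  An empty result is a "no recombination" call.
    """
    if min_run_bins < 1:
        raise ValueError("min_run_bins must be >= 1")
    counts = bins.het_counts[sample]
    runs: list[HomozygousRun] = []
    n = len(counts)
    i = 0
    while i < n:
        if counts[i] != 0:
            i += 1
            continue
        j = i
        while j < n and counts[j] == 0:
            j += 1
        length = j - i
        if length >= min_run_bins:
            left = counts[max(0, i - min_run_bins): i]
            right = counts[j: j + min_run_bins]
            ok = True
            if len(left) and left.mean() < min_flank_density:
                ok = False
            if len(right) and right.mean() < min_flank_density:
                ok = False
            if ok:
                start = int(bins.bin_starts[i])
                end = int(bins.bin_starts[j - 1]) + bins.bin_size - 1
                runs.append(HomozygousRun(start, end, length))
        i = j
    return runs


def chr21_read_fraction(mapped_chr: int, total: int) -> float:
    """Percent of mapped reads on the chromosome of interest."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if not (0 <= mapped_chr <= total):
        raise ValueError("mapped_chr must lie in [0, total]")
    return 100.0 * mapped_chr / total


def elimination_efficiency(n_disomy: int, n_picked: int) -> float:
    """Percent of picked colonies that became disomic."""
    if n_picked <= 0:
        raise ValueError("n_picked must be positive")
    if not (0 <= n_disomy <= n_picked):
        raise ValueError("n_disomy must lie in [0, n_picked]")
    return 100.0 * n_disomy / n_picked


def round_percent(value: float, ndigits: int = 2) -> float:
    """Half-up rounding to match printed percent precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MlpaProfile:
    """Eight relative probe ratios for one chromosome."""

    chromosome: str
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        if len(self.ratios) != 8:
            raise ValueError(f"expected exactly 8 probe ratios, got {len(self.ratios)}")
        if any(r < 0 for r in self.ratios):
            raise ValueError("probe ratios must be non-negative")


def mlpa_call(
    profile: MlpaProfile | Sequence[float],
    ratio_threshold: float = 1.30,
    min_probes: int = 4,
) -> str:
    """Trisomy iff at least ``min_probes`` of the 8 ratios are >= threshold."""
    if not isinstance(profile, MlpaProfile):
        profile = MlpaProfile(chromosome="?", ratios=tuple(profile))
    n_high = sum(r >= ratio_threshold for r in profile.ratios)
    return TRISOMY if n_high >= min_probes else NEGATIVE


def write_bin_tsv(bins: BinCounts, path) -> None:
    """Per-sample bin TSV: chrom, bin_start, then one het-count column per
    sample."""
    import pandas as pd

    data = {"chrom": bins.chrom, "bin_start": bins.bin_starts}
    for s, c in bins.het_counts.items():
        data[f"het_{s}"] = c
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_runs_tsv(runs_by_sample: Mapping[str, Sequence[HomozygousRun]], path) -> None:
    import pandas as pd

    rows = [
        (s, r.start, r.end, r.n_bins)
        for s, runs in runs_by_sample.items()
        for r in runs
    ]
    pd.DataFrame(rows, columns=["sample", "start", "end", "n_bins"]).to_csv(
        path, sep="\t", index=False
    )
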