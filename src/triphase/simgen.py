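"""Synthetic trio haplotypes, cell-line designs and read-count simulation.

This module stands in for the wet-lab side of elimination-based trisomy
phasing.  The experiment it emulates starts from a trisomy-21 iPSC line
whose three chromosome-21 homologs are labelled P (paternal), M1 and M2
(the two maternal homologs), plus three "corrected disomy" lines, each of
which has lost exactly one homolog (dP lacks P, dM1 lacks M1, dM2 lacks
M2).  All four lines are whole-genome sequenced and the phasing algorithm
downstream consumes only per-site, per-sample base tallies.

Accordingly the simulator works at the allele-count level: it draws a trio
of haplotypes over a synthetic chromosome, optionally recombines M1/M2,
and then produces Poisson-depth, error-corrupted base counts per sample.
Reads, read lengths and alignment are upstream of the method and are not
modelled.

Coverage follows copy number: a sample carrying ``c`` copies of the
chromosome receives ``Poisson(depth_mean * c / 2)`` reads per site, so
with the default ``depth_mean=30`` (diploid-equivalent coverage) the
trisomic line sees ~45x on the trisomic chromosome and each disomic line
~30x, and summed disomy depth is ~2/3 of trisomy depth — the same
copy-number signal a mapped-read fraction plot shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variantio import BASES, SNV, SiteObservation

__all__ = [
    "HOMOLOGS",
    "CONFIG_CLASSES",
    "DEFAULT_CONFIG_WEIGHTS",
    "DEFAULT_SAMPLE_NAMES",
    "SimParams",
    "TrioHaplotypes",
    "SampleDesign",
    "simulate_haplotypes",
    "apply_recombination",
    "simulate_counts",
    "simulate_dataset",
    "write_truth_tsv",
    "read_truth_tsv",
]

HOMOLOGS = ("P", "M1", "M2")

#: Site configuration classes.  The *_private classes place the alternate
#: base on a single homolog; the *_shared classes place it on P plus one
#: maternal homolog; triallelic sites carry three distinct bases
#: (P = ref, M1 and M2 two different non-ref bases).
CONFIG_CLASSES = (
    "monomorphic",
    "p_private",
    "m1_private",
    "m2_private",
    "pm2_shared",
    "pm1_shared",
    "triallelic",
)

#: Default class weights.  P-private heterozygous sites dominate, which
#: encodes the biological asymmetry that the two maternal homologs of a
#: meiosis-II (or mitotic) trisomy are genetically much closer to each
#: other than either is to the paternal homolog.
DEFAULT_CONFIG_WEIGHTS: Mapping[str, float] = {
    "monomorphic": 0.30,
    "p_private": 0.40,
    "m1_private": 0.07,
    "m2_private": 0.07,
    "pm2_shared": 0.07,
    "pm1_shared": 0.07,
    "triallelic": 0.02,
}

DEFAULT_SAMPLE_NAMES = ("T21", "dP", "dM1", "dM2")

_BASE_ARR = np.array(BASES)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    Parameters
    ----------
    n_sites
        Number of candidate SNP sites to draw (distinct positions).
    chrom_length
        Length of the synthetic chromosome in bp (1-based coordinates).
    depth_mean
        Diploid-equivalent expected coverage per sample per site; a sample
        with ``c`` chromosome copies draws ``Poisson(depth_mean * c / 2)``.
    error_rate
        Per-read substitution probability (uniform over the other three
        bases).
    seed
        RNG seed; every random draw in the run derives from it.
    config_weights
        Probabilities over :data:`CONFIG_CLASSES`; must sum to 1.
    breakpoints
        Strictly increasing M1/M2 crossover positions in
        ``(1, chrom_length)``.
    sample_names
        Labels of the four samples in the order trisomy, dP, dM1, dM2.
    chrom
        Chromosome name used in emitted records.
    """

    n_sites: int
    chrom_length: int
    seed: int
    depth_mean: float = 30.0
    error_rate: float = 0.001
    config_weights: Mapping[str, float] | None = None
    breakpoints: tuple[int, ...] = ()
    sample_names: tuple[str, str, str, str] = DEFAULT_SAMPLE_NAMES
    chrom: str = "21"

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.n_sites > self.chrom_length:
            raise ValueError(
                f"n_sites ({self.n_sites}) exceeds chrom_length ({self.chrom_length})"
            )
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")
        weights = dict(self.config_weights or DEFAULT_CONFIG_WEIGHTS)
        unknown = set(weights) - set(CONFIG_CLASSES)
        if unknown:
            raise ValueError(f"unknown configuration classes: {sorted(unknown)}")
        if any(w < 0 for w in weights.values()):
            raise ValueError("config_weights must be non-negative")
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"config_weights sum to {total}, expected 1")
        object.__setattr__(self, "config_weights", weights)
        bps = tuple(int(b) for b in self.breakpoints)
        _validate_breakpoints(bps, self.chrom_length)
        object.__setattr__(self, "breakpoints", bps)
        if len(self.sample_names) != 4 or len(set(self.sample_names)) != 4:
            raise ValueError("sample_names must be four distinct labels")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.config_weights.get(c, 0.0) for c in CONFIG_CLASSES])


def _validate_breakpoints(breakpoints: Sequence[int], chrom_length: int) -> None:
    for b in breakpoints:
        if not (1 < b < chrom_length):
            raise ValueError(
                f"breakpoint {b} outside open interval (1, {chrom_length})"
            )
    if any(b2 <= b1 for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints must be strictly increasing")


@dataclass(frozen=True)
class TrioHaplotypes:
    """Ground-truth bases of the three homologs at ordered positions."""

    chrom: str
    chrom_length: int
    positions: np.ndarray
    ref: np.ndarray
    alleles: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.positions)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.ref) != n:
            raise ValueError("ref length mismatch")
        if set(self.alleles) != set(HOMOLOGS):
            raise ValueError(f"alleles must be keyed by {HOMOLOGS}")
        for h, arr in self.alleles.items():
            if len(arr) != n:
                raise ValueError(f"alleles[{h}] length mismatch")
        for arr in (self.ref, *self.alleles.values()):
            if not np.all(np.isin(arr, _BASE_ARR)):
                raise ValueError("bases must be in {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.positions)

    def truth_at(self, i: int) -> dict[str, str]:
        """Homolog -> base mapping at site index ``i``."""
        return {h: str(self.alleles[h][i]) for h in HOMOLOGS}

    def heterozygous_mask(self) -> np.ndarray:
        """Boolean mask of sites where the three homologs do not all agree."""
        p, m1, m2 = (self.alleles[h] for h in HOMOLOGS)
        return (p != m1) | (p != m2)


@dataclass(frozen=True)
class SampleDesign:
    """Which homologs each cell line carries.

    Exactly one sample carries all three homologs (the trisomy) and each
    of the other three carries two, jointly omitting each homolog exactly
    once.
    """

    members: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        members = {s: frozenset(h) for s, h in self.members.items()}
        object.__setattr__(self, "members", members)
        if len(members) != 4:
            raise ValueError("a design needs exactly four samples")
        full = frozenset(HOMOLOGS)
        for s, hs in members.items():
            if not hs <= full:
                raise ValueError(f"sample {s} lists unknown homologs {sorted(hs - full)}")
        tris = [s for s, hs in members.items() if hs == full]
        if len(tris) != 1:
            raise ValueError("exactly one sample must carry all three homologs")
        disomies = [s for s, hs in members.items() if len(hs) == 2]
        if len(disomies) != 3:
            raise ValueError("exactly three samples must carry two homologs")
        omitted = sorted(next(iter(full - members[s])) for s in disomies)
        if omitted != sorted(HOMOLOGS):
            raise ValueError("the three disomies must omit each homolog exactly once")

    @classmethod
    def default(cls, sample_names: Sequence[str] = DEFAULT_SAMPLE_NAMES) -> "SampleDesign":
        t21, dp, dm1, dm2 = sample_names
        return cls(
            {
                t21: frozenset(HOMOLOGS),
                dp: frozenset({"M1", "M2"}),
                dm1: frozenset({"P", "M2"}),
                dm2: frozenset({"P", "M1"}),
            }
        )

    @property
    def trisomy_sample(self) -> str:
        return next(s for s, hs in self.members.items() if len(hs) == 3)

    @property
    def disomy_samples(self) -> tuple[str, ...]:
        return tuple(s for s, hs in self.members.items() if len(hs) == 2)

    def sample_lacking(self, homolog: str) -> str:
        """The disomy line in which ``homolog`` was eliminated."""
        return next(
            s for s, hs in self.members.items() if len(hs) == 2 and homolog not in hs
        )

    def missing_homolog(self, sample: str) -> str | None:
        hs = self.members[sample]
        if len(hs) != 2:
            return None
        return next(iter(frozenset(HOMOLOGS) - hs))


def _rng(seed: int, stream: int) -> np.random.Generator:
    # separate streams so toggling error injection leaves every other draw
    # untouched ("same counts minus errors")
    return np.random.default_rng([stream, seed])


def _sample_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Uniform sample of ``n`` distinct 1-based positions in [1, length]."""
    if 3 * n >= length:
        return np.sort(rng.permutation(length)[:n] + 1)
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(1, length + 1, size=n - len(chosen))
        chosen.update(draw.tolist())
    return np.array(sorted(chosen), dtype=np.int64)


def simulate_haplotypes(params: SimParams) -> TrioHaplotypes:
    """Draw ground-truth trio haplotypes.

    Each site is assigned a configuration class per ``config_weights``:
    monomorphic sites carry the reference base on all homologs, *_private
    classes give one homolog an alternate base, *_shared classes give two,
    and triallelic sites carry three distinct bases.  The alternate base is
    uniform over the three non-reference bases.
    """
    rng = _rng(params.seed, 11)
    n = params.n_sites
    positions = _sample_positions(rng, n, params.chrom_length)
    ref_idx = rng.integers(0, 4, size=n)
    cls = rng.choice(len(CONFIG_CLASSES), size=n, p=params.weight_vector)
    off1 = rng.integers(1, 4, size=n)
    # second alternate offset: uniform over the two offsets != off1
    off2 = (off1 - 1 + rng.integers(1, 3, size=n)) % 3 + 1
    alt1_idx = (ref_idx + off1) % 4
    alt2_idx = (ref_idx + off2) % 4

    idx = {h: ref_idx.copy() for h in HOMOLOGS}
    c = {name: cls == i for i, name in enumerate(CONFIG_CLASSES)}
    idx["P"][c["p_private"]] = alt1_idx[c["p_private"]]
    idx["M1"][c["m1_private"]] = alt1_idx[c["m1_private"]]
    idx["M2"][c["m2_private"]] = alt1_idx[c["m2_private"]]
    for h in ("P", "M2"):
        idx[h][c["pm2_shared"]] = alt1_idx[c["pm2_shared"]]
    for h in ("P", "M1"):
        idx[h][c["pm1_shared"]] = alt1_idx[c["pm1_shared"]]
    idx["M1"][c["triallelic"]] = alt1_idx[c["triallelic"]]
    idx["M2"][c["triallelic"]] = alt2_idx[c["triallelic"]]

    return TrioHaplotypes(
        chrom=params.chrom,
        chrom_length=params.chrom_length,
        positions=positions,
        ref=_BASE_ARR[ref_idx],
        alleles={h: _BASE_ARR[idx[h]] for h in HOMOLOGS},
    )


def apply_recombination(
    trio: TrioHaplotypes, breakpoints: Sequence[int]
) -> TrioHaplotypes:
    """Overwrite M2 by M1 in alternating crossover segments.

    Breakpoints split the chromosome into segments; in every odd-numbered
    segment (the first segment is number 0) ``alleles_M2`` is replaced by
    ``alleles_M1``, making the two maternal homologs identical there —
    which is exactly what a first-meiosis M1/M2 crossover looks like to
    the dP line: a run of homozygosity.  P is never modified.
    """
    bps = tuple(int(b) for b in breakpoints)
    _validate_breakpoints(bps, trio.chrom_length)
    if not bps:
        return trio
    seg = np.searchsorted(np.array(bps), trio.positions, side="right")
    odd = seg % 2 == 1
    m2 = np.where(odd, trio.alleles["M1"], trio.alleles["M2"])
    return replace(trio, alleles={"P": trio.alleles["P"], "M1": trio.alleles["M1"], "M2": m2})


def _multinomial_rows(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Row-wise multinomial draws via the chained-binomial decomposition."""
    k = p.shape[1]
    out = np.zeros((len(n), k), dtype=np.int64)
    remaining = np.asarray(n, dtype=np.int64).copy()
    rem_p = np.ones(len(n))
    for j in range(k - 1):
        pj = np.divide(p[:, j], rem_p, out=np.zeros(len(n)), where=rem_p > 0)
        out[:, j] = rng.binomial(remaining, np.clip(pj, 0.0, 1.0))
        remaining -= out[:, j]
        rem_p = rem_p - p[:, j]
    out[:, k - 1] = remaining
    return out


def simulate_counts(
    trio: TrioHaplotypes, design: SampleDesign, params: SimParams
) -> list[SiteObservation]:
    """Draw per-site per-sample base counts.

    Per sample and site the read depth is Poisson with mean proportional
    to the sample's copy number (see module docstring); each read's true
    base is uniform over the sample's homolog copies — heterozygous
    trisomy sites therefore have expected alternate fractions 1/3 or 2/3
    and heterozygous disomy sites 1/2 — and with probability
    ``error_rate`` the read base is replaced by a uniform draw from the
    other three bases.  Counts sum exactly to the drawn depth.
    """
    rng_reads = _rng(params.seed, 22)
    rng_err = _rng(params.seed, 33)
    n = len(trio)
    allele_idx = {
        h: np.searchsorted(_BASE_ARR, trio.alleles[h]) for h in HOMOLOGS
    }

    per_sample: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    for sample in params.sample_names:
        homologs = sorted(design.members[sample])
        n_copies = len(homologs)
        depth = rng_reads.poisson(params.depth_mean * n_copies / 2.0, size=n)
        copy_counts = np.zeros((n, 4))
        for h in homologs:
            copy_counts[np.arange(n), allele_idx[h]] += 1.0
        counts = _multinomial_rows(rng_reads, depth, copy_counts / n_copies)
        # substitution errors: each read independently errs with
        # probability error_rate, landing uniformly on the other 3 bases
        third = np.full((n, 3), 1.0 / 3.0)
        for j in range(4):
            n_err = rng_err.binomial(counts[:, j], params.error_rate)
            counts[:, j] -= n_err
            spread = _multinomial_rows(rng_err, n_err, third)
            others = [b for b in range(4) if b != j]
            for k, b in enumerate(others):
                counts[:, b] += spread[:, k]
        per_sample[sample] = counts
        depths[sample] = depth

    sites: list[SiteObservation] = []
    positions = trio.positions
    for i in range(n):
        ref = str(trio.ref[i])
        observed: set[str] = {str(trio.alleles[h][i]) for h in HOMOLOGS}
        count_maps: dict[str, dict[str, int]] = {}
        for sample in params.sample_names:
            row = per_sample[sample][i]
            cm = {BASES[j]: int(row[j]) for j in range(4) if row[j] > 0}
            count_maps[sample] = cm
            observed.update(cm)
        alts = tuple(sorted(observed - {ref}))
        sites.append(
            SiteObservation(
                chrom=trio.chrom,
                pos=int(positions[i]),
                ref=ref,
                alts=alts,
                variant_class=SNV,
                counts=count_maps,
                depth={s: int(depths[s][i]) for s in params.sample_names},
            )
        )
    return sites


def simulate_dataset(
    params: SimParams, design: SampleDesign | None = None
) -> tuple[TrioHaplotypes, SampleDesign, list[SiteObservation]]:
    """Convenience pipeline: haplotypes -> recombination -> counts."""
    design = design or SampleDesign.default(params.sample_names)
    trio = simulate_haplotypes(params)
    if params.breakpoints:
        trio = apply_recombination(trio, params.breakpoints)
    sites = simulate_counts(trio, design, params)
    return trio, design, sites


def write_truth_tsv(trio: TrioHaplotypes, path) -> None:
    """Write the ground-truth table (chrom, pos, ref, allele_P/M1/M2)."""
    import pandas as pd

    pd.DataFrame(
        {
            "chrom": trio.chrom,
            "pos": trio.positions,
            "ref": trio.ref,
            "allele_P": trio.alleles["P"],
            "allele_M1": trio.alleles["M1"],
            "allele_M2": trio.alleles["M2"],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path, chrom_length: int | None = None) -> TrioHaplotypes:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return TrioHaplotypes(
        chrom=str(df["chrom"].iloc[0]),
        chrom_length=int(chrom_length or df["pos"].max()),
        positions=df["pos"].to_numpy(np.int64),
        ref=df["ref"].to_numpy(str),
        alleles={h: df[f"allele_{h}"].to_numpy(str) for h in HOMOLOGS},
    )
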