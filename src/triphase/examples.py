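"""Packaged worked examples.

The seven-SNP fixture reconstructs the chromosome-21 loci used to
validate elimination phasing by Sanger sequencing: at each locus exactly
one corrected disomy line is homozygous, which pins every base to a
homolog.  Phasing the seven profiles yields the haplotype strings
P = ACCTGAC, M1 = GCTCAGC, M2 = GTCTAGT.

Only rs74753297 (chr21:9,830,857, GRCh37) and rs78248586
(chr21:43,465,959) have published coordinates; the positions of the other
five rsIDs are synthetic, order-preserving placeholders, and the
reference base at each locus is taken to be the majority (two-homolog)
base.  Neither choice affects the phasing result.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

from .simgen import HOMOLOGS, SampleDesign
from .variantio import BaseSetProfile

__all__ = ["profile_from_truth", "seven_snp_fixture", "SEVEN_SNP_LOCI"]

#: (rsID, 1-based position) in chromosome order; non-anchored positions
#: are illustrative.
SEVEN_SNP_LOCI = (
    ("rs74753297", 9_830_857),
    ("rs62218012", 10_905_000),
    ("rs3119486", 16_500_000),
    ("rs447807", 24_100_000),
    ("rs11702254", 31_600_000),
    ("rs460855", 38_800_000),
    ("rs78248586", 43_465_959),
)

#: Truth bases (P, M1, M2) per locus, in the same order.
_SEVEN_SNP_TRUTH = (
    ("A", "G", "G"),
    ("C", "C", "T"),
    ("C", "T", "C"),
    ("T", "C", "T"),
    ("G", "A", "A"),
    ("A", "G", "G"),
    ("C", "C", "T"),
)


def profile_from_truth(
    chrom: str,
    pos: int,
    alleles: Mapping[str, str],
    design: SampleDesign,
    ref: str | None = None,
) -> BaseSetProfile:
    """Noise-free base-set profile implied by known homolog bases.

    Each sample's present set is exactly the bases its homologs carry;
    BAFs are the ideal copy fractions (thirds in the trisomy, halves in a
    heterozygous disomy).
    """
    if ref is None:
        ref = Counter(alleles[h] for h in HOMOLOGS).most_common(1)[0][0]
    present: dict[str, frozenset[str]] = {}
    baf: dict[str, dict[str, float]] = {}
    for sample, homologs in design.members.items():
        bases = [alleles[h] for h in sorted(homologs)]
        present[sample] = frozenset(bases)
        baf[sample] = {
            b: bases.count(b) / len(bases) for b in present[sample]
        }
    trisomy = design.trisomy_sample
    return BaseSetProfile(
        chrom=chrom,
        pos=pos,
        ref=ref,
        candidate_alleles=present[trisomy],
        present=present,
        baf=baf,
    )


def seven_snp_fixture(
    design: SampleDesign | None = None,
) -> tuple[list[BaseSetProfile], SampleDesign]:
    """The seven Sanger-validated loci as base-set profiles."""
    design = design or SampleDesign.default()
    profiles = [
        profile_from_truth(
            "21", pos, dict(zip(HOMOLOGS, truth)), design
        )
        for (_, pos), truth in zip(SEVEN_SNP_LOCI, _SEVEN_SNP_TRUTH)
    ]
    return profiles, design
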