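"""Multi-sample variant I/O and the site/base filters.

The phasing pipeline consumes a four-sample view of each variant site on
the trisomic chromosome: the trisomy line plus the three corrected disomy
lines, with per-sample base counts derived from the caller's allele
depths (AD) and depths (DP).  Two filters precede phasing:

* site filters — every sample must be covered by at least ``min_depth``
  reads (default 10) and the site must be a single-nucleotide variant
  (indels are excluded);
* base-presence filter — a base is treated as *present* in a sample when
  its base allele frequency (BAF: reads carrying the base / depth) is at
  least ``tau_present`` (default 0.06), which suppresses sequencing
  errors.  Candidate alleles at a site are the bases present in the
  trisomy sample; a base never reaching the threshold there is excluded
  everywhere.

Both thresholds are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "BASES",
    "SNV",
    "INDEL",
    "OTHER",
    "LOW_DEPTH",
    "SiteObservation",
    "BaseSetProfile",
    "DroppedSite",
    "classify_variant",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "filter_sites",
    "write_filter_report",
    "compute_base_sets",
    "compute_profiles",
]

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

# variant classes
SNV = "SNV"
INDEL = "INDEL"
OTHER = "OTHER"

# filter reasons (machine-readable)
LOW_DEPTH = "LOW_DEPTH"


def classify_variant(ref: str, alts: Sequence[str]) -> str:
    """SNV / INDEL / OTHER from the ref and alt allele strings.

    A record is an INDEL when the ref or any alt allele is longer than one
    base; alleles containing non-ACGT symbols (symbolic alleles, ``*``,
    breakends) are OTHER.
    """
    alleles = [ref, *alts]
    if not all(a and set(a) <= _BASE_SET for a in alleles):
        return OTHER
    if any(len(a) != 1 for a in alleles):
        return INDEL
    return SNV


@dataclass(frozen=True)
class SiteObservation:
    """One variant site with per-sample base counts for the four lines."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    variant_class: str
    counts: Mapping[str, Mapping[str, int]]
    depth: Mapping[str, int]

    def __post_init__(self) -> None:
        for sample, cm in self.counts.items():
            bad = [b for b in cm if b not in _BASE_SET]
            if bad:
                raise ValueError(f"{self.chrom}:{self.pos} sample {sample}: "
                                 f"counted non-bases {bad}")
            if any(c < 0 for c in cm.values()):
                raise ValueError(f"{self.chrom}:{self.pos} negative count")
            if sum(cm.values()) > self.depth.get(sample, 0):
                raise ValueError(
                    f"{self.chrom}:{self.pos} sample {sample}: base counts "
                    f"exceed depth"
                )


class DroppedSite(NamedTuple):
    site: SiteObservation
    reason: str


@dataclass(frozen=True)
class BaseSetProfile:
    """Per-sample present-base sets at one site, after BAF thresholding."""

    chrom: str
    pos: int
    ref: str
    candidate_alleles: frozenset[str]
    present: Mapping[str, frozenset[str]]
    baf: Mapping[str, Mapping[str, float]]
    diagnostics: tuple[str, ...] = ()


def read_multisample_vcf(
    path, sample_map: Mapping[str, str] | None = None
) -> list[SiteObservation]:
    """Read a four-sample VCF with GT:AD:DP per-sample fields.

    ``sample_map`` renames VCF sample columns to canonical labels
    (e.g. ``{"SRR000001": "T21", ...}``); by default VCF names are kept.
    Per-sample base counts come from AD entries of single-base alleles;
    depth is DP, falling back to the AD sum when DP is missing.
    Multi-allelic records are kept as single sites.  The gVCF
    ``<NON_REF>`` placeholder (used to represent monomorphic records) is
    stripped from the alt list; its AD entry is ignored.
    """
    import pysam

    sites: list[SiteObservation] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        sample_map = dict(sample_map or {s: s for s in vcf_samples})
        missing = set(sample_map) - set(vcf_samples)
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)}")
        if len(sample_map) != 4:
            raise ValueError(
                f"expected exactly four mapped samples, got {len(sample_map)}"
            )
        for rec in vcf:
            where = f"{rec.chrom}:{rec.pos}"
            ref = rec.ref or ""
            raw_alts = tuple(a for a in (rec.alts or ()) if a is not None)
            alts = tuple(a for a in raw_alts if a != "<NON_REF>")
            counts: dict[str, dict[str, int]] = {}
            depth: dict[str, int] = {}
            for vcf_name, name in sample_map.items():
                fmt = rec.samples[vcf_name]
                ad = fmt.get("AD")
                if ad is None or all(a is None for a in ad):
                    raise ValueError(f"{where}: sample {vcf_name} has no AD")
                ad = [int(a or 0) for a in ad]
                if len(ad) != 1 + len(raw_alts):
                    raise ValueError(
                        f"{where}: sample {vcf_name} AD has {len(ad)} entries "
                        f"for {1 + len(raw_alts)} alleles"
                    )
                dp = fmt.get("DP")
                depth[name] = int(dp) if dp is not None else sum(ad)
                cm: dict[str, int] = {}
                for allele, c in zip((ref, *raw_alts), ad):
                    if c > 0 and len(allele) == 1 and allele in _BASE_SET:
                        cm[allele] = cm.get(allele, 0) + c
                counts[name] = cm
            sites.append(
                SiteObservation(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alts=alts,
                    variant_class=classify_variant(ref, alts),
                    counts=counts,
                    depth=depth,
                )
            )
    return sites


def write_multisample_vcf(
    sites: Sequence[SiteObservation],
    path,
    sample_order: Sequence[str],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write sites as an uncompressed VCF 4.2 with GT:AD:DP (GT missing).

    Sites with no alternate base are written with the gVCF ``<NON_REF>``
    placeholder allele (VCF requires at least one alt allele through this
    writer); :func:`read_multisample_vcf` strips it again.
    """
    import pysam

    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={int(length)}>")
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">'
    )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Read counts for the ref and alt alleles">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    for s in sample_order:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            alts = site.alts or ("<NON_REF>",)
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *alts),
            )
            for s in sample_order:
                cm = site.counts.get(s, {})
                ad = [int(cm.get(a, 0)) if a in _BASE_SET else 0
                      for a in (site.ref, *alts)]
                rec.samples[s]["GT"] = (None,)
                rec.samples[s]["AD"] = ad
                rec.samples[s]["DP"] = int(site.depth.get(s, 0))
            out.write(rec)


def filter_sites(
    sites: Iterable[SiteObservation],
    min_depth: int = 10,
    samples: Sequence[str] | None = None,
) -> tuple[list[SiteObservation], list[DroppedSite]]:
    """Apply the site filters; returns (kept, dropped-with-reason).

    A site is dropped when it is not a single-nucleotide variant (reason
    ``INDEL`` or ``OTHER``) or when any sample's depth is below
    ``min_depth`` (reason ``LOW_DEPTH``; the bound is inclusive — depth
    exactly ``min_depth`` is kept).  Input order is preserved.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    kept: list[SiteObservation] = []
    dropped: list[DroppedSite] = []
    for site in sites:
        if site.variant_class != SNV:
            dropped.append(DroppedSite(site, site.variant_class))
            continue
        names = samples if samples is not None else list(site.depth)
        if any(site.depth.get(s, 0) < min_depth for s in names):
            dropped.append(DroppedSite(site, LOW_DEPTH))
            continue
        kept.append(site)
    return kept, dropped


def write_filter_report(
    kept: Sequence[SiteObservation], dropped: Sequence[DroppedSite], path
) -> None:
    """TSV report: chrom, pos, decision, reason ('.' for kept sites)."""
    import pandas as pd

    rows = [(s.chrom, s.pos, "kept", ".") for s in kept]
    rows += [(d.site.chrom, d.site.pos, "dropped", d.reason) for d in dropped]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["chrom", "pos", "decision", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def compute_base_sets(
    site: SiteObservation,
    tau_present: float = 0.06,
    trisomy_sample: str = "T21",
) -> BaseSetProfile:
    """BAF-threshold a site into per-sample present-base sets.

    ``baf[s][b] = counts[s][b] / depth[s]``.  Candidate alleles are the
    bases with BAF >= ``tau_present`` in the trisomy sample; a sample's
    present set is the candidates reaching the same threshold in that
    sample.  A base that passes the threshold in a disomy sample but not
    in the trisomy sample is excluded everywhere and noted in
    ``diagnostics``.
    """
    if trisomy_sample not in site.depth:
        raise ValueError(f"{site.chrom}:{site.pos}: no data for {trisomy_sample}")
    baf: dict[str, dict[str, float]] = {}
    for sample, d in site.depth.items():
        if d <= 0:
            raise ValueError(
                f"{site.chrom}:{site.pos}: zero depth in {sample}; "
                f"run filter_sites first"
            )
        baf[sample] = {b: c / d for b, c in site.counts.get(sample, {}).items()}
    candidates = frozenset(
        b for b, f in baf[trisomy_sample].items() if f >= tau_present
    )
    present = {
        sample: frozenset(b for b in candidates if baf[sample].get(b, 0.0) >= tau_present)
        for sample in baf
    }
    diagnostics: list[str] = []
    for sample, fs in baf.items():
        if sample == trisomy_sample:
            continue
        extra = sorted(
            b for b, f in fs.items() if f >= tau_present and b not in candidates
        )
        if extra:
            diagnostics.append(
                f"bases {','.join(extra)} pass tau in {sample} but not in "
                f"{trisomy_sample}"
            )
    return BaseSetProfile(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        candidate_alleles=candidates,
        present=present,
        baf=baf,
        diagnostics=tuple(diagnostics),
    )


def compute_profiles(
    sites: Iterable[SiteObservation],
    tau_present: float = 0.06,
    trisomy_sample: str = "T21",
) -> list[BaseSetProfile]:
    return [compute_base_sets(s, tau_present, trisomy_sample) for s in sites]
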