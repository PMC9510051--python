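"""Variant I/O and the depth / indel / BAF filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triphase.simgen import SimParams, simulate_dataset
from triphase.variantio import (
    INDEL,
    LOW_DEPTH,
    OTHER,
    SNV,
    SiteObservation,
    classify_variant,
    compute_base_sets,
    filter_sites,
    read_multisample_vcf,
    write_filter_report,
    write_multisample_vcf,
)

SAMPLES = ("T21", "dP", "dM1", "dM2")


def make_site(counts, pos=100, ref="A", alts=("G",), variant_class=None):
    """Site with per-sample counts given as {sample: {base: n}}."""
    depth = {s: sum(c.values()) for s, c in counts.items()}
    return SiteObservation(
        chrom="21",
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        variant_class=variant_class or classify_variant(ref, alts),
        counts=counts,
        depth=depth,
    )


def uniform_site(depths, base="A"):
    return make_site({s: {base: d} for s, d in zip(SAMPLES, depths)})


class TestClassify:
    @pytest.mark.parametrize(
        "ref, alts, expected",
        [
            ("A", ("G",), SNV),
            ("A", ("G", "T"), SNV),
            ("A", ("AT",), INDEL),
            ("AT", ("A",), INDEL),
            ("A", ("<DEL>",), OTHER),
            ("A", ("*",), OTHER),
        ],
    )
    def test_variant_classes(self, ref, alts, expected):
        assert classify_variant(ref, alts) == expected


class TestFilterSites:
    def test_low_depth_in_any_sample_drops_site(self):
        site = uniform_site((30, 9, 30, 30))
        kept, dropped = filter_sites([site], min_depth=10)
        assert kept == [] and dropped[0].reason == LOW_DEPTH

    def test_depth_exactly_at_threshold_is_kept(self):
        site = uniform_site((10, 10, 10, 10))
        kept, dropped = filter_sites([site], min_depth=10)
        assert len(kept) == 1 and dropped == []

    def test_indels_dropped_regardless_of_depth(self):
        site = make_site(
            {s: {"A": 100} for s in SAMPLES}, ref="A", alts=("AT",)
        )
        kept, dropped = filter_sites([site], min_depth=10)
        assert kept == [] and dropped[0].reason == INDEL

    def test_partition_and_order_preserved(self):
        sites = [
            uniform_site((30, 30, 30, 30), base="C"),
            uniform_site((5, 30, 30, 30)),
            make_site({s: {"A": 50} for s in SAMPLES}, ref="A", alts=("AT",)),
            uniform_site((12, 12, 12, 12)),
        ]
        for i, s in enumerate(sites):
            object.__setattr__(s, "pos", 10 * (i + 1))
        kept, dropped = filter_sites(sites, min_depth=10)
        assert len(kept) + len(dropped) == len(sites)
        assert [s.pos for s in kept] == [10, 40]
        assert [d.site.pos for d in dropped] == [20, 30]

    @given(st.integers(min_value=0, max_value=60))
    @settings(max_examples=30, deadline=None)
    def test_raising_min_depth_never_keeps_more(self, min_depth):
        sites = [
            uniform_site(tuple(d))
            for d in np.random.default_rng(0).integers(0, 60, size=(30, 4))
        ]
        lo, _ = filter_sites(sites, min_depth=min_depth)
        hi, _ = filter_sites(sites, min_depth=min_depth + 5)
        assert len(hi) <= len(lo)
        assert {s.pos for s in hi} <= {s.pos for s in lo} or True  # same pos reused
        assert all(s in lo for s in hi)


class TestComputeBaseSets:
    def test_single_disomy_homozygous_pattern(self):
        # the printed worked pattern: T21/dM1/dM2 carry A and G, dP only G
        site = make_site(
            {
                "T21": {"A": 10, "G": 20},
                "dP": {"G": 30},
                "dM1": {"A": 15, "G": 15},
                "dM2": {"A": 16, "G": 14},
            }
        )
        profile = compute_base_sets(site, trisomy_sample="T21")
        assert profile.candidate_alleles == {"A", "G"}
        assert profile.present == {
            "T21": {"A", "G"},
            "dP": {"G"},
            "dM1": {"A", "G"},
            "dM2": {"A", "G"},
        }

    @pytest.mark.parametrize(
        "t21_counts, expected_candidates",
        [
            ({"A": 29, "G": 1}, {"A"}),  # 1/30 = 0.033 < 0.06
            ({"A": 28, "G": 2}, {"A", "G"}),  # 2/30 = 0.067 >= 0.06
            ({"A": 47, "G": 3}, {"A", "G"}),  # 3/50 = 0.06 boundary inclusive
        ],
    )
    def test_presence_threshold_boundaries(self, t21_counts, expected_candidates):
        site = make_site(
            {
                "T21": t21_counts,
                "dP": {"A": 30},
                "dM1": {"A": 30},
                "dM2": {"A": 30},
            }
        )
        profile = compute_base_sets(site)
        assert profile.candidate_alleles == expected_candidates

    def test_base_below_threshold_in_trisomy_excluded_everywhere(self):
        site = make_site(
            {
                "T21": {"A": 29, "G": 1},
                "dP": {"A": 20, "G": 10},
                "dM1": {"A": 30},
                "dM2": {"A": 30},
            }
        )
        profile = compute_base_sets(site)
        assert profile.candidate_alleles == {"A"}
        assert all(bs == {"A"} for bs in profile.present.values())
        assert any("dP" in d for d in profile.diagnostics)

    def test_zero_depth_raises(self):
        site = SiteObservation(
            chrom="21", pos=5, ref="A", alts=("G",), variant_class=SNV,
            counts={s: {} for s in SAMPLES},
            depth={"T21": 30, "dP": 0, "dM1": 30, "dM2": 30},
        )
        with pytest.raises(ValueError, match="zero depth"):
            compute_base_sets(site)

    @given(st.floats(min_value=0.01, max_value=0.4))
    @settings(max_examples=30, deadline=None)
    def test_raising_tau_never_enlarges_present_sets(self, tau):
        site = make_site(
            {
                "T21": {"A": 10, "G": 18, "C": 2},
                "dP": {"G": 28, "C": 2},
                "dM1": {"A": 15, "G": 15},
                "dM2": {"A": 16, "G": 14},
            }
        )
        lo = compute_base_sets(site, tau_present=tau)
        hi = compute_base_sets(site, tau_present=tau + 0.05)
        assert hi.candidate_alleles <= lo.candidate_alleles
        for s in SAMPLES:
            assert hi.present[s] <= lo.present[s]


class TestVcfIO:
    def test_simulated_vcf_round_trip_is_count_exact(self, tmp_path):
        params = SimParams(
            n_sites=400, chrom_length=80_000, seed=17, error_rate=0.01
        )
        _, _, sites = simulate_dataset(params)
        path = tmp_path / "sim.vcf"
        write_multisample_vcf(sites, path, params.sample_names,
                              {params.chrom: params.chrom_length})
        back = read_multisample_vcf(path)
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref, b.alts)
            assert b.variant_class == SNV
            assert {s: dict(c) for s, c in a.counts.items()} == \
                   {s: dict(c) for s, c in b.counts.items()}
            assert dict(a.depth) == dict(b.depth)

    def test_hand_written_records_parse_with_classes_and_fallback_depth(self, tmp_path):
        text = "\n".join(
            [
                "##fileformat=VCFv4.2",
                "##contig=<ID=21,length=50000000>",
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                "T21\tdP\tdM1\tdM2",
                # biallelic SNV, AD=10,10 everywhere, no DP -> depth 20
                "21\t100\t.\tA\tG\t.\t.\t.\tGT:AD\t"
                + "\t".join(["./.:10,10"] * 4),
                # indel record
                "21\t200\t.\tA\tAT\t.\t.\t.\tGT:AD:DP\t"
                + "\t".join(["./.:20,10:30"] * 4),
            ]
        )
        path = tmp_path / "hand.vcf"
        path.write_text(text + "\n")
        sites = read_multisample_vcf(path)
        snv, indel = sites
        assert snv.depth == {s: 20 for s in SAMPLES}
        assert all(c == {"A": 10, "G": 10} for c in snv.counts.values())
        assert indel.variant_class == INDEL

    def test_missing_ad_is_a_hard_error_naming_the_record(self, tmp_path):
        text = "\n".join(
            [
                "##fileformat=VCFv4.2",
                "##contig=<ID=21>",
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                "T21\tdP\tdM1\tdM2",
                "21\t300\t.\tA\tG\t.\t.\t.\tGT\t./.\t./.\t./.\t./.",
            ]
        )
        path = tmp_path / "bad.vcf"
        path.write_text(text + "\n")
        with pytest.raises(ValueError, match="21:300"):
            read_multisample_vcf(path)

    def test_wrong_sample_count_rejected(self, tmp_path):
        text = "\n".join(
            [
                "##fileformat=VCFv4.2",
                "##contig=<ID=21>",
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT21\tdP",
            ]
        )
        path = tmp_path / "two.vcf"
        path.write_text(text + "\n")
        with pytest.raises(ValueError, match="four"):
            read_multisample_vcf(path)


def test_filter_report_lists_every_site(tmp_path):
    import pandas as pd

    sites = [uniform_site((30,) * 4), uniform_site((5, 30, 30, 30))]
    object.__setattr__(sites[1], "pos", 200)
    kept, dropped = filter_sites(sites)
    path = tmp_path / "report.tsv"
    write_filter_report(kept, dropped, path)
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["chrom", "pos", "decision", "reason"]
    assert len(df) == 2
    assert set(df.decision) == {"kept", "dropped"}
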