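"""Tier-engine rules, precedence, monotonicity, and oracle equivalence."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import binomtest

from valk.filtering import (DEFAULT_WHITELIST, FilterConfig, RegionSet, Tier,
                            classify_variant, codon_of, load_filter_config,
                            load_region_set, run_filter)
from valk.io import SampleTable, VariantCall, VariantClass


def call(**kw):
    base = dict(sample_id="S", chrom="chr2", pos=29_440_000, ref="G", alt="A",
                variant_class=VariantClass.SNV, gene="ALK",
                protein_change="p.G1202R", af=0.01, read_depth=21261,
                read_alt_count=200, mol_depth=1670, mol_alt_count=17)
    base.update(kw)
    return VariantCall(**base)


@pytest.fixture(scope="module")
def cfg():
    return FilterConfig()


class TestClassifyExamples:
    def test_high_af_hotspot_is_commercial(self, cfg):
        v = classify_variant(call(protein_change="p.G1269A", af=0.0336,
                                  mol_alt_count=56), cfg)
        assert v.tier is Tier.COMMERCIAL

    def test_low_af_hotspot_with_molecular_depth_is_rescued(self, cfg):
        v = classify_variant(call(af=0.0005, mol_depth=1600, mol_alt_count=3,
                                  read_alt_count=11), cfg)
        assert v.tier is Tier.VALK_RESCUED

    def test_af_below_rescue_floor_is_raw_only(self, cfg):
        v = classify_variant(call(protein_change="p.A1200V", af=0.0002,
                                  mol_alt_count=3, read_alt_count=4), cfg)
        assert v.tier is Tier.RAW_ONLY

    def test_germline_af_rejected(self, cfg):
        v = classify_variant(call(af=0.52, mol_alt_count=868,
                                  read_alt_count=11000), cfg)
        assert v.tier is Tier.REJECTED and "germline" in v.reasons[0]

    def test_blacklist_precedence_over_everything(self, cfg):
        black = replace(cfg, blacklist=RegionSet(
            genomic=(("chr2", 29_430_000, 29_450_000, "artifact"),)))
        v = classify_variant(call(af=0.0004, mol_alt_count=5), black)
        assert v.tier is Tier.REJECTED and v.reasons == ("blacklist",)

    def test_molecular_floor_rejects(self, cfg):
        v = classify_variant(call(af=0.0006, mol_alt_count=1, read_alt_count=13), cfg)
        assert v.tier is Tier.REJECTED and "mol_alt_floor" in v.reasons[0]

    def test_noise_indistinguishable_rejected(self, cfg):
        # 2 molecules out of 1670 is not significant vs 1e-4 error at alpha 0.01
        v = classify_variant(call(af=0.0012, mol_alt_count=2, read_alt_count=26), cfg)
        assert v.tier is Tier.REJECTED and v.reasons[0].startswith("noise")

    def test_non_hotspot_low_af_is_raw_only(self, cfg):
        v = classify_variant(call(gene="TP53", chrom="chr17", pos=7_578_000,
                                  protein_change="p.R175H", af=0.002,
                                  mol_alt_count=4, read_alt_count=42), cfg)
        assert v.tier is Tier.RAW_ONLY

    def test_cnv_gain_loss_and_neutral(self, cfg):
        cnv = dict(variant_class=VariantClass.CNV, ref="", alt="", gene="MYC",
                   protein_change="", af=0.0, read_alt_count=0, mol_depth=0,
                   mol_alt_count=0)
        assert classify_variant(call(cnv_ratio=3.08, **cnv), cfg).tier is Tier.COMMERCIAL
        assert classify_variant(call(cnv_ratio=0.38, **cnv), cfg).tier is Tier.COMMERCIAL
        v = classify_variant(call(cnv_ratio=1.2, **cnv), cfg)
        assert v.tier is Tier.REJECTED

    def test_fusion_read_support(self, cfg):
        fus = dict(variant_class=VariantClass.FUSION, gene="ALK",
                   protein_change="", ref="N", alt="EML4-ALK", af=0.0,
                   mol_depth=0, mol_alt_count=0)
        assert classify_variant(call(read_alt_count=25, **fus), cfg).tier \
            is Tier.COMMERCIAL
        assert classify_variant(call(read_alt_count=5, **fus), cfg).tier \
            is Tier.REJECTED


def test_codon_parsing():
    assert codon_of("p.G1202R") == 1202
    assert codon_of("p.E746_A750del") == 746
    assert codon_of("p.T256fs") == 256
    assert codon_of("") is None


def test_whitelist_protein_space_bounds(cfg):
    inside = call(protein_change="p.V1180L", af=0.001, mol_alt_count=3,
                  read_alt_count=21)
    outside = call(protein_change="p.G1121S", af=0.001, mol_alt_count=3,
                   read_alt_count=21)
    assert classify_variant(inside, cfg).tier is Tier.VALK_RESCUED
    assert classify_variant(outside, cfg).tier is Tier.RAW_ONLY


def test_run_filter_preserves_order_and_length(cfg):
    calls = [call(pos=29_440_000 + i, af=0.0005, mol_alt_count=3,
                  read_alt_count=11) for i in range(5)]
    table = SampleTable(sample_id="S", calls=calls)
    out = run_filter(table, cfg)
    assert [c.pos for c, _ in out] == [c.pos for c in calls]
    assert run_filter(SampleTable(sample_id="E"), cfg) == []


# ---------------------------------------------------------------------------
# independent oracle: a literal, separately coded translation of the rules
# ---------------------------------------------------------------------------

def oracle_tier(c: VariantCall, f: FilterConfig) -> Tier:
    in_black = any(c.chrom == ch and s <= c.pos <= e
                   for ch, s, e, _ in f.blacklist.genomic)
    codon = codon_of(c.protein_change)
    if not in_black and codon is not None:
        in_black = any(c.gene == g and s <= codon <= e
                       for g, s, e, _ in f.blacklist.protein)
    if in_black:
        return Tier.REJECTED
    if c.variant_class.value in ("SNV", "MNP") and c.af >= f.germline_af_min:
        return Tier.REJECTED
    if c.variant_class.value not in ("FUSION", "CNV") and c.mol_alt_count < f.mol_alt_min:
        return Tier.REJECTED
    if c.variant_class.value in ("SNV", "INDEL", "MNP"):
        if c.mol_depth == 0:
            return Tier.REJECTED
        p = binomtest(c.mol_alt_count, c.mol_depth, f.assay_error_rate,
                      alternative="greater").pvalue
        if p >= f.noise_alpha:
            return Tier.REJECTED
    if c.variant_class.value == "CNV":
        if c.cnv_ratio >= f.cnv_gain_min or c.cnv_ratio <= f.cnv_loss_max:
            return Tier.COMMERCIAL
        return Tier.REJECTED
    if c.variant_class.value == "FUSION":
        return Tier.COMMERCIAL if c.read_alt_count >= f.fusion_read_min else Tier.REJECTED
    if c.af >= f.commercial_af_min and c.read_depth >= f.read_depth_min:
        return Tier.COMMERCIAL
    in_white = any(c.chrom == ch and s <= c.pos <= e
                   for ch, s, e, _ in f.whitelist.genomic)
    if not in_white and codon is not None:
        in_white = any(c.gene == g and s <= codon <= e
                       for g, s, e, _ in f.whitelist.protein)
    if c.af >= f.valk_af_min and c.mol_depth >= f.mol_depth_min and in_white:
        return Tier.VALK_RESCUED
    return Tier.RAW_ONLY


def random_calls(n, seed):
    """Threshold-straddling random calls across classes and regions."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        kind = rng.choice(["SNV", "SNV", "SNV", "INDEL", "MNP", "CNV", "FUSION"])
        mol_depth = int(rng.choice([0, 150, 299, 300, 1670, 2500]))
        af = float(10 ** rng.uniform(-4.6, -0.2))
        mol_alt = int(min(rng.choice([0, 1, 2, 3, 5, round(af * mol_depth)]),
                          mol_depth))
        gene, prot = ("ALK", f"p.G{int(rng.integers(1100, 1300))}R") \
            if rng.random() < 0.5 else ("TP53", "p.R175H")
        kw = dict(sample_id="S", chrom="chr2" if gene == "ALK" else "chr17",
                  pos=int(rng.integers(1, 40_000_000)), ref="G", alt="A",
                  variant_class=VariantClass(kind), gene=gene,
                  protein_change=prot, af=af,
                  read_depth=int(rng.choice([500, 999, 1000, 21261])),
                  mol_depth=mol_depth, mol_alt_count=mol_alt)
        kw["read_alt_count"] = min(round(af * kw["read_depth"]), kw["read_depth"])
        if kind == "CNV":
            kw.update(ref="", alt="", protein_change="", af=0.0,
                      cnv_ratio=float(rng.choice([0.3, 0.5, 1.0, 1.9, 2.0, 3.1])),
                      mol_depth=0, mol_alt_count=0, read_alt_count=0)
        elif kind == "FUSION":
            kw.update(ref="N", alt="FUS", protein_change="", af=0.0,
                      read_alt_count=int(rng.choice([0, 19, 20, 40])))
        out.append(VariantCall(**kw))
    return out


def test_oracle_equivalence_on_1000_calls(cfg):
    """run_filter agrees 100% with the independently coded rule list."""
    config = replace(cfg, blacklist=RegionSet(
        genomic=(("chr17", 7_577_000, 7_577_050, "artifact"),),
        protein=(("ALK", 1123, 1125, "edge_artifact"),)))
    calls = random_calls(1000, seed=20240917)
    table = SampleTable(sample_id="S", calls=calls)
    got = [v.tier for _, v in run_filter(table, config)]
    want = [oracle_tier(c, config) for c in calls]
    assert got == want


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

RANK = {t: t.rank for t in Tier}


@pytest.mark.parametrize("seed", range(5))
def test_monotonicity_under_threshold_tightening(cfg, seed):
    """Raising valk_af_min or mol_alt_min never promotes any call."""
    calls = random_calls(200, seed=seed)
    tighter_af = replace(cfg, valk_af_min=cfg.valk_af_min * 3)
    tighter_mol = replace(cfg, mol_alt_min=cfg.mol_alt_min + 2)
    for c in calls:
        base = classify_variant(c, cfg).tier.rank
        assert classify_variant(c, tighter_af).tier.rank <= base
        assert classify_variant(c, tighter_mol).tier.rank <= base


def test_commercial_nested_in_rescue_requirements(cfg):
    """A whitelisted COMMERCIAL call with adequate molecular depth would be
    rescued if the commercial bar were out of reach."""
    calls = [c for c in random_calls(500, seed=3)
             if c.variant_class is VariantClass.SNV and c.mol_depth >= cfg.mol_depth_min]
    no_commercial = replace(cfg, commercial_af_min=0.39)
    checked = 0
    for c in calls:
        if classify_variant(c, cfg).tier is Tier.COMMERCIAL \
                and cfg.whitelist.contains(c) and c.af < 0.39:
            assert classify_variant(c, no_commercial).tier is Tier.VALK_RESCUED
            checked += 1
    assert checked > 0


def test_config_invariant_validation():
    with pytest.raises(ValueError):
        FilterConfig(valk_af_min=0.01, commercial_af_min=0.005)
    with pytest.raises(ValueError):
        FilterConfig(cnv_gain_min=0.9)
    with pytest.raises(ValueError):
        FilterConfig(mol_alt_min=0)


# ---------------------------------------------------------------------------
# region files and config files
# ---------------------------------------------------------------------------

def test_load_region_set_bed_and_protein(tmp_path):
    path = tmp_path / "regions.txt"
    path.write_text("chr2\t29000000\t29000100\tartifact\n"
                    "ALK 1180 1275 kinase_hotspots\n"
                    "# comment\n")
    rs = load_region_set(path)
    # BED half-open 0-based -> 1-based inclusive
    assert rs.genomic == (("chr2", 29000001, 29000100, "artifact"),)
    assert rs.protein == (("ALK", 1180, 1275, "kinase_hotspots"),)


def test_load_region_set_merges_overlaps(tmp_path):
    path = tmp_path / "regions.txt"
    path.write_text("ALK 1180 1200 hs\nALK 1195 1275 hs\n")
    rs = load_region_set(path)
    assert rs.protein == (("ALK", 1180, 1275, "hs"),)


def test_load_region_set_errors(tmp_path):
    bad = tmp_path / "bad.txt"
    bad.write_text("ALK 1275 1180 hs\n")
    with pytest.raises(ValueError, match="line 1"):
        load_region_set(bad)
    bad.write_text("chr1\t100\n")
    with pytest.raises(ValueError, match="4 fields"):
        load_region_set(bad)


def test_load_filter_config_roundtrip(tmp_path):
    regions = tmp_path / "wl.txt"
    regions.write_text("ALK 1123 1278 kinase\n")
    cfg_file = tmp_path / "filter.cfg"
    cfg_file.write_text("commercial_af_min=0.004\nmol_alt_min=3\nwhitelist=wl.txt\n")
    config = load_filter_config(cfg_file)
    assert config.commercial_af_min == 0.004
    assert config.mol_alt_min == 3
    assert config.whitelist.protein[0][:3] == ("ALK", 1123, 1278)
    cfg_file.write_text("not_a_key=1\n")
    with pytest.raises(ValueError, match="unknown key"):
        load_filter_config(cfg_file)
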