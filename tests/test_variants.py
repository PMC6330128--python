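import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from indelenrich.variants import (
    ReferenceVariantList,
    apply_qc_filters,
    classify_allele_pair,
    classify_variants,
    compute_maf,
    match_reference_list,
    read_sumstats,
    strip_chr_prefix,
)

alleles = st.text(alphabet="ACGT", min_size=1, max_size=8)


@pytest.mark.parametrize(
    "ref,alt,category,length",
    [
        ("A", "T", "SNP", 0),
        ("TGCTG", "T", "deletion", 4),
        ("T", "TAC", "insertion", 2),
        ("AT", "A", "deletion", 1),
        ("G", "GA", "insertion", 1),
    ],
)
def test_classification(ref, alt, category, length):
    vc = classify_allele_pair(ref, alt)
    assert vc.category == category
    assert vc.indel_length == length
    assert vc.is_indel == (category != "SNP")
    assert vc.is_single_base_indel == (length == 1)


@pytest.mark.parametrize(
    "ref,alt",
    [("", "A"), ("A", ""), ("AN", "A"), ("a", "t"), ("A", "A"), ("AT", "GC")],
)
def test_classification_rejects_invalid_pairs(ref, alt):
    with pytest.raises(ValueError):
        classify_allele_pair(ref, alt)


@given(ref=alleles, alt=alleles)
@settings(max_examples=200, deadline=None)
def test_swapping_alleles_mirrors_insertion_and_deletion(ref, alt):
    if ref == alt or (len(ref) == len(alt) and len(ref) > 1):
        return
    fwd, rev = classify_allele_pair(ref, alt), classify_allele_pair(alt, ref)
    assert fwd.indel_length == rev.indel_length
    if fwd.category == "insertion":
        assert rev.category == "deletion"
    elif fwd.category == "deletion":
        assert rev.category == "insertion"
    else:
        assert rev.category == "SNP"


def test_classify_variants_table(variant_table):
    out = classify_variants(variant_table)
    assert list(out["vclass"]) == ["SNP", "deletion", "insertion", "SNP", "SNP"]
    assert list(out["indel_len"]) == [0, 4, 2, 0, 0]
    bad = variant_table.copy()
    bad.loc[0, "ALT"] = "A"  # ref == alt
    with pytest.raises(ValueError, match="invalid variant"):
        classify_variants(bad)


@pytest.mark.parametrize(
    "maf,rsqr,passes,reason",
    [
        (0.05, 0.40, True, None),     # satisfies both stages
        (0.005, 0.50, False, "rsqr"),  # rare variant below the 0.6 rule
        (0.005, 0.70, False, "maf"),   # quality ok but below the MAF cutoff
        (0.02, 0.25, False, "rsqr"),   # common variant below the 0.3 rule
        (0.01, 0.31, True, None),      # inclusive MAF boundary
    ],
)
def test_qc_filter_rules(maf, rsqr, passes, reason):
    df = pd.DataFrame(
        {"CHROM": ["1"], "POS": [1], "REF": ["A"], "ALT": ["T"],
         "MAF": [maf], "RSQR": [rsqr]}
    )
    passed, rejected = apply_qc_filters(df)
    assert (len(passed) == 1) == passes
    if not passes:
        assert rejected["reject_reason"].iloc[0] == reason


def test_qc_partitions_input(rng):
    n = 500
    df = pd.DataFrame(
        {
            "CHROM": ["1"] * n,
            "POS": np.arange(1, n + 1),
            "REF": ["A"] * n,
            "ALT": ["T"] * n,
            "MAF": rng.uniform(0, 0.5, n),
            "RSQR": rng.uniform(0, 1, n),
        }
    )
    passed, rejected = apply_qc_filters(df)
    assert len(passed) + len(rejected) == n
    assert set(passed.index).isdisjoint(rejected.index)
    assert (passed["MAF"] >= 0.01).all() and (passed["RSQR"] > 0.3).all()


def test_qc_missing_values_error(variant_table):
    df = variant_table.copy()
    df.loc[1, "RSQR"] = np.nan
    with pytest.raises(ValueError, match="missing MAF/RSQR"):
        apply_qc_filters(df)


def test_compute_maf_folds_frequencies():
    assert np.allclose(compute_maf([0.3, 0.9, 0.5]), [0.3, 0.1, 0.5])
    with pytest.raises(ValueError):
        compute_maf([1.2])


def test_reference_list_exact_match():
    rl = ReferenceVariantList([("1", 100, "A", "AT")])
    df = pd.DataFrame(
        {"CHROM": ["1", "1", "2"], "POS": [100, 100, 5],
         "REF": ["A", "A", "C"], "ALT": ["AT", "AC", "G"]}
    )
    present, summary = match_reference_list(df, rl)
    assert list(present) == [True, False, False]
    assert summary["n_absent"] == 2
    assert summary["fraction_absent"] == pytest.approx(2 / 3)


def test_reference_list_dialect_mismatch_is_an_error():
    rl = ReferenceVariantList([("chr1", 100, "A", "T")])
    df = pd.DataFrame({"CHROM": ["1"], "POS": [100], "REF": ["A"], "ALT": ["T"]})
    with pytest.raises(ValueError, match="dialect"):
        match_reference_list(df, rl)
    # explicit normalisation is available, never implicit
    assert strip_chr_prefix(pd.DataFrame({"CHROM": ["chr1"]}))["CHROM"].iloc[0] == "1"


def test_reference_list_io(tmp_path):
    tab = tmp_path / "ref.tsv"
    tab.write_text("1\t100\tA\tAT\n2\t5\tC\tG\n")
    rl = ReferenceVariantList.from_table(tab)
    assert ("1", 100, "A", "AT") in rl and len(rl) == 2

    vcf = tmp_path / "sites.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1,length=1000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\trs1\tA\tAT\t.\t.\t.\n"
        "1\t200\trs2\tC\tG,T\t.\t.\t.\n"
    )
    rl = ReferenceVariantList.from_vcf(vcf)
    assert ("1", 200, "C", "G") in rl and ("1", 200, "C", "T") in rl
    assert len(rl) == 3


def test_read_sumstats_requires_columns(tmp_path, variant_table):
    path = tmp_path / "ss.tsv"
    variant_table.to_csv(path, sep="\t", index=False)
    df = read_sumstats(path, trait="height")
    assert df["TRAIT"].eq("height").all() and df["CHROM"].dtype == object
    variant_table.drop(columns=["RSQR"]).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="RSQR"):
        read_sumstats(path)
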