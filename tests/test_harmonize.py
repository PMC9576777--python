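import io

import numpy as np
import pandas as pd
import pytest

from pqtlmr.harmonize import (
    COLUMNS,
    SummaryStatError,
    harmonize,
    is_palindromic,
    read_summary_stats,
    write_summary_stats,
)


def make_assoc(rows, trait_id="t", trait_type="quantitative"):
    df = pd.DataFrame(rows)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["trait_id"] = df["trait_id"].fillna(trait_id) if df["trait_id"].notna().any() else trait_id
    df["trait_type"] = trait_type
    return df[COLUMNS]


BASE = dict(chrom="1", pos=100, eaf=0.3, pvalue=1e-9, info=0.99, n=5000)


def test_read_back_identity(tmp_path):
    """A well-formed table reads into one validated record per row and round-trips."""
    df = make_assoc([
        dict(rsid="rs1", effect_allele="A", other_allele="G", beta=0.2, se=0.02, **BASE),
        dict(rsid="rs2", effect_allele="C", other_allele="T", beta=-0.1, se=0.03, **BASE),
        dict(rsid="rs3", effect_allele="AT", other_allele="A", beta=0.05, se=0.01, **BASE),
    ])
    path = tmp_path / "stats.tsv"
    write_summary_stats(df, path)
    got = read_summary_stats(path)
    assert len(got) == 3
    assert (got["se"] > 0).all()
    write_summary_stats(got, tmp_path / "again.tsv")
    again = read_summary_stats(tmp_path / "again.tsv")
    pd.testing.assert_frame_equal(got, again)


def test_invalid_rows_rejected_with_reason(tmp_path):
    df = make_assoc([
        dict(rsid="rs1", effect_allele="A", other_allele="G", beta=0.2, se=0.0, **BASE),
        dict(rsid="rs2", effect_allele="A", other_allele="G", beta=0.1, se=0.02, **BASE),
    ])
    path = tmp_path / "bad.tsv"
    write_summary_stats(df, path)
    with pytest.raises(SummaryStatError, match="nonpositive_se"):
        read_summary_stats(path)
    got = read_summary_stats(path, on_invalid="drop")
    assert list(got["rsid"]) == ["rs2"]
    assert got.attrs["excluded"]["reason"].tolist() == ["nonpositive_se"]


def test_missing_required_column_is_config_error(tmp_path):
    path = tmp_path / "nocol.tsv"
    path.write_text("rsid\tbeta\nrs1\t0.2\n")
    with pytest.raises(SummaryStatError, match="missing required"):
        read_summary_stats(path)


def test_dialect_mapping(tmp_path):
    path = tmp_path / "mapped.csv"
    path.write_text("SNP,A1,A2,b,stderr,pval\nrs1,a,g,0.2,0.02,1e-9\n")
    got = read_summary_stats(path, dialect={
        "SNP": "rsid", "A1": "effect_allele", "A2": "other_allele",
        "b": "beta", "stderr": "se", "pval": "pvalue",
    })
    assert got.loc[0, "effect_allele"] == "A"  # uppercased
    assert got.loc[0, "beta"] == 0.2


def exposure_outcome():
    exp = make_assoc([
        dict(rsid="rs1", effect_allele="A", other_allele="G", beta=0.2, se=0.02, **BASE),
        dict(rsid="rs2", effect_allele="C", other_allele="T", beta=0.3, se=0.02, **BASE),
        dict(rsid="rs3", effect_allele="A", other_allele="T", beta=0.1, se=0.02,
             chrom="1", pos=300, eaf=0.5, pvalue=1e-9, info=0.99, n=5000),
    ])
    out = make_assoc([
        # rs1: outcome coded for the exposure's other allele -> flip
        dict(rsid="rs1", effect_allele="G", other_allele="A", beta=0.3, se=0.05,
             chrom="1", pos=100, eaf=0.1, pvalue=1e-4, info=0.99, n=40000),
        # rs2: same coding
        dict(rsid="rs2", effect_allele="C", other_allele="T", beta=0.15, se=0.04, **BASE),
        # rs3: palindromic A/T at eaf 0.5
        dict(rsid="rs3", effect_allele="A", other_allele="T", beta=0.05, se=0.04,
             chrom="1", pos=300, eaf=0.5, pvalue=0.1, info=0.99, n=40000),
    ], trait_type="binary")
    return exp, out


def test_flip_sign_and_frequency():
    exp, out = exposure_outcome()
    res = harmonize(exp, out)
    rs1 = res.pairs.set_index("rsid").loc["rs1"]
    assert rs1["flipped"]
    assert rs1["beta_y"] == pytest.approx(-0.3)
    rs2 = res.pairs.set_index("rsid").loc["rs2"]
    assert not rs2["flipped"]
    assert rs2["beta_y"] == pytest.approx(0.15)


def test_palindromic_dropped_by_default():
    exp, out = exposure_outcome()
    res = harmonize(exp, out, palindrome_policy="drop")
    assert "rs3" not in set(res.pairs["rsid"])
    reasons = dict(zip(res.excluded["rsid"], res.excluded["reason"]))
    assert reasons["rs3"] == "palindromic"


def test_palindromic_eaf_inference():
    exp = make_assoc([dict(rsid="rs9", effect_allele="A", other_allele="T",
                           beta=0.2, se=0.02, chrom="1", pos=1, eaf=0.10,
                           pvalue=1e-9, info=1.0, n=5000)])
    # same minor-allele side: keep label orientation
    out_same = make_assoc([dict(rsid="rs9", effect_allele="A", other_allele="T",
                                beta=0.1, se=0.04, chrom="1", pos=1, eaf=0.12,
                                pvalue=0.01, info=1.0, n=40000)])
    res = harmonize(exp, out_same, palindrome_policy="infer_by_eaf")
    assert res.pairs.loc[0, "beta_y"] == pytest.approx(0.1)
    assert not res.pairs.loc[0, "flipped"]
    # opposite side: the outcome file is on the other strand -> flip
    out_flip = out_same.assign(eaf=0.88)
    res2 = harmonize(exp, out_flip, palindrome_policy="infer_by_eaf")
    assert res2.pairs.loc[0, "flipped"]
    assert res2.pairs.loc[0, "beta_y"] == pytest.approx(-0.1)
    # ambiguous eaf -> dropped
    out_amb = out_same.assign(eaf=0.49)
    res3 = harmonize(exp, out_amb, palindrome_policy="infer_by_eaf")
    assert res3.pairs.empty
    assert res3.excluded["reason"].tolist() == ["palindromic_ambiguous"]


def test_incompatible_alleles_excluded():
    exp = make_assoc([dict(rsid="rs1", effect_allele="A", other_allele="G",
                           beta=0.2, se=0.02, **BASE)])
    out = make_assoc([dict(rsid="rs1", effect_allele="A", other_allele="C",
                           beta=0.1, se=0.04, **BASE)])
    res = harmonize(exp, out)
    assert res.pairs.empty
    assert res.excluded["reason"].tolist() == ["allele_mismatch"]


def test_strand_complement_match():
    exp = make_assoc([dict(rsid="rs1", effect_allele="A", other_allele="G",
                           beta=0.2, se=0.02, **BASE)])
    # T/C is the reverse-complement coding of A/G on the other strand
    out = make_assoc([dict(rsid="rs1", effect_allele="T", other_allele="C",
                           beta=0.1, se=0.04, **BASE)])
    res = harmonize(exp, out)
    assert len(res.pairs) == 1
    assert not res.pairs.loc[0, "flipped"]
    assert res.pairs.loc[0, "beta_y"] == pytest.approx(0.1)


def test_position_mismatch_excluded():
    exp = make_assoc([dict(rsid="rs1", effect_allele="A", other_allele="G",
                           beta=0.2, se=0.02, **BASE)])
    out = make_assoc([dict(rsid="rs1", effect_allele="A", other_allele="G",
                           beta=0.1, se=0.04, chrom="2", pos=100, eaf=0.3,
                           pvalue=0.01, info=1.0, n=1000)])
    res = harmonize(exp, out)
    assert res.pairs.empty
    assert res.excluded["reason"].tolist() == ["position_mismatch"]


def pairs_to_outcome(pairs, trait_type="binary"):
    """Re-express harmonized pairs as an outcome association table."""
    return make_assoc([
        dict(rsid=r["rsid"], effect_allele=r["effect_allele"],
             other_allele=r["other_allele"], beta=r["beta_y"], se=r["se_y"],
             chrom=r["chrom"], pos=r["pos"], eaf=r["eaf"], pvalue=0.5,
             info=1.0, n=40000)
        for _, r in pairs.iterrows()
    ], trait_type=trait_type)


def test_harmonization_is_involution():
    """Harmonizing an already-harmonized outcome table changes nothing."""
    exp, out = exposure_outcome()
    first = harmonize(exp, out)
    second = harmonize(exp, pairs_to_outcome(first.pairs))
    assert len(second.pairs) == len(first.pairs)
    np.testing.assert_allclose(second.pairs["beta_y"], first.pairs["beta_y"])
    assert not second.pairs["flipped"].any()


def test_global_allele_flip_invariance():
    """Recoding every outcome record to the opposite allele leaves pairs unchanged."""
    exp, out = exposure_outcome()
    flipped = out.copy()
    flipped[["effect_allele", "other_allele"]] = out[["other_allele", "effect_allele"]].to_numpy()
    flipped["beta"] = -out["beta"]
    flipped["eaf"] = 1 - out["eaf"]
    a = harmonize(exp, out).pairs
    b = harmonize(exp, flipped).pairs
    assert list(a["rsid"]) == list(b["rsid"])
    np.testing.assert_allclose(a["beta_y"], b["beta_y"])
    np.testing.assert_allclose(a["eaf"], b["eaf"])


def test_is_palindromic():
    assert is_palindromic("A", "T") and is_palindromic("C", "G")
    assert not is_palindromic("A", "G")
    assert not is_palindromic("AT", "A")
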