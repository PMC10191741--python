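"""Tucson/VCF/matrix012/climate readers: examples, errors, round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pial import dataio
from pial.dataio import MalformedFileError, RingWidthSeries


# ---------------------------------------------------------------------------
# Tucson ring-width files
# ---------------------------------------------------------------------------


def test_rwl_basic_line_001mm_dialect(tmp_path):
    p = tmp_path / "a.rwl"
    p.write_text("T01A 1970 100 200 999\n")
    (series,) = dataio.read_rwl(p, dialect="units_0.01mm")
    assert series.years.tolist() == [1970, 1971]
    assert series.widths.tolist() == [1.00, 2.00]


def test_rwl_missing_stop_marker_is_flagged(tmp_path):
    # under the 0.001 mm dialect the trailing 999 is a 0.999 mm ring,
    # so the series reaches EOF unterminated
    p = tmp_path / "a.rwl"
    p.write_text("T01A 1970 100 200 999\n")
    with pytest.raises(MalformedFileError, match="stop marker"):
        dataio.read_rwl(p, dialect="units_0.001mm")


def test_rwl_auto_detect_both_dialects(tmp_path):
    p1 = tmp_path / "a.rwl"
    p1.write_text("T01A 1970 100 200 999\n")
    assert dataio.read_rwl(p1, dialect="auto")[0].widths.tolist() == [1.0, 2.0]
    p2 = tmp_path / "b.rwl"
    p2.write_text("T01A 1970 1000 2000 -9999\n")
    assert dataio.read_rwl(p2, dialect="auto")[0].widths.tolist() == [1.0, 2.0]


def test_rwl_non_consecutive_decades_error(tmp_path):
    p = tmp_path / "a.rwl"
    p.write_text("T01A 1970 100 200\nT01A 1990 100 999\n")
    with pytest.raises(MalformedFileError, match="non-consecutive"):
        dataio.read_rwl(p, dialect="units_0.01mm")


@pytest.mark.parametrize("dialect", ["units_0.01mm", "units_0.001mm"])
def test_rwl_round_trip_preserves_widths(tmp_path, dialect):
    rng = np.random.default_rng(0)
    decimals = 2 if dialect == "units_0.01mm" else 3
    series = [
        RingWidthSeries(
            tree_id=f"T{i:02d}",
            site_id="S",
            years=np.arange(1965 + i, 1965 + i + n),
            widths=np.round(rng.uniform(0.05, 8.0, n), decimals),
        )
        for i, n in enumerate([5, 23, 41])
    ]
    p = tmp_path / "rt.rwl"
    dataio.write_rwl(series, p, dialect=dialect)
    back = dataio.read_rwl(p, dialect=dialect)
    assert len(back) == 3
    for a, b in zip(series, back):
        assert a.years.tolist() == b.years.tolist()
        np.testing.assert_allclose(a.widths, b.widths, atol=5e-4)
        assert np.all(np.diff(b.years) == 1) and np.all(b.widths >= 0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    widths=st.lists(
        st.integers(min_value=1, max_value=9000).map(lambda v: v / 1000.0),
        min_size=1,
        max_size=60,
    ),
    start=st.integers(min_value=1500, max_value=2015),
)
def test_rwl_round_trip_fuzzed(tmp_path_factory, widths, start):
    """Any series of positive mm widths survives write -> read exactly."""
    tmp = tmp_path_factory.mktemp("fuzz")
    s = RingWidthSeries(
        "FUZZ", "S", np.arange(start, start + len(widths)), np.array(widths)
    )
    p = tmp / "f.rwl"
    dataio.write_rwl([s], p, dialect="units_0.001mm")
    (back,) = dataio.read_rwl(p, dialect="units_0.001mm")
    assert back.years.tolist() == s.years.tolist()
    np.testing.assert_allclose(back.widths, s.widths, atol=5e-4)
    # reader output satisfies the type invariants by construction
    assert np.all(np.diff(back.years) == 1) and np.all(back.widths >= 0)


def test_ring_width_series_invariants():
    with pytest.raises(ValueError, match="consecutive"):
        RingWidthSeries("t", "s", [2000, 2002], [1.0, 1.0])
    with pytest.raises(ValueError, match="negative"):
        RingWidthSeries("t", "s", [2000, 2001], [1.0, -1.0])
    with pytest.raises(ValueError, match="dbh"):
        RingWidthSeries("t", "s", [2000], [1.0], dbh_cm=0.0)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _sheet(tmp_path, individuals):
    p = tmp_path / "sheet.csv"
    pd.DataFrame(
        {
            "individual_id": individuals,
            "site_id": ["A"] * len(individuals),
            "utm_e": 0.0,
            "utm_n": 0.0,
            "latitude": 38.0,
        }
    ).to_csv(p, index=False)
    return p


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
)


def test_vcf_gt_dosage_coding(tmp_path):
    p = tmp_path / "a.vcf"
    p.write_text(
        VCF_HEADER + "i1\ti2\ti3\n"
        "chr1\t100\tL1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
    )
    gm = dataio.read_genotype_table(p, "vcf", _sheet(tmp_path, ["i1", "i2", "i3"]))
    assert gm.calls[:, 0].tolist() == [0.0, 1.0, 2.0]


def test_vcf_minor_allele_orientation_flips_majority_alt(tmp_path):
    # allele 0 (REF) is the minor allele: dosages must be flipped
    p = tmp_path / "a.vcf"
    p.write_text(
        VCF_HEADER + "i1\ti2\ti3\ti4\ti5\n"
        "chr1\t100\tL1\tA\tG\t.\t.\t.\tGT\t1/1\t1/1\t1/1\t0/1\t0/0\n"
    )
    gm = dataio.read_genotype_table(
        p, "vcf", _sheet(tmp_path, ["i1", "i2", "i3", "i4", "i5"])
    )
    # raw alt dosages 2,2,2,1,0 (freq 0.7) -> minor counts 0,0,0,1,2
    assert gm.calls[:, 0].tolist() == [0.0, 0.0, 0.0, 1.0, 2.0]
    assert gm.loci.loc[0, "flipped"]


def test_vcf_multiallelic_skipped_and_missing_individual_errors(tmp_path):
    p = tmp_path / "a.vcf"
    p.write_text(
        VCF_HEADER + "i1\ti2\n"
        "chr1\t100\tL1\tA\tG,T\t.\t.\t.\tGT\t0/1\t1/1\n"
        "chr1\t200\tL2\tA\tG\t.\t.\t.\tGT\t0/1\t./.\n"
    )
    gm = dataio.read_genotype_table(p, "vcf", _sheet(tmp_path, ["i1", "i2"]))
    assert gm.n_loci == 1  # multi-allelic record skipped
    assert np.isnan(gm.calls[1, 0])  # ./. is missing
    with pytest.raises(MalformedFileError, match="missing from sample sheet"):
        dataio.read_genotype_table(p, "vcf", _sheet(tmp_path, ["i1"]))


def test_matrix012_na_and_validation(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("individual_id,L1_1,L2_1\ni1,0,NA\ni2,1,2\ni3,2,0\n")
    gm = dataio.read_genotype_table(p, "matrix012", _sheet(tmp_path, ["i1", "i2", "i3"]))
    assert np.isnan(gm.calls[0, 1])
    assert gm.loci["parent_locus"].tolist() == ["L1", "L2"]
    bad = tmp_path / "bad.csv"
    bad.write_text("individual_id,L1_1\ni1,5\n")
    with pytest.raises(MalformedFileError, match="dosages"):
        dataio.read_genotype_table(bad, "matrix012", _sheet(tmp_path, ["i1"]))


def test_matrix012_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    from tests.conftest import make_genotype_matrix

    calls = rng.integers(0, 3, size=(6, 4)).astype(float)
    calls[0, 0] = np.nan
    gm = make_genotype_matrix([calls[:3].tolist(), calls[3:].tolist()])
    out = tmp_path / "g.csv"
    dataio.write_matrix012(gm, out, seed=1)
    sheet = gm.individuals.merge(gm.sites, on="site_id")
    back = dataio.read_genotype_table(out, "matrix012", sheet)
    # same missingness; dosages equal up to dataset-wide minor-allele flips
    assert np.array_equal(np.isnan(back.calls), np.isnan(gm.calls))
    for j in range(gm.n_loci):
        col_a, col_b = gm.calls[:, j], back.calls[:, j]
        ok = ~np.isnan(col_a)
        assert (
            np.array_equal(col_a[ok], col_b[ok])
            or np.array_equal(col_a[ok], 2.0 - col_b[ok])
        )


# ---------------------------------------------------------------------------
# climate tables
# ---------------------------------------------------------------------------


def test_monthly_october_assigned_to_next_water_year(tmp_path, monthly_climate):
    p = tmp_path / "clim.csv"
    monthly_climate.to_csv(p, index=False)
    wy = dataio.read_climate_table(p, resolution="monthly")
    assert sorted(wy["water_year"]) == [2000, 2001]
    assert (wy["PPT"] == 120.0).all()  # 12 months x 10 mm


def test_incomplete_water_year_dropped(tmp_path, monthly_climate):
    p = tmp_path / "clim.csv"
    monthly_climate.iloc[:-1].to_csv(p, index=False)  # WY2001 has 11 months
    wy = dataio.read_climate_table(p, resolution="monthly")
    assert wy["water_year"].tolist() == [2000]


def test_water_year_table_validation(tmp_path):
    df = pd.DataFrame(
        {
            "site_id": ["A", "A"],
            "water_year": [2000, 2000],
            "PPT": [1.0, 2.0],
        }
    )
    p = tmp_path / "c.csv"
    df.to_csv(p, index=False)
    with pytest.raises(MalformedFileError, match="duplicate"):
        dataio.read_climate_table(p)
    df2 = pd.DataFrame(
        {
            "site_id": ["A"],
            "water_year": [2000],
            "PET": [100.0],
            "AET": [60.0],
            "CWD": [10.0],
        }
    )
    df2.to_csv(p, index=False)
    with pytest.raises(MalformedFileError, match="CWD"):
        dataio.read_climate_table(p)
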