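"""Readers and writers for the pipeline's on-disk formats.

Three families of inputs are handled, each with strict validation:

* ring-width series in decadal Tucson (``.rwl``) layout, in either the
  0.01 mm or 0.001 mm dialect;
* SNP genotypes, from a biallelic VCF or a 0/1/2 dosage matrix CSV,
  joined against a required sample sheet carrying site membership and
  site UTM coordinates;
* site climate tables (monthly or water-year CSV) with the water-balance
  variables Tmn, Tmx, PPT, PET, AET and CWD.

Genotype dosages are re-oriented at read time so that every locus counts
its dataset-wide *minor* allele; downstream differentiation and
ordination statistics are therefore orientation-stable regardless of how
the caller's VCF was polarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLIMATE_VARS = ["Tmn", "Tmx", "PPT", "PET", "AET", "CWD"]

#: columns every sample sheet must provide
SAMPLE_SHEET_COLUMNS = ["individual_id", "site_id", "utm_e", "utm_n", "latitude"]


class MalformedFileError(ValueError):
    """A file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RingWidthSeries:
    """One tree's dated annual ring widths, pith-to-bark, in mm.

    ``years`` are strictly consecutive calendar years; ``widths`` has one
    entry per year with the outermost (most recent) ring last.  ``dbh_cm``
    is the stem diameter at breast height, used to anchor the outer radius
    in the basal-area-increment conversion.
    """

    tree_id: str
    site_id: str
    years: np.ndarray
    widths: np.ndarray
    dbh_cm: float | None = None
    height_m: float | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.years.size != self.widths.size:
            raise ValueError(
                f"series {self.tree_id}: {self.years.size} years vs "
                f"{self.widths.size} widths"
            )
        if self.years.size == 0:
            raise ValueError(f"series {self.tree_id}: empty")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError(f"series {self.tree_id}: years not consecutive")
        if np.any(self.widths < 0):
            raise ValueError(f"series {self.tree_id}: negative ring width")
        if self.dbh_cm is not None and not self.dbh_cm > 0:
            raise ValueError(f"series {self.tree_id}: dbh_cm must be > 0")

    def __len__(self) -> int:
        return int(self.years.size)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs coded as minor-allele counts.

    ``calls`` is a float array with values in {0, 1, 2} and NaN for
    missing.  ``individuals`` (individual_id, site_id) aligns with rows;
    ``loci`` (locus_id, parent_locus, position) aligns with columns;
    ``sites`` carries one row per site with UTM coordinates in meters and
    latitude.
    """

    calls: np.ndarray
    individuals: pd.DataFrame
    loci: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype calls must be in {0, 1, 2, NaN}")
        if self.loci["locus_id"].duplicated().any():
            dups = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"]
            raise ValueError(f"duplicate locus ids: {list(dups[:5])}")
        unknown = set(self.individuals["site_id"]) - set(self.sites["site_id"])
        if unknown:
            raise ValueError(f"individuals assigned to unknown sites: {sorted(unknown)}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def site_of_individuals(self) -> np.ndarray:
        return self.individuals["site_id"].to_numpy()

    def subset(self, *, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column masks or indices."""
        calls = self.calls
        individuals = self.individuals
        loci = self.loci
        if rows is not None:
            calls = calls[rows, :]
            individuals = individuals.iloc[np.arange(len(individuals))[rows] if np.asarray(rows).dtype == bool else rows]
        if cols is not None:
            calls = calls[:, cols]
            loci = loci.iloc[np.arange(len(loci))[cols] if np.asarray(cols).dtype == bool else cols]
        return GenotypeMatrix(
            calls=calls.copy(),
            individuals=individuals.reset_index(drop=True),
            loci=loci.reset_index(drop=True),
            sites=self.sites,
        )


# ---------------------------------------------------------------------------
# Tucson ring-width files
# ---------------------------------------------------------------------------

_STOP_MARKERS = {"units_0.01mm": 999, "units_0.001mm": -9999}
_UNIT_DIVISORS = {"units_0.01mm": 100.0, "units_0.001mm": 1000.0}


def _detect_dialect(path: Path) -> str:
    """A file whose series terminate in -9999 is 0.001 mm; else 999 is 0.01 mm.

    -9999 is decisive because it can never be a ring width, whereas a
    trailing 999 in a 0.001 mm file is just a 0.999 mm ring.
    """
    last_values = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 3:
                try:
                    last_values.add(int(parts[-1]))
                except ValueError:
                    continue
    if -9999 in last_values:
        return "units_0.001mm"
    if 999 in last_values:
        return "units_0.01mm"
    raise MalformedFileError(
        f"{path}: cannot auto-detect Tucson dialect "
        "(stop markers ambiguous or absent); pass dialect explicitly"
    )


def read_rwl(path: str | Path, dialect: str = "auto") -> list[RingWidthSeries]:
    """Read a decadal Tucson ring-width file.

    Parameters
    ----------
    path
        Path to the ``.rwl`` file.
    dialect
        ``units_0.01mm`` (stop marker 999), ``units_0.001mm`` (stop
        marker -9999) or ``auto`` to detect from the terminal markers.

    Returns
    -------
    list of :class:`RingWidthSeries` with widths in mm.  Site ids are
    left equal to the series id prefix; attach metadata separately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in _STOP_MARKERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    stop = _STOP_MARKERS[dialect]
    divisor = _UNIT_DIVISORS[dialect]

    series: list[RingWidthSeries] = []
    current_id: str | None = None
    first_year = 0
    values: list[float] = []
    expected_year: int | None = None
    last_lineno = 0

    def finish(terminated: bool, lineno: int) -> None:
        nonlocal current_id, values, expected_year
        if current_id is None:
            return
        if not terminated:
            raise MalformedFileError(
                f"{path}:{lineno}: series {current_id} has no stop marker "
                f"({stop}) before end"
            )
        series.append(
            RingWidthSeries(
                tree_id=current_id,
                site_id=current_id,
                years=np.arange(first_year, first_year + len(values)),
                widths=np.array(values, dtype=float),
            )
        )
        current_id, values, expected_year = None, [], None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            last_lineno = lineno
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise MalformedFileError(f"{path}:{lineno}: unparseable line")
            sid = parts[0]
            try:
                decade_year = int(parts[1])
                raw = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise MalformedFileError(f"{path}:{lineno}: non-numeric field") from exc
            if sid != current_id:
                finish(terminated=False, lineno=lineno)
                current_id = sid
                first_year = decade_year
                expected_year = decade_year
            if decade_year != expected_year:
                raise MalformedFileError(
                    f"{path}:{lineno}: series {sid} non-consecutive decades "
                    f"(expected {expected_year}, got {decade_year})"
                )
            terminated = False
            n_on_line = 0
            for v in raw:
                if v == stop:
                    terminated = True
                    break
                values.append(v / divisor)
                n_on_line += 1
            expected_year = decade_year + n_on_line
            if terminated:
                finish(terminated=True, lineno=lineno)
        finish(terminated=False, lineno=last_lineno)
    return series


def write_rwl(series: Iterable[RingWidthSeries], path: str | Path, dialect: str = "units_0.001mm") -> None:
    """Write series in decadal Tucson layout with the dialect's stop marker."""
    if dialect not in _STOP_MARKERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    stop = _STOP_MARKERS[dialect]
    divisor = _UNIT_DIVISORS[dialect]
    path = Path(path)
    with open(path, "w") as fh:
        for s in series:
            vals = [int(round(w * divisor)) for w in s.widths] + [stop]
            yr = int(s.years[0])
            i = 0
            while i < len(vals):
                # fill to the next decade boundary
                n = min(10 - (yr % 10), len(vals) - i)
                chunk = vals[i : i + n]
                fh.write(
                    f"{s.tree_id:<8s}{yr:>6d}" + "".join(f"{v:>6d}" for v in chunk) + "\n"
                )
                yr += n
                i += n


def attach_tree_metadata(
    series: Sequence[RingWidthSeries], meta: pd.DataFrame
) -> list[RingWidthSeries]:
    """Join per-tree DBH/height/site from a metadata table keyed by tree_id."""
    meta = meta.set_index("tree_id")
    out = []
    for s in series:
        if s.tree_id not in meta.index:
            raise ValueError(f"tree {s.tree_id} missing from metadata table")
        row = meta.loc[s.tree_id]
        out.append(
            RingWidthSeries(
                tree_id=s.tree_id,
                site_id=str(row["site_id"]),
                years=s.years,
                widths=s.widths,
                dbh_cm=float(row["dbh_cm"]) if pd.notna(row.get("dbh_cm")) else None,
                height_m=float(row["height_m"]) if pd.notna(row.get("height_m", np.nan)) else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the required sample sheet (individual -> site -> UTM/latitude)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedFileError(f"sample sheet {path} lacks columns {missing}")
    if df["individual_id"].duplicated().any():
        raise MalformedFileError(f"sample sheet {path}: duplicate individual ids")
    return df


def _sites_from_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    sites = (
        sheet.groupby("site_id", sort=True)[["utm_e", "utm_n", "latitude"]]
        .first()
        .reset_index()
    )
    return sites


def _orient_minor(calls: np.ndarray, loci: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosages so every locus counts its dataset-wide minor allele."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    flip = freq > 0.5
    calls = calls.copy()
    calls[:, flip] = 2.0 - calls[:, flip]
    loci = loci.copy()
    loci["flipped"] = flip
    return calls, loci


def _split_locus_id(locus_id: str) -> tuple[str, int]:
    """Parent locus and SNP position from ids of the form ``parent_pos``."""
    if "_" in locus_id:
        parent, _, pos = locus_id.rpartition("_")
        try:
            return parent, int(pos)
        except ValueError:
            pass
    return locus_id, 0


def read_genotype_table(
    path: str | Path,
    format: str,
    sample_sheet: str | Path | pd.DataFrame,
) -> GenotypeMatrix:
    """Read genotypes from a VCF or a 0/1/2 matrix CSV.

    Dosages are recoded to minor-allele counts (minor allele determined
    over the whole file, per locus).  Multi-allelic VCF records are
    skipped with a logged count.  Every individual in the genotype file
    must appear in the sample sheet.
    """
    if isinstance(sample_sheet, (str, Path)):
        sheet = read_sample_sheet(sample_sheet)
    else:
        sheet = sample_sheet

    if format == "vcf":
        calls, individuals, loci = _read_vcf(Path(path))
    elif format == "matrix012":
        calls, individuals, loci = _read_matrix012(Path(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    sheet_ids = set(sheet["individual_id"])
    absent = [i for i in individuals if i not in sheet_ids]
    if absent:
        raise MalformedFileError(
            f"{path}: individuals missing from sample sheet: {absent[:5]}"
        )
    ind_df = pd.DataFrame({"individual_id": individuals}).merge(
        sheet[["individual_id", "site_id"]], on="individual_id", how="left"
    )
    calls, loci = _orient_minor(calls, loci)
    return GenotypeMatrix(
        calls=calls,
        individuals=ind_df,
        loci=loci,
        sites=_sites_from_sheet(sheet),
    )


def _read_vcf(path: Path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 3=hom alt, 2=unknown
        gt = rec.gt_types.astype(float)
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        rows.append(dosage)
        locus_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        meta.append(
            {
                "locus_id": locus_id,
                "parent_locus": rec.CHROM,
                "position": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    if n_skipped:
        logger.info("%s: skipped %d multi-allelic records", path, n_skipped)
    if not meta:
        raise MalformedFileError(f"{path}: no biallelic records")
    calls = np.vstack(rows).T  # individuals x loci
    return calls, individuals, pd.DataFrame(meta)


def _read_matrix012(path: Path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    df = pd.read_csv(path, comment="#", index_col=0, na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    bad = calls[~np.isnan(calls)]
    if bad.size and not np.isin(bad, [0.0, 1.0, 2.0]).all():
        raise MalformedFileError(f"{path}: dosages outside {{0,1,2,NA}}")
    parents, positions = zip(*(_split_locus_id(c) for c in df.columns))
    loci = pd.DataFrame(
        {
            "locus_id": list(df.columns),
            "parent_locus": list(parents),
            "position": list(positions),
        }
    )
    return calls, list(df.index.astype(str)), loci


def write_matrix012(gm: GenotypeMatrix, path: str | Path, seed: int | None = None) -> None:
    """Write dosages as a matrix012 CSV (NA for missing) with a provenance comment."""
    from pial import __version__

    df = pd.DataFrame(
        gm.calls, index=gm.individuals["individual_id"], columns=gm.loci["locus_id"]
    )
    with open(path, "w") as fh:
        fh.write(f"# pial {__version__} seed={seed}\n")
        df.to_csv(fh, na_rep="NA", float_format="%.0f", index_label="individual_id")


# ---------------------------------------------------------------------------
# climate tables
# ---------------------------------------------------------------------------


def validate_climate_table(df: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check water-year climate table invariants; returns the table."""
    required = ["site_id", "water_year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedFileError(f"climate table lacks columns {missing}")
    if df.duplicated(subset=["site_id", "water_year"]).any():
        raise MalformedFileError("duplicate (site, water_year) rows")
    if "PPT" in df.columns and (df["PPT"] < 0).any():
        raise MalformedFileError("negative PPT")
    if all(c in df.columns for c in ("PET", "AET", "CWD")):
        resid = df["CWD"] - (df["PET"] - df["AET"])
        if not np.allclose(resid, 0.0, atol=max(atol, 1e-6 * df["PET"].abs().max())):
            raise MalformedFileError("CWD != PET - AET beyond tolerance")
    return df


def read_climate_table(path: str | Path, resolution: str = "water_year") -> pd.DataFrame:
    """Read a site climate CSV, aggregating monthly input to water years.

    Monthly input needs ``year`` and ``month`` columns; October of
    calendar year Y is assigned to water year Y+1.  Water years with
    fewer than 12 months are dropped with a warning.
    """
    df = pd.read_csv(path, comment="#")
    if resolution == "monthly":
        from pial.climate import water_year_aggregate

        return water_year_aggregate(df)
    if resolution != "water_year":
        raise ValueError(f"unknown resolution {resolution!r}")
    return validate_climate_table(df)


def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a CSV with a header comment recording package version and seed."""
    from pial import __version__

    with open(path, "w") as fh:
        fh.write(f"# pial {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)
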