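"""Readers/writers for feature tables and MS2 spectra, plus packaged fixtures.

Fixtures are versioned delimited text shipped inside the package and verified
against a SHA-256 checksum at load time, so no test ever downloads anything.
"""

from __future__ import annotations

import csv
import hashlib
import io
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .chemcalc import MolecularFormula, ParsedIonLabel, parse_formula, parse_ion_label

__all__ = [
    "Feature",
    "Ms2Spectrum",
    "AnnotationTableRow",
    "ConcentrationRange",
    "ProductInfo",
    "CalibrationParams",
    "ValidationError",
    "FixtureIntegrityError",
    "read_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
    "load_table1_fixture",
    "load_table2_fixture",
    "load_table3_fixture",
    "load_table4_fixture",
    "FIXTURE_CHECKSUMS",
]


class ValidationError(ValueError):
    """Raised on malformed or inconsistent input data."""


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum."""


@dataclass(frozen=True)
class Feature:
    """One detected ion: m/z, RT (seconds) and per-sample intensities."""

    feature_id: str
    mz: float
    rt: float
    polarity: str
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"{self.feature_id}: mz must be positive")
        if self.rt < 0:
            raise ValidationError(f"{self.feature_id}: rt must be >= 0")
        if self.polarity not in ("+", "-"):
            raise ValidationError(f"{self.feature_id}: polarity must be '+' or '-'")
        if not self.intensities:
            raise ValidationError(f"{self.feature_id}: at least one sample intensity required")
        if any(v < 0 for v in self.intensities.values()):
            raise ValidationError(f"{self.feature_id}: negative intensity")

    @property
    def total_intensity(self) -> float:
        return sum(self.intensities.values())


@dataclass(frozen=True)
class Ms2Spectrum:
    """Fragment spectrum with peaks as (m/z, relative intensity in [0, 1])."""

    precursor_mz: float
    polarity: str
    rt: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValidationError("precursor m/z must be positive")
        if self.polarity not in ("+", "-"):
            raise ValidationError("polarity must be '+' or '-'")
        peaks = tuple(sorted((float(mz), float(i)) for mz, i in self.peaks))
        if peaks:
            top = max(i for _, i in peaks)
            if top <= 0:
                raise ValidationError("all peak intensities are zero")
            peaks = tuple((mz, i / top) for mz, i in peaks)
        object.__setattr__(self, "peaks", peaks)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)


# ---------------------------------------------------------------------------
# Feature tables (delimited text: feature_id, mz, rt, one column per sample)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("feature_id", "mz", "rt")


def read_feature_table(path: str | Path, polarity: str) -> list[Feature]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise ValidationError(f"missing column {col!r} in {path}")
        sample_cols = [c for c in header if c not in _REQUIRED_COLUMNS]
        if not sample_cols:
            raise ValidationError(f"no sample intensity columns in {path}")
        features: list[Feature] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            fid = row["feature_id"]
            if fid in seen:
                raise ValidationError(f"duplicate feature_id {fid!r} (line {lineno})")
            seen.add(fid)
            try:
                mz = float(row["mz"])
                rt = float(row["rt"])
                intens = {s: float(row[s]) for s in sample_cols}
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"non-numeric cell at line {lineno}: {exc}") from exc
            features.append(Feature(fid, mz, rt, polarity, intens))
    return features


def write_feature_table(features: Iterable[Feature], path: str | Path) -> None:
    features = list(features)
    if not features:
        raise ValidationError("nothing to write")
    samples = sorted({s for f in features for s in f.intensities})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_REQUIRED_COLUMNS) + samples)
        for f in features:
            writer.writerow([f.feature_id, repr(f.mz), repr(f.rt)]
                            + [repr(f.intensities.get(s, 0.0)) for s in samples])


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read an MGF dialect with PEPMASS, CHARGE (e.g. '1-'), RTINSECONDS."""
    spectra: list[Ms2Spectrum] = []
    in_block = False
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, meta, peaks = True, {}, []
            elif line == "END IONS":
                if "PEPMASS" not in meta:
                    raise ValidationError("MGF block without PEPMASS")
                charge = meta.get("CHARGE", "1+")
                polarity = "-" if charge.endswith("-") else "+"
                if not peaks:
                    warnings.warn("empty MS2 spectrum retained", stacklevel=2)
                spectra.append(Ms2Spectrum(
                    precursor_mz=float(meta["PEPMASS"].split()[0]),
                    polarity=polarity,
                    rt=float(meta.get("RTINSECONDS", "0")),
                    peaks=tuple(peaks),
                ))
                in_block = False
            elif in_block:
                if "=" in line:
                    key, value = line.split("=", 1)
                    meta[key.upper()] = value
                else:
                    parts = line.split()
                    peaks.append((float(parts[0]), float(parts[1])))
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE=1{s.polarity}\n")
            fh.write(f"RTINSECONDS={s.rt:.3f}\n")
            for mz, intensity in s.peaks:
                fh.write(f"{mz:.6f} {intensity:.6f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_CHECKSUMS = {
    "table1_annotations.tsv": "1a36e95a80cb22e4e24aefe373c7be376c633b36c4d93b7968f0c1f07ef9a868",
    "table2_calibration.tsv": "40d4ce5edd93cbf6fd58b57ef9af640c99b6928415c34803c66e26cddef1c548",
    "table3_concentrations.tsv": "6781323e6992cdb55ad7eb2feb771d4882f3317bae149d31359a4144f25a8fee",
    "table4_products.tsv": "7438191de19493a12f921d9f3bed650ed5df7ff896c3b06a1f9b2150b3d1104f",
}


def _read_fixture(name: str) -> str:
    text = (resources.files("oleomics.data") / name).read_text()
    _verify_checksum(name, text)
    return text


def _verify_checksum(name: str, text: str) -> None:
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = FIXTURE_CHECKSUMS[name]
    if digest != expected:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {expected}")


@dataclass(frozen=True)
class AnnotationTableRow:
    """One annotated compound: id, formula, RT, printed ion list, level."""

    compound_id: str
    name: str
    formula: MolecularFormula
    rt_s: float
    ion_entries: tuple[tuple[float, str], ...]
    level: str
    evidence: str

    @property
    def parsed_ions(self) -> tuple[tuple[float, ParsedIonLabel], ...]:
        return tuple((mz, parse_ion_label(lbl)) for mz, lbl in self.ion_entries)

    @property
    def is_generic_unknown(self) -> bool:
        """Unknown compound assigned only to a generic structural class."""
        return "derivative" in self.name.lower()


def load_table1_fixture() -> list[AnnotationTableRow]:
    text = _read_fixture("table1_annotations.tsv")
    rows: list[AnnotationTableRow] = []
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    for rec in reader:
        ions = []
        for entry in rec["ions"].split(";"):
            entry = entry.strip()
            mz_txt, label = entry.split(" ", 1)
            ions.append((float(mz_txt), label.strip()))
        rows.append(AnnotationTableRow(
            compound_id=rec["compound_id"],
            name=rec["name"],
            formula=parse_formula(rec["formula"]),
            rt_s=float(rec["rt_s"]),
            ion_entries=tuple(ions),
            level=rec["level"],
            evidence=rec["evidence"],
        ))
    if len(rows) != 202:
        raise FixtureIntegrityError(f"expected 202 annotation rows, got {len(rows)}")
    return rows


@dataclass(frozen=True)
class CalibrationParams:
    """Published calibration-curve parameters for one analyte."""

    analyte: str
    detector: str
    ldr: tuple[float, float]
    intercept: float
    slope: float
    r2: float
    intra_day_rsd: float
    inter_day_rsd: float
    repeatability_rsd: float


def load_table2_fixture() -> list[CalibrationParams]:
    text = _read_fixture("table2_calibration.tsv")
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    rows = [CalibrationParams(
        analyte=rec["analyte"],
        detector=rec["detector"],
        ldr=(float(rec["ldr_lo_mg_l"]), float(rec["ldr_hi_mg_l"])),
        intercept=float(rec["intercept"]),
        slope=float(rec["slope"]),
        r2=float(rec["r2"]),
        intra_day_rsd=float(rec["intra_day_rsd"]),
        inter_day_rsd=float(rec["inter_day_rsd"]),
        repeatability_rsd=float(rec["repeatability_rsd"]),
    ) for rec in reader]
    if len(rows) != 12:
        raise FixtureIntegrityError(f"expected 12 calibration rows, got {len(rows)}")
    return rows


@dataclass(frozen=True)
class ConcentrationRange:
    """Concentration range (mg/g) of one compound in one product.

    Censored cells carry lo = hi = 0 so that product totals are deterministic:
    'ND' and '<LOQ' -> (0, 0); 'LOQ-x' and 'ND-x' -> (0, x).
    """

    compound: str
    product: str
    lo: float
    hi: float
    censoring: str

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError(f"{self.compound}/{self.product}: lo > hi")
        if self.censoring not in ("measured", "below_loq", "not_detected", "mixed"):
            raise ValidationError(f"bad censoring tag {self.censoring!r}")


_RANGE = re.compile(r"^(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)$")


def parse_range_cell(cell: str) -> tuple[float, float, str]:
    """Parse one printed range cell into (lo, hi, censoring)."""
    cell = cell.strip()
    if cell == "ND":
        return 0.0, 0.0, "not_detected"
    if cell == "<LOQ":
        return 0.0, 0.0, "below_loq"
    if cell == "ND-<LOQ":
        return 0.0, 0.0, "mixed"
    m = _RANGE.match(cell)
    if m:
        return float(m.group(1)), float(m.group(2)), "measured"
    m = re.match(r"^(?:LOQ|ND)-(\d+(?:\.\d+)?)$", cell)
    if m:
        return 0.0, float(m.group(1)), "mixed"
    raise ValidationError(f"unparseable concentration cell {cell!r}")


def load_table3_fixture() -> list[ConcentrationRange]:
    text = _read_fixture("table3_concentrations.tsv")
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    products = [c for c in (reader.fieldnames or []) if c != "compound"]
    if len(products) != 14:
        raise FixtureIntegrityError(f"expected 14 product columns, got {len(products)}")
    out: list[ConcentrationRange] = []
    n_compounds = 0
    for rec in reader:
        n_compounds += 1
        for product in products:
            lo, hi, censoring = parse_range_cell(rec[product])
            out.append(ConcentrationRange(rec["compound"], product, lo, hi, censoring))
    if n_compounds != 26:
        raise FixtureIntegrityError(f"expected 26 quantified compounds, got {n_compounds}")
    return out


@dataclass(frozen=True)
class ProductInfo:
    """Product metadata incl. the supplier's recommended daily dose in grams."""

    product: str
    plant_part: str
    form: str
    daily_dose_g: float
    extraction: str
    other_extracts: bool

    def __post_init__(self) -> None:
        if self.daily_dose_g <= 0:
            raise ValidationError(f"{self.product}: daily dose must be positive")


_PLANT_PARTS = {"buds": "buds", "leaves": "leaves",
                "leaves and fruit": "leaves+fruit", "fruit": "fruit"}


def load_table4_fixture() -> list[ProductInfo]:
    text = _read_fixture("table4_products.tsv")
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    rows = [ProductInfo(
        product=rec["product"],
        plant_part=_PLANT_PARTS[rec["plant_part"]],
        form=rec["form"],
        daily_dose_g=float(rec["daily_dose_g"]),
        extraction=rec["extraction"],
        other_extracts=rec["other_extracts"] == "yes",
    ) for rec in reader]
    if len(rows) != 14:
        raise FixtureIntegrityError(f"expected 14 products, got {len(rows)}")
    return rows
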