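"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator takes a single seed and is byte-reproducible; output objects
carry a ``metadata`` dict documenting the distributions used, so recovery
tests are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import DEFAULT_RULES, DiagnosticRule, FRAGMENT_TOL_DA
from .chemcalc import ADDUCTS, NEUTRAL_LOSSES, AdductSpec, MolecularFormula
from .feature_io import AnnotationTableRow, Feature, Ms2Spectrum, ValidationError

__all__ = [
    "GroundTruthIon",
    "SyntheticFeatureSet",
    "simulate_feature_tables",
    "simulate_ms2",
    "simulate_calibration",
]


@dataclass(frozen=True)
class GroundTruthIon:
    """Planted identity of one synthetic feature."""

    compound_id: str
    role: str            # molecular_ion | isotope | adduct | multimer | in_source_fragment
    detail: str


@dataclass
class SyntheticFeatureSet:
    features_neg: list[Feature]
    features_pos: list[Feature]
    truth: dict[str, GroundTruthIon]
    samples: list[str]
    metadata: dict = field(default_factory=dict)


def _role_of(spec: AdductSpec) -> str:
    if spec.isotope_shift:
        return "isotope"
    if spec.name in ("[M-H]-", "[M+H]+"):
        return "molecular_ion"
    if spec.multimer > 1:
        return "multimer"
    return "adduct"


# (species name, relative abundance) per polarity; the 13C ion is kept well
# below its monoisotopic partner so the isotope sanity constraint holds.
_NEG_TEMPLATE = (
    ("[M-H]-", 1.0),
    ("13C[M-H]-", 0.12),
    ("[M+Cl]-", 0.35),
    ("[M-H+HCOOH]-", 0.30),
    ("[2M-H]-", 0.18),
)
_POS_TEMPLATE = (
    ("[M+H]+", 1.0),
    ("13C[M+H]+", 0.12),
    ("[M+NH4]+", 0.45),
    ("[M+Na]+", 0.22),
)
_NEG_FRAGMENT_LOSS = "H2O"
_NEG_FRAGMENT_REL = 0.25


def simulate_feature_tables(
    library: Sequence[AnnotationTableRow],
    n_products: int = 4,
    n_replicates: int = 3,
    ppm_sigma: float = 1.0,
    rt_sigma_s: float = 1.0,
    seed: int = 0,
    rt_spacing_s: float = 40.0,
    with_fragment: bool = True,
    replicate_sigma: float = 0.05,
) -> SyntheticFeatureSet:
    """Generate co-eluting ion clusters for each library compound.

    Per compound: adduct/isotope/fragment ions via the registry with
    Gaussian relative mass noise (sigma = ``ppm_sigma`` ppm), a shared
    retention time with Gaussian jitter (sigma = ``rt_sigma_s`` s), and a
    log-normal per-sample abundance profile identical across the compound's
    ions (the correlation structure the grouping stage assumes).
    """
    if not library:
        raise ValidationError("library must be nonempty")
    if ppm_sigma < 0 or rt_sigma_s < 0:
        raise ValidationError("noise sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    samples = [f"P{p + 1}_r{r + 1}"
               for p in range(n_products) for r in range(n_replicates)]

    features_neg: list[Feature] = []
    features_pos: list[Feature] = []
    truth: dict[str, GroundTruthIon] = {}

    for idx, row in enumerate(library):
        M = row.formula.mass
        rt_center = 60.0 + idx * rt_spacing_s
        # log-normal product levels, tight replicates, profile shared by
        # every ion of the compound
        base = 10 ** rng.uniform(5.0, 7.0)
        levels = base * rng.lognormal(mean=0.0, sigma=1.0, size=n_products)
        profile = np.repeat(levels, n_replicates) * rng.lognormal(
            mean=0.0, sigma=replicate_sigma, size=len(samples))

        def emit(mz_theo: float, rel: float, polarity: str,
                 role: str, detail: str, tag: str) -> None:
            mz = mz_theo * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)
            rt = max(0.0, rt_center + rng.normal(0.0, rt_sigma_s))
            fid = f"{row.compound_id}_{tag}"
            feature = Feature(fid, mz, rt, polarity,
                              dict(zip(samples, (rel * profile).tolist())))
            (features_neg if polarity == "-" else features_pos).append(feature)
            truth[fid] = GroundTruthIon(row.compound_id, role, detail)

        def detail_of(spec: AdductSpec) -> str:
            # isotope roles are described by their order k, not the label
            return str(spec.isotope_shift) if spec.isotope_shift else spec.name

        for name, rel in _NEG_TEMPLATE:
            spec = ADDUCTS[name]
            emit(spec.mz(M), rel, "-", _role_of(spec), detail_of(spec),
                 name.strip("[]-+").replace("+", "p"))
        if with_fragment:
            loss = NEUTRAL_LOSSES[_NEG_FRAGMENT_LOSS]
            frag_mz = ADDUCTS["[M-H]-"].mz(M) - loss.mass
            if frag_mz > 50:
                emit(frag_mz, _NEG_FRAGMENT_REL, "-", "in_source_fragment",
                     f"[M-H]- - {loss.name}", "fragH2O")
        for name, rel in _POS_TEMPLATE:
            spec = ADDUCTS[name]
            emit(spec.mz(M), rel, "+", _role_of(spec), detail_of(spec),
                 "pos" + name.strip("[]-+").replace("+", "p"))

    return SyntheticFeatureSet(
        features_neg=features_neg,
        features_pos=features_pos,
        truth=truth,
        samples=samples,
        metadata={
            "seed": seed,
            "ppm_noise": f"relative Gaussian, sigma {ppm_sigma} ppm",
            "rt_noise": f"Gaussian jitter, sigma {rt_sigma_s} s",
            "abundance": "log-normal(sigma=1) profile shared across a compound's ions",
            "rt_spacing_s": rt_spacing_s,
            "n_samples": len(samples),
        },
    )


@dataclass
class SyntheticMs2Set:
    spectra: list[Ms2Spectrum]
    labels: list[str | None]
    metadata: dict = field(default_factory=dict)


def simulate_ms2(
    rules: tuple[DiagnosticRule, ...] = DEFAULT_RULES,
    n_per_class: int = 5,
    mz_noise_da: float = 0.0,
    n_decoy_peaks: int = 4,
    n_decoy_spectra: int = 0,
    seed: int = 0,
) -> SyntheticMs2Set:
    """Spectra carrying each class's diagnostic peaks plus decoy peaks.

    Decoy peaks are kept away (> 0.05 Da) from every diagnostic target so
    that, at zero noise, each planted class is recoverable.  Decoy-only
    spectra get label ``None``.
    """
    if not rules:
        raise ValidationError("rules must be nonempty")
    rng = np.random.default_rng(seed)
    forbidden = sorted({mz for r in rules for mz in r.required_any})

    def decoy_mzs(n: int, lo: float, hi: float,
                  extra_forbidden: tuple[float, ...] = ()) -> list[float]:
        taboo = forbidden + list(extra_forbidden)
        out: list[float] = []
        while len(out) < n:
            mz = float(rng.uniform(lo, hi))
            if all(abs(mz - t) > 10 * FRAGMENT_TOL_DA for t in taboo):
                out.append(mz)
        return out

    spectra: list[Ms2Spectrum] = []
    labels: list[str | None] = []
    for rule in rules:
        for _ in range(n_per_class):
            precursor = float(rng.uniform(450.0, 800.0))
            peaks = [(mz + float(rng.normal(0, mz_noise_da)) if mz_noise_da else mz,
                      float(rng.uniform(0.2, 1.0)))
                     for mz in rule.required_any]
            loss_targets = tuple(precursor - loss.mass for loss in rule.required_losses)
            peaks += [(t, float(rng.uniform(0.2, 1.0))) for t in loss_targets]
            peaks += [(mz, float(rng.uniform(0.05, 0.5)))
                      for mz in decoy_mzs(n_decoy_peaks, 80.0, precursor - 5.0,
                                          loss_targets)]
            spectra.append(Ms2Spectrum(precursor, rule.polarity, 0.0, tuple(peaks)))
            labels.append(rule.class_name)
    for _ in range(n_decoy_spectra):
        precursor = float(rng.uniform(450.0, 800.0))
        loss_targets = tuple(precursor - loss.mass
                             for r in rules for loss in r.required_losses)
        peaks = [(mz, float(rng.uniform(0.05, 1.0)))
                 for mz in decoy_mzs(6, 80.0, precursor - 5.0, loss_targets)]
        spectra.append(Ms2Spectrum(precursor, "-", 0.0, tuple(peaks)))
        labels.append(None)

    return SyntheticMs2Set(
        spectra=spectra,
        labels=labels,
        metadata={"seed": seed, "mz_noise_da": mz_noise_da,
                  "n_decoy_peaks": n_decoy_peaks},
    )


def simulate_calibration(
    slope: float,
    intercept: float,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Linear calibration series with multiplicative Gaussian noise."""
    if not concentrations:
        raise ValidationError("empty concentration grid")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for c in concentrations:
        response = slope * float(c) + intercept
        if noise_cv:
            response *= 1.0 + float(rng.normal(0.0, noise_cv))
        points.append((float(c), response))
    return points
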