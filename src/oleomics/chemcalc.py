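"""Molecular-formula arithmetic and the adduct / isotope / neutral-loss m/z calculus.

All annotation logic in this package reduces, at some point, to the three
primitives defined here: monoisotopic mass of a formula, m/z of a registered
adduct species for a neutral mass M, and ppm deviation between two m/z
values.  Charged-species deltas include the electron mass so that theoretical
values agree with 4-decimal printed references.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "NeutralLoss",
    "FormulaError",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_SHIFT",
    "ADDUCTS",
    "NEUTRAL_LOSSES",
    "parse_formula",
    "monoisotopic_mass",
    "mz_for_adduct",
    "neutral_mass_from_mz",
    "ppm_error",
    "parse_ion_label",
    "ParsedIonLabel",
]

# IUPAC monoisotopic atomic masses (Da), most abundant isotope.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType({
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
})

ELECTRON_MASS = 0.00054858
PROTON_MASS = 1.00727646
#: mass difference between 13C and 12C
C13_SHIFT = 1.003355


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings."""


#: Hill-order convention: C first, H second, remaining elements alphabetical.
_HILL_TAIL = ("Cl", "K", "N", "Na", "O", "P", "S")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with monoisotopic-mass semantics.

    Immutable; supports only C, H, N, O, S, P, Na, K, Cl.  The empty formula
    is allowed and has mass zero.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        frozen: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}")
            if n:
                frozen[el] = n
        object.__setattr__(self, "counts", MappingProxyType(frozen))

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __hash__(self) -> int:  # counts proxy itself is unhashable
        return hash(frozenset(self.counts.items()))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(f"subtraction yields negative {el} count")
        return MolecularFormula(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Canonical Hill-order string ('' for the empty formula)."""
        parts = []
        for el in ("C", "H") + _HILL_TAIL:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string (any element order) into a formula.

    Repeated element symbols accumulate, so 'COCH2' parses as C2H2O.
    """
    if not isinstance(text, str):
        raise FormulaError("formula must be a string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula string: {text!r}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula string: {text!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of IUPAC monoisotopic atomic masses (empty formula -> 0.0)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """One registered ionized species relative to a neutral mass M.

    m/z = (multimer * M + isotope_shift * 1.003355 + mass_delta) / |charge|
    where ``mass_delta`` already carries the electron-mass correction.
    """

    name: str
    multimer: int
    charge: int
    mass_delta: float
    isotope_shift: int = 0

    def __post_init__(self) -> None:
        if self.multimer < 1:
            raise ValueError("multimer must be >= 1")
        if self.charge == 0:
            raise ValueError("charge must be nonzero")
        if self.isotope_shift < 0:
            raise ValueError("isotope_shift must be >= 0")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"

    def mz(self, neutral_mass: float) -> float:
        return (self.multimer * neutral_mass
                + self.isotope_shift * C13_SHIFT
                + self.mass_delta) / abs(self.charge)

    def invert(self, mz: float) -> float:
        """Neutral mass M implied by an observed m/z under this species."""
        return (mz * abs(self.charge)
                - self.isotope_shift * C13_SHIFT
                - self.mass_delta) / self.multimer


def _m(formula: str) -> float:
    return parse_formula(formula).mass


# Charged-moiety masses (electron correction applied per unit charge).
_H_POS = PROTON_MASS                      # add H+  (gain charge +1)
_H_NEG = -PROTON_MASS                     # lose H+ (gain charge -1)
_NH4_POS = _m("NH4") - ELECTRON_MASS
_NA_POS = _m("Na") - ELECTRON_MASS
_K_POS = _m("K") - ELECTRON_MASS
_CL_NEG = _m("Cl") + ELECTRON_MASS
_FORMATE_NEG = _m("CH2O2") - PROTON_MASS  # -H +HCOOH
_C2H8N_POS = _m("C2H8N") - ELECTRON_MASS
_CH3COOK_H_POS = _m("C2H3O2K") + PROTON_MASS


def _registry() -> dict[str, AdductSpec]:
    base = [
        # negative mode
        AdductSpec("[M-H]-", 1, -1, _H_NEG),
        AdductSpec("[2M-H]-", 2, -1, _H_NEG),
        AdductSpec("[M+Cl]-", 1, -1, _CL_NEG),
        AdductSpec("[M-H+HCOOH]-", 1, -1, _FORMATE_NEG),
        # positive mode
        AdductSpec("[M+H]+", 1, 1, _H_POS),
        AdductSpec("[2M+H]+", 2, 1, _H_POS),
        AdductSpec("[M+NH4]+", 1, 1, _NH4_POS),
        AdductSpec("[2M+NH4]+", 2, 1, _NH4_POS),
        AdductSpec("[M+Na]+", 1, 1, _NA_POS),
        AdductSpec("[2M+Na]+", 2, 1, _NA_POS),
        AdductSpec("[M+K]+", 1, 1, _K_POS),
        AdductSpec("[M+C2H8N]+", 1, 1, _C2H8N_POS),
        AdductSpec("[M+H+CH3COOK]+", 1, 1, _CH3COOK_H_POS),
        AdductSpec("[4M+3H]3+", 4, 3, 3 * _H_POS),
        AdductSpec("[4M+H+K]2+", 4, 2, _H_POS + _K_POS),
    ]
    reg: dict[str, AdductSpec] = {}
    for spec in base:
        reg[spec.name] = spec
        # every base species occurs with one or two 13C substitutions
        for k, prefix in ((1, "13C"), (2, "(2)13C")):
            name = f"{prefix}{spec.name}"
            reg[name] = AdductSpec(name, spec.multimer, spec.charge,
                                   spec.mass_delta, isotope_shift=k)
    return reg


#: Registered bracket species; unlisted species are rejected, not guessed.
ADDUCTS: Mapping[str, AdductSpec] = MappingProxyType(_registry())


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral loss; mass always equals the formula's monoisotopic mass."""

    name: str
    formula: MolecularFormula
    mass: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", self.formula.mass)


def _loss(name: str, formula: str) -> NeutralLoss:
    return NeutralLoss(name, parse_formula(formula))


#: Registered in-source / MS2 neutral losses.  Open-ended loss search is
#: deliberately not offered.
NEUTRAL_LOSSES: Mapping[str, NeutralLoss] = MappingProxyType({
    loss.name: loss
    for loss in (
        _loss("hexose", "C6H10O5"),          # 162.05282
        _loss("rhamnose", "C6H10O4"),        # 146.05791
        _loss("H2O", "H2O"),                 # 18.01056
        _loss("CO2", "CO2"),                 # 43.98983
        _loss("CH2O", "CH2O"),               # 30.01057
        _loss("CH3OH", "CH3OH"),             # 32.02621
        _loss("CO", "CO"),                   # 27.99491
        _loss("C2H4O2", "C2H4O2"),           # 60.02113
        _loss("hydroxytyrosol", "C8H8O2"),   # 136.05243
        _loss("caffeoyl", "C9H6O3"),         # 162.03169
    )
})


def mz_for_adduct(f: MolecularFormula, a: AdductSpec) -> float:
    """Theoretical m/z of formula ``f`` under registered species ``a``."""
    return a.mz(monoisotopic_mass(f))


def neutral_mass_from_mz(mz: float, a: AdductSpec) -> float:
    """Invert ``mz_for_adduct``: neutral mass implied by an observed m/z."""
    return a.invert(mz)


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Ion-label grammar
# ---------------------------------------------------------------------------

#: loss-token aliases used in printed ion labels
_LOSS_ALIASES = {
    "hexose": "hexose",
    "rhamnose": "rhamnose",
    "hydroxytyrosol": "hydroxytyrosol",
    "OHTYR": "hydroxytyrosol",
    "caffeoyl": "caffeoyl",
}

_ISO_PREFIX = re.compile(r"^(?:\((?P<k2>\d)\))?13C(?=\[)")
_BRACKET = re.compile(r"^\[(?P<body>[^\]]+)\](?P<charge>\d?[+-])$")
_MULTI_LOSS = re.compile(r"^(\d)\((.+)\)$")


@dataclass(frozen=True)
class ParsedIonLabel:
    """Decomposition of a printed ion label.

    ``kind`` is 'adduct' for a pure registered species, 'fragment' for a
    registered species minus registered/parseable neutral losses, and
    'other' for labels outside the M-relative grammar (e.g. '[frag]-',
    '[add-1]-', fragment names like '[caffeic-H]-').
    """

    label: str
    kind: str
    adduct: AdductSpec | None = None
    losses: tuple[tuple[str, float], ...] = ()

    @property
    def loss_mass(self) -> float:
        return sum(m for _, m in self.losses)

    def mz(self, neutral_mass: float) -> float:
        if self.adduct is None:
            raise ValueError(f"label {self.label!r} is not M-relative")
        return self.adduct.mz(neutral_mass) - self.loss_mass / abs(self.adduct.charge)


def _resolve_loss(token: str) -> tuple[str, float] | None:
    mult = 1
    m = _MULTI_LOSS.match(token)
    if m:
        mult, token = int(m.group(1)), m.group(2)
    if token in _LOSS_ALIASES:
        loss = NEUTRAL_LOSSES[_LOSS_ALIASES[token]]
        return (f"{mult}({loss.name})" if mult > 1 else loss.name,
                mult * loss.mass)
    try:
        f = parse_formula(token)
    except FormulaError:
        return None
    if not f:
        return None
    return (f"{mult}({token})" if mult > 1 else token, mult * f.mass)


def parse_ion_label(label: str) -> ParsedIonLabel:
    """Parse one printed ion label into species + losses, or tag it 'other'."""
    text = label.strip()
    iso = 0
    m = _ISO_PREFIX.match(text)
    if m:
        iso = int(m.group("k2") or 1)
        text = text[m.end():]
    m = _BRACKET.match(text)
    if not m or not re.match(r"^\d?M([+-]|$)", m.group("body")):
        return ParsedIonLabel(label, "other")
    body, charge_txt = m.group("body"), m.group("charge")
    # try longest pure-species prefix first, remainder must be '-loss' tokens
    for cut in range(len(body), 0, -1):
        head, tail = body[:cut], body[cut:]
        candidate = f"[{head}]{charge_txt}"
        if iso == 1:
            candidate = "13C" + candidate
        elif iso == 2:
            candidate = "(2)13C" + candidate
        spec = ADDUCTS.get(candidate)
        if spec is None:
            continue
        if tail and not tail.startswith("-"):
            continue
        losses: list[tuple[str, float]] = []
        ok = True
        for token in filter(None, tail.split("-")):
            resolved = _resolve_loss(token)
            if resolved is None:
                ok = False
                break
            losses.append(resolved)
        if not ok:
            continue
        kind = "fragment" if losses else "adduct"
        return ParsedIonLabel(label, kind, spec, tuple(losses))
    return ParsedIonLabel(label, "other")
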