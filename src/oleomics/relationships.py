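"""Infer each grouped feature's ion role relative to a neutral mass M.

Candidate neutral masses are generated by inverting every registered adduct
for every group member; the hypothesis explaining the most members wins.
Cross-polarity reconciliation merges hypotheses whose neutral masses agree
within tolerance at matching retention times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import chemcalc
from .chemcalc import ADDUCTS, NEUTRAL_LOSSES, AdductSpec
from .feature_io import Feature, ValidationError
from .grouping import FeatureGroup

__all__ = [
    "IonAssignment",
    "NeutralHypothesis",
    "infer_roles",
    "reconcile_polarities",
    "DEFAULT_TOL_PPM",
]

DEFAULT_TOL_PPM = 5.0

#: default species used to invert a bare (de)protonated ion per polarity
_MOLECULAR_ION = {"-": "[M-H]-", "+": "[M+H]+"}


@dataclass(frozen=True)
class IonAssignment:
    """Inferred role of one feature relative to a neutral mass M.

    ``role`` is one of molecular_ion / isotope / adduct / multimer /
    in_source_fragment / unexplained; ``detail`` carries the adduct name,
    the isotope order k, or the neutral-loss name.
    """

    feature_id: str
    mz: float
    role: str
    detail: str
    neutral_mass: float
    ppm: float

    def theoretical_mz(self) -> float:
        """Re-derive m/z from (M, role); inverse of the inference step."""
        if self.role == "in_source_fragment":
            polarity = "-" if self.detail.endswith("-") else "+"
            base, loss_name = self.detail.split(" - ")
            spec = ADDUCTS[base]
            return spec.mz(self.neutral_mass) - NEUTRAL_LOSSES[loss_name].mass
        if self.role == "unexplained":
            raise ValueError("unexplained assignment has no theoretical m/z")
        return ADDUCTS[self.detail].mz(self.neutral_mass)


@dataclass(frozen=True)
class NeutralHypothesis:
    """One neutral mass M with the member roles it explains."""

    M: float
    polarity_support: frozenset[str]
    explained_count: int
    assignments: tuple[IonAssignment, ...]
    rt_centroid: float
    degenerate: bool = False


def _role_kind(spec: AdductSpec) -> tuple[str, str]:
    if spec.isotope_shift > 0:
        return "isotope", str(spec.isotope_shift)
    if spec.name in _MOLECULAR_ION.values():
        return "molecular_ion", spec.name
    if spec.multimer > 1:
        return "multimer", spec.name
    return "adduct", spec.name


def _assign_member(
    f: Feature,
    M: float,
    tol_ppm: float,
    intensity_by_theoretical: dict[str, float],
) -> IonAssignment:
    """Best role for one member under hypothesis M (or 'unexplained')."""
    best: IonAssignment | None = None

    for spec in ADDUCTS.values():
        if spec.polarity != f.polarity:
            continue
        theo = spec.mz(M)
        ppm = chemcalc.ppm_error(f.mz, theo)
        if abs(ppm) > tol_ppm:
            continue
        if spec.isotope_shift > 0:
            # isotope requires a more intense monoisotopic partner in-group
            base_name = spec.name.split("C[", 1)[1]
            base_name = "[" + base_name
            base_intensity = intensity_by_theoretical.get(base_name)
            if base_intensity is None or base_intensity <= f.total_intensity:
                continue
        kind, detail = _role_kind(spec)
        cand = IonAssignment(f.feature_id, f.mz, kind, detail, M, ppm)
        if best is None or abs(cand.ppm) < abs(best.ppm):
            best = cand

    if best is None:
        base = ADDUCTS[_MOLECULAR_ION[f.polarity]]
        base_mz = base.mz(M)
        for loss in NEUTRAL_LOSSES.values():
            theo = base_mz - loss.mass
            if theo <= 0:
                continue
            ppm = chemcalc.ppm_error(f.mz, theo)
            if abs(ppm) > tol_ppm:
                continue
            cand = IonAssignment(f.feature_id, f.mz, "in_source_fragment",
                                 f"{base.name} - {loss.name}", M, ppm)
            if best is None or abs(cand.ppm) < abs(best.ppm):
                best = cand

    if best is None:
        return IonAssignment(f.feature_id, f.mz, "unexplained", "", M, 0.0)
    return best


def _evaluate(group: FeatureGroup, M: float, tol_ppm: float) -> NeutralHypothesis:
    # intensities keyed by the base (non-isotope) species a member matches
    intensity_by_theoretical: dict[str, float] = {}
    for f in group.members:
        for spec in ADDUCTS.values():
            if spec.polarity != f.polarity or spec.isotope_shift:
                continue
            if abs(chemcalc.ppm_error(f.mz, spec.mz(M))) <= tol_ppm:
                prev = intensity_by_theoretical.get(spec.name, 0.0)
                intensity_by_theoretical[spec.name] = max(prev, f.total_intensity)

    assignments = tuple(
        _assign_member(f, M, tol_ppm, intensity_by_theoretical)
        for f in group.members
    )
    explained = sum(1 for a in assignments if a.role != "unexplained")
    return NeutralHypothesis(
        M=M,
        polarity_support=frozenset({group.polarity}),
        explained_count=explained,
        assignments=assignments,
        rt_centroid=group.rt_centroid,
    )


def infer_roles(group: FeatureGroup, tol_ppm: float = DEFAULT_TOL_PPM) -> NeutralHypothesis:
    """Pick the neutral mass M that explains the most group members."""
    if not group.members:
        raise ValidationError("empty group")

    candidates: list[float] = []
    for f in group.members:
        for spec in ADDUCTS.values():
            if spec.polarity != f.polarity or spec.isotope_shift:
                continue
            M = spec.invert(f.mz)
            if M > 2 * chemcalc.MONOISOTOPIC_MASS["O"]:  # exclude absurd masses
                candidates.append(M)

    seed = group.seed
    best: NeutralHypothesis | None = None
    best_key: tuple | None = None
    for M in candidates:
        hyp = _evaluate(group, M, tol_ppm)
        mol_ion_ids = {a.feature_id for a in hyp.assignments
                       if a.role == "molecular_ion"}
        seed_is_mol_ion = 0 if seed.feature_id in mol_ion_ids else 1
        total_ppm = sum(abs(a.ppm) for a in hyp.assignments
                        if a.role != "unexplained")
        key = (-hyp.explained_count, seed_is_mol_ion, total_ppm, hyp.M)
        if best_key is None or key < best_key:
            best, best_key = hyp, key

    assert best is not None
    if len(group.members) == 1:
        best = replace(best, degenerate=True)
    return best


def reconcile_polarities(
    neg: NeutralHypothesis,
    pos: NeutralHypothesis,
    rt_window: float = 5.0,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> NeutralHypothesis | None:
    """Merge opposite-polarity hypotheses that agree on M and RT."""
    if neg.polarity_support == pos.polarity_support:
        raise ValidationError("hypotheses must come from opposite polarities")
    if abs(neg.rt_centroid - pos.rt_centroid) > rt_window:
        return None
    mean_m = 0.5 * (neg.M + pos.M)
    if abs(neg.M - pos.M) / mean_m * 1e6 > tol_ppm:
        return None
    return NeutralHypothesis(
        M=mean_m,
        polarity_support=neg.polarity_support | pos.polarity_support,
        explained_count=neg.explained_count + pos.explained_count,
        assignments=neg.assignments + pos.assignments,
        rt_centroid=0.5 * (neg.rt_centroid + pos.rt_centroid),
        degenerate=neg.degenerate and pos.degenerate,
    )
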