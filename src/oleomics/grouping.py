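"""Cluster co-eluting, intensity-correlated features into pseudo-spectra.

Greedy, deterministic algorithm: features are visited in decreasing total
intensity; each feature either joins the first compatible existing group
(RT within the window of the group seed AND Pearson correlation of
log10-intensities with the seed above the threshold) or seeds a new group.
Ties between compatible seeds are broken by smaller RT gap, then smaller
m/z gap.  The result is independent of input order because the intensity
sort fixes the visiting order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .feature_io import Feature, ValidationError

__all__ = ["FeatureGroup", "group_features", "intensity_correlation"]

DEFAULT_RT_WINDOW_S = 5.0
DEFAULT_MIN_CORR = 0.8


@dataclass(frozen=True)
class FeatureGroup:
    """A co-eluting correlated cluster of same-polarity features."""

    group_id: str
    polarity: str
    members: tuple[Feature, ...]
    rt_centroid: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("group must be nonempty")
        if len({f.polarity for f in self.members}) != 1:
            raise ValidationError("group members must share polarity")

    @property
    def seed(self) -> Feature:
        """Most intense member (the group's reference for correlation)."""
        return max(self.members, key=lambda f: f.total_intensity)


def intensity_correlation(a: Feature, b: Feature) -> float:
    """Pearson correlation of log10(intensity + 1) across shared samples."""
    samples = sorted(set(a.intensities) & set(b.intensities))
    if len(samples) < 3:
        return math.nan
    x = np.log10(np.array([a.intensities[s] for s in samples]) + 1.0)
    y = np.log10(np.array([b.intensities[s] for s in samples]) + 1.0)
    if x.std() == 0 or y.std() == 0:
        # constant profiles: identical constants correlate perfectly
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def group_features(
    features: list[Feature],
    rt_window: float = DEFAULT_RT_WINDOW_S,
    min_corr: float = DEFAULT_MIN_CORR,
) -> list[FeatureGroup]:
    """Partition same-polarity features into pseudo-spectra."""
    if not features:
        raise ValidationError("no features to group")
    polarities = {f.polarity for f in features}
    if len(polarities) > 1:
        raise ValidationError("mixed polarities; group each mode separately")
    polarity = polarities.pop()

    n_samples = len({s for f in features for s in f.intensities})
    use_corr = n_samples >= 3
    if not use_corr:
        warnings.warn("fewer than 3 samples: correlation criterion skipped",
                      stacklevel=2)

    order = sorted(features,
                   key=lambda f: (-f.total_intensity, f.rt, f.mz, f.feature_id))
    seeds: list[Feature] = []
    assignment: dict[str, list[Feature]] = {}
    for f in order:
        best: Feature | None = None
        best_key: tuple[float, float] | None = None
        for seed in seeds:
            d_rt = abs(f.rt - seed.rt)
            if d_rt > rt_window:
                continue
            if use_corr and not (intensity_correlation(f, seed) >= min_corr):
                continue
            key = (d_rt, abs(f.mz - seed.mz))
            if best_key is None or key < best_key:
                best, best_key = seed, key
        if best is None:
            seeds.append(f)
            assignment[f.feature_id] = [f]
        else:
            assignment[best.feature_id].append(f)

    return [
        FeatureGroup(
            group_id=f"{'neg' if polarity == '-' else 'pos'}_g{i:04d}",
            polarity=polarity,
            members=tuple(assignment[seed.feature_id]),
            rt_centroid=seed.rt,
        )
        for i, seed in enumerate(seeds, start=1)
    ]
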