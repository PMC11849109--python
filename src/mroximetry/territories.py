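"""Venous drainage territories over an integer parcellation.

Each of the five large veins (SSS V, SSS H, SS, BVs, ICVs) drains an
exclusive set of parcellation regions. Because the smaller veins flow into
larger ones, the oxygen saturation measured in a large vein reflects a
composite territory: the straight sinus receives the internal cerebral and
basal veins (SS_total = SS + ICVs + BVs), and the vertical superior sagittal
sinus receives its horizontal segment (SSS V_total = SSS V + SSS H).
Regional CBF/ATT are therefore aggregated over the composed territory when
paired with vein-level SvO2.

The default label->vein assignment ships as an editable JSON asset; it is a
synthetic approximation sufficient for phantom work, not an anatomical
ground truth, and real studies should supply their own atlas file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import EmptyRegionError

__all__ = ["VeinTerritoryAtlas", "compose_territories", "aggregate"]


@dataclass(frozen=True)
class VeinTerritoryAtlas:
    """Mapping from veins to exclusive parcellation labels plus upstream rules.

    ``exclusive`` maps each vein to the labels it drains exclusively;
    exclusive sets are pairwise disjoint. ``upstream`` lists, per vein, the
    tributary veins whose territories are folded into its composed territory.
    """

    exclusive: dict[str, frozenset[int]]
    upstream: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for vein, labels in self.exclusive.items():
            labels = frozenset(int(v) for v in labels)
            if seen & labels:
                raise ValueError(f"exclusive labels of {vein!r} overlap another vein")
            seen |= labels
        for vein, ups in self.upstream.items():
            if vein not in self.exclusive:
                raise ValueError(f"upstream rule for unknown vein {vein!r}")
            for u in ups:
                if u not in self.exclusive:
                    raise ValueError(f"unknown upstream vein {u!r} for {vein!r}")

    @property
    def veins(self) -> tuple[str, ...]:
        return tuple(self.exclusive)

    def compose(self, vein: str) -> frozenset[int]:
        """Union of the vein's exclusive labels and its upstream territories."""
        if vein not in self.exclusive:
            raise ValueError(f"unknown vein {vein!r}")
        labels = set(self.exclusive[vein])
        for u in self.upstream.get(vein, ()):
            labels |= self.exclusive[u]
        return frozenset(labels)

    def vein_of_label(self, label: int) -> str:
        for vein, labels in self.exclusive.items():
            if label in labels:
                return vein
        raise ValueError(f"label {label} is not assigned to any vein")

    @classmethod
    def from_json(cls, path) -> "VeinTerritoryAtlas":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "VeinTerritoryAtlas":
        return cls(
            exclusive={v: frozenset(labels) for v, labels in d["exclusive"].items()},
            upstream={v: tuple(ups) for v, ups in d.get("upstream", {}).items()},
        )

    def to_dict(self) -> dict:
        return {
            "exclusive": {v: sorted(labels) for v, labels in self.exclusive.items()},
            "upstream": {v: list(ups) for v, ups in self.upstream.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def default(cls) -> "VeinTerritoryAtlas":
        """The packaged synthetic default atlas (phantom labels, not anatomy)."""
        text = resources.files("mroximetry.data").joinpath(
            "vein_atlas.json").read_text()
        return cls.from_dict(json.loads(text))


def compose_territories(atlas: VeinTerritoryAtlas, vein: str) -> frozenset[int]:
    """Labels of the composed (exclusive + upstream) territory of a vein."""
    return atlas.compose(vein)


def aggregate(values, parcellation, labels) -> float:
    """Pooled-voxel median of a map over the union of parcellation labels.

    The pooled median keeps the composite statistic consistent with the
    per-territory median: all in-territory voxels enter one order statistic
    rather than averaging component medians.
    """
    values = np.asarray(values, dtype=float)
    parc = np.asarray(parcellation)
    if values.shape != parc.shape:
        raise ValueError("map and parcellation shapes differ")
    labels = set(int(v) for v in labels)
    if not labels:
        raise ValueError("no labels given")
    sel = values[np.isin(parc, sorted(labels))]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise EmptyRegionError("territory has no non-missing voxels")
    return float(np.median(sel))


def aggregate_mean_of_medians(values, parcellation,
                              atlas: VeinTerritoryAtlas, vein: str) -> float:
    """Alternative combiner: volume-weighted mean of component-territory medians."""
    values = np.asarray(values, dtype=float)
    parc = np.asarray(parcellation)
    comps = [vein, *atlas.upstream.get(vein, ())]
    medians, weights = [], []
    for comp in comps:
        sel = values[np.isin(parc, sorted(atlas.exclusive[comp]))]
        sel = sel[np.isfinite(sel)]
        if sel.size:
            medians.append(np.median(sel))
            weights.append(sel.size)
    if not medians:
        raise EmptyRegionError("territory has no non-missing voxels")
    return float(np.average(medians, weights=weights))
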