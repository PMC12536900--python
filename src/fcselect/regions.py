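"""Atlas region mappings.

A :class:`RegionMap` groups atlas parcellation labels (here, Human
Brainnetome Atlas label IDs) into the coarser meta-analytic regions whose
pairwise functional connectivity serves as candidate predictors. The default
map ships with the package: 17 regions covering 106 unique labels, selected
for altered activity in post-traumatic stress disorder relative to
trauma-exposed controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["RegionMap", "default_region_map", "load_region_map"]


@dataclass(frozen=True)
class RegionMap:
    """Ordered mapping from region short codes to atlas label IDs.

    Parameters
    ----------
    regions
        Ordered ``(region_name, label_ids)`` pairs. Region names must be
        unique and label IDs must not be shared between regions.
    atlas_name
        Name of the parcellation the label IDs refer to.
    """

    regions: tuple[tuple[str, tuple[int, ...]], ...]
    atlas_name: str = "brainnetome"
    descriptions: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        seen: dict[int, str] = {}
        for name, labels in self.regions:
            if not labels:
                raise ValueError(f"region {name!r} has no atlas labels")
            for lab in labels:
                if lab in seen:
                    raise ValueError(
                        f"atlas label {lab} assigned to both {seen[lab]!r} and {name!r}"
                    )
                if int(lab) <= 0:
                    raise ValueError(f"atlas label IDs must be positive, got {lab}")
                seen[lab] = name

    @property
    def region_names(self) -> list[str]:
        return [name for name, _ in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def all_labels(self) -> list[int]:
        """All atlas label IDs, in region order."""
        return [lab for _, labels in self.regions for lab in labels]

    @property
    def n_labels(self) -> int:
        return len(self.all_labels)

    def labels_for(self, region: str) -> tuple[int, ...]:
        for name, labels in self.regions:
            if name == region:
                return labels
        raise KeyError(region)

    def edge_labels(self) -> list[str]:
        """Upper-triangle edge names ``"A-B"`` in region order."""
        names = self.region_names
        return [
            f"{names[i]}-{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]


def load_region_map(path) -> RegionMap:
    """Read a region map from a YAML config file.

    The file holds ``atlas_name`` and a ``regions`` list of
    ``{name, labels}`` entries (``description`` optional).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _from_dict(raw)


def _from_dict(raw: dict) -> RegionMap:
    regions = tuple(
        (entry["name"], tuple(int(x) for x in entry["labels"]))
        for entry in raw["regions"]
    )
    descriptions = {
        entry["name"]: entry.get("description", "") for entry in raw["regions"]
    }
    return RegionMap(
        regions=regions,
        atlas_name=raw.get("atlas_name", "unknown"),
        descriptions=descriptions,
    )


def default_region_map() -> RegionMap:
    """The shipped 17-region / 106-label meta-analytic PTSD map."""
    ref = resources.files("fcselect.data").joinpath("brainnetome_ptsd_regions.yaml")
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    return _from_dict(raw)
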