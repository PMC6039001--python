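"""The canonical descriptor registry (69 names in 7 categories).

Weighted-neighbour-average (WNA) variants are distinct entries: each base
contact/potential descriptor that has WNA forms appears once per weighting
(distance, surface), which is what brings the registry to 69 names.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

REGISTRY_SIZE = 69

CATEGORIES = ("Structural", "Geometric", "Contacts", "Unused Contacts",
              "Physical Chemical", "WNA", "Others")


@dataclass(frozen=True)
class DescriptorRegistry:
    names: tuple[str, ...]
    categories: dict[str, str]

    def __len__(self) -> int:
        return len(self.names)

    def by_category(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [n for n in self.names if self.categories[n] == category]


def load_registry() -> DescriptorRegistry:
    ref = resources.files("helixenv.data").joinpath("descriptor_registry.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    names = tuple(table["name"])
    if len(set(names)) != len(names):
        raise ValueError("registry names are not unique")
    return DescriptorRegistry(
        names=names,
        categories=dict(zip(table["name"], table["category"])))
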