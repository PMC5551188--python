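"""Canonical land-use/land-cover category registry.

Sixteen buffer categories are extracted by default: eight areal land-cover
fractions, five line networks (road classes and rail), and three
quantity-weighted features (freeway vehicle-miles, housing units,
permitted NOx emissions). With 12 buffer radii plus the three point
features (x, y, elevation) this yields the ~200-column predictor table.
"""

from __future__ import annotations

#: Areal land-cover categories (per-cell area fractions; buffer features in ha).
AREAL_CATEGORIES = [
    "crops",
    "dev_high",
    "dev_med",
    "dev_open",
    "grassland",
    "pasture",
    "shrub",
    "trees",
]

#: Line-network categories (buffer features are lengths in km).
LINE_CATEGORIES = ["freeway", "local", "primary", "rail", "secondary"]

#: Quantity categories: freeway vehicle-miles/day, housing unit counts,
#: permitted NOx emissions (tons/year) summed within the buffer.
QUANTITY_CATEGORIES = ["emissions", "housing", "vmt_freeway"]

#: All buffer categories, alphabetical (fixes feature-table column order).
ALL_CATEGORIES = sorted(AREAL_CATEGORIES + LINE_CATEGORIES + QUANTITY_CATEGORIES)

#: Tree sub-layers that are summed into the "trees" category on extraction.
TREE_SUBLAYERS = ["trees_deciduous", "trees_evergreen", "trees_mixed"]

#: Default buffer radii in metres: 100 m to 1200 m in 100 m steps.
DEFAULT_RADII = list(range(100, 1300, 100))

#: Point features appended after the buffer columns.
POINT_FEATURES = ["x", "y", "elevation"]

METERS_PER_MILE = 1609.344


def feature_column(category: str, radius: int) -> str:
    """Canonical feature-table column name for (category, radius)."""
    return f"{category}_{int(radius):04d}"


def parse_feature_column(name: str) -> tuple[str, int]:
    """Inverse of :func:`feature_column`."""
    category, radius = name.rsplit("_", 1)
    return category, int(radius)
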