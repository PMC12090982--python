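"""Region assignment and per-region class-frequency summaries.

An assignment maps detected glycans (many-to-many) to named anatomical
regions or spatial clusters of a tissue section.  From it, the summary
computes the region-level glycome profile: how many glycans of each class
co-localize with each region, the within-region percentage of each class,
and the per-region glycan totals.

A toy spatial path is included: ion images (2-D intensity grids) can be
scored against binary region masks by cosine similarity, and glycans
assigned to every region whose score clears a threshold.  This stands in
for the co-localization machinery of spatial-metabolomics platforms; it is
not a re-implementation of any platform's internal measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import GlycanComposition
from .classification import (ClassLabel, ClassificationResult, classify,
                             DECORATION_CLASSES, TYPE_CLASSES)

__all__ = [
    "RegionAssignment",
    "RegionClassSummary",
    "IonImage",
    "summarize_regions",
    "colocalize",
    "assign_regions",
    "COMPLEX_PLAIN",
]

# Explicit bucket for complex glycans carrying no decoration at all.
COMPLEX_PLAIN = "complex (no decorations)"


@dataclass(frozen=True)
class RegionAssignment:
    """Rows of (glycan id, composition, region, optional co-localization score).

    A glycan may appear in several regions; scores, when present, must lie
    in [0, 1].
    """

    rows: tuple

    def __init__(self, rows: Iterable[tuple]) -> None:
        normalized = []
        for row in rows:
            if len(row) == 3:
                glycan, comp, region = row
                score = None
            elif len(row) == 4:
                glycan, comp, region, score = row
            else:
                raise ValueError("rows must be (glycan, composition, region[, score])")
            if not str(region):
                raise ValueError(f"empty region name for glycan {glycan!r}")
            if comp is not None and not isinstance(comp, GlycanComposition):
                raise TypeError("composition must be a GlycanComposition or None")
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} for glycan {glycan!r} not in [0, 1]")
            normalized.append((glycan, comp, str(region), score))
        object.__setattr__(self, "rows", tuple(normalized))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def regions(self) -> list[str]:
        return sorted({r for _, _, r, _ in self.rows})

    def to_frame(self) -> pd.DataFrame:
        from .composition import format_composition
        return pd.DataFrame(
            [(g, format_composition(c) if c is not None else None, r, s)
             for g, c, r, s in self.rows],
            columns=["glycan", "composition", "region", "score"])


@dataclass(frozen=True)
class RegionClassSummary:
    """Region × class surfaces: counts, within-region percentages, totals.

    ``counts`` and ``percents`` are region × term DataFrames over the type
    classes, the decoration classes, and the plain-complex bucket;
    ``combination_counts`` tabulates exact class combinations (display
    names) so combination-level views can be produced as well.
    ``totals[r]`` is the number of distinct glycans assigned to region r —
    decoration multi-labelling means class counts can sum past it.
    """

    counts: pd.DataFrame
    percents: pd.DataFrame
    totals: pd.Series
    combination_counts: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: region, class, count, percent, region_total."""
        records = []
        for region in self.counts.index:
            for term in self.counts.columns:
                count = int(self.counts.loc[region, term])
                if count == 0:
                    continue
                records.append({
                    "region": region,
                    "class": term,
                    "count": count,
                    "percent": float(self.percents.loc[region, term]),
                    "region_total": int(self.totals[region]),
                })
        return pd.DataFrame(records,
                            columns=["region", "class", "count", "percent",
                                     "region_total"])


@dataclass(frozen=True)
class IonImage:
    """Toy MALDI-MSI ion image: a non-negative intensity grid for one glycan."""

    intensities: np.ndarray
    glycan: object
    pixel_size_um: float = 50.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("intensity grid must be 2-D")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "intensities", arr)


def _summary_columns(extra_terms: Iterable[str]) -> list[str]:
    ordered = [str(t) for t in TYPE_CLASSES] + [str(t) for t in DECORATION_CLASSES]
    ordered.append(COMPLEX_PLAIN)
    for term in sorted(set(extra_terms) - set(ordered)):
        ordered.append(term)
    return ordered


def summarize_regions(assignment: RegionAssignment,
                      classifier: Callable[[GlycanComposition], ClassificationResult] = classify,
                      regions: Sequence[str] | None = None) -> RegionClassSummary:
    """Build the region × class count/percentage surfaces.

    Each region's distinct glycans are classified; counts cover every type
    class, every decoration term, and an explicit "complex (no decorations)"
    bucket.  Percentages use the per-region distinct-glycan total as the
    denominator.  Row/column order is deterministic (regions sorted, terms
    in vocabulary order).  Regions named in ``regions`` but absent from the
    assignment appear with total 0 and no percentage rows.
    """
    if len(assignment) == 0:
        raise ValueError("assignment must be non-empty")

    region_names = sorted(set(assignment.regions) | set(regions or ()))
    # Distinct glycans per region (first composition seen wins for a glycan id).
    per_region: dict[str, dict] = {r: {} for r in region_names}
    for glycan, comp, region, _ in assignment:
        if comp is None:
            raise ValueError(f"glycan {glycan!r} has no composition; "
                             "summaries need compositions to classify")
        per_region[region].setdefault(glycan, comp)

    columns = _summary_columns([])
    counts = pd.DataFrame(0, index=region_names, columns=columns, dtype=int)
    combos: dict[str, dict[str, int]] = {r: {} for r in region_names}
    totals = pd.Series(0, index=region_names, dtype=int, name="total")

    for region in region_names:
        glycans = per_region[region]
        totals[region] = len(glycans)
        for glycan in sorted(glycans, key=repr):
            result = classifier(glycans[glycan])
            for term in result.terms:
                counts.loc[region, str(term)] += 1
            if result.type_class is ClassLabel.COMPLEX and not result.decorations:
                counts.loc[region, COMPLEX_PLAIN] += 1
            name = result.display_name
            combos[region][name] = combos[region].get(name, 0) + 1

    percents = counts.astype(float)
    for region in region_names:
        if totals[region] > 0:
            percents.loc[region] = 100.0 * counts.loc[region] / totals[region]
        else:
            percents.loc[region] = np.nan

    combo_records = [
        {"region": region, "class_combination": name, "count": count}
        for region in region_names
        for name, count in sorted(combos[region].items())
    ]
    combination_counts = pd.DataFrame(
        combo_records, columns=["region", "class_combination", "count"])

    return RegionClassSummary(counts=counts, percents=percents, totals=totals,
                              combination_counts=combination_counts)


def colocalize(image: IonImage, mask: np.ndarray) -> float:
    """Cosine similarity between an ion image and a binary region mask.

    Both are flattened; an all-zero image scores 0.  A uniform image over a
    mask covering a fraction f of the pixels scores sqrt(f).
    """
    mask = np.asarray(mask, dtype=float)
    if mask.shape != image.intensities.shape:
        raise ValueError(f"shape mismatch: image {image.intensities.shape} "
                         f"vs mask {mask.shape}")
    if not np.any(mask > 0):
        raise ValueError("mask must contain at least one positive pixel")
    x = image.intensities.ravel()
    m = mask.ravel()
    norm = np.linalg.norm(x) * np.linalg.norm(m)
    if norm == 0:
        return 0.0
    return float(np.clip(np.dot(x, m) / norm, 0.0, 1.0))


def assign_regions(images: Sequence[IonImage],
                   masks: Mapping[str, np.ndarray],
                   threshold: float = 0.5,
                   compositions: Mapping[object, GlycanComposition] | None = None,
                   ) -> RegionAssignment:
    """Assign each glycan to every region whose co-localization score clears
    the threshold.

    Monotone in the threshold: raising it only removes assignments.  An
    empty assignment is a valid outcome.  ``compositions``, when given,
    attaches each glycan's composition so the result can feed
    :func:`summarize_regions` directly.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    rows = []
    for image in images:
        comp = (compositions or {}).get(image.glycan)
        for region in sorted(masks):
            score = colocalize(image, masks[region])
            if score >= threshold:
                rows.append((image.glycan, comp, region, score))
    return RegionAssignment(rows)
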