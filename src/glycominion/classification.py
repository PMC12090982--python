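"""Composition-to-class rules for released N-glycans.

Because canonical N-glycan biosynthesis builds every structure on the shared
Hex:3 HexNAc:2 core, the residue counts alone (H = Hex, N = HexNAc,
F = dHex/fucose, S = NeuAc/sialic acid) predict much of the structure even
though isomers share a composition.  The rule system implemented here assigns
each composition exactly one *type* class

* high-mannose:   H > 3 and N <= 2, no fucose or sialic acid
* pauci-mannose:  H < 4 and N < 3, no sialic acid (fucose allowed)
* hybrid:         N = 3 and H >= 4  (heuristic; see docs/methods.md)
* complex:        N >= 4
* unclassified:   anything else (never an error)

and, for hybrid/complex glycans, a set of *decoration* classes

* fucosylated (F = 1) / multi-fucosylated (F > 1)
* sialylated (S >= 1)
* polylactosamine (N > 6 and H > 7)
* bisecting (N = H and N = 5 or N > 6)
* tetra-antennary (N >= 6)
* the H = 6, N = 6 composition is ambiguous between bisecting and
  tetra-antennary and carries a dedicated combined label instead of either.

Isomer- or linkage-level resolution is explicitly out of scope.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

from .composition import GlycanComposition

__all__ = [
    "ClassLabel",
    "ClassificationResult",
    "classify",
    "ontology_terms",
    "class_counts",
    "TYPE_CLASSES",
    "DECORATION_CLASSES",
]

logger = logging.getLogger(__name__)


class ClassLabel(str, Enum):
    """Closed, versioned vocabulary of N-glycan class labels."""

    PAUCI_MANNOSE = "pauci-mannose"
    HIGH_MANNOSE = "high-mannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"
    FUCOSYLATED = "fucosylated"
    MULTI_FUCOSYLATED = "multifucose"
    SIALYLATED = "sialylated"
    BISECTING = "bisecting"
    TETRA_ANTENNARY = "tetra antennary"
    POLYLACTOSAMINE = "polylactosamine"
    BISECTING_OR_TETRA_ANTENNARY = "bisecting-or-tetra antennary"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # value doubles as the display token
        return self.value


TYPE_CLASSES = (
    ClassLabel.PAUCI_MANNOSE,
    ClassLabel.HIGH_MANNOSE,
    ClassLabel.HYBRID,
    ClassLabel.COMPLEX,
    ClassLabel.UNCLASSIFIED,
)

DECORATION_CLASSES = (
    ClassLabel.FUCOSYLATED,
    ClassLabel.MULTI_FUCOSYLATED,
    ClassLabel.SIALYLATED,
    ClassLabel.BISECTING,
    ClassLabel.TETRA_ANTENNARY,
    ClassLabel.POLYLACTOSAMINE,
    ClassLabel.BISECTING_OR_TETRA_ANTENNARY,
)

# Residue symbols the rules know about; anything else (NeuGc, Pent, ...) is
# ignored by the predicates but triggers a conservative warning.
_RULE_SYMBOLS = frozenset({"Hex", "HexNAc", "dHex", "NeuAc"})


def default_hybrid_rule(H: int, N: int, F: int, S: int) -> bool:
    """One antenna on a mannose-extended core: N = 3 and H >= 4.

    The class vocabulary names hybrid glycans but no compositional bound
    pins them down uniquely; this predicate is the package's documented
    choice and can be swapped via the ``hybrid_rule`` argument of
    :func:`classify` without touching any other rule.
    """
    return N == 3 and H >= 4


@dataclass(frozen=True)
class ClassificationResult:
    """Type class, decoration set, and ambiguity flag for one composition."""

    composition: GlycanComposition
    type_class: ClassLabel
    decorations: frozenset[ClassLabel] = field(default_factory=frozenset)
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.type_class not in TYPE_CLASSES:
            raise ValueError(f"{self.type_class} is not a type class")
        extra = set(self.decorations) - set(DECORATION_CLASSES)
        if extra:
            raise ValueError(f"not decoration labels: {sorted(str(e) for e in extra)}")

    @property
    def terms(self) -> frozenset[ClassLabel]:
        """All ontology terms carried by this glycan: {type} ∪ decorations."""
        return frozenset({self.type_class}) | self.decorations

    @property
    def display_name(self) -> str:
        """Human-readable class string, e.g.
        ``"complex bisecting-multifucose-polylactosamine-tetra antennary"``.

        Fucose flags on pauci-mannose glycans are metadata only and are not
        shown in the display name.
        """
        shown = self.decorations
        if self.type_class is ClassLabel.PAUCI_MANNOSE:
            shown = shown - {ClassLabel.FUCOSYLATED, ClassLabel.MULTI_FUCOSYLATED}
        tokens = sorted(str(d) for d in shown)
        if not tokens:
            return str(self.type_class)
        return f"{self.type_class} " + "-".join(tokens)


def classify(comp: GlycanComposition,
             hybrid_rule: Callable[[int, int, int, int], bool] = default_hybrid_rule,
             ) -> ClassificationResult:
    """Assign the type class and decoration classes of one composition.

    A pure function of the residue counts; unknown residue symbols never
    block type assignment (the predicates only read Hex/HexNAc/dHex/NeuAc)
    but are logged since decorations are then computed from the known
    symbols only.  The fallback is UNCLASSIFIED, never an exception.
    """
    unknown = set(comp.counts) - _RULE_SYMBOLS
    if unknown:
        logger.warning(
            "composition %s contains residue symbols outside the rule "
            "vocabulary (%s); classes computed from known symbols only",
            comp, ", ".join(sorted(unknown)))

    H, N, F, S = comp["Hex"], comp["HexNAc"], comp["dHex"], comp["NeuAc"]

    # Type class, first match wins.
    if H > 3 and N <= 2 and F == 0 and S == 0:
        type_class = ClassLabel.HIGH_MANNOSE
    elif H < 4 and N < 3 and S == 0:
        type_class = ClassLabel.PAUCI_MANNOSE
    elif hybrid_rule(H, N, F, S):
        type_class = ClassLabel.HYBRID
    elif N >= 4:
        type_class = ClassLabel.COMPLEX
    else:
        type_class = ClassLabel.UNCLASSIFIED

    decorations: set[ClassLabel] = set()
    ambiguous = False
    if type_class in (ClassLabel.HYBRID, ClassLabel.COMPLEX):
        if F == 1:
            decorations.add(ClassLabel.FUCOSYLATED)
        elif F > 1:
            decorations.add(ClassLabel.MULTI_FUCOSYLATED)
        if S >= 1:
            decorations.add(ClassLabel.SIALYLATED)
        if N > 6 and H > 7:
            decorations.add(ClassLabel.POLYLACTOSAMINE)
        if H == 6 and N == 6:
            # Composition alone cannot separate a bisected tri-antennary
            # arrangement from a tetra-antennary one here.
            decorations.add(ClassLabel.BISECTING_OR_TETRA_ANTENNARY)
            ambiguous = True
        else:
            if N == H and (N == 5 or N > 6):
                decorations.add(ClassLabel.BISECTING)
            if N >= 6:
                decorations.add(ClassLabel.TETRA_ANTENNARY)
    elif type_class is ClassLabel.PAUCI_MANNOSE:
        # Fucose status surfaced as metadata (pauci-mannose may carry fucose).
        if F == 1:
            decorations.add(ClassLabel.FUCOSYLATED)
        elif F > 1:
            decorations.add(ClassLabel.MULTI_FUCOSYLATED)

    return ClassificationResult(comp, type_class, frozenset(decorations), ambiguous)


def ontology_terms(comps: Sequence[GlycanComposition],
                   hybrid_rule: Callable[[int, int, int, int], bool] = default_hybrid_rule,
                   ) -> tuple[list[frozenset[ClassLabel]], dict[ClassLabel, list[int]]]:
    """Per-glycan ontology term lists plus the inverted term index.

    Returns ``(terms_per_glycan, index)`` where ``terms_per_glycan[i]`` is
    the term set of ``comps[i]`` and ``index`` maps each term to the sorted
    positions of the glycans that carry it.  Duplicated compositions keep
    multiset semantics: each occurrence contributes its own position.
    """
    if not comps:
        raise ValueError("ontology_terms requires a non-empty composition list")
    terms_per_glycan = [classify(c, hybrid_rule).terms for c in comps]
    index: dict[ClassLabel, list[int]] = {}
    for i, terms in enumerate(terms_per_glycan):
        for term in sorted(terms, key=lambda t: t.value):
            index.setdefault(term, []).append(i)
    # Deterministic term ordering: vocabulary order.
    ordered = {label: index[label] for label in ClassLabel if label in index}
    return terms_per_glycan, ordered


def class_counts(comps: Sequence[GlycanComposition],
                 hybrid_rule: Callable[[int, int, int, int], bool] = default_hybrid_rule,
                 ) -> dict[ClassLabel, int]:
    """Number of glycans carrying each term.

    Type classes partition the list (their counts sum to ``len(comps)``);
    decoration counts may overlap.
    """
    if not comps:
        raise ValueError("class_counts requires a non-empty composition list")
    counter: Counter[ClassLabel] = Counter()
    for comp in comps:
        counter.update(classify(comp, hybrid_rule).terms)
    return {label: counter[label] for label in ClassLabel if counter[label]}
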