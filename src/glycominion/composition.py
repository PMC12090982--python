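"""Glycan compositional annotations and monoisotopic mass arithmetic.

A released N-glycan is described here at the *compositional* level: a bag of
monosaccharide residue counts such as ``Hex:5 HexNAc:4 dHex:1``.  This module
parses and formats those annotation strings, computes the neutral monoisotopic
mass of the free reducing-end glycan (sum of residue masses plus one water),
and derives singly charged adduct m/z values ([M+H]+, [M+Na]+, [M+K]+) for
annotation and lock-mass checking in MALDI-MSI experiments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MonosaccharideRegistry",
    "GlycanComposition",
    "CompositionParseError",
    "DEFAULT_REGISTRY",
    "parse_composition",
    "format_composition",
    "neutral_mass",
    "adduct_mz",
    "match_mz",
    "MzMatch",
]

# Monoisotopic residue masses (Da): the mass of the dehydrated residue as it
# occurs inside the glycan chain.  Free reducing-end convention adds one water.
_RESIDUE_MASSES = {
    "Hex": 162.052824,      # hexose (mannose, galactose, glucose)
    "HexNAc": 203.079373,   # N-acetylhexosamine (GlcNAc, GalNAc)
    "dHex": 146.057909,     # deoxyhexose (fucose)
    "NeuAc": 291.095417,    # N-acetylneuraminic (sialic) acid
    "NeuGc": 307.090331,    # N-glycolylneuraminic acid
    "Pent": 132.042259,     # pentose (xylose)
}

_WATER = 18.0105646863
_ELECTRON = 0.00054857990907

# Atomic monoisotopic masses of the cationizing atom X in [M+X]+.
_ADDUCT_MASSES = {
    "H": 1.00782503207,
    "Na": 22.9897692809,
    "K": 38.96370668,
}


class CompositionParseError(ValueError):
    """Raised when an annotation string cannot be parsed into a composition."""


@dataclass(frozen=True)
class MonosaccharideRegistry:
    """Residue masses and physical constants used by the mass arithmetic.

    The registry is deliberately independent of the classification rules:
    new residue symbols can be registered (via :meth:`with_residue`) without
    touching any classification logic.
    """

    residues: Mapping[str, float] = field(default_factory=lambda: dict(_RESIDUE_MASSES))
    water: float = _WATER
    electron: float = _ELECTRON
    adducts: Mapping[str, float] = field(default_factory=lambda: dict(_ADDUCT_MASSES))

    def __post_init__(self) -> None:
        for symbol, mass in self.residues.items():
            if mass <= 0:
                raise ValueError(f"residue mass for {symbol!r} must be positive")

    def with_residue(self, symbol: str, mass: float) -> "MonosaccharideRegistry":
        """Return a new registry with one residue added or replaced."""
        residues = dict(self.residues)
        residues[symbol] = mass
        return MonosaccharideRegistry(residues=residues, water=self.water,
                                      electron=self.electron, adducts=self.adducts)

    def residue_mass(self, symbol: str) -> float:
        try:
            return self.residues[symbol]
        except KeyError:
            raise KeyError(f"unknown residue symbol: {symbol!r}") from None

    def adduct_mass(self, symbol: str) -> float:
        try:
            return self.adducts[symbol]
        except KeyError:
            raise KeyError(f"unknown adduct symbol: {symbol!r}") from None


DEFAULT_REGISTRY = MonosaccharideRegistry()

# Canonical residue ordering for formatted annotations; symbols outside this
# list sort alphabetically after it.
_CANONICAL_ORDER = ("Hex", "HexNAc", "dHex", "NeuAc")


@dataclass(frozen=True)
class GlycanComposition:
    """Residue counts of one released N-glycan.

    ``counts`` maps residue symbols to strictly positive integers; zero-count
    symbols are dropped at construction.  The original annotation text, when
    parsed from a string, is kept in ``source_text``.
    """

    counts: Mapping[str, int]
    source_text: str | None = None

    def __post_init__(self) -> None:
        cleaned = {}
        for symbol, count in self.counts.items():
            if not isinstance(count, int) or isinstance(count, bool):
                raise TypeError(f"count for {symbol!r} must be an integer")
            if count < 0:
                raise ValueError(f"count for {symbol!r} must be non-negative")
            if count > 0:
                cleaned[symbol] = count
        if not cleaned:
            raise ValueError("empty composition: at least one residue count must be > 0")
        object.__setattr__(self, "counts", cleaned)

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        return format_composition(self)

    def merge(self, other: "GlycanComposition") -> "GlycanComposition":
        """Residue-wise sum of two compositions (one shared reducing end)."""
        counts = dict(self.counts)
        for symbol, count in other.counts.items():
            counts[symbol] = counts.get(symbol, 0) + count
        return GlycanComposition(counts)


# "Hex:5", "HexNAc : 4" — colon-delimited token.
_COLON_TOKEN = re.compile(r"^([A-Za-z][A-Za-z0-9']*)\s*:\s*([+-]?\d+)$")
# "Hex5dHex1HexNAc4" — concatenated dialect (figure-caption spelling).
_CONCAT_TOKEN = re.compile(r"([A-Za-z][A-Za-z']*?)(\d+)")


def _canonical_symbol(symbol: str, known: Iterable[str]) -> str:
    """Case-insensitive recognition of known symbols, case-preserving otherwise."""
    lowered = symbol.lower()
    for candidate in known:
        if candidate.lower() == lowered:
            return candidate
    return symbol


def parse_composition(text: str,
                      registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> GlycanComposition:
    """Parse an annotation string into a :class:`GlycanComposition`.

    Both spellings seen in MALDI-MSI glycan annotations are accepted:
    ``"Hex:5 HexNAc:4 dHex:1"`` (colon-delimited, whitespace/comma/semicolon
    separated) and ``"Hex5 dHex1 HexNAc4"`` / ``"Hex5dHex1HexNAc4"``
    (concatenated).  Known residue symbols are recognised case-insensitively
    and normalised to their canonical casing; unknown symbols are preserved
    verbatim so that downstream classification can treat them conservatively.

    Raises
    ------
    CompositionParseError
        On empty input, malformed tokens, negative counts, duplicate symbols,
        or an all-zero composition.
    """
    if text is None or not text.strip():
        raise CompositionParseError("empty annotation string")
    stripped = text.strip()
    known = list(registry.residues)

    pairs: list[tuple[str, int]] = []
    if ":" in stripped:
        tokens = [t for t in re.split(r"[\s,;]+", stripped) if t]
        for token in tokens:
            m = _COLON_TOKEN.match(token)
            if not m:
                raise CompositionParseError(f"malformed token: {token!r}")
            symbol, count_text = m.groups()
            count = int(count_text)
            if count < 0:
                raise CompositionParseError(f"negative count in token: {token!r}")
            pairs.append((_canonical_symbol(symbol, known), count))
    else:
        consumed = "".join(sym + num for sym, num in _CONCAT_TOKEN.findall(stripped))
        if consumed != re.sub(r"[\s,;]+", "", stripped):
            raise CompositionParseError(f"malformed annotation: {stripped!r}")
        for symbol, count_text in _CONCAT_TOKEN.findall(stripped):
            pairs.append((_canonical_symbol(symbol, known), int(count_text)))

    counts: dict[str, int] = {}
    for symbol, count in pairs:
        if symbol in counts:
            raise CompositionParseError(f"duplicate symbol in annotation: {symbol!r}")
        counts[symbol] = count
    if all(c == 0 for c in counts.values()):
        raise CompositionParseError(f"empty composition (all counts zero): {stripped!r}")
    return GlycanComposition(counts, source_text=text)


def format_composition(comp: GlycanComposition) -> str:
    """Canonical annotation string: ``Hex, HexNAc, dHex, NeuAc`` first, then
    remaining symbols alphabetically; zero counts omitted."""
    def key(symbol: str) -> tuple[int, str]:
        try:
            return (_CANONICAL_ORDER.index(symbol), "")
        except ValueError:
            return (len(_CANONICAL_ORDER), symbol)

    ordered = sorted(comp.counts, key=key)
    return " ".join(f"{symbol}:{comp.counts[symbol]}" for symbol in ordered)


def neutral_mass(comp: GlycanComposition,
                 registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> float:
    """Neutral monoisotopic mass (Da) of the free reducing-end glycan.

    Sum of dehydrated residue masses plus one water, the convention for
    glycans enzymatically released from their carrier protein.
    """
    total = registry.water
    for symbol, count in comp.counts.items():
        total += count * registry.residue_mass(symbol)
    return total


def adduct_mz(comp: GlycanComposition, adduct: str,
              registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> float:
    """m/z of the singly charged [M+X]+ ion (X in the registry adduct table).

    The electron removed on cationization is subtracted, which matters at the
    fourth decimal for high-resolution lock-mass work.
    """
    return neutral_mass(comp, registry) + registry.adduct_mass(adduct) - registry.electron


@dataclass(frozen=True)
class MzMatch:
    """One observed peak matched to a candidate composition/adduct pair."""

    observed_mz: float
    composition: GlycanComposition
    adduct: str
    theoretical_mz: float
    ppm_error: float


def match_mz(observed: Sequence[float],
             candidates: Sequence[GlycanComposition],
             adducts: Sequence[str] = ("Na",),
             tol_ppm: float = 2.0,
             registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> list[MzMatch]:
    """Match observed m/z values against theoretical candidate/adduct m/z.

    Every (observed, candidate, adduct) combination within ``tol_ppm`` parts
    per million is returned, sorted by absolute ppm error (ties broken by
    observed m/z, then adduct).  An empty list is a valid outcome.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    theoretical = [(comp, adduct, adduct_mz(comp, adduct, registry))
                   for comp in candidates for adduct in adducts]
    matches = []
    for obs in observed:
        for comp, adduct, theo in theoretical:
            ppm = (obs - theo) / theo * 1e6
            if abs(ppm) <= tol_ppm:
                matches.append(MzMatch(obs, comp, adduct, theo, ppm))
    matches.sort(key=lambda m: (abs(m.ppm_error), m.observed_mz, m.adduct))
    return matches
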