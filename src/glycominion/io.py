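"""File IO, synthetic fixtures, run configuration and the pipeline driver.

Everything here is plumbing around the analysis modules: reading glycan
tables from CSV/TSV, generating synthetic composition tables and toy ion
images for testing and demonstration, and running the full
annotate → classify → co-localize → summarize → enrich pipeline from one
seeded configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import (GlycanComposition, CompositionParseError,
                          format_composition, parse_composition, match_mz)
from .classification import ClassLabel, classify, ontology_terms
from .enrichment import EnrichmentInput, fisher_enrichment, ease_enrichment, \
    binomial_enrichment, ks_rank_enrichment
from .regions import IonImage, RegionAssignment, assign_regions, summarize_regions

__all__ = [
    "RunConfig",
    "ParseFailure",
    "read_glycan_table",
    "generate_fixture_compositions",
    "generate_fixture_images",
    "run_pipeline",
    "PipelineError",
    "FIXTURE_GRID",
]

logger = logging.getLogger(__name__)


def sniff_read(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV, detecting the delimiter from the header line.

    A tab in the header means TSV, otherwise comma; this stays correct for
    single-column files, where generic sniffers guess wildly.
    """
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


# Sampling grid for synthetic compositions: every composition with
# Hex <= 12, HexNAc <= 12, dHex <= 4, NeuAc <= 4 (all-zero excluded).
FIXTURE_GRID = {"Hex": 12, "HexNAc": 12, "dHex": 4, "NeuAc": 4}


@dataclass(frozen=True)
class ParseFailure:
    """One row that failed to parse, with its 1-based data line number."""

    line: int
    text: str
    error: str


def read_glycan_table(path: str | Path,
                      all_or_nothing: bool = False,
                      ) -> tuple[list[tuple[object, GlycanComposition, dict]], list[ParseFailure]]:
    """Read a glycan table (CSV or TSV, delimiter sniffed).

    The file must carry a ``composition`` column; a ``glycan`` column, when
    present, provides identifiers (row number otherwise).  Returns
    ``(entries, failures)`` where each entry is
    ``(identifier, composition, extra_columns)``.  With ``all_or_nothing``
    any parse failure raises instead of being collected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"glycan table not found: {path}")
    frame = sniff_read(path)
    if "composition" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'composition'")

    entries = []
    failures = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_dict = dict(zip(frame.columns, row))
        text = row_dict.pop("composition")
        identifier = row_dict.pop("glycan", i)
        try:
            comp = parse_composition(str(text))
        except CompositionParseError as exc:
            failure = ParseFailure(line=i + 1, text=str(text), error=str(exc))
            if all_or_nothing:
                raise CompositionParseError(
                    f"{path} line {failure.line}: {failure.error}") from exc
            failures.append(failure)
            continue
        entries.append((identifier, comp, row_dict))
    return entries, failures


def _grid_compositions() -> list[GlycanComposition]:
    comps = []
    for h in range(FIXTURE_GRID["Hex"] + 1):
        for n in range(FIXTURE_GRID["HexNAc"] + 1):
            for f in range(FIXTURE_GRID["dHex"] + 1):
                for s in range(FIXTURE_GRID["NeuAc"] + 1):
                    if h + n + f + s == 0:
                        continue
                    comps.append(GlycanComposition(
                        {"Hex": h, "HexNAc": n, "dHex": f, "NeuAc": s}))
    return comps


def _quotas(n: int, class_mix: Mapping[ClassLabel, float]) -> dict[ClassLabel, int]:
    """Largest-remainder apportionment of n rows to the requested classes."""
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class mix proportions must sum to 1")
    raw = {label: n * p for label, p in class_mix.items()}
    quotas = {label: int(x) for label, x in raw.items()}
    remainder = n - sum(quotas.values())
    by_frac = sorted(class_mix, key=lambda lb: (quotas[lb] - raw[lb], str(lb)))
    for label in by_frac[:remainder]:
        quotas[label] += 1
    return quotas


def generate_fixture_compositions(n: int, seed: int,
                                  class_mix: Mapping[ClassLabel, float],
                                  ) -> pd.DataFrame:
    """Synthesize a composition table with a prescribed class mix.

    Compositions are rejection-sampled uniformly from the fixture grid until
    each class quota is met: a draw counts towards a class only if
    :func:`classify` puts that class among its terms.  The intended class is
    emitted next to each row so the table doubles as an independent oracle
    for the classifier.  Deterministic for a fixed seed.

    Raises if a requested class has no representative on the grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = _grid_compositions()
    terms_by_comp = [classify(c).terms for c in grid]

    quotas = _quotas(n, class_mix)
    for label in quotas:
        if not any(label in terms for terms in terms_by_comp):
            raise ValueError(f"class {label} is infeasible on the fixture grid")

    records = []
    for label in sorted(quotas, key=str):
        need = quotas[label]
        while need > 0:
            idx = int(rng.integers(len(grid)))
            if label in terms_by_comp[idx]:
                comp = grid[idx]
                records.append({
                    "glycan": f"G{len(records):04d}",
                    "composition": format_composition(comp),
                    "intended_class": str(label),
                })
                need -= 1
    return pd.DataFrame(records, columns=["glycan", "composition", "intended_class"])


def generate_fixture_images(masks: Mapping[str, np.ndarray],
                            intended: Mapping[object, Sequence[str]],
                            noise: float = 0.0,
                            seed: int = 0,
                            pixel_size_um: float = 50.0) -> list[IonImage]:
    """Build toy ion images realising an intended region assignment.

    Each glycan's image is the sum of its intended region masks plus
    zero-mean Gaussian noise clipped at 0.  With ``noise=0`` and
    non-overlapping masks of comparable area, ``assign_regions`` at the
    default 0.5 cosine threshold recovers the intended assignment exactly
    (the cosine of a k-region sum with one member mask is sqrt(w/W) for
    mask area w out of total support W, which stays >= 0.5 for up to four
    equal-area regions per glycan).
    """
    shapes = {np.asarray(m).shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError("all masks must share one shape")
    shape = shapes.pop()
    rng = np.random.default_rng(seed)
    images = []
    for glycan in intended:
        signal = np.zeros(shape, dtype=float)
        for region in intended[glycan]:
            if region not in masks:
                raise KeyError(f"unknown region {region!r} for glycan {glycan!r}")
            signal += np.asarray(masks[region], dtype=float)
        if noise > 0:
            signal = signal + rng.normal(0.0, noise, size=shape)
        images.append(IonImage(np.clip(signal, 0.0, None), glycan=glycan,
                               pixel_size_um=pixel_size_um))
    return images


# ---------------------------------------------------------------------------
# Pipeline

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    All randomness (fixture generation, image noise) flows from ``seed``,
    so a fixed seed makes the whole run bit-reproducible.
    """

    out_dir: str | Path = "glycominion_out"
    compositions_path: str | Path | None = None   # CSV/TSV; None -> fixtures
    peaks_path: str | Path | None = None          # optional observed m/z list
    adducts: tuple[str, ...] = ("Na",)
    ppm_tolerance: float = 2.0
    enrichment_test: str = "fisher"               # fisher|ease|binomial|ks
    adjust_method: str = "bh"
    coloc_threshold: float = 0.5
    seed: int = 0
    n_fixture_glycans: int = 60
    fixture_class_mix: Mapping[str, float] = field(default_factory=lambda: {
        "high-mannose": 0.25, "complex": 0.45, "hybrid": 0.15,
        "pauci-mannose": 0.15,
    })
    image_noise: float = 0.0
    log_level: str = "INFO"

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["compositions_path"] = (str(self.compositions_path)
                                  if self.compositions_path else None)
        d["peaks_path"] = str(self.peaks_path) if self.peaks_path else None
        d["adducts"] = list(self.adducts)
        d["fixture_class_mix"] = dict(self.fixture_class_mix)
        return d


_ENRICH_FUNCS = {
    "fisher": fisher_enrichment,
    "ease": ease_enrichment,
    "binomial": binomial_enrichment,
    "ks": ks_rank_enrichment,
}

_DEMO_REGIONS = ("adventitia", "submucosal gland", "cartilage", "smooth muscle")


def _demo_masks(shape: tuple[int, int] = (20, 20)) -> dict[str, np.ndarray]:
    """Four non-overlapping equal quadrant masks standing in for anatomy."""
    h, w = shape
    masks = {}
    quadrants = [(slice(0, h // 2), slice(0, w // 2)),
                 (slice(0, h // 2), slice(w // 2, w)),
                 (slice(h // 2, h), slice(0, w // 2)),
                 (slice(h // 2, h), slice(w // 2, w))]
    for name, (rs, cs) in zip(_DEMO_REGIONS, quadrants):
        m = np.zeros(shape)
        m[rs, cs] = 1.0
        masks[name] = m
    return masks


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write its report bundle.

    Stages: load/generate compositions → (optional) m/z matching → classify
    → build/assign regions → summarize → enrich.  Outputs are written to
    ``config.out_dir``: classes.csv, assignments.csv, region_summary.csv,
    enrichment.csv and manifest.json (config echo + version + seed).  Any
    stage failure raises :class:`PipelineError` naming the stage, after
    removing partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> Path:
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    try:
        # -- stage: load ----------------------------------------------------
        try:
            if config.compositions_path is not None:
                entries, failures = read_glycan_table(config.compositions_path)
                if failures:
                    logger.warning("%d rows failed to parse", len(failures))
                glycans = {ident: comp for ident, comp, _ in entries}
            else:
                table = generate_fixture_compositions(
                    config.n_fixture_glycans, config.seed,
                    {ClassLabel(k): v for k, v in config.fixture_class_mix.items()})
                glycans = {row.glycan: parse_composition(row.composition)
                           for row in table.itertuples(index=False)}
            if not glycans:
                raise ValueError("no parsable compositions")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc

        ids = sorted(glycans, key=repr)
        comps = [glycans[g] for g in ids]

        # -- stage: match (optional) ---------------------------------------
        try:
            if config.peaks_path is not None:
                peaks = sniff_read(config.peaks_path)
                if "mz" not in peaks.columns:
                    raise ValueError("peaks file missing required column 'mz'")
                matches = match_mz(list(peaks["mz"]), comps,
                                   adducts=config.adducts,
                                   tol_ppm=config.ppm_tolerance)
                emit("matches.csv", pd.DataFrame(
                    [(m.observed_mz, format_composition(m.composition),
                      m.adduct, m.theoretical_mz, m.ppm_error)
                     for m in matches],
                    columns=["observed_mz", "composition", "adduct",
                             "theoretical_mz", "ppm_error"]))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("match", str(exc)) from exc

        # -- stage: classify ------------------------------------------------
        try:
            results = {g: classify(glycans[g]) for g in ids}
            emit("classes.csv", pd.DataFrame(
                [(g, format_composition(glycans[g]), str(r.type_class),
                  ";".join(sorted(str(d) for d in r.decorations)),
                  r.ambiguous, r.display_name)
                 for g, r in results.items()],
                columns=["glycan", "composition", "type_class", "decorations",
                         "ambiguous", "display_name"]))
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc

        # -- stage: assign --------------------------------------------------
        try:
            masks = _demo_masks()
            rng = np.random.default_rng(config.seed)
            region_names = list(masks)
            # Each glycan intends 1-2 regions, chosen reproducibly.
            intended = {}
            for g in ids:
                k = int(rng.integers(1, 3))
                chosen = rng.choice(region_names, size=k, replace=False)
                intended[g] = [str(c) for c in chosen]
            images = generate_fixture_images(masks, intended,
                                             noise=config.image_noise,
                                             seed=config.seed)
            assignment = assign_regions(images, masks,
                                        threshold=config.coloc_threshold,
                                        compositions=glycans)
            if len(assignment) == 0:
                raise ValueError("no glycan cleared the co-localization threshold")
            emit("assignments.csv", assignment.to_frame())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("assign", str(exc)) from exc

        # -- stage: summarize -----------------------------------------------
        try:
            summary = summarize_regions(assignment, regions=region_names)
            emit("region_summary.csv", summary.to_tidy())
        except Exception as exc:
            raise PipelineError("summarize", str(exc)) from exc

        # -- stage: enrich --------------------------------------------------
        try:
            _, index = ontology_terms(comps)
            term_index = {str(term): frozenset(ids[i] for i in positions)
                          for term, positions in index.items()}
            enrich = _ENRICH_FUNCS[config.enrichment_test]
            rows = []
            for region in assignment.regions:
                query = {g for g, _, r, _ in assignment if r == region}
                kwargs = {}
                ranks = None
                if config.enrichment_test == "ks":
                    # Rank = within-region co-localization score (descending).
                    scores = {g: 0.0 for g in ids}
                    for g, _, r, s in assignment:
                        if r == region and s is not None:
                            scores[g] = max(scores[g], s)
                    ordered = sorted(ids, key=lambda g: (-scores[g], repr(g)))
                    ranks = {g: i + 1 for i, g in enumerate(ordered)}
                inp = EnrichmentInput(query=query, universe=ids,
                                      term_index=term_index, ranks=ranks)
                for res in enrich(inp, adjust=config.adjust_method):
                    rows.append({
                        "region": region, "term": str(res.term),
                        "k": res.k, "n": res.n, "K": res.K, "N": res.N,
                        "odds_ratio": res.odds_ratio,
                        "p_value": res.p_value, "q_value": res.q_value,
                        "untestable": res.untestable,
                    })
            emit("enrichment.csv", pd.DataFrame(
                rows, columns=["region", "term", "k", "n", "K", "N",
                               "odds_ratio", "p_value", "q_value", "untestable"]))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc

        manifest = {
            "package": "glycominion",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_jsonable(),
            "outputs": [p.name for p in written],
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        return manifest
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
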