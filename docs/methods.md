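# Methods

## Scope and model

`glycominion` operates on *compositional* N-glycan annotations — residue
counts H (Hex), N (HexNAc), F (dHex/fucose), S (NeuAc/sialic acid) — as
produced by database annotation of MALDI-MSI peak lists. The package makes
one core modelling assumption: because all N-glycans are elaborations of
the common Hex₃HexNAc₂ core, residue counts alone predict structural
classes with useful (but not perfect) fidelity. Isomer and linkage
resolution is explicitly out of scope; every class call is a statement
about what the counts are consistent with, not a structure determination.

## Mass arithmetic

Neutral monoisotopic mass = Σ countᵢ × residue-massᵢ + m(H₂O), the free
reducing-end convention appropriate for PNGase-released glycans. Residue
masses are the standard monoisotopic values (Hex 162.052824,
HexNAc 203.079373, dHex 146.057909, NeuAc 291.095417, NeuGc 307.090331,
Pent 132.042259 Da). Singly charged adduct m/z subtracts one electron mass:
m/z = M + m(X) − mₑ for X ∈ {H, Na, K}. The electron term (≈0.00055 Da)
matters at the 4-decimal precision used for lock-mass work. The residue
registry is extensible (`MonosaccharideRegistry.with_residue`) without
touching classification.

Peak matching (`match_mz`) is a plain ppm-window comparison, default
tolerance 2 ppm — the accuracy class of 7 T magnetic-resonance MS — and is
configurable. Isotope envelopes, multiple charging, negative-ion adducts
and derivatization shifts are non-goals.

## Classification rules

Type classes are mutually exclusive, evaluated first-match-wins:
high-mannose (H > 3, N ≤ 2, F = S = 0), pauci-mannose (H < 4, N < 3,
S = 0), hybrid (N = 3, H ≥ 4), complex (N ≥ 4), else unclassified.
Decorations are evaluated for hybrid and complex glycans: fucosylated
(F = 1) xor multifucose (F > 1), sialylated (S ≥ 1), polylactosamine
(N > 6 and H > 7), bisecting (N = H and N ∈ {5} ∪ {7, 8, …}),
tetra-antennary (N ≥ 6). H = 6, N = 6 yields the single ambiguous label
`bisecting-or-tetra antennary` in place of both branch labels, because the
composition genuinely underdetermines the branch topology.

Design choices that were genuinely open:

* **Hybrid predicate.** The class vocabulary includes hybrid glycans but no
  count-based bound defines them uniquely; N = 3 with H ≥ 4 (one antenna on
  a mannose-extended core) is this package's heuristic. It is injected as a
  swappable predicate (`classify(..., hybrid_rule=...)`) so alternative
  definitions do not disturb the other rules.
* **High-mannose HexNAc bound.** "At most the two core HexNAc, rarely one"
  is read as N ≤ 2; N = 3 would collide with the hybrid predicate.
* **Pauci-mannose and sialylation.** Pauci-mannose tolerates fucose only;
  S ≥ 1 excludes it. Fucose flags on pauci-mannose glycans are surfaced in
  the decoration set as metadata but kept out of the display name, which
  follows the convention of naming decorations on hybrid/complex glycans.
* **Bisecting at N = H = 5 with heavy fucosylation.** The rules as stated
  add the bisecting label to e.g. Hex:5 HexNAc:5 dHex:4 even though such a
  composition is often reported as plain complex-multifucose; the rule is
  kept as stated rather than special-cased.
* **Unknown residues.** Symbols outside {Hex, HexNAc, dHex, NeuAc} (NeuGc,
  Pent, user extensions) never block type assignment — predicates read the
  four known counts — but a warning is logged since decorations then
  describe only the known part.

An independent, deliberately flat re-statement of these predicates serves
as a brute-force oracle in the tests and the acceptance script; the two
agree on the full grid H ≤ 12, N ≤ 12, F ≤ 4, S ≤ 4 (4 224 compositions,
every non-zero count vector).

## Enrichment statistics

All tests are one-sided towards over-representation, the standard ontology
enrichment convention. Fisher: p = P(X ≥ k), X ~ Hypergeometric(N, K, n),
computed via the scipy survival function. EASE: the identical tail with the
hit count replaced by max(k − 1, 0); this dominates the Fisher p on every
table and de-emphasises single-hit terms. Binomial: exact tail at rate
K/N (converges to Fisher as N → ∞ at fixed K/N). KS: two-sample
Kolmogorov–Smirnov on the rank positions of term members vs non-members,
asymptotic p-value; rank ties are broken by a stable sort on the glycan
identifier; a one-sample variant against the uniform distribution sits
behind `mode="one-sample"`. Terms whose members are the whole universe or
empty are flagged untestable rather than raising. Multiset queries collapse
to sets (logged). Adjustment is Benjamini–Hochberg by default, Bonferroni
selectable; both via statsmodels.

The enrichment universe must be supplied explicitly; the pipeline defaults
to the set of detected glycans, the natural background for within-section
questions.

Numerical notes: exact-test conservatism means empirical type-I error under
a null simulation sits below the nominal α (≈0.015–0.02 at α = 0.05 for
universe 60, query 15, 2 000 replicates); the asymptotic KS p is likewise
conservative at the universe sizes typical here (tens of glycans), which
the calibration test asserts as an upper bound on the rejection rate, not a
two-sided match to uniformity. Odds ratios use a 0.5 continuity substitute
only when a table cell is zero, for display.

## Regions and co-localization

A region assignment is a many-to-many table of (glycan, composition,
region, optional score). The summary classifies each region's *distinct*
glycans and reports counts and within-region percentages for every type
class, every decoration term, an explicit "complex (no decorations)"
bucket, and exact decoration-set combinations (display names), so both
marginal and combination-level views can be tabulated. Percentages use the
region's distinct-glycan total as denominator; decoration multi-labelling
means decoration counts may legitimately sum past that total, while type
counts always partition it.

Co-localization between a toy ion image and a binary region mask is cosine
similarity of the flattened arrays — a transparent stand-in for the
platform-internal measures used in spatial metabolomics, not a
re-implementation of any of them. A uniform image over a mask covering a
fraction f of pixels scores √f. `assign_regions` assigns a glycan to every
region whose score reaches the threshold (default 0.5; no published cutoff
exists for such tables, so the default is the midpoint and is configurable)
and is monotone in that threshold.

## Synthetic data

The fixture generator emulates the *logical* shape of a region-annotated
glycan table, not the physics of imaging. Compositions are
rejection-sampled uniformly from the H ≤ 12, N ≤ 12, F ≤ 4, S ≤ 4 grid
until per-class quotas (largest-remainder apportionment of the requested
mix) are met; each row carries its intended class, making the generator an
independent oracle for the classifier. The default pipeline mix —
25 % high-mannose, 45 % complex, 15 % hybrid, 15 % pauci-mannose over 60
glycans — mirrors the complex-dominated profile typical of mammalian
tissue glycomes at a detected-glycan count of the order seen in a tissue
section. Toy ion images are sums of the intended regions' masks plus
clipped Gaussian noise on a 20 × 20 grid with four quadrant regions; at
noise 0 the cosine of a k-region sum with a member mask is
√(w/W) ≥ 0.5 for up to four equal-area regions per glycan, so threshold
0.5 recovers intended assignments exactly, and the pipeline assigns each
glycan to 1–2 regions. All randomness flows from the single seed in
`RunConfig`, making runs byte-reproducible.

What passing these fixtures does **not** show: robustness to real spectral
artefacts (isotope overlap, matrix clusters, in-source decay), to
annotation false discovery, or to spatially correlated noise; the toy
images share none of the optics of real ion images beyond masked support.

## Problem sizes

The exhaustive classification check covers the full 4 224-composition
grid. The Fisher-vs-enumeration check covers all 23 400 achievable tables
with N ≤ 25; the EASE domination sweep uses 10 000 random tables with
n, k ≤ 30 and K ≤ N ≤ 60; null calibration uses 2 000 replicates at
universe 60, query 15, term size 20. These sizes give exact (enumeration)
or tight Monte-Carlo answers while keeping the whole suite and the
acceptance script in the tens of seconds.

## Known limitations

* Compositional classes cannot resolve isomers; the ambiguous H6N6 label
  and the bisecting-at-N=H=5 caveat above are irreducible at this level.
* The hybrid predicate is a heuristic, not a community standard.
* Cosine co-localization ignores spatial autocorrelation and intensity
  calibration; scores are comparable within a run, not across instruments.
* imzML ingestion is not implemented; the spatial path works on in-memory
  arrays (NPY/CSV masks) only.
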