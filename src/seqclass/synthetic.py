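"""Synthetic cohorts with planted regulatory structure.

Every generator is deterministic under its seed. Generators draw from
independent ``numpy.random.Generator`` streams spawned from a master seed,
so partial outputs can be pinned in tests.

The generated structure mirrors what the downstream pipeline assumes:

* a small multi-contig genome with motif instances planted at element
  positions,
* per-(cell type, assay) peak profiles covering elements active in that
  cell type — broad peaks for histone assays, narrow for TF/accessibility,
* variants whose probability of being common (AF > threshold) decays
  logistically with the magnitude of their planted regulatory effect,
* tissue expression coupled to enhancer proximity around each TSS,
* prediction matrices with planted cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats import (
    GenomeSequence,
    Interval,
    IntervalSet,
    Profile,
    ProfileCompendium,
    Variant,
)

__all__ = [
    "RegulatoryGrammar",
    "ElementSpec",
    "PlantedElement",
    "SyntheticCohort",
    "random_pwm",
    "gen_genome",
    "gen_profiles",
    "gen_variants",
    "gen_effect_af_pairs",
    "gen_expression",
    "gen_prediction_matrix",
    "default_grammar",
    "generate_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ElementSpec:
    """A kind of regulatory element: which motifs it carries, where it is
    active, and how wide its peaks are."""

    kind: str
    motif_ids: tuple[int, ...]
    active_cell_types: tuple[str, ...]
    half_width: int = 75


@dataclass
class RegulatoryGrammar:
    motifs: list[np.ndarray]  # each 4 x width, column-stochastic
    cell_types: list[str]
    element_specs: list[ElementSpec]

    def __post_init__(self) -> None:
        for i, pwm in enumerate(self.motifs):
            if pwm.shape[0] != 4 or not np.allclose(pwm.sum(axis=0), 1.0):
                raise ValueError(f"motif {i} is not a column-stochastic 4 x w PWM")
        for spec in self.element_specs:
            if any(m >= len(self.motifs) for m in spec.motif_ids):
                raise ValueError(f"element {spec.kind!r} references unknown motif")
            if any(ct not in self.cell_types for ct in spec.active_cell_types):
                raise ValueError(f"element {spec.kind!r} references unknown cell type")


@dataclass(frozen=True)
class PlantedElement:
    """One planted element instance: a motif match centred at ``center``."""

    contig: str
    center: int
    spec_index: int
    kind: str


@dataclass
class SyntheticCohort:
    genome: GenomeSequence
    grammar: RegulatoryGrammar
    elements: list[PlantedElement]
    profiles: ProfileCompendium
    variants: list[Variant] = field(default_factory=list)
    variant_effects: Optional[np.ndarray] = None
    expression: Optional[pd.DataFrame] = None
    tss_table: Optional[pd.DataFrame] = None
    eqtls: Optional[pd.DataFrame] = None


def random_pwm(width: int, rng: np.random.Generator, sharpness: float = 8.0) -> np.ndarray:
    """A column-stochastic PWM with one strongly preferred base per column."""
    pwm = rng.dirichlet(np.full(4, 0.3), size=width).T
    favored = rng.integers(0, 4, size=width)
    pwm[favored, np.arange(width)] += sharpness
    return pwm / pwm.sum(axis=0, keepdims=True)


def consensus(pwm: np.ndarray) -> str:
    return "".join(_BASES[pwm.argmax(axis=0)])


def _sample_motif(pwm: np.ndarray, rng: np.random.Generator) -> str:
    idx = np.array([rng.choice(4, p=pwm[:, j]) for j in range(pwm.shape[1])])
    return "".join(_BASES[idx])


def default_grammar(
    n_cell_types: int = 4,
    seed: int = 0,
    motif_width: int = 8,
    half_width: int = 150,
    sharpness: float = 50.0,
) -> RegulatoryGrammar:
    """One enhancer element kind per cell type, each with its own
    near-consensus motif."""
    rng = np.random.default_rng(seed)
    cell_types = [f"ct{i}" for i in range(n_cell_types)]
    motifs = [random_pwm(motif_width, rng, sharpness=sharpness) for _ in range(n_cell_types)]
    specs = [
        ElementSpec(
            kind=f"enh_{ct}",
            motif_ids=(i,),
            active_cell_types=(ct,),
            half_width=half_width,
        )
        for i, ct in enumerate(cell_types)
    ]
    return RegulatoryGrammar(motifs, cell_types, specs)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def gen_genome(
    n_contigs: int,
    contig_len: int,
    gc: float = 0.5,
    seed: int = 0,
    grammar: Optional[RegulatoryGrammar] = None,
    elements_per_contig: int = 0,
    margin: int = 1000,
) -> tuple[GenomeSequence, list[PlantedElement]]:
    """i.i.d. background sequence with motif instances planted at element
    positions. Returns the genome and the planted-element truth table."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if elements_per_contig and grammar is None:
        raise ValueError("grammar required to plant elements")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs: dict[str, str] = {}
    elements: list[PlantedElement] = []
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        seq = rng.choice(4, size=contig_len, p=probs)
        if elements_per_contig:
            assert grammar is not None
            lo, hi = margin, contig_len - margin
            min_gap = 2 * max(s.half_width for s in grammar.element_specs) + 50
            centers = _spaced_positions(rng, lo, hi, elements_per_contig, min_gap)
            for center in centers:
                si = int(rng.integers(len(grammar.element_specs)))
                spec = grammar.element_specs[si]
                mid = spec.motif_ids[int(rng.integers(len(spec.motif_ids)))]
                motif = _sample_motif(grammar.motifs[mid], rng)
                start = center - len(motif) // 2
                seq[start : start + len(motif)] = [
                    int(np.where(_BASES == b)[0][0]) for b in motif
                ]
                elements.append(PlantedElement(name, int(center), si, spec.kind))
        contigs[name] = "".join(_BASES[seq])
    return GenomeSequence(contigs), elements


def _spaced_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, min_gap: int
) -> np.ndarray:
    """Sample n positions in [lo, hi) at least min_gap apart."""
    span = hi - lo - (n - 1) * min_gap
    if span <= 0:
        raise ValueError("contig too short for requested element count/spacing")
    raw = np.sort(rng.integers(0, span, size=n))
    return lo + raw + min_gap * np.arange(n)


# ---------------------------------------------------------------------------
# Peak profiles
# ---------------------------------------------------------------------------

_HISTONE_HALF = (500, 1000)  # broad marks: 1-2 kb peaks
_NARROW_HALF = (50, 150)  # TF / accessibility: 100-300 bp peaks


def gen_profiles(
    genome: GenomeSequence,
    grammar: RegulatoryGrammar,
    elements: Sequence[PlantedElement],
    n_profiles_per_type: int = 1,
    noise: float = 0.0,
    seed: int = 0,
    assay_classes: Sequence[str] = ("TF", "histone", "accessibility"),
) -> ProfileCompendium:
    """One or more peak profiles per (cell type, assay class).

    Each profile carries a peak over every planted element active in the
    profile's cell type, plus ``Poisson(noise)`` false peaks per contig.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    profiles: list[Profile] = []
    for cell_type in grammar.cell_types:
        for assay in assay_classes:
            for rep in range(n_profiles_per_type):
                half_lo, half_hi = (
                    _HISTONE_HALF if assay == "histone" else _NARROW_HALF
                )
                records: list[Interval] = []
                for elem in elements:
                    spec = grammar.element_specs[elem.spec_index]
                    if cell_type not in spec.active_cell_types:
                        continue
                    half = (
                        int(rng.integers(half_lo, half_hi + 1))
                        if assay == "histone"
                        else spec.half_width
                    )
                    clen = lengths[elem.contig]
                    start = max(0, elem.center - half)
                    end = min(clen, elem.center + half)
                    records.append(Interval(elem.contig, start, end))
                for contig, clen in lengths.items():
                    for _ in range(rng.poisson(noise)):
                        half = int(rng.integers(half_lo, half_hi + 1))
                        center = int(rng.integers(half, clen - half))
                        records.append(Interval(contig, center - half, center + half))
                profiles.append(
                    Profile(
                        profile_id=f"{assay}_{cell_type}_r{rep}",
                        target=f"{assay}_mark",
                        assay_class=assay,
                        cell_type=cell_type,
                        peaks=IntervalSet(records),
                    )
                )
    return ProfileCompendium(profiles)


# ---------------------------------------------------------------------------
# Variants with AF coupled to effect magnitude
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_effect_af_pairs(
    n: int,
    intercept: float,
    slope: float,
    effect_sd: float = 1.0,
    common_threshold: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path used by calibration simulations: signed effects with
    ``P(common) = sigmoid(intercept - slope * |effect|)``.

    ``slope = 0`` is the null model. Returns (effects, allele frequencies).
    """
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, effect_sd, size=n)
    p_common = _sigmoid(intercept - slope * np.abs(effects))
    is_common = rng.random(n) < p_common
    af = np.where(
        is_common,
        np.exp(rng.uniform(np.log(common_threshold), np.log(0.5), size=n)),
        np.exp(rng.uniform(np.log(1e-4), np.log(common_threshold), size=n)),
    )
    # nudge the boundary so "common" is strictly AF > threshold
    af[is_common] = np.maximum(af[is_common], common_threshold * 1.0001)
    af[~is_common] = np.minimum(af[~is_common], common_threshold * 0.9999)
    return effects, af


def gen_variants(
    genome: GenomeSequence,
    elements: Sequence[PlantedElement],
    grammar: Optional[RegulatoryGrammar],
    n: int,
    intercept: float = 0.0,
    slope: float = 0.0,
    effect_sd: float = 1.0,
    common_threshold: float = 0.01,
    seed: int = 0,
) -> tuple[list[Variant], np.ndarray]:
    """Uniformly placed SNVs; those inside planted elements carry a signed
    regulatory effect whose magnitude lowers P(AF > threshold) via the
    logistic AF model. Returns (variants, true effects)."""
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    names = list(lengths)
    sizes = np.array([lengths[c] for c in names], dtype=float)
    contig_idx = rng.choice(len(names), size=n, p=sizes / sizes.sum())

    element_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in names:
        spans = [
            (
                e.center - grammar.element_specs[e.spec_index].half_width,
                e.center + grammar.element_specs[e.spec_index].half_width,
            )
            for e in elements
            if e.contig == contig
        ] if grammar is not None else []
        if spans:
            starts = np.array(sorted(s for s, _ in spans))
            ends = np.array([e for _, e in sorted(spans)])
            element_index[contig] = (starts, ends)

    effects = np.zeros(n)
    variants: list[Variant] = []
    for i in range(n):
        contig = names[contig_idx[i]]
        pos0 = int(rng.integers(0, lengths[contig]))
        ref = genome.base_at(contig, pos0)
        if ref == "N":
            ref = "A"
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        inside = False
        if contig in element_index:
            starts, ends = element_index[contig]
            j = int(np.searchsorted(starts, pos0, side="right")) - 1
            inside = j >= 0 and pos0 < ends[j]
        effect = float(rng.normal(0.0, effect_sd)) if inside else 0.0
        effects[i] = effect
        p_common = float(_sigmoid(intercept - slope * abs(effect)))
        if rng.random() < p_common:
            af = float(
                max(
                    np.exp(rng.uniform(np.log(common_threshold), np.log(0.5))),
                    common_threshold * 1.0001,
                )
            )
        else:
            af = float(
                min(
                    np.exp(rng.uniform(np.log(1e-4), np.log(common_threshold))),
                    common_threshold * 0.9999,
                )
            )
        variants.append(
            Variant(contig=contig, pos=pos0 + 1, ref=ref, alt=alt, af=af, id=f"v{i}")
        )
    return variants, effects


# ---------------------------------------------------------------------------
# Expression with enhancer-proximity structure
# ---------------------------------------------------------------------------


def gen_expression(
    genome: GenomeSequence,
    elements: Sequence[PlantedElement],
    grammar: RegulatoryGrammar,
    n_genes: int,
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    baseline: float = 1.0,
    window: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue expression coupled to enhancer proximity.

    ``log expression = baseline + effect_size * (# of that tissue's
    enhancers within `window` bp of the TSS) + noise``. Tissues are the
    grammar's cell types. Returns (expression gene x tissue, TSS table).
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    names = list(lengths)
    tissues = grammar.cell_types
    gene_contigs = [names[int(rng.integers(len(names)))] for _ in range(n_genes)]
    tss = np.array(
        [int(rng.integers(0, lengths[c])) for c in gene_contigs], dtype=np.int64
    )
    counts = np.zeros((n_genes, len(tissues)))
    for elem in elements:
        spec = grammar.element_specs[elem.spec_index]
        for ti, tissue in enumerate(tissues):
            if tissue not in spec.active_cell_types:
                continue
            for gi in range(n_genes):
                if gene_contigs[gi] == elem.contig and abs(tss[gi] - elem.center) <= window:
                    counts[gi, ti] += 1
    log_expr = baseline + effect_size * counts + rng.normal(0, noise_sd, counts.shape)
    expr = pd.DataFrame(
        np.exp(log_expr),
        index=[f"g{i}" for i in range(n_genes)],
        columns=tissues,
    )
    tss_table = pd.DataFrame(
        {"gene": expr.index, "contig": gene_contigs, "tss": tss}
    )
    return expr, tss_table


# ---------------------------------------------------------------------------
# Prediction matrices with planted clusters
# ---------------------------------------------------------------------------


def gen_prediction_matrix(
    n_points: int,
    n_profiles: int,
    n_clusters: int,
    separation: float,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows are cluster-mean probability vectors plus Gaussian noise,
    clipped into [0, 1]. ``separation`` is the distance between cluster
    means in units of the noise standard deviation. Returns (matrix,
    true labels)."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_clusters, n_profiles))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    means = 0.5 + 0.5 * separation * noise_sd * directions
    labels = rng.integers(0, n_clusters, size=n_points)
    X = means[labels] + rng.normal(0, noise_sd, size=(n_points, n_profiles))
    return np.clip(X, 0.0, 1.0), labels


# ---------------------------------------------------------------------------
# Full cohort convenience
# ---------------------------------------------------------------------------


def generate_cohort(
    n_contigs: int = 3,
    contig_len: int = 50_000,
    elements_per_contig: int = 40,
    n_cell_types: int = 4,
    n_variants: int = 2000,
    n_genes: int = 200,
    noise: float = 0.0,
    af_intercept: float = 0.0,
    af_slope: float = 1.5,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a complete cohort from a master seed, one RNG stream per
    generator (seeds derived with ``SeedSequence.spawn``)."""
    streams = np.random.SeedSequence(seed).spawn(6)
    seeds = [int(s.generate_state(1)[0]) for s in streams]
    grammar = default_grammar(n_cell_types=n_cell_types, seed=seeds[0])
    genome, elements = gen_genome(
        n_contigs,
        contig_len,
        seed=seeds[1],
        grammar=grammar,
        elements_per_contig=elements_per_contig,
    )
    profiles = gen_profiles(genome, grammar, elements, noise=noise, seed=seeds[2])
    variants, effects = gen_variants(
        genome,
        elements,
        grammar,
        n_variants,
        intercept=af_intercept,
        slope=af_slope,
        seed=seeds[3],
    )
    expression, tss_table = gen_expression(
        genome, elements, grammar, n_genes, seed=seeds[4]
    )
    return SyntheticCohort(
        genome=genome,
        grammar=grammar,
        elements=elements,
        profiles=profiles,
        variants=variants,
        variant_effects=effects,
        expression=expression,
        tss_table=tss_table,
    )
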