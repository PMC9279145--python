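"""Class scores, directional variant effects and mutation-class assignment.

A class score is the projection of a prediction vector onto a class's unit
direction vector. A variant's class-level effect is the difference between
the Alt- and Ref-allele scores; positive effects mean increased class
activity. Histone-mark predictions are rescaled before scoring so that
nucleosome-occupancy shifts do not masquerade as mark changes: both
alleles' histone sums are equalized to their common average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chromnet.model import SequenceModel, one_hot
from .formats import GenomeSequence, Variant
from .seqclasses import UNASSIGNED, GenomeAnnotation, SequenceClassModel

__all__ = [
    "class_score",
    "adjust_histone",
    "variant_effect",
    "variant_effects_table",
    "write_effects_vcf",
    "assign_mutation_class",
    "VariantEffectRecord",
]


def class_score(p: np.ndarray, model: SequenceClassModel) -> np.ndarray:
    """Project prediction vector(s) onto each kept class's unit vector.

    Accepts a single length-T vector or an (n, T) matrix; returns scores
    of shape (n_classes,) or (n, n_classes) accordingly.
    """
    p = np.asarray(p)
    t = model.vectors.shape[1]
    if p.shape[-1] != t:
        raise ValueError(
            f"prediction dimension {p.shape[-1]} does not match the "
            f"class model's {t} profiles"
        )
    return p @ model.vectors.T


def adjust_histone(
    p_ref: np.ndarray, p_alt: np.ndarray, histone_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nucleosome-occupancy normalization of histone-mark predictions.

    With S_R and S_A the allele-wise sums over histone profiles, histone
    entries of Ref are scaled by (S_R + S_A) / (2 S_R) and of Alt by
    (S_R + S_A) / (2 S_A); non-histone entries pass through unchanged.
    After adjustment both alleles' histone sums equal (S_R + S_A) / 2.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_alt = np.asarray(p_alt, dtype=float)
    mask = np.asarray(histone_mask, dtype=bool)
    if p_ref.shape != p_alt.shape or mask.shape[0] != p_ref.shape[-1]:
        raise ValueError("shape mismatch between predictions and histone mask")
    if not mask.any():
        return p_ref.copy(), p_alt.copy()
    s_ref = float(p_ref[..., mask].sum())
    s_alt = float(p_alt[..., mask].sum())
    if s_ref == 0.0 or s_alt == 0.0:
        raise ValueError(
            "histone prediction sum is zero for one allele; occupancy "
            "adjustment is undefined (caller may skip adjustment)"
        )
    out_ref, out_alt = p_ref.copy(), p_alt.copy()
    total = s_ref + s_alt
    out_ref[..., mask] *= total / (2.0 * s_ref)
    out_alt[..., mask] *= total / (2.0 * s_alt)
    return out_ref, out_alt


@dataclass
class VariantEffectRecord:
    variant: Variant
    score_ref: np.ndarray  # (n_classes,)
    score_alt: np.ndarray
    delta: np.ndarray  # score_alt - score_ref, exactly
    assigned_class: int = UNASSIGNED
    provenance: str = "unassigned"  # "positional" | "reassigned" | "unassigned"


def _build_allele_windows(
    variant: Variant, genome: GenomeSequence, seq_len: int
) -> tuple[str, str]:
    """Ref and Alt sequences of length ``seq_len`` centred on the variant.

    For indels, the Alt window is re-centred on the substituted allele's
    midpoint and trimmed/padded back to ``seq_len`` with flanking genome
    sequence.
    """
    half = seq_len // 2
    pos0 = variant.pos0
    contig_len = genome.lengths[variant.contig]
    genome_ref = genome.fetch(variant.contig, pos0, pos0 + len(variant.ref))
    if genome_ref != variant.ref:
        raise ValueError(
            f"REF mismatch at {variant.contig}:{variant.pos}: variant says "
            f"{variant.ref!r}, genome has {genome_ref!r}"
        )
    if pos0 - half < 0 or pos0 + half > contig_len:
        raise ValueError(
            f"window of length {seq_len} centred at {variant.contig}:"
            f"{variant.pos} extends outside the contig"
        )
    ref_window = genome.fetch(variant.contig, pos0 - half, pos0 + half)

    # splice the alt allele into a generous context, then recentre
    pad = half + max(len(variant.ref), len(variant.alt))
    ctx_start = max(0, pos0 - pad)
    ctx_end = min(contig_len, pos0 + len(variant.ref) + pad)
    context = genome.fetch(variant.contig, ctx_start, ctx_end)
    offset = pos0 - ctx_start
    alt_context = context[:offset] + variant.alt + context[offset + len(variant.ref) :]
    alt_center = offset + len(variant.alt) // 2
    alt_start = alt_center - half
    alt_window = alt_context[max(0, alt_start) : alt_start + seq_len]
    if len(alt_window) < seq_len:  # near contig edges: pad with N
        left = max(0, -alt_start)
        alt_window = "N" * left + alt_window
        alt_window = alt_window + "N" * (seq_len - len(alt_window))
    return ref_window, alt_window


def variant_effect(
    model: SequenceModel,
    scm: SequenceClassModel,
    variant: Variant,
    genome: GenomeSequence,
    histone_adjust: bool = True,
) -> VariantEffectRecord:
    """Predict both alleles, normalize histone marks, and score.

    ``delta`` is exactly ``score_alt - score_ref`` per class. The record's
    class assignment is left for :func:`assign_mutation_class`.
    """
    seq_len = model.config.seq_len
    ref_seq, alt_seq = _build_allele_windows(variant, genome, seq_len)
    preds = model.predict(one_hot([ref_seq, alt_seq]))
    p_ref, p_alt = preds[0], preds[1]
    if histone_adjust and scm.histone_mask is not None and scm.histone_mask.any():
        p_ref, p_alt = adjust_histone(p_ref, p_alt, scm.histone_mask)
    score_ref = class_score(p_ref, scm)
    score_alt = class_score(p_alt, scm)
    return VariantEffectRecord(
        variant=variant,
        score_ref=score_ref,
        score_alt=score_alt,
        delta=score_alt - score_ref,
    )


def assign_mutation_class(
    record: VariantEffectRecord,
    annotation: GenomeAnnotation,
    abs_gap: float = 1.0,
    fold_gap: float = 2.5,
    exclude: Optional[Sequence[int]] = None,
) -> VariantEffectRecord:
    """Positional class assignment with effect-based reassignment.

    The variant starts in the class annotated at its position. It is
    reassigned to the class with the largest absolute effect iff that
    class differs from the positional one and BOTH
    ``|delta_best| - |delta_orig| > abs_gap`` and
    ``|delta_best| / |delta_orig| > fold_gap`` hold (a zero original
    effect makes the ratio infinite, satisfying the fold condition).
    Classes in ``exclude`` (e.g. low-interpretability ones) are never
    reassignment candidates. Applying the rule twice is idempotent.
    """
    excluded = set(exclude) if exclude is not None else set()
    positional = annotation.class_at(record.variant.contig, record.variant.pos0)
    abs_delta = np.abs(record.delta)
    candidates = [
        i for i in range(len(abs_delta)) if i not in excluded
    ]
    record.assigned_class = positional
    record.provenance = "positional" if positional != UNASSIGNED else "unassigned"
    if not candidates:
        return record
    best = max(candidates, key=lambda i: (abs_delta[i], -i))
    if best == positional:
        return record
    d_orig = float(abs_delta[positional]) if positional != UNASSIGNED else 0.0
    d_best = float(abs_delta[best])
    gap_ok = d_best - d_orig > abs_gap
    fold_ok = d_orig == 0.0 or d_best / d_orig > fold_gap
    if gap_ok and fold_ok:
        record.assigned_class = best
        record.provenance = "reassigned"
    return record


def write_effects_vcf(
    records: Sequence[VariantEffectRecord],
    scm: SequenceClassModel,
    path: str,
    contig_lengths: Optional[dict] = None,
) -> None:
    """Write variant effects as VCF INFO annotations: one ``SCD_<class>``
    field per kept class plus the assigned class and provenance."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for rank in range(scm.n_classes):
            name = scm.class_name(rank)
            handle.write(
                f'##INFO=<ID=SCD_{name},Number=1,Type=Float,'
                f'Description="Class-level effect (Alt - Ref) for {name}">\n'
            )
        handle.write(
            '##INFO=<ID=SC,Number=1,Type=String,Description="Assigned sequence class">\n'
        )
        handle.write(
            '##INFO=<ID=SCPROV,Number=1,Type=String,Description="Assignment provenance">\n'
        )
        if contig_lengths:
            for name, length in contig_lengths.items():
                handle.write(f"##contig=<ID={name},length={length}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            v = rec.variant
            info = ";".join(
                [f"SCD_{scm.class_name(r)}={rec.delta[r]:.6g}" for r in range(scm.n_classes)]
                + [f"SC={scm.class_name(rec.assigned_class)}", f"SCPROV={rec.provenance}"]
            )
            handle.write(
                f"{v.contig}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )


def variant_effects_table(
    records: Sequence[VariantEffectRecord], scm: SequenceClassModel
) -> pd.DataFrame:
    """Flatten effect records into a TSV-ready frame: one delta column per
    class plus the assignment."""
    rows = []
    for rec in records:
        row = {
            "variant_id": rec.variant.id or rec.variant.key,
            "contig": rec.variant.contig,
            "pos": rec.variant.pos,
            "ref": rec.variant.ref,
            "alt": rec.variant.alt,
        }
        for rank in range(scm.n_classes):
            row[f"delta_{scm.class_name(rank)}"] = rec.delta[rank]
        row["assigned_class"] = scm.class_name(rec.assigned_class)
        row["provenance"] = rec.provenance
        rows.append(row)
    return pd.DataFrame(rows)
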