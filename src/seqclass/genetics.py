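"""Downstream population-genetics statistics over sequence classes.

Covers: log fold-change enrichment of interval annotations per class
(Fisher exact + Benjamini-Hochberg), class-coverage vs tissue-expression
correlations, variant-effect vs eQTL-slope correlations, the six-bin
variant-effect layout, per-sign logistic-regression constraint z-scores
combined with Stouffer's method, and the plumbing around external
LD-score-regression runs (annotation export and conservative
heritability post-processing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact, norm, spearmanr
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .formats import IntervalSet, Variant
from .scoring import VariantEffectRecord
from .seqclasses import UNASSIGNED, GenomeAnnotation

__all__ = [
    "logfc_enrichment",
    "expression_correlation",
    "eqtl_correlation",
    "bin_effects",
    "constraint_zscore",
    "constraint_analysis",
    "export_ldsc_annot",
    "conservative_h2",
    "ConstraintResult",
]


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def logfc_enrichment(
    annotation: GenomeAnnotation,
    features: Mapping[str, IntervalSet],
    n_classes: int,
    top_n: int = 25,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-(class, feature) log fold-change enrichment with Fisher tests.

    The background is every bin assigned to any class. For each class the
    proportion of its bins whose centre lies in the feature is compared
    against the background proportion; the two-sided Fisher exact p comes
    from the 2x2 count table (class vs rest of background). q-values are
    Benjamini-Hochberg-adjusted across features within each class, and
    ``selected`` flags the top ``top_n`` features by logFC among those
    with q below ``q_max``.
    """
    class_in_feat = {name: np.zeros(n_classes, dtype=np.int64) for name in features}
    class_total = np.zeros(n_classes, dtype=np.int64)
    for contig, (starts, ranks) in annotation.bins.items():
        assigned = ranks != UNASSIGNED
        centers = starts[assigned] + annotation.bin_size // 2
        kept_ranks = ranks[assigned]
        for rank in range(n_classes):
            class_total[rank] += int((kept_ranks == rank).sum())
        for name, feat in features.items():
            hits = feat.contains_many(contig, centers)
            for rank in range(n_classes):
                class_in_feat[name][rank] += int(hits[kept_ranks == rank].sum())

    total = int(class_total.sum())
    rows = []
    for rank in range(n_classes):
        n_class = int(class_total[rank])
        if n_class == 0:
            warnings.warn(f"class rank {rank} has zero annotated bins; skipped")
            continue
        for name in features:
            a = int(class_in_feat[name][rank])  # class bins in feature
            feat_total = int(sum(class_in_feat[name]))
            b = n_class - a
            c = feat_total - a  # other assigned bins in feature
            d = (total - n_class) - c
            prop_class = a / n_class
            prop_bg = feat_total / total
            with np.errstate(divide="ignore"):
                logfc = (
                    np.log(prop_class / prop_bg) if prop_bg > 0 else np.nan
                )
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "class_rank": rank,
                    "feature": name,
                    "n_class_in_feature": a,
                    "n_class": n_class,
                    "n_background_in_feature": feat_total,
                    "n_background": total,
                    "logfc": logfc,
                    "p": float(p),
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["q"] = np.nan
    frame["selected"] = False
    for rank, sub in frame.groupby("class_rank"):
        q = multipletests(sub["p"].to_numpy(), method="fdr_bh")[1]
        frame.loc[sub.index, "q"] = q
        eligible = sub.index[q < q_max]
        top = (
            frame.loc[eligible]
            .sort_values("logfc", ascending=False)
            .head(top_n)
            .index
        )
        frame.loc[top, "selected"] = True
    return frame


# ---------------------------------------------------------------------------
# Expression correlation
# ---------------------------------------------------------------------------


def expression_correlation(
    annotation: GenomeAnnotation,
    tss_table: pd.DataFrame,
    expression: pd.DataFrame,
    n_classes: int,
    window: int = 10_000,
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Spearman correlation between per-gene class coverage near the TSS
    and tissue-relative log expression.

    Expression is transformed to ``log(x + pseudocount)`` and the per-gene
    mean across tissues is subtracted, so each value is a log fold change
    over the tissue average. Coverage is the fraction of annotation bins
    in ``[TSS - window, TSS + window]`` assigned to the class. Pairs with
    constant coverage across genes are reported as NaN.
    """
    log_expr = np.log(expression + pseudocount)
    rel_expr = log_expr.sub(log_expr.mean(axis=1), axis=0)

    genes = tss_table["gene"].tolist()
    coverage = np.zeros((len(genes), n_classes))
    for gi, row in enumerate(tss_table.itertuples()):
        contig = str(row.contig)
        tss = int(row.tss)
        if contig not in annotation.bins:
            continue
        starts, ranks = annotation.bins[contig]
        lo = np.searchsorted(starts, tss - window - annotation.bin_size + 1, side="left")
        hi = np.searchsorted(starts, tss + window, side="right")
        local = ranks[lo:hi]
        if len(local) == 0:
            continue
        for rank in range(n_classes):
            coverage[gi, rank] = (local == rank).sum() / len(local)

    rel_expr = rel_expr.loc[genes]
    rows = []
    for rank in range(n_classes):
        cov = coverage[:, rank]
        for tissue in expression.columns:
            if np.all(cov == cov[0]):
                rho = np.nan
            else:
                rho = float(spearmanr(cov, rel_expr[tissue].to_numpy()).statistic)
            rows.append({"class_rank": rank, "tissue": tissue, "rho": rho})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eQTL correlation
# ---------------------------------------------------------------------------


def eqtl_correlation(
    effects: Sequence[VariantEffectRecord],
    eqtl_slopes: Mapping[str, float],
    top_n: int = 15_000,
    exclude_classes: Optional[Sequence[int]] = None,
    min_variants: int = 10,
) -> pd.DataFrame:
    """Per-class Spearman correlation between predicted class-level variant
    effects and eQTL slopes.

    For each class, the ``top_n`` matched variants ranked by absolute
    predicted effect are selected and the signed effects correlated with
    the slopes. p-values are two-sided; q is Benjamini-Hochberg-adjusted
    across classes. Classes in ``exclude_classes`` or with fewer than
    ``min_variants`` matched variants are skipped.
    """
    excluded = set(exclude_classes) if exclude_classes is not None else set()
    matched = [
        (rec, eqtl_slopes[rec.variant.key])
        for rec in effects
        if rec.variant.key in eqtl_slopes
    ]
    if not matched:
        return pd.DataFrame(columns=["class_rank", "n", "rho", "p", "q"])
    n_classes = len(matched[0][0].delta)
    deltas = np.array([rec.delta for rec, _ in matched])
    slopes = np.array([s for _, s in matched])

    rows = []
    for rank in range(n_classes):
        if rank in excluded:
            continue
        d = deltas[:, rank]
        if len(d) < min_variants:
            warnings.warn(f"class rank {rank}: fewer than {min_variants} matched variants; skipped")
            continue
        k = min(top_n, len(d))
        if top_n > len(d):
            warnings.warn(
                f"class rank {rank}: top_n={top_n} exceeds {len(d)} available "
                "variants; using all"
            )
        idx = np.argsort(-np.abs(d), kind="stable")[:k]
        res = spearmanr(d[idx], slopes[idx])
        rows.append(
            {
                "class_rank": rank,
                "n": int(k),
                "rho": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    return frame


# ---------------------------------------------------------------------------
# Effect binning and constraint z-scores
# ---------------------------------------------------------------------------


def bin_effects(deltas: np.ndarray) -> np.ndarray:
    """Assign signed effects to six bins: +/-3 (top 1% of the arm by
    magnitude), +/-2 (top 1-10%), +/-1 (remaining 90%).

    Quantile cut points are computed within each sign arm separately;
    exact zeros go to the positive arm's +1 bin.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("deltas are empty")
    if np.all(deltas == 0):
        warnings.warn("all effects are zero; every variant lands in bin +1")
        return np.ones(len(deltas), dtype=np.int64)
    out = np.zeros(len(deltas), dtype=np.int64)
    for sign, arm in ((1, deltas >= 0), (-1, deltas < 0)):
        idx = np.flatnonzero(arm)
        if idx.size == 0:
            continue
        mags = np.abs(deltas[idx])
        # stable descending rank: 0 is the strongest effect in the arm
        order = np.argsort(-mags, kind="stable")
        ranks = np.empty(idx.size, dtype=np.int64)
        ranks[order] = np.arange(idx.size)
        n = idx.size
        n_top1 = int(np.ceil(0.01 * n))
        n_top10 = int(np.ceil(0.10 * n))
        bins = np.full(n, 1, dtype=np.int64)
        bins[ranks < n_top10] = 2
        bins[ranks < n_top1] = 3
        out[idx] = sign * bins
    return out


@dataclass
class ConstraintResult:
    z_pos: float  # Wald z of |effect| in the positive arm's logistic fit
    z_neg: float
    z: float  # -(z_pos + z_neg) / sqrt(2), NaN when either arm failed
    bin_stats: pd.DataFrame  # per-bin common-variant frequency +/- s.e.
    n_pos: int
    n_neg: int
    note: str = ""


def _logistic_wald_z(x: np.ndarray, y: np.ndarray) -> float:
    """Wald z of the slope in logit(P(y=1)) = a + b x, by IRLS MLE."""
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise PerfectSeparationError(str(exc))
    return float(fit.params[1] / fit.bse[1])


def constraint_zscore(
    deltas: np.ndarray,
    af: np.ndarray,
    common_threshold: float = 0.01,
) -> ConstraintResult:
    """Bidirectional constraint statistic for one class.

    Fits ``is_common ~ intercept + |delta|`` by logistic regression
    separately for positive- and negative-effect variants, takes the Wald
    z of each slope, and combines them as ``-(z_pos + z_neg) / sqrt(2)``
    (unweighted Stouffer, negated so depletion of common variants at
    large effects gives positive constraint). Also reports per-bin
    common-variant frequencies with binomial standard errors. A perfectly
    separated arm is flagged and yields a missing combined z.
    """
    deltas = np.asarray(deltas, dtype=float)
    af = np.asarray(af, dtype=float)
    if deltas.shape != af.shape:
        raise ValueError("deltas and af must align")
    is_common = (af > common_threshold).astype(float)

    bins = bin_effects(deltas)
    bin_rows = []
    for b in (3, 2, 1, -1, -2, -3):
        sel = bins == b
        n = int(sel.sum())
        if n == 0:
            continue
        freq = float(is_common[sel].mean())
        se = float(np.sqrt(freq * (1 - freq) / n))
        bin_rows.append({"bin": b, "n": n, "common_freq": freq, "se": se})
    bin_stats = pd.DataFrame(bin_rows)

    zs = {}
    notes = []
    for name, arm in (("pos", deltas >= 0), ("neg", deltas < 0)):
        x = np.abs(deltas[arm])
        y = is_common[arm]
        if len(np.unique(y)) < 2:
            zs[name] = np.nan
            notes.append(f"{name} arm lacks both common and rare variants")
            continue
        try:
            zs[name] = _logistic_wald_z(x, y)
        except PerfectSeparationError:
            zs[name] = np.nan
            notes.append(f"perfect separation in {name} arm")
    z_pos, z_neg = zs["pos"], zs["neg"]
    combined = (
        -(z_pos + z_neg) / np.sqrt(2.0)
        if np.isfinite(z_pos) and np.isfinite(z_neg)
        else np.nan
    )
    return ConstraintResult(
        z_pos=z_pos,
        z_neg=z_neg,
        z=combined,
        bin_stats=bin_stats,
        n_pos=int((deltas >= 0).sum()),
        n_neg=int((deltas < 0).sum()),
        note="; ".join(notes),
    )


def constraint_analysis(
    per_class: Mapping[Union[int, str], tuple[np.ndarray, np.ndarray]],
    common_threshold: float = 0.01,
) -> pd.DataFrame:
    """Constraint z-scores for several classes with BH correction across
    classes. ``per_class`` maps class id -> (deltas, af)."""
    rows = []
    for cid, (deltas, af) in per_class.items():
        res = constraint_zscore(deltas, af, common_threshold=common_threshold)
        rows.append(
            {
                "class": cid,
                "z_pos": res.z_pos,
                "z_neg": res.z_neg,
                "z": res.z,
                "note": res.note,
            }
        )
    frame = pd.DataFrame(rows)
    ok = frame["z"].notna()
    frame["p"] = np.nan
    frame["q"] = np.nan
    # two-sided p from the combined z
    frame.loc[ok, "p"] = 2.0 * norm.sf(np.abs(frame.loc[ok, "z"]))
    if ok.any():
        frame.loc[ok, "q"] = multipletests(
            frame.loc[ok, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return frame


# ---------------------------------------------------------------------------
# Heritability-partitioning support
# ---------------------------------------------------------------------------


def export_ldsc_annot(
    annotation: GenomeAnnotation,
    variants: Sequence[Variant],
    class_names: Sequence[str],
) -> pd.DataFrame:
    """Per-variant 0/1 class indicators plus an all-ones base column, in
    .annot layout (CHR, BP, SNP, CM, then annotation columns).

    Classes partition the genome, so class-column row sums are 0 (variant
    outside any class) or 1. The number of unpartitioned variants is
    attached as ``frame.attrs['n_unassigned']``.
    """
    rows = []
    n_unassigned = 0
    for v in variants:
        rank = annotation.class_at(v.contig, v.pos0)
        indicators = [0] * len(class_names)
        if rank == UNASSIGNED:
            n_unassigned += 1
        else:
            indicators[rank] = 1
        rows.append(
            [v.contig, v.pos, v.id or v.key, 0.0, 1] + indicators
        )
    frame = pd.DataFrame(
        rows, columns=["CHR", "BP", "SNP", "CM", "base"] + list(class_names)
    )
    frame.attrs["n_unassigned"] = n_unassigned
    return frame


def conservative_h2(estimate: float, se: float) -> float:
    """Conservative heritability proportion: max(0, estimate - se)."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    return max(0.0, estimate - se)
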