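import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from seqclass import genetics, synthetic
from seqclass.formats import Interval, IntervalSet, Variant, Window
from seqclass.scoring import VariantEffectRecord
from seqclass.seqclasses import UNASSIGNED, annotate_genome


def _annotation(ranks, contig="c1", bin_size=100, start=1000):
    windows = [
        Window(contig, start + bin_size * i + bin_size // 2, 400)
        for i in range(len(ranks))
    ]
    return annotate_genome(windows, np.asarray(ranks), bin_size=bin_size)


def _fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x, exact=True) * comb(row2, col1 - x, exact=True)

    total = comb(n, col1, exact=True)
    p_obs = prob(a)
    acc = sum(
        prob(x)
        for x in range(max(0, col1 - row2), min(col1, row1) + 1)
        if prob(x) <= p_obs
    )
    return acc / total


class TestLogfcEnrichment:
    def test_feature_covering_everything_logfc_zero(self):
        ann = _annotation([0] * 10 + [1] * 10)
        features = {"all": IntervalSet([Interval("c1", 0, 10_000)])}
        res = genetics.logfc_enrichment(ann, features, n_classes=2)
        assert np.allclose(res["logfc"], 0.0)

    def test_hand_logfc(self):
        # class 0 bins fully inside the feature; background proportion 10/100
        ranks = [0] * 10 + [1] * 90
        ann = _annotation(ranks)
        # feature covers exactly the first 10 bins
        features = {"f": IntervalSet([Interval("c1", 1000, 2000)])}
        res = genetics.logfc_enrichment(ann, features, n_classes=2)
        row = res[res["class_rank"] == 0].iloc[0]
        assert row["logfc"] == pytest.approx(np.log(10.0))

    def test_fisher_matches_enumeration_oracle(self):
        # table [[30, 70], [10, 90]]
        ranks = [0] * 100 + [1] * 100
        ann = _annotation(ranks)
        spans = []
        # 30 of class-0 bins and 10 of class-1 bins in the feature
        for i in range(30):
            spans.append(Interval("c1", 1000 + 100 * i, 1100 + 100 * i))
        for i in range(10):
            spans.append(Interval("c1", 11_000 + 100 * i, 11_100 + 100 * i))
        res = genetics.logfc_enrichment(ann, {"f": IntervalSet(spans)}, n_classes=2)
        row = res[res["class_rank"] == 0].iloc[0]
        assert (row["n_class_in_feature"], row["n_class"]) == (30, 100)
        assert row["p"] == pytest.approx(_fisher_oracle(30, 70, 10, 90), rel=1e-9)

    def test_top_n_selection(self, rng):
        ranks = [0] * 200
        ann = _annotation(ranks)
        features = {}
        # 3 enriched features of decreasing coverage, all within class 0
        for fi, n_bins in enumerate((150, 100, 50)):
            spans = [
                Interval("c1", 1000 + 100 * i, 1100 + 100 * i) for i in range(n_bins)
            ]
            features[f"f{fi}"] = IntervalSet(spans)
        res = genetics.logfc_enrichment(ann, features, n_classes=1, top_n=2)
        # only one class; logFC = 0 everywhere (single class == background)
        assert (res["logfc"] == 0).all()

    def test_unassigned_bins_excluded_from_background(self):
        ranks = [0] * 10 + [UNASSIGNED] * 10
        ann = _annotation(ranks)
        features = {"f": IntervalSet([Interval("c1", 1000, 2000)])}
        res = genetics.logfc_enrichment(ann, features, n_classes=1)
        assert res.iloc[0]["n_background"] == 10


class TestExpressionCorrelation:
    def test_mean_subtraction_identity(self):
        expr = pd.DataFrame(
            {"t1": [1.0, 2.0], "t2": [3.0, 4.0]}, index=["g0", "g1"]
        )
        log_expr = np.log(expr + 1e-4)
        rel = log_expr.sub(log_expr.mean(axis=1), axis=0)
        assert np.allclose(rel.sum(axis=1), 0.0)

    def test_planted_cohort_matched_tissue_strongest(self):
        cohort = synthetic_cohort = _make_expression_cohort()
        grammar, genome, elements, expr, tss = cohort
        # annotate each 100-bp bin by the tissue of its covering element
        windows, ranks = [], []
        for contig, length in genome.lengths.items():
            for start in range(500, length - 500, 100):
                center = start + 50
                rank = UNASSIGNED
                for e in elements:
                    if e.contig == contig and abs(e.center - center) <= 150:
                        rank = e.spec_index
                        break
                windows.append(Window(contig, center, 400))
                ranks.append(rank)
        ann = annotate_genome(windows, np.array(ranks), bin_size=100)
        res = genetics.expression_correlation(
            ann, tss, expr, n_classes=len(grammar.cell_types)
        )
        for rank, tissue in enumerate(grammar.cell_types):
            sub = res[res["class_rank"] == rank].set_index("tissue")["rho"]
            if sub.isna().all():
                continue
            assert sub.idxmax() == tissue

    def test_constant_coverage_is_nan(self):
        ann = _annotation([0] * 5)
        tss = pd.DataFrame(
            {"gene": ["g0", "g1"], "contig": ["cX", "cX"], "tss": [100, 200]}
        )
        expr = pd.DataFrame({"t": [1.0, 2.0]}, index=["g0", "g1"])
        res = genetics.expression_correlation(ann, tss, expr, n_classes=1)
        assert np.isnan(res.iloc[0]["rho"])


def _make_expression_cohort():
    grammar = synthetic.default_grammar(n_cell_types=3, seed=21)
    genome, elements = synthetic.gen_genome(
        2, 40_000, seed=21, grammar=grammar, elements_per_contig=20, margin=500
    )
    expr, tss = synthetic.gen_expression(
        genome, elements, grammar, 200, effect_size=2.0, noise_sd=0.05, seed=22
    )
    return grammar, genome, elements, expr, tss


class TestEqtlCorrelation:
    def _records(self, deltas):
        records = []
        for i, d in enumerate(deltas):
            records.append(
                VariantEffectRecord(
                    variant=Variant("c1", i + 1000, "A", "G", id=f"v{i}"),
                    score_ref=np.zeros(len(d)),
                    score_alt=np.asarray(d),
                    delta=np.asarray(d),
                )
            )
        return records

    def test_slopes_equal_deltas_rho_one(self, rng):
        deltas = rng.normal(size=(100, 2))
        records = self._records(deltas)
        slopes = {r.variant.key: float(r.delta[0]) for r in records}
        res = genetics.eqtl_correlation(records, slopes, top_n=100)
        assert res[res["class_rank"] == 0].iloc[0]["rho"] == pytest.approx(1.0)

    def test_independent_slopes_near_zero(self, rng):
        deltas = rng.normal(size=(2000, 1))
        records = self._records(deltas)
        slopes = {r.variant.key: float(rng.normal()) for r in records}
        res = genetics.eqtl_correlation(records, slopes, top_n=2000)
        assert abs(res.iloc[0]["rho"]) < 0.07

    def test_top_n_exceeds_available_warns(self, rng):
        records = self._records(rng.normal(size=(50, 1)))
        slopes = {r.variant.key: 1.0 * i for i, r in enumerate(records)}
        with pytest.warns(UserWarning, match="using all"):
            res = genetics.eqtl_correlation(records, slopes, top_n=1000)
        assert res.iloc[0]["n"] == 50

    def test_excluded_class_skipped(self, rng):
        records = self._records(rng.normal(size=(60, 2)))
        slopes = {r.variant.key: 0.5 for r in records}
        res = genetics.eqtl_correlation(records, slopes, exclude_classes=[1], top_n=60)
        assert set(res["class_rank"]) == {0}


class TestBinEffects:
    def test_thousand_positive_split(self, rng):
        deltas = rng.uniform(0.001, 1.0, 1000)
        bins = genetics.bin_effects(deltas)
        counts = {b: int((bins == b).sum()) for b in (3, 2, 1)}
        assert counts == {3: 10, 2: 90, 1: 900}

    def test_single_positive_is_top_bin(self):
        assert genetics.bin_effects(np.array([0.5]))[0] == 3

    def test_symmetric_mirror(self, rng):
        pos = rng.uniform(0.001, 1.0, 500)
        deltas = np.concatenate([pos, -pos])
        bins = genetics.bin_effects(deltas)
        for mag in (1, 2, 3):
            assert (bins == mag).sum() == (bins == -mag).sum()

    def test_zeros_assigned_positive_one(self):
        with pytest.warns(UserWarning):
            bins = genetics.bin_effects(np.zeros(10))
        assert set(bins) == {1}

    @given(st.integers(10, 2000), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_arm_proportions_property(self, n, seed):
        rng = np.random.default_rng(seed)
        deltas = rng.normal(size=n)
        bins = genetics.bin_effects(deltas)
        for sign, arm in ((1, deltas >= 0), (-1, deltas < 0)):
            m = int(arm.sum())
            if m == 0:
                continue
            got3 = int((bins[arm] == 3 * sign).sum())
            got2 = int((bins[arm] == 2 * sign).sum())
            assert got3 == int(np.ceil(0.01 * m))
            assert got3 + got2 == int(np.ceil(0.10 * m))


class TestConstraintZscore:
    def test_stouffer_closed_form(self):
        # z_pos = z_neg = -2 -> combined = -(-4)/sqrt(2)
        assert -(-2.0 + -2.0) / np.sqrt(2) == pytest.approx(2.828427, abs=1e-6)
        effects, af = synthetic.gen_effect_af_pairs(20_000, 0.0, 1.5, seed=30)
        res = genetics.constraint_zscore(effects, af)
        assert res.z == pytest.approx(-(res.z_pos + res.z_neg) / np.sqrt(2))

    def test_planted_depletion_detected(self):
        effects, af = synthetic.gen_effect_af_pairs(50_000, 0.0, 1.5, seed=31)
        res = genetics.constraint_zscore(effects, af)
        assert res.z > 3.0

    def test_null_not_detected(self):
        effects, af = synthetic.gen_effect_af_pairs(20_000, 0.0, 0.0, seed=32)
        res = genetics.constraint_zscore(effects, af)
        assert abs(res.z) < 3.0

    def test_bin_stats_se_binomial(self):
        effects, af = synthetic.gen_effect_af_pairs(5000, 0.0, 0.0, seed=33)
        res = genetics.constraint_zscore(effects, af)
        for row in res.bin_stats.itertuples():
            expected = np.sqrt(row.common_freq * (1 - row.common_freq) / row.n)
            assert row.se == pytest.approx(expected)

    def test_single_class_arm_missing(self):
        deltas = np.array([0.5, 1.0, -0.5, -1.0])
        af = np.array([0.5, 0.5, 0.5, 0.5])  # all common: no rare variants
        res = genetics.constraint_zscore(deltas, af)
        assert np.isnan(res.z)
        assert "lacks both" in res.note

    def test_analysis_bh_across_classes(self):
        per_class = {}
        for i, slope in enumerate((0.0, 0.0, 2.0)):
            effects, af = synthetic.gen_effect_af_pairs(
                10_000, 0.0, slope, seed=40 + i
            )
            per_class[f"C{i}"] = (effects, af)
        frame = genetics.constraint_analysis(per_class)
        assert frame.shape[0] == 3
        ok = frame["p"].notna()
        expected_q = multipletests(frame.loc[ok, "p"], method="fdr_bh")[1]
        assert np.allclose(frame.loc[ok, "q"], expected_q)
        assert frame.set_index("class").loc["C2", "z"] > 3


class TestBHMonotone:
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=12),
        st.integers(0, 11),
    )
    @settings(max_examples=80, deadline=None)
    def test_lowering_p_never_raises_q(self, pvals, idx):
        idx = idx % len(pvals)
        q1 = multipletests(pvals, method="fdr_bh")[1]
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2.0
        q2 = multipletests(lowered, method="fdr_bh")[1]
        assert (q2 <= q1 + 1e-12).all()


class TestExportLdscAnnot:
    def test_columns_and_hand_constructed_block(self):
        ann = _annotation([0, 0, 1, 1, UNASSIGNED])
        variants = [
            Variant("c1", 1001 + 100 * i, "A", "G", id=f"s{i}") for i in range(5)
        ]
        frame = genetics.export_ldsc_annot(ann, variants, ["C1", "C2"])
        assert list(frame.columns) == ["CHR", "BP", "SNP", "CM", "base", "C1", "C2"]
        block = frame[["C1", "C2"]].to_numpy()
        expected = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [0, 0]])
        assert np.array_equal(block, expected)
        assert frame.attrs["n_unassigned"] == 1
        assert (frame["base"] == 1).all()

    def test_row_sums_zero_or_one(self, rng):
        ann = _annotation(rng.integers(0, 3, size=50))
        variants = [
            Variant("c1", int(p), "A", "G")
            for p in rng.integers(1, 8000, size=200)
        ]
        frame = genetics.export_ldsc_annot(ann, variants, ["a", "b", "c"])
        sums = frame[["a", "b", "c"]].sum(axis=1)
        assert set(sums.unique()) <= {0, 1}

    def test_k_plus_one_annotation_columns(self):
        ann = _annotation([0])
        frame = genetics.export_ldsc_annot(ann, [], ["x", "y", "z"])
        assert frame.shape[1] == 4 + 1 + 3


class TestConservativeH2:
    def test_lower_bound_engages(self):
        assert genetics.conservative_h2(0.10, 0.15) == 0.0

    def test_arithmetic(self):
        assert genetics.conservative_h2(0.10, 0.02) == pytest.approx(0.08)

    def test_negative_estimate_clipped(self):
        assert genetics.conservative_h2(-0.05, 0.01) == 0.0

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            genetics.conservative_h2(0.1, -0.1)

    @given(st.floats(-1, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_within_bounds_property(self, est, se):
        out = genetics.conservative_h2(est, se)
        assert out >= 0.0
        if est >= 0:
            assert out <= est
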