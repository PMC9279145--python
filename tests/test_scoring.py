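import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqclass.formats import GenomeSequence, Variant, Window
from seqclass.scoring import (
    VariantEffectRecord,
    adjust_histone,
    assign_mutation_class,
    class_score,
    variant_effect,
)
from seqclass.seqclasses import (
    UNASSIGNED,
    ClassSelection,
    ReductionModel,
    SequenceClassModel,
    annotate_genome,
)


def _make_scm(vectors: np.ndarray, histone_mask=None) -> SequenceClassModel:
    n_classes, t = vectors.shape
    return SequenceClassModel(
        reduction=ReductionModel(
            components=np.eye(t)[:1], mean=np.zeros(t), scales=np.ones(1)
        ),
        labels=np.arange(n_classes),
        selection=ClassSelection(
            kept_cluster_ids=list(range(n_classes)),
            sizes=[1] * n_classes,
            rank_of_cluster={i: i for i in range(n_classes)},
        ),
        vectors=vectors,
        histone_mask=histone_mask,
    )


class TestClassScore:
    def test_self_projection(self):
        v = np.array([[0.6, 0.8]])
        scm = _make_scm(v)
        assert class_score(v[0], scm)[0] == pytest.approx(1.0)

    def test_orthogonal(self):
        scm = _make_scm(np.array([[1.0, 0.0]]))
        assert class_score(np.array([0.0, 0.7]), scm)[0] == 0.0

    def test_linearity(self, rng):
        scm = _make_scm(rng.random((3, 6)))
        p = rng.random(6)
        assert np.allclose(class_score(0.5 * p, scm), 0.5 * class_score(p, scm))

    def test_matrix_input(self, rng):
        scm = _make_scm(rng.random((3, 6)))
        p = rng.random((10, 6))
        scores = class_score(p, scm)
        assert scores.shape == (10, 3)
        assert np.allclose(scores[2], class_score(p[2], scm))

    def test_dimension_mismatch(self):
        scm = _make_scm(np.ones((1, 4)) / 2.0)
        with pytest.raises(ValueError):
            class_score(np.ones(3), scm)

    def test_unnormalized_mean_scores_its_norm(self, rng):
        # score of the class's raw mean vector against its own unit vector
        mean = rng.random(5)
        scm = _make_scm((mean / np.linalg.norm(mean))[None, :])
        assert class_score(mean, scm)[0] == pytest.approx(np.linalg.norm(mean))


class TestAdjustHistone:
    def test_equal_alleles_unchanged(self, rng):
        p = rng.random(6)
        mask = np.array([True, True, False, False, True, False])
        out_ref, out_alt = adjust_histone(p, p, mask)
        assert np.allclose(out_ref, p) and np.allclose(out_alt, p)

    def test_hand_arithmetic(self):
        # histone sums S_R=2, S_A=4 -> ref scaled 6/4=1.5, alt 6/8=0.75
        mask = np.array([True, True, False])
        p_ref = np.array([0.5, 1.5, 0.2])
        p_alt = np.array([3.0, 1.0, 0.9])
        out_ref, out_alt = adjust_histone(p_ref, p_alt, mask)
        assert np.allclose(out_ref[:2], [0.75, 2.25])
        assert np.allclose(out_alt[:2], [2.25, 0.75])
        assert out_ref[2] == 0.2 and out_alt[2] == 0.9  # non-histone untouched
        assert out_ref[:2].sum() == pytest.approx(3.0)
        assert out_alt[:2].sum() == pytest.approx(3.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        t = 8
        mask = np.zeros(t, dtype=bool)
        mask[rng.choice(t, size=3, replace=False)] = True
        p_ref = rng.uniform(0.01, 1.0, t)
        p_alt = rng.uniform(0.01, 1.0, t)
        out_ref, out_alt = adjust_histone(p_ref, p_alt, mask)
        expected = (p_ref[mask].sum() + p_alt[mask].sum()) / 2.0
        assert out_ref[mask].sum() == pytest.approx(expected, abs=1e-9)
        assert out_alt[mask].sum() == pytest.approx(expected, abs=1e-9)
        assert np.array_equal(out_ref[~mask], p_ref[~mask])

    def test_zero_histone_sum_errors(self):
        mask = np.array([True, False])
        with pytest.raises(ValueError):
            adjust_histone(np.array([0.0, 0.5]), np.array([0.3, 0.5]), mask)

    def test_empty_mask_passthrough(self, rng):
        p_ref, p_alt = rng.random(4), rng.random(4)
        out_ref, out_alt = adjust_histone(p_ref, p_alt, np.zeros(4, dtype=bool))
        assert np.array_equal(out_ref, p_ref) and np.array_equal(out_alt, p_alt)


class TestVariantEffect:
    @pytest.fixture()
    def setup(self):
        from seqclass.chromnet import ModelConfig, build_model

        cfg = ModelConfig(
            seq_len=64,
            n_targets=4,
            channels=8,
            stem_kernel=5,
            n_dual_blocks=1,
            dual_kernel=3,
            pool_factors=(4,),
            dilations=(2,),
            dilated_kernel=3,
            n_spatial_bins=16,
            spline_df=4,
            hidden=8,
        )
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        genome = GenomeSequence({"c1": "".join(rng.choice(list("ACGT"), 300))})
        vectors = rng.random((2, 4))
        vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
        scm = _make_scm(vectors, histone_mask=np.array([True, True, False, False]))
        return model, scm, genome

    def test_ref_equals_alt_zero_delta(self, setup):
        model, scm, genome = setup
        ref = genome.base_at("c1", 149)
        rec = variant_effect(model, scm, Variant("c1", 150, ref, ref), genome)
        assert np.all(rec.delta == 0.0)

    def test_delta_is_exact_difference(self, setup):
        model, scm, genome = setup
        ref = genome.base_at("c1", 149)
        alt = "A" if ref != "A" else "C"
        rec = variant_effect(model, scm, Variant("c1", 150, ref, alt), genome)
        assert np.array_equal(rec.delta, rec.score_alt - rec.score_ref)

    def test_decomposes_into_predict_adjust_score(self, setup):
        from seqclass.chromnet import one_hot
        from seqclass.scoring import _build_allele_windows

        model, scm, genome = setup
        ref = genome.base_at("c1", 149)
        alt = "G" if ref != "G" else "T"
        variant = Variant("c1", 150, ref, alt)
        rec = variant_effect(model, scm, variant, genome)
        ref_seq, alt_seq = _build_allele_windows(variant, genome, 64)
        preds = model.predict(one_hot([ref_seq, alt_seq]))
        p_ref, p_alt = adjust_histone(preds[0], preds[1], scm.histone_mask)
        manual = class_score(p_alt, scm) - class_score(p_ref, scm)
        assert np.array_equal(rec.delta, manual)

    def test_ref_mismatch_raises(self, setup):
        model, scm, genome = setup
        ref = genome.base_at("c1", 149)
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="REF mismatch"):
            variant_effect(model, scm, Variant("c1", 150, wrong, "G"), genome)

    def test_window_out_of_bounds(self, setup):
        model, scm, genome = setup
        ref = genome.base_at("c1", 4)
        with pytest.raises(ValueError, match="outside"):
            variant_effect(model, scm, Variant("c1", 5, ref, "A" if ref != "A" else "C"), genome)

    def test_indel_windows_have_model_length(self, setup):
        from seqclass.scoring import _build_allele_windows

        model, scm, genome = setup
        pos0 = 149
        ref = genome.fetch("c1", pos0, pos0 + 3)
        variant = Variant("c1", 150, ref, ref[0])  # 2-bp deletion
        ref_seq, alt_seq = _build_allele_windows(variant, genome, 64)
        assert len(ref_seq) == 64 and len(alt_seq) == 64


class TestWriteEffectsVcf:
    def test_roundtrip_through_pysam(self, tmp_path, rng):
        from seqclass.scoring import write_effects_vcf

        scm = _make_scm(np.eye(2))
        records = [
            VariantEffectRecord(
                variant=Variant("c1", 10, "A", "G", id="v0"),
                score_ref=np.array([0.1, 0.2]),
                score_alt=np.array([0.4, 0.1]),
                delta=np.array([0.3, -0.1]),
                assigned_class=0,
                provenance="positional",
            )
        ]
        path = tmp_path / "eff.vcf"
        write_effects_vcf(records, scm, str(path), contig_lengths={"c1": 100})
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            rec = next(iter(vcf))
            assert rec.info["SCD_C1"] == pytest.approx(0.3)
            assert rec.info["SCD_C2"] == pytest.approx(-0.1)
            assert rec.info["SC"] == "C1"
            assert rec.info["SCPROV"] == "positional"


class TestAssignMutationClass:
    def _record(self, deltas, contig="c1", pos=1000):
        ref = "A"
        return VariantEffectRecord(
            variant=Variant(contig, pos, ref, "G"),
            score_ref=np.zeros(len(deltas)),
            score_alt=np.asarray(deltas, dtype=float),
            delta=np.asarray(deltas, dtype=float),
        )

    def _annotation(self, rank=0):
        windows = [Window("c1", 950 + 100 * i, 400) for i in range(2)]
        return annotate_genome(windows, np.array([rank, rank]), bin_size=100)

    def test_reassigned_when_both_conditions_hold(self):
        # |orig|=0.2, |best|=1.5: gap 1.3>1, ratio 7.5>2.5
        rec = self._record([0.2, -1.5])
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == 1
        assert rec.provenance == "reassigned"

    def test_kept_when_gap_too_small(self):
        # |orig|=1.0, |best|=1.9: gap 0.9 <= 1
        rec = self._record([1.0, 1.9])
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == 0
        assert rec.provenance == "positional"

    def test_kept_when_fold_too_small(self):
        # gap 1.1 > 1 but ratio 2.1 < 2.5
        rec = self._record([1.0, 2.1])
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == 0

    def test_best_is_positional(self):
        rec = self._record([5.0, 0.1])
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == 0
        assert rec.provenance == "positional"

    def test_zero_original_infinite_ratio(self):
        rec = self._record([0.0, 1.5])
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == 1

    def test_unassigned_position_no_qualifying_effect(self):
        rec = self._record([0.5, 0.4], pos=5000)  # outside annotation
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == UNASSIGNED
        assert rec.provenance == "unassigned"

    def test_unassigned_position_with_strong_effect(self):
        rec = self._record([0.1, 1.5], pos=5000)
        assign_mutation_class(rec, self._annotation(0))
        assert rec.assigned_class == 1
        assert rec.provenance == "reassigned"

    def test_excluded_class_never_candidate(self):
        rec = self._record([0.2, 9.0])
        assign_mutation_class(rec, self._annotation(0), exclude=[1])
        assert rec.assigned_class == 0

    def test_idempotent(self):
        rec = self._record([0.2, -1.5])
        assign_mutation_class(rec, self._annotation(0))
        first = (rec.assigned_class, rec.provenance)
        assign_mutation_class(rec, self._annotation(0))
        assert (rec.assigned_class, rec.provenance) == first
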