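"""End-to-end miniature pipeline runner and its configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__, genetics, scoring, synthetic
from .chromnet import (
    ModelConfig,
    Partition,
    TrainConfig,
    build_model,
    evaluate,
    make_labels,
    one_hot,
    train,
)
from .formats import write_fasta, write_vcf, windows_to_bed, tile_genome
from .seqclasses import annotate_genome, fit_sequence_classes

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for the end-to-end run; defaults carry the published
    parameter values (k=14, 180 components, 100-bp bins, AF 0.01,
    reassignment gaps 1 / 2.5, top 15,000 eQTL variants) scaled where the
    desk-size preset demands it."""

    seed: int = 0
    # synthetic cohort
    n_contigs: int = 3
    contig_len: int = 20_000
    elements_per_contig: int = 12
    n_cell_types: int = 3
    n_variants: int = 40
    # model
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(n_targets=1, **synthetic_model_preset())
    )
    train_steps: int = 150
    train_batch: int = 32
    optimizer: str = "adam"
    lr: float = 2e-3
    # clustering
    n_components: int = 180
    knn_k: int = 14
    keep_classes: int = 5
    # tiling / annotation
    step: int = 100
    bin_size: int = 100
    # scoring
    abs_gap: float = 1.0
    fold_gap: float = 2.5
    # genetics
    af_threshold: float = 0.01
    eqtl_top_n: int = 15_000

    def to_yaml(self) -> str:
        raw = asdict(self)
        return yaml.safe_dump(raw, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        model_raw = raw.pop("model")
        model_raw["pool_factors"] = tuple(model_raw["pool_factors"])
        model_raw["dilations"] = tuple(model_raw["dilations"])
        return cls(model=ModelConfig(**model_raw), **raw)


def synthetic_model_preset() -> dict:
    from .chromnet.model import TINY_PRESET

    return dict(TINY_PRESET)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str, log=print) -> dict:
    """Execute synth -> train -> predict-tiles -> fit classes -> annotate
    -> variant effects -> genetics statistics, writing every artifact plus
    a manifest under ``out_dir``. Any stage failure aborts with the stage
    name; partial outputs are preserved."""
    os.makedirs(out_dir, exist_ok=True)
    artifacts: list[str] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
        "stages": [],
    }

    def path(name: str) -> str:
        artifacts.append(name)
        return os.path.join(out_dir, name)

    def stage(name: str):
        log(f"[pipeline] stage: {name}")
        manifest["stages"].append(name)

    t0 = time.time()
    try:
        stage("synth")
        cohort = synthetic.generate_cohort(
            n_contigs=config.n_contigs,
            contig_len=config.contig_len,
            elements_per_contig=config.elements_per_contig,
            n_cell_types=config.n_cell_types,
            n_variants=config.n_variants,
            seed=config.seed,
        )
        write_fasta(cohort.genome, path("genome.fa"))
        cohort.profiles.write(os.path.join(out_dir, "profiles"))
        artifacts.append("profiles/profiles.tsv")
        write_vcf(
            cohort.variants, path("variants.vcf"), contig_lengths=cohort.genome.lengths
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synth", exc)

    try:
        stage("train")
        model_cfg = dataclasses.replace(
            config.model, n_targets=len(cohort.profiles), init_seed=config.seed
        )
        model = build_model(model_cfg)
        names = cohort.genome.names
        partition = Partition(
            train_contigs=tuple(names[:-2]) or (names[0],),
            val_contigs=(names[-2],),
            test_contigs=(names[-1],),
        )
        history = train(
            model,
            cohort.genome,
            cohort.profiles,
            partition,
            TrainConfig(
                n_steps=config.train_steps,
                batch_size=config.train_batch,
                optimizer=config.optimizer,
                lr=config.lr,
                seed=config.seed,
            ),
        )
        with open(path("train_history.tsv"), "w") as handle:
            handle.write("step\ttrain_loss\tval_loss\n")
            for rec in history:
                handle.write(
                    f"{rec['step']}\t{rec['train_loss']:.6f}\t"
                    f"{rec.get('val_loss', float('nan')):.6f}\n"
                )
        model.save(os.path.join(out_dir, "model.ckpt.npz"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("train", exc)

    try:
        stage("predict-tiles")
        windows = tile_genome(cohort.genome, model_cfg.seq_len, config.step)
        windows_to_bed(windows, path("windows.bed"))
        seqs = [
            cohort.genome.fetch(w.contig, w.start, w.end) for w in windows
        ]
        preds = model.predict(one_hot(seqs))
        np.savetxt(path("predictions.tsv"), preds, delimiter="\t")
        labels = make_labels(windows, cohort.profiles)
        ev = evaluate(preds, labels, profile_ids=cohort.profiles.ids, min_positives=5)
        ev.per_profile.to_csv(path("evaluation.tsv"), sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("predict-tiles", exc)

    try:
        stage("fit-classes")
        scm = fit_sequence_classes(
            preds,
            n_components=config.n_components,
            k=config.knn_k,
            keep=config.keep_classes,
            seed=config.seed,
            histone_mask=cohort.profiles.histone_mask(),
        )
        scm.save(os.path.join(out_dir, "class_model"))
        artifacts.append("class_model/meta.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit-classes", exc)

    try:
        stage("annotate")
        annotation = annotate_genome(windows, scm.rank_labels(), bin_size=config.bin_size)
        annotation.to_bed(path("annotation.bed"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", exc)

    try:
        stage("variant-effects")
        records = []
        for variant in cohort.variants:
            half = model_cfg.seq_len // 2
            if (
                variant.pos0 - half < 0
                or variant.pos0 + half > cohort.genome.lengths[variant.contig]
            ):
                continue
            rec = scoring.variant_effect(model, scm, variant, cohort.genome)
            scoring.assign_mutation_class(
                rec, annotation, abs_gap=config.abs_gap, fold_gap=config.fold_gap
            )
            records.append(rec)
        effects_table = scoring.variant_effects_table(records, scm)
        effects_table.to_csv(path("variant_effects.tsv"), sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("variant-effects", exc)

    try:
        stage("genetics")
        # enrichment of planted-element intervals per class
        from .formats import Interval, IntervalSet

        element_intervals = IntervalSet(
            Interval(e.contig, max(0, e.center - 75), e.center + 75)
            for e in cohort.elements
        )
        enrich = genetics.logfc_enrichment(
            annotation, {"planted_elements": element_intervals}, scm.n_classes
        )
        enrich.to_csv(path("enrichment.tsv"), sep="\t", index=False)

        af = np.array([r.variant.af for r in records], dtype=float)
        if len(records) >= 20 and np.isfinite(af).all():
            per_class = {}
            for rank in range(scm.n_classes):
                deltas = np.array([r.delta[rank] for r in records])
                per_class[scm.class_name(rank)] = (deltas, af)
            constraint = genetics.constraint_analysis(
                per_class, common_threshold=config.af_threshold
            )
            constraint.to_csv(path("constraint.tsv"), sep="\t", index=False)

        annot = genetics.export_ldsc_annot(
            annotation,
            [r.variant for r in records],
            [scm.class_name(i) for i in range(scm.n_classes)],
        )
        annot.to_csv(path("ldsc.annot.tsv"), sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("genetics", exc)

    manifest["artifacts"] = {
        name: _sha256(os.path.join(out_dir, name)) for name in sorted(set(artifacts))
    }
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    with open(os.path.join(out_dir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    log(f"[pipeline] done in {manifest['wall_time_s']} s")
    return manifest
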