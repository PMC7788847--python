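"""End-to-end study runner: generate, split, augment, train, quantify, compare.

Mirrors the full study design on synthetic phantoms: a pool of finger images
is split into training and test sets (30/10 by default), the training set is
expanded by three lossless rotations (to 120 inputs), an encoder-decoder
bone segmenter is trained, test images are segmented and visibility-gated,
residual lesions are quantified, and two area estimators — the
region-growing pixel-count area and the ellipse estimate from measured axes
— are compared with the full agreement analysis. Every artifact lands under
one output directory together with a manifest (config snapshot, per-file
checksums, stage counts) so a run is reproducible from its master seed and
any tampered intermediate is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from .agreement import AgreementResult, PairedSeries, validate
from .quantify import QuantificationResult, RegionGrowParams, quantify_image, measurements_to_frame
from .segment import TrainConfig, UNetSegmenter, dice, segment_bone, train_segmenter

__all__ = ["RunConfig", "RunManifest", "StudyResult", "run_study", "report"]

logger = logging.getLogger("calciquant.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic study run."""

    n_train: int = 30
    n_test: int = 10
    n_rotations: int = 3
    n_truncated_test: int = 0  # test phantoms generated with clipped phalanges
    phantom: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    grow: RegionGrowParams = field(default_factory=RegionGrowParams)
    alpha: float = 0.05
    border_margin_px: int = 1
    master_seed: int = 42
    write_images: bool = True

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("split sizes must be positive")
        if self.n_truncated_test < 0 or self.n_truncated_test > self.n_test:
            raise ValueError("n_truncated_test must be in [0, n_test]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            p = dict(kwargs["phantom"])
            if "lesion_radius_range" in p:
                p["lesion_radius_range"] = tuple(p["lesion_radius_range"])
            kwargs["phantom"] = ph.PhantomSpec(**p)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "grow" in kwargs:
            kwargs["grow"] = RegionGrowParams(**kwargs["grow"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Record of what a run did: config, counts, artifact checksums."""

    config: dict
    counts: dict
    checksums: dict[str, str]
    failure_ids: list[str]
    started_at: float
    finished_at: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def content_fields(self) -> dict:
        """Everything except wall-clock timestamps (for determinism checks)."""
        d = dataclasses.asdict(self)
        d.pop("started_at")
        d.pop("finished_at")
        return d


@dataclass
class StudyResult:
    manifest: RunManifest
    agreement: AgreementResult | None
    measurements: pd.DataFrame
    test_dice: float
    model: UNetSegmenter


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n) % (2**31 - 1)]


def run_study(config: RunConfig, out_dir: str | Path) -> StudyResult:
    """Execute the full study; write artifacts and manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    checksums: dict[str, str] = {}
    seed_gen, seed_train, seed_trunc = _derive_seeds(config.master_seed, 3)

    stage = "generate"
    try:
        samples = ph.generate_phantoms(
            config.n_train + config.n_test - config.n_truncated_test,
            base_seed=seed_gen,
            base_spec=config.phantom,
        )
        truncated = ph.generate_phantoms(
            config.n_truncated_test,
            base_seed=seed_trunc,
            base_spec=dataclasses.replace(config.phantom, truncate_phalanges=True),
        ) if config.n_truncated_test else []
        train_samples = samples[: config.n_train]
        test_samples = samples[config.n_train :] + truncated
        logger.info("generated %d train + %d test phantoms", len(train_samples), len(test_samples))

        if config.write_images:
            ph.write_dataset(train_samples, out / "train")
            ph.write_dataset(test_samples, out / "test")
            for f in sorted((out / "train").rglob("*")) + sorted((out / "test").rglob("*")):
                if f.is_file():
                    checksums[str(f.relative_to(out))] = _sha256_file(f)

        stage = "augment"
        pairs = [(s.image, s.bone_mask) for s in train_samples]
        augmented = ph.rotate_augment(pairs, config.n_rotations)
        logger.info("augmented %d -> %d training pairs", len(pairs), len(augmented))

        stage = "train"
        cfg = dataclasses.replace(config.train, seed=seed_train)
        model = train_segmenter(augmented, cfg)
        ckpt = out / "model.ckpt.npz"
        model.save(ckpt)
        # checkpoint zip containers embed timestamps; hash the parameters instead
        h = hashlib.sha256()
        for a in model.net_.state_arrays():
            h.update(a.tobytes())
        checksums["model.ckpt.npz"] = h.hexdigest()
        logger.info("trained segmenter: validation Dice %s", model.val_dice_)

        stage = "quantify"
        results: dict[str, QuantificationResult] = {}
        dices = []
        for i, s in enumerate(test_samples):
            image_id = f"test_{i:04d}"
            bone = segment_bone(s.image, model, model.threshold)
            dices.append(dice(bone, s.bone_mask))
            results[image_id] = quantify_image(
                s.image,
                bone,
                config.grow,
                expected_components=config.phantom.n_phalanges,
                border_margin_px=config.border_margin_px,
            )
        failure_ids = [k for k, v in results.items() if v.measurements is None]
        for fid in failure_ids:
            logger.warning("image %s excluded: incomplete phalange visualization", fid)
        frame = measurements_to_frame(results)
        frame.to_csv(out / "measurements.csv", index=False)
        checksums["measurements.csv"] = _sha256_file(out / "measurements.csv")
        summary = {
            "n_images": len(results),
            "n_failed": len(failure_ids),
            "failure_ids": failure_ids,
        }
        (out / "quantify_summary.json").write_text(json.dumps(summary, indent=1))
        checksums["quantify_summary.json"] = _sha256_file(out / "quantify_summary.json")

        stage = "agreement"
        ok = frame[frame["visibility_complete"] == True]  # noqa: E712
        agreement = None
        if len(ok) >= 3:
            series = PairedSeries.from_arrays(
                ok["area_mm2"].to_numpy(float),
                ok["ellipse_area_mm2"].to_numpy(float),
                labels=[f"{r.image_id}/{r.lesion_id}" for r in ok.itertuples()],
            )
            agreement = validate(series, alpha=config.alpha, out_dir=out / "agreement")
            for name in ("plot_data.csv", "agreement.json"):
                checksums[f"agreement/{name}"] = _sha256_file(out / "agreement" / name)
        else:
            logger.warning("fewer than 3 lesions measured; agreement analysis skipped")
    except Exception as err:
        manifest = RunManifest(
            config=_config_dict(config),
            counts={"failed_stage": stage},
            checksums=checksums,
            failure_ids=[],
            started_at=started,
            finished_at=time.time(),
        )
        (out / "manifest.json").write_text(manifest.to_json())
        raise RuntimeError(f"run_study failed in stage '{stage}': {err}") from err

    counts = {
        "images_generated": len(train_samples) + len(test_samples),
        "training_images": len(train_samples),
        "augmented_training_images": len(augmented),
        "test_images": len(test_samples),
        "trained_epochs": config.train.epochs,
        "validation_dice": model.val_dice_,
        "mean_test_dice": float(np.mean(dices)),
        "images_quantified": len(results) - len(failure_ids),
        "images_failed": len(failure_ids),
        "lesions_measured": int((frame["visibility_complete"] == True).sum()),  # noqa: E712
    }
    manifest = RunManifest(
        config=_config_dict(config),
        counts=counts,
        checksums=checksums,
        failure_ids=failure_ids,
        started_at=started,
        finished_at=time.time(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    (out / "report.txt").write_text(report(manifest, agreement))
    return StudyResult(
        manifest=manifest,
        agreement=agreement,
        measurements=frame,
        test_dice=float(np.mean(dices)),
        model=model,
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["phantom"]["lesion_radius_range"] = list(d["phantom"]["lesion_radius_range"])
    return d


def report(manifest: RunManifest, agreement: AgreementResult | None) -> str:
    """Human-readable run summary."""
    c = manifest.counts
    lines = [
        "calciquant study report",
        "=======================",
        f"images generated:        {c['images_generated']}",
        f"training images:         {c['training_images']} "
        f"(augmented to {c['augmented_training_images']})",
        f"test images:             {c['test_images']}",
        f"validation Dice:         {c['validation_dice'] if c['validation_dice'] is not None else 'n/a'}",
        f"mean test Dice:          {c['mean_test_dice']:.4f}",
        f"excluded (visibility):   {c['images_failed']} of {c['test_images']} images not amenable",
        f"lesions measured:        {c['lesions_measured']}",
        "",
    ]
    if c["lesions_measured"] == 0:
        lines.append("no lesions detected; agreement analysis omitted")
    elif agreement is None:
        lines.append("too few lesions for agreement analysis; section omitted")
    else:
        lines += [
            "agreement: region-growing area vs ellipse-estimate area",
            f"  Spearman rho:   {agreement.spearman_rho:.3f} (p = {agreement.spearman_p:.2e})",
            f"  Lin CCC:        {agreement.ccc:.3f} "
            f"(95% CI {agreement.ccc_ci_low:.3f} to {agreement.ccc_ci_high:.3f})",
            f"  Bland-Altman:   bias {agreement.bias:.3f} mm² "
            f"(95% LoA {agreement.loa_low:.3f} to {agreement.loa_high:.3f}), "
            f"difference = {agreement.difference_direction}",
        ]
    return "\n".join(lines) + "\n"
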