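"""End-to-end orchestration: phantom -> segmentation -> quantification ->
reconstruction, as a configured, logged, reproducible run."""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import phantom as ph
from . import quantification as quant
from . import reconstruction as recon
from . import segmentation as seg
from .errors import ConfigError, StageError
from .transforms import RigidTransform

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration for one full run.

    The defaults mirror the study-replica scenario: 3 hearts of 5 random
    sections each, K initialized at 6, z-replication factor 7, and the
    690x970 analysis frame.
    """

    # study design
    n_hearts: int = 3
    slices_per_heart: int = 5
    seed: int = 0
    # phantom
    frame_height: int = 970
    frame_width: int = 690
    left_fraction: float = 0.9
    noise_sd: float = 4.0
    jitter_translation_max: float = 0.0
    jitter_rotation_max: float = 0.0
    n_stain_patches: int = 20
    patch_radius_range: tuple = (6.0, 8.0)
    section_thickness_um: float = 20.0
    # segmentation
    k_init: int = seg.DEFAULT_K
    tune: bool = False
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 10
    sample_size: int | None = 50000
    stain_reference: tuple | None = None  # L*a*b*; None = derived from stain color
    # quantification
    standardize: bool = True
    t_test_variant: str = "pooled"
    # reconstruction
    replication_factor: int = recon.DEFAULT_REPLICATION
    register: bool = True
    translation_bound: int = 15
    rotation_bound_deg: float = 10.0

    def __post_init__(self):
        if self.n_hearts < 1 or self.slices_per_heart < 1:
            raise ConfigError("n_hearts and slices_per_heart must be >= 1")
        if not 0.0 <= self.left_fraction <= 1.0:
            raise ConfigError("left_fraction must be in [0, 1]")
        if self.replication_factor < 1:
            raise ConfigError("replication_factor must be >= 1")
        if self.k_init < 2 or not (2 <= self.k_min <= self.k_max):
            raise ConfigError("invalid K settings")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patch_radius_range"] = list(self.patch_radius_range)
        if self.stain_reference is not None:
            d["stain_reference"] = list(self.stain_reference)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "patch_radius_range" in d:
            d["patch_radius_range"] = tuple(d["patch_radius_range"])
        if d.get("stain_reference") is not None:
            d["stain_reference"] = tuple(d["stain_reference"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _phantom_params(config: RunConfig, heart_seed: int) -> ph.PhantomParams:
    return ph.PhantomParams(
        n_slices=config.slices_per_heart,
        frame_height=config.frame_height,
        frame_width=config.frame_width,
        left_fraction=config.left_fraction,
        noise_sd=config.noise_sd,
        jitter_translation_max=config.jitter_translation_max,
        jitter_rotation_max=config.jitter_rotation_max,
        n_stain_patches=config.n_stain_patches,
        patch_radius_range=config.patch_radius_range,
        section_thickness_um=config.section_thickness_um,
        seed=heart_seed,
    )


def _segment_stack(config: RunConfig, slices, seed: int) -> list:
    ref = (np.asarray(config.stain_reference, dtype=float)
           if config.stain_reference is not None else seg.default_stain_reference())
    masks = []
    for sl in slices:
        lab = seg.rgb_to_lab(sl)
        if config.tune:
            mask = seg.tune_k(lab, ref, k_min=config.k_min, k_max=config.k_max,
                              seed=seed, n_restarts=config.n_restarts,
                              sample_size=config.sample_size)
        else:
            model = seg.cluster_colors(lab, K=config.k_init, seed=seed,
                                       n_restarts=config.n_restarts,
                                       sample_size=config.sample_size)
            mask = seg.select_stain_cluster(model, ref)
        masks.append(mask)
    return masks


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages and write per-stage outputs plus a machine-
    readable ``report.json``.  Deterministic given ``config`` (which
    includes the master seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    report: dict = {"config": config.to_dict(), "hearts": [], "files": files}
    heart_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in np.random.SeedSequence(config.seed).spawn(config.n_hearts)]

    summaries = []
    first_heart_masks = None
    first_heart_truth = None
    for h_idx, heart_seed in enumerate(heart_seeds):
        heart_id = f"heart_{h_idx + 1}"
        stage = "phantom"
        try:
            params = _phantom_params(config, heart_seed)
            slices, truth = ph.generate_stack(params)
            heart_dir = outdir / heart_id
            manifest = ph.write_stack(heart_dir, slices, truth)
            files.extend(manifest["slices"] + manifest["truth_masks"]
                         + [manifest["sidecar"], manifest["counts"]])

            stage = "segmentation"
            masks = _segment_stack(config, slices, seed=heart_seed)

            stage = "quantification"
            quants = []
            for k, (mask, line) in enumerate(zip(masks, truth.lines)):
                m = mask.mask
                if config.standardize and m.shape != (quant.FRAME_HEIGHT, quant.FRAME_WIDTH):
                    m = quant.standardize_mask(m)
                left, right = quant.split_by_partition(m, line)
                quants.append(quant.SliceQuant(
                    slice_id=k, left_count=left, right_count=right,
                    total_frame_pixels=int(m.size),
                ))
            summary = quant.summarize_heart(quants, heart_id=heart_id)
            summaries.append(summary)
            per_slice_csv = heart_dir / "per_slice_counts.csv"
            with open(per_slice_csv, "w", newline="") as fh:
                wr = csv.writer(fh)
                wr.writerow(["slice", "left_count", "right_count", "total_frame_pixels"])
                for q in quants:
                    wr.writerow([q.slice_id, q.left_count, q.right_count, q.total_frame_pixels])
            files.append(str(per_slice_csv))
            report["hearts"].append({
                "heart_id": heart_id,
                "seed": heart_seed,
                "summary": summary.to_dict(),
                "true_left_fraction": truth.true_left_fraction,
                "segmentation": [
                    {"slice": k, "positive_count": m.positive_count,
                     "selected_cluster": m.selected_cluster,
                     "K": None if m.model is None else m.model.K,
                     "flagged_no_stain": m.flagged_no_stain}
                    for k, m in enumerate(masks)
                ],
            })
            if h_idx == 0:
                first_heart_masks = masks
                first_heart_truth = truth
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, f"{heart_id}: {exc}") from exc

    try:
        stage = "quantification"
        hearts_csv = outdir / "per_heart_summary.csv"
        with open(hearts_csv, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["heart", "n_slices", "mean_left", "sem_left",
                         "mean_right", "sem_right", "pct_left", "pct_right"])
            for s in summaries:
                wr.writerow([s.heart_id, s.n_slices,
                             f"{s.mean_left:.3f}", f"{s.sem_left:.3f}",
                             f"{s.mean_right:.3f}", f"{s.sem_right:.3f}",
                             f"{s.pct_left:.3f}", f"{s.pct_right:.3f}"])
        files.append(str(hearts_csv))
        group_left, group_left_sem = quant.summarize_group([s.mean_left for s in summaries])
        group_right, group_right_sem = quant.summarize_group([s.mean_right for s in summaries])
        report["group"] = {
            "mean_left": group_left, "sem_left": group_left_sem,
            "mean_right": group_right, "sem_right": group_right_sem,
            "mean_pct_left": float(np.mean([s.pct_left for s in summaries])),
            "mean_pct_right": float(np.mean([s.pct_right for s in summaries])),
        }
        if len(summaries) >= 2:
            cmp_res = quant.compare_sides(
                [s.mean_left for s in summaries],
                [s.mean_right for s in summaries],
                variant=config.t_test_variant,
            )
            report["comparison"] = cmp_res.to_dict()
            cmp_path = outdir / "comparison.json"
            cmp_path.write_text(json.dumps(cmp_res.to_dict(), indent=2, sort_keys=True))
            files.append(str(cmp_path))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    try:
        stage = "reconstruction"
        if config.register and (config.jitter_translation_max > 0
                                or config.jitter_rotation_max > 0):
            aligned, transforms = recon.align_series(
                first_heart_masks,
                translation_bound=config.translation_bound,
                rotation_bound_deg=config.rotation_bound_deg,
            )
        else:
            aligned = [m.mask for m in first_heart_masks]
            transforms = [RigidTransform.identity() for _ in aligned]
        volume = recon.stack_volume(
            aligned,
            replication_factor=config.replication_factor,
            section_thickness_um=config.section_thickness_um,
        )
        mhd, raw = recon.write_metaimage(volume, outdir / "heart_1" / "stain_volume.mhd")
        files.extend([str(mhd), str(raw)])
        views = recon.export_orthogonal_views(volume, outdir / "heart_1")
        files.extend(str(outdir / "heart_1" / f"projection_{n}.png") for n in views)
        tr_path = outdir / "heart_1" / "transforms.json"
        tr_path.write_text(json.dumps([t.to_dict() for t in transforms],
                                      indent=2, sort_keys=True))
        files.append(str(tr_path))
        report["volume"] = volume.to_dict()
        report["registration"] = {
            "performed": config.register and (config.jitter_translation_max > 0
                                              or config.jitter_rotation_max > 0),
            "transforms_to_first_frame": [t.to_dict() for t in transforms],
        }
        if first_heart_truth is not None:
            report["volume_truth_left_fraction"] = first_heart_truth.true_left_fraction
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    report_path = outdir / "report.json"
    files.append(str(report_path))
    files.sort()
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
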