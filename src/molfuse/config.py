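"""Run configuration: one YAML-backed schema for every knob.

Defaults mirror the published training recipe where one exists (1000
batches × 10 cycles, learning rate 0.001, 3 tasks per batch, 5 support
iterations, 2-way/3-shot episodes at a 1:5 support:query ratio, 80/10/10
scaffold split); the remaining values are package defaults documented in
the methods note. Unknown keys are rejected with the offending key path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    # reproducibility: one root seed, split per stage
    seed: int = 0

    # data
    smiles_column: str = "smiles"
    split_fractions: tuple = (0.8, 0.1, 0.1)

    # fixtures
    fixture_backbone_size: int = 900
    fixture_noise_rate: float = 0.0

    # image autoencoder pretraining
    image_epochs: int = 2
    image_lr: float = 1.0
    image_batch_size: int = 8
    image_alpha: float = 1.0
    image_theta_init: float = 1.0

    # graph/fusion model
    n_iterations: int = 3
    n_head: int = 4
    d_head: int = 4
    bam_reduction: int = 16
    head_widths: tuple = (256, 64)
    clamp_eps: float = 1.0e-7

    # meta-training
    batches: int = 1000
    cycles: int = 10
    tasks_per_batch: int = 3
    support_iters: int = 5
    lr: float = 0.001
    meta_step: float = 0.1
    way: int = 2
    shot: int = 3
    support_query_ratio: int = 5
    eval_every: int = 5

    # fine-tuning
    finetune_epochs: int = 15
    finetune_lr: float = 0.01
    finetune_batch_size: int = 32

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        for key in ("split_fractions", "head_widths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        offsets = {"fixtures": 1, "image": 2, "model": 3, "meta": 4, "finetune": 5, "episode": 6}
        return (self.seed * 1000 + offsets.get(stage, 0)) % (2**31)
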