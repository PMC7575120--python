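"""Pipeline configuration: one plain-text (YAML) file drives the whole run.

Every analysis parameter is a named default here — the 10 TPM detection
threshold, the 0.75 gene-network threshold, MCL inflation 1.7, the 10 M read
downsampling depth with 5 replicate draws, and the 0.9 detection fraction —
so a reproduction run is fully described by its config and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from .mcl import MclParams


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # inputs: either file paths or a synthetic-spec override mapping
    tpm_path: str | None = None
    counts_path: str | None = None
    lengths_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    synthetic: dict | None = None        # overrides for SyntheticSpec fields

    # depth normalisation
    downsample: bool = True
    downsample_depth: int = 10_000_000
    n_replicate_draws: int = 5

    # detection filter
    min_tpm: float = 10.0
    min_samples: int = 1
    detection_fraction: float = 0.9

    # correlation
    method: str = "pearson"
    log2p1: bool = False
    block_size: int = 4096

    # networks
    gene_r_threshold: float = 0.75
    scan_step: float = 0.01

    # clustering
    mcl: MclParams = field(default_factory=MclParams)
    min_cluster_size: int = 5

    # marker screen
    screen_group_a: str = "mononuclear"
    screen_group_b: str = "DC"
    screen_epsilon: float = 1.0

    outdir: str = "coexnet_out"
    seed: int = 0

    def validate(self) -> None:
        if self.tpm_path is None and self.counts_path is None \
                and self.synthetic is None:
            raise ConfigError(
                "no input: set tpm_path, counts_path or a synthetic block")
        for name in ("tpm_path", "counts_path", "lengths_path",
                     "annotation_path", "gene_sets_path"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name} does not exist: {path}")
        if not 0 <= self.gene_r_threshold <= 1:
            raise ConfigError(
                f"gene_r_threshold must be in [0, 1], got {self.gene_r_threshold}")
        if not 0 < self.detection_fraction <= 1:
            raise ConfigError("detection_fraction must be in (0, 1]")
        if self.min_tpm <= 0:
            raise ConfigError("min_tpm must be > 0")
        if self.method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown correlation method {self.method!r}")
        if not 0 < self.scan_step <= 1:
            raise ConfigError("scan_step must be in (0, 1]")
        if self.downsample_depth < 1 or self.n_replicate_draws < 1:
            raise ConfigError("downsample_depth and n_replicate_draws must be >= 1")
        if self.min_cluster_size < 1:
            raise ConfigError("min_cluster_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mcl"] = asdict(self.mcl)
        return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "mcl" in d and isinstance(d["mcl"], dict):
        d["mcl"] = MclParams(**d["mcl"])
    unknown = set(d) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**d)
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
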