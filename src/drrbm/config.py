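"""Structured run configuration with study defaults.

Defaults: batch size 100, 600 fine-tuning epochs, learning rate 1e-3,
10-fold CV, PCA to 100 components (so layer widths are 100/50/50/100),
ADRSVM variant, 3:1 train:test ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .deep import VARIANTS, DeepTrainConfig
from .rbm import RBMTrainConfig
from .synthetic import SyntheticConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    input_path: str | None = None        # CSV to read; None -> simulate
    output_dir: str = "."
    label_column: str = "happiness"
    variant: str = "ADRSVM"              # DRRBM | DRSVM | ADRSVM
    baselines: list = field(default_factory=list)  # e.g. ["knn", "svm", "bpnn"]
    ratios: list = field(default_factory=lambda: [[3, 1]])
    pca_components: int = 100
    cv_folds: int = 10
    sentinel_map: dict = field(default_factory=lambda: {-8: 3})
    households_column: str | None = None  # constant-1 imputation target
    income_columns: list = field(default_factory=list)  # column-mean imputation targets
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    train: DeepTrainConfig = field(default_factory=DeepTrainConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {sorted(VARIANTS)}")
        self.ratios = [tuple(r) for r in self.ratios]
        if not self.income_columns and self.input_path is None:
            # synthetic study: income-archetype columns take the survey's
            # column-mean imputation rule
            from .synthetic import archetype_columns

            self.income_columns = archetype_columns(self.synthetic.n_features)["income"]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["class_probs"] = list(map(float, self.synthetic.class_probs))
        d["ratios"] = [list(r) for r in self.ratios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if isinstance(t.get("pretrain"), dict):
                t["pretrain"] = RBMTrainConfig(**t["pretrain"])
            d["train"] = DeepTrainConfig(**t)
        if "sentinel_map" in d:
            d["sentinel_map"] = {float(k): v for k, v in d["sentinel_map"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
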