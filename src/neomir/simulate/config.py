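"""Configuration of the synthetic study.

Defaults mirror the study design the rest of the package analyses: 6 tissues
x 2 stages x 3 replicates with one postnatal spleen replicate dropped
(35 samples), a negative-binomial count model, and desk-scale library sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

DEFAULT_TISSUES = ("heart", "liver", "spleen", "lung", "muscle", "duodenum")
STAGES = ("prenatal", "postnatal")

#: Illumina TruSeq small-RNA 3' adapter.
TRUSEQ_SMALLRNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_props(name: str, props: tuple[float, ...], n: int) -> None:
    if len(props) != n:
        raise ValueError(f"{name} must have {n} entries, got {len(props)}")
    if any(p < 0 for p in props):
        raise ValueError(f"{name} entries must be non-negative")
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(props)})")


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, validated on construction."""

    seed: int = 0
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_reps: int = 3
    #: sample ids omitted from the design; the default drops one postnatal
    #: spleen replicate, leaving 35 of the 36 design cells.
    drop_samples: tuple[str, ...] = ("spleen_postnatal_3",)
    n_mirnas: int = 300
    #: fraction of miRNAs with one-tissue-dominant expression
    frac_specific: float = 0.55
    #: per-tissue fraction of miRNAs differentially expressed between stages
    frac_de: float = 0.10
    #: fold-change interval for planted stage effects (lower bound > 1)
    fc_range: tuple[float, float] = (2.0, 6.0)
    #: dominance of the specific tissue over the others (log-uniform draw);
    #: tissue-restricted miRNAs are typically enriched 1-2+ orders of
    #: magnitude in their home tissue
    dominance_range: tuple[float, float] = (16.0, 256.0)
    #: negative-binomial dispersion phi (var = mu + phi * mu^2)
    dispersion: float = 0.1
    #: reads per sample (uniform draw per sample)
    libsize_range: tuple[int, int] = (20_000, 40_000)
    adapter: str = TRUSEQ_SMALLRNA_ADAPTER
    #: proportions of known / conserved / novel precursors
    class_props: tuple[float, float, float] = (0.294, 0.461, 0.245)
    #: proportions of intronic / intergenic / exonic / intron_exon precursors
    context_props: tuple[float, float, float, float] = (0.5314, 0.3285, 0.0010, 0.1391)
    #: proportions of 5p-only / 3p-only / both-arm precursors
    arm_props: tuple[float, float, float] = (0.209, 0.235, 0.556)
    #: fraction of extra junk reads (adapter dimers, <18 nt inserts)
    junk_frac: float = 0.02
    read_length: int = 50
    #: per-base substitution rate in synthesized reads (exact-match
    #: quantification assumes 0)
    base_error: float = 0.0
    #: fraction of miRNAs given planted 3'UTR target sites
    frac_targeted: float = 0.2
    #: qPCR Ct noise standard deviation (cycles)
    ct_noise_sd: float = 0.1
    #: blood-glucose measurement noise (mmol/L)
    glucose_noise_sd: float = 0.1

    def __post_init__(self):
        if len(self.tissues) < 2:
            raise ValueError("tissues: need at least 2 tissues")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues: names must be unique")
        if self.n_reps < 2:
            raise ValueError(f"n_reps must be >= 2, got {self.n_reps}")
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be positive")
        for name in ("frac_specific", "frac_de", "junk_frac", "base_error",
                     "frac_targeted"):
            _check_fraction(name, getattr(self, name))
        if not self.fc_range[0] > 1.0:
            raise ValueError(f"fc_range lower bound must be > 1, got {self.fc_range[0]}")
        if self.fc_range[1] < self.fc_range[0]:
            raise ValueError("fc_range upper bound below lower bound")
        if self.dominance_range[0] < 1 or self.dominance_range[1] < self.dominance_range[0]:
            raise ValueError("dominance_range must be an increasing interval >= 1")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.libsize_range[0] < 1 or self.libsize_range[1] < self.libsize_range[0]:
            raise ValueError("libsize_range must be an increasing positive interval")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        _check_props("class_props", self.class_props, 3)
        _check_props("context_props", self.context_props, 4)
        _check_props("arm_props", self.arm_props, 3)
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if self.ct_noise_sd < 0 or self.glucose_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent reproducible generator for one pipeline stage.

        All randomness flows from ``seed``; per-stage streams keep each
        artifact byte-reproducible when an operation is called on its own.
        """
        return np.random.default_rng([int(self.seed), int(stream)])

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)


def make_manifest(config: SyntheticConfig) -> pd.DataFrame:
    """Full tissue x stage x replicate design minus ``drop_samples``."""
    rows = []
    for tissue in config.tissues:
        for stage in STAGES:
            for rep in range(1, config.n_reps + 1):
                sid = f"{tissue}_{stage}_{rep}"
                if sid in config.drop_samples:
                    continue
                rows.append((sid, tissue, stage, rep))
    if not rows:
        raise ValueError("design is empty after dropping samples")
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "stage", "replicate"])
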