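"""Pipeline configuration: YAML-backed dataclasses with validation.

The committed defaults reproduce the protocol constants: 40 MHz sampling,
7 MHz center frequency, 4-9 MHz analysis band, 10-wavelength sub-ROIs with
94% overlap, 16-level symmetric GLCM at distance 1 over four angles, seven
balanced subsets, at most 3 forward-selected features, LOOCV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from qustex.phantom_sim import DEFAULT_SPEED_OF_SOUND, PulseModel


@dataclass
class AcquisitionConfig:
    sampling_frequency: float = 40e6
    center_frequency: float = 7e6
    band: tuple[float, float] = (4e6, 9e6)
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND
    line_spacing: float = 3e-4
    frame_spacing: float = 0.01
    fractional_bandwidth: float = 5.0 / 7.0

    def pulse(self) -> PulseModel:
        return PulseModel(
            center_frequency=self.center_frequency,
            fractional_bandwidth=self.fractional_bandwidth,
            sampling_frequency=self.sampling_frequency,
            speed_of_sound=self.speed_of_sound,
        )

    def validate(self) -> None:
        self.pulse()  # PulseModel enforces its invariants
        if not self.band[0] < self.center_frequency < self.band[1]:
            raise ValueError("center frequency must lie inside the analysis band")


@dataclass
class SubROIConfig:
    overlap: float = 0.94
    inclusion: str = "center"

    def validate(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.inclusion not in ("center", "inside"):
            raise ValueError("inclusion must be 'center' or 'inside'")


@dataclass
class GLCMBlockConfig:
    levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True
    neighborhood: int = 15
    step: int = 1

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.neighborhood < 3:
            raise ValueError("neighborhood must be >= 3")


@dataclass
class ClassifierConfig:
    n_subsets: int = 7
    max_features: int = 3
    selection_mode: str = "nested"
    knn_k: int = 5
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"

    def validate(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.selection_mode not in ("nested", "per_subset", "none"):
            raise ValueError("selection_mode must be nested | per_subset | none")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be a positive odd integer")


@dataclass
class SimConfig:
    n_per_class: int = 5
    n_lines: int = 48
    extent_axial: float = 0.010
    n_frames: int = 1
    noise: float = 0.0
    responder_radius_um: tuple[float, float] = (25.0, 2.0)
    responder_density_mm2: tuple[float, float] = (150.0, 10.0)
    responder_amplitude_cv: tuple[float, float] = (0.2, 0.02)
    nonresponder_radius_um: tuple[float, float] = (55.0, 2.0)
    nonresponder_density_mm2: tuple[float, float] = (150.0, 10.0)
    nonresponder_amplitude_cv: tuple[float, float] = (0.2, 0.02)

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")


@dataclass
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    subroi: SubROIConfig = field(default_factory=SubROIConfig)
    glcm: GLCMBlockConfig = field(default_factory=GLCMBlockConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.acquisition.validate()
        self.subroi.validate()
        self.glcm.validate()
        self.classifier.validate()
        self.sim.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def _block(klass, key):
            block = data.get(key, {}) or {}
            kwargs = {}
            for name, value in block.items():
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[name] = value
            return klass(**kwargs)

        cfg = cls(
            acquisition=_block(AcquisitionConfig, "acquisition"),
            subroi=_block(SubROIConfig, "subroi"),
            glcm=_block(GLCMBlockConfig, "glcm"),
            classifier=_block(ClassifierConfig, "classifier"),
            sim=_block(SimConfig, "sim"),
            seed=int(data.get("seed", 0)),
        )
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
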