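"""Run configuration: YAML/JSON parsing with explicit length units.

Config files quote lengths the way microscopists do — nm for section and
organelle scales, μm for cell scales — with unit-suffixed keys.  The
parser normalises everything to the package's internal μm and the run
manifest records the normalised values, so a manifest alone is enough to
replay a run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import InvalidInputError
from .classifier import ClassifierParams
from .scene import CultureParams, OMEGA_RATE_43PCT


@dataclass
class SectionConfig:
    thickness_nm: float = 70.0
    mode: str = "both"  # serial | single_random_per_cell | both
    min_profile_nm: float = 20.0
    omega_span_slabs: int = 1
    fov_um: Optional[float] = None


@dataclass
class EstimatorConfig:
    band_height_um: float = 2.0
    site_method: str = "linear"


@dataclass
class ClassifierConfig:
    enabled: bool = False
    n_patches: int = 0
    min_diameter_nm: float = 200.0
    separation_threshold: float = 2.0
    nm_per_px: float = 4.0
    inverted: bool = False

    def params(self) -> ClassifierParams:
        return ClassifierParams(min_diameter=self.min_diameter_nm,
                                separation_threshold=self.separation_threshold)


@dataclass
class RunConfig:
    """Full pipeline configuration with one master seed."""

    culture: CultureParams = field(default_factory=CultureParams)
    section: SectionConfig = field(default_factory=SectionConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    out_dir: str = "evstereo_out"
    seed: int = 0
    log_level: str = "INFO"

    # -- dict round-trip (unit-suffixed external keys) -------------------------

    def to_dict(self) -> dict:
        c = self.culture
        return {
            "seed": self.seed,
            "log_level": self.log_level,
            "out_dir": self.out_dir,
            "culture": {
                "n_cells": c.n_cells,
                "cell_diameter_um": c.cell_diameter_mean,
                "cell_height_um": c.cell_height_mean,
                "site_rate": c.site_rate,
                "site_z_extent_um": c.site_z_extent,
                "n_mcmv": c.n_mcmv,
                "mcmv_diameter_nm": c.mcmv_diameter_mean * 1000.0,
                "mcmv_diameter_cv": c.mcmv_diameter_cv,
                "mvb_per_mcmv_mean": c.mvb_per_mcmv_mean,
                "mvb_diameter_nm": c.mvb_diameter_mean * 1000.0,
                "mvb_diameter_cv": c.mvb_diameter_cv,
                "mvb_count_model": c.mvb_count_model,
                "ilv_occupancy": c.ilv_occupancy,
                "ilv_extra_mean": c.ilv_extra_mean,
                "ilv_diameter_nm": [c.ilv_diameter_range[0] * 1000.0,
                                    c.ilv_diameter_range[1] * 1000.0],
                "omega_rate": c.omega_rate,
                "fixed_sizes": c.fixed_sizes,
                "bottom_jitter_um": c.bottom_jitter,
                "field_um": c.field_um,
            },
            "section": asdict(self.section),
            "estimator": asdict(self.estimator),
            "classifier": asdict(self.classifier),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cd = dict(d.get("culture", {}))
        ilv_nm = cd.pop("ilv_diameter_nm", [50.0, 100.0])
        culture = CultureParams(
            n_cells=cd.pop("n_cells", 100),
            cell_diameter_mean=cd.pop("cell_diameter_um", 24.0),
            cell_height_mean=cd.pop("cell_height_um", 4.0),
            site_rate=cd.pop("site_rate", 0.75),
            site_z_extent=cd.pop("site_z_extent_um", 2.0),
            n_mcmv=cd.pop("n_mcmv", 100),
            mcmv_diameter_mean=cd.pop("mcmv_diameter_nm", 1080.0) / 1000.0,
            mcmv_diameter_cv=cd.pop("mcmv_diameter_cv", 0.2),
            mvb_per_mcmv_mean=cd.pop("mvb_per_mcmv_mean", 1.0),
            mvb_diameter_mean=cd.pop("mvb_diameter_nm", 367.0) / 1000.0,
            mvb_diameter_cv=cd.pop("mvb_diameter_cv", 0.2),
            mvb_count_model=cd.pop("mvb_count_model", "poisson"),
            ilv_occupancy=cd.pop("ilv_occupancy", 0.65),
            ilv_extra_mean=cd.pop("ilv_extra_mean", 2.0),
            ilv_diameter_range=(ilv_nm[0] / 1000.0, ilv_nm[1] / 1000.0),
            omega_rate=cd.pop("omega_rate", OMEGA_RATE_43PCT),
            fixed_sizes=cd.pop("fixed_sizes", False),
            bottom_jitter=cd.pop("bottom_jitter_um", 0.7),
            field_um=cd.pop("field_um", None),
        )
        if cd:
            raise InvalidInputError(f"unknown culture config keys: {sorted(cd)}")
        cfg = cls(
            culture=culture,
            section=SectionConfig(**d.get("section", {})),
            estimator=EstimatorConfig(**d.get("estimator", {})),
            classifier=ClassifierConfig(**d.get("classifier", {})),
            out_dir=d.get("out_dir", "evstereo_out"),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
        )
        culture.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
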