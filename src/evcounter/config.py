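"""Configuration objects for the simulator, optics and sample geometry.

The geometry follows a counting-chamber workflow: whole blood is diluted
(default 500x), a fixed aliquot (default 10 uL) is loaded into a well, so
each well represents ``loaded_volume / dilution_factor`` microlitres of
undiluted blood (0.02 uL at the defaults).  An EpCAM-enriched mode instead
represents a full processed blood volume (default 7.5 mL) with strong
per-class depletion expressed as retention probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

CLASS_NAMES = ("leukocyte", "ldEV", "platelet", "RBC")
EXPRESSION_LEVELS = ("negative", "low", "positive")

#: channel roles understood by the gate engine
NUCLEAR = "nuclear"
EXTRA = "extra"

MODES = ("whole_blood", "epcam_enriched")


@dataclass(frozen=True)
class PopulationSpec:
    """One object class in the simulated sample.

    Parameters
    ----------
    class_name : str
        One of ``leukocyte``, ``ldEV``, ``platelet``, ``RBC``.
    concentration : float
        Objects per microlitre of *undiluted* blood.
    diameter_range : (float, float)
        Physical diameter range in micrometres; diameters are drawn
        uniformly within it.
    marker_expression : mapping role -> level
        Expression level (``negative``/``low``/``positive``) for every
        channel role of the active panel.  ``negative`` renders exactly
        zero signal.
    nucleated : bool
        Whether the object carries a nuclear-dye signal (informational;
        the nuclear signal itself comes from ``marker_expression``).
    suspended : bool
        Suspended (small, unsettled) objects receive a per-particle
        defocus blur drawn from the optics' defocus range; settled
        objects are rendered in focus.
    """

    class_name: str
    concentration: float
    diameter_range: tuple[float, float]
    marker_expression: Mapping[str, str]
    nucleated: bool = False
    suspended: bool = False

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        lo, hi = self.diameter_range
        if not (0 < lo <= hi):
            raise ValueError("diameter_range must satisfy 0 < min <= max")
        for role, level in self.marker_expression.items():
            if level not in EXPRESSION_LEVELS:
                raise ValueError(f"unknown expression level {level!r} for {role!r}")


def _wb_roles() -> dict[str, str]:
    return {NUCLEAR: "Hoechst", "CD45": "CD45", "CD61": "CD61",
            "CD235a": "CD235a", EXTRA: "extra"}


def _epcam_roles() -> dict[str, str]:
    return {NUCLEAR: "DAPI", "CK": "CK", "CD45": "CD45", EXTRA: "extra"}


@dataclass
class OpticsConfig:
    """Imaging model parameters.

    Intensities are arbitrary units calibrated so that ``positive``
    expression comfortably clears the positivity gates (background-
    subtracted mean > 30 and max > 50) while ``low`` straddles them and
    ``negative`` contributes nothing beyond noise.
    """

    pixel_pitch: float = 0.64            # um / pixel
    frame_shape: tuple[int, int] = (512, 512)
    channel_names: tuple[str, ...] = ("Hoechst", "CD45", "CD61", "CD235a", "extra")
    channel_roles: dict[str, str] = field(default_factory=_wb_roles)
    background_level: float = 20.0       # a.u. per pixel
    noise_sd: float = 2.0                # a.u. per pixel
    defocus_sigma_range: tuple[float, float] = (0.0, 2.0)   # pixels
    intensity_per_expression: dict[str, float] = field(
        default_factory=lambda: {"negative": 0.0, "low": 45.0, "positive": 400.0})
    intensity_cv: float = 0.10           # lognormal spread of per-particle brightness
    exposure_times_ms: dict[str, float] = field(
        default_factory=lambda: {"Hoechst": 20.0, "CD61": 500.0,
                                 "CD45": 400.0, "CD235a": 1000.0})

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if "extra" not in self.channel_names:
            raise ValueError("channel list must contain the noise-only 'extra' channel")
        for role, ch in self.channel_roles.items():
            if ch not in self.channel_names:
                raise ValueError(f"role {role!r} maps to unknown channel {ch!r}")
        lo, hi = self.defocus_sigma_range
        if lo < 0 or hi < lo:
            raise ValueError("defocus_sigma_range must satisfy 0 <= min <= max")
        for level, val in self.intensity_per_expression.items():
            if val < 0:
                raise ValueError(f"intensity for {level!r} must be >= 0")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be >= 0")

    @classmethod
    def whole_blood(cls, **kw) -> "OpticsConfig":
        return cls(**kw)

    @classmethod
    def epcam_enriched(cls, **kw) -> "OpticsConfig":
        kw.setdefault("channel_names", ("DAPI", "CK", "CD45", "extra"))
        kw.setdefault("channel_roles", _epcam_roles())
        kw.setdefault("exposure_times_ms", {"DAPI": 20.0, "CK": 400.0, "CD45": 1000.0})
        return cls(**kw)

    @classmethod
    def for_mode(cls, mode: str, **kw) -> "OpticsConfig":
        if mode == "epcam_enriched":
            return cls.epcam_enriched(**kw)
        return cls.whole_blood(**kw)

    @property
    def panel_roles(self) -> tuple[str, ...]:
        return tuple(self.channel_roles)


def whole_blood_populations(
    leukocyte_concentration: float = 4500.0,
    rbc_concentration: float = 5.0e6,
    platelet_concentration: float = 2.5e5,
    ldev_concentration: float = 1500.0,
) -> tuple[PopulationSpec, ...]:
    """Default whole-blood populations at typical hematology concentrations.

    The ldEV diameter range is anchored on the minimum detectable object
    area of ~9 um^2 (equivalent diameter ~3.4 um) at 0.64 um/pixel: the
    class is operationally defined by what the imaging resolves.
    """
    neg = "negative"
    return (
        PopulationSpec("leukocyte", leukocyte_concentration, (7.0, 20.0),
                       {NUCLEAR: "positive", "CD45": "positive", "CD61": neg,
                        "CD235a": neg, EXTRA: neg},
                       nucleated=True, suspended=False),
        PopulationSpec("RBC", rbc_concentration, (6.0, 10.0),
                       {NUCLEAR: neg, "CD45": neg, "CD61": neg,
                        "CD235a": "positive", EXTRA: neg},
                       nucleated=False, suspended=False),
        PopulationSpec("platelet", platelet_concentration, (2.0, 5.0),
                       {NUCLEAR: neg, "CD45": neg, "CD61": "positive",
                        "CD235a": neg, EXTRA: neg},
                       nucleated=False, suspended=True),
        PopulationSpec("ldEV", ldev_concentration, (3.4, 6.0),
                       {NUCLEAR: neg, "CD45": "positive", "CD61": neg,
                        "CD235a": neg, EXTRA: neg},
                       nucleated=False, suspended=True),
    )


def epcam_populations(
    leukocyte_concentration: float = 4500.0,
    ldev_concentration: float = 1500.0,
) -> tuple[PopulationSpec, ...]:
    """Populations present after EpCAM enrichment (CD45+ classes only)."""
    neg = "negative"
    return (
        PopulationSpec("leukocyte", leukocyte_concentration, (7.0, 20.0),
                       {NUCLEAR: "positive", "CK": neg, "CD45": "positive", EXTRA: neg},
                       nucleated=True, suspended=False),
        PopulationSpec("ldEV", ldev_concentration, (3.4, 6.0),
                       {NUCLEAR: neg, "CK": neg, "CD45": "positive", EXTRA: neg},
                       nucleated=False, suspended=True),
    )


DEFAULT_RETENTION = {"leukocyte": 1.0e-3, "ldEV": 0.5e-3, "platelet": 0.0, "RBC": 0.0}


@dataclass
class SampleConfig:
    """Sample preparation and well-loading geometry.

    In ``whole_blood`` mode each well holds ``loaded_volume_ul /
    dilution_factor`` uL of undiluted blood.  In ``epcam_enriched`` mode a
    cartridge represents ``processed_volume_ul`` of blood (default 7.5 mL)
    and each class survives enrichment with probability ``retention``.
    """

    populations: tuple[PopulationSpec, ...]
    dilution_factor: float = 500.0
    loaded_volume_ul: float = 10.0
    frames_per_well: int = 60
    replicate_wells: int = 5
    mode: str = "whole_blood"
    retention: Mapping[str, float] | None = None
    processed_volume_ul: float = 7500.0
    cluster_fraction: float = 0.0
    seed: int = 0
    max_expected_per_well: float = 1.0e6

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.loaded_volume_ul <= 0 or self.processed_volume_ul <= 0:
            raise ValueError("volumes must be > 0")
        if self.frames_per_well < 1:
            raise ValueError("frames_per_well must be >= 1")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.retention is not None:
            for cls, p in self.retention.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"retention for {cls!r} must be in [0, 1]")
            if self.mode == "whole_blood" and any(p != 1.0 for p in self.retention.values()):
                raise ValueError("whole_blood mode requires retention identically 1")
        if not self.populations:
            raise ValueError("at least one population required")

    def retention_for(self, class_name: str) -> float:
        if self.mode == "whole_blood":
            return 1.0
        if self.retention is not None:
            return float(self.retention.get(class_name, 0.0))
        return float(DEFAULT_RETENTION.get(class_name, 0.0))

    def with_seed(self, seed: int) -> "SampleConfig":
        return replace(self, seed=int(seed))


def whole_blood_sample(seed: int = 0, **population_kw) -> SampleConfig:
    """Standard whole-blood study conditions: 500x dilution, 10 uL/well."""
    return SampleConfig(populations=whole_blood_populations(**population_kw), seed=seed)


def epcam_sample(seed: int = 0, retention: Mapping[str, float] | None = None,
                 cluster_fraction: float = 0.3, **population_kw) -> SampleConfig:
    """EpCAM-enriched cartridge conditions: 7.5 mL processed, strong depletion."""
    return SampleConfig(populations=epcam_populations(**population_kw),
                        mode="epcam_enriched",
                        retention=dict(retention) if retention is not None else dict(DEFAULT_RETENTION),
                        cluster_fraction=cluster_fraction, seed=seed)


# ---------------------------------------------------------------------------
# JSON (de)serialization, used by the CLI and the sidecar metadata files.

def sample_config_to_dict(cfg: SampleConfig) -> dict:
    return {
        "populations": [
            {"class_name": p.class_name, "concentration": p.concentration,
             "diameter_range": list(p.diameter_range),
             "marker_expression": dict(p.marker_expression),
             "nucleated": p.nucleated, "suspended": p.suspended}
            for p in cfg.populations
        ],
        "dilution_factor": cfg.dilution_factor,
        "loaded_volume_ul": cfg.loaded_volume_ul,
        "frames_per_well": cfg.frames_per_well,
        "replicate_wells": cfg.replicate_wells,
        "mode": cfg.mode,
        "retention": dict(cfg.retention) if cfg.retention is not None else None,
        "processed_volume_ul": cfg.processed_volume_ul,
        "cluster_fraction": cfg.cluster_fraction,
        "seed": cfg.seed,
        "max_expected_per_well": cfg.max_expected_per_well,
    }


def sample_config_from_dict(d: Mapping) -> SampleConfig:
    pops = tuple(
        PopulationSpec(p["class_name"], p["concentration"],
                       tuple(p["diameter_range"]), p["marker_expression"],
                       p.get("nucleated", False), p.get("suspended", False))
        for p in d["populations"]
    )
    kw = {k: d[k] for k in
          ("dilution_factor", "loaded_volume_ul", "frames_per_well",
           "replicate_wells", "mode", "retention", "processed_volume_ul",
           "cluster_fraction", "seed", "max_expected_per_well") if k in d}
    return SampleConfig(populations=pops, **kw)


def optics_config_to_dict(cfg: OpticsConfig) -> dict:
    return {
        "pixel_pitch": cfg.pixel_pitch,
        "frame_shape": list(cfg.frame_shape),
        "channel_names": list(cfg.channel_names),
        "channel_roles": dict(cfg.channel_roles),
        "background_level": cfg.background_level,
        "noise_sd": cfg.noise_sd,
        "defocus_sigma_range": list(cfg.defocus_sigma_range),
        "intensity_per_expression": dict(cfg.intensity_per_expression),
        "intensity_cv": cfg.intensity_cv,
        "exposure_times_ms": dict(cfg.exposure_times_ms),
    }


def optics_config_from_dict(d: Mapping) -> OpticsConfig:
    kw = dict(d)
    for key in ("frame_shape", "channel_names", "defocus_sigma_range"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return OpticsConfig(**kw)


def load_run_config(path: str) -> dict:
    """Load a pipeline config file holding sample/optics/segmentation blocks."""
    with open(path) as fh:
        return json.load(fh)
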