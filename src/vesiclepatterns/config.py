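"""Pipeline configuration: study conditions, generator parameters, and
YAML (de)serialisation.

The defaults encode the study conditions the synthetic data emulates:
solid area fraction φ = 0.17, vesicle diameters 15–40 μm, domain counts
in the experimental range, per-class excess-area windows, and osmotic
condition mixtures that qualitatively reproduce the observed shift —
neutral conditions dominated by lattices and the dynamic disordered
state, inflated conditions by associated structures and the disordered
state.  The mixture weights are package defaults, not measured values.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import yaml

from .errors import InvalidInputError
from .synth import DEFAULT_AXS_RANGES, DEFAULT_DISORDERED_EXCLUSION

__all__ = ["ConditionSpec", "PipelineConfig", "GENERATOR_CLASSES"]

#: Pattern classes a condition may request (associated resolves to a
#: chain, or a plaque when the chain does not fit a single belt).
GENERATOR_CLASSES = ("lattice", "associated", "disordered")


@dataclass
class ConditionSpec:
    """Number of vesicles of each pattern class under one osmotic condition."""

    class_counts: dict[str, int]

    def __post_init__(self) -> None:
        for cls, count in self.class_counts.items():
            if cls not in GENERATOR_CLASSES:
                raise InvalidInputError(f"unknown generator class {cls!r}")
            if count < 0:
                raise InvalidInputError(f"negative count for class {cls!r}")

    @property
    def n_vesicles(self) -> int:
        return sum(self.class_counts.values())


def _default_conditions() -> dict[str, ConditionSpec]:
    return {
        "neutral": ConditionSpec({"lattice": 24, "disordered": 24, "associated": 2}),
        "inflated": ConditionSpec({"lattice": 2, "disordered": 22, "associated": 26}),
    }


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a synthetic state-space run.

    Attributes
    ----------
    phi : float
        Target solid area fraction (the study composition is 0.17 ± 0.03).
    conditions : dict[str, ConditionSpec]
        Vesicles to generate per osmotic condition.
    n_range : dict[str, tuple[int, int]]
        Inclusive domain-count range sampled per class.  Associated
        vesicles default to the chain-feasible range at φ = 0.17.
    dv_range : tuple[float, float]
        Vesicle diameter range (μm).
    lattice_jitter, chain_jitter, plaque_jitter : float
        Tangential positional noise of each generator (fractions of the
        lattice spacing / plate diameter).
    gap_ratio : float
        Edge–edge gap of associated structures, in plate diameters.
    disordered_exclusion : float
        Minimum-separation factor of the disordered generator.
    axs_ranges : dict
        Per-class excess-area sampling windows.
    focal_band_half_angle : float or None
        Fixed focal band (radians); ``None`` selects the adaptive default
        targeting ~7 visible plates.
    render : bool
        If true, render micrographs and re-detect domains (image route);
        otherwise analyse the projected ground-truth views directly.
    pixel_scale, noise_sd, shot_noise
        Rendering parameters (μm/px; additive Gaussian sd; Poisson flag).
    """

    phi: float = 0.17
    conditions: dict[str, ConditionSpec] = field(default_factory=_default_conditions)
    n_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "lattice": (12, 48),
            "disordered": (12, 48),
            "associated": (5, 10),
        }
    )
    dv_range: tuple[float, float] = (15.0, 40.0)
    lattice_jitter: float = 0.03
    chain_jitter: float = 0.02
    plaque_jitter: float = 0.02
    gap_ratio: float = 0.2
    disordered_exclusion: float = DEFAULT_DISORDERED_EXCLUSION
    axs_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_AXS_RANGES)
    )
    focal_band_half_angle: float | None = None
    k_max: int = 6
    central_fraction: float = 0.5
    render: bool = False
    pixel_scale: float = 0.34
    noise_sd: float = 0.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise InvalidInputError(f"phi must be in (0, 1), got {self.phi}")
        if self.dv_range[0] <= 0 or self.dv_range[1] < self.dv_range[0]:
            raise InvalidInputError(f"bad vesicle diameter range {self.dv_range}")

    @classmethod
    def balanced(cls, n_per_class: int = 50, **kwargs) -> "PipelineConfig":
        """Single-condition config with equal class counts (the default
        end-to-end demonstration: three CV clusters, one per class)."""
        conditions = {
            "custom": ConditionSpec(
                {
                    "lattice": n_per_class,
                    "associated": n_per_class,
                    "disordered": n_per_class,
                }
            )
        }
        return cls(conditions=conditions, **kwargs)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        data = asdict(self)
        data["conditions"] = {
            name: dict(spec.class_counts) for name, spec in self.conditions.items()
        }
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = copy.deepcopy(data)
        raw_conditions = data.pop("conditions", None)
        kwargs = {}
        for key, value in data.items():
            if key in ("dv_range",):
                value = tuple(value)
            if key == "n_range":
                value = {k: tuple(v) for k, v in value.items()}
            if key == "axs_ranges":
                value = {k: tuple(v) for k, v in value.items()}
            kwargs[key] = value
        config = cls(**kwargs)
        if raw_conditions is not None:
            config.conditions = {
                name: ConditionSpec(dict(counts)) for name, counts in raw_conditions.items()
            }
        return config

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
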