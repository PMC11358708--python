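"""State-space assembly: per-vesicle records, the excess-area class
boundary, condition histograms, and the step-function summary of
edge–edge separations.

The central observable is the (Axs, N) state space of persistent
patterns: vesicle-encompassing quasi-lattices occur only above an excess
area of about 1.025 while closely associated structures occur only below
about 1.015, independent of plate number — a sharp horizontal boundary.
The boundary estimator used here is the empirical gap interval
[max Axs among associated vesicles, min Axs among lattice vesicles],
matching how one reads the scatter plot; no parametric classifier is
fitted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, patterns, synth
from .config import PipelineConfig
from .errors import (
    GenerationFailureError,
    InsufficientClassError,
    InvalidInputError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RECORD_COLUMNS",
    "VesicleRecord",
    "BoundaryEstimate",
    "StateSpaceTable",
    "StepFunctionSummary",
    "generate_vesicles",
    "analyze_entries",
    "analyze_configuration",
    "run_pipeline",
    "estimate_boundary",
    "condition_histogram",
    "step_function_summary",
    "write_records",
    "read_records",
]

RECORD_COLUMNS = [
    "vesicle_id",
    "condition",
    "pattern_class",  # generated (ground-truth) class: lattice/associated/disordered
    "generator",  # detailed generator: lattice/associated_chain/associated_plaque/disordered
    "N",
    "Dv_um",
    "Dd_um",
    "phi",
    "axs",
    "cv",
    "lindemann",
    "label",  # measured class from the CV bands (may be indeterminate)
    "dee_over_dd_mean",
    "theta_max_deg",
    "seed",
]

_SCHEMA_VERSION = 1

_COLUMN_DTYPES = {
    "vesicle_id": "object",
    "condition": "object",
    "pattern_class": "object",
    "generator": "object",
    "N": "int64",
    "Dv_um": "float64",
    "Dd_um": "float64",
    "phi": "float64",
    "axs": "float64",
    "cv": "float64",
    "lindemann": "float64",
    "label": "object",
    "dee_over_dd_mean": "float64",
    "theta_max_deg": "float64",
    "seed": "int64",
}


@dataclass(frozen=True)
class VesicleRecord:
    """One row of the state space."""

    vesicle_id: str
    condition: str
    pattern_class: str
    generator: str
    N: int
    Dv_um: float
    Dd_um: float
    phi: float
    axs: float
    cv: float
    lindemann: float
    label: str
    dee_over_dd_mean: float
    theta_max_deg: float
    seed: int


@dataclass(frozen=True)
class BoundaryEstimate:
    """Empirical excess-area gap between the persistent pattern classes."""

    lower: float  # max Axs among associated vesicles
    upper: float  # min Axs among lattice vesicles
    overlapping: bool

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class StateSpaceTable:
    """Collection of vesicle records plus derived summaries."""

    records: pd.DataFrame
    config: PipelineConfig | None = None
    seed: int | None = None
    failures: list[dict] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def estimate_boundary(self, class_column: str = "pattern_class") -> BoundaryEstimate:
        return estimate_boundary(self.records, class_column=class_column)

    def condition_histogram(
        self, condition: str, class_column: str = "pattern_class"
    ) -> dict[str, int]:
        return condition_histogram(self.records, condition, class_column=class_column)

    def step_function_summary(self) -> "StepFunctionSummary":
        return step_function_summary(self.records)


# ---------------------------------------------------------------------------
# pipeline


def _generate_vesicle(
    cls: str, config: PipelineConfig, rng: np.random.Generator, seed: int
) -> synth.DomainConfiguration:
    nmin, nmax = config.n_range[cls]
    n = int(rng.integers(nmin, nmax + 1))
    dv = float(rng.uniform(*config.dv_range))
    rv = dv / 2.0
    if cls == "lattice":
        return synth.make_lattice(
            n, config.phi, rv, jitter=config.lattice_jitter, seed=seed
        )
    if cls == "disordered":
        return synth.make_disordered(
            n, config.phi, rv, seed=seed, exclusion=config.disordered_exclusion
        )
    if cls == "associated":
        alpha = synth.cap_half_angle(config.phi, n)
        step = synth._chain_angular_step(alpha, config.gap_ratio)
        dd = 2.0 * rv * math.sin(alpha)
        chain_fits = (
            n <= geometry.belt_capacity(dv, dd) and n * step <= 2.0 * math.pi
        )
        if chain_fits:
            return synth.make_chain(
                n,
                config.phi,
                rv,
                gap_ratio=config.gap_ratio,
                jitter=config.chain_jitter,
                seed=seed,
            )
        return synth.make_plaque(
            n,
            config.phi,
            rv,
            gap_ratio=config.gap_ratio,
            jitter=config.plaque_jitter,
            seed=seed,
        )
    raise InvalidInputError(f"unknown generator class {cls!r}")


def _choose_pole(config_obj: synth.DomainConfiguration) -> np.ndarray:
    """Viewing pole per pattern class.

    Lattice and disordered vesicles are statistically isotropic, so a
    random (but seed-determined) viewing direction emulates the arbitrary
    orientation of a vesicle under the microscope.  Associated structures
    occupy a small part of the sphere; the microscopist focuses on them,
    so the view is centred on the first plate of the chain/plaque.
    """
    if config_obj.pattern_class == "associated_chain":
        # middle plate of the chain arc, so neighbours flank the pole
        return config_obj.centers[config_obj.n_domains // 2].copy()
    if config_obj.pattern_class == "associated_plaque":
        return config_obj.centers[0].copy()
    rng = np.random.default_rng(config_obj.seed + 2)
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def generate_vesicles(
    config: PipelineConfig | None = None, seed: int = 0
) -> tuple[list[tuple[str, str, synth.DomainConfiguration]], list[dict]]:
    """Generate all requested vesicle configurations (with assigned
    excess areas), deterministically from ``(config, seed)``.

    Returns ``(entries, failures)`` where each entry is
    ``(vesicle_id, condition, configuration)``.
    """
    from dataclasses import replace

    if config is None:
        config = PipelineConfig.balanced(50)
    master = np.random.SeedSequence(seed)
    entries: list[tuple[str, str, synth.DomainConfiguration]] = []
    failures: list[dict] = []
    vesicle_index = 0
    for condition in sorted(config.conditions):
        spec = config.conditions[condition]
        for cls in sorted(spec.class_counts):
            for _ in range(spec.class_counts[cls]):
                child = np.random.SeedSequence(
                    entropy=master.entropy, spawn_key=(vesicle_index,)
                )
                child_seed = int(child.generate_state(1)[0] % (2**31))
                vesicle_id = f"{condition}-{cls}-{vesicle_index:04d}"
                vesicle_index += 1
                rng = np.random.default_rng(child_seed)
                try:
                    domain_config = _generate_vesicle(cls, config, rng, child_seed)
                    axs = synth.assign_excess_area(
                        cls, seed=child_seed + 1, ranges=config.axs_ranges
                    )
                    domain_config = replace(domain_config, excess_area=axs)
                except Exception as exc:
                    logger.warning("vesicle %s generation failed: %s", vesicle_id, exc)
                    failures.append(
                        {
                            "vesicle_id": vesicle_id,
                            "stage": type(exc).__name__,
                            "message": str(exc),
                        }
                    )
                    continue
                entries.append((vesicle_id, condition, domain_config))
    return entries, failures


def analyze_configuration(
    domain_config: synth.DomainConfiguration,
    config: PipelineConfig,
    pole: np.ndarray,
    seed: int = 0,
) -> dict:
    """Measure one vesicle: project, (optionally render and re-detect),
    triangulate, classify, and measure edge–edge separations."""
    theta_max = config.focal_band_half_angle or synth.default_focal_half_angle(
        domain_config.n_domains
    )
    view = synth.project_focal_plane(
        domain_config, pole=pole, focal_band_half_angle=theta_max
    )
    if config.render:
        image = synth.render_micrograph(
            view,
            pixel_scale=config.pixel_scale,
            noise_sd=config.noise_sd,
            shot_noise=config.shot_noise,
            seed=seed,
        )
        centers, radii = patterns.detect_domains(image, config.pixel_scale)
        rv = domain_config.vesicle_radius
        angular = np.arcsin(np.clip(radii / rv, 0.0, 1.0))
        r = np.linalg.norm(centers, axis=1)
        polar = np.arcsin(np.clip(r / rv, 0.0, 1.0))
        view = synth.FocalPlaneView(
            centers_xy=centers,
            apparent_radii=radii,
            major_radii=radii,
            orientations=np.zeros(len(radii)),
            angular_radii=angular,
            polar_angles=polar,
            domain_ids=np.arange(len(radii)),
            vesicle_radius=rv,
            focal_band_half_angle=theta_max,
        )
    _, classified = patterns.measure_view(view, k_max=config.k_max)
    dee = patterns.edge_edge_separations(
        view, central_fraction=config.central_fraction
    )
    return {
        "cv": classified.cv,
        "lindemann": classified.lindemann,
        "label": classified.label,
        "dee_over_dd_mean": float(np.mean(dee)),
        "theta_max_deg": math.degrees(theta_max),
    }


_BASE_CLASS = {
    "lattice": "lattice",
    "disordered": "disordered",
    "associated_chain": "associated",
    "associated_plaque": "associated",
}


def analyze_entries(
    entries: list[tuple[str, str, synth.DomainConfiguration]],
    config: PipelineConfig | None = None,
    seed: int | None = None,
    failures: list[dict] | None = None,
) -> StateSpaceTable:
    """Measure a list of labelled configurations into a state-space table.

    Per-vesicle measurement failures are recorded and analysis continues.
    """
    if config is None:
        config = PipelineConfig.balanced(50)
    rows: list[dict] = []
    failures = list(failures or [])
    for vesicle_id, condition, domain_config in entries:
        pole = _choose_pole(domain_config)
        try:
            measured = analyze_configuration(
                domain_config, config, pole, seed=domain_config.seed
            )
        except Exception as exc:  # recorded, pipeline continues
            logger.warning("vesicle %s analysis failed: %s", vesicle_id, exc)
            failures.append(
                {
                    "vesicle_id": vesicle_id,
                    "stage": type(exc).__name__,
                    "message": str(exc),
                }
            )
            continue
        rows.append(
            {
                "vesicle_id": vesicle_id,
                "condition": condition,
                "pattern_class": _BASE_CLASS[domain_config.pattern_class],
                "generator": domain_config.pattern_class,
                "N": domain_config.n_domains,
                "Dv_um": domain_config.vesicle_diameter,
                "Dd_um": float(np.mean(domain_config.domain_diameters)),
                "phi": config.phi,
                "axs": domain_config.excess_area,
                "seed": domain_config.seed,
                **measured,
            }
        )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return StateSpaceTable(records=records, config=config, seed=seed, failures=failures)


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> StateSpaceTable:
    """Generate and measure a full synthetic state space.

    For every requested vesicle: draw (N, Dv), generate the configuration
    for its class, assign an excess area from the class window, project a
    focal-plane view (optionally render a micrograph and re-detect the
    domains), run the limited-Delaunay classification, and measure mean
    Dee/Dd.  Per-vesicle failures are recorded and the pipeline
    continues.  Fully deterministic in ``(config, seed)``.
    """
    if config is None:
        config = PipelineConfig.balanced(50)
    entries, failures = generate_vesicles(config, seed)
    return analyze_entries(entries, config, seed=seed, failures=failures)


# ---------------------------------------------------------------------------
# summaries


def estimate_boundary(
    records: pd.DataFrame, class_column: str = "pattern_class"
) -> BoundaryEstimate:
    """Empirical excess-area gap between associated and lattice vesicles.

    Returns ``[max Axs among associated, min Axs among lattice]``.  If
    the classes overlap in Axs the interval is inverted and flagged.
    """
    classes = records[class_column].astype(str)
    associated = records.loc[classes.str.startswith("associated"), "axs"]
    lattice = records.loc[classes == "lattice", "axs"]
    if associated.empty or lattice.empty:
        raise InsufficientClassError(
            "boundary estimation needs at least one associated and one lattice record"
        )
    lower = float(associated.max())
    upper = float(lattice.min())
    return BoundaryEstimate(lower=lower, upper=upper, overlapping=lower > upper)


def condition_histogram(
    records: pd.DataFrame, condition: str, class_column: str = "pattern_class"
) -> dict[str, int]:
    """Counts of each pattern class under one osmotic condition."""
    present = records["condition"].unique()
    if condition not in present:
        raise InvalidInputError(
            f"condition {condition!r} not in table (has {sorted(present)})"
        )
    subset = records.loc[records["condition"] == condition, class_column]
    return {str(k): int(v) for k, v in subset.value_counts().items()}


@dataclass(frozen=True)
class StepFunctionSummary:
    """Edge–edge separations ordered by excess area, with the two-group
    contrast that exposes the step-function transition."""

    table: pd.DataFrame  # columns: axs, dee_over_dd, pattern_class, phi (sorted by axs)
    associated_mean: float | None
    lattice_mean: float | None
    lattice_expected: float | None  # hex-cell prediction at the records' mean φ
    group_means: dict[str, float]
    consistent: bool


def step_function_summary(
    records: pd.DataFrame, phi_split: float = 0.17
) -> StepFunctionSummary:
    """Summarise mean Dee/Dd against Axs.

    Verifies the step-function contrast: associated vesicles sit at small
    normalised separations (< 0.5) while lattice vesicles scatter around
    the hexagonal-cell prediction for their solid area fraction (± 0.15).
    Lattice records are additionally split into low-/high-φ groups at
    ``phi_split`` to mirror how solid-fraction variation spreads the
    lattice branch.
    """
    table = (
        records[["axs", "dee_over_dd_mean", "pattern_class", "phi"]]
        .rename(columns={"dee_over_dd_mean": "dee_over_dd"})
        .sort_values("axs", kind="mergesort")
        .reset_index(drop=True)
    )
    associated = table[table["pattern_class"].str.startswith("associated")]
    lattice = table[table["pattern_class"] == "lattice"]
    associated_mean = float(associated["dee_over_dd"].mean()) if len(associated) else None
    lattice_mean = float(lattice["dee_over_dd"].mean()) if len(lattice) else None
    lattice_expected = (
        float(geometry.hex_edge_separation(float(lattice["phi"].mean())))
        if len(lattice)
        else None
    )
    group_means: dict[str, float] = {}
    if len(lattice):
        low = lattice[lattice["phi"] < phi_split]
        high = lattice[lattice["phi"] >= phi_split]
        if len(low):
            group_means["lattice_low_phi"] = float(low["dee_over_dd"].mean())
        if len(high):
            group_means["lattice_high_phi"] = float(high["dee_over_dd"].mean())
    if associated_mean is not None:
        group_means["associated"] = associated_mean
    consistent = True
    if associated_mean is not None and not (associated_mean < 0.5):
        consistent = False
    if len(lattice):
        deviations = np.array(
            [
                abs(row.dee_over_dd - geometry.hex_edge_separation(row.phi))
                for row in lattice.itertuples()
            ]
        )
        if np.any(deviations > 0.15):
            consistent = False
    return StepFunctionSummary(
        table=table,
        associated_mean=associated_mean,
        lattice_mean=lattice_mean,
        lattice_expected=lattice_expected,
        group_means=group_means,
        consistent=consistent,
    )


# ---------------------------------------------------------------------------
# persistence


def write_records(table: StateSpaceTable, directory) -> tuple[Path, Path]:
    """Write a records CSV plus JSON metadata sidecar.

    Floats are serialised at 12 significant digits; writing the same
    table twice produces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "records.csv"
    meta_path = directory / "records.meta.json"
    table.records.to_csv(csv_path, index=False, float_format="%.12g")
    meta = {
        "schema_version": _SCHEMA_VERSION,
        "columns": RECORD_COLUMNS,
        "n_records": int(table.n_records),
        "seed": table.seed,
        "config": table.config.to_dict() if table.config is not None else None,
        "failures": table.failures,
    }
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, meta_path


def read_records(directory) -> StateSpaceTable:
    """Read a records CSV (+ optional sidecar) back into a table.

    Raises :class:`SchemaError` naming the first missing column.
    """
    directory = Path(directory)
    csv_path = directory / "records.csv" if directory.is_dir() else directory
    records = pd.read_csv(csv_path)
    for column in RECORD_COLUMNS:
        if column not in records.columns:
            raise SchemaError(f"records file {csv_path} is missing column {column!r}")
    records = records[RECORD_COLUMNS].astype(_COLUMN_DTYPES)
    meta_path = (
        csv_path.parent / "records.meta.json"
        if csv_path.name.endswith(".csv")
        else None
    )
    config = None
    seed = None
    failures: list[dict] = []
    if meta_path is not None and meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        if meta.get("schema_version") != _SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {meta.get('schema_version')!r}"
            )
        if meta.get("config"):
            config = PipelineConfig.from_dict(meta["config"])
        seed = meta.get("seed")
        failures = meta.get("failures", [])
    return StateSpaceTable(records=records, config=config, seed=seed, failures=failures)
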