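"""Synthetic fate-mapping cohorts and composition tables with known truth.

The cohort generator mirrors the measurement chain of Y-chromosome in situ
fate mapping after sex-mismatched peripheral blood stem cell transplantation
(PBSCT): donor engraftment in a CNS border compartment rises linearly on
log10 time, a histological section samples a finite number of marker-positive
cells, and chromogenic in situ hybridisation detects the Y chromosome only in
a fraction ``d`` of truly male cells because sectioning truncates nuclei.
Male control tissue — where every cell carries a Y chromosome — calibrates
``d``.

Generative model per transplanted patient in compartment ``c``::

    t        ~ LogUniform(time_range)                  (days post-PBSCT)
    latent   = clip(b0_c + b1_c * log10(t), 0, 100)    (percent donor)
    latent   = clip(latent + Normal(0, noise_sd), 0, 100)
    donor    ~ Binomial(cells_per_section, latent/100)
    n_y_pos  ~ Binomial(donor, d_c)                    (detected donor cells)

and per male control sample::

    n_y_pos  ~ Binomial(control_cells_per_section, d_c)

Ground-truth parameters (intercept, slope, detection rate, implied T50) are
returned alongside the table so downstream recovery tests never re-derive
them.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentSpec",
    "SimulationConfig",
    "DEFAULT_COMPARTMENTS",
    "simulate_cohort",
    "simulate_composition",
]


@dataclass(frozen=True)
class CompartmentSpec:
    """Ground-truth engraftment kinetics for one anatomical compartment.

    Parameters
    ----------
    name : compartment label (e.g. ``"CP"``, ``"LM"``, ``"DM"``, ``"PC"``).
    intercept : b0, engraftment percent at t = 1 day.
    slope : b1, percent per log10-day.
    detection_rate : probability of observing a Y chromosome in a truly
        male cell of this compartment; in (0, 1].
    """

    name: str
    intercept: float
    slope: float
    detection_rate: float = 0.8

    @classmethod
    def from_t50(
        cls,
        name: str,
        t50_days: float,
        slope: float = 50.0,
        detection_rate: float = 0.8,
    ) -> "CompartmentSpec":
        """Build a spec whose line crosses 50 % at ``t50_days``."""
        if t50_days <= 0:
            raise ValueError(f"t50_days: must be positive for compartment {name!r}")
        intercept = 50.0 - slope * math.log10(t50_days)
        return cls(name=name, intercept=intercept, slope=slope, detection_rate=detection_rate)

    @property
    def t50_days(self) -> float:
        """Time at which the latent line crosses 50 % (nan if slope <= 0)."""
        if self.slope <= 0:
            return math.nan
        return 10.0 ** ((50.0 - self.intercept) / self.slope)


# Default cohort: four CNS border compartments spanning the fast-turnover
# choroid plexus (T50 ~51.5 d) to the slow parenchyma (~264.6 d), with the
# leptomeninges and dura in between.
DEFAULT_COMPARTMENTS: tuple[CompartmentSpec, ...] = (
    CompartmentSpec.from_t50("CP", 51.52),
    CompartmentSpec.from_t50("LM", 100.0),
    CompartmentSpec.from_t50("DM", 150.0),
    CompartmentSpec.from_t50("PC", 264.55),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design and noise parameters for :func:`simulate_cohort`.

    Defaults emulate the study design: ~12 sex-mismatched PBSCT recipients
    per compartment sampled between one month and three years after
    transplantation, >=100 marker-positive cells counted per patient and
    compartment, 3 male control samples for calibration, and a residual
    biological scatter of 10 percentage points on the latent engraftment.
    """

    compartments: tuple[CompartmentSpec, ...] = DEFAULT_COMPARTMENTS
    n_patients: int = 12
    time_range: tuple[float, float] = (30.0, 1095.0)
    cells_per_section: int = 100
    n_control_samples: int = 3
    control_cells_per_section: int = 200
    residual_noise_sd: float = 10.0
    marker: str = "Iba1"
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on any violation."""
        if not self.compartments:
            raise ValueError("compartments: at least one compartment is required")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("compartments: names must be unique")
        for comp in self.compartments:
            if not (0.0 < comp.detection_rate <= 1.0):
                raise ValueError(
                    f"detection_rate: must lie in (0, 1] for compartment {comp.name!r}, "
                    f"got {comp.detection_rate}"
                )
        if self.n_patients < 1:
            raise ValueError(f"n_patients: must be >= 1, got {self.n_patients}")
        lo, hi = self.time_range
        if lo <= 0:
            raise ValueError(f"time_range: minimum must be > 0 days, got {lo}")
        if hi < lo:
            raise ValueError(f"time_range: maximum {hi} is below minimum {lo}")
        if self.cells_per_section < 1:
            raise ValueError(f"cells_per_section: must be >= 1, got {self.cells_per_section}")
        if self.n_control_samples < 1:
            raise ValueError(f"n_control_samples: must be >= 1, got {self.n_control_samples}")
        if self.control_cells_per_section < 1:
            raise ValueError(
                f"control_cells_per_section: must be >= 1, got {self.control_cells_per_section}"
            )
        if self.residual_noise_sd < 0:
            raise ValueError(
                f"residual_noise_sd: must be >= 0, got {self.residual_noise_sd}"
            )

    def ground_truth(self) -> dict:
        """Structured ground-truth record (the sidecar written next to cohorts)."""
        return {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "time_range": list(self.time_range),
            "cells_per_section": self.cells_per_section,
            "n_control_samples": self.n_control_samples,
            "control_cells_per_section": self.control_cells_per_section,
            "residual_noise_sd": self.residual_noise_sd,
            "marker": self.marker,
            "compartments": {
                c.name: {
                    "intercept": c.intercept,
                    "slope": c.slope,
                    "detection_rate": c.detection_rate,
                    "t50_days": c.t50_days,
                }
                for c in self.compartments
            },
        }


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic cohort (male controls + transplanted patients).

    Returns
    -------
    table : DataFrame with columns ``patient_id, compartment, marker,
        days_post_transplant, n_marker_pos, n_y_pos, is_male_control``.
        Control rows carry ``days_post_transplant = NaN``.
    ground_truth : dict of the generating parameters (see
        :meth:`SimulationConfig.ground_truth`).

    The same config (including seed) always yields a byte-identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    log_lo, log_hi = (math.log10(config.time_range[0]), math.log10(config.time_range[1]))

    for comp in config.compartments:
        # male controls: every cell truly Y+, detection thins binomially
        n_y_ctrl = rng.binomial(
            config.control_cells_per_section, comp.detection_rate, size=config.n_control_samples
        )
        for i, n_y in enumerate(n_y_ctrl, start=1):
            rows.append(
                {
                    "patient_id": f"{comp.name}-M{i:02d}",
                    "compartment": comp.name,
                    "marker": config.marker,
                    "days_post_transplant": np.nan,
                    "n_marker_pos": config.control_cells_per_section,
                    "n_y_pos": int(n_y),
                    "is_male_control": True,
                }
            )

        days = 10.0 ** rng.uniform(log_lo, log_hi, size=config.n_patients)
        latent = np.clip(comp.intercept + comp.slope * np.log10(days), 0.0, 100.0)
        if config.residual_noise_sd > 0:
            latent = np.clip(
                latent + rng.normal(0.0, config.residual_noise_sd, size=config.n_patients),
                0.0,
                100.0,
            )
        donor = rng.binomial(config.cells_per_section, latent / 100.0)
        n_y = rng.binomial(donor, comp.detection_rate)
        for i in range(config.n_patients):
            rows.append(
                {
                    "patient_id": f"{comp.name}-P{i + 1:02d}",
                    "compartment": comp.name,
                    "marker": config.marker,
                    "days_post_transplant": float(days[i]),
                    "n_marker_pos": config.cells_per_section,
                    "n_y_pos": int(n_y[i]),
                    "is_male_control": False,
                }
            )

    table = pd.DataFrame(rows)
    return table, config.ground_truth()


def simulate_composition(
    n_cells: int,
    n_clusters: int,
    condition_props: "list[float] | np.ndarray",
    planted: "list[tuple[int | str, int | str, float]] | None" = None,
    seed: int = 0,
    cluster_labels: "list[str] | None" = None,
    condition_labels: "list[str] | None" = None,
) -> pd.DataFrame:
    """Multinomial cluster x condition cell-count table with planted effects.

    Cells fall into (cluster, condition) pairs with probability proportional
    to ``cluster_weight * condition_props[j] * fold``, where ``fold`` is 1
    except for entries listed in ``planted`` as ``(cluster, condition,
    fold-enrichment)``; clusters are equally weighted. The grand total of the
    returned table equals ``n_cells`` exactly. With no planted effects the
    per-cluster condition proportions converge to ``condition_props``.

    Raises ``ValueError`` for degenerate proportions (any < 0, or zero sum)
    or non-positive folds.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells: must be >= 1, got {n_cells}")
    if n_clusters < 1:
        raise ValueError(f"n_clusters: must be >= 1, got {n_clusters}")
    props = np.asarray(condition_props, dtype=float)
    if props.ndim != 1 or props.size < 1:
        raise ValueError("condition_props: must be a non-empty 1-d sequence")
    if np.any(props < 0):
        raise ValueError("condition_props: proportions must be non-negative")
    total = props.sum()
    if total <= 0:
        raise ValueError("condition_props: proportions must sum to a positive value")
    props = props / total

    if cluster_labels is None:
        cluster_labels = [f"C{i}" for i in range(n_clusters)]
    if condition_labels is None:
        condition_labels = [f"cond{j}" for j in range(props.size)]
    if len(cluster_labels) != n_clusters or len(condition_labels) != props.size:
        raise ValueError("label lists must match n_clusters / condition_props lengths")

    weight = np.tile(props, (n_clusters, 1))
    for entry in planted or []:
        cluster, condition, fold = entry
        if fold <= 0:
            raise ValueError(f"planted: fold-enrichment must be > 0, got {fold}")
        ci = cluster_labels.index(cluster) if isinstance(cluster, str) else int(cluster)
        cj = condition_labels.index(condition) if isinstance(condition, str) else int(condition)
        weight[ci, cj] *= fold
    cell_probs = weight / weight.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, cell_probs.ravel()).reshape(n_clusters, props.size)
    return pd.DataFrame(counts, index=list(cluster_labels), columns=list(condition_labels))
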