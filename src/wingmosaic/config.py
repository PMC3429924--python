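"""Configuration objects for the simulator and the pipeline.

The defaults encode the biology of the assay: a mid-third-instar wing disc
of ~5,500 cells is exposed, its cells complete about three more synchronous
division rounds before proliferation stops, roughly half of the resulting
cells end up in the screened wing-blade area, and the screened area of one
adult wing comprises about 30,000 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

__all__ = ["SimulationConfig", "CallingConfig", "StatsConfig", "PipelineConfig"]

#: hard ceiling on the simulated cell population (guards runaway configs)
DEFAULT_CELL_CAP = 2**23


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated wing.

    Parameters
    ----------
    n0 : int
        Unlabeled disc cells present at treatment (default 5500).
    rounds : int
        Synchronous division rounds between treatment and the end of
        proliferation (default 3).
    p_loss : float
        Per-division probability that a dividing unlabeled cell loses the
        rescuing Y chromosome, producing exactly one labeled (mwh) daughter.
        Dimensionless, in [0, 1]. Default is the spontaneous control rate
        1.7e-4 per cell division.
    blade_fraction : float
        Fraction of the final disc population sampled into the screened
        wing-blade area (default 0.5).
    screened_cells : int
        C, the number of screened (non-hinge) cells per wing (default 30000).
        The blade sample is truncated or padded with unlabeled cells to
        exactly this count.
    death_fraction : float
        Regeneration mode: fraction of treatment-time cells killed outright
        (default 0; X-ray-like conditions use 0.4-0.6).
    extra_rounds : int
        Regeneration mode: compensatory division rounds performed by all
        survivors, labeled and unlabeled alike (default 0).
    trichome_min, trichome_max : int
        Trichome count range rendered on labeled (mwh) cells; mwh cells bear
        2-5 short trichomes of divergent polarity instead of one.
    noise_rate : float
        Fraction of wild-type cells rendered with two *same-direction*
        trichomes (a scoring confounder that must not be called mwh).
    clone_gap : int
        Minimum number of unlabeled lattice cells separating distinct clone
        patches when the wing is embedded (default 5, i.e. comfortably more
        than the 3-cell merging rule).
    seed : int
        Seed for the single random stream driving all draws.
    max_cells : int
        Safety cap on ``n0 * 2**(rounds + extra_rounds)``.
    """

    n0: int = 5500
    rounds: int = 3
    p_loss: float = 1.7e-4
    blade_fraction: float = 0.5
    screened_cells: int = 30000
    death_fraction: float = 0.0
    extra_rounds: int = 0
    trichome_min: int = 2
    trichome_max: int = 5
    noise_rate: float = 0.0
    clone_gap: int = 5
    seed: int = 0
    max_cells: int = DEFAULT_CELL_CAP

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_loss <= 1.0:
            raise ValueError(f"p_loss must be in [0, 1], got {self.p_loss}")
        if not 0.0 <= self.death_fraction < 1.0:
            raise ValueError(
                f"death_fraction must be in [0, 1), got {self.death_fraction}"
            )
        if self.n0 < 1:
            raise ValueError(f"n0 must be >= 1, got {self.n0}")
        if self.rounds < 0 or self.extra_rounds < 0:
            raise ValueError("rounds and extra_rounds must be >= 0")
        if not 0.0 < self.blade_fraction <= 1.0:
            raise ValueError(
                f"blade_fraction must be in (0, 1], got {self.blade_fraction}"
            )
        if self.screened_cells < 1:
            raise ValueError("screened_cells must be >= 1")
        if self.trichome_min < 2:
            raise ValueError("trichome_min must be >= 2 (the mwh phenotype)")
        if self.trichome_max < self.trichome_min:
            raise ValueError("trichome_max must be >= trichome_min")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if self.clone_gap < 1:
            raise ValueError("clone_gap must be >= 1")
        ceiling = self.n0 * 2 ** (self.rounds + self.extra_rounds)
        if ceiling > self.max_cells:
            raise ResourceWarningError(
                f"population ceiling {ceiling} exceeds the safety cap "
                f"{self.max_cells}; raise max_cells deliberately if intended"
            )

    @property
    def total_rounds(self) -> int:
        return self.rounds + self.extra_rounds

    def replace(self, **changes: Any) -> "SimulationConfig":
        return replace(self, **changes)


class ResourceWarningError(RuntimeError):
    """Raised when a configuration would exceed the simulated-cell cap."""


@dataclass(frozen=True)
class CallingConfig:
    """Clone-scoring parameters: the merging distance and the hinge mask."""

    max_gap: int = 3
    hinge_x: int | None = None  # exclude cells with x < hinge_x
    min_trichomes_solo: int = 2

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_trichomes_solo < 2:
            raise ValueError("min_trichomes_solo must be >= 2")


@dataclass(frozen=True)
class StatsConfig:
    """Summary-statistic parameters mirroring the published table layout."""

    screened_cells: int = 30000
    classes: int = 8
    pool_below: float = 1.0
    m_override: Mapping[str, float] | None = None
    i_max: int = 6
    n_bootstrap: int = 500


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group of a pipeline run."""

    label: str
    n_wings: int
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.n_wings < 1:
            raise ValueError("n_wings must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of a simulate -> call -> summarise run."""

    groups: tuple[GroupSpec, ...]
    calling: CallingConfig = field(default_factory=CallingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: str = "wingmosaic_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate group labels: {labels}")


def _coerce(value: str, target_type: type) -> Any:
    if target_type is bool:
        return value.strip().lower() in {"1", "true", "yes"}
    return target_type(value)


def load_pipeline_config(path: str) -> PipelineConfig:
    """Read a flat key-value config file with block prefixes.

    Lines look like ``simulation.p_loss: 1.7e-4``, ``calling.max_gap: 3``,
    ``group.control.n_wings: 108``, ``group.control.p_loss: 0.00017``,
    ``seed: 1``. Group-scoped simulation fields override the shared
    ``simulation.*`` block. ``#`` starts a comment.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")

    sim_fields = {f.name: f.type for f in fields(SimulationConfig)}
    base_sim: dict[str, Any] = {}
    calling_kw: dict[str, Any] = {}
    stats_kw: dict[str, Any] = {}
    top: dict[str, Any] = {}
    group_kw: dict[str, dict[str, Any]] = {}

    for key, value in raw.items():
        parts = str(key).split(".")
        if parts[0] == "simulation" and len(parts) == 2:
            base_sim[parts[1]] = value
        elif parts[0] == "calling" and len(parts) == 2:
            calling_kw[parts[1]] = value
        elif parts[0] == "stats" and len(parts) == 2:
            stats_kw[parts[1]] = value
        elif parts[0] == "group" and len(parts) == 3:
            group_kw.setdefault(parts[1], {})[parts[2]] = value
        elif len(parts) == 1:
            top[parts[0]] = value
        else:
            raise ValueError(f"{path}: unrecognised key {key!r}")

    if not group_kw:
        group_kw = {"default": {"n_wings": top.pop("n_wings", 1)}}

    groups = []
    for label, kw in group_kw.items():
        kw = dict(kw)
        n_wings = int(kw.pop("n_wings", 1))
        sim_kw = dict(base_sim)
        for k, v in kw.items():
            if k not in sim_fields:
                raise ValueError(f"{path}: unknown simulation field {k!r} in group {label!r}")
            sim_kw[k] = v
        groups.append(GroupSpec(label=label, n_wings=n_wings, simulation=SimulationConfig(**sim_kw)))

    return PipelineConfig(
        groups=tuple(groups),
        calling=CallingConfig(**calling_kw),
        stats=StatsConfig(**stats_kw),
        output_dir=str(top.get("output_dir", "wingmosaic_out")),
        seed=int(top.get("seed", 0)),
        log_level=str(top.get("log_level", "INFO")),
    )
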