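"""Configuration objects for every pipeline stage.

All stages are driven by plain dataclasses so that a whole run can be
serialized to / loaded from JSON or YAML, hashed, and recorded alongside the
outputs it produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# Driver names used by the default synthetic scenario.
DEFAULT_DRIVERS = (
    "altitude",
    "temperature",
    "precipitation",
    "drought",
    "eutrophication",
    "livestock",
    "human_footprint",
    "fragmentation",
    "artificial_cover",
    "forest_cover",
)


@dataclass
class LandscapeConfig:
    """Synthetic landscape: sites in a rectangle with correlated driver fields.

    Each driver field is a deterministic trend in the site coordinates and
    altitude plus a Gaussian random field with exponential covariance whose
    correlation length is ``sac_range`` (km).
    """

    n_sites: int = 400
    extent: tuple[float, float] = (200.0, 200.0)  # km x km
    sac_range: float = 50.0  # km; spatial correlation length of residual fields
    #: per-driver (intercept, coef_x, coef_y, coef_altitude) trend coefficients
    driver_gradients: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "altitude": (1200.0, 0.0, -5.0, 0.0),  # altitude falls with latitude (y)
            "temperature": (16.0, 0.0, 0.0, -0.0065),  # lapse rate ~6.5 C/km
            "precipitation": (700.0, 0.0, 0.0, 0.45),  # wetter uplands
            "drought": (45.0, 0.0, 0.0, -0.012),  # longer dry spells in lowlands
            "eutrophication": (60.0, 0.0, 0.0, -0.035),  # nutrient-rich lowlands
            "livestock": (80.0, 0.0, 0.0, -0.045),
            "human_footprint": (30.0, 0.0, 0.0, -0.012),
            "fragmentation": (0.25, 0.0, 0.0, 0.00025),  # more barriers upland
            "artificial_cover": (12.0, 0.0, 0.0, -0.006),
            "forest_cover": (25.0, 0.0, 0.0, 0.025),
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "altitude": 150.0,
            "temperature": 1.2,
            "precipitation": 90.0,
            "drought": 6.0,
            "eutrophication": 9.0,
            "livestock": 25.0,
            "human_footprint": 8.0,
            "fragmentation": 0.08,
            "artificial_cover": 4.0,
            "forest_cover": 8.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError(f"n_sites must be >= 2, got {self.n_sites}")
        if self.sac_range <= 0:
            raise ValueError(f"sac_range must be > 0, got {self.sac_range}")
        if any(e <= 0 for e in self.extent):
            raise ValueError(f"extent sides must be positive, got {self.extent}")


@dataclass
class SpeciesPoolConfig:
    """Niche construction for the synthetic species pool.

    Exotics are biased toward low-altitude, warm, nutrient-enriched optima;
    natives are spread across the full gradient.  ``exotic_niche_drivers``
    restricts which drivers actually shape exotic niches (others get infinite
    breadth, i.e. no response), which is how planted-signal scenarios declare
    "exotic abundance is driven by these drivers".
    """

    n_native: int = 15
    n_exotic: int = 8
    exotic_niche_drivers: tuple[str, ...] = ("eutrophication", "temperature")
    native_niche_drivers: tuple[str, ...] = ("temperature", "precipitation")
    #: bias of exotic optima, in sd units above the landscape mean of each
    #: exotic niche driver (low-altitude end of the gradient)
    exotic_bias: float = 1.0
    niche_breadth_factor: float = 1.0  # multiplies the default breadth (field sd)
    #: when False, the corresponding origin carries no altitude niche term
    #: (planted-signal scenarios constrain responses to the named drivers only)
    exotic_altitude_niche: bool = True
    native_altitude_niche: bool = True
    #: per-driver multiplier on exotic niche breadth (smaller = sharper
    #: response = stronger effect); drivers not listed use 1.0
    exotic_breadth_scale: dict[str, float] = field(default_factory=dict)
    max_expected_abundance: float = 500.0
    seed: int = 0


@dataclass
class CommunityConfig:
    """Moyle-class sampling of communities from Gaussian niche responses."""

    #: abundance breakpoints mapping realized abundance to Moyle classes 1..5;
    #: below the first breakpoint the species is recorded absent (class 0)
    moyle_breakpoints: tuple[float, ...] = (1.0, 4.0, 16.0, 64.0, 256.0)
    #: negative-binomial-style gamma overdispersion (variance of the
    #: multiplicative noise); 0 disables noise entirely
    dispersion: float = 0.5
    seed: int = 0


@dataclass
class RiverConfig:
    """Synthetic dendritic (binary-tree) river network."""

    depth: int = 6  # tree depth; 2**(depth+1) - 2 edges
    edge_length_km: tuple[float, float] = (2.0, 12.0)  # uniform range
    seed: int = 0


@dataclass
class BarrierConfig:
    density_per_km: float = 0.1
    #: probabilities of categories 1..4 (small jump, high jump, minor dam, major dam)
    category_probs: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if len(self.category_probs) != 4 or any(p < 0 for p in self.category_probs):
            raise ValueError("category_probs must be 4 nonnegative values")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError(
                f"category_probs must sum to 1, got {sum(self.category_probs)}"
            )
        if self.density_per_km < 0:
            raise ValueError("density_per_km must be >= 0")


@dataclass
class MoyleWeightConfig:
    """Moyle class -> body-mass-corrected abundance.

    abundance = class midpoint x body-size weight.  Defaults: geometric class
    midpoints and size weights doubling from small to large.  Any positive,
    monotone table is valid.
    """

    class_midpoints: tuple[float, ...] = (0.0, 2.0, 8.0, 32.0, 128.0, 512.0)
    size_weights: dict[str, float] = field(
        default_factory=lambda: {"small": 1.0, "medium": 2.0, "large": 4.0}
    )


@dataclass
class FragmentationConfig:
    cutoff_km: float = 10.0
    #: distances are floored at this value (a barrier sitting on the site)
    min_distance_km: float = 0.01
    #: how multiple reachable barriers enter the index: "sum" (arctan of the
    #: summed category/distance terms), "nearest", or "mean_max" (mean distance
    #: x max category)
    mode: str = "sum"


@dataclass
class EutrophicationConfig:
    """Composite water-quality score; high = clean (low eutrophication).

    Each parameter is scored 0-100 by linear interpolation between a pristine
    and a degraded reference value; the station index is the mean of available
    subscores.
    """

    #: parameter -> (pristine value, degraded value); orientation is implied by
    #: which is larger (oxygen saturation: high is good; the rest: low is good)
    references: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "oxygen_saturation": (100.0, 20.0),
            "bod": (1.0, 15.0),
            "cod": (5.0, 50.0),
            "nh4": (0.02, 2.0),
            "no3": (0.5, 25.0),
            "total_p": (0.02, 0.6),
            "e_coli": (100.0, 50000.0),
        }
    )


@dataclass
class BRTConfig:
    """Boosted-regression-tree protocol parameters.

    ``bag_fraction`` is the share of sites withheld from each tree (the
    out-of-bag set used for the CV R-squared); trees are therefore grown on
    1 - bag_fraction of the data.
    """

    bag_fraction: float = 0.25
    min_trees: int = 1000
    learning_rate: float = 0.01
    tree_depth: int = 3
    vi_threshold: float = 7.0
    redundancy_rho: float = 0.8  # |Spearman| above which a pair is redundant
    cv_r2_drop_tolerance: float = 0.02
    direction_mix_tolerance: float = 0.3  # PD curve counter-trend share -> "mixed"
    moran_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.bag_fraction < 1:
            raise ValueError("bag_fraction must be in (0, 1)")
        if self.min_trees < 1000:
            raise ValueError("min_trees must be >= 1000")


@dataclass
class VarpartConfig:
    vif_threshold: float = 8.0
    n_perm_fraction: int = 999
    n_perm_axis: int = 499
    permute_residuals: bool = True  # reduced-model residual permutation scheme
    hellinger: bool = False  # optional transform of the species matrix for RDA
    rda_scaling: int = 2  # correlation biplot
    seed: int = 0


@dataclass
class PipelineConfig:
    """Top-level configuration wiring all stages."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    species: SpeciesPoolConfig = field(default_factory=SpeciesPoolConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    river: RiverConfig = field(default_factory=RiverConfig)
    barriers: BarrierConfig = field(default_factory=BarrierConfig)
    moyle: MoyleWeightConfig = field(default_factory=MoyleWeightConfig)
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    eutrophication: EutrophicationConfig = field(default_factory=EutrophicationConfig)
    brt: BRTConfig = field(default_factory=BRTConfig)
    varpart: VarpartConfig = field(default_factory=VarpartConfig)
    #: variable -> group membership for variation partitioning / RDA
    driver_groups: dict[str, list[str]] = field(
        default_factory=lambda: {
            "Geography": ["altitude"],
            "Climate": ["temperature", "precipitation", "drought"],
            "Human factors": [
                "eutrophication",
                "livestock",
                "human_footprint",
                "fragmentation",
            ],
            "Land use": ["artificial_cover", "forest_cover"],
        }
    )
    top_n_species: int = 10
    seed: int = 0

    def reseed(self, seed: int) -> "PipelineConfig":
        """Return a copy with all stage seeds derived from ``seed``."""
        cfg = replace_deep(self)
        cfg.seed = seed
        cfg.landscape.seed = seed
        cfg.species.seed = seed + 1
        cfg.community.seed = seed + 2
        cfg.river.seed = seed + 3
        cfg.barriers.seed = seed + 4
        cfg.brt.seed = seed + 5
        cfg.varpart.seed = seed + 6
        return cfg


def replace_deep(cfg):
    """Deep copy of a (possibly nested) dataclass."""
    if dataclasses.is_dataclass(cfg):
        return type(cfg)(
            **{
                f.name: replace_deep(getattr(cfg, f.name))
                for f in dataclasses.fields(cfg)
            }
        )
    if isinstance(cfg, dict):
        return {k: replace_deep(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return type(cfg)(replace_deep(v) for v in cfg)
    return cfg


def to_dict(cfg: Any) -> Any:
    if dataclasses.is_dataclass(cfg):
        return {
            f.name: to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)
        }
    if isinstance(cfg, dict):
        return {k: to_dict(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return [to_dict(v) for v in cfg]
    return cfg


def config_hash(cfg: Any) -> str:
    """Stable short hash of a config, recorded in every output bundle."""
    payload = json.dumps(to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type.endswith("Config")
        ):
            sub = getattr(cls, "__dataclass_fields__")[f.name]
            target = sub.default_factory() if callable(sub.default_factory) else None
            if target is not None and isinstance(value, dict):
                value = _build(type(target), value)
        elif isinstance(value, list):
            value = tuple(value) if isinstance(f.default, tuple) else value
        kwargs[f.name] = value
    return cls(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base = PipelineConfig()
    for key, value in (data or {}).items():
        if not hasattr(base, key):
            raise ValueError(f"unknown config section: {key}")
        current = getattr(base, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            setattr(base, key, _build(type(current), value))
        else:
            setattr(base, key, value)
    return base
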