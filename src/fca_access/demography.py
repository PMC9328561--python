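"""Demand-side derivations: small-area MSM estimation and unit centroids.

MSM counts are rarely published directly; the standard small-area approach
scales a per-urbanicity baseline proportion of adult males by the local
share of same-sex male (SSM) households relative to the urbanicity-class
reference share:

    MSM_i = male_pop_i * p_base(urbanicity_i) * ssm_share_i / ssm_ref(urbanicity_i)

("proportional" mode). "baseline-only" mode drops the household rescaling
and applies the baseline proportion alone. Estimates are rounded to the
nearest integer (ties to even) and clamped to [0, male_pop].

The default parameter table below is a documented placeholder with
plausible magnitudes (urban MSM shares of adult males a few percent, rural
near one percent); studies should supply their own table via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from shapely.geometry import Point

from .errors import ConfigError, DataError, ValidationError
from .model import Group, PopulationUnit

#: Placeholder per-urbanicity constants; override from a YAML table for real use.
DEFAULT_P_BASE = {"urban": 0.045, "suburban": 0.025, "rural": 0.013}
DEFAULT_SSM_REF = {"urban": 0.0060, "suburban": 0.0040, "rural": 0.0025}


@dataclass(frozen=True)
class MsmModelParams:
    """Parameters of the SSM-household MSM estimator.

    p_base: baseline MSM proportion of adult males per urbanicity class.
    ssm_share_ref: reference SSM-household share per urbanicity class
        (denominator of the local rescaling ratio).
    mode: "proportional" (rescale by local SSM share) or "baseline-only".
    male_fraction: fallback male share of the 15-64 population when a unit
        lacks an explicit male_pop.
    """

    p_base: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P_BASE))
    ssm_share_ref: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SSM_REF))
    mode: str = "proportional"
    male_fraction: float = 0.49

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "baseline-only"):
            raise ConfigError(f"unknown MSM estimation mode {self.mode!r}")
        for name, table in (("p_base", self.p_base), ("ssm_share_ref", self.ssm_share_ref)):
            for k, v in table.items():
                if not (0.0 <= v <= 1.0):
                    raise ConfigError(f"{name}[{k!r}] = {v} outside [0, 1]")
        if not (0.0 < self.male_fraction <= 1.0):
            raise ConfigError("male_fraction must lie in (0, 1]")


def _male_pop(unit: PopulationUnit, params: MsmModelParams) -> int:
    if unit.male_pop is not None:
        return int(unit.male_pop)
    return int(round(unit.count(Group.AGE15_64) * params.male_fraction))


def estimate_msm(units: Sequence[PopulationUnit],
                 params: Optional[MsmModelParams] = None) -> list[PopulationUnit]:
    """Fill each unit's MSM count from its male population and SSM-household
    share. Returns the same unit objects with counts[MSM] set."""
    params = params or MsmModelParams()
    for unit in units:
        urb = unit.urbanicity
        if urb is None:
            raise ValidationError(f"unit {unit.unit_id!r} has no urbanicity class")
        if urb not in params.p_base:
            raise ConfigError(f"urbanicity {urb!r} missing from p_base table")
        male = _male_pop(unit, params)
        p = params.p_base[urb]
        if params.mode == "proportional":
            ref = params.ssm_share_ref.get(urb)
            if ref is None:
                raise ConfigError(f"urbanicity {urb!r} missing from ssm_share_ref table")
            if ref == 0.0:
                raise ConfigError(
                    f"ssm_share_ref[{urb!r}] is 0; proportional rescaling undefined")
            if unit.households is None or unit.ssm_households is None:
                raise ValidationError(
                    f"unit {unit.unit_id!r} lacks households/ssm_households "
                    "needed for proportional mode")
            if unit.households <= 0:
                raise ValidationError(f"unit {unit.unit_id!r} has non-positive households")
            share = unit.ssm_households / unit.households
            est = male * p * (share / ref)
        else:
            est = male * p
        # round half to even, then clamp to the male population
        msm = min(max(int(round(est)), 0), male)
        unit.counts[Group.MSM] = msm
    return list(units)


def unit_centroid(unit: PopulationUnit) -> Point:
    """Representative demand point: the geometric centroid of the unit's
    polygon (the point itself for point units)."""
    geom = unit.geometry
    if geom is None or geom.is_empty:
        raise DataError(f"unit {unit.unit_id!r} has empty geometry")
    if isinstance(geom, Point):
        return geom
    return geom.centroid
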