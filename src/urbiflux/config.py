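"""Run configuration: YAML loading, defaults, validation.

A run config is a YAML mapping with optional blocks ``soil``,
``irrigation``, ``vegetation`` (per-density-tile overrides), ``weights``,
``scenario`` (classification thresholds, heatwave windows) and
``accounting``, plus top-level ``archetype``, ``start_date``, ``n_days``,
``seed`` and ``out``.  Anything omitted falls back to the packaged
defaults for the chosen archetype; unknown keys are warned about and
ignored; type-invariant violations raise :class:`ConfigError` naming the
offending keys.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .accounting import AccountingInputs
from .biogenic import CanyonGeometry, TileWeights, VegTileParams
from .errors import ConfigError, InvalidArgumentError
from .forcing import HeatwaveWindow, get_archetype
from .scenario import (
    DEFAULT_DOMINANCE_TOL,
    DEFAULT_EPS,
    DEFAULT_SHARE_LO,
    default_surface,
)
from .soil import IrrigationPolicy, SoilParams

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "save_config"]

_TILE_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated effective configuration of one scenario run."""

    archetype: str = "arid"
    start_date: dt.date = dt.date(2015, 5, 1)
    n_days: int = 30
    seed: int = 0
    out: str = "runs"
    soil: SoilParams = field(default_factory=SoilParams)
    irrigation: IrrigationPolicy = field(default_factory=IrrigationPolicy)
    tiles: tuple[VegTileParams, ...] = ()
    weights: TileWeights = field(default_factory=TileWeights)
    heatwaves: tuple[HeatwaveWindow, ...] = ()
    eps: float = DEFAULT_EPS
    share_lo: float = DEFAULT_SHARE_LO
    dominance_tol: float = DEFAULT_DOMINANCE_TOL
    accounting: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        get_archetype(self.archetype)  # raises ConfigError when unknown


def _replace_checked(obj, overrides: dict, section: str):
    """dataclasses.replace with unknown-key warnings and ConfigError wrapping."""
    names = {f.name for f in dataclasses.fields(obj)}
    unknown = sorted(set(overrides) - names)
    if unknown:
        log.warning("ignoring unknown key(s) in %r block: %s", section, unknown)
    known = {k: v for k, v in overrides.items() if k in names}
    try:
        return dataclasses.replace(obj, **known)
    except InvalidArgumentError as exc:
        raise ConfigError(f"invalid {section!r} block: {exc}") from exc


def _parse_date(value, key: str) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigError(f"{key}: not an ISO date: {value!r}") from exc


def load_config(source: str | Path | dict) -> RunConfig:
    """Build a validated RunConfig from a YAML file path or a mapping."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    known_top = {
        "archetype", "start_date", "n_days", "seed", "out", "soil",
        "irrigation", "vegetation", "weights", "scenario", "accounting",
    }
    unknown = sorted(set(raw) - known_top)
    if unknown:
        log.warning("ignoring unknown top-level key(s): %s", unknown)

    archetype = str(raw.get("archetype", "arid"))
    soil, irrigation, tiles, weights = default_surface(archetype)

    if "soil" in raw:
        soil = _replace_checked(soil, raw["soil"] or {}, "soil")
    if "irrigation" in raw:
        irrigation = _replace_checked(irrigation, raw["irrigation"] or {}, "irrigation")
    if "weights" in raw:
        weights = _replace_checked(weights, raw["weights"] or {}, "weights")
    if "vegetation" in raw:
        veg = raw["vegetation"] or {}
        unknown_tiles = sorted(set(veg) - set(_TILE_NAMES))
        if unknown_tiles:
            log.warning("ignoring unknown vegetation tile(s): %s", unknown_tiles)
        def _tile(name: str, tile: VegTileParams) -> VegTileParams:
            overrides = dict(veg.get(name, {}) or {})
            if isinstance(overrides.get("canyon"), dict):
                try:
                    overrides["canyon"] = CanyonGeometry(**overrides["canyon"])
                except (TypeError, InvalidArgumentError) as exc:
                    raise ConfigError(
                        f"invalid 'vegetation.{name}.canyon' block: {exc}"
                    ) from exc
            return _replace_checked(tile, overrides, f"vegetation.{name}")

        tiles = tuple(_tile(n, t) for n, t in zip(_TILE_NAMES, tiles))

    scen = raw.get("scenario", {}) or {}
    heatwaves = tuple(
        HeatwaveWindow(
            start=_parse_date(w["start"], "scenario.heatwaves.start"),
            end=_parse_date(w["end"], "scenario.heatwaves.end"),
            t_offset=float(w.get("t_offset", 4.0)),
        )
        for w in scen.get("heatwaves", [])
    )

    try:
        return RunConfig(
            archetype=archetype,
            start_date=_parse_date(raw.get("start_date", "2015-05-01"), "start_date"),
            n_days=int(raw.get("n_days", 30)),
            seed=int(raw.get("seed", 0)),
            out=str(raw.get("out", "runs")),
            soil=soil,
            irrigation=irrigation,
            tiles=tiles,
            weights=weights,
            heatwaves=heatwaves,
            eps=float(scen.get("eps", DEFAULT_EPS)),
            share_lo=float(scen.get("share_lo", DEFAULT_SHARE_LO)),
            dominance_tol=float(scen.get("dominance_tol", DEFAULT_DOMINANCE_TOL)),
            accounting=dict(raw.get("accounting", {}) or {}),
        )
    except InvalidArgumentError as exc:
        raise ConfigError(str(exc)) from exc


def as_dict(cfg: RunConfig) -> dict:
    """Effective configuration as a plain YAML/JSON-serializable mapping."""
    out = {
        "archetype": cfg.archetype,
        "start_date": cfg.start_date.isoformat(),
        "n_days": cfg.n_days,
        "seed": cfg.seed,
        "out": cfg.out,
        "soil": dataclasses.asdict(cfg.soil),
        "irrigation": dataclasses.asdict(cfg.irrigation),
        "weights": dataclasses.asdict(cfg.weights),
        "vegetation": {
            name: dataclasses.asdict(t) for name, t in zip(_TILE_NAMES, cfg.tiles)
        },
        "scenario": {
            "eps": cfg.eps,
            "share_lo": cfg.share_lo,
            "dominance_tol": cfg.dominance_tol,
            "heatwaves": [
                {"start": w.start.isoformat(), "end": w.end.isoformat(),
                 "t_offset": w.t_offset}
                for w in cfg.heatwaves
            ],
        },
        "accounting": dict(cfg.accounting),
    }
    return out


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Serialize the effective configuration; round-trips via load_config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(as_dict(cfg), sort_keys=True))
    return path


def accounting_inputs(cfg: RunConfig, dnee: float) -> AccountingInputs:
    """AccountingInputs from the config's accounting block and a dnee value."""
    known = {f.name for f in dataclasses.fields(AccountingInputs)} - {"dnee"}
    overrides = {k: v for k, v in cfg.accounting.items() if k in known}
    unknown = sorted(set(cfg.accounting) - known)
    if unknown:
        log.warning("ignoring unknown accounting key(s): %s", unknown)
    try:
        return AccountingInputs(dnee=dnee, **overrides)
    except InvalidArgumentError as exc:
        raise ConfigError(f"invalid 'accounting' block: {exc}") from exc
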