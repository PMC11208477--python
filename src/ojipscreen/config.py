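"""Hierarchical run configuration: schema, defaults, validation, I/O.

One structured config file (YAML or JSON) fully determines a run:
``model`` (rate constants, pool sizes, initial splits, fluorescence
weights), ``light``, ``design`` (Morris parameters), ``screening`` and
``output``.  Unspecified fields take the documented defaults — in
particular the tabulated rate-constant values.  Unknown keys are
rejected everywhere (typo safety).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .etc_model import (
    INTENSE_PFD,
    LOW_PFD,
    InitialStateConfig,
    LightRegime,
    PoolConfig,
    QuenchConfig,
    RateConstantSet,
)
from .morris import MorrisDesign
from .screening import ScreeningConfig

__all__ = ["RunConfig", "load_config", "dump_config", "config_to_dict"]


@dataclass
class RunConfig:
    """Validated bundle of everything a pipeline run needs."""

    rates: RateConstantSet = field(default_factory=RateConstantSet)
    pools: PoolConfig = field(default_factory=PoolConfig)
    init: InitialStateConfig = field(default_factory=InitialStateConfig)
    quench: QuenchConfig = field(default_factory=QuenchConfig)
    k8_both_qa_states: bool = False
    light: LightRegime = field(default_factory=LightRegime.intense)
    design_p: int = 4
    design_m: int = 4
    design_delta: float | None = None
    group: str = "forward"
    scale_fraction: float = 0.20
    aggregation: str = "two_stage"
    points_per_decade: int = 60
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0
    out_dir: str = "ojipscreen-out"

    def design(self, k: int) -> MorrisDesign:
        return MorrisDesign(
            k=k, p=self.design_p, m=self.design_m, delta=self.design_delta
        )

    def screening_config(self) -> ScreeningConfig:
        names_len = 18 if self.group == "forward" else 14
        return ScreeningConfig(
            group=self.group,
            scale_fraction=self.scale_fraction,
            light=self.light,
            design=self.design(names_len),
            seed=self.seed,
            rates=self.rates,
            pools=self.pools,
            init=self.init,
            quench=self.quench,
            aggregation=self.aggregation,
            points_per_decade=self.points_per_decade,
            rtol=self.rtol,
            atol=self.atol,
        )


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {where!r}"
        )


def _build_from_dict(data: dict) -> RunConfig:
    _check_keys(data, {"model", "light", "design", "screening", "output"}, "<root>")
    cfg = RunConfig()

    model = data.get("model") or {}
    _check_keys(
        model,
        {"rates", "fnr_activation", "fnr_sink", "pools", "init", "quench",
         "k8_both_qa_states"},
        "model",
    )
    rates = model.get("rates") or {}
    for key, val in rates.items():
        if not isinstance(val, (int, float)):
            raise ValueError(f"rate constant {key} must be numeric, got {val!r}")
    # RateConstantSet rejects unknown names and negative values itself
    cfg.rates = RateConstantSet(
        dict(rates),
        fnr_activation=float(model.get("fnr_activation", 0.0)),
        fnr_sink=float(model.get("fnr_sink", 0.0)),
    )
    if "pools" in model:
        _check_keys(model["pools"], {"pq_total", "pc_total", "fd_total", "fnr_total"}, "model.pools")
        cfg.pools = PoolConfig(**model["pools"])
    if "init" in model:
        _check_keys(model["init"], {"s1_fraction", "qb_semi_fraction", "fnr_active"}, "model.init")
        cfg.init = InitialStateConfig(**model["init"])
    if "quench" in model:
        _check_keys(
            model["quench"],
            {"phi_open", "phi_closed", "gamma_pq", "gamma_p680_ox"},
            "model.quench",
        )
        cfg.quench = QuenchConfig(**model["quench"])
    cfg.k8_both_qa_states = bool(model.get("k8_both_qa_states", False))

    light = data.get("light") or {}
    _check_keys(light, {"pfd", "regime"}, "light")
    if "pfd" in light and "regime" in light:
        raise ValueError("light: give either 'pfd' or 'regime', not both")
    if "regime" in light:
        regime = light["regime"]
        if regime not in ("intense", "low"):
            raise ValueError(f"light.regime must be 'intense' or 'low', got {regime!r}")
        cfg.light = LightRegime(INTENSE_PFD if regime == "intense" else LOW_PFD)
    elif "pfd" in light:
        cfg.light = LightRegime(float(light["pfd"]))

    design = data.get("design") or {}
    _check_keys(design, {"p", "m", "delta"}, "design")
    cfg.design_p = int(design.get("p", 4))
    cfg.design_m = int(design.get("m", 4))
    cfg.design_delta = design.get("delta")
    cfg.design(k=2)  # validates p/m/delta early

    screening = data.get("screening") or {}
    _check_keys(
        screening,
        {"group", "scale_fraction", "aggregation", "points_per_decade", "rtol",
         "atol", "seed"},
        "screening",
    )
    cfg.group = screening.get("group", "forward")
    if cfg.group not in ("forward", "backward"):
        raise ValueError(f"screening.group must be 'forward' or 'backward', got {cfg.group!r}")
    cfg.scale_fraction = float(screening.get("scale_fraction", 0.20))
    cfg.aggregation = screening.get("aggregation", "two_stage")
    cfg.points_per_decade = int(screening.get("points_per_decade", 60))
    cfg.rtol = float(screening.get("rtol", 1e-8))
    cfg.atol = float(screening.get("atol", 1e-10))
    cfg.seed = int(screening.get("seed", 0))

    output = data.get("output") or {}
    _check_keys(output, {"directory"}, "output")
    cfg.out_dir = output.get("directory", "ojipscreen-out")
    return cfg


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a configuration from a YAML/JSON file or dict.

    An absent or empty file yields pure defaults (tabulated rate
    constants, p=4, m=4, intense light).  Validation errors name the
    offending key.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(path)
            text = path.read_text()
            data = yaml.safe_load(text) or {}  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _build_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    """Serialise a RunConfig back to the hierarchical schema."""
    return {
        "model": {
            "rates": dict(cfg.rates.values),
            "fnr_activation": cfg.rates.fnr_activation,
            "fnr_sink": cfg.rates.fnr_sink,
            "pools": asdict(cfg.pools),
            "init": asdict(cfg.init),
            "quench": asdict(cfg.quench),
            "k8_both_qa_states": cfg.k8_both_qa_states,
        },
        "light": {"pfd": cfg.light.pfd},
        "design": {"p": cfg.design_p, "m": cfg.design_m, "delta": cfg.design_delta},
        "screening": {
            "group": cfg.group,
            "scale_fraction": cfg.scale_fraction,
            "aggregation": cfg.aggregation,
            "points_per_decade": cfg.points_per_decade,
            "rtol": cfg.rtol,
            "atol": cfg.atol,
            "seed": cfg.seed,
        },
        "output": {"directory": cfg.out_dir},
    }


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config file; format chosen by suffix (.json or YAML)."""
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
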