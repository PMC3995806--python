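"""Run configuration: embedded stage configs, TOML load/dump.

Configs round-trip through TOML: ``load_config(path)`` reads with stdlib
tomllib and ``dumps_config(cfg)`` emits TOML text such that loading it
reproduces an equal RunConfig.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

from .models import (
    ClassifierConfig,
    FilterConfig,
    ProbeSelectionConfig,
    QcProbeConfig,
    ReportConfig,
    SampleQcConfig,
    ScoreWeights,
    SelectionConfig,
)
from .simulate import IntensityModel, PopulationSpec, SimScenario


@dataclass
class RunConfig:
    """Paths plus every stage configuration for a pipeline run."""

    genome: Optional[str] = None
    vcf: Optional[str] = None
    outdir: str = "panelforge_out"
    log_level: str = "INFO"
    scenario: SimScenario = field(default_factory=SimScenario)
    filter: FilterConfig = field(default_factory=FilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    probe_selection: ProbeSelectionConfig = field(default_factory=ProbeSelectionConfig)
    qc_probes: QcProbeConfig = field(default_factory=QcProbeConfig)
    sample_qc: SampleQcConfig = field(default_factory=SampleQcConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    report: ReportConfig = field(default_factory=ReportConfig)


_SECTIONS = {
    "filter": FilterConfig,
    "selection": SelectionConfig,
    "probe_selection": ProbeSelectionConfig,
    "qc_probes": QcProbeConfig,
    "sample_qc": SampleQcConfig,
    "classifier": ClassifierConfig,
    "weights": ScoreWeights,
    "report": ReportConfig,
}


def config_to_dict(cfg: RunConfig) -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for name in ("genome", "vcf", "outdir", "log_level"):
        value = getattr(cfg, name)
        if value is not None:
            out[name] = value
    for name in _SECTIONS:
        out[name] = dataclasses.asdict(getattr(cfg, name))
    out["report"]["spacing_bin_edges"] = list(cfg.report.spacing_bin_edges)
    scenario = dataclasses.asdict(cfg.scenario)
    out["scenario"] = scenario
    return out


def config_from_dict(data: Dict[str, Any]) -> RunConfig:
    kwargs: Dict[str, Any] = {}
    for name in ("genome", "vcf", "outdir", "log_level"):
        if name in data:
            kwargs[name] = data[name]
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = cls(**data[name])
    if "scenario" in data:
        sc = dict(data["scenario"])
        if "populations" in sc:
            sc["populations"] = [PopulationSpec(**p) for p in sc["populations"]]
        if "intensity" in sc:
            sc["intensity"] = IntensityModel(**sc["intensity"])
        kwargs["scenario"] = SimScenario(**sc)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))


def loads_config(text: str) -> RunConfig:
    return config_from_dict(tomllib.loads(text))


# ---------------------------------------------------------------------------
# minimal TOML emitter (stdlib has a reader only)
# ---------------------------------------------------------------------------


def _fmt_scalar(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt_scalar(v) for v in value) + "]"
    raise TypeError(f"cannot emit TOML value of type {type(value).__name__}")


def _emit_table(name: str, table: Dict[str, Any], lines: list) -> None:
    scalars = {k: v for k, v in table.items()
               if not isinstance(v, dict)
               and not (isinstance(v, list) and v and isinstance(v[0], dict))}
    subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
    arrays = {k: v for k, v in table.items()
              if isinstance(v, list) and v and isinstance(v[0], dict)}
    if name:
        lines.append(f"[{name}]")
    for k, v in scalars.items():
        lines.append(f"{k} = {_fmt_scalar(v)}")
    if name or scalars:
        lines.append("")
    for k, v in subtables.items():
        _emit_table(f"{name}.{k}" if name else k, v, lines)
    for k, items in arrays.items():
        full = f"{name}.{k}" if name else k
        for item in items:
            lines.append(f"[[{full}]]")
            for ik, iv in item.items():
                if isinstance(iv, dict):
                    if iv:
                        inline = ", ".join(f"{a} = {_fmt_scalar(b)}" for a, b in iv.items())
                        lines.append(f"{ik} = {{ {inline} }}")
                    else:
                        lines.append(f"{ik} = {{}}")
                else:
                    lines.append(f"{ik} = {_fmt_scalar(iv)}")
            lines.append("")


def dumps_config(cfg: RunConfig) -> str:
    data = config_to_dict(cfg)
    lines: list = []
    top = {k: v for k, v in data.items() if not isinstance(v, (dict,))}
    _emit_table("", top, lines)
    for k, v in data.items():
        if isinstance(v, dict):
            _emit_table(k, v, lines)
    return "\n".join(lines).rstrip() + "\n"


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_config(cfg))
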