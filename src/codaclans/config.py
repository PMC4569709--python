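"""Run configuration: YAML round-trip with validation and full defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .demography import DemographyParams
from .learning import Scenario

__all__ = ["AnalysisParams", "RunConfig", "load_config", "save_config"]


@dataclass
class AnalysisParams:
    """Analysis-stage knobs: Walktrap, null ensemble and link bootstrap."""

    walktrap_steps: int = 4
    null_replicates: int = 1000
    bootstrap_iters: int = 1000
    weight_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.walktrap_steps < 1:
            raise ValueError("walktrap_steps must be >= 1")
        if self.null_replicates < 1:
            raise ValueError("null_replicates must be >= 1")
        if self.bootstrap_iters < 1:
            raise ValueError("bootstrap_iters must be >= 1")


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    scenario: Scenario = field(default_factory=lambda: Scenario.from_abm_id(1))
    demography: DemographyParams = field(default_factory=DemographyParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    years: int = 700
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        scen: dict = (
            {"abm_id": self.scenario.abm_id}
            if 1 <= self.scenario.abm_id <= 20
            else {
                "mechanism": self.scenario.mechanism,
                "biases": sorted(self.scenario.biases),
                "level": self.scenario.level,
            }
        )
        d = {
            "scenario": {
                **scen,
                "ilearn": self.scenario.ilearn,
                "conformity_exponent": self.scenario.conformity_exponent,
                "replace_fraction": self.scenario.replace_fraction,
                "repertoire_size": self.scenario.repertoire_size,
            },
            "demography": asdict(self.demography),
            "analysis": asdict(self.analysis),
            "years": self.years,
            "seed": self.seed,
            "outdir": self.outdir,
        }
        return d


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys fall back to defaults.

    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offending key. An empty file yields the full published defaults
    (N0=1000, 700 years, ilearn=0.02, ...).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys("config", raw, {"scenario", "demography", "analysis", "years", "seed", "outdir"})

    scen_raw = dict(raw.get("scenario") or {})
    scen_keys = {"abm_id", "mechanism", "biases", "level", "ilearn", "conformity_exponent", "replace_fraction", "repertoire_size"}
    _check_keys("scenario", scen_raw, scen_keys)
    overrides = {
        k: scen_raw[k]
        for k in ("ilearn", "conformity_exponent", "replace_fraction", "repertoire_size")
        if k in scen_raw
    }
    try:
        if "abm_id" in scen_raw:
            scenario = Scenario.from_abm_id(int(scen_raw["abm_id"]), **overrides)
        elif "mechanism" in scen_raw:
            scenario = Scenario(
                abm_id=0,
                mechanism=scen_raw["mechanism"],
                biases=frozenset(scen_raw.get("biases") or ()),
                level=scen_raw.get("level"),
                **overrides,
            )
        else:
            scenario = Scenario.from_abm_id(1, **overrides)
    except ValueError as exc:
        raise ValueError(f"invalid scenario: {exc}") from exc

    demo_raw = dict(raw.get("demography") or {})
    _check_keys("demography", demo_raw, {f.name for f in fields(DemographyParams)})
    try:
        demography = DemographyParams(**demo_raw)
    except ValueError as exc:
        raise ValueError(f"invalid demography: {exc}") from exc

    ana_raw = dict(raw.get("analysis") or {})
    _check_keys("analysis", ana_raw, {f.name for f in fields(AnalysisParams)})
    analysis = AnalysisParams(**ana_raw)

    years = int(raw.get("years", 700))
    if years < 1:
        raise ValueError("years must be >= 1")
    return RunConfig(
        scenario=scenario,
        demography=demography,
        analysis=analysis,
        years=years,
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "results")),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration to YAML (lossless round-trip with load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
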