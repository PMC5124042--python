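"""Run configuration: YAML parsing with exhaustive validation.

``validate_config`` parses a YAML document into a :class:`RunConfig`.  It
collects EVERY violation — unknown keys (typo guard), missing labels, bad
ranges, unresolvable paths — and raises a single :class:`ConfigError`
carrying the full list, rather than stopping at the first problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Raised with the complete list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


@dataclass
class RunConfig:
    output_dir: Path = Path("t2contrast_out")
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    region_pairs: list[tuple[str, str]] = dc_field(default_factory=list)
    modalities: list[str] = dc_field(default_factory=lambda: ["T2w", "T2map"])
    trend: dict = dc_field(default_factory=lambda: {"n_boot": 500, "level": 0.95})
    reliability: dict = dc_field(
        default_factory=lambda: {"enabled": True, "magnitudes": [0.5, 1.0], "n_iter": 20}
    )

    def tissue_labels(self) -> list[str]:
        if self.simulate:
            return [t["label"] for t in self.simulate.get("tissues", [])]
        return []


_TOP_KEYS = {"output_dir", "seed", "simulate", "inputs", "region_pairs",
             "modalities", "trend", "reliability"}
_SIM_KEYS = {"n_subjects", "age_range", "geometry", "tissues", "acquisition",
             "reference_age"}
_GEOM_KEYS = {"shape", "voxel_size_mm", "layout"}
_TISSUE_KEYS = {"label", "region_label", "proton_density", "t2_ms", "t2_age_slope"}
_ACQ_KEYS = {"n_echoes", "echo_spacing_ms", "tr_ms", "noise_sigma",
             "bias_amplitude", "bias_smoothness", "first_echo_gain"}
_INPUT_KEYS = {"subject_csv", "volumes_dir", "masks"}
_TREND_KEYS = {"n_boot", "level"}
_RELIABILITY_KEYS = {"enabled", "magnitudes", "n_iter"}
_MODALITIES = {"T1w", "T2w", "T2map"}


def _unknown(d: dict, allowed: set[str], where: str, out: list[str]) -> None:
    for k in d:
        if k not in allowed:
            out.append(f"unknown key {k!r} in {where} (allowed: {sorted(allowed)})")


def validate_config(config_text: str, base_dir: str | Path | None = None) -> RunConfig:
    """Parse and validate YAML configuration text.

    Returns a fully resolved :class:`RunConfig` with defaults filled in, or
    raises :class:`ConfigError` listing every violation found.  Relative
    paths resolve against ``base_dir`` (default: current directory).
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ConfigError([f"not parseable YAML: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])

    v: list[str] = []
    base = Path(base_dir) if base_dir else Path.cwd()
    _unknown(raw, _TOP_KEYS, "top level", v)

    cfg = RunConfig()
    if "output_dir" in raw:
        cfg.output_dir = Path(raw["output_dir"])
    if "seed" in raw:
        try:
            cfg.seed = int(raw["seed"])
        except (TypeError, ValueError):
            v.append(f"seed must be an integer, got {raw['seed']!r}")

    known_labels: set[str] = set()

    sim = raw.get("simulate")
    if sim is not None:
        if not isinstance(sim, dict):
            v.append("simulate must be a mapping")
        else:
            _unknown(sim, _SIM_KEYS, "simulate", v)
            n = sim.get("n_subjects", 8)
            if not isinstance(n, int) or n < 3:
                v.append(f"simulate.n_subjects must be an integer >= 3, got {n!r}")
            ar = sim.get("age_range", [49, 87])
            if (not isinstance(ar, (list, tuple)) or len(ar) != 2
                    or not ar[1] > ar[0]):
                v.append(f"simulate.age_range must be [low, high] with high > low, got {ar!r}")
            geom = sim.get("geometry", {})
            if isinstance(geom, dict):
                _unknown(geom, _GEOM_KEYS, "simulate.geometry", v)
            tissues = sim.get("tissues", [])
            if not isinstance(tissues, list) or not tissues:
                v.append("simulate.tissues must be a non-empty list")
            else:
                for i, t in enumerate(tissues):
                    if not isinstance(t, dict):
                        v.append(f"simulate.tissues[{i}] must be a mapping")
                        continue
                    _unknown(t, _TISSUE_KEYS, f"simulate.tissues[{i}]", v)
                    missing = {"label", "region_label", "proton_density", "t2_ms"} - set(t)
                    if missing:
                        v.append(f"simulate.tissues[{i}] missing keys: {sorted(missing)}")
                    if "label" in t:
                        known_labels.add(t["label"])
            acq = sim.get("acquisition", {})
            if isinstance(acq, dict):
                _unknown(acq, _ACQ_KEYS, "simulate.acquisition", v)
            cfg.simulate = sim

    inputs = raw.get("inputs")
    if inputs is not None:
        if not isinstance(inputs, dict):
            v.append("inputs must be a mapping")
        else:
            _unknown(inputs, _INPUT_KEYS, "inputs", v)
            for key in ("subject_csv", "volumes_dir"):
                if key in inputs:
                    p = base / inputs[key]
                    if not p.exists():
                        v.append(f"inputs.{key}: path not found: {p}")
            for lab, mp in (inputs.get("masks") or {}).items():
                known_labels.add(lab)
                p = base / mp
                if not p.exists():
                    v.append(f"inputs.masks[{lab!r}]: path not found: {p}")
            cfg.inputs = inputs

    if sim is None and inputs is None:
        v.append("one of 'simulate' or 'inputs' is required")

    pairs = raw.get("region_pairs", [])
    if not isinstance(pairs, list):
        v.append("region_pairs must be a list of [gray_label, white_label] pairs")
    else:
        for i, pr in enumerate(pairs):
            if not isinstance(pr, (list, tuple)) or len(pr) != 2:
                v.append(f"region_pairs[{i}] must be a [gray_label, white_label] pair, got {pr!r}")
                continue
            for lab in pr:
                if known_labels and lab not in known_labels:
                    v.append(f"region_pairs[{i}]: label {lab!r} not declared "
                             f"(known labels: {sorted(known_labels)})")
            cfg.region_pairs.append((pr[0], pr[1]))

    mods = raw.get("modalities")
    if mods is not None:
        bad = [m for m in mods if m not in _MODALITIES]
        if bad:
            v.append(f"unknown modalities {bad}; allowed: {sorted(_MODALITIES)}")
        else:
            cfg.modalities = list(mods)

    for section, allowed, attr in (
        ("trend", _TREND_KEYS, "trend"),
        ("reliability", _RELIABILITY_KEYS, "reliability"),
    ):
        if section in raw:
            if not isinstance(raw[section], dict):
                v.append(f"{section} must be a mapping")
            else:
                _unknown(raw[section], allowed, section, v)
                getattr(cfg, attr).update(raw[section])

    nb = cfg.trend.get("n_boot", 500)
    if not isinstance(nb, int) or nb < 100:
        v.append(f"trend.n_boot must be an integer >= 100, got {nb!r}")

    if v:
        raise ConfigError(v)
    return cfg
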