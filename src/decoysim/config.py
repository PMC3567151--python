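"""Control-file parsing: one ``key = value`` per line, ``#`` comments.

An empty file yields the full published default configuration; any key
may be overridden.  Keys are case-sensitive; unknown keys are rejected so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from . import conflict_model as cm
from .errors import ConfigurationError
from .population import LOCI, SimConfig

__all__ = ["parse_config", "parse_config_text", "config_to_text", "CONFIG_KEYS"]

_SIM_INT = {"N", "generations", "n_encounters", "seed", "n_replicates", "window"}
_SIM_FLOAT = {"mu", "jump_prob"}
_SIM_BOOL = {"decoy_enabled"}
_INIT_KEYS = {f"init_{locus}": locus for locus in LOCI}
_MODEL_FLOAT = {
    "P_opt", "B_max", "s_w", "x_w", "s_p", "x_p",
    "si", "xi", "sd", "xd", "c0", "D_opt",
}
_MODEL_INT = {"allele_max"}
_MODEL_BOOL = {"normalize"}

CONFIG_KEYS = sorted(
    _SIM_INT | _SIM_FLOAT | _SIM_BOOL | set(_INIT_KEYS)
    | _MODEL_FLOAT | _MODEL_INT | _MODEL_BOOL
)


def _parse_bool(key: str, raw: str) -> bool:
    low = raw.lower()
    if low in ("1", "true", "yes", "on"):
        return True
    if low in ("0", "false", "no", "off"):
        return False
    raise ConfigurationError(f"key '{key}': cannot parse boolean from '{raw}'")


def parse_config_text(text: str) -> tuple[SimConfig, cm.ModelParams]:
    """Parse control-file text into a validated (SimConfig, ModelParams)."""
    sim_kwargs: dict = {}
    model_kwargs: dict = {}
    initial = dict(SimConfig().initial_alleles)
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(
                f"line {lineno}: expected 'key = value', got '{raw_line.strip()}'"
            )
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        try:
            if key in _SIM_INT:
                sim_kwargs[key] = int(raw)
            elif key in _SIM_FLOAT:
                sim_kwargs[key] = float(raw)
            elif key in _SIM_BOOL:
                sim_kwargs[key] = _parse_bool(key, raw)
            elif key in _INIT_KEYS:
                initial[_INIT_KEYS[key]] = int(raw)
            elif key in _MODEL_FLOAT:
                model_kwargs[key] = float(raw)
            elif key in _MODEL_INT:
                model_kwargs[key] = int(raw)
            elif key in _MODEL_BOOL:
                model_kwargs[key] = _parse_bool(key, raw)
            else:
                raise ConfigurationError(f"unknown key '{key}' (line {lineno})")
        except ValueError as exc:
            raise ConfigurationError(
                f"key '{key}': cannot parse value '{raw}' (line {lineno})"
            ) from exc
    params = cm.validate_params(cm.ModelParams(**model_kwargs))
    config = SimConfig(initial_alleles=initial, **sim_kwargs).validate(params)
    return config, params


def parse_config(path) -> tuple[SimConfig, cm.ModelParams]:
    """Parse a control file; see :func:`parse_config_text`."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config_text(fh.read())


def config_to_text(config: SimConfig, params: cm.ModelParams) -> str:
    """Serialize a configuration back to control-file text (full echo)."""
    lines = ["# simulation"]
    for key in sorted(_SIM_INT | _SIM_FLOAT | _SIM_BOOL):
        lines.append(f"{key} = {getattr(config, key)}")
    for key, locus in sorted(_INIT_KEYS.items()):
        lines.append(f"{key} = {config.initial_alleles[locus]}")
    lines.append("# model")
    for key in sorted(_MODEL_FLOAT | _MODEL_INT | _MODEL_BOOL):
        lines.append(f"{key} = {getattr(params, key)}")
    return "\n".join(lines) + "\n"
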