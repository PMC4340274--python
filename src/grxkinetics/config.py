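"""Run configuration: parsing, validation, parameter profiles, manifests.

Configs are flat YAML key-value documents.  Validation is strict and
complete: unknown keys are rejected by name, every problem in a document
is reported (not just the first), and a seed is mandatory whenever the
noise coefficient of variation is positive.  The shipped profiles
``grx1`` and ``grx2`` carry the yeast assay backgrounds
and fitted constants in uM/s units.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from importlib import resources

import yaml

from .model_core import ConfigurationError, KineticParameters

__all__ = [
    "RunConfig",
    "PROFILE_NAMES",
    "load_profile",
    "parse_config",
    "write_config",
    "config_hash",
]

PROFILE_NAMES = ("grx1", "grx2")

_MODELS = ("wildtype", "mutant", "ecoli", "hed_assay")
_TASKS = ("generate", "simulate", "steady-state", "reciprocal", "hillfit",
          "fit", "recover", "preset")

_PARAM_KEYS = (
    "k1", "k2_wt", "k2p_mut", "k_hed", "keq_deglut",
    "gr_kcat", "gr_K_NADPH", "gr_K_GSSG", "gr_conc", "grx_tot",
)

_TOP_KEYS = {
    "task", "model", "profile", "preset", "params", "species", "protocol",
    "noise", "output", "seed", "verbosity", "free_params",
}
_PROTOCOL_KEYS = {
    "varied_species", "grid", "gsh_values", "reversible", "pssG_fixed",
    "t_end", "n_points", "fix_n",
}
_NOISE_KEYS = {"cv", "replicates", "seed"}


def load_profile(name: str) -> tuple[KineticParameters, dict[str, float]]:
    """Load a shipped parameter profile: (constants, species table)."""
    if name not in PROFILE_NAMES:
        raise ConfigurationError(
            f"unknown profile {name!r}; shipped profiles: {PROFILE_NAMES}"
        )
    text = resources.files("grxkinetics.data").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    species = {k: float(v) for k, v in raw.pop("species").items()}
    params = KineticParameters(**{k: float(v) for k, v in raw.items()})
    return params, species


@dataclass
class RunConfig:
    """Validated pipeline configuration (uM and seconds throughout)."""

    task: str = "simulate"
    model: str = "wildtype"
    profile: str = "grx1"
    preset: str | None = None
    params: dict[str, float] = field(default_factory=dict)
    species: dict[str, float] = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    output: str | None = None
    seed: int | None = None
    verbosity: int = 0
    free_params: list[str] = field(default_factory=list)

    def kinetic_parameters(self) -> KineticParameters:
        base, _ = load_profile(self.profile)
        return base.replace(**self.params) if self.params else base

    def species_table(self) -> dict[str, float]:
        _, table = load_profile(self.profile)
        table.update(self.species)
        return table


def parse_config(text: str) -> RunConfig:
    """Parse and fully validate a YAML config document.

    All validation errors are collected and reported together in one
    ConfigurationError.
    """
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a key-value document")
    errors: list[str] = []

    unknown = sorted(set(raw) - _TOP_KEYS)
    for key in unknown:
        errors.append(f"unknown key: {key!r}")

    def _get(key, default, kind, check=None, msg=""):
        value = raw.get(key, default)
        if value is None and default is None:
            return None
        try:
            value = kind(value)
        except (TypeError, ValueError):
            errors.append(f"key {key!r}: expected {kind.__name__}, got {raw[key]!r}")
            return default
        if check is not None and not check(value):
            errors.append(f"key {key!r}: {msg} (got {value!r})")
            return default
        return value

    task = _get("task", "simulate", str, lambda v: v in _TASKS,
                f"must be one of {_TASKS}")
    model = _get("model", "wildtype", str, lambda v: v in _MODELS,
                 f"must be one of {_MODELS}")
    profile = _get("profile", "grx1", str, lambda v: v in PROFILE_NAMES,
                   f"must be one of {PROFILE_NAMES}")
    preset = raw.get("preset")
    if preset is not None and not isinstance(preset, str):
        errors.append(f"key 'preset': expected string, got {preset!r}")
        preset = None

    params = raw.get("params") or {}
    if not isinstance(params, dict):
        errors.append(f"key 'params': expected a mapping, got {params!r}")
        params = {}
    else:
        for key in sorted(set(params) - set(_PARAM_KEYS)):
            errors.append(f"unknown key: params.{key!r}")
        params = {k: float(v) for k, v in params.items() if k in _PARAM_KEYS}
        for k, v in params.items():
            if v <= 0:
                errors.append(f"key params.{k!r}: must be positive (got {v})")

    species = raw.get("species") or {}
    if not isinstance(species, dict):
        errors.append(f"key 'species': expected a mapping, got {species!r}")
        species = {}
    else:
        bad = {k: v for k, v in species.items() if float(v) < 0}
        for k, v in bad.items():
            errors.append(f"key species.{k!r}: must be non-negative (got {v})")
        species = {k: float(v) for k, v in species.items() if float(v) >= 0}

    protocol = raw.get("protocol") or {}
    if not isinstance(protocol, dict):
        errors.append(f"key 'protocol': expected a mapping, got {protocol!r}")
        protocol = {}
    else:
        for key in sorted(set(protocol) - _PROTOCOL_KEYS):
            errors.append(f"unknown key: protocol.{key!r}")
        protocol = {k: v for k, v in protocol.items() if k in _PROTOCOL_KEYS}

    noise = raw.get("noise") or {}
    if not isinstance(noise, dict):
        errors.append(f"key 'noise': expected a mapping, got {noise!r}")
        noise = {}
    else:
        for key in sorted(set(noise) - _NOISE_KEYS):
            errors.append(f"unknown key: noise.{key!r}")
        noise = {k: noise[k] for k in noise if k in _NOISE_KEYS}
        if float(noise.get("cv", 0.0)) < 0:
            errors.append("key noise.cv: must be non-negative")

    output = raw.get("output")
    if output is not None:
        output = str(output)
    seed = raw.get("seed")
    if seed is not None:
        if not isinstance(seed, int):
            errors.append(f"key 'seed': expected integer, got {seed!r}")
            seed = None
    verbosity = _get("verbosity", 0, int)
    free_params = raw.get("free_params") or []
    if not isinstance(free_params, list):
        errors.append(f"key 'free_params': expected a list, got {free_params!r}")
        free_params = []
    else:
        for p in free_params:
            if p not in _PARAM_KEYS:
                errors.append(f"key 'free_params': unknown parameter {p!r}")

    effective_cv = float(noise.get("cv", 0.0))
    effective_seed = noise.get("seed", seed)
    if effective_cv > 0 and effective_seed is None:
        errors.append("a seed is required whenever noise cv > 0")

    if errors:
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(errors)
        )
    return RunConfig(
        task=task,
        model=model,
        profile=profile,
        preset=preset,
        params=params,
        species=species,
        protocol=protocol,
        noise=noise,
        output=output,
        seed=seed,
        verbosity=verbosity,
        free_params=list(free_params),
    )


def write_config(config: RunConfig) -> str:
    """Serialise a RunConfig to YAML; parse(write(c)) == c."""
    data = asdict(config)
    data = {k: v for k, v in data.items() if v not in (None, {}, [], "")}
    # defaults that must survive the round trip even when empty
    data.setdefault("task", config.task)
    data.setdefault("model", config.model)
    data.setdefault("profile", config.profile)
    data.setdefault("verbosity", config.verbosity)
    return yaml.safe_dump(data, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical serialisation (for manifests).

    The output path and verbosity are excluded: they do not affect the
    computed results, and two runs of the same protocol must hash alike.
    """
    import dataclasses

    canonical = dataclasses.replace(config, output=None, verbosity=0)
    return hashlib.sha256(write_config(canonical).encode()).hexdigest()[:12]
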