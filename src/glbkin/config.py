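"""Structured run configuration (YAML/JSON) for simulate/analyze runs.

A run config declares the protein model (sites with named rate constants,
units in the key suffixes: ``_per_s`` for s^-1, ``_per_M_s`` for
M^-1 s^-1, concentrations in M), the assay (kind, concentrations, pH),
the instrument profile, inference thresholds, and the master seed.  Every
run writes the resolved config next to its results so a run is fully
reproducible from its output directory.

Schema violations raise :class:`ConfigError` carrying the offending field
path (e.g. ``protein.sites[0].k_off_O2_per_s``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .kinetics import AssayConditions, AssayKind, HemeSite, ProteinModel
from .presets import no_distal_his, two_heme, one_heme
from .synth import (
    DEFAULT_NOISE_SD,
    InstrumentProfile,
    laser_flash,
    scanning_spectrophotometer,
    stopped_flow,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "resolved_config_dict",
    "config_hash",
]


class ConfigError(ValueError):
    """Configuration schema violation; message carries the field path."""


_SITE_RATE_KEYS = {
    "k_minus_H_per_s": "k_minus_H",
    "k_H_per_s": "k_H",
    "k_prime_on_NO_per_M_s": "k_prime_on_NO",
    "k_on_O2_per_M_s": "k_on_O2",
    "k_off_O2_per_s": "k_off_O2",
    "k_on_CO_per_M_s": "k_on_CO",
    "k_NOD_per_M_s": "k_NOD",
    "k_NiR_pH7_per_M_s": "k_NiR_pH7",
}

_PRESETS = {"two_heme": two_heme, "one_heme": one_heme}


def _require(mapping: Dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"missing required field {path}.{key}")
    return mapping[key]


def _as_float(value, path: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"field {path} must be a number, got {value!r}")


def parse_protein(block: Dict, path: str = "protein") -> ProteinModel:
    if not isinstance(block, dict):
        raise ConfigError(f"{path} must be a mapping")
    if "preset" in block:
        name = str(block["preset"]).lower()
        if name not in _PRESETS:
            raise ConfigError(
                f"{path}.preset must be one of {sorted(_PRESETS)}, got {name!r}"
            )
        protein = _PRESETS[name]()
        if block.get("distal_his_mutant"):
            protein = no_distal_his(protein)
        if "nir_per_molecule" in block:
            protein.nir_per_molecule = bool(block["nir_per_molecule"])
        return protein
    sites_block = _require(block, "sites", path)
    if not isinstance(sites_block, list) or not 1 <= len(sites_block) <= 2:
        raise ConfigError(f"{path}.sites must be a list of 1 or 2 sites")
    sites: List[HemeSite] = []
    for i, sb in enumerate(sites_block):
        spath = f"{path}.sites[{i}]"
        if not isinstance(sb, dict):
            raise ConfigError(f"{spath} must be a mapping")
        kwargs = {"has_distal_his": bool(sb.get("has_distal_his", True))}
        for key, attr in _SITE_RATE_KEYS.items():
            if key in sb:
                kwargs[attr] = (
                    None if sb[key] is None else _as_float(sb[key], f"{spath}.{key}")
                )
        unknown = set(sb) - set(_SITE_RATE_KEYS) - {"has_distal_his"}
        if unknown:
            raise ConfigError(
                f"unknown field(s) {sorted(unknown)} in {spath}; "
                f"supported: {sorted(_SITE_RATE_KEYS) + ['has_distal_his']}"
            )
        try:
            sites.append(HemeSite(**kwargs))
        except ValueError as exc:
            raise ConfigError(f"{spath}: {exc}") from exc
    weights = block.get("signal_weights")
    try:
        return ProteinModel(
            name=str(block.get("name", "protein")),
            sites=sites,
            heme_equivalent=bool(block.get("heme_equivalent", False)),
            signal_weights=tuple(weights) if weights else None,
            nir_per_molecule=bool(block.get("nir_per_molecule", True)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def parse_assay(block: Dict, path: str = "assay") -> Tuple[
    AssayConditions, Optional[Tuple[str, List[float]]], int
]:
    """Returns (template conditions, vary spec, n_replicates).

    A list-valued concentration field becomes the varied parameter; at
    most one field may be a list.
    """
    if not isinstance(block, dict):
        raise ConfigError(f"{path} must be a mapping")
    kind_raw = _require(block, "kind", path)
    try:
        kind = AssayKind(kind_raw)
    except ValueError:
        raise ConfigError(
            f"{path}.kind must be one of "
            f"{[k.value for k in AssayKind]}, got {kind_raw!r}"
        )
    conc_keys = {
        "protein_conc_M": "protein_conc",
        "ligand_conc_M": "ligand_conc",
        "dithionite_conc_M": "dithionite_conc",
        "CO_conc_M": "CO_conc",
        "O2_conc_M": "O2_conc",
    }
    kwargs: Dict[str, float] = {}
    vary: Optional[Tuple[str, List[float]]] = None
    for key, attr in conc_keys.items():
        if key not in block:
            continue
        value = block[key]
        if isinstance(value, (list, tuple)):
            if vary is not None:
                raise ConfigError(
                    f"{path}: only one field may hold a value list "
                    f"(both {vary[0]!r} and {attr!r} do)"
                )
            vary = (attr, [_as_float(v, f"{path}.{key}") for v in value])
        else:
            kwargs[attr] = _as_float(value, f"{path}.{key}")
    if "pH" in block:
        kwargs["pH"] = _as_float(block["pH"], f"{path}.pH")
    if "temperature_C" in block:
        kwargs["temperature"] = _as_float(
            block["temperature_C"], f"{path}.temperature_C"
        )
    try:
        cond = AssayConditions(assay_kind=kind, **kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    n_rep = int(block.get("replicates", 1))
    if n_rep < 1:
        raise ConfigError(f"{path}.replicates must be >= 1")
    return cond, vary, n_rep


_INSTR_FACTORIES = {
    "stopped_flow": stopped_flow,
    "lfp": laser_flash,
    "scanning_spectrophotometer": scanning_spectrophotometer,
}


def parse_instrument(block: Optional[Dict],
                     path: str = "instrument") -> Optional[InstrumentProfile]:
    if block is None:
        return None
    if not isinstance(block, dict):
        raise ConfigError(f"{path} must be a mapping")
    kind = str(block.get("kind", "stopped_flow"))
    if kind not in _INSTR_FACTORIES:
        raise ConfigError(
            f"{path}.kind must be one of {sorted(_INSTR_FACTORIES)}, got {kind!r}"
        )
    base = _INSTR_FACTORIES[kind]()
    kwargs = dict(
        kind=kind,
        dead_time=_as_float(block.get("dead_time_s", base.dead_time),
                            f"{path}.dead_time_s"),
        sampling_interval=_as_float(block.get("sampling_s",
                                              base.sampling_interval),
                                    f"{path}.sampling_s"),
        duration=_as_float(block.get("duration_s", base.duration),
                           f"{path}.duration_s"),
        noise_sd=_as_float(block.get("noise_sd_au", base.noise_sd),
                           f"{path}.noise_sd_au"),
        pathlength=_as_float(block.get("pathlength_cm", base.pathlength),
                             f"{path}.pathlength_cm"),
    )
    try:
        return InstrumentProfile(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    protein: ProteinModel
    assay: AssayConditions
    vary: Optional[Tuple[str, List[float]]]
    n_replicates: int
    instrument: Optional[InstrumentProfile]
    wavelength_nm: Optional[float]
    seed: int
    k_on_floor_per_M_s: Optional[float] = None
    n_phases_expected: Optional[int] = None
    raw: Dict = field(default_factory=dict)


def load_config(path, seed_override: Optional[int] = None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    protein = parse_protein(_require(raw, "protein", "<root>"))
    assay, vary, n_rep = parse_assay(_require(raw, "assay", "<root>"))
    instrument = parse_instrument(raw.get("instrument"))
    wavelength = raw.get("wavelength_nm")
    if wavelength is not None:
        wavelength = _as_float(wavelength, "wavelength_nm")
    seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)
    k_on_floor = raw.get("k_on_floor_per_M_s")
    if k_on_floor is not None:
        k_on_floor = _as_float(k_on_floor, "k_on_floor_per_M_s")
    n_phases = raw.get("n_phases_expected")
    if n_phases is not None:
        n_phases = int(n_phases)
        if n_phases not in (1, 2):
            raise ConfigError("n_phases_expected must be 1 or 2")
    return RunConfig(
        protein=protein, assay=assay, vary=vary, n_replicates=n_rep,
        instrument=instrument, wavelength_nm=wavelength, seed=seed,
        k_on_floor_per_M_s=k_on_floor, n_phases_expected=n_phases, raw=raw,
    )


def resolved_config_dict(cfg: RunConfig) -> Dict:
    """Fully resolved config (all defaults filled in) for provenance."""
    protein = {
        "name": cfg.protein.name,
        "heme_equivalent": cfg.protein.heme_equivalent,
        "signal_weights": list(cfg.protein.signal_weights),
        "nir_per_molecule": cfg.protein.nir_per_molecule,
        "sites": [
            {
                "has_distal_his": s.has_distal_his,
                **{key: getattr(s, attr)
                   for key, attr in _SITE_RATE_KEYS.items()},
            }
            for s in cfg.protein.sites
        ],
    }
    assay = {
        "kind": cfg.assay.assay_kind.value,
        "protein_conc_M": cfg.assay.protein_conc,
        "ligand_conc_M": cfg.assay.ligand_conc,
        "dithionite_conc_M": cfg.assay.dithionite_conc,
        "CO_conc_M": cfg.assay.CO_conc,
        "O2_conc_M": cfg.assay.O2_conc,
        "pH": cfg.assay.pH,
        "temperature_C": cfg.assay.temperature,
        "replicates": cfg.n_replicates,
    }
    if cfg.vary:
        assay[f"vary.{cfg.vary[0]}"] = list(cfg.vary[1])
    instr = None
    if cfg.instrument:
        instr = {
            "kind": cfg.instrument.kind,
            "dead_time_s": cfg.instrument.dead_time,
            "sampling_s": cfg.instrument.sampling_interval,
            "duration_s": cfg.instrument.duration,
            "noise_sd_au": cfg.instrument.noise_sd,
            "pathlength_cm": cfg.instrument.pathlength,
        }
    return {
        "protein": protein,
        "assay": assay,
        "instrument": instr,
        "wavelength_nm": cfg.wavelength_nm,
        "seed": cfg.seed,
        "k_on_floor_per_M_s": cfg.k_on_floor_per_M_s,
        "n_phases_expected": cfg.n_phases_expected,
    }


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the resolved configuration."""
    payload = json.dumps(resolved_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
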