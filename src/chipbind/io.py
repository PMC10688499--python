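"""Structured-config parsing/serialisation and profile normalisation.

Run configurations are flat YAML documents::

    M: 100
    alpha_syn: 2.0e-4
    kappa_bin: 2.0e-2
    D_tilde: 9.8e-3
    dt: 1.0
    n_steps: 30000
    record_every: 10
    rate_units: per_dt          # or per_time
    sources: [7, 8, 9, 10, 11, 12, 13, 14]
    traps:
      kind: restricted          # homogeneous | explicit | restricted
      capacity: 25.0
      anchor: 15
      k_dist: 10
      k_width: 8

``traps.kind: homogeneous`` takes ``capacity`` only; ``explicit`` takes
``values`` (a length-M list).  Floats are written with ``repr`` precision
so that save(load(x)) round-trips bit-exactly.
"""
from __future__ import annotations

from typing import Union

import numpy as np
import yaml

from .core import ConfigError, SystemConfig, SynthesisPattern, TrapPattern
from .patterns import RestrictedDomainSpec, build_trap_pattern
from .simulate import Trajectory

__all__ = ["load_config", "save_config", "normalize_profile"]

_TOP_KEYS = {
    "alpha_syn", "kappa_bin", "D_tilde", "dt", "n_steps", "M",
    "record_every", "rate_units", "sources", "traps",
}
_TRAP_KEYS = {
    "homogeneous": {"kind", "capacity"},
    "explicit": {"kind", "values"},
    "restricted": {"kind", "capacity", "anchor", "k_dist", "k_width"},
}


class _ReprDumper(yaml.SafeDumper):
    pass


def _float_representer(dumper, value):
    return dumper.represent_scalar("tag:yaml.org,2002:float", repr(float(value)))


_ReprDumper.add_representer(float, _float_representer)


def _traps_from_dict(spec: dict, M: int) -> TrapPattern:
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError("traps section must be a mapping with a 'kind' key")
    kind = spec["kind"]
    if kind not in _TRAP_KEYS:
        raise ConfigError(
            f"unknown traps.kind {kind!r}; expected one of {sorted(_TRAP_KEYS)}"
        )
    unknown = set(spec) - _TRAP_KEYS[kind]
    if unknown:
        raise ConfigError(f"unknown keys in traps section: {sorted(unknown)}")
    if kind == "homogeneous":
        return build_trap_pattern(float(spec["capacity"]), M)
    if kind == "explicit":
        values = spec.get("values")
        if not isinstance(values, list):
            raise ConfigError("traps.values must be a list of per-box capacities")
        return build_trap_pattern(np.asarray(values, dtype=float), M)
    return build_trap_pattern(
        RestrictedDomainSpec(
            k_dist=int(spec["k_dist"]),
            k_width=int(spec.get("k_width", 8)),
            anchor=int(spec.get("anchor", 15)),
            capacity=float(spec["capacity"]),
        ),
        M,
    )


def _traps_to_dict(traps: TrapPattern) -> dict:
    cap = traps.capacities
    if np.all(cap == cap[0]):
        return {"kind": "homogeneous", "capacity": float(cap[0])}
    return {"kind": "explicit", "values": [float(c) for c in cap]}


def load_config(path: str):
    """Parse and validate a YAML run configuration.

    Returns ``(config, traps, sources)``.  Unknown keys, malformed vectors
    and guard violations each raise :class:`ConfigError` with the
    offending key named.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    missing = {"alpha_syn", "kappa_bin", "D_tilde", "dt", "n_steps", "M"} - set(doc)
    if missing:
        raise ConfigError(f"{path}: missing config keys: {sorted(missing)}")

    config = SystemConfig(
        alpha_syn=float(doc["alpha_syn"]),
        kappa_bin=float(doc["kappa_bin"]),
        D_tilde=float(doc["D_tilde"]),
        dt=float(doc["dt"]),
        n_steps=int(doc["n_steps"]),
        M=int(doc["M"]),
        record_every=int(doc.get("record_every", 1)),
        rate_units=str(doc.get("rate_units", "per_time")),
    )
    sources_raw = doc.get("sources", [])
    if not isinstance(sources_raw, list):
        raise ConfigError(f"{path}: sources must be a list of box indices")
    sources = SynthesisPattern(sources_raw)
    sources.validate(config.M)
    traps = _traps_from_dict(doc.get("traps", {"kind": "homogeneous", "capacity": 0.0}),
                             config.M)
    config.validate_against_traps(traps)
    return config, traps, sources


def save_config(
    config: SystemConfig,
    traps: TrapPattern,
    sources: SynthesisPattern,
    path: str,
) -> None:
    """Write a configuration bundle as YAML (bit-exact float round-trip)."""
    doc = {
        "alpha_syn": config.alpha_syn,
        "kappa_bin": config.kappa_bin,
        "D_tilde": config.D_tilde,
        "dt": config.dt,
        "n_steps": int(config.n_steps),
        "M": int(config.M),
        "record_every": int(config.record_every),
        "rate_units": config.rate_units,
        "sources": sorted(int(i) for i in sources.source_boxes),
        "traps": _traps_to_dict(traps),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.dump(doc, fh, Dumper=_ReprDumper, sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# normalisation for model-vs-signal comparison
# ---------------------------------------------------------------------------


def normalize_profile(
    data: Union[np.ndarray, Trajectory],
    mode: str,
    capacities: np.ndarray = None,
    times: np.ndarray = None,
    reference_time: float = None,
    which: str = "bound",
):
    """Normalise a spatial profile for comparison with fluorescence signals.

    ``mode="per-box-capacity"`` divides each box's counts by its trap
    capacity (the convention used to overlay model output on trap-bound
    signal); boxes without traps are undefined and map to NaN.
    ``mode="global-max-at-reference-time"`` divides the whole profile by
    its spatial maximum at ``reference_time`` (the convention used for
    signals normalised to their maximum at a late reference frame); this
    makes the output invariant under rescaling of the raw profile.

    ``data`` is either a ``(n_times, M)``/(``M``,) array (then
    ``capacities`` and, for mode 2, ``times`` must be given) or a
    :class:`Trajectory` (``which`` selects ``"bound"`` or ``"total"``
    counts).
    """
    if isinstance(data, Trajectory):
        values = data.N_b if which == "bound" else data.N_b + data.N_u
        capacities = data.traps.capacities
        times = data.times
    else:
        values = np.asarray(data, dtype=float)

    if mode == "per-box-capacity":
        if capacities is None:
            raise ConfigError("per-box-capacity normalisation requires capacities")
        cap = np.asarray(capacities, dtype=float)
        return np.divide(values, cap, out=np.full_like(values, np.nan), where=cap > 0)
    if mode == "global-max-at-reference-time":
        if reference_time is None:
            raise ConfigError("global-max normalisation requires reference_time")
        if values.ndim != 2:
            raise ConfigError("global-max normalisation needs a (time, box) profile")
        if times is None:
            raise ConfigError("global-max normalisation requires the time grid")
        times = np.asarray(times, dtype=float)
        hits = np.nonzero(np.isclose(times, reference_time, rtol=1e-12, atol=1e-12))[0]
        if hits.size == 0:
            raise ConfigError(
                f"reference time {reference_time!r} is not on the recorded grid"
            )
        ref_max = values[hits[0]].max()
        if ref_max <= 0:
            raise ConfigError("profile is zero at the reference time")
        return values / ref_max
    raise ConfigError(
        "mode must be 'per-box-capacity' or 'global-max-at-reference-time', "
        f"got {mode!r}"
    )
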