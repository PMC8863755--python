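"""Study configuration and its QR-compatible text codec.

A study is configured as an ordered list of collection phases — contextual
snapshot, continuous logging, past-usage extraction — each with its own
options. The configuration is serialized to a flat, self-delimiting
UTF-8 key-value payload small enough to fit in a QR code, which is how
the logger app receives its instructions in the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Phase",
    "StudyConfig",
    "ConfigSchemaError",
    "encode_config",
    "decode_config",
]

_SOURCES = ("contextual", "continuous", "past")

_CONTINUOUS_FLAGS = ("track_screen", "track_apps", "track_installs", "track_notifications")


class ConfigSchemaError(ValueError):
    """Raised when a payload does not conform to the config schema."""


@dataclass(frozen=True)
class Phase:
    """One collection phase.

    ``source`` is one of ``contextual``, ``continuous``, ``past``.
    Continuous phases carry four boolean tracking switches; past phases
    carry ``retention_days`` (how far back the OS history is queried);
    contextual phases have no options.
    """

    source: str
    track_screen: bool = True
    track_apps: bool = True
    track_installs: bool = True
    track_notifications: bool = True
    retention_days: int = 5

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"unknown phase source: {self.source!r}")
        if self.source == "past" and self.retention_days <= 0:
            raise ValueError("retention_days must be positive")


@dataclass
class StudyConfig:
    """Ordered phases plus a switch allowing repeated sources.

    Phase order matters: participants trigger the switch from one source
    to the next, so e.g. past-usage extraction can be scheduled after a
    continuous-logging window to backfill any dropout.
    """

    phases: list[Phase] = field(default_factory=lambda: [Phase("continuous")])
    allow_duplicate_sources: bool = False

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("config must have at least one phase")
        sources = [p.source for p in self.phases]
        if not self.allow_duplicate_sources and len(set(sources)) != len(sources):
            raise ValueError(
                "duplicate phase sources; set allow_duplicate_sources=True to permit"
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StudyConfig)
            and self.phases == other.phases
            and self.allow_duplicate_sources == other.allow_duplicate_sources
        )


def _b(v: bool) -> str:
    return "true" if v else "false"


def _parse_bool(key: str, v: str) -> bool:
    if v == "true":
        return True
    if v == "false":
        return False
    raise ConfigSchemaError(f"field {key!r}: expected true/false, got {v!r}")


def encode_config(config: StudyConfig) -> str:
    """Serialize a config to the flat key-value payload.

    One ``key=value`` pair per line; phases are numbered from 1 so the
    payload is self-delimiting and order-preserving. The result is plain
    UTF-8 text, renderable as a QR code by any generator.
    """
    lines = ["v=1", f"n_phases={len(config.phases)}"]
    if config.allow_duplicate_sources:
        lines.append("allow_duplicate_sources=true")
    for i, p in enumerate(config.phases, start=1):
        lines.append(f"phase.{i}.source={p.source}")
        if p.source == "continuous":
            for flag in _CONTINUOUS_FLAGS:
                lines.append(f"phase.{i}.{flag}={_b(getattr(p, flag))}")
        elif p.source == "past":
            lines.append(f"phase.{i}.retention_days={p.retention_days}")
    return "\n".join(lines) + "\n"


def decode_config(payload: str) -> StudyConfig:
    """Exact inverse of :func:`encode_config`.

    Unknown keys are ignored with a warning (forward compatibility);
    missing required fields raise :class:`ConfigSchemaError` naming the
    field.
    """
    kv: dict[str, str] = {}
    for lineno, line in enumerate(payload.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigSchemaError(f"line {lineno}: not a key=value pair: {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    if kv.get("v") != "1":
        raise ConfigSchemaError("missing or unsupported field 'v' (payload version)")
    if "n_phases" not in kv:
        raise ConfigSchemaError("missing field 'n_phases'")
    try:
        n_phases = int(kv["n_phases"])
    except ValueError as exc:
        raise ConfigSchemaError("field 'n_phases' is not an integer") from exc
    if n_phases < 1:
        raise ConfigSchemaError("n_phases must be >= 1")

    allow_dup = _parse_bool(
        "allow_duplicate_sources", kv.get("allow_duplicate_sources", "false")
    )

    known: set[str] = {"v", "n_phases", "allow_duplicate_sources"}
    phases: list[Phase] = []
    for i in range(1, n_phases + 1):
        skey = f"phase.{i}.source"
        if skey not in kv:
            raise ConfigSchemaError(f"missing field {skey!r}")
        source = kv[skey]
        known.add(skey)
        kwargs: dict = {}
        if source == "continuous":
            for flag in _CONTINUOUS_FLAGS:
                fkey = f"phase.{i}.{flag}"
                known.add(fkey)
                if fkey in kv:
                    kwargs[flag] = _parse_bool(fkey, kv[fkey])
        elif source == "past":
            rkey = f"phase.{i}.retention_days"
            known.add(rkey)
            if rkey in kv:
                try:
                    kwargs["retention_days"] = int(kv[rkey])
                except ValueError as exc:
                    raise ConfigSchemaError(f"field {rkey!r} is not an integer") from exc
        try:
            phases.append(Phase(source, **kwargs))
        except ValueError as exc:
            raise ConfigSchemaError(str(exc)) from exc

    unknown = sorted(set(kv) - known)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(unknown)}", stacklevel=2)

    try:
        return StudyConfig(phases, allow_duplicate_sources=allow_dup)
    except ValueError as exc:
        raise ConfigSchemaError(str(exc)) from exc
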