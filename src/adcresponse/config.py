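"""Flat key/value run configuration.

Config files are plain text, one ``section.key = value`` per line, ``#``
comments allowed.  Every key must exist in the schema of defaults for the
command being run — unknown keys are hard errors so typos never silently
fall back to defaults.
"""

from __future__ import annotations

import hashlib

__all__ = ["ConfigError", "parse_config", "apply_config", "config_hash"]


class ConfigError(ValueError):
    pass


def parse_config(path) -> dict[str, str]:
    """Read a flat dotted-key config file into a string->string map."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw.strip()!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if not key:
                raise ConfigError(f"line {lineno}: empty key")
            if key in out:
                raise ConfigError(f"line {lineno}: duplicate key {key!r}")
            out[key] = value
    return out


def _coerce(value: str, default):
    if isinstance(default, bool):
        low = value.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ConfigError(f"cannot parse boolean from {value!r}")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return value


def apply_config(overrides: dict[str, str], defaults: dict) -> dict:
    """Merge string overrides onto typed defaults; unknown keys are errors."""
    unknown = sorted(set(overrides) - set(defaults))
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    merged = dict(defaults)
    for key, value in overrides.items():
        try:
            merged[key] = _coerce(value, defaults[key])
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"bad value for {key!r}: {exc}") from None
    return merged


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration."""
    canon = "\n".join(f"{k}={config[k]!r}" for k in sorted(config))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
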