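"""Flat key=value configuration with namespaced dotted keys.

Every threshold the pipeline uses lives here with its default; a config file
overrides defaults line by line (``key = value``, ``#`` comments allowed).
Values are coerced to the type of the default.
"""

from __future__ import annotations

from pathlib import Path

DEFAULTS: dict[str, object] = {
    "filtration.min_dp": 10,
    "filtration.min_gq": 20,
    "filtration.mode": "supported_carrier",  # or "site_mean"
    "classify.rare_maf": 0.01,
    "classify.fold_af": True,
    "novelty.match": "either",  # gene | variant | either
    "burden.ratio_threshold": 1.5,
    "burden.min_cases": 3,
    "duration.long_years": 3.0,
    "duration.short_years": 1.0,
    "enrich.alpha": 0.05,
    "enrich.statistic": "ease",  # ease | fisher
    "enrich.fdr": False,
}


def _coerce(value: str, default):
    if isinstance(default, bool):
        v = value.strip().lower()
        if v in ("1", "true", "yes", "on"):
            return True
        if v in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {value!r}")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return value.strip()


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a key=value file and a dict of overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cfg:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            cfg[key] = _coerce(value, DEFAULTS[key])
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        cfg[key] = value
    return cfg
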