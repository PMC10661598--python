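"""Flat key=value configuration files.

One dotted key per line, mirroring the dataclass fields, e.g.::

    acoustic.fs = 20e6
    encoder.coda_len = 1500
    encoder.lateral_fwhm_mm = 2.5
    recon.lam = 0.05

Blank lines and ``#`` comments are ignored. Values are parsed as int,
float, bool, or left as strings.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["parse_scalar", "load_flat_config", "dump_flat_config"]


def parse_scalar(text: str):
    s = text.strip()
    low = s.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    if low in ("none", "null"):
        return None
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def load_flat_config(path) -> dict:
    cfg = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        cfg[key.strip()] = parse_scalar(value)
    return cfg


def dump_flat_config(cfg: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in sorted(cfg.items())]
    Path(path).write_text("\n".join(lines) + "\n")
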