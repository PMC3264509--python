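"""Runtime configuration for the CLI.

Defaults live here; a TOML file (``--config path.toml``) overrides them and
individual command-line flags override the file. All values are validated
against the operations' preconditions on load.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields, replace
from pathlib import Path

from .errors import DomainError, FormatError


@dataclass(frozen=True)
class Config:
    n_frames: int = 9
    mapping_mode: str = "pointwise"
    easing: str = "linear"
    fade_mode: str = "fade"
    delay_ms: int = 100
    loop: bool = True
    formula_form: str = "long"
    canvas_width: int = 400
    canvas_height: int = 300
    scale: float = 40.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise DomainError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.mapping_mode not in ("pointwise", "triangles", "squares"):
            raise DomainError(f"invalid mapping_mode {self.mapping_mode!r}")
        if self.easing not in ("linear", "ping_pong"):
            raise DomainError(f"invalid easing {self.easing!r}")
        if self.fade_mode not in ("fade", "shrink"):
            raise DomainError(f"invalid fade_mode {self.fade_mode!r}")
        if self.delay_ms < 10:
            raise DomainError(f"delay_ms must be >= 10, got {self.delay_ms}")
        if self.formula_form not in ("long", "short"):
            raise DomainError(f"invalid formula_form {self.formula_form!r}")
        if self.canvas_width < 1 or self.canvas_height < 1:
            raise DomainError("canvas must be at least 1x1")
        if self.scale <= 0:
            raise DomainError("scale must be positive")


def load_config(path: str | Path | None) -> Config:
    """Config from a TOML file, or the defaults when ``path`` is None."""
    if path is None:
        return Config()
    try:
        data = tomllib.loads(Path(path).read_text())
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise FormatError(f"cannot load config {path}: {exc}") from exc
    known = {f.name for f in fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return replace(Config(), **data)
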