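"""Architecture recipes for the CSP/PANet detector family.

A :class:`ModelConfig` is the complete structural recipe of one model:
channel widths, CSP repeat counts, which detection scales are active,
whether convolutions inside CSP blocks are depth-wise separable, the
anchor priors and the class count.  Named presets cover the whole
family studied for aortic-valve detection, from the standard small
model down to the pruned lightweight configuration.

Scaling conventions
-------------------
``depth_multiple`` scales the per-stage CSP repeat counts declared in a
recipe (``max(round(n * depth_multiple), 1)``, ties rounding half away
from zero); ``width_multiple`` scales channel widths, rounded *up* to
the nearest multiple of 8.  ``ModelConfig`` stores repeats
post-scaling, so a config is always an exact description of the built
network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = [
    "ModelConfig", "ConfigError", "scale_repeats", "scale_channels",
    "parse_config", "get_preset", "preset_names", "config_to_yaml",
    "DEFAULT_ANCHORS", "GENERATED_ANCHORS",
]

SCALE_STRIDES = {"P3": 8, "P4": 16, "P5": 32}

#: COCO-default anchor priors, three per scale, smallest first (pixels).
DEFAULT_ANCHORS = ((10, 13), (16, 30), (33, 23),
                   (30, 61), (62, 45), (59, 119),
                   (116, 90), (156, 198), (373, 326))

#: K-means anchors fitted to aortic-valve box sizes at 768-px input.
GENERATED_ANCHORS = ((91, 88), (98, 85), (99, 100),
                     (108, 96), (109, 111), (115, 106),
                     (128, 108), (120, 116), (134, 124))

BASE_CHANNELS = (64, 128, 256, 512, 1024)
BASE_BACKBONE_REPEATS = (3, 6, 9, 3)
BASE_NECK_REPEATS = (3, 3, 3, 3)


class ConfigError(ValueError):
    """Raised for invalid or unparseable model configuration input."""


def scale_repeats(n: int, depth_multiple: float) -> int:
    """Scale a CSP repeat count by the depth multiple.

    Ties round half away from zero (so ``scale_repeats(5, 0.5) == 3``),
    and the result never drops below one repeat.
    """
    if n < 1 or depth_multiple <= 0:
        raise ConfigError(f"scale_repeats requires n >= 1 and depth > 0, got {n}, {depth_multiple}")
    x = n * depth_multiple
    rounded = math.floor(x + 0.5)  # half away from zero (x > 0 here)
    return max(rounded, 1)


def scale_channels(c: int, width_multiple: float) -> int:
    """Scale a channel width and round up to the nearest multiple of 8."""
    if c < 1 or width_multiple <= 0:
        raise ConfigError(f"scale_channels requires c >= 1 and width > 0, got {c}, {width_multiple}")
    return int(math.ceil(c * width_multiple / 8) * 8)


@dataclass
class ModelConfig:
    """Full recipe for one detector in the family.

    ``backbone_repeats`` / ``neck_repeats`` are the *post-scaling* CSP
    repeat counts actually built.  ``active_scales`` names the detect
    branches kept (P3/P4/P5 at strides 8/16/32); the pruned two-scale
    configurations keep P3 and P4 — dropping the stride-32 tail is the
    scale reduction whose layer/parameter savings match the published
    family statistics.
    """

    name: str
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    backbone_repeats: tuple = (1, 2, 3, 1)
    neck_repeats: tuple = (1, 1, 1, 1)
    active_scales: tuple = ("P3", "P4", "P5")
    conv_mode: str = "standard"
    base_channels: tuple = BASE_CHANNELS
    halve_conv_channels: bool = False
    num_classes: int = 1
    anchors: tuple = DEFAULT_ANCHORS
    anchor_reference: int = 0  # px size anchors are quoted at; 0 = input_size
    input_size: int = 768
    activation: str = "leaky_relu"

    def __post_init__(self):
        self.backbone_repeats = tuple(int(r) for r in self.backbone_repeats)
        self.neck_repeats = tuple(int(r) for r in self.neck_repeats)
        self.active_scales = tuple(self.active_scales)
        self.base_channels = tuple(int(c) for c in self.base_channels)
        self.anchors = tuple((int(w), int(h)) for w, h in self.anchors)
        self.validate()

    def validate(self) -> None:
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ConfigError("depth/width multiples must be positive")
        if not self.active_scales:
            raise ConfigError("active_scales must be non-empty")
        bad = [s for s in self.active_scales if s not in SCALE_STRIDES]
        if bad:
            raise ConfigError(f"unknown scales {bad}; expected subset of {list(SCALE_STRIDES)}")
        if len(set(self.active_scales)) != len(self.active_scales):
            raise ConfigError("duplicate entries in active_scales")
        if len(self.backbone_repeats) != 4 or len(self.neck_repeats) != 4:
            raise ConfigError("backbone_repeats and neck_repeats must each have 4 entries")
        if any(r < 1 for r in self.backbone_repeats + self.neck_repeats):
            raise ConfigError("all CSP repeats must be >= 1")
        if len(self.base_channels) != 5:
            raise ConfigError("base_channels must list 5 stage widths")
        if self.conv_mode not in ("standard", "ds"):
            raise ConfigError(f"conv_mode must be 'standard' or 'ds', got {self.conv_mode!r}")
        if self.activation not in ("leaky_relu", "silu"):
            raise ConfigError(f"activation must be 'leaky_relu' or 'silu', got {self.activation!r}")
        if self.num_classes < 1:
            raise ConfigError("num_classes must be >= 1")
        if self.input_size % 32 != 0 or self.input_size <= 0:
            raise ConfigError(f"input_size must be a positive multiple of 32, got {self.input_size}")
        if len(self.anchors) % 3 != 0 or len(self.anchors) < 3:
            raise ConfigError("anchor count must be a positive multiple of 3")
        if self.anchor_reference < 0:
            raise ConfigError("anchor_reference must be >= 0")
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ConfigError("anchor dimensions must be positive")

    # -- derived widths -------------------------------------------------

    def stage_channels(self) -> tuple:
        """Width-scaled channels of the five backbone stages (stem first)."""
        base = self.base_channels
        if self.halve_conv_channels:
            base = (base[0],) + tuple(b // 2 for b in base[1:])
        return tuple(scale_channels(b, self.width_multiple) for b in base)

    def strides(self) -> tuple:
        return tuple(SCALE_STRIDES[s] for s in sorted(self.active_scales, key=SCALE_STRIDES.get))

    def with_input_size(self, input_size: int) -> "ModelConfig":
        return replace(self, input_size=input_size)


def _scaled(name, *, width, depth, base_bb=BASE_BACKBONE_REPEATS,
            base_neck=BASE_NECK_REPEATS, **kw) -> ModelConfig:
    return ModelConfig(
        name=name,
        depth_multiple=depth,
        width_multiple=width,
        backbone_repeats=tuple(scale_repeats(n, depth) for n in base_bb),
        neck_repeats=tuple(scale_repeats(n, depth) for n in base_neck),
        **kw,
    )


def _build_presets() -> dict:
    p = {}
    p["baseline-s"] = _scaled("baseline-s", width=0.50, depth=0.33, anchor_reference=640)
    p["two-scale-s"] = _scaled("two-scale-s", width=0.50, depth=0.33,
                               active_scales=("P3", "P4"), anchor_reference=640)
    p["dsconv-s"] = _scaled("dsconv-s", width=0.50, depth=0.33, conv_mode="ds",
                            anchor_reference=640)
    for w in (0.1, 0.2, 0.3, 0.4, 0.5):
        p[f"width-{w}"] = _scaled(f"width-{w}", width=w, depth=0.33, anchor_reference=640)
    for d in (0.1, 0.2, 0.3):
        p[f"depth-{d}"] = _scaled(f"depth-{d}", width=0.50, depth=d, anchor_reference=640)
    # best bottleneck-count ablation row: base (1,2,3,1)/(1,1,1,1) at default depth
    p["csp-reduced"] = _scaled("csp-reduced", width=0.50, depth=0.33,
                               base_bb=(1, 2, 3, 1), base_neck=(1, 1, 1, 1),
                               anchor_reference=640)
    p["avd"] = _scaled("avd", width=0.10, depth=0.33,
                       base_bb=(1, 2, 3, 1), base_neck=(1, 1, 1, 1),
                       active_scales=("P3", "P4"), conv_mode="ds",
                       anchors=GENERATED_ANCHORS, anchor_reference=768)
    return p


_PRESETS = _build_presets()

_CONFIG_FIELDS = {f for f in ModelConfig.__dataclass_fields__}


def preset_names() -> list:
    return sorted(_PRESETS)


def get_preset(name: str) -> ModelConfig:
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    return replace(_PRESETS[name])


def parse_config(text: str) -> ModelConfig:
    """Parse a YAML config document into a validated :class:`ModelConfig`.

    The document either provides every field, or names a ``preset`` to
    inherit from and overrides individual fields.  Unknown keys are
    rejected.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    doc = dict(doc)
    preset = doc.pop("preset", None)
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if preset is not None:
        base = asdict(get_preset(preset))
        base.update(doc)
        doc = base
    missing = {"name"} - set(doc)
    if missing:
        raise ConfigError(f"missing required config keys: {sorted(missing)}")
    try:
        return ModelConfig(**doc)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def config_to_yaml(cfg: ModelConfig) -> str:
    d = asdict(cfg)
    d["backbone_repeats"] = list(cfg.backbone_repeats)
    d["neck_repeats"] = list(cfg.neck_repeats)
    d["active_scales"] = list(cfg.active_scales)
    d["base_channels"] = list(cfg.base_channels)
    d["anchors"] = [list(a) for a in cfg.anchors]
    return yaml.safe_dump(d, sort_keys=False)
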