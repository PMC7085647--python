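"""Declarative channel-threshold rules and canopy/flower segmentation.

A rule is a disjunction (OR) of conjunctions (AND) of atomic inequalities on
single channels or channel differences, e.g. for white pea flowers in 8-bit
RGB::

    R > 200 AND G > 200 AND B > 200 AND G - R <= 20

and for pea canopy in CIE L*a*b*::

    a* < -13

Rules referencing L*, a* or b* trigger an internal sRGB -> L*a*b*
conversion; R/G/B/NIR constants are taken at the scale the rule declares
(raw_8bit or reflectance) with no implicit rescaling, so each crop-sensor
profile stores separate constants per scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .raster import RAW_8BIT, RasterImage, rgb_to_lab

LAB_CHANNELS = ("L*", "a*", "b*")
BAND_CHANNELS = ("R", "G", "B", "NIR")
ALL_CHANNELS = BAND_CHANNELS + LAB_CHANNELS

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}

_TERM_RE = re.compile(
    r"^\s*([A-Za-z]+\*?)\s*(?:-\s*([A-Za-z]+\*?)\s*)?(<=|>=|<|>)\s*(-?\d+(?:\.\d+)?)\s*$"
)


class RuleError(ValueError):
    """Malformed rule text or a channel absent from the target raster."""


def _canon(channel: str) -> str:
    aliases = {"L": "L*", "a": "a*", "b": "b*"}
    channel = aliases.get(channel, channel)
    if channel not in ALL_CHANNELS:
        raise RuleError(f"unknown channel {channel!r}; expected one of {ALL_CHANNELS}")
    return channel


@dataclass(frozen=True)
class Term:
    """One inequality: ``channel <op> value`` or ``channel - minus <op> value``."""

    channel: str
    op: str
    value: float
    minus: str | None = None

    @classmethod
    def parse(cls, text: str) -> "Term":
        m = _TERM_RE.match(text)
        if not m:
            raise RuleError(f"cannot parse rule term {text!r}")
        ch, minus, op, val = m.groups()
        return cls(_canon(ch), op, float(val), _canon(minus) if minus else None)

    def __str__(self) -> str:
        lhs = self.channel if self.minus is None else f"{self.channel} - {self.minus}"
        return f"{lhs} {self.op} {self.value:g}"

    def evaluate(self, channels: Mapping[str, np.ndarray]) -> np.ndarray:
        for name in filter(None, (self.channel, self.minus)):
            if name not in channels:
                raise RuleError(f"channel {self.channel!r} not present in raster")
        lhs = channels[self.channel]
        if self.minus is not None:
            lhs = lhs - channels[self.minus]
        return _OPS[self.op](lhs, self.value)


@dataclass(frozen=True)
class ThresholdRule:
    """OR over AND-blocks of :class:`Term`; true where any block holds."""

    alternatives: tuple[tuple[Term, ...], ...]
    scale: str = RAW_8BIT  # scale at which R/G/B/NIR constants are expressed

    def __post_init__(self) -> None:
        if not self.alternatives or any(not alt for alt in self.alternatives):
            raise RuleError("a rule needs at least one term in every AND-block")

    @classmethod
    def parse(
        cls,
        terms: str | Sequence[str] | Sequence[Sequence[str]],
        scale: str = RAW_8BIT,
    ) -> "ThresholdRule":
        """Build a rule from term strings.

        A flat list is one AND-block; a list of lists is an OR of AND-blocks.
        """
        if isinstance(terms, str):
            terms = [terms]
        if terms and isinstance(terms[0], str):
            terms = [terms]  # type: ignore[list-item]
        alts = tuple(tuple(Term.parse(t) for t in block) for block in terms)
        return cls(alts, scale=scale)

    def channels(self) -> set[str]:
        out: set[str] = set()
        for block in self.alternatives:
            for t in block:
                out.add(t.channel)
                if t.minus:
                    out.add(t.minus)
        return out

    def uses_lab(self) -> bool:
        return bool(self.channels() & set(LAB_CHANNELS))

    def evaluate(self, channels: Mapping[str, np.ndarray]) -> np.ndarray:
        mask = None
        for block in self.alternatives:
            block_mask = None
            for t in block:
                m = t.evaluate(channels)
                block_mask = m if block_mask is None else (block_mask & m)
            mask = block_mask if mask is None else (mask | block_mask)
        return mask

    def to_spec(self) -> list[list[str]]:
        return [[str(t) for t in block] for block in self.alternatives]


def build_channels(img: RasterImage, needed: Iterable[str]) -> dict[str, np.ndarray]:
    """Assemble the channel rasters a rule needs, converting to L*a*b* on demand."""
    needed = set(needed)
    channels: dict[str, np.ndarray] = {b: img.band(b) for b in img.bands}
    if needed & set(LAB_CHANNELS):
        lab = rgb_to_lab(img)
        channels.update({"L*": lab[:, :, 0], "a*": lab[:, :, 1], "b*": lab[:, :, 2]})
    return channels


def evaluate_rule(img: RasterImage | Mapping[str, np.ndarray], rule: ThresholdRule) -> np.ndarray:
    """Evaluate a threshold rule against an image (or prebuilt channel dict)."""
    if isinstance(img, RasterImage):
        if not rule.uses_lab() and img.scale != rule.scale:
            raise RuleError(
                f"rule constants are on the {rule.scale!r} scale but the image "
                f"is {img.scale!r}; profiles store constants per scale"
            )
        channels = build_channels(img, rule.channels())
    else:
        channels = img
    return rule.evaluate(channels)


@dataclass(frozen=True)
class MorphologyLimits:
    """Component-level keep limits: area window, elongation and solidity floors.

    ``max_area_frac`` resolves ``max_area_px`` as a fraction of the image area
    when no absolute cap is given (elongation and compactness limits are
    resolution-free; area limits are not).
    """

    min_area_px: int = 5
    max_area_px: int | None = None
    max_axis_ratio: float = 4.0
    min_solidity: float = 0.6
    max_area_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.max_area_px is not None and self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must not exceed max_area_px")
        if self.max_axis_ratio < 1:
            raise ValueError("max_axis_ratio must be >= 1")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must lie in (0, 1]")

    def resolve_max_area(self, image_area_px: int) -> float:
        if self.max_area_px is not None:
            return float(self.max_area_px)
        return self.max_area_frac * image_area_px

    def scaled(self, factor: int) -> "MorphologyLimits":
        """Limits for imagery block-downsampled by ``factor`` (areas shrink f^2)."""
        return MorphologyLimits(
            min_area_px=max(1, self.min_area_px // (factor * factor)),
            max_area_px=self.max_area_px,
            max_axis_ratio=self.max_axis_ratio,
            min_solidity=self.min_solidity,
            max_area_frac=self.max_area_frac,
        )


@dataclass
class CropSensorProfile:
    """Segmentation recipe for one crop-sensor combination.

    ``canopy_rule`` and ``flower_rule`` map value scale -> rule; rules in
    CIE L*a*b* are scale-free and stored under the key ``"any"``.
    ``kmeans_color_rule`` classifies cluster centroids on the unit scale.
    """

    crop: str
    sensor: str
    canopy_rule: dict[str, ThresholdRule]
    flower_rule: dict[str, ThresholdRule]
    morphology: MorphologyLimits = field(default_factory=MorphologyLimits)
    kmeans_color_rule: ThresholdRule | None = None

    def rule_for(self, which: str, scale: str) -> ThresholdRule:
        rules = getattr(self, f"{which}_rule")
        if "any" in rules:
            return rules["any"]
        try:
            return rules[scale]
        except KeyError:
            raise RuleError(
                f"profile {self.crop}/{self.sensor} has no {which} rule for "
                f"scale {scale!r} (available: {sorted(rules)})"
            ) from None

    @classmethod
    def from_dict(cls, d: Mapping) -> "CropSensorProfile":
        def load_rules(entry) -> dict[str, ThresholdRule]:
            if isinstance(entry, (list, str)):
                # scale-free (lab) shorthand
                return {"any": ThresholdRule.parse(entry)}
            return {
                scale: ThresholdRule.parse(spec, scale=scale if scale != "any" else RAW_8BIT)
                for scale, spec in entry.items()
            }

        morph = MorphologyLimits(**d.get("morphology", {}))
        km = d.get("kmeans_color_rule")
        return cls(
            crop=d["crop"],
            sensor=d.get("sensor", "C-RGB"),
            canopy_rule=load_rules(d["canopy_rule"]),
            flower_rule=load_rules(d["flower_rule"]),
            morphology=morph,
            kmeans_color_rule=ThresholdRule.parse(km, scale="reflectance") if km else None,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CropSensorProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def builtin(cls, crop: str) -> "CropSensorProfile":
        """Load a packaged profile by crop name (pea, canola, camelina, chickpea)."""
        ref = resources.files("floralquant.profiles").joinpath(f"{crop}.yaml")
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise KeyError(f"no built-in profile for crop {crop!r}") from None
        return cls.from_dict(yaml.safe_load(text))


def segment_canopy(img: RasterImage, profile: CropSensorProfile) -> np.ndarray:
    """Binary canopy mask under the profile's canopy rule (L*a*b* for pea)."""
    return evaluate_rule(img, profile.rule_for("canopy", img.scale))


def segment_flower_candidates(img: RasterImage, profile: CropSensorProfile) -> np.ndarray:
    """Binary flower-candidate mask, color rule only — noise not yet removed."""
    return evaluate_rule(img, profile.rule_for("flower", img.scale))
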