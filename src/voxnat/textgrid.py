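"""Praat long-format TextGrid I/O and utterance annotations.

An :class:`UtteranceAnnotation` carries the *phone*, *syllable* and *word*
interval tiers of a single-word utterance plus per-syllable stress flags.
Stress is encoded in the syllable-tier labels by a trailing ``*`` (e.g.
``"sa*"`` is stressed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormatError

__all__ = ["Interval", "UtteranceAnnotation", "read_textgrid", "write_textgrid"]

TIER_NAMES = ("phone", "syllable", "word")
STRESS_MARK = "*"


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class UtteranceAnnotation:
    """Word/syllable/phone tiers with stress flags for one utterance."""

    word: str
    tiers: dict = field(default_factory=dict)  # tier name -> list[Interval]

    def __post_init__(self) -> None:
        for name, ivs in self.tiers.items():
            if name not in TIER_NAMES:
                raise ValueError(f"unknown tier {name!r}")
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end - 1e-9:
                    raise ValueError(f"overlapping intervals in tier {name!r}")
        syl = self.tiers.get("syllable", [])
        if syl and sum(iv.label.endswith(STRESS_MARK) for iv in syl) != 1:
            raise ValueError("exactly one stressed syllable required")

    @property
    def syllables(self) -> list:
        return self.tiers["syllable"]

    @property
    def stress(self) -> list:
        """Per-syllable stress flags, in tier order."""
        return [iv.label.endswith(STRESS_MARK) for iv in self.syllables]

    @property
    def stressed_index(self) -> int:
        return self.stress.index(True)

    def stressed_interval(self) -> Interval:
        return self.syllables[self.stressed_index]

    def unstressed_intervals(self) -> list:
        return [iv for iv, s in zip(self.syllables, self.stress) if not s]


_FLOAT = r"(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"


def read_textgrid(path) -> UtteranceAnnotation:
    """Parse a long-format TextGrid with phone/syllable/word tiers."""
    text = open(path, encoding="utf-8").read()
    if "TextGrid" not in text.split("\n", 3)[1] and "TextGrid" not in text:
        raise FormatError(f"{path} is not a TextGrid")
    tiers: dict = {}
    # split into per-item blocks
    blocks = re.split(r"item \[\d+\]:", text)[1:]
    if not blocks:
        raise FormatError(f"no tiers found in {path}")
    for block in blocks:
        m = re.search(r'name = "([^"]*)"', block)
        if m is None:
            raise FormatError("tier without name")
        name = m.group(1)
        ivs = []
        for im in re.finditer(
            rf"xmin = {_FLOAT}\s*\n\s*xmax = {_FLOAT}\s*\n\s*text = \"([^\"]*)\"",
            block,
        ):
            label = im.group(3)
            if label.strip():
                ivs.append(Interval(float(im.group(1)), float(im.group(2)), label))
        if name in TIER_NAMES:
            tiers[name] = ivs
    words = tiers.get("word", [])
    word = words[0].label if words else ""
    return UtteranceAnnotation(word=word, tiers=tiers)


def write_textgrid(ann: UtteranceAnnotation, path, xmax: float | None = None) -> None:
    """Write a long-format TextGrid readable by Praat."""
    if xmax is None:
        xmax = max(iv.end for ivs in ann.tiers.values() for iv in ivs)
    names = [n for n in TIER_NAMES if n in ann.tiers]
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(names)}",
        "item []:",
    ]
    for i, name in enumerate(names, 1):
        ivs = ann.tiers[name]
        lines += [
            f"    item [{i}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(ivs)}",
        ]
        for j, iv in enumerate(ivs, 1):
            lines += [
                f"        intervals [{j}]:",
                f"            xmin = {iv.start:.6f}",
                f"            xmax = {iv.end:.6f}",
                f'            text = "{iv.label}"',
            ]
    open(path, "w", encoding="utf-8").write("\n".join(lines) + "\n")
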