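"""The eight experimental conditions, grouped into blocks.

Conditions vary in the visual information shown, the localization target
(acoustic vs. visual search) and whether the head-mounted display is worn.
Blocks run in fixed order I..IV to control exposure to the loudspeaker
layout; conditions are randomized within blocks.  Slugs encode
``block-visual-stimulus-hmd`` and are the condition identifiers used in all
on-disk tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Condition",
    "CONDITIONS",
    "get_condition",
    "condition_table",
    "visual_search_slugs",
    "bias_exempt_slugs",
]


@dataclass(frozen=True)
class Condition:
    slug: str
    block: str
    visual: str  # visual information shown to the subject
    stimulus: str  # 'acoustic' (sound localization) or 'visual' (visual search)
    hmd: bool
    bias_exempt: bool = False  # pointing-bias correction is skipped (laser pointer)


CONDITIONS: tuple[Condition, ...] = (
    Condition("I-blind-acoustic-nohmd", "I", "blind-folded", "acoustic", False),
    Condition("I-blind-acoustic-hmd", "I", "blind-folded", "acoustic", True),
    Condition("II-room-acoustic-hmd", "II", "virtual room, no loudspeakers", "acoustic", True),
    Condition("III-ve_ls-visual-hmd", "III", "virtual room, loudspeakers", "visual", True),
    Condition("III-re-visual-nohmd", "III", "real room", "visual", False),
    Condition("III-re-acoustic-nohmd", "III", "real room", "acoustic", False),
    Condition("III-ve_ls-acoustic-hmd", "III", "virtual room, loudspeakers", "acoustic", True),
    Condition(
        "IV-laser-acoustic-hmd",
        "IV",
        "virtual room, loudspeakers, laser pointer",
        "acoustic",
        True,
        bias_exempt=True,
    ),
)

_BY_SLUG = {c.slug: c for c in CONDITIONS}


def get_condition(slug: str) -> Condition:
    try:
        return _BY_SLUG[slug]
    except KeyError:
        raise KeyError(
            f"unknown condition '{slug}'; known: {sorted(_BY_SLUG)}"
        ) from None


def condition_table() -> pd.DataFrame:
    """Machine-readable condition overview."""
    return pd.DataFrame(
        [
            {
                "slug": c.slug,
                "block": c.block,
                "visual_information": c.visual,
                "stimulus": c.stimulus,
                "hmd": c.hmd,
                "bias_exempt": c.bias_exempt,
            }
            for c in CONDITIONS
        ]
    )


def visual_search_slugs() -> list[str]:
    """The visual-localization (pointing-accuracy) conditions."""
    return [c.slug for c in CONDITIONS if c.stimulus == "visual"]


def bias_exempt_slugs() -> list[str]:
    """Conditions excluded from pointing-bias correction."""
    return [c.slug for c in CONDITIONS if c.bias_exempt]
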