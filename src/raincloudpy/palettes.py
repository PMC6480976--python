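"""Fixed color tables.

The two ColorBrewer qualitative palettes used throughout the tutorials,
plus a neutral default.  Colors are assigned cyclically by level order.
"""

from __future__ import annotations

PALETTES: dict[str, list[str]] = {
    # ColorBrewer qualitative, 8 classes each
    "Dark2": [
        "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
        "#66a61e", "#e6ab02", "#a6761d", "#666666",
    ],
    "Set2": [
        "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3",
        "#a6d854", "#ffd92f", "#e5c494", "#b3b3b3",
    ],
    "default": [
        "#4c72b0", "#dd8452", "#55a868", "#c44e52",
        "#8172b3", "#937860", "#da8bc3", "#8c8c8c",
    ],
}


def get_palette(name: str) -> list[str]:
    try:
        return PALETTES[name]
    except KeyError:
        raise KeyError(
            f"unknown palette {name!r}; available: {sorted(PALETTES)}"
        ) from None


def color_for(name: str, index: int) -> str:
    pal = get_palette(name)
    return pal[index % len(pal)]
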