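"""The 64-element ICP-MS panel measured on egg components.

Egg white, yolk and shell are digested and measured for macro-minerals,
heavy/trace metals, alkaline and alkaline-earth metals, rare-earth elements
(REEs), technology-critical elements (TCEs), platinum-group elements (PGEs),
transition/post-transition metals and thorium.  The panel is the fixed
vocabulary every :class:`~ovorisk.concentration.ElementTable` is validated
against.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

_DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "macro": ("Na", "Mg", "P", "K", "Ca"),
    "heavy_trace": (
        "Al", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
        "As", "Se", "Cd", "Sn", "Sb", "Hg", "Pb",
    ),
    "alkali_alkaline_earth": ("Li", "Cs", "Rb", "Be", "Ba", "Sr"),
    "ree": (
        "Sc", "Y", "La", "Ce", "Pr", "Nd", "Sm", "Eu",
        "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
    ),
    "tce": ("Te", "Ge", "Ga", "In", "Nb", "Ta"),
    "pge": ("Pt", "Pd", "Rh", "Os", "Ir", "Ru"),
    "transition_post_transition": ("Ti", "V", "Zr", "Mo", "Hf", "W", "Re", "Bi", "Tl"),
    "actinide": ("Th",),
}


@dataclass(frozen=True)
class ElementPanel:
    """Disjoint element groups; the default instance carries 64 symbols."""

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )

    def __post_init__(self) -> None:
        symbols = [s for grp in self.groups.values() for s in grp]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"element groups are not disjoint: {dupes}")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for grp in self.groups.values() for s in grp)

    def group_of(self, symbol: str) -> str:
        for name, grp in self.groups.items():
            if symbol in grp:
                return name
        raise KeyError(f"{symbol!r} is not in the panel")

    def __contains__(self, symbol: str) -> bool:
        return any(symbol in grp for grp in self.groups.values())

    def __len__(self) -> int:
        return len(self.symbols)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.groups.items()}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ElementPanel":
        raw = json.loads(Path(path).read_text())
        return cls(groups={k: tuple(v) for k, v in raw.items()})


DEFAULT_PANEL = ElementPanel()
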