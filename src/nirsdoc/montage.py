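"""Probe montage: 48 optical channels grouped into six cortical regions.

The default layout mirrors a 24-source / 16-detector whole-head arrangement
(10-20 placement, 3 cm source-detector separation) covering bilateral
prefrontal (PFC), motor (MC) and occipital (OC) cortex.  Channel ids are
1-based as printed on the cap; array indices throughout the package are
0-based (`channel_index = channel_id - 1`).

Note: channels 20 and 43 each belong to two regions in the reference layout
(20 in R_PFC and L_PFC, 43 in R_OC and L_OC).  This overlap is preserved
verbatim; ROI averaging simply counts those channels in both regions.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

REGION_NAMES = ("R_PFC", "L_PFC", "R_MC", "L_MC", "R_OC", "L_OC")

_DEFAULT_REGIONS: dict[str, tuple[int, ...]] = {
    "R_PFC": (3, 4, 5, 6, 7, 17, 18, 19, 20, 21),
    "L_PFC": (8, 9, 10, 11, 12, 20, 22, 23, 24, 25),
    "R_MC": (1, 2, 15, 16, 28, 35, 36, 37, 38, 40),
    "L_MC": (13, 14, 26, 27, 29, 30, 31, 32, 33, 34),
    "R_OC": (39, 41, 43, 45, 46),
    "L_OC": (42, 43, 44, 47, 48),
}


@dataclass(frozen=True)
class Montage:
    """Channel layout and region (ROI) membership.

    Parameters
    ----------
    n_channels:
        Total number of optical channels (default 48).
    regions:
        Mapping region name -> tuple of 1-based channel ids.  A channel id
        may appear in more than one region.
    """

    n_channels: int = 48
    regions: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS)
    )

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for name, chans in self.regions.items():
            for c in chans:
                if not 1 <= c <= self.n_channels:
                    raise ValueError(
                        f"region {name!r} lists channel {c}, outside 1..{self.n_channels}"
                    )
            if len(set(chans)) != len(chans):
                raise ValueError(f"region {name!r} lists a channel twice")

    def region_indices(self, region: str) -> list[int]:
        """0-based array indices of the channels in *region*."""
        return [c - 1 for c in self.regions[region]]

    def module_assignment(self) -> list[int]:
        """Partition channels into disjoint modules for generative models.

        Each channel is assigned to the last region (in ``regions`` order)
        that contains it, so the two doubly-listed channels (20, 43) are
        resolved to L_PFC and L_OC respectively and those regions form
        clean modules.  Channels in no region get module -1.
        """
        assign = [-1] * self.n_channels
        for m, (_, chans) in enumerate(self.regions.items()):
            for c in chans:
                assign[c - 1] = m
        return assign

    # ---- TOML round trip -------------------------------------------------

    def to_toml(self) -> str:
        lines = ["[montage]", f"n_channels = {self.n_channels}", "", "[montage.regions]"]
        for name, chans in self.regions.items():
            lines.append(f"{name} = [{', '.join(str(c) for c in chans)}]")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "Montage":
        doc = tomllib.loads(text)["montage"]
        regions = {k: tuple(int(c) for c in v) for k, v in doc["regions"].items()}
        return cls(n_channels=int(doc["n_channels"]), regions=regions)


def default_montage() -> Montage:
    """The 48-channel, six-region reference montage."""
    return Montage()
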