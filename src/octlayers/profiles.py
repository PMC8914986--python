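"""Layer rosters for the supported OCT segmentation profiles.

Two anatomical profiles are supported: ``retinal7`` carries the seven retinal
boundaries of a macular B-scan (internal limiting membrane down to the retinal
pigment epithelium), whose consecutive pairs bound six intra-retinal regions;
``choroid3`` carries the coarse retina/choroid split (ILM, RPE and the
choroid–scleral interface), bounding the full retina and the choroid.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Profile:
    """A named, anatomically ordered set of boundaries and layer regions."""

    name: str
    #: boundary names, top of the image to the bottom
    boundary_names: tuple[str, ...]
    #: region names; region k lies between boundary k and boundary k+1
    layer_names: tuple[str, ...]

    @property
    def n_boundaries(self) -> int:
        return len(self.boundary_names)

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)


RETINAL7 = Profile(
    name="retinal7",
    boundary_names=("ILM", "NFL", "IPL", "OPL", "ELM", "ISOS", "RPE"),
    layer_names=("ILM-NFL", "NFL-IPL", "IPL-OPL", "OPL-ELM", "ELM-ISOS", "ISOS-RPE"),
)

CHOROID3 = Profile(
    name="choroid3",
    boundary_names=("ILM", "RPE", "CSI"),
    layer_names=("ILM-RPE", "RPE-CSI"),
)

PROFILES: dict[str, Profile] = {p.name: p for p in (RETINAL7, CHOROID3)}


def get_profile(profile: str | Profile) -> Profile:
    """Resolve a profile name (or pass a Profile through)."""
    if isinstance(profile, Profile):
        return profile
    try:
        return PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
        ) from None
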