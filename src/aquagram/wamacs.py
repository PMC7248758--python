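"""Water matrix coordinates (WAMACs).

The twelve WAMACs are experimentally established water absorbance band
ranges in the first overtone region (1300-1600 nm), each assigned to a
water molecular species (free OH, differently hydrogen-bonded species,
hydration water, ...).  Both aquagram flavors evaluate spectra at these
coordinates; the default scheme places each coordinate's range at its
center +/- 6 nm, so C01 (center 1342 nm) spans 1336-1348 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = ["Wamac", "WamacScheme", "default_scheme", "validate_scheme"]

#: Canonical center wavelengths (nm) of C01..C12.
DEFAULT_CENTERS = (
    1342.0, 1364.0, 1374.0, 1384.0, 1412.0, 1426.0,
    1440.0, 1452.0, 1462.0, 1476.0, 1488.0, 1512.0,
)

DEFAULT_LABELS = (
    "free OH / water shell (OH-(H2O)n)",
    "water solvation shell",
    "OH- / solvated electron region",
    "OH- / water solvation",
    "free water molecules (S0)",
    "hydrated / weakly bonded water",
    "water hydration band",
    "S1: singly hydrogen-bonded water",
    "strongly hydrogen-bonded water (S2)",
    "S3 water species",
    "S4 water species",
    "strongly bonded water / aqueous protons",
)


@dataclass(frozen=True)
class Wamac:
    id: str
    center_nm: float
    lo_nm: float
    hi_nm: float
    label: str = ""

    @property
    def width_nm(self) -> float:
        return self.hi_nm - self.lo_nm


@dataclass(frozen=True)
class WamacScheme:
    """An immutable, ordered collection of WAMACs."""

    coordinates: tuple[Wamac, ...]

    def __iter__(self):
        return iter(self.coordinates)

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.coordinates]

    @property
    def centers_nm(self) -> list[float]:
        return [c.center_nm for c in self.coordinates]

    def replace(self, coord_id: str, **changes) -> "WamacScheme":
        """New scheme with one coordinate's fields overridden."""
        coords = []
        for c in self.coordinates:
            if c.id == coord_id:
                d = {**c.__dict__, **changes}
                c = Wamac(**d)
            coords.append(c)
        return WamacScheme(tuple(coords))

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = [
            {"id": c.id, "center_nm": c.center_nm, "lo_nm": c.lo_nm,
             "hi_nm": c.hi_nm, "label": c.label}
            for c in self.coordinates
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WamacScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(tuple(Wamac(**rec) for rec in payload))


def default_scheme(halfwidth_nm: float = 6.0) -> WamacScheme:
    """The canonical 12-coordinate scheme, ranges = center +/- ``halfwidth_nm``."""
    return WamacScheme(
        tuple(
            Wamac(
                id=f"C{i + 1:02d}",
                center_nm=c,
                lo_nm=c - halfwidth_nm,
                hi_nm=c + halfwidth_nm,
                label=DEFAULT_LABELS[i],
            )
            for i, c in enumerate(DEFAULT_CENTERS)
        )
    )


def validate_scheme(scheme: WamacScheme) -> list[str]:
    """Return a list of violation messages; empty list means the scheme is ok.

    Checks: exactly 12 coordinates, ordered by center; lo < center < hi;
    width between 6 and 12 nm; ranges within [1300, 1600] nm.  Overlap
    between adjacent ranges is permitted.
    """
    violations: list[str] = []
    coords = scheme.coordinates
    if len(coords) != 12:
        violations.append(f"scheme has {len(coords)} coordinates, expected 12")
    centers = [c.center_nm for c in coords]
    if sorted(centers) != centers:
        violations.append("coordinates are not ordered by center wavelength")
    for c in coords:
        if not (c.lo_nm < c.center_nm < c.hi_nm):
            violations.append(f"{c.id}: center {c.center_nm} outside ({c.lo_nm}, {c.hi_nm})")
        if not (6.0 <= c.width_nm <= 12.0):
            violations.append(f"{c.id}: width {c.width_nm} nm outside [6, 12] nm")
        if c.lo_nm < 1300.0 or c.hi_nm > 1600.0:
            violations.append(f"{c.id}: range [{c.lo_nm}, {c.hi_nm}] outside [1300, 1600] nm")
    return violations
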