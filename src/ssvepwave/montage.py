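"""Electrode montages on a spherical head model.

Electrode positions are represented as (latitude, longitude) pairs on a
sphere of configurable radius (default 9 cm).  Latitude is measured from
the equatorial plane — the circle through nasion, inion and both
pre-auricular points — so the vertex electrode Cz sits at latitude +90°.
Longitude 0 points at the right ear and +90° at the nasion.

Inter-electrode distances are great-circle distances computed with the
haversine formula,

    haversin(α) = sin²((φ₁−φ₂)/2) + cos φ₁ cos φ₂ sin²((λ₁−λ₂)/2)
    Δδ₁₂        = 2 r asin(√haversin(α)),

which is numerically stable for the small angular separations typical of
neighbouring electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Electrode",
    "Montage",
    "MontageError",
    "great_circle_distance",
    "default_montage",
    "load_montage",
    "save_montage",
]


class MontageError(ValueError):
    """Invalid montage definition or lookup of an unknown channel."""


# Idealized spherical angles (degrees) for the 32-channel extension of the
# international 10-20 system as used by 32-electrode BioSemi caps.  Exactly
# symmetric, Cz at the pole.
_BIOSEMI32_DEG: tuple[tuple[str, float, float], ...] = (
    ("Fp1", -2.0, 108.0),
    ("AF3", 16.0, 115.0),
    ("F7", -2.0, 144.0),
    ("F3", 30.0, 129.0),
    ("FC1", 58.0, 135.0),
    ("FC5", 18.0, 159.0),
    ("T7", -2.0, 180.0),
    ("C3", 44.0, 180.0),
    ("CP1", 58.0, -135.0),
    ("CP5", 18.0, -159.0),
    ("P7", -2.0, -144.0),
    ("P3", 30.0, -129.0),
    ("Pz", 44.0, -90.0),
    ("PO3", 16.0, -115.0),
    ("O1", -2.0, -108.0),
    ("Oz", -2.0, -90.0),
    ("O2", -2.0, -72.0),
    ("PO4", 16.0, -65.0),
    ("P4", 30.0, -51.0),
    ("P8", -2.0, -36.0),
    ("CP6", 18.0, -21.0),
    ("CP2", 58.0, -45.0),
    ("C4", 44.0, 0.0),
    ("T8", -2.0, 0.0),
    ("FC6", 18.0, 21.0),
    ("FC2", 58.0, 45.0),
    ("F4", 30.0, 51.0),
    ("F8", -2.0, 36.0),
    ("AF4", 16.0, 65.0),
    ("Fp2", -2.0, 72.0),
    ("Fz", 44.0, 90.0),
    ("Cz", 90.0, 0.0),
)

DEFAULT_HEAD_RADIUS_CM = 9.0


def _wrap_longitude(lon: float) -> float:
    """Map a longitude to the canonical interval (−π, π]."""
    wrapped = math.remainder(lon, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class Electrode:
    """A named electrode position on the unit sphere (angles in radians)."""

    name: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.latitude) and math.isfinite(self.longitude)):
            raise MontageError(f"non-finite coordinates for electrode {self.name!r}")
        if not -math.pi / 2 <= self.latitude <= math.pi / 2:
            raise MontageError(
                f"latitude {self.latitude!r} of {self.name!r} outside [-pi/2, pi/2]"
            )
        object.__setattr__(self, "longitude", _wrap_longitude(self.longitude))

    @property
    def unit_vector(self) -> np.ndarray:
        """Cartesian position on the unit sphere (x→right ear, y→nasion, z→vertex)."""
        cl = math.cos(self.latitude)
        return np.array(
            [
                cl * math.cos(self.longitude),
                cl * math.sin(self.longitude),
                math.sin(self.latitude),
            ]
        )


def great_circle_distance(
    a: Electrode, b: Electrode, radius: float = DEFAULT_HEAD_RADIUS_CM
) -> float:
    """Great-circle distance between two electrodes, in units of ``radius``.

    Uses the haversine formula; symmetric in its arguments and bounded by
    π·radius (antipodal points).
    """
    if radius <= 0:
        raise MontageError(f"radius must be positive, got {radius!r}")
    hav = (
        math.sin((a.latitude - b.latitude) / 2.0) ** 2
        + math.cos(a.latitude)
        * math.cos(b.latitude)
        * math.sin((a.longitude - b.longitude) / 2.0) ** 2
    )
    # clip guards against rounding slightly above 1 for antipodal points
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(hav)))


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set on a spherical head model."""

    electrodes: tuple[Electrode, ...]
    head_radius: float = DEFAULT_HEAD_RADIUS_CM

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise MontageError(f"head_radius must be positive, got {self.head_radius!r}")
        names = [e.name for e in self.electrodes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MontageError(f"duplicate electrode names: {dupes}")

    @property
    def channel_names(self) -> list[str]:
        return [e.name for e in self.electrodes]

    def __len__(self) -> int:
        return len(self.electrodes)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.electrodes)

    def __getitem__(self, name: str) -> Electrode:
        for e in self.electrodes:
            if e.name == name:
                return e
        raise MontageError(f"unknown channel {name!r}; montage has {self.channel_names}")

    def positions_3d(self, radius: float | None = None) -> np.ndarray:
        """(n, 3) Cartesian positions at ``radius`` (default: head_radius)."""
        r = self.head_radius if radius is None else radius
        return r * np.array([e.unit_vector for e in self.electrodes])

    def distance(self, a: str, b: str) -> float:
        return great_circle_distance(self[a], self[b], self.head_radius)

    def distance_matrix(self, source: str) -> dict[str, float]:
        """Great-circle distance (cm) from ``source`` to every channel."""
        src = self[source]
        return {
            e.name: great_circle_distance(src, e, self.head_radius)
            for e in self.electrodes
        }

    def subset(self, names: list[str]) -> "Montage":
        return Montage(tuple(self[n] for n in names), self.head_radius)

    def with_radius(self, radius: float) -> "Montage":
        return replace(self, head_radius=radius)


def default_montage(head_radius: float = DEFAULT_HEAD_RADIUS_CM) -> Montage:
    """The built-in 32-channel 10-20 montage (idealized spherical angles)."""
    electrodes = tuple(
        Electrode(name, math.radians(lat), math.radians(lon))
        for name, lat, lon in _BIOSEMI32_DEG
    )
    return Montage(electrodes, head_radius)


def load_montage(
    path: str | Path, head_radius: float = DEFAULT_HEAD_RADIUS_CM
) -> Montage:
    """Read a montage from a columnar text file.

    Format: ``# unit: deg`` (or ``rad``) header line, then one
    ``name<TAB or comma or space>lat<sep>lon`` row per electrode.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    unit = None
    electrodes: list[Electrode] = []
    seen: set[str] = set()
    n_rows = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip().lower()
            if body.startswith("unit"):
                unit = body.split(":", 1)[-1].strip()
            continue
        if unit is None:
            raise MontageError(
                f"{path}:{lineno}: montage file must declare '# unit: deg|rad' "
                "before any electrode rows"
            )
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise MontageError(
                f"{path}:{lineno}: expected 'name lat lon', got {raw!r}"
            )
        name, lat_s, lon_s = parts
        if name in seen:
            raise MontageError(f"{path}:{lineno}: duplicate electrode {name!r}")
        seen.add(name)
        try:
            lat, lon = float(lat_s), float(lon_s)
        except ValueError as exc:
            raise MontageError(f"{path}:{lineno}: non-numeric coordinate") from exc
        if unit == "deg":
            lat, lon = math.radians(lat), math.radians(lon)
        elif unit != "rad":
            raise MontageError(f"{path}: unknown unit {unit!r} (use deg or rad)")
        try:
            electrodes.append(Electrode(name, lat, lon))
        except MontageError as exc:
            raise MontageError(f"{path}:{lineno}: {exc}") from exc
        n_rows += 1
    if n_rows == 0:
        raise MontageError(f"{path}: no electrode rows found")
    return Montage(tuple(electrodes), head_radius)


def save_montage(montage: Montage, path: str | Path, unit: str = "deg") -> None:
    """Write a montage in the columnar text format read by :func:`load_montage`."""
    if unit not in ("deg", "rad"):
        raise MontageError(f"unknown unit {unit!r}")
    lines = [f"# unit: {unit}"]
    for e in montage.electrodes:
        lat, lon = e.latitude, e.longitude
        if unit == "deg":
            lat, lon = math.degrees(lat), math.degrees(lon)
        lines.append(f"{e.name}\t{lat:.17g}\t{lon:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")
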