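"""Solvent-accessible surface area, the tetramer compactness filter,
and radius of gyration.

SASA follows Shrake-Rupley: each bead sphere is expanded by the probe
radius and covered with a deterministic quasi-uniform point set (golden
section spiral, so results are reproducible bit for bit); the
accessible area is the fraction of points not buried inside any other
expanded sphere, times the expanded sphere area.

A configuration counts as an assembled tetramer when

    SASA(ABCD) / (SASA(AB) + SASA(CD)) < 0.95,

with each term computed on the configuration's own coordinates with
the complementary chains deleted (no re-relaxation).  The ratio is 1
for well-separated dimers and drops as dimer-dimer contact buries
surface.

Internally coordinates and radii are nm; SASA values are reported in
Angstrom^2, the conventional unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Configuration

__all__ = [
    "SasaParams",
    "sasa",
    "tetramer_filter",
    "radius_of_gyration",
    "TETRAMER_RATIO_THRESHOLD",
]

#: SASA ratio below which a configuration is an assembled tetramer
#: (strict inequality; a ratio of exactly 0.95 is rejected).
TETRAMER_RATIO_THRESHOLD = 0.95

NM2_TO_A2 = 100.0


def _spiral_points(n: int) -> np.ndarray:
    """Golden-section spiral: n quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


@dataclass(frozen=True)
class SasaParams:
    """Probe radius (A), sphere-point count, and bead radius table (A,
    keyed by bead kind; the coarse chains use a single 'bead' entry)."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radius_table: dict = field(
        default_factory=lambda: {"bead": 3.4, "CU": 1.4, "N": 1.55}
    )

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be nonnegative")
        if self.n_sphere_points < 60:
            raise ValueError("need at least 60 sphere points")


def sasa(
    xyz_nm: np.ndarray,
    radii_nm: np.ndarray,
    params: SasaParams = SasaParams(),
) -> float:
    """Shrake-Rupley SASA (A^2) of a set of spheres evaluated in
    isolation.  ``radii_nm`` must supply one radius per sphere."""
    xyz = np.atleast_2d(np.asarray(xyz_nm, dtype=float))
    radii = np.asarray(radii_nm, dtype=float)
    if xyz.shape[0] == 0:
        raise ValueError("empty coordinate set")
    if radii.shape != (xyz.shape[0],):
        raise ValueError("one radius per sphere required")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = int(np.argmin(radii))
        raise ValueError(f"missing or invalid radius for bead {bad}")
    # drop exact duplicates (coincident center and radius) so fully
    # degenerate overlaps count their surface once
    key = np.round(np.column_stack([xyz, radii[:, None]]), 9)
    _, keep = np.unique(key, axis=0, return_index=True)
    if keep.size < xyz.shape[0]:
        xyz = xyz[np.sort(keep)]
        radii = radii[np.sort(keep)]
    probe_nm = params.probe_radius / 10.0
    R = radii + probe_nm
    pts = _spiral_points(params.n_sphere_points)
    tree = cKDTree(xyz)
    total = 0.0
    r_max = R.max()
    for i in range(xyz.shape[0]):
        nb = [j for j in tree.query_ball_point(xyz[i], R[i] + r_max) if j != i]
        if nb:
            sphere = xyz[i] + R[i] * pts
            d2 = ((sphere[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            exposed = float(np.mean(~(d2 < R[nb][None, :] ** 2).any(axis=1)))
        else:
            exposed = 1.0
        total += exposed * 4.0 * np.pi * R[i] ** 2
    return total * NM2_TO_A2


def _chain_sasa(
    conf: Configuration, chains: tuple[str, ...], params: SasaParams
) -> float:
    xyz = conf.beads(chains)
    radii = np.full(xyz.shape[0], conf.bead_radius)
    return sasa(xyz, radii, params)


def tetramer_filter(
    conf: Configuration, params: SasaParams = SasaParams()
) -> tuple[bool, float]:
    """Assembled-tetramer test: ``(is_tetramer, ratio)`` with
    ratio = SASA(ABCD) / (SASA(AB) + SASA(CD))."""
    for c in ("A", "B", "C", "D"):
        if c not in conf.chains:
            raise ValueError(f"chain {c} missing from configuration")
    s_all = _chain_sasa(conf, ("A", "B", "C", "D"), params)
    s_ab = _chain_sasa(conf, ("A", "B"), params)
    s_cd = _chain_sasa(conf, ("C", "D"), params)
    denom = s_ab + s_cd
    if denom <= 0:
        raise ValueError("zero dimer surface area")
    ratio = s_all / denom
    return ratio < TETRAMER_RATIO_THRESHOLD, float(ratio)


def radius_of_gyration(
    conf: Configuration, chains: tuple[str, ...] | None = None
) -> float:
    """Mass-unweighted radius of gyration of the bead centers (nm)."""
    xyz = conf.beads(chains)
    if xyz.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
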