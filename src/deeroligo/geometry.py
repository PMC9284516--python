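"""Ensemble containers and Cu-Cu distance / orientation statistics.

A tetramer configuration carries four coarse-grained peptide chains
labeled A-D (one bead per residue) and two or four Cu sites.  Each Cu
site records the Cu position and the two His nitrogen ligand positions
(Ndelta of the His6-role residue, Nepsilon of the His13-role residue)
that span the coordination plane; the unit normal of that plane is the
geometric proxy for the Cu g-tensor z axis.

Cu-Cu pairs partition into two classes: intra-dimer (AB and CD, the
preformed dimers) and inter-dimer (AC, AD, BC, BD, across dimers).
All distances are in nm (PDB Angstrom coordinates are divided by 10 on
read); orientation statistics are reported as scalar products of unit
normals and as an RMS angle in degrees.

PDB conventions (also produced by :mod:`deeroligo.synthetic`):

====================  =======================================
record                meaning
====================  =======================================
ATOM  CA / resn ALA   one coarse bead per residue, element C
HETATM CU / resn CU   Cu ion, element CU, resseq 901
HETATM ND1 / resn L06 His6-role Ndelta ligand, resseq 902
HETATM NE2 / resn L13 His13-role Nepsilon ligand, resseq 903
====================  =======================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CuSite",
    "Configuration",
    "OligomerEnsemble",
    "PairClass",
    "read_ensemble",
    "write_ensemble",
    "pair_distances",
    "distance_distribution",
    "summarize_distances",
    "coordination_normal",
    "orientation_distribution",
    "OrientationStats",
]

ANGSTROM_PER_NM = 10.0

#: Maximum Cu-ligand bond length accepted when building a CuSite (nm).
MAX_LIGAND_BOND_NM = 0.35

CHAIN_LABELS = ("A", "B", "C", "D")

#: Residue/atom naming convention used in PDB files (see module docstring).
BEAD_RESNAME = "ALA"
BEAD_ATOM = "CA"
CU_RESNAME = "CU"
HIS6_RESNAME = "L06"
HIS6_ATOM = "ND1"
HIS13_RESNAME = "L13"
HIS13_ATOM = "NE2"


@dataclass(frozen=True)
class CuSite:
    """One Cu position and its two coordination-plane ligand atoms (nm)."""

    chain: str
    cu: np.ndarray
    n_his6: np.ndarray
    n_his13: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cu", "n_his6", "n_his13"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if self.chain not in CHAIN_LABELS:
            raise ValueError(f"chain must be one of {CHAIN_LABELS}")
        for lig in (self.n_his6, self.n_his13):
            d = float(np.linalg.norm(lig - self.cu))
            if d < 1e-9:
                raise ValueError("ligand coincides with Cu position")
            if d > MAX_LIGAND_BOND_NM:
                raise ValueError(
                    f"ligand {d:.3f} nm from Cu exceeds "
                    f"{MAX_LIGAND_BOND_NM} nm bond limit"
                )


@dataclass
class Configuration:
    """One tetramer configuration: bead chains plus Cu sites (nm)."""

    chains: dict[str, np.ndarray]
    bead_radius: float
    cu_sites: list[CuSite] = field(default_factory=list)

    def site(self, chain: str) -> CuSite | None:
        for s in self.cu_sites:
            if s.chain == chain:
                return s
        return None

    def beads(self, chains: tuple[str, ...] | None = None) -> np.ndarray:
        labels = chains if chains is not None else tuple(self.chains)
        return np.vstack([self.chains[c] for c in labels])


@dataclass
class OligomerEnsemble:
    """Ordered set of tetramer configurations sharing chain labels."""

    configurations: list[Configuration]
    stoichiometry: str = "Cub"

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)


class PairClass(Enum):
    """Partition of Cu-Cu pairs into within- and across-dimer classes."""

    INTRA_DIMER = (("A", "B"), ("C", "D"))
    INTER_DIMER = (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"))


# ------------------------------------------------------------- PDB round trip


def write_ensemble(ens: OligomerEnsemble, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL) using the documented
    bead/Cu/ligand naming convention; coordinates converted nm -> A."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("ens")
    serial = 1
    for imodel, conf in enumerate(ens.configurations):
        builder.init_model(imodel)
        for chain_id in sorted(conf.chains):
            builder.init_chain(chain_id)
            builder.init_seg("    ")
            for ires, bead in enumerate(conf.chains[chain_id], start=1):
                builder.init_residue(BEAD_RESNAME, " ", ires, " ")
                builder.init_atom(
                    BEAD_ATOM,
                    np.asarray(bead) * ANGSTROM_PER_NM,
                    0.0,
                    1.0,
                    " ",
                    f" {BEAD_ATOM} ",
                    serial,
                    element="C",
                )
                serial += 1
            site = conf.site(chain_id)
            if site is None:
                continue
            for resname, resseq, atom, element, pos in (
                (CU_RESNAME, 901, "CU", "CU", site.cu),
                (HIS6_RESNAME, 902, HIS6_ATOM, "N", site.n_his6),
                (HIS13_RESNAME, 903, HIS13_ATOM, "N", site.n_his13),
            ):
                builder.init_residue(resname, f"H_{resname}", resseq, " ")
                builder.init_atom(
                    atom,
                    np.asarray(pos) * ANGSTROM_PER_NM,
                    0.0,
                    1.0,
                    " ",
                    atom.center(4),
                    serial,
                    element=element,
                )
                serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_ensemble(
    path: str | Path,
    bead_radius: float = 0.34,
    stoichiometry: str | None = None,
) -> OligomerEnsemble:
    """Read a multi-model PDB into an :class:`OligomerEnsemble`.

    One configuration per MODEL.  Models missing a required chain, Cu,
    or ligand atom are skipped with a logged warning.  ``bead_radius``
    (nm) is attached to every bead for downstream SASA use.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    configurations: list[Configuration] = []
    n_skipped = 0
    for model in structure:
        chains: dict[str, np.ndarray] = {}
        sites: list[CuSite] = []
        ok = True
        for chain_id in CHAIN_LABELS:
            if chain_id not in model:
                logger.warning(
                    "model %s: missing chain %s; skipped", model.id, chain_id
                )
                ok = False
                break
            chain = model[chain_id]
            beads = [
                atom.coord / ANGSTROM_PER_NM
                for res in chain
                for atom in res
                if res.resname.strip() == BEAD_RESNAME
                and atom.name == BEAD_ATOM
            ]
            if not beads:
                logger.warning(
                    "model %s chain %s: no bead atoms; skipped",
                    model.id,
                    chain_id,
                )
                ok = False
                break
            chains[chain_id] = np.asarray(beads)
            parts: dict[str, np.ndarray] = {}
            for res in chain:
                rn = res.resname.strip()
                if rn == CU_RESNAME and "CU" in res:
                    parts["cu"] = res["CU"].coord / ANGSTROM_PER_NM
                elif rn == HIS6_RESNAME and HIS6_ATOM in res:
                    parts["n_his6"] = res[HIS6_ATOM].coord / ANGSTROM_PER_NM
                elif rn == HIS13_RESNAME and HIS13_ATOM in res:
                    parts["n_his13"] = res[HIS13_ATOM].coord / ANGSTROM_PER_NM
            if "cu" in parts:
                if len(parts) != 3:
                    logger.warning(
                        "model %s chain %s: incomplete Cu site; model skipped",
                        model.id,
                        chain_id,
                    )
                    ok = False
                    break
                sites.append(CuSite(chain=chain_id, **parts))
        if not ok:
            n_skipped += 1
            continue
        configurations.append(
            Configuration(chains=chains, bead_radius=bead_radius, cu_sites=sites)
        )
    if n_skipped:
        logger.warning("skipped %d of %d models", n_skipped, n_skipped + len(configurations))
    if stoichiometry is None:
        cu_chains = {s.chain for c in configurations for s in c.cu_sites}
        stoichiometry = "Cuh" if cu_chains == {"A", "C"} else "Cub"
    return OligomerEnsemble(configurations=configurations, stoichiometry=stoichiometry)


# ----------------------------------------------------------- distance stats


def _class_pairs(conf: Configuration, cls: PairClass) -> list[tuple[CuSite, CuSite]]:
    pairs = []
    for c1, c2 in cls.value:
        s1, s2 = conf.site(c1), conf.site(c2)
        if s1 is not None and s2 is not None:
            pairs.append((s1, s2))
    return pairs


def pair_distances(ens: OligomerEnsemble, cls: PairClass) -> np.ndarray:
    """Pooled Cu-Cu distances (nm) for all pairs of the class, over all
    configurations.  An empty result (e.g. the intra-dimer class of a
    Cuh ensemble, which has Cu on chains A and C only) is returned as an
    empty array with a logged notice."""
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    out = []
    for conf in ens:
        for s1, s2 in _class_pairs(conf, cls):
            out.append(float(np.linalg.norm(s1.cu - s2.cu)))
    if not out:
        logger.info(
            "no %s Cu-Cu pairs for stoichiometry %s",
            cls.name.lower(),
            ens.stoichiometry,
        )
        return np.empty(0)
    return np.asarray(out)


def distance_distribution(
    distances: np.ndarray, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of distances scaled to unit trapezoid integral.

    Returns ``(centers, density)``.  The grid is padded with two empty
    bins on each side so the curve closes to zero; curves from samples
    of any size therefore integrate to the same value, 1.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("no distances to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = np.floor(distances.min() / bin_width) * bin_width - 2 * bin_width
    hi = np.ceil(distances.max() / bin_width) * bin_width + 2 * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(distances, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts.astype(float)
    z = np.trapezoid(density, centers)
    return centers, density / z


def summarize_distances(distances: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (nm)."""
    distances = np.asarray(distances, dtype=float)
    if distances.size < 2:
        raise ValueError("need at least 2 distances to summarize")
    return float(distances.mean()), float(distances.std(ddof=0))


# -------------------------------------------------------- orientation stats


def coordination_normal(site: CuSite) -> np.ndarray:
    """Unit normal of the Cu coordination plane.

    Proportional to (n_his6 - cu) x (n_his13 - cu); the His6 ligand
    comes first by convention, fixing the sign.  Collinear bonds raise.
    """
    b1 = site.n_his6 - site.cu
    b2 = site.n_his13 - site.cu
    n = np.cross(b1, b2)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * np.linalg.norm(b1) * np.linalg.norm(b2):
        raise ValueError("collinear Cu-ligand bonds: coordination plane undefined")
    return n / norm


@dataclass(frozen=True)
class OrientationStats:
    """Scalar products of coordination-plane normals for one pair class."""

    scalar_products: np.ndarray
    angle_sd_deg: float
    bin_centers: np.ndarray
    density: np.ndarray


def orientation_distribution(
    ens: OligomerEnsemble,
    cls: PairClass,
    bin_width: float = 0.05,
) -> OrientationStats:
    """Per-pair scalar products u_z(i) . u_z(j) of plane normals, their
    unit-integral histogram, and the RMS angle arccos(s) in degrees
    (measured about perfect alignment, the natural center for the
    near-parallel within-dimer statistics)."""
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    dots = []
    for conf in ens:
        for s1, s2 in _class_pairs(conf, cls):
            d = float(np.dot(coordination_normal(s1), coordination_normal(s2)))
            dots.append(min(1.0, max(-1.0, d)))
    if not dots:
        logger.info("no %s pairs for orientation statistics", cls.name.lower())
        return OrientationStats(np.empty(0), float("nan"), np.empty(0), np.empty(0))
    s = np.asarray(dots)
    angles = np.degrees(np.arccos(s))
    angle_sd = float(np.sqrt(np.mean(angles**2)))
    edges = np.arange(-1.0 - bin_width, 1.0 + 2 * bin_width, bin_width)
    counts, edges = np.histogram(s, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts.astype(float)
    z = np.trapezoid(density, centers)
    return OrientationStats(s, angle_sd, centers, density / (z if z > 0 else 1.0))
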