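"""Ground-truth-known synthetic inputs: tetramer ensembles and DEER traces.

The ensemble generator emulates dimer-of-dimers Cu-amyloid tetramers at
the level of the observables the analysis consumes: Cu-Cu distances
within (AB, CD) and across (AC, AD, BC, BD) the preformed dimers,
coordination-plane orientations, and coarse bead clouds for SASA and
radius-of-gyration statistics.  It makes no claim to peptide energetics
or chain connectivity.

Construction of one configuration (all lengths nm):

1. Intra-dimer Cu-Cu distances d_AB, d_CD are exact draws from a
   truncated normal (lower bound 0.3 nm, hard-sphere contact).
2. The four cross-dimer Cu positions are built sequentially; each
   cross distance (AC, then BC, AD, BD) is drawn from the inter-dimer
   truncated-normal law restricted to its geometric feasibility
   interval, so the pooled inter-dimer marginal follows the requested
   law up to placement feasibility (the restriction windows are wide
   and nearly symmetric about the mean, so pooled means are unbiased
   to well below sampling error).
3. A compactness factor c in (0, 1] rescales the dimer-center
   separation by 1/c after Cu placement: c = 1 leaves the distance
   laws exact; small c pulls the dimers apart into clearly
   non-assembled configurations.
4. Each dimer draws a base coordination-plane normal uniformly on the
   sphere; the first site of the dimer uses it exactly and the second
   is tilted about a random in-plane axis by an angle ~ N(0,
   plane_angle_sd), so the within-dimer relative angle has RMS equal
   to plane_angle_sd while across-dimer normals are uncorrelated.
   Ligand pseudo-atoms sit 0.2 nm from Cu along two orthogonal
   in-plane directions whose cross product reproduces the normal.
5. Each chain is a cloud of beads_per_chain beads uniform in a sphere
   of radius ``blob_radius`` anchored halfway between the chain's Cu
   site (its dimer partner's Cu for the Cu-free chains of Cuh) and the
   tetramer Cu centroid, mimicking peptide mass filling the space
   between metal centers.

Stoichiometries: Cu1 and Cub carry one Cu per chain (their geometric
statistics differ only through the distance/orientation laws supplied);
Cuh carries Cu on chains A and C only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .forward import (
    DeerTrace,
    DistanceDistribution,
    background,
    form_factor,
    write_trace,
)
from .geometry import Configuration, CuSite, OligomerEnsemble, write_ensemble

__all__ = [
    "EnsembleSpec",
    "DeerAcquisitionSpec",
    "generate_ensemble",
    "generate_deer_trace",
    "write_ground_truth",
]

#: Lower truncation of every distance law: hard-sphere Cu-Cu contact (nm).
MIN_DISTANCE_NM = 0.3

#: Cu-N ligand bond length for the coordination-plane pseudo-atoms (nm).
LIGAND_BOND_NM = 0.20

STOICHIOMETRIES = ("Cu1", "Cub", "Cuh")


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a synthetic tetramer ensemble (distances in nm,
    angles in degrees)."""

    n_configs: int = 100
    stoichiometry: str = "Cub"
    intra_mean: float = 2.0
    intra_sd: float = 0.2
    inter_mean: float = 3.6
    inter_sd: float = 0.9
    plane_angle_sd: float = 20.0
    compactness: float = 1.0
    beads_per_chain: int = 42
    blob_radius: float = 1.4
    bead_radius: float = 0.34
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_configs < 1:
            raise ValueError("n_configs must be >= 1")
        if self.stoichiometry not in STOICHIOMETRIES:
            raise ValueError(f"stoichiometry must be one of {STOICHIOMETRIES}")
        for name in ("intra_mean", "inter_mean"):
            v = getattr(self, name)
            if not MIN_DISTANCE_NM < v < 10.0:
                raise ValueError(
                    f"{name}={v} nm infeasible: must lie in "
                    f"({MIN_DISTANCE_NM}, 10) nm (hard-sphere contact below)"
                )
        if self.intra_sd < 0 or self.inter_sd < 0 or self.plane_angle_sd < 0:
            raise ValueError("spreads must be nonnegative")
        if not 0.0 < self.compactness <= 1.0:
            raise ValueError("compactness must be in (0, 1]")
        if self.beads_per_chain < 1:
            raise ValueError("beads_per_chain must be >= 1")


@dataclass(frozen=True)
class DeerAcquisitionSpec:
    """DEER acquisition grid and signal parameters.

    Defaults reproduce the experimental grid: initial delay 100 ns,
    10 ns increments, 200 points.  The zero of dipolar evolution is at
    the first sample.
    """

    t0: float = 100.0
    dt: float = 10.0
    n_points: int = 200
    modulation_depth: float = 0.3
    background_rate: float = 5e-4
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 < 0 or self.dt <= 0 or self.n_points < 2:
            raise ValueError("invalid acquisition grid")
        if not 0.0 <= self.modulation_depth < 1.0:
            raise ValueError("modulation depth must be in [0, 1)")
        if self.background_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_points)


# ------------------------------------------------------------ distance draws


def _tdraw(rng, mean, sd, lo, hi=np.inf):
    """One draw from Normal(mean, sd) truncated to [lo, hi]; degenerate
    sd clips the mean into the interval."""
    lo = max(lo, 1e-6)
    if hi <= lo:
        return lo
    if sd == 0:
        return float(min(max(mean, lo), hi))
    a = (lo - mean) / sd
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _cu_positions(spec: EnsembleSpec, rng) -> dict[str, np.ndarray]:
    """Cu positions of one configuration in a canonical frame."""
    eps = 1e-6
    if spec.stoichiometry == "Cuh":
        d = _tdraw(rng, spec.inter_mean, spec.inter_sd, MIN_DISTANCE_NM)
        return {"A": np.zeros(3), "C": np.array([d, 0.0, 0.0])}

    d_ab = _tdraw(rng, spec.intra_mean, spec.intra_sd, MIN_DISTANCE_NM)
    d_cd = _tdraw(rng, spec.intra_mean, spec.intra_sd, MIN_DISTANCE_NM)
    d_ac = _tdraw(rng, spec.inter_mean, spec.inter_sd, MIN_DISTANCE_NM)
    A = np.zeros(3)
    B = np.array([d_ab, 0.0, 0.0])
    # C in the upper half plane, BC from the law on its triangle window
    d_bc = _tdraw(
        rng, spec.inter_mean, spec.inter_sd, abs(d_ac - d_ab) + eps, d_ac + d_ab - eps
    )
    cos_g = (d_ab**2 + d_ac**2 - d_bc**2) / (2 * d_ab * d_ac)
    C = d_ac * np.array([cos_g, np.sqrt(max(1 - cos_g**2, 0.0)), 0.0])
    # D on the sphere-intersection circle around the AC axis
    d_ad = _tdraw(
        rng, spec.inter_mean, spec.inter_sd, abs(d_ac - d_cd) + eps, d_ac + d_cd - eps
    )
    e = C / d_ac
    x = (d_ac**2 + d_ad**2 - d_cd**2) / (2 * d_ac)
    rho = np.sqrt(max(d_ad**2 - x**2, 0.0))
    e1 = np.array([-e[1], e[0], 0.0])
    n1 = np.linalg.norm(e1)
    e1 = e1 / n1 if n1 > 1e-12 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e, e1)
    v = B - x * e
    v1, v2 = float(v @ e1), float(v @ e2)
    w = float(np.hypot(v1, v2))
    vv = float(v @ v)
    lo2 = max(vv + rho**2 - 2 * rho * w, 1e-12)
    hi2 = vv + rho**2 + 2 * rho * w
    d_bd = _tdraw(rng, spec.inter_mean, spec.inter_sd, np.sqrt(lo2), np.sqrt(hi2))
    if w > 1e-9 and rho > 1e-9:
        cpsi = np.clip((vv + rho**2 - d_bd**2) / (2 * rho * w), -1.0, 1.0)
        psi = np.arctan2(v2, v1) + rng.choice([-1.0, 1.0]) * np.arccos(cpsi)
    else:
        psi = rng.uniform(0.0, 2.0 * np.pi)
    D = x * e + rho * (np.cos(psi) * e1 + np.sin(psi) * e2)
    return {"A": A, "B": B, "C": C, "D": D}


def _apply_compactness(cus: dict[str, np.ndarray], c: float) -> None:
    """Rescale the dimer-center separation by 1/c (in place)."""
    if c == 1.0:
        return
    d1 = [cus[k] for k in ("A", "B") if k in cus]
    d2 = [cus[k] for k in ("C", "D") if k in cus]
    m1 = np.mean(d1, axis=0)
    m2 = np.mean(d2, axis=0)
    shift = (m1 + (m2 - m1) / c) - m2
    for k in ("C", "D"):
        if k in cus:
            cus[k] = cus[k] + shift


def _make_site(chain: str, cu: np.ndarray, normal: np.ndarray, rng) -> CuSite:
    """Ligand pseudo-atoms spanning a plane with the requested normal."""
    ref = _random_unit(rng)
    e1 = np.cross(normal, ref)
    while np.linalg.norm(e1) < 1e-6:  # ref parallel to normal; redraw
        ref = _random_unit(rng)
        e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return CuSite(
        chain=chain,
        cu=cu,
        n_his6=cu + LIGAND_BOND_NM * e1,
        n_his13=cu + LIGAND_BOND_NM * e2,
    )


def _dimer_normals(spec: EnsembleSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Base normal and tilted partner normal for one dimer."""
    base = _random_unit(rng)
    angle = np.radians(rng.normal(0.0, spec.plane_angle_sd))
    ref = _random_unit(rng)
    axis = np.cross(base, ref)
    while np.linalg.norm(axis) < 1e-6:
        ref = _random_unit(rng)
        axis = np.cross(base, ref)
    tilted = _rotation_about(axis, angle) @ base if angle != 0.0 else base.copy()
    return base, tilted


def _chain_blob(anchor: np.ndarray, spec: EnsembleSpec, rng) -> np.ndarray:
    u = rng.random(spec.beads_per_chain) ** (1.0 / 3.0)
    v = rng.standard_normal((spec.beads_per_chain, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return anchor + spec.blob_radius * u[:, None] * v


def generate_ensemble(
    spec: EnsembleSpec, pdb_path: str | Path | None = None
) -> OligomerEnsemble:
    """Generate a synthetic tetramer ensemble; optionally write it as a
    multi-model PDB.  Deterministic for a fixed spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    configs: list[Configuration] = []
    for _ in range(spec.n_configs):
        cus = _cu_positions(spec, rng)
        _apply_compactness(cus, spec.compactness)

        # random global orientation and offset so configurations are
        # not all canonically aligned
        R = _rotation_about(_random_unit(rng), rng.uniform(0.0, 2.0 * np.pi))
        shift = rng.uniform(5.0, 15.0, size=3)
        cus = {k: R @ v + shift for k, v in cus.items()}

        sites: list[CuSite] = []
        if spec.stoichiometry == "Cuh":
            for chain in ("A", "C"):
                sites.append(_make_site(chain, cus[chain], _random_unit(rng), rng))
        else:
            for c1, c2 in (("A", "B"), ("C", "D")):
                n1, n2 = _dimer_normals(spec, rng)
                sites.append(_make_site(c1, cus[c1], n1, rng))
                sites.append(_make_site(c2, cus[c2], n2, rng))

        centroid = np.mean(list(cus.values()), axis=0)
        chains: dict[str, np.ndarray] = {}
        for chain, partner in (("A", "A"), ("B", "B"), ("C", "C"), ("D", "D")):
            key = partner if partner in cus else {"B": "A", "D": "C"}[chain]
            anchor = cus[key] + 0.5 * (centroid - cus[key])
            chains[chain] = _chain_blob(anchor, spec, rng)
        configs.append(
            Configuration(
                chains=chains, bead_radius=spec.bead_radius, cu_sites=sites
            )
        )
    ens = OligomerEnsemble(configurations=configs, stoichiometry=spec.stoichiometry)
    if pdb_path is not None:
        write_ensemble(ens, pdb_path)
    return ens


# ----------------------------------------------------------------- traces


def generate_deer_trace(
    p: DistanceDistribution,
    acq: DeerAcquisitionSpec,
    trace_path: str | Path | None = None,
) -> tuple[DeerTrace, dict]:
    """Simulate a noisy DEER trace from a known distance distribution.

    V(t) = B(tau) (1 - lambda + lambda F(tau)) + noise, with tau = t - t0
    (dipolar zero at the first sample) and additive white Gaussian noise.
    Returns the trace and a ground-truth record.
    """
    if abs(p.integral - 1.0) > 1e-6:
        raise ValueError("distance distribution must be normalized")
    rng = np.random.default_rng(acq.seed)
    t = acq.times
    tau = t - acq.t0
    lam = acq.modulation_depth
    F = form_factor(p, tau)
    v = background(tau, acq.background_rate) * (1.0 - lam + lam * F)
    v = v + acq.noise_sd * rng.standard_normal(t.size)
    meta = {
        "lambda": lam,
        "k_per_ns": acq.background_rate,
        "noise_sd": acq.noise_sd,
        "seed": acq.seed,
        "t0_ns": acq.t0,
    }
    trace = DeerTrace(t=t, v=v, meta=meta)
    truth = {
        "p": p,
        "lambda": lam,
        "k_per_ns": acq.background_rate,
        "noise_sd": acq.noise_sd,
        "seed": acq.seed,
    }
    if trace_path is not None:
        write_trace(trace_path, trace)
        write_ground_truth(Path(trace_path).with_suffix(".truth"), truth)
    return trace, truth


def write_ground_truth(path: str | Path, truth: dict) -> None:
    """Plain-text key-value sidecar; the ground-truth distribution is
    appended as 'p <r_nm> <density>' lines."""
    with open(path, "w") as fh:
        for key in ("lambda", "k_per_ns", "noise_sd", "seed"):
            fh.write(f"{key} = {truth[key]}\n")
        p: DistanceDistribution = truth["p"]
        for r, dens in zip(p.r, p.p):
            fh.write(f"p {r:.6f} {dens:.8e}\n")
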