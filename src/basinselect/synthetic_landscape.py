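"""Seeded generators of synthetic decoy ensembles with planted landscape structure.

Real decoy sets come from template-free structure prediction: tens of
thousands of conformations whose semi-empirical energies form an overly
rugged surface with a (hopefully) funnel-shaped region around the native and
a multitude of deceptive low-energy false minima elsewhere. The molecular
generator emulates exactly those features at desk scale: a self-avoiding
C-alpha walk serves as the native; near-native decoys are Cartesian
perturbations of it with target RMSDs planted inside the near-native
threshold; non-native decoys congregate around a few false attractor
structures far from the native, plus a scattered background. Energies
combine a funnel term increasing in true RMSD, Gaussian wells at the false
attractors (deep enough to rival the funnel bottom), and observation noise.
Pseudo-potential feature columns are noisy linear encodings of true RMSD --
standing in for knowledge-based potentials -- with a few pure-noise columns
mixed in so regressors must ignore uninformative features.

The abstract generator drops the molecular geometry: points in a
low-dimensional Euclidean space around m planted well centers, with radially
increasing energy per well. Planted labels are exported for
basin-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures_io import (
    Decoy,
    DecoyEnsemble,
    DistanceStore,
    _rmsd_one_to_many,
    least_rmsd,
)

__all__ = [
    "SimSpec",
    "simulate_ensemble",
    "difficulty_preset",
    "AbstractLandscape",
    "simulate_abstract",
]


@dataclass
class SimSpec:
    """Parameters of one synthetic decoy ensemble.

    Geometry is in angstroms, energies in arbitrary Rosetta-like units.
    ``min_dist`` is the planted best-decoy RMSD; ``near_native_fraction`` the
    share of decoys planted strictly inside ``dist_thresh``.
    """

    seed: int
    n_decoys: int = 2000
    n_residues: int = 24
    min_dist: float = 0.7
    dist_thresh: float = 2.0
    near_native_fraction: float = 0.25
    n_false_minima: int = 4
    funnel_strength: float = 3.0  # energy units per A of true RMSD
    energy_noise_sd: float = 0.5
    feature_noise_sd: float = 0.5
    n_pseudo_potentials: int = 20
    n_noise_potentials: int = 4
    potential_seed: int = 20011  # shared across ensembles: potentials are fixed functions
    background_fraction: float = 0.15  # share of non-natives not in any false well
    false_min_spread: float = 1.0  # RMSD spread (A) within a false well
    deception: float = 0.9  # well depth relative to the funnel at its center
    well_width: float = 1.0  # Gaussian well width (A)

    def __post_init__(self) -> None:
        if not 0.0 <= self.near_native_fraction <= 1.0:
            raise ValueError("near_native_fraction must lie in [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if self.n_decoys < 1 or self.n_residues < 3:
            raise ValueError("need n_decoys >= 1 and n_residues >= 3")
        if self.min_dist >= self.dist_thresh and self.near_native_fraction > 0:
            raise ValueError("min_dist must be below dist_thresh")


_PRESETS = {
    # planted best-decoy quality, near-native threshold, and abundance per
    # difficulty level, patterned on template-free decoy sets
    "easy": dict(min_dist=0.7, dist_thresh=2.0, near_native_fraction=0.25),
    "medium": dict(min_dist=1.5, dist_thresh=2.5, near_native_fraction=0.08),
    "hard": dict(min_dist=3.5, dist_thresh=4.5, near_native_fraction=0.02),
}


def difficulty_preset(level: str, seed: int, **overrides) -> SimSpec:
    """A SimSpec emulating an easy, medium, or hard decoy set."""
    if level not in _PRESETS:
        raise ValueError(f"unknown difficulty level {level!r}")
    params = dict(_PRESETS[level])
    params.update(overrides)
    return SimSpec(seed=seed, **params)


def _self_avoiding_walk(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """C-alpha trace: 3.8 A virtual bonds, no two non-bonded atoms under 3.5 A."""
    for _ in range(50):  # walk-level restarts
        coords = [np.zeros(3)]
        prev_dir = None
        ok = True
        for _ in range(n_res - 1):
            placed = False
            for _ in range(100):
                step = rng.standard_normal(3)
                if prev_dir is not None:
                    step = 0.8 * prev_dir + step  # persistence keeps the chain open
                step *= 3.8 / np.linalg.norm(step)
                cand = coords[-1] + step
                prior = np.asarray(coords[:-1])
                if len(prior) == 0 or np.min(
                    np.linalg.norm(prior - cand, axis=1)
                ) >= 3.5:
                    coords.append(cand)
                    prev_dir = step / 3.8
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(coords)
    raise RuntimeError("failed to generate a self-avoiding walk")


def _perturb_to_rmsd(
    base: np.ndarray, target: float, rng: np.random.Generator, iters: int = 4
) -> np.ndarray:
    """Gaussian Cartesian perturbation rescaled to hit a target least RMSD."""
    if target <= 0:
        return base.copy()
    p = rng.standard_normal(base.shape)
    p -= p.mean(axis=0)
    s = 1.0
    for _ in range(iters):
        cur = least_rmsd(base, base + s * p)
        if cur <= 1e-12:
            s *= 2.0
            continue
        s *= target / cur
    return base + s * p


def simulate_ensemble(spec: SimSpec) -> DecoyEnsemble:
    """Generate one molecular ensemble with native, energies and potentials.

    Deterministic given the spec (bit-identical across runs with the same
    seed). Raises if the planted min_dist cannot be realized within a small
    relative tolerance after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    native = _self_avoiding_walk(spec.n_residues, rng)
    n = spec.n_decoys

    n_near = int(round(spec.near_native_fraction * n))
    n_far = n - n_near
    n_false = spec.n_false_minima if n_far > 0 else 0

    # far attractor structures: deceptive false minima well beyond dist_thresh
    center_rmsds = (
        rng.uniform(max(spec.dist_thresh + 2.5, 5.0), 10.0, size=n_false)
        if n_false
        else np.empty(0)
    )
    centers = [
        _perturb_to_rmsd(native, r, rng) for r in center_rmsds
    ]

    coords_list: list[np.ndarray] = []
    origins: list[str] = []

    # near-native component: targets strictly inside dist_thresh, one at min_dist
    near_targets = np.concatenate(
        [
            [spec.min_dist],
            rng.uniform(spec.min_dist, 0.95 * spec.dist_thresh, size=max(n_near - 1, 0)),
        ]
    )[:n_near]
    for t in near_targets:
        coords_list.append(_perturb_to_rmsd(native, t, rng))
        origins.append("near")

    # far component: clustered around false attractors plus scattered background
    n_bg = int(round(spec.background_fraction * n_far)) if n_false else n_far
    n_clustered = n_far - n_bg
    assignments = (
        rng.integers(0, n_false, size=n_clustered) if n_false else np.empty(0, int)
    )
    for j in assignments:
        local = np.clip(abs(rng.normal(0.0, spec.false_min_spread)) + 0.2, 0.2, 2.5)
        coords_list.append(_perturb_to_rmsd(centers[j], local, rng))
        origins.append(f"well{j}")
    for _ in range(n_bg):
        t = rng.uniform(spec.dist_thresh + 1.0, 12.0)
        coords_list.append(_perturb_to_rmsd(native, t, rng))
        origins.append("background")

    coords = np.stack(coords_list)
    r = _rmsd_one_to_many(native, coords)

    if n_near > 0:
        realized = float(r.min())
        tol = 0.05 * spec.min_dist + 0.02
        retries = 0
        while abs(realized - spec.min_dist) > tol and retries < 5:
            coords[0] = _perturb_to_rmsd(native, spec.min_dist, rng, iters=8)
            r[0] = least_rmsd(native, coords[0])
            realized = float(r.min())
            retries += 1
        if abs(realized - spec.min_dist) > tol:
            raise RuntimeError(
                f"could not realize min_dist={spec.min_dist} "
                f"(got {realized:.3f}) after bounded retries"
            )

    # energy surface: funnel + deceptive Gaussian wells + observation noise
    energy = spec.funnel_strength * r
    for c, rc in zip(centers, center_rmsds):
        d = _rmsd_one_to_many(c, coords)
        depth = spec.deception * spec.funnel_strength * rc
        energy -= depth * np.exp(-(d**2) / (2.0 * spec.well_width**2))
    if spec.energy_noise_sd > 0:
        energy += rng.normal(0.0, spec.energy_noise_sd, size=n)

    # pseudo-potentials: noisy linear encodings of true RMSD plus pure-noise
    # columns. The linear maps come from their own fixed seed: real
    # knowledge-based potentials are the same functions for every target, so
    # ensembles sharing a potential_seed share the feature semantics and
    # regressors trained on one ensemble transfer to another.
    prng = np.random.default_rng(spec.potential_seed)
    n_pot = spec.n_pseudo_potentials
    n_noise = min(spec.n_noise_potentials, n_pot)
    pots = np.empty((n, n_pot))
    for k in range(n_pot - n_noise):
        a = prng.uniform(0.5, 2.0) * prng.choice([-1.0, 1.0])
        b = prng.normal(0.0, 5.0)
        pots[:, k] = a * (r + rng.normal(0.0, spec.feature_noise_sd, size=n)) + b
    for k in range(n_pot - n_noise, n_pot):
        pots[:, k] = rng.normal(0.0, 1.0, size=n)

    width = len(str(n - 1))
    decoys = [
        Decoy(
            id=f"d{i:0{width}d}",
            coords=coords[i],
            energy=float(energy[i]),
            potentials=pots[i],
            true_rmsd=float(r[i]),
        )
        for i in range(n)
    ]
    ensemble = DecoyEnsemble(
        target_id=f"sim-{spec.seed}", decoys=decoys, native=native
    )
    # ground-truth provenance of each decoy (near / wellK / background),
    # exported by the simulate CLI as the truth table
    ensemble.planted_origin = dict(zip([d.id for d in decoys], origins))
    return ensemble


# ---------------------------------------------------------------------------
# abstract (non-molecular) landscapes
# ---------------------------------------------------------------------------


@dataclass
class AbstractLandscape:
    """Planted-well point cloud: coordinates, energies, and ground-truth labels."""

    points: np.ndarray
    energies: np.ndarray
    labels: np.ndarray
    ids: list[str] = field(default=None)  # type: ignore[assignment]
    centers: np.ndarray = None  # type: ignore[assignment]
    depths: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ids is None:
            width = len(str(len(self.points) - 1))
            self.ids = [f"p{i:0{width}d}" for i in range(len(self.points))]

    def distance_store(self) -> DistanceStore:
        return DistanceStore(self.ids, squareform(pdist(self.points)))

    def energy_map(self) -> dict[str, float]:
        return dict(zip(self.ids, map(float, self.energies)))


def simulate_abstract(
    n_points: int = 400,
    m_wells: int = 5,
    dim: int = 2,
    seed: int = 0,
    spread: float = 1.0,
    center_radius: float = 12.0,
    slope: float = 2.0,
    depths: Sequence[float] | None = None,
    noise_sd: float = 0.05,
    bridge: bool = False,
    bridge_points: int = 9,
) -> AbstractLandscape:
    """Planted-well landscape in low-dimensional Euclidean space.

    ``m_wells`` centers sit on a circle of ``center_radius``; each point is a
    Gaussian displacement (sd ``spread``) of its well center, with energy
    increasing radially at ``slope`` from a per-well base level (``depths``,
    lower = deeper; zeros by default). With ``bridge=True`` a ridge of
    high-energy points joins consecutive centers so wells share one graph
    component; the ridge tops sit above every well point, making the ridge
    the landscape's global maximum.
    """
    rng = np.random.default_rng(seed)
    if m_wells < 1:
        raise ValueError("need at least one well")
    angles = 2.0 * np.pi * np.arange(m_wells) / max(m_wells, 2)
    centers = np.zeros((m_wells, dim))
    centers[:, 0] = center_radius * np.cos(angles)
    if dim > 1:
        centers[:, 1] = center_radius * np.sin(angles)
    if m_wells == 1:
        centers[:] = 0.0
    base = np.zeros(m_wells) if depths is None else np.asarray(depths, float)
    if len(base) != m_wells:
        raise ValueError("depths must have one entry per well")

    labels = rng.integers(0, m_wells, size=n_points)
    points = centers[labels] + rng.normal(0.0, spread, size=(n_points, dim))
    radial = np.linalg.norm(points - centers[labels], axis=1)
    energies = base[labels] + slope * radial
    if noise_sd > 0:
        energies += rng.normal(0.0, noise_sd, size=n_points)

    if bridge and m_wells > 1:
        ridge_top = energies.max() + slope * 2.0
        bp, bl, be = [], [], []
        for j in range(m_wells - 1):
            a, b = centers[j], centers[j + 1]
            for t in np.linspace(0.0, 1.0, bridge_points + 2)[1:-1]:
                bp.append(a + t * (b - a))
                bl.append(-1)
                # parabolic ridge peaking mid-bridge, everywhere above the wells
                be.append(ridge_top - slope * abs(t - 0.5) * 2.0)
        points = np.vstack([points, np.asarray(bp)])
        labels = np.concatenate([labels, np.asarray(bl)])
        energies = np.concatenate([energies, np.asarray(be)])

    return AbstractLandscape(
        points=points,
        energies=energies,
        labels=labels,
        centers=centers,
        depths=base,
    )
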