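"""Synthetic 3D culture generator with full ground truth.

Emulates the generative structure behind serial-section EM surveys of
cultured endothelial cells: pancake-shaped adherent cells bearing rare
lateral-wall protrusion sites, plus free multi-compartmented microvesicles
(MCMVs) resting near the coverslip that contain MVB-like spheres, which in
turn contain ILV-like spheres; omega figures are point marks on the MCMV
limiting membrane.  Every generated object carries an id so downstream
observations can be scored against ground truth.

Statistical model (stated assumptions, since surveys report only means):

* per-cell protrusion-site counts ~ Poisson(λ), sites uniform over the
  total surface with face/lateral allocation proportional to area;
* per-MCMV MVB counts ~ Poisson(μ_N) (or exactly μ_N, see
  ``mvb_count_model``), placed by rejection sampling without overlap;
* each MVB holds ≥1 ILV with probability ``ilv_occupancy``; occupied MVBs
  get ``1 + Poisson(ilv_extra_mean)`` ILVs;
* per-MCMV omega counts ~ Poisson(``omega_rate``), marks uniform over the
  limiting membrane (z therefore uniform over the sphere's z-extent);
* diameters are lognormal about the stated means with a fixed CV, or exact
  when ``fixed_sizes`` is set (for exact-arithmetic oracles).

A single integer master seed drives independent, deterministically derived
streams for cells, bodies and omega marks, so identical (params, seed)
yields byte-identical scenes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .errors import InvalidGeometryError, InvalidInputError, PackingError
from .geometry import BodyKind, PancakeCell, SphereBody

#: Poisson rate of omega figures per MCMV calibrated so that the fraction of
#: MCMVs bearing at least one omega figure is 43%: 1 - exp(-rate) = 0.43.
OMEGA_RATE_43PCT = -math.log(1.0 - 0.43)

_COUNT_MODELS = ("poisson", "fixed")


@dataclass
class CultureParams:
    """Parameters of the synthetic culture.

    Lengths are μm.  Defaults are the literature model values: 24 × 4 μm
    cells, 0.75 protrusion sites per cell with a 2 μm vertical extent,
    1.08 μm MCMVs holding on average one 367 nm MVB, 65% ILV occupancy,
    50–100 nm ILVs, and an omega rate giving 43% of MCMVs ≥1 omega figure.
    """

    n_cells: int = 100
    cell_diameter_mean: float = 24.0
    cell_height_mean: float = 4.0
    site_rate: float = 0.75
    site_z_extent: float = 2.0
    n_mcmv: int = 100
    mcmv_diameter_mean: float = 1.08
    mcmv_diameter_cv: float = 0.2
    mvb_per_mcmv_mean: float = 1.0
    mvb_diameter_mean: float = 0.367
    mvb_diameter_cv: float = 0.2
    mvb_count_model: str = "poisson"
    ilv_occupancy: float = 0.65
    ilv_extra_mean: float = 2.0
    ilv_diameter_range: Tuple[float, float] = (0.05, 0.10)
    omega_rate: float = OMEGA_RATE_43PCT
    fixed_sizes: bool = False
    #: MCMV bottoms are lifted by U(0, bottom_jitter) μm above the coverslip,
    #: emulating the random phase between each structure and the first cut
    #: (block faces are never perfectly flat).  The default, ten section
    #: thicknesses, makes the section phase of each body uniform.
    bottom_jitter: float = 0.7
    #: Side of the square field the scene occupies (μm); auto-scaled with
    #: object counts when None.  Lateral positions do not affect en-face
    #: sectioning statistics.
    field_um: Optional[float] = None
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_cells < 0 or self.n_mcmv < 0:
            raise InvalidInputError("object counts must be >= 0")
        for name in ("site_rate", "mvb_per_mcmv_mean", "omega_rate",
                     "ilv_extra_mean"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if not 0.0 <= self.ilv_occupancy <= 1.0:
            raise InvalidInputError("ilv_occupancy must be in [0, 1]")
        for name in ("cell_diameter_mean", "cell_height_mean", "site_z_extent",
                     "mcmv_diameter_mean", "mvb_diameter_mean"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")
        lo, hi = self.ilv_diameter_range
        if not (0 < lo <= hi):
            raise InvalidInputError("ilv_diameter_range must satisfy 0 < lo <= hi")
        if not (self.mcmv_diameter_mean > self.mvb_diameter_mean > hi / 2 or
                self.mcmv_diameter_mean > self.mvb_diameter_mean):
            raise InvalidInputError(
                "nested diameter means must decrease: MCMV > MVB")
        if self.mvb_diameter_mean <= lo:
            raise InvalidInputError("MVB mean diameter must exceed ILV diameters")
        if self.mvb_count_model not in _COUNT_MODELS:
            raise InvalidInputError(
                f"mvb_count_model must be one of {_COUNT_MODELS}")


@dataclass(frozen=True)
class ProtrusionSite:
    """A protrusion-site band on one cell.

    Lateral-wall sites occupy the z-interval ``[z_center - z_extent/2,
    z_center + z_extent/2]`` and are the only sites detectable in en-face
    sections; sites landing on the top/bottom faces are retained in the
    ground truth but flagged ``on_lateral=False``.
    """

    cell_index: int
    z_center: float
    z_extent: float
    azimuth: float
    on_lateral: bool

    @property
    def z_interval(self) -> Tuple[float, float]:
        return (self.z_center - self.z_extent / 2.0,
                self.z_center + self.z_extent / 2.0)


@dataclass(frozen=True)
class CellInstance:
    """One cell of the culture with its protrusion sites."""

    index: int
    cell: PancakeCell
    center_xy: Tuple[float, float]
    sites: Tuple[ProtrusionSite, ...]


@dataclass
class Scene:
    """Ground-truthed 3D culture: cells + sites, nested bodies, omega marks."""

    params: CultureParams
    cells: List[CellInstance]
    bodies: List[SphereBody]
    omega_marks: Dict[int, Tuple[float, ...]]  # MCMV body_id -> z positions
    seed_used: int

    # -- convenience accessors -------------------------------------------------

    def bodies_of_kind(self, kind: BodyKind) -> List[SphereBody]:
        return [b for b in self.bodies if b.kind == kind]

    def children_of(self, body_id: int) -> List[SphereBody]:
        return [b for b in self.bodies
                if b.parent is not None and b.parent.body_id == body_id]

    @property
    def z_max(self) -> float:
        tops = [c.cell.height for c in self.cells]
        tops += [b.z_top for b in self.bodies]
        return max(tops, default=0.0)

    # -- invariants ------------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise if containment, non-overlap or coverslip rules are violated."""
        by_parent: Dict[int, List[SphereBody]] = {}
        for b in self.bodies:
            if b.kind == BodyKind.MCMV and b.z < b.radius - 1e-12:
                raise InvalidGeometryError(
                    f"MCMV {b.body_id} intersects the coverslip plane")
            if b.parent is not None:
                gap = (b.parent.diameter - b.diameter) / 2.0
                if math.dist(b.center, b.parent.center) > gap + 1e-9:
                    raise InvalidGeometryError(
                        f"body {b.body_id} escapes parent {b.parent.body_id}")
                by_parent.setdefault(b.parent.body_id, []).append(b)
        for pid, sibs in by_parent.items():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    a, b2 = sibs[i], sibs[j]
                    if (math.dist(a.center, b2.center)
                            < (a.radius + b2.radius) - 1e-9):
                        raise InvalidGeometryError(
                            f"siblings {a.body_id}/{b2.body_id} overlap in {pid}")

    # -- serialization ---------------------------------------------------------

    def to_json_dict(self) -> dict:
        params = asdict(self.params)
        params["ilv_diameter_range"] = list(self.params.ilv_diameter_range)
        return {
            "format": "evstereo-scene",
            "version": 1,
            "length_unit": "um",
            "seed_used": self.seed_used,
            "params": params,
            "cells": [
                {
                    "index": c.index,
                    "diameter": c.cell.diameter,
                    "height": c.cell.height,
                    "center_xy": list(c.center_xy),
                    "sites": [
                        {
                            "z_center": s.z_center,
                            "z_extent": s.z_extent,
                            "azimuth": s.azimuth,
                            "on_lateral": s.on_lateral,
                        }
                        for s in c.sites
                    ],
                }
                for c in self.cells
            ],
            "bodies": [
                {
                    "body_id": b.body_id,
                    "kind": b.kind.value,
                    "center": list(b.center),
                    "diameter": b.diameter,
                    "parent_id": None if b.parent is None else b.parent.body_id,
                }
                for b in self.bodies
            ],
            "omega_marks": {str(k): list(v) for k, v in self.omega_marks.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json_dict(cls, d: dict) -> "Scene":
        pd = dict(d["params"])
        pd["ilv_diameter_range"] = tuple(pd["ilv_diameter_range"])
        params = CultureParams(**pd)
        cells = []
        for c in d["cells"]:
            cell = PancakeCell(c["diameter"], c["height"])
            sites = tuple(
                ProtrusionSite(c["index"], s["z_center"], s["z_extent"],
                               s["azimuth"], s["on_lateral"])
                for s in c["sites"]
            )
            cells.append(CellInstance(c["index"], cell,
                                      tuple(c["center_xy"]), sites))
        by_id: Dict[int, SphereBody] = {}
        bodies: List[SphereBody] = []
        for rec in d["bodies"]:
            parent = None if rec["parent_id"] is None else by_id[rec["parent_id"]]
            b = SphereBody(tuple(rec["center"]), rec["diameter"],
                           BodyKind(rec["kind"]), parent, rec["body_id"])
            by_id[b.body_id] = b
            bodies.append(b)
        omega = {int(k): tuple(v) for k, v in d["omega_marks"].items()}
        return cls(params, cells, bodies, omega, d["seed_used"])

    @classmethod
    def load(cls, path) -> "Scene":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# generation helpers
# ---------------------------------------------------------------------------

class _LognormalSize:
    """Lognormal diameter law parameterised by arithmetic mean and CV."""

    def __init__(self, mean: float, cv: float):
        self.mean = mean
        self.cv = cv
        if cv > 0:
            self.sigma2 = math.log(1.0 + cv * cv)
            self.mu = math.log(mean) - self.sigma2 / 2.0
            # crowding may shrink a child, but never below the -4σ quantile:
            # arbitrarily small bodies are not part of the modelled population
            self.floor = math.exp(self.mu - 4.0 * math.sqrt(self.sigma2))
        else:
            self.floor = mean

    def draw(self, rng: np.random.Generator) -> float:
        if self.cv <= 0:
            return self.mean
        return float(rng.lognormal(self.mu, math.sqrt(self.sigma2)))

    def draw_truncated(self, rng: np.random.Generator,
                       d_max: float) -> Optional[float]:
        """Inverse-CDF draw conditioned on diameter <= d_max."""
        if d_max < self.floor:
            return None
        if self.cv <= 0:
            return self.mean if self.mean <= d_max else None
        sigma = math.sqrt(self.sigma2)
        upper = norm.cdf((math.log(d_max) - self.mu) / sigma)
        if upper <= 0:
            return None
        u = rng.random() * upper
        if u <= 0:
            return None
        return float(math.exp(self.mu + sigma * norm.ppf(u)))


class _UniformSize:
    """Uniform diameter law over [lo, hi]."""

    def __init__(self, lo: float, hi: float):
        self.lo, self.hi = lo, hi
        self.floor = lo

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    def draw_truncated(self, rng: np.random.Generator,
                       d_max: float) -> Optional[float]:
        if d_max <= self.lo:
            return None
        return float(rng.uniform(self.lo, min(self.hi, d_max)))


def _uniform_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    if norm == 0.0:  # pragma: no cover - probability zero
        v, norm = np.array([1.0, 0.0, 0.0]), 1.0
    r = radius * rng.random() ** (1.0 / 3.0)
    return v / norm * r


_MAX_ATTEMPTS = 1000  # rejection attempts per body
_MAX_RESTARTS = 10    # whole-brood restarts before giving up


def _place_children(
    rng: np.random.Generator,
    parent: SphereBody,
    n: int,
    size_law,
    fixed_sizes: bool,
    kind: BodyKind,
    next_id: int,
) -> List[SphereBody]:
    """Place ``n`` non-overlapping spheres inside ``parent``.

    Primary path is rejection sampling: each attempt redraws position (and
    diameter, in random-size mode).  When a child exhausts its attempt cap
    in random-size mode, a conditional fallback draws a candidate position
    and then the diameter from ``size_law`` truncated to the clearance
    available there — crowded containers thereby hold smaller children, the
    correlation real vesicles show.  Fixed sizes cannot shrink, so
    exhaustion there (or a fallback that finds no clearance) restarts the
    whole brood and ultimately raises :class:`PackingError` naming the
    parent: infeasible packings fail loudly instead of looping forever.
    """
    for restart in range(_MAX_RESTARTS):
        # later restarts cap all diameters ever more tightly, driving a
        # crowded brood toward the size-law floor before giving up
        d_cap = parent.diameter * (0.9 ** restart)
        placed: List[SphereBody] = []
        ok = True
        for i in range(n):
            child = None
            for _ in range(_MAX_ATTEMPTS):
                if fixed_sizes:
                    d = size_law.mean
                elif restart == 0:
                    d = size_law.draw(rng)
                else:
                    d = size_law.draw_truncated(rng, d_cap)
                    if d is None:
                        break
                if d >= parent.diameter:
                    continue
                max_off = (parent.diameter - d) / 2.0
                off = _uniform_in_ball(rng, max_off)
                center = (parent.center[0] + off[0],
                          parent.center[1] + off[1],
                          parent.center[2] + off[2])
                if any(math.dist(center, s.center) < (d + s.diameter) / 2.0
                       for s in placed):
                    continue
                child = SphereBody(center, d, kind, parent,
                                   next_id + len(placed))
                break
            if child is None and not fixed_sizes:
                child = _conditional_place(rng, parent, placed, size_law,
                                           kind, next_id + len(placed))
            if child is None:
                ok = False
                break
            placed.append(child)
        if ok:
            return placed
    raise PackingError(
        f"could not pack {n} {kind.value} bodies "
        f"inside {parent.kind.value} {parent.body_id} "
        f"(d={parent.diameter:.4g}) after {_MAX_RESTARTS} restarts"
    )


def _conditional_place(
    rng: np.random.Generator,
    parent: SphereBody,
    placed: List[SphereBody],
    size_law,
    kind: BodyKind,
    body_id: int,
) -> Optional[SphereBody]:
    """Fallback placement: best-clearance pocket, diameter truncated to fit.

    Scans candidate positions, keeps the one with the largest clearance to
    the parent wall and every sibling, then draws the diameter from
    ``size_law`` truncated to that pocket.
    """
    best_center, best_clear = None, 0.0
    for _ in range(200):
        x = _uniform_in_ball(rng, parent.radius)
        center = (parent.center[0] + x[0], parent.center[1] + x[1],
                  parent.center[2] + x[2])
        clearance = parent.radius - float(np.linalg.norm(x))
        for s in placed:
            clearance = min(clearance, math.dist(center, s.center) - s.radius)
        if clearance > best_clear:
            best_center, best_clear = center, clearance
    if best_center is None or 2.0 * best_clear < size_law.floor:
        return None
    d = size_law.draw_truncated(rng, 2.0 * best_clear)
    if d is None or d <= 0:
        return None
    return SphereBody(best_center, d, kind, parent, body_id)


def generate_scene(params: CultureParams, seed: Optional[int] = None) -> Scene:
    """Generate a ground-truthed culture from ``params``.

    ``seed`` overrides ``params.seed``; one of the two must be given for a
    reproducible scene (defaults to 0 otherwise).  Identical (params, seed)
    produce byte-identical scenes.
    """
    params.validate()
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    ss = np.random.SeedSequence(seed)
    cells_rng, bodies_rng, omega_rng = (np.random.default_rng(s)
                                        for s in ss.spawn(3))

    # --- cells and protrusion sites ---
    cell_proto = PancakeCell(params.cell_diameter_mean, params.cell_height_mean)
    h = params.cell_height_mean
    extent = params.site_z_extent
    p_lateral = (cell_proto.lateral_area
                 / (2.0 * cell_proto.face_area + cell_proto.lateral_area))
    n_side = max(1, math.ceil(math.sqrt(max(params.n_cells, 1))))
    pitch = 2.0 * params.cell_diameter_mean
    cells: List[CellInstance] = []
    site_counts = cells_rng.poisson(params.site_rate, size=params.n_cells)
    for i in range(params.n_cells):
        xy = ((i % n_side + 0.5) * pitch, (i // n_side + 0.5) * pitch)
        sites = []
        for _ in range(int(site_counts[i])):
            azimuth = float(cells_rng.uniform(0.0, 2.0 * math.pi))
            if cells_rng.random() < p_lateral:
                # Lateral-wall band, kept wholly on the wall: a site of
                # extent e has its centre uniform over [e/2, H - e/2], so a
                # uniformly positioned section samples it with probability
                # exactly e/H and the detection probability of one site is
                # the band fraction p = A_band / A_total.
                e = min(extent, h)
                zc = (h / 2.0 if e >= h
                      else float(cells_rng.uniform(e / 2.0, h - e / 2.0)))
                sites.append(ProtrusionSite(i, zc, e, azimuth, True))
            else:
                z_face = 0.0 if cells_rng.random() < 0.5 else h
                sites.append(ProtrusionSite(i, z_face, extent, azimuth, False))
        cells.append(CellInstance(i, cell_proto, xy, tuple(sites)))

    # --- free MCMVs with nested MVBs and ILVs ---
    field = params.field_um
    if field is None:
        field = max(100.0,
                    3.0 * params.mcmv_diameter_mean
                    * math.sqrt(max(params.n_mcmv, 1)))
    bodies: List[SphereBody] = []
    omega_marks: Dict[int, Tuple[float, ...]] = {}
    next_id = 0
    mcmv_law = _LognormalSize(params.mcmv_diameter_mean,
                              params.mcmv_diameter_cv)
    mvb_law = _LognormalSize(params.mvb_diameter_mean, params.mvb_diameter_cv)
    ilv_law = _UniformSize(*params.ilv_diameter_range)
    for _ in range(params.n_mcmv):
        d = (params.mcmv_diameter_mean if params.fixed_sizes
             else mcmv_law.draw(bodies_rng))
        lift = float(bodies_rng.uniform(0.0, params.bottom_jitter))
        center = (float(bodies_rng.uniform(0.0, field)),
                  float(bodies_rng.uniform(0.0, field)),
                  d / 2.0 + lift)
        mcmv = SphereBody(center, d, BodyKind.MCMV, None, next_id)
        next_id += 1
        bodies.append(mcmv)

        if params.mvb_count_model == "fixed":
            n_mvb = int(round(params.mvb_per_mcmv_mean))
        else:
            n_mvb = int(bodies_rng.poisson(params.mvb_per_mcmv_mean))
        mvbs = _place_children(bodies_rng, mcmv, n_mvb, mvb_law,
                               params.fixed_sizes, BodyKind.MVB, next_id)
        next_id += len(mvbs)
        bodies.extend(mvbs)

        for mvb in mvbs:
            if bodies_rng.random() >= params.ilv_occupancy:
                continue
            n_ilv = 1 + int(bodies_rng.poisson(params.ilv_extra_mean))
            # occupancy only promises >= 1 ILV; a crowded MVB holds fewer
            while True:
                try:
                    ilvs = _place_children(bodies_rng, mvb, n_ilv, ilv_law,
                                           False, BodyKind.ILV, next_id)
                    break
                except PackingError:
                    if n_ilv == 1:
                        raise
                    n_ilv -= 1
            next_id += len(ilvs)
            bodies.extend(ilvs)

        n_omega = int(omega_rng.poisson(params.omega_rate))
        if n_omega:
            u = omega_rng.uniform(-1.0, 1.0, size=n_omega)
            zs = tuple(float(mcmv.z + mcmv.radius * ui) for ui in u)
            omega_marks[mcmv.body_id] = zs

    return Scene(params, cells, bodies, omega_marks, seed)


# ---------------------------------------------------------------------------
# grey-level patch rendering
# ---------------------------------------------------------------------------

def render_patch(
    inner_mean: float,
    outer_mean: float,
    noise_sd: float,
    profile_diameter_nm: float,
    nm_per_px: float,
    seed: int,
    patch_px: Optional[int] = None,
):
    """Render a synthetic vesicle-profile patch with ground-truth masks.

    A disk of the stated diameter is drawn at the patch centre; pixels
    inside sample Normal(``inner_mean``, ``noise_sd``), pixels outside
    Normal(``outer_mean``, ``noise_sd``), clipped to [0, 255] and quantised
    to 8 bits.  Masks exclude a one-pixel boundary band on either side of
    the membrane, as an annotator drawing a region of interest would.
    Higher grey value = lighter (electron-lucent) by package convention.

    Returns a :class:`~evstereo.classifier.PatchROI`.
    """
    from .classifier import PatchROI  # local import: avoid a module cycle

    for name, v in (("inner_mean", inner_mean), ("outer_mean", outer_mean)):
        if not 0.0 <= v <= 255.0:
            raise InvalidInputError(f"{name} must be in [0, 255], got {v}")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if nm_per_px <= 0 or profile_diameter_nm <= 0:
        raise InvalidInputError("calibration and diameter must be positive")

    r_px = (profile_diameter_nm / 2.0) / nm_per_px
    side = patch_px if patch_px is not None else max(48, int(math.ceil(4 * r_px)))
    if 2 * r_px + 4 > side:
        raise InvalidGeometryError(
            f"disk of {profile_diameter_nm} nm ({2 * r_px:.1f} px) does not "
            f"fit a {side}-px patch at {nm_per_px} nm/px")

    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    dist = np.hypot(xx - c, yy - c)
    disk = dist <= r_px
    inside_mask = dist <= r_px - 1.0
    outside_mask = dist >= r_px + 1.0

    rng = np.random.default_rng(seed)
    means = np.where(disk, inner_mean, outer_mean).astype(float)
    pixels = rng.normal(means, noise_sd) if noise_sd > 0 else means.copy()
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return PatchROI(pixels=pixels, inside_mask=inside_mask,
                    outside_mask=outside_mask, nm_per_px=nm_per_px)
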