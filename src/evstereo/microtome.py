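"""Virtual sectioning of a synthetic culture into per-slab observations.

Converts a :class:`~evstereo.scene.Scene` into exactly what a microscopist
scoring 70-nm en-face serial sections would record: per cell, whether at
least one protrusion-site profile is visible in the slab; per body, the
profile diameter if it exceeds the detection floor; per MCMV profile, the
number of omega figures falling in the slab; per MVB profile, whether an
ILV profile is co-sighted in the same slab.

Two survey modes mirror the two kinds of counting done on real sections:

``serial``
    contiguous slabs from z = 0 until the tallest object is exhausted —
    the serial-section reconstruction workflow;
``single_random_per_cell``
    one slab per cell at uniform z within the cell height — the
    single-section frequency survey used for the per-cell site rate.

A lateral-wall site is sighted iff its z-interval intersects the slab;
face sites are never visible en face.  The default minimum detectable
profile diameter is 20 nm: caps thinner than the membrane scale are
invisible in real sections, and this floor is the main bias knob for the
profile-count correction's small-cap losses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InconsistencyError, InvalidInputError
from .geometry import (BodyKind, SectionSlab, SphereBody, nm_to_um,
                       sphere_slab_profile, um_to_nm)
from .scene import Scene

DEFAULT_MIN_PROFILE_NM = 20.0

_MODES = ("serial", "single_random_per_cell")


@dataclass(frozen=True)
class BodyProfile:
    """One body's cross-section in one slab."""

    body_id: int
    kind: BodyKind
    parent_id: Optional[int]
    profile_nm: float
    contains_ilv_profile: bool
    #: True when the body is visible but its parent's cap is below the
    #: detection floor in this slab (an MVB that would look "free").
    orphan: bool


@dataclass
class SectionObservation:
    """Everything scored in one slab."""

    slab: SectionSlab
    cell_sightings: Dict[int, bool]
    body_profiles: List[BodyProfile]
    omega_counts: Dict[int, int]  # MCMV body_id -> omegas seen in this slab


def _site_visible(z_interval: Tuple[float, float], slab: SectionSlab) -> bool:
    a, b = z_interval
    return a < slab.z_hi and b > slab.z_lo


def section_scene(
    scene: Scene,
    thickness_nm: float = 70.0,
    mode: str = "serial",
    seed: Optional[int] = None,
    min_profile_nm: float = DEFAULT_MIN_PROFILE_NM,
    omega_span_slabs: int = 1,
    fov_um: Optional[float] = None,
) -> List[SectionObservation]:
    """Cut ``scene`` into observations.

    Parameters
    ----------
    thickness_nm : float
        Section thickness (nm); 70 by default.
    mode : {"serial", "single_random_per_cell"}
        Survey mode (see module docstring).  ``single_random_per_cell``
        scores cells only and requires a ``seed``-able random draw.
    seed : int, optional
        Seed for the single-section survey's slab positions.
    min_profile_nm : float
        Detection floor for body profiles.
    omega_span_slabs : int
        Vertical reach of an omega mark in sections (1 by default; 2 lets
        a figure straddle two sections, as fusion profiles can).
    fov_um : float, optional
        When given, restricts scoring to a square field of view
        ``[0, fov_um]²`` and excludes cells whose disk crosses its edge
        (the partial-cell exclusion rule); bodies outside are dropped.

    An empty scene yields an empty list.
    """
    if mode not in _MODES:
        raise InvalidInputError(f"mode must be one of {_MODES}, got {mode!r}")
    if not thickness_nm > 0:
        raise InvalidInputError("thickness_nm must be positive")
    if omega_span_slabs < 1:
        raise InvalidInputError("omega_span_slabs must be >= 1")
    T = nm_to_um(thickness_nm)

    cells = scene.cells
    bodies = scene.bodies
    if fov_um is not None:
        cells = [c for c in cells
                 if (c.cell.radius <= c.center_xy[0] <= fov_um - c.cell.radius
                     and c.cell.radius <= c.center_xy[1] <= fov_um - c.cell.radius)]
        keep_roots = {b.body_id for b in bodies
                      if b.parent is None
                      and 0 <= b.center[0] <= fov_um
                      and 0 <= b.center[1] <= fov_um}
        bodies = [b for b in bodies
                  if (b.body_id in keep_roots if b.parent is None
                      else _root_id(b) in keep_roots)]

    if mode == "single_random_per_cell":
        rng = np.random.default_rng(seed)
        out: List[SectionObservation] = []
        for c in cells:
            z = float(rng.uniform(0.0, c.cell.height))
            slab = SectionSlab(index=int(z // T), thickness=T, z_lo=z)
            seen = any(s.on_lateral and _site_visible(s.z_interval, slab)
                       for s in c.sites)
            out.append(SectionObservation(slab, {c.index: seen}, [], {}))
        return out

    # --- serial mode ---
    z_max = 0.0
    if cells:
        z_max = max(z_max, max(c.cell.height for c in cells))
    if bodies:
        z_max = max(z_max, max(b.z_top for b in bodies))
    for zs in scene.omega_marks.values():
        if zs:
            z_max = max(z_max, max(zs))
    n_slabs = int(math.ceil(z_max / T)) if z_max > 0 else 0

    children: Dict[int, List[SphereBody]] = {}
    for b in bodies:
        if b.parent is not None:
            children.setdefault(b.parent.body_id, []).append(b)

    out = []
    for k in range(n_slabs):
        slab = SectionSlab(index=k, thickness=T)
        sightings = {
            c.index: any(s.on_lateral and _site_visible(s.z_interval, slab)
                         for s in c.sites)
            for c in cells
        }
        visible: Dict[int, float] = {}
        for b in bodies:
            p = sphere_slab_profile(b, slab)
            if p is not None and um_to_nm(p) >= min_profile_nm:
                visible[b.body_id] = um_to_nm(p)
        profiles: List[BodyProfile] = []
        for b in bodies:
            if b.body_id not in visible:
                continue
            has_ilv = any(ch.kind == BodyKind.ILV and ch.body_id in visible
                          for ch in children.get(b.body_id, ()))
            parent_id = None if b.parent is None else b.parent.body_id
            orphan = parent_id is not None and parent_id not in visible
            profiles.append(BodyProfile(b.body_id, b.kind, parent_id,
                                        visible[b.body_id], has_ilv, orphan))
        omega_counts: Dict[int, int] = {}
        reach = omega_span_slabs * T
        for mcmv_id, zs in scene.omega_marks.items():
            if mcmv_id not in visible:
                continue
            n = sum(1 for z in zs if slab.z_lo <= z < slab.z_lo + reach)
            if n:
                omega_counts[mcmv_id] = n
        out.append(SectionObservation(slab, sightings, profiles, omega_counts))
    return out


def _root_id(b: SphereBody) -> int:
    while b.parent is not None:
        b = b.parent
    return b.body_id


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

_COLUMNS = ["slab_index", "z_lo_um", "object_id", "kind", "parent_id",
            "profile_nm", "contains_ilv", "orphan", "n_omega", "sighted"]


class CountsTable:
    """Row-level counts plus the derived survey summaries.

    Wraps a :class:`pandas.DataFrame` with one row per (slab, object):
    body rows carry profile diameters and flags, cell rows carry the
    site-sighting flag.  Summaries are always recomputed from the rows, so
    they can never disagree with them.
    """

    def __init__(self, rows: pd.DataFrame, thickness_nm: float):
        self.rows = rows.reset_index(drop=True)
        self.thickness_nm = float(thickness_nm)

    # -- derived summaries -----------------------------------------------------

    @property
    def f_sites(self) -> float:
        """Fraction of surveyed cells with ≥1 site sighting (NaN if no cells)."""
        cells = self.rows[self.rows["kind"] == "cell"]
        if cells.empty:
            return float("nan")
        return float(cells.groupby("object_id")["sighted"].any().mean())

    @property
    def n_cells(self) -> int:
        cells = self.rows[self.rows["kind"] == "cell"]
        return int(cells["object_id"].nunique())

    @property
    def mean_mvb_profiles_per_mcmv(self) -> float:
        """Mean MVB profiles per MCMV profile, n̄ (NaN if no MCMV profiles).

        Orphan MVB profiles (parent cap below the detection floor) are not
        attributed to an MCMV profile and are excluded from the numerator.
        """
        n_mcmv = int((self.rows["kind"] == BodyKind.MCMV.value).sum())
        if n_mcmv == 0:
            return float("nan")
        mvb = self.rows[(self.rows["kind"] == BodyKind.MVB.value)
                        & (~self.rows["orphan"].astype(bool))]
        return float(len(mvb) / n_mcmv)

    @property
    def omega_fraction(self) -> float:
        """Fraction of MCMV profiles bearing ≥1 omega figure."""
        mcmv = self.rows[self.rows["kind"] == BodyKind.MCMV.value]
        if mcmv.empty:
            return float("nan")
        return float((mcmv["n_omega"] >= 1).mean())

    @property
    def ilv_fraction(self) -> float:
        """Fraction of MVB profiles with an ILV profile co-sighted."""
        mvb = self.rows[self.rows["kind"] == BodyKind.MVB.value]
        if mvb.empty:
            return float("nan")
        return float(mvb["contains_ilv"].astype(bool).mean())

    def per_mcmv_counts(self) -> np.ndarray:
        """Per-MCMV (profile slabs, attributed MVB profiles) pairs.

        Shape (k, 2) array used for bootstrap uncertainty on the
        MVB-per-MCMV correction.
        """
        mcmv = self.rows[self.rows["kind"] == BodyKind.MCMV.value]
        mvb = self.rows[(self.rows["kind"] == BodyKind.MVB.value)
                        & (~self.rows["orphan"].astype(bool))]
        slabs = mcmv.groupby("object_id").size()
        per_parent = mvb.groupby("parent_id").size()
        return np.array([
            [int(slabs[oid]), int(per_parent.get(oid, 0))]
            for oid in slabs.index
        ], dtype=int)

    def summary(self) -> dict:
        return {
            "thickness_nm": self.thickness_nm,
            "n_cells": self.n_cells,
            "f_sites": self.f_sites,
            "mean_mvb_profiles_per_mcmv": self.mean_mvb_profiles_per_mcmv,
            "omega_fraction": self.omega_fraction,
            "ilv_fraction": self.ilv_fraction,
        }

    # -- I/O -------------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def write_summary_json(self, path) -> None:
        clean = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                 for k, v in self.summary().items()}
        with open(path, "w") as fh:
            json.dump(clean, fh, sort_keys=True, indent=1)

    @classmethod
    def from_csv(cls, path, thickness_nm: float) -> "CountsTable":
        rows = pd.read_csv(path)
        missing = set(_COLUMNS) - set(rows.columns)
        if missing:
            raise InconsistencyError(f"counts CSV missing columns {sorted(missing)}")
        return cls(rows, thickness_nm)


def tabulate(observations: List[SectionObservation]) -> CountsTable:
    """Flatten observations from one sectioning run into a counts table.

    Raises :class:`InconsistencyError` when the observations mix section
    thicknesses.  An empty observation list yields an empty table whose
    summary fractions are all NaN.
    """
    thicknesses = {round(obs.slab.thickness, 12) for obs in observations}
    if len(thicknesses) > 1:
        raise InconsistencyError(
            f"observations mix section thicknesses: {sorted(thicknesses)}")
    T_um = thicknesses.pop() if thicknesses else nm_to_um(70.0)
    records = []
    for obs in observations:
        k, z = obs.slab.index, obs.slab.z_lo
        for cell_id, seen in obs.cell_sightings.items():
            records.append((k, z, cell_id, "cell", None, float("nan"),
                            False, False, 0, bool(seen)))
        for p in obs.body_profiles:
            records.append((k, z, p.body_id, p.kind.value, p.parent_id,
                            p.profile_nm, p.contains_ilv_profile, p.orphan,
                            obs.omega_counts.get(p.body_id, 0), False))
    rows = pd.DataFrame(records, columns=_COLUMNS)
    return CountsTable(rows, thickness_nm=um_to_nm(T_um))
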