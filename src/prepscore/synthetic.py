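"""Parametric synthetic tooth preparations with known ground-truth scores.

The study conditions this package targets are Class II (occlusal + mesial)
cavity preparations on a lower first molar, scanned as surface meshes and
marked on a 20-point rubric.  Since real scans are not available, this
module builds molar-like closed surfaces by radial displacement of a
subdivided icosphere — cusps as smooth bumps, cavities as smooth
depressions, residual caries as floor roughness, an undermined margin as a
flared rim, pulp exposure as a deep narrow pit — plus adjacent teeth as
separate displaced spheres, with iatrogenic damage as a depression on the
neighbour facing the preparation.  Every geometric feature is driven by an
explicit parameter, and a deterministic scoring map turns those parameters
into the ground-truth score sheet, so a regenerated case recovers its
labels exactly.

The geometry→score cutoffs (clearance bands at 0.25/0.5 mm, isthmus bands
at 0.5/1.0 mm, linear damage bands) are this package's own clinically
plausible conventions: the rubric states point values, not the metric
criteria examiners applied.  They are module constants, not magic numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from .geometry import TriangleMesh
from .rubric import CRITERION_KEYS, ScoreSheet, total_score, write_label_json

__all__ = [
    "OcclusalCavity",
    "MesialBox",
    "PrepParams",
    "SyntheticCase",
    "CohortRanges",
    "SelfIntersectionError",
    "generate_mesh",
    "base_tooth_mesh",
    "scoring_map",
    "generate_cohort",
    "write_obj",
    "mesh_features",
    "prep_component",
    "enclosed_volume",
]


class SelfIntersectionError(ValueError):
    """Requested cavities would punch through the tooth body."""


# --- geometry -> score conventions (mm unless noted) -----------------------
CLEARANCE_FULL_MM = 0.5     # gap >= this: full 2 points per direction
CLEARANCE_PARTIAL_MM = 0.25  # gap >= this: 1 point
ISTHMUS_FULL_MM = 1.0
ISTHMUS_PARTIAL_MM = 0.5
DAMAGE_MINOR_SLOPE = 2.0    # points lost per mm below 1 mm
CUSP_POLAR_RAD = 0.65       # polar angle of the four cusp directions
CUSP_CLEAR_MARGIN_RAD = 0.15  # cavity rim must stay this far from the cusps
# displacement-field amplitudes
CARIES_BUMP_MM = 0.8        # residual-caries roughness at fraction 1.0
UNDERMINE_RIDGE_MM = 0.35   # rim flare at extent 1.0
PULP_PIT_MM = 1.2
ADJACENT_RADIUS_FACTOR = 0.85
ADJACENT_CONTACT_GAP_MM = 0.35
EDGE_SOFTNESS_RAD = 0.08


@dataclass(frozen=True)
class OcclusalCavity:
    center: tuple[float, float] = (0.0, 0.0)  # tangential offset of the axis
    radius: float = 1.8  # mm footprint radius
    depth: float = 1.8   # mm


@dataclass(frozen=True)
class MesialBox:
    width: float = 2.5           # mm, base lateral extent
    depth: float = 2.2           # mm recession
    gingival_margin: float = 2.0  # mm extension below the equator


@dataclass(frozen=True)
class PrepParams:
    """Everything that defines one synthetic preparation."""

    seed: int = 0
    base_radius: float = 5.0
    cusp_amplitude: float = 0.6
    occlusal_cavity: OcclusalCavity = OcclusalCavity()
    mesial_box: MesialBox = MesialBox()
    clearance_buccal: float = 0.6
    clearance_lingual: float = 0.6
    clearance_gingival: float = 0.6
    residual_caries_fraction: float = 0.0
    isthmus_thickness: float = 1.2
    undermined_extent: float = 0.0
    adjacent_damage_depth: float = 0.0
    pulp_exposure: bool = False
    include_adjacent_teeth: bool = True
    mesh_resolution: int = 4
    jitter_sigma: float = 0.0

    def validate(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        for name in ("clearance_buccal", "clearance_lingual", "clearance_gingival"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("residual_caries_fraction", "undermined_extent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.adjacent_damage_depth <= 2.0:
            raise ValueError("adjacent_damage_depth must lie in [0, 2] mm")
        if self.occlusal_cavity.radius < 0 or self.occlusal_cavity.depth < 0:
            raise ValueError("occlusal cavity radius/depth must be >= 0")
        if self.mesial_box.width < 0 or self.mesial_box.depth < 0:
            raise ValueError("mesial box width/depth must be >= 0")
        if self.isthmus_thickness <= 0:
            raise ValueError("isthmus_thickness must be positive")
        total_depth = self.occlusal_cavity.depth + (PULP_PIT_MM if self.pulp_exposure else 0.0)
        if total_depth >= self.base_radius or self.mesial_box.depth >= self.base_radius:
            raise SelfIntersectionError(
                "cavity depth reaches or exceeds the tooth radius; "
                "the surface would self-intersect"
            )


@dataclass
class SyntheticCase:
    case_id: str
    params: PrepParams
    mesh: TriangleMesh
    sheet: ScoreSheet
    split: str = ""


# ---------------------------------------------------------------------------
# Displacement-field mesh construction


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(t))


def _cusp_directions() -> np.ndarray:
    az = np.deg2rad([45.0, 135.0, 225.0, 315.0])
    s, c = np.sin(CUSP_POLAR_RAD), np.cos(CUSP_POLAR_RAD)
    return np.stack([s * np.cos(az), s * np.sin(az), np.full(4, c)], axis=1)


def _angles_to(dirs: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return np.arccos(np.clip(dirs @ axis, -1.0, 1.0))


def _prep_radii(params: PrepParams, dirs: np.ndarray) -> np.ndarray:
    """Radial displacement field of the prepared tooth, evaluated at unit
    directions ``dirs``.  Pure function of params."""
    p = params
    R = p.base_radius
    r = np.full(len(dirs), R)

    # cusps: four smooth bumps on the occlusal table
    for d in _cusp_directions():
        r += p.cusp_amplitude * np.exp(-((_angles_to(dirs, d) / 0.30) ** 2))

    occ = p.occlusal_cavity
    cx, cy = occ.center
    d_occ = np.array([cx, cy, 1.0])
    d_occ /= np.linalg.norm(d_occ)
    th_occ = _angles_to(dirs, d_occ)
    phi_occ = occ.radius / R  # angular footprint radius
    occ_presence = occ.depth / (occ.depth + 0.3) if occ.depth > 0 else 0.0
    if occ.depth > 0 and phi_occ > 0:
        # quartic profile: flat-ish floor, soft walls
        r -= occ.depth * np.exp(-((th_occ / phi_occ) ** 4))

    # mesial box: +y is mesial; buccal is -x, lingual is +x, gingival is -z.
    box = p.mesial_box
    mes_presence = box.depth / (box.depth + 0.3) if box.depth > 0 else 0.0
    if box.depth > 0 and box.width > 0:
        ux, uy, uz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        alpha = np.arctan2(ux, np.maximum(uy, 1e-9))   # lateral angle
        beta = np.arctan2(uz, np.maximum(uy, 1e-9))    # vertical angle
        half_b = (box.width / 2 + p.clearance_buccal) / R
        half_l = (box.width / 2 + p.clearance_lingual) / R
        beta_top = 0.55
        beta_bot = -(box.gingival_margin + p.clearance_gingival) / R
        w = EDGE_SOFTNESS_RAD
        gx = _smoothstep((alpha + half_b) / w) * _smoothstep((half_l - alpha) / w)
        gz = _smoothstep((beta - beta_bot) / w) * _smoothstep((beta_top - beta) / w)
        gy = _smoothstep((uy - 0.25) / 0.08)
        r -= box.depth * gx * gz * gy

    # isthmus erosion between the two cavities (thin ridge -> eroded ridge)
    erosion = max(0.0, 1.2 - p.isthmus_thickness) * 0.8
    if erosion > 0:
        d_isth = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
        r -= erosion * np.exp(-((_angles_to(dirs, d_isth) / 0.25) ** 2))

    # residual caries: the cavity was not cut to full depth — the floor is
    # raised back by a fraction of the cavity depth over a lobe of the
    # footprint, with small bumps for carious texture on top
    if p.residual_caries_fraction > 0:
        frac = p.residual_caries_fraction
        if occ.depth > 0 and phi_occ > 0:
            lobe_c = d_occ + np.array([0.25 * phi_occ, 0.15 * phi_occ, 0.0])
            lobe_c /= np.linalg.norm(lobe_c)
            lobe = np.exp(-((_angles_to(dirs, lobe_c) / (0.8 * phi_occ)) ** 2))
            refill = frac * occ.depth * lobe * np.exp(-((th_occ / phi_occ) ** 4))
            r += np.minimum(refill, occ.depth)
        if box.depth > 0:
            mes_spot = np.array([0.1, 1.0, -0.2])
            mes_spot /= np.linalg.norm(mes_spot)
            r += (frac * box.depth * mes_presence
                  * np.exp(-((_angles_to(dirs, mes_spot) / 0.22) ** 2)))
        bump_amp = frac * CARIES_BUMP_MM
        for dx, dy in ((0.12, 0.0), (-0.08, 0.1)):
            s = d_occ + np.array([dx, dy, 0.0])
            s = s / np.linalg.norm(s)
            r += bump_amp * occ_presence * np.exp(-((_angles_to(dirs, s) / 0.10) ** 2))

    # undermined enamel: flared ridge at the occlusal cavity rim
    if p.undermined_extent > 0 and occ.depth > 0:
        r += (p.undermined_extent * UNDERMINE_RIDGE_MM * occ_presence
              * np.exp(-(((th_occ - phi_occ) / 0.08) ** 2)))

    # pulp exposure: deep narrow pit at the cavity centre
    if p.pulp_exposure:
        r -= PULP_PIT_MM * np.exp(-((th_occ / 0.07) ** 2))

    return r


def base_tooth_mesh(params: PrepParams) -> TriangleMesh:
    """The un-prepared tooth: sphere plus cusp bumps only."""
    p = replace(
        params,
        occlusal_cavity=replace(params.occlusal_cavity, depth=0.0),
        mesial_box=replace(params.mesial_box, depth=0.0),
        residual_caries_fraction=0.0,
        undermined_extent=0.0,
        isthmus_thickness=max(params.isthmus_thickness, 1.2),
        pulp_exposure=False,
        adjacent_damage_depth=0.0,
        include_adjacent_teeth=False,
    )
    return generate_mesh(p)


def _neighbour_mesh(params: PrepParams, mesial: bool) -> tuple[np.ndarray, np.ndarray]:
    R = params.base_radius
    r_adj = ADJACENT_RADIUS_FACTOR * R
    ico = trimesh.creation.icosphere(subdivisions=max(2, params.mesh_resolution - 1), radius=1.0)
    dirs = np.asarray(ico.vertices)
    radii = np.full(len(dirs), r_adj)
    sign = 1.0 if mesial else -1.0
    if mesial and params.adjacent_damage_depth > 0:
        facing = np.array([0.0, -1.0, 0.0])  # the side facing the preparation
        radii -= params.adjacent_damage_depth * np.exp(
            -((_angles_to(dirs, facing) / 0.30) ** 2)
        )
    centre = np.array([0.0, sign * (R + r_adj + ADJACENT_CONTACT_GAP_MM), 0.0])
    return dirs * radii[:, None] + centre, np.asarray(ico.faces)


def generate_mesh(params: PrepParams) -> TriangleMesh:
    """Build the synthetic scan: the prepared tooth, optionally flanked by
    mesial and distal neighbours.  Deterministic in (params, seed); the
    prepared tooth is always the first connected component."""
    params.validate()
    ico = trimesh.creation.icosphere(subdivisions=params.mesh_resolution, radius=1.0)
    dirs = np.asarray(ico.vertices)
    radii = _prep_radii(params, dirs)
    if radii.min() < 0.1 * params.base_radius:
        raise SelfIntersectionError(
            "combined depressions exceed the tooth body; reduce depths"
        )
    vertices = dirs * radii[:, None]
    faces = np.asarray(ico.faces)

    if params.jitter_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0x6A177E]))
        vertices = vertices + rng.normal(0.0, params.jitter_sigma, vertices.shape)

    all_v = [vertices]
    all_f = [faces]
    if params.include_adjacent_teeth:
        for mesial in (True, False):
            nv, nf = _neighbour_mesh(params, mesial=mesial)
            all_f.append(nf + sum(len(v) for v in all_v))
            all_v.append(nv)
    return TriangleMesh(
        np.vstack(all_v), np.vstack(all_f), source_id=f"synthetic_seed{params.seed}"
    )


# ---------------------------------------------------------------------------
# Deterministic scoring map


def _round_half(x: float) -> float:
    return float(np.floor(x * 2.0 + 0.5) / 2.0)


def _clearance_points(gap_mm: float) -> float:
    if gap_mm >= CLEARANCE_FULL_MM:
        return 2.0
    if gap_mm >= CLEARANCE_PARTIAL_MM:
        return 1.0
    return 0.0


def _damage_points(depth_mm: float) -> float:
    if depth_mm <= 0.0:
        return 0.0
    if depth_mm < 1.0:
        return -DAMAGE_MINOR_SLOPE * depth_mm          # minor band: down to -2
    return -(2.0 + 2.0 * (depth_mm - 1.0))             # moderate band: down to -4


def scoring_map(params: PrepParams) -> ScoreSheet:
    """Ground-truth score sheet implied by the preparation's geometry."""
    params.validate()
    p = params
    phi_occ = p.occlusal_cavity.radius / p.base_radius
    cusp_untouched = (phi_occ + CUSP_CLEAR_MARGIN_RAD) < CUSP_POLAR_RAD

    if p.isthmus_thickness >= ISTHMUS_FULL_MM:
        preservation = 2.0
    elif p.isthmus_thickness >= ISTHMUS_PARTIAL_MM:
        preservation = 1.0
    else:
        preservation = 0.0

    values = {
        "caries_removal": _round_half(9.0 * (1.0 - p.residual_caries_fraction)),
        "clearance_buccal": _clearance_points(p.clearance_buccal),
        "clearance_lingual": _clearance_points(p.clearance_lingual),
        "clearance_gingival": _clearance_points(p.clearance_gingival),
        "preservation_between": preservation,
        "occlusal_preservation": 1.0 if cusp_untouched else 0.0,
        "no_undermined_enamel": _round_half(2.0 * (1.0 - p.undermined_extent)),
        "adjacent_damage": _damage_points(p.adjacent_damage_depth),
    }
    return ScoreSheet(
        case_id=f"synthetic_seed{p.seed}", values=values, pulp_exposure=p.pulp_exposure
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortRanges:
    """Uniform parameter ranges per stratum.  The cohort mirrors the study
    design the rubric was applied to: most preparations acceptable with
    deliberate variation, a few ideal, a few deliberately poor, so cohort
    totals always span [<=8, 20]."""

    frac_ideal: float = 0.20
    frac_poor: float = 0.15
    pulp_probability: float = 0.0
    damage_probability: float = 0.30
    occ_radius: tuple[float, float] = (1.2, 3.2)
    occ_depth: tuple[float, float] = (1.2, 2.4)
    mesial_width: tuple[float, float] = (2.2, 2.8)
    mesial_depth: tuple[float, float] = (1.9, 2.4)
    residual: tuple[float, float] = (0.0, 0.4)
    gap: tuple[float, float] = (0.0, 0.8)
    isthmus: tuple[float, float] = (0.3, 1.4)
    undermined: tuple[float, float] = (0.0, 1.0)
    damage_depth: tuple[float, float] = (0.0, 2.0)


def _u(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _draw_params(rng: np.random.Generator, stratum: str, ranges: CohortRanges,
                 seed: int) -> PrepParams:
    rg = ranges
    if stratum == "ideal":
        return PrepParams(
            seed=seed,
            occlusal_cavity=OcclusalCavity(radius=_u(rng, (1.4, 1.9)), depth=_u(rng, (1.2, 1.8))),
            mesial_box=MesialBox(width=_u(rng, rg.mesial_width), depth=_u(rng, rg.mesial_depth)),
            clearance_buccal=_u(rng, (0.55, 0.8)),
            clearance_lingual=_u(rng, (0.55, 0.8)),
            clearance_gingival=_u(rng, (0.55, 0.8)),
            residual_caries_fraction=0.0,
            isthmus_thickness=_u(rng, (1.2, 1.5)),
            undermined_extent=0.0,
            adjacent_damage_depth=0.0,
        )
    if stratum == "poor":
        return PrepParams(
            seed=seed,
            occlusal_cavity=OcclusalCavity(radius=_u(rng, (2.6, 3.2)), depth=_u(rng, (1.8, 2.4))),
            mesial_box=MesialBox(width=_u(rng, rg.mesial_width), depth=_u(rng, rg.mesial_depth)),
            clearance_buccal=_u(rng, (0.0, 0.2)),
            clearance_lingual=_u(rng, (0.0, 0.2)),
            clearance_gingival=_u(rng, (0.0, 0.2)),
            residual_caries_fraction=_u(rng, (0.3, 0.5)),
            isthmus_thickness=_u(rng, (0.3, 0.45)),
            undermined_extent=_u(rng, (0.7, 1.0)),
            adjacent_damage_depth=_u(rng, (1.0, 2.0)),
        )
    damage = _u(rng, ranges.damage_depth) if rng.random() < rg.damage_probability else 0.0
    pulp = bool(rng.random() < rg.pulp_probability)
    return PrepParams(
        seed=seed,
        occlusal_cavity=OcclusalCavity(radius=_u(rng, rg.occ_radius), depth=_u(rng, rg.occ_depth)),
        mesial_box=MesialBox(width=_u(rng, rg.mesial_width), depth=_u(rng, rg.mesial_depth)),
        clearance_buccal=_u(rng, rg.gap),
        clearance_lingual=_u(rng, rg.gap),
        clearance_gingival=_u(rng, rg.gap),
        residual_caries_fraction=_u(rng, rg.residual),
        isthmus_thickness=_u(rng, rg.isthmus),
        undermined_extent=_u(rng, rg.undermined),
        adjacent_damage_depth=damage,
        pulp_exposure=pulp,
    )


def write_obj(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write the mesh as ascii OBJ (vertices to nine decimals)."""
    path = Path(path)
    lines = [f"v {x:.9f} {y:.9f} {z:.9f}" for x, y, z in mesh.vertices]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
    path.write_text("\n".join(lines) + "\n")
    return path


def generate_cohort(
    n: int = 30,
    seed: int = 0,
    ranges: CohortRanges = CohortRanges(),
    out_dir: Optional[str | Path] = None,
    test_fraction: float = 1.0 / 3.0,
    mesh_resolution: int = 4,
) -> list[SyntheticCase]:
    """Generate ``n`` scored synthetic cases with a seeded train/test split.

    Stratum counts (ideal / poor / varied) are fixed fractions of ``n`` so
    every cohort contains both full-mark and failing preparations.  With
    ``out_dir`` set, writes ``train/`` and ``test/`` folders of
    ``<case_id>.obj`` + ``<case_id>.json`` pairs plus a ``manifest.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0407]))
    n_ideal = max(1, round(ranges.frac_ideal * n)) if n >= 3 else (1 if n >= 1 else 0)
    n_poor = max(1, round(ranges.frac_poor * n)) if n >= 3 else (1 if n >= 2 else 0)
    strata = ["ideal"] * n_ideal + ["poor"] * n_poor + ["varied"] * (n - n_ideal - n_poor)

    cases: list[SyntheticCase] = []
    for i, stratum in enumerate(strata):
        case_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(
            _draw_params(rng, stratum, ranges, seed=case_seed),
            mesh_resolution=mesh_resolution,
        )
        mesh = generate_mesh(params)
        sheet = scoring_map(params)
        case_id = f"case_{i:03d}"
        mesh.source_id = case_id
        sheet.case_id = case_id
        cases.append(SyntheticCase(case_id=case_id, params=params, mesh=mesh, sheet=sheet))

    n_test = int(round(n * test_fraction))
    order = rng.permutation(n)
    test_ids = {cases[i].case_id for i in order[:n_test]}
    for c in cases:
        c.split = "test" if c.case_id in test_ids else "train"

    if out_dir is not None:
        import pandas as pd

        out_dir = Path(out_dir)
        rows = []
        for c in cases:
            d = out_dir / c.split
            d.mkdir(parents=True, exist_ok=True)
            write_obj(c.mesh, d / f"{c.case_id}.obj")
            write_label_json(c.sheet, d / f"{c.case_id}.json")
            row = {"case_id": c.case_id, "split": c.split, "total": total_score(c.sheet)}
            row.update({k: c.sheet.values[k] for k in CRITERION_KEYS})
            row["params"] = json.dumps(asdict(c.params), sort_keys=True)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return cases


# ---------------------------------------------------------------------------
# Geometric feature probes (learnability checks)


def prep_component(mesh: TriangleMesh) -> trimesh.Trimesh:
    """The prepared-tooth component: the connected component whose centroid
    is nearest the origin."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    parts = tm.split(only_watertight=False)
    if len(parts) == 0:
        return tm
    dists = [np.linalg.norm(p.vertices.mean(axis=0)) for p in parts]
    return parts[int(np.argmin(dists))]


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume of the prepared tooth (divergence theorem)."""
    return float(abs(prep_component(mesh).volume))


def mesh_features(mesh: TriangleMesh) -> dict[str, float]:
    """Simple geometric probes computed from the mesh alone.

    ``occlusal_floor_roughness``: azimuthal asymmetry of the surface inside
    the occlusal cavity footprint — the residual-caries lobe breaks the
    cavity's radial symmetry, so this rises with the fraction of caries
    left, while a cleanly cut cavity of any depth stays symmetric.
    ``mesial_recession``: mean material loss on the mesial aspect, driven
    by box depth and clearance widening.  ``prep_volume``: enclosed volume
    of the prepared tooth.
    """
    prep = prep_component(mesh)
    v = np.asarray(prep.vertices)
    radii = np.linalg.norm(v, axis=1)
    dirs = v / np.maximum(radii[:, None], 1e-12)
    base_r = float(np.median(radii))

    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    occ_mask = theta < 0.40
    if occ_mask.sum() > 10:
        th = theta[occ_mask]
        rr = radii[occ_mask]
        bins = np.minimum((th / 0.05).astype(int), 7)
        resid = rr - np.array([rr[bins == b].mean() for b in bins])
        roughness = float(np.std(resid))
    else:
        roughness = 0.0

    mes_mask = dirs[:, 1] > 0.5
    recession = float(np.mean(np.maximum(base_r - radii[mes_mask], 0.0))) if mes_mask.any() else 0.0

    return {
        "occlusal_floor_roughness": roughness,
        "mesial_recession": recession,
        "prep_volume": float(abs(prep.volume)),
    }
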