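"""The 20-point cavity-preparation rubric and score-sheet arithmetic.

A preparation is marked on eight criteria.  Seven carry positive marks
(caries removal up to 9; buccal, lingual and gingival proximal clearance
up to 2 each; preservation of the ridge between the two cavities up to 2;
occlusal cusp preservation up to 1; absence of undermined enamel up to 2)
and one is a deduction (iatrogenic damage to the adjacent tooth, 0 down to
-4 points).  Simulated pulp exposure zeroes the whole sheet.  Reference
sheets are the average of two examiners and may therefore hold half-point
values; model-predicted sheets are unconstrained reals within bounds.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CRITERIA",
    "CRITERION_KEYS",
    "CriterionDef",
    "ScoreSheet",
    "LabeledCase",
    "SplitReport",
    "RubricError",
    "OutOfRangeError",
    "SchemaError",
    "ConsistencyError",
    "CaseMismatchError",
    "total_score",
    "max_total",
    "average_examiners",
    "write_label_json",
    "read_label_json",
    "validate_split",
    "output_bounds",
]


class RubricError(ValueError):
    """Base class for rubric/score-sheet errors."""


class OutOfRangeError(RubricError):
    """A criterion value lies outside its rubric range."""


class SchemaError(RubricError):
    """A label file is missing a required field."""


class ConsistencyError(RubricError):
    """A label file's stored total disagrees with its criteria."""


class CaseMismatchError(RubricError):
    """Two sheets that must describe the same case do not."""


@dataclass(frozen=True)
class CriterionDef:
    key: str
    display_name: str
    min: float
    max: float


#: Canonical criterion order; also the output order of the regression network.
CRITERIA: tuple[CriterionDef, ...] = (
    CriterionDef("caries_removal", "Complete caries removal", 0.0, 9.0),
    CriterionDef("clearance_buccal", "Proximal clearance (buccal)", 0.0, 2.0),
    CriterionDef("clearance_lingual", "Proximal clearance (lingual)", 0.0, 2.0),
    CriterionDef("clearance_gingival", "Proximal clearance (gingival)", 0.0, 2.0),
    CriterionDef("preservation_between", "Preservation between cavities", 0.0, 2.0),
    CriterionDef("occlusal_preservation", "Avoidance of cusp weakening", 0.0, 1.0),
    CriterionDef("no_undermined_enamel", "No undermined enamel at margins", 0.0, 2.0),
    CriterionDef("adjacent_damage", "Damage to adjacent tooth (deduction)", -4.0, 0.0),
)

CRITERION_KEYS: tuple[str, ...] = tuple(c.key for c in CRITERIA)
_BY_KEY: dict[str, CriterionDef] = {c.key: c for c in CRITERIA}

# Sum of positive maxima; the rubric's full-mark total.
MAX_TOTAL: float = sum(c.max for c in CRITERIA if c.max > 0)
assert MAX_TOTAL == 20.0


def max_total() -> float:
    """Best achievable total: every positive criterion at its maximum,
    no deduction, no pulp exposure."""
    sheet = ScoreSheet(
        case_id="__max__",
        values={c.key: (c.max if c.max > 0 else 0.0) for c in CRITERIA},
        pulp_exposure=False,
    )
    return total_score(sheet)


@dataclass
class ScoreSheet:
    """One marked preparation: a value per criterion plus the pulp flag."""

    case_id: str
    values: dict[str, float]
    pulp_exposure: bool = False

    def validate(self, half_points: bool = False) -> None:
        """Check completeness and bounds; optionally enforce the examiner
        convention that every value is a multiple of 0.5."""
        for c in CRITERIA:
            if c.key not in self.values:
                raise SchemaError(f"sheet {self.case_id!r}: missing criterion {c.key!r}")
            v = float(self.values[c.key])
            if not math.isfinite(v):
                raise OutOfRangeError(f"sheet {self.case_id!r}: {c.key} is not finite")
            if v < c.min - 1e-9 or v > c.max + 1e-9:
                raise OutOfRangeError(
                    f"sheet {self.case_id!r}: {c.key}={v} outside [{c.min}, {c.max}]"
                )
            if half_points and abs(v * 2 - round(v * 2)) > 1e-9:
                raise OutOfRangeError(
                    f"sheet {self.case_id!r}: {c.key}={v} is not a half-point multiple"
                )

    def as_vector(self) -> np.ndarray:
        """Criterion values in canonical order (length 8, no total)."""
        return np.array([self.values[k] for k in CRITERION_KEYS], dtype=float)

    @classmethod
    def from_vector(
        cls, vec: Sequence[float], case_id: str, pulp_exposure: bool = False
    ) -> "ScoreSheet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(CRITERIA),):
            raise SchemaError(f"expected {len(CRITERIA)} criterion values, got {vec.shape}")
        return cls(
            case_id=case_id,
            values={k: float(v) for k, v in zip(CRITERION_KEYS, vec)},
            pulp_exposure=pulp_exposure,
        )


def total_score(sheet: ScoreSheet) -> float:
    """Total mark for a sheet.

    The deduction enters with its stored (negative) sign; pulp exposure
    zeroes the sheet; the total is clamped to [0, 20].
    """
    sheet.validate()
    if sheet.pulp_exposure:
        return 0.0
    total = sum(float(sheet.values[k]) for k in CRITERION_KEYS)
    return float(min(max(total, 0.0), MAX_TOTAL))


def average_examiners(a: ScoreSheet, b: ScoreSheet) -> ScoreSheet:
    """Reference sheet: per-criterion mean of two examiners' sheets.

    Pulp exposure is an OR — one examiner recording a breach zeroes the case.
    """
    if a.case_id != b.case_id:
        raise CaseMismatchError(f"case ids differ: {a.case_id!r} vs {b.case_id!r}")
    a.validate()
    b.validate()
    return ScoreSheet(
        case_id=a.case_id,
        values={k: (float(a.values[k]) + float(b.values[k])) / 2.0 for k in CRITERION_KEYS},
        pulp_exposure=a.pulp_exposure or b.pulp_exposure,
    )


# ---------------------------------------------------------------------------
# JSON label files


def write_label_json(sheet: ScoreSheet, path: str | Path) -> Path:
    """Write a sheet to the JSON label schema (one numeric field per
    criterion key, the pulp flag, and the stored total)."""
    sheet.validate()
    path = Path(path)
    payload = {"case_id": sheet.case_id}
    payload.update({k: float(sheet.values[k]) for k in CRITERION_KEYS})
    payload["pulp_exposure"] = bool(sheet.pulp_exposure)
    payload["total"] = total_score(sheet)
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    return path


def read_label_json(path: str | Path) -> ScoreSheet:
    """Read and validate a JSON label file.

    Raises SchemaError for missing keys, OutOfRangeError for bad values and
    ConsistencyError when the stored total disagrees with the recomputed one.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON ({exc})") from exc
    for required in ("case_id", "pulp_exposure", "total", *CRITERION_KEYS):
        if required not in payload:
            raise SchemaError(f"{path}: missing field {required!r}")
    sheet = ScoreSheet(
        case_id=str(payload["case_id"]),
        values={k: float(payload[k]) for k in CRITERION_KEYS},
        pulp_exposure=bool(payload["pulp_exposure"]),
    )
    sheet.validate()
    stored = float(payload["total"])
    recomputed = total_score(sheet)
    if abs(stored - recomputed) > 1e-6:
        raise ConsistencyError(
            f"{path}: stored total {stored} != recomputed {recomputed}"
        )
    return sheet


# ---------------------------------------------------------------------------
# Train/test split hygiene


@dataclass
class LabeledCase:
    """A scored 3D case: mesh file + label file + split membership."""

    case_id: str
    mesh_path: Path
    label_path: Path
    sheet: ScoreSheet
    split: str  # "train" | "test"


@dataclass
class SplitReport:
    duplicate_ids: list[str] = field(default_factory=list)
    duplicate_meshes: list[tuple[str, str]] = field(default_factory=list)
    near_duplicates: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.duplicate_ids or self.duplicate_meshes or self.near_duplicates)


def _mesh_fingerprint(vertices: np.ndarray, faces: np.ndarray) -> str:
    v = np.ascontiguousarray(np.round(np.asarray(vertices, dtype=np.float64), 9))
    f = np.ascontiguousarray(np.asarray(faces, dtype=np.int64))
    h = hashlib.sha256()
    h.update(v.tobytes())
    h.update(f.tobytes())
    return h.hexdigest()


def validate_split(
    cases: Iterable[LabeledCase],
    near_duplicate_threshold: float = 1e-3,
    probe_points: int = 1024,
) -> SplitReport:
    """Report-only hygiene check across the train/test split.

    Flags duplicate case ids, byte-identical mesh content (hash of
    canonicalised vertex/face arrays) and near-duplicates: pairs of cases in
    opposite splits whose pose-normalised probe clouds have a mean
    nearest-neighbour distance below ``near_duplicate_threshold``.  Rigid
    translations and uniform rescalings of the same scan therefore collide,
    which is the point.
    """
    from scipy.spatial import cKDTree

    from . import geometry

    cases = list(cases)
    report = SplitReport()

    seen_ids: dict[str, LabeledCase] = {}
    for c in cases:
        if c.case_id in seen_ids:
            report.duplicate_ids.append(c.case_id)
        seen_ids.setdefault(c.case_id, c)

    meshes = {c.case_id: geometry.read_obj(c.mesh_path) for c in cases}
    fingerprints: dict[str, str] = {}
    for c in cases:
        m = meshes[c.case_id]
        fp = _mesh_fingerprint(m.vertices, m.faces)
        for other_id, other_fp in fingerprints.items():
            if fp == other_fp and other_id != c.case_id:
                report.duplicate_meshes.append((other_id, c.case_id))
        fingerprints[c.case_id] = fp

    # one shared sampling stream: a moved/rescaled copy of a mesh then
    # normalizes to the *same* probe cloud, making its NN distance ~0
    cfg = geometry.SamplerConfig(n_points=probe_points, seed=0, derive_from_source=False)
    clouds = {}
    for c in cases:
        pc = geometry.sample_point_cloud(meshes[c.case_id], cfg)
        clouds[c.case_id] = geometry.normalize(pc).points
    train = [c for c in cases if c.split == "train"]
    test = [c for c in cases if c.split == "test"]
    for a in train:
        tree = cKDTree(clouds[a.case_id])
        for b in test:
            d, _ = tree.query(clouds[b.case_id])
            mean_d = float(np.mean(d))
            if mean_d < near_duplicate_threshold:
                report.near_duplicates.append((a.case_id, b.case_id, mean_d))
    return report


def output_bounds(include_total: bool = True) -> np.ndarray:
    """(n_outputs, 2) array of (min, max) per network output: the eight
    criteria in canonical order, plus the total head bounded to [0, 20]."""
    bounds = [(c.min, c.max) for c in CRITERIA]
    if include_total:
        bounds.append((0.0, MAX_TOTAL))
    return np.asarray(bounds, dtype=float)
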