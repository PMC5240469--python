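"""Upper-limb kinematic model definition.

The kinematic chain has seven degrees of freedom: three in the shoulder
(elevation plane, elevation angle, axial rotation), two in the elbow (flexion
and forearm pronation/supination) and two compound coordinates in the wrist
(radial/ulnar deviation and flexion, each distributed over the proximal and
distal carpal rows).  Each anatomical joint carries an orthonormal basis in
which its compound rotation is expressed:

* ``shoulder_basis`` (B_sh_orth): column 2 is the shared elevation-plane /
  axial-rotation axis, column 3 the elevation axis.  It is obtained from the
  slightly oblique raw model axes by QR orthogonalization.
* ``elbow_basis`` (B_pro_sup): column 1 is the forearm-rotation axis; the
  elbow-flexion axis is a general unit vector expressed in this basis.
* ``wrist_basis`` (B_pdr3): column 1 is the distal-row flexion axis; the
  remaining wrist rotation axes (deviation, proximal-row flexion, distal-row
  deviation) are general unit vectors expressed in this basis.

All public angle interfaces are in degrees; internal math uses radians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "COORDINATES",
    "FIXED_LIMITS",
    "DEFAULT_LIMITS",
    "ModelDefinition",
    "PrototypeMarker",
    "PrototypeMarkerSet",
    "ModelConfigError",
    "orthogonalize_basis",
    "build_reference_model",
    "load_model_config",
    "save_model_config",
    "generate_prototype_markers",
]

#: Canonical order of the seven joint coordinates.
COORDINATES = (
    "theta_elv",
    "theta_sh_elv",
    "theta_sh_rot",
    "theta_el_flex",
    "theta_pro_sup",
    "theta_dev_c",
    "theta_flex_c",
)

#: Model-defined coordinate ranges (degrees).  theta_flex_c is the compound
#: wrist flexion; its +/-70 range follows from the +/-35 per-row limit and the
#: even split of flexion between the carpal rows.
FIXED_LIMITS = {
    "theta_sh_elv": (0.0, 180.0),
    "theta_sh_rot": (-90.0, 20.0),
    "theta_el_flex": (0.0, 130.0),
    "theta_pro_sup": (-90.0, 90.0),
    "theta_flex_c": (-70.0, 70.0),
}

#: Default ranges for the two coordinates whose limits the chain itself does
#: not pin down.  These are surrogate, configurable values.
DEFAULT_LIMITS = {
    "theta_elv": (-90.0, 130.0),
    "theta_dev_c": (-10.0, 25.0),
    **FIXED_LIMITS,
}

_ORTHO_TOL = 1e-12


class ModelConfigError(ValueError):
    """Raised for invalid or inconsistent model configuration data."""


def orthogonalize_basis(raw_axes: np.ndarray) -> np.ndarray:
    """Orthonormalize a near-orthogonal set of unit axes via QR decomposition.

    Parameters
    ----------
    raw_axes:
        3x3 matrix whose columns are unit-length axes with pairwise angles
        within 5 degrees of 90.

    Returns
    -------
    Q from the QR factorization of ``raw_axes`` with the sign convention that
    each output column has positive dot product with its input column (i.e.
    positive diagonal of the triangular factor), which keeps the columns
    maximally aligned with the originals.
    """
    raw = np.asarray(raw_axes, dtype=float)
    if raw.shape != (3, 3):
        raise ModelConfigError(f"expected a 3x3 axis matrix, got {raw.shape}")
    norms = np.linalg.norm(raw, axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ModelConfigError(f"axis columns must be unit length (norms {norms})")
    if abs(np.linalg.det(raw)) < 1e-6:
        raise ModelConfigError("degenerate basis: raw axes are not invertible")
    gram = raw.T @ raw
    off = np.abs(gram[np.triu_indices(3, 1)])
    if np.any(off > np.sin(np.deg2rad(5.0))):
        raise ModelConfigError(
            "raw axes deviate from pairwise orthogonality by more than 5 degrees"
        )
    q, r = np.linalg.qr(raw)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    if np.linalg.det(q) < 0:  # cannot occur after sign fix of a proper triad
        q[:, 2] *= -1.0
    return q


@dataclass(frozen=True)
class ModelDefinition:
    """Bases, axes and limits of the 7-DOF upper-limb chain."""

    shoulder_axes_raw: np.ndarray  # 3x3, columns = raw shoulder axes
    shoulder_basis: np.ndarray  # 3x3 orthonormal (B_sh_orth)
    elbow_basis: np.ndarray  # 3x3 orthonormal, col 1 = forearm-rotation axis
    elbow_flex_axis: np.ndarray  # unit 3-vector in elbow_basis coordinates
    wrist_basis: np.ndarray  # 3x3 orthonormal, col 1 = distal-row flexion axis
    wrist_dev_axis: np.ndarray  # unit 3-vectors in wrist_basis coordinates
    wrist_flex_axis: np.ndarray
    wrist_pdr1_axis: np.ndarray
    joint_limits: dict = field(default_factory=lambda: dict(DEFAULT_LIMITS))
    segment_offsets: dict = field(
        default_factory=lambda: {
            "shoulder": np.zeros(3),
            "elbow": np.array([0.0, -0.30, 0.0]),
            "wrist": np.array([0.0, -0.55, 0.0]),
        }
    )
    wrist_split: float = 0.5  # fraction of each compound wrist coordinate
    # applied at the proximal carpal row

    def __post_init__(self):
        for name in (
            "shoulder_axes_raw",
            "shoulder_basis",
            "elbow_basis",
            "elbow_flex_axis",
            "wrist_basis",
            "wrist_dev_axis",
            "wrist_flex_axis",
            "wrist_pdr1_axis",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(
            self,
            "segment_offsets",
            {k: np.asarray(v, dtype=float) for k, v in self.segment_offsets.items()},
        )
        self.validate()

    def validate(self) -> None:
        for name in ("shoulder_basis", "elbow_basis", "wrist_basis"):
            b = getattr(self, name)
            if np.max(np.abs(b.T @ b - np.eye(3))) > _ORTHO_TOL:
                raise ModelConfigError(f"{name} is not orthonormal")
            if abs(np.linalg.det(b) - 1.0) > _ORTHO_TOL:
                raise ModelConfigError(f"{name} does not have determinant +1")
        for name in (
            "elbow_flex_axis",
            "wrist_dev_axis",
            "wrist_flex_axis",
            "wrist_pdr1_axis",
        ):
            v = getattr(self, name)
            if v.shape != (3,):
                raise ModelConfigError(f"{name} must be a 3-vector")
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-6:
                raise ModelConfigError(f"{name} is not unit length (norm {n:.8f})")
        if abs(self.elbow_flex_axis[0]) > 1 - 1e-9:
            raise ModelConfigError(
                "elbow_flex_axis may not be parallel to the forearm-rotation axis"
            )
        if set(self.joint_limits) != set(COORDINATES):
            raise ModelConfigError(
                f"joint_limits must define exactly the coordinates {COORDINATES}"
            )
        for coord, (lo, hi) in self.joint_limits.items():
            if not lo < hi:
                raise ModelConfigError(f"joint_limits[{coord}]: min must be < max")
            if coord in FIXED_LIMITS and tuple(FIXED_LIMITS[coord]) != (lo, hi):
                raise ModelConfigError(
                    f"joint_limits[{coord}] is fixed to {FIXED_LIMITS[coord]} "
                    f"by the chain definition, got ({lo}, {hi})"
                )
        if not 0.0 < self.wrist_split <= 1.0:
            raise ModelConfigError("wrist_split must be in (0, 1]")

    # -- convenience ------------------------------------------------------
    def limits_array(self) -> np.ndarray:
        """(7, 2) array of [min, max] in degrees, in COORDINATES order."""
        return np.array([self.joint_limits[c] for c in COORDINATES])

    def with_limits(self, **overrides) -> "ModelDefinition":
        """Copy with surrogate (non-fixed) limits replaced."""
        limits = dict(self.joint_limits)
        for coord, rng in overrides.items():
            if coord in FIXED_LIMITS:
                raise ModelConfigError(f"limits for {coord} are fixed")
            limits[coord] = tuple(rng)
        return replace(self, joint_limits=limits)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1.0
    return q


def _tilted(base: np.ndarray, tilt_rad: float, azimuth_rad: float) -> np.ndarray:
    """Unit vector at angle ``tilt_rad`` from ``base`` toward ``azimuth_rad``."""
    base = base / np.linalg.norm(base)
    # any perpendicular pair
    helper = np.array([1.0, 0.0, 0.0])
    if abs(base @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(base, helper)
    u /= np.linalg.norm(u)
    v = np.cross(base, u)
    perp = np.cos(azimuth_rad) * u + np.sin(azimuth_rad) * v
    return np.cos(tilt_rad) * base + np.sin(tilt_rad) * perp


def build_reference_model(obliquity_deg: float = 0.0029, seed: int = 0) -> ModelDefinition:
    """Deterministic synthetic model emulating the published chain's structure.

    The shoulder raw axes form a near-orthogonal triad whose pairwise angular
    deviations from 90 degrees all equal ``obliquity_deg`` (symmetric Gram
    construction), emulating the published model's ~0.003 degree obliquity.
    The elbow-flexion axis is tilted 5-15 degrees out of the elbow basis
    plane so the general axis-angle solution is exercised, and the wrist axes
    are distinct non-orthogonal unit vectors within 30 degrees of their
    nominal basis columns.
    """
    if not 0.0 <= obliquity_deg <= 1.0:
        raise ValueError("obliquity_deg must be in [0, 1]")
    rng = np.random.default_rng(seed)

    # shoulder: raw triad with exact pairwise obliquity, then QR
    delta = np.sin(np.deg2rad(obliquity_deg))
    gram = (1.0 - delta) * np.eye(3) + delta * np.ones((3, 3))
    w, v = np.linalg.eigh(gram)
    gram_sqrt = v @ np.diag(np.sqrt(w)) @ v.T
    raw = _random_rotation(rng) @ gram_sqrt
    raw /= np.linalg.norm(raw, axis=0)  # guard rounding of unit columns
    shoulder_basis = orthogonalize_basis(raw)

    # elbow: random proper basis; flexion axis 5-15 degrees out of the
    # plane perpendicular to the forearm-rotation axis (= column 1)
    elbow_basis = _random_rotation(rng)
    rho = np.deg2rad(rng.uniform(5.0, 15.0))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    elbow_flex_axis = np.array(
        [np.sin(rho), np.cos(rho) * np.cos(phi), np.cos(rho) * np.sin(phi)]
    )

    # wrist: random proper basis; axes tilted 10-25 degrees off their
    # nominal columns (flexion axes near column 1, deviation axes near
    # column 2), pairwise distinct via distinct azimuths
    wrist_basis = _random_rotation(rng)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    az = rng.uniform(0.0, 2.0 * np.pi, size=3)
    tilts = np.deg2rad(rng.uniform(10.0, 25.0, size=3))
    wrist_flex_axis = _tilted(e1, tilts[0], az[0])
    wrist_dev_axis = _tilted(e2, tilts[1], az[1])
    wrist_pdr1_axis = _tilted(e2, tilts[2], az[2] + np.pi / 2.0)

    return ModelDefinition(
        shoulder_axes_raw=raw,
        shoulder_basis=shoulder_basis,
        elbow_basis=elbow_basis,
        elbow_flex_axis=elbow_flex_axis,
        wrist_basis=wrist_basis,
        wrist_dev_axis=wrist_dev_axis,
        wrist_flex_axis=wrist_flex_axis,
        wrist_pdr1_axis=wrist_pdr1_axis,
    )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_MATRIX_FIELDS = ("shoulder_axes_raw", "elbow_basis", "wrist_basis")
_VECTOR_FIELDS = (
    "elbow_flex_axis",
    "wrist_dev_axis",
    "wrist_flex_axis",
    "wrist_pdr1_axis",
)


def save_model_config(model: ModelDefinition, path) -> None:
    """Serialize a model to JSON or YAML (by file extension).

    Matrices are stored row-major; their *columns* are the axes.
    """
    data = {name: getattr(model, name).tolist() for name in _MATRIX_FIELDS}
    data.update({name: getattr(model, name).tolist() for name in _VECTOR_FIELDS})
    data["joint_limits"] = {k: list(v) for k, v in model.joint_limits.items()}
    data["segment_offsets"] = {k: v.tolist() for k, v in model.segment_offsets.items()}
    data["wrist_split"] = model.wrist_split
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(data, fh)
        else:
            json.dump(data, fh, indent=1)


def load_model_config(path) -> ModelDefinition:
    """Load and validate a model configuration (JSON or YAML).

    Raw shoulder axes are passed through :func:`orthogonalize_basis` on load,
    so configs may carry slightly oblique axes.
    """
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    required = set(_MATRIX_FIELDS) | set(_VECTOR_FIELDS) | {"joint_limits"}
    missing = required - set(data)
    if missing:
        raise ModelConfigError(f"model config missing fields: {sorted(missing)}")
    kwargs = {}
    for name in _MATRIX_FIELDS + _VECTOR_FIELDS:
        try:
            kwargs[name] = np.asarray(data[name], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ModelConfigError(f"field {name} is not numeric: {exc}") from None
    for name in _VECTOR_FIELDS:
        n = np.linalg.norm(kwargs[name])
        if abs(n - 1.0) > 1e-6:
            raise ModelConfigError(f"field {name} is not a unit vector (norm {n:.8f})")
    try:
        kwargs["shoulder_basis"] = orthogonalize_basis(kwargs["shoulder_axes_raw"])
    except ModelConfigError as exc:
        raise ModelConfigError(f"field shoulder_axes_raw: {exc}") from None
    kwargs["joint_limits"] = {
        k: tuple(float(x) for x in v) for k, v in data["joint_limits"].items()
    }
    if "segment_offsets" in data:
        kwargs["segment_offsets"] = {
            k: np.asarray(v, dtype=float) for k, v in data["segment_offsets"].items()
        }
    if "wrist_split" in data:
        kwargs["wrist_split"] = float(data["wrist_split"])
    return ModelDefinition(**kwargs)


# ---------------------------------------------------------------------------
# prototype markers
# ---------------------------------------------------------------------------

_JOINTS = ("SH", "EL", "WR")
_ROLES = ("O", "X", "Y", "Z")


@dataclass(frozen=True)
class PrototypeMarker:
    name: str
    joint: str  # SH | EL | WR
    role: str  # O | X | Y | Z
    basis: str  # model attribute holding the parent basis
    offset: np.ndarray  # local offset in the joint basis


@dataclass(frozen=True)
class PrototypeMarkerSet:
    """The 12 prototype markers: per joint one origin + three unit axis tips."""

    markers: tuple

    def __post_init__(self):
        if len(self.markers) != 12:
            raise ValueError("a prototype marker set has exactly 12 markers")

    @property
    def names(self):
        return [m.name for m in self.markers]

    def by_joint(self, joint: str):
        return [m for m in self.markers if m.joint == joint]


def generate_prototype_markers(model: ModelDefinition) -> PrototypeMarkerSet:
    """Place four markers per joint basis: origin plus one per basis column.

    Marker names follow the convention ``PMx_[SH|EL|WR]_[O|X|Y|Z]`` with x the
    serial number of the basis (1-3).  Difference vectors between axis markers
    and the origin marker reproduce the basis columns, hence (after motion)
    the joint's compound rotation.
    """
    basis_attr = {"SH": "shoulder_basis", "EL": "elbow_basis", "WR": "wrist_basis"}
    markers = []
    for i, joint in enumerate(_JOINTS, start=1):
        for k, role in enumerate(_ROLES):
            offset = np.zeros(3) if role == "O" else np.eye(3)[k - 1]
            markers.append(
                PrototypeMarker(
                    name=f"PM{i}_{joint}_{role}",
                    joint=joint,
                    role=role,
                    basis=basis_attr[joint],
                    offset=offset,
                )
            )
    return PrototypeMarkerSet(markers=tuple(markers))


#: Canonical prototype-marker name order used throughout the package.
MARKER_NAMES = tuple(
    f"PM{i}_{j}_{r}" for i, j in enumerate(_JOINTS, start=1) for r in _ROLES
)
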