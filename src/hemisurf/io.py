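"""Reading and writing of radial-section datasets and coefficient matrices.

On-disk dialects
----------------
* Section files: 2-column delimited text ``x_mm, z_mm`` (comma, tab or
  semicolon; auto-detected).  Lines starting with ``#`` are comments.
* Manifests: a JSON array of ``{"file": str, "angle_deg": number}``.
  Angles are human-facing degrees in files and radians in memory.
* Coefficient matrices: CSV with a one-line header
  ``# kind=<A|B> rows=<r> cols=<c>`` followed by the rows.  Values are
  written with ``repr`` so the write -> read round trip is bit-exact.

All lengths are millimetres.  Sections span a half turn [0, pi): a
diametral profile with signed x already covers both sides of the
rotation axis, so angles are normalized modulo pi.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SectionFormatError

_DELIMITERS = (",", ";", "\t")

__all__ = [
    "RadialSection",
    "SectionSet",
    "CoeffMatrix",
    "normalize_angle",
    "read_section_file",
    "write_section_file",
    "read_section_set",
    "write_section_set",
    "read_coeff_matrix",
    "write_coeff_matrix",
    "save_surface_model",
    "load_surface_model",
]


def normalize_angle(angle: float) -> float:
    """Map a section angle (radians) into [0, pi).  Idempotent."""
    a = math.fmod(float(angle), math.pi)
    if a < 0.0:
        a += math.pi
    # fmod can return exactly pi after the negative branch for tiny inputs
    if a >= math.pi:
        a -= math.pi
    return a


@dataclass(frozen=True)
class RadialSection:
    """One diametral height profile z(x) at a fixed rotation angle.

    ``xs`` are signed in-section coordinates (mm) measured from the
    rotation axis; ``zs`` are heights above the base plane (mm).
    """

    angle: float
    xs: np.ndarray
    zs: np.ndarray

    def __post_init__(self):
        xs = np.asarray(self.xs, dtype=float)
        zs = np.asarray(self.zs, dtype=float)
        if xs.ndim != 1 or zs.ndim != 1 or len(xs) != len(zs):
            raise SectionFormatError("xs and zs must be 1-D and equal length")
        if len(xs) < 2:
            raise SectionFormatError("a section needs at least 2 samples")
        if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(zs))):
            raise SectionFormatError("section contains non-finite values")
        if np.any(np.diff(xs) <= 0):
            raise SectionFormatError("xs must be strictly increasing")
        object.__setattr__(self, "angle", normalize_angle(self.angle))
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "zs", zs)

    @property
    def n_samples(self) -> int:
        return len(self.xs)


@dataclass(frozen=True)
class SectionSet:
    """An angle-ordered collection of radial sections (units: mm)."""

    sections: tuple
    units: str = "mm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        secs = tuple(sorted(self.sections, key=lambda s: s.angle))
        if len(secs) < 2:
            raise SectionFormatError("a SectionSet needs at least 2 sections")
        angles = [s.angle for s in secs]
        if len(set(angles)) != len(angles):
            raise SectionFormatError("section angles must be distinct modulo pi")
        object.__setattr__(self, "sections", secs)

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)

    @property
    def angles(self) -> np.ndarray:
        return np.array([s.angle for s in self.sections])


@dataclass(frozen=True)
class CoeffMatrix:
    """A coefficient matrix with its file tag (per-section 'A' or surface 'B')."""

    values: np.ndarray
    kind: str = "B"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise SectionFormatError("coefficient matrix must be 2-D")
        if not np.all(np.isfinite(v)):
            raise SectionFormatError("coefficient matrix has non-finite entries")
        if self.kind not in ("A", "B"):
            raise SectionFormatError(f"kind must be 'A' or 'B', got {self.kind!r}")
        object.__setattr__(self, "values", v)


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise SectionFormatError(
            "could not detect delimiter (expected comma, tab or semicolon)"
        )
    return best


def read_section_file(path, angle: float) -> RadialSection:
    """Read one 2-column (x, z) section file; rows are sorted by x.

    Duplicate x values are rejected: each signed radial coordinate may
    carry only one height.
    """
    path = Path(path)
    if not path.exists():
        raise SectionFormatError(f"section file not found: {path}")
    rows = []
    delim = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise SectionFormatError(f"{path}:{lineno}: expected 2 columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SectionFormatError(f"{path}:{lineno}: non-numeric cell") from exc
    if len(rows) < 2:
        raise SectionFormatError(f"{path}: fewer than 2 data rows")
    rows.sort(key=lambda r: r[0])
    xs = np.array([r[0] for r in rows])
    zs = np.array([r[1] for r in rows])
    if np.any(np.diff(xs) == 0):
        raise SectionFormatError(f"{path}: duplicate x values")
    return RadialSection(angle=angle, xs=xs, zs=zs)


def write_section_file(section: RadialSection, path) -> None:
    """Write a section as 2-column CSV (exact round trip via repr floats)."""
    path = Path(path)
    lines = [f"# angle_deg={math.degrees(section.angle)!r}"]
    for x, z in zip(section.xs, section.zs):
        lines.append(f"{float(x)!r},{float(z)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_section_set(manifest) -> SectionSet:
    """Read a JSON manifest mapping section files to acquisition angles."""
    manifest = Path(manifest)
    if not manifest.exists():
        raise SectionFormatError(f"manifest not found: {manifest}")
    try:
        entries = json.loads(manifest.read_text())
    except json.JSONDecodeError as exc:
        raise SectionFormatError(f"{manifest}: invalid JSON") from exc
    if not isinstance(entries, list) or not entries:
        raise SectionFormatError(f"{manifest}: manifest must be a non-empty array")
    sections = []
    seen = set()
    for e in entries:
        try:
            fname, angle_deg = e["file"], float(e["angle_deg"])
        except (TypeError, KeyError) as exc:
            raise SectionFormatError(
                f"{manifest}: entries need 'file' and 'angle_deg'"
            ) from exc
        angle = normalize_angle(math.radians(angle_deg))
        if angle in seen:
            raise SectionFormatError(
                f"{manifest}: repeated angle {angle_deg} deg (modulo 180)"
            )
        seen.add(angle)
        sections.append(read_section_file(manifest.parent / fname, angle))
    return SectionSet(sections=tuple(sections), meta={"manifest": str(manifest)})


def write_section_set(ss: SectionSet, outdir, prefix: str = "section") -> Path:
    """Write one CSV per section plus a manifest.json; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sec in ss:
        deg = math.degrees(sec.angle)
        fname = f"{prefix}_{deg:07.2f}deg.csv"
        write_section_file(sec, outdir / fname)
        entries.append({"file": fname, "angle_deg": deg})
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=2) + "\n")
    return manifest


def write_coeff_matrix(matrix: CoeffMatrix, path) -> None:
    """Write a coefficient matrix as headered CSV (bit-exact round trip)."""
    path = Path(path)
    r, c = matrix.values.shape
    lines = [f"# kind={matrix.kind} rows={r} cols={c}"]
    for row in matrix.values:
        lines.append(",".join(f"{float(v)!r}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_coeff_matrix(path) -> CoeffMatrix:
    path = Path(path)
    if not path.exists():
        raise SectionFormatError(f"coefficient file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise SectionFormatError(f"{path}: missing '# kind=... rows=... cols=...' header")
    header = dict(
        tok.split("=", 1) for tok in lines[0].lstrip("#").split() if "=" in tok
    )
    try:
        kind = header["kind"]
        rows, cols = int(header["rows"]), int(header["cols"])
    except (KeyError, ValueError) as exc:
        raise SectionFormatError(f"{path}: malformed header") from exc
    data = []
    for ln in lines[1:]:
        try:
            data.append([float(v) for v in ln.split(",")])
        except ValueError as exc:
            raise SectionFormatError(f"{path}: non-numeric cell") from exc
    values = np.array(data, dtype=float)
    if values.shape != (rows, cols):
        raise SectionFormatError(
            f"{path}: header says {rows}x{cols}, file has {values.shape}"
        )
    return CoeffMatrix(values=values, kind=kind)


def save_surface_model(model, basename) -> tuple:
    """Save a fitted surface: B matrix CSV plus a JSON sidecar of orders/scalings.

    Returns (matrix_path, sidecar_path).
    """
    basename = Path(basename)
    basename.parent.mkdir(parents=True, exist_ok=True)
    mpath = basename.with_suffix(".csv")
    spath = basename.with_suffix(".json")
    write_coeff_matrix(CoeffMatrix(values=model.B, kind="B"), mpath)
    sidecar = {
        "order_n": model.order_n,
        "order_m": model.order_m,
        "x_scale": list(model.x_scale),
        "y_scale": list(model.y_scale),
        "frame": model.frame,
    }
    spath.write_text(json.dumps(sidecar, indent=2) + "\n")
    return mpath, spath


def load_surface_model(basename):
    """Load a surface saved by :func:`save_surface_model`."""
    from .reconstruction import SurfaceModel

    basename = Path(basename)
    matrix = read_coeff_matrix(basename.with_suffix(".csv"))
    sidecar = json.loads(basename.with_suffix(".json").read_text())
    return SurfaceModel(
        B=matrix.values,
        order_n=int(sidecar["order_n"]),
        order_m=int(sidecar["order_m"]),
        x_scale=tuple(sidecar["x_scale"]),
        y_scale=tuple(sidecar["y_scale"]),
        frame=sidecar["frame"],
    )
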