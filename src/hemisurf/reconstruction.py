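"""Two-layer polynomial reconstruction of a surface from radial sections.

The method
----------
Each radial section k is a height profile z_k(x) sampled at a rotation
angle y_k.  Stage one fits every section with a degree-N polynomial

    z_k(x) = sum_i a_{ki} x^i            (least squares),

collecting the per-section coefficients into a matrix A whose row k is
(a_{k0}, ..., a_{kN}).  Stage two observes that each column i of A is a
sampled function a_i(y) of the section angle, and fits it with a
degree-M polynomial

    a_i(y) = sum_k b_{ik} y^k.

The resulting (N+1) x (M+1) matrix B is a closed-form bivariate model

    z(x, y) = sum_i sum_k b_{ik} y^k x^i

evaluable at arbitrary (x, y).  Defaults N = 12, M = 5 give a 13 x 6
coefficient matrix for the canonical six-section acquisition.

Numerical note: both stages fit on coordinates affinely mapped to
[-1, 1].  At order 12 a raw-coordinate Vandermonde matrix is too ill
conditioned to be reproducible; the affine scalings are stored in the
model so the bivariate form above is reproduced exactly in original
units.  Raw-coordinate fitting remains available behind ``scale=False``
for comparison.

The module also carries two fixed boundary polynomials (degree 3 for a
concave contour segment, degree 5 for a convex one) with an additive
correction offset G, used when a lesion outline is approximated
piecewise in a 2-D projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from numpy.polynomial import Polynomial

from .errors import ExtrapolationWarning, FitError
from .io import RadialSection, SectionSet

__all__ = [
    "SectionFit",
    "CoeffMatrixA",
    "SurfaceModel",
    "BoundaryPoly",
    "CONCAVE_BOUNDARY",
    "CONVEX_BOUNDARY",
    "fit_section",
    "build_matrix_A",
    "fit_coefficient_curves",
    "eval_surface",
    "reconstruct",
    "eval_boundary_poly",
    "RadialSurfaceModel",
    "SurfaceFitResult",
]


def _scaled(values: np.ndarray, scale: tuple) -> np.ndarray:
    center, halfwidth = scale
    return (np.asarray(values, dtype=float) - center) / halfwidth


def _make_scale(values: np.ndarray) -> tuple:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise FitError("cannot build an affine scale from a single distinct value")
    return ((lo + hi) / 2.0, (hi - lo) / 2.0)


def _lstsq_poly(t: np.ndarray, z: np.ndarray, order: int) -> tuple:
    """Least-squares polynomial fit on already-scaled coordinates.

    Solved by orthogonal decomposition (minimum-norm solution on ties).
    Returns (coeffs, rms_residual).  Raises on underdetermined or rank-
    deficient systems.
    """
    if len(t) < order + 1:
        raise FitError(f"need >= {order + 1} samples for a degree-{order} fit, got {len(t)}")
    V = npoly.polyvander(t, order)
    coef, _, rank, _ = np.linalg.lstsq(V, z, rcond=None)
    if rank < order + 1:
        raise FitError("rank-deficient design matrix (coincident sample coordinates?)")
    resid = V @ coef - z
    return coef, float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class SectionFit:
    """Degree-N fit of one section; coefficients live in the scaled basis."""

    angle: float
    coeffs: np.ndarray  # basis: powers of (x - center)/halfwidth
    order_n: int
    x_scale: tuple  # (center, halfwidth)
    rms_residual: float

    @property
    def coeffs_unscaled(self) -> np.ndarray:
        """Coefficients in powers of raw x (length N+1, constant first)."""
        c, h = self.x_scale
        p = Polynomial(self.coeffs, domain=[c - h, c + h], window=[-1, 1])
        out = p.convert(kind=Polynomial).coef
        full = np.zeros(self.order_n + 1)
        full[: len(out)] = out
        return full

    def __call__(self, x):
        return npoly.polyval(_scaled(x, self.x_scale), self.coeffs)


@dataclass(frozen=True)
class CoeffMatrixA:
    """Per-section coefficients: row k holds section k's (a_k0 ... a_kN)."""

    values: np.ndarray  # (n_sections, N+1)
    angles: np.ndarray  # (n_sections,)
    x_scale: tuple
    order_n: int


@dataclass(frozen=True)
class SurfaceModel:
    """Closed-form bivariate surface z(x, y) = sum b_ik yhat^k xhat^i.

    ``frame`` records how (x, y) map to 3-D: 'section-space' means x is
    the signed in-section coordinate and y the rotation angle, so a
    surface point is (x cos y, x sin y, z); 'cartesian' means (x, y, z)
    directly.
    """

    B: np.ndarray  # (N+1, M+1)
    order_n: int
    order_m: int
    x_scale: tuple
    y_scale: tuple
    frame: str = "section-space"

    def __post_init__(self):
        B = np.asarray(self.B, dtype=float)
        if B.shape != (self.order_n + 1, self.order_m + 1):
            raise FitError(
                f"B must be {(self.order_n + 1, self.order_m + 1)}, got {B.shape}"
            )
        if not np.all(np.isfinite(B)):
            raise FitError("B has non-finite entries")
        if self.frame not in ("section-space", "cartesian"):
            raise FitError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "B", B)

    def __call__(self, x, y):
        return eval_surface(self, x, y)


def fit_section(s: RadialSection, order_n: int, x_scale: tuple = None,
                scale: bool = True) -> SectionFit:
    """Least-squares degree-N polynomial fit of one section profile.

    ``x_scale`` may be supplied to share a scaling across sections (as
    the matrix-A builder does); by default the section's own x range is
    mapped to [-1, 1].  ``scale=False`` fits raw coordinates (unstable
    at high order; kept for comparison only).
    """
    if scale:
        xsc = x_scale if x_scale is not None else _make_scale(s.xs)
    else:
        warnings.warn(
            "fitting raw (unscaled) coordinates; ill conditioned above order ~8",
            UserWarning,
            stacklevel=2,
        )
        xsc = (0.0, 1.0)
    coef, rms = _lstsq_poly(_scaled(s.xs, xsc), s.zs, order_n)
    return SectionFit(angle=s.angle, coeffs=coef, order_n=order_n,
                      x_scale=xsc, rms_residual=rms)


def build_matrix_A(ss: SectionSet, order_n: int, scale: bool = True) -> CoeffMatrixA:
    """Fit every section with one shared x scaling; stack coefficient rows."""
    all_x = np.concatenate([s.xs for s in ss])
    xsc = _make_scale(all_x) if scale else (0.0, 1.0)
    rows = []
    for k, sec in enumerate(ss):
        try:
            fit = fit_section(sec, order_n, x_scale=xsc, scale=True) if scale \
                else fit_section(sec, order_n, scale=False)
        except FitError as exc:
            raise FitError(f"section {k} (angle {sec.angle:.4f} rad): {exc}") from exc
        rows.append(fit.coeffs)
    return CoeffMatrixA(values=np.vstack(rows), angles=ss.angles,
                        x_scale=xsc, order_n=order_n)


def fit_coefficient_curves(A: CoeffMatrixA, order_m: int) -> SurfaceModel:
    """Fit each coefficient a_i across sections as a degree-M polynomial in y."""
    n_sections = A.values.shape[0]
    if n_sections < order_m + 1:
        raise FitError(
            f"second-layer fit of degree {order_m} needs >= {order_m + 1} sections, "
            f"got {n_sections}"
        )
    ysc = _make_scale(A.angles)
    yhat = _scaled(A.angles, ysc)
    B = np.empty((A.order_n + 1, order_m + 1))
    for i in range(A.order_n + 1):
        B[i, :], _ = _lstsq_poly(yhat, A.values[:, i], order_m)
    return SurfaceModel(B=B, order_n=A.order_n, order_m=order_m,
                        x_scale=A.x_scale, y_scale=ysc)


def eval_surface(model: SurfaceModel, x, y):
    """Evaluate z(x, y); broadcasts over array inputs.

    Evaluation outside the fitted (x, y) ranges is permitted but raises
    an :class:`ExtrapolationWarning`.
    """
    xhat = _scaled(x, model.x_scale)
    yhat = _scaled(y, model.y_scale)
    xhat, yhat = np.broadcast_arrays(np.atleast_1d(xhat), np.atleast_1d(yhat))
    if np.any(np.abs(xhat) > 1.0 + 1e-9) or np.any(np.abs(yhat) > 1.0 + 1e-9):
        warnings.warn(
            "evaluating the surface outside its fitted region",
            ExtrapolationWarning,
            stacklevel=2,
        )
    Vx = npoly.polyvander(xhat.ravel(), model.order_n)
    Vy = npoly.polyvander(yhat.ravel(), model.order_m)
    z = np.einsum("pi,ik,pk->p", Vx, model.B, Vy)
    z = z.reshape(xhat.shape)
    if np.isscalar(x) and np.isscalar(y):
        return float(z[0])
    return z


def reconstruct(ss: SectionSet, order_n: int = 12, order_m: int = 5,
                scale: bool = True) -> SurfaceModel:
    """Full two-stage reconstruction: sections -> matrix A -> surface B."""
    return fit_coefficient_curves(build_matrix_A(ss, order_n, scale=scale), order_m)


# --- fixed boundary polynomials -------------------------------------------

@dataclass(frozen=True)
class BoundaryPoly:
    """A fixed contour-segment polynomial plus additive correction G.

    ``coeffs`` are highest power first (numpy.polyval order); degree is
    3 for the concave segment and 5 for the convex one.
    """

    coeffs: tuple
    G: float = 0.0

    def __post_init__(self):
        if len(self.coeffs) - 1 not in (3, 5):
            raise FitError("boundary polynomials are degree 3 or 5")

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1


CONCAVE_BOUNDARY = BoundaryPoly(coeffs=(896.436, -64.994, 1.206, 0.023))
CONVEX_BOUNDARY = BoundaryPoly(
    coeffs=(9617.999, -847.094, -104.9966, 15.369, -0.661, 0.011)
)


def eval_boundary_poly(p: BoundaryPoly, x):
    """Evaluate the boundary polynomial plus its correction offset G."""
    return np.polyval(np.asarray(p.coeffs, dtype=float), x) + p.G


# --- model / results layer --------------------------------------------------

class RadialSurfaceModel:
    """Two-layer polynomial surface model of a rotationally acquired lesion.

    Parameters
    ----------
    sections : SectionSet
        Radial height profiles z(x) at distinct rotation angles.
    order_x : int
        Polynomial degree N along the in-section coordinate (default 12).
    order_angle : int
        Polynomial degree M across section angles (default 5).

    Examples
    --------
    >>> model = RadialSurfaceModel.from_manifest("phantom/manifest.json")
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
    >>> res.predict(3.0, 0.5)         # height at x=3 mm, angle=0.5 rad  # doctest: +SKIP
    """

    def __init__(self, sections: SectionSet, order_x: int = 12, order_angle: int = 5):
        self.sections = sections
        self.order_x = int(order_x)
        self.order_angle = int(order_angle)
        if self.order_x < 1 or self.order_angle < 1:
            raise FitError("polynomial orders must be >= 1")

    @classmethod
    def from_manifest(cls, manifest, order_x: int = 12, order_angle: int = 5):
        from .io import read_section_set

        return cls(read_section_set(manifest), order_x=order_x, order_angle=order_angle)

    def fit(self, scale: bool = True) -> "SurfaceFitResult":
        A = build_matrix_A(self.sections, self.order_x, scale=scale)
        section_fits = tuple(
            SectionFit(angle=float(a), coeffs=row, order_n=self.order_x,
                       x_scale=A.x_scale,
                       rms_residual=float(np.sqrt(np.mean(
                           (npoly.polyval(_scaled(s.xs, A.x_scale), row) - s.zs) ** 2))))
            for a, row, s in zip(A.angles, A.values, self.sections)
        )
        surface = fit_coefficient_curves(A, self.order_angle)
        return SurfaceFitResult(model=self, surface=surface, matrix_A=A,
                                section_fits=section_fits)


@dataclass(frozen=True)
class SurfaceFitResult:
    """Fitted surface with residual diagnostics and convenience methods."""

    model: RadialSurfaceModel
    surface: SurfaceModel
    matrix_A: CoeffMatrixA
    section_fits: tuple
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> np.ndarray:
        """The coefficient matrix B, shape (N+1, M+1)."""
        return self.surface.B

    @property
    def rms_per_section(self) -> np.ndarray:
        """Residual RMS (mm) of the final surface against each section's samples."""
        if "rms_sec" not in self._cache:
            vals = []
            for sec in self.model.sections:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ExtrapolationWarning)
                    pred = eval_surface(self.surface, sec.xs, np.full_like(sec.xs, sec.angle))
                vals.append(float(np.sqrt(np.mean((pred - sec.zs) ** 2))))
            self._cache["rms_sec"] = np.array(vals)
        return self._cache["rms_sec"]

    @property
    def rms_global(self) -> float:
        """Residual RMS (mm) over all samples of all sections."""
        sq, n = 0.0, 0
        for sec, r in zip(self.model.sections, self.rms_per_section):
            sq += r * r * sec.n_samples
            n += sec.n_samples
        return float(np.sqrt(sq / n))

    def predict(self, x, y):
        """Height z (mm) at in-section coordinate x (mm) and angle y (rad)."""
        return eval_surface(self.surface, x, y)

    def to_mesh(self, domain=None, element_size: float = 0.4):
        """Triangulate the fitted surface (default: full disc it was fitted on)."""
        from .meshing import DiscDomain, mesh_from_model

        if domain is None:
            c, h = self.surface.x_scale
            domain = DiscDomain(radius=max(abs(c - h), abs(c + h)))
        return mesh_from_model(self.surface, domain, element_size)

    def save(self, basename):
        from .io import save_surface_model

        return save_surface_model(self.surface, basename)

    def summary(self) -> str:
        """Plain-text fit report in the spirit of statsmodels results."""
        lines = [
            "Two-layer polynomial surface fit",
            "=" * 44,
            f"sections:            {len(self.model.sections)}",
            f"samples total:       {sum(s.n_samples for s in self.model.sections)}",
            f"order N (x):         {self.model.order_x}",
            f"order M (angle):     {self.model.order_angle}",
            f"B matrix shape:      {self.params.shape[0]} x {self.params.shape[1]}",
            f"x scale (c, h):      ({self.surface.x_scale[0]:.6g}, {self.surface.x_scale[1]:.6g})",
            f"angle scale (c, h):  ({self.surface.y_scale[0]:.6g}, {self.surface.y_scale[1]:.6g})",
            "-" * 44,
            "per-section residual RMS (mm):",
        ]
        for sec, f, r in zip(self.model.sections, self.section_fits, self.rms_per_section):
            lines.append(
                f"  angle {np.degrees(sec.angle):7.2f} deg: "
                f"stage-1 {f.rms_residual:.3e}   surface {r:.3e}"
            )
        lines.append("-" * 44)
        lines.append(f"global surface RMS:  {self.rms_global:.3e} mm")
        return "\n".join(lines)

    def plot_sections(self, ax=None):
        """Overlay sampled sections and the fitted surface along each angle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sec in self.model.sections:
            ax.plot(sec.xs, sec.zs, ".", ms=3)
            xs = np.linspace(sec.xs.min(), sec.xs.max(), 200)
            ax.plot(xs, self.predict(xs, np.full_like(xs, sec.angle)),
                    label=f"{np.degrees(sec.angle):.0f} deg")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("z (mm)")
        ax.legend(fontsize=7)
        return ax
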