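"""Frequency-domain diffusion forward model for multi-wavelength NIRST.

Maps nodal chromophore/scattering images to predicted boundary data
``d = f(x)``: Beer-law spectral composition of the absorption coefficient,
a Mie-type power law for reduced scattering, a linear-triangle Galerkin FEM
solve of the frequency-domain diffusion equation

    -div( D grad Phi ) + (mua + i w/c) Phi = S,    D = 1/(3 (mua + mus')),

with a Robin (type-III) boundary condition for the tissue-air refractive
index mismatch, projection onto detector optodes, and reference-phantom
calibration of measured data.

Data space is (log-amplitude, phase): frequency-domain wavelengths contribute
both rows, continuous-wave wavelengths contribute log-amplitude only.  Phase
is stored as a positive delay (it grows with source-detector separation).

Sources and detectors share the same discrete operator: a normalized nodal
Gaussian (sigma 1 mm, i.e. roughly 2 mm full width) centered one transport
mean free path inside the boundary at the optode position.  Because the FEM
system matrix is complex symmetric, this makes source-detector reciprocity
exact up to solver tolerance.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import least_squares
from scipy.sparse.linalg import splu

from .phantom_synth import (AcquisitionSpec, ChromophorePhantom,
                            InvalidParameterError, Mesh, OptodeLayout,
                            TissueProperties)

__all__ = [
    "RangeError",
    "SolverError",
    "ConsistencyError",
    "ExtinctionTable",
    "DEFAULT_EXTINCTION",
    "OpticalProperties",
    "ChromophoreState",
    "MeasurementSet",
    "mua_from_chromophores",
    "musp_from_scatter",
    "optical_properties",
    "solve_fd_diffusion",
    "forward",
    "calibrate",
    "write_measurements",
    "read_measurements",
]

SPEED_OF_LIGHT_MM_S = 2.99792458e11
DEFAULT_TISSUE_INDEX = 1.33
DEFAULT_OUTSIDE_INDEX = 1.0
SOURCE_SIGMA_MM = 2.0
SCATTER_REFERENCE_NM = 785.0


class RangeError(ValueError):
    """Wavelength outside the supported 650-1000 nm band."""


class SolverError(RuntimeError):
    """The FEM system could not be solved (non-physical properties)."""


class ConsistencyError(ValueError):
    """Measurement sets disagree in wavelengths or pair tables."""


# --------------------------------------------------------------------------
# chromophore extinction spectra
# --------------------------------------------------------------------------

# Approximate literature compilation over 650-1000 nm.  Hemoglobin molar
# extinction (cm^-1 / M) follows the widely used compiled oxy/deoxy spectra
# (Prahl's tabulation); water absorption (mm^-1, pure water) follows
# Hale & Querry-type data; lipid specific absorption (mm^-1 at 100% lipid)
# follows van Veen-type measurements.  Values are smoothed to a coarse grid;
# interpolation is piecewise linear.
_TABLE_NM = np.array([650, 660, 680, 700, 720, 740, 750, 760, 780, 800,
                      820, 840, 850, 860, 880, 900, 920, 930, 950, 970, 1000],
                     dtype=float)
_HBO2_EXT_CM_M = np.array([368.0, 319.6, 277.6, 290.0, 334.7, 446.0, 518.0,
                           586.0, 710.0, 816.0, 916.0, 1022.0, 1058.0, 1092.0,
                           1154.0, 1198.0, 1226.0, 1236.0, 1220.0, 1160.0,
                           1058.0])
_HB_EXT_CM_M = np.array([3750.0, 3226.6, 2407.0, 1794.3, 1294.0, 1115.9,
                         1405.2, 1548.5, 1101.0, 761.7, 693.0, 692.4, 691.3,
                         696.1, 726.0, 761.0, 787.0, 790.0, 711.0, 672.0,
                         618.0])
_WATER_MM = np.array([0.00034, 0.00040, 0.00050, 0.00060, 0.00120, 0.00270,
                      0.00280, 0.00280, 0.00235, 0.00220, 0.00290, 0.00400,
                      0.00430, 0.00480, 0.00560, 0.00680, 0.01150, 0.01500,
                      0.03200, 0.04500, 0.03900])
_LIPID_MM = np.array([0.00010, 0.00009, 0.00008, 0.00009, 0.00010, 0.00011,
                      0.00012, 0.00013, 0.00011, 0.00010, 0.00014, 0.00020,
                      0.00027, 0.00032, 0.00040, 0.00065, 0.00160, 0.00280,
                      0.00045, 0.00060, 0.00120])

# cm^-1/M -> mm^-1/mM: ln(10) * 1e-3 (M->mM) * 0.1 (cm->mm)
_MOLAR_TO_MM_MM = np.log(10.0) * 1e-4


class ExtinctionTable:
    """Piecewise-linear chromophore absorption spectra.

    ``coefficient(name, wavelength)`` returns the absorption contribution per
    unit of the chromophore's concentration variable: mm^-1 per mM for
    hemoglobins, mm^-1 per unit volume fraction for water and lipid.
    """

    def __init__(self, wavelengths_nm=None, spectra=None):
        self.wavelengths_nm = (np.asarray(wavelengths_nm, float)
                               if wavelengths_nm is not None else _TABLE_NM)
        if spectra is None:
            spectra = {
                "hbo": _HBO2_EXT_CM_M * _MOLAR_TO_MM_MM,
                "hb": _HB_EXT_CM_M * _MOLAR_TO_MM_MM,
                "water": _WATER_MM,
                "lipid": _LIPID_MM,
            }
        self.spectra = {k: np.asarray(v, float) for k, v in spectra.items()}
        for name, vals in self.spectra.items():
            if (vals <= 0).any():
                raise InvalidParameterError(f"{name} spectrum must be positive")

    @property
    def support(self) -> tuple:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def coefficient(self, name: str, wavelength_nm: float) -> float:
        lo, hi = self.support
        if not lo <= wavelength_nm <= hi:
            raise RangeError(
                f"wavelength {wavelength_nm} nm outside table support [{lo}, {hi}]")
        return float(np.interp(wavelength_nm, self.wavelengths_nm,
                               self.spectra[name]))


DEFAULT_EXTINCTION = ExtinctionTable()


# --------------------------------------------------------------------------
# state and spectral maps
# --------------------------------------------------------------------------

CHROMOPHORE_FIELDS = ("hbo", "hb", "water", "lipid")
SCATTER_FIELDS = ("scatter_amplitude", "scatter_power")
ALL_FIELDS = CHROMOPHORE_FIELDS + SCATTER_FIELDS


@dataclass(frozen=True)
class ChromophoreState:
    """Nodal unknown vector of the reconstruction: chromophore concentrations
    (hbo/hb in mM, water/lipid as fractions) and scattering-law parameters.

    The flattened ordering convention used throughout is: for a given tuple
    of field names, concatenate the full nodal array of each field in order
    (``pack``/``with_packed``).
    """

    hbo: np.ndarray
    hb: np.ndarray
    water: np.ndarray
    lipid: np.ndarray
    scatter_amplitude: np.ndarray
    scatter_power: np.ndarray

    def __post_init__(self) -> None:
        n = len(np.asarray(self.hbo))
        for name in ALL_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise InvalidParameterError(f"{name} must have shape ({n},)")
            object.__setattr__(self, name, arr)
        if (self.hbo < 0).any() or (self.hb < 0).any():
            raise InvalidParameterError("concentrations must be non-negative")
        for name in ("water", "lipid"):
            v = getattr(self, name)
            if (v < 0).any() or (v > 1).any():
                raise InvalidParameterError(f"{name} must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.hbo)

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hb

    @classmethod
    def uniform(cls, n: int, props: TissueProperties) -> "ChromophoreState":
        return cls(**{name: np.full(n, getattr(props, name), dtype=float)
                      for name in ALL_FIELDS})

    @classmethod
    def from_phantom(cls, phantom: ChromophorePhantom) -> "ChromophoreState":
        return cls(**{name: np.asarray(getattr(phantom, name), float).copy()
                      for name in ALL_FIELDS})

    def pack(self, fields) -> np.ndarray:
        return np.concatenate([getattr(self, f) for f in fields])

    def with_packed(self, fields, vector: np.ndarray) -> "ChromophoreState":
        n = self.n_nodes
        parts = dict()
        for k, f in enumerate(fields):
            parts[f] = np.asarray(vector[k * n:(k + 1) * n], float)
        kwargs = {f: parts.get(f, getattr(self, f)) for f in ALL_FIELDS}
        return ChromophoreState(**kwargs)


def mua_from_chromophores(state: ChromophoreState, wavelength_nm: float,
                          table: ExtinctionTable = DEFAULT_EXTINCTION) -> np.ndarray:
    """Nodal absorption mua(lambda) = sum_c eps_c(lambda) C_c (mm^-1)."""
    mua = np.zeros(state.n_nodes)
    for name in CHROMOPHORE_FIELDS:
        mua += table.coefficient(name, wavelength_nm) * getattr(state, name)
    return mua


def musp_from_scatter(state: ChromophoreState, wavelength_nm: float,
                      reference_wavelength_nm: float = SCATTER_REFERENCE_NM
                      ) -> np.ndarray:
    """Nodal reduced scattering mus'(lambda) = a (lambda/lambda0)^-b (mm^-1)."""
    ratio = wavelength_nm / reference_wavelength_nm
    return state.scatter_amplitude * ratio ** (-state.scatter_power)


@dataclass(frozen=True)
class OpticalProperties:
    """Per-node absorption and reduced scattering at one wavelength."""

    mua: np.ndarray
    musp: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        mua = np.asarray(self.mua, float)
        musp = np.asarray(self.musp, float)
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)
        if (mua <= 0).any() or (musp <= 0).any():
            raise SolverError("optical properties must be strictly positive")
        if (musp / mua).min() < 10:
            warnings.warn("musp/mua < 10 somewhere: diffusion approximation "
                          "is questionable", stacklevel=2)


def optical_properties(state: ChromophoreState, wavelength_nm: float,
                       table: ExtinctionTable = DEFAULT_EXTINCTION
                       ) -> OpticalProperties:
    return OpticalProperties(mua=mua_from_chromophores(state, wavelength_nm, table),
                             musp=musp_from_scatter(state, wavelength_nm),
                             wavelength=wavelength_nm)


# --------------------------------------------------------------------------
# measurement container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementSet:
    """Boundary data for all wavelengths over an ordered source-detector
    pair table.

    ``log_amplitude`` and ``phase`` have shape (n_wavelengths, n_pairs);
    phase rows of CW wavelengths are NaN.  The real data vector used by
    calibration and reconstruction is, per wavelength, the log-amplitude
    block followed (for FD wavelengths) by the phase block.
    """

    wavelengths: tuple
    is_fd: tuple
    pairs: np.ndarray
    log_amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, int)
        la = np.asarray(self.log_amplitude, float)
        ph = np.asarray(self.phase, float)
        w, p = len(self.wavelengths), len(pairs)
        if la.shape != (w, p) or ph.shape != (w, p):
            raise ConsistencyError("log_amplitude/phase shape mismatch")
        object.__setattr__(self, "wavelengths", tuple(float(x) for x in self.wavelengths))
        object.__setattr__(self, "is_fd", tuple(bool(x) for x in self.is_fd))
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "log_amplitude", la)
        object.__setattr__(self, "phase", ph)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_data(self) -> int:
        return self.n_pairs * (len(self.wavelengths) + sum(self.is_fd))

    def as_vector(self) -> np.ndarray:
        blocks = []
        for w in range(len(self.wavelengths)):
            blocks.append(self.log_amplitude[w])
            if self.is_fd[w]:
                blocks.append(self.phase[w])
        return np.concatenate(blocks)

    def same_layout(self, other: "MeasurementSet") -> bool:
        return (self.wavelengths == other.wavelengths
                and self.is_fd == other.is_fd
                and np.array_equal(self.pairs, other.pairs))


def _require_same_layout(*sets: MeasurementSet) -> None:
    for other in sets[1:]:
        if not sets[0].same_layout(other):
            raise ConsistencyError(
                "measurement sets differ in wavelengths or pair table")


# --------------------------------------------------------------------------
# FEM machinery
# --------------------------------------------------------------------------

def _effective_reflection(n_rel: float) -> float:
    """Empirical internal-reflection coefficient for the Robin condition."""
    return (-1.440 / n_rel ** 2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel)


class FemContext:
    """Precomputed geometry, Robin boundary matrix and optode load vectors
    for repeated diffusion solves on one mesh/layout."""

    def __init__(self, mesh: Mesh, layout: OptodeLayout,
                 n_tissue: float = DEFAULT_TISSUE_INDEX,
                 n_outside: float = DEFAULT_OUTSIDE_INDEX,
                 source_sigma_mm: float = SOURCE_SIGMA_MM):
        self.mesh = mesh
        self.layout = layout
        self.n_tissue = n_tissue
        self.source_sigma_mm = source_sigma_mm

        tri = mesh.elements
        xy = mesh.nodes
        p = xy[tri]
        self.tri = tri
        area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                 - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        self.area = 0.5 * area2
        # linear shape-function gradients (constant per element)
        b = np.stack([p[:, 1, 1] - p[:, 2, 1],
                      p[:, 2, 1] - p[:, 0, 1],
                      p[:, 0, 1] - p[:, 1, 1]], axis=1) / area2[:, None]
        c = np.stack([p[:, 2, 0] - p[:, 1, 0],
                      p[:, 0, 0] - p[:, 2, 0],
                      p[:, 1, 0] - p[:, 0, 0]], axis=1) / area2[:, None]
        self.grad_dot = (np.einsum("ei,ej->eij", b, b)
                         + np.einsum("ei,ej->eij", c, c))        # (E,3,3)
        # third-order mass tensor: int phi_n phi_i phi_j = (A/60) P[n,i,j]
        P = np.array([[[6, 2, 2], [2, 2, 1], [2, 1, 2]],
                      [[2, 2, 1], [2, 6, 2], [1, 2, 2]],
                      [[2, 1, 2], [1, 2, 2], [2, 2, 6]]], dtype=float)
        self.mass_tensor = P / 60.0
        self.rows = np.repeat(tri, 3, axis=1).ravel()            # (9E,)
        self.cols = np.tile(tri, (1, 3)).ravel()

        n_rel = n_tissue / n_outside
        reff = _effective_reflection(n_rel)
        a_coef = (1.0 + reff) / (1.0 - reff)
        edges = mesh.boundary_edges()
        ell = np.hypot(*(xy[edges[:, 0]] - xy[edges[:, 1]]).T)
        scale = ell / (2.0 * a_coef)
        local = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        vals = scale[:, None, None] * local[None]
        r = np.repeat(edges, 2, axis=1).ravel()
        cidx = np.tile(edges, (1, 2)).ravel()
        n = mesh.n_nodes
        self.robin = sparse.coo_matrix(
            (vals.ravel(), (r, cidx)), shape=(n, n)).tocsr()

        # incidence matrix scattering (element, local node) -> global node
        e_count = len(tri)
        self.scatter = sparse.coo_matrix(
            (np.ones(3 * e_count),
             (np.arange(3 * e_count), tri.ravel())),
            shape=(3 * e_count, n)).tocsr()

        # unit mass matrix, for consistent (density -> load) conversion
        loc = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
        mvals = (self.area[:, None, None] * loc[None]).ravel()
        self.unit_mass = sparse.coo_matrix(
            (mvals, (self.rows, self.cols)), shape=(n, n)).tocsr()

    # -- loads ------------------------------------------------------------
    def source_vectors(self, musp: np.ndarray) -> np.ndarray:
        """Mass-consistent load per optode: a unit-strength Gaussian source
        density centered one transport mean free path inside the boundary
        (inward = toward the domain centroid).

        Using the consistent load M g (rather than a nodal point load) keeps
        the represented source density fixed under mesh refinement.
        """
        depth = 1.0 / float(np.mean(musp))
        centroid = self.mesh.nodes.mean(axis=0)
        q = np.empty((self.mesh.n_nodes, self.layout.n_optodes))
        for k, pos in enumerate(self.layout.positions):
            direction = centroid - pos
            norm = np.hypot(*direction)
            inner = pos + depth * direction / norm
            d2 = ((self.mesh.nodes - inner) ** 2).sum(axis=1)
            g = np.exp(-d2 / (2.0 * self.source_sigma_mm ** 2))
            load = self.unit_mass @ g
            q[:, k] = load / load.sum()
        return q

    # -- assembly and solve ------------------------------------------------
    def assemble(self, props: OpticalProperties, omega: float):
        mua = props.mua
        dcoef = 1.0 / (3.0 * (props.mua + props.musp))
        alpha = mua.astype(complex)
        if omega != 0.0:
            alpha = alpha + 1j * omega / (SPEED_OF_LIGHT_MM_S / self.n_tissue)
        dbar = dcoef[self.tri].mean(axis=1)
        stiff = (dbar * self.area)[:, None, None] * self.grad_dot
        mass = self.area[:, None, None] * np.einsum(
            "en,nij->eij", alpha[self.tri], self.mass_tensor)
        vals = (stiff + mass).ravel()
        n = self.mesh.n_nodes
        k = sparse.coo_matrix((vals, (self.rows, self.cols)), shape=(n, n))
        return (k + self.robin.astype(complex)).tocsc()

    def solve_all(self, props: OpticalProperties, omega: float):
        """LU-factorize and solve for every optode load; returns (Phi, Q, lu)
        with Phi of shape (n, k)."""
        k = self.assemble(props, omega)
        try:
            lu = splu(k)
        except RuntimeError as exc:
            raise SolverError(f"singular FEM system: {exc}") from exc
        q = self.source_vectors(props.musp)
        phi = lu.solve(q.astype(complex))
        if not np.isfinite(phi).all():
            raise SolverError("FEM solution is not finite")
        return phi, q, lu


def solve_fd_diffusion(mesh: Mesh, props: OpticalProperties,
                       layout: OptodeLayout, source_idx: int,
                       modulation_frequency: float) -> np.ndarray:
    """Nodal complex fluence for one source optode at one wavelength."""
    ctx = FemContext(mesh, layout)
    omega = 2.0 * np.pi * modulation_frequency
    phi, _q, _lu = ctx.solve_all(props, omega)
    return phi[:, source_idx]


# --------------------------------------------------------------------------
# forward operator
# --------------------------------------------------------------------------

def forward(state: ChromophoreState, mesh: Mesh, layout: OptodeLayout,
            acquisition: AcquisitionSpec,
            table: ExtinctionTable = DEFAULT_EXTINCTION,
            ctx: FemContext | None = None) -> MeasurementSet:
    """Predict boundary data for every wavelength and source-detector pair."""
    if state.n_nodes != mesh.n_nodes:
        raise ConsistencyError("state and mesh node counts differ")
    if ctx is None:
        ctx = FemContext(mesh, layout)
    pairs = layout.source_detector_pairs()
    wl = acquisition.wavelengths
    is_fd = acquisition.is_fd
    la = np.empty((len(wl), len(pairs)))
    ph = np.full((len(wl), len(pairs)), np.nan)
    for w, lam in enumerate(wl):
        props = optical_properties(state, lam, table)
        omega = 2 * np.pi * acquisition.modulation_frequency if is_fd[w] else 0.0
        try:
            phi, q, _lu = ctx.solve_all(props, omega)
        except SolverError as exc:
            raise SolverError(
                f"forward solve failed at {lam} nm: {exc}") from exc
        meas = q.T @ phi                      # (k, k): detector x source
        m = meas[pairs[:, 1], pairs[:, 0]]
        la[w] = np.log(np.abs(m))
        if is_fd[w]:
            # positive phase delay; delays are < 2*pi at breast scale and
            # 100 MHz, so reducing mod 2*pi unwraps exactly
            ph[w] = np.mod(-np.angle(m), 2.0 * np.pi)
    return MeasurementSet(wavelengths=wl, is_fd=is_fd, pairs=pairs,
                          log_amplitude=la, phase=ph)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibrate(measured: MeasurementSet,
              reference_measured: MeasurementSet,
              reference_model: MeasurementSet,
              mesh: Mesh, layout: OptodeLayout, acquisition: AcquisitionSpec,
              base: TissueProperties | None = None,
              fit_fields: tuple = ("hbo", "hb", "water"),
              table: ExtinctionTable = DEFAULT_EXTINCTION):
    """Reference-phantom calibration plus a homogeneous initial estimate.

    The measured data are corrected by the instrument offset estimated from a
    reference phantom, ``calibrated = measured - (reference_measured -
    reference_model)`` in (log-amplitude, phase) space.  A single uniform
    chromophore state is then fit to the calibrated data by nonlinear least
    squares, providing the initial estimate for iterative reconstruction.
    """
    _require_same_layout(measured, reference_measured, reference_model)
    la = (measured.log_amplitude
          - (reference_measured.log_amplitude - reference_model.log_amplitude))
    ph = measured.phase - (reference_measured.phase - reference_model.phase)
    calibrated = dataclasses.replace(measured, log_amplitude=la, phase=ph)

    if base is None:
        base = TissueProperties()
    target = calibrated.as_vector()
    n = mesh.n_nodes
    ctx = FemContext(mesh, layout)

    x0 = np.array([getattr(base, f) for f in fit_fields], float)
    upper = np.array([1.0 if f in ("water", "lipid") else np.inf
                      for f in fit_fields])

    def residual(x):
        props = dataclasses.replace(
            base, **{f: float(v) for f, v in zip(fit_fields, x)})
        st = ChromophoreState.uniform(n, props)
        pred = forward(st, mesh, layout, acquisition, table, ctx=ctx)
        return pred.as_vector() - target

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(residual, x0, bounds=(1e-6, upper),
                            x_scale=np.abs(x0) + 1e-3, xtol=1e-12, ftol=1e-12)
    props = dataclasses.replace(
        base, **{f: float(v) for f, v in zip(fit_fields, res.x)})
    return calibrated, ChromophoreState.uniform(n, props)


# --------------------------------------------------------------------------
# CSV interface (bit-exact round trip)
# --------------------------------------------------------------------------

def write_measurements(ms: MeasurementSet, path) -> None:
    """CSV: wavelength_nm, source, detector, log_amplitude, phase_rad
    (phase empty for CW rows); 1-based optode indices."""
    rows = []
    for w, lam in enumerate(ms.wavelengths):
        for p, (s, d) in enumerate(ms.pairs):
            phase = ms.phase[w, p] if ms.is_fd[w] else None
            rows.append((lam, s + 1, d + 1, ms.log_amplitude[w, p], phase))
    df = pd.DataFrame(rows, columns=["wavelength_nm", "source", "detector",
                                     "log_amplitude", "phase_rad"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path) -> MeasurementSet:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    wl = tuple(sorted(df["wavelength_nm"].unique()))
    first = df[df["wavelength_nm"] == wl[0]]
    pairs = first[["source", "detector"]].to_numpy(int) - 1
    npairs = len(pairs)
    la = np.empty((len(wl), npairs))
    ph = np.full((len(wl), npairs), np.nan)
    is_fd = []
    for w, lam in enumerate(wl):
        sub = df[df["wavelength_nm"] == lam]
        la[w] = sub["log_amplitude"].to_numpy()
        fd = sub["phase_rad"].notna().all()
        is_fd.append(bool(fd))
        if fd:
            ph[w] = sub["phase_rad"].to_numpy()
    return MeasurementSet(wavelengths=wl, is_fd=tuple(is_fd), pairs=pairs,
                          log_amplitude=la, phase=ph)
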