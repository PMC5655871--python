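"""Iterative spectral NIRST reconstruction with a grayscale-prior penalty.

Each iteration linearizes the forward model at the current chromophore image
x and applies the regularized update

    dx_k = (J_k^T J_k + lambda L^T L)^-1 J_k^T (d - f(x_{k-1})),
    lambda = lambda_scale * max(diag(J_k^T J_k)),

where J_k is the Jacobian of the (log-amplitude, phase) data with respect to
the nodal unknowns, assembled by the adjoint method and chained through the
spectral maps, and L is the grayscale-weighted matrix of
:mod:`mrnirst.prior_regularization`, applied block-diagonally (one block per
unknown field).  Updates are projected to physical bounds after each step.

All wavelengths are fitted jointly and the unknowns are the chromophore
images directly (not per-wavelength absorption).  By default the unknown
fields are (hbo, hb, water); lipid and the scattering-law parameters stay at
their calibrated homogeneous values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from . import forward_model as fm
from .phantom_synth import AcquisitionSpec, Mesh, OptodeLayout
from .prior_regularization import (PriorWeights, RegularizationParams,
                                   regularization_lambda)

__all__ = [
    "IllConditionedError",
    "UpdateResult",
    "ReconstructionResult",
    "DEFAULT_UNKNOWNS",
    "compute_jacobian",
    "update_step",
    "reconstruct",
    "write_result",
]

DEFAULT_UNKNOWNS = ("hbo", "hb", "water")


class IllConditionedError(np.linalg.LinAlgError):
    """The damped normal equations could not be solved reliably."""


# --------------------------------------------------------------------------
# Jacobian (adjoint method)
# --------------------------------------------------------------------------

def _jacobian_blocks(state: fm.ChromophoreState, ctx: fm.FemContext,
                     acquisition: AcquisitionSpec, table: fm.ExtinctionTable):
    """Complex sensitivities d(log m)/d(mua_n) and d(log m)/d(musp_n) per
    wavelength, plus the predicted complex log data.

    Because source and detection use the same load vectors and the system is
    complex symmetric, the adjoint fields are the already-computed forward
    fields: d m / d p = -Psi_d^T (dK/dp) Phi_s.
    """
    mesh, layout = ctx.mesh, ctx.layout
    pairs = layout.source_detector_pairs()
    tri = ctx.tri
    area = ctx.area
    out = []
    for w, lam in enumerate(acquisition.wavelengths):
        props = fm.optical_properties(state, lam, table)
        omega = (2 * np.pi * acquisition.modulation_frequency
                 if acquisition.is_fd[w] else 0.0)
        phi, q, _lu = ctx.solve_all(props, omega)
        meas = (q.T @ phi)[pairs[:, 1], pairs[:, 0]]      # (P,)

        el = phi[tri]                                      # (E, 3, k)
        phi_p = el[:, :, pairs[:, 0]]                      # (E, 3, P)
        psi_p = el[:, :, pairs[:, 1]]

        # mass term: dK/dmua_n = A_e * mass_tensor[l] on elements with node n
        mass_out = np.einsum("eip,lij,ejp->pel", psi_p, ctx.mass_tensor, phi_p)
        mass_out *= -area[None, :, None]
        j_mass = (ctx.scatter.T @ mass_out.reshape(len(pairs), -1).T).T

        # diffusion term: dK/dD_n = (A_e/3) G_e; dD/dmua = dD/dmusp = -3 D^2
        g = np.einsum("eip,eij,ejp->pe", psi_p, ctx.grad_dot, phi_p)
        g *= -area[None, :] / 3.0
        g_flat = np.repeat(g, 3, axis=1)
        j_geom = (ctx.scatter.T @ g_flat.T).T              # (P, n)
        dcoef = 1.0 / (3.0 * (props.mua + props.musp))
        dd = -3.0 * dcoef ** 2
        j_geom = j_geom * dd[None, :]

        j_mua = (j_mass + j_geom) / meas[:, None]
        j_musp = j_geom / meas[:, None]
        out.append((lam, acquisition.is_fd[w], j_mua, j_musp))
    return out


def compute_jacobian(state: fm.ChromophoreState, mesh: Mesh,
                     layout: OptodeLayout, acquisition: AcquisitionSpec,
                     unknowns: tuple = DEFAULT_UNKNOWNS,
                     table: fm.ExtinctionTable = fm.DEFAULT_EXTINCTION,
                     ctx: fm.FemContext | None = None) -> np.ndarray:
    """Real Jacobian of the data vector with respect to the flattened nodal
    unknowns; rows follow the MeasurementSet vector ordering (per wavelength:
    log-amplitude rows, then phase rows for FD channels)."""
    if ctx is None:
        ctx = fm.FemContext(mesh, layout)
    blocks = _jacobian_blocks(state, ctx, acquisition, table)
    n = state.n_nodes
    rows = []
    for lam, is_fd, j_mua, j_musp in blocks:
        ratio = lam / fm.SCATTER_REFERENCE_NM
        cols = []
        for f in unknowns:
            if f in fm.CHROMOPHORE_FIELDS:
                cols.append(table.coefficient(f, lam) * j_mua)
            elif f == "scatter_amplitude":
                factor = ratio ** (-state.scatter_power)
                cols.append(j_musp * factor[None, :])
            elif f == "scatter_power":
                musp = fm.musp_from_scatter(state, lam)
                cols.append(j_musp * (-np.log(ratio) * musp)[None, :])
            else:
                raise fm.ConsistencyError(f"unknown field {f!r}")
        jc = np.concatenate(cols, axis=1)                  # complex (P, m*n)
        rows.append(jc.real)                               # log-amplitude
        if is_fd:
            rows.append(-jc.imag)                          # phase delay
    jac = np.concatenate(rows, axis=0)
    if not np.isfinite(jac).all():
        raise fm.SolverError("Jacobian contains non-finite entries")
    return jac


# --------------------------------------------------------------------------
# update equation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UpdateResult:
    state: fm.ChromophoreState
    misfit: float
    lambda_value: float
    delta: np.ndarray


def _project_packed(vector: np.ndarray, unknowns, n: int) -> np.ndarray:
    """Clip each unknown block of the packed update to its physical bounds."""
    out = vector.copy()
    for k, f in enumerate(unknowns):
        sl = slice(k * n, (k + 1) * n)
        if f in ("hbo", "hb"):
            out[sl] = np.clip(out[sl], 0.0, None)
        elif f in ("water", "lipid"):
            out[sl] = np.clip(out[sl], 1e-6, 1.0)
        elif f == "scatter_amplitude":
            out[sl] = np.clip(out[sl], 1e-3, None)
    return out


def update_step(state: fm.ChromophoreState, d: fm.MeasurementSet,
                weights: PriorWeights, mesh: Mesh, layout: OptodeLayout,
                acquisition: AcquisitionSpec,
                reg_params: RegularizationParams | None = None,
                unknowns: tuple = DEFAULT_UNKNOWNS,
                lambda_value: float | None = None,
                table: fm.ExtinctionTable = fm.DEFAULT_EXTINCTION,
                ctx: fm.FemContext | None = None) -> UpdateResult:
    """One regularized Gauss-Newton step of the update equation, with the
    grayscale penalty applied block-diagonally over the unknown fields."""
    if reg_params is None:
        reg_params = RegularizationParams()
    if ctx is None:
        ctx = fm.FemContext(mesh, layout)
    predicted = fm.forward(state, mesh, layout, acquisition, table, ctx=ctx)
    if not d.same_layout(predicted):
        raise fm.ConsistencyError("data and model measurement layouts differ")
    residual = d.as_vector() - predicted.as_vector()
    jac = compute_jacobian(state, mesh, layout, acquisition, unknowns,
                           table, ctx=ctx)
    lam = (regularization_lambda(jac, reg_params)
           if lambda_value is None else float(lambda_value))

    n = state.n_nodes
    m = len(unknowns)
    hess = jac.T @ jac
    ltl = (weights.L.T @ weights.L).toarray()
    for k in range(m):
        sl = slice(k * n, (k + 1) * n)
        hess[sl, sl] += lam * ltl
    rhs = jac.T @ residual
    try:
        cho = sla.cho_factor(hess, check_finite=False)
        delta = sla.cho_solve(cho, rhs, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise IllConditionedError(
            f"normal equations not positive definite "
            f"(cond ~ {np.linalg.cond(hess):.3e})") from exc

    new_vec = _project_packed(state.pack(unknowns) + delta, unknowns, n)
    new_state = state.with_packed(unknowns, new_vec)
    new_pred = fm.forward(new_state, mesh, layout, acquisition, table, ctx=ctx)
    misfit = float(np.sum((d.as_vector() - new_pred.as_vector()) ** 2))
    return UpdateResult(state=new_state, misfit=misfit, lambda_value=lam,
                        delta=delta)


# --------------------------------------------------------------------------
# outer iteration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconstructionResult:
    state: fm.ChromophoreState
    misfits: tuple          # misfit trajectory, starting with the initial one
    lambdas: tuple          # lambda used at each iteration
    iterations: int
    converged: bool
    diverged: bool


def reconstruct(d: fm.MeasurementSet, initial: fm.ChromophoreState,
                weights: PriorWeights, mesh: Mesh, layout: OptodeLayout,
                acquisition: AcquisitionSpec,
                reg_params: RegularizationParams | None = None,
                unknowns: tuple = DEFAULT_UNKNOWNS,
                max_iterations: int = 15,
                tolerance: float = 0.02,
                lambda_policy: str = "per_iteration",
                table: fm.ExtinctionTable = fm.DEFAULT_EXTINCTION
                ) -> ReconstructionResult:
    """Iterate the regularized update until the relative misfit change drops
    below ``tolerance`` (default 2%) or ``max_iterations`` is reached.

    ``lambda_policy`` is "per_iteration" (recompute the regularization
    parameter from the current Jacobian each step) or "first" (compute it
    once at the first iteration and hold it fixed).  Divergence (misfit
    growing three iterations in a row) yields a flagged, non-converged
    result holding the best state seen, not an exception.
    """
    if lambda_policy not in ("per_iteration", "first"):
        raise ValueError("lambda_policy must be 'per_iteration' or 'first'")
    ctx = fm.FemContext(mesh, layout)
    pred0 = fm.forward(initial, mesh, layout, acquisition, table, ctx=ctx)
    misfit_prev = float(np.sum((d.as_vector() - pred0.as_vector()) ** 2))
    misfits = [misfit_prev]
    lambdas = []
    state = initial
    best_state, best_misfit = initial, misfit_prev
    converged = False
    diverged = False
    grow_streak = 0
    fixed_lambda = None
    for _k in range(max_iterations):
        step = update_step(state, d, weights, mesh, layout, acquisition,
                           reg_params=reg_params, unknowns=unknowns,
                           lambda_value=fixed_lambda, table=table, ctx=ctx)
        if lambda_policy == "first" and fixed_lambda is None:
            fixed_lambda = step.lambda_value
        state = step.state
        misfits.append(step.misfit)
        lambdas.append(step.lambda_value)
        if step.misfit < best_misfit:
            best_state, best_misfit = state, step.misfit
        if step.misfit > misfit_prev:
            grow_streak += 1
            if grow_streak >= 3:
                diverged = True
                break
        else:
            grow_streak = 0
        if step.misfit < 1e-14 or (misfit_prev > 0 and
                                   abs(misfit_prev - step.misfit) / misfit_prev
                                   < tolerance):
            converged = True
            misfit_prev = step.misfit
            break
        misfit_prev = step.misfit
    final = best_state if diverged else state
    return ReconstructionResult(state=final, misfits=tuple(misfits),
                                lambdas=tuple(lambdas),
                                iterations=len(lambdas),
                                converged=converged, diverged=diverged)


def write_result(result: ReconstructionResult, json_path, maps_dir) -> None:
    """Serialize scalars/trajectory to JSON and nodal maps (including HbT) to
    per-field CSV files (node_id, value)."""
    from pathlib import Path

    payload = {
        "iterations": result.iterations,
        "converged": result.converged,
        "diverged": result.diverged,
        "misfits": list(result.misfits),
        "lambdas": list(result.lambdas),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2))
    maps_dir = Path(maps_dir)
    maps_dir.mkdir(parents=True, exist_ok=True)
    fields = {f: getattr(result.state, f) for f in fm.ALL_FIELDS}
    fields["hbt"] = result.state.hbt
    for name, values in fields.items():
        df = pd.DataFrame({"node_id": np.arange(1, len(values) + 1),
                           "value": values})
        df.to_csv(maps_dir / f"{name}.csv", index=False, float_format="%.17g")
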