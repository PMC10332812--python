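"""Flux estimation from MIDs and extracellular fluxes.

Weighted least squares against measured mass isotopomer distributions and
extracellular fluxes over the free-flux parameterization of the network,
with multi-start optimization, a chi-square goodness-of-fit test on the
variance-weighted sum of squared residuals (SSR), and SSR-sensitivity
confidence intervals (scan a flux, re-optimize everything else, bound where
SSR exceeds the minimum by the chi-square 1-dof 95% increment of 3.84).

The steady-state residual model carries analytic EMU sensitivities: the
per-size linear systems are differentiated exactly (dX = A^{-1}(dB - dA X),
propagated through convolutions by the product rule), which makes the
Jacobian a by-product of each simulation instead of ~P extra simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares

from .emu import EMU, emu_decomposition
from .network import EXCHANGE_CAP, FluxMap, Network, free_flux_parameterization
from .tracers import InputLabeling, TracerSpec

__all__ = [
    "MeasurementSet",
    "FitOptions",
    "FitResult",
    "compute_ssr",
    "chi2_acceptance_interval",
    "fit_fluxes",
    "confidence_intervals",
    "flux_ratio_table",
    "growth_normalized_fluxes",
    "SteadyStateModel",
]

#: default floor on MID fraction standard deviations (mol fraction)
MID_SD_FLOOR = 0.003
#: chi-square(1) 95% increment used for single-parameter SSR-scan intervals
CI_DELTA_SSR = 3.84
_PENALTY = 1.0e3
#: smoothing half-width (fmol/cell/h) for the net-flux sign split
_SMOOTH_EPS = 1.0e-3


# ---------------------------------------------------------------------------
# measurements


@dataclass
class MeasurementSet:
    """Aligned observations for one fit.

    ``mids``: columns experiment, metabolite, mass_shift, fraction, sd.
    ``fluxes``: columns reaction, value, sd (growth rate enters as the
    biomass reaction).  ``tracers`` maps experiment name to tracer specs.
    """

    mids: pd.DataFrame
    fluxes: pd.DataFrame
    tracers: dict[str, list[TracerSpec]]

    def __post_init__(self):
        need = {"experiment", "metabolite", "mass_shift", "fraction", "sd"}
        if not need <= set(self.mids.columns):
            raise ValueError(f"mids table needs columns {sorted(need)}")
        if np.any(self.mids["sd"] <= 0) or np.any(self.fluxes["sd"] <= 0):
            raise ValueError("all measurement SDs must be positive")
        unknown = set(self.mids["experiment"]) - set(self.tracers)
        if unknown:
            raise ValueError(f"experiments without tracer specs: {sorted(unknown)}")

    @classmethod
    def from_replicate_tables(
        cls,
        mid_table: pd.DataFrame,
        flux_table: pd.DataFrame,
        tracers: dict[str, list[TracerSpec]],
        sd_floor: float = MID_SD_FLOOR,
    ) -> "MeasurementSet":
        """Aggregate replicate MID rows to means with floored SDs."""
        g = mid_table.groupby(["experiment", "metabolite", "mass_shift"])["fraction"]
        agg = g.agg(["mean", "std"]).reset_index()
        agg["std"] = agg["std"].fillna(0.0).clip(lower=sd_floor)
        agg = agg.rename(columns={"mean": "fraction", "std": "sd"})
        return cls(mids=agg, fluxes=flux_table.copy(), tracers=tracers)

    @property
    def n_residuals(self) -> int:
        return len(self.mids) + len(self.fluxes)


def compute_ssr(simulated: np.ndarray, measured: np.ndarray, sds: np.ndarray) -> float:
    """Variance-weighted sum of squared residuals."""
    simulated = np.asarray(simulated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if simulated.shape != measured.shape or simulated.shape != sds.shape:
        raise ValueError("simulated, measured and sds must align")
    return float(np.sum(((simulated - measured) / sds) ** 2))


def chi2_acceptance_interval(dof: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided chi-square acceptance interval for the SSR at ``dof``."""
    if dof < 1:
        raise ValueError("degrees of freedom must be >= 1")
    lo = stats.chi2.ppf(alpha / 2.0, dof)
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, dof)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# steady-state residual model with analytic sensitivities


class SteadyStateModel:
    """Residual vector (and exact Jacobian) for steady-state MFA fitting."""

    def __init__(self, network: Network, measurements: MeasurementSet):
        self.network = network
        self.meas = measurements
        self.basis = free_flux_parameterization(network)
        observed = sorted(set(measurements.mids["metabolite"]))
        self.system = emu_decomposition(network, [(m, None) for m in observed])
        self.obs_emu = {e.metabolite: e for e in self.system.observed}

        # --- parameter layout
        b = self.basis
        self.n_params = b.n_params
        self._nf, self._ne, self._nm = b.n_free_net, b.n_exchange, b.n_mixing
        self._Jnet = b.net_jacobian()  # (n_reactions, n_free) constant
        self._rxn_index = {rid: j for j, rid in enumerate(b.reaction_order)}
        self._exch_index = {rid: j for j, rid in enumerate(b.exchange_ids)}
        self._reversible = {r.id for r in network.all_reactions() if r.reversible}

        # mixing layout: params are the first len(group)-1 weights; the last
        # weight is 1 - sum and carries gradient -1 on each group parameter
        self._mix_grad: dict[str, list[tuple[int, float]]] = {}
        self._mix_value: dict[str, tuple[list[int], bool]] = {}
        k = 0
        for _, rids in b.mixing_groups.items():
            idxs = [self._nf + self._ne + k + i for i in range(len(rids) - 1)]
            for i, rid in enumerate(rids[:-1]):
                self._mix_value[rid] = ([idxs[i]], False)
                self._mix_grad[rid] = [(idxs[i], 1.0)]
            self._mix_value[rids[-1]] = (idxs, True)
            self._mix_grad[rids[-1]] = [(p, -1.0) for p in idxs]
            k += len(rids) - 1
        grouped = {x for g in b.mixing_groups.values() for x in g}
        self._sink_rids = {r.id for r in network.mixing if r.id not in grouped}

        # --- unidirectional rate table
        self.rate_keys: list[tuple[str, int]] = []
        for r in network.all_flux_entries():
            self.rate_keys.append((r.id, 1))
            if r.reversible:
                self.rate_keys.append((r.id, -1))
        self.rate_index = {key: i for i, key in enumerate(self.rate_keys)}

        # --- per-size compiled structure (integer-indexed, for vectorized
        # assembly of A, B and their parameter derivatives).  EMU references
        # are resolved to ("inp", k) or (size, row) pairs at compile time.
        self.sizes = self.system.sizes
        self.input_order = list(self.system.inputs)
        self._input_pos = {e: k for k, e in enumerate(self.input_order)}
        layer_index = {
            size: {e: i for i, e in enumerate(self.system.layers[size])}
            for size in self.sizes
        }

        def ref(emu):
            if emu in self._input_pos:
                return ("inp", self._input_pos[emu], emu.size + 1)
            return (emu.size, layer_index[emu.size][emu], emu.size + 1)

        self.compiled = {}
        for size in self.sizes:
            emus = self.system.layers[size]
            index = layer_index[size]
            diag = []
            internal = []
            source = []  # (i, rate_idx, coef, [refs])
            for i, e in enumerate(emus):
                for rid, d, coef in self.system.consumption[e.metabolite]:
                    diag.append((i, self.rate_index[(rid, d)], coef))
                for term in self.system.producers[e]:
                    ridx = self.rate_index[(term.reaction, term.direction)]
                    c = term.weight * term.coef
                    if len(term.sources) == 1 and term.sources[0] in index:
                        internal.append((i, index[term.sources[0]], ridx, c))
                    else:
                        source.append((i, ridx, c, [ref(s) for s in term.sources]))
            entries = []  # (row_of_dRHS, rate_idx, +/-coef, ('X', row) )
            diag_a = (
                np.array([r[0] for r in diag], dtype=int),
                np.array([r[1] for r in diag], dtype=int),
                np.array([r[2] for r in diag], dtype=float),
            )
            int_a = (
                np.array([r[0] for r in internal], dtype=int),
                np.array([r[1] for r in internal], dtype=int),
                np.array([r[2] for r in internal], dtype=int),
                np.array([r[3] for r in internal], dtype=float),
            ) if internal else None
            src_i = np.array([r[0] for r in source], dtype=int)
            src_r = np.array([r[1] for r in source], dtype=int)
            src_c = np.array([r[2] for r in source], dtype=float)
            self.compiled[size] = (emus, index, diag_a, int_a, source, src_i, src_r, src_c)

        # --- input labeling per experiment (arrays in input_order)
        carbon = {e.metabolite: network.carbon_count(e.metabolite) for e in self.system.inputs}
        self.exp_inputs: dict[str, list[np.ndarray]] = {}
        for exp, specs in measurements.tracers.items():
            lab = InputLabeling.from_tracers(specs, carbon)
            self.exp_inputs[exp] = [
                lab.emu_mid(e.metabolite, e.atoms) for e in self.input_order
            ]

        # --- measurement row bookkeeping
        mids = measurements.mids.sort_values(
            ["experiment", "metabolite", "mass_shift"]
        ).reset_index(drop=True)
        self.mid_rows = mids
        self._mid_plan = []
        for (exp, met), grp in mids.groupby(["experiment", "metabolite"], sort=True):
            emu = self.obs_emu[met]
            self._mid_plan.append(
                (
                    exp,
                    (emu.size, layer_index[emu.size][emu]),
                    grp["mass_shift"].to_numpy(dtype=int),
                    grp["fraction"].to_numpy(dtype=float),
                    grp["sd"].to_numpy(dtype=float),
                )
            )
        self.flux_rows = measurements.fluxes.reset_index(drop=True)
        self._flux_plan = [
            (self._rxn_index[r["reaction"]], float(r["value"]), float(r["sd"]))
            for _, r in self.flux_rows.iterrows()
        ]
        for rid in self.flux_rows["reaction"]:
            if rid not in self._rxn_index:
                raise ValueError(f"flux observation on unknown reaction {rid!r}")
        self.n_meas = len(mids) + len(self.flux_rows)
        # penalty rows: irreversible reactions that can go negative
        self._irrev = [
            self._rxn_index[r.id]
            for r in network.all_reactions()
            if not r.reversible
        ]

    # -- parameter/rate plumbing -------------------------------------------

    def rates(self, theta: np.ndarray, need_jac: bool):
        th_net = theta[: self._nf]
        th_ex = theta[self._nf : self._nf + self._ne]
        v = self._Jnet @ th_net
        exch = np.clip(10.0**th_ex, 0.0, EXCHANGE_CAP)
        R = np.empty(len(self.rate_keys))
        dR = np.zeros((len(self.rate_keys), self.n_params)) if need_jac else None
        for i, (rid, d) in enumerate(self.rate_keys):
            if rid in self._mix_value:
                idxs, is_last = self._mix_value[rid]
                if is_last:
                    R[i] = 1.0 - sum(theta[p] for p in idxs)
                else:
                    R[i] = theta[idxs[0]]
                if need_jac:
                    for p, g in self._mix_grad[rid]:
                        dR[i, p] = g
                continue
            if rid in self._sink_rids:
                R[i] = 1.0
                continue
            j = self._rxn_index[rid]
            vj = v[j]
            e = exch[self._exch_index[rid]] if rid in self._exch_index else 0.0
            # smoothed positive part keeps the Jacobian continuous where a
            # reversible net flux changes sign (the eps/2 residual
            # bidirectional flux is far below measurement noise)
            s = np.hypot(vj, _SMOOTH_EPS)
            if d == 1:
                R[i] = 0.5 * (vj + s) + e
                dv = 0.5 * (1.0 + vj / s)
            else:
                R[i] = 0.5 * (-vj + s) + e
                dv = 0.5 * (-1.0 + vj / s)
            if need_jac:
                if dv:
                    dR[i, : self._nf] = dv * self._Jnet[j]
                if rid in self._exch_index:
                    ke = self._exch_index[rid]
                    dR[i, self._nf + ke] = np.log(10.0) * exch[ke]
        return R, dR, v

    # -- forward simulation with optional sensitivities ---------------------

    def simulate(self, theta: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Simulated MIDs of the observed metabolites per experiment."""
        R, _, _ = self.rates(theta, need_jac=False)
        results = {}
        for exp, inputs in self.exp_inputs.items():
            X, _ = self._solve_experiment(R, None, inputs, False)
            results[exp] = {
                met: X[emu.size][self.compiled[emu.size][1][emu]].copy()
                for met, emu in self.obs_emu.items()
            }
        return results

    def _solve_experiment(self, R, dR, inputs, need_jac):
        X: dict = {}  # size -> (n, size+1) solved layer
        dX: dict = {}  # size -> (n, size+1, P) sensitivities
        P = self.n_params

        def vec(ref):
            kind, idx, _ = ref
            return inputs[idx] if kind == "inp" else X[kind][idx]

        def dvec(ref):
            kind, idx, _ = ref
            return None if kind == "inp" else dX[kind][idx]

        for size in self.sizes:
            emus, index, diag_a, int_a, source, src_i, src_r, src_c = self.compiled[size]
            di, dr, dc = diag_a
            n, w = len(emus), size + 1
            A = np.zeros((n, n))
            np.subtract.at(A, (di, di), dc * R[dr])
            if int_a is not None:
                ii, jj, ir, ic = int_a
                np.add.at(A, (ii, jj), ic * R[ir])
            B = np.zeros((n, w))
            src_mids = np.empty((len(source), w))
            for k, (i, ridx, coef, refs) in enumerate(source):
                mid = vec(refs[0])
                for s in refs[1:]:
                    mid = np.convolve(mid, vec(s))
                src_mids[k] = mid
            if len(source):
                np.subtract.at(B, src_i, (src_c * R[src_r])[:, None] * src_mids)
            # tiny ridge keeps zero-throughput EMUs finite at pathological
            # parameter values visited by random restarts
            ridge = 1e-10 * max(np.abs(np.diag(A)).max(), 1.0) + 1e-12
            A[np.diag_indices(n)] -= ridge
            lu = lu_factor(A, check_finite=False)
            Xs = lu_solve(lu, B, check_finite=False)
            if need_jac:
                dRHS = np.zeros((n, w, P))
                # d(-B): df * mid part, vectorized over source entries
                if len(source):
                    contrib = np.einsum("ew,ep->ewp", src_mids, dc_dr(src_c, dR, src_r))
                    np.subtract.at(dRHS, src_i, contrib)
                # d(-B): f * dmid part (convolution product rule)
                for (i, ridx, coef, refs) in source:
                    fr = coef * R[ridx]
                    if fr == 0.0:
                        continue
                    for j, s in enumerate(refs):
                        ds = dvec(s)
                        if ds is None:
                            continue
                        other = None
                        for kk, s2 in enumerate(refs):
                            if kk == j:
                                continue
                            v2 = vec(s2)
                            other = v2 if other is None else np.convolve(other, v2)
                        T = _conv_operator(other, w, s[2])
                        dRHS[i] -= fr * (T @ ds)
                # dA X terms
                np.add.at(dRHS, di, np.einsum("ew,ep->ewp", Xs[di], dc_dr(dc, dR, dr)))
                if int_a is not None:
                    np.subtract.at(
                        dRHS, ii, np.einsum("ew,ep->ewp", Xs[jj], dc_dr(ic, dR, ir))
                    )
                # dRHS accumulates dB - dA X, so dX = A^{-1} dRHS
                sol = lu_solve(lu, dRHS.reshape(n, w * P), check_finite=False)
                dX[size] = sol.reshape(n, w, P)
            X[size] = Xs
        return (X, dX) if need_jac else (X, None)

    # -- residuals ----------------------------------------------------------

    def residuals(self, theta: np.ndarray, need_jac: bool = False):
        R, dR, v = self.rates(theta, need_jac)
        r = np.empty(self.n_meas + len(self._irrev))
        J = np.zeros((r.size, self.n_params)) if need_jac else None
        row = 0
        sims = {}
        for exp, inputs in self.exp_inputs.items():
            sims[exp] = self._solve_experiment(R, dR, inputs, need_jac)
        for exp, (size, idx), shifts, y, sd in self._mid_plan:
            X, dX = sims[exp]
            k = shifts.size
            r[row : row + k] = (X[size][idx][shifts] - y) / sd
            if need_jac:
                J[row : row + k] = dX[size][idx][shifts] / sd[:, None]
            row += k
        for j, val, sd in self._flux_plan:
            r[row] = (v[j] - val) / sd
            if need_jac:
                J[row, : self._nf] = self._Jnet[j] / sd
            row += 1
        for j in self._irrev:
            r[row] = _PENALTY * min(v[j], 0.0)
            if need_jac and v[j] < 0:
                J[row, : self._nf] = _PENALTY * self._Jnet[j]
            row += 1
        r = np.nan_to_num(r, nan=1e8, posinf=1e8, neginf=-1e8)
        if need_jac:
            J = np.nan_to_num(J, nan=0.0, posinf=0.0, neginf=0.0)
        return (r, J) if need_jac else r

    def ssr(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(np.sum(r[: self.n_meas] ** 2))

    def default_bounds(self, flux_cap: float = 2.0e4):
        lb = np.empty(self.n_params)
        ub = np.empty(self.n_params)
        for i, rid in enumerate(self.basis.free_ids):
            rev = rid in self._reversible
            lb[i] = -flux_cap if rev else 0.0
            ub[i] = flux_cap
        lb[self._nf : self._nf + self._ne] = -3.0
        ub[self._nf : self._nf + self._ne] = np.log10(EXCHANGE_CAP)
        lb[self._nf + self._ne :] = 0.0
        ub[self._nf + self._ne :] = 1.0
        return lb, ub


def dc_dr(coefs: np.ndarray, dR: np.ndarray, ridx: np.ndarray) -> np.ndarray:
    """Per-entry rate derivatives scaled by stoichiometric coefficients."""
    return coefs[:, None] * dR[ridx]


def _conv_operator(other: np.ndarray | None, out_len: int, in_len: int) -> np.ndarray:
    """Linear map u -> conv(other, u) truncated to ``out_len`` rows."""
    T = np.zeros((out_len, in_len))
    if other is None:
        other = np.array([1.0])
    for a in range(out_len):
        for b in range(in_len):
            d = a - b
            if 0 <= d < other.size:
                T[a, b] = other[d]
    return T


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    """Multi-start options.

    Each start runs a two-stage homotopy: a coarse fit against MID SDs
    inflated by ``homotopy_factor`` (which smooths the SSR landscape and
    reliably finds the right basin), then a polish at the true SDs with
    strict tolerances (the SSR valley is long and shallow; loose ftol stops
    far from the optimum).
    """

    restarts: int = 50
    seed: int = 0
    flux_cap: float = 2.0e4
    ftol: float = 1e-11
    xtol: float = 1e-12
    gtol: float = 1e-10
    max_nfev: int = 600
    homotopy_factor: float = 8.0
    coarse_nfev: int = 300
    #: keep adding restarts (up to this total) while the chi-square test
    #: rejects the best fit; ``restarts`` is the minimum, as in standard
    #: MFA practice
    max_restarts: int | None = None
    #: final strict polish of the best start (the SSR valley is shallow;
    #: profile confidence intervals need the true minimum)
    polish_nfev: int = 800
    #: deterministic first starts: flux-observation-informed net fluxes
    #: with all exchanges at these log10 levels (exchange magnitude is the
    #: dominant mode variable of the SSR landscape)
    canonical_levels: tuple[float, ...] = (-2.0, -1.0, 0.0, 2.0)
    #: skip the polish stage when the coarse solution's SSR exceeds this
    #: multiple of the residual count (a hopeless basin); the per-start
    #: decision is absolute, so best-of-restarts stays prefix-monotone
    polish_threshold: float = 50.0

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class FitResult:
    fluxmap: FluxMap
    theta: np.ndarray
    ssr: float
    dof: int
    chi2_interval: tuple[float, float]
    accepted: bool
    restarts: pd.DataFrame
    model: SteadyStateModel = field(repr=False, default=None)

    def flux_frame(self) -> pd.DataFrame:
        return self.fluxmap.to_frame(self.model.network if self.model else None)


def _canonical_start(model: SteadyStateModel, lb, ub) -> np.ndarray:
    """Deterministic start: net fluxes from a linear fit of the flux
    observations, exchanges low (a nearly unidirectional network), mixing
    weights at the simplex center."""
    x = np.empty(model.n_params)
    nf, ne = model._nf, model._ne
    if model._flux_plan:
        Jobs = np.array([model._Jnet[j] / sd for j, _, sd in model._flux_plan])
        yobs = np.array([val / sd for _, val, sd in model._flux_plan])
        th_lin, *_ = np.linalg.lstsq(Jobs, yobs, rcond=None)
        x[:nf] = th_lin
    else:
        x[:nf] = 1.0
    x[nf : nf + ne] = -1.0
    x[nf + ne :] = 0.5
    return np.clip(x, lb, ub)


def _random_start(model: SteadyStateModel, rng: np.random.Generator, lb, ub) -> np.ndarray:
    nf, ne = model._nf, model._ne
    x = np.empty(model.n_params)
    # net free fluxes: reactions with a direct flux observation start near
    # it; the rest draw uniformly at the typical measured scale
    obs = {model.basis.reaction_order[j]: val for j, val, _ in model._flux_plan}
    scale = max((abs(v) for v in obs.values()), default=1.0e3)
    scale = max(scale, 1.0)
    for i, rid in enumerate(model.basis.free_ids):
        if rid in obs:
            x[i] = obs[rid] * (1.0 + 0.3 * rng.standard_normal())
        elif lb[i] >= 0.0:
            x[i] = rng.uniform(0.0, scale)
        else:
            x[i] = rng.uniform(-0.5 * scale, scale)
    x[:nf] = np.clip(x[:nf], lb[:nf], ub[:nf])
    # exchange fluxes log-uniform (moderate range: huge exchanges flatten
    # the labeling response and waste restarts)
    x[nf : nf + ne] = rng.uniform(-3.0, 4.0, size=ne)
    # mixing weights uniform on the simplex
    x[nf + ne :] = rng.uniform(0.0, 1.0, size=model.n_params - nf - ne)
    return x


def fit_fluxes(
    network: Network,
    measurements: MeasurementSet,
    options: FitOptions | None = None,
    model: SteadyStateModel | None = None,
    start: np.ndarray | None = None,
) -> FitResult:
    """Bounded multi-start weighted least squares over the free fluxes.

    The best converged SSR across ``options.restarts`` random starts is
    kept; the fit is accepted when its SSR lies inside the two-sided 95%
    chi-square interval at DOF = #residuals - #free parameters.
    Deterministic for a given seed.
    """
    options = options or FitOptions()
    if model is None:
        model = SteadyStateModel(network, measurements)
    coarse = None
    if options.homotopy_factor > 1:
        inflated = MeasurementSet(
            mids=measurements.mids.assign(sd=measurements.mids["sd"] * options.homotopy_factor),
            fluxes=measurements.fluxes,
            tracers=measurements.tracers,
        )
        coarse = SteadyStateModel(model.network, inflated)
    lb, ub = model.default_bounds(options.flux_cap)
    rng = np.random.default_rng(options.seed)
    rows = []
    best = None
    best_coarse = None
    dof = model.n_meas - model.n_params
    if dof < 1:
        raise ValueError("model has no degrees of freedom")
    interval = chi2_acceptance_interval(dof)
    max_restarts = options.max_restarts or options.restarts
    i = -1
    while True:
        i += 1
        if i >= options.restarts:
            done = best is not None and interval[0] <= best[0] <= interval[1]
            if done or i >= max_restarts:
                break
        offset = 1 if start is not None else 0
        if start is not None and i == 0:
            x0 = np.clip(start, lb, ub)
        elif i - offset < len(options.canonical_levels):
            x0 = _canonical_start(model, lb, ub)
            x0[model._nf : model._nf + model._ne] = options.canonical_levels[i - offset]
            x0 = np.clip(x0, lb, ub)
        else:
            x0 = _random_start(model, rng, lb, ub)
        try:
            if coarse is not None:
                pre = least_squares(
                    lambda th: coarse.residuals(th),
                    x0,
                    jac=lambda th: coarse.residuals(th, need_jac=True)[1],
                    bounds=(lb, ub),
                    method="trf",
                    x_scale="jac",
                    max_nfev=options.coarse_nfev,
                )
                pre_ssr = model.ssr(pre.x)
                if best_coarse is None or pre_ssr < best_coarse[0]:
                    best_coarse = (pre_ssr, pre.x.copy())
                if pre_ssr > options.polish_threshold * model.n_meas:
                    # hopeless basin; polishing would waste the budget
                    rows.append({"start": i, "ssr": np.inf, "status": -1})
                    continue
                x0 = pre.x
            res = least_squares(
                lambda th: model.residuals(th),
                x0,
                jac=lambda th: model.residuals(th, need_jac=True)[1],
                bounds=(lb, ub),
                method="trf",
                x_scale="jac",
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=options.gtol,
                max_nfev=options.max_nfev,
            )
            ssr = float(np.sum(res.fun[: model.n_meas] ** 2))
            rows.append({"start": i, "ssr": ssr, "status": int(res.status)})
            if best is None or ssr < best[0]:
                best = (ssr, res.x.copy())
        except Exception as err:  # singular EMU systems at pathological starts
            rows.append({"start": i, "ssr": np.inf, "status": -99, "error": str(err)[:80]})
    if best is None and best_coarse is not None:
        # every basin exceeded the polish threshold; fall back to the best
        best = best_coarse
    if best is None:
        raise RuntimeError(f"all {options.restarts} restarts failed:\n{pd.DataFrame(rows)}")
    ssr, theta = best
    if options.polish_nfev:
        res = least_squares(
            lambda th: model.residuals(th),
            theta,
            jac=lambda th: model.residuals(th, need_jac=True)[1],
            bounds=(lb, ub),
            method="trf",
            x_scale="jac",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-12,
            max_nfev=options.polish_nfev,
        )
        polished = float(np.sum(res.fun[: model.n_meas] ** 2))
        if polished < ssr:
            ssr, theta = polished, res.x.copy()
    return FitResult(
        fluxmap=model.basis.to_fluxmap(theta),
        theta=theta,
        ssr=ssr,
        dof=dof,
        chi2_interval=interval,
        accepted=interval[0] <= ssr <= interval[1],
        restarts=pd.DataFrame(rows),
        model=model,
    )


# ---------------------------------------------------------------------------
# confidence intervals


class _FeasiblePoint(Exception):
    def __init__(self, theta, ssr):
        self.theta, self.ssr = theta, ssr


def _constrained_refit(
    model, theta0, lb, ub, g, target, stop_below=None, max_nfev=300
):
    """Re-optimize all parameters with the net flux ``g . theta_net`` pinned
    at ``target``.

    The constraint is linear, so it is eliminated exactly: the net block is
    reparameterized on the constraint's null space instead of penalized
    (a heavy penalty row wrecks the conditioning of the re-optimization).
    ``stop_below`` short-circuits as soon as a point with measurement SSR
    below that level is found — inside a profile scan only feasibility
    matters, not the exact conditional minimum.
    """
    nf = model._nf
    gn = g / np.linalg.norm(g)
    # orthonormal completion of gn: theta_net = gn * (target/|g|) + E z
    E = _null_basis(gn)
    t_part = gn * (target / np.linalg.norm(g))

    def expand(u):
        th = np.empty(model.n_params)
        th[:nf] = t_part + E @ u[: nf - 1]
        th[nf:] = u[nf - 1 :]
        return th

    def fun(u):
        th = expand(u)
        r = model.residuals(th)
        if stop_below is not None:
            ssr = float(np.sum(r[: model.n_meas] ** 2))
            if ssr < stop_below:
                raise _FeasiblePoint(th.copy(), ssr)
        return r

    def jac(u):
        _, J = model.residuals(expand(u), need_jac=True)
        return np.hstack([J[:, :nf] @ E, J[:, nf:]])

    th0 = np.clip(theta0, lb, ub).copy()
    v_start = float(g @ th0[:nf])
    if v_start != 0.0 and 0.5 < target / v_start < 2.0:
        # scale-like profile directions dominate well-determined fluxes:
        # rescaling the whole net block lands near the conditional optimum
        th0[:nf] *= target / v_start
    u0 = np.concatenate([E.T @ th0[:nf], th0[nf:]])
    lb_u = np.concatenate([np.full(nf - 1, -np.inf), lb[nf:]])
    ub_u = np.concatenate([np.full(nf - 1, np.inf), ub[nf:]])
    try:
        res = least_squares(
            fun, u0, jac=jac, bounds=(lb_u, ub_u), method="trf",
            x_scale="jac", ftol=1e-12, xtol=1e-13, gtol=1e-11, max_nfev=max_nfev,
        )
    except _FeasiblePoint as fp:
        return fp.ssr, fp.theta
    ssr = float(np.sum(res.fun[: model.n_meas] ** 2))
    return ssr, expand(res.x)


def _null_basis(gn: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the hyperplane orthogonal to unit vector gn."""
    n = gn.size
    M = np.eye(n) - np.outer(gn, gn)
    U, s, _ = np.linalg.svd(M)
    return U[:, : n - 1]


def confidence_intervals(
    fit: FitResult,
    fluxes_of_interest: list[str],
    delta_ssr: float = CI_DELTA_SSR,
    flux_cap: float = 2.0e4,
    max_refits: int = 10,
    n_bisect: int = 8,
) -> pd.DataFrame:
    """95% confidence bounds by SSR sensitivity.

    For each net flux of interest the flux is fixed at trial values away
    from its best estimate with all other parameters re-optimized until the
    constrained SSR exceeds ``SSR_min + delta_ssr`` (the chi-square 1-dof
    95% increment); the bound is refined by bisection and reported as the
    outermost value still inside the limit.  The first trial step comes
    from the linearized standard error, so well-determined fluxes bracket
    their bound in a couple of re-optimizations.  Scans that run into the
    flux cap (or an irreversibility floor) report an unbounded (or zero)
    limit, mirroring how unidentifiable exchanges are tabulated.
    """
    model = fit.model
    lb, ub = model.default_bounds(flux_cap)
    # linearized covariance guides the first profile step
    _, J = model.residuals(fit.theta, need_jac=True)
    Jm = J[: model.n_meas]
    C = np.linalg.pinv(Jm.T @ Jm, rcond=1e-12)
    rows = []
    for rid in fluxes_of_interest:
        j = model._rxn_index[rid]
        g = model._Jnet[j]
        v0 = float(g @ fit.theta[: model._nf])
        se = float(np.sqrt(max(g @ C[: model._nf, : model._nf] @ g, 0.0)))
        limit = fit.ssr + delta_ssr
        irreversible = rid not in model._reversible
        bounds = {}
        for direction in (-1, +1):
            step0 = 1.96 * se if np.isfinite(se) and se > 0 else max(0.5 * abs(v0), 1e-6)
            step0 = min(step0, max(abs(v0), 10.0))
            # continuation: march outward, warm-starting each constrained
            # re-optimization from the nearest feasible solution
            theta_ok = fit.theta.copy()
            target = v0 + direction * step0
            last_ok, first_bad, d_bad = v0, None, None
            hit_edge = False
            for _ in range(max_refits):
                if irreversible and target < 0:
                    target = 0.0
                if abs(target) >= flux_cap:
                    target = direction * flux_cap
                    hit_edge = True
                ssr, theta_try = _constrained_refit(
                    model, theta_ok, lb, ub, g, target, stop_below=limit - 0.4
                )
                d = ssr - fit.ssr
                if d > delta_ssr:
                    first_bad, d_bad = target, d
                    break
                last_ok, theta_ok = target, theta_try
                if hit_edge or (irreversible and target == 0.0):
                    break
                # quadratic prediction of where the SSR reaches the limit
                factor = np.sqrt(delta_ssr / max(d, delta_ssr / 25.0))
                target = v0 + (target - v0) * min(max(factor, 1.3), 3.0)
            if first_bad is None:
                if irreversible and direction < 0 and last_ok == 0.0:
                    bounds[direction] = 0.0
                else:
                    bounds[direction] = direction * np.inf
                continue
            # refine by guarded quadratic interpolation on the ~parabolic
            # SSR profile (bisection alone wastes refits when the first
            # bracket is much wider than the interval)
            lo_v, hi_v = last_ok, first_bad
            use_interp = True
            for _ in range(n_bisect):
                if abs(hi_v - lo_v) <= max(0.07 * abs(hi_v - v0), 1e-9):
                    break
                if use_interp and d_bad is not None and d_bad > delta_ssr:
                    est = v0 + (hi_v - v0) * np.sqrt(delta_ssr / d_bad)
                else:
                    est = 0.5 * (lo_v + hi_v)
                lo_g, hi_g = sorted((lo_v, hi_v))
                span = hi_g - lo_g
                est = min(max(est, lo_g + 0.1 * span), hi_g - 0.1 * span)
                ssr, theta_try = _constrained_refit(
                    model, theta_ok, lb, ub, g, est, stop_below=limit - 0.4
                )
                if ssr - fit.ssr > delta_ssr:
                    hi_v, d_bad = est, ssr - fit.ssr
                    use_interp = not use_interp  # alternate with bisection
                else:
                    lo_v, theta_ok = est, theta_try
                    use_interp = True
            bounds[direction] = lo_v
        rows.append(
            {"reaction": rid, "flux": v0, "lb": bounds[-1], "ub": bounds[+1], "se_lin": se}
        )
    out = pd.DataFrame(rows)
    for _, row in out.iterrows():
        fit.fluxmap.net_bounds[row["reaction"]] = (row["lb"], row["ub"])
    return out


# ---------------------------------------------------------------------------
# reporting


def flux_ratio_table(fit_a: pd.DataFrame, fit_b: pd.DataFrame) -> pd.DataFrame:
    """Per-reaction flux ratios (condition b over reference a).

    Inputs are flux tables in the published layout (type, id, flux, lb, ub).
    Reactions whose reference flux is ~0 get no ratio; reactions whose
    confidence intervals do not overlap are flagged.
    """
    key = ["type", "id"]
    a = fit_a.set_index(key)
    b = fit_b.set_index(key)
    common = a.index.intersection(b.index)
    rows = []
    for idx in common:
        fa, fb = a.loc[idx, "flux"], b.loc[idx, "flux"]
        ratio = fb / fa if abs(fa) > 1e-6 else np.nan
        lo_a, hi_a = a.loc[idx].get("lb", np.nan), a.loc[idx].get("ub", np.nan)
        lo_b, hi_b = b.loc[idx].get("lb", np.nan), b.loc[idx].get("ub", np.nan)
        disjoint = (
            np.isfinite([lo_a, hi_a, lo_b, hi_b]).all()
            and (hi_a < lo_b or hi_b < lo_a)
        )
        rows.append(
            {
                "type": idx[0],
                "id": idx[1],
                "flux_a": fa,
                "flux_b": fb,
                "ratio": np.round(ratio, 2) if np.isfinite(ratio) else np.nan,
                "non_overlapping": bool(disjoint),
            }
        )
    return pd.DataFrame(rows)


def growth_normalized_fluxes(flux_table: pd.DataFrame, mu: float) -> pd.DataFrame:
    """Divide every flux by the growth rate (fmol/cell per unit growth).

    Expressing fluxes per growth-rate unit separates changes in metabolic
    activity from changes in proliferation.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    out = flux_table.copy()
    for col in ("flux", "lb", "ub"):
        if col in out.columns:
            out[col] = out[col] / mu
    return out
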