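"""Predict mass isotopomer distributions from a flux map and tracer mix.

Two simulation regimes are provided:

* isotopic steady state — cascaded linear EMU solves, one dense system per
  EMU size, smaller sizes feeding larger ones through convolution;
* isotopically nonstationary — the same EMU balances integrated in time,
  scaled by intracellular pool sizes, from unlabeled initial conditions.

A brute-force positional-isotopomer fixed-point solver doubles as an
independent oracle for testing on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .emu import EMU, EMUSystem, emu_decomposition
from .network import FluxMap, Network
from .tracers import InputLabeling, TracerSpec

__all__ = [
    "PoolSizeSet",
    "SimulationResult",
    "simulate_steady_state_mids",
    "simulate_inst_mids",
    "brute_force_isotopomer_oracle",
    "SingularEMUSystem",
]


class SingularEMUSystem(RuntimeError):
    """An EMU balance system is singular (an EMU has no throughput)."""


@dataclass
class PoolSizeSet:
    """Intracellular pool sizes, fmol/cell, governing labeling kinetics."""

    sizes: dict[str, float] = field(default_factory=dict)
    default: float = 10.0

    def __getitem__(self, met: str) -> float:
        size = self.sizes.get(met, self.default)
        if size <= 0:
            raise ValueError(f"pool size for {met} must be positive, got {size}")
        return size

    def scaled(self, factor: float) -> "PoolSizeSet":
        return PoolSizeSet(
            {k: v * factor for k, v in self.sizes.items()}, self.default * factor
        )


@dataclass
class SimulationResult:
    """MIDs per observed EMU; time-resolved results carry a time axis."""

    mids: dict[EMU, np.ndarray]  # steady: (k+1,); inst: (ntimes, k+1)
    times: np.ndarray | None = None

    def mid(self, met: str, atoms: tuple[int, ...] | None = None) -> np.ndarray:
        for emu, v in self.mids.items():
            if emu.metabolite == met and (atoms is None or emu.atoms == tuple(sorted(atoms))):
                return v
        raise KeyError(f"no simulated MID for {met} {atoms}")


def _unidirectional_fluxes(network: Network, flux: FluxMap) -> dict[tuple[str, int], float]:
    rates = {}
    for rxn in network.all_flux_entries():
        fwd, bwd = flux.forward_backward(rxn.id, rxn.reversible)
        rates[(rxn.id, 1)] = fwd
        if rxn.reversible:
            rates[(rxn.id, -1)] = bwd
    return rates


def _outflux(system: EMUSystem, rates) -> dict[str, float]:
    return {
        met: sum(coef * rates[(rid, d)] for rid, d, coef in terms)
        for met, terms in system.consumption.items()
    }


def _input_mids(system: EMUSystem, labeling: InputLabeling) -> dict[EMU, np.ndarray]:
    return {e: labeling.emu_mid(e.metabolite, e.atoms) for e in system.inputs}


def simulate_steady_state_mids(
    network: Network,
    flux: FluxMap,
    tracers: list[TracerSpec],
    observed: list[tuple[str, tuple[int, ...] | None]] | None = None,
    system: EMUSystem | None = None,
) -> SimulationResult:
    """Steady-state MIDs of the observed fragments.

    Solves, for each EMU size k in ascending order, the linear balance
    ``A(v) X = B(v) Y`` where Y stacks input MIDs and convolutions of
    smaller-size solutions.  All outputs lie on the probability simplex.
    """
    if system is None:
        system = emu_decomposition(network, observed or [])
    labeling = InputLabeling.from_tracers(
        tracers, {e.metabolite: network.carbon_count(e.metabolite) for e in system.inputs}
    )
    rates = _unidirectional_fluxes(network, flux)
    solved = dict(_input_mids(system, labeling))
    out = _outflux(system, rates)

    for size in system.sizes:
        emus = system.layers[size]
        index = {e: i for i, e in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for i, emu in enumerate(emus):
            A[i, i] -= out[emu.metabolite]
            for term in system.producers[emu]:
                f = term.weight * term.coef * rates[(term.reaction, term.direction)]
                if f == 0.0:
                    continue
                if len(term.sources) == 1 and term.sources[0] in index:
                    A[i, index[term.sources[0]]] += f
                else:
                    mid = _term_mid(term, solved, index, None)
                    B[i, :] -= f * mid
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            dead = [str(emus[i]) for i in range(n) if abs(A[i, i]) < 1e-300]
            raise SingularEMUSystem(
                f"size-{size} EMU system singular; zero-throughput EMUs: {dead or 'coupled'}"
            ) from None
        for e, row in zip(emus, X):
            solved[e] = row

    return SimulationResult(mids={e: solved[e] for e in system.observed})


def _term_mid(term, solved, same_size_index, interpolants, t=None):
    """MID contributed by a production term's sources (convolving if needed)."""
    mid = None
    for src in term.sources:
        if src in solved:
            v = solved[src]
        elif interpolants is not None and src in interpolants:
            v = interpolants[src](t)
        else:  # pragma: no cover - decomposition guarantees availability
            raise KeyError(f"unsolved source EMU {src}")
        mid = v if mid is None else np.convolve(mid, v)
    return mid


def simulate_inst_mids(
    network: Network,
    flux: FluxMap,
    pools: PoolSizeSet,
    tracers: list[TracerSpec],
    times: np.ndarray,
    observed: list[tuple[str, tuple[int, ...] | None]] | None = None,
    system: EMUSystem | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Time-resolved MIDs from unlabeled initial conditions.

    Integrates ``dX/dt = P^{-1} (production - outflux * X)`` for the whole
    EMU cascade as one coupled system with an implicit stiff solver (Radau)
    and an analytic sparse Jacobian.  ``times`` must be sorted and start at
    0 (the unlabeled state).  Mixing measurement pools are evaluated
    algebraically from the integrated trajectories.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or times[0] < 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted and nonnegative")
    if system is None:
        system = emu_decomposition(network, observed or [])
    labeling = InputLabeling.from_tracers(
        tracers, {e.metabolite: network.carbon_count(e.metabolite) for e in system.inputs}
    )
    rates = _unidirectional_fluxes(network, flux)
    out = _outflux(system, rates)
    inputs = _input_mids(system, labeling)

    from scipy import sparse

    # global state layout: one slice per non-algebraic internal EMU,
    # ordered by (size, EMU); algebraic mixing pools evaluated afterwards
    dynamic = [
        e
        for size in system.sizes
        for e in system.layers[size]
        if e.metabolite not in system.algebraic_mets
    ]
    algebraic = [
        e
        for size in system.sizes
        for e in system.layers[size]
        if e.metabolite in system.algebraic_mets
    ]
    offsets: dict[EMU, tuple[int, int]] = {}
    pos = 0
    for e in dynamic:
        offsets[e] = (pos, e.size + 1)
        pos += e.size + 1
    n_state = pos
    inv_pool = np.empty(n_state)
    for e, (start, width) in offsets.items():
        inv_pool[start : start + width] = 1.0 / pools[e.metabolite]

    # linear part: dilution by total outflux + same-size direct transfers
    rows, cols, vals = [], [], []
    const_prod = np.zeros(n_state)
    # conv terms: (start, width, rate, parts) with parts ('y', start, width)
    # or ('c', const_vector)
    conv_terms: list[tuple[int, int, float, list]] = []
    for e in dynamic:
        start, width = offsets[e]
        o = out[e.metabolite]
        rows.extend(range(start, start + width))
        cols.extend(range(start, start + width))
        vals.extend([-o] * width)
        for term in system.producers[e]:
            f = term.weight * term.coef * rates[(term.reaction, term.direction)]
            if f == 0.0:
                continue
            src = term.sources
            if len(src) == 1 and src[0] in offsets:
                s0, w0 = offsets[src[0]]
                for w in range(min(width, w0)):
                    rows.append(start + w)
                    cols.append(s0 + w)
                    vals.append(f)
            elif all(s in inputs for s in src):
                mid = inputs[src[0]]
                for s in src[1:]:
                    mid = np.convolve(mid, inputs[s])
                const_prod[start : start + width] += f * mid
            else:
                parts = [
                    ("y", *offsets[s]) if s in offsets else ("c", inputs[s])
                    for s in src
                ]
                conv_terms.append((start, width, f, parts))
    L = sparse.csr_matrix((vals, (rows, cols)), shape=(n_state, n_state))

    def _part_vec(part, y):
        return y[part[1] : part[1] + part[2]] if part[0] == "y" else part[1]

    def rhs(t, y):
        p = const_prod.copy()
        for start, width, f, parts in conv_terms:
            mid = _part_vec(parts[0], y)
            for part in parts[1:]:
                mid = np.convolve(mid, _part_vec(part, y))
            p[start : start + width] += f * mid[:width]
        return inv_pool * (L @ y + p)

    def jac(t, y):
        jr, jc, jv = [], [], []
        for start, width, f, parts in conv_terms:
            for j, part in enumerate(parts):
                if part[0] != "y":
                    continue
                other = None
                for k, q in enumerate(parts):
                    if k == j:
                        continue
                    v = _part_vec(q, y)
                    other = v if other is None else np.convolve(other, v)
                if other is None:
                    other = np.array([1.0])
                s0, w0 = part[1], part[2]
                for a in range(width):
                    for b in range(w0):
                        d = a - b
                        if 0 <= d < other.size:
                            jr.append(start + a)
                            jc.append(s0 + b)
                            jv.append(f * other[d])
        J = L + sparse.csr_matrix((jv, (jr, jc)), shape=(n_state, n_state))
        return sparse.diags(inv_pool) @ J

    y0 = np.zeros(n_state)
    for e, (start, _) in offsets.items():
        y0[start] = 1.0  # unlabeled initial pools
    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="Radau",  # L-stable; BDF loses steps to roundoff at tight atol
        jac=jac,
        t_eval=np.clip(times, 0.0, t_end),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"EMU ODE integration failed: {sol.message}")

    trajectories: dict[EMU, np.ndarray] = {}
    Y = sol.y.T  # (ntimes, n_state)
    for e, (start, width) in offsets.items():
        trajectories[e] = _renormalize(Y[:, start : start + width])

    for e in algebraic:
        total = out[e.metabolite]
        acc = np.zeros((len(times), e.size + 1))
        for term in system.producers[e]:
            f = term.weight * term.coef * rates[(term.reaction, term.direction)]
            if f == 0.0:
                continue
            mid = _source_trajectory(term.sources[0], trajectories, inputs, len(times))
            for s in term.sources[1:]:
                nxt = _source_trajectory(s, trajectories, inputs, len(times))
                mid = np.stack([np.convolve(a, b) for a, b in zip(mid, nxt)])
            acc += (f / total) * mid[:, : e.size + 1]
        trajectories[e] = acc

    return SimulationResult(
        mids={e: trajectories[e] for e in system.observed}, times=times
    )


def _source_trajectory(src, trajectories, inputs, ntimes):
    if src in trajectories:
        return trajectories[src]
    return np.tile(inputs[src], (ntimes, 1))


def _renormalize(rows: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    s = rows.sum(axis=-1, keepdims=True)
    return np.where(np.abs(s - 1.0) > tol, rows / s, rows)


# ---------------------------------------------------------------------------
# brute-force positional isotopomer oracle


def brute_force_isotopomer_oracle(
    network: Network,
    flux: FluxMap,
    tracers: list[TracerSpec],
    observed: list[tuple[str, tuple[int, ...] | None]] | None = None,
    max_total_carbons: int = 16,
    tol: float = 1e-14,
    max_iter: int = 200_000,
) -> SimulationResult:
    """Exact steady-state MIDs by full positional-isotopomer enumeration.

    Maintains one 2^c distribution per internal metabolite and iterates the
    (bilinear, for condensations) balance to its fixed point; marginalizes
    to MIDs at the end.  Refuses networks whose internal metabolites carry
    more than ``max_total_carbons`` carbons in total.
    """
    input_species = {m.id for m in network.metabolites.values() if not m.balanced}
    mixing_targets = {r.products[0].metabolite for r in network.mixing if r.reactants[0].coef == 0}
    internal = sorted(
        m.id
        for m in network.metabolites.values()
        if (m.balanced or m.id in mixing_targets) and m.n_carbons
    )
    total_c = sum(network.carbon_count(m) for m in internal)
    if total_c > max_total_carbons:
        raise ValueError(
            f"network has {total_c} internal carbons; oracle limited to {max_total_carbons}"
        )
    rates = _unidirectional_fluxes(network, flux)
    labeling = InputLabeling.from_tracers(
        tracers,
        {
            m.id: m.n_carbons
            for m in network.metabolites.values()
            if not m.balanced and m.n_carbons
        },
    )
    dist = {m: _unlabeled(network.carbon_count(m)) for m in internal}
    inputs = {
        m.id: labeling.isotopomer_distribution(m.id, m.n_carbons)
        for m in network.metabolites.values()
        if m.id in input_species and m.n_carbons
    }
    symmetric = {m.id for m in network.metabolites.values() if m.symmetric}

    # precompute production routes: per internal metabolite, list of
    # (rate_key, [(source_met_or_None, src_atom_order)], product_atom_map)
    routes: dict[str, list] = {m: [] for m in internal}
    outflux: dict[str, float] = {m: 0.0 for m in internal}
    for rxn in network.all_flux_entries():
        for direction, lhs, rhs in (
            [(1, rxn.reactants, rxn.products)]
            + ([(-1, rxn.products, rxn.reactants)] if rxn.reversible else [])
        ):
            for sterm in lhs:
                if sterm.metabolite in outflux and sterm.coef > 0:
                    outflux[sterm.metabolite] += sterm.coef * rates[(rxn.id, direction)]
            letter_src = {}
            for term_idx, sterm in enumerate(lhs):
                if sterm.atoms:
                    for pos, letter in enumerate(sterm.atoms, start=1):
                        letter_src[letter] = (term_idx, sterm.metabolite, pos)
            for pterm in rhs:
                if pterm.metabolite not in routes or pterm.atoms is None:
                    continue
                src = [letter_src[a] for a in pterm.atoms]
                routes[pterm.metabolite].append(
                    ((rxn.id, direction), pterm.coef if pterm.coef > 0 else 1.0, src)
                )

    for _ in range(max_iter):
        delta = 0.0
        for met in internal:
            prod = np.zeros_like(dist[met])
            for rate_key, coef, src in routes[met]:
                f = coef * rates[rate_key]
                if f == 0.0:
                    continue
                prod += f * _map_isotopomers(src, dist, inputs, len(prod))
            if outflux[met] <= 0:
                raise SingularEMUSystem(f"metabolite {met} has zero outflux")
            new = prod / outflux[met]
            # renormalize: with balanced fluxes the fixed point sums to 1,
            # and projecting intermediate iterates back to the simplex
            # keeps recycling networks from transiently diverging
            s = new.sum()
            if s > 0:
                new = np.clip(new, 0.0, None) / s
            if met in symmetric:
                new = 0.5 * (new + _reverse_orientation(new))
            delta = max(delta, float(np.max(np.abs(new - dist[met]))))
            dist[met] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")

    obs = observed or [(m, None) for m in internal]
    mids = {}
    for met, atoms in obs:
        n = network.carbon_count(met)
        if atoms is None:
            atoms = tuple(range(1, n + 1))
        d = dist[met] if met in dist else inputs[met]
        mids[EMU(met, tuple(sorted(atoms)))] = _marginal_mid(d, atoms, n)
    return SimulationResult(mids=mids)


def _unlabeled(n: int) -> np.ndarray:
    d = np.zeros(2**n)
    d[0] = 1.0
    return d


def _map_isotopomers(src, dist, inputs, size_out) -> np.ndarray:
    """Distribution of a product whose atom i comes from src[i]=(term, met, pos).

    Distinct substrate molecules (even of the same metabolite, e.g. a
    transketolase condensing two pentoses) are statistically independent.
    """
    terms: list[tuple[int, str]] = []
    for term_idx, met, _ in src:
        if (term_idx, met) not in terms:
            terms.append((term_idx, met))
    dists = [dist.get(m, inputs.get(m)) for _, m in terms]
    shapes = [d.size for d in dists]
    joint = np.ones(1)
    for d in dists:
        joint = np.outer(joint, d).ravel()
    joint = joint.reshape(shapes)
    out = np.zeros(size_out)
    for idx in np.ndindex(*shapes):
        p = joint[idx]
        if p == 0.0:
            continue
        pat = 0
        for bit, (term_idx, met, pos) in enumerate(src):
            m_idx = terms.index((term_idx, met))
            if (idx[m_idx] >> (pos - 1)) & 1:
                pat |= 1 << bit
        out[pat] += p
    return out


def _reverse_orientation(d: np.ndarray) -> np.ndarray:
    n = int(np.log2(d.size))
    out = np.empty_like(d)
    for pat in range(d.size):
        rev = 0
        for i in range(n):
            if (pat >> i) & 1:
                rev |= 1 << (n - 1 - i)
        out[rev] = d[pat]
    return out


def _marginal_mid(d: np.ndarray, atoms: tuple[int, ...], n: int) -> np.ndarray:
    mid = np.zeros(len(atoms) + 1)
    for pat, p in enumerate(d):
        weight = sum((pat >> (a - 1)) & 1 for a in atoms)
        mid[weight] += p
    return mid
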