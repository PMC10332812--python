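"""Compartmented carbon-transition networks for metabolic flux analysis.

A network is read from a small plain-text dialect, one reaction per line::

    PGI: G6P (abcdef) <-> F6P (abcdef)
    PC: PYR.m (abc) + CO2 (d) -> OAC (abcd)
    BIOMASS: 1216*AcCoA.c + 295.6*ALA + ... -> biomass

Lowercase letters name carbon atoms (1-based positions); the letters on the
reactant side must be a permutation of the letters on the product side unless
a species is left unmapped (pure mass drains such as biomass).  ``->`` marks
an irreversible reaction (net flux only), ``<->`` a reversible one carrying a
net and an exchange flux.  ``%`` lines are directives declaring unbalanced
(source/sink) species and rotationally symmetric molecules; ``|`` trailers
attach metadata (pathway tag, pseudo-reaction class).

Compartments are encoded as id suffixes: ``.c`` cytosol, ``.m`` mitochondria,
``.x`` extracellular, ``.ms`` measurement mixing pool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "Network",
    "FluxMap",
    "NetworkParseError",
    "parse_network",
    "load_network",
    "packaged_network",
    "packaged_flux_table",
    "stoichiometric_matrix",
    "check_flux_balance",
    "FreeFluxBasis",
    "free_flux_parameterization",
    "read_flux_table",
    "write_flux_table",
    "fluxmap_from_table",
    "EXCHANGE_CAP",
]

#: Upper cap on exchange fluxes (fmol/cell/h); fits that push an exchange
#: against this cap are reported as unbounded.
EXCHANGE_CAP = 1.0e7

_COMPARTMENTS = {"c": "cytosol", "m": "mitochondria", "x": "extracellular", "ms": "mixing"}


class NetworkParseError(ValueError):
    """Raised for malformed network files; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int | None
    balanced: bool
    symmetric: bool = False

    @property
    def compartment(self) -> str:
        if "." in self.id:
            return _COMPARTMENTS.get(self.id.rsplit(".", 1)[1], "cytosol")
        return "cytosol"


@dataclass(frozen=True)
class ReactionTerm:
    metabolite: str
    coef: float
    atoms: tuple[str, ...] | None  # one lowercase letter per carbon, or None


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[ReactionTerm, ...]
    products: tuple[ReactionTerm, ...]
    reversible: bool
    pathway: str = ""
    pseudo: str | None = None  # None | "mixing" | "source"

    @property
    def is_mixing(self) -> bool:
        return self.pseudo == "mixing"

    def species(self) -> set[str]:
        return {t.metabolite for t in self.reactants + self.products}

    def __str__(self) -> str:  # round-trips through parse_network
        arrow = "<->" if self.reversible else "->"

        def side(terms):
            parts = []
            for t in terms:
                s = t.metabolite if t.coef == 1 else f"{t.coef:g}*{t.metabolite}"
                if t.atoms is not None:
                    s += " (" + "".join(t.atoms) + ")"
                parts.append(s)
            return " + ".join(parts)

        return f"{self.id}: {side(self.reactants)} {arrow} {side(self.products)}"


@dataclass
class Network:
    """Parsed reaction network with metabolite metadata.

    ``reactions`` excludes pseudo-entries; ``mixing`` holds measurement-pool
    blending pseudo-reactions and ``sources`` unlabeled source terms (e.g. an
    aggregate fatty-acid-oxidation acetyl-CoA supply).
    """

    reactions: list[Reaction]
    mixing: list[Reaction] = field(default_factory=list)
    sources: list[Reaction] = field(default_factory=list)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    name: str = ""

    def all_reactions(self) -> list[Reaction]:
        """Reactions carrying flux in mass balances: real + source pseudo."""
        return self.reactions + self.sources

    def all_flux_entries(self) -> list[Reaction]:
        """Everything with a flux value, including mixing pseudo-reactions."""
        return self.reactions + self.sources + self.mixing

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.all_reactions()]

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.all_reactions() if r.reversible]

    @property
    def balanced_ids(self) -> list[str]:
        return sorted(m.id for m in self.metabolites.values() if m.balanced)

    def reaction(self, rid: str) -> Reaction:
        for r in self.all_flux_entries():
            if r.id == rid:
                return r
        raise KeyError(rid)

    def carbon_count(self, met: str) -> int:
        n = self.metabolites[met].n_carbons
        if n is None:
            raise ValueError(f"metabolite {met!r} has no atom-mapped carbons")
        return n


@dataclass
class FluxMap:
    """Net and exchange flux values, fmol/cell/h.

    ``net`` covers every flux-carrying reaction (mixing weights included);
    ``exch`` covers reversible reactions only.  Optional per-flux bounds hold
    confidence-interval output in the same table layout the fitters emit.
    """

    net: dict[str, float]
    exch: dict[str, float] = field(default_factory=dict)
    net_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    exch_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def forward_backward(self, rid: str, reversible: bool) -> tuple[float, float]:
        v = self.net[rid]
        e = self.exch.get(rid, 0.0) if reversible else 0.0
        return max(v, 0.0) + e, max(-v, 0.0) + e

    def to_frame(self, network: Network | None = None) -> pd.DataFrame:
        rows = []
        order = (
            [r.id for r in network.all_flux_entries()] if network is not None else list(self.net)
        )
        for rid in order:
            if rid in self.net:
                lb, ub = self.net_bounds.get(rid, (np.nan, np.nan))
                rxn = network.reaction(rid) if network is not None else None
                rows.append(
                    {
                        "type": "NET",
                        "pathway": rxn.pathway if rxn else "",
                        "id": rid,
                        "reaction": str(rxn).split(": ", 1)[1] if rxn else "",
                        "flux": self.net[rid],
                        "lb": lb,
                        "ub": ub,
                    }
                )
        for rid, v in self.exch.items():
            lb, ub = self.exch_bounds.get(rid, (np.nan, np.nan))
            rxn = network.reaction(rid) if network is not None else None
            rows.append(
                {
                    "type": "EXCH",
                    "pathway": rxn.pathway if rxn else "",
                    "id": rid,
                    "reaction": str(rxn).split(": ", 1)[1] if rxn else "",
                    "flux": v,
                    "lb": lb,
                    "ub": ub,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parsing

_TERM_RE = re.compile(
    r"^(?:(?P<coef>[0-9.eE+-]+)\*)?\s*(?P<met>[A-Za-z0-9_.]+)\s*(?:\((?P<atoms>[a-z]+)\))?$"
)


def _parse_side(text: str, lineno: int) -> list[ReactionTerm]:
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        if not raw:
            raise NetworkParseError("empty reaction term", lineno)
        m = _TERM_RE.match(raw)
        if not m:
            raise NetworkParseError(f"cannot parse term {raw!r}", lineno)
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        atoms = tuple(m.group("atoms")) if m.group("atoms") else None
        terms.append(ReactionTerm(m.group("met"), coef, atoms))
    return terms


def parse_network(text: str, name: str = "") -> Network:
    """Parse the plain-text atom-map dialect into a :class:`Network`."""
    reactions: list[Reaction] = []
    mixing: list[Reaction] = []
    sources: list[Reaction] = []
    unbalanced: set[str] = set()
    symmetric: set[str] = set()
    seen_ids: set[str] = set()

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("%"):
            directive = line[1:].strip()
            if ":" not in directive:
                raise NetworkParseError(f"malformed directive {line!r}", lineno)
            key, vals = directive.split(":", 1)
            names = vals.split()
            if key.strip() == "unbalanced":
                unbalanced.update(names)
            elif key.strip() == "symmetric":
                symmetric.update(names)
            else:
                raise NetworkParseError(f"unknown directive {key.strip()!r}", lineno)
            continue
        if ":" not in line:
            raise NetworkParseError("expected 'ID: reactants -> products'", lineno)
        rid, rest = line.split(":", 1)
        rid = rid.strip()
        meta = {}
        if "|" in rest:
            rest, trailer = rest.split("|", 1)
            for kv in trailer.split():
                if "=" not in kv:
                    raise NetworkParseError(f"malformed metadata {kv!r}", lineno)
                k, v = kv.split("=", 1)
                meta[k] = v
        if "<->" in rest:
            lhs, rhs = rest.split("<->")
            reversible = True
        elif "->" in rest:
            lhs, rhs = rest.split("->")
            reversible = False
        else:
            raise NetworkParseError("missing reaction arrow", lineno)
        if rid in seen_ids:
            raise NetworkParseError(f"duplicate reaction id {rid!r}", lineno)
        seen_ids.add(rid)
        rxn = Reaction(
            rid,
            tuple(_parse_side(lhs, lineno)),
            tuple(_parse_side(rhs, lineno)),
            reversible,
            pathway=meta.get("pathway", ""),
            pseudo=meta.get("pseudo"),
        )
        _check_atom_balance(rxn, lineno)
        {None: reactions, "mixing": mixing, "source": sources}[rxn.pseudo].append(rxn)

    mets: dict[str, Metabolite] = {}
    ncarbons: dict[str, int] = {}
    species: set[str] = set()
    for rxn in reactions + mixing + sources:
        for term in rxn.reactants + rxn.products:
            species.add(term.metabolite)
            if term.atoms is not None:
                n = len(term.atoms)
                if ncarbons.setdefault(term.metabolite, n) != n:
                    raise NetworkParseError(
                        f"inconsistent carbon count for {term.metabolite!r} in {rxn.id}"
                    )
    for mid in sorted(species):
        n = ncarbons.get(mid)
        mets[mid] = Metabolite(
            id=mid,
            n_carbons=n,
            balanced=mid not in unbalanced,
            symmetric=mid in symmetric,
        )
    missing = (unbalanced | symmetric) - set(mets)
    if missing:
        raise NetworkParseError(f"directive names unknown species: {sorted(missing)}")
    return Network(reactions, mixing, sources, mets, name=name)


def _check_atom_balance(rxn: Reaction, lineno: int) -> None:
    """Mapped letters must occur once per side and match across sides."""
    for side_name, side in (("reactant", rxn.reactants), ("product", rxn.products)):
        letters = [a for t in side if t.atoms for a in t.atoms]
        if len(letters) != len(set(letters)):
            raise NetworkParseError(f"repeated atom letter on {side_name} side of {rxn.id}", lineno)
    if any(t.atoms is None for t in rxn.reactants + rxn.products):
        return  # mass drains (biomass) are exempt from the letter check
    lhs = {a for t in rxn.reactants for a in t.atoms}
    rhs = {a for t in rxn.products for a in t.atoms}
    if lhs != rhs:
        raise NetworkParseError(
            f"atom letters unbalanced in {rxn.id}: {sorted(lhs ^ rhs)}", lineno
        )


def load_network(path: str | Path) -> Network:
    path = Path(path)
    return parse_network(path.read_text(), name=path.stem)


def packaged_network(cell_type: str = "lf") -> Network:
    """Load a packaged 48-reaction central-carbon network.

    ``cell_type`` selects the biomass-coefficient variant: ``"lf"`` (lung
    fibroblast) or ``"pasmc"`` (pulmonary artery smooth muscle cell).
    """
    ref = resources.files("cellflux.data") / f"{cell_type}.net"
    return parse_network(ref.read_text(), name=cell_type)


def packaged_flux_table(name: str) -> pd.DataFrame:
    """Load a packaged published flux solution (e.g. ``"lf_21"``, ``"pasmc_05"``)."""
    ref = resources.files("cellflux.data") / f"fluxes_{name}.tsv"
    with resources.as_file(ref) as p:
        return read_flux_table(p)


# ---------------------------------------------------------------------------
# stoichiometry and balance checking


def stoichiometric_matrix(network: Network) -> pd.DataFrame:
    """S over balanced metabolites (rows) x flux-carrying reactions (columns).

    Feasible net flux vectors satisfy S v = 0 (metabolic steady state).
    Mixing pseudo-reactions carry zero stoichiometry and are excluded.
    """
    mets = network.balanced_ids
    rxns = network.all_reactions()
    S = np.zeros((len(mets), len(rxns)))
    idx = {m: i for i, m in enumerate(mets)}
    for j, rxn in enumerate(rxns):
        for term in rxn.reactants:
            if term.metabolite in idx:
                S[idx[term.metabolite], j] -= term.coef
        for term in rxn.products:
            if term.metabolite in idx:
                S[idx[term.metabolite], j] += term.coef
    return pd.DataFrame(S, index=mets, columns=[r.id for r in rxns])


def check_flux_balance(
    network: Network, flux: FluxMap, tol_rel: float = 0.02
) -> pd.DataFrame:
    """Steady-state residual report for a net flux vector.

    For each balanced metabolite the absolute residual ``sum_j S_mj v_j`` and
    its size relative to the largest inflow are reported; the vector passes
    when every relative residual is at most ``tol_rel``.  The default 2%
    tolerance absorbs 3-significant-figure rounding of published solutions.
    """
    S = stoichiometric_matrix(network)
    missing = [rid for rid in S.columns if rid not in flux.net]
    if missing:
        raise ValueError(f"flux map missing reactions: {missing}")
    v = np.array([flux.net[rid] for rid in S.columns])
    resid = S.to_numpy() @ v
    contrib = S.to_numpy() * v  # signed flow per (metabolite, reaction)
    inflow = np.maximum(contrib, 0.0).sum(axis=1)
    rel = np.abs(resid) / np.where(inflow > 0, inflow, np.inf)
    report = pd.DataFrame(
        {
            "residual": resid,
            "inflow": inflow,
            "rel_residual": rel,
            "ok": rel <= tol_rel,
        },
        index=S.index,
    )
    report.attrs["passed"] = bool(report["ok"].all())
    report.attrs["tol_rel"] = tol_rel
    return report


# ---------------------------------------------------------------------------
# free-flux parameterization


class FreeFluxBasis:
    """Bidirectional map between a free parameter vector and a FluxMap.

    Net fluxes live in the null space of S; a full-column-rank set of
    "dependent" reactions is eliminated so the free parameters are actual
    reaction fluxes (chosen deterministically by QR column pivoting).
    Exchange fluxes are parameterized as log10 values clipped to
    [0, EXCHANGE_CAP]; mixing weights as points on the unit simplex.
    """

    def __init__(self, network: Network):
        self.network = network
        S = stoichiometric_matrix(network)
        self.reaction_order = list(S.columns)
        A = S.to_numpy()
        # rank-revealing QR on columns
        _, _, piv = _qr_pivot(A)
        rank = np.linalg.matrix_rank(A)
        self.rank = rank
        dep = sorted(piv[:rank])
        free = sorted(set(range(A.shape[1])) - set(dep))
        self._dep, self._free = dep, free
        self.free_ids = [self.reaction_order[j] for j in free]
        self.dep_ids = [self.reaction_order[j] for j in dep]
        Adep = A[:, dep]
        # v_dep = -pinv(A_dep) A_free v_free  (exact: A_dep spans col space)
        self._T = -np.linalg.pinv(Adep) @ A[:, free]
        self.exchange_ids = [r.id for r in network.all_reactions() if r.reversible]
        self.mixing_groups = _mixing_groups(network)

    @property
    def n_free_net(self) -> int:
        return len(self.free_ids)

    @property
    def n_exchange(self) -> int:
        return len(self.exchange_ids)

    @property
    def n_mixing(self) -> int:
        return sum(len(g) - 1 for g in self.mixing_groups.values())

    @property
    def n_params(self) -> int:
        return self.n_free_net + self.n_exchange + self.n_mixing

    def net_vector(self, theta_net: np.ndarray) -> np.ndarray:
        v = np.empty(len(self.reaction_order))
        v[self._free] = theta_net
        v[self._dep] = self._T @ theta_net
        return v

    def net_jacobian(self) -> np.ndarray:
        """d(net flux vector)/d(theta_net), constant (linear map)."""
        J = np.zeros((len(self.reaction_order), self.n_free_net))
        J[self._free, :] = np.eye(self.n_free_net)
        J[self._dep, :] = self._T
        return J

    def to_fluxmap(self, theta: np.ndarray) -> FluxMap:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        t_net = theta[: self.n_free_net]
        t_ex = theta[self.n_free_net : self.n_free_net + self.n_exchange]
        t_mix = theta[self.n_free_net + self.n_exchange :]
        v = self.net_vector(t_net)
        net = dict(zip(self.reaction_order, v))
        exch = {rid: float(np.clip(10.0**x, 0.0, EXCHANGE_CAP)) for rid, x in zip(self.exchange_ids, t_ex)}
        k = 0
        for _, rids in self.mixing_groups.items():
            w = np.asarray(t_mix[k : k + len(rids) - 1], dtype=float)
            k += len(rids) - 1
            weights = np.append(w, 1.0 - w.sum())
            for rid, wi in zip(rids, weights):
                net[rid] = float(wi)
            sink = self._mixing_sink(rids[0])
            if sink is not None:
                net[sink] = 1.0
        return FluxMap(net=net, exch=exch)

    def from_fluxmap(self, flux: FluxMap) -> np.ndarray:
        t_net = [flux.net[rid] for rid in self.free_ids]
        t_ex = [np.log10(max(flux.exch.get(rid, 0.0), 1e-300)) for rid in self.exchange_ids]
        t_mix = []
        for _, rids in self.mixing_groups.items():
            t_mix.extend(flux.net[rid] for rid in rids[:-1])
        return np.array(t_net + t_ex + t_mix, dtype=float)

    def project(self, flux: FluxMap, enforce_irreversibility: bool = True) -> FluxMap:
        """Nearest exactly-balanced flux map (least squares in net space).

        By default the projection also keeps irreversible net fluxes
        nonnegative, so the result is a feasible simulation input even when
        the source vector sits right at an irreversibility boundary (as
        rounded published solutions do).
        """
        S = stoichiometric_matrix(self.network).to_numpy()
        v = np.array([flux.net[rid] for rid in self.reaction_order])
        ns = _null_space(S)
        theta = ns.T @ v  # orthogonal projection coordinates
        irr = [
            j
            for j, r in enumerate(self.network.all_reactions())
            if not r.reversible
        ]
        v_bal = ns @ theta
        if enforce_irreversibility and np.any(v_bal[irr] < 0):
            from scipy.optimize import minimize

            res = minimize(
                lambda th: 0.5 * np.sum((ns @ th - v) ** 2),
                theta,
                jac=lambda th: ns.T @ (ns @ th - v),
                constraints=[
                    {
                        "type": "ineq",
                        "fun": lambda th: (ns @ th)[irr],
                        "jac": lambda th: ns[irr, :],
                    }
                ],
                method="SLSQP",
                options={"maxiter": 200, "ftol": 1e-14},
            )
            v_bal = ns @ res.x
            v_bal[irr] = np.maximum(v_bal[irr], 0.0)
        out = FluxMap(net=dict(flux.net), exch=dict(flux.exch))
        out.net.update(dict(zip(self.reaction_order, v_bal)))
        for _, rids in self.mixing_groups.items():
            total = sum(out.net.get(rid, 0.0) for rid in rids)
            if total > 0:
                for rid in rids:
                    out.net[rid] = out.net.get(rid, 0.0) / total
        return out

    def _mixing_sink(self, any_mix_rid: str) -> str | None:
        pool = self.network.reaction(any_mix_rid).products[0].metabolite
        for r in self.network.mixing:
            if any(t.metabolite == pool for t in r.reactants):
                return r.id
        return None


def _mixing_groups(network: Network) -> dict[str, list[str]]:
    """Group mixing pseudo-reactions by their target measurement pool."""
    groups: dict[str, list[str]] = {}
    for r in network.mixing:
        if r.reactants and r.reactants[0].coef == 0.0:
            groups.setdefault(r.products[0].metabolite, []).append(r.id)
    return {k: sorted(v) for k, v in sorted(groups.items())}


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    return qr(A, pivoting=True, mode="economic")


def _null_space(S: np.ndarray) -> np.ndarray:
    from scipy.linalg import null_space

    return null_space(S)


def free_flux_parameterization(network: Network) -> FreeFluxBasis:
    """Build the free-flux basis used by the fitting stage."""
    return FreeFluxBasis(network)


# ---------------------------------------------------------------------------
# flux table I/O (published-table column layout)

_FLUX_COLUMNS = ["type", "pathway", "id", "reaction", "flux", "lb", "ub"]


def read_flux_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".net")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("type", "id", "flux") if c not in df.columns]
    if missing:
        raise ValueError(f"flux table missing columns {missing} in {path}")
    for col in ("flux", "lb", "ub"):
        if col in df.columns:
            df[col] = df[col].map(_parse_bound)
    return df


def _parse_bound(x):
    if isinstance(x, str):
        x = x.strip()
        if x in ("", "NA"):
            return np.nan
        if x in ("Inf", "inf"):
            return np.inf
        if x in ("-Inf", "-inf"):
            return -np.inf
    return float(x)


def write_flux_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _FLUX_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def fluxmap_from_table(df: pd.DataFrame) -> FluxMap:
    """Build a FluxMap from a table in the published layout."""
    net = {}
    exch = {}
    net_b = {}
    exch_b = {}
    for _, row in df.iterrows():
        rid = str(row["id"]).strip()
        bounds = (row.get("lb", np.nan), row.get("ub", np.nan))
        if str(row["type"]).strip().upper() == "EXCH":
            exch[rid] = row["flux"]
            exch_b[rid] = bounds
        else:
            net[rid] = row["flux"]
            net_b[rid] = bounds
    return FluxMap(net=net, exch=exch, net_bounds=net_b, exch_bounds=exch_b)
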