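"""Elementary metabolite unit (EMU) decomposition of atom-transition networks.

An EMU is a metabolite together with a subset of its carbon atoms; its
labeling state is the mass distribution over that subset.  Starting from the
observed fragments, the decomposition traces atoms backwards through every
producing reaction and collects the minimal set of EMUs whose balances
determine the observed MIDs, layered by size so that the size-k linear
system depends only on smaller sizes and on network inputs.

Rotationally symmetric molecules (succinate, fumarate) are handled by
orientation averaging: every production term into a symmetric pool is split
into two half-weight terms, one per orientation, so the stored distribution
is the 50/50 average and is invariant to the orientation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Network, Reaction

__all__ = ["EMU", "ProductionTerm", "EMUSystem", "emu_decomposition"]


@dataclass(frozen=True, order=True)
class EMU:
    metabolite: str
    atoms: tuple[int, ...]  # sorted, 1-based

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return f"{self.metabolite}[{','.join(map(str, self.atoms))}]"


@dataclass(frozen=True)
class ProductionTerm:
    """One production route into an EMU.

    ``rate = weight * coef * flux(reaction, direction)``; ``sources`` holds
    one EMU for a direct transfer or several for a condensation (the source
    MIDs convolve).  Sources may be input-species EMUs.
    """

    reaction: str
    direction: int  # +1 forward, -1 backward
    coef: float
    weight: float  # 0.5 per orientation for symmetric products, else 1.0
    sources: tuple[EMU, ...]


@dataclass
class EMUSystem:
    network: Network
    observed: list[EMU]
    #: internal (solvable) EMUs grouped by size, deterministic order
    layers: dict[int, list[EMU]]
    #: production terms per internal EMU
    producers: dict[EMU, list[ProductionTerm]]
    #: input-species EMUs appearing as sources
    inputs: list[EMU]
    #: total consumption terms per internal metabolite: (reaction, direction, coef)
    consumption: dict[str, list[tuple[str, int, float]]]
    #: metabolites fed exclusively by mixing pseudo-reactions (algebraic pools)
    algebraic_mets: set[str] = field(default_factory=set)

    @property
    def sizes(self) -> list[int]:
        return sorted(self.layers)

    def emus(self) -> list[EMU]:
        return [e for k in self.sizes for e in self.layers[k]]

    def __len__(self) -> int:
        return sum(len(v) for v in self.layers.values())


def _directions(rxn: Reaction):
    yield 1, rxn.reactants, rxn.products
    if rxn.reversible:
        yield -1, rxn.products, rxn.reactants


def _canonical(network: Network, met: str, atoms: frozenset[int]) -> EMU:
    """Canonical atom set; symmetric molecules pick the lexicographically
    smaller of the two orientations so mirror EMUs coincide."""
    n = network.metabolites[met].n_carbons
    a = tuple(sorted(atoms))
    if network.metabolites[met].symmetric:
        b = tuple(sorted(n + 1 - i for i in atoms))
        a = min(a, b)
    return EMU(met, a)


def emu_decomposition(
    network: Network, observed: list[tuple[str, tuple[int, ...] | None]]
) -> EMUSystem:
    """Decompose ``network`` into the EMU basis of the observed fragments.

    ``observed`` lists ``(metabolite, atoms)`` pairs; ``atoms=None`` selects
    the full carbon backbone.  Raises ``ValueError`` for unknown metabolites
    or fragments larger than the molecule.
    """
    input_species = {m.id for m in network.metabolites.values() if not m.balanced}
    # measurement pools fed by mixing pseudo-reactions are solvable
    mixing_targets = {r.products[0].metabolite for r in network.mixing if r.reactants[0].coef == 0}
    input_species -= mixing_targets

    obs: list[EMU] = []
    for met, atoms in observed:
        if met not in network.metabolites:
            raise ValueError(f"unknown metabolite {met!r}")
        n = network.metabolites[met].n_carbons
        if n is None:
            raise ValueError(f"metabolite {met!r} carries no mapped carbons")
        if atoms is None:
            atoms = tuple(range(1, n + 1))
        if any(a < 1 or a > n for a in atoms):
            raise ValueError(f"fragment {atoms} outside {met} (C{n})")
        obs.append(_canonical(network, met, frozenset(atoms)))

    producers: dict[EMU, list[ProductionTerm]] = {}
    inputs: set[EMU] = set()
    stack = [e for e in obs if e.metabolite not in input_species]
    inputs.update(e for e in obs if e.metabolite in input_species)

    while stack:
        emu = stack.pop()
        if emu in producers:
            continue
        terms = _producing_terms(network, emu)
        producers[emu] = terms
        for t in terms:
            for src in t.sources:
                if src.metabolite in input_species:
                    inputs.add(src)
                elif src not in producers:
                    stack.append(src)

    layers: dict[int, list[EMU]] = {}
    for e in sorted(producers):
        layers.setdefault(e.size, []).append(e)
    layers = dict(sorted(layers.items()))

    consumption: dict[str, list[tuple[str, int, float]]] = {}
    mets = {e.metabolite for e in producers}
    for rxn in network.all_flux_entries():
        for direction, lhs, _ in _directions(rxn):
            for term in lhs:
                if term.metabolite in mets and term.coef > 0:
                    consumption.setdefault(term.metabolite, []).append(
                        (rxn.id, direction, term.coef)
                    )

    algebraic = set()
    for met in mets:
        feeding = {
            t.reaction for e, ts in producers.items() if e.metabolite == met for t in ts
        }
        if feeding and feeding <= {r.id for r in network.mixing}:
            algebraic.add(met)

    return EMUSystem(
        network=network,
        observed=obs,
        layers=layers,
        producers=producers,
        inputs=sorted(inputs),
        consumption=consumption,
        algebraic_mets=algebraic,
    )


def _producing_terms(network: Network, emu: EMU) -> list[ProductionTerm]:
    met = network.metabolites[emu.metabolite]
    n = met.n_carbons
    atom_sets: list[tuple[float, frozenset[int]]] = [(1.0, frozenset(emu.atoms))]
    if met.symmetric:
        mirror = frozenset(n + 1 - a for a in emu.atoms)
        atom_sets = [(0.5, frozenset(emu.atoms)), (0.5, mirror)]

    terms: list[ProductionTerm] = []
    for rxn in network.all_flux_entries():
        for direction, lhs, rhs in _directions(rxn):
            for pterm in rhs:
                if pterm.metabolite != emu.metabolite or pterm.atoms is None:
                    continue
                for weight, atoms in atom_sets:
                    letters = {pterm.atoms[a - 1] for a in atoms}
                    sources = _pull_back(network, lhs, letters, rxn.id)
                    terms.append(
                        ProductionTerm(
                            reaction=rxn.id,
                            direction=direction,
                            coef=pterm.coef if pterm.coef > 0 else 1.0,
                            weight=weight,
                            sources=sources,
                        )
                    )
    if not terms:
        raise ValueError(f"EMU {emu} has no producing reactions")
    return terms


def _pull_back(network, lhs, letters: set[str], rid: str) -> tuple[EMU, ...]:
    found: dict[int, tuple[str, set[int]]] = {}
    remaining = set(letters)
    for idx, sterm in enumerate(lhs):
        if sterm.atoms is None:
            continue
        hit = {i + 1 for i, a in enumerate(sterm.atoms) if a in letters}
        if hit:
            found[idx] = (sterm.metabolite, hit)
            remaining -= {sterm.atoms[i - 1] for i in hit}
    if remaining:
        raise ValueError(f"atoms {sorted(remaining)} of {rid} have no mapped source")
    return tuple(
        _canonical(network, met, frozenset(atoms))
        for _, (met, atoms) in sorted(found.items())
    )
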