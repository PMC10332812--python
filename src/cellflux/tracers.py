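"""Isotopic tracer specifications and input labeling states.

A tracer describes one commercially labeled substrate species: which carbon
positions carry the heavy isotope, the isotopic enrichment of those
positions, the mole fraction of the substrate pool supplied as this tracer,
and the chemical purity of the label.  Simulation runs in
natural-abundance-corrected space, so unlabeled positions carry exactly zero
heavy-isotope probability; natural-abundance handling lives in the MID
correction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TracerSpec", "InputLabeling", "position_probabilities", "bernoulli_mid"]


@dataclass(frozen=True)
class TracerSpec:
    """One labeled form of one substrate.

    Parameters
    ----------
    substrate:
        Network id of the extracellular species (e.g. ``"GLC.x"``).
    positions:
        1-based labeled carbon positions (e.g. ``(1, 2)`` for [1,2-13C2]).
    fraction:
        Mole fraction of the substrate pool supplied as this tracer; the
        remainder of the pool (and any position not listed) is unlabeled.
    enrichment:
        Isotopic enrichment of each labeled position.
    purity:
        Chemical/isotopic purity of the label; each nominally labeled
        position carries 13C with probability ``enrichment * purity``.
    """

    substrate: str
    positions: tuple[int, ...]
    fraction: float = 1.0
    enrichment: float = 1.0
    purity: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("tracer fraction must be in [0, 1]")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")


def apply_tracer_impurity(tracer: TracerSpec, purity: float) -> TracerSpec:
    """Return a copy of ``tracer`` with the stated label purity."""
    return TracerSpec(
        tracer.substrate, tracer.positions, tracer.fraction, tracer.enrichment, purity
    )


def position_probabilities(tracer: TracerSpec, n_carbons: int) -> np.ndarray:
    """Per-position probability of carrying the heavy isotope."""
    p = np.zeros(n_carbons)
    for pos in tracer.positions:
        if not 1 <= pos <= n_carbons:
            raise ValueError(
                f"tracer position {pos} outside {tracer.substrate} (C{n_carbons})"
            )
        p[pos - 1] = tracer.enrichment * tracer.purity
    return p


def bernoulli_mid(probs: np.ndarray) -> np.ndarray:
    """MID of independent per-position labeling probabilities (Poisson binomial)."""
    mid = np.array([1.0])
    for p in probs:
        mid = np.convolve(mid, [1.0 - p, p])
    return mid


@dataclass
class InputLabeling:
    """Labeling state of every unbalanced input species.

    Each substrate maps to a list of ``(fraction, per-position probabilities)``
    mixture components; unspecified substrates are unlabeled.
    """

    components: dict[str, list[tuple[float, np.ndarray]]] = field(default_factory=dict)

    @classmethod
    def from_tracers(
        cls, tracers: list[TracerSpec], carbon_counts: dict[str, int]
    ) -> "InputLabeling":
        comp: dict[str, list[tuple[float, np.ndarray]]] = {}
        for t in tracers:
            n = carbon_counts[t.substrate]
            comp.setdefault(t.substrate, []).append(
                (t.fraction, position_probabilities(t, n))
            )
        for sub, parts in comp.items():
            tot = sum(f for f, _ in parts)
            if tot > 1.0 + 1e-9:
                raise ValueError(f"tracer fractions for {sub} sum to {tot} > 1")
            if tot < 1.0 - 1e-12:
                n = carbon_counts[sub]
                parts.append((1.0 - tot, np.zeros(n)))
        return cls(comp)

    def emu_mid(self, substrate: str, atoms: tuple[int, ...]) -> np.ndarray:
        """MID of the EMU of ``substrate`` restricted to ``atoms`` (1-based)."""
        parts = self.components.get(substrate)
        if parts is None:
            return np.eye(len(atoms) + 1)[0]  # unlabeled: all mass in M0
        out = np.zeros(len(atoms) + 1)
        for frac, probs in parts:
            out += frac * bernoulli_mid(probs[[a - 1 for a in atoms]])
        return out

    def isotopomer_distribution(self, substrate: str, n_carbons: int) -> np.ndarray:
        """Full 2^n positional isotopomer distribution (bit i = position i+1)."""
        parts = self.components.get(substrate, [(1.0, np.zeros(n_carbons))])
        out = np.zeros(2**n_carbons)
        for frac, probs in parts:
            d = np.array([1.0])
            for p in probs:  # bit order: position 1 = least significant
                d = np.concatenate([d * (1.0 - p), d * p])
            out += frac * d
        return out
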