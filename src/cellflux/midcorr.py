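"""Natural-isotope-abundance correction of mass isotopomer distributions.

Raw isotopologue peak areas measured by LC-MS mix the biological 13C
enrichment with naturally occurring heavy isotopes of every atom in the
measured ion.  The correction builds the matrix whose column j is the
expected measured MID of a molecule carrying exactly j tracer-element
labels, then inverts it by nonnegative least squares so corrected fractions
stay on the probability simplex even for noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ElementComposition",
    "MassIsotopomerDistribution",
    "NATURAL_ABUNDANCE",
    "build_correction_matrix",
    "correct_natural_abundance",
    "normalize_peak_areas",
    "convolve_natural_abundance",
    "correct_mid_table",
]

#: Representative isotopic abundances (fraction of each heavy isotope by
#: mass shift relative to the monoisotopic form).
NATURAL_ABUNDANCE: dict[str, dict[int, float]] = {
    "C": {1: 0.0107},
    "H": {1: 0.000115},
    "N": {1: 0.00364},
    "O": {1: 0.00038, 2: 0.00205},
    "S": {1: 0.0075, 2: 0.0421},
    "Si": {1: 0.046832, 2: 0.030872},
}


@dataclass(frozen=True)
class ElementComposition:
    """Element counts of the measured ion (C is the tracer element)."""

    C: int
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    Si: int = 0

    def __post_init__(self):
        for el in ("C", "H", "N", "O", "S", "Si"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")
        if self.C < 1:
            raise ValueError("tracer element C requires at least one carbon")

    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ("C", "H", "N", "O", "S", "Si")}

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Parse a Hill-style formula like ``C3H4O3`` or ``C5H8NO4Si``."""
        import re

        counts: dict[str, int] = {}
        for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
            if not el:
                continue
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        unknown = set(counts) - set(NATURAL_ABUNDANCE)
        if unknown:
            raise ValueError(f"unknown element(s) {sorted(unknown)} in {formula!r}")
        return cls(**{k: v for k, v in counts.items()})


@dataclass
class MassIsotopomerDistribution:
    """Fractional abundances M0..Mn of one metabolite fragment."""

    metabolite: str
    fractions: np.ndarray
    sds: np.ndarray | None = None
    corrected: bool = False
    composition: ElementComposition | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1


def _shift_distribution(element: str, n_atoms: int, abundances, max_shift: int) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` atoms of one element."""
    iso = abundances.get(element, {})
    single = np.zeros(max(max_shift + 1, max(iso, default=0) + 1))
    single[0] = 1.0 - sum(iso.values())
    for shift, frac in iso.items():
        single[shift] = frac
    dist = np.array([1.0])
    for _ in range(n_atoms):
        dist = np.convolve(dist, single)
    return dist[: max_shift + 1]


def build_correction_matrix(
    comp: ElementComposition,
    abundances: dict[str, dict[int, float]] | None = None,
) -> np.ndarray:
    """(n+1) x (n+1) natural-abundance matrix for an ion with n carbons.

    Column j is the expected measured MID of a species with exactly j 13C
    labels: the multinomial mass-shift expansion of all non-tracer atoms
    convolved with the natural 13C distribution of the remaining n-j
    carbons.  Mass shifts beyond n are truncated, so columns sum to <= 1.
    """
    abundances = NATURAL_ABUNDANCE if abundances is None else abundances
    unknown = {el for el, n in comp.counts().items() if n > 0} - set(abundances)
    if unknown:
        raise ValueError(f"no abundance data for element(s) {sorted(unknown)}")
    n = comp.C
    non_tracer = np.array([1.0])
    for el, count in comp.counts().items():
        if el == "C" or count == 0:
            continue
        non_tracer = np.convolve(non_tracer, _shift_distribution(el, count, abundances, n))
    non_tracer = non_tracer[: n + 1]

    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = np.convolve(non_tracer, _shift_distribution("C", n - j, abundances, n))
        col = col[: n + 1 - j]
        M[j : j + col.size, j] = col
    return M


def convolve_natural_abundance(
    mid: np.ndarray, comp: ElementComposition, abundances=None
) -> np.ndarray:
    """Forward-convolve a clean MID into the measured (uncorrected) space."""
    M = build_correction_matrix(comp, abundances)
    return M @ np.asarray(mid, dtype=float)


def correct_natural_abundance(
    raw: MassIsotopomerDistribution | np.ndarray,
    comp: ElementComposition,
    abundances=None,
    max_condition: float = 1e8,
) -> MassIsotopomerDistribution:
    """Remove natural-abundance contributions from a raw MID.

    Solves ``M x = raw`` by nonnegative least squares and renormalizes x to
    the simplex; the NNLS residual is recorded in the result's metadata.
    """
    if isinstance(raw, MassIsotopomerDistribution):
        vec = raw.fractions
        name = raw.metabolite
    else:
        vec = np.asarray(raw, dtype=float)
        name = ""
    if vec.size != comp.C + 1:
        raise ValueError(f"MID length {vec.size} does not match C{comp.C} ion")
    M = build_correction_matrix(comp, abundances)
    cond = np.linalg.cond(M)
    if cond > max_condition:
        raise ValueError(f"correction matrix ill-conditioned (cond={cond:.3g})")
    total = vec.sum()
    if total <= 0:
        raise ValueError("raw MID has non-positive total")
    x, resid = nnls(M, vec / total)
    if x.sum() <= 0:
        raise ValueError("correction produced an all-zero MID")
    x = x / x.sum()
    out = MassIsotopomerDistribution(
        metabolite=name, fractions=x, corrected=True, composition=comp
    )
    out.residual = float(resid)
    return out


def normalize_peak_areas(areas: np.ndarray, metabolite: str = "") -> MassIsotopomerDistribution:
    """Convert raw isotopologue peak areas M0..Mn into a MID.

    Negative areas (baseline-subtraction artifacts) are clamped to zero
    with a warning before normalization.
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        warnings.warn("negative peak areas clamped to zero", stacklevel=2)
        areas = np.clip(areas, 0.0, None)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all peak areas are zero")
    return MassIsotopomerDistribution(metabolite=metabolite, fractions=areas / total)


def correct_mid_table(
    table: pd.DataFrame,
    quadrupole_bias: dict[int, float] | None = None,
    abundances=None,
) -> pd.DataFrame:
    """Correct a tidy isotopologue table to a tidy corrected-MID table.

    Expected columns: metabolite, formula, mass_shift, area, and optional
    grouping columns (sample, tracer, time_h).  ``quadrupole_bias`` is a
    pass-through hook applying per-mass-shift multiplicative factors to the
    raw areas before correction (identity when omitted).
    """
    required = {"metabolite", "formula", "mass_shift", "area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"isotopologue table missing columns {sorted(missing)}")
    group_cols = [c for c in table.columns if c not in ("mass_shift", "area")]
    rows = []
    for keys, grp in table.groupby(group_cols, sort=False, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        meta = dict(zip(group_cols, keys))
        comp = ElementComposition.from_formula(meta["formula"])
        areas = np.zeros(comp.C + 1)
        for _, r in grp.iterrows():
            shift = int(r["mass_shift"])
            if not 0 <= shift <= comp.C:
                raise ValueError(
                    f"mass shift {shift} outside 0..{comp.C} for {meta['metabolite']}"
                )
            areas[shift] += r["area"]
        if quadrupole_bias:
            for shift, factor in quadrupole_bias.items():
                if 0 <= shift < areas.size:
                    areas[shift] *= factor
        mid = normalize_peak_areas(areas, meta["metabolite"])
        corrected = correct_natural_abundance(mid, comp, abundances)
        for shift, frac in enumerate(corrected.fractions):
            rows.append({**meta, "mass_shift": shift, "fraction": frac})
    return pd.DataFrame(rows)
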