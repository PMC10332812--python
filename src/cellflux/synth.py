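"""Synthetic culture, labeling, and metabolomics data from known truth.

Every downstream stage of the pipeline has a parameter-recovery surface:
this module generates data with exactly the statistical structure those
stages assume — exponential growth, linear evaporative volume loss,
first-order metabolite degradation, labeling dynamics from a known flux
map, Gaussian measurement noise, and injection-order instrument drift —
from a :class:`GroundTruth` whose parameters the tests then try to recover.

A single integer seed fans out into independent per-operation substreams,
so each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .network import FluxMap, Network, free_flux_parameterization, fluxmap_from_table
from .network import packaged_flux_table, packaged_network
from .simulate import PoolSizeSet, simulate_inst_mids, simulate_steady_state_mids
from .tracers import TracerSpec

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "default_ground_truth",
    "MEDIUM_SPECIES",
    "MEASURED_METABOLITES",
    "TRACER_EXPERIMENTS",
    "simulate_growth_timecourse",
    "simulate_medium_timecourse",
    "simulate_labeling_measurements",
    "simulate_metabolomics_batch",
    "medium_mass",
]

#: medium species -> (transport reaction, sign of medium change per unit
#: net flux); negative flux convention: consumption depletes the medium.
MEDIUM_SPECIES: dict[str, tuple[str, float]] = {
    "GLC.x": ("GLUT", -1.0),
    "PYR.x": ("PYRR", -1.0),
    "LAC.x": ("MCT", +1.0),
    "ALA.x": ("ALAR", +1.0),
    "GLN.x": ("GLNR", -1.0),
    "GLU.x": ("GLUR", +1.0),
    "ASP.x": ("ASPR", +1.0),
    "SER.x": ("SERR", -1.0),
    "CYX.x": ("CYSR", -1.0),
    "GLY.x": ("GLYR", +1.0),
}

#: the intracellular metabolites whose MIDs constrain the flux fit
MEASURED_METABOLITES: list[str] = [
    "AKG", "3PG", "ALA", "ASP", "CIT", "FBP",
    "GLU", "GLN", "LAC", "MAL", "PYR.ms", "SER",
]

#: the three-tracer design of the labeling experiments: parallel cultures,
#: each with one substrate fully replaced by the labeled form
TRACER_EXPERIMENTS: dict[str, list[TracerSpec]] = {
    "glc12": [TracerSpec("GLC.x", (1, 2), purity=0.995)],
    "glcU": [TracerSpec("GLC.x", (1, 2, 3, 4, 5, 6), purity=0.995)],
    "glnU": [TracerSpec("GLN.x", (1, 2, 3, 4, 5), purity=0.995)],
}

_STREAMS = {"growth": 11, "medium": 12, "labeling": 13, "metabolomics": 14, "weights": 15}


@dataclass
class NoiseModel:
    """Per-channel measurement noise (SDs; all >= 0)."""

    count_cv: float = 0.10  # lognormal sigma on cell counts
    conc_cv: float = 0.05  # Gaussian CV on concentrations
    mid_sd: float = 0.003  # additive SD per MID fraction (mol fraction)
    weight_sd_g: float = 0.005  # dish weighing error

    def __post_init__(self):
        for name in ("count_cv", "conc_cv", "mid_sd", "weight_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator needs; the recovery target of the tests.

    Units: mu 1/h; x0 cells; fluxes fmol/cell/h; pool sizes fmol/cell;
    degradation rates 1/h (positive = decay, dM/dt = -kM + vX); evaporation
    g/h; initial medium masses nmol; volume mL.
    """

    mu: float
    x0: float
    fluxes: FluxMap
    pool_sizes: PoolSizeSet
    k_map: dict[str, float]
    evap_rate: float
    m0_map: dict[str, float]
    volume0_ml: float = 2.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("growth rate must be nonnegative")
        if self.x0 <= 0:
            raise ValueError("initial cell count must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self) -> str:
        fnum = lambda d: {k: float(v) for k, v in d.items()}
        doc = {
            "mu": float(self.mu),
            "x0": float(self.x0),
            "volume0_ml": float(self.volume0_ml),
            "evap_rate": float(self.evap_rate),
            "k_map": fnum(self.k_map),
            "m0_map": fnum(self.m0_map),
            "pool_sizes": {"default": float(self.pool_sizes.default), **fnum(self.pool_sizes.sizes)},
            "noise": {
                "count_cv": float(self.noise.count_cv),
                "conc_cv": float(self.noise.conc_cv),
                "mid_sd": float(self.noise.mid_sd),
                "weight_sd_g": float(self.noise.weight_sd_g),
            },
            "seed": int(self.seed),
            "fluxes": {"net": fnum(self.fluxes.net), "exch": fnum(self.fluxes.exch)},
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruth":
        doc = yaml.safe_load(text)
        pools = dict(doc.get("pool_sizes", {}))
        default = pools.pop("default", 10.0)
        return cls(
            mu=doc["mu"],
            x0=doc["x0"],
            fluxes=FluxMap(net=doc["fluxes"]["net"], exch=doc["fluxes"].get("exch", {})),
            pool_sizes=PoolSizeSet(pools, default=default),
            k_map=doc.get("k_map", {}),
            evap_rate=doc.get("evap_rate", 0.0),
            m0_map=doc.get("m0_map", {}),
            volume0_ml=doc.get("volume0_ml", 2.0),
            noise=NoiseModel(**doc.get("noise", {})),
            seed=doc.get("seed", 0),
        )


def default_ground_truth(
    cell_type: str = "lf",
    condition: str = "normoxia",
    seed: int = 0,
    exchange_cap: float = 1000.0,
    network: Network | None = None,
) -> GroundTruth:
    """A plausible ground truth built on a published flux solution.

    The net fluxes are the published solution for the chosen cell type and
    oxygen condition, projected onto exact steady-state balance; exchange
    fluxes are clipped at ``exchange_cap`` because the very large published
    exchange values are unidentifiable and only slow the labeling system.
    Growth rate is taken equal to the biomass flux; culture parameters are
    a 35 mm dish seeded at 25,000 cells in 2 mL of standard medium.
    """
    table = {"normoxia": "21", "hypoxia": "05"}[condition]
    net = network if network is not None else packaged_network(cell_type)
    basis = free_flux_parameterization(net)
    printed = fluxmap_from_table(packaged_flux_table(f"{cell_type}_{table}"))
    fm = basis.project(printed)
    fm.exch = {rid: min(v, exchange_cap) for rid, v in fm.exch.items()}
    volume0 = 2.0
    # low-substrate flux medium with plasma-like amino acid levels, so the
    # 72 h concentration change of every measured species is resolvable
    m0_mM = {
        "GLC.x": 5.5, "GLN.x": 0.65, "PYR.x": 1.0, "LAC.x": 0.5,
        "SER.x": 0.15, "GLY.x": 0.25, "CYX.x": 0.05, "ALA.x": 0.02,
        "GLU.x": 0.1, "ASP.x": 0.025,
    }
    return GroundTruth(
        mu=fm.net["BIOMASS"],
        x0=25_000.0,
        fluxes=fm,
        pool_sizes=PoolSizeSet(default=10.0),
        k_map={"GLN.x": 0.004},  # spontaneous glutamine breakdown
        evap_rate=0.2 / 72.0,  # ~0.2 g lost over a 72 h run
        m0_map={k: v * volume0 * 1000.0 for k, v in m0_mM.items()},  # nmol
        volume0_ml=volume0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# growth and medium


def simulate_growth_timecourse(
    truth: GroundTruth,
    times: np.ndarray,
    n_replicates: int = 4,
    noise: bool = True,
) -> pd.DataFrame:
    """Cell-count series per replicate; lognormal multiplicative noise."""
    times = _check_times(times)
    rng = truth.rng("growth")
    expected = truth.x0 * np.exp(truth.mu * times)
    rows = []
    for rep in range(1, n_replicates + 1):
        vals = expected.copy()
        if noise and truth.noise.count_cv > 0:
            vals = vals * rng.lognormal(0.0, truth.noise.count_cv, size=times.size)
        for t, x in zip(times, vals):
            rows.append({"replicate": rep, "time_h": t, "cells": x})
    return pd.DataFrame(rows)


def medium_mass(
    truth: GroundTruth, species: str, times: np.ndarray
) -> np.ndarray:
    """Noiseless medium metabolite mass (nmol) under the growth/decay model.

    Closed form of dM/dt = -kM + vX with X = X0 exp(mu t); the mu + k = 0
    degenerate case uses the analytic limit M exp(kt) = v X0 t + M0.
    """
    times = np.asarray(times, dtype=float)
    rid, sign = MEDIUM_SPECIES[species]
    v_fmol = sign * truth.fluxes.net[rid]
    v = v_fmol * 1e-6  # nmol per cell-hour
    k = truth.k_map.get(species, 0.0)
    m0 = truth.m0_map.get(species, 0.0)
    mu_k = truth.mu + k
    if abs(mu_k) < 1e-12:
        y = v * truth.x0 * times + m0
    else:
        y = v * truth.x0 / mu_k * np.expm1(mu_k * times) + m0
    return y * np.exp(-k * times)


def _volume_ml(truth: GroundTruth, times: np.ndarray, density: float = 1.0) -> np.ndarray:
    mass_g = truth.volume0_ml * density - truth.evap_rate * times
    if np.any(mass_g <= 0):
        t_dep = truth.volume0_ml * density / truth.evap_rate
        raise ValueError(f"medium volume depleted by evaporation at t = {t_dep:.1f} h")
    return mass_g / density


def simulate_medium_timecourse(
    truth: GroundTruth,
    times: np.ndarray,
    n_replicates: int = 4,
    noise: bool = True,
    cell_free: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentration series (mM) per species/replicate + dish-weight series.

    ``cell_free=True`` simulates unconditioned medium (no cells): only
    first-order degradation/accumulation acts, which is exactly the series
    the degradation-rate stage consumes.
    """
    times = _check_times(times)
    rng = truth.rng("medium")
    vol = _volume_ml(truth, times)
    rows = []
    for species in truth.m0_map:
        if cell_free:
            k = truth.k_map.get(species, 0.0)
            mass = truth.m0_map.get(species, 0.0) * np.exp(-k * times)
        else:
            mass = medium_mass(truth, species, times)
        conc = mass / vol / 1000.0  # nmol/mL -> mM
        for rep in range(1, n_replicates + 1):
            vals = conc.copy()
            if noise and truth.noise.conc_cv > 0:
                vals = vals + rng.normal(0.0, truth.noise.conc_cv * np.abs(conc))
                vals = np.clip(vals, 0.0, None)
            for t, c in zip(times, vals):
                rows.append(
                    {"species": species, "replicate": rep, "time_h": t, "conc_mM": c}
                )
    wrng = truth.rng("weights")
    weights = truth.volume0_ml * 1.0 - truth.evap_rate * times
    if noise and truth.noise.weight_sd_g > 0:
        weights = weights + wrng.normal(0.0, truth.noise.weight_sd_g, size=times.size)
    wdf = pd.DataFrame({"time_h": times, "weight_g": weights})
    return pd.DataFrame(rows), wdf


# ---------------------------------------------------------------------------
# labeling


def simulate_labeling_measurements(
    truth: GroundTruth,
    network: Network,
    tracers: dict[str, list[TracerSpec]] | None = None,
    times: np.ndarray | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 3,
    observed: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy MID table per tracer experiment (and time, if nonstationary).

    Noiseless rows equal the flux-simulation output exactly; noise is
    additive Gaussian truncated at zero and renormalized to the simplex.
    Columns: experiment, metabolite, time_h (NaN for steady state),
    replicate, mass_shift, fraction.
    """
    tracers = TRACER_EXPERIMENTS if tracers is None else tracers
    observed = MEASURED_METABOLITES if observed is None else observed
    obs = [(m, None) for m in observed]
    noise_sd = truth.noise.mid_sd if noise_sd is None else noise_sd
    rng = truth.rng("labeling")
    rows = []
    for exp_name, spec in tracers.items():
        if times is None:
            result = simulate_steady_state_mids(network, truth.fluxes, spec, observed=obs)
            time_points = [np.nan]
            mid_at = {m: {np.nan: result.mid(m)} for m in observed}
        else:
            t = _check_times(times)
            result = simulate_inst_mids(
                network, truth.fluxes, truth.pool_sizes, spec, t, observed=obs
            )
            time_points = list(t)
            mid_at = {
                m: dict(zip(time_points, result.mid(m))) for m in observed
            }
        for met in observed:
            for tp in time_points:
                clean = np.asarray(mid_at[met][tp], dtype=float)
                for rep in range(1, n_replicates + 1):
                    vals = clean
                    if noise_sd > 0:
                        vals = np.clip(clean + rng.normal(0.0, noise_sd, clean.size), 0.0, None)
                        vals = vals / vals.sum()
                    for shift, frac in enumerate(vals):
                        rows.append(
                            {
                                "experiment": exp_name,
                                "metabolite": met,
                                "time_h": tp,
                                "replicate": rep,
                                "mass_shift": shift,
                                "fraction": frac,
                            }
                        )
    return pd.DataFrame(rows)


def synthetic_measurement_set(
    truth: GroundTruth,
    network: Network,
    tracers: dict[str, list[TracerSpec]] | None = None,
    observed: list[str] | None = None,
    mid_sd: float | None = None,
    flux_cv: float = 0.05,
    include_growth: bool = True,
):
    """Noisy, SD-matched measurement set for flux-fitting recovery studies.

    One measured MID per tracer experiment and metabolite (noise SD equals
    the SD handed to the fit, so the SSR of a correct fit is chi-square
    distributed), plus extracellular flux observations at ``flux_cv``
    relative error and, optionally, the growth rate as the biomass flux.
    """
    from .fitting import MeasurementSet

    tracers = TRACER_EXPERIMENTS if tracers is None else tracers
    mid_sd = truth.noise.mid_sd if mid_sd is None else mid_sd
    midtab = simulate_labeling_measurements(
        truth, network, tracers=tracers, noise_sd=0.0, n_replicates=1,
        observed=observed,
    )
    mids = midtab[["experiment", "metabolite", "mass_shift", "fraction"]].copy()
    # untruncated Gaussian noise: corrected MID fractions scatter below
    # zero in practice, and the chi-square calibration assumes exactly the
    # error model the estimator weights with
    if mid_sd > 0:
        nrng = truth.rng("labeling")
        mids["fraction"] = mids["fraction"] + nrng.normal(0.0, mid_sd, len(mids))
    mids["sd"] = mid_sd if mid_sd > 0 else 1e-4
    rng = truth.rng("medium")  # independent of the labeling stream
    rows = []
    for species, (rid, _) in MEDIUM_SPECIES.items():
        v = truth.fluxes.net[rid]
        sd = max(flux_cv * abs(v), 0.01)
        rows.append({"reaction": rid, "value": v + rng.normal(0.0, sd), "sd": sd})
    if include_growth:
        v = truth.fluxes.net["BIOMASS"]
        sd = max(flux_cv * v, 1e-4)
        rows.append({"reaction": "BIOMASS", "value": v + rng.normal(0.0, sd), "sd": sd})
    return MeasurementSet(mids=mids, fluxes=pd.DataFrame(rows), tracers=tracers)


# ---------------------------------------------------------------------------
# metabolomics batches


def simulate_metabolomics_batch(
    true_abundance: pd.DataFrame,
    drift_profile=None,
    qc_every: int = 4,
    missing_rate: float = 0.0,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Peak-area matrix with injection order, QC flags, drift and missingness.

    ``true_abundance`` is samples x features.  Pooled QC injections (the
    feature-wise mean of the biological samples) are placed at the start,
    the end, and between every ``qc_every`` samples.  ``drift_profile`` maps
    injection order (0-based) to a positive multiplicative factor applied
    to every feature.  Missingness is MCAR at ``missing_rate``.
    """
    if qc_every < 1:
        raise ValueError("qc_every must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, _STREAMS["metabolomics"]])
    qc_profile = true_abundance.mean(axis=0)

    labels: list[tuple[str, str]] = [("QC_0", "qc")]
    qc_n = 1
    for i, sample in enumerate(true_abundance.index):
        if i > 0 and i % qc_every == 0:
            labels.append((f"QC_{qc_n}", "qc"))
            qc_n += 1
        labels.append((str(sample), "sample"))
    labels.append((f"QC_{qc_n}", "qc"))

    rows = []
    for order, (name, cls) in enumerate(labels):
        base = qc_profile if cls == "qc" else true_abundance.loc[name]
        factor = 1.0 if drift_profile is None else float(drift_profile(order))
        if factor <= 0:
            raise ValueError(f"drift profile non-positive at injection {order}")
        vals = base.to_numpy(dtype=float) * factor
        if noise_cv > 0:
            vals = vals * rng.lognormal(0.0, noise_cv, size=vals.size)
        if missing_rate > 0:
            mask = rng.random(vals.size) < missing_rate
            vals = np.where(mask, np.nan, vals)
        rows.append(
            {"injection": order, "sample": name, "class": cls,
             **dict(zip(true_abundance.columns, vals))}
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# randomized small networks (EMU-vs-oracle cross-checks)

# structural templates: each reaction is (id, reactants, products) with
# (metabolite, carbon-count) pairs; every template keeps the internal
# carbon total at 11 so exhaustive isotopomer enumeration stays cheap
_TOY_TEMPLATES = [
    (  # chain with cleavage and recombination
        [
            ("IN", [("S.x", 3)], [("M1", 3)]),
            ("SPL", [("M1", 3)], [("M2", 2), ("M3", 1)]),
            ("ISO", [("M2", 2)], [("M4", 2)]),
            ("CMB", [("M4", 2), ("M3", 1)], [("M5", 3)]),
            ("OUT", [("M5", 3)], [("P.x", 3)]),
        ],
        [],
    ),
    (  # loop with condensation and a symmetric pool
        [
            ("IN1", [("S.x", 2)], [("A", 2)]),
            ("IN2", [("T.x", 2)], [("B", 2)]),
            ("CND", [("A", 2), ("B", 2)], [("C", 4)]),
            ("DEC", [("C", 4)], [("E", 3), ("CO2.x", 1)]),
            ("REC", [("E", 3)], [("B", 2), ("CO2b.x", 1)]),
            ("OUT", [("E", 3)], [("P.x", 3)]),
        ],
        ["E"],
    ),
    (  # branch point with two competing products
        [
            ("IN", [("S.x", 3)], [("X", 3)]),
            ("BR1", [("X", 3)], [("Y", 3)]),
            ("BR2", [("X", 3)], [("Z", 1), ("C1.x", 2)]),
            ("MRG", [("Y", 3), ("Z", 1)], [("W", 4)]),
            ("OUT1", [("W", 4)], [("P.x", 4)]),
            ("OUT2", [("Y", 3)], [("Q.x", 3)]),
        ],
        [],
    ),
]


def random_toy_case(seed: int):
    """A random small network, balanced flux map, tracer and observations.

    Atom maps are random bijections, all reactions are reversible with
    positive exchange (guaranteeing positive pool throughput), and net
    fluxes are sampled from the stoichiometric null space; useful as a
    stress surface for simulator cross-validation.
    """
    from scipy.linalg import null_space

    from .network import parse_network, stoichiometric_matrix

    rng = np.random.default_rng(seed)
    reactions, symmetric = _TOY_TEMPLATES[seed % len(_TOY_TEMPLATES)]
    lines = []
    externals = sorted(
        {m for _, lhs, rhs in reactions for m, _ in lhs + rhs if m.endswith(".x")}
    )
    lines.append("% unbalanced: " + " ".join(externals))
    if symmetric:
        lines.append("% symmetric: " + " ".join(symmetric))
    alphabet = "abcdefghijkl"
    for rid, lhs, rhs in reactions:
        n = sum(c for _, c in lhs)
        letters = list(alphabet[:n])
        pos = 0
        lhs_txt = []
        for met, c in lhs:
            lhs_txt.append(f"{met} ({''.join(letters[pos:pos+c])})")
            pos += c
        perm = list(letters)
        rng.shuffle(perm)
        pos = 0
        rhs_txt = []
        for met, c in rhs:
            rhs_txt.append(f"{met} ({''.join(perm[pos:pos+c])})")
            pos += c
        lines.append(f"{rid}: {' + '.join(lhs_txt)} <-> {' + '.join(rhs_txt)}")
    net = parse_network("\n".join(lines))

    S = stoichiometric_matrix(net)
    ns = null_space(S.to_numpy())
    for _ in range(100):
        v = ns @ rng.normal(1.0, 1.0, ns.shape[1])
        if np.max(np.abs(v)) > 0.3:
            break
    flux = FluxMap(
        net=dict(zip(S.columns, v)),
        exch={rid: float(rng.uniform(0.2, 2.0)) for rid in S.columns},
    )
    substrate = externals[0]
    n_sub = net.carbon_count(substrate)
    k = int(rng.integers(1, n_sub + 1))
    positions = tuple(sorted(rng.choice(np.arange(1, n_sub + 1), size=k, replace=False)))
    tracers = [TracerSpec(substrate, positions, fraction=float(rng.uniform(0.4, 1.0)))]
    observed = [(m.id, None) for m in net.metabolites.values() if m.balanced]
    return net, flux, tracers, observed


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    return times
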