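"""Synthetic fluxome datasets: conditions paired with feasible flux vectors.

Real training data for this pipeline comes from curated isotope-tracing
studies; this module emulates that table's exact shape so every stage is
testable offline.  A deterministic response kernel maps each sampled culture
condition to a target point in flux space (substrate entries fix the
boundary constants; the oxygen level throttles TCA-cycle fluxes; species
offsets shift the pentose-phosphate/Entner-Doudoroff split; growth rate
modulates biomass drains with a saturating response).  The target is then
projected onto the stoichiometric polytope of its own substrate mix (unit
weights, reusing the QP machinery) and stepped a random fraction toward the
Chebyshev center so every "true" vector is strictly feasible.  Observed
fluxes add iid Gaussian noise per flux on the normalized scale, mimicking
roughly symmetric isotope-tracing confidence intervals.

The kernel is synthetic: it is smooth and qualitatively biology-shaped, but
its coefficients are not fitted to any organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .encoding import TABLE_COLUMNS, CultureCondition
from .qp_correction import FluxBounds, correct
from .stoichiometry import (
    FLUX_IDS,
    N_FLUXES,
    SUBSTRATES,
    ConstraintSystem,
    FluxVector,
    SubstrateMix,
    assemble_constraints,
    check_feasibility,
)

__all__ = [
    "DEFAULT_VOCABULARIES",
    "ResponseKernel",
    "SyntheticSample",
    "SyntheticDataset",
    "sample_condition",
    "sample_feasible_flux",
    "chebyshev_center",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_VOCABULARIES: dict[str, list[str]] = {
    "species": [
        "E. coli",
        "B. subtilis",
        "C. glutamicum",
        "P. putida",
        "S. oneidensis",
        "G. thermoglucosidasius",
    ],
    "nutrient_type": ["minimal", "rich"],
    "oxygen": ["aerobic", "microaerobic", "anaerobic"],
    "engineering_method": ["none", "knockout", "overexpression"],
    "genetic_background": ["wild_type", "engineered"],
    "cultivation_method": ["shake_flask", "fermentor", "chemostat", "sealed_batch"],
}

_OXYGEN_FACTOR = {"aerobic": 1.0, "microaerobic": 0.55, "anaerobic": 0.15}

# per-species shifts of the oxidative-PP fraction and ED-pathway share
_SPECIES_PP = {
    "E. coli": 0.25,
    "B. subtilis": 0.30,
    "C. glutamicum": 0.40,
    "P. putida": 0.05,
    "S. oneidensis": 0.15,
    "G. thermoglucosidasius": 0.20,
}
_SPECIES_ED = {
    "E. coli": 0.05,
    "B. subtilis": 0.02,
    "C. glutamicum": 0.02,
    "P. putida": 0.75,
    "S. oneidensis": 0.40,
    "G. thermoglucosidasius": 0.05,
}
_SPECIES_PYR_SHUNT = {"P. putida": 12.0, "S. oneidensis": 5.0}

#: box used only to keep the Chebyshev-center LP bounded (normalized units)
_SAMPLER_BOX = (-25.0, 250.0)


@dataclass(frozen=True)
class ResponseKernel:
    """Deterministic condition -> target-flux-point mapping plus noise model."""

    noise_sd: np.ndarray = field(
        default_factory=lambda: np.full(N_FLUXES, 2.0)
    )  # per flux, normalized units
    growth_saturation: float = 0.5  # 1/h scale of the saturating biomass response
    biomass_gain: float = 25.0  # flux units routed to drains at saturation

    def __post_init__(self):
        sd = np.broadcast_to(np.asarray(self.noise_sd, float), (N_FLUXES,)).copy()
        if np.any(sd < 0):
            raise ValueError("noise sd must be non-negative")
        object.__setattr__(self, "noise_sd", sd)

    def target_point(self, cond: CultureCondition) -> np.ndarray:
        """Heuristic routing of the substrate entries through the network."""
        r = {s: cond.mix.ratio(s) for s in SUBSTRATES}
        oxf = _OXYGEN_FACTOR.get(cond.oxygen, 0.5)
        bm = self.biomass_gain * np.tanh(cond.growth_rate / self.growth_saturation)
        pp = _SPECIES_PP.get(cond.species, 0.2)
        ed = _SPECIES_ED.get(cond.species, 0.1)
        shunt = _SPECIES_PYR_SHUNT.get(cond.species, 1.0)

        in_g6p = 100 * (r["glucose"] + r["galactose"])
        in_f6p = 100 * r["fructose"]
        in_dhap = 100 * r["glycerol"]
        in_x5p = 100 * r["xylose"]
        in_6pg = 100 * r["gluconate"]
        in_cit = 100 * r["citrate"]
        in_akg = 100 * r["glutamate"]
        in_suc = 100 * r["succinate"]
        in_mal = 100 * r["malate"]
        in_pyr = 100 * (r["pyruvate"] + r["lactate"])
        in_ac = 100 * r["acetate"]

        v = np.zeros(N_FLUXES)

        def put(fid, val):
            v[FLUX_IDS.index(fid)] = val

        put("v1", in_g6p)
        v10 = pp * in_g6p
        put("v10", v10)
        pool_6pg = v10 + in_6pg
        v25 = ed * pool_6pg
        v11 = pool_6pg - v25
        put("v25", v25)
        put("v11", v11)
        v13 = v11 / 3.0 + 0.02 * bm
        v12 = v11 - v13
        put("v12", v12)
        put("v13", v13)
        x5p_pool = v12 + in_x5p
        v14 = x5p_pool / 2.0
        v15 = x5p_pool - v14
        v16 = v14
        put("v14", v14)
        put("v15", v15)
        put("v16", v16)
        v2 = in_g6p - v10 - 0.10 * bm
        put("v2", v2)
        v3 = v2 + v15 + v16 + in_f6p - 0.05 * bm
        put("v3", v3)
        v4 = v3 + in_dhap
        put("v4", v4)
        v5 = v3 + v4 + v14 + v15 + v25 - v16 - 0.10 * bm
        put("v5", v5)
        v6 = v5 - 0.05 * bm
        put("v6", v6)
        v28 = 0.05 * max(v6, 0.0) + 4.0 * oxf
        put("v28", v28)
        v7 = v6 - v28 - 0.05 * bm
        put("v7", v7)
        v29 = shunt * oxf
        put("v29", v29)
        pyr_pool = v7 + v25 + v29 + in_pyr
        v27 = 0.15 * (1.0 - oxf) * max(pyr_pool, 0.0)
        v8 = max(pyr_pool - v27 - 0.10 * bm, 0.0) * (0.4 + 0.6 * oxf)
        put("v27", v27)
        put("v8", v8)
        ac_pool = v8 + in_ac
        v24 = 0.25 * in_ac + 0.5
        v9 = 0.10 * (1.0 - oxf) * ac_pool
        v26 = 0.02 * ac_pool
        v17 = max(ac_pool - v24 - v9 - v26 - 0.08 * bm, 0.0) * (0.3 + 0.7 * oxf)
        put("v24", v24)
        put("v9", v9)
        put("v26", v26)
        put("v17", v17)
        v18 = v17 + in_cit
        put("v18", v18)
        v19 = v18 - v24
        put("v19", v19)
        v20 = v19 + in_akg - 0.08 * bm
        put("v20", v20)
        v21 = v20 + v24 + in_suc
        put("v21", v21)
        v22 = v21
        put("v22", v22)
        v23 = v22 + v24 + in_mal - v29
        put("v23", v23)
        return v


@dataclass(frozen=True)
class SyntheticSample:
    condition: CultureCondition
    true_fluxes: FluxVector
    observed_fluxes: FluxVector
    seed: int


@dataclass
class SyntheticDataset:
    samples: list[SyntheticSample]
    kernel: ResponseKernel
    seed: int

    def observed_table(self) -> pd.DataFrame:
        return self._table(lambda s: s.observed_fluxes)

    def truth_table(self) -> pd.DataFrame:
        return self._table(lambda s: s.true_fluxes)

    def _table(self, pick) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = s.condition.to_row()
            row.update(pick(s).as_dict())
            rows.append(row)
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def sample_condition(
    rng: np.random.Generator, vocabularies: dict[str, list[str]] | None = None
) -> CultureCondition:
    """Draw one random culture condition that passes the default input rules.

    The substrate mix is a Dirichlet draw over a random subset of 1-3 carbon
    substrates; growth rates are log-uniform within oxygen-dependent ranges.
    """
    voc = vocabularies or DEFAULT_VOCABULARIES
    oxygen = voc["oxygen"][rng.integers(len(voc["oxygen"]))]
    lo, hi = {
        "aerobic": (0.08, 1.5),
        "microaerobic": (0.04, 0.8),
        "anaerobic": (0.02, 0.5),
    }.get(oxygen, (0.05, 1.0))
    growth = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    uptake = float(np.exp(rng.uniform(np.log(0.5), np.log(25.0))))
    background = voc["genetic_background"][rng.integers(len(voc["genetic_background"]))]
    if background == "wild_type":
        engineering = "none"
    else:
        methods = [m for m in voc["engineering_method"] if m != "none"] or ["none"]
        engineering = methods[rng.integers(len(methods))]
    carbon = [s for s in SUBSTRATES if s != "NaHCO3"]
    n_sub = int(rng.integers(1, 4))
    chosen = rng.choice(len(carbon), size=n_sub, replace=False)
    weights = rng.dirichlet(np.full(n_sub, 1.5))
    weights = weights / weights.sum()
    mix = SubstrateMix({carbon[i]: float(w) for i, w in zip(chosen, weights)})
    return CultureCondition(
        species=voc["species"][rng.integers(len(voc["species"]))],
        nutrient_type=voc["nutrient_type"][rng.integers(len(voc["nutrient_type"]))],
        oxygen=oxygen,
        cultivation_method=voc["cultivation_method"][
            rng.integers(len(voc["cultivation_method"]))
        ],
        genetic_background=background,
        engineering_method=engineering,
        growth_rate=growth,
        uptake_rate=uptake,
        mix=mix,
    )


def chebyshev_center(cs: ConstraintSystem) -> tuple[np.ndarray, float]:
    """Deepest interior point of the polytope (within a bounding box).

    Maximizes the inequality-slack radius subject to the equalities; the
    generous sampler box only keeps the LP bounded.
    """
    n = N_FLUXES
    lo, hi = _SAMPLER_BOX
    # the sampler box joins the radius constraints so the center stays off it
    A_all = np.vstack([cs.A, np.eye(n), -np.eye(n)])
    b_all = np.concatenate([cs.b_in, np.full(n, lo), np.full(n, -hi)])
    norms = np.linalg.norm(A_all, axis=1)
    # variables: (v, radius); maximize radius
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-A_all, norms[:, None]])
    b_ub = -b_all
    A_eq = np.hstack([cs.S, np.zeros((cs.S.shape[0], 1))])
    bounds = [(None, None)] * n + [(0, None)]
    res = optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=cs.b_eq, bounds=bounds, method="highs"
    )
    if res.status != 0:
        raise ValueError(f"could not locate an interior point: {res.message}")
    return res.x[:n], float(res.x[-1])


def hit_and_run(
    cs: ConstraintSystem,
    rng: np.random.Generator,
    n_steps: int = 50,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """One hit-and-run draw from the constraint polytope.

    Walks within the equality null space: from the current point, pick a
    random feasible chord direction, intersect it with the inequality rows
    (and the sampler box), and jump to a uniform point on the segment.
    Meant for distributional studies; the default generator uses the faster
    projection + interior-step scheme instead.
    """
    x = np.array(chebyshev_center(cs)[0] if start is None else start, float)
    _, _, VT = np.linalg.svd(cs.S)
    null = VT[np.linalg.matrix_rank(cs.S):]
    lo, hi = _SAMPLER_BOX
    A = np.vstack([cs.A, np.eye(N_FLUXES), -np.eye(N_FLUXES)])
    b = np.concatenate([cs.b_in, np.full(N_FLUXES, lo), np.full(N_FLUXES, -hi)])
    for _ in range(n_steps):
        d = null.T @ rng.normal(size=null.shape[0])
        d /= np.linalg.norm(d)
        slack = A @ x - b  # >= 0
        rate = A @ d
        with np.errstate(divide="ignore"):
            t_hi = np.min(np.where(rate < -1e-12, slack / -rate, np.inf))
            t_lo = -np.min(np.where(rate > 1e-12, slack / rate, np.inf))
        if not np.isfinite(t_hi) or not np.isfinite(t_lo) or t_hi <= t_lo:
            continue
        x = x + rng.uniform(t_lo, t_hi) * d
    return _reproject_equalities(x, cs)


def _reproject_equalities(v: np.ndarray, cs: ConstraintSystem) -> np.ndarray:
    resid = cs.S @ v - cs.b_eq
    correction, *_ = np.linalg.lstsq(cs.S, resid, rcond=None)
    return v - correction


def sample_feasible_flux(
    mix: SubstrateMix,
    kernel: ResponseKernel,
    rng: np.random.Generator,
    cond: CultureCondition | None = None,
    cs: ConstraintSystem | None = None,
    method: str = "project",
) -> FluxVector:
    """A strictly feasible flux vector near the kernel's target point.

    The default ``project`` method projects the target onto the constraint
    polytope (unit weights), then steps a random fraction toward the
    Chebyshev center to stay clear of the boundary, and finally re-projects
    the equalities exactly.  ``hit_and_run`` instead draws approximately
    uniformly from the polytope (ignoring the kernel target); use it for
    distributional studies of the feasible set.
    """
    if cs is None:
        cs = assemble_constraints(mix)
    if method == "hit_and_run":
        return FluxVector(hit_and_run(cs, rng))
    if method != "project":
        raise ValueError(f"unknown sampling method {method!r}")
    if cond is not None:
        target = kernel.target_point(cond)
    else:
        target = np.zeros(N_FLUXES)
    proj = correct(FluxVector(target), cs, FluxBounds.unit(), use_boxes=False)
    center, radius = chebyshev_center(cs)
    u = rng.uniform(0.05, 0.25) if radius > 1e-9 else 0.0
    v = (1 - u) * proj.corrected.values + u * center
    v = _reproject_equalities(v, cs)
    vec = FluxVector(v)
    report = check_feasibility(vec, cs, tol=1e-8)
    if not report.feasible:
        # boundary-degenerate polytope: fall back to the exact projection
        vec = FluxVector(_reproject_equalities(proj.corrected.values, cs))
    return vec


def generate_dataset(
    n: int,
    kernel: ResponseKernel | None = None,
    noise_sd: float | np.ndarray | None = None,
    seed: int = 0,
    vocabularies: dict[str, list[str]] | None = None,
) -> SyntheticDataset:
    """Generate ``n`` condition/flux pairs, fully reproducible from ``seed``."""
    if n < 1:
        raise ValueError("need n >= 1")
    if kernel is None:
        kernel = ResponseKernel()
    if noise_sd is not None:
        kernel = ResponseKernel(
            noise_sd=np.broadcast_to(np.asarray(noise_sd, float), (N_FLUXES,)).copy(),
            growth_saturation=kernel.growth_saturation,
            biomass_gain=kernel.biomass_gain,
        )
    rng = np.random.default_rng(seed)
    cs_cache: dict[tuple, ConstraintSystem] = {}
    samples = []
    for i in range(n):
        cond = sample_condition(rng, vocabularies)
        key = tuple(round(cond.mix.ratio(s), 12) for s in SUBSTRATES)
        cs = cs_cache.get(key)
        if cs is None:
            cs = assemble_constraints(cond.mix)
            cs_cache[key] = cs
        true = sample_feasible_flux(cond.mix, kernel, rng, cond=cond, cs=cs)
        noise = rng.normal(0.0, kernel.noise_sd)
        observed = FluxVector(true.values + noise)
        samples.append(SyntheticSample(cond, true, observed, seed=i))
    return SyntheticDataset(samples=samples, kernel=kernel, seed=seed)


def write_dataset(ds: SyntheticDataset, path, truth_path=None) -> None:
    """Write the observed table (and optionally the truth table) as TSV."""
    ds.observed_table().to_csv(path, sep="\t", index=False, float_format="%.10g")
    if truth_path is not None:
        ds.truth_table().to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
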