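"""Universal central-carbon network: 29 lumped fluxes over 21 balanced pools.

The model covers glycolysis (EMP), the pentose phosphate (PP) pathway, the
Entner-Doudoroff (ED) pathway, the TCA cycle, the glyoxylate shunt and two
lumped anaplerotic routes (PEP + CO2 -> OAA and MAL -> PYR + CO2) of
heterotrophic bacteria.  All fluxes are normalized so that the total carbon
uptake equals 100.  Each of the 21 metabolite pools yields a steady-state
mass balance; pools that feed biomass synthesis or excretion carry an
implicit non-negative drain, so their balances relax to inequalities, while
the remaining pools give strict equalities.  For a given substrate mix the
balances assemble into the linear system

    S . v  = b_eq      (9 equality rows)
    A . v >= b_in      (12 inequality rows, 13 with the optional SUC row)

with the 100*ratio substrate-entry constants moved to the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_FLUXES",
    "FLUX_IDS",
    "SUBSTRATES",
    "FLUX_ANNOTATIONS",
    "FluxVector",
    "SubstrateMix",
    "MetaboliteBalance",
    "ConstraintSystem",
    "build_network",
    "assemble_constraints",
    "check_feasibility",
    "balance_residuals",
    "write_flux_table",
    "export_lp",
]

N_FLUXES = 29
FLUX_IDS = tuple(f"v{i}" for i in range(1, N_FLUXES + 1))

#: the 14 carbon substrates the network can be fed with, in canonical order
SUBSTRATES = (
    "glucose",
    "fructose",
    "galactose",
    "gluconate",
    "glutamate",
    "citrate",
    "xylose",
    "succinate",
    "malate",
    "lactate",
    "pyruvate",
    "glycerol",
    "acetate",
    "NaHCO3",
)

# flux_id -> (label, reactant pool, product pool, reversible, inferred)
# Endpoints are read off the balance equations; labels marked inferred where
# the pathway-map detail does not pin down the exact enzyme.
FLUX_ANNOTATIONS: dict[str, tuple[str, str, str, bool, bool]] = {
    "v1": ("glucose/galactose uptake to G6P", "substrate", "G6P", False, False),
    "v2": ("phosphoglucose isomerase (G6P->F6P)", "G6P", "F6P/FBP", True, False),
    "v3": ("FBP aldolase (FBP->DHAP+GAP)", "F6P/FBP", "DHAP+GAP", True, False),
    "v4": ("triose phosphate isomerase (DHAP->GAP)", "DHAP", "GAP", True, False),
    "v5": ("GAP dehydrogenase branch (GAP->3PG)", "GAP", "3PG", True, False),
    "v6": ("phosphoglycerate mutase/enolase (3PG->PEP)", "3PG", "PEP", True, False),
    "v7": ("pyruvate kinase (PEP->PYR)", "PEP", "PYR", False, False),
    "v8": ("pyruvate dehydrogenase (PYR->AcCoA)", "PYR", "AceCoA", False, False),
    "v9": ("acetyl-CoA overflow/excretion", "AceCoA", "out", False, True),
    "v10": ("G6P dehydrogenase, oxidative PP (G6P->6PG)", "G6P", "6PG", False, False),
    "v11": ("6PG dehydrogenase, oxidative PP (6PG->Ru5P)", "6PG", "Ru5P", False, False),
    "v12": ("Ru5P epimerase (Ru5P->X5P)", "Ru5P", "X5P", True, False),
    "v13": ("Ru5P isomerase (Ru5P->R5P)", "Ru5P", "R5P", True, False),
    "v14": ("transketolase 1 (R5P+X5P->S7P+GAP)", "R5P+X5P", "S7P+GAP", True, False),
    "v15": ("transaldolase/transketolase 2 toward F6P+GAP", "S7P/X5P+E4P", "F6P+GAP", True, True),
    "v16": ("transketolase 2 (X5P+E4P->F6P+GAP)", "S7P+GAP", "F6P+E4P", True, True),
    "v17": ("citrate synthase (AcCoA+OAA->CIT)", "AceCoA+OAA", "CIT", False, False),
    "v18": ("aconitase (CIT->ICIT)", "CIT", "ICIT", True, False),
    "v19": ("isocitrate dehydrogenase (ICIT->AKG)", "ICIT", "AKG", False, False),
    "v20": ("AKG dehydrogenase (AKG->SUC)", "AKG", "SUC", False, False),
    "v21": ("succinate dehydrogenase (SUC->FUM)", "SUC", "FUM", True, False),
    "v22": ("fumarase (FUM->MAL)", "FUM", "MAL", True, False),
    "v23": ("malate dehydrogenase (MAL->OAA)", "MAL", "OAA", True, False),
    "v24": ("glyoxylate shunt (ICIT+AcCoA->SUC+MAL)", "ICIT+AceCoA", "SUC+MAL", False, False),
    "v25": ("Entner-Doudoroff pathway (6PG->PYR+GAP)", "6PG", "PYR+GAP", False, False),
    "v26": ("acetyl-CoA-consuming synthesis/excretion", "AceCoA", "out", False, True),
    "v27": ("pyruvate-consuming excretion", "PYR", "out", False, True),
    "v28": ("PEP carboxylation, anaplerosis (PEP+CO2->OAA)", "PEP", "OAA", True, False),
    "v29": ("malic enzyme, anaplerosis (MAL->PYR+CO2)", "MAL", "PYR", True, False),
}


def _flux_index(flux_id: str) -> int:
    try:
        return FLUX_IDS.index(flux_id)
    except ValueError:
        raise KeyError(f"unknown flux id {flux_id!r}; expected one of v1..v29") from None


@dataclass(frozen=True)
class FluxVector:
    """The 29 central-carbon fluxes, normalized to a total uptake of 100."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_FLUXES,):
            raise ValueError(f"flux vector must have exactly {N_FLUXES} entries, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("flux vector entries must be finite")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, flux_id: str) -> float:
        return float(self.values[_flux_index(flux_id)])

    def as_dict(self) -> dict[str, float]:
        return {fid: float(x) for fid, x in zip(FLUX_IDS, self.values)}


@dataclass(frozen=True)
class SubstrateMix:
    """Uptake ratios of the 14 substrates; nonzero ratios must sum to 1.

    With ``strict=False`` the simplex invariants are not enforced at
    construction, so the input-validation layer can inspect and report
    out-of-domain ratios instead of an opaque constructor error.
    """

    ratios: dict[str, float]
    total_uptake: float = 100.0
    strict: bool = True

    def __post_init__(self):
        unknown = set(self.ratios) - set(SUBSTRATES)
        if unknown:
            raise ValueError(f"unknown substrate(s): {sorted(unknown)}")
        full = {s: float(self.ratios.get(s, 0.0)) for s in SUBSTRATES}
        if self.strict:
            for s, r in full.items():
                if not (0.0 <= r <= 1.0):
                    raise ValueError(f"ratio for {s} must lie in [0, 1], got {r}")
            total = sum(full.values())
            if total > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError(f"nonzero substrate ratios must sum to 1, got {total}")
        object.__setattr__(self, "ratios", full)

    def ratio(self, substrate: str) -> float:
        return self.ratios[substrate]

    @classmethod
    def single(cls, substrate: str) -> "SubstrateMix":
        return cls({substrate: 1.0})


@dataclass(frozen=True)
class MetaboliteBalance:
    """Steady-state mass balance of one pool: producers - consumers (- drain) = 0.

    ``terms`` maps flux ids to signed coefficients (producers +1, consumers -1)
    and ``entry`` maps substrate names to their entry coefficients (each
    contributes ``100 * ratio`` on the producer side).  ``drain`` marks pools
    with a non-negative biomass/excretion slack; drained balances relax to
    inequalities, undrained ones are strict equalities.
    """

    metabolite: str
    terms: dict[str, float]
    entry: dict[str, float] = field(default_factory=dict)
    drain: bool = False

    def slack(self, v: FluxVector, mix: SubstrateMix) -> float:
        """Producers minus consumers; the implied drain flux when drained."""
        total = sum(c * v[fid] for fid, c in self.terms.items())
        total += sum(c * 100.0 * mix.ratio(s) for s, c in self.entry.items())
        return total


def build_network(
    *, lactate_to_pyruvate: bool = True, acetate_to_accoa: bool = True
) -> list[MetaboliteBalance]:
    """The 21 steady-state balances of the universal central-carbon network.

    Lactate and acetate are substrates without an explicit balance term in the
    canonical equations; by default lactate enters at the PYR pool and acetate
    at the AceCoA pool (their biochemical entry points), each switchable off.
    NaHCO3 carries no carbon-balance constant (CO2 pools are not balanced).
    """
    pyr_entry = {"pyruvate": 1.0}
    if lactate_to_pyruvate:
        pyr_entry["lactate"] = 1.0
    accoa_entry = {"acetate": 1.0} if acetate_to_accoa else {}

    return [
        MetaboliteBalance("G6P", {"v1": 1, "v2": -1, "v10": -1}, drain=True),
        MetaboliteBalance(
            "F6P/FBP", {"v2": 1, "v15": 1, "v16": 1, "v3": -1}, {"fructose": 1.0}, drain=True
        ),
        MetaboliteBalance("DHAP", {"v3": 1, "v4": -1}, {"glycerol": 1.0}),
        MetaboliteBalance(
            "GAP",
            {"v3": 1, "v4": 1, "v14": 1, "v15": 1, "v25": 1, "v5": -1, "v16": -1},
            drain=True,
        ),
        MetaboliteBalance("3PG", {"v5": 1, "v6": -1}, drain=True),
        MetaboliteBalance("PEP", {"v6": 1, "v7": -1, "v28": -1}, drain=True),
        MetaboliteBalance(
            "PYR", {"v7": 1, "v25": 1, "v29": 1, "v8": -1, "v27": -1}, pyr_entry, drain=True
        ),
        MetaboliteBalance(
            "AceCoA", {"v8": 1, "v9": -1, "v17": -1, "v24": -1, "v26": -1}, accoa_entry, drain=True
        ),
        MetaboliteBalance("Ru5P", {"v11": 1, "v12": -1, "v13": -1}),
        MetaboliteBalance("R5P", {"v13": 1, "v14": -1}, drain=True),
        MetaboliteBalance("E4P", {"v16": 1, "v15": -1}, drain=True),
        MetaboliteBalance("S7P", {"v14": 1, "v16": -1}),
        MetaboliteBalance("X5P", {"v12": 1, "v14": -1, "v15": -1}, {"xylose": 1.0}),
        MetaboliteBalance("6PG", {"v10": 1, "v11": -1, "v25": -1}, {"gluconate": 1.0}),
        MetaboliteBalance("CIT", {"v17": 1, "v18": -1}, {"citrate": 1.0}),
        MetaboliteBalance("ICIT", {"v18": 1, "v19": -1, "v24": -1}),
        MetaboliteBalance("AKG", {"v19": 1, "v20": -1}, {"glutamate": 1.0}, drain=True),
        MetaboliteBalance(
            "SUC", {"v20": 1, "v24": 1, "v21": -1}, {"succinate": 1.0}, drain=True
        ),
        MetaboliteBalance("FUM", {"v22": 1, "v21": -1}, drain=True),
        MetaboliteBalance(
            "MAL", {"v22": 1, "v24": 1, "v23": -1, "v29": -1}, {"malate": 1.0}
        ),
        MetaboliteBalance("OAA", {"v23": 1, "v28": 1, "v17": -1}, drain=True),
    ]


@dataclass(frozen=True)
class ConstraintSystem:
    """S·v = b_eq and A·v ≥ b_in for one substrate mix."""

    S: np.ndarray
    b_eq: np.ndarray
    A: np.ndarray
    b_in: np.ndarray
    eq_labels: tuple[str, ...]
    in_labels: tuple[str, ...]

    @property
    def row_labels(self) -> tuple[str, ...]:
        return self.eq_labels + self.in_labels


def _row(coeffs: dict[str, float]) -> np.ndarray:
    row = np.zeros(N_FLUXES)
    for fid, c in coeffs.items():
        row[_flux_index(fid)] = c
    return row


_KNOWN_OPTIONS = frozenset(
    {"zwf_knockout", "suc_inequality", "lactate_to_pyruvate", "acetate_to_accoa"}
)


def assemble_constraints(mix: SubstrateMix, **options) -> ConstraintSystem:
    """Assemble the linear constraint system for one substrate mix.

    Equality rows (in order): the glucose/galactose entry into G6P and the
    balances of the eight undrained pools (DHAP, Ru5P, S7P, 6PG, CIT, X5P,
    ICIT, MAL).  Inequality rows: the twelve drained balances whose
    biomass/excretion slack must be non-negative.  Substrate-entry constants
    100*ratio are moved to the right-hand side.

    Options
    -------
    zwf_knockout : bool
        Reverse the OAA inequality for a *zwf*-knockout strain (the one case
        in which its direction flips).
    suc_inequality : bool
        Add the optional 13th inequality for the SUC pool (off by default:
        the canonical system leaves the SUC excretion slack unconstrained).
    lactate_to_pyruvate, acetate_to_accoa : bool
        Substrate entry-point mappings, default True.
    """
    unknown = set(options) - _KNOWN_OPTIONS
    if unknown:
        raise ValueError(
            f"unknown option(s) {sorted(unknown)}; valid: {sorted(_KNOWN_OPTIONS)}"
        )
    zwf = bool(options.get("zwf_knockout", False))
    suc = bool(options.get("suc_inequality", False))
    lac = bool(options.get("lactate_to_pyruvate", True))
    ace = bool(options.get("acetate_to_accoa", True))

    r = {s: mix.ratio(s) for s in SUBSTRATES}
    U = mix.total_uptake

    # equality rows, coefficients exactly as the canonical constraint list
    # prints them; the entry constants land on the right-hand side
    eq: list[tuple[str, dict[str, float], float]] = [
        ("G6P entry", {"v1": 1}, U * (r["glucose"] + r["galactose"])),
        ("DHAP", {"v3": 1, "v4": -1}, -U * r["glycerol"]),
        ("Ru5P", {"v11": 1, "v12": -1, "v13": -1}, 0.0),
        ("S7P", {"v14": 1, "v16": -1}, 0.0),
        ("6PG", {"v10": 1, "v11": -1, "v25": -1}, -U * r["gluconate"]),
        ("CIT", {"v17": -1, "v18": 1}, U * r["citrate"]),
        ("X5P", {"v12": -1, "v14": 1, "v15": 1}, U * r["xylose"]),
        ("ICIT", {"v18": -1, "v19": 1, "v24": 1}, 0.0),
        ("MAL", {"v22": -1, "v23": 1, "v24": -1, "v29": 1}, U * r["malate"]),
    ]

    pyr_const = r["pyruvate"] + (r["lactate"] if lac else 0.0)
    accoa_const = r["acetate"] if ace else 0.0
    ineq: list[tuple[str, dict[str, float], float]] = [
        ("G6P drain", {"v1": 1, "v2": -1, "v10": -1}, 0.0),
        ("F6P/FBP drain", {"v2": 1, "v3": -1, "v15": 1, "v16": 1}, -U * r["fructose"]),
        (
            "GAP drain",
            {"v3": 1, "v4": 1, "v5": -1, "v14": 1, "v15": 1, "v16": -1, "v25": 1},
            0.0,
        ),
        ("3PG drain", {"v5": 1, "v6": -1}, 0.0),
        ("PEP drain", {"v6": 1, "v7": -1, "v28": -1}, 0.0),
        (
            "PYR drain",
            {"v7": 1, "v8": -1, "v25": 1, "v27": -1, "v29": 1},
            -U * pyr_const,
        ),
        (
            "AceCoA drain",
            {"v8": 1, "v9": -1, "v17": -1, "v24": -1, "v26": -1},
            -U * accoa_const,
        ),
        ("R5P drain", {"v13": 1, "v14": -1}, 0.0),
        ("E4P drain", {"v15": -1, "v16": 1}, 0.0),
        ("AKG drain", {"v19": 1, "v20": -1}, -U * r["glutamate"]),
        ("OAA drain", {"v17": -1, "v23": 1, "v28": 1}, 0.0),
        ("FUM drain", {"v21": -1, "v22": 1}, 0.0),
    ]
    if zwf:
        label, coeffs, rhs = ineq[10]
        ineq[10] = (
            "OAA drain (zwf-reversed)",
            {k: -c for k, c in coeffs.items()},
            -rhs,
        )
    if suc:
        ineq.append(
            ("SUC drain", {"v20": 1, "v21": -1, "v24": 1}, -U * r["succinate"])
        )

    S = np.array([_row(c) for _, c, _ in eq])
    b_eq = np.array([rhs for _, _, rhs in eq])
    A = np.array([_row(c) for _, c, _ in ineq])
    b_in = np.array([rhs for _, _, rhs in ineq])
    return ConstraintSystem(
        S=S,
        b_eq=b_eq,
        A=A,
        b_in=b_in,
        eq_labels=tuple(lbl for lbl, _, _ in eq),
        in_labels=tuple(lbl for lbl, _, _ in ineq),
    )


@dataclass(frozen=True)
class Violation:
    kind: str  # "equality" | "inequality"
    row: int
    label: str
    amount: float  # |S·v − b| for equalities, b − A·v for inequalities


@dataclass(frozen=True)
class FeasibilityReport:
    violations: tuple[Violation, ...]

    @property
    def feasible(self) -> bool:
        return not self.violations

    def worst(self) -> float:
        return max((v.amount for v in self.violations), default=0.0)


def check_feasibility(
    v: FluxVector, cs: ConstraintSystem, tol: float = 1e-6
) -> FeasibilityReport:
    """List every constraint row violated beyond ``tol``."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    x = v.values
    out: list[Violation] = []
    for i, (resid, lbl) in enumerate(zip(cs.S @ x - cs.b_eq, cs.eq_labels)):
        if abs(resid) > tol:
            out.append(Violation("equality", i, lbl, abs(float(resid))))
    for i, (slack, lbl) in enumerate(zip(cs.A @ x - cs.b_in, cs.in_labels)):
        if slack < -tol:
            out.append(Violation("inequality", i, lbl, -float(slack)))
    return FeasibilityReport(tuple(out))


def balance_residuals(
    v: FluxVector, mix: SubstrateMix, network: list[MetaboliteBalance] | None = None
) -> dict[str, dict]:
    """Evaluate all 21 pool balances at ``v``.

    For undrained pools the value is the balance residual (zero when
    feasible); for drained pools it is the implied drain flux (non-negative
    when feasible).
    """
    if network is None:
        network = build_network()
    return {
        bal.metabolite: {
            "value": bal.slack(v, mix),
            "drained": bal.drain,
        }
        for bal in network
    }


def write_flux_table(path) -> None:
    """Write the flux annotation table as TSV."""
    with open(path, "w") as fh:
        fh.write("flux_id\tlabel\treactant_pool\tproduct_pool\treversible_flag\tinferred\n")
        for fid in FLUX_IDS:
            label, rpool, ppool, rev, inf = FLUX_ANNOTATIONS[fid]
            fh.write(f"{fid}\t{label}\t{rpool}\t{ppool}\t{int(rev)}\t{int(inf)}\n")


def export_lp(cs: ConstraintSystem, path) -> None:
    """Dump the constraint system in a plain-text LP-like format for inspection."""

    def _expr(row: np.ndarray) -> str:
        parts = []
        for fid, c in zip(FLUX_IDS, row):
            if c == 0:
                continue
            sign = "+" if c > 0 else "-"
            mag = abs(c)
            coeff = "" if mag == 1 else f"{mag:g} "
            parts.append(f"{sign} {coeff}{fid}")
        s = " ".join(parts) if parts else "0"
        return s[2:] if s.startswith("+ ") else s

    with open(path, "w") as fh:
        fh.write("Subject To\n")
        for lbl, row, rhs in zip(cs.eq_labels, cs.S, cs.b_eq):
            fh.write(f" {lbl.replace(' ', '_')}: {_expr(row)} = {rhs:g}\n")
        for lbl, row, rhs in zip(cs.in_labels, cs.A, cs.b_in):
            fh.write(f" {lbl.replace(' ', '_')}: {_expr(row)} >= {rhs:g}\n")
        fh.write("End\n")
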