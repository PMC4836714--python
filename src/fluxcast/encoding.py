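"""Feature encoding: culture conditions -> numeric vectors, fluxes -> [0, 1].

Six categorical descriptors (species, nutrient type, oxygen condition,
engineering method, genetic background, cultivation method) are one-hot
encoded; sixteen continuous descriptors (growth rate, substrate uptake rate
and the 14 substrate-uptake ratios) are standardized to zero mean and unit
variance using population (divide-by-N) statistics.  Flux targets are
min-max scaled to [0, 1] so that cross-validation errors are comparable
across fluxes with very different dynamic ranges; the same per-flux extremes
later weight the quadratic correction.  All scaler state is held in one
JSON-serializable object so an encoding is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stoichiometry import FLUX_IDS, N_FLUXES, SUBSTRATES, FluxVector, SubstrateMix

__all__ = [
    "CATEGORICAL_FEATURES",
    "CONTINUOUS_FEATURES",
    "TABLE_COLUMNS",
    "CultureCondition",
    "ScalerState",
    "EncodedSample",
    "UnseenLevelError",
    "fit_scalers",
    "encode",
    "encode_table",
    "scale_targets",
    "unscale_targets",
    "read_training_table",
]

CATEGORICAL_FEATURES = (
    "species",
    "nutrient_type",
    "oxygen",
    "engineering_method",
    "genetic_background",
    "cultivation_method",
)

RATIO_COLUMNS = tuple(f"ratio_{s}" for s in SUBSTRATES)
CONTINUOUS_FEATURES = ("growth_rate", "uptake_rate") + RATIO_COLUMNS

#: fixed training-table header: 6 categorical + 16 continuous + 29 fluxes
TABLE_COLUMNS = CATEGORICAL_FEATURES + CONTINUOUS_FEATURES + FLUX_IDS

OXYGEN_LEVELS = ("aerobic", "microaerobic", "anaerobic")


@dataclass(frozen=True)
class CultureCondition:
    """One culture experiment: categorical + continuous descriptors."""

    species: str
    nutrient_type: str
    oxygen: str
    cultivation_method: str
    genetic_background: str = "wild_type"
    engineering_method: str = "none"
    growth_rate: float = 0.0  # 1/h
    uptake_rate: float = 0.0  # substrate uptake, e.g. mmol/gDW/h
    mix: SubstrateMix = field(default_factory=lambda: SubstrateMix.single("glucose"))

    # rate signs and the ratio simplex are enforced by the input-validation
    # rules rather than here, so bad requests yield a readable report

    def continuous(self) -> np.ndarray:
        return np.array(
            [self.growth_rate, self.uptake_rate]
            + [self.mix.ratio(s) for s in SUBSTRATES]
        )

    def categorical(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in CATEGORICAL_FEATURES}

    def to_row(self) -> dict:
        row = dict(self.categorical())
        row.update(zip(CONTINUOUS_FEATURES, self.continuous()))
        return row

    @classmethod
    def from_row(cls, row) -> "CultureCondition":
        ratios = {s: float(row[f"ratio_{s}"]) for s in SUBSTRATES}
        return cls(
            species=str(row["species"]),
            nutrient_type=str(row["nutrient_type"]),
            oxygen=str(row["oxygen"]),
            cultivation_method=str(row["cultivation_method"]),
            genetic_background=str(row["genetic_background"]),
            engineering_method=str(row["engineering_method"]),
            growth_rate=float(row["growth_rate"]),
            uptake_rate=float(row["uptake_rate"]),
            mix=SubstrateMix({s: r for s, r in ratios.items() if r != 0.0}),
        )


class UnseenLevelError(KeyError):
    """A categorical level absent from the training vocabulary (strict mode)."""


@dataclass
class ScalerState:
    """All state needed to encode features and (un)scale flux targets."""

    feature_means: np.ndarray  # 16 continuous features
    feature_sds: np.ndarray  # population sds; 1.0 where the feature is constant
    constant_features: np.ndarray  # bool flags
    flux_min: np.ndarray  # per-flux extremes, also the QP range weights
    flux_max: np.ndarray
    vocabularies: dict[str, list[str]]  # per categorical feature, first-seen order
    flux_mean: np.ndarray | None = None  # for the alternative z-score target scaling
    flux_sd: np.ndarray | None = None  # population sd; 1.0 where the flux is constant

    def __post_init__(self):
        self.feature_means = np.asarray(self.feature_means, float)
        self.feature_sds = np.asarray(self.feature_sds, float)
        self.constant_features = np.asarray(self.constant_features, bool)
        self.flux_min = np.asarray(self.flux_min, float)
        self.flux_max = np.asarray(self.flux_max, float)
        if self.flux_mean is None:
            self.flux_mean = (self.flux_min + self.flux_max) / 2.0
        if self.flux_sd is None:
            self.flux_sd = np.ones(self.flux_min.size)
        self.flux_mean = np.asarray(self.flux_mean, float)
        self.flux_sd = np.asarray(self.flux_sd, float)
        if np.any(self.flux_max < self.flux_min):
            raise ValueError("per-flux max must be >= min")

    @property
    def constant_fluxes(self) -> np.ndarray:
        """Fluxes whose training range is degenerate (Max == Min)."""
        return self.flux_max == self.flux_min

    def feature_names(self) -> list[str]:
        names = [
            f"{feat}={level}"
            for feat in CATEGORICAL_FEATURES
            for level in self.vocabularies[feat]
        ]
        return names + list(CONTINUOUS_FEATURES)

    @property
    def n_features(self) -> int:
        return sum(len(v) for v in self.vocabularies.values()) + len(CONTINUOUS_FEATURES)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_means": self.feature_means.tolist(),
                "feature_sds": self.feature_sds.tolist(),
                "constant_features": self.constant_features.astype(int).tolist(),
                "flux_min": self.flux_min.tolist(),
                "flux_max": self.flux_max.tolist(),
                "vocabularies": self.vocabularies,
                "flux_mean": self.flux_mean.tolist(),
                "flux_sd": self.flux_sd.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerState":
        d = json.loads(text)
        return cls(
            feature_means=d["feature_means"],
            feature_sds=d["feature_sds"],
            constant_features=np.array(d["constant_features"], bool),
            flux_min=d["flux_min"],
            flux_max=d["flux_max"],
            vocabularies={k: list(v) for k, v in d["vocabularies"].items()},
            flux_mean=d.get("flux_mean"),
            flux_sd=d.get("flux_sd"),
        )


@dataclass(frozen=True)
class EncodedSample:
    features: np.ndarray
    target: np.ndarray | None = None  # fluxes scaled to [0, 1]


def read_training_table(path) -> pd.DataFrame:
    """Read a training table (TSV or CSV by extension), validating the header."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"training table missing column(s): {missing}")
    return df


def fit_scalers(training: pd.DataFrame) -> ScalerState:
    """Fit feature standardization, flux min-max ranges and vocabularies.

    Continuous features use population (divide-by-N) moments.  A constant
    continuous feature is flagged and passed through as zero rather than
    triggering a divide-by-zero.  Vocabularies keep first-appearance order so
    the encoded column order is a pure function of the training table.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training rows to fit scalers")
    cont = training[list(CONTINUOUS_FEATURES)].to_numpy(float)
    if np.isnan(cont).any():
        raise ValueError("continuous features contain missing values")
    means = cont.mean(axis=0)
    sds = cont.std(axis=0, ddof=0)
    constant = sds == 0.0
    sds = np.where(constant, 1.0, sds)
    fluxes = training[list(FLUX_IDS)].to_numpy(float)
    vocabularies = {
        feat: list(dict.fromkeys(training[feat].astype(str))) for feat in CATEGORICAL_FEATURES
    }
    flux_sd = fluxes.std(axis=0, ddof=0)
    return ScalerState(
        feature_means=means,
        feature_sds=sds,
        constant_features=constant,
        flux_min=fluxes.min(axis=0),
        flux_max=fluxes.max(axis=0),
        vocabularies=vocabularies,
        flux_mean=fluxes.mean(axis=0),
        flux_sd=np.where(flux_sd == 0.0, 1.0, flux_sd),
    )


def encode(
    cond: CultureCondition, sc: ScalerState, *, strict: bool = False
) -> EncodedSample:
    """One-hot the categoricals and standardize the 16 continuous slots.

    An unseen categorical level encodes as an all-zero block with a warning
    (lenient default, matching a service that must accept novel species);
    with ``strict=True`` it raises :class:`UnseenLevelError` instead.
    """
    blocks: list[np.ndarray] = []
    for feat in CATEGORICAL_FEATURES:
        vocab = sc.vocabularies[feat]
        level = str(getattr(cond, feat))
        block = np.zeros(len(vocab))
        if level in vocab:
            block[vocab.index(level)] = 1.0
        elif strict:
            raise UnseenLevelError(f"unseen level {level!r} for feature {feat!r}")
        else:
            warnings.warn(
                f"unseen level {level!r} for feature {feat!r}; encoding as all-zero block",
                stacklevel=2,
            )
        blocks.append(block)
    cont = (cond.continuous() - sc.feature_means) / sc.feature_sds
    cont = np.where(sc.constant_features, 0.0, cont)
    return EncodedSample(features=np.concatenate(blocks + [cont]))


def encode_table(
    training: pd.DataFrame, sc: ScalerState, *, strict: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every row; returns (X, Y_scaled) with Y min-max scaled."""
    X = np.stack(
        [
            encode(CultureCondition.from_row(row), sc, strict=strict).features
            for _, row in training.iterrows()
        ]
    )
    Y = np.stack(
        [
            scale_targets(FluxVector(row[list(FLUX_IDS)].to_numpy(float)), sc)
            for _, row in training.iterrows()
        ]
    )
    return X, Y


def scale_targets(v: FluxVector, sc: ScalerState, method: str = "minmax") -> np.ndarray:
    """Scale a flux vector for regression targets.

    The default ``minmax`` maps flux i to (v_i - Min_i) / (Max_i - Min_i);
    degenerate ranges (Max == Min) scale to 0 by convention and are treated
    as constants throughout the pipeline.  ``zscore`` standardizes each flux
    by its population mean and sd instead (the two behave very similarly in
    practice; min-max additionally supplies the QP range weights).
    """
    if method == "zscore":
        return (v.values - sc.flux_mean) / sc.flux_sd
    if method != "minmax":
        raise ValueError(f"unknown target scaling method {method!r}")
    rng = sc.flux_max - sc.flux_min
    safe = np.where(rng == 0.0, 1.0, rng)
    out = (v.values - sc.flux_min) / safe
    return np.where(rng == 0.0, 0.0, out)


def unscale_targets(
    scaled: np.ndarray, sc: ScalerState, method: str = "minmax"
) -> FluxVector:
    """Exact affine inverse of :func:`scale_targets` (no clipping)."""
    scaled = np.asarray(scaled, float)
    if scaled.shape != (N_FLUXES,):
        raise ValueError(f"scaled target must have length {N_FLUXES}")
    if method == "zscore":
        return FluxVector(sc.flux_mean + scaled * sc.flux_sd)
    if method != "minmax":
        raise ValueError(f"unknown target scaling method {method!r}")
    rng = sc.flux_max - sc.flux_min
    return FluxVector(np.where(rng == 0.0, sc.flux_min, sc.flux_min + scaled * rng))
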