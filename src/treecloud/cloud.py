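"""Cloud-model classifier.

A cloud model represents a qualitative concept (here: "pixels of species
s") by three numbers estimated from data by the *backward cloud generator*:

    Ex  expectation     sample mean
    En  entropy         sqrt(pi/2) * mean absolute deviation from Ex
    He  hyper-entropy   sqrt(S^2 - En^2), S^2 the unbiased sample variance
                        (clamped to 0 when S^2 < En^2, which light-tailed
                        samples can produce)

The *X-conditional (forward) generator* turns the triple into a membership
degree for a query value x0 via a Gaussian kernel of randomized width:
En' ~ |Normal(En, He^2)| and CT(x0) = exp(-(x0 - Ex)^2 / (2 En'^2)).  In
deterministic mode En' is fixed at En, making the membership a pure
Gaussian kernel; stochastic mode averages the kernel over seeded En'
draws.  Multi-dimensional memberships are the product of per-dimension
memberships (axis-aligned; no cross-feature covariance), and samples are
assigned to the species with the maximum joint membership ("maximum
determination"), with exact ties broken to the lexicographically smallest
species id and flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SQRT_HALF_PI = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class CloudParams:
    """The (Ex, En, He) digital characteristics of one concept dimension."""

    Ex: float
    En: float
    He: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.Ex, self.En, self.He]).all():
            raise ValueError("cloud parameters must be finite")
        if self.En < 0 or self.He < 0:
            raise ValueError("En and He must be non-negative")


def backward_generate(values) -> CloudParams:
    """Estimate (Ex, En, He) from a feature sample (backward generator)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("backward generator needs at least 2 finite values")
    ex = float(x.mean())
    en = float(_SQRT_HALF_PI * np.mean(np.abs(x - ex)))
    s2 = float(x.var(ddof=1))
    gap = s2 - en**2
    if gap < 0:
        if gap < -1e-12 * max(s2, 1.0):
            warnings.warn(
                "S^2 < En^2: hyper-entropy clamped to 0", stacklevel=2
            )
        he = 0.0
    else:
        he = float(np.sqrt(gap))
    return CloudParams(ex, en, he)


def forward_drops(
    params: CloudParams, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate n cloud drops (x, membership) from (Ex, En, He).

    Per drop: En' = |Normal(En, He^2)|, x ~ Normal(Ex, En'^2), membership
    exp(-(x - Ex)^2 / (2 En'^2)).  With En = 0 every drop sits at Ex with
    membership 1.
    """
    if n < 1:
        raise ValueError("need at least one drop")
    rng = np.random.default_rng(seed)
    if params.En == 0:
        return np.full(n, params.Ex), np.ones(n)
    en_prime = np.abs(rng.normal(params.En, params.He, size=n))
    en_prime = np.where(en_prime == 0, params.En, en_prime)
    x = rng.normal(params.Ex, en_prime)
    membership = np.exp(-((x - params.Ex) ** 2) / (2.0 * en_prime**2))
    return x, membership


def membership_1d(
    params: CloudParams,
    x0,
    mode: str = "deterministic",
    m_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray | float:
    """X-conditional membership of x0 in the cloud (vectorized over x0)."""
    x0 = np.asarray(x0, dtype=float)
    if params.En == 0:
        out = np.where(x0 == params.Ex, 1.0, 0.0)
        if np.any(x0 != params.Ex):
            warnings.warn(
                "En = 0: membership is 0 away from Ex", stacklevel=2
            )
        return out if out.ndim else float(out)
    d2 = (x0 - params.Ex) ** 2
    if mode == "deterministic":
        out = np.exp(-d2 / (2.0 * params.En**2))
    elif mode == "stochastic":
        rng = np.random.default_rng(seed)
        en_prime = np.abs(rng.normal(params.En, params.He, size=m_draws))
        en_prime = en_prime[en_prime > 0]
        if en_prime.size == 0:
            en_prime = np.array([params.En])
        out = np.exp(
            -d2[..., None] / (2.0 * en_prime**2)
        ).mean(axis=-1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


@dataclass
class CloudClassifier:
    """Per-species cloud models over a shared ordered feature set."""

    feature_ids: tuple[str, ...]
    species_params: dict[str, tuple[CloudParams, ...]]
    mode: str = "deterministic"
    m_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        d = len(self.feature_ids)
        for sp, plist in self.species_params.items():
            if len(plist) != d:
                raise ValueError(
                    f"species {sp!r} has {len(plist)} dims, expected {d}"
                )
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def species(self) -> list[str]:
        return sorted(self.species_params)

    @property
    def n_dims(self) -> int:
        return len(self.feature_ids)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "feature_ids": list(self.feature_ids),
            "mode": self.mode,
            "m_draws": self.m_draws,
            "seed": self.seed,
            "species": {
                sp: {
                    fid: {"Ex": p.Ex, "En": p.En, "He": p.He}
                    for fid, p in zip(self.feature_ids, plist)
                }
                for sp, plist in self.species_params.items()
            },
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CloudClassifier":
        obj = json.loads(text)
        fids = tuple(obj["feature_ids"])
        params = {
            sp: tuple(
                CloudParams(d[f]["Ex"], d[f]["En"], d[f]["He"]) for f in fids
            )
            for sp, d in obj["species"].items()
        }
        return cls(fids, params, obj["mode"], obj["m_draws"], obj["seed"])


@dataclass(frozen=True)
class MembershipResult:
    memberships: dict[str, float]
    winner: str
    tie_flag: bool


def membership_nd(
    dims: tuple[CloudParams, ...],
    sample,
    mode: str = "deterministic",
    m_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Joint membership: product over dimensions of the 1-D memberships.

    NaN feature values drop their dimension from the product (with a
    warning); a sample missing every dimension is unclassifiable (NaN).
    """
    x = np.asarray(sample, dtype=float)
    if x.shape != (len(dims),):
        raise ValueError("sample dimension does not match the classifier")
    valid = np.isfinite(x)
    if not valid.any():
        return float("nan")
    if not valid.all():
        warnings.warn(
            "missing feature values excluded from the joint membership",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # En=0 handled per dimension
        out = 1.0
        for k, (p, ok) in enumerate(zip(dims, valid)):
            if ok:
                out *= float(
                    membership_1d(p, x[k], mode, m_draws, seed + 7919 * k)
                )
    return out


def fit_classifier(
    train: pd.DataFrame,
    feature_ids,
    labels=None,
    mode: str = "deterministic",
    m_draws: int = 1000,
    seed: int = 0,
) -> CloudClassifier:
    """One backward generation per species per feature dimension.

    ``train`` holds the feature columns; labels come from its ``label``
    column unless passed separately.  Every species needs at least 2 finite
    training values per feature.
    """
    feature_ids = tuple(feature_ids)
    y = np.asarray(train["label"] if labels is None else labels)
    params: dict[str, tuple[CloudParams, ...]] = {}
    for sp in np.unique(y):
        rows = train.loc[y == sp, list(feature_ids)]
        plist = []
        for fid in feature_ids:
            vals = rows[fid].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                raise ValueError(
                    f"species {sp!r} has < 2 finite samples for {fid!r}"
                )
            # light-tailed classes routinely clamp He; not worth a warning
            # per species x feature during a fit
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                plist.append(backward_generate(vals))
        params[str(sp)] = tuple(plist)
    return CloudClassifier(feature_ids, params, mode, m_draws, seed)


def classify_max(
    classifier: CloudClassifier, samples: pd.DataFrame
) -> list[MembershipResult]:
    """Maximum-determination classification of each sample row."""
    cols = list(classifier.feature_ids)
    X = samples[cols].to_numpy(dtype=float)
    results = []
    for row in X:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = {
                sp: membership_nd(
                    classifier.species_params[sp],
                    row,
                    classifier.mode,
                    classifier.m_draws,
                    classifier.seed,
                )
                for sp in classifier.species
            }
        finite = {sp: m for sp, m in ms.items() if np.isfinite(m)}
        if not finite:
            results.append(MembershipResult(ms, "", True))
            continue
        best = max(finite.values())
        winners = sorted(sp for sp, m in finite.items() if m == best)
        results.append(MembershipResult(ms, winners[0], len(winners) > 1))
    return results


def predict_cloud(classifier: CloudClassifier, samples: pd.DataFrame) -> np.ndarray:
    """Predicted species labels (winners only)."""
    return np.array([r.winner for r in classify_max(classifier, samples)])
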