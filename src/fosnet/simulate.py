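"""Synthetic count and behavior tables with planted network structure.

The generator emulates the two coactivation regimes the analysis is built
to distinguish: a low-interference-like (LI) regime in which the
hippocampal subfields (DG, CA3, CA2, CA1) and the parahippocampal areas
(PRH35, PRH36, DLENT) form two internally correlated blocks joined by a
single strong DLENT-DG bridge, and a high-interference-like (HI) regime in
which all seven regions form one integrated block.

Counts are drawn from a Gaussian copula: a latent multivariate normal with
the block-structured correlation matrix is mapped through a monotone
lognormal quantile transform, so the *rank* structure the downstream
pipeline consumes matches the latent correlation up to the known
Pearson-to-Spearman attenuation 6/pi * arcsin(rho/2).  Marginals are
lognormal rounded to 0.1, mimicking per-animal counts averaged over three
tissue sections (non-integer by construction).

Behavior is generated subject-wise: a discrimination index D2 drawn around
a target mean is combined with a lognormal total exploration time T to
give t_old = T(1+D2)/2 and t_recent = T(1-D2)/2, both strictly positive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import DEFAULT_REGIONS, BehaviorTable, CountTable

__all__ = [
    "SimConfig",
    "li_preset",
    "hi_preset",
    "build_latent_correlation",
    "generate_condition_counts",
    "generate_behavior",
    "spearman_attenuation",
]

#: Tolerance below which a negative eigenvalue is considered numerical
#: noise rather than a genuinely indefinite construction.
PSD_TOL = 1e-8

_MAX_BEHAVIOR_RETRIES = 1000


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    block_structure maps a condition label to a list of region blocks;
    pairs inside a block get ``rho_within``, listed ``bridge_pairs`` get
    ``rho_bridge``, and all remaining cross-block pairs get
    ``rho_between``.  Same-block membership takes precedence over a bridge
    listing.  ``count_dispersion`` is the sigma of the underlying normal of
    the lognormal marginal (dimensionless log-scale SD).
    """

    n_subjects_per_condition: int = 8
    regions: tuple[str, ...] = DEFAULT_REGIONS
    block_structure: dict[str, tuple[tuple[str, ...], ...]] = field(
        default_factory=dict)
    rho_within: float = 0.85
    rho_between: float = 0.05
    bridge_pairs: tuple[tuple[str, str], ...] = ()
    rho_bridge: float = 0.8
    count_mean: float = 80.0
    count_dispersion: float = 0.4
    behavior_d2_mean: float = 0.35
    behavior_noise_sd: float = 0.2
    behavior_total_time_mean: float = 30.0
    behavior_total_time_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_condition < 4:
            raise SimConfigError("need at least 4 subjects per condition")
        for r in (self.rho_within, self.rho_between, self.rho_bridge):
            if not -1.0 <= r <= 1.0:
                raise SimConfigError(f"correlation {r} outside [-1, 1]")
        if not (0.0 <= self.rho_within <= 1.0
                and 0.0 <= self.rho_between <= 1.0):
            raise SimConfigError("rho_within and rho_between must be in [0,1]")
        if self.rho_between >= self.rho_within:
            raise SimConfigError("rho_between must be < rho_within")
        if self.count_mean <= 0 or self.count_dispersion <= 0:
            raise SimConfigError("count_mean and count_dispersion must be > 0")
        if not -1.0 < self.behavior_d2_mean < 1.0:
            raise SimConfigError("behavior_d2_mean must lie in (-1, 1)")
        if self.behavior_noise_sd < 0:
            raise SimConfigError("behavior_noise_sd must be >= 0")
        if len(set(self.regions)) != len(self.regions):
            raise SimConfigError("duplicate region labels")
        for cond, blocks in self.block_structure.items():
            seen: set[str] = set()
            for block in blocks:
                for region in block:
                    if region not in self.regions:
                        raise SimConfigError(
                            f"{cond}: unknown region {region!r} in blocks")
                    if region in seen:
                        raise SimConfigError(
                            f"{cond}: region {region!r} in two blocks")
                    seen.add(region)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.block_structure)


def li_preset(n_subjects: int = 8, seed: int = 0) -> SimConfig:
    """Two-block regime: hippocampus and parahippocampus joined only by a
    strong DLENT-DG bridge (the low-interference-like topology)."""
    return SimConfig(
        n_subjects_per_condition=n_subjects,
        block_structure={
            "LI": (("DG", "CA3", "CA2", "CA1"), ("PRH35", "PRH36", "DLENT")),
        },
        rho_within=0.85,
        rho_between=0.05,
        bridge_pairs=(("DLENT", "DG"),),
        rho_bridge=0.8,
        behavior_d2_mean=0.35,
        behavior_noise_sd=0.2,
        seed=seed,
    )


def hi_preset(n_subjects: int = 8, seed: int = 0) -> SimConfig:
    """Single integrated block over all seven regions (the
    high-interference-like topology)."""
    return SimConfig(
        n_subjects_per_condition=n_subjects,
        block_structure={"HI": (DEFAULT_REGIONS,)},
        rho_within=0.8,
        rho_between=0.05,
        behavior_d2_mean=0.35,
        behavior_noise_sd=0.105,
        seed=seed,
    )


def _repair_psd(mat: np.ndarray, tol: float = PSD_TOL
                ) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues to zero and rescale to unit diagonal.

    Returns the repaired matrix and the max elementwise deviation from the
    input.  A matrix already PSD (to tol) is returned unchanged.
    """
    eigval, eigvec = np.linalg.eigh(mat)
    if eigval.min() >= -tol:
        return mat, 0.0
    clipped = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    d = np.sqrt(np.diag(clipped))
    if (d <= 0).any():
        raise SimConfigError("PSD repair produced a zero-variance region")
    repaired = clipped / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2.0
    return repaired, float(np.abs(repaired - mat).max())


def build_latent_correlation(config: SimConfig, condition: str
                             ) -> pd.DataFrame:
    """Latent (Pearson) correlation matrix for one condition.

    Entry rules: unit diagonal; rho_within inside a block; rho_bridge for
    listed bridge pairs; rho_between otherwise.  Repaired to positive
    semi-definiteness by eigenvalue clipping if needed; the max deviation
    introduced by repair is stored in ``DataFrame.attrs['repair_max_delta']``.
    """
    if condition not in config.block_structure:
        raise SimConfigError(
            f"unknown condition {condition!r}; "
            f"known: {list(config.block_structure)}")
    regions = list(config.regions)
    idx = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    mat = np.full((n, n), config.rho_between)
    for a, b in config.bridge_pairs:
        if a not in idx or b not in idx:
            raise SimConfigError(f"bridge pair ({a}, {b}) has unknown region")
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = config.rho_bridge
    for block in config.block_structure[condition]:
        ids = [idx[r] for r in block]
        for i in ids:
            for j in ids:
                if i != j:
                    mat[i, j] = config.rho_within
    np.fill_diagonal(mat, 1.0)
    repaired, delta = _repair_psd(mat)
    out = pd.DataFrame(repaired, index=regions, columns=regions)
    out.attrs["repair_max_delta"] = delta
    return out


def spearman_attenuation(rho: float) -> float:
    """Spearman correlation implied by a Gaussian-copula Pearson rho.

    Any monotone marginal transform of a bivariate normal has population
    Spearman correlation (6/pi) arcsin(rho/2).
    """
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


def _rng(config: SimConfig, condition: str, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, condition, purpose)."""
    key = zlib.crc32(f"{condition}/{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def _correlated_normals(config: SimConfig, condition: str, n: int
                        ) -> np.ndarray:
    latent = build_latent_correlation(config, condition).to_numpy()
    eigval, eigvec = np.linalg.eigh(latent)
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = _rng(config, condition, "counts").standard_normal(
        (n, len(config.regions)))
    return z @ factor.T


def generate_condition_counts(config: SimConfig, condition: str,
                              n_subjects: int | None = None) -> CountTable:
    """Draw a subjects x regions count table for one condition.

    Lognormal marginals with mean ``count_mean`` and log-scale SD
    ``count_dispersion``, correlated through the Gaussian copula, rounded
    to 0.1 and floored at 0.1 so every count is strictly positive.
    """
    n = config.n_subjects_per_condition if n_subjects is None else n_subjects
    z = _correlated_normals(config, condition, n)
    sigma = config.count_dispersion
    counts = config.count_mean * np.exp(sigma * z - sigma * sigma / 2.0)
    counts = np.maximum(np.round(counts, 1), 0.1)
    subjects = [f"{condition}{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame(counts, index=pd.Index(subjects, name="subject"),
                      columns=list(config.regions))
    return CountTable(condition=condition, data=df)


def generate_behavior(config: SimConfig, condition: str,
                      n_subjects: int | None = None) -> BehaviorTable:
    """Draw per-subject exploration times with target mean D2.

    D2 values outside (-0.999, 0.999) are resampled (bounded retries) so
    both times stay strictly positive; the retry count is recorded in
    ``BehaviorTable.data.attrs['n_resampled']``.
    """
    if condition not in config.block_structure:
        raise SimConfigError(f"unknown condition {condition!r}")
    n = config.n_subjects_per_condition if n_subjects is None else n_subjects
    rng = _rng(config, condition, "behavior")
    d2 = rng.normal(config.behavior_d2_mean, config.behavior_noise_sd, size=n)
    n_resampled = 0
    bad = np.abs(d2) >= 0.999
    tries = 0
    while bad.any():
        tries += 1
        if tries > _MAX_BEHAVIOR_RETRIES:
            raise SimConfigError(
                "behavior_noise_sd too large: could not draw D2 in (-1, 1) "
                f"after {_MAX_BEHAVIOR_RETRIES} retries")
        n_resampled += int(bad.sum())
        d2[bad] = rng.normal(config.behavior_d2_mean,
                             config.behavior_noise_sd, size=int(bad.sum()))
        bad = np.abs(d2) >= 0.999
    log_sd = config.behavior_total_time_log_sd
    total = config.behavior_total_time_mean * np.exp(
        log_sd * rng.standard_normal(n) - log_sd * log_sd / 2.0)
    t_old = total * (1.0 + d2) / 2.0
    t_recent = total * (1.0 - d2) / 2.0
    subjects = [f"{condition}{i + 1:02d}" for i in range(n)]
    table = BehaviorTable.from_times(condition, subjects, t_old, t_recent)
    table.data.attrs["n_resampled"] = n_resampled
    return table
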