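"""Seeded synthetic data with the exact statistical structure the
downstream analyses assume.

Generative scheme (canonical group order, documented in :data:`GROUPS`):

* group j has mean ``nu_j = alpha[type_j] + beta[type_j] * copper_j``
* replicate k of group j has mean ``lambda_{j,k} ~ Normal(nu_j, tau_j)``
* each isolate value is ``Normal(lambda_{j,k}, sigma_j)``

Raw CAS reads are emitted by inverting the quantification formula,
``A_i = a_ref * (1 - s * OD)``, so that zero-noise reads round-trip
exactly through :mod:`siderotrait.cas`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUPS, X1, X2
from .fitness import CompetitionAssay

__all__ = [
    "SyntheticConfig",
    "generate_design",
    "simulate_siderophore",
    "simulate_cas_reads",
    "simulate_competition",
]


@dataclass
class SyntheticConfig:
    """Seed, true generative parameters and design sizes."""

    seed: int = 0
    n_groups: int = 4
    n_replicates: int = 6
    n_isolates: int = 24
    dropout_prob: float = 0.0
    alpha: tuple[float, float] = (0.5, 0.7)
    beta: tuple[float, float] = (0.04, -0.04)
    tau: tuple[float, ...] = (0.02, 0.02, 0.02, 0.02)
    sigma: tuple[float, ...] = (0.10, 0.07, 0.03, 0.035)
    assay_noise_sd: float = 0.0
    a_ref: float = 0.6
    od_range: tuple[float, float] = (0.3, 1.2)
    # optional genus structure for community isolates: label -> (prob, mean offset)
    genus_table: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_groups != 4:
            raise ValueError("n_groups must be 4 (isolate type x copper)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_isolates < 1:
            raise ValueError("n_isolates must be >= 1")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if len(self.alpha) != 2 or len(self.beta) != 2:
            raise ValueError("alpha and beta must have one entry per isolate type")
        if len(self.tau) != 4 or len(self.sigma) != 4:
            raise ValueError("tau and sigma must have one entry per group")
        if any(t < 0 for t in self.tau):
            raise ValueError("tau entries must be >= 0")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma entries must be >= 0")
        if self.assay_noise_sd < 0:
            raise ValueError("assay_noise_sd must be >= 0")
        if self.a_ref <= 0:
            raise ValueError("a_ref must be > 0")
        if self.genus_table:
            total = sum(p for p, _ in self.genus_table.values())
            if not np.isclose(total, 1.0):
                raise ValueError("genus_table probabilities must sum to 1")

    @property
    def nu(self) -> np.ndarray:
        """True group means nu_j = alpha[X1[j]] + beta[X1[j]] * X2[j]."""
        a = np.asarray(self.alpha)
        b = np.asarray(self.beta)
        t = np.asarray(X1) - 1
        return a[t] + b[t] * np.asarray(X2)


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # independent, reproducible streams per generator
    ss = np.random.SeedSequence(config.seed, spawn_key=(hash(stream) % (2**32),))
    return np.random.default_rng(ss)


def generate_design(config: SyntheticConfig) -> pd.DataFrame:
    """Factorial layout: one row per retained (group, replicate, isolate) slot.

    Isolate slots are dropped i.i.d. with probability ``dropout_prob``, so
    each replicate retains Binomial(n_isolates, 1 - dropout_prob) rows.
    """
    rng = _rng(config, "design")
    rows = []
    for g, (itype, cu) in enumerate(GROUPS, start=1):
        for rep in range(1, config.n_replicates + 1):
            keep = rng.random(config.n_isolates) >= config.dropout_prob
            for iso in np.nonzero(keep)[0] + 1:
                rows.append(
                    {
                        "group": g,
                        "replicate": rep,
                        "isolate": int(iso),
                        "isolate_type": itype,
                        "copper": cu,
                    }
                )
    df = pd.DataFrame(rows)
    df["microcosm_id"] = df["group"].astype(str) + "." + df["replicate"].astype(str)
    df["isolate_id"] = df["microcosm_id"] + "." + df["isolate"].astype(str)
    return df


def simulate_siderophore(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate isolate-level siderophore scores from the hierarchical model.

    Returns the canonical isolate table plus ``true_lambda`` (the replicate
    mean each value was drawn around) for test introspection.
    """
    design = generate_design(config)
    rng = _rng(config, "siderophore")
    nu = config.nu
    lam = np.empty((4, config.n_replicates))
    for j in range(4):
        lam[j] = rng.normal(nu[j], config.tau[j], size=config.n_replicates)
    g = design["group"].to_numpy() - 1
    r = design["replicate"].to_numpy() - 1
    mean = lam[g, r]
    sd = np.asarray(config.sigma)[g]
    values = rng.normal(mean, sd)

    genus = np.where(design["isolate_type"] == "SBW25", "SBW25", "community")
    genus = genus.astype(object)
    if config.genus_table:
        labels = list(config.genus_table)
        probs = np.array([config.genus_table[k][0] for k in labels])
        offsets = {k: v[1] for k, v in config.genus_table.items()}
        mask = (design["isolate_type"] == "community").to_numpy()
        draw = rng.choice(labels, size=int(mask.sum()), p=probs)
        genus[mask] = draw
        values[mask] += np.array([offsets[k] for k in draw])

    out = design.copy()
    out["genus"] = genus
    out["community_context"] = 1  # coculture layout: both types share microcosms
    out["siderophore"] = values
    out["true_lambda"] = mean
    cols = [
        "isolate_id",
        "microcosm_id",
        "group",
        "replicate",
        "isolate_type",
        "copper",
        "community_context",
        "genus",
        "siderophore",
        "true_lambda",
    ]
    return out[cols]


def simulate_cas_reads(records: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Emit raw CAS reads whose quantification recovers ``records.siderophore``.

    ``A_i = a_ref * (1 - s * OD) + Normal(0, assay_noise_sd)``; OD values are
    Uniform over ``config.od_range``.  With noise, some reads invert to
    negative raw scores, exercising the min-zero standardization.
    """
    if "siderophore" not in records.columns:
        raise ValueError("records must carry a 'siderophore' column")
    rng = _rng(config, "cas")
    n = len(records)
    od = rng.uniform(*config.od_range, size=n)
    if np.any(od <= 0):
        raise ValueError("od_range must generate positive OD values")
    s = records["siderophore"].to_numpy(float)
    a630 = config.a_ref * (1.0 - s * od)
    if config.assay_noise_sd > 0:
        a630 = a630 + rng.normal(0.0, config.assay_noise_sd, size=n)
    return pd.DataFrame(
        {
            "isolate_id": records["isolate_id"].to_numpy(),
            "a630": np.clip(a630, 0.0, None),
            "a630_ref": config.a_ref,
            "od600": od,
        }
    )


def simulate_competition(
    m_a: float,
    m_b: float,
    n0_a: float,
    n0_b: float,
    t: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    strain_a: str = "producer",
    strain_b: str = "nonproducer",
) -> CompetitionAssay:
    """Simulate a pairwise competition: N(t) = N0 * exp(m t) with
    multiplicative log-normal noise on the final densities.

    At zero noise the downstream Malthusian / selection-rate recovery is
    exact.
    """
    if n0_a <= 0 or n0_b <= 0:
        raise ValueError("initial densities must be positive")
    if t <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    eps_a = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    eps_b = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    n1_a = n0_a * np.exp(m_a * t + eps_a)
    n1_b = n0_b * np.exp(m_b * t + eps_b)
    return CompetitionAssay(
        strain_a=strain_a,
        strain_b=strain_b,
        density_t0_a=n0_a,
        density_t1_a=float(n1_a),
        density_t0_b=n0_b,
        density_t1_b=float(n1_b),
        duration=t,
        initial_frequency_a=n0_a / (n0_a + n0_b),
    )
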