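"""Synthetic germination studies with the statistical structure the pipeline assumes.

The generator emulates a common-garden germination screen of wild-pea-like
accessions: three latent dormancy classes (non-dormant N, temperature
responsive R, dormant D) with class- and treatment-specific final
germination fractions and speeds; a clustered sampling landscape with
spatially autocorrelated environmental fields, one of which (a "BIO7
analog", temperature annual range) drives class membership; and
class-structured seed-coat traits.  It reproduces statistical structure
(spatial autocorrelation, class linkage, effect sizes), not realistic
Mediterranean climate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curve_model import GerminationRecord
from .raster import Grid
from .spatial import haversine_distances

__all__ = [
    "ClassParams",
    "SimulationConfig",
    "simulate_germination",
    "simulate_landscape",
    "simulate_traits",
    "simulate_study",
    "SyntheticStudy",
]


@dataclass
class ClassParams:
    """Germination behaviour of one dormancy class under both regimes.

    ``p`` = (willingness at 25/15, at 35/15); ``median_day`` = median
    imbibition day per regime; ``log_sd`` = log-normal spread of imbibition
    times.
    """

    p: tuple
    median_day: tuple
    log_sd: float = 0.35


@dataclass
class SimulationConfig:
    """Study design and generative parameters (defaults mirror the emulated screen)."""

    n_accessions: int = 97
    class_counts: dict = field(default_factory=lambda: {"N": 28, "R": 40, "D": 29})
    seeds_total: int = 25
    replicates: int = 2
    horizon: int = 28
    class_params: dict = field(default_factory=lambda: {
        "N": ClassParams(p=(0.92, 0.95), median_day=(6.0, 5.0)),
        "R": ClassParams(p=(0.15, 0.75), median_day=(12.0, 8.0)),
        "D": ClassParams(p=(0.15, 0.20), median_day=(14.0, 12.0)),
    })
    accession_logit_sd: float = 0.35  # accession-level jitter of willingness
    # landscape
    extent: tuple = (-10.0, 40.0, 30.0, 48.0)  # lon_min, lon_max, lat_min, lat_max
    n_clusters: int = 8
    cluster_sd_deg: float = 2.0
    env_names: tuple = ("BIO1", "BIO6", "BIO7", "BIO12", "CRFVOL", "PHIHOX")
    linked_env: str = "BIO7"
    gp_range_km: float = 500.0
    gp_sd: float = 1.0
    link_strength: float = 2.0  # latent-score units per SD of the linked field
    raster_shape: tuple = (24, 36)  # nrows, ncols for exported grids
    # traits
    thickness_median: dict = field(default_factory=lambda: {"D": 138.0, "R": 140.0, "N": 84.0})
    thickness_log_sd: dict = field(default_factory=lambda: {"D": 0.12, "R": 0.12, "N": 0.35})
    pa_mean: dict = field(default_factory=lambda: {"D": 2.18, "R": 1.87, "N": 1.77})
    pa_sd: float = 0.60
    pa_range: tuple = (1.21, 4.70)
    soluble_fraction: tuple = (0.94, 0.99)
    lwr_mean: dict = field(default_factory=lambda: {"D": 1.10, "R": 1.12, "N": 1.22})
    seed: int = 0

    def class_labels(self) -> list:
        if sum(self.class_counts.values()) != self.n_accessions:
            raise ValueError("class counts must sum to n_accessions")
        labels = []
        for c, n in self.class_counts.items():
            labels += [c] * n
        return labels

    def accession_ids(self) -> list:
        return [f"ACC{i:03d}" for i in range(1, self.n_accessions + 1)]


TREATMENT_INDEX = {"T25_15": 0, "T35_15": 1}


def simulate_germination(config: SimulationConfig, labels=None, rng=None):
    """Daily cumulative imbibition counts per accession x treatment x replicate.

    Each seed is independently "willing" with the accession's class- and
    treatment-specific probability (jittered per accession on the logit
    scale); willing seeds draw a log-normal imbibition day with the class
    median and spread, censored at the horizon.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = labels if labels is not None else config.class_labels()
    ids = config.accession_ids()
    days = np.arange(1, config.horizon + 1, dtype=float)
    records = []
    for acc, lab in zip(ids, labels):
        params = config.class_params[lab]
        jitter = rng.normal(0.0, config.accession_logit_sd)
        for tr, ti in TREATMENT_INDEX.items():
            p = params.p[ti]
            if not 0.0 <= p <= 1.0:
                raise ValueError("willingness probability outside [0, 1]")
            logit = np.log(p / (1 - p)) if 0 < p < 1 else np.inf * np.sign(p - 0.5)
            p_acc = 1 / (1 + np.exp(-(logit + jitter))) if np.isfinite(logit) else p
            mu = np.log(params.median_day[ti])
            for rep in range(1, config.replicates + 1):
                willing = rng.random(config.seeds_total) < p_acc
                times = np.exp(mu + params.log_sd * rng.standard_normal(config.seeds_total))
                times[~willing] = np.inf
                counts = (times[None, :] <= days[:, None]).sum(axis=1).astype(float)
                records.append(GerminationRecord(acc, tr, rep, config.seeds_total,
                                                 days, counts))
    return records


def _exp_cov(D, sd, range_km):
    return sd**2 * np.exp(-D / range_km)


def simulate_landscape(config: SimulationConfig, rng=None):
    """Clustered accession coordinates plus spatially autocorrelated env fields.

    Each field is a Gaussian process with exponential covariance sampled
    jointly at the accession points and on an export raster; class labels are
    assigned through an ordered latent score ``link_strength * z_linked +
    logistic noise`` (link 0 => labels independent of the environment), with
    class sizes held at the configured counts.  Dormant accessions sit at the
    low end of the linked field (small temperature annual range).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lon0, lon1, lat0, lat1 = config.extent
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError("degenerate landscape extent")
    n = config.n_accessions
    centers = np.column_stack([
        rng.uniform(lon0 + 2, lon1 - 2, config.n_clusters),
        rng.uniform(lat0 + 2, lat1 - 2, config.n_clusters),
    ])
    which = rng.integers(0, config.n_clusters, n)
    pts = centers[which] + rng.normal(0, config.cluster_sd_deg, (n, 2))
    pts[:, 0] = np.clip(pts[:, 0], lon0, lon1)
    pts[:, 1] = np.clip(pts[:, 1], lat0, lat1)

    nrows, ncols = config.raster_shape
    cellsize = max((lon1 - lon0) / ncols, (lat1 - lat0) / nrows)
    base = Grid(np.zeros((nrows, ncols)), lon0, lat0, cellsize)
    glon, glat = base.cell_centers()
    cells = np.column_stack([glon.ravel(), glat.ravel()])

    allpts = np.vstack([pts, cells])
    D = haversine_distances(allpts)
    C = _exp_cov(D, config.gp_sd, config.gp_range_km)
    C[np.diag_indices_from(C)] += 1e-8
    L = np.linalg.cholesky(C)

    env = {}
    grids = {}
    for name in config.env_names:
        f = L @ rng.standard_normal(len(allpts))
        env[name] = f[:n]
        grids[name] = base.copy_with(f[n:].reshape(nrows, ncols))
    env_df = pd.DataFrame(env, index=config.accession_ids())

    if sum(config.class_counts.values()) != n:
        raise ValueError("class counts must sum to n_accessions")
    z = env_df[config.linked_env].to_numpy()
    z = (z - z.mean()) / z.std()
    score = config.link_strength * z + rng.logistic(0, 1, n)
    order = np.argsort(score)  # low score -> D, middle -> R, high -> N
    labels = np.empty(n, dtype=object)
    nd, nr = config.class_counts["D"], config.class_counts["R"]
    labels[order[:nd]] = "D"
    labels[order[nd:nd + nr]] = "R"
    labels[order[nd + nr:]] = "N"

    coords = pd.DataFrame(pts, columns=["lon", "lat"], index=config.accession_ids())
    return coords, env_df, grids, list(labels)


def simulate_traits(config: SimulationConfig, labels, rng=None) -> pd.DataFrame:
    """Class-structured seed traits (thickness, PA fractions, morphology).

    Testa thickness is log-normal with class-specific medians (N more
    variable); total PA is a truncated normal per class; soluble PA is
    94-99% of total with the remainder insoluble; morphology is linked to
    class only through the length-to-width ratio.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = list(labels)
    ids = config.accession_ids()
    lo, hi = config.pa_range
    rows = []
    for acc, lab in zip(ids, labels):
        thick = np.exp(np.log(config.thickness_median[lab])
                       + config.thickness_log_sd[lab] * rng.standard_normal())
        total_pa = np.clip(rng.normal(config.pa_mean[lab], config.pa_sd), lo, hi)
        sfrac = rng.uniform(*config.soluble_fraction)
        spa = sfrac * total_pa
        length = rng.normal(4.8, 0.35)
        lwr = max(rng.normal(config.lwr_mean[lab], 0.06), 1.0)
        width = length / lwr
        area = np.pi * length * width / 4
        perim = np.pi * (3 * (length + width) / 2 - np.sqrt(length * width))
        rows.append({
            "accession_id": acc,
            "category": lab,
            "testa_um": thick,
            "total_pa": total_pa,
            "soluble_pa": spa,
            "insoluble_pa": total_pa - spa,
            "AS": area,
            "PL": perim,
            "L": length,
            "W": width,
            "LWR": lwr,
            "CS": 4 * np.pi * area / perim**2,
            "DS": rng.normal(0.25, 0.05),
            "HSW": rng.normal(11.0, 2.0),
        })
    return pd.DataFrame(rows).set_index("accession_id")


@dataclass
class SyntheticStudy:
    """One complete synthetic study: counts, landscape, labels and traits."""

    config: SimulationConfig
    records: list
    coords: pd.DataFrame
    env: pd.DataFrame
    env_grids: dict
    labels: list
    traits: pd.DataFrame


def simulate_study(config: SimulationConfig | None = None, seed=None) -> SyntheticStudy:
    """Generate a full study; ``seed`` overrides ``config.seed``."""
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = int(seed)
    rng = np.random.default_rng(config.seed)
    coords, env, grids, labels = simulate_landscape(config, rng=rng)
    records = simulate_germination(config, labels=labels, rng=rng)
    traits = simulate_traits(config, labels, rng=rng)
    return SyntheticStudy(config, records, coords, env, grids, labels, traits)
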