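"""Synthetic imaging–genetics triplets with planted sparse cross-modal structure.

A sparse set of variants drives a latent factor; the latent factor
drives a sparse set of imaging features and the continuous target
(age-at-onset-like, in years). All three pairwise associations of the
objective-specific sparse CCA are therefore simultaneously positive,
and the planted supports provide ground truth for recovery tests. The
default shape emulates the motivating cohort: 146 subjects, 90 imaging
regions, 72 candidate variants, 14 true imaging features and 24 true
variants.

Deliberately not modeled: linkage disequilibrium between variants,
spatially correlated imaging noise, population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np

from .data import Dataset, write_imaging_table, write_plink_raw, write_target
from .enrichment import GeneSetCollection, write_annotation, write_gmt

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "gen_genotypes",
    "gen_dataset",
    "gen_annotation",
    "paper_shape_config",
    "SIGNAL_LEVELS",
    "write_dataset_files",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Effects: ``beta_g`` scales each true variant's contribution to the
    latent factor; ``gamma_x`` the latent loading of true imaging
    columns; ``delta_z`` the latent→target effect in years per latent
    sd. ``noise_l``/``noise_x`` are on the latent/imaging scale
    (off-support imaging columns are unit-variance noise), ``noise_z``
    in years. ``target_mean`` anchors the target to a realistic
    age-at-onset scale.
    """

    n: int = 146
    p: int = 90
    q: int = 72
    s_x: int = 14
    s_y: int = 24
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_g: float = 0.5
    gamma_x: float = 1.0
    delta_z: float = 5.0
    noise_l: float = 0.6
    noise_x: float = 0.6
    noise_z: float = 8.0
    target_mean: float = 61.35
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.s_x <= self.p and 1 <= self.s_y <= self.q):
            raise ValueError("support sizes must fit inside their blocks")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if min(self.noise_l, self.noise_x, self.noise_z) <= 0:
            raise ValueError("noise sds must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n < 2:
            raise ValueError("need at least 2 subjects")


@dataclass
class SyntheticDataset:
    """A Dataset plus the planted ground truth."""

    dataset: Dataset
    support_x: np.ndarray  # sorted true imaging feature indices
    support_y: np.ndarray  # sorted true variant indices
    latent: np.ndarray
    config: SyntheticConfig


def gen_genotypes(n: int, q: int, mafs: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independent additive genotypes: entry ~ Binomial(2, maf_j)."""
    mafs = np.asarray(mafs, dtype=float).ravel()
    if mafs.size != q:
        raise ValueError("mafs must have length q")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("each maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n, q)).astype(float)


def gen_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one (X, Y, Z) triplet with planted supports and recorded truth."""
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.q)
    Y = gen_genotypes(config.n, config.q, mafs, seed=int(rng.integers(2**31)))

    support_y = np.sort(rng.choice(config.q, size=config.s_y, replace=False))
    support_x = np.sort(rng.choice(config.p, size=config.s_x, replace=False))

    raw = config.beta_g * Y[:, support_y].sum(axis=1) + rng.normal(
        0.0, config.noise_l, config.n
    )
    sd = raw.std()
    latent = (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    X = rng.normal(0.0, 1.0, size=(config.n, config.p))
    X[:, support_x] = config.gamma_x * latent[:, None] + rng.normal(
        0.0, config.noise_x, size=(config.n, config.s_x)
    )
    # map to a plausible mean-FA scale; affine, so correlations are unchanged
    X = 0.45 + 0.05 * X

    Z = config.target_mean + config.delta_z * latent + rng.normal(
        0.0, config.noise_z, config.n
    )

    if config.dropout > 0:
        mask = rng.random(Y.shape) < config.dropout
        Y = Y.copy()
        Y[mask] = np.nan

    ids = [f"s{i + 1:04d}" for i in range(config.n)]
    imaging_names = [f"ROI{j + 1:03d}" for j in range(config.p)]
    alleles = rng.choice(list("ACGT"), size=config.q)
    numbers: set[int] = set()
    while len(numbers) < config.q:  # rsID numbers must be unique
        numbers.update(rng.integers(10**4, 10**8, config.q - len(numbers)).tolist())
    variant_names = [f"rs{v}_{a}" for v, a in zip(sorted(numbers), alleles)]
    ds = Dataset(
        subject_ids=ids,
        X=X,
        Y=Y,
        Z=Z,
        imaging_names=imaging_names,
        variant_names=variant_names,
    )
    return SyntheticDataset(
        dataset=ds, support_x=support_x, support_y=support_y, latent=latent, config=config
    )


def gen_annotation(
    synth: SyntheticDataset,
    n_genes: int = 60,
    enriched_set_size: int = 10,
    n_decoy_sets: int = 19,
    seed: int = 0,
) -> tuple[dict[str, str], GeneSetCollection]:
    """Build an rsID→gene table plus gene sets with one planted enriched set.

    True-support variants map preferentially into the planted set's
    genes; every other variant maps to a gene outside it. Decoy sets are
    random draws from the universe.
    """
    if not (1 <= enriched_set_size <= n_genes):
        raise ValueError("enriched_set_size must be between 1 and n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    planted = genes[:enriched_set_size]
    others = genes[enriched_set_size:]
    if not others:
        raise ValueError("need at least one gene outside the planted set")
    names = synth.dataset.variant_names
    rsids = [v.rsplit("_", 1)[0] for v in names]
    annotation: dict[str, str] = {}
    support = set(synth.support_y.tolist())
    for j, rsid in enumerate(rsids):
        if j in support:
            annotation[rsid] = planted[len([i for i in support if i < j]) % len(planted)]
        else:
            annotation[rsid] = str(rng.choice(others))
    sets: dict[str, list[str]] = {"PLANTED": list(planted)}
    for d in range(n_decoy_sets):
        size = int(rng.integers(max(2, enriched_set_size // 2), enriched_set_size + 5))
        sets[f"DECOY{d + 1:02d}"] = list(rng.choice(genes, size=min(size, n_genes), replace=False))
    return annotation, GeneSetCollection(sets=sets, universe=genes)


# Named signal regimes used across tests and examples. "strong" is the
# detectability-maximal realistic regime: common variants (each of the 24
# equal contributors then sits at its per-variant correlation ceiling of
# 1/sqrt(24) with the latent) and low latent/imaging/target noise. "null"
# severs the latent→target link entirely.
SIGNAL_LEVELS: dict[str, dict] = {
    "strong": dict(beta_g=0.5, noise_l=0.3, gamma_x=1.0, noise_x=0.25, delta_z=9.0,
                   noise_z=3.5, maf_range=(0.2, 0.5)),
    "moderate": dict(beta_g=0.5, noise_l=0.6, gamma_x=1.0, noise_x=0.6, delta_z=5.0,
                     noise_z=8.0),
    "weak": dict(beta_g=0.5, noise_l=0.8, gamma_x=1.0, noise_x=0.8, delta_z=2.5,
                 noise_z=9.0),
    "null": dict(beta_g=0.5, noise_l=0.6, gamma_x=1.0, noise_x=0.6, delta_z=0.0,
                 noise_z=8.0),
}


def paper_shape_config(signal: str = "moderate", seed: int = 0) -> SyntheticConfig:
    """The cohort-shaped configuration: n=146, p=90, q=72, s_x=14, s_y=24."""
    if signal not in SIGNAL_LEVELS:
        raise ValueError(f"signal must be one of {sorted(SIGNAL_LEVELS)}")
    return replace(SyntheticConfig(seed=seed), **SIGNAL_LEVELS[signal])


def write_dataset_files(synth: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write imaging CSV, genotype .raw, target CSV and the ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = synth.dataset
    paths = {
        "imaging": out / "imaging.csv",
        "genotypes": out / "genotypes.raw",
        "target": out / "target.csv",
        "truth": out / "truth.json",
    }
    write_imaging_table(paths["imaging"], ds.X, ds.subject_ids, ds.imaging_names)
    write_plink_raw(paths["genotypes"], ds.Y, ds.subject_ids, ds.variant_names)
    write_target(paths["target"], ds.Z, ds.subject_ids)
    paths["truth"].write_text(
        json.dumps(
            {
                "support_x": [int(i) for i in synth.support_x],
                "support_y": [int(i) for i in synth.support_y],
                "imaging_names": [ds.imaging_names[i] for i in synth.support_x],
                "variant_names": [ds.variant_names[i] for i in synth.support_y],
                "latent": [float(v) for v in synth.latent],
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths
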