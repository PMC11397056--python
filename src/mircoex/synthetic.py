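"""Synthetic count data with known ground truth for every pipeline stage.

Counts are negative-binomial with heterogeneous log-normal library sizes.
A configurable minority of miRNAs carry a planted group effect, and a
configurable set of (miRNA, gene) pairs share a per-sample latent Gaussian
factor whose loading is calibrated numerically so the realized correlation
on the transformed-CPM scale matches the requested value.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from mircoex import io
from mircoex.targets import REGIONS, NameMap, TargetDB

MIRNA_TISSUE = "ULF-EV"


class ConfigError(ValueError):
    """Invalid synthetic configuration; message names the offending field."""


def _default_groups() -> dict[str, int]:
    return {"AI": 7, "IVP-ET": 7, "NCP": 5}


def _default_tissues() -> tuple[str, ...]:
    return ("EET", "CAR", "ICAR")


@dataclass
class SyntheticConfig:
    n_samples_per_group: dict[str, int] = field(default_factory=_default_groups)
    n_mirna: int = 263
    n_mrna: int = 500
    baseline_mean: float = 200.0        # expected count at library size 1e6
    feature_log_sd: float = 0.5         # spread of per-feature baselines (ln scale)
    dispersion: float = 0.1             # NB phi: var = mu + phi mu^2
    libsize_log_sd: float = 0.2
    n_de: int = 0
    de_log2fc: float = 2.0
    n_pairs: int = 0
    pair_rho: float = -0.8
    target_db_coverage: float = 1.0
    decoy_targets: int = 0
    mrna_tissues: tuple[str, ...] = field(default_factory=_default_tissues)
    conceptus_tissue: str = "EET"       # absent for the no-conceptus group
    no_conceptus_group: str = "NCP"
    n_categories: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not self.n_samples_per_group:
            raise ConfigError("n_samples_per_group: must name at least one group")
        for g, n in self.n_samples_per_group.items():
            if n < 0:
                raise ConfigError(f"n_samples_per_group[{g!r}]: negative sample count")
        for name in ("n_mirna", "n_mrna", "n_de", "n_pairs", "decoy_targets", "n_categories"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean: must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion: must be positive")
        if self.libsize_log_sd < 0:
            raise ConfigError("libsize_log_sd: must be non-negative")
        if self.feature_log_sd < 0:
            raise ConfigError("feature_log_sd: must be non-negative")
        if not abs(self.pair_rho) < 1:
            raise ConfigError("pair_rho: |rho| must be < 1")
        if not 0 <= self.target_db_coverage <= 1:
            raise ConfigError("target_db_coverage: must be in [0, 1]")
        if self.n_de > self.n_mirna:
            raise ConfigError("n_de: exceeds n_mirna")
        if self.n_pairs > self.n_mirna * self.n_mrna:
            raise ConfigError("n_pairs: exceeds n_mirna * n_mrna")


@dataclass
class GroundTruth:
    """What was planted: DE features, correlated pairs, true library sizes."""

    de_features: list[tuple[str, str, int]]          # (feature, contrast, sign)
    planted_pairs: list[tuple[str, str, float]]      # (mirna, gene, true_rho)
    true_libsize_factors: dict[str, dict[str, float]]  # matrix -> sample -> size
    latent_loading: float

    def to_json(self) -> dict:
        return {
            "de_features": [list(t) for t in self.de_features],
            "planted_pairs": [list(t) for t in self.planted_pairs],
            "true_libsize_factors": self.true_libsize_factors,
            "latent_loading": self.latent_loading,
        }


@dataclass
class Dataset:
    mirna_counts: pd.DataFrame
    mrna_counts: dict[str, pd.DataFrame]
    sample_sheet: pd.DataFrame
    target_db: TargetDB
    name_map: NameMap
    annotation: pd.DataFrame
    truth: GroundTruth


def _sub_rng(seed: int, tag: str) -> np.random.Generator:
    """Stable named RNG stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]))


@lru_cache(maxsize=64)
def _calibrate_lambda(rho_abs: float, mean: float, phi: float,
                      negative: bool, n_sim: int = 4000) -> float:
    """Loading lambda such that asinh-CPM correlation of a planted pair ~ rho.

    Bisection against a deterministic internal simulation (common random
    numbers via a fixed seed) of two NB features sharing lambda*Z on the
    log2-mean scale, the second side negated for negative pairs.
    """
    if rho_abs == 0:
        return 0.0
    sign = -1.0 if negative else 1.0

    def realized(lam: float) -> float:
        rng = np.random.default_rng(987654321)
        z = rng.normal(size=n_sim)
        mu1 = mean * 2.0 ** (lam * z)
        mu2 = mean * 2.0 ** (sign * lam * z)
        c1 = rng.poisson(rng.gamma(1.0 / phi, phi * mu1))
        c2 = rng.poisson(rng.gamma(1.0 / phi, phi * mu2))
        t1 = np.arcsinh(c1.astype(float))
        t2 = np.arcsinh(c2.astype(float))
        r = np.corrcoef(t1, t2)[0, 1]
        return abs(r)

    lo, hi = 1e-4, 6.0
    if realized(hi) < rho_abs:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rho_abs:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    return 0.5 * (lo + hi)


def _mirna_ids(n: int) -> list[str]:
    return [f"bta-mir-{i + 1}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _mature_names(precursor: str) -> tuple[str, str]:
    stem = precursor.replace("-mir-", "-miR-")
    return f"{stem}-5p", f"{stem}-3p"


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate count matrices, sample sheet, target table and ground truth.

    Identical config + seed reproduces identical output bit-for-bit.  The
    conceptus tissue has no samples for the no-conceptus group.
    """
    config.validate()
    seed = config.seed
    groups = config.n_samples_per_group
    samples = [f"{g}_{i + 1}" for g in groups for i in range(groups[g])]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    mirnas = _mirna_ids(config.n_mirna)
    genes = _gene_ids(config.n_mrna)
    phi = config.dispersion

    # planted DE miRNAs: effect applied in the first group vs all others
    first_group = next(iter(groups))
    rng_de = _sub_rng(seed, "de")
    de_idx = rng_de.choice(config.n_mirna, size=config.n_de, replace=False) if config.n_de else np.array([], dtype=int)
    de_signs = rng_de.choice([1, -1], size=config.n_de) if config.n_de else np.array([], dtype=int)
    de_features = [
        (mirnas[i], f"{first_group}:{g}", int(s))
        for i, s in zip(de_idx, de_signs)
        for g in groups if g != first_group
    ]

    # planted co-expressed pairs: disjoint feature usage when sizes allow
    rng_pairs = _sub_rng(seed, "pairs")
    if config.n_pairs <= min(config.n_mirna, config.n_mrna):
        pm = rng_pairs.choice(config.n_mirna, size=config.n_pairs, replace=False)
        pg = rng_pairs.choice(config.n_mrna, size=config.n_pairs, replace=False)
        pair_idx = list(zip(pm.tolist(), pg.tolist()))
    else:
        seen: set[tuple[int, int]] = set()
        pair_idx = []
        while len(pair_idx) < config.n_pairs:
            t = (int(rng_pairs.integers(config.n_mirna)), int(rng_pairs.integers(config.n_mrna)))
            if t not in seen:
                seen.add(t)
                pair_idx.append(t)
    lam = _calibrate_lambda(abs(config.pair_rho), config.baseline_mean, phi,
                            config.pair_rho < 0)
    planted_pairs = [(mirnas[i], genes[j], config.pair_rho) for i, j in pair_idx]

    # one latent factor per pair, shared across all matrices (same animals)
    rng_latent = _sub_rng(seed, "latent")
    z = rng_latent.normal(size=(max(config.n_pairs, 1), len(samples)))
    z_of_sample = {s: k for k, s in enumerate(samples)}

    gene_sign = -1.0 if config.pair_rho < 0 else 1.0
    mirna_load = np.zeros((config.n_mirna, len(samples)))
    gene_load_full = np.zeros((config.n_mrna, len(samples)))
    for p, (i, j) in enumerate(pair_idx):
        mirna_load[i] += lam * z[p]
        gene_load_full[j] += gene_sign * lam * z[p]

    true_lib: dict[str, dict[str, float]] = {}

    def _make_matrix(tag: str, feature_ids: list[str], cols: list[str],
                     loads: np.ndarray, de_effect: bool) -> pd.DataFrame:
        rng_lib = _sub_rng(seed, f"lib:{tag}")
        lib = np.exp(rng_lib.normal(np.log(1e6), config.libsize_log_sd, size=len(cols)))
        true_lib[tag] = {s: float(v) for s, v in zip(cols, lib)}
        rng_base = _sub_rng(seed, f"base:{tag}")
        base = config.baseline_mean * np.exp(
            rng_base.normal(0.0, config.feature_log_sd, size=len(feature_ids))
            - 0.5 * config.feature_log_sd**2)
        col_pos = [z_of_sample[s] for s in cols]
        log2mu = np.log2(base)[:, None] + loads[:, col_pos]
        if de_effect and config.n_de:
            in_first = np.array([group_of[s] == first_group for s in cols])
            for i, s in zip(de_idx, de_signs):
                log2mu[i, in_first] += s * config.de_log2fc
        mu = 2.0 ** log2mu * (lib / 1e6)[None, :]
        rng_counts = _sub_rng(seed, f"counts:{tag}")
        counts = rng_counts.poisson(rng_counts.gamma(1.0 / phi, phi * mu))
        return pd.DataFrame(counts.astype(np.int64),
                            index=pd.Index(feature_ids, name="feature_id"), columns=cols)

    mirna_counts = _make_matrix(MIRNA_TISSUE, mirnas, samples, mirna_load, de_effect=True)
    mrna_counts: dict[str, pd.DataFrame] = {}
    for tissue in config.mrna_tissues:
        cols = samples
        if tissue == config.conceptus_tissue:
            cols = [s for s in samples if group_of[s] != config.no_conceptus_group]
        mrna_counts[tissue] = _make_matrix(tissue, genes, cols, gene_load_full, de_effect=False)

    sheet_rows = [(s, group_of[s], MIRNA_TISSUE) for s in samples]
    for tissue, cm in mrna_counts.items():
        sheet_rows += [(s, group_of[s], tissue) for s in cm.columns]
    sample_sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "group", "tissue"])

    # target table: covered fraction of planted negative pairs, plus decoys
    rng_t = _sub_rng(seed, "targets")
    records: list[tuple[str, str, str]] = []
    planted_set = {(m, g) for m, g, _ in planted_pairs}
    if config.pair_rho < 0:
        for m, g, _ in planted_pairs:
            if rng_t.random() < config.target_db_coverage:
                arm = _mature_names(m)[int(rng_t.integers(2))]
                records.append((arm, g, REGIONS[int(rng_t.integers(len(REGIONS)))]))
    n_decoys = 0
    while n_decoys < config.decoy_targets:
        m = mirnas[int(rng_t.integers(config.n_mirna))]
        g = genes[int(rng_t.integers(config.n_mrna))]
        if (m, g) in planted_set:
            continue
        arm = _mature_names(m)[int(rng_t.integers(2))]
        records.append((arm, g, REGIONS[int(rng_t.integers(len(REGIONS)))]))
        n_decoys += 1
    tdb = TargetDB(records=pd.DataFrame(records, columns=["mirna", "gene", "region"])
                   .drop_duplicates().reset_index(drop=True))
    nmap = NameMap(mapping={m.casefold(): set(_mature_names(m)) for m in mirnas})

    rng_ann = _sub_rng(seed, "annotation")
    ann_rows = []
    for g in genes:
        k = int(rng_ann.integers(1, 4))
        for c in rng_ann.choice(config.n_categories, size=min(k, config.n_categories),
                                replace=False):
            ann_rows.append((g, f"CAT{c + 1:03d}", f"category {c + 1}"))
    annotation = pd.DataFrame(ann_rows, columns=["gene", "category_id", "category_name"])

    truth = GroundTruth(
        de_features=de_features,
        planted_pairs=planted_pairs,
        true_libsize_factors=true_lib,
        latent_loading=float(lam),
    )
    return Dataset(mirna_counts, mrna_counts, sample_sheet, tdb, nmap, annotation, truth)


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write all dataset components as plain-text files; round-trips losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["mirna_counts"] = io.write_counts(dataset.mirna_counts, directory / "mirna_counts.tsv")
    for tissue, cm in dataset.mrna_counts.items():
        paths[f"mrna_counts_{tissue}"] = io.write_counts(
            cm, directory / f"mrna_counts_{tissue}.tsv")
    paths["sample_sheet"] = io.write_sample_sheet(dataset.sample_sheet, directory / "samples.csv")
    dataset.target_db.records.to_csv(directory / "targets.tsv", sep="\t", index=False)
    paths["target_db"] = directory / "targets.tsv"
    paths["name_map"] = dataset.name_map.to_tsv(directory / "name_map.tsv")
    dataset.annotation.to_csv(directory / "annotation.tsv", sep="\t", index=False)
    paths["annotation"] = directory / "annotation.tsv"
    paths["truth"] = io.write_json(dataset.truth.to_json(), directory / "truth.json")
    return paths


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain mapping (e.g. a YAML section)."""
    d = dict(d)
    if "mrna_tissues" in d:
        d["mrna_tissues"] = tuple(d["mrna_tissues"])
    cfg = SyntheticConfig(**d)
    cfg.validate()
    return cfg
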