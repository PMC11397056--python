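"""End-to-end orchestration: simulate -> preprocess -> DE -> co-expression ->
target integration -> enrichment, driven by a YAML config.

Every stage is also independently invocable (see :mod:`mircoex.cli`); stages
communicate through files inside the run directory, so a stage can be re-run
on its own as long as its inputs exist.  All randomness flows from one
master seed through stable named sub-streams.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mircoex import coexpression, da, enrichment, io, preprocessing, synthetic, targets

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_total": 50,
    "alpha": 0.05,
    "efdr": 4e-5,
    "fwer": 0.01,
    "n_rand": 10_000,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    th = dict(DEFAULT_THRESHOLDS)
    th.update(cfg.get("thresholds", {}))
    cfg["thresholds"] = th
    cfg.setdefault("contrasts", [])
    cfg.setdefault("strata", [])
    return cfg


def _stage_seed(seed: int, tag: str) -> int:
    return int(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]).generate_state(1)[0])


def _data_paths(cfg: dict, outdir: Path) -> dict:
    """Resolve input paths from the config, preferring simulated data if present."""
    data = dict(cfg.get("data", {}))
    simdir = outdir / "data"
    if cfg.get("simulate") is not None and simdir.exists():
        data.setdefault("mirna_counts", simdir / "mirna_counts.tsv")
        data.setdefault("sample_sheet", simdir / "samples.csv")
        data.setdefault("target_db", simdir / "targets.tsv")
        data.setdefault("name_map", simdir / "name_map.tsv")
        data.setdefault("annotation", simdir / "annotation.tsv")
        mrna = dict(data.get("mrna_counts", {}))
        for p in sorted(simdir.glob("mrna_counts_*.tsv")):
            tissue = p.stem.removeprefix("mrna_counts_")
            mrna.setdefault(tissue, p)
        data["mrna_counts"] = mrna
    if "mirna_counts" not in data or "sample_sheet" not in data:
        raise ConfigError("config must provide data.mirna_counts and data.sample_sheet "
                          "(or a simulate section, after running the simulate stage)")
    data.setdefault("mrna_counts", {})
    return data


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> dict:
    sim = cfg.get("simulate")
    if sim is None:
        return {"simulated": False}
    sim = dict(sim)
    sim["seed"] = _stage_seed(seed, "simulate")
    ds = synthetic.generate_dataset(synthetic.config_from_dict(sim))
    synthetic.write_dataset(ds, outdir / "data")
    return {
        "simulated": True,
        "n_mirna": int(ds.mirna_counts.shape[0]),
        "mrna_tissues": sorted(ds.mrna_counts),
        "n_planted_de": len({f for f, _, _ in ds.truth.de_features}),
        "n_planted_pairs": len(ds.truth.planted_pairs),
    }


def _validate_design(cfg: dict, sheet: pd.DataFrame) -> None:
    groups = set(sheet["group"])
    tissues = set(sheet["tissue"])
    for a, b in cfg["contrasts"]:
        for g in (a, b):
            if g not in groups:
                raise ConfigError(f"contrast group {g!r} not in sample sheet groups {sorted(groups)}")
    for g, t in cfg["strata"]:
        if g not in groups:
            raise ConfigError(f"stratum group {g!r} not in sample sheet")
        if t not in tissues:
            raise ConfigError(f"stratum tissue {t!r} not in sample sheet")


def stage_preprocess(cfg: dict, outdir: Path) -> dict:
    data = _data_paths(cfg, outdir)
    th = cfg["thresholds"]
    sheet = io.read_sample_sheet(data["sample_sheet"])
    _validate_design(cfg, sheet)
    pre = outdir / "preprocess"
    pre.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_features_after_filter": {}}

    matrices = {"mirna": Path(data["mirna_counts"])}
    for tissue, p in data["mrna_counts"].items():
        matrices[f"mrna_{tissue}"] = Path(p)
    for name, path in matrices.items():
        cm = io.read_counts(path)
        filt = preprocessing.filter_low_counts(cm, min_total=th["min_total"])
        io.write_counts(filt, pre / f"{name}_filtered.tsv")
        if filt.shape[0] and filt.shape[1] >= 2:
            nf = preprocessing.tmm_factors(filt)
            em = preprocessing.asinh_transform(preprocessing.cpm(filt, nf))
            io.write_expression(em, pre / f"{name}_asinh_cpm.tsv")
        summary["n_features_after_filter"][name] = int(filt.shape[0])
    if summary["n_features_after_filter"].get("mirna"):
        filt = io.read_counts(pre / "mirna_filtered.tsv")
        summary["top40_share"] = round(
            preprocessing.top_k_share(filt, min(40, filt.shape[0])), 6)
    return summary


def stage_de(cfg: dict, outdir: Path) -> dict:
    data = _data_paths(cfg, outdir)
    th = cfg["thresholds"]
    sheet = io.read_sample_sheet(data["sample_sheet"])
    pre = outdir / "preprocess"
    dedir = outdir / "de"
    dedir.mkdir(parents=True, exist_ok=True)
    cm = io.read_counts(pre / "mirna_filtered.tsv")
    nf = preprocessing.tmm_factors(cm)
    out: dict = {"de_counts": {}}
    for a, b in cfg["contrasts"]:
        res = da.run_contrast(cm, sheet, a, b, nf, alpha=th["alpha"])
        res.to_csv(dedir / f"de_mirna_{a}_vs_{b}.tsv", sep="\t", float_format="%.6g")
        out["de_counts"][f"{a}:{b}"] = int(res["consensus_de"].sum())
    return out


def _stratum_samples(sheet: pd.DataFrame, group: str, tissue: str) -> list[str]:
    sub = sheet[(sheet["group"] == group) & (sheet["tissue"] == tissue)]
    return sub["sample_id"].tolist()


def _stratum_expression(counts: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-stratum TMM-CPM + asinh, as normalization is stratum-local."""
    sub = counts[samples]
    nf = preprocessing.tmm_factors(sub)
    return preprocessing.asinh_transform(preprocessing.cpm(sub, nf))


def stage_coexpress(cfg: dict, outdir: Path, seed: int) -> dict:
    data = _data_paths(cfg, outdir)
    th = cfg["thresholds"]
    sheet = io.read_sample_sheet(data["sample_sheet"])
    pre = outdir / "preprocess"
    codir = outdir / "coexpr"
    codir.mkdir(parents=True, exist_ok=True)
    mirna_counts = io.read_counts(pre / "mirna_filtered.tsv")
    out: dict = {"significant_pairs": {}}
    for group, tissue in cfg["strata"]:
        mirna_samples = set(_stratum_samples(sheet, group, synthetic.MIRNA_TISSUE))
        tissue_samples = _stratum_samples(sheet, group, tissue)
        samples = [s for s in tissue_samples if s in mirna_samples]
        key = f"{group}_{tissue}"
        if len(samples) < 3:
            logger.warning("stratum %s has %d matched samples; skipped", key, len(samples))
            out["significant_pairs"][key] = None
            continue
        mrna_counts = io.read_counts(pre / f"mrna_{tissue}_filtered.tsv")
        mirna_em = _stratum_expression(mirna_counts, samples)
        mrna_em = _stratum_expression(mrna_counts, samples)
        table = coexpression.all_pairs(mirna_em, mrna_em)
        table = coexpression.empirical_fdr(
            table, mirna_em, mrna_em, n_rand=th["n_rand"],
            seed=_stage_seed(seed, f"coexpr:{key}"))
        table = coexpression.infer_significant(table, efdr_threshold=th["efdr"])
        table.to_csv(codir / f"coexpr_{key}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        out["significant_pairs"][key] = int(table["significant"].sum())
    return out


def stage_integrate(cfg: dict, outdir: Path) -> dict:
    data = _data_paths(cfg, outdir)
    th = cfg["thresholds"]
    sheet = io.read_sample_sheet(data["sample_sheet"])
    intdir = outdir / "integrate"
    intdir.mkdir(parents=True, exist_ok=True)
    db = targets.load_target_db(data["target_db"])
    nmap = targets.NameMap.from_tsv(data["name_map"])
    out: dict = {"supported_pairs": {}, "de_target_overlap": {}}

    for group, tissue in cfg["strata"]:
        key = f"{group}_{tissue}"
        path = outdir / "coexpr" / f"coexpr_{key}.tsv"
        if not path.exists():
            continue
        table = pd.read_csv(path, sep="\t")
        sup = targets.supported_pairs(table, db, nmap)
        sup.to_csv(intdir / f"supported_pairs_{key}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        out["supported_pairs"][key] = int(len(sup))

    overlap_contrast = cfg.get("de_overlap_contrast")
    if overlap_contrast:
        a, b = overlap_contrast
        de_path = outdir / "de" / f"de_mirna_{a}_vs_{b}.tsv"
        de = pd.read_csv(de_path, sep="\t", index_col=0)
        up = set(de.index[(de["consensus_de"]) & (de["log2fc"] > 0)])
        pre = outdir / "preprocess"
        for tissue in sorted(data["mrna_counts"]):
            cm = io.read_counts(pre / f"mrna_{tissue}_filtered.tsv")
            tissue_sheet = sheet[sheet["tissue"] == tissue]
            groups_present = set(tissue_sheet["group"])
            if not {a, b} <= groups_present or cm.shape[0] == 0:
                continue
            nf = preprocessing.tmm_factors(cm)
            res = da.run_contrast(cm, tissue_sheet, a, b, nf, alpha=th["alpha"])
            down = set(res.index[(res["consensus_de"]) & (res["log2fc"] < 0)])
            tab = targets.de_target_overlap(up, down, db, nmap)
            tab.to_csv(intdir / f"de_target_overlap_{tissue}.tsv", sep="\t", index=False)
            out["de_target_overlap"][tissue] = int(len(tab))
    return out


def stage_enrich(cfg: dict, outdir: Path) -> dict:
    data = _data_paths(cfg, outdir)
    th = cfg["thresholds"]
    endir = outdir / "enrich"
    endir.mkdir(parents=True, exist_ok=True)
    if "annotation" not in data:
        return {"enrichment": {}}
    ann = enrichment.read_annotation(data["annotation"])
    pre = outdir / "preprocess"
    out: dict = {"enrichment": {}}
    for tissue in sorted(data["mrna_counts"]):
        overlap_path = outdir / "integrate" / f"de_target_overlap_{tissue}.tsv"
        if not overlap_path.exists():
            continue
        overlap = pd.read_csv(overlap_path, sep="\t")
        interest = set(overlap["gene"]) if len(overlap) else set()
        background = set(io.read_counts(pre / f"mrna_{tissue}_filtered.tsv").index)
        res = enrichment.hypergeom_enrich(interest & background, background, ann,
                                          fwer_threshold=th["fwer"])
        res.to_csv(endir / f"enrichment_{tissue}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        out["enrichment"][tissue] = int(res["significant"].sum()) if len(res) else 0
    return out


def run_all(config_path: str | Path, outdir: str | Path, seed: int,
            n_rand: int | None = None) -> dict:
    """Run every stage in order and write ``summary.json``.

    Identical config + seed produces a byte-identical summary.
    """
    cfg = load_config(config_path)
    if n_rand is not None:
        cfg["thresholds"]["n_rand"] = int(n_rand)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "seed": int(seed),
        "thresholds": cfg["thresholds"],
        "contrasts": [list(c) for c in cfg["contrasts"]],
        "strata": [list(s) for s in cfg["strata"]],
    }
    stages = [
        ("simulate", lambda: stage_simulate(cfg, outdir, seed)),
        ("preprocess", lambda: stage_preprocess(cfg, outdir)),
        ("de", lambda: stage_de(cfg, outdir)),
        ("coexpress", lambda: stage_coexpress(cfg, outdir, seed)),
        ("integrate", lambda: stage_integrate(cfg, outdir)),
        ("enrich", lambda: stage_enrich(cfg, outdir)),
    ]
    for name, fn in stages:
        try:
            summary[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    io.write_json(summary, outdir / "summary.json")
    return summary
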