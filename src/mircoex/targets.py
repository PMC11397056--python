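"""Predicted miRNA-target table integration.

Target databases list (mature miRNA, gene, region) records; co-expression
and DE results use precursor names, so a precursor -> mature name map joins
the two vocabularies.  Matching is case-insensitive throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("3UTR", "5UTR", "CDS")


@dataclass
class TargetDB:
    """Deduplicated (mature miRNA, gene, region) records with lookup indexes."""

    records: pd.DataFrame  # columns: mirna, gene, region
    _by_mirna: dict[str, set[str]] = field(init=False, repr=False)
    _by_gene: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_mirna = {}
        self._by_gene = {}
        for mirna, gene in zip(self.records["mirna"], self.records["gene"]):
            self._by_mirna.setdefault(mirna.casefold(), set()).add(gene)
            self._by_gene.setdefault(gene.casefold(), set()).add(mirna)

    def __len__(self) -> int:
        return len(self.records)

    def genes_of(self, mature: str) -> set[str]:
        return self._by_mirna.get(mature.casefold(), set())

    def targets_gene(self, mature: str, gene: str) -> bool:
        return gene.casefold() in {g.casefold() for g in self.genes_of(mature)}


def load_target_db(path: str | Path) -> TargetDB:
    """Load a target TSV with columns mirna, gene, region.

    Region labels are normalized to upper case and must be one of
    3UTR/5UTR/CDS; exact duplicate records are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna", "gene", "region"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: target table missing columns {sorted(missing)}")
    df = df[["mirna", "gene", "region"]].copy()
    df["region"] = df["region"].str.upper().str.replace("'", "", regex=False)
    bad = set(df["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"{path}: unknown region label(s) {sorted(bad)}; expected {REGIONS}")
    df = df.drop_duplicates().reset_index(drop=True)
    return TargetDB(records=df)


def write_target_db(db: TargetDB, path: str | Path) -> Path:
    db.records.to_csv(path, sep="\t", index=False)
    return Path(path)


@dataclass
class NameMap:
    """Precursor -> set of mature miRNA names (e.g. -5p/-3p arms)."""

    mapping: dict[str, set[str]]

    def matures(self, precursor: str) -> set[str] | None:
        return self.mapping.get(precursor.casefold())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NameMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"precursor", "mature"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: name map missing columns {sorted(missing)}")
        mapping: dict[str, set[str]] = {}
        seen: dict[str, str] = {}
        for prec, mat in zip(df["precursor"], df["mature"]):
            key = mat.casefold()
            if key in seen and seen[key] != prec.casefold():
                raise ValueError(f"{path}: mature {mat!r} maps to multiple precursors")
            seen[key] = prec.casefold()
            mapping.setdefault(prec.casefold(), set()).add(mat)
        return cls(mapping=mapping)

    def to_tsv(self, path: str | Path) -> Path:
        rows = [(p, m) for p, ms in sorted(self.mapping.items()) for m in sorted(ms)]
        pd.DataFrame(rows, columns=["precursor", "mature"]).to_csv(path, sep="\t", index=False)
        return Path(path)


_MIR_GENE = re.compile(r"^MIR(\d+)([A-Z]*)(?:-(\d+))?$")


def heuristic_matures(precursor: str) -> set[str]:
    """Guess mature arm names for a precursor when no explicit map entry exists.

    "bta-mir-17" -> {bta-miR-17-5p, bta-miR-17-3p}; gene-style symbols like
    "MIR18A" are normalized to the miR-18a form first.  Always logged by
    callers because this mapping is a fallback, not ground truth.
    """
    name = precursor
    m = _MIR_GENE.match(precursor.upper())
    if m:
        num, letter, _copy = m.groups()
        name = f"miR-{num}{letter.lower()}"
    else:
        name = re.sub(r"-mir-", "-miR-", precursor, flags=re.IGNORECASE)
        name = re.sub(r"-(\d+)$", "", name) if re.search(r"-\d+-\d+$", name) else name
    return {f"{name}-5p", f"{name}-3p"}


def supported_pairs(coexpr: pd.DataFrame, db: TargetDB, nmap: NameMap,
                    require_negative: bool = True) -> pd.DataFrame:
    """Significant co-expression pairs backed by a predicted-target record.

    Keeps rows that are significant, (optionally) have r < 0, and whose
    precursor has at least one mature form targeting the row's gene in the
    database.  Precursors absent from the name map are skipped with a
    warning.
    """
    if "significant" not in coexpr.columns:
        raise ValueError("co-expression table lacks significance flags")
    keep_rows = []
    support = []
    for idx, row in coexpr.iterrows():
        if not row["significant"]:
            continue
        if require_negative and not row["r"] < 0:
            continue
        matures = nmap.matures(row["mirna"])
        if matures is None:
            logger.warning("precursor %s absent from name map; row skipped", row["mirna"])
            continue
        hit = sorted(m for m in matures if db.targets_gene(m, row["gene"]))
        if hit:
            keep_rows.append(idx)
            support.append(";".join(hit))
    out = coexpr.loc[keep_rows].copy()
    out["supporting_matures"] = support
    return out


def de_target_overlap(de_up_mirnas: set[str], down_genes: set[str], db: TargetDB,
                      nmap: NameMap) -> pd.DataFrame:
    """Down-regulated genes targeted by mature forms of up-regulated miRNAs.

    Returns one row per gene with the sorted list of supporting mature
    miRNAs; genes are sorted for deterministic output.
    """
    down_lookup = {g.casefold(): g for g in down_genes}
    hits: dict[str, set[str]] = {}
    for prec in sorted(de_up_mirnas):
        matures = nmap.matures(prec)
        if matures is None:
            logger.warning("precursor %s absent from name map; skipped in overlap", prec)
            continue
        for mat in sorted(matures):
            for gene in db.genes_of(mat):
                key = gene.casefold()
                if key in down_lookup:
                    hits.setdefault(down_lookup[key], set()).add(mat)
    rows = [(g, ";".join(sorted(ms))) for g, ms in sorted(hits.items())]
    return pd.DataFrame(rows, columns=["gene", "supporting_matures"])
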