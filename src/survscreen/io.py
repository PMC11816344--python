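"""Readers/writers for expression matrices, clinical tables and GMT gene sets.

Expression values are assumed to arrive already normalized on a log scale
(the pipeline never re-normalizes).  Missing clinical categories are kept as
an explicit ``"Unknown"`` level rather than dropping samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger("survscreen")

__all__ = [
    "ExpressionMatrix",
    "ClinicalRecord",
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "clinical_frame",
    "read_gmt",
    "write_gmt",
]

CATEGORICAL_FIELDS = ("sex", "lauren", "t_stage", "nodal", "site", "subtype")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous (log-scale) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def shape(self):
        return self.values.shape

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index[gene_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalRecord:
    """Per-sample survival endpoints and covariates.

    ``dfs_time``/``dfs_event`` may be ``None`` when the relapse endpoint was
    not recorded; categorical covariates may be ``None`` (treated downstream
    as "Unknown").
    """

    sample_id: str
    os_time: float
    os_event: int
    dfs_time: float | None = None
    dfs_event: int | None = None
    age: float | None = None
    sex: str | None = None
    lauren: str | None = None
    t_stage: str | None = None
    nodal: str | None = None
    site: str | None = None
    subtype: str | None = None

    def __post_init__(self):
        if self.os_time < 0:
            raise ValueError(f"{self.sample_id}: negative os_time")
        if self.os_event not in (0, 1):
            raise ValueError(f"{self.sample_id}: os_event must be 0/1")
        if self.dfs_time is not None and self.dfs_time < 0:
            raise ValueError(f"{self.sample_id}: negative dfs_time")
        if self.dfs_event is not None and self.dfs_event not in (0, 1):
            raise ValueError(f"{self.sample_id}: dfs_event must be 0/1")


@dataclass
class GeneSet:
    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self):
        return len(self.members)


def _sep_for(path, dialect=None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, dialect=None) -> ExpressionMatrix:
    """Read a genes-in-rows expression table (first column = gene ids).

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean (logged); any non-numeric cell is a parse error naming its
    location.
    """
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = {h for h in header if header.count(h) > 1}
    if dups:
        raise ValueError(f"duplicate sample id {sorted(dups)[0]!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(vals.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if vals.index.duplicated().any():
        means = vals.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for pos, gid in enumerate(vals.index):
            if gid not in best or means[pos] > means[best[gid]]:
                best[gid] = pos
        keep_pos = sorted(best.values())
        logger.warning(
            "collapsed %d duplicate gene rows (kept highest-mean row)", len(vals) - len(keep_pos)
        )
        vals = vals.iloc[keep_pos]
    return ExpressionMatrix(list(vals.index), list(vals.columns), vals.to_numpy())


def write_expression(matrix: ExpressionMatrix, path, dialect=None) -> None:
    matrix.to_frame().to_csv(path, sep=_sep_for(path, dialect), index_label="gene")


DEFAULT_SCHEMA = {
    "sample_id": "sample_id", "os_time": "os_time", "os_event": "os_event",
    "dfs_time": "dfs_time", "dfs_event": "dfs_event", "age": "age",
    "sex": "sex", "lauren": "lauren", "t_stage": "t_stage",
    "nodal": "nodal", "site": "site", "subtype": "subtype",
}


def read_clinical(path, schema_map: dict | None = None, dialect=None) -> list[ClinicalRecord]:
    """Read a per-sample clinical table; ``schema_map`` maps record fields to columns."""
    schema = dict(DEFAULT_SCHEMA)
    if schema_map:
        schema.update(schema_map)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    records = []
    for _, row in df.iterrows():
        kw = {}
        for f in fields(ClinicalRecord):
            col = schema.get(f.name)
            if col is None or col not in df.columns:
                continue
            v = row[col]
            if pd.isna(v):
                continue
            if f.name in ("os_time", "dfs_time", "age"):
                v = float(v)
            elif f.name in ("os_event", "dfs_event"):
                fv = float(v)
                if fv not in (0.0, 1.0):
                    raise ValueError(f"{row[schema['sample_id']]}: event value {v!r} is not 0/1")
                v = int(fv)
            else:
                v = str(v)
            kw[f.name] = v
        records.append(ClinicalRecord(**kw))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in clinical table")
    return records


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by sample id (None preserved as NaN)."""
    return pd.DataFrame([vars(r) for r in records]).set_index("sample_id")


def write_clinical(records: list[ClinicalRecord], path, dialect=None) -> None:
    clinical_frame(records).to_csv(path, sep=_sep_for(path, dialect), index_label="sample_id")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets, seen = [], set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {ln}: fewer than 3 fields")
            name, members = parts[0], [g for g in parts[2:] if g]
            if name in seen:
                raise ValueError(f"gene set {name!r} listed twice")
            if not members:
                raise ValueError(f"GMT line {ln}: set {name!r} has no members")
            seen.add(name)
            sets.append(GeneSet(name=name, members=frozenset(members)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.members)]) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
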