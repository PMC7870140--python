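"""Clone-table file formats, configuration, and result serialization.

The canonical on-disk format is a tab-separated clone table with a header
row.  Column names are resolved through a dialect table so that generic
exports and immunoSEQ-style exports are read through the same path; the
zero-insertion status of a clone is derived as (VD insertions + DJ
insertions == 0) whenever both junction columns are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import CloneSizeSample, CohortSample, RepertoireSnapshot

__all__ = [
    "CloneTableDialect",
    "GENERIC_DIALECT",
    "IMMUNOSEQ_DIALECT",
    "read_clone_table",
    "write_clone_table",
    "write_snapshot",
    "write_cohort",
    "read_cohort_manifest",
    "read_memory_fraction_table",
    "read_trajectories",
    "load_config",
    "dump_config",
]


class CloneTableError(ValueError):
    """Malformed clone table."""


@dataclass(frozen=True)
class CloneTableDialect:
    """Column mapping for a clone-table flavour.

    ``columns`` maps canonical names (clone_id, count, vd_insertions,
    dj_insertions, productive) to the file's column names; only ``count``
    is mandatory.
    """

    name: str
    columns: dict = field(default_factory=dict)
    delimiter: str = "\t"

    def resolve(self, header: list[str]) -> dict:
        present = {}
        for canonical, alias in self.columns.items():
            if alias in header:
                present[canonical] = alias
        return present


GENERIC_DIALECT = CloneTableDialect(
    name="generic",
    columns={
        "clone_id": "clone_id",
        "count": "count",
        "vd_insertions": "vd_insertions",
        "dj_insertions": "dj_insertions",
        "productive": "productive",
        "t_recruit": "t_recruit",
        "zero_insertions": "zero_insertions",
    },
)

IMMUNOSEQ_DIALECT = CloneTableDialect(
    name="immunoseq",
    columns={
        "clone_id": "nucleotide",
        "count": "count (templates/reads)",
        "vd_insertions": "n1Insertion",
        "dj_insertions": "n2Insertion",
        "productive": "sequenceStatus",
    },
)

DIALECTS = (GENERIC_DIALECT, IMMUNOSEQ_DIALECT)


def _detect_dialect(header: list[str]) -> CloneTableDialect:
    for dialect in DIALECTS:
        if dialect.columns["count"] in header:
            return dialect
    raise CloneTableError(
        f"no known dialect provides a count column for header {header}"
    )


def read_clone_table(
    path,
    dialect: CloneTableDialect | None = None,
):
    """Read a delimited clone table into a :class:`CloneSizeSample`.

    Returns ``(sample, flags)`` where ``flags`` is a boolean zero-insertion
    array (or None when the table carries no insertion information).  The
    dialect is auto-detected from the header when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise CloneTableError(f"{path} is empty")
    head = pd.read_csv(path, sep=None, engine="python", nrows=0)
    header = list(head.columns)
    if dialect is None:
        dialect = _detect_dialect(header)
    cols = dialect.resolve(header)
    if "count" not in cols:
        raise CloneTableError(
            f"count column {dialect.columns['count']!r} missing in {path}"
        )
    df = pd.read_csv(path, sep=dialect.delimiter)
    counts_raw = df[cols["count"]]
    counts = pd.to_numeric(counts_raw, errors="coerce")
    if counts.isna().any() or not np.allclose(counts, counts.round()):
        raise CloneTableError(f"non-integer counts in {path}")
    counts = counts.astype(np.int64)
    flags = None
    if "zero_insertions" in cols:
        flags = df[cols["zero_insertions"]].astype(bool).to_numpy()
    elif "vd_insertions" in cols and "dj_insertions" in cols:
        total_ins = df[cols["vd_insertions"]] + df[cols["dj_insertions"]]
        flags = (total_ins == 0).to_numpy()
    keep = counts.to_numpy() >= 1
    sample = CloneSizeSample(counts=counts.to_numpy()[keep])
    if flags is not None:
        flags = flags[keep]
    return sample, flags


def write_clone_table(path, df: pd.DataFrame) -> None:
    """Write a clone table in the generic tab-separated dialect."""
    df.to_csv(path, sep="\t", index=False)


def write_snapshot(path, snapshot: RepertoireSnapshot) -> None:
    write_clone_table(path, snapshot.to_frame())


def write_cohort(out_dir, samples: list[CohortSample], seed=None) -> Path:
    """Write per-individual clone tables plus a manifest TSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for s in samples:
        fname = f"individual_{s.individual_id:04d}.tsv"
        df = pd.DataFrame(
            {
                "clone_id": np.arange(s.n_clones),
                "count": s.counts,
                "zero_insertions": s.zero_insertions.astype(int),
            }
        )
        write_clone_table(out_dir / fname, df)
        records.append(
            {"individual_id": s.individual_id, "age": s.age, "file": fname}
        )
    manifest = pd.DataFrame(records)
    if seed is not None:
        manifest["seed"] = seed
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort_manifest(manifest_path) -> list[CohortSample]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    samples = []
    for _, row in manifest.iterrows():
        sample, flags = read_clone_table(manifest_path.parent / row["file"])
        if flags is None:
            flags = np.zeros(sample.n_clones, dtype=bool)
        samples.append(
            CohortSample(
                individual_id=int(row["individual_id"]),
                age=float(row["age"]),
                counts=sample.counts,
                zero_insertions=flags,
            )
        )
    return samples


def read_memory_fraction_table(path):
    """Age -> memory-cell-fraction interpolator from a two-column table.

    Piecewise-linear between tabulated ages, constant beyond the range
    ends.  Ages must be strictly increasing and fractions in (0, 1].
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise CloneTableError("memory fraction table needs two columns (age, fraction)")
    ages = df.iloc[:, 0].to_numpy(dtype=float)
    fracs = df.iloc[:, 1].to_numpy(dtype=float)
    if len(ages) > 1 and np.any(np.diff(ages) <= 0):
        raise CloneTableError("ages must be strictly increasing")
    if np.any((fracs <= 0) | (fracs > 1)):
        raise CloneTableError("fractions must lie in (0, 1]")

    def fn(age):
        return np.interp(age, ages, fracs)

    return fn


def read_trajectories(path) -> pd.DataFrame:
    """Long-format (clone_id, time, count) trajectory table."""
    df = pd.read_csv(path, sep="\t")
    missing = {"clone_id", "time", "count"} - set(df.columns)
    if missing:
        raise CloneTableError(f"trajectory table missing columns {sorted(missing)}")
    return df


def _normalize(obj):
    if isinstance(obj, dict):
        return {k: _normalize(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_normalize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path, schema: dict | None = None) -> dict:
    """Load a YAML config; with ``schema`` given (name -> required flag),
    unknown keys are rejected and required keys enforced."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    if schema is not None:
        unknown = set(cfg) - set(schema)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {k for k, required in schema.items() if required} - set(cfg)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
    return _normalize(cfg)


def dump_config(cfg: dict, path=None) -> str:
    """Serialize a config deterministically (sorted keys); round-trips with
    :func:`load_config` up to normalization."""
    text = yaml.safe_dump(_normalize(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
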