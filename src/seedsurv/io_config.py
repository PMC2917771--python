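"""Domain containers, file formats and run configuration.

Expression matrices travel as TSV (probes as rows, ``NA`` missing marker),
clinical tables as TSV with required ``sample``/``time``/``event`` columns,
and gene sets as standard GMT. All readers validate invariants and refuse to
silently coerce malformed input.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("seedsurv")

GENE_SYMBOL_COLUMN = "gene_symbol"
ER_LEVELS = {"positive", "negative"}
NODE_LEVELS = {"positive", "negative"}


def configure_logging(log_file: str | Path | None = None, level: int = logging.INFO) -> None:
    """Send run logs to stderr and optionally to *log_file*."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probes × samples expression values with probe→gene annotation.

    ``values[i, j]`` is the expression of probe ``probe_ids[i]`` in sample
    ``sample_ids[j]``; log2 intensity when ``is_log2`` is set, raw intensity
    otherwise. Missing values are NaN.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    gene_symbols: list[str] | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.gene_symbols is not None:
            self.gene_symbols = [str(g) for g in self.gene_symbols]
            if len(self.gene_symbols) != len(self.probe_ids):
                raise ValueError("gene_symbols length does not match probe_ids")
        if np.isinf(self.values).any():
            raise ValueError("expression values must be finite or NaN")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in matrix") from None

    def probes_for_gene(self, gene: str) -> list[int]:
        """Row indices of all probes annotated to *gene* (empty if none)."""
        if self.gene_symbols is None:
            return []
        return [i for i, g in enumerate(self.gene_symbols) if g == gene]

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def gene_values(self, gene: str) -> np.ndarray:
        """Per-sample expression of *gene*: its single probe, or the mean
        across probes when several target it."""
        rows = self.probes_for_gene(gene)
        if not rows:
            # fall back to probe-id lookup so callers may pass either
            return self.probe_values(gene)
        return self.values[rows].mean(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            sample_ids=list(sample_ids),
            gene_symbols=None if self.gene_symbols is None else list(self.gene_symbols),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def read_expression(path: str | Path, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Read a probes × samples expression TSV.

    First column is the probe id; an optional second column named
    ``gene_symbol`` carries per-probe symbols; remaining columns are samples.
    Missing values are encoded ``NA``. Probes missing in more than
    *max_missing_frac* of samples are dropped (logged).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: expected at least one sample column")
    has_symbols = len(header) > 2 and header[1] == GENE_SYMBOL_COLUMN
    sample_ids = header[2:] if has_symbols else header[1:]
    _check_unique(sample_ids, "sample id")

    df = pd.read_csv(path, sep="\t", dtype={header[0]: str}, na_values=["NA"],
                     keep_default_na=False, float_precision="round_trip")
    probe_ids = df.iloc[:, 0].astype(str).tolist()
    _check_unique(probe_ids, "probe id")
    gene_symbols = df[GENE_SYMBOL_COLUMN].astype(str).tolist() if has_symbols else None
    value_cols = df.columns[2:] if has_symbols else df.columns[1:]
    block = df[value_cols]
    non_numeric = block.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = block.notna() & non_numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {block.iat[r, c]!r} at probe "
            f"{probe_ids[r]!r}, sample {value_cols[c]!r}"
        )
    values = non_numeric.to_numpy(dtype=float)

    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("read_expression: %d missing values in %s", n_missing, path.name)
    frac_missing = np.isnan(values).mean(axis=1)
    keep = frac_missing <= max_missing_frac
    if not keep.all():
        logger.info(
            "read_expression: dropped %d probes with >%.0f%% missing samples",
            int((~keep).sum()), 100 * max_missing_frac,
        )
        values = values[keep]
        probe_ids = [p for p, k in zip(probe_ids, keep) if k]
        if gene_symbols is not None:
            gene_symbols = [g for g, k in zip(gene_symbols, keep) if k]
    m = ExpressionMatrix(values, probe_ids, sample_ids, gene_symbols)
    logger.info("read_expression: %d probes x %d samples from %s", m.n_probes, m.n_samples, path.name)
    return m


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV format read by :func:`read_expression` (lossless)."""
    df = pd.DataFrame(m.values, index=pd.Index(m.probe_ids, name="probe_id"), columns=m.sample_ids)
    if m.gene_symbols is not None:
        df.insert(0, GENE_SYMBOL_COLUMN, m.gene_symbols)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


@dataclass
class ClinicalCohort:
    """Per-sample covariates plus a right-censored time-to-event outcome.

    ``table`` holds one row per sample with at least ``sample``, ``time``
    (follow-up, months) and ``event`` (1 = relapse/event, 0 = censored).
    Recognised covariates: ``age`` (years), ``er_status``
    (positive/negative), ``grade`` (ordinal 1–3), ``tumour_size`` (cm),
    ``node_status`` (positive/negative). Unknown columns are preserved.
    """

    table: pd.DataFrame
    endpoint_label: str = "RFS"

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample", "time", "event"):
            if col not in t.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        t = t.copy()
        t["sample"] = t["sample"].astype(str)
        _check_unique(t["sample"].tolist(), "sample id")
        t["time"] = pd.to_numeric(t["time"])
        t["event"] = pd.to_numeric(t["event"])
        neg = t.loc[t["time"] < 0, "sample"]
        if len(neg):
            raise ValueError(f"negative follow-up time for sample {neg.iloc[0]!r}")
        bad = t.loc[~t["event"].isin([0, 1]), "sample"]
        if len(bad):
            raise ValueError(f"event indicator outside {{0,1}} for sample {bad.iloc[0]!r}")
        t["event"] = t["event"].astype(int)
        for col, levels in (("er_status", ER_LEVELS), ("node_status", NODE_LEVELS)):
            if col in t.columns:
                vals = set(t[col].dropna().unique())
                if not vals <= levels:
                    raise ValueError(f"{col} has levels {vals - levels}, expected {levels}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClinicalCohort":
        """Reorder/subset rows to match *sample_ids* (e.g. matrix columns)."""
        t = self.table.set_index("sample").loc[list(sample_ids)].reset_index()
        return ClinicalCohort(t, self.endpoint_label)


def read_clinical(path: str | Path, endpoint_label: str = "RFS") -> ClinicalCohort:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"sample": str}, float_precision="round_trip")
    cohort = ClinicalCohort(df, endpoint_label)
    logger.info("read_clinical: %d samples, %d events from %s",
                len(cohort), int(cohort.event.sum()), Path(path).name)
    return cohort


def write_clinical(cohort: ClinicalCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``name<TAB>description<TAB>member...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, expected >=3")
            name, _desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            deduped = list(dict.fromkeys(m for m in members if m))
            if len(deduped) < len([m for m in members if m]):
                logger.warning("read_gmt: set %r contained duplicate members, deduplicated", name)
            sets[name] = deduped
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored, order preserved."""
    with open(path) as fh:
        return list(dict.fromkeys(line.strip() for line in fh if line.strip()))


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


@dataclass
class RunConfig:
    """Knobs shared across the stochastic pipeline stages.

    ``rng_seed`` must be given explicitly — no silent default, so every run
    is reproducible. ``bootstrap_reps`` (B) and ``null_sims`` (R) size the
    bootstrap and the random-seed-pair null; ``support_threshold`` is the
    minimum fraction of replicates in which a transcript must be significant
    with consistent sign; ``p_exit`` is the backward-selection exit p-value.
    """

    rng_seed: int
    bootstrap_reps: int = 1000
    alpha: float = 0.05
    support_threshold: float = 0.95
    null_sims: int = 200
    p_exit: float = 0.05
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValueError("rng_seed must be set explicitly")
        self.rng_seed = int(self.rng_seed)
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.null_sims < 1:
            raise ValueError("null_sims must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.support_threshold <= 1:
            raise ValueError("support_threshold must be in [0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {k: raw.pop(k) for k in
                 ("rng_seed", "bootstrap_reps", "alpha", "support_threshold", "null_sims", "p_exit")
                 if k in raw}
        known.update(overrides)
        if "rng_seed" not in known:
            raise ValueError(f"{path}: rng_seed is required in the config")
        return cls(extras=raw, **known)
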