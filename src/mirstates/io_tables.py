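"""Tabular input/output with strict validation.

All artifacts are tab-separated UTF-8 text with a '.' decimal separator.
Matrix files carry the literal header ``id`` in the first column, sample
identifiers in the remaining columns and one probe (or interaction) per row.
Readers reject malformed files instead of coercing; writers emit files their
paired reader accepts unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ID_COLUMN = "id"

#: Default (fold threshold f, neighborhood threshold n) pairs tried per probe.
#: Reproductions of a specific study should override these from its config.
DEFAULT_THRESHOLD_PAIRS: tuple[tuple[float, float], ...] = ((2.0, 1.5), (1.5, 1.25))


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


@dataclass
class ExpressionMatrix:
    """Log-normalized expression values, probes x samples.

    ``data`` is a DataFrame indexed by probe id with sample ids as columns.
    ``entity`` records whether the probes measure miRNAs or mRNAs.
    """

    data: pd.DataFrame
    entity: str = "mRNA"

    def __post_init__(self) -> None:
        if self.entity not in ("miRNA", "mRNA"):
            raise ValidationError(f"entity must be 'miRNA' or 'mRNA', got {self.entity!r}")
        validate_unique(self.data.index, "probe id")
        validate_unique(self.data.columns, "sample id")
        if self.data.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            bad = self.data.index[~np.isfinite(values).all(axis=1)]
            raise ValidationError(f"non-finite expression values in probes: {list(bad[:5])}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.entity)


@dataclass
class GroupAssignment:
    """Mapping sample id -> experimental group label."""

    labels: pd.Series  # index: sample id, values: group label

    def __post_init__(self) -> None:
        validate_unique(self.labels.index, "sample id")
        if self.labels.isna().any():
            raise ValidationError("every sample must carry a group label")
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.labels:
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])

    def subset(self, sample_ids: Sequence[str]) -> "GroupAssignment":
        return GroupAssignment(self.labels.loc[list(sample_ids)])


@dataclass
class AnalysisConfig:
    """All tunables of the interaction-state pipeline.

    ``threshold_pairs`` are (fold threshold f, neighborhood threshold n)
    candidates tried per probe; each pair requires f > n >= 1.
    ``probe_score_factor`` t scales the per-probe score cutoff t * n_samples.
    ``medium_ratio_max`` r_M and ``undefined_freq_max`` u are strict upper
    bounds on the fraction of medium states per row and of undefined
    interaction states per interaction, respectively.
    """

    threshold_pairs: tuple[tuple[float, float], ...] = DEFAULT_THRESHOLD_PAIRS
    probe_score_factor: float = 0.5
    medium_ratio_max: float = 0.5
    undefined_freq_max: float = 0.5
    correlation_cutoff: float = -0.4
    present_call_min_fraction: float = 0.20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.threshold_pairs = tuple((float(f), float(n)) for f, n in self.threshold_pairs)
        if not self.threshold_pairs:
            raise ValidationError("threshold_pairs must not be empty")
        for f, n in self.threshold_pairs:
            if not (f > n >= 1.0):
                raise ValidationError(f"threshold pair ({f}, {n}) violates f > n >= 1")
        for name in ("medium_ratio_max", "undefined_freq_max", "present_call_min_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")

    MANDATORY_KEYS = ("threshold_pairs", "probe_score_factor", "medium_ratio_max", "undefined_freq_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a key-value mapping")
        for key in cls.MANDATORY_KEYS:
            if key not in raw:
                raise ValidationError(f"config file {path} is missing mandatory key {key!r}")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "threshold_pairs": [list(p) for p in self.threshold_pairs],
            "probe_score_factor": self.probe_score_factor,
            "medium_ratio_max": self.medium_ratio_max,
            "undefined_freq_max": self.undefined_freq_max,
            "correlation_cutoff": self.correlation_cutoff,
            "present_call_min_fraction": self.present_call_min_fraction,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def validate_unique(index: Iterable, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique()
        raise ValidationError(f"duplicate {what}: {list(dup[:5])}")
    if (idx.astype(str) == "").any():
        raise ValidationError(f"empty {what} not allowed")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.columns[0] != ID_COLUMN:
        raise ValidationError(f"{path}: first column header must be {ID_COLUMN!r}, got {df.columns[0]!r}")
    return df


def read_expression(path: str | Path, entity: str) -> ExpressionMatrix:
    """Read a probes x samples expression TSV; row order is preserved."""
    df = _read_tsv(path)
    validate_unique(df[ID_COLUMN], "probe id")
    validate_unique(df.columns[1:], "sample id")
    data = df.set_index(ID_COLUMN)
    numeric = pd.DataFrame(index=data.index, columns=data.columns, dtype=float)
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & (data[col].astype(str) != "nan")
        if bad.any():
            row = data.index[bad][0]
            raise ValidationError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        numeric[col] = converted
    return ExpressionMatrix(numeric, entity)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = ID_COLUMN
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_probe_gene_map(path: str | Path) -> pd.Series:
    """Two-column TSV probe id -> gene id; every probe maps to one gene."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: probe->gene map must have exactly 2 columns")
    validate_unique(df.iloc[:, 0], "probe id")
    if (df.iloc[:, 1] == "").any():
        raise ValidationError(f"{path}: empty gene id")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="gene_id")


def write_probe_gene_map(mapping: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"probe_id": mapping.index, "gene_id": mapping.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_interaction_catalog(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of putative (mirna_id, gene_id) pairs; pairs unique."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: interaction catalog must have exactly 2 columns")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if any(m == "" or g == "" for m, g in pairs):
        raise ValidationError(f"{path}: empty identifier in interaction catalog")
    if len(set(pairs)) != len(pairs):
        raise ValidationError(f"{path}: duplicate interaction pairs")
    return pairs


def write_interaction_catalog(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["mirna_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> GroupAssignment:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: group file must have exactly 2 columns")
    validate_unique(df.iloc[:, 0], "sample id")
    return GroupAssignment(pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy()))


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": groups.labels.index, "group": groups.labels.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_present_calls(path: str | Path) -> pd.DataFrame:
    """Probes x samples matrix of {0,1} present-call indicators."""
    df = _read_tsv(path).set_index(ID_COLUMN)
    validate_unique(df.index, "probe id")
    try:
        calls = df.astype(int)
    except ValueError as exc:
        raise ValidationError(f"{path}: present calls must be 0/1 integers ({exc})") from exc
    if not calls.isin([0, 1]).all().all():
        raise ValidationError(f"{path}: present calls must be 0 or 1")
    return calls.astype(bool)


def apply_present_call_filter(
    matrix: ExpressionMatrix,
    calls: pd.DataFrame | None,
    min_fraction: float,
) -> ExpressionMatrix:
    """Keep probes flagged present in at least ``min_fraction`` of samples.

    ``calls`` must be aligned with the matrix (same probes and samples). When
    no present-call matrix is available the filter is a no-op with a warning,
    so pipelines on data lacking detection flags still run.
    """
    if calls is None:
        warnings.warn("no present-call matrix supplied; present-call filter skipped")
        return matrix
    if list(calls.index) != matrix.probe_ids or list(calls.columns) != matrix.sample_ids:
        raise ValidationError("present-call matrix is not aligned with the expression matrix")
    frac = calls.to_numpy().mean(axis=1)
    keep = frac >= min_fraction  # "at least" is inclusive
    logger.info("present-call filter kept %d/%d probes", int(keep.sum()), len(keep))
    return ExpressionMatrix(matrix.data.loc[keep], matrix.entity)


def read_state_matrix(path: str | Path, alphabet: frozenset[str]) -> pd.DataFrame:
    df = _read_tsv(path).set_index(ID_COLUMN)
    bad = set(np.unique(df.to_numpy())) - set(alphabet)
    if bad:
        raise ValidationError(f"{path}: states outside alphabet: {sorted(bad)}")
    return df


def write_state_matrix(states: pd.DataFrame, path: str | Path) -> None:
    out = states.copy()
    out.index.name = ID_COLUMN
    out.to_csv(path, sep="\t")
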