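"""Core in-memory containers for multi-modal patient cohorts.

A :class:`ModalityMatrix` is one samples x features numeric block (genotype,
expression, or brain ROI volumes) with an explicit missing-value mask; a
:class:`Cohort` is an aligned set of such blocks plus per-sample metadata
(conversion label, intracranial volume, optional subtype ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MODALITY_TAGS = ("snp", "expr", "roi")

#: Conversion-label coding: stable MCI (no AD within three years) = 0,
#: progressive MCI (converts to AD within three years) = 1.
LABEL_CODES = {"S-MCI": 0, "P-MCI": 1, "0": 0, "1": 1, 0: 0, 1: 1}


class SchemaError(ValueError):
    """Raised when matrices/metadata disagree on samples or features."""


@dataclass
class ModalityMatrix:
    """One samples x features block for a single data modality.

    Parameters
    ----------
    values
        Numeric array of shape (n_samples, n_features).  Genotype matrices
        use additive minor-allele coding 0/1/2; masked entries may hold any
        placeholder value (by convention ``np.nan``).
    feature_ids
        Unique feature names, one per column.
    tag
        Modality tag, one of ``{"snp", "expr", "roi"}``.
    mask
        Boolean array, same shape as ``values``; True marks a missing entry.
    """

    values: np.ndarray
    feature_ids: list[str]
    tag: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError(f"values must be 2-D, got shape {self.values.shape}")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != self.values.shape[1]:
            raise SchemaError(
                f"{len(self.feature_ids)} feature ids for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise SchemaError("duplicate feature ids")
        if self.tag not in MODALITY_TAGS:
            raise SchemaError(f"unknown modality tag {self.tag!r}")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise SchemaError("mask shape differs from values shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "ModalityMatrix":
        idx = np.asarray(idx)
        return ModalityMatrix(
            self.values[idx], list(self.feature_ids), self.tag, self.mask[idx]
        )

    def select_features(self, ids: Sequence[str]) -> "ModalityMatrix":
        """Column-subset by feature id, preserving the requested order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise SchemaError(f"unknown feature ids: {missing[:10]}")
        cols = np.asarray([pos[f] for f in ids], dtype=int)
        return ModalityMatrix(
            self.values[:, cols], list(ids), self.tag, self.mask[:, cols]
        )

    def dense(self) -> np.ndarray:
        """Values with masked entries as NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out


@dataclass
class Cohort:
    """Aligned multi-modal cohort.

    All modality blocks share ``sample_ids`` in the same order.  ``labels``
    is the binary conversion outcome (S-MCI=0 / P-MCI=1), ``icv`` the
    intracranial volume in mL, and ``subtype_truth`` an optional known
    subtype per sample (1-based; synthetic cohorts carry it as ground truth).
    """

    modalities: dict[str, ModalityMatrix]
    sample_ids: list[str]
    labels: np.ndarray
    icv: np.ndarray
    subtype_truth: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise SchemaError("duplicate sample ids")
        for tag, block in self.modalities.items():
            if block.tag != tag:
                raise SchemaError(f"block tagged {block.tag!r} stored under {tag!r}")
            if block.n_samples != n:
                raise SchemaError(
                    f"modality {tag!r} has {block.n_samples} samples, expected {n}"
                )
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise SchemaError("labels shape mismatch")
        if not np.isin(self.labels, [0, 1]).all():
            raise SchemaError("conversion labels must be binary 0/1")
        self.icv = np.asarray(self.icv, dtype=float)
        if self.icv.shape != (n,):
            raise SchemaError("icv shape mismatch")
        if not (self.icv > 0).all():
            raise SchemaError("ICV must be strictly positive")
        if self.subtype_truth is not None:
            self.subtype_truth = np.asarray(self.subtype_truth, dtype=int)
            if self.subtype_truth.shape != (n,):
                raise SchemaError("subtype_truth shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take(self, idx: Sequence[int] | np.ndarray) -> "Cohort":
        """Row-subset the whole cohort (all blocks + metadata)."""
        idx = np.asarray(idx)
        return Cohort(
            modalities={t: b.take_samples(idx) for t, b in self.modalities.items()},
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            icv=self.icv[idx],
            subtype_truth=None
            if self.subtype_truth is None
            else self.subtype_truth[idx],
            truth=self.truth,
        )

    def replace_modality(self, block: ModalityMatrix) -> "Cohort":
        mods = dict(self.modalities)
        mods[block.tag] = block
        return replace(self, modalities=mods)
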