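"""Tab-separated readers/writers and model serialization.

Feature matrices travel as TSV with the sample id in the first column and
feature ids in the header; genotype matrices use ``NA`` for missing calls.
Metadata tables carry sample_id, label (S-MCI/P-MCI or 0/1), icv, and an
optional subtype column.  Trained models are serialized with joblib inside
a versioned wrapper so stale archives fail loudly instead of mispredicting.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .datatypes import LABEL_CODES, Cohort, ModalityMatrix, SchemaError

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    pass


def read_modality(path: str | Path, tag: str) -> ModalityMatrix:
    """Read one samples x features TSV block (NA = missing)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    def _unparseable(v) -> bool:
        try:
            float(v)
            return False
        except (TypeError, ValueError):
            return True

    if df.size:
        bad = df.map(_unparseable).to_numpy()
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ParseError(f"{path}: non-numeric cell at line {r + 2}, "
                             f"column {df.columns[c]!r}")
    values = df.astype(float).to_numpy()
    block = ModalityMatrix(values, list(df.columns), tag)
    block.sample_ids = [str(s) for s in df.index]  # carried for alignment
    return block


def write_modality(x: ModalityMatrix, sample_ids: list[str],
                   path: str | Path) -> None:
    dense = x.dense()
    df = pd.DataFrame(dense, index=sample_ids, columns=x.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, label, icv[, subtype])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    try:
        df["label"] = df["label"].map(
            lambda v: LABEL_CODES[v if isinstance(v, str) else int(v)])
    except KeyError as exc:
        raise ParseError(
            f"{path}: unknown label {exc.args[0]!r}; "
            "expected S-MCI/P-MCI or 0/1"
        ) from exc
    return df


def load_cohort(directory: str | Path,
                tags: tuple[str, ...] = ("snp", "expr", "roi")) -> Cohort:
    """Assemble a cohort from ``<tag>.tsv`` blocks plus ``metadata.tsv``.

    All blocks must cover exactly the metadata's sample set; a mismatch
    raises with the symmetric difference.
    """
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    ids = list(meta["sample_id"])
    blocks = {}
    for tag in tags:
        block = read_modality(directory / f"{tag}.tsv", tag)
        got = set(block.sample_ids)
        want = set(ids)
        if got != want:
            diff = sorted(got.symmetric_difference(want))
            raise SchemaError(
                f"modality {tag!r} and metadata disagree on samples: {diff[:10]}"
            )
        order = [block.sample_ids.index(s) for s in ids]
        blocks[tag] = block.take_samples(np.asarray(order))
    if "roi" in blocks:
        if "icv" not in meta.columns or meta["icv"].isna().any():
            raise SchemaError("ICV required (and complete) when ROI data present")
        icv = meta["icv"].to_numpy(dtype=float)
    else:
        icv = np.ones(len(ids))
    subtype = (meta["subtype"].to_numpy(dtype=int)
               if "subtype" in meta.columns else None)
    return Cohort(blocks, ids, meta["label"].to_numpy(dtype=int), icv, subtype)


def save_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tag, block in cohort.modalities.items():
        write_modality(block, cohort.sample_ids, directory / f"{tag}.tsv")
    meta = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "label": cohort.labels,
        "icv": cohort.icv,
    })
    if cohort.subtype_truth is not None:
        meta["subtype"] = cohort.subtype_truth
    meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
    if cohort.truth:
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cohort.truth.items()
        }
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)


def save_model(model, path: str | Path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path):
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive version {version} != supported "
            f"{MODEL_FORMAT_VERSION}; retrain or upgrade the archive"
        )
    return payload["model"]
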