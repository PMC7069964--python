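"""Reading, validation, alignment and model-ready encoding of cohort files.

File dialects: expression as TSV (genes in rows, header row of sample
IDs), clinical and survival as CSV, interactome as 2- or 3-column TSV
(geneA, geneB[, weight]), splits as CSV (sample_id, split). UTF-8, '.'
decimal throughout.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Interactome
from .synthetic import (CohortBundle, GroundTruth, STAGE_LEVELS)

__all__ = [
    "DataError", "FeatureBlock", "read_expression", "read_clinical",
    "read_survival", "read_splits", "read_interactome", "load_cohort",
    "align_cohort", "write_cohort", "encode_clinical", "encode_expression",
]

log = logging.getLogger(__name__)

SEX_LEVELS = ("male", "female")
SPLIT_LEVELS = ("train", "validation", "test")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene symbols: {dups}")
    if df.columns.has_duplicates:
        raise DataError("duplicate sample IDs in expression matrix")
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric expression values: {exc}") from exc
    if not np.all(np.isfinite(vals)):
        raise DataError("expression matrix contains missing/non-finite values")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("sample_id")
    return df[["age", "sex", "stage"]]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with missing fields (logged); error on invalid categories."""
    complete = df.dropna(subset=["age", "sex", "stage"])
    dropped = len(df) - len(complete)
    if dropped:
        log.info("dropped %d samples with incomplete clinical data", dropped)
    for sid, row in complete.iterrows():
        if row["sex"] not in SEX_LEVELS:
            raise DataError(f"sample {sid!r}: sex {row['sex']!r} not in "
                            f"{SEX_LEVELS}")
        if row["stage"] not in STAGE_LEVELS:
            raise DataError(f"sample {sid!r}: stage {row['stage']!r} not in "
                            f"{STAGE_LEVELS}")
        if not 0.0 <= float(row["age"]) <= 120.0:
            raise DataError(f"sample {sid!r}: age {row['age']} outside [0, 120]")
    return complete


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("sample_id")
    return df[["time_months", "event"]]


def validate_survival(df: pd.DataFrame) -> None:
    if (df["time_months"] < 0).any():
        raise DataError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise DataError("event flag must be 0 or 1")


def read_splits(path) -> pd.Series:
    df = pd.read_csv(path).set_index("sample_id")
    s = df["split"]
    bad = sorted(set(s) - set(SPLIT_LEVELS))
    if bad:
        raise DataError(f"unknown split labels: {bad}")
    return s


def read_interactome(path) -> Interactome:
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] not in (2, 3):
        raise DataError("interactome TSV must have 2 or 3 columns")
    weights = df[2].tolist() if df.shape[1] == 3 else None
    return Interactome.from_pairs(df[[0, 1]].itertuples(index=False),
                                  weights)


def align_cohort(expression: pd.DataFrame, clinical: pd.DataFrame,
                 survival: pd.DataFrame, splits: pd.Series | None = None,
                 truth: GroundTruth | None = None) -> CohortBundle:
    """Intersect sample IDs across components and return an aligned bundle.

    Samples missing any clinical field are dropped first (logged count).
    An empty intersection is a hard error.
    """
    validate_expression(expression)
    clinical = validate_clinical(clinical)
    validate_survival(survival)
    ids = [s for s in expression.columns
           if s in set(clinical.index) and s in set(survival.index)
           and (splits is None or s in set(splits.index))]
    if not ids:
        raise DataError("no samples shared across cohort components")
    return CohortBundle(
        expression.loc[:, ids],
        clinical.loc[ids],
        survival.loc[ids],
        splits.loc[ids] if splits is not None else None,
        truth,
    )


def load_cohort(expr_path, clinical_path, survival_path,
                splits_path=None) -> CohortBundle:
    """Read and align a cohort from disk."""
    splits = read_splits(splits_path) if splits_path is not None else None
    return align_cohort(read_expression(expr_path),
                        read_clinical(clinical_path),
                        read_survival(survival_path), splits)


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, Path]:
    """Write a bundle as expression.tsv, clinical.csv, survival.csv,
    splits.csv and (if present) truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expression.tsv",
             "clinical": out / "clinical.csv",
             "survival": out / "survival.csv"}
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.clinical.to_csv(paths["clinical"])
    bundle.survival.to_csv(paths["survival"])
    if bundle.splits is not None:
        paths["splits"] = out / "splits.csv"
        bundle.splits.to_frame().to_csv(paths["splits"])
    if bundle.truth is not None:
        t = bundle.truth
        paths["truth"] = out / "truth.json"
        payload = {
            "planted_prognostic_genes": list(t.planted_prognostic_genes),
            "planted_edge_differences": sorted(map(list, t.planted_edge_differences)),
            "true_log_hr": t.true_log_hr,
            "true_biomarker_thresholds": t.true_biomarker_thresholds,
            "subtype": ({k: int(v) for k, v in t.subtype.items()}
                        if t.subtype is not None else None),
        }
        paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


@dataclass
class FeatureBlock:
    """A sample x feature matrix with training-split scaling statistics.

    Standardized columns use center/scale learned on the training split
    only (population SD, divisor n); indicator columns keep center 0 and
    scale 1. Constant training columns are flagged and given scale 1.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray

    def matrix_for(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [pos[s] for s in ids]
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} not in feature block")
        return self.values[rows]


def _standardize(raw: pd.DataFrame, train_ids: Sequence[str],
                 scaled_cols: Sequence[str]) -> FeatureBlock:
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("training split is empty")
    missing = [s for s in train_ids if s not in raw.index]
    if missing:
        raise DataError(f"training samples missing from table: {missing[:5]}")
    center = np.zeros(raw.shape[1])
    scale = np.ones(raw.shape[1])
    const = np.zeros(raw.shape[1], dtype=bool)
    tr = raw.loc[train_ids]
    for j, col in enumerate(raw.columns):
        sd = float(tr[col].std(ddof=0))
        if col in scaled_cols:
            center[j] = float(tr[col].mean())
            if sd == 0.0:
                const[j] = True
            else:
                scale[j] = sd
        elif sd == 0.0:
            const[j] = True
    values = (raw.to_numpy(dtype=float) - center) / scale
    return FeatureBlock(tuple(raw.index), tuple(raw.columns), values,
                        center, scale, const)


def encode_clinical(clinical: pd.DataFrame,
                    train_ids: Sequence[str]) -> FeatureBlock:
    """Encode age (z-scored on the training split), sex (0/1, male = 1)
    and stage (one-hot over the five categories): 7 columns."""
    clinical = validate_clinical(clinical)
    raw = pd.DataFrame(index=clinical.index)
    raw["age"] = clinical["age"].astype(float)
    raw["sex_male"] = (clinical["sex"] == "male").astype(float)
    for s in STAGE_LEVELS:
        raw[f"stage_{s}"] = (clinical["stage"] == s).astype(float)
    return _standardize(raw, train_ids, scaled_cols=("age",))


def encode_expression(expression: pd.DataFrame, panel_genes: Sequence[str],
                      train_ids: Sequence[str]) -> FeatureBlock:
    """One z-scored column per panel gene (training-split statistics)."""
    missing = [g for g in panel_genes if g not in expression.index]
    if missing:
        raise DataError(f"panel genes missing from expression: {missing}")
    raw = expression.loc[list(panel_genes)].T.astype(float)
    return _standardize(raw, train_ids, scaled_cols=tuple(panel_genes))
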