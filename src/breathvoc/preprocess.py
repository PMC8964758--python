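"""Peak-table preprocessing: blank subtraction, alignment, prevalence
filtering and log2 normalization.

The analysis-ready object is a :class:`VOCTable`: the raw samples × compounds
peak-area matrix (AU), its ambient-blank-corrected view, the log2(1+AU)
view, and per-compound prevalence (fraction of samples with corrected
signal). Small sklearn transformers (:class:`BlankSubtractor`,
:class:`PrevalenceFilter`, :class:`Log2Transformer`) expose the same steps
for pipeline composition; the module-level functions are the primary API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import substream

__all__ = [
    "CompoundID",
    "VOCTable",
    "accept_identification",
    "subtract_blank",
    "prevalence_filter",
    "log2_normalize",
    "align_days",
    "split_train_test",
    "read_voc_table",
    "read_meta",
    "read_blanks",
    "BlankSubtractor",
    "PrevalenceFilter",
    "Log2Transformer",
]


@dataclass(frozen=True)
class CompoundID:
    """A putative GC–MS compound identification.

    ``score`` is the spectral matching score as a fraction in [0, 1];
    ``ri_diff`` is |RI_calculated − RI_database| in retention-index units.
    MSI level 2 (putatively annotated) is the typical annotation level for
    library-matched breath VOCs.
    """

    name: str
    score: float
    ri_diff: float
    msi_level: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("matching score must lie in [0, 1]")
        if self.ri_diff < 0:
            raise ValueError("RI difference must be nonnegative")


def accept_identification(cid: CompoundID, score_min: float = 0.80, ri_max: float = 20.0) -> bool:
    """Identification acceptance rule: score ≥ ``score_min`` and RI
    difference ≤ ``ri_max`` (both boundaries inclusive)."""
    return cid.score >= score_min and cid.ri_diff <= ri_max


def subtract_blank(
    raw: pd.DataFrame, blanks: pd.DataFrame, sample_days: pd.Series | Sequence[int]
) -> pd.DataFrame:
    """Subtract each sample's same-day ambient blank, floored at zero.

    An ambient reading exceeding the breath signal means no endogenous
    signal, so negative corrected values are clamped to 0 AU.
    """
    sample_days = pd.Series(np.asarray(sample_days), index=raw.index)
    missing_days = sorted(set(sample_days) - set(blanks.index))
    if missing_days:
        raise KeyError(f"no ambient blank for day(s): {missing_days}")
    unmatched = sorted(set(raw.columns) ^ set(blanks.columns))
    if unmatched:
        raise ValueError(f"compound names differ between table and blanks: {unmatched}")
    blank_rows = blanks.loc[sample_days, raw.columns].to_numpy()
    corrected = np.maximum(raw.to_numpy(dtype=float) - blank_rows, 0.0)
    return pd.DataFrame(corrected, index=raw.index, columns=raw.columns)


def log2_normalize(corrected: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """log2(1 + AU): strictly monotone, maps absent (0 AU) to exactly 0."""
    values = np.asarray(corrected, dtype=float)
    if np.any(values < 0):
        raise ValueError("log2 normalization requires nonnegative corrected AU")
    out = np.log2(1.0 + values)
    if isinstance(corrected, pd.DataFrame):
        return pd.DataFrame(out, index=corrected.index, columns=corrected.columns)
    return out


@dataclass
class VOCTable:
    """Samples × compounds peak table with corrected and log2 views."""

    raw: pd.DataFrame
    corrected: pd.DataFrame
    log2: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.log2 is None:
            self.log2 = log2_normalize(self.corrected)
        if not (self.raw.shape == self.corrected.shape == self.log2.shape):
            raise ValueError("raw/corrected/log2 matrices must share dimensions")

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        blanks: pd.DataFrame | None = None,
        sample_days: pd.Series | Sequence[int] | None = None,
    ) -> "VOCTable":
        """Build from raw AU, blank-correcting when blanks are supplied."""
        if blanks is not None:
            if sample_days is None:
                raise ValueError("sample_days required for blank subtraction")
            corrected = subtract_blank(raw, blanks, sample_days)
        else:
            corrected = raw.clip(lower=0.0)
        return cls(raw=raw, corrected=corrected)

    @property
    def sample_ids(self) -> pd.Index:
        return self.raw.index

    @property
    def compounds(self) -> pd.Index:
        return self.raw.columns

    @property
    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each compound has corrected AU > 0."""
        if len(self.corrected) == 0:
            return pd.Series(0.0, index=self.compounds)
        return (self.corrected > 0).mean(axis=0)

    def select_samples(self, ids: Sequence[str]) -> "VOCTable":
        return VOCTable(self.raw.loc[ids], self.corrected.loc[ids], self.log2.loc[ids])

    def write(self, directory: str | Path, min_prevalence: float | None = None) -> None:
        """Write the processed log2 matrix plus a JSON processing sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.log2.to_csv(directory / "processed_log2.csv", float_format="%.17g")
        sidecar = {
            "blank_subtracted": not self.raw.equals(self.corrected),
            "prevalence_filter": min_prevalence,
            "transform": "log2(1+AU)",
            "n_samples": int(len(self.raw)),
            "n_compounds": int(self.raw.shape[1]),
        }
        (directory / "processing.json").write_text(json.dumps(sidecar, indent=2))


def prevalence_filter(table: VOCTable, min_frac: float = 0.05) -> VOCTable:
    """Keep compounds detected in strictly more than ``min_frac`` of samples.

    Survivor ordering is preserved; the result may have zero compounds.
    """
    keep = table.prevalence > min_frac
    cols = table.compounds[keep.to_numpy()]
    return VOCTable(table.raw[cols], table.corrected[cols], table.log2[cols])


def align_days(per_day_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-day peak tables over the union of compound names.

    Compounds are keyed on their (library-matched) names; a compound absent
    on a day is recorded as 0 AU for that day's samples. Compound order is
    first appearance across the day tables.
    """
    compounds: list[str] = []
    seen_samples: set[str] = set()
    for tab in per_day_tables:
        dup = set(tab.index) & seen_samples
        if dup:
            raise ValueError(f"duplicate sample id(s) across days: {sorted(dup)}")
        seen_samples.update(tab.index)
        compounds.extend(c for c in tab.columns if c not in compounds)
    if not per_day_tables:
        return pd.DataFrame(columns=pd.Index([], name="compound"))
    merged = pd.concat(
        [tab.reindex(columns=compounds, fill_value=0.0) for tab in per_day_tables], axis=0
    )
    return merged.fillna(0.0)


def split_train_test(
    table: VOCTable,
    meta: pd.DataFrame,
    train_ids: Sequence[str] | None = None,
    train_frac: float | None = None,
    seed: int | None = None,
    stratify_by: str | None = "group",
) -> tuple[tuple[VOCTable, pd.DataFrame], tuple[VOCTable, pd.DataFrame], dict]:
    """Split into independent training and test sets.

    Either pass ``train_ids`` explicitly (for published-style splits) or a
    ``train_frac`` with a ``seed``; the fractional split is stratified by
    ``stratify_by`` (rounding per stratum by largest remainder). Returns
    ((train table, train meta), (test table, test meta), composition log).
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    ids = list(table.sample_ids)
    if train_ids is not None:
        train_ids = list(train_ids)
        unknown = set(train_ids) - set(ids)
        if unknown:
            raise ValueError(f"train ids not in table: {sorted(unknown)}")
        if len(set(train_ids)) != len(train_ids):
            raise ValueError("overlapping/duplicate train ids")
        test_ids = [i for i in ids if i not in set(train_ids)]
    else:
        if train_frac is None:
            raise ValueError("pass train_ids or train_frac")
        rng = substream(0 if seed is None else seed, "split")
        if stratify_by and stratify_by in meta.columns:
            strata = meta.loc[ids, stratify_by]
            sizes = {g: len(sub) for g, sub in strata.groupby(strata)}
            raw = {g: n * train_frac for g, n in sizes.items()}
            take = {g: int(np.floor(v)) for g, v in raw.items()}
            short = int(round(train_frac * len(ids))) - sum(take.values())
            for g in sorted(raw, key=lambda g: raw[g] - take[g], reverse=True)[: max(short, 0)]:
                take[g] += 1
            train_ids = []
            for g in sorted(sizes):
                members = [i for i in ids if strata.loc[i] == g]
                picked = rng.choice(len(members), size=take[g], replace=False)
                train_ids.extend(members[p] for p in sorted(picked))
        else:
            n_train = int(round(train_frac * len(ids)))
            picked = rng.choice(len(ids), size=n_train, replace=False)
            train_ids = [ids[p] for p in sorted(picked)]
        test_ids = [i for i in ids if i not in set(train_ids)]

    train_tab, test_tab = table.select_samples(train_ids), table.select_samples(test_ids)
    train_meta, test_meta = meta.loc[train_ids], meta.loc[test_ids]
    composition = {
        "train": {"n": len(train_ids), **train_meta.get("group", pd.Series(dtype=str)).value_counts().to_dict()},
        "test": {"n": len(test_ids), **test_meta.get("group", pd.Series(dtype=str)).value_counts().to_dict()},
    }
    return (train_tab, train_meta), (test_tab, test_meta), composition


# -- CSV readers (cohort dialects) -----------------------------------------

def read_voc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(
        path,
        dtype={"sample_id": str, "group": str, "bclc_stage": str, "pair_id": str,
               "timepoint": str, "responder": str, "modality": str},
        keep_default_na=False,
    )
    meta["day"] = meta["day"].astype(int)
    return meta


def read_blanks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="day")


# -- sklearn transformer facades -------------------------------------------

class BlankSubtractor(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`subtract_blank`."""

    def __init__(self, blanks: pd.DataFrame = None, sample_days=None):
        self.blanks = blanks
        self.sample_days = sample_days

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return subtract_blank(X, self.blanks, self.sample_days)


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Keep features (compounds) with nonzero fraction strictly above ``min_frac``."""

    def __init__(self, min_frac: float = 0.05):
        self.min_frac = min_frac

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float)
        self.support_ = (values > 0).mean(axis=0) > self.min_frac
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Stateless log2(1+AU) transform."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return log2_normalize(X)
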