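"""Dataset loading for tabular binary-classification data.

Two on-disk formats are supported: plain CSV with a header row, and the
ARFF-like ``.dat`` format used by the KEEL imbalanced-classification
benchmark suite (``@attribute``/``@data`` blocks).  Loading always ends
with labels coded 0/1 with the designated positive class mapped to 1 — by
convention the minority class, since every metric here treats class 1 as
the class of interest.  Every label recoding and row drop is logged, never
silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "read_csv_dataset", "read_keel_dat", "write_csv_dataset", "KeelParseError"]


class KeelParseError(ValueError):
    """Malformed KEEL/ARFF-style file; message carries the line number."""


@dataclass
class Dataset:
    """In-memory tabular dataset with 0/1 labels (minority class coded 1)."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.size:
            raise ValueError("feature rows and labels disagree in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be coded 0/1")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(self.features.shape[1])]

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    @property
    def imbalance_ratio(self) -> float:
        """Majority-class size over minority-class size."""
        n1 = int(self.labels.sum())
        n0 = self.n - n1
        if n1 == 0 or n0 == 0:
            raise ValueError("imbalance ratio undefined for single-class data")
        return max(n0, n1) / min(n0, n1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame["label"] = self.labels
        return frame


def _finalize(
    frame: pd.DataFrame, label_column: str, positive_label, source: str, auto_positive: bool
) -> Dataset:
    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        logger.warning("%s: dropped %d rows with missing values", source, dropped)
    if len(frame) == 0:
        raise ValueError(f"{source}: no data rows after loading")

    raw = frame[label_column]
    values = raw.value_counts()
    if len(values) < 2:
        raise ValueError(f"{source}: label column has a single class ({values.index.tolist()})")
    if len(values) > 2:
        raise ValueError(f"{source}: label column has {len(values)} distinct values; expected 2")

    if auto_positive and positive_label is None:
        positive_label = values.idxmin()  # rarer label becomes class 1
        logger.warning(
            "%s: auto-detected positive (minority) label %r (%d of %d rows)",
            source,
            positive_label,
            int(values.min()),
            len(frame),
        )
    if positive_label is None:
        raise ValueError("positive_label must be given (or enable auto_positive)")
    if positive_label not in set(values.index):
        raise ValueError(f"{source}: positive label {positive_label!r} not present in the data")

    labels = (raw == positive_label).astype(int).to_numpy()
    feats = frame.drop(columns=[label_column])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: non-numeric feature column ({exc})") from exc

    ds = Dataset(
        features=X,
        labels=labels,
        feature_names=[str(c) for c in feats.columns],
        source=source,
    )
    logger.info(
        "%s: %d rows, %d features, positive=%r -> 1 (%d rows), IR=%.2f, pi=%.2f%%",
        source,
        ds.n,
        X.shape[1],
        positive_label,
        int(labels.sum()),
        ds.imbalance_ratio,
        100 * ds.prevalence,
    )
    return ds


def read_csv_dataset(
    path, label_column: str, positive_label=None, auto_positive: bool = False
) -> Dataset:
    """Load a CSV dataset, recoding ``positive_label`` in ``label_column`` to 1.

    Rows with missing values are dropped (and counted in the log).  With
    ``auto_positive=True`` and no explicit positive label, the rarer label
    is mapped to 1 with a logged warning.  The imbalance ratio and
    prevalence are logged on success.
    """
    frame = pd.read_csv(path)
    if len(frame) == 0:
        raise ValueError(f"{path}: file has a header but no data rows")
    if label_column not in frame.columns:
        raise ValueError(f"{path}: label column {label_column!r} not found in {list(frame.columns)}")
    return _finalize(frame, label_column, positive_label, str(path), auto_positive)


def read_keel_dat(
    path, class_attribute: str | None = None, positive_label=None, auto_positive: bool = True
) -> Dataset:
    """Load a KEEL-style ``.dat`` file (ARFF-like @attribute/@data blocks).

    The last declared attribute is taken as the class unless
    ``class_attribute`` names another.  Class values are stripped of
    whitespace; when they are the conventional ``negative``/``positive``
    pair, ``positive`` maps to 1; otherwise the minority value maps to 1
    (``auto_positive``, on by default for this format) unless
    ``positive_label`` is given.  Numeric (real/integer) attributes only.
    """
    names: list[str] = []
    data_rows: list[list[str]] = []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            lowered = text.lower()
            if in_data:
                data_rows.append([tok.strip() for tok in text.split(",")])
                continue
            if lowered.startswith("@relation") or lowered.startswith("@inputs") or lowered.startswith("@outputs"):
                continue
            if lowered.startswith("@attribute"):
                parts = text.split(None, 2)
                if len(parts) < 3:
                    raise KeelParseError(f"{path}:{lineno}: malformed @attribute line: {text!r}")
                name, spec = parts[1], parts[2].strip()
                # nominal attributes look like {a, b}; numeric are real/integer
                if not (
                    spec.startswith("{")
                    or spec.lower().startswith("real")
                    or spec.lower().startswith("integer")
                    or spec.lower().startswith("numeric")
                ):
                    raise KeelParseError(
                        f"{path}:{lineno}: unknown attribute type {spec!r} for {name!r}"
                    )
                names.append(name)
                continue
            if lowered.startswith("@data"):
                in_data = True
                continue
            raise KeelParseError(f"{path}:{lineno}: unexpected line outside @data: {text!r}")
    if not names:
        raise KeelParseError(f"{path}: no @attribute declarations found")
    if not data_rows:
        raise KeelParseError(f"{path}: no rows after @data")
    widths = {len(r) for r in data_rows}
    if widths != {len(names)}:
        raise KeelParseError(
            f"{path}: data rows have {sorted(widths)} fields but {len(names)} attributes declared"
        )
    frame = pd.DataFrame(data_rows, columns=names)
    label_column = class_attribute if class_attribute is not None else names[-1]
    if label_column not in frame.columns:
        raise ValueError(f"{path}: class attribute {label_column!r} not declared")
    for col in frame.columns:
        if col != label_column:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")

    class_values = {str(v).strip().lower() for v in frame[label_column].unique()}
    if positive_label is None and class_values == {"negative", "positive"}:
        mask = frame[label_column].str.strip().str.lower() == "positive"
        frame[label_column] = np.where(mask, "positive", "negative")
        positive_label = "positive"
        logger.info("%s: class values negative/positive -> positive coded 1", path)
    return _finalize(frame, label_column, positive_label, str(path), auto_positive)


def write_csv_dataset(dataset: Dataset, path) -> None:
    """Write features plus a ``label`` column as plain CSV (round-trippable
    with ``read_csv_dataset(path, 'label', positive_label=1)``)."""
    dataset.to_frame().to_csv(path, index=False)
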